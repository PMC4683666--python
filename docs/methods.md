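# Methods

## Scope and model

`heteromap` dissects heterosis — the superiority of an F1 hybrid over the
mean of its two inbred parents — by association mapping in a partial North
Carolina II (NCII) mating design. A set of `a` maternal lines is crossed
with `b` paternal lines; in the partial design each maternal line
contributes only `t` crosses (plus optional padding crosses), matching
hybrid-breeding practice where a sterile line is mated to a handful of
restorer lines.

Four dependent variables are mapped with the same genetic model:

* **trait** — the F1 phenotype itself;
* **GCA** — a parent's mean F1 performance over its crosses, as a deviation
  from the grand mean of the F1 values (mapped onto the parents'
  genotypes);
* **SCA** — the cross-specific residual `F_ij − μ̂ − g_i − g_j` (mapped onto
  the F1 genotypes);
* **MPH** — mid-parent heterosis, `100·(F1 − MP)/MP` with
  `MP = (P_i + P_j)/2` (mapped onto the F1 genotypes).

The genetic model treats every marker as a putative QTL and fits all main
and two-locus epistatic effects jointly:

    y_i = μ + Σ_k a_k w_ik + Σ_k d_k v_ik
            + Σ_{k<s} [ (aa)_{ks} w_ik w_is + (ad)_{ks} w_ik v_is
                      + (da)_{ks} v_ik w_is + (dd)_{ks} v_ik v_is ] + e_i

with Cockerham-style dummies `w ∈ {1, 0, −1}` and `v ∈ {0, 1}` for
{QQ, Qq, qq}. Under F1 genotype frequencies 1/4 : 1/2 : 1/4 the two
predictors are uncorrelated. With two environments, an environment
covariate (±1) joins the unpenalized block and every genetic effect gains
one ×E interaction column; population-structure covariates (a Q matrix) are
likewise unpenalized. For `m` markers and one environment the model has
`2m + 4·m(m−1)/2` penalized effects — 84,050 at m = 205 — so a sparse
solver is essential.

## The EBLASSO solver

Effects carry a three-level hierarchy: `β_j ~ N(0, σ²_j)`,
`σ²_j ~ Exponential(λ)`, `λ ~ Gamma(a, b)`. Writing
`s_j = x_j' C_{-j}^{-1} x_j` and `q_j = x_j' C_{-j}^{-1} ỹ` (the covariance
`C_{-j}` excludes effect j; ỹ is the response residualized on the
unpenalized block), the λ-penalized marginal likelihood is maximized in
closed form one effect at a time:

* retain effect j iff `q_j² > s_j + 2λ`, with
  `σ²_j = (u − 1)/s_j`, `u = (−s_j + √(s_j² + 8λ q_j²)) / (4λ)`;
* the λ → 0 limit, `σ²_j = (q_j² − s_j)/s_j²`, is the fast
  relevance-vector-machine update, which serves as an independent oracle in
  the test suite.

The inner iteration repeatedly applies the single add / re-estimate /
delete action with the largest marginal-likelihood gain; each action costs
O(M² + p) via Schur-complement updates of the posterior covariance and
Sherman–Morrison updates of every candidate's (S, Q), with exact refreshes
at each sweep start to bound numerical drift. The outer iteration
re-estimates

* the noise variance `σ₀² = ‖ỹ − Xβ̂‖² / (n − Σ_j γ_j)`,
  `γ_j = 1 − Σ_jj/σ²_j`, and
* the penalty `λ = max(0, (p − 1 + a) / (Σ_j σ²_j + b))`, where `p` counts
  **all** candidate effects: the exponential prior applies to every
  candidate's σ²_j, with excluded effects sitting at the boundary σ²_j = 0.

Counting only retained effects makes λ grow like M/Σσ², which is far too
slow to control thousands of candidates at n ≈ 240: the noise-variance
feedback then saturates the model (σ₀² → 0 with ~n columns retained, even
on pure noise). With the all-candidates count the solver is sparse and
stable at p ≈ 10⁵, n ≈ 200.

Numerical design choices:

* **Initialization.** σ₀² starts at var(ỹ) and λ at its null-state
  posterior mode `(p − 1 + a)/b`. As strong effects enter, σ₀² anneals
  downward and progressively weaker effects become visible at a nearly
  constant λ. Starting σ₀² low (the common 0.1·var(y) heuristic)
  mass-recruits noise columns and triggers the saturation spiral;
  starting λ far above its equilibrium traps the fit in an all-null state
  because weak effects are invisible at high σ₀².
* **Basis cap.** At most `0.8·n` effects may be active (configurable),
  which forbids the interpolation regime outright.
* **Convergence.** Inner: no action with likelihood gain above 1e−8.
  Outer: relative changes of σ₀² and λ below 1e−4 (default), followed by a
  final polishing sweep so the retention criterion holds exactly at the
  reported hyperparameters. The penalized marginal likelihood is recorded
  after every action; it is non-decreasing *within* each outer round's
  sweep. Monotonicity across outer rounds is not asserted because the σ₀²
  and λ updates change the objective being maximized.
* **Default hyperprior (a, b) = (0.1, 30).** b sets the null-state
  λ ≈ p/b and hence the recruitment threshold on the per-effect χ² scale,
  `1 + 2λσ₀²/‖x_j‖²`. At the simulation scale (n = 240, p ≈ 7,000 effects
  with column variances near 1/4) b = 30 puts that threshold around 9–17,
  keeping the expected count of falsely recruited effects of order ten
  while admitting effects with heritability ≥ 0.05. `select_hyper`
  implements k-fold cross-validation over an (a, b) grid (the procedure
  used for real data); note that CV optimizes *prediction* and tends to
  prefer denser fits than are appropriate for effect testing, so the
  simulation studies use the fixed default.

Retained effects are reported with `t_j = β̂_j / √Σ_jj` and two-sided P
from a t distribution with `n − (retained) − rank(U)` degrees of freedom
(the reference does not fix the df; this is the package's choice);
significance is declared at P < 0.05, unadjusted.

## Synthetic data

Inbred parents are doubled haplotypes simulated by a first-order two-state
Markov chain along each chromosome: stationary distribution (p, 1−p) and
second eigenvalue `1 − 2c` over each inter-marker interval, with
`c = (1 − exp(−2Δ/100))/2` (Haldane) — at p = 0.5 this is exactly "keep the
allele with probability 1−c, switch with probability c", and adjacent-marker
genotype correlation is (1 − 2c). F1 genotypes are deduced from the two
homozygous parents.

Each QTL's effect size is calibrated from its heritability: with
`σ²_P = σ²_e / (1 − Σ_k h²_k)`, the effect is the positive value whose
squared product with its design-column variance equals `h²_k σ²_P`. Column
variances use the unlinked closed forms (1/2 for w; 1/4 for v, w·w and w·v;
3/16 for v·v) or, when a simulated F1 population is supplied, the empirical
column variance — which accounts for linkage between paired loci. The
dominance-degree models attach `d = r·a` to each additive locus and
calibrate the combined predictor `w + r·v`.

Defaults μ = 100 and σ²_e = 1 are package choices (the scale of MPH
depends on μ; detection powers do not). The preset experiments place six
QTL — two each at h² = 0.05, 0.10, 0.15 — on 60 markers spanning three
95 cM chromosomes (main effects at 25, 75, 135, 175, 220, 270 cM on the
concatenated axis; epistatic pairs at 20&60, 90&125, 155&205, 180&235,
40&275, 75&220 cM), with 120+120 parents and the t = 2 partial design
(240 F1 hybrids). The mating-proportion presets use one 100 cM chromosome
with 21 markers, six h² = 0.05 QTL (one per effect type), and eight designs
from t = 1 (F1 share 33%) to the complete 15×15 factorial (88%).

What the generator does *not* emulate: genotyping error and missingness
patterns of real SSR panels (missing calls are handled at the model layer
by imputation or case dropping, but never generated), multi-allelic
markers, residual heterozygosity in "inbred" parents, genotype-environment
interaction in the generative model, and population structure (the Q matrix
is consumed, never simulated). Passing simulation tests therefore shows
correctness of the machinery under idealized biallelic inbred-line data,
not robustness to those artifacts.

## Monte-Carlo studies

* **Power studies** simulate the full maternal×paternal factorial per
  replicate (so GCA, SCA and MPH are well defined), form the mapping
  population for the chosen dependent variable (parents for GCA, the
  partial-design F1s otherwise), fit the full epistatic model, and count a
  QTL as detected when its true effect term — correct type at the correct
  marker or marker pair — has P < 0.05. A relaxed tally (same effect type
  within 10 cM) is reported alongside, since attribution of a significant
  neighbouring marker is a matter of convention. Mean absolute deviation of
  the estimate from the generative effect is averaged over replicates where
  the term was retained; shrinkage makes these deviations systematically
  larger for weakly determined effects.
* **Heterosis ranking** simulates nine single-effect-type genetic models
  (additive; partial, complete and over-dominance; pure dominance; aa, ad,
  da, dd) on the same six-QTL layout and reports mean |MPH| over all
  hybrids of `replicates` 120×120 factorials. With additive coding the F1
  additive value equals the mid-parent value exactly, so the additive model
  measures pure noise (signed mean ≈ 0). Under the variance-equalizing
  calibration the mean MPH contributions are proportional to 0.5·Σd for
  dominance-family models and to E[v_k v_s]·Σ(dd) for the dd model, which
  fixes the ordering dominance > over-dominance > dd > complete >
  partial at these settings; dd and over-dominance are close, and their
  relative order is sensitive to how the dd pairs' column variance is
  standardized. Absolute percentages scale with 1/μ and are not
  comparable across studies that fix μ differently.
* **Mating-proportion study** maps parents and F1s together on the trait
  phenotype across the eight designs and reports power and absolute effect
  deviation per effect type against the F1 share of the population.

Study sizes used by the bundled acceptance script and tests: 100
replicates for the power contrast, 10 replicates of the full factorial for
the ranking. The packaged defaults (1,000 and 150) reproduce the same
quantities at publication scale.

## LD score regression

A continuous trait is binarized by the 35%/35% rule (top 35% → 1, bottom
35% → 0, middle 30% dropped; ties broken by stable sort). LD scores
`ℓ_j = Σ_k r²_jk` (self term included) come from the full genotype panel;
per-marker association χ² is the Armitage-trend form `n·r²` computed on the
retained individuals — the reference does not name its association
statistic, so the trend test is this package's choice. OLS of χ² on ℓ
yields the intercept, and `t = (intercept − 1)/SE` with m − 2 df tests for
structure-driven inflation. Monomorphic markers contribute nothing to LD
sums and are excluded from the regression (flagged). No r² bias adjustment
or windowing is applied; with few markers the intercept is noisy though
unbiased, so null calibration is asserted on the replicate mean.

## Known limitations

* The per-effect t-test is conditional on model selection; its P-values
  are not selection-adjusted (by design — the 0.05 threshold is applied to
  retained effects directly).
* Cross-validated hyperparameter choice optimizes prediction, not
  selection; users mapping real data should inspect the retained-effect
  count, not only CV error.
* Environments are limited to one or two (±1 coding); reciprocal effects,
  three-way epistasis and best-parent heterosis are out of scope.
* GCA/SCA estimates in unbalanced partial designs use observed-cross means
  rather than mixed-model BLUPs.
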