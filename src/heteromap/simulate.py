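"""Synthetic genotype/phenotype generation for NCII heterosis experiments.

Inbred parental lines are simulated as doubled haplotypes on a cM linkage
map: along each chromosome the allele follows a first-order two-state
Markov chain whose stationary distribution is ``(p, 1-p)`` and whose
second eigenvalue over a map distance of ``d`` cM is ``1 - 2c`` with
``c = (1 - exp(-2 d / 100)) / 2`` (Haldane map function).  At ``p = 0.5``
this is exactly "retain the allele with probability 1-c, switch with
probability c", and adjacent-marker genotype correlation equals
``(1 - 2c)``.

F1 genotypes are deduced from the two homozygous parents (QQ x qq -> Qq and
so on).  Phenotypes follow the joint additive-dominance-epistasis model:
each QTL's effect size is calibrated so that its design-column variance
times the squared effect equals the genetic variance implied by its
heritability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import MatingDesign, build_partial_ncii

GENO_STR = {0: "qq", 1: "Qq", 2: "QQ"}
STR_GENO = {"qq": 0, "Qq": 1, "QQ": 2, "0": 0, "1": 1, "2": 2}

#: Variance of each coded predictor in an F1 population with genotype
#: frequencies 1/4 QQ : 1/2 Qq : 1/4 qq and unlinked loci.
THEORETICAL_COLUMN_VAR = {
    "a": 0.5,        # w in {1, 0, -1}
    "d": 0.25,       # v in {0, 1}
    "aa": 0.25,      # w*w
    "ad": 0.25,      # w*v
    "da": 0.25,      # v*w
    "dd": 3.0 / 16,  # v*v
}

EFFECT_KINDS = ("a", "d", "aa", "ad", "da", "dd")


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genome map and genotype containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeMap:
    """Marker positions (cM) on one or more chromosome segments."""

    lengths: tuple[float, ...]
    positions: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        if len(self.lengths) != len(self.positions):
            raise SimulationError("lengths and positions must align")
        for pos in self.positions:
            d = np.diff(pos)
            if len(pos) and np.any(d <= 0):
                raise SimulationError("marker positions must be strictly increasing")

    @classmethod
    def equally_spaced(cls, n_chromosomes: int, length_cm: float, markers_per_chrom: int) -> "GenomeMap":
        pos = tuple(np.linspace(0.0, length_cm, markers_per_chrom))
        return cls(tuple([length_cm] * n_chromosomes), tuple([pos] * n_chromosomes))

    @property
    def marker_count(self) -> int:
        return sum(len(p) for p in self.positions)

    @property
    def offsets(self) -> tuple[float, ...]:
        """Start of each chromosome on the concatenated cM axis."""
        out, acc = [], 0.0
        for length in self.lengths:
            out.append(acc)
            acc += length
        return tuple(out)

    @property
    def concat_positions(self) -> np.ndarray:
        """Marker positions on the concatenated axis (chromosomes laid end to end)."""
        return np.concatenate(
            [np.asarray(p) + off for p, off in zip(self.positions, self.offsets)]
        ) if self.marker_count else np.empty(0)

    def chrom_of(self) -> np.ndarray:
        return np.concatenate(
            [np.full(len(p), i, dtype=int) for i, p in enumerate(self.positions)]
        ) if self.marker_count else np.empty(0, dtype=int)

    def marker_at(self, concat_cm: float, tol: float = 1e-6) -> int:
        """Index of the marker at a concatenated-axis position (exact match)."""
        hits = np.flatnonzero(np.abs(self.concat_positions - concat_cm) <= tol)
        if hits.size == 0:
            raise SimulationError(f"no marker at {concat_cm} cM")
        return int(hits[0])


@dataclass
class GenotypeTable:
    """Biallelic genotypes coded 0=qq, 1=Qq, 2=QQ (-1 = missing)."""

    ids: list[str]
    codes: np.ndarray
    markers: list[str]
    roles: list[str]
    gmap: GenomeMap | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        n, m = self.codes.shape
        if len(self.ids) != n or len(self.roles) != n or len(self.markers) != m:
            raise SimulationError("genotype table dimensions do not align")
        if len(set(self.ids)) != n:
            raise SimulationError("duplicate individual ids")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def m(self) -> int:
        return self.codes.shape[1]

    def assert_inbred(self) -> None:
        """Parents must be homozygous (QQ or qq) at every marker."""
        par = [i for i, r in enumerate(self.roles) if r == "parent"]
        if par and np.any(self.codes[par] == 1):
            raise SimulationError("heterozygous genotype in an inbred parent")

    def subset(self, idx) -> "GenotypeTable":
        idx = np.asarray(idx)
        return GenotypeTable(
            [self.ids[i] for i in idx],
            self.codes[idx],
            list(self.markers),
            [self.roles[i] for i in idx],
            self.gmap,
        )

    def row_index(self) -> dict[str, int]:
        return {ind: i for i, ind in enumerate(self.ids)}


@dataclass
class PhenotypeSet:
    """Parent and cross phenotypes as tidy tables.

    ``parents`` columns: id, env, value.  ``crosses`` columns: maternal,
    paternal, env, value.
    """

    parents: pd.DataFrame
    crosses: pd.DataFrame


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------

def haldane(d_cm: float) -> float:
    """Recombination fraction for a map distance in cM (Haldane)."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_parents(
    gmap: GenomeMap,
    n: int,
    p: float = 0.5,
    seed=None,
    prefix: str = "L",
    rng: np.random.Generator | None = None,
) -> GenotypeTable:
    """Simulate ``n`` fully inbred parents as doubled haplotypes."""
    if n < 1:
        raise SimulationError("n must be >= 1")
    if not 0.0 < p < 1.0:
        raise SimulationError("allele frequency p must be in (0, 1)")
    rng = rng if rng is not None else _as_rng(seed)
    m = gmap.marker_count
    hap = np.empty((n, m), dtype=bool)
    col = 0
    for positions in gmap.positions:
        h = rng.random(n) < p
        hap[:, col] = h
        col += 1
        for delta in np.diff(positions):
            lam = 1.0 - 2.0 * haldane(float(delta))
            p_qq = p + (1.0 - p) * lam  # P(Q -> Q)
            p_qq_from_q = p * (1.0 - lam)  # P(q -> Q)
            r = rng.random(n)
            h = np.where(h, r < p_qq, r < p_qq_from_q)
            hap[:, col] = h
            col += 1
    codes = hap.astype(np.int8) * 2
    ids = [f"{prefix}{i + 1}" for i in range(n)]
    markers = [f"M{j + 1}" for j in range(m)]
    return GenotypeTable(ids, codes, markers, ["parent"] * n, gmap)


def deduce_f1(parents: GenotypeTable, design: MatingDesign) -> GenotypeTable:
    """Deduce F1 genotypes from homozygous parents (deterministic)."""
    parents.assert_inbred()
    if np.any(parents.codes == 1):
        raise SimulationError("heterozygous parent; NCII assumes inbred lines")
    idx = parents.row_index()
    try:
        mi = [idx[m] for m, _ in design.crosses]
        pi = [idx[p] for _, p in design.crosses]
    except KeyError as exc:  # pragma: no cover - defensive
        raise SimulationError(f"design references unknown parent {exc}") from exc
    codes = (parents.codes[mi] + parents.codes[pi]) // 2
    return GenotypeTable(design.f1_ids(), codes, list(parents.markers),
                         ["f1"] * len(design.crosses), parents.gmap)


# ---------------------------------------------------------------------------
# QTL model, calibration, phenotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QTL:
    """One simulated QTL: effect kind, marker index/index pair, heritability."""

    kind: str
    markers: tuple[int, ...]
    h2: float

    def __post_init__(self) -> None:
        if self.kind not in EFFECT_KINDS:
            raise SimulationError(f"unknown effect kind {self.kind!r}")
        need = 1 if self.kind in ("a", "d") else 2
        if len(self.markers) != need:
            raise SimulationError(f"{self.kind} QTL needs {need} marker(s)")
        if not 0.0 <= self.h2 < 1.0:
            raise SimulationError("h2 must be in [0, 1)")


@dataclass
class QTLModel:
    """Generative phenotype model: QTL list plus population parameters.

    ``dominance_degree`` (ratio d/a), when set, attaches a dominance effect
    ``d = ratio * a`` to every additive QTL; the pair is calibrated jointly
    so the locus still explains its nominal heritability.
    """

    qtl: list[QTL]
    mu: float = 100.0
    sigma2_e: float = 1.0
    dominance_degree: float | None = None
    p: float = 0.5

    @property
    def sigma2_p(self) -> float:
        """Total phenotypic variance implied by the heritability budget."""
        total_h2 = sum(q.h2 for q in self.qtl)
        if total_h2 >= 1.0:
            raise SimulationError("sum of QTL heritabilities must be < 1")
        return self.sigma2_e / (1.0 - total_h2)

    @classmethod
    def at_positions(
        cls,
        gmap: GenomeMap,
        kinds,
        positions_cm,
        h2s,
        **kwargs,
    ) -> "QTLModel":
        """Build a model from effect kinds and concatenated-axis cM positions."""
        qtl = []
        for kind, pos, h2 in zip(kinds, positions_cm, h2s):
            pos = (pos,) if np.isscalar(pos) else tuple(pos)
            markers = tuple(gmap.marker_at(p) for p in pos)
            qtl.append(QTL(kind, markers, h2))
        return cls(qtl, **kwargs)


def qtl_columns(codes: np.ndarray, model: QTLModel) -> np.ndarray:
    """Coded predictor column for each QTL (n x K), per the mapping-model coding."""
    codes = np.asarray(codes)
    W = codes.astype(float) - 1.0
    V = (codes == 1).astype(float)
    cols = []
    r = model.dominance_degree
    for q in model.qtl:
        if q.kind == "a":
            col = W[:, q.markers[0]]
            if r is not None:
                col = col + r * V[:, q.markers[0]]
        elif q.kind == "d":
            col = V[:, q.markers[0]]
        else:
            k, s = q.markers
            first, second = q.kind
            left = W[:, k] if first == "a" else V[:, k]
            right = W[:, s] if second == "a" else V[:, s]
            col = left * right
        cols.append(col)
    return np.column_stack(cols) if cols else np.empty((codes.shape[0], 0))


def calibrate_effects(model: QTLModel, codes: np.ndarray | None = None) -> np.ndarray:
    """Effect size per QTL from its heritability.

    ``sigma2_P = sigma2_e / (1 - sum h2)``; QTL k's genetic variance is
    ``h2_k * sigma2_P`` and its effect is the positive value whose squared
    product with the predictor-column variance equals that.  With ``codes``
    (an F1 population) the column variance is empirical, which accounts for
    linkage between paired loci; otherwise the unlinked 1/4:1/2:1/4
    closed forms are used.
    """
    sp = model.sigma2_p
    r = model.dominance_degree
    if codes is not None:
        variances = np.var(qtl_columns(codes, model), axis=0)
    else:
        variances = np.array([
            0.5 + 0.25 * r * r if (q.kind == "a" and r is not None)
            else THEORETICAL_COLUMN_VAR[q.kind]
            for q in model.qtl
        ])
    effects = np.zeros(len(model.qtl))
    for i, q in enumerate(model.qtl):
        if q.h2 == 0.0:
            continue
        if variances[i] <= 0:
            raise SimulationError(f"QTL {i} predictor is constant; cannot calibrate")
        effects[i] = math.sqrt(q.h2 * sp / variances[i])
    return effects


def true_terms(model: QTLModel, effects: np.ndarray) -> list[tuple[str, tuple[int, ...], float]]:
    """Ground-truth effect terms (kind, marker indices, value) for detection scoring.

    A dominance-degree model contributes both an additive and a dominance
    term per locus.
    """
    out = []
    r = model.dominance_degree
    for q, eff in zip(model.qtl, effects):
        if q.kind == "a" and r is not None:
            out.append(("a", q.markers, float(eff)))
            out.append(("d", q.markers, float(r * eff)))
        else:
            out.append((q.kind, q.markers, float(eff)))
    return out


def genetic_values(genotypes_or_codes, model: QTLModel, effects: np.ndarray) -> np.ndarray:
    codes = getattr(genotypes_or_codes, "codes", genotypes_or_codes)
    return qtl_columns(codes, model) @ effects


def simulate_phenotypes(
    genotypes: GenotypeTable,
    model: QTLModel,
    seed=None,
    effects: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Phenotypes ``y = mu + genetic value + N(0, sigma2_e)``.

    Pass the ``effects`` calibrated on the F1 population so that parents and
    hybrids share one generative model.
    """
    rng = rng if rng is not None else _as_rng(seed)
    if effects is None:
        effects = calibrate_effects(model)
    g = genetic_values(genotypes, model, effects)
    return model.mu + g + rng.normal(0.0, math.sqrt(model.sigma2_e), size=g.shape)


# ---------------------------------------------------------------------------
# experiment presets
# ---------------------------------------------------------------------------

MAIN_POSITIONS_CM = (25.0, 75.0, 135.0, 175.0, 220.0, 270.0)
EPI_PAIRS_CM = (
    (20.0, 60.0),
    (90.0, 125.0),
    (155.0, 205.0),
    (180.0, 235.0),
    (40.0, 275.0),
    (75.0, 220.0),
)
SIX_QTL_H2 = (0.05, 0.05, 0.10, 0.10, 0.15, 0.15)

#: t -> (a = b, extra padding crosses) for the mating-proportion study.
PROPORTION_DESIGNS = {
    1: (80, 0), 2: (60, 0), 3: (48, 0), 4: (40, 0),
    5: (34, 2), 6: (30, 0), 7: (26, 6), 15: (15, 0),
}

PROPORTION_QTL = (
    ("a", 20.0), ("d", 85.0), ("aa", (10.0, 30.0)),
    ("ad", (40.0, 55.0)), ("da", (45.0, 80.0)), ("dd", (65.0, 95.0)),
)

_PRESET_ALIASES = {
    "1": "additive", "2": "dominance", "3": "aa", "4": "ad", "5": "da", "6": "dd",
    "additive": "additive", "dominance": "dominance",
    "aa": "aa", "ad": "ad", "da": "da", "dd": "dd",
    "partial-dominance": "partial-dominance", "partial_dom": "partial-dominance",
    "complete-dominance": "complete-dominance", "complete_dom": "complete-dominance",
    "over-dominance": "over-dominance", "over_dom": "over-dominance",
    "proportion": "proportion", "mating-proportion": "proportion",
}

_DOMINANCE_DEGREE = {"partial-dominance": 0.5, "complete-dominance": 1.0, "over-dominance": 2.0}


def preset_experiment(name, t: int | None = None, mu: float = 100.0, sigma2_e: float = 1.0):
    """Named experiment configurations: (GenomeMap, MatingDesign, QTLModel).

    Presets ``1``-``6`` (aliases additive/dominance/aa/ad/da/dd) use three
    95 cM chromosomes with 20 markers each, 120+120 parents, and the t=2
    partial design (240 F1 hybrids).  The dominance-degree presets reuse the
    additive layout with d/a in {0.5, 1, 2}.  ``proportion`` (requires
    ``t`` in {1,...,7,15}) uses one 100 cM chromosome with 21 markers and
    six h2=0.05 QTL, one of each effect kind.
    """
    key = _PRESET_ALIASES.get(str(name))
    if key is None:
        raise SimulationError(f"unknown experiment preset {name!r}")
    common = dict(mu=mu, sigma2_e=sigma2_e)
    if key == "proportion":
        if t not in PROPORTION_DESIGNS:
            raise SimulationError(f"proportion preset needs t in {sorted(PROPORTION_DESIGNS)}")
        gmap = GenomeMap.equally_spaced(1, 100.0, 21)
        a, extra = PROPORTION_DESIGNS[t]
        design = build_partial_ncii(a, a, t=t, extra=extra)
        kinds = [k for k, _ in PROPORTION_QTL]
        positions = [p for _, p in PROPORTION_QTL]
        model = QTLModel.at_positions(gmap, kinds, positions, [0.05] * 6, **common)
        return gmap, design, model

    gmap = GenomeMap.equally_spaced(3, 95.0, 20)
    design = build_partial_ncii(120, 120, t=2)
    if key in ("additive", "dominance") or key in _DOMINANCE_DEGREE:
        kind = "d" if key == "dominance" else "a"
        model = QTLModel.at_positions(
            gmap, [kind] * 6, MAIN_POSITIONS_CM, SIX_QTL_H2,
            dominance_degree=_DOMINANCE_DEGREE.get(key), **common,
        )
    else:  # aa / ad / da / dd
        model = QTLModel.at_positions(gmap, [key] * 6, EPI_PAIRS_CM, SIX_QTL_H2, **common)
    return gmap, design, model
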