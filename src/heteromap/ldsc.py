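"""LD score regression to diagnose population-structure inflation.

A continuous trait is binarized — the extreme 35% largest values become
cases, the 35% smallest become controls, the middle 30% are dropped — and
each marker's association chi-square (Armitage-trend form, ``n * r^2``)
is regressed on its LD score ``l_j = sum_k r^2_jk`` (all markers, self
term included).  An intercept significantly different from 1 flags
population structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class LDSCError(ValueError):
    pass


@dataclass
class LDSCResult:
    ell: np.ndarray
    chi2: np.ndarray
    intercept: float
    intercept_se: float
    slope: float
    slope_se: float
    t_intercept: float
    p_intercept: float
    n_used: int
    markers_used: int
    monomorphic: np.ndarray


def binarize_trait(values) -> tuple[np.ndarray, np.ndarray]:
    """(binary vector, kept indices): top 35% -> 1, bottom 35% -> 0, rest dropped.

    Ties are broken by stable sort order.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 3:
        raise LDSCError("need at least 3 values")
    if np.all(v == v[0]):
        raise LDSCError("constant trait: degenerate 35/35 split")
    k = int(np.floor(0.35 * n))
    if k < 1:
        raise LDSCError("too few values for a 35/35 split")
    order = np.argsort(v, kind="stable")
    low, high = order[:k], order[-k:]
    idx = np.concatenate([low, high])
    y = np.concatenate([np.zeros(k), np.ones(k)])
    return y, idx


def ld_scores(genotypes) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker LD scores and a monomorphic-marker flag vector.

    ``l_j = sum_k r^2_jk`` over all markers including ``k = j``; pairs
    involving a monomorphic marker contribute 0 (the marker's own score is
    its self term, 1).
    """
    codes = getattr(genotypes, "codes", genotypes)
    D = np.asarray(codes, dtype=float)
    if D.shape[1] < 2:
        raise LDSCError("need at least 2 markers")
    mono = D.var(axis=0) <= 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(D, rowvar=False)
    R = np.nan_to_num(R, nan=0.0)
    R[mono, :] = 0.0
    R[:, mono] = 0.0
    np.fill_diagonal(R, 1.0)
    return (R**2).sum(axis=1), mono


def ldsc_regress(genotypes, binary: np.ndarray, idx: np.ndarray | None = None) -> LDSCResult:
    """OLS of per-marker chi-square on LD score, with the intercept-vs-1 t-test.

    LD scores come from the full genotype panel; the association statistics
    use only the retained (case/control) individuals.
    """
    codes = getattr(genotypes, "codes", genotypes)
    D = np.asarray(codes, dtype=float)
    ell, mono = ld_scores(D)
    y = np.asarray(binary, dtype=float)
    sub = D[np.asarray(idx)] if idx is not None else D
    if sub.shape[0] != y.size:
        raise LDSCError("binary trait does not align with the individuals")
    n_used = y.size
    yc = y - y.mean()
    sy = float(yc @ yc)
    Xc = sub - sub.mean(axis=0, keepdims=True)
    sx = np.einsum("ij,ij->j", Xc, Xc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / np.sqrt(sx * sy)
    r = np.nan_to_num(r, nan=0.0)
    chi2 = n_used * r**2
    use = ~mono & (sx > 1e-12)
    if use.sum() < 3:
        raise LDSCError("fewer than 3 polymorphic markers: regression underdetermined")
    reg = stats.linregress(ell[use], chi2[use])
    t = (reg.intercept - 1.0) / reg.intercept_stderr
    df = int(use.sum() - 2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return LDSCResult(
        ell=ell,
        chi2=chi2,
        intercept=float(reg.intercept),
        intercept_se=float(reg.intercept_stderr),
        slope=float(reg.slope),
        slope_se=float(reg.stderr),
        t_intercept=float(t),
        p_intercept=float(p),
        n_used=n_used,
        markers_used=int(use.sum()),
        monomorphic=mono,
    )


def ldsc(genotypes, values) -> LDSCResult:
    """Binarize a continuous trait and run the LD score regression."""
    y, idx = binarize_trait(values)
    return ldsc_regress(genotypes, y, idx)


def intercept_test(intercept: float, se: float, df: int | None = None):
    """t statistic (and P, when df is given) for H0: intercept = 1."""
    if se <= 0:
        raise LDSCError("standard error must be positive")
    t = (intercept - 1.0) / se
    if df is None:
        return t
    return t, 2.0 * stats.t.sf(abs(t), df)
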