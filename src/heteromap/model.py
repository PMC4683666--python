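"""Additive-dominance-epistasis design matrices.

Every marker is treated as a putative QTL.  Marker genotypes are coded
Cockerham-style: additive dummy ``w`` in {1, 0, -1} for {QQ, Qq, qq} and
dominance dummy ``v`` in {0, 1, 0}, so the two predictors are uncorrelated
at F1 genotype frequencies 1/4 : 1/2 : 1/4.  For each ordered marker pair
``k < s`` the four epistatic columns are the element-wise products
``w_k w_s`` (aa), ``w_k v_s`` (ad), ``v_k w_s`` (da) and ``v_k v_s`` (dd).
With two environments a +/-1-coded environment covariate joins the
unpenalized block and every genetic effect gains one x-environment
interaction column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import GenotypeTable

CONSTANT_VAR_TOL = 1e-12


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class EffectLabel:
    """Identifier of one genetic effect column, e.g. ``aa@M3:M12xE``."""

    type: str
    markers: tuple[str, ...]
    env: bool = False

    @property
    def name(self) -> str:
        return f"{self.type}@{':'.join(self.markers)}" + ("xE" if self.env else "")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def encode_marker(genotype):
    """(additive, dominance) dummy codes for one genotype.

    QQ -> (1, 0); Qq -> (0, 1); qq -> (-1, 0).  Accepts the string codes or
    the numeric aliases 2/1/0.
    """
    lookup = {"QQ": (1.0, 0.0), "Qq": (0.0, 1.0), "qq": (-1.0, 0.0),
              2: (1.0, 0.0), 1: (0.0, 1.0), 0: (-1.0, 0.0)}
    try:
        return lookup[genotype if isinstance(genotype, str) else int(genotype)]
    except (KeyError, TypeError, ValueError):
        raise ModelError(f"invalid genotype code {genotype!r}") from None


@dataclass
class EffectDesign:
    """Response, penalized effect matrix, labels and unpenalized block.

    ``active`` flags columns with non-negligible variance; constant columns
    (for example every dominance column in an all-inbred GCA population)
    keep their label but are excluded from estimation.
    """

    y: np.ndarray
    X: np.ndarray
    labels: list[EffectLabel]
    U: np.ndarray
    active: np.ndarray
    unpenalized_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[0] != self.y.size or self.U.shape[0] != self.y.size:
            raise ModelError("response / design dimension mismatch")
        if self.X.shape[1] != len(self.labels):
            raise ModelError("label count must equal column count")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_arrays(cls, y, X, labels=None, U=None) -> "EffectDesign":
        """Generic constructor for arbitrary (y, X) problems."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if labels is None:
            labels = [EffectLabel("a", (f"X{j + 1}",)) for j in range(X.shape[1])]
        if U is None:
            U = np.ones((y.size, 1))
        active = X.var(axis=0) > CONSTANT_VAR_TOL
        return cls(y, X, list(labels), np.asarray(U, dtype=float), active,
                   ["intercept"] + [f"U{j}" for j in range(1, np.asarray(U).shape[1])])

    def subset(self, rows) -> "EffectDesign":
        rows = np.asarray(rows)
        X = self.X[rows]
        return EffectDesign(self.y[rows], X, self.labels, self.U[rows],
                            X.var(axis=0) > CONSTANT_VAR_TOL, list(self.unpenalized_names))


def count_effects(m: int, envs: int = 1) -> dict:
    """Model-dimension accounting for ``m`` markers and ``envs`` environments.

    Main effects 2m; epistatic 4*m*(m-1)/2; with >= 2 environments one
    environment main effect plus one xE copy of every genetic effect.
    """
    if m < 1 or envs < 1:
        raise ModelError("m and envs must be >= 1")
    main = 2 * m
    epistatic = 4 * (m * (m - 1)) // 2
    env_main = 1 if envs >= 2 else 0
    main_x_env = main if envs >= 2 else 0
    epistatic_x_env = epistatic if envs >= 2 else 0
    return {
        "main": main,
        "epistatic": epistatic,
        "env_main": env_main,
        "main_x_env": main_x_env,
        "epistatic_x_env": epistatic_x_env,
        "total": main + epistatic + env_main + main_x_env + epistatic_x_env,
    }


def _dummy_matrices(codes: np.ndarray, missing: str):
    """Full-length (W, V) plus, in drop mode, the indices of complete rows."""
    codes = np.asarray(codes, dtype=float)
    mask = codes < 0
    W = codes - 1.0
    V = (codes == 1).astype(float)
    if mask.any():
        if missing == "drop":
            return W, V, np.flatnonzero(~mask.any(axis=1))
        if missing != "impute":
            raise ModelError("missing must be 'impute' or 'drop'")
        W[mask] = np.nan
        V[mask] = np.nan
        W = np.where(np.isnan(W), np.nanmean(W, axis=0, keepdims=True), W)
        V = np.where(np.isnan(V), np.nanmean(V, axis=0, keepdims=True), V)
    return W, V, None


def build_design(
    genotypes: GenotypeTable | np.ndarray,
    response,
    rows=None,
    env=None,
    Q=None,
    markers: list[str] | None = None,
    missing: str = "impute",
) -> EffectDesign:
    """Full main + epistatic effect design for a mapping population.

    Parameters
    ----------
    genotypes : GenotypeTable or (n, m) code array
    response : length-N vector (N = number of observations; with repeated
        environments N may exceed the number of individuals)
    rows : observation -> genotype-row index (default: one obs per row)
    env : per-observation environment labels; exactly 2 distinct labels are
        supported and coded +/-1 in the unpenalized block, with one xE
        interaction column per genetic effect
    Q : population-structure covariates, one row per genotype row; appended
        to the unpenalized block
    """
    codes = getattr(genotypes, "codes", genotypes)
    marker_names = markers or getattr(genotypes, "markers", None) or [
        f"M{j + 1}" for j in range(np.asarray(codes).shape[1])
    ]
    W, V, kept = _dummy_matrices(codes, missing)
    n_geno, m = W.shape
    y = np.asarray(response, dtype=float).ravel()
    if rows is None:
        if len(y) != n_geno:
            raise ModelError("response length must equal the individual count")
        rows = kept if kept is not None else np.arange(n_geno)
        if kept is not None:
            y = y[rows]  # drop responses of incomplete individuals
    else:
        rows = np.asarray(rows)
        if len(rows) != len(y):
            raise ModelError("rows must align with the response")
        if rows.max(initial=-1) >= n_geno:
            raise ModelError("row index out of range")
        if kept is not None and not np.isin(rows, kept).all():
            raise ModelError("rows reference individuals with missing genotypes")
    W, V = W[rows], V[rows]

    iu_k, iu_s = np.triu_indices(m, 1)
    blocks = [W, V, W[:, iu_k] * W[:, iu_s], W[:, iu_k] * V[:, iu_s],
              V[:, iu_k] * W[:, iu_s], V[:, iu_k] * V[:, iu_s]]
    labels = [EffectLabel("a", (mk,)) for mk in marker_names]
    labels += [EffectLabel("d", (mk,)) for mk in marker_names]
    for etype in ("aa", "ad", "da", "dd"):
        labels += [EffectLabel(etype, (marker_names[k], marker_names[s]))
                   for k, s in zip(iu_k, iu_s)]
    X = np.concatenate(blocks, axis=1)

    unpen = [np.ones((len(y), 1))]
    unpen_names = ["intercept"]
    if env is not None:
        env = np.asarray(env)
        levels = sorted(set(env.tolist()))
        if len(levels) == 2:
            ecol = np.where(env == levels[0], -1.0, 1.0)
            X = np.concatenate([X, X * ecol[:, None]], axis=1)
            labels = labels + [EffectLabel(l.type, l.markers, env=True) for l in labels]
            unpen.append(ecol[:, None])
            unpen_names.append("env")
        elif len(levels) > 2:
            raise ModelError("only 1 or 2 environments are supported")
    if Q is not None:
        Q = np.asarray(Q, dtype=float)
        Q = Q[rows] if Q.shape[0] == n_geno else Q
        if Q.ndim == 1:
            Q = Q[:, None]
        if Q.shape[0] != len(y):
            raise ModelError("Q matrix must align with the response")
        unpen.append(Q)
        unpen_names += [f"Q{j + 1}" for j in range(Q.shape[1])]

    U = np.concatenate(unpen, axis=1)
    active = X.var(axis=0) > CONSTANT_VAR_TOL
    return EffectDesign(y, X, labels, U, active, unpen_names)
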