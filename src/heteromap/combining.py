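"""Dependent variables for heterosis mapping: trait, GCA, SCA and MPH.

General combining ability (GCA) of a parent is its mean F1 performance over
all its crosses, expressed as a deviation from the grand mean of the F1
values; specific combining ability (SCA) of a cross is the residual after
removing the grand mean and both parents' GCAs; mid-parent heterosis (MPH)
is the percentage deviation of the hybrid from its parents' average.
In an NCII design maternal and paternal GCA are kept as separate ledgers
(the two rosters are disjoint).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import MatingDesign
from .simulate import GenotypeTable, PhenotypeSet


class DecompositionError(ValueError):
    pass


@dataclass
class CombiningAbility:
    grand_mean: float
    g_maternal: pd.Series
    g_paternal: pd.Series
    sca: pd.Series | None = None  # indexed by (maternal, paternal)


@dataclass
class DependentVariable:
    """A response vector aligned with its mapping-population genotypes."""

    kind: str
    values: np.ndarray
    ids: list[str]
    env: np.ndarray | None = None
    genotypes: GenotypeTable | None = None


def _single_env(df: pd.DataFrame) -> pd.DataFrame:
    if "env" in df.columns and df["env"].nunique() > 1:
        raise DecompositionError(
            "multiple environments: compute per environment (see by_environment)"
        )
    return df


def combining_ability(
    phenos: PhenotypeSet | pd.DataFrame,
    design: MatingDesign,
    with_sca: bool = True,
) -> CombiningAbility:
    """GCA (and optionally SCA) from the observed crosses of a design.

    For partial designs the grand mean and parent means use observed
    crosses only.
    """
    crosses = phenos.crosses if isinstance(phenos, PhenotypeSet) else phenos
    crosses = _single_env(crosses)
    obs = {(m, p) for m, p in zip(crosses["maternal"], crosses["paternal"])}
    missing = [c for c in design.crosses if c not in obs]
    if missing:
        raise DecompositionError(f"{len(missing)} design crosses lack phenotypes, e.g. {missing[0]}")
    grand = float(crosses["value"].mean())
    gm = crosses.groupby("maternal")["value"].mean() - grand
    gp = crosses.groupby("paternal")["value"].mean() - grand
    for ids, g, side in ((design.maternal_ids, gm, "maternal"), (design.paternal_ids, gp, "paternal")):
        absent = set(ids) - set(g.index)
        if absent:
            raise DecompositionError(f"{side} parent(s) with no crosses: {sorted(absent)[:3]}")
    gm = gm.reindex(design.maternal_ids)
    gp = gp.reindex(design.paternal_ids)
    sca = None
    if with_sca:
        sca_vals = (
            crosses["value"].to_numpy()
            - grand
            - gm[crosses["maternal"]].to_numpy()
            - gp[crosses["paternal"]].to_numpy()
        )
        sca = pd.Series(
            sca_vals,
            index=pd.MultiIndex.from_arrays(
                [crosses["maternal"], crosses["paternal"]], names=["maternal", "paternal"]
            ),
        )
    return CombiningAbility(grand, gm, gp, sca)


def gca(phenos, design: MatingDesign) -> CombiningAbility:
    """General combining ability only (no SCA column)."""
    return combining_ability(phenos, design, with_sca=False)


def sca(phenos, design: MatingDesign) -> CombiningAbility:
    """GCA plus per-cross specific combining ability."""
    return combining_ability(phenos, design, with_sca=True)


def combining_from_matrix(F: np.ndarray):
    """(grand, g_maternal, g_paternal, SCA matrix) for a complete factorial."""
    F = np.asarray(F, dtype=float)
    grand = F.mean()
    gm = F.mean(axis=1) - grand
    gp = F.mean(axis=0) - grand
    S = F - grand - gm[:, None] - gp[None, :]
    return grand, gm, gp, S


def mph(f1_value, maternal_value, paternal_value):
    """Mid-parent heterosis in percent: ``100 * (F1 - MP) / MP``."""
    f1 = np.asarray(f1_value, dtype=float)
    mp = (np.asarray(maternal_value, dtype=float) + np.asarray(paternal_value, dtype=float)) / 2.0
    if np.any(mp == 0):
        raise DecompositionError("mid-parent value of 0: MPH undefined")
    out = 100.0 * (f1 - mp) / mp
    return float(out) if np.isscalar(f1_value) else out


def mph_matrix(F: np.ndarray, maternal_values: np.ndarray, paternal_values: np.ndarray) -> np.ndarray:
    mp = (np.asarray(maternal_values)[:, None] + np.asarray(paternal_values)[None, :]) / 2.0
    if np.any(mp == 0):
        raise DecompositionError("mid-parent value of 0: MPH undefined")
    return 100.0 * (np.asarray(F, dtype=float) - mp) / mp


def heterosis_table(phenos: PhenotypeSet, design: MatingDesign) -> pd.DataFrame:
    """Per-cross mid-parent value and MPH percentage."""
    crosses = _single_env(phenos.crosses)
    parents = _single_env(phenos.parents).set_index("id")["value"]
    pm = parents.reindex(crosses["maternal"]).to_numpy()
    pp = parents.reindex(crosses["paternal"]).to_numpy()
    if np.isnan(pm).any() or np.isnan(pp).any():
        raise DecompositionError("parental phenotypes missing for some crosses")
    midparent = (pm + pp) / 2.0
    return pd.DataFrame(
        {
            "maternal": crosses["maternal"].to_numpy(),
            "paternal": crosses["paternal"].to_numpy(),
            "midparent": midparent,
            "mph": mph(crosses["value"].to_numpy(), pm, pp),
        }
    )


DEPENDENT_KINDS = ("trait", "gca", "sca", "mph")


def dependent_variable(
    kind: str,
    phenos: PhenotypeSet,
    design: MatingDesign,
    genotypes: GenotypeTable | None = None,
) -> DependentVariable:
    """Response vector plus the matching mapping population.

    GCA maps onto the parents themselves (one value per parent, parental
    genotypes); trait, SCA and MPH map onto the F1 hybrids (one value per
    cross, F1 genotypes).
    """
    if kind not in DEPENDENT_KINDS:
        raise DecompositionError(f"unknown dependent variable {kind!r}")
    crosses = _single_env(phenos.crosses).set_index(["maternal", "paternal"])["value"]

    if kind == "gca":
        ca = gca(phenos, design)
        ids = list(design.maternal_ids) + list(design.paternal_ids)
        values = np.concatenate([ca.g_maternal.to_numpy(), ca.g_paternal.to_numpy()])
    else:
        ids = design.f1_ids()
        if kind == "trait":
            values = crosses.reindex(list(design.crosses)).to_numpy()
        elif kind == "sca":
            counts = pd.Series([m for m, _ in design.crosses]).value_counts()
            counts_p = pd.Series([p for _, p in design.crosses]).value_counts()
            if counts.max() < 2 and counts_p.max() < 2:
                raise DecompositionError("SCA degenerate: every parent has a single cross")
            ca = sca(phenos, design)
            values = ca.sca.reindex(list(design.crosses)).to_numpy()
        else:  # mph
            if phenos.parents is None or phenos.parents.empty:
                raise DecompositionError("MPH requires parental phenotypes")
            het = heterosis_table(phenos, design)
            values = het.set_index(["maternal", "paternal"])["mph"].reindex(list(design.crosses)).to_numpy()
    if np.isnan(values).any():
        raise DecompositionError("missing phenotypes for some mapping units")

    sub = None
    if genotypes is not None:
        idx = genotypes.row_index()
        try:
            sub = genotypes.subset([idx[i] for i in ids])
        except KeyError as exc:
            raise DecompositionError(f"genotypes missing for {exc}") from exc
    return DependentVariable(kind, values, ids, None, sub)


def by_environment(phenos: PhenotypeSet):
    """Split a multi-environment phenotype set into per-environment sets."""
    envs = sorted(set(phenos.crosses.get("env", pd.Series(["E1"]))))
    for env in envs:
        yield env, PhenotypeSet(
            phenos.parents[phenos.parents["env"] == env].reset_index(drop=True)
            if "env" in phenos.parents.columns else phenos.parents,
            phenos.crosses[phenos.crosses["env"] == env].reset_index(drop=True)
            if "env" in phenos.crosses.columns else phenos.crosses,
        )
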