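"""Tab-delimited file formats, run configuration and the analysis pipeline.

All tables are UTF-8, tab-delimited, with a header row:

* genotypes — columns ``id``, ``role`` then one column per marker with
  cells in {QQ, Qq, qq} (numeric alias {2, 1, 0} accepted);
* map — columns ``marker``, ``chrom``, ``cM`` (within-chromosome);
* parent phenotypes — ``id``, ``env``, ``value``;
* cross phenotypes — ``maternal``, ``paternal``, ``env``, ``value``;
* cross schedule — ``maternal``, ``paternal``;
* Q matrix — ``id`` then one column per structure covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .combining import dependent_variable
from .design import MatingDesign
from .eblasso import fit as eblasso_fit, test_effects
from .ldsc import ldsc
from .model import build_design
from .simulate import (
    STR_GENO,
    GENO_STR,
    GenomeMap,
    GenotypeTable,
    PhenotypeSet,
)

logger = logging.getLogger(__name__)


class IOError_(ValueError):
    pass


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_genotypes(table: GenotypeTable, path) -> None:
    df = pd.DataFrame(
        np.vectorize(GENO_STR.get)(table.codes), columns=table.markers
    )
    df.insert(0, "role", table.roles)
    df.insert(0, "id", table.ids)
    df.to_csv(path, sep="\t", index=False)


def read_genotypes(path, gmap: GenomeMap | None = None) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("id", "role"):
        if col not in df.columns:
            raise IOError_(f"genotype table missing column {col!r}")
    ids = df["id"].tolist()
    if len(set(ids)) != len(ids):
        raise IOError_("duplicated individual id in genotype table")
    markers = [c for c in df.columns if c not in ("id", "role")]
    raw = df[markers].to_numpy()
    codes = np.empty(raw.shape, dtype=np.int8)
    for tok in np.unique(raw):
        if tok not in STR_GENO:
            raise IOError_(f"unknown genotype token {tok!r}")
        codes[raw == tok] = STR_GENO[tok]
    table = GenotypeTable(ids, codes, markers, df["role"].tolist(), gmap)
    table.assert_inbred()
    return table


def write_map(gmap: GenomeMap, path, markers: list[str] | None = None) -> None:
    chrom = gmap.chrom_of()
    pos = np.concatenate([np.asarray(p) for p in gmap.positions])
    markers = markers or [f"M{j + 1}" for j in range(gmap.marker_count)]
    pd.DataFrame({"marker": markers, "chrom": chrom + 1, "cM": pos}).to_csv(
        path, sep="\t", index=False
    )


def read_map(path) -> tuple[GenomeMap, list[str]]:
    df = pd.read_csv(path, sep="\t")
    lengths, positions, markers = [], [], []
    for _, grp in df.groupby("chrom", sort=True):
        pos = grp["cM"].to_numpy(dtype=float)
        positions.append(tuple(pos))
        lengths.append(float(pos.max()) if len(pos) else 0.0)
        markers += grp["marker"].tolist()
    return GenomeMap(tuple(lengths), tuple(positions)), markers


def write_phenotypes(phenos: PhenotypeSet, parents_path, crosses_path) -> None:
    phenos.parents.to_csv(parents_path, sep="\t", index=False)
    phenos.crosses.to_csv(crosses_path, sep="\t", index=False)


def read_phenotypes(parents_path, crosses_path) -> PhenotypeSet:
    parents = pd.read_csv(parents_path, sep="\t") if parents_path else pd.DataFrame(
        columns=["id", "env", "value"]
    )
    crosses = pd.read_csv(crosses_path, sep="\t")
    for col in ("maternal", "paternal", "value"):
        if col not in crosses.columns:
            raise IOError_(f"cross table missing column {col!r}")
    if "env" not in crosses.columns:
        crosses["env"] = "E1"
    if not parents.empty and "env" not in parents.columns:
        parents["env"] = "E1"
    return PhenotypeSet(parents, crosses)


def write_schedule(design: MatingDesign, path) -> None:
    pd.DataFrame(design.crosses, columns=["maternal", "paternal"]).to_csv(
        path, sep="\t", index=False
    )


def read_schedule(path) -> MatingDesign:
    df = pd.read_csv(path, sep="\t")
    maternal = tuple(dict.fromkeys(df["maternal"]))
    paternal = tuple(dict.fromkeys(df["paternal"]))
    crosses = tuple(zip(df["maternal"], df["paternal"]))
    return MatingDesign(maternal, paternal, crosses)


def read_q_matrix(path, ids: list[str]) -> np.ndarray:
    df = pd.read_csv(path, sep="\t").set_index("id")
    missing = [i for i in ids if i not in df.index]
    if missing:
        raise IOError_(f"Q matrix missing individuals, e.g. {missing[0]!r}")
    return df.loc[ids].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    genotypes: str
    crosses: str
    out_dir: str
    kind: str = "trait"
    map: str | None = None
    parents: str | None = None
    q_matrix: str | None = None
    alpha: float = 0.05
    hyper_a: float = 0.1
    hyper_b: float = 30.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise IOError_(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for attr in ("genotypes", "crosses", "map", "parents", "q_matrix"):
            value = getattr(self, attr)
            if value is not None and not Path(value).exists():
                raise IOError_(f"{attr} path does not exist: {value}")
        if self.kind == "mph" and self.parents is None:
            raise IOError_("dependent variable 'mph' requires parental phenotypes")
        if self.kind == "gca" and self.genotypes is None:
            raise IOError_("dependent variable 'gca' requires parental genotypes")


def run_pipeline(config: RunConfig) -> dict:
    """Read inputs, compute the dependent variable, fit EBLASSO, write outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gmap = markers = None
    if config.map:
        gmap, markers = read_map(config.map)
    genotypes = read_genotypes(config.genotypes, gmap)
    phenos = read_phenotypes(config.parents, config.crosses)
    design = read_schedule(config.crosses)

    dv = dependent_variable(config.kind, phenos, design, genotypes)
    pd.DataFrame({"unit_id": dv.ids, "kind": config.kind, "value": dv.values}).to_csv(
        out / "dependent_variable.tsv", sep="\t", index=False
    )

    Q = read_q_matrix(config.q_matrix, dv.ids) if config.q_matrix else None
    des = build_design(dv.genotypes, dv.values, Q=Q, markers=markers)
    fit_res = eblasso_fit(des, hyper=(config.hyper_a, config.hyper_b))
    effects = test_effects(fit_res, alpha=config.alpha)
    effects.to_csv(out / "effects.tsv", sep="\t", index=False)

    ldsc_line = None
    try:
        res = ldsc(dv.genotypes, dv.values)
        ldsc_line = {
            "intercept": res.intercept,
            "intercept_se": res.intercept_se,
            "slope": res.slope,
            "t": res.t_intercept,
            "P": res.p_intercept,
        }
        pd.DataFrame([ldsc_line]).to_csv(out / "ldsc.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001 - LDSC is a diagnostic side channel
        logger.warning("LDSC skipped: %s", exc)

    log = {
        "version": _pkg_version,
        "seed": config.seed,
        "kind": config.kind,
        "n": int(des.n),
        "candidates": int(des.p),
        "retained": int(fit_res.n_retained),
        "sigma0_sq": fit_res.sigma0_sq,
        "lambda": fit_res.lam,
        "converged": bool(fit_res.converged),
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)
    return {"fit": fit_res, "effects": effects, "ldsc": ldsc_line, "log": log}
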