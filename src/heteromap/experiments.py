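"""Monte-Carlo simulation studies.

Three study families:

* :func:`run_power_study` — empirical power to detect each simulated QTL
  when the dependent variable is the trait phenotype, GCA, SCA or MPH.
  Per replicate the full maternal x paternal factorial is simulated (so the
  combining abilities and MPH are well defined), the mapping population for
  the chosen dependent variable is formed, the full main + epistatic model
  is fitted by EBLASSO and a QTL counts as detected when its true effect
  term (correct type at the correct marker or marker pair) has P < alpha.
* :func:`run_mph_ranking` — mean |MPH| over full-factorial hybrid
  populations under nine single-effect-type genetic models, ranking the
  contribution of each component to heterosis.
* :func:`run_proportion_study` — power as a function of the proportion of
  F1 hybrids in the mapping population (parents + F1s mapped together)
  across eight partial-NCII mating strategies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import combining, eblasso
from .design import MatingDesign, f1_proportion
from .model import build_design
from .simulate import (
    GenomeMap,
    QTLModel,
    calibrate_effects,
    preset_experiment,
    qtl_columns,
    simulate_parents,
    true_terms,
)

logger = logging.getLogger(__name__)

RANKING_MODELS = (
    "additive",
    "partial-dominance",
    "complete-dominance",
    "over-dominance",
    "dominance",
    "aa",
    "ad",
    "da",
    "dd",
)


@dataclass
class PowerReport:
    preset: str
    kind: str
    replicates: int
    failures: int
    table: pd.DataFrame


@dataclass
class MPHSummary:
    replicates: int
    hybrids_per_replicate: int
    table: pd.DataFrame  # columns: model, mean_abs_mph

    def ranking(self) -> list[str]:
        return list(self.table.sort_values("mean_abs_mph", ascending=False)["model"])


def _label_name(kind: str, markers: tuple[int, ...], marker_names: list[str]) -> str:
    return f"{kind}@{':'.join(marker_names[i] for i in markers)}"


def _replicate_population(gmap: GenomeMap, design: MatingDesign, model: QTLModel, rng):
    """Parents, full-factorial F1 codes and phenotypes for one replicate."""
    a, b = design.a, design.b
    mat = simulate_parents(gmap, a, model.p, rng=rng, prefix="M")
    pat = simulate_parents(gmap, b, model.p, rng=rng, prefix="P")
    m = gmap.marker_count
    f1_codes = ((mat.codes[:, None, :] + pat.codes[None, :, :]) // 2).reshape(a * b, m)
    effects = calibrate_effects(model, f1_codes)
    g_f1 = (qtl_columns(f1_codes, model) @ effects).reshape(a, b)
    sd = np.sqrt(model.sigma2_e)
    F = model.mu + g_f1 + rng.normal(0.0, sd, size=(a, b))
    parent_codes = np.concatenate([mat.codes, pat.codes])
    g_par = qtl_columns(parent_codes, model) @ effects
    y_par = model.mu + g_par + rng.normal(0.0, sd, size=a + b)
    return mat, pat, parent_codes, f1_codes, F, y_par, effects


def _mapping_population(kind, design, parent_codes, f1_codes, F, y_par):
    """(response, genotype codes) for the requested dependent variable."""
    a, b = design.a, design.b
    mi, pi = design.cross_indices()
    sub = np.asarray(mi) * b + np.asarray(pi)
    if kind == "gca":
        grand, gm, gp, _ = combining.combining_from_matrix(F)
        return np.concatenate([gm, gp]), parent_codes
    if kind == "trait":
        return F[mi, pi], f1_codes[sub]
    if kind == "sca":
        _, _, _, S = combining.combining_from_matrix(F)
        return S[mi, pi], f1_codes[sub]
    if kind == "mph":
        MPH = combining.mph_matrix(F, y_par[:a], y_par[a:])
        return MPH[mi, pi], f1_codes[sub]
    if kind == "mixed":  # parents and F1 hybrids mapped together on the trait
        return np.concatenate([y_par, F[mi, pi]]), np.concatenate([parent_codes, f1_codes[sub]])
    raise ValueError(f"unknown dependent variable {kind!r}")


def _score_replicate(sig_table, terms, marker_names, concat_pos, relaxed_cm):
    """Per-term (detected_exact, detected_relaxed, estimate or nan)."""
    sig = sig_table[sig_table["significant"]]
    sig_names = set(sig["label"])
    est = dict(zip(sig_table["label"], sig_table["estimate"]))
    by_type: dict[str, list] = {}
    for _, row in sig.iterrows():
        by_type.setdefault(row["type"], []).append(row["markers"].split(":"))
    name_pos = dict(zip(marker_names, concat_pos))
    out = []
    for kind, markers, truth in terms:
        label = _label_name(kind, markers, marker_names)
        exact = label in sig_names
        relaxed = exact
        if not relaxed:
            tpos = sorted(concat_pos[i] for i in markers)
            for cand in by_type.get(kind, []):
                cpos = sorted(name_pos[mk] for mk in cand)
                if len(cpos) == len(tpos) and all(
                    abs(c - t) <= relaxed_cm for c, t in zip(cpos, tpos)
                ):
                    relaxed = True
                    break
        out.append((exact, relaxed, est.get(label, np.nan)))
    return out


def run_power_study(
    preset,
    kind: str,
    replicates: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    hyper: tuple[float, float] = eblasso.DEFAULT_HYPER,
    relaxed_cm: float = 10.0,
    t: int | None = None,
    progress: bool = False,
) -> PowerReport:
    """Empirical power per simulated QTL for one preset and dependent variable."""
    gmap, design, model = preset_experiment(preset, t=t)
    marker_names = [f"M{j + 1}" for j in range(gmap.marker_count)]
    concat_pos = gmap.concat_positions
    children = np.random.SeedSequence(seed).spawn(replicates)
    records = []
    failures = 0
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        try:
            _, _, parent_codes, f1_codes, F, y_par, effects = _replicate_population(
                gmap, design, model, rng
            )
            y, codes = _mapping_population(kind, design, parent_codes, f1_codes, F, y_par)
            des = build_design(codes, y, markers=marker_names)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", eblasso.ConvergenceWarning)
                f = eblasso.fit(des, hyper=hyper)
            table = eblasso.test_effects(f, alpha=alpha)
            terms = true_terms(model, effects)
            records.append((terms, _score_replicate(table, terms, marker_names, concat_pos, relaxed_cm)))
        except Exception:  # noqa: BLE001 - a failed replicate is logged and excluded
            failures += 1
            logger.exception("replicate %d failed", r)
        if progress and (r + 1) % 10 == 0:
            logger.info("%s/%s: %d/%d replicates", preset, kind, r + 1, replicates)
    if not records:
        raise RuntimeError("all replicates failed")

    terms0 = records[0][0]
    rows = []
    for i, (tkind, markers, _) in enumerate(terms0):
        truths = np.array([rec[0][i][2] for rec in records])
        exact = np.array([rec[1][i][0] for rec in records])
        relaxed = np.array([rec[1][i][1] for rec in records])
        ests = np.array([rec[1][i][2] for rec in records])
        got = ~np.isnan(ests)
        h2 = None
        for q in model.qtl:  # locate the defining QTL for bookkeeping
            if q.markers == markers:
                h2 = q.h2
        rows.append(
            {
                "term": _label_name(tkind, markers, marker_names),
                "type": tkind,
                "markers": ":".join(marker_names[j] for j in markers),
                "h2": h2,
                "true_effect": float(np.mean(truths)),
                "power": float(np.mean(exact)),
                "power_relaxed": float(np.mean(relaxed)),
                "mean_estimate": float(np.nanmean(ests)) if got.any() else np.nan,
                "mean_abs_dev": float(np.nanmean(np.abs(ests - truths))) if got.any() else np.nan,
                "n_detected": int(exact.sum()),
            }
        )
    table = pd.DataFrame(rows)
    return PowerReport(str(preset), kind, len(records), failures, table)


def run_mph_ranking(
    replicates: int = 150,
    seed: int = 0,
    mu: float = 100.0,
    sigma2_e: float = 1.0,
    models=RANKING_MODELS,
) -> MPHSummary:
    """Mean |MPH| (%) per genetic model over full-factorial hybrid populations."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    children = np.random.SeedSequence(seed).spawn(len(models))
    rows = []
    hybrids = None
    for name, child in zip(models, children):
        gmap, design, model = preset_experiment(name, mu=mu, sigma2_e=sigma2_e)
        a, b = design.a, design.b
        hybrids = a * b
        rng = np.random.default_rng(child)
        means_abs, means_signed = [], []
        for _ in range(replicates):
            _, _, _, _, F, y_par, _ = _replicate_population(gmap, design, model, rng)
            MPH = combining.mph_matrix(F, y_par[:a], y_par[a:])
            means_abs.append(float(np.mean(np.abs(MPH))))
            means_signed.append(float(np.mean(MPH)))
        rows.append({
            "model": name,
            "mean_abs_mph": float(np.mean(means_abs)),
            "mean_mph": float(np.mean(means_signed)),
        })
    return MPHSummary(replicates, hybrids, pd.DataFrame(rows))


def run_proportion_study(
    t_values=(1, 2, 3, 4, 5, 6, 7, 15),
    replicates: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    hyper: tuple[float, float] = eblasso.DEFAULT_HYPER,
    relaxed_cm: float = 10.0,
) -> pd.DataFrame:
    """Power and effect deviation per effect type across mating strategies.

    The mapping population mixes the parents with the F1 subset; the trait
    phenotype is the dependent variable.
    """
    frames = []
    ss = np.random.SeedSequence(seed).spawn(len(t_values))
    for t, child in zip(t_values, ss):
        seed_t = int(child.generate_state(1)[0] % (2**31))
        report = run_power_study(
            "proportion", "mixed", replicates=replicates, seed=seed_t,
            alpha=alpha, hyper=hyper, relaxed_cm=relaxed_cm, t=t,
        )
        _, design, _ = preset_experiment("proportion", t=t)
        tab = report.table.copy()
        tab.insert(0, "t", t)
        tab.insert(1, "proportion", f1_proportion(design))
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# report figures
# ---------------------------------------------------------------------------

def plot_power(report: PowerReport, path) -> None:
    """Bar chart of per-QTL power, grouped by heritability."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = report.table
    fig, ax = plt.subplots(figsize=(7, 4))
    colors = {0.05: "0.7", 0.10: "0.45", 0.15: "0.1"}
    ax.bar(range(len(tab)), 100 * tab["power"],
           color=[colors.get(h, "0.5") for h in tab["h2"]])
    ax.set_xticks(range(len(tab)), tab["term"], rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("power (%)")
    ax.set_title(f"preset {report.preset}, dependent variable {report.kind}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_proportion(table: pd.DataFrame, path) -> None:
    """Power vs F1 proportion, one line per effect type."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    for etype, grp in table.groupby("type"):
        grp = grp.sort_values("proportion")
        ax1.plot(grp["proportion"], 100 * grp["power"], marker="o", label=etype)
        ax2.plot(grp["proportion"], grp["mean_abs_dev"], marker="o", label=etype)
    ax1.set_xlabel("F1 proportion (%)")
    ax1.set_ylabel("power (%)")
    ax2.set_xlabel("F1 proportion (%)")
    ax2.set_ylabel("mean |estimate - truth|")
    ax1.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
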