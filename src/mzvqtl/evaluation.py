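"""Simulation study of the six twin variance-QTL models.

Runs the coefficient grid (additive weight a_G x interaction weight a_GxE,
with the error weight fixed at 0.2 and the environmental weight absorbing
the remainder) across noise laws and methylation scales, and tabulates how
often each model declares the genotype term nominally significant.  That
frequency is the false positive rate in cells without an interaction and
the discovery rate in cells with one.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import ols_fit
from .simulate import SimulationConfig, simulate_covariates, simulate_genotype, simulate_methylation
from .twin_models import TWINS_MODELS, VQTLTestResult, fit_twins_model, residualize_arrays

__all__ = [
    "FULL_GRID_VALUES",
    "CI_GRID",
    "full_grid",
    "run_cell",
    "run_grid",
    "compare_models",
    "bartlett_comparator",
]

#: canonical weight-grid values for both a_G and a_GxE
FULL_GRID_VALUES = (0, 0.005, 0.01, 0.03, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4)

#: reduced grid for routine runs
CI_GRID = tuple((a_g, a_gxe) for a_g in (0.0, 0.1, 0.3) for a_gxe in (0.0, 0.05, 0.1, 0.2))

A_ERROR = 0.2
ALPHA = 0.05


def full_grid():
    """All feasible (a_G, a_GxE) cells of the full evaluation grid."""
    cells = []
    for a_g in FULL_GRID_VALUES:
        for a_gxe in FULL_GRID_VALUES:
            if 1.0 - a_g - a_gxe - A_ERROR >= -1e-9:
                cells.append((a_g, a_gxe))
    return cells


def run_cell(
    a_g: float,
    a_gxe: float,
    noise_law: str = "normal",
    scale: str = "beta",
    n_pairs: int = 350,
    n_reps: int = 1000,
    seed=0,
    maf: float = 0.3,
    alpha: float = ALPHA,
    models=TWINS_MODELS,
) -> pd.DataFrame:
    """Replicate loop for one grid cell; returns per-model discovery rates.

    Each replicate draws a fresh cohort (covariates, one HWE genotype with
    the >=5-pairs-per-group constraint, methylation from the weighted
    four-component model), residualizes the within-pair difference and mean,
    and fits the requested models.  Rates carry their binomial Monte-Carlo
    standard error sqrt(r(1-r)/n_reps).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfg = SimulationConfig(n_pairs=n_pairs, a_g=a_g, a_gxe=a_gxe,
                           noise_law=noise_law, scale=scale, maf=maf)
    rng = np.random.default_rng(seed if isinstance(seed, np.random.SeedSequence)
                                else np.random.SeedSequence(seed))
    hits = {m: 0 for m in models}
    valid = {m: 0 for m in models}
    for _ in range(n_reps):
        cov = simulate_covariates(n_pairs, rng)
        g = simulate_genotype(n_pairs, maf, rng)
        y, _ = simulate_methylation(cfg, g, cov, rng)
        res_abs, res_mean = residualize_arrays(y, cov)
        for m in models:
            try:
                r = fit_twins_model(m, res_abs, res_mean, g)
            except ValueError:
                continue
            valid[m] += 1
            if r.p < alpha:
                hits[m] += 1
    rows = []
    for m in models:
        nv = valid[m]
        rate = hits[m] / nv if nv else np.nan
        rows.append({
            "a_g": a_g, "a_gxe": a_gxe, "noise_law": noise_law, "scale": scale,
            "model": m, "n_reps": nv,
            "discovery_rate": rate,
            "mc_se": np.sqrt(rate * (1 - rate) / nv) if nv else np.nan,
        })
    return pd.DataFrame(rows)


def run_grid(
    grid=CI_GRID,
    noise_laws=("normal",),
    scales=("beta",),
    n_pairs: int = 350,
    n_reps: int = 200,
    seed: int = 0,
    maf: float = 0.3,
    models=TWINS_MODELS,
) -> pd.DataFrame:
    """Evaluate every feasible (a_G, a_GxE) cell x noise law x scale.

    Infeasible cells (environmental weight would go negative) are skipped
    with a warning.  Per-cell seeds are spawned deterministically from the
    master seed, so results do not depend on execution order.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    frames = []
    cell_idx = 0
    for noise_law in noise_laws:
        for scale in scales:
            for a_g, a_gxe in grid:
                cell_seed = np.random.SeedSequence([int(seed), cell_idx])
                cell_idx += 1
                if 1.0 - a_g - a_gxe - A_ERROR < -1e-9:
                    warnings.warn(
                        f"skipping infeasible cell a_G={a_g}, a_GxE={a_gxe}: "
                        "environmental weight would be negative")
                    continue
                frames.append(run_cell(a_g, a_gxe, noise_law, scale,
                                       n_pairs=n_pairs, n_reps=n_reps,
                                       seed=cell_seed, maf=maf, models=models))
    return pd.concat(frames, ignore_index=True)


def compare_models(table: pd.DataFrame, alpha: float = ALPHA) -> pd.DataFrame:
    """Findings report over an evaluation table.

    Emits one row per finding: null-cell calibration flags per model
    ("calibrated" if the rate is within 3 Monte-Carlo SE of alpha,
    "inflated" otherwise), Twins1-vs-Twins2 rate comparisons in
    low-interaction cells, and a monotonicity check of the discovery rate in
    a_GxE per model.
    """
    rows = []
    # every a_GxE = 0 cell is a false-positive-rate cell, whatever a_G is
    null_cells = table[table.a_gxe == 0]
    for _, r in null_cells.iterrows():
        bound = alpha + 3 * np.sqrt(alpha * (1 - alpha) / r.n_reps)
        rows.append({
            "finding": "null_calibration", "model": r.model,
            "noise_law": r.noise_law, "scale": r.scale, "a_g": r.a_g,
            "value": r.discovery_rate,
            "flag": "calibrated" if r.discovery_rate <= bound else "inflated",
        })
    low = table[(table.a_gxe > 0) & (table.a_gxe <= 0.1)]
    for (a_g, a_gxe, noise, scale), grp in low.groupby(
            ["a_g", "a_gxe", "noise_law", "scale"]):
        t1 = grp[grp.model == "Twins1"]
        t2 = grp[grp.model == "Twins2"]
        if len(t1) and len(t2):
            r1, r2 = float(t1.discovery_rate.iloc[0]), float(t2.discovery_rate.iloc[0])
            se = float(np.hypot(t1.mc_se.iloc[0], t2.mc_se.iloc[0]))
            rows.append({
                "finding": "twins1_vs_twins2", "model": "Twins1-Twins2",
                "noise_law": noise, "scale": scale, "value": r1 - r2,
                "flag": "twins1_ge" if r1 >= r2 - 2 * se else "twins2_higher",
            })
    for (model, a_g, noise, scale), grp in table[table.model.isin(
            ("Twins1", "Twins2"))].groupby(["model", "a_g", "noise_law", "scale"]):
        grp = grp.sort_values("a_gxe")
        if len(grp) < 2:
            continue
        rates = grp.discovery_rate.to_numpy()
        ses = grp.mc_se.to_numpy()
        ok = all(rates[i + 1] >= rates[i] - 2 * np.hypot(ses[i], ses[i + 1])
                 for i in range(len(rates) - 1))
        rows.append({
            "finding": "monotone_in_a_gxe", "model": model, "noise_law": noise,
            "scale": scale, "value": float(rates[-1] - rates[0]),
            "flag": "monotone" if ok else "non-monotone",
        })
    return pd.DataFrame(rows)


def bartlett_comparator(phenotype: np.ndarray, genotype: np.ndarray) -> VQTLTestResult:
    """Bartlett's equal-variance test across genotype groups.

    Included only as a comparator: it is the classical vQTL test whose false
    positive rate inflates badly under non-normal phenotypes, which the twin
    difference models are designed to avoid.
    """
    y = np.asarray(phenotype, dtype=float)
    g = np.round(np.asarray(genotype, dtype=float)).astype(int)
    groups = [y[g == k] for k in np.unique(g)]
    if len(groups) < 2 or any(gr.size < 2 for gr in groups):
        raise ValueError("Bartlett comparator needs >= 2 groups with >= 2 "
                         "observations each")
    stat, p = stats.bartlett(*groups)
    return VQTLTestResult("Bartlett", slope=np.nan, se=np.nan,
                          statistic=float(stat), p=float(p), n=int(y.size))
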