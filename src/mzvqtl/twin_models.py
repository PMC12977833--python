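"""Within-pair residualization and the six twin variance-QTL models.

The monozygotic-twin design turns variance detection into a mean problem:
co-twins share genotype and age, so the covariate-adjusted absolute
methylation difference |twin1 - twin2| carries the variance signal, while
the within-pair mean carries the ordinary mean-QTL signal.  Six regression
forms (Twins1..Twins6) relate the residualized difference — raw, squared,
ratio to the mean residual, or with the mean residual as covariate — to
genotype dosage:

    Twins1:  res(abs)              ~ G
    Twins2:  res(abs)^2            ~ G
    Twins3:  res(abs)/res(mean)    ~ G
    Twins4:  res(abs)^2/res(mean)^2~ G
    Twins5:  res(abs)              ~ G + res(mean)
    Twins6:  res(abs)^2            ~ G + res(mean)

plus the companion mean-QTL test res(mean) ~ G.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from ._stats import ols_fit, ols_residuals
from .simulate import TwinPairCohort

__all__ = [
    "TWINS_MODELS",
    "VQTLTestResult",
    "pair_difference",
    "pair_mean",
    "residualize_difference",
    "residualize_mean",
    "fit_twins_model",
    "fit_meqtl",
    "refit_conditional_on_meqtl",
    "results_to_frame",
]

TWINS_MODELS = ("Twins1", "Twins2", "Twins3", "Twins4", "Twins5", "Twins6")

MIN_USABLE_PAIRS = 10


@dataclass
class VQTLTestResult:
    """Genotype-slope test from one model on one SNP-CpG combination."""

    model_id: str
    slope: float
    se: float
    statistic: float
    p: float
    n: int
    n_dropped: int = 0
    cpg: Optional[str] = None
    snp: Optional[str] = None


def pair_difference(y: np.ndarray) -> np.ndarray:
    """|twin1 - twin2| per pair from a pair-major individual vector."""
    y = np.asarray(y, dtype=float)
    return np.abs(y[0::2] - y[1::2])


def pair_mean(y: np.ndarray) -> np.ndarray:
    """(twin1 + twin2)/2 per pair from a pair-major individual vector."""
    y = np.asarray(y, dtype=float)
    return (y[0::2] + y[1::2]) / 2.0


def _pair_covariate_blocks(cov: pd.DataFrame, cohort_mode: bool,
                           cells: Optional[pd.DataFrame]):
    """Per-pair covariate pieces shared by the two residualizations.

    Returns (age, sex, bmi1, bmi2, smoke_discord, cell diffs/means, batch
    discord) with the cell/batch entries None in simulation mode.
    """
    age = cov["age"].to_numpy(dtype=float)[0::2]
    sex = cov["sex"].to_numpy(dtype=float)[0::2]
    bmi = cov["bmi"].to_numpy(dtype=float)
    smoking = cov["smoking"].to_numpy(dtype=float)
    diff_bmi = np.abs(bmi[0::2] - bmi[1::2])
    mean_bmi = (bmi[0::2] + bmi[1::2]) / 2.0
    # binary concordance indicator: 0 same status, 1 discordant
    diff_smoke = (smoking[0::2] != smoking[1::2]).astype(float)
    diff_cells = mean_cells = diff_batch = None
    if cohort_mode:
        if "batch" in cov.columns:
            batch = cov["batch"].to_numpy()
            diff_batch = (batch[0::2] != batch[1::2]).astype(float)
        if cells is not None:
            cv = cells.to_numpy(dtype=float)
            diff_cells = np.abs(cv[0::2] - cv[1::2])
            mean_cells = (cv[0::2] + cv[1::2]) / 2.0
    return age, sex, diff_bmi, mean_bmi, diff_smoke, diff_cells, mean_cells, diff_batch


def _check_complete(y: np.ndarray, label: str):
    if np.isnan(y).any():
        raise ValueError(f"missing values in {label}; probes with missing "
                         "values are excluded upstream")


def residualize_difference(
    cohort: TwinPairCohort, cpg: str, covariate_set: str = "simulation"
) -> np.ndarray:
    """Residualized intra-pair |difference| for one CpG.

    simulation mode adjusts for age, sex, diff(BMI) and the smoking
    discordance indicator; cohort mode additionally adjusts for per-pair
    cell-proportion differences and the batch discordance indicator.
    """
    y = cohort.methylation.loc[cpg].to_numpy(dtype=float)
    _check_complete(y, f"CpG {cpg}")
    d = pair_difference(y)
    X = _difference_design(cohort, covariate_set)
    return ols_residuals(X, d)


def residualize_mean(
    cohort: TwinPairCohort, cpg: str, covariate_set: str = "simulation"
) -> np.ndarray:
    """Residualized within-pair mean methylation for one CpG."""
    y = cohort.methylation.loc[cpg].to_numpy(dtype=float)
    _check_complete(y, f"CpG {cpg}")
    m = pair_mean(y)
    X = _mean_design(cohort, covariate_set)
    return ols_residuals(X, m)


def _difference_design(cohort: TwinPairCohort, covariate_set: str) -> np.ndarray:
    cohort_mode = covariate_set == "cohort"
    (age, sex, diff_bmi, _mean_bmi, diff_smoke,
     diff_cells, _mean_cells, diff_batch) = _pair_covariate_blocks(
        cohort.covariates, cohort_mode, cohort.cell_proportions)
    cols = [np.ones_like(age), age, sex, diff_bmi, diff_smoke]
    if cohort_mode:
        if diff_cells is not None:
            cols.extend(diff_cells.T)
        if diff_batch is not None:
            cols.append(diff_batch)
    return np.column_stack(cols)


def _mean_design(cohort: TwinPairCohort, covariate_set: str) -> np.ndarray:
    cohort_mode = covariate_set == "cohort"
    (age, sex, _diff_bmi, mean_bmi, diff_smoke,
     _diff_cells, mean_cells, diff_batch) = _pair_covariate_blocks(
        cohort.covariates, cohort_mode, cohort.cell_proportions)
    cols = [np.ones_like(age), age, sex, mean_bmi, diff_smoke]
    if cohort_mode:
        if mean_cells is not None:
            cols.extend(mean_cells.T)
        if diff_batch is not None:
            cols.append(diff_batch)
    return np.column_stack(cols)


# fast array-level entry points used by the simulation grids -----------------

def residualize_arrays(y: np.ndarray, covariates: pd.DataFrame):
    """(res_abs, res_mean) for a single simulated CpG given per-twin values.

    Same models as :func:`residualize_difference` / :func:`residualize_mean`
    in simulation mode, skipping the cohort container.
    """
    d = pair_difference(y)
    m = pair_mean(y)
    age = covariates["age"].to_numpy(dtype=float)[0::2]
    sex = covariates["sex"].to_numpy(dtype=float)[0::2]
    bmi = covariates["bmi"].to_numpy(dtype=float)
    smoking = covariates["smoking"].to_numpy(dtype=float)
    diff_bmi = np.abs(bmi[0::2] - bmi[1::2])
    mean_bmi = (bmi[0::2] + bmi[1::2]) / 2.0
    diff_smoke = (smoking[0::2] != smoking[1::2]).astype(float)
    ones = np.ones_like(age)
    X_abs = np.column_stack([ones, age, sex, diff_bmi, diff_smoke])
    X_mean = np.column_stack([ones, age, sex, mean_bmi, diff_smoke])
    return ols_residuals(X_abs, d), ols_residuals(X_mean, m)


def fit_twins_model(
    model_id: str,
    res_abs: np.ndarray,
    res_mean: np.ndarray | None,
    genotype: np.ndarray,
) -> VQTLTestResult:
    """Fit one of Twins1..Twins6 and return the genotype-slope test.

    Dosage is coded additively.  For the ratio models (Twins3/4) pairs with a
    zero mean residual are dropped and counted; fewer than 10 usable pairs is
    refused.  A constant genotype is a degenerate design and refused.
    """
    if model_id not in TWINS_MODELS:
        raise ValueError(f"unknown model {model_id!r}")
    res_abs = np.asarray(res_abs, dtype=float)
    g = np.asarray(genotype, dtype=float)
    if np.unique(g).size < 2:
        raise ValueError("genotype is constant: degenerate design")
    if model_id in ("Twins3", "Twins4", "Twins5", "Twins6"):
        if res_mean is None:
            raise ValueError(f"{model_id} requires res_mean")
        res_mean = np.asarray(res_mean, dtype=float)

    n_dropped = 0
    extra = None
    if model_id == "Twins1":
        y = res_abs
    elif model_id == "Twins2":
        y = res_abs**2
    elif model_id in ("Twins3", "Twins4"):
        keep = res_mean != 0
        n_dropped = int((~keep).sum())
        if keep.sum() < MIN_USABLE_PAIRS:
            raise ValueError(
                f"{model_id}: only {int(keep.sum())} usable pairs after "
                "dropping zero mean-residuals")
        if model_id == "Twins3":
            y = res_abs[keep] / res_mean[keep]
        else:
            y = res_abs[keep] ** 2 / res_mean[keep] ** 2
        g = g[keep]
        if np.unique(g).size < 2:
            raise ValueError("genotype constant among usable pairs")
    elif model_id == "Twins5":
        y, extra = res_abs, res_mean
    else:  # Twins6
        y, extra = res_abs**2, res_mean

    cols = [np.ones_like(g), g]
    if extra is not None:
        cols.append(extra)
    X = np.column_stack(cols)
    coef, se, t, p, _df, _r = ols_fit(X, y)
    return VQTLTestResult(model_id, float(coef[1]), float(se[1]), float(t[1]),
                          float(p[1]), n=int(y.size), n_dropped=n_dropped)


def fit_meqtl(res_mean: np.ndarray, genotype: np.ndarray) -> VQTLTestResult:
    """Mean-QTL test: residualized within-pair mean regressed on dosage."""
    g = np.asarray(genotype, dtype=float)
    if np.unique(g).size < 2:
        raise ValueError("genotype is constant: degenerate design")
    y = np.asarray(res_mean, dtype=float)
    X = np.column_stack([np.ones_like(g), g])
    coef, se, t, p, _df, _r = ols_fit(X, y)
    return VQTLTestResult("meQTL", float(coef[1]), float(se[1]), float(t[1]),
                          float(p[1]), n=int(y.size))


def adjust_for_meqtl(y: np.ndarray, genotype: np.ndarray) -> np.ndarray:
    """Remove the mean genotype effect from individual-level methylation.

    Mixed-model view: with a family random intercept and a pair-constant
    dosage, the fixed genotype slope is estimated between pairs; subtracting
    slope * G from each twin is the exact within-pair-preserving adjustment,
    so this fast path is equivalent to the REML fit for every downstream
    quantity that depends only on within-pair differences.
    """
    y = np.asarray(y, dtype=float)
    g_ind = np.repeat(np.asarray(genotype, dtype=float), 2)
    m = pair_mean(y)
    g = np.asarray(genotype, dtype=float)
    X = np.column_stack([np.ones_like(g), g])
    coef, *_ = np.linalg.lstsq(X, m, rcond=None)
    return y - coef[1] * g_ind


def refit_conditional_on_meqtl(
    cohort: TwinPairCohort, cpg: str, snp: str,
    covariate_set: str = "simulation",
) -> VQTLTestResult:
    """Re-test the variance signal after regressing out the mean-QTL effect.

    The individual-level methylation is adjusted for the SNP's mean effect
    (family-random-intercept model; see :func:`adjust_for_meqtl`), the
    intra-pair |difference| is recomputed and residualized, and Twins1 is
    refit against the dosage.  A SNP acting purely on the mean leaves the
    within-pair difference untouched, so surviving signal indicates genuine
    variance control.
    """
    y = cohort.methylation.loc[cpg].to_numpy(dtype=float)
    _check_complete(y, f"CpG {cpg}")
    g = cohort.genotypes.loc[snp].to_numpy(dtype=float)
    y_adj = adjust_for_meqtl(y, g)
    d = pair_difference(y_adj)
    X = _difference_design(cohort, covariate_set)
    res = ols_residuals(X, d)
    out = fit_twins_model("Twins1", res, None, g)
    out.cpg, out.snp = cpg, snp
    return out


def results_to_frame(results) -> pd.DataFrame:
    """Tidy table (cpg, snp, model, slope, se, stat, p, n, n_dropped)."""
    return pd.DataFrame(
        [
            {
                "cpg": r.cpg, "snp": r.snp, "model": r.model_id,
                "slope": r.slope, "se": r.se, "stat": r.statistic,
                "p": r.p, "n": r.n, "n_dropped": r.n_dropped,
            }
            for r in results
        ]
    )
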