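"""Two-stage gene-environment interaction testing at the individual-twin level.

Stage 1 removes relatedness (family random intercept), technical batch
(random intercept) and the environmental main effects other than the
modifier of interest from individual methylation; stage 2 regresses the
stage-1 residuals on dosage, the modifier, and their product, testing the
interaction slope.  Keeping the modifier of interest out of stage 1 is
essential — adjusting for it there would absorb part of the interaction.

Seven modifiers are supported: BMI, smoking, naive CD8 T cells, CD8 T
cells, granulocytes, monocytes, and the myeloid/lymphoid ratio (MLR).  MLR
is always excluded from stage 1; when MLR itself is the modifier, stage 1
adjusts for age, BMI, smoking and the four cell components instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from ._stats import bh_fdr, ols_fit, ols_residuals

__all__ = [
    "MODIFIERS",
    "InteractionResult",
    "compute_mlr",
    "stage1_residualize",
    "test_interaction",
    "fdr_adjust",
    "intersect_interactions",
]

MODIFIERS = ("BMI", "smoking", "naiveCD8T", "CD8T", "granulocytes",
             "monocytes", "MLR")

#: cell columns entering the MLR denominator
_MLR_DENOM = ("B", "CD8T", "CD4T", "NK")


@dataclass
class InteractionResult:
    cpg: Optional[str]
    snp: Optional[str]
    modifier: str
    beta_gxe: float
    se: float
    statistic: float
    p: float
    q: float = np.nan
    n: int = 0


def compute_mlr(cells: pd.DataFrame) -> pd.Series:
    """Myeloid/lymphoid ratio: monocytes / (B + CD8T + CD4T + NK).

    A zero denominator yields a missing value (logged) rather than an error.
    """
    required = ("monocytes",) + _MLR_DENOM
    missing = [c for c in required if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table lacks columns {missing}")
    if (cells[list(required)] < 0).any().any():
        raise ValueError("cell proportions must be nonnegative")
    denom = cells[list(_MLR_DENOM)].sum(axis=1)
    zero = denom == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} individuals with zero lymphoid "
                      "denominator: MLR set to missing")
    out = cells["monocytes"] / denom.where(~zero)
    out.name = "MLR"
    return out


def stage1_residualize(
    methylation: np.ndarray,
    family: np.ndarray,
    batch: np.ndarray,
    covariates: pd.DataFrame,
    exclude: set | str = frozenset(),
    method: str = "auto",
) -> np.ndarray:
    """Stage-1 conditional residuals of individual-level methylation.

    Fits methylation ~ (1|family) + (1|batch) + age + remaining covariates,
    with the modifier(s) in ``exclude`` (and always MLR) kept out of the
    fixed effects, and returns the conditional residuals — observed values
    minus fixed effects and predicted random intercepts.

    ``method='reml'`` fits crossed random intercepts by restricted maximum
    likelihood (variance components within a single super-group);
    ``method='demean'`` absorbs family and batch as fixed-effect dummies,
    the documented fallback which is also used automatically when the REML
    fit fails, degenerates, or every group is a singleton.
    """
    y = np.asarray(methylation, dtype=float)
    family = np.asarray(family)
    batch = np.asarray(batch)
    if isinstance(exclude, str):
        exclude = {exclude}
    exclude = set(exclude) | {"MLR"}
    bad = exclude & {"age"}
    if bad:
        raise ValueError("age is a stage-1 covariate, not a modifier")
    leak = [c for c in covariates.columns if c in exclude]
    if leak:
        raise ValueError(
            f"modifier-of-interest column(s) {leak} present in stage-1 "
            "covariates: would absorb the interaction signal")
    X = np.column_stack([np.ones(y.size)]
                        + [covariates[c].to_numpy(dtype=float)
                           for c in covariates.columns])

    singleton_fam = np.unique(family).size == family.size
    singleton_batch = np.unique(batch).size == batch.size
    if method == "demean" or (method == "auto" and singleton_fam and singleton_batch):
        return _demean_residuals(y, X, family, batch,
                                 singleton_fam, singleton_batch)
    try:
        return _reml_conditional_residuals(y, X, family, batch,
                                           singleton_fam, singleton_batch)
    except Exception as err:  # singular fit, convergence failure
        if method == "reml":
            raise
        warnings.warn(f"mixed fit failed ({err}); falling back to "
                      "fixed-effects demeaning")
        return _demean_residuals(y, X, family, batch,
                                 singleton_fam, singleton_batch)


def _demean_residuals(y, X, family, batch, singleton_fam, singleton_batch):
    cols = [X]
    if not singleton_fam:
        cols.append(pd.get_dummies(pd.Series(family), drop_first=True)
                    .to_numpy(dtype=float))
    if not singleton_batch:
        cols.append(pd.get_dummies(pd.Series(batch), drop_first=True)
                    .to_numpy(dtype=float))
    return ols_residuals(np.column_stack(cols), y)


def _reml_conditional_residuals(y, X, family, batch,
                                singleton_fam, singleton_batch):
    import statsmodels.api as sm

    vc = {}
    df = pd.DataFrame({"fam": family.astype(str), "batch": batch.astype(str)})
    if not singleton_fam:
        vc["fam"] = "0 + C(fam)"
    if not singleton_batch:
        vc["batch"] = "0 + C(batch)"
    if not vc:
        raise ValueError("no non-degenerate random effect")
    groups = np.zeros(y.size, dtype=int)  # single super-group: crossed design
    data = df.assign(y=y)
    for j in range(1, X.shape[1]):
        data[f"x{j}"] = X[:, j]
    fixed = "y ~ 1" + "".join(f" + x{j}" for j in range(1, X.shape[1]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = sm.MixedLM.from_formula(fixed, data=data, groups=groups,
                                     vc_formula=vc)
        fit = md.fit(reml=True)
    fe_pred = md.exog @ fit.fe_params
    # reconstruct the VC random-effect contribution Z @ b for the super-group
    re = fit.random_effects[0]
    zb = np.zeros(y.size)
    vcomp_names = list(md.exog_vc.names)
    offset = fit.k_re  # ordinary RE coefficients come first (none here)
    pos = offset
    for vi, name in enumerate(vcomp_names):
        mat = md.exog_vc.mats[vi][0]
        k = mat.shape[1]
        zb += np.asarray(mat) @ np.asarray(re[pos:pos + k])
        pos += k
    return y - fe_pred - zb


def test_interaction(
    residuals: np.ndarray,
    genotype: np.ndarray,
    modifier: np.ndarray,
    modifier_name: str = "E",
    cpg: Optional[str] = None,
    snp: Optional[str] = None,
) -> InteractionResult:
    """Stage-2 interaction test: residual ~ G + E + G:E, t-test on G:E."""
    y = np.asarray(residuals, dtype=float)
    g = np.asarray(genotype, dtype=float)
    e = np.asarray(modifier, dtype=float)
    if not (y.size == g.size == e.size):
        raise ValueError("vectors are not conformable")
    if np.unique(g).size < 2:
        raise ValueError("genotype is constant")
    if np.unique(e).size < 2:
        raise ValueError("modifier is constant")
    X = np.column_stack([np.ones_like(y), g, e, g * e])
    coef, se, t, p, _df, _r = ols_fit(X, y)
    return InteractionResult(cpg=cpg, snp=snp, modifier=modifier_name,
                             beta_gxe=float(coef[3]), se=float(se[3]),
                             statistic=float(t[3]), p=float(p[3]),
                             n=int(y.size))


def fdr_adjust(results, per_modifier: bool = False) -> pd.DataFrame:
    """BH-adjust interaction p-values; pooled across all tests by default."""
    df = pd.DataFrame([r.__dict__ for r in results]) if not isinstance(
        results, pd.DataFrame) else results.copy()
    if df.empty:
        df["q"] = []
        return df
    if per_modifier:
        df["q"] = df.groupby("modifier")["p"].transform(
            lambda s: bh_fdr(s.to_numpy()))
    else:
        df["q"] = bh_fdr(df["p"].to_numpy())
    return df


def intersect_interactions(results_a: pd.DataFrame, results_b: pd.DataFrame,
                           q_threshold: float = 0.05,
                           require_sign: bool = False) -> pd.DataFrame:
    """Interactions significant (q < threshold) in both cohorts.

    Matched on (cpg, snp, modifier); sign concordance of the interaction
    slope is only enforced when ``require_sign`` is set.
    """
    keys = ["cpg", "snp", "modifier"]
    a = results_a[results_a["q"] < q_threshold]
    b = results_b[results_b["q"] < q_threshold]
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"))
    if require_sign and not merged.empty:
        merged = merged[np.sign(merged["beta_gxe_a"])
                        == np.sign(merged["beta_gxe_b"])]
    return merged.reset_index(drop=True)
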