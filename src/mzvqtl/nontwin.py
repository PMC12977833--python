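"""Variance-QTL tests for unrelated individuals: DRM and SVLM.

Twin-free replication needs single-sample variance tests.  The deviation
regression model (DRM) regresses each sample's absolute distance from its
genotype group's median on the dosage; the squared-residual linear model
(SVLM) first removes the genetic mean effect and then regresses the squared
residuals on dosage.  Both reduce variance heterogeneity to a slope t-test
and are robust alternatives to Bartlett-type statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from ._stats import bh_fdr, ols_fit

__all__ = [
    "SingletonVQTLResult",
    "drm_test",
    "svlm_test",
    "joint_fdr_replication",
]


@dataclass
class SingletonVQTLResult:
    method: str
    slope: float
    se: float
    statistic: float
    p: float
    n: int
    genotype_group_sizes: tuple
    cpg: Optional[str] = None
    snp: Optional[str] = None


def _group_labels(genotype: np.ndarray) -> np.ndarray:
    """Hard genotype calls for grouping; the raw dosage stays the regressor."""
    return np.clip(np.round(np.asarray(genotype, dtype=float)), 0, 2).astype(int)


def _check_groups(labels: np.ndarray, min_per_group: int = 2):
    counts = np.bincount(labels, minlength=3)
    present = counts[counts > 0]
    if present.size < 2:
        raise ValueError("need >= 2 genotype groups")
    if present.min() < min_per_group:
        raise ValueError(
            f"each present genotype group needs >= {min_per_group} "
            f"observations, got counts {tuple(counts)}")
    return counts


def drm_test(phenotype: np.ndarray, genotype: np.ndarray,
             cpg=None, snp=None) -> SingletonVQTLResult:
    """Deviation regression model: |y - median(group)| ~ dosage.

    A constant phenotype gives all-zero deviations; the slope is 0 and p = 1
    by convention.
    """
    y = np.asarray(phenotype, dtype=float)
    g = np.asarray(genotype, dtype=float)
    labels = _group_labels(g)
    counts = _check_groups(labels)
    d = np.empty_like(y)
    for k in np.unique(labels):
        sel = labels == k
        d[sel] = np.abs(y[sel] - np.median(y[sel]))
    if np.all(d == 0):
        return SingletonVQTLResult("DRM", 0.0, np.nan, 0.0, 1.0, y.size,
                                   tuple(counts), cpg, snp)
    X = np.column_stack([np.ones_like(g), g])
    coef, se, t, p, *_ = ols_fit(X, d)
    return SingletonVQTLResult("DRM", float(coef[1]), float(se[1]),
                               float(t[1]), float(p[1]), int(y.size),
                               tuple(counts), cpg, snp)


def svlm_test(phenotype: np.ndarray, genotype: np.ndarray,
              cpg=None, snp=None) -> SingletonVQTLResult:
    """Squared-residual linear model.

    Stage 1 regresses the phenotype on dosage (removing the mean-QTL
    effect); stage 2 regresses the squared stage-1 residuals on dosage and
    tests that slope.  Pure mean shifts therefore do not register.
    """
    y = np.asarray(phenotype, dtype=float)
    g = np.asarray(genotype, dtype=float)
    labels = _group_labels(g)
    counts = _check_groups(labels)
    if np.unique(g).size < 2:
        raise ValueError("genotype is constant")
    X = np.column_stack([np.ones_like(g), g])
    _, _, _, _, _, resid = ols_fit(X, y)
    r2 = resid**2
    if np.all(r2 == r2[0]):
        return SingletonVQTLResult("SVLM", 0.0, np.nan, 0.0, 1.0, y.size,
                                   tuple(counts), cpg, snp)
    coef, se, t, p, *_ = ols_fit(X, r2)
    return SingletonVQTLResult("SVLM", float(coef[1]), float(se[1]),
                               float(t[1]), float(p[1]), int(y.size),
                               tuple(counts), cpg, snp)


def joint_fdr_replication(drm: pd.DataFrame, svlm: pd.DataFrame,
                          keys=("cpg", "snp"),
                          fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Associations replicating under FDR < threshold for BOTH methods.

    Each table gets its own BH adjustment over its own p-values; the result
    is the key intersection of the two significant sets.
    """
    keys = list(keys)
    out = []
    for df in (drm, svlm):
        df = df.copy()
        df["q"] = bh_fdr(df["p"].to_numpy()) if len(df) else []
        out.append(df[df["q"] < fdr_threshold])
    a, b = out
    if a.empty or b.empty:
        return a.iloc[0:0][keys]
    return a.merge(b, on=keys, suffixes=("_drm", "_svlm")).reset_index(drop=True)
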