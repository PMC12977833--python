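"""Fisher's-exact enrichment of QTL/CpG sets in genomic annotations.

Enrichment of a query set (e.g. replicated variance-QTL SNPs) within an
annotation (e.g. CpG islands) relative to a universe of tested loci, via the
two-tailed exact test on the 2x2 membership table, with a minimum-overlap
rule: annotations carrying fewer than ``min_signals`` query hits are
skipped rather than reported.  Families of related annotations can be
summarized with a harmonic-mean odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from ._stats import bh_fdr

__all__ = [
    "EnrichmentResult",
    "fisher_enrichment",
    "enrichment_table",
    "interval_overlap",
    "harmonic_mean_or",
]


@dataclass
class EnrichmentResult:
    annotation: str
    table: tuple                      # ((a, b), (c, d)) query x annotation
    or_estimate: float                # conditional MLE odds ratio
    or_sample: float                  # ad/bc, Haldane-corrected when a cell is 0
    ci95: tuple
    p: float
    q: float = np.nan
    skipped: bool = False
    reason: Optional[str] = None


def fisher_enrichment(query, annotation, universe,
                      min_signals: int = 10) -> EnrichmentResult:
    """Two-tailed Fisher's exact enrichment of ``query`` in ``annotation``.

    Both sets must be subsets of ``universe``.  The 2x2 table counts
    universe members by (in query) x (in annotation).  Annotations with
    fewer than ``min_signals`` overlapping query members are skipped, and
    degenerate margins (empty or full annotation/query) are flagged rather
    than tested.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query)
    annotation = set(annotation)
    if not query <= universe or not annotation <= universe:
        raise ValueError("query and annotation must be subsets of the universe")
    a = len(query & annotation)
    b = len(query - annotation)
    c = len(annotation - query)
    d = len(universe) - a - b - c
    table = ((a, b), (c, d))
    if a < min_signals:
        return EnrichmentResult("", table, np.nan, np.nan, (np.nan, np.nan),
                                np.nan, skipped=True,
                                reason=f"overlap {a} < min_signals {min_signals}")
    if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
        return EnrichmentResult("", table, np.nan, np.nan, (np.nan, np.nan),
                                np.nan, skipped=True, reason="degenerate margins")
    res = _odds_ratio([[a, b], [c, d]], kind="conditional")
    ci = res.confidence_interval(0.95)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        or_sample = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        or_sample = (a * d) / (b * c)
    return EnrichmentResult("", table, float(res.statistic), float(or_sample),
                            (float(ci.low), float(ci.high)), float(p))


def enrichment_table(query, annotations: dict, universe,
                     min_signals: int = 10) -> pd.DataFrame:
    """Run :func:`fisher_enrichment` over named annotations; BH-adjust p."""
    rows = []
    for name, ann in annotations.items():
        r = fisher_enrichment(query, ann, universe, min_signals=min_signals)
        r.annotation = name
        rows.append(r)
    df = pd.DataFrame([r.__dict__ for r in rows])
    tested = ~df["skipped"]
    df["q"] = np.nan
    if tested.any():
        df.loc[tested, "q"] = bh_fdr(df.loc[tested, "p"].to_numpy())
    return df


def interval_overlap(points, regions) -> np.ndarray:
    """Membership mask of (chrom, pos) points in half-open [start, end) regions."""
    regs = []
    for c, s, e in regions:
        if e < s:
            raise ValueError(f"malformed interval ({c}, {s}, {e})")
        regs.append((str(c), int(s), int(e)))
    mask = np.zeros(len(points), dtype=bool)
    for i, (chrom, pos) in enumerate(points):
        mask[i] = any(str(chrom) == c and s <= int(pos) < e for c, s, e in regs)
    return mask


def harmonic_mean_or(ors) -> float:
    """Harmonic mean of odds ratios: n / sum(1/OR_i)."""
    ors = np.asarray(list(ors), dtype=float)
    if ors.size == 0:
        raise ValueError("no odds ratios supplied")
    if np.any(ors <= 0):
        raise ValueError("odds ratios must be positive")
    return float(ors.size / np.sum(1.0 / ors))
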