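"""End-to-end twin variance-QTL pipeline on a multi-locus cohort.

Chains the stages the way the full analysis runs them: SNP/probe QC,
covariate residualization of the within-pair difference and mean,
permutation-calibrated cis scans for variance- and mean-QTLs, joint LD
clumping of the two signal types with the spurious-variance-call filter,
and the conditional refit that adjudicates SNPs carrying both signals.
Used by the synthetic-genome recovery analyses; real tabular inputs can be
assembled into the same cohort container via :mod:`mzvqtl.io`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import qtl, twin_models
from .simulate import TwinPairCohort

__all__ = ["run_cis_pipeline", "score_recovery"]


def run_cis_pipeline(
    cohort: TwinPairCohort,
    covariate_set: str = "simulation",
    window_bp: float = 1e6,
    n_perm: int = 2000,
    seed: int = 0,
    q_threshold: float = 0.05,
    clump_window_bp: float = 5e5,
    clump_r2: float = 0.2,
    refit_alpha: float = 0.05,
) -> dict:
    """QC -> residualize -> cis scans -> clump/spurious filter -> refit.

    Returns a dict with the QC report, both scan tables, the filtered
    variance-QTL calls, the discard audit, and the conditional-refit table
    for SNPs that were both mean- and variance-significant for a CpG.
    """
    keep_snps, snp_report = qtl.filter_snps(cohort.genotypes)
    genotypes = cohort.genotypes[keep_snps]
    keep_probes = qtl.filter_probes(cohort.methylation)
    cpgs = cohort.methylation.index[keep_probes]

    res_abs = pd.DataFrame(
        {c: twin_models.residualize_difference(cohort, c, covariate_set)
         for c in cpgs}).T
    res_mean = pd.DataFrame(
        {c: twin_models.residualize_mean(cohort, c, covariate_set)
         for c in cpgs}).T

    scan_v = qtl.cis_scan(res_abs, genotypes, cohort.snp_pos, cohort.cpg_pos,
                          window_bp=window_bp, n_perm=n_perm, seed=seed,
                          q_threshold=q_threshold)
    scan_m = qtl.cis_scan(res_mean, genotypes, cohort.snp_pos, cohort.cpg_pos,
                          window_bp=window_bp, n_perm=n_perm, seed=seed + 1,
                          q_threshold=q_threshold)

    vme = (scan_v[scan_v["significant"]]
           .rename(columns={"lead_snp": "snp", "p_true": "p"})
           [["cpg", "snp", "p"]].reset_index(drop=True))
    me = (scan_m[scan_m["significant"]]
          .rename(columns={"lead_snp": "snp", "p_true": "p"})
          [["cpg", "snp", "p"]].reset_index(drop=True))

    filtered, audit = qtl.remove_spurious_vmeqtls(
        vme, me, genotypes, cohort.snp_pos,
        window_bp=clump_window_bp, r2_threshold=clump_r2)

    # conditional refit adjudicates shared mean+variance SNPs
    refit_rows = []
    shared = audit[audit["action"] == "shared_snp_refit"]
    drop_after_refit = []
    for _, r in shared.iterrows():
        res = twin_models.refit_conditional_on_meqtl(
            cohort, r["cpg"], r["discarded_snp"], covariate_set)
        keep = res.p < refit_alpha
        refit_rows.append({"cpg": r["cpg"], "snp": r["discarded_snp"],
                           "p_conditional": res.p, "kept": keep})
        if not keep:
            drop_after_refit.append((r["cpg"], r["discarded_snp"]))
    if drop_after_refit:
        bad = filtered.apply(
            lambda row: (row["cpg"], row["snp"]) in set(drop_after_refit), axis=1)
        filtered = filtered[~bad].reset_index(drop=True)

    return {
        "snp_report": snp_report,
        "scan_vme": scan_v,
        "scan_me": scan_m,
        "vme_calls": filtered,
        "audit": audit,
        "refit": pd.DataFrame(refit_rows,
                              columns=["cpg", "snp", "p_conditional", "kept"]),
    }


def score_recovery(result: dict, truth: pd.DataFrame) -> dict:
    """Recovery metrics of the filtered variance-QTL calls against truth.

    ``recovered_vqtl`` is the fraction of loci simulated with an interaction
    effect (variance-only and dual classes) whose CpG keeps a variance call;
    ``false_vqtl`` is the fraction of mean-effect-only loci whose CpG is
    still called a variance-QTL after filtering.
    """
    called = set(result["vme_calls"]["cpg"])
    true_v = truth[truth["type"].isin(("vmeQTL", "dual"))]["cpg"]
    me_only = truth[truth["type"] == "meQTL"]["cpg"]
    return {
        "n_true_vqtl": int(len(true_v)),
        "n_me_only": int(len(me_only)),
        "recovered_vqtl": float(np.mean([c in called for c in true_v]))
        if len(true_v) else np.nan,
        "false_vqtl": float(np.mean([c in called for c in me_only]))
        if len(me_only) else np.nan,
    }
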