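"""QTL mapping: QC filters, permutation-calibrated cis/trans scans, LD
clumping, and removal of spurious variance signals.

The cis scan follows the permutation/beta-approximation scheme: for each CpG
the best nominal association over SNPs within the cis window is compared to
the distribution of per-permutation minimum p-values, summarized by a fitted
beta law whose CDF at the observed minimum gives a calibrated empirical
p-value; a Storey q-value across CpGs then sets the study-wide threshold.
The trans scan pools all out-of-window pairs and derives its significance
threshold from a small number of whole-matrix permutations via

    FDR(t) = (N_perm(p < t) / N_real(p < t)) / n_perm.

Variance-QTL calls that merely tag a strong mean-QTL are removed by joint LD
clumping of the two signal types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import corr_pvalues, storey_qvalue, bh_fdr

__all__ = [
    "ClumpSet",
    "filter_snps",
    "filter_probes",
    "cis_scan",
    "conditional_cis_scan",
    "trans_scan",
    "ld_clump",
    "remove_spurious_vmeqtls",
    "exclude_regions",
    "correlation_filter",
    "bonferroni_replicate",
    "hwe_pvalue",
]


# ---------------------------------------------------------------- QC filters

def hwe_pvalue(counts) -> float:
    """1-df chi-square goodness-of-fit p-value for Hardy-Weinberg proportions.

    ``counts`` are genotype counts (n_AA, n_Aa, n_aa) at the pair level.
    """
    n0, n1, n2 = (float(c) for c in counts)
    n = n0 + n1 + n2
    if n == 0:
        return 1.0
    p = (2 * n2 + n1) / (2 * n)
    exp = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * n
    obs = np.array([n0, n1, n2])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0))
    return float(stats.chi2.sf(chi2, df=1))


def filter_snps(
    genotypes: pd.DataFrame,
    hwe_alpha: float = 1e-6,
    maf_min: float = 0.05,
    min_group: int = 5,
) -> tuple[pd.Series, pd.DataFrame]:
    """SNP inclusion mask with per-SNP reason codes.

    Drops SNPs with Hardy-Weinberg p < 1e-6, minor allele frequency < 0.05,
    or fewer than ``min_group`` pairs in any of the three genotype groups.
    Dosages must be hard calls in {0, 1, 2}.
    """
    G = genotypes.to_numpy(dtype=float)
    if not np.all(np.isin(G, (0.0, 1.0, 2.0))):
        raise ValueError("filter_snps expects hard-call dosages in {0,1,2}")
    rows = []
    for snp, g in zip(genotypes.index, G):
        counts = np.bincount(g.astype(int), minlength=3)
        n = counts.sum()
        maf = (2 * counts[2] + counts[1]) / (2 * n)
        maf = min(maf, 1 - maf)
        hwe_p = hwe_pvalue(counts)
        reasons = []
        if hwe_p < hwe_alpha:
            reasons.append("hwe")
        if maf < maf_min:
            reasons.append("maf")
        if counts.min() < min_group:
            reasons.append("group_size")
        rows.append({"snp": snp, "maf": maf, "hwe_p": hwe_p,
                     "n0": counts[0], "n1": counts[1], "n2": counts[2],
                     "keep": not reasons, "reasons": ",".join(reasons)})
    report = pd.DataFrame(rows).set_index("snp")
    return report["keep"], report


def filter_probes(methylation: pd.DataFrame) -> pd.Series:
    """Keep a probe only if it has no missing values in any sample."""
    return ~methylation.isna().any(axis=1)


# -------------------------------------------------------- cis mapping helpers

def _standardize_rows(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    sd[sd == 0] = np.inf  # constant rows -> zero correlation with anything
    return (M - mu) / sd


def _fit_beta(perm_p: np.ndarray):
    """MLE beta fit (method-of-moments start); None when the fit fails."""
    perm_p = np.clip(perm_p, 1e-300, 1.0)
    m, v = perm_p.mean(), perm_p.var()
    if v <= 0 or not (0 < m < 1):
        return None
    common = m * (1 - m) / v - 1
    a0, b0 = max(m * common, 1e-3), max((1 - m) * common, 1e-3)
    try:
        a, b, _loc, _scale = stats.beta.fit(perm_p, a0, b0, floc=0, fscale=1)
        if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
            return None
        return a, b
    except Exception:
        return None


def _cis_pairs_mask(snp_pos: pd.DataFrame, cpg_pos: pd.DataFrame,
                    window_bp: float) -> np.ndarray:
    """Boolean (n_cpg x n_snp) mask of pairs within the cis window (inclusive)."""
    same_chrom = (cpg_pos["chrom"].to_numpy()[:, None]
                  == snp_pos["chrom"].to_numpy()[None, :])
    dist = np.abs(cpg_pos["pos"].to_numpy(dtype=float)[:, None]
                  - snp_pos["pos"].to_numpy(dtype=float)[None, :])
    return same_chrom & (dist <= window_bp)


def _scan_window(yz: np.ndarray, Gz_win: np.ndarray, n: int):
    """Best nominal association of one residual vector against window SNPs."""
    r = Gz_win @ yz / n
    p = corr_pvalues(r, n)
    best = int(np.argmin(p))
    return best, float(p[best]), p


def _perm_min_p(yz: np.ndarray, Gz_win: np.ndarray, n: int, n_perm: int,
                rng: np.random.Generator) -> np.ndarray:
    """Per-permutation minimum p over the window (pair-label permutations)."""
    perm = rng.permuted(np.broadcast_to(yz, (n_perm, n)).copy(), axis=1)
    R = perm @ Gz_win.T / n
    max_abs_r = np.abs(R).max(axis=1)
    return corr_pvalues(max_abs_r, n)


def cis_scan(
    residuals: pd.DataFrame,
    genotypes: pd.DataFrame,
    snp_pos: pd.DataFrame,
    cpg_pos: pd.DataFrame,
    window_bp: float = 1e6,
    n_perm: int = 10_000,
    seed: int = 0,
    q_threshold: float = 0.05,
    qvalue_method: str = "storey",
) -> pd.DataFrame:
    """Per-CpG cis scan with permutation/beta-approximated empirical p-values.

    ``residuals`` holds the covariate-adjusted per-pair response for each CpG
    (the |difference| residuals for a variance scan, the mean residuals for a
    mean scan); ``genotypes`` the pair-level dosages.  For each CpG the
    pair-label permutation null of the window-minimum p-value is summarized
    by a fitted beta distribution; ``p_beta`` is its CDF at the observed
    minimum.  Storey q-values across CpGs define significance, and each
    tested CpG receives the nominal threshold implied by the q-crossing
    (its beta quantile), reported as ``nominal_threshold``.
    """
    snp_pos = (snp_pos.set_index("snp").loc[genotypes.index]
               .rename_axis("snp").reset_index())
    cpg_pos = (cpg_pos.set_index("cpg").loc[residuals.index]
               .rename_axis("cpg").reset_index())
    n = residuals.shape[1]
    Y = residuals.to_numpy(dtype=float)
    G = genotypes.to_numpy(dtype=float)
    Gz = _standardize_rows(G)
    cis_mask = _cis_pairs_mask(snp_pos, cpg_pos, window_bp)
    master = np.random.SeedSequence(seed)

    rows = []
    for i, cpg in enumerate(residuals.index):
        in_win = np.flatnonzero(cis_mask[i])
        base = {"cpg": cpg, "lead_snp": None, "p_true": np.nan,
                "beta_shape1": np.nan, "beta_shape2": np.nan,
                "p_beta": np.nan, "n_snps": int(in_win.size),
                "status": "untested"}
        if in_win.size == 0:
            rows.append(base)
            continue
        y = Y[i]
        sd = y.std()
        if sd == 0:
            rows.append(base | {"status": "degenerate"})
            continue
        yz = (y - y.mean()) / sd
        Gw = Gz[in_win]
        best, p_true, _ = _scan_window(yz, Gw, n)
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        perm_p = _perm_min_p(yz, Gw, n, n_perm, rng)
        fit = _fit_beta(perm_p)
        if fit is None:
            # degenerate permutation distribution: empirical rank fallback
            p_beta = (1 + np.sum(perm_p <= p_true)) / (n_perm + 1)
            status = "empirical_fallback"
            a = b = np.nan
        else:
            a, b = fit
            p_beta = float(stats.beta.cdf(p_true, a, b))
            status = "ok"
        rows.append(base | {
            "lead_snp": genotypes.index[in_win[best]], "p_true": p_true,
            "beta_shape1": a, "beta_shape2": b, "p_beta": p_beta,
            "status": status,
        })
    out = pd.DataFrame(rows)

    tested = out["p_beta"].notna()
    qfun = storey_qvalue if qvalue_method == "storey" else bh_fdr
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = qfun(out.loc[tested, "p_beta"].to_numpy())
    out["significant"] = tested & (out["q"] < q_threshold)

    pt = _pbeta_crossing(out.loc[tested, "p_beta"].to_numpy(),
                         out.loc[tested, "q"].to_numpy(), q_threshold)
    out.attrs["p_beta_threshold"] = pt
    out["nominal_threshold"] = np.nan
    if pt is not None:
        ok = tested & out["beta_shape1"].notna()
        out.loc[ok, "nominal_threshold"] = stats.beta.ppf(
            pt, out.loc[ok, "beta_shape1"], out.loc[ok, "beta_shape2"])
    return out


def _pbeta_crossing(p_beta: np.ndarray, q: np.ndarray, q_threshold: float):
    """Empirical p_beta value at which the q-value crosses the threshold.

    Linear interpolation in q between the last significant and the first
    non-significant sorted p_beta; None when nothing is significant, the
    maximum p_beta when everything is.
    """
    if p_beta.size == 0:
        return None
    order = np.argsort(p_beta)
    pb, qq = p_beta[order], q[order]
    sig = qq < q_threshold
    if not sig.any():
        return None
    last = int(np.max(np.flatnonzero(sig)))
    if last == pb.size - 1:
        return float(pb[-1])
    p_lo, p_hi = pb[last], pb[last + 1]
    q_lo, q_hi = qq[last], qq[last + 1]
    if q_hi == q_lo:
        return float((p_lo + p_hi) / 2)
    return float(p_lo + (q_threshold - q_lo) * (p_hi - p_lo) / (q_hi - q_lo))


def conditional_cis_scan(
    cis_results: pd.DataFrame,
    residuals: pd.DataFrame,
    genotypes: pd.DataFrame,
    snp_pos: pd.DataFrame,
    cpg_pos: pd.DataFrame,
    window_bp: float = 1e6,
    n_perm: int = 10_000,
    seed: int = 1,
) -> pd.DataFrame:
    """Single forward conditional step for CpGs with a significant lead SNP.

    The lead dosage is regressed out of the CpG's residual vector and the
    window (minus the lead) rescanned with the same permutation scheme; a
    secondary signal is reported when its beta-approximated p falls below
    the study's p_beta crossing threshold from the primary scan.
    """
    pt = cis_results.attrs.get("p_beta_threshold")
    sig = cis_results[cis_results["significant"]]
    snp_pos_idx = snp_pos.set_index("snp")
    cpg_pos_idx = cpg_pos.set_index("cpg")
    n = residuals.shape[1]
    rows = []
    for k, (_, row) in enumerate(sig.iterrows()):
        cpg, lead = row["cpg"], row["lead_snp"]
        g_lead = genotypes.loc[lead].to_numpy(dtype=float)
        if np.unique(g_lead).size < 2:
            raise ValueError(f"lead SNP {lead} has constant dosage")
        y = residuals.loc[cpg].to_numpy(dtype=float)
        X = np.column_stack([np.ones(n), g_lead])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        y2 = y - X @ coef
        cpos = cpg_pos_idx.loc[cpg]
        win = snp_pos_idx[(snp_pos_idx["chrom"] == cpos["chrom"])
                          & (np.abs(snp_pos_idx["pos"] - cpos["pos"]) <= window_bp)]
        win = win[win.index != lead]
        if win.empty or y2.std() == 0:
            continue
        yz = (y2 - y2.mean()) / y2.std()
        Gw = _standardize_rows(genotypes.loc[win.index].to_numpy(dtype=float))
        best, p_true, _ = _scan_window(yz, Gw, n)
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        perm_p = _perm_min_p(yz, Gw, n, n_perm, rng)
        fit = _fit_beta(perm_p)
        if fit is None:
            p_beta = (1 + np.sum(perm_p <= p_true)) / (n_perm + 1)
        else:
            p_beta = float(stats.beta.cdf(p_true, *fit))
        rows.append({"cpg": cpg, "lead_snp": lead,
                     "secondary_snp": win.index[best], "p_true": p_true,
                     "p_beta": p_beta,
                     "significant": pt is not None and p_beta < pt})
    return pd.DataFrame(rows, columns=["cpg", "lead_snp", "secondary_snp",
                                       "p_true", "p_beta", "significant"])


# ------------------------------------------------------------- trans mapping

def trans_scan(
    residuals: pd.DataFrame,
    genotypes: pd.DataFrame,
    snp_pos: pd.DataFrame,
    cpg_pos: pd.DataFrame,
    window_bp: float = 1e6,
    n_perm: int = 20,
    seed: int = 0,
    fdr_threshold: float = 0.05,
    clump_window_bp: float = 5e5,
    clump_r2: float = 0.2,
):
    """Distal (trans) scan with a permutation-count FDR threshold.

    Trans pairs are all SNP-CpG pairs outside the cis window (different
    chromosome, or same chromosome farther than ``window_bp``).  The p-value
    threshold is the largest observed p-value t with

        FDR(t) = (N(p_perm < t) / N(p_real < t)) / n_perm <= fdr_threshold,

    where the permutation pool aggregates ``n_perm`` whole-matrix pair-label
    permutations.  Significant trans SNPs are LD-clumped per CpG so a single
    index SNP represents each locus.
    """
    snp_pos = (snp_pos.set_index("snp").loc[genotypes.index]
               .rename_axis("snp").reset_index())
    cpg_pos = (cpg_pos.set_index("cpg").loc[residuals.index]
               .rename_axis("cpg").reset_index())
    n = residuals.shape[1]
    Yz = _standardize_rows(residuals.to_numpy(dtype=float))
    Gz = _standardize_rows(genotypes.to_numpy(dtype=float))
    trans_mask = ~_cis_pairs_mask(snp_pos, cpg_pos, window_bp)

    def _pool(Ymat):
        R = Ymat @ Gz.T / n
        return corr_pvalues(R, n)[trans_mask]

    real_p = _pool(Yz)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    perm_pool = np.concatenate([
        _pool(Yz[:, rng.permutation(n)]) for _ in range(n_perm)
    ])

    real_sorted = np.sort(real_p)
    perm_sorted = np.sort(perm_pool)
    n_real = np.arange(1, real_sorted.size + 1, dtype=float)
    n_perm_le = np.searchsorted(perm_sorted, real_sorted, side="right")
    fdr = (n_perm_le / n_real) / n_perm
    ok = fdr <= fdr_threshold
    threshold = float(real_sorted[np.max(np.flatnonzero(ok))]) if ok.any() else np.nan

    pairs = pd.DataFrame(columns=["cpg", "snp", "p", "is_index"])
    if np.isfinite(threshold):
        ci, si = np.nonzero(trans_mask)
        P = np.full(trans_mask.shape, np.nan)
        P[trans_mask] = real_p
        hit = trans_mask & (P <= threshold)
        ci, si = np.nonzero(hit)
        pairs = pd.DataFrame({
            "cpg": residuals.index.to_numpy()[ci],
            "snp": genotypes.index.to_numpy()[si],
            "p": P[ci, si],
        })
        pairs["is_index"] = False
        for cpg, grp in pairs.groupby("cpg"):
            clumps = ld_clump(grp["snp"].tolist(),
                              grp.set_index("snp")["p"],
                              genotypes, snp_pos,
                              window_bp=clump_window_bp, r2_threshold=clump_r2)
            idx_snps = {c["index_snp"] for c in clumps.clumps}
            pairs.loc[(pairs["cpg"] == cpg) & pairs["snp"].isin(idx_snps),
                      "is_index"] = True
    return {"threshold": threshold, "pairs": pairs,
            "n_real": int(real_p.size), "n_perm": n_perm}


# ---------------------------------------------------------------- clumping

@dataclass
class ClumpSet:
    """Greedy LD clumps: each clump holds an index SNP and its tagged members."""

    clumps: list = field(default_factory=list)
    window_bp: float = 5e5
    r2_threshold: float = 0.2

    def assignment(self) -> dict:
        """member SNP -> index SNP map (indexes map to themselves)."""
        out = {}
        for c in self.clumps:
            for m in c["members"]:
                out[m] = c["index_snp"]
        return out


def ld_clump(
    snps,
    pvalues: pd.Series,
    genotypes: pd.DataFrame,
    positions: pd.DataFrame,
    window_bp: float = 5e5,
    r2_threshold: float = 0.2,
) -> ClumpSet:
    """Greedy LD clumping by p-value.

    Repeatedly takes the smallest-p unassigned SNP as an index and assigns
    every unassigned SNP within ``window_bp`` whose squared dosage
    correlation with the index reaches ``r2_threshold``.  Ties in p are
    broken by (chromosome, position, id) so the result is deterministic.
    """
    snps = list(snps)
    pos = positions.set_index("snp").loc[snps]
    G = genotypes.loc[snps].to_numpy(dtype=float)
    order = sorted(
        range(len(snps)),
        key=lambda i: (float(pvalues[snps[i]]), str(pos["chrom"].iloc[i]),
                       int(pos["pos"].iloc[i]), snps[i]),
    )
    assigned = np.zeros(len(snps), dtype=bool)
    clumps = []
    for i in order:
        if assigned[i]:
            continue
        assigned[i] = True
        members, r2s = [snps[i]], [1.0]
        for j in range(len(snps)):
            if assigned[j]:
                continue
            if pos["chrom"].iloc[j] != pos["chrom"].iloc[i]:
                continue
            if abs(int(pos["pos"].iloc[j]) - int(pos["pos"].iloc[i])) > window_bp:
                continue
            gi, gj = G[i], G[j]
            if gi.std() == 0 or gj.std() == 0:
                continue
            r2 = float(np.corrcoef(gi, gj)[0, 1] ** 2)
            if r2 >= r2_threshold:
                assigned[j] = True
                members.append(snps[j])
                r2s.append(r2)
        clumps.append({"index_snp": snps[i], "members": members, "r2": r2s})
    return ClumpSet(clumps=clumps, window_bp=window_bp, r2_threshold=r2_threshold)


def remove_spurious_vmeqtls(
    vme: pd.DataFrame,
    me: pd.DataFrame,
    genotypes: pd.DataFrame,
    positions: pd.DataFrame,
    window_bp: float = 5e5,
    r2_threshold: float = 0.2,
    exempt_shared_snps: bool = True,
):
    """Discard variance-QTL calls that tag a stronger mean-QTL in LD.

    For each CpG carrying both signal types, the union of its variance-QTL
    and mean-QTL SNPs is jointly LD-clumped; when the most significant
    signal in a clump is a mean-QTL, the variance-QTL members of that clump
    are discarded.  A SNP that is itself both a mean- and a variance-QTL for
    the CpG is exempt (``exempt_shared_snps``): such dual signals are
    resolved downstream by the conditional refit
    (:func:`mzvqtl.twin_models.refit_conditional_on_meqtl`) rather than
    discarded outright; the audit log marks them ``shared_snp_refit``.  Run
    separately for each cis/trans combination by passing the corresponding
    result tables.  Returns (filtered vme table, audit log).
    """
    for df, name in ((vme, "vme"), (me, "me")):
        missing = {"cpg", "snp", "p"} - set(df.columns)
        if missing:
            raise ValueError(f"{name} table lacks columns {missing}")
    audit = []
    keep_mask = np.ones(len(vme), dtype=bool)
    vme = vme.reset_index(drop=True)
    for cpg, vgrp in vme.groupby("cpg"):
        mgrp = me[me["cpg"] == cpg]
        if mgrp.empty:
            continue
        best_p = {}
        kind = {}
        for _, r in pd.concat([vgrp.assign(_k="vme"), mgrp.assign(_k="me")]).iterrows():
            s, p = r["snp"], float(r["p"])
            if s not in best_p or p < best_p[s]:
                best_p[s] = p
            # a SNP that is both keeps both labels
            kind.setdefault(s, set()).add((r["_k"], p))
        snps = sorted(best_p)
        clumps = ld_clump(snps, pd.Series(best_p), genotypes, positions,
                          window_bp=window_bp, r2_threshold=r2_threshold)
        for c in clumps.clumps:
            records = [(k, p, s) for s in c["members"] for (k, p) in kind[s]]
            k_best, p_best, s_best = min(records, key=lambda t: (t[1], t[0], t[2]))
            if k_best != "me":
                continue
            for s in c["members"]:
                vme_rows = vgrp[vgrp["snp"] == s]
                kinds_s = {k for k, _ in kind[s]}
                shared = exempt_shared_snps and {"vme", "me"} <= kinds_s
                for ridx, r in vme_rows.iterrows():
                    if not shared:
                        keep_mask[ridx] = False
                    audit.append({"cpg": cpg, "discarded_snp": s,
                                  "vme_p": float(r["p"]),
                                  "dominating_me_snp": s_best,
                                  "me_p": p_best,
                                  "clump_index": c["index_snp"],
                                  "action": "shared_snp_refit" if shared
                                  else "discarded"})
    return vme[keep_mask].reset_index(drop=True), pd.DataFrame(
        audit, columns=["cpg", "discarded_snp", "vme_p",
                        "dominating_me_snp", "me_p", "clump_index", "action"])


# ---------------------------------------------------- small auxiliary filters

def exclude_regions(cpgs, cpg_pos: pd.DataFrame, regions) -> list:
    """Remove CpGs falling inside any half-open [start, end) interval.

    ``regions`` is an iterable of (chrom, start, end); a CpG at pos == end is
    retained.  Used to drop imprinted-region probes whose variance signal is
    parent-of-origin rather than gene-environment driven.
    """
    pos = cpg_pos.set_index("cpg")
    kept = []
    for cpg in cpgs:
        chrom, p = pos.loc[cpg, "chrom"], int(pos.loc[cpg, "pos"])
        inside = any(str(chrom) == str(c) and s <= p < e for c, s, e in regions)
        if not inside:
            kept.append(cpg)
    return kept


def correlation_filter(values_a, values_b, min_rho: float = 0.2):
    """Cross-platform consistency gate: keep iff Spearman rho >= min_rho."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need >= 3 paired complete observations")
    rho = float(stats.spearmanr(a, b).statistic)
    return rho >= min_rho, rho


def bonferroni_replicate(discovery: pd.DataFrame, replication: pd.DataFrame,
                         keys=("cpg", "snp"), alpha: float = 0.05) -> pd.DataFrame:
    """Associations replicating at strict Bonferroni over the tested set.

    m is the number of discovery associations present in the replication
    table; an association replicates iff its replication p < alpha/m
    (strictly — a p exactly on the boundary does not pass).
    """
    keys = list(keys)
    merged = discovery.merge(replication, on=keys, suffixes=("_disc", "_rep"))
    m = len(merged)
    if m == 0:
        return merged
    pcol = "p_rep" if "p_rep" in merged.columns else "p"
    return merged[merged[pcol] < alpha / m].reset_index(drop=True)
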