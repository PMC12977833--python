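"""QC, cis/trans mapping, clumping and spurious-filter tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mzvqtl import qtl, simulate, twin_models
from mzvqtl._stats import bh_fdr, corr_pvalues, storey_qvalue


def _geno_frame(rows, prefix="snp"):
    arr = np.asarray(rows, dtype=float)
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(len(arr))])


class TestFilterSnps:
    def test_full_disequilibrium_dropped(self):
        g = np.array([0] * 100 + [2] * 100, dtype=float)
        keep, rep = qtl.filter_snps(_geno_frame([g]))
        assert not keep.iloc[0]
        assert "hwe" in rep.reasons.iloc[0]
        assert rep.hwe_p.iloc[0] < 1e-6

    def test_good_snp_kept(self):
        rng = np.random.default_rng(1)
        g = simulate.simulate_genotype(350, 0.5, rng)
        keep, rep = qtl.filter_snps(_geno_frame([g]))
        assert keep.iloc[0] and rep.reasons.iloc[0] == ""

    def test_small_group_dropped(self):
        g = np.array([0] * 340 + [1] * 7 + [2] * 3, dtype=float)
        keep, rep = qtl.filter_snps(_geno_frame([g]))
        assert not keep.iloc[0]
        assert "group_size" in rep.reasons.iloc[0]

    def test_low_maf_dropped(self):
        g = np.array([0] * 330 + [1] * 15 + [2] * 5, dtype=float)
        keep, rep = qtl.filter_snps(_geno_frame([g]))
        assert "maf" in rep.reasons.iloc[0]

    def test_soft_calls_rejected(self):
        with pytest.raises(ValueError, match="hard-call"):
            qtl.filter_snps(_geno_frame([[0.5, 1.0, 2.0]]))


class TestFilterProbes:
    def test_missingness_rule(self):
        M = pd.DataFrame(np.ones((3, 10)))
        M.iloc[0, 4] = np.nan
        M.iloc[2] = np.nan
        keep = qtl.filter_probes(M)
        assert keep.tolist() == [False, True, False]


class TestCisScan:
    def test_beta_p_close_to_empirical_permutation_p(self, small_cohort):
        """Beta-approximated empirical p within 0.05 of a direct permutation
        oracle computed with an independent seed."""
        coh = small_cohort
        R = pd.DataFrame({c: twin_models.residualize_difference(coh, c)
                          for c in coh.methylation.index}).T
        scan = qtl.cis_scan(R, coh.genotypes, coh.snp_pos, coh.cpg_pos,
                            n_perm=2000, seed=1)
        n = R.shape[1]
        G = coh.genotypes.to_numpy()
        Gz = (G - G.mean(1, keepdims=True)) / G.std(1, keepdims=True)
        orng = np.random.default_rng(999)
        for i, cpg in enumerate(R.index):
            row = scan[scan.cpg == cpg].iloc[0]
            if row.status != "ok":
                continue
            y = R.loc[cpg].to_numpy()
            yz = (y - y.mean()) / y.std()
            mask = qtl._cis_pairs_mask(coh.snp_pos, coh.cpg_pos.iloc[[i]], 1e6)[0]
            Gw = Gz[mask]
            nperm = 3000
            perm = orng.permuted(np.broadcast_to(yz, (nperm, n)).copy(), axis=1)
            pm = corr_pvalues(np.abs(perm @ Gw.T / n).max(axis=1), n)
            emp = (1 + np.sum(pm <= row.p_true)) / (nperm + 1)
            assert abs(emp - row.p_beta) <= 0.05

    def test_null_p_beta_uniform(self):
        """Across null CpGs the beta-approximated p must be uniform."""
        coh = simulate.simulate_cohort_genome(
            n_pairs=120, n_snps=30, n_cpgs=60, ld_block_size=1,
            frac_me_only=0, frac_v_only=0, frac_dual=0, seed=31)
        R = pd.DataFrame({c: twin_models.residualize_difference(coh, c)
                          for c in coh.methylation.index}).T
        scan = qtl.cis_scan(R, coh.genotypes, coh.snp_pos, coh.cpg_pos,
                            n_perm=1000, seed=2)
        pb = scan[scan.status == "ok"].p_beta
        assert stats.kstest(pb, "uniform").pvalue > 0.01

    def test_untested_cpg_without_window_snps(self, small_cohort):
        coh = small_cohort
        cpg_pos = coh.cpg_pos.copy()
        cpg_pos.loc[0, "chrom"] = "99"  # no SNP on that chromosome
        R = pd.DataFrame({c: twin_models.residualize_difference(coh, c)
                          for c in coh.methylation.index}).T
        scan = qtl.cis_scan(R, coh.genotypes, coh.snp_pos, cpg_pos,
                            n_perm=200, seed=3)
        assert scan.iloc[0].status == "untested"
        assert np.isnan(scan.iloc[0].p_true)

    def test_storey_q_monotone_in_p(self, small_cohort):
        coh = small_cohort
        R = pd.DataFrame({c: twin_models.residualize_difference(coh, c)
                          for c in coh.methylation.index}).T
        scan = qtl.cis_scan(R, coh.genotypes, coh.snp_pos, coh.cpg_pos,
                            n_perm=500, seed=4)
        sub = scan.dropna(subset=["p_beta"]).sort_values("p_beta")
        assert sub.q.is_monotonic_increasing
        assert (sub.q <= 1).all()


class TestConditionalScan:
    def _scan(self, coh, seed):
        R = pd.DataFrame({c: twin_models.residualize_difference(coh, c)
                          for c in coh.methylation.index}).T
        scan = qtl.cis_scan(R, coh.genotypes, coh.snp_pos, coh.cpg_pos,
                            n_perm=1000, seed=seed)
        return R, scan

    def test_single_causal_snp_no_secondary(self):
        false_secondary = 0
        n_reps = 20
        for rep in range(n_reps):
            coh = simulate.simulate_cohort_genome(
                n_pairs=250, n_snps=20, n_cpgs=6, ld_block_size=1,
                frac_me_only=0, frac_v_only=0.5, frac_dual=0,
                a_gxe_v=0.3, seed=400 + rep)
            R, scan = self._scan(coh, rep)
            cond = qtl.conditional_cis_scan(scan, R, coh.genotypes,
                                            coh.snp_pos, coh.cpg_pos,
                                            n_perm=1000, seed=rep)
            false_secondary += int(cond.significant.sum() > 0)
        assert false_secondary <= int(0.05 * n_reps) + 1

    def test_two_causal_snps_secondary_recovered(self):
        recovered = 0
        n_reps = 10
        for rep in range(n_reps):
            rng = np.random.default_rng(600 + rep)
            n_pairs = 350
            cov = simulate.simulate_covariates(n_pairs, rng)
            g1 = simulate.simulate_genotype(n_pairs, 0.3, rng)
            g2 = simulate.simulate_genotype(n_pairs, 0.3, rng)
            smoking = cov.smoking.to_numpy(dtype=float)
            from mzvqtl.simulate import scale01
            # cg0 carries two independent interaction effects; the other
            # CpGs are null and anchor the study-wide q-value crossing
            y0 = (0.4 * scale01(np.repeat(g1, 2) * smoking)
                  + 0.4 * scale01(np.repeat(g2, 2) * smoking)
                  + 0.2 * scale01(rng.normal(size=2 * n_pairs)))
            nulls = [scale01(rng.normal(size=2 * n_pairs)) for _ in range(9)]
            geno = pd.DataFrame([g1, g2] + [simulate.simulate_genotype(
                n_pairs, 0.3, rng) for _ in range(8)],
                index=[f"snp{i}" for i in range(10)])
            cpgs = [f"cg{i}" for i in range(10)]
            coh = simulate.TwinPairCohort(
                covariates=cov, genotypes=geno,
                methylation=pd.DataFrame(
                    [y0] + nulls, index=cpgs,
                    columns=[f"p{i}_t{t}" for i in range(n_pairs)
                             for t in (1, 2)]),
                snp_pos=pd.DataFrame({"snp": geno.index, "chrom": "1",
                                      "pos": 1 + 50_000 * np.arange(10)}),
                cpg_pos=pd.DataFrame({"cpg": cpgs, "chrom": "1",
                                      "pos": 250_000 + np.arange(10)}))
            R, scan = self._scan(coh, rep)
            if not scan.significant.any():
                continue
            cond = qtl.conditional_cis_scan(scan, R, coh.genotypes,
                                            coh.snp_pos, coh.cpg_pos,
                                            n_perm=1000, seed=rep)
            sig = cond[cond.significant]
            if len(sig):
                recovered += sig.secondary_snp.iloc[0] in ("snp0", "snp1")
        assert recovered >= int(0.8 * n_reps)


class TestTransScan:
    def _null_data(self, seed, n_pairs=100, n_snps=20, n_cpgs=10):
        rng = np.random.default_rng(seed)
        G = np.stack([simulate.simulate_genotype(n_pairs, 0.3, rng)
                      for _ in range(n_snps)])
        R = rng.normal(size=(n_cpgs, n_pairs))
        geno = pd.DataFrame(G, index=[f"snp{i}" for i in range(n_snps)])
        res = pd.DataFrame(R, index=[f"cg{i}" for i in range(n_cpgs)])
        snp_pos = pd.DataFrame({"snp": geno.index, "chrom": "1",
                                "pos": 1 + 1000 * np.arange(n_snps)})
        cpg_pos = pd.DataFrame({"cpg": res.index, "chrom": "2",
                                "pos": 1 + 1000 * np.arange(n_cpgs)})
        return res, geno, snp_pos, cpg_pos

    def test_fdr_formula_against_brute_force(self):
        """The reported threshold must satisfy the permutation-count FDR
        formula when pools are recomputed independently."""
        res, geno, snp_pos, cpg_pos = self._null_data(5)
        # plant one strong trans signal
        g0 = geno.iloc[0].to_numpy()
        res.iloc[0] = 2.0 * g0 + np.random.default_rng(6).normal(
            0, 0.3, res.shape[1])
        out = qtl.trans_scan(res, geno, snp_pos, cpg_pos, n_perm=20, seed=9)
        t = out["threshold"]
        assert np.isfinite(t)
        # independent recomputation of both pools
        n = res.shape[1]
        Y = res.to_numpy()
        G = geno.to_numpy()
        def pool(Ym):
            ps = np.empty((Ym.shape[0], G.shape[0]))
            for i in range(Ym.shape[0]):
                for j in range(G.shape[0]):
                    r = np.corrcoef(Ym[i], G[j])[0, 1]
                    tt = r * np.sqrt((n - 2) / (1 - r**2))
                    ps[i, j] = 2 * stats.t.sf(abs(tt), n - 2)
            return ps.ravel()
        real = pool(Y)
        rng = np.random.default_rng(np.random.SeedSequence([9, 0]))
        perm = np.concatenate([pool(Y[:, rng.permutation(n)])
                               for _ in range(20)])
        tol = t * (1 + 1e-9)  # allow last-digit differences between routes
        fdr_at_t = (np.sum(perm <= tol) / np.sum(real <= tol)) / 20
        assert np.sum(real <= tol) >= 1
        assert fdr_at_t <= 0.05
        assert (out["pairs"].p <= t).all()

    def test_quoted_formula_arithmetic(self):
        # 10 pooled permutation hits vs 100 real hits at 20 permutations
        assert (10 / 100) / 20 == pytest.approx(0.005)

    def test_pure_null_yields_no_threshold(self):
        empty = 0
        for rep in range(10):
            res, geno, snp_pos, cpg_pos = self._null_data(100 + rep)
            out = qtl.trans_scan(res, geno, snp_pos, cpg_pos, seed=rep)
            empty += not np.isfinite(out["threshold"])
        assert empty >= 9

    def test_strong_signal_detected_with_index(self):
        res, geno, snp_pos, cpg_pos = self._null_data(7)
        g0 = geno.iloc[0].to_numpy()
        res.iloc[0] = 3.0 * g0 + np.random.default_rng(8).normal(
            0, 0.1, res.shape[1])
        out = qtl.trans_scan(res, geno, snp_pos, cpg_pos, seed=11)
        pairs = out["pairs"]
        hit = pairs[(pairs.cpg == "cg0") & (pairs.snp == "snp0")]
        assert len(hit) == 1 and hit.is_index.iloc[0]


def _brute_force_clump(snps, pvals, pos, r2mat, window, r2thr):
    """Literal greedy re-implementation used as the clumping oracle."""
    remaining = set(range(len(snps)))
    clumps = []
    while remaining:
        i = min(remaining, key=lambda k: (pvals[k], pos[k][0], pos[k][1], snps[k]))
        members = [i]
        for j in sorted(remaining - {i}):
            if (pos[j][0] == pos[i][0]
                    and abs(pos[j][1] - pos[i][1]) <= window
                    and r2mat[i, j] >= r2thr):
                members.append(j)
        remaining -= set(members)
        clumps.append((snps[i], sorted(snps[j] for j in members)))
    return sorted(clumps)


class TestLdClump:
    def _random_instance(self, seed, n_snps=12, n_pairs=80):
        rng = np.random.default_rng(seed)
        G = np.stack([simulate.simulate_genotype(n_pairs, 0.4, rng)
                      for _ in range(n_snps // 2)])
        # add correlated copies to create real clumps
        copies = np.stack([simulate._ld_copy(G[i % len(G)], 0.2, 0.4, rng)
                           for i in range(n_snps - len(G))])
        G = np.vstack([G, copies])
        snps = [f"s{i}" for i in range(n_snps)]
        pvals = {s: float(p) for s, p in zip(snps, rng.uniform(size=n_snps))}
        chrom = rng.choice(["1", "2"], n_snps)
        bp = rng.integers(1, 2_000_000, n_snps)
        positions = pd.DataFrame({"snp": snps, "chrom": chrom, "pos": bp})
        geno = pd.DataFrame(G, index=snps)
        return snps, pvals, geno, positions

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle(self, seed):
        snps, pvals, geno, positions = self._random_instance(seed)
        cs = qtl.ld_clump(snps, pd.Series(pvals), geno, positions)
        got = sorted((c["index_snp"], sorted(c["members"])) for c in cs.clumps)
        pos = {s: (positions.set_index("snp").loc[s, "chrom"],
                   int(positions.set_index("snp").loc[s, "pos"]))
               for s in snps}
        G = geno.to_numpy()
        r2 = np.corrcoef(G) ** 2
        want = _brute_force_clump(snps, [pvals[s] for s in snps],
                                  [pos[s] for s in snps], r2, 5e5, 0.2)
        assert got == want

    def test_partition_property(self):
        snps, pvals, geno, positions = self._random_instance(999)
        cs = qtl.ld_clump(snps, pd.Series(pvals), geno, positions)
        members = [m for c in cs.clumps for m in c["members"]]
        assert sorted(members) == sorted(snps)

    def test_unlinked_snps_each_own_index(self):
        rng = np.random.default_rng(2)
        G = np.stack([simulate.simulate_genotype(200, 0.4, rng)
                      for _ in range(5)])
        snps = [f"s{i}" for i in range(5)]
        geno = pd.DataFrame(G, index=snps)
        positions = pd.DataFrame({"snp": snps, "chrom": "1",
                                  "pos": 1 + 10_000 * np.arange(5)})
        pvals = pd.Series(dict(zip(snps, [0.5, 0.1, 0.3, 0.2, 0.4])))
        cs = qtl.ld_clump(snps, pvals, geno, positions, r2_threshold=0.9)
        assert len(cs.clumps) == 5

    def test_identical_snps_one_clump(self):
        rng = np.random.default_rng(3)
        g = simulate.simulate_genotype(100, 0.4, rng)
        geno = pd.DataFrame([g, g], index=["a", "b"])
        positions = pd.DataFrame({"snp": ["a", "b"], "chrom": "1",
                                  "pos": [100_000, 110_000]})
        cs = qtl.ld_clump(["a", "b"], pd.Series({"a": 0.2, "b": 0.01}),
                          geno, positions)
        assert len(cs.clumps) == 1
        assert cs.clumps[0]["index_snp"] == "b"


class TestSpuriousFilter:
    def _setup(self, seed=4):
        rng = np.random.default_rng(seed)
        g_causal = simulate.simulate_genotype(200, 0.4, rng)
        g_tag = simulate._ld_copy(g_causal, 0.25, 0.4, rng)  # partial LD
        g_far = simulate.simulate_genotype(200, 0.4, rng)
        geno = pd.DataFrame([g_causal, g_tag, g_far],
                            index=["causal", "tag", "far"])
        positions = pd.DataFrame({"snp": ["causal", "tag", "far"],
                                  "chrom": "1",
                                  "pos": [100_000, 150_000, 5_000_000]})
        return geno, positions

    def test_tagged_vmeqtl_discarded(self):
        geno, positions = self._setup()
        vme = pd.DataFrame({"cpg": ["cg0"], "snp": ["tag"], "p": [1e-5]})
        me = pd.DataFrame({"cpg": ["cg0"], "snp": ["causal"], "p": [1e-12]})
        kept, audit = qtl.remove_spurious_vmeqtls(vme, me, geno, positions)
        assert kept.empty
        assert audit.iloc[0].discarded_snp == "tag"
        assert audit.iloc[0].dominating_me_snp == "causal"

    def test_independent_vmeqtl_retained(self):
        geno, positions = self._setup()
        vme = pd.DataFrame({"cpg": ["cg0"], "snp": ["far"], "p": [1e-5]})
        me = pd.DataFrame({"cpg": ["cg0"], "snp": ["causal"], "p": [1e-12]})
        kept, audit = qtl.remove_spurious_vmeqtls(vme, me, geno, positions)
        assert len(kept) == 1 and audit.empty

    def test_shared_snp_flagged_for_refit_not_discarded(self):
        geno, positions = self._setup()
        vme = pd.DataFrame({"cpg": ["cg0"], "snp": ["causal"], "p": [1e-5]})
        me = pd.DataFrame({"cpg": ["cg0"], "snp": ["causal"], "p": [1e-12]})
        kept, audit = qtl.remove_spurious_vmeqtls(vme, me, geno, positions)
        assert len(kept) == 1
        assert (audit.action == "shared_snp_refit").all()

    def test_stronger_vmeqtl_keeps_clump(self):
        geno, positions = self._setup()
        vme = pd.DataFrame({"cpg": ["cg0"], "snp": ["tag"], "p": [1e-12]})
        me = pd.DataFrame({"cpg": ["cg0"], "snp": ["causal"], "p": [1e-5]})
        kept, audit = qtl.remove_spurious_vmeqtls(vme, me, geno, positions)
        assert len(kept) == 1 and audit.empty


class TestSmallFilters:
    def test_exclude_regions_half_open(self):
        cpg_pos = pd.DataFrame({"cpg": ["a", "b", "c"], "chrom": ["1"] * 3,
                                "pos": [100, 150, 200]})
        regions = [("1", 100, 200)]
        kept = qtl.exclude_regions(["a", "b", "c"], cpg_pos, regions)
        assert kept == ["c"]  # pos==start removed, pos==end retained

    def test_exclude_regions_empty_list(self):
        cpg_pos = pd.DataFrame({"cpg": ["a"], "chrom": ["1"], "pos": [5]})
        assert qtl.exclude_regions(["a"], cpg_pos, []) == ["a"]

    def test_correlation_filter(self):
        x = np.arange(10.0)
        assert qtl.correlation_filter(x, x) == (True, pytest.approx(1.0))
        keep, rho = qtl.correlation_filter(x, -x)
        assert not keep and rho == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            qtl.correlation_filter([1.0, 2.0], [1.0, 2.0])

    def test_correlation_filter_rejects_independent_noise(self):
        rng = np.random.default_rng(5)
        dropped = 0
        for _ in range(30):
            keep, _ = qtl.correlation_filter(rng.normal(size=56),
                                             rng.normal(size=56))
            dropped += not keep
        assert dropped > 15

    def test_bonferroni_boundary_strict(self):
        m = 1317
        disc = pd.DataFrame({"cpg": [f"c{i}" for i in range(m)],
                             "snp": "s", "p": 1e-8})
        rep = disc.copy()
        rep["p"] = 1.0
        rep.loc[0, "p"] = 0.05 / m  # exactly on the boundary
        rep.loc[1, "p"] = 0.04 / m
        out = qtl.bonferroni_replicate(disc, rep)
        assert out.cpg.tolist() == ["c1"]

    def test_bonferroni_single_test(self):
        disc = pd.DataFrame({"cpg": ["c"], "snp": ["s"], "p": [1e-8]})
        rep = pd.DataFrame({"cpg": ["c"], "snp": ["s"], "p": [0.04]})
        assert len(qtl.bonferroni_replicate(disc, rep)) == 1


class TestQValues:
    def test_storey_vs_bh_relationship(self, rng):
        p = rng.uniform(size=300)
        qs = storey_qvalue(p)
        qb = bh_fdr(p)
        assert np.all(qs <= qb + 1e-12)  # pi0 <= 1 scales BH down
        order = np.argsort(p)
        assert np.all(np.diff(qs[order]) >= -1e-12)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            storey_qvalue(np.array([0.5, 1.5]))
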