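#!/usr/bin/env python
"""Replicate variance-QTL signals in an unrelated-singleton cohort.

Simulates candidate loci with genotype-dependent phenotype SDs (plus null
loci), applies both singleton variance tests (DRM and SVLM), and keeps the
associations that pass FDR < 0.05 under both — the joint replication rule.
"""

import os

import pandas as pd

from mzvqtl import nontwin, simulate

rows_drm, rows_svlm = [], []
for i in range(20):
    variance = (1.0, 1.3, 1.6) if i < 8 else (1.0, 1.0, 1.0)
    coh = simulate.simulate_unrelated_cohort(1348, variance, seed=100 + i)
    key = {"cpg": f"cg{i:02d}", "snp": f"snp{i:02d}"}
    d = nontwin.drm_test(coh.phenotype, coh.genotype)
    s = nontwin.svlm_test(coh.phenotype, coh.genotype)
    rows_drm.append(key | {"p": d.p, "slope": d.slope})
    rows_svlm.append(key | {"p": s.p, "slope": s.slope})

drm = pd.DataFrame(rows_drm)
svlm = pd.DataFrame(rows_svlm)
replicated = nontwin.joint_fdr_replication(drm, svlm)

os.makedirs("results", exist_ok=True)
drm.to_csv("results/nontwin_drm.tsv", sep="\t", index=False)
svlm.to_csv("results/nontwin_svlm.tsv", sep="\t", index=False)
replicated.to_csv("results/nontwin_replicated.tsv", sep="\t", index=False)

print(f"{len(replicated)} of 20 associations replicate under both DRM and "
      f"SVLM at FDR < 0.05 (8 loci carried a true variance signal)")
print(replicated[["cpg", "p_drm", "p_svlm"]].to_string(index=False))
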