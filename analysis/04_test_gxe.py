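#!/usr/bin/env python
"""Two-stage gene-environment interaction tests on a simulated twin cohort.

Simulates CpGs with and without a genotype-by-smoking interaction, runs the
two-stage procedure (stage 1: mixed-model removal of relatedness, batch and
the non-focal covariates; stage 2: residual ~ G + E + G:E) for the smoking
and BMI modifiers, BH-adjusts across all tests, and writes the tidy table.
"""

import os

import numpy as np

from mzvqtl import gxe, simulate
from mzvqtl.simulate import SimulationConfig

rng = np.random.default_rng(31)
n_pairs = 350
cov = simulate.simulate_covariates(n_pairs, rng)
fam = cov.pair_id.to_numpy()
batch = rng.integers(0, 8, 2 * n_pairs)

results = []
for j, a_gxe in enumerate((0.0, 0.0, 0.2, 0.3)):
    g = simulate.simulate_genotype(n_pairs, 0.3, rng)
    cfg = SimulationConfig(n_pairs=n_pairs, a_g=0.1, a_gxe=a_gxe)
    y, _ = simulate.simulate_methylation(cfg, g, cov, rng=rng)
    for modifier in ("smoking", "BMI"):
        keep = [c for c in ("age", "bmi", "smoking")
                if c != modifier.lower()]
        res = gxe.stage1_residualize(y, fam, batch, cov[keep],
                                     exclude={modifier}, method="demean")
        mod = cov[modifier.lower()].to_numpy(dtype=float)
        r = gxe.test_interaction(res, np.repeat(g, 2), mod, modifier,
                                 cpg=f"cg{j:02d}", snp=f"snp{j:02d}")
        results.append(r)

table = gxe.fdr_adjust(results)
os.makedirs("results", exist_ok=True)
table.to_csv("results/gxe_interactions.tsv", sep="\t", index=False)

sig = table[table.q < 0.05]
print(table[["cpg", "modifier", "beta_gxe", "p", "q"]].to_string(index=False))
print(f"\n{len(sig)} significant interactions (q < 0.05); the simulated "
      "G x smoking loci (cg02, cg03) should carry the smoking hits")
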