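#!/usr/bin/env python
"""Generate an example MZ-twin cohort and write its tables.

Draws a 350-pair cohort with a multi-locus genome (LD blocks, labelled
mean-/variance-QTL loci) and writes genotype, methylation, covariate,
position and truth tables under results/cohort/, plus a minimal VCF.
"""

from mzvqtl import io, simulate

cohort = simulate.simulate_cohort_genome(
    n_pairs=350, n_snps=200, n_cpgs=40, ld_block_size=4, seed=11)

paths = io.write_cohort(cohort, "results/cohort")
io.write_vcf(cohort, "results/cohort/genotypes.vcf")

counts = cohort.truth["type"].value_counts().to_dict()
print(f"cohort: {cohort.n_pairs} MZ pairs, "
      f"{cohort.genotypes.shape[0]} SNPs, "
      f"{cohort.methylation.shape[0]} CpGs")
print(f"locus classes: {counts}")
print("written:", ", ".join(sorted(paths.values())))
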