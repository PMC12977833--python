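"""Tabular readers/writers for the cohort container and result tables.

Everything is plain TSV: genotype dosages (rows = SNPs, columns = pair
IDs), methylation (rows = CpGs, columns = twin individuals), per-twin
covariates, BED-like position tables (chrom, 1-based pos, id) and the
simulation truth table.  A minimal VCF export (GT only) is provided for
interoperability with standard genetics tooling.
"""

from __future__ import annotations

import os

import pandas as pd

from .simulate import TwinPairCohort

__all__ = ["write_cohort", "read_cohort", "write_vcf", "read_vcf_genotypes"]

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}
_DOSAGE = {"0/0": 0.0, "0/1": 1.0, "1/0": 1.0, "1/1": 2.0,
           "0|0": 0.0, "0|1": 1.0, "1|0": 1.0, "1|1": 2.0}


def write_cohort(cohort: TwinPairCohort, out_dir: str) -> dict:
    """Write every table of a cohort to ``out_dir``; returns the path map."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "genotypes": os.path.join(out_dir, "genotypes.tsv"),
        "methylation": os.path.join(out_dir, "methylation.tsv"),
        "covariates": os.path.join(out_dir, "covariates.tsv"),
        "snp_pos": os.path.join(out_dir, "snp_pos.tsv"),
        "cpg_pos": os.path.join(out_dir, "cpg_pos.tsv"),
    }
    cohort.genotypes.to_csv(paths["genotypes"], sep="\t")
    cohort.methylation.to_csv(paths["methylation"], sep="\t")
    cohort.covariates.to_csv(paths["covariates"], sep="\t", index=False)
    cohort.snp_pos.to_csv(paths["snp_pos"], sep="\t", index=False)
    cohort.cpg_pos.to_csv(paths["cpg_pos"], sep="\t", index=False)
    if cohort.truth is not None:
        paths["truth"] = os.path.join(out_dir, "truth.tsv")
        cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    if cohort.cell_proportions is not None:
        paths["cells"] = os.path.join(out_dir, "cell_proportions.tsv")
        cohort.cell_proportions.to_csv(paths["cells"], sep="\t")
    return paths


def read_cohort(out_dir: str, scale: str = "beta") -> TwinPairCohort:
    """Inverse of :func:`write_cohort`."""
    def _p(name):
        return os.path.join(out_dir, name)

    truth_path = _p("truth.tsv")
    cells_path = _p("cell_proportions.tsv")
    return TwinPairCohort(
        covariates=pd.read_csv(_p("covariates.tsv"), sep="\t"),
        genotypes=pd.read_csv(_p("genotypes.tsv"), sep="\t", index_col=0),
        methylation=pd.read_csv(_p("methylation.tsv"), sep="\t", index_col=0),
        snp_pos=pd.read_csv(_p("snp_pos.tsv"), sep="\t"),
        cpg_pos=pd.read_csv(_p("cpg_pos.tsv"), sep="\t"),
        scale=scale,
        # keep_default_na: the locus class label "null" is data, not NaN
        truth=pd.read_csv(truth_path, sep="\t", keep_default_na=False,
                          na_values=[""]) if os.path.exists(truth_path) else None,
        cell_proportions=pd.read_csv(cells_path, sep="\t", index_col=0)
        if os.path.exists(cells_path) else None,
    )


def read_vcf_genotypes(path: str):
    """Parse a plain-text VCF into (dosage DataFrame, position table).

    Only the GT field is interpreted (hard-call biallelic dosages); this is
    the inverse of :func:`write_vcf` and intentionally minimal — for rich
    VCFs use cyvcf2 and assemble the cohort container directly.
    """
    rows, pos_rows, samples = [], [], None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            chrom, bp, snp = fields[0], int(fields[1]), fields[2]
            gts = [g.split(":")[0] for g in fields[9:]]
            rows.append((snp, [_DOSAGE.get(g, float("nan")) for g in gts]))
            pos_rows.append({"snp": snp, "chrom": chrom, "pos": bp})
    geno = pd.DataFrame(dict(rows), index=samples).T
    return geno, pd.DataFrame(pos_rows)


def write_vcf(cohort: TwinPairCohort, path: str):
    """Minimal VCF 4.2 export of pair-level hard-call genotypes (GT only)."""
    pos = cohort.snp_pos.set_index("snp")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(str(c) for c in cohort.genotypes.columns)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        order = pos.sort_values(["chrom", "pos"]).index
        for snp in order:
            row = cohort.genotypes.loc[snp]
            gts = "\t".join(_GT[int(round(v))] for v in row)
            fh.write(f"{pos.loc[snp, 'chrom']}\t{int(pos.loc[snp, 'pos'])}\t"
                     f"{snp}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")
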