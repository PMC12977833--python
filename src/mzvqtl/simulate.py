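"""Synthetic monozygotic-twin and unrelated cohorts for variance-QTL analysis.

The generator emulates the statistical structure a twin-based variance-meQTL
analysis assumes: MZ co-twins share genotype, age and sex; BMI and smoking
vary within pairs; and methylation at a CpG is a weighted sum of a genetic
main effect, an environmental composite, a gene-by-smoking interaction and
noise, each min-max scaled to [0, 1] before weighting so the phenotype is a
valid methylation beta value.

All randomness flows from a single seed; sub-streams for replicates and loci
are spawned deterministically so regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "TwinPairCohort",
    "simulate_covariates",
    "simulate_genotype",
    "simulate_methylation",
    "simulate_cohort_genome",
    "simulate_unrelated_cohort",
    "beta_to_m",
    "scale01",
]

NOISE_LAWS = ("normal", "chisq_df1", "gamma_2_half")


@dataclass
class SimulationConfig:
    """Weights and settings for one simulated CpG phenotype.

    The four weights must sum to one; ``a_error`` defaults to the study's
    constant 0.2 and the environmental weight absorbs the remainder.
    """

    n_pairs: int = 350
    a_g: float = 0.0
    a_gxe: float = 0.0
    a_error: float = 0.2
    a_e: float = field(default=-1.0)  # -1 means "fill to sum 1"
    noise_law: str = "normal"
    scale: str = "beta"
    maf: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.a_e < 0:
            self.a_e = max(1.0 - self.a_g - self.a_gxe - self.a_error, -1.0)
            if abs(self.a_e) < 1e-9:
                self.a_e = 0.0
        total = self.a_g + self.a_gxe + self.a_e + self.a_error
        if not np.isclose(total, 1.0):
            raise ValueError(f"weights must sum to 1, got {total}")
        if min(self.a_g, self.a_gxe, self.a_e, self.a_error) < -1e-12:
            raise ValueError("weights must be nonnegative (a_e computed as "
                             f"{self.a_e}; infeasible cell)")
        if self.noise_law not in NOISE_LAWS:
            raise ValueError(f"noise_law must be one of {NOISE_LAWS}")
        if self.scale not in ("beta", "M"):
            raise ValueError("scale must be 'beta' or 'M'")
        if not (0 < self.maf <= 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


@dataclass
class TwinPairCohort:
    """Paired genotype/methylation/covariate container.

    Genotype is stored once per pair (MZ co-twins are genetically
    identical).  Methylation rows are CpGs, columns are twin individuals in
    pair-major order (pair 0 twin 1, pair 0 twin 2, pair 1 twin 1, ...).
    """

    covariates: pd.DataFrame          # one row per twin individual
    genotypes: pd.DataFrame           # SNP x pair dosage in {0,1,2}
    methylation: pd.DataFrame         # CpG x twin individual
    snp_pos: pd.DataFrame             # columns: snp, chrom, pos (1-based)
    cpg_pos: pd.DataFrame             # columns: cpg, chrom, pos (1-based)
    scale: str = "beta"
    cell_proportions: Optional[pd.DataFrame] = None
    truth: Optional[pd.DataFrame] = None

    @property
    def n_pairs(self) -> int:
        return self.genotypes.shape[1]

    def __post_init__(self):
        if self.scale == "beta":
            vals = self.methylation.to_numpy()
            if np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9:
                raise ValueError("beta-scale methylation must lie in [0, 1]")
        if self.cell_proportions is not None:
            cp = self.cell_proportions.to_numpy()
            if (cp < -1e-12).any() or (cp.sum(axis=1) > 1 + 1e-9).any():
                raise ValueError("cell proportions must be nonnegative and "
                                 "sum to <= 1 per individual")


def scale01(x: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant vector maps to all zeros."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def beta_to_m(beta, eps: float = 1e-6) -> np.ndarray:
    """Logit-2 transform of methylation beta values: M = log2(beta/(1-beta)).

    Values within ``eps`` of the boundaries are clipped; values outside
    [0, 1] raise.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0) or np.any(beta > 1):
        raise ValueError("beta values must lie in [0, 1]")
    b = np.clip(beta, eps, 1.0 - eps)
    return np.log2(b / (1.0 - b))


def simulate_covariates(n_pairs: int, seed=None) -> pd.DataFrame:
    """Per-twin covariate table for ``n_pairs`` MZ pairs.

    Age ~ Uniform(20, 70) and sex ~ Bernoulli(0.5) are shared within a pair.
    Each pair is assigned a BMI regime (80% Normal(25, 1), 20% Normal(25, 3))
    and each twin draws BMI independently from the pair's regime.  Smoking is
    Bernoulli(0.1) independently per twin, so roughly 18% of pairs are
    smoking-discordant — the within-pair environmental exposure the variance
    models exploit.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    age = rng.uniform(20.0, 70.0, n_pairs)
    sex = rng.binomial(1, 0.5, n_pairs)
    wide_regime = rng.random(n_pairs) < 0.2
    bmi_sd = np.where(wide_regime, 3.0, 1.0)
    bmi = rng.normal(25.0, np.repeat(bmi_sd, 2))
    smoking = rng.binomial(1, 0.1, 2 * n_pairs)
    pair = np.repeat(np.arange(n_pairs), 2)
    return pd.DataFrame(
        {
            "pair_id": pair,
            "twin": np.tile([1, 2], n_pairs),
            "age": np.repeat(age, 2),
            "sex": np.repeat(sex, 2),
            "bmi": bmi,
            "smoking": smoking,
        }
    )


def simulate_genotype(
    n_pairs: int,
    maf: float,
    seed=None,
    min_group: int = 5,
    max_retries: int = 1000,
) -> np.ndarray:
    """Per-pair dosage vector under Hardy-Weinberg proportions.

    Redraws (up to ``max_retries`` times) until all three genotype groups
    hold at least ``min_group`` pairs — the minor-homozygote group in
    particular, mirroring the SNP inclusion rule of the twin analysis;
    raises if the constraint is unreachable.
    """
    if not (0 < maf <= 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    probs = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    for _ in range(max_retries):
        g = rng.choice(3, size=n_pairs, p=probs)
        counts = np.bincount(g, minlength=3)
        if counts.min() >= min_group:
            return g.astype(float)
    raise RuntimeError(
        f"could not draw a genotype with >= {min_group} pairs per present "
        f"group after {max_retries} tries (n_pairs={n_pairs}, maf={maf}; "
        f"expected minor-homozygote count {n_pairs * maf**2:.2f})"
    )


def _draw_noise(law: str, size: int, rng: np.random.Generator) -> np.ndarray:
    if law == "normal":
        return rng.standard_normal(size)
    if law == "chisq_df1":
        return rng.chisquare(1, size)
    if law == "gamma_2_half":
        return rng.gamma(2.0, 0.5, size)
    raise ValueError(f"unknown noise law {law!r}")


def simulate_methylation(
    config: SimulationConfig,
    genotype: np.ndarray,
    covariates: pd.DataFrame,
    rng=None,
):
    """Per-twin methylation phenotype from the weighted four-component model.

    Y = a_G * s(G) + a_E * s(E) + a_GxE * s(G x smoking) + a_error * s(noise)

    where s() is min-max scaling over all twin individuals, E is the
    min-max-scaled equal-weight sum of scaled age, sex, scaled BMI and
    smoking, and the interaction pairs the genetic dosage with the twin's
    smoking status.  Returns ``(y, truth)`` with ``truth`` holding the scaled
    components, so downstream power checks can recompute from ground truth.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    genotype = np.asarray(genotype, dtype=float)
    n_ind = 2 * genotype.size
    if len(covariates) != n_ind:
        raise ValueError("covariates and genotype are not conformable")
    g_ind = np.repeat(genotype, 2)
    smoking = covariates["smoking"].to_numpy(dtype=float)
    e_raw = (
        scale01(covariates["age"].to_numpy())
        + covariates["sex"].to_numpy(dtype=float)
        + scale01(covariates["bmi"].to_numpy())
        + smoking
    ) / 4.0
    noise = _draw_noise(config.noise_law, n_ind, rng)
    comp = {
        "G": scale01(g_ind),
        "E": scale01(e_raw),
        "GxE": scale01(g_ind * smoking),
        "error": scale01(noise),
    }
    y = (
        config.a_g * comp["G"]
        + config.a_e * comp["E"]
        + config.a_gxe * comp["GxE"]
        + config.a_error * comp["error"]
    )
    if config.scale == "M":
        y = beta_to_m(y)
    truth = dict(comp, weights=(config.a_g, config.a_e, config.a_gxe, config.a_error))
    return y, truth


def _ld_copy(base: np.ndarray, copy_noise: float, maf: float,
             rng: np.random.Generator) -> np.ndarray:
    """Copy of a dosage vector with per-pair redraw probability ``copy_noise``.

    copy_noise 0 gives r^2 = 1; larger values decay the within-block LD.
    """
    g = base.copy()
    flip = rng.random(g.size) < copy_noise
    if flip.any():
        probs = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
        g[flip] = rng.choice(3, size=int(flip.sum()), p=probs)
    return g


def simulate_cohort_genome(
    n_pairs: int = 350,
    n_snps: int = 50,
    n_cpgs: int = 20,
    ld_block_size: int = 1,
    copy_noise: float = 0.1,
    maf: float = 0.3,
    a_g_me: float = 0.3,
    a_gxe_v: float = 0.25,
    frac_me_only: float = 0.30,
    frac_v_only: float = 0.10,
    frac_dual: float = 0.15,
    noise_law: str = "normal",
    seed: int = 0,
) -> TwinPairCohort:
    """Multi-locus twin cohort with labelled mean-QTL and variance-QTL loci.

    SNPs are laid out in LD blocks on two chromosomes with positions that
    yield both cis (within 1 Mb) and trans SNP-CpG pairs.  A fraction of
    CpGs are wired to a causal cis SNP as mean-effect only (``a_g_me``
    additive weight), variance-effect only (``a_gxe_v`` interaction weight),
    or both; the remainder are null.  The default composition mirrors real
    blood methylation, where mean-QTLs vastly outnumber variance-QTLs and
    most variance-CpGs also carry a mean signal.  The truth table labels
    each CpG with its causal SNP and effect type, which the end-to-end
    recovery tests consume.
    """
    if min(n_pairs, n_snps, n_cpgs, ld_block_size) < 1:
        raise ValueError("counts must be >= 1")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    covariates = simulate_covariates(n_pairs, rng)

    # genotype blocks: first SNP of each block drawn fresh, others LD copies
    geno = np.empty((n_snps, n_pairs))
    for i in range(n_snps):
        if i % ld_block_size == 0:
            geno[i] = simulate_genotype(n_pairs, maf, rng)
        else:
            geno[i] = _ld_copy(geno[i - (i % ld_block_size)], copy_noise, maf, rng)

    # positions: split SNPs across chr1/chr2, 50 kb spacing keeps blocks
    # within the 500 kb clump window while spanning > 1 Mb overall
    half = n_snps // 2
    snp_chrom = np.where(np.arange(n_snps) < half, "1", "2")
    snp_offset = np.concatenate([np.arange(half), np.arange(n_snps - half)])
    snp_bp = 1 + snp_offset * 50_000
    snp_ids = [f"snp{i:04d}" for i in range(n_snps)]
    snp_pos = pd.DataFrame({"snp": snp_ids, "chrom": snp_chrom, "pos": snp_bp})

    # assign CpG classes
    n_me = int(round(frac_me_only * n_cpgs))
    n_v = int(round(frac_v_only * n_cpgs))
    n_dual = int(round(frac_dual * n_cpgs))
    classes = (["meQTL"] * n_me + ["vmeQTL"] * n_v + ["dual"] * n_dual
               + ["null"] * (n_cpgs - n_me - n_v - n_dual))
    rng.shuffle(classes)

    cpg_ids = [f"cg{i:06d}" for i in range(n_cpgs)]
    causal_idx = rng.integers(0, n_snps, n_cpgs)
    meth = np.empty((n_cpgs, 2 * n_pairs))
    cpg_chrom, cpg_bp, truth_rows = [], [], []
    for j, cls in enumerate(classes):
        k = int(causal_idx[j])
        # place the CpG 10 kb from its (potential) causal SNP -> cis pair
        cpg_chrom.append(snp_chrom[k])
        cpg_bp.append(int(snp_bp[k]) + 10_000)
        a_g = a_g_me if cls in ("meQTL", "dual") else 0.0
        a_gxe = a_gxe_v if cls in ("vmeQTL", "dual") else 0.0
        cfg = SimulationConfig(n_pairs=n_pairs, a_g=a_g, a_gxe=a_gxe,
                               noise_law=noise_law, maf=maf)
        y, _ = simulate_methylation(cfg, geno[k], covariates, rng)
        meth[j] = y
        truth_rows.append({"cpg": cpg_ids[j], "causal_snp": snp_ids[k],
                           "type": cls, "a_g": a_g, "a_gxe": a_gxe})

    ind_ids = [f"p{p}_t{t}" for p in range(n_pairs) for t in (1, 2)]
    pair_ids = [f"p{p}" for p in range(n_pairs)]
    return TwinPairCohort(
        covariates=covariates,
        genotypes=pd.DataFrame(geno, index=snp_ids, columns=pair_ids),
        methylation=pd.DataFrame(meth, index=cpg_ids, columns=ind_ids),
        snp_pos=snp_pos,
        cpg_pos=pd.DataFrame({"cpg": cpg_ids, "chrom": cpg_chrom, "pos": cpg_bp}),
        scale="beta",
        truth=pd.DataFrame(truth_rows),
    )


def simulate_unrelated_cohort(
    n: int,
    variance_model=(1.0, 1.0, 1.0),
    maf: float = 0.3,
    seed=None,
) -> pd.DataFrame:
    """Unrelated-singleton cohort with genotype-dependent phenotype variance.

    Phenotype for an individual with dosage g is Normal(0, sd[g]); equal SDs
    give the homoscedastic null used for type-I checks of the DRM and SVLM
    tests.  Requires at least 3 individuals in every represented genotype
    group.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sds = np.asarray(variance_model, dtype=float)
    if sds.size != 3 or (sds <= 0).any():
        raise ValueError("variance_model must be 3 positive SDs")
    probs = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    g = rng.choice(3, size=n, p=probs)
    counts = np.bincount(g, minlength=3)
    present = counts[counts > 0]
    if present.min() < 3:
        raise ValueError(
            f"each represented genotype group needs >= 3 individuals, got {counts}"
        )
    y = rng.standard_normal(n) * sds[g]
    age = rng.uniform(20, 70, n)
    sex = rng.binomial(1, 0.5, n)
    bmi = rng.normal(25, np.where(rng.random(n) < 0.2, 3.0, 1.0))
    smoking = rng.binomial(1, 0.1, n)
    return pd.DataFrame(
        {"genotype": g.astype(float), "phenotype": y, "age": age, "sex": sex,
         "bmi": bmi, "smoking": smoking}
    )
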