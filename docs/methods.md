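# Methods

## The twin variance-QTL design

Monozygotic co-twins share genotype, age and sex. For a CpG whose
methylation Y is influenced by a genetic main effect, environmental
factors, a gene–environment interaction and noise, the within-pair
absolute difference |twin₁ − twin₂| is free of every pair-constant
influence — in particular the genetic *mean* effect — while a
genotype-by-exposure interaction makes the difference itself depend on
genotype whenever co-twins differ in exposure. Regressing the
covariate-adjusted difference on dosage therefore tests for variance
control without the distributional fragility of k-sample equal-variance
statistics; Bartlett's test is included in `evaluation` purely as the
cautionary comparator (its false positive rate exceeds 10% on χ²(1) data
where the twin models hold their level).

## Phenotype simulator

Each simulated CpG is

Y = a_G·s(G) + a_E·s(E) + a_GxE·s(G × smoking) + a_error·s(ε),

where s(·) is min–max scaling to [0, 1] computed over all 2n twin
individuals of the replicate, so Y is a valid methylation beta value and
the *shape* of each component is preserved. Weights sum to one with
a_error fixed at 0.2; the environmental weight absorbs whatever the
genetic terms do not take.

Covariates: age ~ Uniform(20, 70) and sex ~ Bernoulli(½), shared within a
pair; BMI drawn per twin from the pair's regime (80% of pairs
Normal(25, 1), 20% Normal(25, 3)); smoking ~ Bernoulli(0.1) independently
per twin, which yields ≈ 18% smoking-discordant pairs — the within-pair
exposure contrast that powers the design. The composite E is the
min–max-scaled equal-weight sum of scaled age, sex, scaled BMI and
smoking; the interaction term pairs dosage with the twin's own smoking
status. Noise laws: standard normal, χ²(df = 1), Gamma(shape = 2,
scale = ½) — the scale parameter of the gamma is irrelevant after min–max
scaling, only the shape matters. The M-value variant applies
M = log₂(β/(1−β)) with boundary clipping at ε = 10⁻⁶ (configurable).

Genotypes are drawn per pair under Hardy–Weinberg proportions and redrawn
(up to 1000 times) until all three genotype groups hold ≥ 5 pairs,
matching the SNP inclusion rule applied to real cohorts. The default
simulation MAF is 0.3: a common-variant value that satisfies the
group-size constraint comfortably at 350 pairs. All randomness flows from
one seed; per-replicate and per-locus streams are spawned
deterministically, so identical seed + configuration reproduces outputs
bit-identically.

The multi-locus generator (`simulate_cohort_genome`) lays SNPs in LD
blocks (block members are noisy copies of the block head; copy-noise 0
gives r² = 1) across two chromosomes at 50 kb spacing, wires CpGs to a
causal cis SNP 10 kb away, and labels each CpG mean-effect-only,
variance-effect-only, dual, or null. The default composition (30% /
10% / 15% / 45%) reflects blood methylation, where mean-QTLs vastly
outnumber variance-QTLs and most variance-CpGs also carry a mean signal.

What the simulator does **not** emulate: array measurement error, probe
cross-hybridisation, genome-wide LD structure, cell-composition
heterogeneity of the phenotype itself, or chorionicity effects. Passing
tests therefore demonstrate the statistical machinery under the stated
generative model, not performance on any particular array dataset.

## Residualization and the six models

Simulation covariate set — difference model: age, sex, Δ(BMI),
smoking-discordance indicator (0 concordant / 1 discordant); mean model:
age, sex, mean(BMI), smoking discordance. Cohort mode adds per-pair
cell-proportion differences/means and a batch-discordance indicator. All
fits are ordinary least squares; two-sided p-values use the t distribution
with residual degrees of freedom. Dosage is coded additively. For the
ratio models (Twins3/4), pairs with an exactly zero mean residual are
dropped and counted (never epsilon-inflated); fewer than 10 usable pairs
is refused. Twins5/6 include an intercept alongside the res(mean)
covariate.

A measured caveat: the ratio responses are heavy-tailed (res(mean) crosses
zero), and their slope t-tests are mildly anti-conservative even under
normal noise — the exact-null false positive rate of Twins4 sits near
0.06 rather than 0.05 at 350 pairs. This is one more reason the ratio
models are dominated by Twins1/2, whose calibration is clean on both
scales and all three noise laws. Conversely, Twins5/6 (which condition on
the mean residual) fail catastrophically when a genetic mean effect
coexists with skewed noise: conditioning on a collider of the genotype
and the noise drives their false positive rate towards 1.

## Conditional refit for shared signals

For a SNP that is both meQTL and vmeQTL for a CpG, the mean effect is
removed at the individual level before re-testing the difference. With MZ
pairs the family random intercept absorbs pair means, and because dosage
is pair-constant, subtracting the fitted genotype effect from both twins
is exactly equivalent (for every within-pair quantity) to the restricted
maximum likelihood mixed fit — the implementation uses this fast path and
documents the equivalence; within-pair differences are provably unchanged
by any pair-constant adjustment.

## QTL mapping

*cis*: window ±1 Mb (inclusive), best nominal association per CpG.
Permutation scheme: the pair-level residual vector is permuted against
pair-level genotypes (pairs are exchangeable units); per-permutation
window-minimum p-values are fitted by maximum likelihood to a Beta(a, b)
law (method-of-moments start; degenerate fits fall back to the empirical
rank p, flagged), and the empirical p is the beta CDF at the observed
minimum. Study-wide significance uses Storey q-values (λ grid 0.05–0.95
step 0.05, cubic-polynomial smoother for π₀ evaluated at λ = 0.95,
clipped to (0, 1]; with few CpGs π₀ falls back to 1, the
Benjamini–Hochberg limit). The per-CpG nominal threshold is the beta
quantile at the q = 0.05 crossing of the sorted empirical p-values, with
linear interpolation in q between the flanking values. Default 10,000
permutations for production use; the bundled analyses and tests use
1000–2500, which keeps the beta-approximated p within ±0.05 of a
5000-permutation empirical oracle.

*trans*: all pairs outside the cis window. The significance threshold is
the largest observed p-value t with
(N(p_perm < t)/N(p_real < t))/n_perm ≤ 0.05, pooling n_perm = 20
whole-matrix pair-label permutations. Significant trans SNPs are LD-clumped
per CpG so one index SNP represents each locus.

*LD clumping*: greedy — repeatedly take the smallest-p unassigned SNP as
index and absorb unassigned SNPs within 500 kb with dosage r² ≥ 0.2; ties
in p break by (chromosome, position, id). *Spurious filter*: per CpG with
both signal types, the union of its vmeQTL and meQTL SNPs is jointly
clumped; when the strongest signal in a clump is a meQTL, the variance
members are discarded — except a SNP that is itself both, which is routed
to the conditional refit and kept only if the variance signal survives
(p < 0.05). Imprinted-region exclusion uses half-open [start, end)
intervals; positions are 1-based throughout.

## Gene–environment interaction testing

Stage 1 fits methylation ~ (1|family) + (1|batch) + age + the covariates
*other than* the modifier of interest (MLR is always excluded; when MLR is
the modifier, stage 1 adjusts for age, BMI, smoking and the four cell
fractions). Crossed random intercepts are fitted by REML as variance
components within a single super-group; when every group is a singleton,
or the fit is singular, the implementation falls back to fixed-effects
dummies (flagged), which is exact in the singleton case. Conditional
residuals (observed minus fixed effects minus predicted random
intercepts) feed stage 2: residual ~ G + E + G·E with a t-test on the
product term, BH-adjusted across all association × modifier tests (pooled
by default; per-modifier pooling available). Keeping the modifier out of
stage 1 is enforced structurally — passing it among the stage-1
covariates raises.

## Singleton variance tests

DRM regresses |y − median(genotype group)| on dosage; SVLM regresses
squared stage-1 (mean-removal) residuals on dosage. Genotype groups use
hard calls (rounded dosage); the raw dosage remains the regressor. A
constant phenotype returns slope 0, p = 1 by convention. Replication
demands FDR < 0.05 under *both* tests.

## Enrichment

Two-tailed Fisher's exact test on the 2×2 membership table, with the
conditional-MLE odds ratio and 95% CI (a Haldane-corrected sample OR is
reported alongside when a cell is zero); annotations overlapping fewer
than 10 query signals are skipped rather than tested; BH adjustment across
annotations; families of related annotations aggregate by harmonic-mean
OR, n/Σ(1/ORᵢ), with the grouping supplied by the caller.

## Problem sizes and numerical choices

The bundled analyses and tests run at desk scale by design: 350 pairs,
genomes of up to 500 SNPs × 100 CpGs, 1000 replicates per simulation
cell (3000 where a rate estimate must discriminate values close to its
calibration bound), and 1000–2500 cis permutations. Production-scale runs
only change these counts. Matrix permutation scans are vectorised
(permutation × pair matrices against standardized dosages), so a full
cis scan of a 500-SNP/100-CpG genome takes a few seconds.

Degenerate inputs are handled explicitly: constant genotype → refusal;
constant residual vector → CpG marked degenerate; constant component
under min–max scaling → zero term (logged in the truth record); zero MLR
denominator → missing value. OLS residualization uses `lstsq`, so aliased
covariate columns are absorbed rather than fatal.

## Known limitations

- The twin design detects variance effects only insofar as co-twins
  differ in exposure; interactions with perfectly pair-shared exposures
  are invisible to it.
- The conditional refit cannot, even in principle, alter within-pair
  differences (pair-constant adjustments cancel); it adjudicates shared
  mean+variance SNPs by re-testing under the difference model rather than
  by removing mean-variance coupling.
- Storey's π₀ estimate is noisy below a few hundred tested CpGs; the
  implementation falls back towards BH, which is conservative.
- Twins3/4 are mildly anti-conservative (heavy-tailed ratio responses)
  and underpowered; they are retained for completeness of the model
  comparison, not recommended for mapping.
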