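# Methods

This note documents the statistical models implemented in `coralmme`,
the synthetic data they are validated against, and the design choices
made where alternatives existed.

## Setting

A reef-building coral metapopulation is sampled at site × habitat groups
(backreef 1–3 m, shallow forereef 3–5 m, deep forereef 10–14 m) at three
timepoints spanning a marine-heatwave mass-mortality event: adults during
the bleaching event ("pre", with a 1–5 bleaching health score, 1 = fully
bleached), adults after mortality subsided ("post"), and juveniles
recruited two years later (deep forereef only). Genotypes are hard-called
allele dosages (0/1/2, with a missing sentinel) at bi-allelic SNPs;
per-sample metadata carry site, habitat, depth, colony surface area,
health score, and WGS read counts mapping to three Symbiodiniaceae genera
(*Symbiodinium*, *Cladocopium*, *Durusdinium*; *Breviolum* is absent in
this system and excluded).

All statistics use pairwise-complete deletion: a missing dosage is
excluded from that statistic's denominator, never the whole sample.

## Quality control

- **Locus filters.** Minor-allele frequency among called genotypes ≥
  `maf_min` (default 0.05) and missing fraction ≤ `max_missing_frac`
  (default 0.2). Idempotent by construction.
- **Clones.** Pairwise identity-by-state distance = fraction of jointly
  called loci with unequal dosage; average-linkage hierarchical
  clustering cut at `clone_ibs_cutoff` (default 0.05, calibrated in tests
  with synthetic duplicates — with error-free hard calls true clones sit
  at distance ≈ 0 and unrelated colonies near 2pq·(…) ≈ 0.4). One
  representative per clonal group is kept (highest call rate, ties by
  id).
- **Relatedness.** Method-of-moments estimate: mean over loci of
  (dᵢ−2p)(dⱼ−2p)/(2p(1−p)) with sample allele frequencies — twice the
  kinship, so duplicates ≈ 1, full sibs ≈ 0.5, unrelated ≈ 0 (with a
  small negative bias of order −1/(n−1) from frequency estimation; panels
  of ≥ ~30 samples keep the sib/half-sib boundary usable). Pairs at
  ≥ 0.25 are treated as kin; the member of each flagged pair with more
  flagged partners is dropped first, ties dropping the lower call rate.
  "Below 0.25" is read as the *unrelated* region: sibs and half-sibs sit
  at or above 0.25 and are what the filter removes.

## Diversity and differentiation

- **Watterson's θ** per locus: S / a₂ₙ / L, with S the count of loci
  segregating among called genotypes, a₂ₙ = Σ_{i<2n} 1/i for n diploids,
  and L the loci with ≥ 2 called samples. Reported per usable locus so
  groups with unequal L are comparable.
- **π** per locus: mean over usable loci of 2p(1−p)·2n_l/(2n_l−1) with the
  per-locus called allele count 2n_l. Equals the mean pairwise haplotype
  difference (verified against a phased oracle).
- **Individual heterozygosity**: fraction of called loci with dosage 1.
- **Hudson F_ST** (Bhatia parameterization): per locus
  N = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1) and
  D = p₁(1−p₂) + p₂(1−p₁) with n the called allele counts; genome-wide
  F_ST = ΣN/ΣD (ratio of averages, which is consistent where the average
  of ratios is not). The raw estimate may be slightly negative under the
  null; only the report matrix clips to [0, 1] (logged).
- **Ordination**: dosages standardized by √(2pq), sample correlation
  matrix r, distance 1 − r, classical double-centered eigendecomposition
  (verified against scikit-bio's PCoA). The first two coordinates serve
  as ancestry covariates in the GWAS.
- **Group comparisons** of windowed θ/π use Dunn's rank test with tie
  correction and Benjamini–Hochberg adjustment; windows default to 1000
  loci (the windowing granularity is a config choice).

The statistics operate on hard calls. The study-scale analogue works from
genotype likelihoods; with synthetic, error-free data there is no call
uncertainty to propagate, so hard-call estimators are exact here. That
also means the test suite says nothing about likelihood-model robustness
at low coverage.

## GWAS

Quantitative trait: health score mapped through Φ⁻¹((rank−0.5)/n)
(average ranks for ties). Per locus, OLS of trait on dosage plus
covariates — the first two PCos, surface area, depth, and the
*Symbiodinium* and *Cladocopium* read proportions; depth is dropped
automatically when constant (single-habitat subsets). The scan is
computed by Frisch–Waugh–Lovell residualization (exact, and reduces a
genome scan to dense matrix products); loci with missing dosages are
refit exactly on their called subset.

Binary trait (pre vs post membership as a survival proxy): per-locus
logistic maximum likelihood via chunked batched Newton iterations, Wald
tests. Non-convergence (quasi-separation) falls back to a
linear-probability fit, flagged per locus, never silent. Zero-variance
dosage columns are skipped with p = 1.

**Genome-wide significance**: trait values are permuted across samples
(covariates stay with their samples), the scan re-run, and the minimum p
recorded; the threshold is the 5% quantile of that min-p distribution —
the cutoff below which only 5% of null genome scans produce any hit,
i.e. a 5% family-wise error rate. Desk-scale default 200 permutations
(configurable to the study-scale 10,000); fewer than 20 is refused as the
quantile is unstable. Missing dosages are mean-imputed inside the
permutation scans.

## Polygenic scores

PGS construction is p-value thresholding followed by greedy LD clumping:
candidates with p below the threshold are visited in ascending p (ties by
chromosome, position); a candidate is dropped if an already kept locus on
the same chromosome lies within `clump_window_bp` (default 250 kb) and
has dosage r² > `clump_r2_max` (default 0.5) — PLINK's documented
defaults, configurable. The greedy keep-list has a prefix property (the
list at a stricter threshold is the loose-threshold list filtered by p),
which the cross-validation exploits to clump once per partition.

Scores are PGS_i = Σ_l dosage_il·β_l with training-GWAS betas;
missing dosages are mean-imputed (logged), and model loci absent from a
target matrix are dropped (error if over half are).

**Jackknife cross-validation**: 100 seeded random 85/15 train/test
partitions; per partition a training-only GWAS, the threshold grid
{5e-8 … 0.5}, and test-set R² from the score alone. R² is the squared
Pearson correlation between score and trait — for a binary trait the
squared point-biserial correlation, so both trait kinds report on one
scale. The threshold maximizing mean test R² wins.

**Null PGS**: each partition's selected set is mapped through one fixed
random permutation of the locus index (drawn once per CV), keeping its
training betas. This is a random locus set of matched size, but it
inherits the real sets' persistence across overlapping partitions —
without that, the real-vs-null Mann–Whitney comparison is
anticonservative under zero heritability, because the best-threshold
selection gains more from the higher between-partition variance of the
persistent real sets. With the matched construction the comparison is
calibrated (measured: ~1 false significance in 10 null cohorts) while
power under h² = 0.5 is unchanged.

**Model comparison**: per partition, trait ~ covariates and trait ~
covariates + PGS are fit on the test samples; the two R² distributions
are compared by one-sided Mann–Whitney U, BH-adjusted across the supplied
PGS family (the null PGS serving as the overfitting control).

**Transfer**: betas trained in one habitat score another habitat's
samples; the observed R² is placed within the distribution from 500
random locus sets of the same size, at thresholds {1e-2, 1e-3, 1e-4}.

## Temporal selection

- **Convergent correlation**: Pearson r between two sites' per-locus
  allele-frequency shifts Δp = p_post − p_pre over shared loci (≥ 50
  required). Shared selection produces concordant shifts; drift is
  uncorrelated between sites. CIs are percentile bootstrap over loci,
  default 95% from 1000 resamples (both configurable; a 97.5%/100
  variant is a flag away). Self-comparison returns exactly 1.
- **Effect-size-sum test**: Σ|β| over a locus set from a GWAS, against
  the same statistic on `n_random_sets` (default 500) random equal-size
  sets; reported as the observed percentile and exceedance of the null
  95th percentile. |β| (not signed β) measures total signal magnitude;
  the signed variant is available behind a flag.
- **Overlap**: loci below p = 1e-2 in both of two GWAS; optional gene
  annotation within ±500 kb.
- **DAPC**: standardized dosages → PCA (retaining by default the axes
  explaining 80% of variance, a retention rule that had to be fixed
  somewhere) → linear discriminant analysis on group labels → query
  samples projected and assigned by maximum posterior. Used for juvenile
  source assignment (trained on adult site groups, χ² goodness-of-fit of
  predicted source counts against uniform) and for the pre/post LD1 axis
  onto which juveniles are projected.
- **Forward simulation of the MME**: genotypes ~ Binomial(2, p₀ = 0.1);
  individual score = summed dosage over the adaptive loci (unit effects —
  no effect-size distribution is asserted beyond that, configurable);
  survivors = top 30% of scores (seeded random tie-break); pre-subsample
  from the full population and post-subsample from survivors emulate
  field subsampling; per-locus logistic regression pre- vs post-subsample
  flags outliers at p < 0.01; juveniles ~ Binomial(2, survivor allele
  frequency). Outlier sets mix true adaptive loci with subsampling false
  positives: in the next generation the false positives regress to the
  survivor (≈ population) frequency while true adaptive loci stay
  shifted, so juveniles project between the two subsamples on the
  outlier-locus LD1 — the simulation's central qualitative result.

  The outlier scan uses the likelihood-ratio p rather than the Wald p:
  at subsample sizes of ~20 per timepoint the Wald statistic is severely
  conservative (measured ~0.0005 at nominal 0.01) where the LRT is close
  to nominal (~0.013–0.015, mildly liberal), and under quasi-separation
  the likelihood supremum is still well-defined even though the
  coefficient diverges. Degenerate likelihoods fall back to a
  Firth-penalized fit. Consequently the null outlier count sits within a
  factor ~1.5 of L·p_cut at these sample sizes, not exactly at it.

## Symbionts

Genus proportions are read counts normalized per sample; zero-total
samples are flagged undefined and excluded. Health associations per
habitat use Pearson correlation with the t-transform p. The cross-habitat
model is a Gaussian-identity GLM (the link had to be chosen; identity is
the simplest defensible reading for a 1–5 score):
health ~ habitat × (prop_Symbiodinium + prop_Cladocopium) + surface area
+ site, with the shallow forereef as the reference level. Timepoint
shifts use Mann–Whitney U (exact for ≤ 10 per group, tie-corrected normal
otherwise). The redundancy analysis regresses a response matrix (e.g.
one-hot symbiont dominance, defined as the argmax-proportion genus) on a
predictor design; R² = trace(fitted′fitted)/trace(Yc′Yc), p from
permuting predictor rows. Note the two compositional proportions are
strongly collinear when communities are two-genus dominated; the
interaction GLM loses power in that regime even when the per-habitat
correlations are strong — a caveat that applies to real data too.

## Synthetic cohorts

The generator reproduces the statistical structure the analyses assume,
not coral biology:

- **Structure**: per-site allele frequencies from the Balding–Nichols
  construction, Beta(p(1−F)/F, (1−p)(1−F)/F) around ancestral frequencies
  (default Beta(2,2) clipped to [0.02, 0.98]; a fixed-p mode matches the
  forward simulation's Binomial(2, 0.1) scheme) with F = `fst_target`
  (default 0.015, realized mean pairwise Hudson F_ST lands within ±50% of
  target). 19 site × habitat × timepoint groups of 12–26 colonies: 9 pre,
  7 post, 3 juvenile (deep forereef).
- **Pools**: each group is backed by a population pool (default 80
  colonies). Pre and post cohorts are random subsamples of the pool and
  its survivors respectively, so the post groups keep field-realistic
  sizes and timepoint sampling bias is part of the design.
- **Liability**: standardized polygenic term scaled to variance h²
  (default 0.3) + covariate term (depth −0.2, size +0.3 on standardized
  scales) + habitat-signed symbiont term, with the structured environment
  carrying 40% of the non-genetic variance and Gaussian noise the rest —
  a fixed split chosen so covariate and symbiont signals are detectable
  without dominating. Health score = pool liability quintiles mapped to
  1–5.
- **Mortality**: top `survival_fraction` (default 0.3) of each pool by
  liability.
- **Juveniles**: dosage ~ Binomial(2, p_source) with p_source the
  fecundity-weighted survivor allele frequency over deep-forereef sites
  (default weights 0.6 on the least-stressed site, emulating
  recruitment dominated by one source). An explicit-mating mode draws two
  site-weighted survivor parents per juvenile and transmits one allele
  from each, recording parentage for pedigree tests.
- **Symbionts**: per-habitat Dirichlet communities whose mean shifts with
  the health z-score by habitat-signed slopes in [−1, 1] (defaults encode
  the shallow-vs-deep sign reversal), multinomial read counts at
  Poisson-distributed depth.

What the generator does **not** emulate: linkage (loci are independent,
spread evenly over 14 chromosomes of a 450 Mb genome, so LD clumping is
exercised by engineered correlated columns in tests rather than by the
generator), genotyping error and coverage variation, isolation by
distance, overlapping generations, migration from unsampled reefs, and
temporal environmental autocorrelation. Passing tests therefore validate
the estimators and the pipeline's calibration under the assumed design,
not robustness to those real-data complications.

## Problem sizes and numerical choices

Default test and acceptance runs use 300–5000 loci, cohorts of 150–500
samples, 200–400 permutations, 500 random sets, and 1000 bootstrap
resamples — sizes chosen so every calibration (family-wise error over 200
replicate cohorts, 20-seed null cross-validations, 100-seed coverage
checks) is a routine run on a laptop; all counts scale up by config.
Every stochastic routine takes a seed or `numpy.random.Generator`;
outputs echo the seed. Ties are broken deterministically (stable sorts,
id order) except the truncation cut in the forward simulation, where the
tie-break is an explicit seeded coin flip. Eigenvalues below 1e-10 are
treated as null axes in the PCoA; logistic Newton iterations cap steps at
5 and declare separation at |β| > 12.

## Known limitations

- The jackknife partitions overlap, so their test R² values are not
  independent; the Mann–Whitney real-vs-null p is calibrated by the
  matched-null construction but remains approximate.
- The permutation-threshold FWER is itself a stochastic quantity; with
  200–400 permutations its realized value varies by a few percentage
  points around 5% between cohort realizations.
- Binary GWAS betas mix logistic log-odds with (flagged)
  linear-probability fallback values; sum-based statistics should be
  computed on scans with few fallbacks (the tables carry the flag).
- Relatedness estimates shrink toward zero at very small panel sizes
  because allele frequencies are estimated from the same samples.
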