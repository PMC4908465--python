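# Methods

This document describes the statistical models and algorithms implemented
in `hybridzone`, the defaults they ship with, and their known limitations.
Throughout, "ancestry" (q) means the proportion of an individual's genome
tracing to parental pool 1 (the red-wolf pool), and genotypes are diploid
multilocus microsatellite-style data with whole-locus missingness.

## 1. Synthetic data generation (`hybridzone.synthetic`)

### Parental pools

`generate_parental_frequencies` draws, per locus, an ancestral frequency
vector from a symmetric Dirichlet with concentration `ancestral_alpha`
(default 1), then derives the two parental pools as independent
Balding–Nichols perturbations: each pool's frequency vector is
Dirichlet-distributed with concentration `ancestral · (1 − d)/d`, where
`d` is the divergence parameter. Under this construction the expected
Weir–Cockerham F_ST between the two pools increases monotonically with
`d` and empirically tracks it closely (e.g. mean F_ST ≈ 0.198 at
d = 0.2). The two limits are handled exactly: `d = 0` duplicates the
ancestral draw, `d = 1` fixes the pools for different alleles wherever the
locus has at least two.

Defaults (17 loci, 8 alleles per locus, divergence 0.5) mimic a
moderately diagnostic microsatellite panel for two well-differentiated
species. Note that Balding–Nichols sampling at d = 0.5 loses much of the
ancestral diversity (mean within-pool expected heterozygosity ≈ 0.39);
simulated panels are therefore somewhat less polymorphic than typical
empirical canid panels at the same F_ST.

### Landscapes

`generate_landscape` lays zones out west→east as consecutive unit
intervals on the x-axis (or user-supplied polygons, sampled by rejection),
draws each zone's configured counts of red wolves, coyotes, F1, F2 and
backcross individuals via the hybrid simulator (§5), and records true
class and true ancestry in the metadata. The packaged
`study_default_config` produces a 311-individual, 6-zone survey (75 red
wolves, 224 coyotes, 12 hybrids) with an east-to-west declining ancestry
gradient.

### Replicate-PCR observation model

`simulate_replicate_pcrs` generates per-sample, per-locus, per-replicate
observed allele sets under three error processes applied in order:
whole-reaction amplification failure (probability `failure_rate`, default
0.2 — the replicate observes nothing), allelic dropout (each true allele
of a heterozygote independently lost with `dropout_rate`, default 0.15),
and false alleles (with `false_allele_rate`, default 0.05, one uniformly
chosen wrong allele from the locus registry is added). The default rates
are in the range reported for noninvasive scat genotyping; they are
deliberately pessimistic so that the consensus rules (§2) are exercised.

## 2. Consensus genotyping, matching, PID (`hybridzone.matching`)

### Consensus rules

Per sample and locus, over all replicates: an allele is *supported* if it
appears in ≥ 2 replicates. A heterozygote is called iff exactly two
alleles are supported. A homozygote is called iff exactly one allele is
supported and it appears *alone* in ≥ 3 replicates. Three or more
supported alleles flag the locus as contaminated/erroneous, and it is set
missing. Samples with fewer than `min_loci` (default 6) accepted loci are
excluded and reported with a reason.

### Matching and regrouping

`match_genotypes` compares genotypes over shared typed loci; a pair with
fewer than `min_overlap` comparable loci is "no-comparison", with ≤
`max_mismatch` (default 0) mismatching loci a "match". Regrouping builds
connected components (union–find) over pairwise matches, so repeated
detections of one individual collapse into a single record whose genotype
is the per-locus majority consensus (deterministic tie-breaks make the
result invariant to input order), whose coordinates are the centroid of
the member samples, and whose zone is derived from that centroid — a
repeatedly detected animal is counted once, in one zone.

### Probability of identity

For allele frequencies p_i at one locus,
PID = Σ p_i⁴ + Σ_{i<j} (2 p_i p_j)², and
PID_sibs = 0.25 + 0.5 Σ p_i² + 0.5 (Σ p_i²)² − 0.25 Σ p_i⁴.
Multilocus values are products over loci; the report includes cumulative
products in panel order so the resolving power of a locus subset can be
read off directly.

## 3. Population-genetic summaries (`hybridzone.popgen`)

- **Hardy–Weinberg exact test**: Monte-Carlo version of the exact test —
  the observed allele pool is randomly re-paired into diploid genotypes
  (equivalently, tables are drawn conditional on allele counts), each
  table's probability is evaluated under Levene's conditional
  distribution, and p = (#{P_table ≤ P_obs} + 1)/(n_mc + 1), with the
  observed table included in numerator and denominator. The test suite
  validates the implementation against complete enumeration of all tables
  with the observed allele margins. A global test across loci combines
  per-locus p-values with Fisher's method.
- **F-statistics**: Weir & Cockerham (1984) variance components a, b, c
  per allele, summed over alleles and loci before taking ratios
  (F_ST = a/(a+b+c), F_IS = 1 − c/(b+c), F_IT = 1 − c/(a+b+c)). With a
  single population only F_IS is defined. Frozen hand-computed toy values
  guard the implementation.
- **Heterozygosity**: observed and unbiased expected
  (H_E = 2n/(2n−1) · (1 − Σ p²)).
- **Allelic richness**: groups are resampled with replacement to the
  smallest group's size; A_R is the mean over resamples of the mean
  per-locus distinct-allele count, with a percentile 95% CI.
- **Wahlund regression**: per-locus F_IS regressed on per-locus F_ST
  (Pearson r, slope, intercept, p). When a sample pools two differentiated
  populations, the most differentiated loci show the largest heterozygote
  deficits, so a positive correlation is a Wahlund-effect signature.
- **F_IS bootstrap**: bias-corrected percentile CI over loci resampled
  with replacement.

## 4. Bayesian admixture model (`hybridzone.admixture`)

A Gibbs sampler over the classical admixture model: each allele copy of
individual i at locus l carries a latent cluster of origin Z; given Z,
q_i ~ Dirichlet(α + counts) and cluster frequencies P_k are conjugate
Dirichlet. Two frequency models:

- *uncorrelated*: P_k ~ Dirichlet(λ = 1) prior per locus;
- *correlated* (default): P_k ~ Dirichlet(P_A (1 − F_k)/F_k) around an
  ancestral vector P_A with per-cluster drift F_k. P_A is updated by
  Metropolis with a Dirichlet proposal (concentration 100); F_k by
  Metropolis on log F with a uniform(0,1) prior.

The symmetric Dirichlet hyperparameter α (one value shared by all
clusters) is updated by Metropolis on log α (step 0.1, uniform(0, 10)
prior). All log-scale Metropolis updates include the proposal Jacobian.
Sweeps: `burnin` discarded, `reps` retained, every `thin`-th (default 10)
contributing to the posterior summaries (mean q and equal-tailed 90%
interval, widened if needed to bracket the mean). The model
log-probability used for ΔK is the harmonic-style estimator
mean(log L) − var(log L)/2 over retained sweeps.

Replicate runs (default 5) differ only by seed. `align_runs` resolves
label switching by permuting each run's clusters to best match the
running mean of the previously aligned runs; the optimal permutation is
found as a linear assignment on the q-matrix cross-products, which is
exactly the best of all K! permutations. `evanno_deltaK` implements
ΔK = |L(K+1) − 2L(K) + L(K−1)| / sd(L(K)) over ≥3 consecutive K with ≥2
runs each. `anchor_clusters` orients the composite so cluster 1 is the
red-wolf cluster, using known-species individuals; knowns whose majority
cluster contradicts their species raise an error (or a warning with
`strict=False`), and the mean q of knowns in their species' cluster is
reported as anchoring confidence.

Default chain lengths (burn-in 5 000, 50 000 reps) are desk-scale: on
typical two-cluster problems they reproduce far longer runs' composite q
within a few hundredths, while keeping a full 5-run composite on ~300
individuals around four minutes.

### Accuracy expectations

On the default synthetic landscape (divergence 0.5, 17 loci, 50
individuals in each of 6 classes) the composite posterior-mean ancestry
has a mean absolute error of ≈ 0.057 against the class expectations.
Two floors bound what is achievable: the realized ancestry of F2 and
backcross individuals scatters around the class expectation (sd 0.086 and
0.061 at 17 unlinked loci), and even a maximum-likelihood oracle given
the *true* pool frequencies attains MAE ≈ 0.048 on the same data.
Parental-class error (≈ 0.035) is dominated by Dirichlet(α) shrinkage
with the data-supported α ≈ 0.65 — expected behaviour when most of the
sample is genuinely admixed.

## 5. Hybrid-class simulation (`hybridzone.hybridsim`)

Gamete-based: parental gametes draw one allele per locus from the pool
frequencies; an F1 gamete picks, independently per locus, the P1- or
P2-derived allele of a fresh F1 parent with probability ½. Classes are
composed from gametes (F1 = P1×P2, F2 = F1×F1, BC1 = F1×P1, BC2 = F1×P2).
Loci are unlinked, there is no mutation, and expected ancestries are
exactly 1, 0, 0.5, 0.5, 0.75, 0.25 for P1, P2, F1, F2, BC1, BC2. The
test suite pins the Mendelian consequences (fully heterozygous F1 under
diagnostic pools, 1:2:1 F2 segregation, backcross allele dosages).

## 6. Scenario testing (`hybridzone.scenario`)

### Composition solve

Each region contributes a total T and an observed mean ancestry q̄. For a
*core* region, the scenario's hybrid proportion p_h fixes
H = round(p_h · T), and the ancestry balance q̄·T = 0.5·H + R gives the
red-wolf count R (hybrids contribute ancestry 0.5 by construction),
with coyotes the remainder. A *peripheral* region attributes its small
residual ancestry to hybrids when the scenario allows hybridization
(H = round(q̄·T/0.5)) and to red wolves otherwise (R = round(q̄·T)). All
rounding is half-up; infeasible regions (negative implied counts) raise
an error naming the region. The hybrid total is split as evenly as
possible over F1, F2, BC1, BC2, assigning any remainder in the order F1,
BC1, BC2, F2.

For the study's region totals (180 at q̄ = 0.437, 131 at q̄ = 0.024) the
solve yields 44/192/75 (red wolves/coyotes/hybrids) at p_h = 0.386,
54/201/56 at 0.276, 62/209/40 at 0.189 and 82/229/0 at 0. Note the
assortative row sums to 311 with 201 coyotes — this is the direct result
of the balance equation; an off-by-one coyote count in this scenario
would make the region totals inconsistent.

### Comparison metrics

Each scenario composition is simulated (§5), pushed through the same
admixture pipeline as the empirical data (K = 2 replicate runs,
composited, anchored via appended simulated known parentals), and
compared to the empirical ancestry distribution by:

- the two-sample Kolmogorov–Smirnov distance D (supremum over pooled
  points, exact for ties; asymptotic p-value), and
- the steepness c of y = a / (1 + e^(−c (x − b))) fitted by nonlinear
  least squares to the ancestry values sorted ascending against their
  1-based rank. A bimodal, parental-dominated distribution jumps from
  coyote-like to wolf-like over few individuals (large c); abundant
  intermediates flatten the curve (small c). Initialisation:
  a₀ = max(y), b₀ = N/2, c₀ = 4(y₍₃N/₄₎ − y₍N/₄₎)/(N/2).

A practical caveat: the K-S distance between two nearly-point-mass
samples at slightly different support values is large (~0.5) even when
their shapes agree, so empirical reference distributions should come from
the same estimator (the admixture pipeline), not from idealised 0/1
values.

### Zone summaries

`zone_summary` reports per-zone mean ancestry with a one-way ANOVA
(computed from sums of squares so the pooled mean square is shared with
the post-hoc test), Fisher's-LSD letter groupings, Bonferroni-corrected
t-based zone CIs, and a chi-square test of the observed distribution of
classified hybrids across zones against equal expected counts — both
asymptotic and Monte-Carlo p-values, the latter preferred when hybrid
counts are small. Classification thresholds default to q ≥ 0.875 (red
wolf) and q < 0.125 (coyote), the conventional two-backcross-generation
boundaries.

## Limitations

- The admixture sampler has no linkage model, no location prior, and no
  option to condition on known-origin individuals during sampling;
  anchoring is purely a post-hoc labelling step.
- The Balding–Nichols pool construction ties within-pool diversity to the
  divergence parameter; highly diverged pools are also low-diversity.
- The observation model treats loci and replicates as independent; real
  noninvasive data show sample-quality correlations across loci.
- Peripheral-region composition attributes residual ancestry entirely to
  one class (hybrids or red wolves); mixtures are not solved for.
- The logistic steepness is a shape summary of the sorted-ancestry curve,
  not a spatial cline model; coordinates do not enter the fit.
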