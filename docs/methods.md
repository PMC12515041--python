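# Methods

`guildcraft` analyses gut-microbiome amplicon data at the level of
*guilds* — co-abundance groups (CAGs) of ASVs that covary across samples
and are treated as single ecological units — and compares that route
against conventional genus-level aggregation.  This note documents the
models, the estimators, the numerical choices, and what the synthetic
benchmark does and does not establish.

## The guild inference chain

1. **Rarefaction.** Counts are subsampled without replacement to a fixed
   library size per sample (default 18 000 reads), drawing from the
   multivariate hypergeometric distribution.  Samples below the depth are
   dropped with a warning; the behaviour for shallow samples is a package
   choice, since rarefaction conventions differ.

2. **Prevalence filter.** ASVs present (nonzero) in more than 25% of
   samples are retained.  "More than" is read strictly (`>`); a flag
   switches to `>=`.  Prevalence is computed across all supplied samples
   pooled (both sampling timepoints), since the correlations downstream
   also use both.

3. **Robust CLR.** Each sample is transformed to
   `ln(value / geometric mean of the sample's nonzero values)`; zero cells
   become missing values, never pseudo-counted.  Missingness therefore
   propagates to the correlation step as pairwise-complete observation.

4. **Repeated-observations correlation.** Because every mouse contributes
   a baseline and an end-of-study sample, ordinary correlation across
   samples would conflate between-animal and within-animal covariation.
   The correlation between ASVs j and k removes per-subject means
   (Bland–Altman repeated-observations form):

       r = Σ_ij (x_ij − x̄_i)(y_ij − ȳ_i)
           / sqrt( Σ_ij (x_ij − x̄_i)² · Σ_ij (y_ij − ȳ_i)² )

   with i over subjects and j over their observations, restricted to
   observations where both ASVs are non-missing.  Undefined entries (zero
   within-subject variance, or too few complete pairs) are recorded as 0,
   i.e. a neutral distance of 1 — dropping the feature would silently
   change the variable set.  The matrix implementation expands the
   centered sums into masked matrix products per subject, so all pairs are
   computed at once; it is exact, and a test checks every entry against
   the scalar formula.

5. **Ward tree and clade testing.** The 1 − r distance matrix is
   clustered with Ward's method (the `ward.D2` criterion operating on the
   distances as given; `ward.D1` is available by clustering sqrt(d) and
   squaring merge heights).  From the root downward, each internal node's
   two child clades are a candidate split scored by the PERMANOVA
   pseudo-F on the node's distance sub-matrix.  Splitting recurses while
   p < 0.001 (9 999 permutations by default); where it stops, the subtree
   is one CAG.  CAG abundance is the sum of member ASV counts, and CAGs
   are numbered by decreasing mean abundance.

### The split-test null (a deliberate design choice)

The tested grouping at each node is the Ward-optimal division of the very
matrix being tested.  Freely permuting item labels therefore compares a
maximized statistic against unmaximized ones: on structureless distance
matrices the observed F sits at or near the permutation maximum and the
label-permutation p-value hits its floor at every node, so pure noise
fragments into many spurious CAGs.  `split_cags` instead uses a
selection-aware empirical null: each permutation shuffles the node's
condensed pairwise distances, re-runs Ward on the shuffled matrix, and
scores the F of *that* tree's own top split.  The same optimization is
applied to exchangeable-pair data, which calibrates the test — i.i.d.
distances yield a single CAG at the nominal rate, while planted blocks
are still detected immediately.  Two consequences:

- The permutation loop stops early once enough permuted F values exceed
  the observed one to force p ≥ alpha; the reported p is then a
  conservative partial estimate but the split/stop decision equals the
  full run's.  Each node derives its RNG stream from the node id, so
  decisions are reproducible and monotone in alpha.
- Nodes too small for the permutation granularity to reach significance
  (factorial of the pair count below 1/alpha) become CAGs untested.

The standalone `permanova` function keeps the conventional contract —
pseudo-F with label permutations, exhaustive enumeration when the number
of distinct relabelings is at most `n_perm` — and is what the community
module uses for group comparisons, where groups are defined a priori and
the issue above does not arise.

Limits: with many features and moderate within-guild correlation
(measured at 300 ASVs, within-block r = 0.6, 60 samples), correlation-
estimation errors — which are mutually dependent because pairs share
features — occasionally look like genuine sub-structure, and a large
guild splits once more than planted (adjusted Rand index 0.84–0.97
instead of 1.0).  At within-block r = 0.7, recovery at 60–120 features is
essentially exact.

## Genus comparator and the data-reduction ledger

The genus route mirrors published practice: ASVs whose taxonomy string
lacks a usable genus rank (empty, `g__`, `uncultured…`, `unclassified…`,
or truncated above genus) are excluded; the rest are summed into genera,
where genus identity is the full lineage down to the genus rank so
homonymous genera in different families do not merge; the same strict
prevalence cutoff is then applied.  The four-level ledger tracks, for
each route, the number of variables, the reads retained (aggregation
conserves member reads exactly, so stage sums map back to ASV reads),
the percentage of the rarefied total, and the sparsity (percent zero
cells).  Percentages are rounded half-up to two decimals to match
printed-table conventions.

## Community statistics

- Shannon diversity uses log base 2 (bits), the QIIME2 convention; a
  natural-log option exists.  Observed richness is the nonzero count.
- Bray–Curtis is computed by `scipy.spatial.distance.pdist`.
- PCoA double-centers −d²/2 and eigendecomposes.  Negative eigenvalues
  (expected for semi-metric dissimilarities) are reported, not silently
  dropped, but excluded from coordinates; no Cailliez correction.
- Pairwise PERMANOVA adjusts p-values across group pairs with
  Benjamini–Hochberg.
- Procrustes superimposes two ordinations after centering, unit
  sum-of-squares scaling and optimal rotation; m₁₂² is the residual sum
  of squares (`scipy.spatial.procrustes`).  PROTEST permutes the sample
  rows of the second configuration; p = (1 + #{m₁₂²_perm ≤ observed}) /
  (1 + n_perm), 999 permutations by default.  Axes are truncated to the
  shared positive-eigenvalue count (configurable cap); both full-rank and
  2-axis comparisons are legitimate published variants, and the choice is
  logged with the result.
- The information-loss score is m₁₂²(genus vs ASV) / m₁₂²(guild vs ASV);
  it is undefined (NaN) when the guild residual is exactly zero.

## Marker discovery

Shadow-feature selection follows the Boruta scheme on a random forest
(500 trees by default): each iteration appends a row-permuted shadow copy
of every candidate, and a candidate scores a hit when its
mean-decrease-in-impurity importance exceeds the best shadow's.  A
cumulative two-sided binomial test (p = 0.5, Bonferroni across features)
promotes features to confirmed or rejected; rejected features leave the
model matrix, which progressively lowers the shadow ceiling — without
this, weaker true signals rarely confirm.  Hits are scored on the
forest-level mean importance rather than the per-tree Z-score because the
per-tree standard deviation of impurity importance scales with its mean,
making the Z ranking unstable for rarely selected features; per-tree
Z-scores are still recorded for the conventional Boruta box plots.
Tentative features are reported as such, never force-resolved.

Classifier validation uses 5-fold, 5-repeat stratified cross-validation;
out-of-fold class probabilities are pooled across all folds and repeats
into one trapezoidal ROC/AUC.  The phenotype screen computes Spearman rho
with tie-corrected p for every feature × phenotype pair and applies BH
across the whole grid; health-relevant features are those both confirmed
by the selector and significant (q < 0.05) for at least one phenotype.

## Diurnal rhythm detection

The empirical JTK test fixes the period (24 h) and compares each series
against cosine references `cos(2π(t − φ)/period)` on a phase grid (step =
sampling interval, 6 h by default; references with identical rank
patterns are deduplicated, leaving ≤ 4 per cycle at 6-h sampling).
Replicates within a timepoint share the reference value, so Kendall's
tau-b with tie correction is the match statistic; the observed statistic
is the maximum tau over phases, and the p-value is empirical, from
permutations of the values across all time-replicate slots.  Asymmetric
waveforms (full eJTK's asymmetry grid) are not searched; only the period
is fixed, matching the analysis being emulated.  Waveform values are
rounded to 12 decimals so symmetric timepoints tie exactly.  The
permutation arithmetic runs on precomputed sign matrices, which is what
makes the 1 000-series calibration suites affordable.  Because the test
is rank-based, its p-value is invariant to monotone transforms of the
series; the floor is 1/(n_perm + 1).

## Synthetic data generator

The generator emulates the study design it is benchmarked against: four
arms (normal-fat vs high-fat diet × ad libitum vs time-restricted
feeding), 15 mice per arm sampled at baseline and after intervention,
~1 100 ASVs at ~80% sparsity and depth 18 000; a 6-hourly two-day time
course with 3–5 replicates per timepoint; SILVA-style taxonomy strings
with a configurable fraction of genus-unclassifiable ASVs (default 0.4,
matching the roughly 40% of ASVs a murine dataset loses at genus rank).

Each feature belongs to one block (planted guild).  Log abundance is
`mu_f + sigma(√ρ·z_block + √(1−ρ)·ε) + subject intercept + group effect`,
with `z_block` shared within a block per sample, so the pairwise
within-block log-scale correlation is ρ by construction.  Group log-fold
effects apply to post-intervention samples only; rhythmic blocks add
`amplitude · cos(2π(zt − phase)/24)`.  Compositions are the softmax of
the log abundances; a per-cell dropout calibrated against the expected
multinomial zero rate brings the zero fraction to the sparsity target
(±5 points), and multinomial sampling at the library depth makes every
sample total exact.  Log-normal latent factors with multinomial counts
were chosen over a Dirichlet-multinomial because the pipeline's target
statistic is the pairwise correlation structure, which this model
controls directly.  Phenotypes are linear in block relative abundances
plus Gaussian noise; an OGTT-shaped glucose curve can be emitted whose
trapezoidal AUC equals the sample's planted value exactly.

What the generator does *not* emulate: phylogenetic signal in the
taxonomy, cage effects beyond labels, sequencing batch effects,
overdispersion beyond the log-normal latent scale, and the abundance-
dependent zero patterns of real libraries (dropout here is uniform per
cell).  Passing benchmarks therefore demonstrate correctness of the
estimators under the stated generative model, not performance guarantees
on real sequencing runs.

## Benchmark conditions and their sizes

The recovery and calibration suites run at the scales the analysis is
designed for, with permutation counts chosen as the smallest that leave
the significance thresholds reachable:

- Guild recovery: 60 samples (30 mice × 2 timepoints), depth 20 000,
  planted 4-block (60 ASVs) and 8-block (120 ASVs) communities at
  within-block r = 0.7, split alpha 0.001 with 1 999 permutations (floor
  5×10⁻⁴); 20 seeds.  Unstructured (r = 0) communities must stay a
  single CAG.  Recovery configs use a moderate abundance spread
  (log-scale SD 1.0): under the study-like heavy tail, rare ASVs'
  attenuated correlation estimates form genuine abundance tiers inside
  blocks, which real pipelines remove with the prevalence filter.
- Rhythm: type-I error over 1 000 Gaussian null series (8 timepoints × 3
  replicates, 499 permutations) must stay within [0.03, 0.07]; power at
  amplitude/noise = 2 must reach 0.9 with the recovered phase within ±3 h
  (half the sampling interval) of truth.
- Markers: 5 planted features at exactly 1 SD class separation among 50
  noise features, 60 samples — ≥4/5 confirmed in ≥90% of 20 seeds with on
  average ≤2 chance confirmations; a pure-noise run must leave ≥95%
  unconfirmed.  Classifier AUC ≥ 0.9 on generator communities with 1.2
  log-fold group shifts, and near 0.5 on label-independent features.
  The 1-SD separation is enforced in realization (not just in
  expectation) because at this sample size the realized shift otherwise
  varies by ±0.4 SD, which tests the draw rather than the selector.

Reference values recorded from the emulated study, reproducible only
from its deposited sequencing data (not recomputed here): 293 prevalent
ASVs forming 34 CAGs (96% of reads) vs 660 classifiable ASVs forming 126
genera (78% of reads); discriminating-CAG AUC 0.960; information-loss
scores 1.99 (baseline) and 0.51 (week 12); rhythmic CAGs rising from 5
(ad libitum high-fat) to 20 (time-restricted high-fat).
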