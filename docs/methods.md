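# Methods

## The measurement model

A two-species mixture experiment produces one library per known spike
fraction Q_j ∈ [0, 1]. After mapping against a joint two-genome reference
and per-gene counting (htseq-count dialect: two tab-separated columns,
trailing `__`-prefixed summary counters), gene *i*'s count in library *j*
is A_ij. Comparisons across libraries assume equal depth, so all
libraries are first subsampled to a common target — by default the
minimum mapped depth across libraries. Subsampling is implemented as a
multivariate hypergeometric draw on each count vector (drawing reads
without replacement after counting is statistically identical to
subsampling the mapped reads before counting); column sums hit the target
exactly and no count can grow.

### Normalization

Each gene is rescaled by the least-squares no-intercept slope of its
counts on the spike fractions:

    s_i = Σ_j Q_j A_ij / Σ_j Q_j² ,   Â_ij = A_ij / s_i .

This is a per-gene positive constant whenever the gene has any count in a
positive-Q library, so it changes neither the per-gene Pearson
correlation with Q nor the shape of the response — it only maps a
perfectly proportional gene onto Â = Q (slope 1, intercept 0). Genes with
s_i = 0 have no defined normalization; they are flagged `excluded` and
carried through so downstream reports can count them. The exact
projection identity Σ_j Q_j Â_ij / Σ_j Q_j² = 1 holds for every
non-excluded gene and is enforced by tests to 1e-9.

### Filtering and fitting

Only spike-species genes with at least 20 fragments (inclusive) in the
highest-Q library are analyzed; below that, counting noise at the lower
fractions (a gene at the threshold carries an expected ~5 fragments in
the 5% library) dominates any protocol effect. Species assignment is by
gene-name prefix (default `Dvir\`, the convention of two-genome FlyBase
references), with per-gene overrides available since the naming rule is a
property of the reference, not of the method.

Per gene, ordinary least squares of Â on Q (with intercept) and the
Pearson correlation are computed from the centered normal equations; the
vectorized path used by the pipeline is the same algebra as the scalar
`fit_gene` and both are cross-checked against `scipy.stats.linregress`
and an independent `lstsq` oracle. A constant response leaves r undefined
(flagged, excluded from r summaries but counted). Fits require ≥ 3 levels
and accept any number ≥ 3, so four-level and five-level designs run
unchanged.

### Summaries and tests

Per protocol: mean and standard deviation (sample convention, n−1) of
slopes, intercepts and correlations; one-sample t-tests of slopes against
1 and intercepts against 0; the interquartile range of slopes with
quartiles by linear interpolation; Welch's unequal-variance t-test for
comparing two protocols on per-gene r. The choices not fixed by the
method — sd convention, quantile rule, Welch over pooled variance — follow
common statistical practice; the variance convention is used consistently
everywhere, including the noise decomposition below. No multiple-testing
correction is applied to these tests. (A note on reading the slope
t-tests: a small p-value in a one-sample test against 1 is evidence
*against* m̄ = 1, not for it; the summaries report the plain test
statistic and leave the inference to the reader.)

## The multinomial null

An ideal protocol adds no bias, so the only stochasticity is which reads
are sampled: counts per library are one multinomial draw of the library's
depth over per-gene probabilities. The reference (highest-Q) library
supplies base probabilities — either a measured count vector, loadable
from any htseq-dialect file, or the synthetic profile below. A library at
level ℓ scales every spike-gene probability by ℓ/ℓ_max and assigns the
freed mass *evenly* — an equal absolute increment per gene — to the
background genes. (The even split is a deliberate literal choice over
proportional redistribution; for small spike masses the two differ
negligibly, and the even split keeps level vectors exactly
reconstructible by hand.) Ensembles replay the experiment n_reps times
through the identical pipeline (normalize → filter → fit → summarize) and
collect mean slope, mean intercept, mean r and slope IQR per replicate;
per-replicate seeds are spawned deterministically from the ensemble seed,
so a fixed seed reproduces the ensemble bit for bit. Observed metrics are
ranked by strict-greater counting: the reported rank is the percentage of
replicates strictly exceeding the observed value. A replicate whose
pipeline fails (e.g. nothing passes the filter at a tiny depth) is
recorded and skipped rather than aborting the ensemble.

## Noise decomposition

Two runs yield paired per-gene slopes; genes are matched by identifier
after each run's own ≥ 20 filter. With the sample-std convention,

    η_int = std(m1 − m2)   (variation perpendicular to the diagonal),
    η_ext = std(m1 + m2)   (variation along the diagonal),

and the identity var(m1−m2) + var(m1+m2) = 2·var(m1) + 2·var(m2) holds
for any consistent moment convention (tested to 1e-9). η_int captures
what is independent between the runs (tagmentation, sequencing); η_ext
what is shared (the pre-amplified cDNA batch, the underlying RNA pools).

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not the sequencing process. Defaults are the study conditions: 6,000
background + 2,000 spike genes, log-uniform expression spanning 1e5-fold
(an explicit, dense coverage of the abundance range; the shape is
configurable), five levels 0/1/5/10/20%, 2.5 × 10⁶ reads per library (the
order of the lowest mapped depths after pooling imbalances, hence of the
common subsampled depth). Spike genes carry total probability mass equal
to the maximum level, so the reference library *is* the ℓ_max mixture;
lower levels are built with the same even-redistribution rule as the
null.

Pre-amplification bias is modeled as one multiplicative lognormal factor
per gene *per mixture level*, drawn once per pre-amplification batch
(`preamp_id`) and reused by every run sharing that batch. The per-level
draw is deliberate: each mixture level is a separate RNA pool and hence a
separate amplification reaction, and a factor constant across all levels
would be divided out exactly by the per-gene normalization, leaving no
batch signature in the slopes. With level-specific factors, same-batch
runs share their per-gene slope perturbations (lower η_int) while
independent batches do not — the qualitative contrast the decomposition
is designed to detect. The default bias magnitude for biased-protocol
emulation is σ = 0.2 on the log factors. Optional overdispersion draws
each library's probabilities from a Dirichlet centered on the level
probabilities (compound multinomial) for variance beyond counting noise.

Seeds are split deterministically (profile / per-batch-per-level bias /
per-run draws) so components can be varied independently; with bias off
and no overdispersion the generator's counts are bit-identical to the
multinomial null under the shared draw seed.

What the generator does **not** model: sequence-level effects (GC or
priming bias, mapping error, multi-mapping), library-complexity
saturation and PCR duplication, strand specificity, and any mechanism for
enrichment-cycle effects (the generator therefore makes no prediction
about η_ext differences between pairings). Passing tests on synthetic
data show the pipeline's algebra, filtering and ranking behave correctly
under the assumed noise structure; they do not certify any real
protocol's linearity.

## Yield bookkeeping

Library molar yield uses Y [fmol] = C·10⁻⁹·V·10¹⁵ / 608.9 / S with C in
ng/µL, V in µL, S in bp, and 608.9 g/mol per base pair used verbatim (not
the more common ≈650 or 607.4-plus-ends variants) for consistency with
the yield ladder it accompanies. Equimolar pooling assigns volumes
inversely proportional to molar concentration, scaled to a target total;
equal femtomoles per library follows by construction.

## Numerical and scale choices

* Exactness: projection identity and fit algebra asserted to 1e-9;
  r-preservation under normalization to 1e-12; probability conservation
  in level construction to 1e-12.
* Problem sizes: the simulation-recovery checks run 20 replicates of the
  8,000-gene, 2.5M-read experiment; the batch-contrast check runs 50
  seeded triplets of experiments at the default generator size; unit
  tests use a few-hundred-gene reduction of the same conditions. The full
  suite completes in well under a minute on one core.
* Degenerate inputs: empty count files parse to empty tables; zero
  simulated depth warns and yields all-zero tables; zero-variance
  summaries and comparisons flag their statistics as undefined rather
  than emitting spurious numbers.

## Known limitations

* **Finite-depth bias of the normalization.** s_i is estimated from the
  same noisy counts it divides, so Â is a ratio estimator: for genes near
  the filter boundary the ensemble-mean OLS slope exceeds 1 by
  O(1/count) — about +1×10⁻³ to +2×10⁻³ at 2.5M reads under the default
  profile (intercepts are correspondingly low by ~−3×10⁻⁴). The bias
  shrinks roughly inversely with depth (unmeasurable by 4×10⁷ reads) and
  with a stricter filter; it is far below the per-gene slope scatter
  (sd ≈ 0.03–0.13) and irrelevant for protocol comparison, but it is
  detectable by tests whose tolerance is the ensemble standard error of
  a deep replicate average, which do flag it.
* Per-gene fits treat the four or five levels as homoscedastic; no
  weighting by expected counting variance is applied (matching the simple
  per-gene regression the summaries describe).
* Absolute expression levels are deliberately out of scope: the
  normalization makes protocols comparable on *linearity*, not on
  absolute abundance calibration.
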