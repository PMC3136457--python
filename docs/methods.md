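# Methods

## The compendium model

`crosscomp` integrates heterogeneous microarray experiments into one
gene × condition-contrast matrix of log2 expression ratios.  A *contrast*
is a (test, reference) pair of conditions assayed within a single
experiment on a single platform; its value for gene *g* is

    x_gc = log2( expression_g(test) / expression_g(reference) ).

Absolute intensities are not comparable across platforms and labs, but
within-experiment expression *changes* largely cancel platform- and
experiment-specific effects, so the contrast — not the hybridization — is
the unit of integration.  A consequence adopted throughout the analysis
layer: 0 means "no change" and is treated as the natural reference state
of every statistic.

## Zero-referenced statistics

All similarity and variability measures are *uncentered* (no sample mean
is subtracted, because the meaningful origin is 0, not the profile mean):

* uncentered Pearson correlation over jointly observed contrasts,
  `r(x, y) = Σ x_c y_c / sqrt(Σ x_c² · Σ y_c²)`;
* uncentered standard deviation, the root mean square
  `sqrt(mean_c x_c²)` of observed log ratios.

Missing values are pairwise-deleted.  A correlation is refused — not
silently returned — when fewer than `min_overlap` contrasts are jointly
observed (default 3; fewer shared contrasts carry essentially no
evidence) or when a restricted profile has numerically zero norm
(`epsilon = 1e-12`); silently returning 0 in those cases would corrupt
rankings.

### Contrast relevance

Given a gene set, each contrast is scored by

    relevance = |mean_g x_gc|
              = magnitude × coherence,
    magnitude = mean_g |x_gc|,
    coherence = |Σ_g x_gc| / Σ_g |x_gc|  ∈ [0, 1],

over the observed member genes.  The factorization is exact and keeps the
two ingredients — strength and sign-consistency of the response —
separately inspectable.  A cut-off of 1 on log2 data therefore selects
contrasts with a sign-consistent average two-fold change.  This score is
a reconstruction from the published tool's qualitative description
(prioritizing "magnitude as well as consistency"); the original exact
formulas were published only in supplementary material and are not
reproduced verbatim here.  When all observed members are exactly zero the
coherence is defined as 0 (the relevance identity still holds, 0 = 0·m).

## Homogenization pipeline

Raw probe-level tables are turned into compendium columns under four
principles: (1) raw intensities are preferred over repository-normalized
data — a per-hybridization `is_log2` flag declares the input's processing
state and already-logged data skip the log step; (2) no local background
or mismatch-probe correction anywhere (it inflates error variance at low
intensities; `PROCESSING_STEPS` makes this checkable); (3) non-linear
normalization absorbs global inter-hybridization differences; (4) log
ratios are assembled per contrast definition and combined with
dual-channel measurements.

* **Contrast definition.**  Dual-channel arrays yield one within-array
  contrast (test vs reference channel).  Channels that do not measure an
  identifiable biological condition (genomic DNA, sample pools) are
  discarded and the surviving channel joins the experiment's
  single-channel pool as a test — its within-array role died with the
  discarded pairing.  Single-channel tests are contrasted against the
  mean log2 of all designated references; ambiguous pairings must be
  given explicitly as hints rather than guessed.
* **Probe → gene mapping.**  With a precomputed sequence-hit table
  (identity ≥ 95%, probe coverage ≥ 0.9 by default) a probe maps to the
  gene of its unique best hit; a best-score tie leaves it unmapped.
  Without hits, identifiers are matched in preference order locus tag →
  alternative tag → gene name, and ambiguity at the winning tier unmaps
  the probe.
* **Dual-channel (loess).**  With per-probe M = log2(test/ref) and
  A = mean log2 intensity, the corrected value is M − loess(M | A):
  the residual of a robust locally linear fit (span 0.4, 3 robustness
  iterations, statsmodels `lowess` with an interpolation `delta` of 1% of
  the A-range for speed).  This removes smooth intensity-dependent dye
  bias; a constant M offset (dye imbalance) is absorbed as a special
  case.
* **Single-channel (quantile).**  All member channels of an
  (experiment, platform) group are quantile-normalized together: each
  column's sorted values are replaced by the across-column mean of sorted
  values.  Ties receive the mean of the reference values at their tied
  ranks.  On tie-free complete matrices the transform is exactly
  idempotent (to 1e-12 relative); tie-averaging changes a tied column's
  multiset and therefore necessarily breaks *exact* idempotence — the two
  properties cannot hold simultaneously.  Matrices with missing entries
  use per-column interpolation of the quantile function onto a common
  grid (approximate, in the style of limma's `normalizeQuantiles`).
* **Aggregation and assembly.**  Probe values are aggregated to genes by
  the median of mapped probes' log2 values (robust to one bad probe);
  a contrast's log ratio is the mean log2 of test members minus the mean
  log2 of reference members, missing when either side is unobserved.
  Rows of the final matrix cover the full gene index, so genes never
  measured appear as all-missing rows; the build log records per-step
  counts and the missing fraction.

## Module analysis

A module is a named (gene set, contrast set) pair.  Creation modes:
from genes (contrasts auto-selected by relevance cut-off), from contrasts
(top-n most variable genes by uncentered std, optionally partitioned into
k co-expression clusters), or fully manual.  Editing and algebra:

* **Cleaning** is a single pass against the mean profile of the *initial*
  gene set — the mean is deliberately not recomputed as genes drop, so
  the result does not depend on removal order.  Genes whose correlation
  with that mean is below the threshold, or cannot be computed at all
  (insufficient overlap, zero norm), are removed: a membership that
  cannot be certified is not kept.
* **Extension** ranks non-member genes by uncentered correlation with the
  module mean profile, keeping those at or above the threshold
  (correlated mode) or at or below its negative (anticorrelated mode —
  useful for probing dual regulators).  Ordering is by |r| descending
  with lexicographic gene-id tie-break; candidate sets are monotone
  (non-increasing) in the threshold.
* **Splitting** clusters either direction hierarchically with distance
  1 − uncentered correlation and average linkage (scipy).  Items with too
  few observations to correlate are excluded and reported; undefined
  pairwise distances among clusterable items fall back to the maximal
  distance 2.  The output partitions the clustered items exactly.
* **Merge/subtract** are plain set union / difference in the chosen
  direction; subtraction that empties a direction is an error.
* **Enrichment** is the hypergeometric upper tail P(X ≥ overlap) per gene
  set with Benjamini–Hochberg adjustment across tested sets (scipy +
  statsmodels); zero-overlap terms report p = 1.  The published tool
  reports unspecified "enrichment scores"; hypergeometric + BH is this
  package's choice of the field-standard test.

All orderings use deterministic lexicographic tie-breaks.

## Workflows

`regulon_extension` chains the case-study recipe: relevance-select
contrasts for a seed gene set → clean the seed against its initial mean →
extend by correlation, recording correlated and anticorrelated candidates
separately and cross-referencing them against supplied regulon/operon
gene sets (known member vs novel proposal).

`meta_analysis_comparison` contrasts direct integration with a
per-experiment "meta-analysis": the same select/clean/extend recipe run
inside each experiment separately, using the same relevance cut-off, and
skipping experiments with fewer than `min_contrasts` (default 3, i.e.
two relevant contrasts or less) selected contrasts — the filter applies
to the *selected* sets, not the experiment's total contrast count.
Per-experiment cleaning reuses the same initial gene set and threshold
for comparability.  The report carries per-experiment candidate sets,
their union and intersection, and the compendium-wide result.

## Synthetic data

The generator plants regulon-like modules into a known truth:
`t_gc = Σ_m β_gm a_mc` with β a signed membership indicator (anti-
regulated members get −1) and a_mc the module's activity — zero outside
its active contrasts, ±effect_size with random sign inside.  The direct
generator observes `t + N(0, noise_sd)` with entries masked missing at a
fixed rate; `noise_sd` is defined at the contrast (log-ratio) level.

The raw generator "un-normalizes" a truth into probe-level files:
log-normal baseline expression (median 1000 arbitrary units, log2 sd 1.5,
a realistic microarray dynamic range), per-platform per-gene sensitivity
multipliers, fixed per-probe efficiencies, per-hybridization global scale
factors, per-measurement probe jitter (log2 sd 0.1), test-condition noise
realizing `noise_sd`, and on dual-channel arrays a smooth
intensity-dependent M distortion (amplitude × centered A) emulating dye
bias.  Dual-channel experiments emit one array per contrast; single-
channel experiments emit a shared reference hybridization plus one test
hybridization per contrast.

What it does *not* emulate: platform-specific probe chemistry (Affymetrix
CDF structure, PM/MM pairs), spatial artifacts, condition-correlated
technical effects, or non-Gaussian noise.  Passing the recovery tests
therefore demonstrates that the pipeline correctly inverts the modeled
distortions at realistic magnitudes, not that it handles every failure
mode of archival data.

### Canned study conditions

* **Homogenization study** — 2000 genes, 20 planted 50-gene modules
  (regulon-sized) with effects 1.5–3 log2 units (3- to 8-fold, the
  physiological range of strong bacterial responses), each active in 30%
  of the 48 contrasts (8 experiments × 6), on two dual-channel (2
  probes/gene, spotted-array-like) and two single-channel (8 probes/gene,
  high-density-oligo-like) platforms; noise 0.3, dye-bias amplitude 0.5.
* **Regulon-recovery study** — one 30-gene regulon, |effect| 1.5, active
  in 20 of 60 contrasts, noise 0.3, 5% missing, 1970 background genes.
  The workflow is seeded with 20 members and judged on the 10 held out.
* **Meta-comparison study** — 8 experiments × 7 contrasts; a 30-gene
  target (active fraction 0.5) plus fifteen 30-gene confounder modules
  (active fraction 0.25), noise 0.3, 5% missing.  Individual experiments
  survey only a handful of relevant contrasts, which is precisely the
  regime where per-experiment co-expression is underdetermined.

These sizes keep every validation run within seconds on one CPU while
leaving the statistical margins comfortable.

## Known limitations

* **Quantile normalization in signal-dense compendia.**  Forcing all
  columns of a group to one distribution is only exact when the columns
  measure the same distribution.  When a large fraction of genes is
  genuinely differentially expressed, ranks cross between columns and
  both DE and background genes acquire distortion; extreme inductions are
  tail-compressed (every column's maximum becomes identical).  In the
  homogenization study this residual distortion is the dominant error of
  the single-channel path (noise-free residual sd ≈ 0.2 log2 units at
  ~15% DE per contrast, roughly half of it a per-gene-per-experiment bias
  from the shared reference column).  Real compendia with genome-scale
  arrays and sparser DE sit well inside this regime; heavily perturbed
  small designs do not.
* **Loess leaks conditional signal.**  The M|A fit absorbs whatever part
  of the true signal is smooth in A; with sign-balanced modules this is
  small but not zero, and slope diagnostics of bias removal are therefore
  computed on background-gene probes.
* **Per-experiment meta-analysis comparison** is a synthetic, directional
  reproduction: it demonstrates that per-experiment extension unions
  accumulate spurious co-expression while intersections lose sensitivity,
  not any particular published count.
* The condition-annotation comparison surface is deliberately minimal
  (shared-property counting via queries); no similarity metric between
  annotation difference vectors is defined.
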