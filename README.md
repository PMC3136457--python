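# crosscomp

Cross-platform expression compendium construction and co-expression
module analysis for bacterial transcriptomics.

Public microarray archives hold thousands of experiments per model
organism, but the data are scattered across incompatible platforms,
channel layouts and processing states.  `crosscomp` implements the
*direct integration* strategy: instead of analyzing each experiment
separately and merging results (meta-analysis), it homogenizes all
experiments into one gene × condition-contrast matrix of log2 expression
ratios — every column the difference between a test and a reference
condition measured within one experiment and platform — and analyzes
expression values jointly across the whole collection.  It is written for
microbiologists and computational biologists who want to place a gene set
(a regulon, an operon, a pathway) in the context of everything measured
for their organism, e.g. to propose new targets of a transcription
factor from compendium-wide co-expression.

## What it does

* **Ingest & homogenize** (`crosscomp.ingest`) — probe→gene mapping (by
  precomputed sequence hits or locus tag / alt tag / gene name
  preference), test/reference contrast definition (including discarding
  non-biological channels such as genomic DNA), robust loess M-vs-A
  correction for dual-channel dye bias, quantile normalization for
  single-channel groups, and assembly into a `LogratioCompendium`.
  No background or mismatch-probe correction anywhere.
* **Statistics** (`crosscomp.stats`) — zero-referenced measures that
  treat a log ratio of 0 as the natural reference state: the uncentered
  Pearson correlation `Σx_c y_c / √(Σx_c² Σy_c²)` and the uncentered
  standard deviation `√(mean x_c²)`, with pairwise deletion of missing
  values.
* **Module analysis** (`crosscomp.analysis`) — modules (gene set ×
  contrast set) created from genes via the relevance score
  `|mean_g x_gc| = magnitude × coherence` (cut-off 1 ⇒ sign-consistent
  average two-fold change), from contrasts via most-variable genes, or
  manually; cleaning against the initial mean profile, correlation-based
  extension (correlated and anticorrelated), hierarchical splits
  (1 − uncentered r, average linkage), merge/subtract algebra,
  hypergeometric gene-set enrichment with Benjamini–Hochberg adjustment,
  heatmap and overview exports.
* **Annotation** (`crosscomp.annotation`) — formal condition properties,
  contrast annotations as test−reference difference vectors, a condition
  ontology with descendant-closure queries, and GMT gene sets.
* **Workflows** (`crosscomp.workflows`) — the regulon-extension recipe
  (select relevant contrasts → clean seed → extend) and a
  direct-integration vs per-experiment meta-analysis comparison.
* **Synthetic data** (`crosscomp.simulate`) — a seeded generator of
  multi-platform studies with planted regulon activity, dye bias,
  platform sensitivity effects, noise and missing values, providing
  ground truth for every claim the test suite makes.

## Worked example: extending a planted regulon

```python
from crosscomp import simulate as sim
from crosscomp.workflows import regulon_extension

# a 2000-gene compendium with a planted 30-gene regulon (|effect| 1.5
# log2 units in 20 of 60 contrasts, noise sd 0.3, 5% missing values)
comp, truth = sim.regulon_recovery_study(seed=7)
members = truth.members_of("regulon")

# seed the workflow with 20 members; defaults: relevance cut-off 1,
# cleaning and extension correlation thresholds 0.8
report = regulon_extension(members[:20], comp)
print(f"selected contrasts : {len(report.selected_contrasts)}")
print(f"cleaned core       : {len(report.retained)} genes ({len(report.removed)} removed)")
print(f"candidates         : {len(report.candidates)}")
print(report.candidates.head(5).round(3).to_string())
```

prints

```
selected contrasts : 20
cleaned core       : 20 genes (0 removed)
candidates         : 10
gene_id
g0026    0.983
g0025    0.983
g0029    0.982
g0027    0.981
g0022    0.981
```

The relevance cut-off of 1 recovers exactly the 20 contrasts where the
planted regulon is active (a sign-consistent average two-fold change);
no seed gene is removed at the 0.8 cleaning threshold; and the
extension proposes exactly the 10 held-out regulon members, each with
uncentered correlation ≈ 0.98 to the core's mean profile.  On real data
the candidate list is the set of putative new targets, to be
cross-referenced against known regulon/operon annotations via the
report's known/novel flags.

A command-line layer wraps the same functionality:

```bash
crosscomp simulate --seed 3 --outdir study/ --raw
crosscomp build --study-dir study/raw --out-matrix comp.tsv --out-sidecar meta.tsv
crosscomp workflow regulon-extend --compendium comp.tsv --sidecar meta.tsv \
    --genes seeds.txt --out report.txt
crosscomp workflow meta-compare --compendium comp.tsv --sidecar meta.tsv \
    --genes seeds.txt --out meta.txt
```

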