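"""Reusable pipelines for regulon extension and meta-analysis comparison.

`regulon_extension` is the co-expression recipe for proposing new targets
of a transcription factor from a seed regulon: select the contrasts where
the seed genes respond most strongly and coherently, drop seed genes that
do not follow the seed's mean profile there, then rank all other genes by
uncentered correlation with the cleaned core (anti-correlated genes are
listed separately — interesting for dual regulators that both activate and
repress).

`meta_analysis_comparison` contrasts that direct-integration result with a
per-experiment "meta-analysis": the same selection/clean/extend recipe run
inside each experiment separately, combining only the resulting gene sets.
Because a single experiment surveys few, similar conditions, per-experiment
extensions admit many spuriously co-expressed genes; the comparison
quantifies that trade-off (union = sensitive but noisy, intersection =
specific but insensitive).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .analysis import (
    clean_module_genes,
    extend_module,
    select_relevant_contrasts,
)
from .annotation import GeneAnnotationSets
from .compendium import ExpressionModule, LogratioCompendium
from .errors import (
    CreationError,
    DegenerateResultError,
    ParameterError,
)
from .stats import DEFAULT_PARAMS, StatParams

logger = logging.getLogger(__name__)

__all__ = [
    "RegulonExtensionReport",
    "MetaAnalysisReport",
    "regulon_extension",
    "meta_analysis_comparison",
]


@dataclass
class RegulonExtensionReport:
    """Full record of one regulon-extension run."""

    initial_genes: tuple[str, ...]
    selected_contrasts: pd.DataFrame  # index contrast_id, column relevance
    removed: pd.Series  # gene -> correlation with initial mean (NaN = undefined)
    retained: tuple[str, ...]
    candidates: pd.Series  # gene -> correlation, correlated direction
    anticorrelated: pd.Series  # gene -> correlation, anticorrelated direction
    known_annotations: dict[str, list[str]] = field(default_factory=dict)
    module: ExpressionModule | None = None

    @property
    def candidate_genes(self) -> list[str]:
        return list(self.candidates.index)

    def candidate_table(self) -> pd.DataFrame:
        """Candidates with direction, correlation and known/novel flag."""
        rows = [
            {
                "gene_id": g,
                "correlation": c,
                "direction": "correlated",
                "known_sets": ";".join(self.known_annotations.get(g, [])),
                "novel": g not in self.known_annotations,
            }
            for g, c in self.candidates.items()
        ] + [
            {
                "gene_id": g,
                "correlation": c,
                "direction": "anticorrelated",
                "known_sets": ";".join(self.known_annotations.get(g, [])),
                "novel": g not in self.known_annotations,
            }
            for g, c in self.anticorrelated.items()
        ]
        return pd.DataFrame(
            rows, columns=["gene_id", "correlation", "direction", "known_sets", "novel"]
        )

    def write(self, path) -> None:
        """Structured-text report mirroring the run's stages."""
        with open(path, "w") as fh:
            fh.write(f"# initial genes ({len(self.initial_genes)})\n")
            fh.write("\t".join(self.initial_genes) + "\n\n")
            fh.write(f"# selected contrasts ({len(self.selected_contrasts)})\n")
            fh.write("contrast_id\trelevance\n")
            for cid, row in self.selected_contrasts.iterrows():
                fh.write(f"{cid}\t{row['relevance']:.4f}\n")
            fh.write(f"\n# removed during cleaning ({len(self.removed)})\n")
            fh.write("gene_id\tcorrelation\n")
            for g, c in self.removed.items():
                fh.write(f"{g}\t{c:.4f}\n" if pd.notna(c) else f"{g}\tundefined\n")
            fh.write(f"\n# retained core ({len(self.retained)})\n")
            fh.write("\t".join(self.retained) + "\n\n")
            fh.write(f"# candidate genes ({len(self.candidates)})\n")
            fh.write("gene_id\tcorrelation\tdirection\tknown_sets\tnovel\n")
            for _, r in self.candidate_table().iterrows():
                fh.write(
                    f"{r['gene_id']}\t{r['correlation']:.4f}\t{r['direction']}\t"
                    f"{r['known_sets']}\t{r['novel']}\n"
                )


def regulon_extension(
    initial_genes: Iterable[str],
    compendium: LogratioCompendium,
    relevance_cutoff: float = 1.0,
    clean_threshold: float = 0.8,
    extend_threshold: float = 0.8,
    annotation_sets: GeneAnnotationSets | None = None,
    params: StatParams = DEFAULT_PARAMS,
    contrast_ids: Sequence[str] | None = None,
) -> RegulonExtensionReport:
    """Select relevant contrasts, clean the seed set, extend by correlation.

    Candidates are disjoint from the initial set by construction (genes
    removed during cleaning are not re-proposed).  When regulon/operon
    annotation sets are given, every candidate is cross-referenced against
    them so known members and novel proposals are distinguishable.
    """
    initial = tuple(dict.fromkeys(initial_genes))
    if len(initial) < 2:
        raise ParameterError("need at least 2 initial genes")

    selected = select_relevant_contrasts(
        initial, compendium, cutoff=relevance_cutoff, contrast_ids=contrast_ids
    )
    if not selected:
        raise CreationError(
            f"no contrast reaches relevance {relevance_cutoff} for the initial "
            "set; lower the cutoff or enlarge the gene set"
        )
    from .analysis import contrast_relevance

    relevance = contrast_relevance(initial, compendium, contrast_ids=selected).loc[selected]

    known_in_comp = [g for g in initial if g in set(compendium.gene_ids)]
    seed = ExpressionModule(
        name="seed",
        gene_ids=tuple(known_in_comp),
        contrast_ids=tuple(selected),
        compendium_ref=compendium.name,
    )
    core, removed = clean_module_genes(seed, compendium, threshold=clean_threshold, params=params)

    candidates = extend_module(
        core,
        compendium,
        threshold=extend_threshold,
        direction="correlated",
        params=params,
        exclude=initial,
    )
    anticorrelated = extend_module(
        core,
        compendium,
        threshold=extend_threshold,
        direction="anticorrelated",
        params=params,
        exclude=initial,
    )

    known: dict[str, list[str]] = {}
    if annotation_sets is not None:
        for g in list(candidates.index) + list(anticorrelated.index):
            hits = annotation_sets.sets_containing(g)
            if hits:
                known[g] = [f"{cat}:{nm}" for cat, nm in hits]

    return RegulonExtensionReport(
        initial_genes=initial,
        selected_contrasts=relevance[["relevance"]],
        removed=removed,
        retained=core.gene_ids,
        candidates=candidates,
        anticorrelated=anticorrelated,
        known_annotations=known,
        module=core,
    )


@dataclass
class MetaAnalysisReport:
    """Per-experiment extension sets versus the compendium-wide extension."""

    per_experiment: dict[str, set[str]]
    skipped_experiments: dict[str, str]
    union: set[str]
    intersection: set[str]
    compendium_wide: set[str]
    per_experiment_contrasts: dict[str, int] = field(default_factory=dict)

    def overlap_statistics(self) -> pd.DataFrame:
        rows = [
            {
                "experiment_id": exp,
                "n_selected_contrasts": self.per_experiment_contrasts.get(exp, 0),
                "n_extension_genes": len(genes),
                "n_shared_with_compendium": len(genes & self.compendium_wide),
            }
            for exp, genes in sorted(self.per_experiment.items())
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "experiment_id",
                "n_selected_contrasts",
                "n_extension_genes",
                "n_shared_with_compendium",
            ],
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# per-experiment extensions\n")
            self.overlap_statistics().to_csv(fh, sep="\t", index=False)
            fh.write(f"\n# skipped experiments ({len(self.skipped_experiments)})\n")
            for exp, why in sorted(self.skipped_experiments.items()):
                fh.write(f"{exp}\t{why}\n")
            fh.write(f"\n# union ({len(self.union)})\n")
            fh.write("\t".join(sorted(self.union)) + "\n")
            fh.write(f"\n# intersection ({len(self.intersection)})\n")
            fh.write("\t".join(sorted(self.intersection)) + "\n")
            fh.write(f"\n# compendium-wide ({len(self.compendium_wide)})\n")
            fh.write("\t".join(sorted(self.compendium_wide)) + "\n")


def meta_analysis_comparison(
    initial_genes: Iterable[str],
    compendium: LogratioCompendium,
    relevance_cutoff: float = 1.0,
    clean_threshold: float = 0.8,
    extend_threshold: float = 0.8,
    min_contrasts: int = 3,
    annotation_sets: GeneAnnotationSets | None = None,
    params: StatParams = DEFAULT_PARAMS,
) -> MetaAnalysisReport:
    """Per-experiment clean+extend versus the compendium-wide extension.

    Within each experiment, only the most relevant contrasts (same cutoff
    as the compendium-wide run) are used; experiments with fewer than
    ``min_contrasts`` selected contrasts (default 3, i.e. experiments with
    two relevant contrasts or less are ignored) are skipped.  Cleaning
    uses the same initial gene set and threshold as the compendium-wide
    run for comparability.
    """
    initial = tuple(dict.fromkeys(initial_genes))
    compendium_report = regulon_extension(
        initial,
        compendium,
        relevance_cutoff=relevance_cutoff,
        clean_threshold=clean_threshold,
        extend_threshold=extend_threshold,
        annotation_sets=annotation_sets,
        params=params,
    )
    compendium_set = set(compendium_report.candidates.index)

    per_experiment: dict[str, set[str]] = {}
    skipped: dict[str, str] = {}
    n_contrasts: dict[str, int] = {}
    for exp in sorted(compendium.experiments):
        contrasts = compendium.contrasts_of_experiment(exp)
        try:
            selected = select_relevant_contrasts(
                initial, compendium, cutoff=relevance_cutoff, contrast_ids=contrasts
            )
        except Exception as err:  # e.g. no member gene observed at all
            skipped[exp] = f"relevance scoring failed: {err}"
            continue
        if len(selected) < min_contrasts:
            skipped[exp] = (
                f"only {len(selected)} relevant contrasts (< {min_contrasts})"
            )
            continue
        n_contrasts[exp] = len(selected)
        try:
            report = regulon_extension(
                initial,
                compendium,
                relevance_cutoff=relevance_cutoff,
                clean_threshold=clean_threshold,
                extend_threshold=extend_threshold,
                params=params,
                contrast_ids=contrasts,
            )
        except (CreationError, DegenerateResultError, ParameterError) as err:
            skipped[exp] = str(err)
            continue
        per_experiment[exp] = set(report.candidates.index)

    if per_experiment:
        union = set().union(*per_experiment.values())
        intersection = set.intersection(*per_experiment.values())
    else:
        warnings.warn("no experiment survived the relevant-contrast filter")
        union, intersection = set(), set()

    return MetaAnalysisReport(
        per_experiment=per_experiment,
        skipped_experiments=skipped,
        union=union,
        intersection=intersection,
        compendium_wide=compendium_set,
        per_experiment_contrasts=n_contrasts,
    )
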