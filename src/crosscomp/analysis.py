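"""The co-expression module analysis suite.

Everything here acts on expression modules — (gene set, contrast set)
pairs bound to a compendium.  Modules are created in three modes (from
genes via relevance-selected contrasts, from contrasts via the most
variable genes, or fully manual), edited (cleaning against the initial
mean profile, correlation-based extension), split by clustering in either
direction, combined with set algebra, and summarized with gene-set
enrichment.

Relevance of a contrast for a gene set is scored as the absolute mean
log ratio of the member genes, which factorizes exactly into

    relevance = magnitude x coherence
    magnitude = mean |x_gc|            (strength of the response)
    coherence = |sum x_gc| / sum |x_gc|  in [0, 1]  (sign consistency)

so a cut-off of 1 on log2 data selects contrasts with a sign-consistent
average two-fold change.  This score is a reconstruction of the published
tool's qualitative description ("magnitude as well as consistency"); the
factorized form keeps both ingredients separately inspectable.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .compendium import ExpressionModule, LogratioCompendium, module_mean_profile
from .errors import (
    ConfigurationError,
    CreationError,
    DegenerateResultError,
    ParameterError,
    ValidationError,
)
from .stats import (
    DEFAULT_PARAMS,
    StatParams,
    correlations_to_reference,
    pairwise_uncentered_distances,
)

logger = logging.getLogger(__name__)

__all__ = [
    "contrast_relevance",
    "select_relevant_contrasts",
    "most_variable_genes",
    "create_module_from_genes",
    "create_module_from_contrasts",
    "clean_module_genes",
    "extend_module",
    "split_module",
    "merge_modules",
    "subtract_modules",
    "go_enrichment",
    "export_heatmap",
    "write_module_overview",
]


# ---------------------------------------------------------------------------
# relevance and variability
# ---------------------------------------------------------------------------


def contrast_relevance(
    gene_ids: Iterable[str],
    compendium: LogratioCompendium,
    contrast_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Score every contrast's relevance for a gene set.

    Returns a DataFrame indexed by contrast id with columns ``relevance``,
    ``magnitude``, ``coherence`` and ``n_observed``; contrasts where no
    member gene is observed are omitted.  ``relevance`` equals
    ``magnitude * coherence`` exactly (up to floating round-off).
    """
    genes = [g for g in gene_ids if g in set(compendium.gene_ids)]
    if not genes:
        raise ValidationError("no resolvable genes for relevance scoring")
    sub = compendium.submatrix(genes, list(contrast_ids) if contrast_ids is not None else None)
    X = sub.to_numpy(dtype=float)
    obs = np.isfinite(X)
    n_obs = obs.sum(axis=0)
    X0 = np.where(obs, X, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        magnitude = np.abs(X0).sum(axis=0) / n_obs
        abs_sum = np.abs(X0).sum(axis=0)
        coherence = np.where(abs_sum > 0, np.abs(X0.sum(axis=0)) / abs_sum, 0.0)
        relevance = np.abs(X0.sum(axis=0)) / n_obs
    frame = pd.DataFrame(
        {
            "relevance": relevance,
            "magnitude": magnitude,
            "coherence": coherence,
            "n_observed": n_obs,
        },
        index=sub.columns,
    )
    return frame[frame["n_observed"] > 0]


def select_relevant_contrasts(
    gene_ids: Iterable[str],
    compendium: LogratioCompendium,
    cutoff: float = 1.0,
    contrast_ids: Sequence[str] | None = None,
) -> list[str]:
    """Contrasts whose relevance for the gene set reaches ``cutoff``.

    Sorted by descending relevance, ties broken by contrast id so the
    order is deterministic.
    """
    if cutoff < 0:
        raise ParameterError("relevance cutoff must be >= 0")
    table = contrast_relevance(gene_ids, compendium, contrast_ids=contrast_ids)
    hits = table[table["relevance"] >= cutoff]
    hits = hits.sort_index().sort_values("relevance", ascending=False, kind="stable")
    return list(hits.index)


def most_variable_genes(
    contrast_ids: Sequence[str],
    compendium: LogratioCompendium,
    top_n: int | None = None,
    cutoff: float | None = None,
    params: StatParams = DEFAULT_PARAMS,
) -> pd.Series:
    """Genes ranked by uncentered standard deviation over given contrasts.

    Genes observed in fewer than ``params.min_overlap`` of the contrasts
    are excluded.  Returns a Series gene id -> uncentered std, sorted
    descending (ties broken by gene id); ``top_n`` and/or ``cutoff``
    truncate the ranking.
    """
    if not len(contrast_ids):
        raise ParameterError("contrast set must be non-empty")
    sub = compendium.submatrix(None, list(contrast_ids))
    X = sub.to_numpy(dtype=float)
    obs = np.isfinite(X)
    n_obs = obs.sum(axis=1)
    X0 = np.where(obs, X, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rms = np.sqrt((X0 * X0).sum(axis=1) / n_obs)
    s = pd.Series(rms, index=sub.index, name="uncentered_std")
    s = s[n_obs >= params.min_overlap]
    s = s.sort_index().sort_values(ascending=False, kind="stable")
    if cutoff is not None:
        s = s[s >= cutoff]
    if top_n is not None:
        s = s.iloc[:top_n]
    return s


# ---------------------------------------------------------------------------
# module creation
# ---------------------------------------------------------------------------


def create_module_from_genes(
    gene_ids: Iterable[str],
    compendium: LogratioCompendium,
    relevance_cutoff: float = 1.0,
    name: str = "module",
) -> ExpressionModule:
    """Module from a manual gene selection plus auto-selected contrasts."""
    genes = list(dict.fromkeys(gene_ids))
    contrasts = select_relevant_contrasts(genes, compendium, cutoff=relevance_cutoff)
    if not contrasts:
        raise CreationError(
            f"no contrast reaches relevance {relevance_cutoff}; lower the cutoff"
        )
    known = set(compendium.gene_ids)
    return ExpressionModule(
        name=name,
        gene_ids=tuple(g for g in genes if g in known),
        contrast_ids=tuple(contrasts),
        compendium_ref=compendium.name,
    )


def create_module_from_contrasts(
    contrast_ids: Sequence[str],
    compendium: LogratioCompendium,
    top_n: int = 50,
    k_clusters: int | None = None,
    name: str = "module",
    params: StatParams = DEFAULT_PARAMS,
) -> list[ExpressionModule]:
    """Module(s) from a manual contrast selection plus variable genes.

    Takes the ``top_n`` most variable genes for the contrasts; with
    ``k_clusters`` they are partitioned by hierarchical clustering
    (distance 1 - uncentered correlation, average linkage) into that many
    co-expression modules, otherwise one module is returned.
    """
    if k_clusters is not None and top_n < k_clusters:
        raise ParameterError("top_n must be >= k_clusters")
    ranked = most_variable_genes(contrast_ids, compendium, top_n=top_n, params=params)
    if ranked.empty:
        raise CreationError("no gene has enough observations on these contrasts")
    genes = list(ranked.index)
    if k_clusters is None or k_clusters == 1:
        return [
            ExpressionModule(
                name=name,
                gene_ids=tuple(genes),
                contrast_ids=tuple(contrast_ids),
                compendium_ref=compendium.name,
            )
        ]
    profiles = compendium.submatrix(genes, list(contrast_ids))
    labels = _cluster_rows(profiles, k_clusters, params)
    modules = []
    for i in range(1, k_clusters + 1):
        members = [g for g, lab in zip(genes, labels) if lab == i]
        if members:
            modules.append(
                ExpressionModule(
                    name=f"{name}_{i}",
                    gene_ids=tuple(members),
                    contrast_ids=tuple(contrast_ids),
                    compendium_ref=compendium.name,
                )
            )
    return modules


def _cluster_rows(profiles: pd.DataFrame, k: int, params: StatParams) -> np.ndarray:
    dist = pairwise_uncentered_distances(profiles, params)
    Z = linkage(dist, method="average")
    return fcluster(Z, t=k, criterion="maxclust")


# ---------------------------------------------------------------------------
# module editing
# ---------------------------------------------------------------------------


def clean_module_genes(
    module: ExpressionModule,
    compendium: LogratioCompendium,
    threshold: float = 0.8,
    params: StatParams = DEFAULT_PARAMS,
) -> tuple[ExpressionModule, pd.Series]:
    """Remove genes poorly correlated with the module's initial mean.

    Single pass: the mean profile is computed once from the full initial
    gene set over the module's contrasts and is NOT recomputed as genes
    are dropped.  Genes whose uncentered correlation with that mean falls
    below ``threshold`` — or cannot be computed at all (insufficient
    overlap, degenerate restricted profile) — are removed.

    Returns the cleaned module and a Series of removed genes with their
    correlations (NaN where the correlation was undefined).
    """
    if module.n_genes < 2:
        raise ParameterError("cleaning needs a module with at least 2 genes")
    mean = module_mean_profile(compendium, module.gene_ids, module.contrast_ids)
    profiles = compendium.submatrix(module.gene_ids, module.contrast_ids)
    corr = correlations_to_reference(profiles, mean, params)
    keep_mask = corr >= threshold  # NaN compares False: undefined => removed
    removed = corr[~keep_mask]
    kept = [g for g in module.gene_ids if keep_mask[g]]
    if not kept:
        raise DegenerateResultError("cleaning removed every gene")
    cleaned = ExpressionModule(
        name=module.name,
        gene_ids=tuple(kept),
        contrast_ids=module.contrast_ids,
        compendium_ref=module.compendium_ref,
    )
    return cleaned, removed


def extend_module(
    module: ExpressionModule,
    compendium: LogratioCompendium,
    threshold: float = 0.8,
    direction: str = "correlated",
    params: StatParams = DEFAULT_PARAMS,
    exclude: Iterable[str] = (),
) -> pd.Series:
    """Rank non-member genes by similarity to the module mean profile.

    ``correlated`` mode returns genes with uncentered correlation to the
    mean profile >= ``threshold``; ``anticorrelated`` mode returns genes
    with correlation <= -``threshold`` (useful for probing dual
    regulation).  Genes with too few shared observations are excluded.
    Result is ordered by \\|correlation\\| descending, ties by gene id.
    """
    if not 0 < threshold <= 1:
        raise ParameterError("threshold must be in (0, 1]")
    if direction not in ("correlated", "anticorrelated"):
        raise ParameterError(f"unknown direction {direction!r}")
    mean = module_mean_profile(compendium, module.gene_ids, module.contrast_ids)
    members = set(module.gene_ids) | set(exclude)
    candidates = [g for g in compendium.gene_ids if g not in members]
    profiles = compendium.submatrix(candidates, module.contrast_ids)
    corr = correlations_to_reference(profiles, mean, params).dropna()
    if direction == "correlated":
        corr = corr[corr >= threshold]
    else:
        corr = corr[corr <= -threshold]
    order = corr.abs().to_frame("abs_corr")
    order["gene"] = order.index
    order = order.sort_values(["abs_corr", "gene"], ascending=[False, True], kind="stable")
    return corr.loc[order.index]


def split_module(
    module: ExpressionModule,
    compendium: LogratioCompendium,
    direction: str = "gene",
    k: int = 2,
    params: StatParams = DEFAULT_PARAMS,
) -> tuple[list[ExpressionModule], list[str]]:
    """Split a module by clustering in the gene or contrast direction.

    Hierarchical clustering with distance 1 - uncentered correlation and
    average linkage, on gene profiles over the module's contrasts or on
    contrast columns over the module's genes.  Items with fewer than
    ``params.min_overlap`` observations cannot be placed and are returned
    separately as the second element; the k resulting modules partition
    the remaining items while the other direction is unchanged.

    ``k = 1`` returns the module unchanged.
    """
    if direction not in ("gene", "contrast"):
        raise ParameterError(f"unknown split direction {direction!r}")
    items = module.gene_ids if direction == "gene" else module.contrast_ids
    if k < 1 or k > len(items):
        raise ParameterError("k must be between 1 and the number of items")
    if k == 1:
        return [module], []

    matrix = module.values(compendium)
    if direction == "contrast":
        matrix = matrix.T
    obs_counts = np.isfinite(matrix.to_numpy(dtype=float)).sum(axis=1)
    usable = [it for it, n in zip(matrix.index, obs_counts) if n >= params.min_overlap]
    excluded = [it for it in matrix.index if it not in set(usable)]
    if excluded:
        logger.warning("split_module: %d items excluded for sparsity", len(excluded))
    if k > len(usable):
        raise ParameterError("k exceeds the number of clusterable items")
    labels = _cluster_rows(matrix.loc[usable], k, params)
    modules = []
    for i in range(1, k + 1):
        members = tuple(it for it, lab in zip(usable, labels) if lab == i)
        if not members:
            continue
        if direction == "gene":
            modules.append(
                ExpressionModule(
                    name=f"{module.name}_g{i}",
                    gene_ids=members,
                    contrast_ids=module.contrast_ids,
                    compendium_ref=module.compendium_ref,
                )
            )
        else:
            modules.append(
                ExpressionModule(
                    name=f"{module.name}_c{i}",
                    gene_ids=module.gene_ids,
                    contrast_ids=members,
                    compendium_ref=module.compendium_ref,
                )
            )
    return modules, excluded


# ---------------------------------------------------------------------------
# module algebra
# ---------------------------------------------------------------------------


def _require_same_backing(modules: Sequence[ExpressionModule]) -> None:
    refs = {m.compendium_ref for m in modules}
    if len(refs) > 1:
        raise ParameterError(f"modules reference different compendia: {sorted(refs)}")


def merge_modules(modules: Sequence[ExpressionModule], name: str | None = None) -> ExpressionModule:
    """Union of gene sets and union of contrast sets."""
    if not modules:
        raise ParameterError("nothing to merge")
    _require_same_backing(modules)
    genes = sorted({g for m in modules for g in m.gene_ids})
    contrasts = sorted({c for m in modules for c in m.contrast_ids})
    return ExpressionModule(
        name=name or "merge(" + "+".join(m.name for m in modules) + ")",
        gene_ids=tuple(genes),
        contrast_ids=tuple(contrasts),
        compendium_ref=modules[0].compendium_ref,
    )


def subtract_modules(
    a: ExpressionModule,
    b: ExpressionModule,
    direction: str = "gene",
    name: str | None = None,
) -> ExpressionModule:
    """Remove b's genes (or contrasts) from a; the other direction is a's."""
    if direction not in ("gene", "contrast"):
        raise ParameterError(f"unknown subtract direction {direction!r}")
    _require_same_backing([a, b])
    if direction == "gene":
        genes = tuple(g for g in a.gene_ids if g not in set(b.gene_ids))
        contrasts = a.contrast_ids
        if not genes:
            raise DegenerateResultError("subtraction emptied the gene direction")
    else:
        genes = a.gene_ids
        contrasts = tuple(c for c in a.contrast_ids if c not in set(b.contrast_ids))
        if not contrasts:
            raise DegenerateResultError("subtraction emptied the contrast direction")
    return ExpressionModule(
        name=name or f"{a.name}-{b.name}",
        gene_ids=genes,
        contrast_ids=contrasts,
        compendium_ref=a.compendium_ref,
    )


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def go_enrichment(
    module_genes: Iterable[str],
    term_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets in a module.

    For each term: upper-tail p-value P(X >= overlap) with population =
    universe size, successes = term size (restricted to the universe),
    draws = module size; Benjamini-Hochberg adjustment across the tested
    terms.  Terms with zero overlap get p = 1.  Returns a frame sorted by
    p-value (ties by term id) with one row per term.
    """
    uni = set(universe)
    if not uni:
        raise ConfigurationError("empty gene universe")
    genes = set(module_genes)
    if genes - uni:
        raise ParameterError("module genes must be a subset of the universe")
    M, N = len(uni), len(genes)
    rows = []
    for term_id in sorted(term_sets):
        term = set(term_sets[term_id]) & uni
        K = len(term)
        k = len(term & genes)
        p = float(hypergeom.sf(k - 1, M, K, N)) if k > 0 else 1.0
        rows.append(
            {
                "term_id": term_id,
                "overlap": k,
                "module_size": N,
                "term_size": K,
                "universe_size": M,
                "p_value": min(p, 1.0),
            }
        )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["p_adjusted"] = multipletests(frame["p_value"], method="fdr_bh")[1]
        frame = frame.sort_values(["p_value", "term_id"], kind="stable").reset_index(drop=True)
    return frame


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------


def export_heatmap(
    module: ExpressionModule,
    compendium: LogratioCompendium,
    path,
    cmap: str = "RdBu_r",
) -> None:
    """Static heatmap of a module (genes x contrasts, diverging, 0-centered)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = module.values(compendium)
    limit = float(np.nanmax(np.abs(values.to_numpy()))) or 1.0
    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * module.n_contrasts), max(3, 0.2 * module.n_genes))
    )
    im = ax.imshow(values.to_numpy(), cmap=cmap, vmin=-limit, vmax=limit, aspect="auto")
    ax.set_xticks(range(module.n_contrasts))
    ax.set_xticklabels(values.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(module.n_genes))
    ax.set_yticklabels(values.index, fontsize=6)
    ax.set_title(module.name)
    fig.colorbar(im, ax=ax, label="log2 ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_module_overview(
    module: ExpressionModule,
    compendium: LogratioCompendium,
    path,
    term_sets: Mapping[str, Iterable[str]] | None = None,
    universe: Iterable[str] | None = None,
    top_terms: int = 10,
) -> None:
    """Structured-text module report: sizes, missingness, top enrichments."""
    lines = [
        f"module\t{module.name}",
        f"compendium\t{module.compendium_ref or compendium.name}",
        f"n_genes\t{module.n_genes}",
        f"n_contrasts\t{module.n_contrasts}",
        f"missing_fraction\t{module.missing_fraction(compendium):.4f}",
    ]
    if term_sets is not None:
        enrich = go_enrichment(
            module.gene_ids, term_sets, universe if universe is not None else compendium.gene_ids
        )
        lines.append("")
        lines.append("term_id\toverlap\tterm_size\tp_value\tp_adjusted")
        for _, row in enrich.head(top_terms).iterrows():
            lines.append(
                f"{row['term_id']}\t{row['overlap']}\t{row['term_size']}\t"
                f"{row['p_value']:.3e}\t{row['p_adjusted']:.3e}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
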