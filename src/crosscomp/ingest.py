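"""Homogenization of heterogeneous microarray experiments into contrasts.

The pipeline turns per-experiment probe-level intensity tables — single- or
dual-channel, from different platforms — into comparable gene-level log2
ratio columns of one compendium.  Its guiding principles:

1. raw intensities are preferred over repository-normalized data (a
   per-experiment flag declares the processing state of the input);
2. no local background or mismatch-probe correction is performed anywhere
   (such corrections inflate the error variance of low intensities);
3. non-linear normalization removes global inter-hybridization differences
   — a robust loess fit of M on A removes dye-related bias on dual-channel
   arrays, quantile normalization aligns single-channel hybridizations;
4. log ratios are assembled per contrast definition and combined with the
   dual-channel measurements into one matrix.

`PROCESSING_STEPS` enumerates the pipeline's steps by name; its contents
make principle 2 checkable by inspection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .compendium import LogratioCompendium
from .errors import (
    AssemblyError,
    ConfigurationError,
    DefinitionError,
    DomainError,
    FitError,
    ParameterError,
    ParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelInfo",
    "HybridizationTable",
    "ContrastDefinition",
    "ProbeMap",
    "map_probes",
    "define_contrasts",
    "quantile_normalize",
    "loess_normalize_dual",
    "aggregate_probes_to_genes",
    "compute_contrast_logratios",
    "assemble_compendium",
    "build_compendium_from_raw",
    "PROCESSING_STEPS",
]

#: Ordered names of the processing steps the pipeline may apply.  There is
#: deliberately no background-subtraction or mismatch-correction step.
PROCESSING_STEPS = (
    "probe_mapping",
    "contrast_definition",
    "loess_normalization",
    "quantile_normalization",
    "log2_transform",
    "probe_aggregation",
    "logratio_assembly",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ChannelInfo:
    """Descriptor of one channel of a hybridization."""

    sample_id: str = ""
    role: str | None = None  # "test" | "reference" | None
    #: False for channels that do not measure an identifiable biological
    #: condition (genomic DNA, pooled heterogeneous samples, ...); such
    #: channels are discarded during contrast definition.
    biological: bool = True


@dataclass
class HybridizationTable:
    """Probe-level intensities of one hybridization.

    ``intensities`` has one row per probe and one column per channel
    (column names must equal the keys of ``channels``).  Intensities are in
    arbitrary positive units unless ``is_log2`` declares the table as
    already log-transformed by its source.
    """

    experiment_id: str
    platform_id: str
    hybridization_id: str
    channel_layout: str  # "single" | "dual"
    intensities: pd.DataFrame
    channels: dict[str, ChannelInfo]
    is_log2: bool = False

    def __post_init__(self) -> None:
        n_expected = {"single": 1, "dual": 2}.get(self.channel_layout)
        if n_expected is None:
            raise ValidationError(f"unknown channel layout {self.channel_layout!r}")
        if len(self.channels) != n_expected:
            raise ValidationError(
                f"{self.channel_layout}-channel hybridization must have "
                f"{n_expected} channel(s), got {len(self.channels)}"
            )
        if set(self.intensities.columns) != set(self.channels):
            raise ValidationError("intensity columns do not match declared channels")
        if not self.is_log2:
            arr = self.intensities.to_numpy(dtype=float)
            if np.nanmin(arr, initial=np.inf) <= 0:
                raise ValidationError("raw intensities must be positive or missing")


@dataclass(frozen=True)
class ContrastDefinition:
    """A (test, reference) pairing of hybridization channels.

    Members are ``(hybridization_id, channel)`` pairs; all members belong
    to one experiment-and-platform combination.
    """

    contrast_id: str
    experiment_id: str
    platform_id: str
    test_members: tuple[tuple[str, str], ...]
    reference_members: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.test_members or not self.reference_members:
            raise ValidationError("test and reference member lists must be non-empty")
        if set(self.test_members) & set(self.reference_members):
            raise ValidationError("test and reference members must be disjoint")


@dataclass
class ProbeMap:
    """Probe -> gene mapping with per-probe provenance.

    ``mapping`` covers mapped probes only; ``provenance`` covers every
    probe, with value ``"unmapped"`` where no unambiguous gene was found
    and otherwise one of ``sequence | locus_tag | alt_tag | gene_name``.
    """

    mapping: pd.Series
    provenance: pd.Series

    @property
    def n_mapped(self) -> int:
        return len(self.mapping)

    def genes_of(self, probes: Iterable[str]) -> pd.Series:
        return self.mapping.reindex(list(probes))


# ---------------------------------------------------------------------------
# probe mapping
# ---------------------------------------------------------------------------


def _split_tags(value) -> list[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    return [t for t in str(value).replace(";", "|").split("|") if t]


def _normalize_gene_index(gene_index) -> pd.DataFrame:
    if isinstance(gene_index, pd.DataFrame):
        if "gene_id" not in gene_index.columns:
            raise ConfigurationError("gene index frame needs a 'gene_id' column")
        frame = gene_index.copy()
    else:
        frame = pd.DataFrame({"gene_id": list(gene_index)})
    if frame.empty:
        raise ConfigurationError("gene index is empty")
    if frame["gene_id"].duplicated().any():
        raise ConfigurationError("gene index ids must be unique")
    return frame


def map_probes(
    probe_table: pd.DataFrame,
    gene_index,
    hits: pd.DataFrame | None = None,
    min_identity: float = 95.0,
    min_coverage: float = 0.9,
) -> ProbeMap:
    """Map probes to unique genes, by sequence hits or by identifiers.

    When a precomputed sequence-hit table is given (columns ``probe_id``,
    ``gene_id``, ``identity`` in percent, ``coverage`` as fraction of the
    probe length), each probe maps to the gene of its unique best hit
    passing the thresholds; a tie between distinct genes at the best score
    leaves the probe unmapped.  Without hits, identifiers are matched in
    order of preference — locus tags, alternative gene tags, common gene
    names — and a probe matching zero or more than one gene at its winning
    tier is unmapped.
    """
    gene_frame = _normalize_gene_index(gene_index)
    if "probe_id" not in probe_table.columns:
        raise ParseError("probe table needs a 'probe_id' column")
    probes = probe_table["probe_id"].astype(str)
    if probes.duplicated().any():
        raise ParseError("duplicate probe ids in probe table")

    provenance = pd.Series("unmapped", index=probes.to_numpy(), dtype=object)
    mapping: dict[str, str] = {}

    if hits is not None:
        required = {"probe_id", "gene_id", "identity", "coverage"}
        if not required.issubset(hits.columns):
            raise ParseError(f"hit table needs columns {sorted(required)}")
        h = hits.copy()
        for col in ("identity", "coverage"):
            h[col] = pd.to_numeric(h[col], errors="coerce")
        if h[["identity", "coverage"]].isna().any().any():
            raise ParseError("non-numeric identity/coverage in hit table")
        if ((h["identity"] < 0) | (h["identity"] > 100)).any():
            raise ParseError("identity must be in [0, 100]")
        if ((h["coverage"] < 0) | (h["coverage"] > 1)).any():
            raise ParseError("coverage must be in [0, 1]")
        known = set(gene_frame["gene_id"])
        h = h[
            (h["identity"] >= min_identity)
            & (h["coverage"] >= min_coverage)
            & h["gene_id"].isin(known)
        ]
        for probe_id, group in h.groupby("probe_id", sort=False):
            probe_id = str(probe_id)
            if probe_id not in provenance.index:
                continue
            best = group.sort_values(
                ["identity", "coverage"], ascending=False, kind="mergesort"
            )
            top_ident, top_cov = best.iloc[0][["identity", "coverage"]]
            top = best[(best["identity"] == top_ident) & (best["coverage"] == top_cov)]
            top_genes = set(top["gene_id"])
            if len(top_genes) == 1:
                mapping[probe_id] = top["gene_id"].iloc[0]
                provenance[probe_id] = "sequence"
        return ProbeMap(
            mapping=pd.Series(mapping, dtype=object, name="gene_id"),
            provenance=provenance,
        )

    # identifier tiers, in order of preference
    locus_lookup: dict[str, list[str]] = {g: [g] for g in gene_frame["gene_id"]}
    alt_lookup: dict[str, list[str]] = {}
    if "alt_tags" in gene_frame.columns:
        for g, tags in zip(gene_frame["gene_id"], gene_frame["alt_tags"]):
            for tag in _split_tags(tags):
                alt_lookup.setdefault(tag, []).append(g)
    name_lookup: dict[str, list[str]] = {}
    if "gene_name" in gene_frame.columns:
        for g, nm in zip(gene_frame["gene_id"], gene_frame["gene_name"]):
            for tag in _split_tags(nm):
                name_lookup.setdefault(tag, []).append(g)

    tiers = (
        ("locus_tag", "locus_tag", locus_lookup),
        ("alt_tag", "alt_tags", alt_lookup),
        ("gene_name", "gene_name", name_lookup),
    )
    for _, row in probe_table.iterrows():
        probe_id = str(row["probe_id"])
        for tier_name, column, lookup in tiers:
            if column not in probe_table.columns:
                continue
            candidates: set[str] = set()
            for tag in _split_tags(row[column]):
                candidates.update(lookup.get(tag, []))
            if candidates:
                # the first tier with any match wins; ambiguity => unmapped
                if len(candidates) == 1:
                    mapping[probe_id] = candidates.pop()
                    provenance[probe_id] = tier_name
                break
    return ProbeMap(
        mapping=pd.Series(mapping, dtype=object, name="gene_id"),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# contrast definition
# ---------------------------------------------------------------------------


def define_contrasts(
    hybs: Sequence[HybridizationTable],
    pairing_hints: Mapping[tuple[str, str], Sequence[tuple]] | None = None,
) -> list[ContrastDefinition]:
    """Derive test/reference contrast definitions from hybridization roles.

    Dual-channel arrays yield one within-array contrast each (the channel
    flagged ``test`` against the one flagged ``reference``; without flags,
    channel 2 vs channel 1) — unless a channel is marked non-biological
    (genomic DNA, sample pools), in which case that channel is discarded
    and the surviving channel joins the group's single-channel pool.
    Within each (experiment, platform) group, single-channel tests are each
    contrasted against all designated references.

    ``pairing_hints`` maps a group key to an explicit list of
    ``(test_members, reference_members)`` pairs that overrides the default
    pairing for that group's single-channel pool.
    """
    groups: dict[tuple[str, str], list[HybridizationTable]] = {}
    for h in hybs:
        groups.setdefault((h.experiment_id, h.platform_id), []).append(h)

    definitions: list[ContrastDefinition] = []
    for (exp, plat), members in groups.items():
        counter = 0

        def next_id() -> str:
            nonlocal counter
            counter += 1
            return f"{exp}:{plat}:c{counter:03d}"

        single_pool: list[tuple[str, str, str | None]] = []  # (hyb, channel, role)
        for h in members:
            if h.channel_layout == "dual":
                bio = {ch: info for ch, info in h.channels.items() if info.biological}
                if len(bio) == 2:
                    roles = {info.role: ch for ch, info in h.channels.items()}
                    if "test" in roles and "reference" in roles:
                        test_ch, ref_ch = roles["test"], roles["reference"]
                    else:
                        ref_ch, test_ch = sorted(h.channels)
                    definitions.append(
                        ContrastDefinition(
                            contrast_id=next_id(),
                            experiment_id=exp,
                            platform_id=plat,
                            test_members=((h.hybridization_id, test_ch),),
                            reference_members=((h.hybridization_id, ref_ch),),
                        )
                    )
                else:
                    # surviving biological channels demote to single-channel
                    # data; their within-array role is meaningless once the
                    # co-channel is gone, so they are treated as tests
                    for ch in sorted(bio):
                        single_pool.append((h.hybridization_id, ch, None))
            else:
                (ch, info), = h.channels.items()
                if info.biological:
                    single_pool.append((h.hybridization_id, ch, info.role))

        if pairing_hints and (exp, plat) in pairing_hints:
            for test_members, ref_members in pairing_hints[(exp, plat)]:
                definitions.append(
                    ContrastDefinition(
                        contrast_id=next_id(),
                        experiment_id=exp,
                        platform_id=plat,
                        test_members=tuple(tuple(m) for m in test_members),
                        reference_members=tuple(tuple(m) for m in ref_members),
                    )
                )
            continue

        refs = [(hy, ch) for hy, ch, role in single_pool if role == "reference"]
        tests = [(hy, ch) for hy, ch, role in single_pool if role != "reference"]
        if tests and not refs:
            raise DefinitionError(
                f"group ({exp}, {plat}) has single-channel tests but no "
                "designated reference"
            )
        for member in tests:
            definitions.append(
                ContrastDefinition(
                    contrast_id=next_id(),
                    experiment_id=exp,
                    platform_id=plat,
                    test_members=(member,),
                    reference_members=tuple(refs),
                )
            )
    return definitions


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize the columns of an intensity matrix.

    Every column's sorted values are replaced by the across-column mean of
    sorted values, so afterwards all columns share one sorted multiset.
    Tied intensities within a column receive the mean of the reference
    values at their tied ranks, which makes the transform exactly
    idempotent.  Matrices with missing entries are handled by per-column
    linear interpolation of each column's quantile function onto a common
    grid (approximate, limma-style).
    """
    if matrix.shape[1] < 2:
        warnings.warn("quantile normalization needs >= 2 columns; returning input")
        return matrix.copy()

    A = matrix.to_numpy(dtype=float)
    out = np.empty_like(A)
    if not np.isnan(A).any():
        n = A.shape[0]
        ref = np.sort(A, axis=0).mean(axis=1)
        for j in range(A.shape[1]):
            col = A[:, j]
            order = np.argsort(col, kind="mergesort")
            assigned = np.empty(n)
            assigned[order] = ref
            # average the reference values over runs of tied intensities
            tied = pd.Series(assigned[order]).groupby(col[order]).transform("mean")
            assigned[order] = tied.to_numpy()
            out[:, j] = assigned
    else:
        grid = np.linspace(0.0, 1.0, num=A.shape[0])
        curves = []
        for j in range(A.shape[1]):
            col = A[:, j]
            obs = np.sort(col[np.isfinite(col)])
            if obs.size == 0:
                raise DomainError(f"column {j} has no observed intensities")
            p = np.linspace(0.0, 1.0, num=obs.size)
            curves.append(np.interp(grid, p, obs))
        ref_curve = np.mean(curves, axis=0)
        for j in range(A.shape[1]):
            col = A[:, j]
            obs_mask = np.isfinite(col)
            n_obs = int(obs_mask.sum())
            ranks = rankdata(col[obs_mask], method="average")
            p = (ranks - 1.0) / max(n_obs - 1, 1)
            new = np.full_like(col, np.nan)
            new[obs_mask] = np.interp(p, grid, ref_curve)
            out[:, j] = new
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def loess_normalize_dual(
    test_channel,
    ref_channel,
    span: float = 0.4,
    degree: int = 1,
    robust_iters: int = 3,
    min_probes: int = 30,
    is_log2: bool = False,
) -> np.ndarray:
    """Remove intensity-dependent dye bias from a dual-channel array.

    With M = log2(test/ref) and A = (log2 test + log2 ref) / 2 per probe,
    returns ``M - loess(M | A)``: the residual of a robust locally linear
    fit of M on A, which has near-zero smooth trend in A.  Probes missing
    in either channel are NaN in the output.

    The fit is locally linear (``degree`` must be 1); ``robust_iters``
    reweighting iterations downweight outlying probes.
    """
    if degree != 1:
        raise ParameterError("only locally linear loess (degree=1) is supported")
    if not 0 < span <= 1:
        raise ParameterError("span must be in (0, 1]")
    t = np.asarray(test_channel, dtype=float).ravel()
    r = np.asarray(ref_channel, dtype=float).ravel()
    if t.shape != r.shape:
        raise ParameterError("test and reference channels must be the same length")
    obs = np.isfinite(t) & np.isfinite(r)
    if not is_log2 and ((t[obs] <= 0).any() or (r[obs] <= 0).any()):
        raise DomainError("raw intensities must be strictly positive")
    n = int(obs.sum())
    if n < min_probes:
        raise FitError(f"only {n} paired probes; need >= {min_probes} for a stable fit")

    if is_log2:
        lt, lr = t[obs], r[obs]
    else:
        lt, lr = np.log2(t[obs]), np.log2(r[obs])
    M = lt - lr
    A = (lt + lr) / 2.0

    if np.ptp(A) <= 0:
        fitted = np.full(n, M.mean())  # constant A: fit collapses to the mean
    else:
        delta = 0.01 * np.ptp(A)
        fitted = lowess(
            M, A, frac=span, it=robust_iters, delta=delta, return_sorted=False
        )
    out = np.full(t.shape, np.nan)
    out[obs] = M - fitted
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def aggregate_probes_to_genes(
    probe_values: pd.DataFrame, probe_map: ProbeMap
) -> pd.DataFrame:
    """Aggregate probe-level values to gene level (median over probes).

    The median of the mapped probes' values per gene is robust against a
    single misbehaving probe.  Unmapped probes are dropped.
    """
    genes = probe_map.mapping.reindex(probe_values.index)
    keep = genes.notna()
    sub = probe_values.loc[keep]
    return sub.groupby(genes[keep]).median()


def compute_contrast_logratios(
    gene_log2: pd.DataFrame, contrast: ContrastDefinition
) -> pd.Series:
    """One log ratio per gene for a contrast definition.

    ``gene_log2`` holds per-gene log2 intensities with one column per
    ``(hybridization_id, channel)`` member.  The ratio is the mean of the
    test members' log2 intensities minus the mean of the reference
    members' — i.e. a log ratio of geometric means — and is missing where
    either side has no observation.
    """
    if not isinstance(gene_log2.columns, pd.MultiIndex):
        raise ParameterError(
            "gene_log2 columns must be a (hybridization_id, channel) MultiIndex"
        )
    available = set(gene_log2.columns)
    missing = (set(contrast.test_members) | set(contrast.reference_members)) - available
    if missing:
        raise DefinitionError(
            f"contrast {contrast.contrast_id} references unknown hybridization "
            f"channels: {sorted(missing)[:5]}"
        )
    test = gene_log2[list(contrast.test_members)].mean(axis=1, skipna=True)
    ref = gene_log2[list(contrast.reference_members)].mean(axis=1, skipna=True)
    out = test - ref
    out.name = contrast.contrast_id
    return out


def assemble_compendium(
    columns: Iterable[tuple[str, pd.Series]] | Mapping[str, pd.Series],
    contrast_meta: Mapping[str, tuple[str, str]],
    gene_index,
    name: str = "compendium",
) -> LogratioCompendium:
    """Assemble per-contrast gene log-ratio columns into a compendium.

    Rows cover the full gene index: genes never measured on any platform
    get all-missing rows.  Duplicate contrast ids abort assembly.
    """
    if isinstance(columns, Mapping):
        items = list(columns.items())
    else:
        items = list(columns)
    ids = [cid for cid, _ in items]
    if len(set(ids)) != len(ids):
        raise AssemblyError("duplicate contrast ids during assembly")
    genes = _normalize_gene_index(gene_index)["gene_id"]
    meta_rows = {}
    for cid, _ in items:
        if cid not in contrast_meta:
            raise AssemblyError(f"no (experiment, platform) metadata for {cid!r}")
        exp, plat = contrast_meta[cid]
        meta_rows[cid] = {"experiment_id": exp, "platform_id": plat}
    values = pd.DataFrame(
        {cid: col.reindex(genes) for cid, col in items}, index=pd.Index(genes, name="gene_id")
    )
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    comp = LogratioCompendium(values, meta, name=name)
    logger.info(
        "assembled compendium %s: %d genes x %d contrasts, %.1f%% missing",
        name,
        comp.n_genes,
        comp.n_contrasts,
        100 * comp.missing_fraction,
    )
    return comp


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------


def _is_within_array_dual(
    definition: ContrastDefinition, hyb_lookup: Mapping[str, HybridizationTable]
) -> bool:
    members = definition.test_members + definition.reference_members
    if len(definition.test_members) != 1 or len(definition.reference_members) != 1:
        return False
    hyb_ids = {m[0] for m in members}
    if len(hyb_ids) != 1:
        return False
    hyb = hyb_lookup.get(next(iter(hyb_ids)))
    return hyb is not None and hyb.channel_layout == "dual"


def build_compendium_from_raw(
    hybridizations: Sequence[HybridizationTable],
    contrast_definitions: Sequence[ContrastDefinition],
    probe_annotations: Mapping[str, pd.DataFrame],
    gene_index,
    sequence_hits: Mapping[str, pd.DataFrame] | None = None,
    span: float = 0.4,
    robust_iters: int = 3,
    name: str = "compendium",
) -> tuple[LogratioCompendium, dict]:
    """Run the full homogenization pipeline on raw experiment tables.

    Per (experiment, platform) group: within-array dual-channel contrasts
    go through the loess M-vs-A correction at probe level and are then
    aggregated to genes; all remaining (single-channel style) member
    channels are quantile-normalized together, log2-transformed if raw,
    aggregated to genes, and turned into log ratios per contrast
    definition.  Returns the compendium and a build log with per-step
    record counts.
    """
    hyb_lookup = {h.hybridization_id: h for h in hybridizations}
    probe_maps = {
        plat: map_probes(
            table,
            gene_index,
            hits=None if sequence_hits is None else sequence_hits.get(plat),
        )
        for plat, table in probe_annotations.items()
    }

    groups: dict[tuple[str, str], list[ContrastDefinition]] = {}
    for definition in contrast_definitions:
        groups.setdefault(
            (definition.experiment_id, definition.platform_id), []
        ).append(definition)

    build_log: dict = {
        "steps": list(PROCESSING_STEPS),
        "n_hybridizations": len(hybridizations),
        "n_contrasts_defined": len(contrast_definitions),
        "probes_mapped": {p: pm.n_mapped for p, pm in probe_maps.items()},
        "loess_arrays": 0,
        "quantile_groups": 0,
    }

    columns: list[tuple[str, pd.Series]] = []
    meta: dict[str, tuple[str, str]] = {}
    for (exp, plat), defs in groups.items():
        if plat not in probe_maps:
            raise ConfigurationError(f"no probe annotation for platform {plat!r}")
        pmap = probe_maps[plat]

        dual_defs = [d for d in defs if _is_within_array_dual(d, hyb_lookup)]
        single_defs = [d for d in defs if not _is_within_array_dual(d, hyb_lookup)]

        for definition in dual_defs:
            (hyb_id, test_ch), = definition.test_members
            (_, ref_ch), = definition.reference_members
            hyb = hyb_lookup[hyb_id]
            corrected_m = loess_normalize_dual(
                hyb.intensities[test_ch],
                hyb.intensities[ref_ch],
                span=span,
                robust_iters=robust_iters,
                is_log2=hyb.is_log2,
            )
            probe_m = pd.DataFrame(
                {"M": corrected_m}, index=hyb.intensities.index
            )
            gene_m = aggregate_probes_to_genes(probe_m, pmap)["M"]
            columns.append((definition.contrast_id, gene_m))
            meta[definition.contrast_id] = (exp, plat)
            build_log["loess_arrays"] += 1

        if single_defs:
            members = sorted(
                {
                    m
                    for d in single_defs
                    for m in d.test_members + d.reference_members
                }
            )
            unknown = [m for m in members if m[0] not in hyb_lookup]
            if unknown:
                raise DefinitionError(
                    f"contrasts reference unknown hybridizations: {unknown[:5]}"
                )
            log_states = {hyb_lookup[m[0]].is_log2 for m in members}
            if len(log_states) > 1:
                raise ConfigurationError(
                    f"mixed raw/log2 hybridizations in group ({exp}, {plat})"
                )
            is_log2 = log_states.pop()
            mat = pd.DataFrame(
                {m: hyb_lookup[m[0]].intensities[m[1]] for m in members}
            )
            mat.columns = pd.MultiIndex.from_tuples(members)
            mat = quantile_normalize(mat)
            build_log["quantile_groups"] += 1
            if not is_log2:
                mat = np.log2(mat)
            gene_log2 = aggregate_probes_to_genes(mat, pmap)
            for definition in single_defs:
                col = compute_contrast_logratios(gene_log2, definition)
                columns.append((definition.contrast_id, col))
                meta[definition.contrast_id] = (exp, plat)

    comp = assemble_compendium(columns, meta, gene_index, name=name)
    build_log["n_genes"] = comp.n_genes
    build_log["n_contrasts"] = comp.n_contrasts
    build_log["missing_fraction"] = comp.missing_fraction
    return comp, build_log
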