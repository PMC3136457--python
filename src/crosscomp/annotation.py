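"""Condition-property annotation of contrasts and gene-set annotations.

Because a contrast measures a *difference* between a test and a reference
condition, its annotation is a sparse difference vector over a registry of
formal condition properties (mutations, medium compounds, treatments,
growth parameters): numeric properties contribute test minus reference,
categorical and flag properties contribute ``added`` / ``removed``.  A
condition ontology — a DAG of biological-process-style terms — groups the
properties for higher-level querying; gene sets (regulons, operons,
pathways, GO terms, custom lists) feed module creation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    AnnotationError,
    ConfigurationError,
    RegistryError,
    SetLookupError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionProperty",
    "PropertyRegistry",
    "PropertyDelta",
    "ContrastAnnotation",
    "AnnotationTable",
    "ConditionOntology",
    "GeneAnnotationSets",
    "annotate_contrast_delta",
    "query_contrasts",
    "query_genes",
    "read_gmt",
    "write_gmt",
]

VALUE_KINDS = ("numeric", "categorical", "flag")


@dataclass(frozen=True)
class ConditionProperty:
    """One formal condition property (e.g. 'oxygen level', 'fur deletion')."""

    property_id: str
    name: str
    value_kind: str  # numeric | categorical | flag
    parent_property_id: str | None = None
    units: str | None = None

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(f"unknown value kind {self.value_kind!r}")


class PropertyRegistry:
    """The set of known condition properties, hierarchically structured."""

    def __init__(self, properties: Iterable[ConditionProperty] = ()) -> None:
        self._props: dict[str, ConditionProperty] = {}
        for p in properties:
            self.add(p)

    def add(self, prop: ConditionProperty) -> None:
        if prop.property_id in self._props:
            raise ValidationError(f"duplicate property id {prop.property_id!r}")
        self._props[prop.property_id] = prop
        self._check_acyclic(prop.property_id)

    def _check_acyclic(self, start: str) -> None:
        seen = set()
        cur: str | None = start
        while cur is not None:
            if cur in seen:
                raise ValidationError(f"property hierarchy cycle at {cur!r}")
            seen.add(cur)
            parent = self._props.get(cur)
            cur = parent.parent_property_id if parent else None

    def __contains__(self, property_id: str) -> bool:
        return property_id in self._props

    def __getitem__(self, property_id: str) -> ConditionProperty:
        try:
            return self._props[property_id]
        except KeyError:
            raise RegistryError(f"unknown property {property_id!r}") from None

    def __len__(self) -> int:
        return len(self._props)

    @property
    def property_ids(self) -> list[str]:
        return list(self._props)

    # structured-text form: one property per TSV row
    def write_tsv(self, path) -> None:
        rows = [
            {
                "property_id": p.property_id,
                "name": p.name,
                "value_kind": p.value_kind,
                "parent_property_id": p.parent_property_id or "",
                "units": p.units or "",
            }
            for p in self._props.values()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "PropertyRegistry":
        frame = pd.read_csv(path, sep="\t", keep_default_na=False)
        props = [
            ConditionProperty(
                property_id=r["property_id"],
                name=r["name"],
                value_kind=r["value_kind"],
                parent_property_id=r["parent_property_id"] or None,
                units=r["units"] or None,
            )
            for _, r in frame.iterrows()
        ]
        return cls(props)


@dataclass(frozen=True)
class PropertyDelta:
    """One property's change from reference to test condition."""

    property_id: str
    change: float | str  # numeric difference, or "added" / "removed"


@dataclass
class ContrastAnnotation:
    """Sparse difference vector of condition-property changes."""

    contrast_id: str
    deltas: tuple[PropertyDelta, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [d.property_id for d in self.deltas]
        if len(set(ids)) != len(ids):
            raise ValidationError(
                f"property annotated twice on contrast {self.contrast_id!r}"
            )
        for d in self.deltas:
            if isinstance(d.change, (int, float)) and not math.isfinite(d.change):
                raise ValidationError("numeric deltas must be finite")

    @property
    def property_ids(self) -> set[str]:
        return {d.property_id for d in self.deltas}


def annotate_contrast_delta(
    contrast_id: str,
    test_properties: Mapping[str, object],
    ref_properties: Mapping[str, object],
    registry: PropertyRegistry,
) -> ContrastAnnotation:
    """Difference vector between test and reference property values.

    Numeric properties yield ``test - ref`` and are omitted when the
    difference is zero; categorical and flag properties present on one
    side only yield ``added`` (test-only) or ``removed`` (reference-only).
    A categorical property present on both sides with different values is
    recorded as ``"<ref>-><test>"``.
    """
    deltas: list[PropertyDelta] = []
    for pid in sorted(set(test_properties) | set(ref_properties)):
        prop = registry[pid]  # RegistryError on unknown ids
        t = test_properties.get(pid)
        r = ref_properties.get(pid)
        if prop.value_kind == "numeric":
            try:
                tv = float(t) if t is not None else 0.0
                rv = float(r) if r is not None else 0.0
            except (TypeError, ValueError):
                raise AnnotationError(
                    f"non-numeric value for numeric property {pid!r}"
                ) from None
            diff = tv - rv
            if diff != 0.0:
                deltas.append(PropertyDelta(pid, diff))
        else:
            if t is not None and r is None:
                deltas.append(PropertyDelta(pid, "added"))
            elif r is not None and t is None:
                deltas.append(PropertyDelta(pid, "removed"))
            elif t != r:
                deltas.append(PropertyDelta(pid, f"{r}->{t}"))
    return ContrastAnnotation(contrast_id=contrast_id, deltas=tuple(deltas))


class AnnotationTable:
    """All contrast annotations of a compendium, queryable by property."""

    def __init__(self, annotations: Iterable[ContrastAnnotation] = ()) -> None:
        self._by_contrast: dict[str, ContrastAnnotation] = {}
        for a in annotations:
            if a.contrast_id in self._by_contrast:
                raise ValidationError(f"duplicate annotation for {a.contrast_id!r}")
            self._by_contrast[a.contrast_id] = a

    def __len__(self) -> int:
        return len(self._by_contrast)

    def __getitem__(self, contrast_id: str) -> ContrastAnnotation:
        return self._by_contrast[contrast_id]

    @property
    def contrast_ids(self) -> list[str]:
        return list(self._by_contrast)

    def contrasts_with_property(self, property_id: str) -> set[str]:
        return {
            cid
            for cid, ann in self._by_contrast.items()
            if property_id in ann.property_ids
        }

    def write_tsv(self, path) -> None:
        rows = [
            {"contrast_id": cid, "property_id": d.property_id, "change": d.change}
            for cid, ann in self._by_contrast.items()
            for d in ann.deltas
        ]
        pd.DataFrame(rows, columns=["contrast_id", "property_id", "change"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read_tsv(cls, path) -> "AnnotationTable":
        frame = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
        annotations = []
        for cid, group in frame.groupby("contrast_id", sort=False):
            deltas = []
            for _, row in group.iterrows():
                change: float | str = row["change"]
                try:
                    change = float(change)
                except ValueError:
                    pass
                deltas.append(PropertyDelta(row["property_id"], change))
            annotations.append(ContrastAnnotation(str(cid), tuple(deltas)))
        return cls(annotations)


@dataclass(frozen=True)
class OntologyTerm:
    term_id: str
    name: str
    parent_ids: tuple[str, ...] = ()
    property_ids: tuple[str, ...] = ()


class ConditionOntology:
    """DAG of condition-ontology terms linking to condition properties.

    A property may sit under one or more terms; queries use descendant
    closure with deduplication.
    """

    def __init__(
        self,
        terms: Iterable[OntologyTerm],
        registry: PropertyRegistry | None = None,
    ) -> None:
        self._terms = {t.term_id: t for t in terms}
        self._children: dict[str, list[str]] = {t: [] for t in self._terms}
        for t in self._terms.values():
            for parent in t.parent_ids:
                if parent not in self._terms:
                    raise ValidationError(
                        f"term {t.term_id!r} has unknown parent {parent!r}"
                    )
                self._children[parent].append(t.term_id)
        self._assert_acyclic()
        if registry is not None:
            for t in self._terms.values():
                for pid in t.property_ids:
                    if pid not in registry:
                        raise RegistryError(
                            f"term {t.term_id!r} links unknown property {pid!r}"
                        )

    def _assert_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(tid: str) -> None:
            state[tid] = 1
            for child in self._children[tid]:
                s = state.get(child, 0)
                if s == 1:
                    raise ValidationError(f"ontology cycle through {child!r}")
                if s == 0:
                    visit(child)
            state[tid] = 2

        for tid in self._terms:
            if state.get(tid, 0) == 0:
                visit(tid)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __getitem__(self, term_id: str) -> OntologyTerm:
        try:
            return self._terms[term_id]
        except KeyError:
            raise RegistryError(f"unknown ontology term {term_id!r}") from None

    @property
    def term_ids(self) -> list[str]:
        return list(self._terms)

    def descendants(self, term_id: str, include_self: bool = True) -> set[str]:
        if term_id not in self._terms:
            raise RegistryError(f"unknown ontology term {term_id!r}")
        out: set[str] = set()
        stack = [term_id]
        while stack:
            cur = stack.pop()
            if cur in out:
                continue
            out.add(cur)
            stack.extend(self._children[cur])
        if not include_self:
            out.discard(term_id)
        return out

    def properties_under(self, term_id: str) -> set[str]:
        """Union of properties linked to the term and all its descendants."""
        return {
            pid
            for tid in self.descendants(term_id)
            for pid in self._terms[tid].property_ids
        }

    def write_tsv(self, path) -> None:
        rows = [
            {
                "term_id": t.term_id,
                "name": t.name,
                "parent_ids": "|".join(t.parent_ids),
                "property_ids": "|".join(t.property_ids),
            }
            for t in self._terms.values()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, registry: PropertyRegistry | None = None) -> "ConditionOntology":
        frame = pd.read_csv(path, sep="\t", keep_default_na=False)
        terms = [
            OntologyTerm(
                term_id=r["term_id"],
                name=r["name"],
                parent_ids=tuple(p for p in str(r["parent_ids"]).split("|") if p),
                property_ids=tuple(p for p in str(r["property_ids"]).split("|") if p),
            )
            for _, r in frame.iterrows()
        ]
        return cls(terms, registry=registry)


def query_contrasts(
    by: str,
    key: str,
    annotations: AnnotationTable | None = None,
    ontology: ConditionOntology | None = None,
    compendium=None,
) -> set[str]:
    """Retrieve contrast ids by experiment, condition property, or term.

    ``by`` is one of ``"experiment"`` (needs ``compendium``),
    ``"property"`` (needs ``annotations``; returns contrasts with a
    nonzero delta on the property), or ``"term"`` (needs ``annotations``
    and ``ontology``; returns the union over the term's linked properties
    and all descendant terms' properties).  An unknown key yields an empty
    set with a warning rather than an error.
    """
    if by == "experiment":
        if compendium is None:
            raise ConfigurationError("experiment queries need a compendium")
        if key not in set(compendium.experiments):
            warnings.warn(f"unknown experiment {key!r}; returning empty set")
            return set()
        return set(compendium.contrasts_of_experiment(key))
    if by == "property":
        if annotations is None:
            raise ConfigurationError("property queries need an annotation table")
        found = annotations.contrasts_with_property(key)
        if not found:
            warnings.warn(f"property {key!r} annotates no contrast")
        return found
    if by == "term":
        if annotations is None or ontology is None:
            raise ConfigurationError("term queries need annotations and an ontology")
        if key not in ontology:
            warnings.warn(f"unknown ontology term {key!r}; returning empty set")
            return set()
        out: set[str] = set()
        for pid in ontology.properties_under(key):
            out |= annotations.contrasts_with_property(pid)
        return out
    raise ConfigurationError(f"unknown query kind {by!r}")


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

GENE_SET_CATEGORIES = ("regulon", "operon", "pathway", "go", "custom")


class GeneAnnotationSets:
    """Named gene sets grouped by category (regulon, operon, pathway, ...)."""

    def __init__(self) -> None:
        self._sets: dict[tuple[str, str], set[str]] = {}

    def add(self, category: str, name: str, gene_ids: Iterable[str]) -> None:
        if category not in GENE_SET_CATEGORIES:
            raise ValidationError(f"unknown gene-set category {category!r}")
        key = (category, name)
        if key in self._sets:
            raise ValidationError(f"duplicate gene set {name!r} in {category!r}")
        self._sets[key] = set(gene_ids)

    def __len__(self) -> int:
        return len(self._sets)

    def names(self, category: str | None = None) -> list[tuple[str, str]]:
        return [k for k in self._sets if category is None or k[0] == category]

    def get(self, name: str, category: str | None = None) -> set[str]:
        matches = [
            k for k in self._sets if k[1] == name and (category is None or k[0] == category)
        ]
        if not matches:
            raise SetLookupError(f"no gene set named {name!r}")
        if len(matches) > 1:
            raise SetLookupError(
                f"gene set name {name!r} is ambiguous across categories "
                f"{sorted(c for c, _ in matches)}; pass a category"
            )
        return set(self._sets[matches[0]])

    def sets_containing(self, gene_id: str, category: str | None = None) -> list[tuple[str, str]]:
        return [
            k
            for k, genes in self._sets.items()
            if gene_id in genes and (category is None or k[0] == category)
        ]

    def items(self):
        return self._sets.items()

    @classmethod
    def from_gmt(cls, path, category: str = "custom") -> "GeneAnnotationSets":
        sets = cls()
        for name, genes in read_gmt(path).items():
            sets.add(category, name, genes)
        return sets


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file (name, description, tab-separated genes)."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"malformed GMT line: {line[:60]!r}")
            out[fields[0]] = [g for g in fields[2:] if g]
    return out


def write_gmt(sets: Mapping[str, Sequence[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def query_genes(
    annotation_sets: GeneAnnotationSets,
    gene_index,
    name: str | None = None,
    category: str | None = None,
    explicit_ids: Iterable[str] | None = None,
) -> tuple[set[str], set[str]]:
    """Resolve a gene query to (known ids, unresolved ids).

    Query either a named set (optionally disambiguated by category) or an
    explicit id list; ids not present in the gene index are reported in
    the second element instead of being silently dropped.
    """
    if isinstance(gene_index, pd.DataFrame):
        index = set(gene_index["gene_id"])
    else:
        index = set(gene_index)
    if not index:
        raise ConfigurationError("gene index is empty")
    if explicit_ids is not None:
        requested = set(explicit_ids)
    elif name is not None:
        requested = annotation_sets.get(name, category=category)
    else:
        raise ConfigurationError("provide a set name or an explicit id list")
    resolved = requested & index
    unresolved = requested - index
    if unresolved:
        logger.info("query_genes: %d unresolved ids", len(unresolved))
    return resolved, unresolved
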