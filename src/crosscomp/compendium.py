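"""The gene x contrast log-ratio compendium and the expression module.

A compendium is a matrix of log2 expression ratios whose rows are the known
genes of one organism and whose columns are *condition contrasts*: each
column measures the expression difference between a test and a reference
condition assayed within one experiment on one platform.  Converting
absolute intensities into within-experiment expression changes is what
makes values comparable across platforms and experiments, so the contrast
(not the hybridization) is the unit of integration.

An :class:`ExpressionModule` is the unit of all downstream analysis: a
named pair (gene set, contrast set) bound to a compendium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError

__all__ = [
    "LogratioCompendium",
    "ExpressionModule",
    "module_mean_profile",
]

MISSING_TOKEN = "NA"


class LogratioCompendium:
    """Gene x contrast matrix of log2 ratios with an explicit missing mask.

    Parameters
    ----------
    values:
        DataFrame of log2 ratios, rows indexed by gene id, columns by
        contrast id.  NaN encodes a missing value; every non-missing entry
        must be finite.
    contrast_meta:
        DataFrame indexed by contrast id with columns ``experiment_id``
        and ``platform_id``; every contrast of ``values`` must be present.
    name:
        Identifier used by modules to reference this compendium.
    """

    def __init__(
        self, values: pd.DataFrame, contrast_meta: pd.DataFrame, name: str = "compendium"
    ) -> None:
        values = values.copy().astype(float)
        if values.index.has_duplicates:
            raise ValidationError("duplicate gene ids in compendium")
        if values.columns.has_duplicates:
            raise ValidationError("duplicate contrast ids in compendium")
        arr = values.to_numpy()
        if np.isinf(arr).any():
            raise ValidationError("non-missing compendium values must be finite")
        missing_meta = values.columns.difference(contrast_meta.index)
        if len(missing_meta):
            raise ValidationError(
                f"contrasts without (experiment, platform) metadata: {list(missing_meta)[:5]}"
            )
        for col in ("experiment_id", "platform_id"):
            if col not in contrast_meta.columns:
                raise ValidationError(f"contrast_meta lacks column {col!r}")
        values.index.name = "gene_id"
        values.columns.name = None
        self.values = values
        self.contrast_meta = contrast_meta.loc[
            values.columns, ["experiment_id", "platform_id"]
        ].copy()
        self.contrast_meta.index.name = "contrast_id"
        self.name = name

    # -- basic introspection -------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def contrast_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_contrasts(self) -> int:
        return self.values.shape[1]

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.values.to_numpy()).mean())

    @property
    def experiments(self) -> pd.Index:
        return pd.Index(self.contrast_meta["experiment_id"].unique())

    def contrasts_of_experiment(self, experiment_id: str) -> list[str]:
        mask = self.contrast_meta["experiment_id"] == experiment_id
        return list(self.contrast_meta.index[mask])

    def profile(self, gene_id: str) -> pd.Series:
        """The full log-ratio profile of one gene (NaN = missing)."""
        return self.values.loc[gene_id]

    def submatrix(
        self,
        gene_ids: Sequence[str] | None = None,
        contrast_ids: Sequence[str] | None = None,
    ) -> pd.DataFrame:
        out = self.values
        if gene_ids is not None:
            unknown = pd.Index(gene_ids).difference(self.gene_ids)
            if len(unknown):
                raise ValidationError(f"unknown gene ids: {list(unknown)[:5]}")
            out = out.loc[list(gene_ids)]
        if contrast_ids is not None:
            unknown = pd.Index(contrast_ids).difference(self.contrast_ids)
            if len(unknown):
                raise ValidationError(f"unknown contrast ids: {list(unknown)[:5]}")
            out = out[list(contrast_ids)]
        return out

    # -- on-disk form --------------------------------------------------------

    def write_tsv(self, matrix_path, sidecar_path) -> None:
        """Write the matrix (TSV, ``NA`` = missing) and its sidecar.

        The sidecar maps every contrast id to its experiment and platform.
        """
        self.values.to_csv(
            matrix_path, sep="\t", na_rep=MISSING_TOKEN, index_label="gene_id"
        )
        self.contrast_meta.to_csv(sidecar_path, sep="\t", index_label="contrast_id")

    @classmethod
    def read_tsv(cls, matrix_path, sidecar_path, name: str | None = None) -> "LogratioCompendium":
        values = pd.read_csv(
            matrix_path,
            sep="\t",
            index_col="gene_id",
            na_values=[MISSING_TOKEN],
            keep_default_na=False,
        )
        meta = pd.read_csv(sidecar_path, sep="\t", index_col="contrast_id")
        if name is None:
            name = Path(matrix_path).stem
        return cls(values, meta, name=name)


def _check_unique(ids: Sequence[str], what: str) -> tuple[str, ...]:
    tup = tuple(ids)
    if not tup:
        raise ValidationError(f"module {what} set is empty")
    if len(set(tup)) != len(tup):
        raise ValidationError(f"duplicate ids in module {what} set")
    return tup


@dataclass
class ExpressionModule:
    """A named (gene set, contrast set) pair bound to a compendium."""

    name: str
    gene_ids: tuple[str, ...] = field(default_factory=tuple)
    contrast_ids: tuple[str, ...] = field(default_factory=tuple)
    compendium_ref: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.contrast_ids = _check_unique(self.contrast_ids, "contrast")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_contrasts(self) -> int:
        return len(self.contrast_ids)

    def validate_against(self, compendium: LogratioCompendium) -> None:
        unknown_g = set(self.gene_ids) - set(compendium.gene_ids)
        unknown_c = set(self.contrast_ids) - set(compendium.contrast_ids)
        if unknown_g:
            raise ValidationError(f"module genes not in compendium: {sorted(unknown_g)[:5]}")
        if unknown_c:
            raise ValidationError(
                f"module contrasts not in compendium: {sorted(unknown_c)[:5]}"
            )
        if self.compendium_ref and self.compendium_ref != compendium.name:
            raise ValidationError(
                f"module references compendium {self.compendium_ref!r}, "
                f"got {compendium.name!r}"
            )

    def values(self, compendium: LogratioCompendium) -> pd.DataFrame:
        """The module's expression submatrix (genes x contrasts)."""
        self.validate_against(compendium)
        return compendium.submatrix(self.gene_ids, self.contrast_ids)

    def missing_fraction(self, compendium: LogratioCompendium) -> float:
        return float(np.isnan(self.values(compendium).to_numpy()).mean())

    # -- on-disk form --------------------------------------------------------

    def write(self, path) -> None:
        record = {
            "name": self.name,
            "compendium": self.compendium_ref,
            "genes": list(self.gene_ids),
            "contrasts": list(self.contrast_ids),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(record, fh, sort_keys=False)

    @classmethod
    def read(cls, path) -> "ExpressionModule":
        with open(path) as fh:
            record = yaml.safe_load(fh)
        return cls(
            name=record["name"],
            gene_ids=tuple(record["genes"]),
            contrast_ids=tuple(record["contrasts"]),
            compendium_ref=record.get("compendium", ""),
        )


def module_mean_profile(
    compendium: LogratioCompendium,
    gene_ids: Iterable[str],
    contrast_ids: Iterable[str],
) -> pd.Series:
    """Per-contrast arithmetic mean of the member genes' log ratios.

    Missing member values are excluded contrast by contrast; a contrast
    where no member is observed is missing (NaN) in the output.  This mean
    profile is the reference object for module cleaning and extension.
    """
    sub = compendium.submatrix(list(gene_ids), list(contrast_ids))
    return sub.mean(axis=0, skipna=True)


def mean_profile_of(module: ExpressionModule, compendium: LogratioCompendium) -> pd.Series:
    """:func:`module_mean_profile` for a bound module."""
    module.validate_against(compendium)
    return module_mean_profile(compendium, module.gene_ids, module.contrast_ids)
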