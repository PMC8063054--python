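"""In-memory containers shared by every pipeline stage.

A :class:`CountMatrix` pairs an integer gene-by-sample count table with
aligned sample metadata (cell type and study/batch of origin).  A
:class:`NormalizedMatrix` is the real-valued analogue carrying an
append-only log of the transforms that produced it, so downstream stages
and written artifacts can state exactly what scale their input was on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "GeneList",
    "FormatError",
    "MetadataError",
    "ConfigurationError",
]


class FormatError(ValueError):
    """A tabular input violates its structural contract."""


class MetadataError(ValueError):
    """Sample metadata does not cover the samples in a count table."""


class ConfigurationError(ValueError):
    """A configuration value is invalid; the message names the field."""


def _check_unique(labels: Iterable[str], what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dups = sorted(set(seen[seen.duplicated()]))
        raise FormatError(f"duplicate {what}: {', '.join(map(str, dups))}")


@dataclass
class CountMatrix:
    """Integer gene×sample counts plus aligned per-sample metadata.

    Parameters
    ----------
    counts
        Genes in rows (index = gene symbols), samples in columns.
        Values must be finite non-negative integers.
    sample_meta
        Indexed by sample id with at least ``cell_type`` and ``study``
        columns; must cover every sample in ``counts``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene ids")
        _check_unique(self.counts.columns, "sample ids")
        values = self.counts.to_numpy()
        if not np.isfinite(values).all():
            raise FormatError("count matrix contains non-finite values")
        if (values < 0).any():
            raise FormatError("count matrix contains negative values")
        if not np.allclose(values, np.round(values)):
            raise FormatError("count matrix contains non-integer values")
        missing = self.counts.columns.difference(self.sample_meta.index)
        if len(missing):
            raise MetadataError(
                "samples missing from metadata: " + ", ".join(map(str, missing))
            )
        for col in ("cell_type", "study"):
            if col not in self.sample_meta.columns:
                raise MetadataError(f"sample metadata lacks required column {col!r}")
        # keep metadata aligned to the column order of the counts
        self.sample_meta = self.sample_meta.loc[self.counts.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def cell_types(self) -> pd.Series:
        return self.sample_meta["cell_type"]

    @property
    def studies(self) -> pd.Series:
        return self.sample_meta["study"]

    def samples_of(self, cell_type: str) -> list[str]:
        """Sample ids belonging to one cell type."""
        mask = self.sample_meta["cell_type"] == cell_type
        if not mask.any():
            raise KeyError(f"unknown cell type {cell_type!r}")
        return list(self.sample_meta.index[mask])

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        ids = list(sample_ids)
        return CountMatrix(self.counts[ids].copy(), self.sample_meta.loc[ids].copy())


@dataclass
class NormalizedMatrix:
    """Real-valued gene×sample matrix with a record of applied transforms."""

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    transform_log: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise FormatError("normalized matrix contains non-finite values")
        if not self.transform_log:
            raise ValueError("transform_log must record at least one transform")
        self.sample_meta = self.sample_meta.loc[self.values.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def with_transform(
        self, values: pd.DataFrame, name: str, **params: Any
    ) -> "NormalizedMatrix":
        """New matrix with ``name`` appended to the transform log."""
        log = [*self.transform_log, {"name": name, **params}]
        return NormalizedMatrix(values, self.sample_meta, log)


@dataclass(frozen=True)
class GeneList:
    """A named set of gene symbols, whitespace-trimmed and case-folded.

    Symbols are normalized to upper case on construction so that lists
    from different studies merge on symbol identity alone.
    """

    name: str
    symbols: frozenset[str]

    @classmethod
    def from_symbols(cls, name: str, symbols: Iterable[str]) -> "GeneList":
        cleaned = {s.strip().upper() for s in symbols if s and s.strip()}
        if not cleaned:
            raise FormatError(f"gene list {name!r} is empty after normalization")
        return cls(name=name, symbols=frozenset(cleaned))

    def __len__(self) -> int:
        return len(self.symbols)


def normalize_symbol(symbol: str) -> str:
    """Canonical form used for all cross-dataset symbol matching."""
    return symbol.strip().upper()


def as_mapping(obj: Mapping[str, Any] | pd.Series) -> dict[str, Any]:
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    return dict(obj)
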