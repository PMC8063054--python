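"""Presence calling and three-set Venn partitioning of expressed genes.

A gene is "expressed" in a cell type when its mean size-factor-normalized
count over that type's samples is strictly greater than the cutoff
(default 10) — the same normalized-count scale the DE base mean uses.
The partition assigns every gene present in at least one set to exactly
one of the seven regions of a three-set diagram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet

from .containers import NormalizedMatrix

__all__ = ["expressed_genes", "venn_partition", "VennPartition", "REGIONS"]

REGIONS = ("A_only", "B_only", "C_only", "AB", "AC", "BC", "ABC")


def expressed_genes(
    m: NormalizedMatrix, cell_type: str, cutoff: float = 10.0
) -> set[str]:
    """Genes whose mean normalized count over a cell type is > cutoff."""
    mask = m.sample_meta["cell_type"] == cell_type
    if not mask.any():
        raise KeyError(f"unknown cell type {cell_type!r}")
    means = m.values.loc[:, mask.index[mask]].mean(axis=1)
    return set(means.index[means > cutoff])


@dataclass(frozen=True)
class VennPartition:
    """Disjoint gene sets for the 7 regions of a 3-set diagram."""

    regions: dict[str, frozenset[str]]
    set_names: tuple[str, str, str]

    @property
    def counts(self) -> dict[str, int]:
        return {r: len(self.regions[r]) for r in REGIONS}

    def __getitem__(self, region: str) -> frozenset[str]:
        return self.regions[region]


def venn_partition(
    a: AbstractSet[str],
    b: AbstractSet[str],
    c: AbstractSet[str],
    set_names: tuple[str, str, str] = ("A", "B", "C"),
) -> VennPartition:
    """Exhaustive disjoint partition of three sets into 7 regions."""
    a, b, c = set(a), set(b), set(c)
    regions = {
        "A_only": a - b - c,
        "B_only": b - a - c,
        "C_only": c - a - b,
        "AB": (a & b) - c,
        "AC": (a & c) - b,
        "BC": (b & c) - a,
        "ABC": a & b & c,
    }
    return VennPartition(
        regions={k: frozenset(v) for k, v in regions.items()}, set_names=set_names
    )
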