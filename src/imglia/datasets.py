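"""Bundled demo inputs, generated programmatically.

The curated microglial signature used in the original analysis is the
union of two published lists: 881 symbols from a brain-microglia
expression study and 42 microglia marker genes from a differentiation
study, overlapping in 9 symbols for 914 unique genes.  Those lists live
in journal supplementary files; the functions here build SYNTHETIC
stand-in lists with the same sizes and overlap so the union operation
and everything downstream can be exercised offline.  A few well-known
microglia markers are placed in the overlap for readability; the rest
are systematic placeholder symbols, not real genes.
"""

from __future__ import annotations

from .containers import GeneList
from .io import union_gene_lists

__all__ = ["synthetic_signature_lists", "synthetic_signature_union"]

# real microglia markers, used for the 9-symbol overlap between the lists
_SHARED_MARKERS = (
    "P2RY12",
    "TMEM119",
    "CX3CR1",
    "TREM2",
    "GPR34",
    "OLFML3",
    "SALL1",
    "MERTK",
    "SIGLEC11",
)


def synthetic_signature_lists() -> tuple[GeneList, GeneList]:
    """Synthetic stand-ins for the two published signature lists.

    Returns (large, small): 881 and 42 symbols sharing exactly the 9
    markers above, so their union has 914 unique symbols.
    """
    large = [f"MGSIG{i:04d}" for i in range(881 - len(_SHARED_MARKERS))]
    large += _SHARED_MARKERS
    small = [f"MGMARK{i:02d}" for i in range(42 - len(_SHARED_MARKERS))]
    small += _SHARED_MARKERS
    return (
        GeneList.from_symbols("brain_microglia_881_synthetic", large),
        GeneList.from_symbols("microglia_markers_42_synthetic", small),
    )


def synthetic_signature_union() -> GeneList:
    """Union of the synthetic stand-in lists (914 unique symbols)."""
    return union_gene_lists(list(synthetic_signature_lists()), name="signature_union")
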