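"""Cross-dataset fold-change consistency scoring and the signature cascade.

The consistency score for a gene with fold change ``x`` in the test
dataset and ``y`` in the reference dataset is

    score(x, y) = 2xy / sqrt(x² + y²),

zero at the origin by convention.  Same-sign fold changes score
positive and the score grows with their common magnitude; genes whose
fold changes disagree in sign score negative.  Geometrically it is twice
the (signed) product over the vector norm, so score(x, x) = √2·|x|·sign(x):
a gene must move by at least ~0.354 log2 units in *both* datasets, in the
same direction, to clear the 0.50 consistency cutoff.

The cascade reproduces the signature-gene filtering chain: start from a
curated microglial signature union, keep genes present in both datasets,
keep genes whose monocyte→microglia fold changes are consistent across
datasets (score > 0.50), then intersect with test-side differential
expression (|FC| ≥ 1.2, p ≤ 0.001, average expression ≥ 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneList, normalize_symbol
from .de import de_test
from .normalize import size_factors_median_of_ratios

__all__ = [
    "consistency_score",
    "consistent_genes",
    "group_log2_fold_changes",
    "signature_cascade",
    "CascadeResult",
]

STAGES = ("signature_union", "overlap_with_data", "consistent", "de_filtered")


def consistency_score(x, y):
    """2xy/sqrt(x² + y²); 0 at the origin.  Accepts scalars or arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("fold changes must be finite")
    norm_sq = x**2 + y**2
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(norm_sq > 0, 2.0 * x * y / np.sqrt(np.where(norm_sq > 0, norm_sq, 1.0)), 0.0)
    if score.ndim == 0:
        return float(score)
    return score


def consistent_genes(records: pd.DataFrame, cutoff: float = 0.50) -> set[str]:
    """Genes with consistency score strictly greater than ``cutoff``.

    ``records`` has one row per gene with columns x, y, score (as built
    by :func:`group_log2_fold_changes` + :func:`consistency_score`).
    """
    return set(records.index[records["score"] > cutoff])


def group_log2_fold_changes(
    m: CountMatrix,
    numerator_type: str,
    denominator_type: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2 fold change of one cell type over another.

    Computed from size-factor-normalized group means with a pseudocount
    protecting all-zero groups.
    """
    f = size_factors_median_of_ratios(m)
    norm_counts = m.counts.div(f, axis=1)
    num = norm_counts[m.samples_of(numerator_type)].mean(axis=1)
    den = norm_counts[m.samples_of(denominator_type)].mean(axis=1)
    return np.log2((num + pseudocount) / (den + pseudocount)).rename("log2fc")


@dataclass
class CascadeResult:
    """Gene sets and counts at each stage of the signature cascade."""

    gene_sets: dict[str, set[str]]
    records: pd.DataFrame  # per-gene x, y, score over the overlap stage
    de_table: pd.DataFrame
    params: dict[str, Any] = field(default_factory=dict)

    @property
    def stage_counts(self) -> dict[str, int]:
        return {stage: len(self.gene_sets[stage]) for stage in STAGES}


def signature_cascade(
    test: CountMatrix,
    ref: CountMatrix,
    sig: GeneList,
    fc_cut: float = 1.2,
    p_cut: float = 0.001,
    expr_cut: float = 5.0,
    cons_cut: float = 0.50,
    test_contrast: tuple[str, str] = ("iMG", "monocyte"),
    ref_contrast: tuple[str, str] = ("ref_microglia", "ref_monocyte"),
    use_adjusted_p: bool = False,
    log_scale: bool = True,
) -> CascadeResult:
    """Run the four-stage signature-gene filtering cascade.

    Stage 1 is the curated signature union; stage 2 intersects it with
    the genes present in both count matrices; stage 3 keeps genes whose
    monocyte→microglia(-like) fold changes in the two datasets have
    consistency score > ``cons_cut``; stage 4 further requires, from a
    test-side NB Wald differential-expression run, linear |FC| ≥
    ``fc_cut``, p ≤ ``p_cut`` and mean normalized expression ≥
    ``expr_cut`` (boundary comparisons inclusive, as the criteria are
    stated).  ``log_scale`` scores log2 fold changes; a linear-ratio
    variant is kept for sensitivity analysis.
    """
    for m, (num, den), name in ((test, test_contrast, "test"), (ref, ref_contrast, "ref")):
        present = set(m.sample_meta["cell_type"])
        missing = {num, den} - present
        if missing:
            raise ValueError(
                f"{name} dataset lacks required cell types: {', '.join(sorted(missing))}"
            )
    if not sig.symbols:
        raise ValueError("signature gene list is empty")

    stage1 = set(sig.symbols)
    test_genes = {normalize_symbol(g): g for g in test.gene_ids}
    ref_genes = {normalize_symbol(g): g for g in ref.gene_ids}
    stage2 = stage1 & set(test_genes) & set(ref_genes)
    if not stage2:
        import warnings

        warnings.warn(
            "signature list shares no genes with the data; all cascade "
            "stages after the union are empty",
            stacklevel=2,
        )

    overlap = sorted(stage2)
    x = group_log2_fold_changes(test, *test_contrast).loc[[test_genes[g] for g in overlap]]
    y = group_log2_fold_changes(ref, *ref_contrast).loc[[ref_genes[g] for g in overlap]]
    x.index = overlap
    y.index = overlap
    if not log_scale:
        x = np.power(2.0, x)
        y = np.power(2.0, y)
    records = pd.DataFrame({"x": x, "y": y})
    records["score"] = consistency_score(records["x"].to_numpy(), records["y"].to_numpy())
    stage3 = consistent_genes(records, cons_cut)

    test_sub = test.subset_samples(
        [s for s in test.sample_ids if test.cell_types[s] in test_contrast]
    )
    de = de_test(test_sub, test_sub.cell_types, reference=test_contrast[1])
    p = de["adj_p"] if use_adjusted_p else de["wald_p"]
    passed = de.index[
        (de["log2fc"].abs() >= np.log2(fc_cut)) & (p <= p_cut) & (de["base_mean"] >= expr_cut)
    ]
    passed_norm = {normalize_symbol(g) for g in passed}
    stage4 = stage3 & passed_norm

    return CascadeResult(
        gene_sets={
            "signature_union": stage1,
            "overlap_with_data": stage2,
            "consistent": stage3,
            "de_filtered": stage4,
        },
        records=records,
        de_table=de,
        params={
            "fc_cut": fc_cut,
            "p_cut": p_cut,
            "expr_cut": expr_cut,
            "cons_cut": cons_cut,
            "test_contrast": test_contrast,
            "ref_contrast": ref_contrast,
            "use_adjusted_p": use_adjusted_p,
            "log_scale": log_scale,
        },
    )
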