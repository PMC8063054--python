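"""Normalization chain applied before embedding and clustering.

Order of operations in the full pipeline: median-of-ratios size factors
→ normalized counts (the scale on which the presence cutoff and DE
base means live) → variance-stabilizing transform → batch-effect
removal on the log-like scale → per-gene min–max rescaling to [0, 1].
FPKM is an alternative depth+length normalization used for the MDS
comparison across external datasets.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .containers import CountMatrix, NormalizedMatrix

__all__ = [
    "size_factors_median_of_ratios",
    "normalize_counts",
    "fpkm",
    "log2_transform",
    "vst_transform",
    "remove_batch_effect",
    "rescale_unit_interval",
]

LN2 = np.log(2.0)


def size_factors_median_of_ratios(m: CountMatrix) -> pd.Series:
    """DESeq-style size factors: median ratio to the per-gene geometric mean.

    Only genes with strictly positive counts in every sample are
    reference-eligible (the geometric mean of a row containing a zero
    is zero).  Raises if no gene qualifies, suggesting the total-count
    fallback.
    """
    counts = m.counts.to_numpy(dtype=float)
    eligible = (counts > 0).all(axis=1)
    if not eligible.any():
        raise ValueError(
            "no gene has positive counts in every sample; median-of-ratios is "
            "undefined — consider total-count size factors instead"
        )
    ref = counts[eligible]
    geo = gmean(ref, axis=1)
    factors = np.median(ref / geo[:, None], axis=0)
    return pd.Series(factors, index=m.counts.columns, name="size_factor")


def _check_factor_cover(m: CountMatrix, f: pd.Series | Mapping[str, float]) -> pd.Series:
    f = pd.Series(f)
    missing = m.counts.columns.difference(f.index)
    if len(missing):
        raise ValueError("no size factor for samples: " + ", ".join(map(str, missing)))
    return f.loc[m.counts.columns].astype(float)


def normalize_counts(m: CountMatrix, f: pd.Series | Mapping[str, float]) -> NormalizedMatrix:
    """Counts divided by their sample's size factor."""
    factors = _check_factor_cover(m, f)
    values = m.counts.div(factors, axis=1)
    return NormalizedMatrix(
        values, m.sample_meta, [{"name": "size_factor", "factors": factors.to_dict()}]
    )


def fpkm(m: CountMatrix, lengths: pd.Series | Mapping[str, float]) -> NormalizedMatrix:
    """Fragments per kilobase of transcript per million mapped reads.

    value[g, s] = count[g, s] * 1e9 / (length_bp[g] * column_total[s]).
    """
    lengths = pd.Series(lengths, dtype=float)
    missing = m.counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError("no length for genes: " + ", ".join(map(str, missing)))
    lengths = lengths.loc[m.counts.index]
    totals = m.counts.sum(axis=0).astype(float)
    values = m.counts.div(lengths, axis=0).div(totals, axis=1) * 1e9
    return NormalizedMatrix(values, m.sample_meta, [{"name": "fpkm"}])


def log2_transform(m: NormalizedMatrix, pseudocount: float = 1.0) -> NormalizedMatrix:
    """log2(x + pseudocount); the default pseudocount of 1 maps 0 to 0."""
    values = np.log2(m.values + pseudocount)
    return m.with_transform(values, "log2", pseudocount=pseudocount)


def vst_transform(
    m: CountMatrix,
    dispersion: float,
    f: pd.Series | Mapping[str, float] | None = None,
) -> NormalizedMatrix:
    """Closed-form variance-stabilizing transform for NB2 counts.

    With variance mu + alpha*mu^2, the stabilizing integral
    ∫ dx/sqrt(x + alpha x^2) gives (2/sqrt(alpha))·asinh(sqrt(alpha·x)).
    The core transform 2·asinh(sqrt(alpha·x))/ln 2 is zero at x = 0 and
    grows like log2(x) + log2(4·alpha); subtracting that constant
    calibrates the output to asymptote to log2(x) for large counts.  One
    pooled dispersion is used; the per-gene dispersion trend of full
    DESeq2 VST is intentionally out of scope — monotone variance
    flattening is all clustering needs.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if f is None:
        f = size_factors_median_of_ratios(m)
    factors = _check_factor_cover(m, f)
    x = m.counts.div(factors, axis=1).to_numpy(dtype=float)
    core = 2.0 * np.arcsinh(np.sqrt(dispersion * x)) / LN2  # -> log2 x + log2(4a)
    values = pd.DataFrame(
        core - np.log2(4.0 * dispersion),
        index=m.counts.index,
        columns=m.counts.columns,
    )
    log = [
        {"name": "size_factor", "factors": factors.to_dict()},
        {"name": "vst", "dispersion": dispersion},
    ]
    return NormalizedMatrix(values, m.sample_meta, log)


def remove_batch_effect(
    m: NormalizedMatrix,
    batches: pd.Series | Mapping[str, str] | None = None,
    keep: pd.Series | Mapping[str, str] | None = None,
) -> NormalizedMatrix:
    """Subtract per-gene additive batch effects on the log scale.

    Fits value ~ condition + batch per gene by least squares (one solve
    for the whole matrix, the design being shared) and subtracts the
    fitted batch component, re-centred per gene so the grand mean of
    every gene is exactly preserved.  ``keep`` protects condition
    (cell-type) differences from being absorbed into the batch term;
    omit it to regress batch out unprotected.  Defaults: ``batches`` =
    the study column, ``keep`` = the cell-type column of the metadata.
    """
    if batches is None:
        batches = m.sample_meta["study"]
    batches = pd.Series(batches).loc[m.sample_ids].astype(str)
    if keep is None and "cell_type" in m.sample_meta.columns:
        keep = m.sample_meta["cell_type"]
    levels = sorted(batches.unique())
    if len(levels) == 1:
        return m.with_transform(m.values.copy(), "remove_batch", batches=levels)

    batch_dummies = pd.get_dummies(batches, dtype=float).loc[:, levels[1:]]
    if keep is not None:
        keep = pd.Series(keep).loc[m.sample_ids].astype(str)
        cond = pd.get_dummies(keep, dtype=float)
    else:
        cond = pd.DataFrame({"intercept": np.ones(len(batches))}, index=batches.index)
    design = np.column_stack([cond.to_numpy(), batch_dummies.to_numpy()])
    rank_full = np.linalg.matrix_rank(design)
    rank_cond = np.linalg.matrix_rank(cond.to_numpy())
    if rank_full < rank_cond + batch_dummies.shape[1]:
        raise ValueError(
            "batch is confounded with the protected condition "
            f"(design columns {list(cond.columns) + list(batch_dummies.columns)} "
            "are linearly dependent); batch effects are not estimable"
        )
    Y = m.values.to_numpy(dtype=float).T  # samples x genes
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    n_cond = cond.shape[1]
    batch_part = batch_dummies.to_numpy() @ coef[n_cond:]
    batch_part -= batch_part.mean(axis=0, keepdims=True)  # grand mean preserved
    corrected = pd.DataFrame(
        (Y - batch_part).T, index=m.values.index, columns=m.values.columns
    )
    return m.with_transform(
        corrected,
        "remove_batch",
        batches=levels,
        protected=sorted(cond.columns.astype(str)) if keep is not None else None,
    )


def rescale_unit_interval(m: NormalizedMatrix) -> NormalizedMatrix:
    """Per-gene affine min→0, max→1 rescaling; constant genes map to 0."""
    vals = m.values.to_numpy(dtype=float)
    lo = vals.min(axis=1, keepdims=True)
    hi = vals.max(axis=1, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(span > 0, (vals - lo) / np.where(span > 0, span, 1.0), 0.0)
    values = pd.DataFrame(scaled, index=m.values.index, columns=m.values.columns)
    return m.with_transform(values, "rescale_unit_interval")
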