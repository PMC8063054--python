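"""Relative qPCR quantification by the 2^-ddCT (Livak) method.

Each replicate's target CT is normalized to the housekeeping gene
(ΔCT = CT_target − CT_housekeeping); treated ΔCTs are then referenced
to the *mean* control ΔCT (ΔΔCT), and fold change is 2^−ΔΔCT.
Per-replicate folds are retained so a mean ± SD can be reported, the
convention behind readouts like "12.20 ± 4.00".  Group comparison uses
Student's t-test for two groups and one-way ANOVA for more.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["delta_ct", "ddct_fold_change", "group_compare", "FoldChangeResult"]


def _validate_ct_table(t: pd.DataFrame) -> None:
    required = {"condition", "replicate", "gene", "ct"}
    missing = required - set(t.columns)
    if missing:
        raise ValueError("CT table missing columns: " + ", ".join(sorted(missing)))
    if not np.isfinite(t["ct"].to_numpy(dtype=float)).all():
        raise ValueError("CT values must be finite")


def delta_ct(t: pd.DataFrame, target: str = "target", housekeeping: str = "housekeeping") -> pd.DataFrame:
    """Per-(condition, replicate) ΔCT = CT_target − CT_housekeeping."""
    _validate_ct_table(t)
    wide = t.pivot_table(index=["condition", "replicate"], columns="gene", values="ct")
    for gene in (target, housekeeping):
        if gene not in wide.columns or wide[gene].isna().any():
            where = (
                wide.index[wide[gene].isna()].tolist() if gene in wide.columns else "all rows"
            )
            raise ValueError(f"missing {gene!r} CT for {where}")
    return (wide[target] - wide[housekeeping]).rename("delta_ct").reset_index()


@dataclass
class FoldChangeResult:
    folds: pd.Series  # per treated replicate
    mean: float
    sd: float
    ddct: pd.Series


def ddct_fold_change(
    t: pd.DataFrame,
    treated: str,
    control: str,
    target: str = "target",
    housekeeping: str = "housekeeping",
) -> FoldChangeResult:
    """Per-replicate 2^−ΔΔCT fold changes of ``treated`` vs ``control``."""
    dct = delta_ct(t, target, housekeeping).set_index(["condition", "replicate"])["delta_ct"]
    for cond in (treated, control):
        if cond not in dct.index.get_level_values("condition"):
            raise ValueError(f"condition {cond!r} not in CT table")
    baseline = dct.loc[control].mean()
    ddct = dct.loc[treated] - baseline
    folds = np.power(2.0, -ddct).rename("fold_change")
    return FoldChangeResult(
        folds=folds, mean=float(folds.mean()),
        sd=float(folds.std(ddof=1)) if len(folds) > 1 else 0.0,
        ddct=ddct.rename("ddct"),
    )


def group_compare(folds_by_group: Mapping[str, Sequence[float]]) -> float:
    """Two-sided t-test (2 groups) or one-way ANOVA (>2 groups) p-value."""
    groups = {k: np.asarray(v, dtype=float) for k, v in folds_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")
    arrays = list(groups.values())
    means = [a.mean() for a in arrays]
    if all(a.var(ddof=1) == 0 for a in arrays) and np.ptp(means) == 0:
        return 1.0  # identical degenerate groups: no evidence of difference
    if len(arrays) == 2:
        return float(stats.ttest_ind(*arrays).pvalue)
    return float(stats.f_oneway(*arrays).pvalue)
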