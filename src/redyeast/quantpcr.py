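"""Relative qPCR quantification by the 2^-ddCt (Livak) method.

dCt_s   = mean Ct(target, s) − mean Ct(housekeeping, s)   per sample
ddCt    = dCt_treated − dCt_control
fold    = 2^−ddCt

Replicates are summarized by the arithmetic mean of Ct.  When the table
carries an ``experiment`` column, per-experiment mode computes one fold
change per experiment and averages the folds; pooled mode (default)
averages all replicates together.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import DataError, UsageError

__all__ = ["FoldChange", "ddct_fold_change"]


@dataclass(frozen=True)
class FoldChange:
    gene: str
    delta_ct_control: float
    delta_ct_treated: float
    delta_delta_ct: float
    fold: float


def _mean_ct(df: pd.DataFrame, sample: str, gene: str) -> float:
    sub = df[(df["sample"] == sample) & (df["gene"] == gene)]
    if sub.empty:
        raise UsageError(f"no Ct rows for sample '{sample}', gene '{gene}'")
    return float(sub["ct"].mean())


def _one_fold(
    df: pd.DataFrame, target: str, housekeeping: str, control: str, treated: str
) -> FoldChange:
    d_ctrl = _mean_ct(df, control, target) - _mean_ct(df, control, housekeeping)
    d_trt = _mean_ct(df, treated, target) - _mean_ct(df, treated, housekeeping)
    ddct = d_trt - d_ctrl
    return FoldChange(target, d_ctrl, d_trt, ddct, 2.0 ** (-ddct))


def ddct_fold_change(
    ct_table: pd.DataFrame,
    target_gene: str,
    housekeeping_gene: str,
    control_label: str = "control",
    treated_label: str = "treated",
    per_experiment: bool = False,
) -> FoldChange:
    """Fold change of ``target_gene`` in treated vs control, normalized to
    the housekeeping gene.

    With ``per_experiment`` and an ``experiment`` column present, the fold
    is computed per experiment and the folds averaged (ddCt is then the
    −log2 of that mean).
    """
    if (ct_table["ct"] <= 0).any():
        raise DataError("Ct values must be positive")
    if per_experiment and "experiment" in ct_table.columns:
        import math

        folds = []
        parts = []
        for _, sub in ct_table.groupby("experiment"):
            fc = _one_fold(sub, target_gene, housekeeping_gene, control_label, treated_label)
            folds.append(fc.fold)
            parts.append(fc)
        mean_fold = sum(folds) / len(folds)
        return FoldChange(
            target_gene,
            sum(p.delta_ct_control for p in parts) / len(parts),
            sum(p.delta_ct_treated for p in parts) / len(parts),
            -math.log2(mean_fold),
            mean_fold,
        )
    return _one_fold(ct_table, target_gene, housekeeping_gene, control_label, treated_label)
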