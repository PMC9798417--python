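"""Stepwise marker selection: VIP filter -> BH-FDR significance -> fold change.

Candidate marker ions survive a fixed three-stage cascade applied to the
TIC-normalized peak matrix of a two-group comparison:

1. multivariate relevance — PLS-DA VIP strictly greater than 1.0;
2. univariate significance — per-ion two-sample t-test on the natural-log
   intensities, Benjamini-Hochberg adjusted q strictly below 0.05;
3. effect size — case/control fold change on the linear normalized scale
   strictly above 2.0 or strictly below 0.5.

All inequalities are strict, the stages are ordered, and an ion's pass
flags are monotone: failing one stage fails all later ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "differential_stats",
    "fold_changes",
    "select_markers",
    "CascadeThresholds",
]


@dataclass(frozen=True)
class CascadeThresholds:
    """Cut-offs for the three-stage cascade (all compared strictly)."""

    vip: float = 1.0
    fdr: float = 0.05
    fc_high: float = 2.0
    fc_low: float = 0.5


def differential_stats(
    X: np.ndarray,
    case_mask: np.ndarray,
    equal_var: bool = False,
    log_transform: bool = True,
    epsilon: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-ion two-sided t-test with BH-FDR adjustment.

    The test runs on natural-log intensities (variance stabilization) of the
    TIC-normalized matrix; Welch's unequal-variance form is the default.
    Ions with zero variance in both groups and equal means get p = 1 by
    convention.

    Returns
    -------
    (p_values, q_values)
    """
    X = np.asarray(X, dtype=float)
    case_mask = np.asarray(case_mask, dtype=bool)
    if case_mask.sum() < 2 or (~case_mask).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    if log_transform:
        if epsilon is None:
            nonzero = X[X > 0]
            epsilon = float(nonzero.min()) / 2.0 if nonzero.size else 1.0
        X = np.log(X + epsilon)
    a, b = X[case_mask], X[~case_mask]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    p = np.where(degenerate & np.isclose(a.mean(axis=0), b.mean(axis=0)), 1.0, p)
    p = np.where(degenerate & ~np.isclose(a.mean(axis=0), b.mean(axis=0)), 0.0, p)
    p = np.nan_to_num(p, nan=1.0)
    q = multipletests(p, method="fdr_bh")[1]
    return p, q


def fold_changes(X: np.ndarray, case_mask: np.ndarray) -> np.ndarray:
    """Case-over-control mean-intensity ratio on the linear normalized scale.

    Degenerate conventions: both group means zero -> FC = 1; control mean
    zero with a positive case mean -> +inf sentinel.
    """
    X = np.asarray(X, dtype=float)
    case_mask = np.asarray(case_mask, dtype=bool)
    case_mean = X[case_mask].mean(axis=0)
    ctrl_mean = X[~case_mask].mean(axis=0)
    fc = np.empty_like(case_mean)
    both_zero = (case_mean == 0) & (ctrl_mean == 0)
    ctrl_zero = (ctrl_mean == 0) & ~both_zero
    ok = ~both_zero & ~ctrl_zero
    fc[both_zero] = 1.0
    fc[ctrl_zero] = np.inf
    fc[ok] = case_mean[ok] / ctrl_mean[ok]
    return fc


def select_markers(
    vip: np.ndarray,
    p: np.ndarray,
    q: np.ndarray,
    fc: np.ndarray,
    bin_mz: np.ndarray | None = None,
    polarity: str | list[str] = "positive",
    thresholds: CascadeThresholds = CascadeThresholds(),
    bin_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Apply the cascade and tabulate every ion's fate.

    Returns a marker table with one row per ion: statistics, direction
    (``up`` iff FC > 1), monotone per-stage pass flags (``pass_vip``,
    ``pass_fdr``, ``pass_fc``), the overall ``selected`` flag, and an empty
    ``annotation`` slot.  Per-stage survivor counts are attached as
    ``table.attrs["stage_counts"]``.
    """
    vip, p, q, fc = (np.asarray(v, dtype=float) for v in (vip, p, q, fc))
    n = vip.size
    if not (p.size == q.size == fc.size == n):
        raise ValueError("vip, p, q, and fc must be aligned over the same ions")
    if bin_mz is None:
        bin_mz = np.full(n, np.nan)
    elif np.asarray(bin_mz).size != n:
        raise ValueError("bin_mz misaligned with statistics vectors")

    pass_vip = vip > thresholds.vip
    pass_fdr = pass_vip & (q < thresholds.fdr)
    pass_fc = pass_fdr & ((fc > thresholds.fc_high) | (fc < thresholds.fc_low))

    table = pd.DataFrame({
        "bin_mz": np.asarray(bin_mz, dtype=float),
        "polarity": polarity if isinstance(polarity, list) else [polarity] * n,
        "vip": vip,
        "p_value": p,
        "q_value": q,
        "fold_change": fc,
        "direction": np.where(fc > 1, "up", "down"),
        "pass_vip": pass_vip,
        "pass_fdr": pass_fdr,
        "pass_fc": pass_fc,
        "selected": pass_fc,
        "annotation": [""] * n,
    })
    if bin_ids is not None:
        table.index = pd.Index(bin_ids, name="bin_id")
    table.attrs["stage_counts"] = {
        "total": int(n),
        "vip": int(pass_vip.sum()),
        "fdr": int(pass_fdr.sum()),
        "fc": int(pass_fc.sum()),
    }
    return table
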