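"""Exposure-group assembly and cohort statistics.

Subjects are assigned to PM2.5 exposure groups from the daily mean ambient
concentration on their examination day (Chinese Ambient Air Quality
Standards thresholds): >= 75 ug/m^3 -> high exposure, < 35 ug/m^3 -> low
exposure, in between -> excluded.  Per-parameter group comparisons use the
unpaired two-sample t test (Welch by default; the pooled-variance test is
available by flag) and exposure-response associations use Spearman rank
correlation.  No multiple-testing correction is applied to the per-parameter
p values, matching per-parameter reporting practice; a Benjamini-Hochberg
column is emitted alongside for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "assign_exposure_group",
    "unpaired_t",
    "spearman",
    "run_group_analysis",
    "HIGH_THRESHOLD",
    "LOW_THRESHOLD",
]

HIGH_THRESHOLD = 75.0  # ug/m^3, daily mean; >= is high exposure
LOW_THRESHOLD = 35.0  # ug/m^3, daily mean; < is low exposure

_META_COLUMNS = frozenset({"subject_id", "group", "daily_pm25"})


@dataclass(frozen=True)
class GroupComparison:
    parameter: str
    n_high: int
    n_low: int
    mean_high: float
    mean_low: float
    sd_high: float
    sd_low: float
    t_statistic: float
    p_value: float
    equal_var: bool


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    rho: float
    p_value: float
    n: int


def assign_exposure_group(daily_pm25) -> np.ndarray | str:
    """Exposure group from daily mean PM2.5 (ug/m^3).

    Total and deterministic: >= 75 -> "high", < 35 -> "low", otherwise
    "excluded".  Accepts a scalar or an array; negative concentrations are
    rejected.
    """
    arr = np.asarray(daily_pm25, dtype=float)
    if np.any(arr < 0):
        raise ValueError("PM2.5 concentration cannot be negative")
    out = np.where(arr >= HIGH_THRESHOLD, "high", np.where(arr < LOW_THRESHOLD, "low", "excluded"))
    return out if arr.ndim else str(out)


def unpaired_t(
    a,
    b,
    equal_var: bool = False,
    parameter: str = "",
    labels: tuple[str, str] = ("high", "low"),
) -> GroupComparison:
    """Unpaired two-sample t test between groups ``a`` and ``b``.

    Welch's unequal-variance form by default (the safer choice when group
    variances are not known to match); ``equal_var=True`` gives the classic
    pooled-variance test.  Two-sided p value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        parameter=parameter,
        n_high=a.size,
        n_low=b.size,
        mean_high=float(a.mean()),
        mean_low=float(b.mean()),
        sd_high=float(a.std(ddof=1)),
        sd_low=float(b.std(ddof=1)),
        t_statistic=float(t),
        p_value=float(p),
        equal_var=equal_var,
    )


def spearman(x, y, pair: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p value via the t approximation.  Requires n >= 4 paired
    finite values; constant input is rejected (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1D samples")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError("need at least 4 paired finite observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman's rho is undefined")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(pair=pair, rho=float(rho), p_value=float(p), n=int(x.size))


def run_group_analysis(
    table: pd.DataFrame,
    parameters: list[str] | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-parameter high-vs-low comparison of a cohort table.

    ``table`` needs a ``daily_pm25`` column (groups are assigned from it;
    an existing ``group`` column is recomputed) and one numeric column per
    biomechanical parameter.  Excluded subjects are dropped.  Returns one
    row per parameter with group sizes, means, SDs, the t statistic, the
    two-sided p value and a Benjamini-Hochberg adjusted column.
    """
    if "daily_pm25" not in table.columns:
        raise ValueError("cohort table must contain a 'daily_pm25' column")
    table = table.copy()
    table["group"] = assign_exposure_group(table["daily_pm25"].to_numpy())
    if parameters is None:
        parameters = [
            c
            for c in table.columns
            if c not in _META_COLUMNS and pd.api.types.is_numeric_dtype(table[c])
        ]
    if not parameters:
        raise ValueError("no parameter columns to analyze")
    kept = table[table["group"] != "excluded"]
    rows = []
    for p in parameters:
        hi = kept.loc[kept["group"] == "high", p].dropna().to_numpy()
        lo = kept.loc[kept["group"] == "low", p].dropna().to_numpy()
        if hi.size < 2 or lo.size < 2:
            raise ValueError(f"parameter {p!r} has fewer than 2 values in a group")
        cmp = unpaired_t(hi, lo, equal_var=equal_var, parameter=p)
        rows.append(
            {
                "parameter": p,
                "n_high": cmp.n_high,
                "n_low": cmp.n_low,
                "mean_high": cmp.mean_high,
                "mean_low": cmp.mean_low,
                "sd_high": cmp.sd_high,
                "sd_low": cmp.sd_low,
                "t": cmp.t_statistic,
                "p": cmp.p_value,
            }
        )
    out = pd.DataFrame(rows)
    out["p_bh"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
    return out
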