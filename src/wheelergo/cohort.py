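"""Cohort-level statistics: estimate-vs-measurement agreement and
robust reconstruction of the scaling regressions.

The protocol's accuracy question is cohort-shaped: are the estimated P30
and POpeak close to what participants actually produced?  Three tools
answer it:

* per-participant percent deviation ``Δ = 100 · (measured − estimated) /
  estimated`` with ±20% boundaries (the 20% mirrors the accepted 10 ± 2 min
  window of a well-scaled graded test);
* a paired systematic-difference test — Shapiro-Wilk decides between the
  Wilcoxon signed-rank test and the paired t-test;
* Theil-Sen regression of the per-kg outcomes on their per-kg predictors,
  reconstructing the scaling equations non-parametrically (slope = median
  of all pairwise slopes, robust to the occasional wild participant).

Explained variance for a Theil-Sen line is not uniquely defined; both the
squared Pearson correlation (reported as ``r_squared``) and
1 − SS_res/SS_tot around the Theil-Sen line (``r_squared_residual``) are
computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._round import round_half_up
from .errors import DegenerateTraceError, InvalidConfigurationError

__all__ = [
    "RegressionFit", "EstimateComparison",
    "percent_deviation", "boundary_flags", "theil_sen",
    "compare_estimates", "cohort_summary", "TABLE1_PRECISION",
]


@dataclass(frozen=True)
class RegressionFit:
    """A Theil-Sen line fit: the cohort-regression row type."""

    slope: float
    intercept: float
    r_squared: float            # squared Pearson correlation of x and y
    r_squared_residual: float   # 1 - SS_res/SS_tot around the Theil-Sen line
    n: int
    slope_p: float              # Kendall rank-correlation test
    intercept_p: float          # signed-rank test of residual median = 0

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class EstimateComparison:
    """Paired estimated-vs-measured comparison for one outcome."""

    n: int
    mean_deviation: float       # %, mean of 100·(meas−est)/est
    sd_deviation: float         # %, SD (ddof=1)
    shapiro_p: float            # normality of the paired differences
    wilcoxon_p: float
    ttest_p: float
    test_used: str              # "wilcoxon" if shapiro_p < 0.05 else "t"
    p_value: float              # headline p from the selected test
    significant: bool           # p_value < 0.05


def percent_deviation(est, meas):
    """Percent deviation of measurement from estimate, 100·(meas − est)/est.

    Negative values mean the estimate overshot the measurement.  Accepts
    scalars or arrays; a non-positive estimate is undefined and raises.
    """
    est_arr = np.asarray(est, dtype=float)
    meas_arr = np.asarray(meas, dtype=float)
    if np.any(est_arr[~np.isnan(est_arr)] <= 0):
        raise DegenerateTraceError("percent deviation undefined for est <= 0")
    out = 100.0 * (meas_arr - est_arr) / est_arr
    return float(out) if out.ndim == 0 else out


def boundary_flags(deviations, bound: float = 20.0,
                   ids: Optional[Sequence] = None):
    """Deviations beyond the ±``bound``% boundaries (strict inequality).

    Returns ``(count, flagged_ids)``; ``ids`` defaults to 0-based
    positions.  NaN deviations (missing tests) are never flagged.
    """
    dev = np.asarray(deviations, dtype=float)
    if ids is None:
        ids = np.arange(dev.size)
    ids = np.asarray(ids)
    mask = np.abs(dev) > bound
    mask &= ~np.isnan(dev)
    flagged = [x.item() if hasattr(x, "item") else x for x in ids[mask]]
    return int(mask.sum()), flagged


def theil_sen(x, y) -> RegressionFit:
    """Theil-Sen regression of ``y`` on ``x`` with rank-based inference.

    Slope is the median over all pairs (i < j, x_i ≠ x_j) of
    (y_j − y_i)/(x_j − x_i); the intercept is median(y − slope·x).  The
    slope p-value comes from the Kendall rank-correlation test, the
    intercept p-value from a Wilcoxon signed-rank test of the residuals'
    median against zero.  Pairs with a NaN in either coordinate are dropped
    listwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise InvalidConfigurationError("Theil-Sen needs at least 3 points")
    if np.ptp(x) == 0:
        raise DegenerateTraceError("all x identical: slope undefined")
    slope, intercept, _, _ = stats.theilslopes(y, x, method="joint")
    resid = y - slope * x
    ss_res = float(np.sum((resid - intercept) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r = stats.pearsonr(x, y).statistic if ss_tot > 0 else np.nan
    slope_p = stats.kendalltau(x, y).pvalue
    centered = resid - intercept
    if np.allclose(centered, 0.0):
        intercept_p = 1.0
    else:
        intercept_p = float(stats.wilcoxon(resid, zero_method="wilcox",
                                           method="auto").pvalue)
    return RegressionFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r**2),
        r_squared_residual=1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
        n=int(n),
        slope_p=float(slope_p),
        intercept_p=float(intercept_p),
    )


def compare_estimates(est, meas) -> EstimateComparison:
    """Paired comparison of estimated vs measured outcomes.

    Shapiro-Wilk on the paired differences gates the headline test at the
    0.05 level: non-normal differences use the Wilcoxon signed-rank test,
    normal ones the paired t-test.  Both test results are always reported.
    """
    est = np.asarray(est, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if est.shape != meas.shape:
        raise InvalidConfigurationError("est and meas must pair up")
    keep = ~(np.isnan(est) | np.isnan(meas))
    est, meas = est[keep], meas[keep]
    n = est.size
    if n < 5:
        raise InvalidConfigurationError("need at least 5 pairs")
    diff = meas - est
    dev = percent_deviation(est, meas)
    # identical differences carry no distributional information
    shapiro_p = 1.0 if np.ptp(diff) == 0 else float(stats.shapiro(diff).pvalue)
    if np.allclose(diff, 0.0):
        wilcoxon_p = 1.0
    else:
        wilcoxon_p = float(stats.wilcoxon(diff, zero_method="wilcox").pvalue)
    ttest_p = float(stats.ttest_rel(meas, est).pvalue)
    use_wilcoxon = shapiro_p < 0.05
    p = wilcoxon_p if use_wilcoxon else ttest_p
    return EstimateComparison(
        n=int(n),
        mean_deviation=float(np.mean(dev)),
        sd_deviation=float(np.std(dev, ddof=1)),
        shapiro_p=shapiro_p,
        wilcoxon_p=wilcoxon_p,
        ttest_p=ttest_p,
        test_used="wilcoxon" if use_wilcoxon else "t",
        p_value=float(p),
        significant=bool(p < 0.05),
    )


#: Display precision (decimal places) per cohort-table column.
TABLE1_PRECISION = {
    "age_y": 0, "body_mass_kg": 0, "height_cm": 0, "training_h_per_week": 0,
    "f_iso_N": 0, "f_iso_N_per_kg": 1,
    "sprint_v_mean_ms": 1, "sprint_v_max_ms": 1,
    "sprint_po_mean_W": 0, "sprint_po_mean_W_per_kg": 1,
    "sprint_po_max_W": 0, "sprint_po_max_W_per_kg": 1,
    "p30_est_W": 0, "p30_meas_W": 0, "delta_p30_pct": 0,
    "p30_meas_W_per_kg": 1,
    "want_p5_W": 0, "want_po_max_W": 0, "want_rf_pct": 0,
    "want_v_mean_ms": 1, "want_v_max_ms": 1,
    "popeak_est_W": 0, "popeak_meas_W": 0, "delta_popeak_pct": 0,
    "popeak_meas_W_per_kg": 1,
    "gxt_duration_s": 0, "hr_peak_bpm": 0,
    "rpe_central": 0, "rpe_peripheral": 0, "rpe_overall": 0,
}


def cohort_summary(table: pd.DataFrame, rounded: bool = True) -> pd.DataFrame:
    """Mean and SD rows over available participants, per numeric column.

    Missing cells are excluded column-wise (n is counted per analysis).
    With ``rounded=True`` values are rounded half-up to each column's
    printed precision.
    """
    numeric = table.select_dtypes(include=[np.number])
    numeric = numeric.drop(columns=[c for c in ("id",) if c in numeric])
    mean = numeric.mean(skipna=True)
    sd = numeric.std(skipna=True, ddof=1)
    count = numeric.count()
    if rounded:
        mean = pd.Series(
            {c: round_half_up(mean[c], TABLE1_PRECISION.get(c, 2)) for c in mean.index}
        )
        sd = pd.Series(
            {c: round_half_up(sd[c], TABLE1_PRECISION.get(c, 2)) for c in sd.index}
        )
    return pd.DataFrame({"mean": mean, "sd": sd, "n": count}).T
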