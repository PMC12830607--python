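"""Longitudinal OCT pachymetry analysis.

Corneal thickness is followed per animal and region over the study
schedule (day -1 = pre-procedure baseline).  The analysis expresses each
day as a percentage of baseline, runs per-day paired t-tests against
baseline across animals, and locates the swelling peak and how much of
the excess has resolved by the last day.  The module is agnostic about
which corneal layer the series quantifies; outputs carry whatever
thickness field the input table holds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BASELINE_DAY = -1
SIGNIFICANCE_BANDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for alpha, stars in SIGNIFICANCE_BANDS:
        if p < alpha:
            return stars
    return "n.s."


@dataclass(frozen=True)
class PairedTestResult:
    """Paired t-test of one follow-up day against baseline."""

    day: int
    n: int
    mean_difference_um: float
    t_stat: float
    p_value: float
    stars: str
    degenerate: bool = False


@dataclass(frozen=True)
class PeakResult:
    """Swelling peak of a cohort mean thickness curve."""

    peak_day: int
    peak_value_um: float
    baseline_um: float
    final_day: int
    final_value_um: float
    residual_fraction: float
    at_boundary: bool


def _series_frame(series: pd.DataFrame) -> pd.DataFrame:
    df = series[["day", "thickness_um"]].sort_values("day")
    if df["day"].duplicated().any():
        raise ValueError("duplicate days in series")
    return df


def percent_of_baseline(series: pd.DataFrame) -> pd.DataFrame:
    """(day, percent) pairs: 100 x thickness(day) / thickness(baseline).

    ``series`` holds one animal/region with columns ``day`` and
    ``thickness_um`` including the day -1 baseline.
    """
    df = _series_frame(series)
    base = df.loc[df["day"] == BASELINE_DAY, "thickness_um"]
    if base.empty:
        raise ValueError(f"baseline day {BASELINE_DAY} missing from series")
    b = float(base.iloc[0])
    if b <= 0:
        raise ValueError("baseline thickness must be > 0")
    out = df.copy()
    out["percent"] = 100.0 * out["thickness_um"] / b
    out.loc[out["day"] == BASELINE_DAY, "percent"] = 100.0
    return out[["day", "percent"]].reset_index(drop=True)


def paired_test_vs_baseline(cohort: pd.DataFrame, day: int,
                            region: str | None = None) -> PairedTestResult:
    """Two-sided paired t-test of one day's thickness against baseline.

    Pairs are animals with both a baseline and a day value; differences
    are (day - baseline).  Zero-variance differences are flagged as
    degenerate with the p-value pinned below machine resolution (or 1.0
    when every difference is exactly zero).
    """
    df = cohort
    if region is not None:
        df = df[df["region"] == region]
    wide = df.pivot_table(index="animal_id", columns="day",
                          values="thickness_um", aggfunc="first")
    if BASELINE_DAY not in wide.columns or day not in wide.columns:
        raise ValueError(f"need both baseline and day {day} in the cohort")
    paired = wide[[BASELINE_DAY, day]].dropna()
    n = len(paired)
    if n < 2:
        raise ValueError(f"paired test needs >= 2 animals, got {n}")
    diffs = (paired[day] - paired[BASELINE_DAY]).to_numpy(dtype=float)
    mean_d = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    if sd == 0:
        degenerate = True
        if mean_d == 0:
            t, p = 0.0, 1.0
        else:
            t = float(np.sign(mean_d)) * float("inf")
            p = float(np.finfo(float).tiny)
        logger.warning(
            "day %d: zero-variance differences (degenerate paired test)", day
        )
    else:
        degenerate = False
        t, p = stats.ttest_rel(paired[day], paired[BASELINE_DAY])
        t, p = float(t), float(p)
    return PairedTestResult(
        day=int(day), n=n, mean_difference_um=mean_d, t_stat=t, p_value=p,
        stars=significance_stars(p), degenerate=degenerate,
    )


def all_paired_tests(cohort: pd.DataFrame,
                     region: str | None = None) -> pd.DataFrame:
    """Paired test for every post-baseline day present in the cohort."""
    df = cohort if region is None else cohort[cohort["region"] == region]
    days = sorted(d for d in df["day"].unique() if d != BASELINE_DAY)
    rows = [paired_test_vs_baseline(df, d).__dict__ for d in days]
    return pd.DataFrame(rows)


def mean_curve(cohort: pd.DataFrame, region: str | None = None) -> pd.DataFrame:
    """Cohort mean (and SD) thickness by day."""
    df = cohort if region is None else cohort[cohort["region"] == region]
    g = df.groupby("day")["thickness_um"]
    return pd.DataFrame(
        {"day": g.mean().index, "mean_um": g.mean().to_numpy(),
         "sd_um": g.std(ddof=1).to_numpy()}
    ).reset_index(drop=True)


def find_peak(cohort: pd.DataFrame, region: str | None = None) -> PeakResult:
    """Swelling peak of the cohort mean curve over post-injury days.

    Ties break toward the earlier day.  The residual fraction is
    (final - baseline) / (peak - baseline): 0 means full recovery, 1 no
    recovery at all.  A peak on the first or last post-injury day is
    flagged as a boundary (the series may be monotone).
    """
    curve = mean_curve(cohort, region)
    if len(curve) < 3:
        raise ValueError("peak detection needs at least 3 time points")
    base_rows = curve[curve["day"] == BASELINE_DAY]
    if base_rows.empty:
        raise ValueError("baseline day missing from cohort")
    baseline = float(base_rows["mean_um"].iloc[0])
    post = curve[curve["day"] > BASELINE_DAY].reset_index(drop=True)
    idx = int(np.argmax(post["mean_um"].to_numpy()))  # argmax takes first max
    peak_day = int(post["day"].iloc[idx])
    peak_val = float(post["mean_um"].iloc[idx])
    final_day = int(post["day"].iloc[-1])
    final_val = float(post["mean_um"].iloc[-1])
    at_boundary = idx in (0, len(post) - 1)
    if at_boundary:
        logger.warning("peak at schedule boundary (day %d); series may be "
                       "monotone", peak_day)
    excess = peak_val - baseline
    residual = float("nan") if excess == 0 else (final_val - baseline) / excess
    return PeakResult(
        peak_day=peak_day, peak_value_um=peak_val, baseline_um=baseline,
        final_day=final_day, final_value_um=final_val,
        residual_fraction=residual, at_boundary=at_boundary,
    )
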