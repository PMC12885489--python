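"""Daily resistance series and coefficient-of-variation time-scale analysis.

From the per-breath table, each subject-day collapses to a single daily
resistance value per sampling scheme (mean over accepted breaths).  Daily
values over the scheduled monitoring days form a series with explicit missing
marks; day-to-day variability at a time scale of ``n`` days is the
coefficient of variation CVR = SDR / meanR computed within windows of ``n``
consecutive scheduled days.

Missing-data rules: a subject is retained only if at least 70% of scheduled
recordings are present; a window contributes only if it holds at least
max(3, ceil(min_points_fraction x scale)) present values.  At the maximal
scale (the full observation period) this reduces to the single-window CVR
with a 10-of-14-points floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

SCHEMES = ("full_breath", "full_insp", "mid_insp")
_SCHEME_COLUMN = {
    "full_breath": "R_full_breath",
    "full_insp": "R_full_insp",
    "mid_insp": "R_mid_insp",
}

#: default per-window point floor, as a fraction of the scale
DEFAULT_MIN_POINTS_FRACTION = 10.0 / 14.0


class VariabilityError(ValueError):
    """Invalid series or time-scale request."""


@dataclass
class SubjectSeries:
    """Daily resistance values of one subject under one sampling scheme."""

    subject_id: str
    group: str
    scheme: str
    values: np.ndarray  # length n_scheduled, NaN where missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scheme not in SCHEMES:
            raise VariabilityError(f"unknown scheme '{self.scheme}'")
        present = self.values[np.isfinite(self.values)]
        if np.any(present <= 0):
            raise VariabilityError("resistance values must be positive")

    @property
    def n_scheduled(self) -> int:
        return len(self.values)

    @property
    def n_present(self) -> int:
        return int(np.isfinite(self.values).sum())


@dataclass
class VariabilityResult:
    """meanR / SDR / CVR of one subject at one time scale."""

    subject_id: str
    group: str
    scheme: str
    time_scale: int
    meanR: float
    SDR: float
    CVR: float
    n_windows: int


def daily_value(
    day_breaths: pd.DataFrame, scheme: str, min_breaths: int = 3
) -> float:
    """Daily resistance: mean over accepted breaths, NaN if too few.

    ``day_breaths`` is the per-breath table restricted to one subject-day.
    """
    col = _SCHEME_COLUMN[scheme]
    vals = day_breaths.loc[day_breaths["accepted"], col].dropna()
    if len(vals) < min_breaths:
        return float("nan")
    return float(vals.mean())


def build_subject_series(
    breaths: pd.DataFrame,
    subject_id: str,
    group: str,
    scheme: str,
    n_scheduled: int,
    min_breaths: int = 3,
) -> SubjectSeries:
    """Assemble one subject's daily series over the scheduled days (1-based)."""
    values = np.full(n_scheduled, np.nan)
    sub = breaths[breaths["subject"] == subject_id]
    for day, day_tab in sub.groupby("day"):
        if 1 <= day <= n_scheduled:
            values[int(day) - 1] = daily_value(day_tab, scheme, min_breaths)
    return SubjectSeries(subject_id, group, scheme, values)


def subject_inclusion(series: SubjectSeries, min_fraction: float = 0.70) -> bool:
    """Retention rule: at least ``min_fraction`` of scheduled days present."""
    if series.n_scheduled == 0:
        raise VariabilityError("series has no scheduled days")
    return series.n_present / series.n_scheduled >= min_fraction


def cv_at_timescale(
    series: SubjectSeries,
    scale: int,
    min_points_fraction: float = DEFAULT_MIN_POINTS_FRACTION,
) -> VariabilityResult | None:
    """CVR (and meanR, SDR) of a subject at one time scale.

    Every window of ``scale`` consecutive scheduled days with enough present
    points contributes one CVR = sd/mean (sample SD, n-1 denominator); the
    result averages CVR, meanR and SDR over all eligible sliding windows.
    Returns None when no window is eligible.
    """
    n = series.n_scheduled
    if not 2 <= scale <= n:
        raise VariabilityError(f"scale must lie in [2, {n}], got {scale}")
    # capped at the scale so the shortest scales stay computable (all-present)
    floor = min(scale, max(3, math.ceil(min_points_fraction * scale)))
    means, sds, cvs = [], [], []
    for i in range(n - scale + 1):
        win = series.values[i : i + scale]
        pts = win[np.isfinite(win)]
        if len(pts) < floor:
            continue
        m = float(np.mean(pts))
        s = float(np.std(pts, ddof=1))
        means.append(m)
        sds.append(s)
        cvs.append(s / m)
    if not cvs:
        return None
    return VariabilityResult(
        subject_id=series.subject_id,
        group=series.group,
        scheme=series.scheme,
        time_scale=scale,
        meanR=float(np.mean(means)),
        SDR=float(np.mean(sds)),
        CVR=float(np.mean(cvs)),
        n_windows=len(cvs),
    )


def cohort_variability_table(
    all_series: list[SubjectSeries],
    scales: list[int] | range,
    min_points_fraction: float = DEFAULT_MIN_POINTS_FRACTION,
) -> pd.DataFrame:
    """Long-format table: subject x scale x scheme -> meanR, SDR, CVR.

    Subjects or scales with no eligible window simply contribute no row.
    """
    rows = []
    for series in all_series:
        for scale in scales:
            if scale > series.n_scheduled:
                continue
            res = cv_at_timescale(series, scale, min_points_fraction)
            if res is None:
                continue
            rows.append(
                {
                    "subject": res.subject_id,
                    "group": res.group,
                    "scheme": res.scheme,
                    "scale": res.time_scale,
                    "meanR": res.meanR,
                    "SDR": res.SDR,
                    "CVR": res.CVR,
                    "n_windows": res.n_windows,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject",
            "group",
            "scheme",
            "scale",
            "meanR",
            "SDR",
            "CVR",
            "n_windows",
        ],
    )


def group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Group mean and standard error of CVR per scheme and scale (plot-ready)."""
    if table.empty:
        return pd.DataFrame(
            columns=["group", "scheme", "scale", "CVR_mean", "CVR_sem", "n"]
        )
    g = table.groupby(["group", "scheme", "scale"])["CVR"]
    out = g.agg(CVR_mean="mean", CVR_sem="sem", n="count").reset_index()
    return out
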