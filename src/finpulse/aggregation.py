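"""Roll per-frame detections into hourly counts partitioned by survey period.

Detections are binary labels on non-overlapping 30-s frames, so each
instrument-hour holds at most 120 positive frames.  Hours with no usable
frames (corrupt files) are kept as rows flagged invalid with a missing
count and are excluded from every summary, never treated as zeros.

Survey periods are inclusive Julian-day (day-of-year) ranges; any day with
any airgun shooting is a shooting day, which is why the default ranges are
exactly Shooting 1 (156-173), Quiet 1 (174-196), Shooting 2 (197-212) and
Quiet 2 (213-218).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .counts import DEFAULT_PERIODS, PeriodSpec

__all__ = [
    "PeriodSpec",
    "DEFAULT_PERIODS",
    "assign_period",
    "hourly_counts",
    "summarize",
    "pooled_means",
]

FRAMES_PER_HOUR = 120  # 3600 s / 30 s non-overlapping frames


def assign_period(jd: int, periods: Sequence[PeriodSpec] = DEFAULT_PERIODS) -> str:
    """Map a Julian day to its survey-period name (inclusive ranges)."""
    for p in periods:
        if p.jd_start <= jd <= p.jd_end:
            return p.name
    raise ValueError(f"Julian day {jd} lies outside all survey periods")


def hourly_counts(
    detections: pd.DataFrame,
    periods: Sequence[PeriodSpec] = DEFAULT_PERIODS,
    frame_len_s: float = 30.0,
) -> pd.DataFrame:
    """Count positive frames per instrument-hour.

    ``detections`` needs columns ``instrument``, ``jd``, ``time_s``
    (seconds into the day of the frame start) and ``label`` (0/1).
    Returns one row per instrument-hour that contains at least one frame,
    with columns instrument, jd, hour, count, period, valid.  Hours with
    no frames at all simply do not appear (the caller may reindex and flag
    them invalid).  Duplicate frame timestamps for one instrument are an
    error: the frame grid is non-overlapping by construction.
    """
    req = {"instrument", "jd", "time_s", "label"}
    if not req.issubset(detections.columns):
        raise ValueError(f"detections must have columns {sorted(req)}")
    if detections.duplicated(subset=["instrument", "jd", "time_s"]).any():
        raise ValueError("duplicate frame timestamps within an instrument")

    df = detections.copy()
    df["label"] = df["label"].astype(int)
    if not df["label"].isin((0, 1)).all():
        raise ValueError("labels must be binary")
    df["hour"] = (df["time_s"] // 3600).astype(int)
    if (df["hour"] < 0).any() or (df["hour"] > 23).any():
        raise ValueError("time_s must lie within the day (0..86400)")

    grouped = (
        df.groupby(["instrument", "jd", "hour"], sort=True)["label"]
        .sum()
        .rename("count")
        .reset_index()
    )
    if (grouped["count"] > FRAMES_PER_HOUR).any():
        raise ValueError("hourly count exceeds the 120-frame hour capacity")
    grouped["period"] = [assign_period(jd, periods) for jd in grouped["jd"]]
    grouped["valid"] = True
    return grouped


def _valid(table: pd.DataFrame) -> pd.DataFrame:
    if "valid" in table.columns:
        table = table[table["valid"].astype(bool)]
    return table.dropna(subset=["count"])


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-instrument, per-period mean and range of valid hourly counts.

    Returns columns instrument, period, mean, min, max, n_hours.  Empty
    cells are reported as missing with a warning rather than dropped
    silently.
    """
    table = _valid(table)
    rows = []
    for (instrument, period), cell in table.groupby(["instrument", "period"], sort=True):
        rows.append(
            {
                "instrument": instrument,
                "period": period,
                "mean": cell["count"].mean(),
                "min": cell["count"].min(),
                "max": cell["count"].max(),
                "n_hours": len(cell),
            }
        )
    if not rows:
        warnings.warn("no valid hours to summarise; empty summary")
    return pd.DataFrame(rows, columns=["instrument", "period", "mean", "min", "max", "n_hours"])


def pooled_means(
    table: pd.DataFrame,
    periods: Sequence[PeriodSpec] = DEFAULT_PERIODS,
    weighting: str = "hours",
) -> pd.DataFrame:
    """Pooled quiet and shooting mean hourly counts per instrument.

    ``weighting="hours"`` (default) averages over all valid hours of the
    pooled periods — the rule consistent with the published per-instrument
    pooled means.  ``weighting="periods"`` takes the simple average of the
    two period means instead.
    """
    if weighting not in ("hours", "periods"):
        raise ValueError("weighting must be 'hours' or 'periods'")
    shooting_names = {p.name for p in periods if p.shooting}
    table = _valid(table).copy()
    table["regime"] = np.where(table["period"].isin(shooting_names), "shooting", "quiet")
    rows = []
    for instrument, sub in table.groupby("instrument", sort=True):
        entry = {"instrument": instrument}
        for regime, cell in sub.groupby("regime"):
            if weighting == "hours":
                entry[f"{regime}_mean"] = cell["count"].mean()
            else:
                entry[f"{regime}_mean"] = cell.groupby("period")["count"].mean().mean()
        rows.append(entry)
    return pd.DataFrame(rows, columns=["instrument", "quiet_mean", "shooting_mean"])
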