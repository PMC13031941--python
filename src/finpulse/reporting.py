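"""Summary outputs: LOESS daily trends with detection-uncertainty ribbons
and per-period box summaries of hourly counts.

The daily trend is a locally weighted linear regression (LOESS, tricube
kernel over the span-nearest neighbours, degree 1, no robustness
iterations) through daily detection totals, evaluated at the observed
days; missing (corrupt) days are excluded from fitting.  The ribbon scales
the smoothed line by the detector's error rates — false positives could
have inflated observed counts (lower bound x (1 - FPR)) and false
negatives could have hidden calls (upper bound x (1 + FNR)) — a
multiplicative band, clipped at zero, that always contains the line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ReportConfig",
    "LoessSmoother",
    "loess_smooth",
    "uncertainty_ribbon",
    "period_boxes",
    "plot_daily_trend",
    "plot_period_boxes",
]


@dataclass
class ReportConfig:
    loess_span: float = 0.3
    fpr: float = 0.158
    fnr: float = 0.132
    corrupt_days: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 < self.loess_span <= 1):
            raise ValueError("loess_span must lie in (0, 1]")
        for name in ("fpr", "fnr"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")


class LoessSmoother(RegressorMixin, BaseEstimator):
    """Locally estimated scatterplot smoothing, degree 1, tricube weights.

    At each evaluation point the ``span``-nearest observations are
    weighted by (1 - (d/h)^3)^3 with h the neighbourhood radius, and a
    weighted straight line is fitted and evaluated there.  Output is
    invariant to input row order.
    """

    def __init__(self, span: float = 0.3):
        self.span = span

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        keep = ~(np.isnan(x) | np.isnan(y))
        x, y = x[keep], y[keep]
        if x.size < 3:
            raise ValueError("LOESS needs at least 3 non-missing points")
        if not (0 < self.span <= 1):
            raise ValueError("span must lie in (0, 1]")
        order = np.argsort(x, kind="stable")
        self.x_, self.y_ = x[order], y[order]
        self.k_ = max(2, int(np.ceil(self.span * x.size)))
        return self

    def predict(self, X):
        check_is_fitted(self, "x_")
        xq = np.asarray(X, dtype=float).reshape(-1)
        out = np.empty_like(xq)
        for i, x0 in enumerate(xq):
            d = np.abs(self.x_ - x0)
            idx = np.argsort(d, kind="stable")[: self.k_]
            h = d[idx].max()
            if h == 0:
                # all neighbours coincide with x0; weighted mean
                out[i] = self.y_[idx].mean()
                continue
            w = (1.0 - (d[idx] / h) ** 3) ** 3
            if w.sum() <= 0:
                raise ValueError("empty LOESS window; increase the span")
            xs, ys = self.x_[idx], self.y_[idx]
            # weighted least squares for a local straight line
            sw = w.sum()
            xm = (w * xs).sum() / sw
            ym = (w * ys).sum() / sw
            sxx = (w * (xs - xm) ** 2).sum()
            slope = (w * (xs - xm) * (ys - ym)).sum() / sxx if sxx > 0 else 0.0
            out[i] = ym + slope * (x0 - xm)
        return out


def loess_smooth(days, values, span: float = 0.3) -> np.ndarray:
    """LOESS-smoothed values evaluated at the observed days.

    Missing values are excluded from fitting but every requested day gets
    a smoothed value.
    """
    smoother = LoessSmoother(span=span).fit(days, values)
    return smoother.predict(np.asarray(days, dtype=float).reshape(-1))


def uncertainty_ribbon(smoothed, fpr: float = 0.158, fnr: float = 0.132):
    """Detector-uncertainty band around a smoothed trend.

    lower = smoothed x (1 - FPR); upper = smoothed x (1 + FNR); both
    clipped at zero.  The band always contains the smoothed line.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    if np.any(smoothed < 0):
        raise ValueError("smoothed counts must be non-negative")
    if not (0 <= fpr <= 1 and 0 <= fnr <= 1):
        raise ValueError("rates must lie in [0, 1]")
    lower = np.clip(smoothed * (1.0 - fpr), 0.0, None)
    upper = np.clip(smoothed * (1.0 + fnr), 0.0, None)
    return lower, upper


def period_boxes(table: pd.DataFrame) -> pd.DataFrame:
    """Five-number box summaries of valid hourly counts per instrument-period.

    Quartiles use linear interpolation (numpy default, type-7); whiskers
    extend to the most extreme observation within 1.5 x IQR of the box;
    points beyond are listed as outliers.  Empty cells are omitted with a
    warning.
    """
    if "valid" in table.columns:
        table = table[table["valid"].astype(bool)]
    table = table.dropna(subset=["count"])
    rows = []
    for (instrument, period), cell in table.groupby(["instrument", "period"], sort=True):
        vals = cell["count"].to_numpy(dtype=float)
        if vals.size == 0:
            warnings.warn(f"empty cell ({instrument}, {period}) omitted")
            continue
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        rows.append(
            {
                "instrument": instrument,
                "period": period,
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_low": inside.min(),
                "whisker_high": inside.max(),
                "outliers": sorted(vals[(vals < lo_fence) | (vals > hi_fence)].tolist()),
                "n": vals.size,
            }
        )
    if not rows:
        warnings.warn("no cells to summarise")
    return pd.DataFrame(
        rows,
        columns=[
            "instrument",
            "period",
            "median",
            "q1",
            "q3",
            "whisker_low",
            "whisker_high",
            "outliers",
            "n",
        ],
    )


# ---------------------------------------------------------------------------
# figures (matplotlib; written to file, data alongside as CSV)

def plot_daily_trend(
    daily: pd.DataFrame,
    config: ReportConfig | None = None,
    out_png=None,
    out_csv=None,
):
    """Daily totals per instrument with LOESS trend and uncertainty ribbon.

    ``daily`` needs columns instrument, jd, total.  Returns the plotted
    data (instrument, jd, total, smoothed, lower, upper).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    config = config or ReportConfig()
    daily = daily[~daily["jd"].isin(config.corrupt_days)]
    frames = []
    fig, ax = plt.subplots(figsize=(9, 4.5))
    for instrument, sub in daily.groupby("instrument", sort=True):
        sub = sub.sort_values("jd")
        smoothed = loess_smooth(sub["jd"], sub["total"], span=config.loess_span)
        lower, upper = uncertainty_ribbon(np.clip(smoothed, 0, None), config.fpr, config.fnr)
        ax.plot(sub["jd"], sub["total"], ".", alpha=0.4)
        ax.plot(sub["jd"], smoothed, label=instrument)
        ax.fill_between(sub["jd"], lower, upper, alpha=0.2)
        frames.append(
            pd.DataFrame(
                {
                    "instrument": instrument,
                    "jd": sub["jd"].to_numpy(),
                    "total": sub["total"].to_numpy(),
                    "smoothed": smoothed,
                    "lower": lower,
                    "upper": upper,
                }
            )
        )
    ax.set_xlabel("Julian day")
    ax.set_ylabel("daily pulse-positive frames")
    ax.legend()
    data = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if out_csv is not None:
        data.to_csv(out_csv, index=False)
    if out_png is not None:
        fig.savefig(out_png, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return data


def plot_period_boxes(table: pd.DataFrame, out_png=None, out_csv=None) -> pd.DataFrame:
    """Box summaries per instrument and period, drawn and exported."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    boxes = period_boxes(table)
    if "valid" in table.columns:
        table = table[table["valid"].astype(bool)]
    fig, axes = plt.subplots(
        1, max(table["instrument"].nunique(), 1), figsize=(11, 4), sharey=True
    )
    axes = np.atleast_1d(axes)
    for ax, (instrument, sub) in zip(axes, table.groupby("instrument", sort=True)):
        periods = sorted(sub["period"].unique())
        ax.boxplot(
            [sub.loc[sub["period"] == p, "count"].dropna() for p in periods],
            tick_labels=periods,
            whis=1.5,
        )
        ax.set_title(instrument)
        ax.tick_params(axis="x", rotation=45)
    axes[0].set_ylabel("positive frames / h")
    if out_csv is not None:
        boxes.assign(outliers=boxes["outliers"].astype(str)).to_csv(out_csv, index=False)
    if out_png is not None:
        fig.savefig(out_png, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return boxes
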