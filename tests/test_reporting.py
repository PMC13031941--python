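"""LOESS trends, uncertainty ribbons, and box summaries."""

import numpy as np
import pandas as pd
import pytest

import finpulse as fp


def _loess_oracle(x, y, x0, span):
    """Independent per-point weighted linear regression via lstsq."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    k = max(2, int(np.ceil(span * x.size)))
    d = np.abs(x - x0)
    idx = np.argsort(d, kind="stable")[:k]
    h = d[idx].max()
    w = (1 - (d[idx] / h) ** 3) ** 3
    A = np.stack([np.ones(k), x[idx] - x0], axis=1) * np.sqrt(w)[:, None]
    b = y[idx] * np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    return coef[0]


class TestLoess:
    def test_constant_series_reproduced(self):
        days = np.arange(156, 186)
        out = fp.loess_smooth(days, np.full(30, 42.0), span=0.3)
        assert np.allclose(out, 42.0)

    def test_linear_series_span_one_exact(self):
        days = np.arange(20, dtype=float)
        y = 3.0 * days + 7.0
        out = fp.loess_smooth(days, y, span=1.0)
        assert np.allclose(out, y, atol=1e-9)

    def test_matches_per_point_regression_oracle(self):
        rng = np.random.default_rng(0)
        days = np.sort(rng.choice(np.arange(156, 219), 40, replace=False)).astype(float)
        y = rng.poisson(100, 40).astype(float)
        out = fp.loess_smooth(days, y, span=0.3)
        expected = [_loess_oracle(days, y, x0, 0.3) for x0 in days]
        assert np.allclose(out, expected, atol=1e-8)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        days = np.arange(30, dtype=float)
        y = rng.random(30)
        perm = rng.permutation(30)
        a = fp.loess_smooth(days, y, span=0.4)
        b = fp.loess_smooth(days[perm], y[perm], span=0.4)
        assert np.allclose(a[perm], b)

    def test_missing_days_excluded_from_fit(self):
        days = np.arange(20, dtype=float)
        y = np.full(20, 10.0)
        y[5] = np.nan
        out = fp.loess_smooth(days, y, span=0.5)
        assert np.allclose(out, 10.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fp.loess_smooth([1.0, 2.0], [1.0, 2.0], span=0.5)


class TestRibbon:
    def test_zero_rates_zero_width(self):
        lo, hi = fp.uncertainty_ribbon(np.array([5.0, 10.0]), fpr=0.0, fnr=0.0)
        assert np.array_equal(lo, hi)

    def test_reported_rates_example(self):
        lo, hi = fp.uncertainty_ribbon(np.array([100.0]), fpr=0.158, fnr=0.132)
        assert lo[0] == pytest.approx(84.2)
        assert hi[0] == pytest.approx(113.2)

    def test_zero_counts_zero_band(self):
        lo, hi = fp.uncertainty_ribbon(np.array([0.0]))
        assert lo[0] == 0.0 and hi[0] == 0.0

    def test_band_contains_smoothed_line(self):
        rng = np.random.default_rng(2)
        s = rng.random(50) * 100
        lo, hi = fp.uncertainty_ribbon(s)
        assert np.all(lo <= s) and np.all(s <= hi)


class TestPeriodBoxes:
    def _table(self, counts, instrument="A", period="Quiet 1"):
        return pd.DataFrame(
            {"instrument": instrument, "period": period, "jd": 180,
             "hour": range(len(counts)), "count": counts, "valid": True}
        )

    def test_constant_data_zero_width_no_outliers(self):
        out = fp.period_boxes(self._table([5.0] * 24))
        row = out.iloc[0]
        assert row["q1"] == row["median"] == row["q3"] == 5.0
        assert row["outliers"] == []

    def test_symmetric_data_median_equals_mean(self):
        vals = list(range(1, 24)) + [12]
        out = fp.period_boxes(self._table(vals))
        assert out.iloc[0]["median"] == pytest.approx(np.mean(vals))

    def test_matches_naive_quantile_and_outlier_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.poisson(40, 200).astype(float)
        out = fp.period_boxes(self._table(vals)).iloc[0]
        q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
        iqr = q3 - q1
        outliers = sorted(v for v in vals if v < q1 - 1.5 * iqr or v > q3 + 1.5 * iqr)
        inside = [v for v in vals if q1 - 1.5 * iqr <= v <= q3 + 1.5 * iqr]
        assert (out["q1"], out["median"], out["q3"]) == (q1, med, q3)
        assert out["outliers"] == outliers
        assert out["whisker_low"] == min(inside) and out["whisker_high"] == max(inside)

    def test_permutation_invariance(self, small_count_table):
        t = small_count_table.assign(valid=True)
        a = fp.period_boxes(t).reset_index(drop=True)
        b = fp.period_boxes(t.sample(frac=1.0, random_state=4)).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestFigures:
    def test_daily_trend_artifacts(self, tmp_path, small_count_table):
        daily = (
            small_count_table.groupby(["instrument", "jd"], as_index=False)["count"]
            .sum()
            .rename(columns={"count": "total"})
        )
        png, csv = tmp_path / "trend.png", tmp_path / "trend.csv"
        data = fp.reporting.plot_daily_trend(daily, out_png=png, out_csv=csv)
        assert png.exists() and csv.exists()
        assert {"smoothed", "lower", "upper"}.issubset(data.columns)
        assert np.all(data["lower"] <= data["smoothed"] + 1e-9)

    def test_period_boxes_artifacts(self, tmp_path, small_count_table):
        png = tmp_path / "boxes.png"
        out = fp.reporting.plot_period_boxes(small_count_table.assign(valid=True), out_png=png)
        assert png.exists() and len(out) > 0
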