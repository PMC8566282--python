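import math

import numpy as np
import pandas as pd
import pytest
import scipy.signal
import scipy.stats

from rhizosense.stats import (
    RateTable,
    compare_groups,
    cumulative_detections,
    daily_rates,
    deeper_half_indices,
    exclude_sparse,
    interaction_anova,
    irrigation_hours,
    smooth,
    time_averaged_rate,
)


def _detections(rows):
    return pd.DataFrame(rows, columns=["device_id", "day", "depth_index"])


class TestDailyRates:
    def test_rate_is_count_over_uptime(self, uptime_frame):
        det = _detections([("DV0000", 1, 0)] * 4)  # nt=4 on day with Ut=0.8
        table = daily_rates(det, uptime_frame)
        assert table.rates.loc[1, "rt"] == pytest.approx(5.0)

    def test_low_uptime_day_is_ignored(self, uptime_frame):
        det = _detections([("DV0000", 2, 0)])  # day 2 has Ut = 0.04
        table = daily_rates(det, uptime_frame)
        assert np.isnan(table.rates.loc[2, "rt"])
        assert np.isnan(table.rates.loc[4, "rt"])  # Ut = 0

    def test_full_uptime_rate_equals_count(self, uptime_frame):
        det = _detections([("DV0000", 0, 3)] * 7)
        table = daily_rates(det, uptime_frame)
        assert table.rates.loc[0, "rt"] == 7

    def test_rate_never_below_count(self, uptime_frame):
        det = _detections([("DV0000", d, 0) for d in (0, 1, 1, 3)])
        table = daily_rates(det, uptime_frame)
        ok = table.rates["rt"].notna()
        assert (table.rates.loc[ok, "rt"] >= table.rates.loc[ok, "nt"]).all()

    def test_depth_rates_sum_to_aggregate_on_full_days(self, uptime_frame):
        det = _detections(
            [("DV0000", 0, d) for d in (0, 0, 3, 7, 21)]  # Ut = Utd = 1
        )
        table = daily_rates(det, uptime_frame)
        day0 = table.depth_rates[table.depth_rates["day"] == 0]
        assert day0["rtd"].sum() == pytest.approx(table.rates.loc[0, "rt"])

    def test_depth_cutoff_applied_per_depth(self, uptime_frame):
        up = uptime_frame.copy()
        up.loc[0, "Utd_0"] = 0.03  # only depth 0 below cutoff on day 0
        det = _detections([("DV0000", 0, 0), ("DV0000", 0, 1)])
        table = daily_rates(det, up)
        day0 = table.depth_rates[table.depth_rates["day"] == 0].set_index(
            "depth_index"
        )
        assert np.isnan(day0.loc[0, "rtd"])
        assert day0.loc[1, "rtd"] == pytest.approx(1.0)


class TestCumulative:
    def test_simple_running_sum(self, uptime_frame):
        rates = pd.DataFrame(
            {"device_id": "DV0000", "day": [0, 1, 2], "rt": [1.0, 2.0, 3.0]}
        )
        ct = cumulative_detections(rates)
        assert list(ct["ct"]) == [1.0, 3.0, 6.0]

    def test_zero_rates_stay_zero(self):
        rates = pd.DataFrame(
            {"device_id": "DV0000", "day": range(5), "rt": [0.0] * 5}
        )
        assert (cumulative_detections(rates)["ct"] == 0).all()

    def test_conservation_with_missing_days(self):
        rng = np.random.default_rng(0)
        rt = rng.poisson(3, size=30).astype(float)
        rt[[4, 9, 17]] = np.nan
        rates = pd.DataFrame({"device_id": "D", "day": range(30), "rt": rt})
        ct = cumulative_detections(rates)
        assert ct["ct"].iloc[-1] == pytest.approx(np.nansum(rt))


class TestTimeAveragedRate:
    def _table(self, rt):
        return pd.DataFrame({"device_id": "D", "day": range(len(rt)), "rt": rt})

    def test_constant_rate(self):
        out = time_averaged_rate(self._table([2.5] * 10), 2, 7)
        assert out.loc[0, "R"] == pytest.approx(2.5)

    def test_single_day_window(self):
        out = time_averaged_rate(self._table([1.0, 4.0, 9.0]), 1, 1)
        assert out.loc[0, "R"] == pytest.approx(4.0)

    def test_matches_enumerated_mean_over_non_missing_days(self):
        rng = np.random.default_rng(1)
        rt = rng.gamma(2, 1, size=20)
        rt[[3, 8]] = np.nan
        out = time_averaged_rate(self._table(rt), 2, 12)
        expected = np.mean([r for d, r in enumerate(rt)
                            if 2 <= d <= 12 and not np.isnan(r)])
        assert out.loc[0, "R"] == pytest.approx(expected)

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            time_averaged_rate(self._table([1.0]), 5, 2)


class TestExcludeSparse:
    def _rates(self, uts):
        return pd.DataFrame(
            {"device_id": "D", "day": range(len(uts)), "Ut": uts,
             "nt": 0, "rt": [u if u > 0.04 else np.nan for u in uts]}
        )

    def _averaged(self):
        return pd.DataFrame({"device_id": ["D"], "R": [1.0], "a": 0, "b": 9})

    def test_majority_zero_days_excluded(self):
        rates = self._rates([0, 0, 0, 0, 0, 0, 1, 1, 1, 1])  # 6/10 empty
        assert exclude_sparse(self._averaged(), rates, 0, 9).empty

    def test_short_span_excluded(self):
        # data on days 0-6 of a 10-day window: span 7/10 < 80%
        rates = self._rates([1, 1, 1, 1, 1, 1, 1, 0, 0, 0])
        assert exclude_sparse(self._averaged(), rates, 0, 9).empty

    def test_full_data_retained(self):
        rates = self._rates([1.0] * 10)
        out = exclude_sparse(self._averaged(), rates, 0, 9)
        assert list(out["device_id"]) == ["D"]

    def test_half_zero_days_exactly_is_retained(self):
        # exactly 50% empty days with a full span fails neither rule
        rates = self._rates([1, 0, 1, 0, 1, 0, 1, 0, 1, 0][:10])
        rates.loc[9, "Ut"] = 1.0  # keep span ending on day 9
        rates.loc[8, "Ut"] = 0.0
        out = exclude_sparse(self._averaged(), rates, 0, 9)
        assert list(out["device_id"]) == ["D"]


class TestSmooth:
    def test_constant_series_unchanged(self):
        x = np.full(50, 3.7)
        np.testing.assert_allclose(smooth(x), x, atol=1e-10)

    def test_nyquist_alternation_attenuated(self):
        x = np.cos(np.pi * np.arange(200))  # +1, -1 alternation
        y = smooth(x)
        assert np.max(np.abs(y[20:-20])) < 0.1 * np.max(np.abs(x))

    def test_linear_ramp_preserved_away_from_boundaries(self):
        x = np.linspace(0.0, 10.0, 100)
        y = smooth(x)
        np.testing.assert_allclose(y[10:-10], x[10:-10], atol=1e-6)

    def test_depth_time_matrix_filtered_both_axes(self):
        rng = np.random.default_rng(2)
        m = rng.standard_normal((22, 40))
        out = smooth(m)
        assert out.shape == m.shape
        assert out.std() < m.std()  # high-frequency energy removed

    def test_too_short_series_returned_unfiltered(self):
        x = np.arange(4.0)
        with pytest.warns(UserWarning, match="too short"):
            np.testing.assert_array_equal(smooth(x), x)


class TestCompareGroups:
    def test_identical_groups_are_null(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        cmp = compare_groups(vals, vals.copy())
        assert cmp.t == pytest.approx(0.0)
        assert cmp.p == pytest.approx(0.5)
        assert cmp.d == pytest.approx(0.0)

    def test_matches_textbook_welch_formulas(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        cmp = compare_groups(a, b, direction="greater")
        # independent textbook computation
        na, nb = len(a), len(b)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / na + vb / nb
        t = (a.mean() - b.mean()) / math.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = scipy.stats.t.sf(t, df)
        d = (a.mean() - b.mean()) / math.sqrt((va + vb) / 2)
        assert cmp.t == pytest.approx(t, abs=1e-9)
        assert cmp.df == pytest.approx(df, abs=1e-9)
        assert cmp.p == pytest.approx(p, abs=1e-9)
        assert cmp.d == pytest.approx(d, abs=1e-9)

    def test_effect_size_is_scale_free(self):
        rng = np.random.default_rng(3)
        a = rng.normal(1.0, 1.0, 30)
        b = rng.normal(0.5, 2.0, 30)
        d1 = compare_groups(a, b).d
        d2 = compare_groups(3.0 * a, 3.0 * b).d
        assert d2 == pytest.approx(d1, rel=1e-12)

    def test_zero_variance_both_groups_flagged(self):
        cmp = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0])
        assert not cmp.valid

    def test_lower_confidence_bound_below_point_estimate(self):
        rng = np.random.default_rng(4)
        cmp = compare_groups(rng.normal(1, 1, 50), rng.normal(0, 1, 50))
        assert cmp.d_lower_95 < cmp.d


class TestInteractionAnova:
    def _table(self, cell_values):
        rows = []
        for (trt, gen), vals in cell_values.items():
            rows += [{"R": v, "treatment": trt, "genotype": gen} for v in vals]
        return pd.DataFrame(rows)

    def test_additive_cells_give_zero_interaction_f(self):
        # cell means are exactly additive, within-cell spread symmetric:
        # the interaction sum of squares vanishes
        cells = {}
        for i, trt in enumerate(["WW", "DR"]):
            for j, gen in enumerate(["G1", "G2"]):
                mean = 1.0 + 2.0 * i + 3.0 * j
                cells[(trt, gen)] = [mean - 0.5, mean + 0.5]
        out = interaction_anova(self._table(cells))
        assert out["F"] == pytest.approx(0.0, abs=1e-12)

    def test_programmed_crossover_interaction_detected(self):
        rng = np.random.default_rng(7)
        cells = {}
        for i, trt in enumerate(["WW", "DR"]):
            for j, gen in enumerate(["G1", "G2"]):
                mean = 1.0 if i == j else 2.0  # crossover
                cells[(trt, gen)] = list(rng.normal(mean, 1.0, 50))
        out = interaction_anova(self._table(cells))
        assert out["p"] < 0.01

    def test_empty_cell_error_names_the_cell(self):
        cells = {
            ("WW", "G1"): [1.0, 2.0],
            ("WW", "G2"): [1.0, 2.0],
            ("DR", "G1"): [1.0, 2.0],
        }
        with pytest.raises(ValueError, match="DR.*G2"):
            interaction_anova(self._table(cells))


class TestIrrigationHours:
    @pytest.mark.parametrize(
        "etc,rate,expected",
        [(1.99, 0.19, 10.5), (0.0, 0.19, 0.0), (0.19 * 8, 0.19, 8.0)],
    )
    def test_watering_time(self, etc, rate, expected):
        assert irrigation_hours(etc, rate) == expected

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            irrigation_hours(1.0, 0.0)


def test_deeper_half_indices_default_geometry(geometry):
    assert deeper_half_indices(geometry) == list(range(11, 22))
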