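"""Rates, percentage differences, Poisson trend model and post-hoc tables."""

import numpy as np
import pandas as pd
import pytest

from capqual.config import ConfigError, DataError
from capqual.trends import (
    MISSING,
    PoissonTrendModel,
    atc_class_breakdown,
    atc_major_class,
    duration_frequency,
    pct_difference,
    poisson_trend,
    rate_per_1000,
)


def _counts(years, counts, populations):
    return pd.DataFrame({"year": years, "count": counts, "population": populations})


class TestRatePer1000:
    def test_crude(self):
        assert rate_per_1000(100, 10_000) == 10.0

    def test_standardized_homogeneous_rates_reduce_to_common_rate(self):
        weights = {"a": 0.5, "b": 0.5}
        counts = {"a": 20, "b": 40}
        pops = {"a": 2000, "b": 4000}  # both bands at 10 per 1000
        assert rate_per_1000(counts, pops, weights) == pytest.approx(10.0)

    def test_weighted_band_rates(self):
        weights = {"a": 0.6, "b": 0.4}
        counts = {"a": 10, "b": 20}
        pops = {"a": 1000, "b": 1000}
        assert rate_per_1000(counts, pops, weights) == pytest.approx(14.0)

    def test_single_band_equals_crude(self):
        assert rate_per_1000({"a": 7}, {"a": 700}, {"a": 1.0}) == rate_per_1000(7, 700)

    def test_zero_population_band_with_count_is_data_error(self):
        with pytest.raises(DataError):
            rate_per_1000({"a": 5}, {"a": 0}, {"a": 1.0})

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            rate_per_1000({"a": 5}, {"a": 100}, {"a": 0.5})


class TestPctDifference:
    @pytest.mark.parametrize(
        "start,end,expected",
        [(2.16, 6.93, 2.21), (159.92, 127.80, -0.20)],
    )
    def test_published_table_cells(self, start, end, expected):
        assert pct_difference(start, end) == expected

    def test_no_change_is_zero(self):
        assert pct_difference(7.7, 7.7) == 0.0

    def test_zero_start_yields_missing_marker(self):
        assert pct_difference(0.0, 5.0) == MISSING


class TestPoissonTrend:
    def test_doubling_counts_give_rate_ratio_two(self):
        res = poisson_trend(_counts([2014, 2018], [120, 240], [1000, 1000]))
        assert res.rate_ratio == pytest.approx(2.0, abs=1e-6)

    def test_saturated_two_cell_equals_closed_form(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c1, c2 = rng.integers(5, 500, size=2)
            p1, p2 = rng.integers(1000, 50_000, size=2)
            res = poisson_trend(_counts([2014, 2018], [c1, c2], [p1, p2]))
            closed_form = (c2 / p2) / (c1 / p1)
            assert res.rate_ratio == pytest.approx(closed_form, rel=1e-6)
            se = np.sqrt(1 / c1 + 1 / c2)
            assert np.log(res.ci_high) - np.log(res.rate_ratio) == pytest.approx(
                1.959963985 * se, rel=1e-4
            )

    def test_flat_series_is_null(self):
        res = poisson_trend(_counts([2014, 2015, 2016], [50, 50, 50],
                                    [1000, 1000, 1000]))
        assert res.rate_ratio == pytest.approx(1.0, abs=1e-8)
        assert res.p_value > 0.99

    def test_reference_and_comparison_year_defaults(self):
        res = poisson_trend(_counts([2014, 2015, 2018], [10, 20, 30],
                                    [100, 100, 100]))
        assert res.reference_year == 2014 and res.comparison_year == 2018

    def test_five_year_categorical_ratio_is_pairwise(self):
        # with a population offset the categorical model is saturated, so
        # the 2018-vs-2014 ratio ignores the middle years
        res = poisson_trend(
            _counts([2014, 2015, 2016, 2017, 2018],
                    [85, 129, 155, 233, 329],
                    [10_000] * 5)
        )
        assert res.rate_ratio == pytest.approx(329 / 85, rel=1e-6)

    def test_zero_count_requires_continuity_strategy(self):
        data = _counts([2014, 2018], [0, 30], [1000, 1000])
        with pytest.raises(DataError):
            poisson_trend(data)
        res = poisson_trend(data, zero_count_strategy="add_half")
        assert res.continuity_corrected
        assert res.rate_ratio == pytest.approx(30.5 / 0.5, rel=1e-6)

    def test_fewer_than_two_years_rejected(self):
        with pytest.raises(DataError):
            poisson_trend(_counts([2014], [10], [100]))

    def test_summary_has_one_row_per_non_reference_year(self):
        model = PoissonTrendModel(_counts([2014, 2015, 2016], [10, 12, 14],
                                          [100, 100, 100]))
        summary = model.fit().summary()
        assert summary["comparison_year"].tolist() == [2015, 2016]
        assert (summary["ci_low"] <= summary["rate_ratio"]).all()
        assert (summary["rate_ratio"] <= summary["ci_high"]).all()

    def test_linear_year_model_exponentiates_slope(self):
        model = PoissonTrendModel(
            _counts([2014, 2015, 2016], [100, 200, 400], [1000, 1000, 1000]),
            linear_year=True,
        )
        res = model.fit().rate_ratio(2016)
        assert res.rate_ratio == pytest.approx(4.0, rel=0.05)


def _linked(durations, agents=None):
    n = len(durations)
    return pd.DataFrame(
        {
            "episode_id": [f"e{i}" for i in range(n)],
            "prescribed": True,
            "agent": agents or ["amoxicillin"] * n,
            "duration_days": durations,
        }
    )


class TestDurationFrequency:
    def test_single_duration(self):
        out = duration_frequency(_linked([7, 7, 7]))
        assert len(out) == 1
        assert out.iloc[0]["proportion"] == 1.0

    def test_tabulation(self):
        out = duration_frequency(_linked([5, 7, 7, 7, 10, 10]))
        freq = out.set_index("duration_days")
        assert freq.loc[7, "n"] == 3
        assert freq["n"].idxmax() == 7
        assert freq.loc[5, "proportion"] == pytest.approx(1 / 6)
        assert freq.loc[10, "proportion"] == pytest.approx(1 / 3)

    def test_restricts_to_first_line_agents(self):
        linked = _linked([5, 9], agents=["amoxicillin", "azithromycin"])
        out = duration_frequency(linked)
        assert out["duration_days"].tolist() == [5]

    def test_suppression(self):
        out = duration_frequency(_linked([7] * 10 + [5] * 3), min_n=6)
        by_dur = out.set_index("duration_days")
        assert by_dur.loc[5, "n"] == "<6" and by_dur.loc[5, "proportion"] == "<6"
        assert by_dur.loc[7, "n"] == 10


class TestAtcClassBreakdown:
    def _classified(self, atcs, category="not_recommended"):
        return pd.DataFrame({"episode_id": range(len(atcs)), "atc_code": atcs,
                             "category": category})

    def test_all_macrolide(self):
        out = atc_class_breakdown(self._classified(["J01FA10"] * 4))
        assert out.iloc[0]["atc_class"] == "macrolides"
        assert out.iloc[0]["proportion"] == 1.0

    def test_tabulation(self):
        out = atc_class_breakdown(
            self._classified(["J01FA10", "J01FA09", "J01FA10", "J01MA12"])
        )
        props = out.set_index("atc_class")["proportion"]
        assert props["macrolides"] == pytest.approx(0.75)
        assert props["quinolones"] == pytest.approx(0.25)

    def test_proportions_sum_to_one_per_category(self):
        rng = np.random.default_rng(3)
        atcs = rng.choice(["J01FA10", "J01MA12", "J01DC02", "J01AA02", "Z99"], 60)
        cats = rng.choice(["clinically_appropriate", "not_recommended"], 60)
        df = pd.DataFrame({"episode_id": range(60), "atc_code": atcs,
                           "category": cats})
        out = atc_class_breakdown(df)
        sums = out.groupby("category")["proportion"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_unmappable_atc_falls_into_other(self):
        assert atc_major_class("Z99XX00") == "other"
        assert atc_major_class("J01CA04") == "beta_lactams_other"
        assert atc_major_class("J01AA02") == "tetracyclines"
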