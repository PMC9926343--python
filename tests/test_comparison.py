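import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from searchshare import (
    ContrastDesign,
    CountyDesignation,
    bh_fdr,
    compare_groups,
    generate_panel,
    group_time_series,
    named_contrast,
    rank_counties,
    set_share,
    share_of_search,
    temporal_contrast,
    two_group_ttest,
)
from searchshare.errors import DegeneracyError, ValidationError
from tests.conftest import base_sim_config


def bh_stepup_oracle(p):
    """Literal step-up definition: q(i) = min_{j >= rank(i)} p(j)*m/j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    scaled = ranked * m / np.arange(1, m + 1)
    q_sorted = np.array([min(1.0, scaled[i:].min()) for i in range(m)])
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestTwoGroupTTest:
    def test_identical_groups(self):
        res = two_group_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_pooled_hand_oracle(self):
        # means 2 vs 3, pooled var 1, se = sqrt(2/3): t = -sqrt(3/2)
        res = two_group_ttest([1, 2, 3], [2, 3, 4], variant="pooled")
        assert res.t == pytest.approx(-1.2247, abs=1e-4)
        assert res.t == pytest.approx(-np.sqrt(1.5))
        assert res.df == 4
        assert res.p == pytest.approx(0.2879, abs=1e-4)

    def test_swap_flips_sign_keeps_p(self):
        a, b = [1.0, 2.0, 5.0], [2.0, 3.0, 4.0, 8.0]
        r1 = two_group_ttest(a, b)
        r2 = two_group_ttest(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    @pytest.mark.parametrize("seed", range(10))
    def test_welch_equals_pooled_when_balanced(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.5, 1, 20)
        w = two_group_ttest(x, y, "welch")
        p = two_group_ttest(x, y, "pooled")
        # equal n: t identical; equal sample variances would also equate df
        assert w.t == pytest.approx(p.t)

    def test_degenerate_zero_variance_equal_means(self):
        res = two_group_ttest([2.0, 2.0], [2.0, 2.0])
        assert (res.t, res.p) == (0.0, 1.0)
        assert res.degenerate

    def test_degenerate_zero_variance_unequal_means(self):
        res = two_group_ttest([2.0, 2.0], [3.0, 3.0])
        assert res.p == 0.0
        assert res.t < 0
        assert res.degenerate

    def test_small_groups_error(self):
        with pytest.raises(DegeneracyError):
            two_group_ttest([1.0], [1.0, 2.0])

    def test_unknown_variant(self):
        with pytest.raises(ValidationError):
            two_group_ttest([1, 2], [3, 4], variant="zzz")


class TestBHFdr:
    def test_single_p_identity(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_frozen_example_uniform_spacing(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_frozen_example_mixed(self):
        np.testing.assert_allclose(
            bh_fdr([0.005, 0.011, 0.02, 0.04, 0.045]),
            [0.025, 0.0275, 1 / 30, 0.045, 0.045],
        )

    def test_out_of_range_errors(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValidationError):
            bh_fdr([-0.1])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=80))
    def test_matches_stepup_oracle(self, p):
        np.testing.assert_array_equal(bh_fdr(p), bh_stepup_oracle(p))

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=80))
    def test_q_at_least_p(self, p):
        assert (bh_fdr(p) >= np.asarray(p) - 1e-15).all()

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=40),
        st.data(),
    )
    def test_monotone_raising_p_never_lowers_q(self, p, data):
        i = data.draw(st.integers(0, len(p) - 1))
        bumped = list(p)
        bumped[i] = min(1.0, bumped[i] + data.draw(st.floats(0, 1, allow_nan=False)))
        assert (bh_fdr(bumped) >= bh_fdr(p) - 1e-12).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.random(rng.integers(1, 60))
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(bh_fdr(p), q_sm)

    def test_by_at_least_bh(self):
        rng = np.random.default_rng(2)
        p = rng.random(30)
        assert (bh_fdr(p, method="by") >= bh_fdr(p) - 1e-12).all()


def _pipeline(cfg, members=("anx", "adhd")):
    panel, desig, truth = generate_panel(cfg)
    table = share_of_search(panel)
    series = set_share(table, list(members))
    return panel, desig, truth, table, series


class TestCompareGroups:
    def test_planted_effect_recovered_exactly(self):
        cfg = base_sim_config(
            n_counties=20, effect_multipliers={("shortage", "anx"): 0.8}, seed=5
        )
        _, desig, truth, table, series = _pipeline(cfg)
        out = compare_groups(
            table, series, named_contrast("shortage_vs_nonshortage"), desig,
            ["anx", "adhd", "cough"],
        )
        row = out.row("anx")
        expected = truth.share_difference(
            "anx", {"status": "shortage"}, {"status": "nonshortage"}
        )
        assert row.mean_a - row.mean_b == pytest.approx(expected, abs=1e-9)
        assert row.q_value < 0.05
        assert row.direction == "nonshortage"

    def test_direction_sign_matches_ground_truth_noise_off(self):
        cfg = base_sim_config(
            n_counties=20,
            effect_multipliers={("shortage", "anx"): 0.8},
            seed=5,
        )
        _, desig, truth, table, series = _pipeline(cfg)
        out = compare_groups(
            table, series, named_contrast("shortage_vs_nonshortage"), desig,
            ["anx", "adhd", "cough"],
        )
        for sid in ("anx", "adhd", "cough"):
            diff = truth.share_difference(
                sid, {"status": "shortage"}, {"status": "nonshortage"}
            )
            row = out.row(sid)
            assert np.sign(row.mean_a - row.mean_b) == np.sign(diff)

    def test_single_symptom_gives_two_rows(self):
        cfg = base_sim_config(n_counties=10, lognormal_sd=0.1, seed=2)
        _, desig, _, table, series = _pipeline(cfg)
        out = compare_groups(
            table, series, named_contrast("shortage_vs_nonshortage"), desig, ["anx"]
        )
        assert [r.symptom_id for r in out.rows] == ["anx", "overall"]

    def test_empty_group_names_predicate(self):
        cfg = base_sim_config(n_counties=10, fraction_shortage=1.0, seed=2)
        _, desig, _, table, series = _pipeline(cfg)
        with pytest.raises(DegeneracyError, match="nonshortage"):
            compare_groups(
                table, series, named_contrast("shortage_vs_nonshortage"), desig,
                ["anx"],
            )

    def test_partial_counties_excluded(self):
        cfg = base_sim_config(
            n_counties=30, fraction_shortage=0.4, fraction_partial=0.3, seed=8
        )
        _, desig, _, table, series = _pipeline(cfg)
        out = compare_groups(
            table, series, named_contrast("shortage_vs_nonshortage"), desig, ["anx"]
        )
        statuses = [d.shortage_status for d in desig.values()]
        assert out.n_counties_a == statuses.count("shortage")
        assert out.n_counties_b == statuses.count("nonshortage")
        assert out.n_counties_a + out.n_counties_b < len(desig)

    def test_county_mean_unit_counts_counties(self):
        cfg = base_sim_config(n_counties=16, n_periods=5, lognormal_sd=0.1, seed=3)
        _, desig, _, table, series = _pipeline(cfg)
        out = compare_groups(
            table, series,
            named_contrast("shortage_vs_nonshortage", unit="county_mean"),
            desig, ["anx"],
        )
        row = out.row("overall")
        assert row.n_a == out.n_counties_a
        assert row.n_b == out.n_counties_b

    def test_q_never_below_p(self):
        cfg = base_sim_config(n_counties=20, lognormal_sd=0.3, seed=4)
        _, desig, _, table, series = _pipeline(cfg, members=("anx",))
        out = compare_groups(
            table, series, named_contrast("shortage_vs_nonshortage"), desig,
            ["anx", "adhd", "cough"],
        )
        for r in out.rows:
            assert r.q_value >= r.p_value - 1e-12

    def test_unknown_contrast_name(self):
        with pytest.raises(ValidationError, match="unknown contrast"):
            named_contrast("zzz")


class TestTemporalContrast:
    def test_planted_step_detected_with_direction(self):
        cfg = base_sim_config(
            n_counties=10, n_periods=10, step_cutoff_index=5,
            step_multipliers={"anx": 1.5}, lognormal_sd=0.05, seed=6,
        )
        _, desig, _, table, series = _pipeline(cfg)
        cutoff = pd.Timestamp(cfg.start_date) + pd.Timedelta(days=14 * 5)
        out = temporal_contrast(table, series, desig, cutoff, ["anx", "adhd", "cough"])
        row = out.row("anx")
        assert row.mean_b > row.mean_a
        assert row.q_value < 0.05
        assert row.direction == "post"

    def test_stationary_noise_free_series_not_flagged(self):
        cfg = base_sim_config(n_counties=10, n_periods=10, seed=6)
        _, desig, _, table, series = _pipeline(cfg)
        cutoff = pd.Timestamp(cfg.start_date) + pd.Timedelta(days=14 * 5)
        out = temporal_contrast(table, series, desig, cutoff, ["anx", "adhd", "cough"])
        assert out.significant() == []

    def test_cutoff_before_all_data_errors(self):
        cfg = base_sim_config(n_periods=6)
        _, desig, _, table, series = _pipeline(cfg)
        with pytest.raises(DegeneracyError, match="pre"):
            temporal_contrast(table, series, desig, "2000-01-01", ["anx"])

    def test_county_predicate_restricts_selection(self):
        cfg = base_sim_config(
            n_counties=14, n_periods=8, step_cutoff_index=4,
            step_multipliers={"anx": 2.0}, seed=9,
        )
        _, desig, _, table, series = _pipeline(cfg)
        cutoff = pd.Timestamp(cfg.start_date) + pd.Timedelta(days=14 * 4)
        out = temporal_contrast(
            table, series, desig, cutoff, ["anx"],
            county_predicate=lambda d: d.shortage_status == "shortage",
        )
        n_shortage = sum(
            1 for d in desig.values() if d.shortage_status == "shortage"
        )
        assert out.n_counties_a == n_shortage


def _series_from_values(values):
    """values: fips -> list of per-period composite shares (built from weights)."""
    records = []
    for fips, shares_list in values.items():
        for i, v in enumerate(shares_list):
            d = pd.Timestamp("2020-01-06") + pd.Timedelta(days=14 * i)
            records.append((fips, d, "a", v))
            records.append((fips, d, "b", 100.0 - v))
    return set_share(share_of_search(make_panel(records)), ["a"])


from searchshare import make_panel  # noqa: E402


class TestRankCounties:
    DESIG = {
        "01001": CountyDesignation("01001", "shortage", 6),
        "01003": CountyDesignation("01003", "partial", 5),
        "01005": CountyDesignation("01005", "nonshortage", 1),
    }

    def test_top_and_bottom(self):
        series = _series_from_values(
            {"01001": [10.0], "01003": [20.0], "01005": [30.0]}
        )
        top, bottom = rank_counties(series, self.DESIG, 1)
        assert top["county_fips"].tolist() == ["01005"]
        assert bottom["county_fips"].tolist() == ["01001"]

    def test_partial_counties_participate(self):
        series = _series_from_values(
            {"01001": [10.0], "01003": [20.0], "01005": [30.0]}
        )
        top, _ = rank_counties(series, self.DESIG, 3)
        assert "01003" in top["county_fips"].tolist()
        assert (
            top.set_index("county_fips")["shortage_status"]["01003"] == "partial"
        )

    def test_ties_break_by_ascending_fips(self):
        series = _series_from_values({"01005": [15.0], "01001": [15.0]})
        top, bottom = rank_counties(series, self.DESIG, 2)
        assert top["county_fips"].tolist() == ["01001", "01005"]
        assert bottom["county_fips"].tolist() == ["01001", "01005"]

    def test_k_larger_than_n_truncates(self):
        series = _series_from_values({"01001": [10.0], "01005": [30.0]})
        top, bottom = rank_counties(series, self.DESIG, 10)
        assert len(top) == 2 and len(bottom) == 2

    def test_k_below_one_errors(self):
        series = _series_from_values({"01001": [10.0]})
        with pytest.raises(ValidationError):
            rank_counties(series, self.DESIG, 0)


class TestGroupTimeSeries:
    DESIG = TestRankCounties.DESIG

    def test_single_county_group_has_missing_band(self):
        series = _series_from_values({"01001": [10.0, 12.0]})
        out = group_time_series(
            series, {"shortage": lambda d: d.shortage_status == "shortage"}, self.DESIG
        )
        assert out["se"].isna().all()
        assert out["lo"].isna().all()

    def test_constant_series_is_flat(self):
        series = _series_from_values({"01001": [10.0, 10.0], "01005": [10.0, 10.0]})
        out = group_time_series(series, {"all": lambda d: True}, self.DESIG)
        np.testing.assert_allclose(out["mean"], 10.0)
        np.testing.assert_allclose(out["se"], 0.0, atol=1e-12)

    def test_planted_trend_gives_negative_slope(self):
        cfg = base_sim_config(
            n_counties=10, n_periods=8, period_trend={"anx": 0.9},
            lognormal_sd=0.02, seed=12,
        )
        panel, desig, _truth = generate_panel(cfg)
        series = set_share(share_of_search(panel), ["anx"])
        out = group_time_series(series, {"all": lambda d: True}, desig)
        means = out.sort_values("period_start")["mean"].to_numpy()
        slope = np.polyfit(np.arange(len(means)), means, 1)[0]
        assert slope < 0

    def test_ci_level_validated(self):
        series = _series_from_values({"01001": [10.0]})
        with pytest.raises(ValidationError):
            group_time_series(series, {"all": lambda d: True}, self.DESIG, ci_level=1.5)


class TestContrastDesign:
    def test_overlapping_predicates_rejected(self):
        design = ContrastDesign(
            group_a=lambda d: d.shortage_status == "shortage",
            group_b=lambda d: d.urban3 == "rural",
            name_a="shortage", name_b="rural",
        )
        desig = {"01001": CountyDesignation("01001", "shortage", 6),
                 "01003": CountyDesignation("01003", "nonshortage", 1)}
        with pytest.raises(ValidationError, match="overlap"):
            design.assign(desig)

    def test_invalid_unit_rejected(self):
        with pytest.raises(ValidationError):
            ContrastDesign(lambda d: True, lambda d: False, unit="bogus")
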