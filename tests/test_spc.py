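"""Control-chart construction, unbiasing constants, and run-rule detection."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_chart, oracle_rule_points, random_rule_sequence, signal_points
from nutrispc.spc import (
    b3,
    b4,
    c4,
    detect_special_cause,
    p_chart,
    run_chart,
    xbar_s_chart,
)


def summaries_frame(quarters, n, prop=None, mean=None, sd=None):
    m = len(quarters)
    return pd.DataFrame({
        "quarter": quarters,
        "n": n,
        "prop_stunted": prop if prop is not None else [np.nan] * m,
        "mean_laz": mean if mean is not None else [np.nan] * m,
        "sd_laz": sd if sd is not None else [np.nan] * m,
        "prop_monitored": [np.nan] * m,
        "prop_micronutrient": [np.nan] * m,
        "n_new": [0] * m,
    })


class TestUnbiasingConstants:
    def test_closed_forms(self):
        # c4(2) = sqrt(2/pi); textbook 4-decimal values for n=5
        assert c4(2) == pytest.approx(np.sqrt(2 / np.pi), rel=1e-12)
        assert c4(5) == pytest.approx(0.9400, abs=5e-5)
        assert b3(5) == 0.0                      # negative raw value clipped
        assert b4(5) == pytest.approx(2.089, abs=5e-4)

    def test_monotone_to_one(self):
        vals = [c4(n) for n in range(2, 101)]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert vals[-1] > 0.997

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            c4(1)


class TestPChart:
    def test_symmetric_clip_boundary(self):
        s = summaries_frame(["2015Q1", "2015Q2"], [9, 9], prop=[0.5, 0.5])
        ch = p_chart(s, ("2015Q1", "2015Q2"))
        assert ch.centerline == pytest.approx(0.5)
        # 0.5 +/- 3*sqrt(0.25/9) = 0.5 +/- 0.5 -> exactly [0, 1]
        assert np.allclose(ch.ucl_i, 1.0) and np.allclose(ch.lcl_i, 0.0)

    def test_hand_computed_limits_with_clipping(self):
        s = summaries_frame(["2015Q1", "2015Q2"], [25, 25], prop=[0.2, 0.3])
        ch = p_chart(s, ("2015Q1", "2015Q1"))
        assert ch.centerline == pytest.approx(0.2)
        assert ch.ucl_i[0] == pytest.approx(0.44)
        assert ch.lcl_i[0] == 0.0               # clipped from -0.04

    def test_count_weighted_baseline(self):
        s = summaries_frame(["2015Q1", "2015Q2"], [10, 30], prop=[0.5, 0.2])
        ch = p_chart(s, ("2015Q1", "2015Q2"))
        assert ch.centerline == pytest.approx((5 + 6) / 40)

    def test_degenerate_centerline_warns_but_emits(self):
        s = summaries_frame(["2015Q1"], [10], prop=[0.0])
        with pytest.warns(UserWarning, match="degenerate"):
            ch = p_chart(s, ("2015Q1", "2015Q1"))
        assert ch.centerline == 0.0

    def test_constant_n_reduces_to_fixed_limits(self):
        rng = np.random.default_rng(0)
        props = rng.uniform(0.2, 0.6, 12)
        s = summaries_frame([str(pd.Period("2015Q1") + i) for i in range(12)],
                            [40] * 12, prop=list(props))
        ch = p_chart(s, ("2015Q1", "2017Q4"))
        pbar = props.mean()                     # equal n: weighting is moot
        assert ch.centerline == pytest.approx(pbar)
        classic = 3 * np.sqrt(pbar * (1 - pbar) / 40)
        assert np.allclose(ch.ucl_i, min(pbar + classic, 1.0))
        assert np.allclose(ch.lcl_i, max(pbar - classic, 0.0))


class TestXbarSChart:
    def test_pooled_sigma_two_subgroups(self):
        s = summaries_frame(["2015Q1", "2015Q2"], [5, 5],
                            mean=[0.0, 0.0], sd=[1.0, 1.0])
        xch, sch = xbar_s_chart(s, ("2015Q1", "2015Q2"))
        assert xch.sigma_hat == pytest.approx(1.0 / c4(9), rel=1e-6)  # ~1.0285
        assert xch.centerline == 0.0
        # s-chart per-point centerline c4(5)*sigma_hat, limits b3/b4-scaled
        assert sch.centerline_i[0] == pytest.approx(c4(5) / c4(9))
        assert sch.lcl_i[0] == 0.0
        assert sch.ucl_i[0] == pytest.approx(b4(5) * c4(5) / c4(9))

    def test_constant_values_flagged_degenerate(self):
        s = summaries_frame(["2015Q1", "2015Q2"], [5, 5],
                            mean=[1.3, 1.3], sd=[0.0, 0.0])
        with pytest.warns(UserWarning, match="degenerate"):
            xch, _ = xbar_s_chart(s, ("2015Q1", "2015Q2"))
        assert xch.centerline == pytest.approx(1.3)
        assert xch.sigma_hat == 0.0

    def test_small_baseline_subgroups_excluded_with_warning(self):
        s = summaries_frame(["2015Q1", "2015Q2"], [1, 5],
                            mean=[5.0, 0.0], sd=[np.nan, 1.0])
        with pytest.warns(UserWarning, match="n < 2"):
            xch, _ = xbar_s_chart(s, ("2015Q1", "2015Q2"))
        assert xch.centerline == 0.0            # the n=1 subgroup is ignored

    def test_mean_s_matches_classic_with_constant_n(self):
        s = summaries_frame(["2015Q1", "2015Q2"], [5, 5],
                            mean=[0.0, 0.4], sd=[0.8, 1.2])
        xch, _ = xbar_s_chart(s, ("2015Q1", "2015Q2"), sigma_method="mean-s")
        assert xch.sigma_hat == pytest.approx(1.0 / c4(5))

    def test_limits_bracket_centerline(self):
        s = summaries_frame(["2015Q1", "2015Q2", "2015Q3"], [8, 12, 20],
                            mean=[-1.8, -1.7, -1.5], sd=[1.0, 0.9, 1.1])
        xch, sch = xbar_s_chart(s, ("2015Q1", "2015Q2"))
        assert (xch.lcl_i <= xch.centerline).all() and (xch.centerline <= xch.ucl_i).all()
        assert (sch.lcl_i <= sch.centerline_i).all() and (sch.centerline_i <= sch.ucl_i).all()


class TestRunChart:
    def test_median_centerline(self):
        assert run_chart(["2018Q1", "2018Q2", "2018Q3"], [0.2, 0.4, 0.6]).centerline == 0.4

    def test_single_point(self):
        assert run_chart(["2018Q1"], [0.7]).centerline == 0.7

    def test_even_count_mean_of_middle_two(self):
        ch = run_chart(["2018Q1", "2018Q2", "2018Q3", "2018Q4"],
                       [0.2, 0.4, 0.6, 0.8])
        assert ch.centerline == pytest.approx(0.5)

    def test_no_limits(self):
        ch = run_chart(["2018Q1", "2018Q2"], [0.2, 0.4])
        assert np.isnan(ch.ucl_i).all() and np.isnan(ch.lcl_i).all()


class TestRuleDetection:
    def test_rule1_point_beyond_limits(self):
        ch = make_chart([0.4, 0.61, 0.4], centerline=0.4, lcl=0.2, ucl=0.6)
        sigs = detect_special_cause(ch, scope="all")
        assert [(s.rule, s.point_indices, s.direction) for s in sigs] == \
            [(1, (1,), "above")]

    def test_rule2_nine_on_one_side(self):
        ch = make_chart([-0.1] * 9 + [0.1], centerline=0.0)
        sigs = [s for s in detect_special_cause(ch, scope="all") if s.rule == 2]
        assert len(sigs) == 1
        assert sigs[0].point_indices == tuple(range(9))
        assert sigs[0].direction == "below"

    def test_rule2_centerline_point_breaks_run(self):
        vals = [-0.1] * 4 + [0.0] + [-0.1] * 4
        ch = make_chart(vals, centerline=0.0)
        assert not [s for s in detect_special_cause(ch, scope="all") if s.rule == 2]

    def test_rule3_six_monotone(self):
        ch = make_chart([1, 2, 3, 4, 5, 6], centerline=3.0)
        sigs = [s for s in detect_special_cause(ch, scope="all") if s.rule == 3]
        assert sigs[0].point_indices == tuple(range(6))
        assert sigs[0].direction == "up"

    def test_rule3_equal_values_break_run(self):
        ch = make_chart([1, 2, 3, 3, 4, 5, 6], centerline=3.0)
        assert not [s for s in detect_special_cause(ch, scope="all") if s.rule == 3]

    def test_rule4_fourteen_alternating(self):
        vals = [(-1.0) ** i * (1 + 0.01 * i) for i in range(14)]
        ch = make_chart(vals, centerline=0.0)
        sigs = [s for s in detect_special_cause(ch, scope="all") if s.rule == 4]
        assert sigs[0].point_indices == tuple(range(14))

    def test_gaps_reset_runs(self):
        vals = [-0.1] * 5 + [np.nan] + [-0.1] * 5
        ch = make_chart(vals, centerline=0.0)
        assert not [s for s in detect_special_cause(ch, scope="all") if s.rule == 2]

    def test_post_scope_needs_a_post_baseline_point(self):
        ch = make_chart([-0.1] * 12 + [0.1] * 3, centerline=0.0,
                        lcl=-1.0, ucl=1.0)
        ch.baseline_range = (ch.quarters[0], ch.quarters[-1])
        assert detect_special_cause(ch, scope="post") == []
        ch.baseline_range = (ch.quarters[0], ch.quarters[10])
        sigs = detect_special_cause(ch, scope="post")
        assert [s.rule for s in sigs] == [2]    # run ends post-baseline

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            vals = random_rule_sequence(rng)
            ch = make_chart(vals, centerline=0.0, lcl=-2.0, ucl=2.0)
            got = signal_points(detect_special_cause(ch, scope="all"))
            want = oracle_rule_points(vals, ch.centerline_i, ch.lcl_i, ch.ucl_i)
            assert got == want


class TestFreezing:
    def test_appending_points_never_moves_baseline_parameters(self):
        rng = np.random.default_rng(7)
        quarters = [str(pd.Period("2014Q4") + i) for i in range(21)]
        n = rng.integers(20, 40, 21)
        prop = rng.uniform(0.3, 0.6, 21)
        mean = rng.normal(-1.8, 0.1, 21)
        sd = rng.uniform(0.8, 1.2, 21)
        s_full = summaries_frame(quarters, list(n), list(prop), list(mean), list(sd))
        s_base = s_full.iloc[:13].reset_index(drop=True)
        baseline = ("2014Q4", "2017Q4")

        p_a, p_b = p_chart(s_base, baseline), p_chart(s_full, baseline)
        assert p_a.centerline == p_b.centerline
        assert np.allclose(p_a.ucl_i, p_b.ucl_i[:13])

        (x_a, s_ca), (x_b, s_cb) = (xbar_s_chart(s_base, baseline),
                                    xbar_s_chart(s_full, baseline))
        assert x_a.centerline == x_b.centerline
        assert x_a.sigma_hat == x_b.sigma_hat
        assert np.allclose(s_ca.centerline_i, s_cb.centerline_i[:13])
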