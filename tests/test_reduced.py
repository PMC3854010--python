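"""Fixed points, fold bifurcation and critical coupling of the reduced model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikeinit import core, reduced
from spikeinit.core import NaChannelSet, ball_and_stick, na_current, na_current_slope
from spikeinit.reduced import (
    ReducedModel,
    critical_coupling,
    critical_distance,
    fold_threshold,
    kink_rate,
    onset_rapidness_theory,
    reduced_activation_curve,
    reduced_from_spec,
    solve_fixed_points,
    threshold_vs_distance,
)

SPEC = ball_and_stick(40.0)
CH = SPEC.channel_sets[0]


def grid_scan_roots(model, V_s, step=1e-3):
    """Independent brute-force oracle: sign changes of the residual on a fine grid."""
    Ra_G = model.R_a * 1e-3
    V = np.arange(V_s - 5.0, model.channels.E_Na + step, step)
    res = (V - V_s) / Ra_G - na_current(V, model.channels)
    idx = np.nonzero(np.diff(np.sign(res)) != 0)[0]
    return 0.5 * (V[idx] + V[idx + 1])


class TestFixedPoints:
    def test_20um_intersections_match_reference(self):
        """Stable roots −59/−52/−40 mV at V_s = −60/−55/−50 for 20 µm coupling."""
        model = reduced_from_spec(SPEC, 20.0)
        assert model.coupling_product == pytest.approx(0.2, rel=1e-6)
        for V_s, expect in [(-60.0, -59.0), (-55.0, -52.5), (-50.0, -40.0)]:
            roots = solve_fixed_points(model, V_s)
            stable = [r.V_a for r in roots if r.stable]
            assert min(stable) == pytest.approx(expect, abs=0.6)

    def test_isopotential_limit(self):
        model = ReducedModel(R_a=0.0, channels=CH)
        roots = solve_fixed_points(model, -55.0)
        assert len(roots) == 1 and roots[0].V_a == -55.0 and roots[0].stable

    def test_root_count_and_alternating_stability(self):
        model = reduced_from_spec(SPEC, 40.0)
        for V_s in (-70.0, -60.0, -58.0, -50.0, -40.0):
            roots = solve_fixed_points(model, V_s)
            assert len(roots) in (1, 3)
            stabilities = [r.stable for r in roots]
            assert stabilities[0] and stabilities[-1]
            if len(roots) == 3:
                assert stabilities == [True, False, True]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        V_s=st.floats(-80.0, -30.0),
        R_a=st.floats(5.0, 400.0),
    )
    def test_roots_match_grid_scan_oracle(self, V_s, R_a):
        model = ReducedModel(R_a=R_a, channels=CH)
        ours = np.array([r.V_a for r in solve_fixed_points(model, V_s)])
        oracle = grid_scan_roots(model, V_s)
        assert ours.size == oracle.size
        if ours.size:
            assert np.max(np.abs(ours - oracle)) < 1e-3


class TestFold:
    def test_threshold_at_40um(self):
        """Loss of voltage control near −56 mV with the cluster at 40 µm."""
        fr = fold_threshold(reduced_from_spec(SPEC, 40.0))
        assert fr is not None
        assert fr.V_s_fold == pytest.approx(-56.0, abs=1.2)
        assert fr.delta_V == pytest.approx(33.0, abs=2.5)

    def test_tangency_relation(self):
        """At the fold, f'(V_a*) = 1/R_a to high relative precision."""
        model = reduced_from_spec(SPEC, 40.0)
        fr = fold_threshold(model)
        slope = float(na_current_slope(fr.V_a_fold, CH))
        assert slope == pytest.approx(1.0 / (model.R_a * 1e-3), rel=1e-8)

    def test_fold_against_grid_scan_root_count_change(self):
        model = reduced_from_spec(SPEC, 40.0)
        fr = fold_threshold(model)
        below = grid_scan_roots(model, fr.V_s_fold - 0.01)
        above = grid_scan_roots(model, fr.V_s_fold + 0.01)
        assert below.size == 3 and above.size == 1

    def test_subcritical_reports_no_fold(self):
        assert fold_threshold(reduced_from_spec(SPEC, 20.0)) is None

    def test_hysteresis_folds_ordered(self):
        fr = fold_threshold(reduced_from_spec(SPEC, 40.0))
        assert fr.V_s_fold_upper < fr.V_s_fold  # de-activation fold is lower


class TestCriticalCoupling:
    def test_critical_product_near_027(self):
        crit = critical_coupling(CH)
        assert crit == pytest.approx(0.27, abs=0.01)

    def test_matches_dense_grid_maximum(self):
        V = np.linspace(-80.0, 60.0, 2_000_001)
        slope = na_current_slope(V, CH) / CH.g_total
        assert critical_coupling(CH) == pytest.approx(1.0 / slope.max(), rel=1e-9)

    def test_broader_activation_raises_critical_product(self):
        broad = NaChannelSet(k_a=12.0, g_total=CH.g_total)
        assert critical_coupling(broad) > critical_coupling(CH)

    def test_critical_distance_near_27um(self):
        assert critical_distance(SPEC) == pytest.approx(27.0, abs=1.0)
        # mixed-form condition R_i·g_Na·x*/d² ≈ 0.21
        x_cm = critical_distance(SPEC) * 1e-4
        g_S = CH.g_total * 1e-9
        d_cm = 1e-4
        assert 150.0 * g_S * x_cm / d_cm**2 == pytest.approx(0.21, abs=0.01)

    def test_critical_distance_inverse_in_conductance(self):
        spec2 = ball_and_stick(40.0, g_na_ratio=4.0)
        assert critical_distance(spec2) == pytest.approx(
            critical_distance(SPEC) / 2.0, rel=1e-9
        )

    def test_fold_exists_exactly_above_critical_distance(self):
        x_star = critical_distance(SPEC)
        assert fold_threshold(reduced_from_spec(SPEC, x_star * 0.97)) is None
        assert fold_threshold(reduced_from_spec(SPEC, x_star * 1.03)) is not None


class TestThresholdVsDistance:
    def test_decreasing_and_log_linear(self):
        xs = [30.0, 40.0, 60.0, 100.0, 150.0, 200.0]
        df = threshold_vs_distance(SPEC, CH, xs)
        thr = df["V_s_fold"].to_numpy()
        assert np.all(np.diff(thr) < 0)
        # per-doubling decrement approaches k_a·ln2 ≈ 4.16 mV from above
        fr50 = fold_threshold(reduced_from_spec(SPEC, 50.0))
        fr100 = fold_threshold(reduced_from_spec(SPEC, 100.0))
        fr200 = fold_threshold(reduced_from_spec(SPEC, 200.0))
        step1 = fr100.V_s_fold - fr50.V_s_fold
        step2 = fr200.V_s_fold - fr100.V_s_fold
        ka_ln2 = CH.k_a * np.log(2.0)
        assert abs(step2 + ka_ln2) < abs(step1 + ka_ln2)  # converging
        assert step2 == pytest.approx(-ka_ln2, abs=0.6)

    def test_conductance_doubling_lowers_threshold_by_about_4mV(self):
        """Threshold drops by ≈k_a·ln2 ≈ 4.2 mV per conductance doubling."""
        f1 = fold_threshold(reduced_from_spec(SPEC, 100.0))
        spec2 = ball_and_stick(100.0, g_na_ratio=4.0)
        f2 = fold_threshold(reduced_from_spec(spec2, 100.0))
        assert f2.V_s_fold - f1.V_s_fold == pytest.approx(-4.2, abs=0.6)

    def test_subcritical_points_excluded_with_reason(self):
        df = threshold_vs_distance(SPEC, CH, [10.0, 40.0])
        assert len(df) == 1
        excluded = df.attrs["excluded"]
        assert excluded[0]["x_um"] == 10.0 and "subcritical" in excluded[0]["reason"]

    def test_site_soma_threshold_difference_approaches_ka(self):
        gaps = []
        for x in (30.0, 60.0, 100.0, 200.0):
            fr = fold_threshold(reduced_from_spec(SPEC, x))
            gaps.append(fr.V_a_fold - fr.V_s_fold)
        assert np.all(np.diff(gaps) < 0)  # monotone approach to k_a from above
        assert gaps[-1] == pytest.approx(CH.k_a, abs=1.0)
        assert gaps[0] == pytest.approx(CH.k_a, abs=3.5)


class TestKinkAndRapidness:
    def test_kink_rate_reference_value(self):
        """ΔV/(C·R_a) ≈ 7.5 mV/ms for the 40 µm model (exact fold gives ≈7.0)."""
        rate = kink_rate(reduced_from_spec(SPEC, 40.0))
        assert rate == pytest.approx(7.5, abs=0.8)

    def test_kink_rate_linearity_in_Ra(self):
        m1 = reduced_from_spec(SPEC, 40.0)
        fr = fold_threshold(m1)
        # doubling R_a at fixed ΔV halves the rate (formula check)
        assert fr.delta_V / (m1.C_soma * 2 * m1.R_a * 1e-3) == pytest.approx(
            0.5 * fr.delta_V / (m1.C_soma * m1.R_a * 1e-3)
        )

    def test_kink_rate_none_below_criticality(self):
        assert kink_rate(reduced_from_spec(SPEC, 20.0)) is None

    @pytest.mark.parametrize(
        "alpha,ka,expect", [(10.0, 6.0, 10 / 6), (6.0, 6.0, 1.0), (10.0, 3.0, 10 / 3)]
    )
    def test_onset_rapidness_theory(self, alpha, ka, expect):
        ch = NaChannelSet(k_a=ka, g_total=1.0)
        assert onset_rapidness_theory(alpha, ch) == pytest.approx(expect)


class TestReducedActivationCurve:
    @staticmethod
    def half_width(df):
        V = df["V_s"].to_numpy()
        f = df["open_fraction"].to_numpy()
        return (np.interp(0.73, f, V) - np.interp(0.27, f, V)) / 2.0

    def test_isopotential_half_width_equals_ka(self):
        model = ReducedModel(R_a=0.0, channels=CH)
        df = reduced_activation_curve(model, np.arange(-70, -10, 0.05))
        assert self.half_width(df) == pytest.approx(CH.k_a, abs=0.1)

    def test_20um_half_width_near_2mV(self):
        model = reduced_from_spec(SPEC, 20.0)
        df = reduced_activation_curve(model, np.arange(-60, -35, 0.02))
        assert self.half_width(df) == pytest.approx(2.0, abs=0.3)

    def test_half_width_decreases_with_coupling_toward_ka(self):
        widths = []
        for x in (1.0, 5.0, 10.0, 20.0, 26.0):
            model = reduced_from_spec(SPEC, x)
            df = reduced_activation_curve(model, np.arange(-70, -30, 0.02))
            widths.append(self.half_width(df))
        assert np.all(np.diff(widths) < 0)
        assert widths[0] == pytest.approx(CH.k_a, abs=0.3)

    def test_supercritical_jump_and_hysteresis(self):
        model = reduced_from_spec(SPEC, 40.0)
        grid = np.arange(-60.0, -50.0, 0.01)
        up = reduced_activation_curve(model, grid, sweep="up")
        down = reduced_activation_curve(model, grid, sweep="down")
        jumps_up = np.diff(up["open_fraction"].to_numpy()).max()
        assert jumps_up > 0.5  # discontinuous opening on the upward sweep
        fr = fold_threshold(model)
        # the downward sweep stays on the depolarized branch below the up-fold
        mid = grid[(grid > fr.V_s_fold_upper + 0.1) & (grid < fr.V_s_fold - 0.1)]
        up_mid = up[up["V_s"].isin(mid)]["open_fraction"].to_numpy()
        down_mid = down[down["V_s"].isin(mid)]["open_fraction"].to_numpy()
        assert np.all(down_mid > up_mid)


def test_fixed_point_diagram_export(tmp_path):
    model = reduced_from_spec(SPEC, 40.0)
    diag = reduced.fixed_point_diagram(model, np.arange(-62, -52, 1.0))
    df = diag.to_frame()
    assert set(df.columns) == {"V_s", "V_a", "stable"}
    path = tmp_path / "diagram.csv"
    diag.to_csv(path)
    assert path.exists() and diag.fold is not None
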