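"""Compartmental solver: discretization, passive oracle, clamps, reset rule."""

import numpy as np
import pytest

from spikeinit import cable, core, stimuli
from spikeinit.cable import (
    Discretization,
    ResetRule,
    State,
    build_compartments,
    initial_state,
    net_currents,
    run_to_steady,
    simulate_iclamp,
    simulate_vclamp,
    steady_state_profile,
)
from spikeinit.core import LinearDecreasingProfile, UniformProfile, ball_and_stick


def sealed_cable_profile(spec, x, V_s):
    """Analytic steady profile of a passive sealed-end cable clamped at the soma."""
    lam = core.space_constant(spec)
    L = spec.geometry.axon_length
    E = spec.passive.E_L
    return E + (V_s - E) * np.cosh((L - x) / lam) / np.cosh(L / lam)


class TestBuild:
    def test_node_counts(self, disc):
        comp = build_compartments(ball_and_stick(40.0), disc)
        assert comp.n == 301  # 300 axonal nodes + soma
        assert comp.x[0] == 0.0 and comp.x[-1] == 300.0

    def test_point_allocation_on_and_off_grid(self, disc):
        comp = build_compartments(ball_and_stick(40.0), disc)
        assert list(comp.ch_node) == [40]
        comp2 = build_compartments(ball_and_stick(40.4), disc)
        assert list(comp2.ch_node) == [40, 41]
        np.testing.assert_allclose(comp2.ch_g / comp2.ch_g.sum(), [0.6, 0.4])

    @pytest.mark.parametrize("profile", [UniformProfile(25.0, 40.0),
                                         LinearDecreasingProfile(25.0, 40.0)])
    def test_distributed_conductance_conserved(self, disc, profile):
        spec = ball_and_stick(profile)
        comp = build_compartments(spec, disc)
        total = spec.channel_sets[0].g_total
        assert comp.ch_g.sum() == pytest.approx(total, rel=1e-3)
        if isinstance(profile, LinearDecreasingProfile):
            # density falls linearly to ~zero at the distal end (the first
            # node's cell is clipped by the profile start, so skip it)
            assert np.all(np.diff(comp.ch_g[1:]) < 0)
            assert comp.ch_g[-1] < comp.ch_g[1] / 10

    def test_axial_coupling_matches_closed_form(self, disc):
        spec = ball_and_stick(40.0)
        comp = build_compartments(spec, disc)
        R_40 = sum(1e3 / comp.gax[i] for i in range(40))  # MΩ
        assert R_40 == pytest.approx(core.axial_resistance(spec, 40.0), rel=1e-9)


class TestVClamp:
    def test_passive_profile_matches_analytic(self, passive_spec, disc):
        comp = build_compartments(passive_spec, disc)
        V, ss = steady_state_profile(passive_spec, disc, -60.0, comp=comp)
        assert ss.converged
        expected = sealed_cable_profile(passive_spec, comp.x, -60.0)
        assert np.max(np.abs(V - expected)) < 0.15  # 1% of the 15 mV step

    def test_command_tracked_exactly(self, standard_spec, disc):
        sched = stimuli.make_step_ladder([-64.0, -61.0, -58.0], hold=5.0)
        tr = simulate_vclamp(standard_spec, disc, sched, record_every=10)
        cmd = sched.as_array(disc.dt)[::10][: tr.V.shape[0]]
        assert np.array_equal(tr.V[:, 0], cmd)

    def test_rest_command_zero_current(self, passive_spec, disc):
        sched = stimuli.make_step_ladder([-75.0], hold=20.0)
        tr = simulate_vclamp(passive_spec, disc, sched)
        assert np.all(np.abs(tr.V - (-75.0)) < 1e-6)
        assert abs(tr.current[-1]) < 1e-6

    def test_na_at_40_peaks_near_minus25_at_site(self, standard_spec, disc):
        """Clamping the soma at −55 mV: the axon escapes to ≈−25 mV at 40 µm."""
        comp = build_compartments(standard_spec, disc)
        V, ss = steady_state_profile(standard_spec, disc, -55.0, comp=comp)
        assert ss.converged
        assert V[np.argmax(V)] == pytest.approx(-25.0, abs=1.5)
        assert comp.x[np.argmax(V)] == 40.0

    def test_below_threshold_space_clamped(self, standard_spec, disc):
        """At −64 mV the axon is effectively space clamped (flat within 1 mV)."""
        V, _ = steady_state_profile(standard_spec, disc, -64.0)
        assert np.ptp(V[:101]) < 1.0

    def test_kirchhoff_balance_at_steady_state(self, standard_spec, disc):
        comp = build_compartments(standard_spec, disc)
        st = initial_state(comp)
        run_to_steady(comp, st, -58.0, disc)
        I = net_currents(comp, st)
        assert np.max(np.abs(I[1:])) < 1e-3  # pA, free nodes only

    def test_gating_bounded(self, standard_spec, disc):
        sched = stimuli.make_step_ladder([-60.0, -50.0, -40.0], hold=10.0)
        tr = simulate_vclamp(standard_spec, disc, sched, record_every=4)
        assert np.all(tr.open_fraction >= 0.0) and np.all(tr.open_fraction <= 1.0)

    def test_refinement_convergence(self, disc):
        """Halving dt and dx moves the steady V_a by < 0.1 mV."""
        spec = ball_and_stick(40.0)
        V1, _ = steady_state_profile(spec, Discretization(dx=1.0, dt=0.025), -58.0)
        V2, _ = steady_state_profile(spec, Discretization(dx=0.5, dt=0.0125), -58.0)
        assert abs(V1[40] - V2[80]) < 0.1


class TestProfiles:
    def test_distributed_profile_concave_peak_distal(self, disc):
        """Suprathreshold uniform [25,40] profile: concave, maximal at 40 µm."""
        spec = ball_and_stick(UniformProfile(25.0, 40.0))
        comp = build_compartments(spec, disc)
        st = initial_state(comp)
        # quasi-static upward ladder reaching a suprathreshold level
        for level in (-64.0, -61.0, -58.0, -55.0, -52.0):
            run_to_steady(comp, st, level, disc)
        d2 = np.diff(st.V, 2)
        region = (comp.x[1:-1] >= 25.0) & (comp.x[1:-1] <= 40.0)
        assert np.max(d2[region]) <= 1e-6
        assert comp.x[np.argmax(st.V)] == 40.0

    def test_linear_decreasing_profile_still_initiates_distally(self, disc):
        spec = ball_and_stick(LinearDecreasingProfile(25.0, 40.0))
        comp = build_compartments(spec, disc)
        st = initial_state(comp)
        for level in (-64.0, -58.0, -52.0):
            run_to_steady(comp, st, level, disc)
        # peak sits at the distal end of the channel region up to the tiny
        # droop the passive distal axon draws (< 0.1 mV)
        i = int(np.argmax(st.V))
        assert 35.0 <= comp.x[i] <= 41.0
        assert st.V[40] > st.V[i] - 0.1

    def test_passive_profile_convex_negative_control(self, passive_spec, disc):
        V, _ = steady_state_profile(passive_spec, disc, -55.0)
        assert np.all(np.diff(V, 2)[:100] >= -1e-9)  # convex decay


class TestIClamp:
    def test_zero_input_stays_at_rest(self, passive_spec, standard_spec, disc):
        tr = simulate_iclamp(passive_spec, disc, np.zeros(4000))
        assert np.max(np.abs(tr.V - passive_spec.passive.E_L)) < 1e-6
        # with Na channels the standing window current depolarizes the true
        # rest by ~1 mV above E_L; no spikes either way
        tr2 = simulate_iclamp(standard_spec, disc, np.zeros(4000),
                              reset_rule=ResetRule())
        assert np.max(np.abs(tr2.V - standard_spec.passive.E_L)) < 1.5
        assert tr2.spike_times.size == 0

    def test_ou_run_bit_reproducible(self, standard_spec, disc):
        I = stimuli.make_ou_current(stimuli.OUParams(duration=2000.0, seed=9), disc.dt)
        a = simulate_iclamp(standard_spec, disc, I, reset_rule=ResetRule(),
                            record_every=40, record_positions=[0.0])
        b = simulate_iclamp(standard_spec, disc, I, reset_rule=ResetRule(),
                            record_every=40, record_positions=[0.0])
        assert np.array_equal(a.V, b.V)
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_reset_rule_resets_and_holds(self, standard_spec, disc):
        I = np.full(int(100.0 / disc.dt), 120.0)  # strong step -> spikes
        tr = simulate_iclamp(standard_spec, disc, I, reset_rule=ResetRule(),
                             record_every=1, record_positions=[0.0, 40.0])
        assert tr.spike_times.size >= 1
        t0 = tr.spike_times[0]
        k = int(round(t0 / disc.dt))
        held = tr.V[k + 2: k + int(4.5 / disc.dt)]
        assert np.max(np.abs(held - standard_spec.passive.E_L)) < 1e-9
        # inter-spike interval exceeds the 5 ms hold
        if tr.spike_times.size > 1:
            assert np.min(np.diff(tr.spike_times)) > 5.0

    def test_mean_na_current_excludes_hold(self, standard_spec, disc):
        I = np.full(int(200.0 / disc.dt), 120.0)
        tr = simulate_iclamp(standard_spec, disc, I, reset_rule=ResetRule(),
                             record_every=100, record_positions=[0.0])
        assert np.isfinite(tr.meta["mean_na_current"])
        assert tr.meta["mean_na_current"] > 0

    def test_trace_long_format_export(self, standard_spec, disc, tmp_path):
        tr = simulate_iclamp(standard_spec, disc, np.zeros(400),
                             record_every=40, record_positions=[0.0, 40.0])
        df = tr.to_frame()
        assert set(df.columns) == {"time_ms", "position_um", "V_mV"}
        assert df.shape[0] == tr.V.size
        tr.to_csv(tmp_path / "trace.csv")
        assert (tmp_path / "trace.csv").exists()


def test_steady_state_cap_flagged_near_fold(standard_spec, disc):
    """Just past the fold the relaxation is slow but must be reported honestly."""
    comp = build_compartments(standard_spec, disc)
    st = initial_state(comp)
    ss = run_to_steady(comp, st, -75.0, disc, cap=0.1)  # absurdly short cap
    assert not ss.converged or ss.elapsed <= 0.1 + disc.dt
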