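"""T-type channel steady-state biophysics: GHK, Boltzmann, window, QC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hsnphys import (
    BoltzmannParams,
    ChannelModel,
    ConductanceCurve,
    GHKSettings,
    SweepSet,
    availability_curve,
    boltzmann,
    chord_conductance_curve,
    extract_peaks,
    fit_boltzmann,
    ghk_drive,
    qc_leak,
    reversal_potential,
    window_curve,
    window_metrics,
)
from hsnphys.channel import (
    DEFAULT_ACTIVATION_PROTOCOL,
    DEFAULT_INACTIVATION_PROTOCOL,
    FARADAY,
    GAS_CONSTANT,
    StepProtocol,
)
from hsnphys.errors import InputError, ParameterError
from hsnphys.synthetic import simulate_sweeps
from conftest import WT_ACT, WT_INACT


class TestBoltzmann:
    def test_midpoint_both_senses(self):
        for sense in ("activation", "inactivation"):
            assert boltzmann(-40.0, BoltzmannParams(-40.0, 5.0, sense)) == pytest.approx(0.5)

    def test_one_slope_factor_above_midpoint(self):
        # activation at v_half + k is 1/(1 + e^-1)
        assert boltzmann(-32.14, WT_ACT) == pytest.approx(0.731059, abs=1e-6)

    def test_saturation(self):
        assert boltzmann(200.0, WT_ACT) == pytest.approx(1.0, abs=1e-9)
        assert boltzmann(-300.0, WT_INACT) == pytest.approx(1.0, abs=1e-9)

    @settings(deadline=None, max_examples=40)
    @given(
        v50=st.floats(-90, 0),
        k=st.floats(1.0, 15.0),
        sense=st.sampled_from(["activation", "inactivation"]),
    )
    def test_strict_monotonicity(self, v50, k, sense):
        # within ±8k of the midpoint the curve is numerically non-saturated
        v = v50 + np.linspace(-8 * k, 8 * k, 200)
        g = boltzmann(v, BoltzmannParams(v50, k, sense))
        diffs = np.diff(g)
        assert np.all(diffs > 0) if sense == "activation" else np.all(diffs < 0)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ParameterError):
            boltzmann(0.0, BoltzmannParams(-40.0, 0.0))


class TestGHK:
    def test_linear_when_symmetric(self):
        ghk = GHKSettings(c_in=10.0, c_out=10.0)
        v = np.array([-80.0, -40.0, -1.0, 1.0, 40.0, 80.0])
        drive = np.asarray(ghk_drive(v, ghk))
        # exactly proportional to V: P z^2 F^2 V c / (RT)
        expect = ghk.z**2 * FARADAY**2 * (v / 1000.0) * 10.0 / (GAS_CONSTANT * ghk.temperature)
        np.testing.assert_allclose(drive, expect, rtol=1e-9)

    def test_zero_at_reversal(self, ghk):
        vrev = reversal_potential(ghk)
        assert vrev == pytest.approx(58.5, abs=0.1)  # (RT/2F) ln(100) at 295 K
        assert abs(ghk_drive(vrev, ghk)) < 1e-9 * abs(ghk_drive(-80.0, ghk))

    def test_reversal_symmetric_concentrations(self):
        assert reversal_potential(GHKSettings(c_in=5.0, c_out=5.0)) == pytest.approx(0.0)

    def test_value_at_zero_voltage(self, ghk):
        # limit z F P (c_in - c_out)
        expect = ghk.z * FARADAY * (ghk.c_in - ghk.c_out)
        assert ghk_drive(0.0, ghk) == pytest.approx(expect, rel=1e-9)

    def test_taylor_splice_continuity(self, ghk):
        # compare splice against the exact expression just outside the switch
        vt = ghk.thermal_voltage_mv
        for u in (1e-3, -1e-3, 9e-5, -9e-5, 1.1e-4):
            v = u * vt / ghk.z
            exact = (
                ghk.z * FARADAY * (ghk.c_in - ghk.c_out * np.exp(-u)) * u / (1 - np.exp(-u))
            )
            assert ghk_drive(v, ghk) == pytest.approx(exact, rel=1e-8)

    def test_inward_negative_at_hyperpolarized(self, ghk):
        assert ghk_drive(-80.0, ghk) < 0


class TestPeaksAndConductance:
    def test_extremum_after_blanking(self):
        protocol = StepProtocol("activation", -90.0, (-30.0,), step_duration=4.0, sample_interval=1.0)
        sweeps = SweepSet(protocol, np.arange(4.0), np.array([[0.0, -0.5, -1.2, -0.8]]))
        _, peaks = extract_peaks(sweeps, blank_ms=0.5)
        assert peaks[0] == pytest.approx(-1.2)

    def test_all_zero_sweep_gives_zero(self):
        protocol = StepProtocol("activation", -90.0, (-30.0,), step_duration=4.0, sample_interval=1.0)
        sweeps = SweepSet(protocol, np.arange(4.0), np.zeros((1, 4)))
        _, peaks = extract_peaks(sweeps, blank_ms=0.5)
        assert peaks[0] == 0.0

    def test_peak_matches_dense_grid_oracle(self, channel_model):
        protocol = StepProtocol(
            "activation", -90.0, (-40.0, -20.0), step_duration=150.0, sample_interval=0.05
        )
        sweeps = simulate_sweeps(channel_model, protocol, noise_sd=0.0, seed=0)
        _, peaks = extract_peaks(sweeps, blank_ms=0.0)
        m0 = boltzmann(-90.0, channel_model.act)
        h0 = boltzmann(-90.0, channel_model.inact)
        t = np.arange(0.0, 150.0, 0.001)
        for v, peak in zip(protocol.steps, peaks):
            m = boltzmann(v, channel_model.act) + (m0 - boltzmann(v, channel_model.act)) * np.exp(
                -t / channel_model.tau_m
            )
            h = boltzmann(v, channel_model.inact) + (h0 - boltzmann(v, channel_model.inact)) * np.exp(
                -t / channel_model.tau_h
            )
            analytic = channel_model.scale * m * h * ghk_drive(v, channel_model.ghk)
            oracle = analytic[np.argmax(np.abs(analytic))]
            assert peak == pytest.approx(oracle, rel=1e-3)

    def test_transient_peak_strictly_inside_step(self, channel_model):
        sweeps = simulate_sweeps(channel_model, DEFAULT_ACTIVATION_PROTOCOL, noise_sd=0.0, seed=0)
        trace = np.abs(sweeps.currents[-1])  # most depolarized step
        ipk = int(np.argmax(trace))
        assert 0 < ipk < trace.size - 1

    def test_chord_curve_inverts_construction(self, ghk):
        v = np.arange(-80.0, 11.0, 10.0)
        m_inf = np.asarray(boltzmann(v, WT_ACT))
        peaks = 3.7e-6 * m_inf * np.asarray(ghk_drive(v, ghk))
        curve = chord_conductance_curve(v, peaks, ghk)
        np.testing.assert_allclose(curve.g, m_inf / m_inf.max(), atol=1e-9)

    def test_chord_curve_scale_invariant(self, ghk):
        v = np.arange(-80.0, 11.0, 10.0)
        peaks = np.asarray(boltzmann(v, WT_ACT)) * np.asarray(ghk_drive(v, ghk))
        g1 = chord_conductance_curve(v, peaks, ghk).g
        g2 = chord_conductance_curve(v, 2 * peaks, ghk).g
        np.testing.assert_allclose(g1, g2, atol=1e-12)

    def test_step_at_reversal_rejected(self, ghk):
        vrev = reversal_potential(ghk)
        with pytest.raises(InputError, match="reversal"):
            chord_conductance_curve([vrev, -40.0], [0.0, -1.0], ghk)

    def test_availability_curve_normalizes_magnitude(self):
        curve = availability_curve([-100.0, -60.0, -40.0], [-2.0, -1.0, -0.1])
        np.testing.assert_allclose(curve.g, [1.0, 0.5, 0.05])


class TestBoltzmannFit:
    def test_noiseless_self_consistency(self):
        v = np.arange(-80.0, 11.0, 10.0)
        truth = BoltzmannParams(-44.69, 4.0, "activation")
        curve = ConductanceCurve(v, np.asarray(boltzmann(v, truth)))
        fit = fit_boltzmann(curve, "activation")
        assert fit.converged
        assert fit.params.v_half == pytest.approx(-44.69, abs=1e-6)
        assert fit.params.k == pytest.approx(4.0, abs=1e-6)

    def test_sense_mismatch_flagged(self):
        v = np.arange(-100.0, -29.0, 5.0)
        g = np.asarray(boltzmann(v, WT_INACT))  # decreasing data
        fit = fit_boltzmann(ConductanceCurve(v, g), "activation")
        assert not fit.converged  # k driven to its bound

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            fit_boltzmann(ConductanceCurve([0.0, 1, 2], [0.1, 0.5, 0.9]), "activation")

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(2)
        v = np.arange(-80.0, 11.0, 10.0)
        g = np.clip(np.asarray(boltzmann(v, WT_ACT)) + rng.normal(0, 0.02, v.size), 0, None)
        fit = fit_boltzmann(ConductanceCurve(v, g), "activation")
        lo, hi = fit.ci95["v_half"]
        assert lo <= fit.params.v_half <= hi


class TestWindow:
    def test_curve_bounded_by_components(self):
        v = np.linspace(-100, 0, 101)
        _, w = window_curve(WT_ACT, WT_INACT, v)
        m = np.asarray(boltzmann(v, WT_ACT))
        h = np.asarray(boltzmann(v, WT_INACT))
        assert np.all(w <= np.minimum(m, h) + 1e-15)
        assert np.all((w > 0) & (w < 1))

    def test_hand_computed_product(self):
        # equal k = 5, midpoints -40/-60: w(-50) = (1/(1+e^2))^2
        act = BoltzmannParams(-40.0, 5.0, "activation")
        inact = BoltzmannParams(-60.0, 5.0, "inactivation")
        _, w = window_curve(act, inact, [-50.0])
        assert w[0] == pytest.approx(0.014209, abs=1e-6)

    def test_translation_equivariance(self):
        v = np.linspace(-100, 0, 201)
        _, w0 = window_curve(WT_ACT, WT_INACT, v)
        delta = -7.5
        act = BoltzmannParams(WT_ACT.v_half + delta, WT_ACT.k, "activation")
        inact = BoltzmannParams(WT_INACT.v_half + delta, WT_INACT.k, "inactivation")
        _, w1 = window_curve(act, inact, v + delta)
        np.testing.assert_allclose(w0, w1, atol=1e-12)

    def test_sense_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            window_curve(WT_INACT, WT_ACT, [-50.0])

    def test_equal_slopes_peak_at_midpoint(self):
        act = BoltzmannParams(-40.0, 5.0, "activation")
        inact = BoltzmannParams(-60.0, 5.0, "inactivation")
        m = window_metrics(act, inact)
        assert m.v_peak == pytest.approx(-50.0, abs=1e-4)
        assert m.v_low <= m.v_peak <= m.v_high
        assert m.width == pytest.approx(m.v_high - m.v_low)

    @settings(deadline=None, max_examples=25)
    @given(
        va=st.floats(-60, -20),
        vi=st.floats(-80, -45),
        ka=st.floats(2.0, 10.0),
        ki=st.floats(2.0, 10.0),
        thr=st.floats(0.05, 0.5),
    )
    def test_metrics_match_dense_grid_oracle(self, va, vi, ka, ki, thr):
        act = BoltzmannParams(va, ka, "activation")
        inact = BoltzmannParams(vi, ki, "inactivation")
        m = window_metrics(act, inact, threshold_frac=thr)
        grid = np.arange(-200.0, 100.0, 0.001)
        _, w = window_curve(act, inact, grid)
        assert m.v_peak == pytest.approx(grid[np.argmax(w)], abs=0.01)
        above = grid[w >= thr * w.max()]
        assert m.v_low == pytest.approx(above[0], abs=0.01)
        assert m.v_high == pytest.approx(above[-1], abs=0.01)

    def test_mutant_window_hyperpolarized_any_shared_k(self):
        for k in np.linspace(3.0, 7.0, 9):
            wt = window_metrics(
                BoltzmannParams(-37.14, k, "activation"), BoltzmannParams(-58.18, k, "inactivation")
            )
            mut = window_metrics(
                BoltzmannParams(-44.69, k, "activation"), BoltzmannParams(-63.11, k, "inactivation")
            )
            assert mut.v_peak < wt.v_peak
            assert abs(mut.width - wt.width) / wt.width < 0.20


class TestQcLeak:
    @pytest.mark.parametrize(
        "current, expected",
        [(-0.05, True), (-0.2, False), (-0.1, False), (0.05, True), (0.1, False)],
    )
    def test_acceptance_rule(self, current, expected):
        assert qc_leak(current) is expected


class TestSweepSimulation:
    def test_steady_state_oracle(self):
        # tau_m -> 0, tau_h -> inf: current is scale * m_inf(V) * h(hold) * drive(V)
        model = ChannelModel(scale=1e-6, act=WT_ACT, inact=WT_INACT, tau_m=1e-9, tau_h=1e12)
        sweeps = simulate_sweeps(model, DEFAULT_ACTIVATION_PROTOCOL, noise_sd=0.0, seed=0)
        h0 = boltzmann(-90.0, WT_INACT)
        for v, trace in zip(DEFAULT_ACTIVATION_PROTOCOL.steps, sweeps.currents):
            expect = 1e-6 * boltzmann(v, WT_ACT) * h0 * ghk_drive(v, model.ghk)
            np.testing.assert_allclose(trace[1:], expect, rtol=1e-9)

    def test_step_to_reversal_is_flat_zero(self, channel_model):
        vrev = reversal_potential(channel_model.ghk)
        protocol = StepProtocol("activation", -90.0, (vrev,), step_duration=50.0)
        sweeps = simulate_sweeps(channel_model, protocol, noise_sd=0.0, seed=0)
        assert np.max(np.abs(sweeps.currents)) < 1e-9 * abs(
            channel_model.scale * ghk_drive(-80.0, channel_model.ghk)
        )

    def test_inactivation_protocol_recovers_availability(self, channel_model):
        sweeps = simulate_sweeps(channel_model, DEFAULT_INACTIVATION_PROTOCOL, noise_sd=0.0, seed=0)
        v, peaks = extract_peaks(sweeps)
        fit = fit_boltzmann(availability_curve(v, peaks), "inactivation")
        assert fit.converged
        assert fit.params.v_half == pytest.approx(WT_INACT.v_half, abs=0.5)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ParameterError):
            ChannelModel(scale=1e-6, act=WT_ACT, inact=WT_INACT, tau_m=0.0).validate()

    def test_seeded_determinism(self, channel_model):
        a = simulate_sweeps(channel_model, DEFAULT_ACTIVATION_PROTOCOL, noise_sd=0.05, seed=9)
        b = simulate_sweeps(channel_model, DEFAULT_ACTIVATION_PROTOCOL, noise_sd=0.05, seed=9)
        np.testing.assert_array_equal(a.currents, b.currents)
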