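"""Synthetic generators: determinism, fidelity to the forward model, closed loops."""

import numpy as np
import pytest

from coccohv.ephys import (fit_activation_tau, leak_subtract, steady_state_iv,
                           tail_reversal, VoltageProtocol)
from coccohv.imaging import calcification_rates, calibrate_two_point, inhibition_percent, ratio_to_ph
from coccohv.model import HvChannelParams, hv_steady_open
from coccohv.synth import (TruthManifest, gen_birefringence, gen_ratio_trace,
                           gen_sweep_family, gen_tail_family, native_channel_truth)


class TestDeterminism:
    def test_same_seed_reproduces_sweeps_bitwise(self):
        truth = native_channel_truth()
        a, ma = gen_sweep_family(truth, noise_sigma_pa=3.0, seed=11, r_seal_gohm=2.0)
        b, mb = gen_sweep_family(truth, noise_sigma_pa=3.0, seed=11, r_seal_gohm=2.0)
        assert np.array_equal(a.currents_pa, b.currents_pa)
        assert ma.to_json() == mb.to_json()

    def test_different_seed_differs(self):
        truth = native_channel_truth()
        a, _ = gen_sweep_family(truth, noise_sigma_pa=3.0, seed=1)
        b, _ = gen_sweep_family(truth, noise_sigma_pa=3.0, seed=2)
        assert not np.array_equal(a.currents_pa, b.currents_pa)

    def test_manifest_round_trips_through_json(self):
        _, m = gen_birefringence("ph6.5", noise_sigma=1.0, seed=5)
        assert TruthManifest.from_json(m.to_json()) == m


class TestSweepForwardModel:
    def test_noiseless_no_leak_equals_gated_channel_model(self):
        truth = native_channel_truth(g_max_ns=2.0)
        proto = VoltageProtocol.iv_family(levels_mv=(50.0,), step_ms=2000.0)
        fam, _ = gen_sweep_family(truth, e_rev_mv=-29.1, protocol=proto,
                                  noise_sigma_pa=0.0, cap_transients=False)
        t = proto.times_ms
        during = (t >= proto.step_onset_ms) & (t < proto.step_onset_ms + proto.step_ms)
        p0 = hv_steady_open(proto.holding_mv, -29.1, truth)
        p_inf = hv_steady_open(50.0, -29.1, truth)
        p = p_inf + (p0 - p_inf) * np.exp(-(t[during] - proto.step_onset_ms) / truth.tau_act_ms)
        expected = truth.g_max_ns * p * (50.0 + 29.1)
        assert np.allclose(fam.currents_pa[0][during], expected, atol=1e-9)
        # holding-level current is the (tiny) steady open fraction at −80 mV
        pre = t < proto.step_onset_ms
        assert np.allclose(fam.currents_pa[0][pre],
                           truth.g_max_ns * p0 * (proto.holding_mv + 29.1), atol=1e-9)

    def test_pure_leak_family_is_flat_after_subtraction(self):
        truth = HvChannelParams(g_max_ns=0.0, tau_act_ms=220.0, tau_deact_ms=220.0)
        fam, _ = gen_sweep_family(truth, noise_sigma_pa=0.5, seed=3, r_seal_gohm=1.0,
                                  cap_transients=False)
        curve = steady_state_iv(leak_subtract(fam, 1.0), window_ms=40.0)
        assert np.all(np.abs(curve.currents_pa) < 3 * 0.5 / np.sqrt(40))

    def test_known_leak_corrected_to_truth_within_noise(self):
        truth = native_channel_truth()
        sigma = 2.0
        noleak, _ = gen_sweep_family(truth, noise_sigma_pa=0.0, cap_transients=False)
        leaky, _ = gen_sweep_family(truth, noise_sigma_pa=sigma, seed=9, r_seal_gohm=1.0,
                                    cap_transients=False)
        corrected = leak_subtract(leaky, 1.0)
        resid = corrected.currents_pa - noleak.currents_pa
        assert np.abs(resid).mean() < 2 * sigma


class TestClosedLoopRecovery:
    @pytest.mark.parametrize("g,e_rev", [(0.5, -60.0), (2.0, -29.1), (5.0, 40.0)])
    def test_tail_reversal_recovered_within_2mv(self, g, e_rev):
        truth = native_channel_truth(g_max_ns=g)
        levels = tuple(np.arange(e_rev - 45.0, e_rev + 50.0, 10.0))
        peak_scale = g * 40.0
        fam, _ = gen_tail_family(truth, e_rev_mv=e_rev, tail_levels_mv=levels,
                                 prepulse_mv=e_rev + 90.0,
                                 noise_sigma_pa=peak_scale / 20.0, seed=4,
                                 r_seal_gohm=2.0)
        est = tail_reversal(leak_subtract(fam), blank_ms=5.0)
        assert est.e_rev_mv == pytest.approx(e_rev, abs=2.0)

    @pytest.mark.parametrize("tau", [22.9, 107.0, 220.0, 400.0])
    def test_activation_tau_recovered_within_5pct(self, tau):
        truth = native_channel_truth(g_max_ns=2.0, tau_ms=tau)
        proto = VoltageProtocol.iv_family(levels_mv=(50.0,), step_ms=max(1000.0, 5 * tau))
        amp = truth.g_max_ns * (50.0 + 29.1)
        fam, _ = gen_sweep_family(truth, protocol=proto, noise_sigma_pa=amp / 20.0,
                                  seed=7, cap_transients=False)
        fit = fit_activation_tau(proto.times_ms, fam.currents_pa[0],
                                 fit_start_ms=proto.step_onset_ms,
                                 fit_end_ms=proto.step_onset_ms + proto.step_ms)
        assert fit.tau_ms == pytest.approx(tau, rel=0.05)

    def test_steady_state_current_recovered_within_5pct(self):
        truth = native_channel_truth(g_max_ns=2.0)
        proto = VoltageProtocol.iv_family(levels_mv=(30.0, 50.0), step_ms=1500.0)
        fam, _ = gen_sweep_family(truth, protocol=proto, noise_sigma_pa=3.0, seed=8,
                                  r_seal_gohm=2.0)
        curve = steady_state_iv(leak_subtract(fam), window_ms=40.0)
        for v, i in zip(curve.voltages_mv, curve.currents_pa):
            expected = truth.g_max_ns * hv_steady_open(v, -29.1, truth) * (v + 29.1)
            assert i == pytest.approx(expected, rel=0.05)

    def test_reversal_insensitive_to_counter_ion_changes(self, solutions):
        """H+-selective truth: widely different K+/Cl- pipettes give the same E_rev."""
        from coccohv.synth import e_rev_from_solutions

        estimates = []
        for label in ("P_KCl80", "P_KCl400", "P_KGlu200"):
            e_rev = e_rev_from_solutions(solutions[label], solutions["E1"])
            truth = native_channel_truth(g_max_ns=2.0)
            fam, _ = gen_tail_family(truth, e_rev_mv=e_rev, prepulse_mv=110.0,
                                     noise_sigma_pa=0.0, seed=0)
            estimates.append(tail_reversal(leak_subtract(fam), blank_ms=5.0).e_rev_mv)
        assert max(estimates) - min(estimates) < 2.0

    def test_zero_conductance_exercises_degenerate_path(self):
        truth = HvChannelParams(g_max_ns=0.0, tau_act_ms=220.0, tau_deact_ms=220.0)
        fam, _ = gen_tail_family(truth, noise_sigma_pa=0.0, cap_transients=False)
        with pytest.raises(ValueError):
            tail_reversal(fam)

    def test_leak_round_trip_leaves_reversal_invariant(self):
        truth = native_channel_truth(g_max_ns=2.0)
        clean, _ = gen_tail_family(truth, e_rev_mv=-29.1, noise_sigma_pa=0.0, seed=0)
        leaky, _ = gen_tail_family(truth, e_rev_mv=-29.1, noise_sigma_pa=0.0, seed=0,
                                   r_seal_gohm=1.5)
        e_clean = tail_reversal(leak_subtract(clean)).e_rev_mv
        e_round = tail_reversal(leak_subtract(leaky, 1.5)).e_rev_mv
        assert e_round == pytest.approx(e_clean, abs=1e-9)


class TestRatioGenerator:
    def test_constant_ph_maps_to_constant_ratio(self):
        cal = calibrate_two_point(2.0, 1.2)
        trace, _ = gen_ratio_trace(np.full(100, 7.2), cal=cal, noise_fraction=0.0)
        assert np.allclose(trace.ratio, cal.ratio(7.2))

    def test_step_recovered_through_calibration_with_noise(self):
        cal = calibrate_two_point(2.0, 1.2)
        t = np.arange(0.0, 240.0, 1.0)
        ph = np.where(t < 120.0, 7.10, 7.10 - 0.13)
        trace, _ = gen_ratio_trace(ph, time_s=t, cal=cal, noise_fraction=0.01, seed=6)
        series = ratio_to_ph(trace, cal, ester_loaded=True)
        from coccohv.imaging import event_delta_ph

        dph = event_delta_ph(series, 120.0, pre_window_s=60.0, post_window_s=60.0,
                             post_delay_s=5.0)
        assert dph == pytest.approx(-0.13, abs=0.01)


class TestBirefringenceGenerator:
    def test_control_noiseless_has_zero_inhibition(self):
        series, _ = gen_birefringence("control", noise_sigma=0.0)
        assert inhibition_percent(calcification_rates(series)) == pytest.approx(0.0, abs=1e-9)

    def test_scenario_truths_exact_when_noiseless(self):
        for name, expected in (("ph6.5", 69.0), ("nh4cl", 67.0)):
            series, manifest = gen_birefringence(name, noise_sigma=0.0)
            inh = inhibition_percent(calcification_rates(series))
            assert inh == pytest.approx(expected, abs=1e-9)
            assert manifest.truth["treatment_inhibition_percent"] == pytest.approx(expected)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            gen_birefringence("martian")

    def test_noisy_replicates_unbiased(self):
        """Mean recovered inhibition over seeded replicates lies within 1 SE of truth."""
        vals = []
        for seed in range(100):
            series, _ = gen_birefringence("nh4cl", noise_sigma=2.0, seed=seed)
            vals.append(inhibition_percent(calcification_rates(series)))
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 67.0) <= max(se, 0.05)
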