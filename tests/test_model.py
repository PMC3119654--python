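"""Cell model: gating, currents, resting potential, clamp/free-running dynamics."""

import numpy as np
import pytest

from coccohv.ephys import VoltageProtocol
from coccohv.model import (CellConfig, ClChannelParams, Event, HvChannelParams,
                           Scenario, cl_current, clamp_step, hv_current,
                           hv_steady_open, proton_budget, resting_potential,
                           simulate_free_running, simulate_voltage_clamp,
                           steady_state)
from coccohv.scenarios import calcifying_config, get_scenario, native_config


def _hv(**kw):
    defaults = dict(g_max_ns=2.0, v_half_offset_mv=15.0, slope_k_mv=8.0)
    defaults.update(kw)
    return HvChannelParams(**defaults)


class TestGating:
    def test_midpoint_and_limits(self):
        p = _hv()
        e_h = -48.0
        assert hv_steady_open(e_h + 15.0, e_h, p) == pytest.approx(0.5)
        assert hv_steady_open(-1e4, e_h, p) == pytest.approx(0.0, abs=1e-12)
        assert hv_steady_open(1e4, e_h, p) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_increasing_in_v(self):
        p = _hv()
        grid = np.linspace(-120.0, 80.0, 60)
        vals = [hv_steady_open(v, -48.0, p) for v in grid]
        assert np.all(np.diff(vals) > 0)

    def test_half_activation_tracks_e_h_one_to_one(self):
        """Lowering pH_o by 1 unit moves E_H by +60 mV and V_half by exactly the same."""
        p = _hv()
        for shift in (10.0, 60.0):
            assert hv_steady_open(-48.0 + 15.0 + shift, -48.0 + shift, p) == pytest.approx(0.5)


class TestCurrents:
    def test_reversal_zero_at_e_h(self):
        p = _hv()
        for popen in (0.0, 0.3, 1.0):
            assert hv_current(-48.0, popen, -48.0, p) == 0.0

    def test_ohmic_arithmetic(self):
        p = _hv(g_max_ns=2.0)
        assert hv_current(2.0, 0.5, -48.0, p) == pytest.approx(50.0)

    def test_full_zn_block_silences_channel(self):
        p = _hv(zn_block_fraction=1.0)
        for v in (-80.0, 0.0, 60.0):
            assert hv_current(v, 1.0, -48.0, p) == 0.0

    def test_cl_rectifier_zero_at_reversal_and_closed_depolarized(self):
        p = ClChannelParams(g_max_ns=1.0, e_cl_mv=-46.0, v_half_mv=-60.0, slope_k_mv=10.0)
        assert cl_current(-46.0, p) == 0.0
        assert abs(cl_current(60.0, p)) < 1e-3  # gate shut when depolarized

    def test_cl_inward_current_grows_with_hyperpolarization(self):
        p = ClChannelParams(g_max_ns=1.0, e_cl_mv=-46.0, v_half_mv=-60.0, slope_k_mv=10.0)
        grid = np.arange(-120.0, -60.0, 5.0)
        i = np.array([cl_current(v, p) for v in grid])
        assert np.all(i < 0)
        assert np.all(np.diff(i) > 0)  # less negative toward e_cl


class TestRestingPotential:
    def test_leak_only_cell_rests_at_e_leak(self):
        cfg = CellConfig(hv=_hv(g_max_ns=0.0), cl=ClChannelParams(g_max_ns=0.0),
                         g_leak_ns=0.1, e_leak_mv=-37.0)
        rp = resting_potential(cfg)
        assert rp.v_rest_mv == pytest.approx(-37.0, abs=1e-6)

    def test_no_conductance_raises(self):
        cfg = CellConfig(hv=_hv(g_max_ns=0.0, background_permeability=0.0),
                         cl=ClChannelParams(g_max_ns=0.0), g_leak_ns=0.0)
        with pytest.raises(ValueError):
            resting_potential(cfg)


class TestVoltageClamp:
    def test_budget_closes_and_channel_term_matches_trapezoid(self):
        """The cumulative channel H+ equals an independent trapezoidal ∫I_h dt/F."""
        from coccohv.constants import MOL_PER_SECOND_PER_PA

        cfg = native_config()
        res, _ = clamp_step(cfg, 70.0, duration_s=5.0, dt_max_s=5e-4)
        budget = proton_budget(res)
        assert budget["relative_residual"] < 1e-5
        oracle = np.trapezoid(res.i_h_pa, res.time_s) * MOL_PER_SECOND_PER_PA
        assert budget["channel"] == pytest.approx(oracle, rel=1e-6)

    def test_depolarization_above_e_h_alkalinises(self):
        _, dph = clamp_step(native_config(), 70.0)
        assert dph > 0.1

    def test_hyperpolarization_is_ph_neutral(self):
        """A −110 mV step activates only Cl- current, which carries no acid."""
        _, dph = clamp_step(native_config(), -110.0, duration_s=10.0)
        assert abs(dph) < 0.005

    def test_gate_stays_in_unit_interval(self):
        proto = VoltageProtocol.iv_family(levels_mv=(-120.0, 70.0), step_ms=500.0)
        for sweep in (0, 1):
            res = simulate_voltage_clamp(proto, native_config(), sweep=sweep)
            assert np.all((res.p_open >= 0.0) & (res.p_open <= 1.0))

    def test_recovery_time_constant_tracks_secondary_regulation(self):
        """After the pulse, pH_i relaxes ~exponentially with tau ≈ 1/k_sec (30–60 s)."""
        cfg = native_config()
        proto = VoltageProtocol(holding_mv=-50.0, sampling_interval_ms=1.0, pre_ms=100.0,
                                step_levels_mv=(70.0,), step_ms=10e3, post_ms=120e3)
        res = simulate_voltage_clamp(proto, cfg)
        t0 = 10.1  # end of pulse
        mask = (res.time_s >= t0) & (res.time_s <= t0 + 100.0)
        t = res.time_s[mask] - t0
        excess = res.ph_i[mask] - res.ph_i[-1]
        # log-linear fit of the decay
        keep = excess > 1e-4
        slope = np.polyfit(t[keep], np.log(excess[keep]), 1)[0]
        tau = -1.0 / slope
        assert 30.0 <= tau <= 60.0


class TestFreeRunning:
    def test_steady_state_is_stationary(self):
        cfg = calcifying_config()
        res = simulate_free_running(cfg, duration_s=30.0)
        assert abs(res.ph_i[-1] - res.ph_i[0]) < 1e-3
        assert abs(res.v_m_mv[-1] - res.v_m_mv[0]) < 0.1

    def test_quiescent_cell_budget_terms_vanish(self):
        cfg = native_config(j_calc_mol_s=0.0)
        v0, ph0 = steady_state(cfg)
        res = simulate_free_running(cfg, duration_s=20.0)
        scale = cfg.buffer_mol_per_ph * 0.01  # mol per 0.01 pH
        b = proton_budget(res)
        for key in ("channel", "background", "acid_load", "secondary_regulation"):
            assert abs(b[key]) < scale

    def test_external_acidification_is_reversible(self):
        sc = get_scenario("ph_o_6.5")
        res = simulate_free_running(sc.config, sc, dt_max_s=5e-3)
        baseline = res.ph_at(55.0)
        acidified = res.ph_at(355.0)
        recovered = res.ph_at(595.0)
        assert acidified < baseline - 0.05
        assert abs(recovered - baseline) < 0.02

    def test_zn_block_acidifies_calcifying_cells_only(self):
        sc = get_scenario("zn_block")
        res = simulate_free_running(sc.config, sc, dt_max_s=2e-3)
        dph = res.ph_at(180.0) - res.ph_at(30.0)
        assert dph == pytest.approx(-0.13, abs=0.03)
        # pH falls monotonically during the block (coarse grid)
        during = (res.time_s >= 31.0) & (res.time_s <= 179.0)
        ph = res.ph_i[during][::2000]
        assert np.all(np.diff(ph) < 1e-6)

        sc_ca = get_scenario("zn_block_ca_free")
        res_ca = simulate_free_running(sc_ca.config, sc_ca, dt_max_s=2e-3)
        assert abs(res_ca.ph_at(180.0) - res_ca.ph_at(30.0)) <= 0.04

    def test_gd_block_mirrors_full_channel_loss(self):
        sc = get_scenario("gd_block")
        res = simulate_free_running(sc.config, sc, dt_max_s=2e-3)
        assert res.ph_at(180.0) - res.ph_at(30.0) < -0.1
        assert np.all(res.i_h_pa[res.time_s > 31.0] == 0.0)

    def test_budget_closure_on_event_run(self):
        sc = get_scenario("zn_block")
        res = simulate_free_running(sc.config, sc, dt_max_s=2e-3)
        assert proton_budget(res)["relative_residual"] < 1e-5


class TestIVProperties:
    def test_outward_current_non_increasing_with_lower_ph_o(self):
        """Acid outside both shifts activation positive and shrinks the driving force."""
        cfg = native_config()
        for v in (0.0, 25.0, 50.0):
            outs = []
            for ph_o in (8.0, 7.5, 7.0, 6.5):
                e_h = cfg.e_h_mv(ph_o=ph_o)
                p = hv_steady_open(v, e_h, cfg.hv)
                outs.append(hv_current(v, p, e_h, cfg.hv, cfg.ph_i, ph_o))
            assert all(a >= b - 1e-12 for a, b in zip(outs, outs[1:]))

    def test_outward_current_grows_with_lower_ph_i(self):
        cfg = native_config()
        for v in np.arange(-20.0, 80.0, 10.0):
            i_75, i_65 = (
                hv_current(v, hv_steady_open(v, cfg.e_h_mv(ph_i=ph), cfg.hv),
                           cfg.e_h_mv(ph_i=ph), cfg.hv, ph, cfg.ph_o)
                for ph in (7.5, 6.5))
            assert i_65 >= i_75 - 1e-12


class TestScenarioValidation:
    def test_events_must_be_ordered(self):
        with pytest.raises(ValueError):
            Scenario("bad", native_config(),
                     events=(Event(10.0, "zn_on"), Event(5.0, "zn_off")))

    def test_unknown_event_kind_rejected(self):
        with pytest.raises(ValueError):
            Scenario("bad", native_config(), events=(Event(1.0, "teleport"),))

    def test_unknown_scenario_name(self):
        with pytest.raises(KeyError):
            get_scenario("not_a_scenario")
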