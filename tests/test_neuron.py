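"""MSO/GBC compartment dynamics: currents, integration, resonance."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mso_itd import _channels as ch
from mso_itd.neuron import (GBCParams, MSOParams, channel_currents,
                            gbc_neuron, impedance_curve, integrate,
                            mso_rhs, run_mso_population)

P = MSOParams()


class TestChannelCurrents:
    def test_sodium_current_vanishes_at_reversal(self):
        state = dict(v=P.e_na, m=0.7, h=0.3, w=0.5, r=0.1)
        assert channel_currents(state, P)["na"] == 0.0

    def test_temperature_factor_closed_form(self):
        assert ch.temperature_factor(37.0) == pytest.approx(3.0**1.5)
        assert ch.temperature_factor(37.0) == pytest.approx(5.196, abs=1e-3)

    def test_gating_variable_out_of_bounds_rejected(self):
        state = dict(v=-50.0, m=1.4, h=0.3, w=0.5, r=0.1)
        with pytest.raises(ValueError):
            channel_currents(state, P)

    def test_currents_balance_at_rest(self):
        rs = P.resting_state()
        state = dict(v=rs["v"], m=rs["m"], h=rs["h"], w=rs["w"], r=rs["r"])
        assert sum(channel_currents(state, P).values()) == pytest.approx(
            0.0, abs=1e-9)


class TestIntegration:
    def test_rest_is_stable_without_input(self):
        t, v, spikes = integrate(P, 0.1)
        assert len(spikes) == 0
        assert abs(v[-1] - P.e_rest) < 0.5
        assert np.all(np.abs(v - P.e_rest) < 1.0)

    def test_matches_adaptive_reference_subthreshold(self):
        """Exponential Euler vs LSODA on a sinusoidally driven compartment."""
        amp, freq = 40.0, 200.0  # pA, Hz

        def i_fn(t_ms):
            return amp * np.sin(2 * np.pi * freq * t_ms * 1e-3)

        dt = 1e-5
        n_steps = 5000  # 50 ms
        i_inj = i_fn(np.arange(n_steps) * dt * 1e3)
        _, v_ee = run_mso_population(P, n_steps * dt, i_inj=i_inj,
                                     n_neurons=1, record_v=True)
        rs = P.resting_state()
        y0 = [rs["v"], rs["m"], rs["h"], rs["w"], rs["r"]]
        t_eval = np.arange(n_steps) * dt * 1e3
        sol = solve_ivp(mso_rhs, (0, t_eval[-1]), y0, t_eval=t_eval,
                        args=(P, i_fn), method="LSODA", rtol=1e-10,
                        atol=1e-10)
        rmse = np.sqrt(np.mean((v_ee[:, 0] - sol.y[0]) ** 2))
        assert rmse < 0.5

    def test_step_current_drives_spiking_with_tall_spikes(self):
        i = np.concatenate([np.zeros(2000), np.full(18000, 5000.0)])
        spikes, v = run_mso_population(P, 0.2, i_inj=i, n_neurons=1,
                                       record_v=True)
        assert len(spikes[0]) >= 1
        assert v[:, 0].max() > P.spike_threshold + 10.0

    def test_spike_count_converges_with_time_step(self):
        rng = np.random.default_rng(3)
        events = np.sort(rng.uniform(0.01, 0.19, 120))
        counts = {}
        for dt in (2e-5, 1e-5, 1e-6):
            _, _, spikes = integrate(P, 0.2, exc_times=events, g_e=45.0,
                                     dt=dt)
            counts[dt] = len(spikes)
        assert counts[1e-6] > 5
        assert abs(counts[2e-5] - counts[1e-5]) <= max(
            2, 0.1 * counts[1e-6])
        assert abs(counts[1e-5] - counts[1e-6]) <= max(
            2, 0.1 * counts[1e-6])

    def test_all_or_none_epsg_threshold_window(self):
        """A <10% conductance window separates 0% from 100% firing."""
        lo, hi = 20.0, 200.0
        for _ in range(24):
            mid = 0.5 * (lo + hi)
            _, _, spikes = integrate(P, 0.04, exc_times=[0.02], g_e=mid)
            if len(spikes):
                hi = mid
            else:
                lo = mid
        assert (hi - lo) / hi < 0.1
        _, _, s_below = integrate(P, 0.04, exc_times=[0.02], g_e=0.9 * lo)
        _, _, s_above = integrate(P, 0.04, exc_times=[0.02], g_e=1.1 * hi)
        assert len(s_below) == 0 and len(s_above) == 1

    def test_excessive_time_step_rejected(self):
        with pytest.raises(ValueError):
            integrate(P, 0.01, dt=5e-5)


class TestImpedance:
    def test_passive_cell_is_low_pass(self):
        passive = MSOParams(g_na=0.0, g_k=0.0, g_h=0.0, g_leak=60.0)
        freqs, z, _ = impedance_curve(passive, duration=4.0, amp_pa=200.0)
        lo = z[(freqs > 15) & (freqs < 30)].mean()
        hi = z[(freqs > 500) & (freqs < 700)].mean()
        assert lo > 2 * hi
        coarse = np.interp(np.geomspace(20, 700, 12), freqs, z)
        assert np.all(np.diff(coarse) < 0.05 * coarse[0])

    def test_full_model_resonates_near_260_hz(self):
        _, _, res = impedance_curve(P, duration=5.0)
        assert 200.0 < res < 330.0

    def test_resonance_stable_across_probe_amplitudes(self):
        res = [impedance_curve(P, duration=5.0, amp_pa=a)[2]
               for a in (25.0, 50.0, 100.0)]
        assert max(res) - min(res) <= 10.0

    def test_impedance_at_resonance_exceeds_dc(self):
        freqs, z, res = impedance_curve(P, duration=5.0)
        z_dc = z[freqs < 20].mean()
        z_res = z.max()
        assert z_res > 1.5 * z_dc

    def test_suprathreshold_probe_rejected(self):
        with pytest.raises(ValueError):
            impedance_curve(P, duration=2.0, amp_pa=20000.0)


class TestGBC:
    def test_no_input_no_output(self):
        silent = [np.empty(0)] * 40
        assert len(gbc_neuron(silent, 0.1)) == 0

    def test_wrong_input_count_rejected(self):
        with pytest.raises(ValueError):
            gbc_neuron([np.empty(0)] * 10, 0.1)

    def test_deterministic_for_identical_inputs(self, rng):
        inputs = [np.sort(rng.uniform(0, 0.1, 15)) for _ in range(40)]
        a = gbc_neuron(inputs, 0.1)
        b = gbc_neuron(inputs, 0.1)
        assert np.array_equal(a, b)

    def test_synchronized_volleys_drive_entrainment(self, rng):
        # phase-locked volleys at 250 Hz: GBC should fire near one
        # spike per cycle
        cycles = np.arange(0.02, 0.1, 1 / 250.0)
        inputs = [np.sort(cycles + rng.normal(0, 0.3e-3, len(cycles)))
                  for _ in range(40)]
        out = gbc_neuron([np.clip(i, 0, None) for i in inputs], 0.1)
        assert len(out) >= 0.7 * len(cycles)
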