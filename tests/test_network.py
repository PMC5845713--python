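"""Circuit wiring, synaptic waveforms and population-level ITD tuning."""

import numpy as np
import pytest
from scipy.integrate import quad

from mso_itd._channels import biexp_peak_time
from mso_itd.decoding import fit_itd_rate, population_rate
from mso_itd.network import (NetworkConfig, build_and_run, epsc_waveform,
                             ipsc_waveform, itd_rate_curve)
from mso_itd.periphery import vector_strength
from mso_itd.stimuli import make_tone

TAU_E = 0.17e-3
TAU_I1, TAU_I2 = 0.14e-3, 1.6e-3


class TestSynapticWaveforms:
    def test_alpha_function_peaks_at_tau(self):
        assert epsc_waveform(TAU_E) == pytest.approx(1.0)
        assert epsc_waveform(0.0) == 0.0
        assert epsc_waveform(-1e-4) == 0.0
        t = np.linspace(0, 10 * TAU_E, 5000)
        assert epsc_waveform(t).max() <= 1.0 + 1e-12

    def test_alpha_integral_matches_quadrature(self):
        # closed form: integral of (t/tau) e^(1 - t/tau) dt = e * tau
        val, _ = quad(epsc_waveform, 0, 50 * TAU_E)
        assert val == pytest.approx(np.e * TAU_E, rel=1e-6)

    def test_biexp_peak_time_closed_form_matches_argmax(self):
        t = np.linspace(0, 10e-3, 200001)
        g = ipsc_waveform(t)
        t_star = biexp_peak_time(TAU_I1, TAU_I2)
        expected = (TAU_I1 * TAU_I2 / (TAU_I2 - TAU_I1)
                    * np.log(TAU_I2 / TAU_I1))
        assert t_star == pytest.approx(expected, rel=1e-12)
        assert t[np.argmax(g)] == pytest.approx(t_star, abs=1e-6)

    def test_biexp_peak_normalized_to_unity(self):
        t = np.linspace(0, 10e-3, 200001)
        assert ipsc_waveform(t).max() == pytest.approx(1.0, abs=1e-6)
        assert ipsc_waveform(0.0) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_time_constants_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(tau_i1=1e-3, tau_i2=1e-3)


class TestBuildAndRun:
    def test_same_seed_is_bit_identical(self, tone_250):
        net = NetworkConfig(n_per_population=15, cf=250.0, rng_seed=5)
        a = build_and_run(tone_250, net)
        b = build_and_run(tone_250, net)
        for pop in ("anf", "gbc", "mso"):
            for h in ("left", "right"):
                for ta, tb in zip(getattr(a, pop)[h].trains,
                                  getattr(b, pop)[h].trains):
                    assert np.array_equal(ta, tb)

    def test_gbc_sharpen_anf_phase_locking(self, small_run_125):
        res = small_run_125
        w0, w1 = 0.05, 0.13
        vs = {}
        for pop in ("anf", "gbc"):
            pooled = getattr(res, pop)["left"].pooled()
            vs[pop] = vector_strength(pooled[(pooled > w0) & (pooled < w1)],
                                      125.0)
        assert vs["gbc"] > vs["anf"]

    def test_left_leading_tone_favors_right_mso(self, small_run_125):
        w = small_run_125.analysis_window
        r_left = population_rate(small_run_125.mso["left"], w)
        r_right = population_rate(small_run_125.mso["right"], w)
        assert r_right > 1.15 * r_left

    def test_diotic_symmetry_without_inhibition(self):
        stim = make_tone(125.0, 0.1, 50.0)
        net = NetworkConfig(n_per_population=40, cf=125.0, g_syn_i=0.0,
                            rng_seed=11)
        res = build_and_run(stim, net)
        w = res.analysis_window
        rl = population_rate(res.mso["left"], w)
        rr = population_rate(res.mso["right"], w)
        se = np.sqrt(rl / (40 * (w[1] - w[0])))
        assert abs(rl - rr) < 4 * se + 2.0

    def test_channel_swap_mirrors_hemispheres(self):
        stim = make_tone(125.0, 0.1, 50.0, itd=-200e-6)
        net = NetworkConfig(n_per_population=40, cf=125.0, rng_seed=11)
        a = build_and_run(stim, net)
        b = build_and_run(stim.swapped(), net)
        w = a.analysis_window
        for h, opp in (("left", "right"), ("right", "left")):
            ra = population_rate(a.mso[h], w)
            rb = population_rate(b.mso[opp], w)
            se = np.sqrt(max(ra, 1.0) / (40 * (w[1] - w[0])))
            assert abs(ra - rb) < 4 * se + 2.0


@pytest.fixture(scope="module")
def curves_by_inhibition():
    grid = np.linspace(-1e-3, 1e-3, 11)
    out = {}
    for gi in (0.0, 15.0, 30.0):
        net = NetworkConfig(n_per_population=30, cf=125.0, g_syn_i=gi,
                            rng_seed=13)
        out[gi] = itd_rate_curve(125.0, grid, net)
    return out


class TestITDTuning:
    def test_bell_shape_with_interior_maximum(self, curves_by_inhibition):
        df = curves_by_inhibition[30.0]
        peak = df.rate_right.idxmax()
        assert 0 < peak < len(df) - 1
        assert df.rate_right.max() > 3 * df.rate_right.min() + 5

    def test_inhibition_lowers_peak_and_shifts_best_itd(
            self, curves_by_inhibition):
        peaks, bests = [], []
        for gi in (0.0, 15.0, 30.0):
            df = curves_by_inhibition[gi]
            fit = fit_itd_rate(df.itd, df.rate_right)
            peaks.append(df.rate_right.max())
            bests.append(fit.b)
        assert peaks[0] > peaks[1] > peaks[2]
        assert bests[0] > bests[1] > bests[2]  # more contralateral (negative)

    def test_hemispheres_mirror_about_zero(self, curves_by_inhibition):
        df = curves_by_inhibition[30.0]
        fit_l = fit_itd_rate(df.itd, df.rate_left)
        fit_r = fit_itd_rate(df.itd, df.rate_right)
        assert fit_l.b == pytest.approx(-fit_r.b, abs=150e-6)
        assert np.corrcoef(df.rate_left,
                           df.rate_right[::-1])[0, 1] > 0.85


def test_best_itd_magnitude_decreases_with_frequency():
    from mso_itd.experiments import best_itd
    b_low = best_itd(125.0, n_neurons=30, n_itd=11, seed=2)
    b_high = best_itd(700.0, n_neurons=30, n_itd=11, seed=2)
    assert abs(b_high) < abs(b_low)
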