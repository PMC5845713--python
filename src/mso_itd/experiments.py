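"""Canned model experiments: resonance, ITD tuning, sensitivity, JND.

These drivers reproduce the package's headline analyses at configurable
scale (population size, repetitions) and are shared by the test suite,
the command-line interface and the acceptance script.  All randomness
derives from an explicit seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .decoding import fit_itd_rate, population_rate, sensitivity_slope
from .network import NetworkConfig, build_and_run
from .neuron import MSOParams, impedance_curve
from .psychoacoustics import jnd_experiment
from .stimuli import make_tone


def resonance_frequency(params: MSOParams | None = None, *,
                        duration: float = 10.0) -> float:
    """Subthreshold resonance (Hz) of the MSO compartment from a ZAP probe."""
    params = params or MSOParams()
    _, _, res = impedance_curve(params, duration=duration)
    return res


def itd_span_for(freq: float, max_span: float = 1e-3) -> float:
    """Half-width of the ITD grid: +-1 ms, restricted to one tuning
    period (1/freq) at high frequencies so the unimodal fit sees a single
    peak of the cyclic tuning function."""
    return min(max_span, 0.5 / freq)


def itd_tuning(freq: float, *, n_neurons: int = 50, n_itd: int = 15,
               n_reps: int = 1, g_syn_i: float | None = None,
               duration: float = 0.1, level: float = 50.0, seed: int = 0,
               span: float | None = None):
    """Measure and fit ITD-rate functions of both hemispheres.

    Returns (DataFrame[itd, rate_left, rate_right], fit_left, fit_right);
    rates are averaged over ``n_reps`` fresh-noise repetitions.
    """
    net = NetworkConfig(n_per_population=n_neurons, cf=freq, rng_seed=seed)
    if g_syn_i is not None:
        net = replace(net, g_syn_i=g_syn_i)
    span = itd_span_for(freq) if span is None else span
    grid = np.linspace(-span, span, n_itd)
    seeds = np.random.SeedSequence(seed).generate_state(n_itd * n_reps)
    seeds = seeds.reshape(n_itd, n_reps)
    rows = []
    for i, itd in enumerate(grid):
        rl, rr = [], []
        for k in range(n_reps):
            stim = make_tone(freq, duration, level, itd=float(itd))
            res = build_and_run(stim, replace(net,
                                              rng_seed=int(seeds[i, k]) %
                                              2**31))
            w = res.analysis_window
            rl.append(population_rate(res.mso["left"], w))
            rr.append(population_rate(res.mso["right"], w))
        rows.append({"itd": float(itd), "rate_left": float(np.mean(rl)),
                     "rate_right": float(np.mean(rr))})
    df = pd.DataFrame(rows)
    fit_l = fit_itd_rate(df.itd, df.rate_left)
    fit_r = fit_itd_rate(df.itd, df.rate_right)
    return df, fit_l, fit_r


def best_itd(freq: float, **kwargs) -> float:
    """Fitted best-ITD (s, signed) of the right-hemisphere MSO."""
    _, _, fit_r = itd_tuning(freq, **kwargs)
    return fit_r.b


def best_itd_magnitude(freq: float, **kwargs) -> float:
    """|best-ITD| (s) averaged over the two mirror-symmetric hemispheres.

    The left and right fits estimate the same magnitude with opposite
    signs, so averaging them halves the sampling variance.
    """
    _, fit_l, fit_r = itd_tuning(freq, **kwargs)
    return 0.5 * (abs(fit_l.b) + abs(fit_r.b))


def sensitivity_curve(freqs=None, *, n_neurons: int = 50, n_reps: int = 3,
                      window: float = 100e-6, n_itd: int = 5,
                      duration: float = 0.1, level: float = 50.0,
                      seed: int = 0) -> pd.DataFrame:
    """Midline slope of the opponent-channel readout across frequency.

    For each frequency the network is run at ``n_itd`` ITDs within
    +-``window`` and the dR-vs-ITD slope is averaged over ``n_reps``
    repetitions.  Returns DataFrame[freq, slope, sensitivity] with
    ``sensitivity`` = -slope (positive; dR falls with ITD because the
    right MSO prefers left-leading sounds).
    """
    freqs = np.geomspace(125.0, 1000.0, 13) if freqs is None else freqs
    grid = np.linspace(-window, window, n_itd)
    rows = []
    ss = np.random.SeedSequence(seed)
    for fi, freq in enumerate(np.asarray(freqs, float)):
        slopes = []
        for k in range(n_reps):
            child = np.random.SeedSequence(entropy=ss.entropy,
                                           spawn_key=(fi, k))
            net = NetworkConfig(n_per_population=n_neurons, cf=freq,
                                rng_seed=int(child.generate_state(1)[0])
                                % 2**31)
            dr = []
            for itd in grid:
                stim = make_tone(freq, duration, level, itd=float(itd))
                res = build_and_run(stim, replace(
                    net, rng_seed=(net.rng_seed + 7919 * len(dr)) % 2**31))
                w = res.analysis_window
                dr.append(population_rate(res.mso["right"], w)
                          - population_rate(res.mso["left"], w))
            slopes.append(sensitivity_slope(grid, dr, window=window))
        rows.append({"freq": freq, "slope": float(np.mean(slopes)),
                     "sensitivity": float(-np.mean(slopes))})
    return pd.DataFrame(rows)


def jnd_vs_frequency(freqs, subset_size: int, *, n_pool: int = 150,
                     n_trials: int = 50, n_deltas: int = 12,
                     n_realizations: int = 3, seed: int = 0,
                     duration: float = 0.1) -> pd.DataFrame:
    """JND at each frequency for one subset size (scaled protocol)."""
    grid = np.geomspace(2e-6, 800e-6, n_deltas)
    rows = []
    for fi, freq in enumerate(np.asarray(freqs, float)):
        net = NetworkConfig(n_per_population=n_pool, cf=freq,
                            rng_seed=seed + 31 * fi)
        res = jnd_experiment(freq, subset_size, n_trials=n_trials,
                             delta_grid=grid, net=net,
                             n_realizations=n_realizations,
                             duration=duration, seed=seed + 31 * fi)
        rows.append({"freq": freq, "jnd": res.jnd,
                     "theta": res.theta, "beta": res.beta,
                     "degenerate": res.degenerate})
    return pd.DataFrame(rows)


def jnd_vs_population_size(freq: float, subset_sizes=(5, 10, 50, 100), *,
                           n_pool: int = 150, n_trials: int = 50,
                           n_deltas: int = 12, n_realizations: int = 3,
                           seed: int = 0,
                           duration: float = 0.1) -> pd.DataFrame:
    """JND as a function of the decoded subset size at one frequency.

    The response bank is shared across subset sizes (the network does not
    depend on the decoder), so the cost is one JND experiment.
    """
    from .psychoacoustics import build_response_banks, psychometric_from_banks

    grid = np.geomspace(2e-6, 800e-6, n_deltas)
    net = NetworkConfig(n_per_population=n_pool, cf=freq, rng_seed=seed)
    banks = build_response_banks(freq, grid, net,
                                 n_realizations=n_realizations,
                                 duration=duration, seed=seed)
    rows = []
    for n_sub in subset_sizes:
        res = psychometric_from_banks(grid, banks, int(n_sub),
                                      n_trials=n_trials, seed=seed)
        rows.append({"n": int(n_sub), "jnd": res.jnd,
                     "degenerate": res.degenerate})
    return pd.DataFrame(rows)
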