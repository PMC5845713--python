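"""Just-noticeable-difference (JND) estimation for the linear decoder.

A two-interval procedure: each trial presents the same tone at ITDs of
-dITD/2 and +dITD/2 and compares the opponent-channel readout dR = R_R -
R_L of a random subset of N neurons between the intervals.  Because the
right MSO prefers left-leading (negative) ITDs, dR decreases with ITD
around the midline, and a trial is counted correct when dR at the
negative ITD exceeds dR at the positive one.  Fractions correct over a
log-spaced dITD grid are fitted with a Weibull psychometric function
P(x) = 0.5 + 0.5 * (1 - exp(-(x/theta)^beta)) (guess rate 0.5, no lapse)
and the JND is the 75%-correct point, theta * ln(2)^(1/beta).

Per-trial stochasticity has two sources, matching the population-noise
reading of the procedure: the neuron subset is redrawn every trial (one
observer listens to both intervals, so the subset is shared within a
trial), and each interval's response is drawn from an independent
fresh-noise realization of the network.  Realizations are simulated once
per grid point in a small bank (``n_realizations``) and sampled by the
trials, which keeps the cost linear in the grid size rather than in the
trial count.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .network import NetworkConfig, build_and_run
from .stimuli import make_tone

DEFAULT_GRID = np.geomspace(2e-6, 800e-6, 20)


def weibull(x, theta, beta):
    """Two-interval Weibull psychometric function (guess 0.5, lapse 0)."""
    return 0.5 + 0.5 * (1.0 - np.exp(-((x / theta) ** beta)))


def weibull_jnd(theta, beta, criterion=0.75):
    """ITD at which the Weibull reaches ``criterion`` fraction correct."""
    q = (criterion - 0.5) / 0.5
    return theta * (-np.log(1.0 - q)) ** (1.0 / beta)


def fit_weibull(delta_itds, fraction_correct):
    """Fit (theta, beta) by least squares over the psychometric samples.

    Falls back to a coarse grid search when the curvature-based fit
    fails (flat or otherwise degenerate psychometric data), so callers
    always get a parameter estimate alongside the degeneracy flag.
    """
    x = np.asarray(delta_itds, float)
    y = np.asarray(fraction_correct, float)
    # initial threshold: first grid point above 75%, else median
    above = x[y >= 0.75]
    theta0 = above.min() if above.size else np.median(x)
    bounds = ([x.min() / 100, 0.2], [x.max() * 100, 20.0])
    try:
        popt, _ = curve_fit(weibull, x, y, p0=[theta0, 1.5],
                            bounds=bounds, maxfev=20000)
        return float(popt[0]), float(popt[1])
    except RuntimeError:
        thetas = np.geomspace(bounds[0][0], bounds[1][0], 120)
        betas = np.geomspace(bounds[0][1], bounds[1][1], 40)
        tt, bb = np.meshgrid(thetas, betas)
        sse = ((weibull(x[None, None, :], tt[..., None],
                        bb[..., None]) - y) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        return float(tt[i, j]), float(bb[i, j])


@dataclass
class PsychometricResult:
    """Outcome of one JND experiment."""

    delta_itd_grid: np.ndarray
    fraction_correct: np.ndarray
    theta: float
    beta: float
    jnd: float
    n_trials_per_point: int
    population_subset_size: int
    extrapolated: bool
    degenerate: bool

    @property
    def guess_rate(self) -> float:
        return 0.5

    @property
    def lapse_rate(self) -> float:
        return 0.0


def _window_counts(res, hemisphere):
    w = res.analysis_window
    return res.mso[hemisphere].counts_in(*w), w[1] - w[0]


def _response_bank(freq, delta, net, *, duration, level, n_realizations,
                   seed_seq):
    """Per-neuron rates for +-delta/2, shape (2, n_realizations, n_pool, 2).

    Last axis: (left, right) hemisphere rates.  All realizations share
    the deterministic wiring of ``net.rng_seed``; only the periphery
    noise is fresh per realization and interval, so neuron identities
    are stable across the bank.
    """
    out = np.empty((2, n_realizations, net.n_per_population, 2))
    for si, sign in enumerate((-1.0, +1.0)):
        for k in range(n_realizations):
            child = np.random.SeedSequence(
                entropy=seed_seq.entropy,
                spawn_key=seed_seq.spawn_key + (si, k))
            stim = make_tone(freq, duration, level, itd=sign * delta / 2)
            res = build_and_run(
                stim, replace(net, rng_seed=int(child.generate_state(1)[0])
                              % 2**31),
                wiring_seed=net.rng_seed)
            for hi, h in enumerate(("left", "right")):
                counts, wlen = _window_counts(res, h)
                out[si, k, :, hi] = counts / wlen
    return out


def trial(freq: float, delta_itd: float, subset_size: int, *,
          net: NetworkConfig | None = None, duration: float = 0.1,
          level: float = 50.0, seed: int = 0) -> bool:
    """Run one two-interval lateralization trial from scratch.

    Simulates the network at -delta_itd/2 and +delta_itd/2 with fresh
    noise, draws one random subset of ``subset_size`` neurons (shared
    between intervals) and returns whether the decoder ordered the two
    intervals correctly.  Convenience wrapper; batch experiments use
    ``jnd_experiment``.
    """
    if delta_itd <= 0:
        raise ValueError("delta_itd must be positive")
    net = net or NetworkConfig(cf=freq)
    if subset_size > net.n_per_population:
        raise ValueError("subset larger than the population")
    bank = _response_bank(freq, delta_itd, net, duration=duration,
                          level=level, n_realizations=1,
                          seed_seq=np.random.SeedSequence(seed))
    rng = np.random.default_rng(np.random.SeedSequence(seed,
                                                       spawn_key=(99,)))
    idx = rng.choice(net.n_per_population, subset_size, replace=False)
    dr_neg = bank[0, 0, idx, 1].mean() - bank[0, 0, idx, 0].mean()
    dr_pos = bank[1, 0, idx, 1].mean() - bank[1, 0, idx, 0].mean()
    if dr_neg == dr_pos:
        return bool(rng.integers(2))
    return bool(dr_neg > dr_pos)


def build_response_banks(freq: float, delta_grid, net: NetworkConfig, *,
                         n_realizations: int = 4, duration: float = 0.1,
                         level: float = 50.0, seed: int = 0):
    """Simulate the response banks for a whole dITD grid.

    Returns a list of arrays as produced by ``_response_bank``, one per
    grid point.  Banks are decoder-independent and can be reused across
    subset sizes.
    """
    root = np.random.SeedSequence(seed)
    return [
        _response_bank(freq, float(delta), net, duration=duration,
                       level=level, n_realizations=n_realizations,
                       seed_seq=np.random.SeedSequence(
                           entropy=root.entropy, spawn_key=(2, gi)))
        for gi, delta in enumerate(delta_grid)
    ]


def psychometric_from_banks(delta_grid, banks, subset_size: int, *,
                            n_trials: int = 100, n_pool: int | None = None,
                            seed: int = 0) -> PsychometricResult:
    """Run the trial loop and Weibull fit over precomputed banks."""
    grid = np.asarray(delta_grid)
    n_pool = banks[0].shape[2] if n_pool is None else n_pool
    if subset_size > n_pool:
        raise ValueError("subset larger than the population")
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(1, subset_size)))
    frac = np.empty(len(grid))
    for gi, bank in enumerate(banks):
        n_real = bank.shape[1]
        n_correct = 0
        for _ in range(n_trials):
            idx = rng.choice(n_pool, subset_size, replace=False)
            ka, kb = rng.integers(n_real, size=2)
            dr_neg = bank[0, ka, idx, 1].mean() - bank[0, ka, idx, 0].mean()
            dr_pos = bank[1, kb, idx, 1].mean() - bank[1, kb, idx, 0].mean()
            if dr_neg == dr_pos:
                n_correct += int(rng.integers(2))
            else:
                n_correct += int(dr_neg > dr_pos)
        frac[gi] = n_correct / n_trials
    theta, beta = fit_weibull(grid, frac)
    jnd = weibull_jnd(theta, beta)
    top = frac[grid >= np.median(grid)]
    degenerate = bool(top.mean() < 0.65)
    extrapolated = not (grid.min() <= jnd <= grid.max())
    return PsychometricResult(grid, frac, theta, beta, float(jnd),
                              n_trials, subset_size, extrapolated,
                              degenerate)


def jnd_experiment(freq: float, subset_size: int, *, n_trials: int = 100,
                   delta_grid=None, net: NetworkConfig | None = None,
                   n_realizations: int = 4, duration: float = 0.1,
                   level: float = 50.0, seed: int = 0) -> PsychometricResult:
    """Estimate the JND at one frequency for one population subset size.

    ``delta_grid`` defaults to 20 log-spaced dITDs between 2 and 800 us.
    The network population provides the pool from which each trial's
    subset is drawn; ``n_realizations`` independent fresh-noise responses
    are simulated per grid point and interval.
    """
    net = net or NetworkConfig(cf=freq)
    if subset_size > net.n_per_population:
        raise ValueError("subset larger than the population")
    grid = np.asarray(DEFAULT_GRID if delta_grid is None else delta_grid)
    banks = build_response_banks(freq, grid, net,
                                 n_realizations=n_realizations,
                                 duration=duration, level=level, seed=seed)
    return psychometric_from_banks(grid, banks, subset_size,
                                   n_trials=n_trials, seed=seed)
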