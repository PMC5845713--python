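"""Population firing rates, the linear opponent-channel decoder, and
ITD-rate function fitting.

The opponent-channel readout is the firing-rate difference
dR = R_R - R_L between the right and left MSO populations; around the
midline it is approximately linear in ITD and its slope doubles the
single-hemisphere sensitivity.  ITD-rate functions are fitted with a
modified Gaussian R(tau) = R_max * exp(-(tau - B)^2 / W^2) + R_offset,
whose location parameter B is the best-ITD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .periphery import SpikeTrains


def population_rate(trains: SpikeTrains, window) -> float:
    """Mean firing rate per neuron (spikes/s) inside ``window`` (s, s).

    The conventional analysis window starts 25 ms after signal onset and
    ends 25 ms after signal offset; callers obtain it from
    ``NetworkResult.analysis_window``.
    """
    start, end = window
    if trains.n_neurons == 0:
        raise ValueError("empty population")
    if end <= start:
        raise ValueError("empty analysis window")
    counts = trains.counts_in(start, end)
    return float(counts.sum() / (trains.n_neurons * (end - start)))


@dataclass
class DecoderOutput:
    """Opponent-channel readout for one analysis window."""

    r_left: float
    r_right: float
    window: tuple

    @property
    def delta_r(self) -> float:
        return self.r_right - self.r_left


def delta_r(mso_left: SpikeTrains, mso_right: SpikeTrains,
            window) -> DecoderOutput:
    """Firing-rate difference R_R - R_L over one window."""
    if abs(mso_left.duration - mso_right.duration) > 1e-9:
        raise ValueError("hemisphere recordings of unequal duration")
    return DecoderOutput(population_rate(mso_left, window),
                         population_rate(mso_right, window), tuple(window))


def binned_delta_r(mso_left: SpikeTrains, mso_right: SpikeTrains,
                   bin_width: float = 0.1, t_start: float = 0.0,
                   t_end: float | None = None):
    """dR computed in consecutive time bins (e.g. 100 ms).

    Returns (bin_start_times, delta_r_values).
    """
    t_end = t_end if t_end is not None else mso_left.duration
    edges = np.arange(t_start, t_end + 1e-12, bin_width)
    vals = [delta_r(mso_left, mso_right, (a, b)).delta_r
            for a, b in zip(edges[:-1], edges[1:])]
    return edges[:-1], np.asarray(vals)


@dataclass
class ITDRateFit:
    """Modified-Gaussian fit of an ITD-rate function.

    Fields follow the fitted form R(tau) = r_max * exp(-(tau - b)^2 / w^2)
    + r_offset, with tau, b and w in seconds and rates in spikes/s.
    """

    r_max: float
    w: float
    b: float
    r_offset: float
    residual: float
    itd: np.ndarray
    rate: np.ndarray

    @property
    def best_itd(self) -> float:
        return self.b

    def __call__(self, tau):
        tau = np.asarray(tau, dtype=float)
        return (self.r_max * np.exp(-((tau - self.b) / self.w) ** 2)
                + self.r_offset)


def fit_itd_rate(itd, rate) -> ITDRateFit:
    """Least-squares fit of the modified Gaussian to (ITD, rate) samples.

    Uses multiple starts (peak location, plus left/right-shifted widths)
    and keeps the lowest-residual solution.  Raises RuntimeError with
    diagnostics if no start converges.
    """
    itd = np.asarray(itd, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if itd.size < 5:
        raise ValueError("need at least 5 (ITD, rate) points")
    span = itd.max() - itd.min()

    def model(tau, r_max, w, b, r_off):
        return r_max * np.exp(-((tau - b) / w) ** 2) + r_off

    peak_b = itd[np.argmax(rate)]
    amp = max(rate.max() - rate.min(), 1e-9)
    starts = [(amp, span / 2, peak_b, rate.min()),
              (amp, span / 4, peak_b, rate.min()),
              (amp, span / 2, peak_b - span / 8, rate.min()),
              (amp, span / 2, peak_b + span / 8, rate.min())]
    best = None
    errors = []
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                model, itd, rate, p0=p0, maxfev=20000,
                bounds=([0, 1e-6 * span + 1e-12, itd.min() - span,
                         -np.inf],
                        [np.inf, 10 * span, itd.max() + span, np.inf]))
        except RuntimeError as err:  # non-convergence for this start
            errors.append(str(err))
            continue
        resid = float(np.sqrt(np.mean((model(itd, *popt) - rate) ** 2)))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise RuntimeError("ITD-rate fit failed for all starts: "
                           + "; ".join(errors))
    (r_max, w, b, r_off), resid = best
    return ITDRateFit(float(r_max), float(w), float(b), float(r_off),
                      resid, itd, rate)


def sensitivity_slope(itd, dr, *, window: float = 100e-6) -> float:
    """Slope of dR vs ITD within +-``window`` of the midline (spikes/s/s).

    Requires samples on both sides of (or at) zero ITD inside the window.
    """
    itd = np.asarray(itd, dtype=float)
    dr = np.asarray(dr, dtype=float)
    sel = np.abs(itd) <= window + 1e-12
    if sel.sum() < 2 or itd[sel].min() > 0 or itd[sel].max() < 0:
        raise ValueError("need >= 2 samples bracketing 0 ITD within the "
                         "midline window")
    res = linregress(itd[sel], dr[sel])
    return float(res.slope)


def psth(trains: SpikeTrains, bin_width: float = 750e-6, ax=None):
    """Post-stimulus time histogram (rate per neuron vs time); plotting aid."""
    edges = np.arange(0.0, trains.duration + bin_width, bin_width)
    counts, _ = np.histogram(trains.pooled(), bins=edges)
    rate = counts / (trains.n_neurons * bin_width)
    if ax is not None:
        ax.bar(edges[:-1], rate, width=bin_width, align="edge")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("rate (spikes/s)")
    return edges[:-1], rate
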