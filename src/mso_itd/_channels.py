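"""Voltage-gated channel kinetics for the MSO and GBC model neurons.

All functions take membrane potential in mV and return steady-state values
(dimensionless) and time constants in ms.  The sodium kinetics follow the
Rothman-Manis (2003) ventral-cochlear-nucleus formulation at a 22 degC
reference; rates are scaled to body temperature with a Q10 of 3
(k = 3**((T-22)/10)) and the sodium *activation* is additionally sped up
fourfold on top of the temperature factor, which is required for realistic
spike shapes and thresholds in the MSO compartment.

The MSO low-threshold potassium (KLT) channel uses the gerbil-MSO
activation curve (half-activation -57.3 mV, slope 11.7 mV) with fourth-power
activation and its inactivation held constant at z = 0.4.  The
hyperpolarization-activated current uses a single sigmoidal activation.
Because the primary literature fits differ in their time-constant scales,
the KLT time-constant scale and the Ih half-activation are treated as
calibration constants fixed so the compartment rests at -55.8 mV and shows
its subthreshold resonance near 260 Hz (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

# LUT grid shared by all kernels
V_MIN = -150.0
V_MAX = 80.0
DV = 0.05
V_GRID = np.arange(V_MIN, V_MAX + DV / 2, DV)


def temperature_factor(temperature: float) -> float:
    """Q10=3 rate scaling relative to the 22 degC reference."""
    return 3.0 ** ((temperature - 22.0) / 10.0)


# ---------------------------------------------------------------- sodium

def na_m_inf(v):
    return 1.0 / (1.0 + np.exp(-(v + 38.0) / 7.0))


def na_h_inf(v):
    return 1.0 / (1.0 + np.exp((v + 65.0) / 6.0))


def na_tau_m(v):
    """Activation time constant, ms at 22 degC."""
    return 10.0 / (5.0 * np.exp((v + 60.0) / 18.0)
                   + 36.0 * np.exp(-(v + 60.0) / 25.0)) + 0.04


def na_tau_h(v):
    return 100.0 / (7.0 * np.exp((v + 60.0) / 11.0)
                    + 10.0 * np.exp(-(v + 60.0) / 25.0)) + 0.6


# ------------------------------------------------- MSO low-threshold K+

def klt_w_inf_mso(v):
    return 1.0 / (1.0 + np.exp(-(v + 57.34) / 11.7))


def klt_tau_w_mso(v):
    """Fast KLT activation time constant, ms (physiological temperature)."""
    return 21.5 / (6.0 * np.exp((v + 60.0) / 7.0)
                   + 24.0 * np.exp(-(v + 60.0) / 50.6)) + 0.35


# -------------------------------------------------------- MSO Ih

def ih_r_inf_mso(v, v_half=-75.0, slope=7.0):
    return 1.0 / (1.0 + np.exp((v - v_half) / slope))


def ih_tau_r_mso(v):
    """Slow HCN activation time constant, ms (physiological temperature)."""
    return 1.0e4 / (237.0 * np.exp((v + 60.0) / 12.0)
                    + 17.0 * np.exp(-(v + 60.0) / 14.0)) + 25.0


# ------------------------------------- Rothman-Manis type II (GBC) gates

def kht_n_inf(v):
    return (1.0 + np.exp(-(v + 15.0) / 5.0)) ** -0.5


def kht_tau_n(v):
    return 100.0 / (11.0 * np.exp((v + 60.0) / 24.0)
                    + 21.0 * np.exp(-(v + 60.0) / 23.0)) + 0.7


def kht_p_inf(v):
    return 1.0 / (1.0 + np.exp(-(v + 23.0) / 6.0))


def kht_tau_p(v):
    return 100.0 / (4.0 * np.exp((v + 60.0) / 32.0)
                    + 5.0 * np.exp(-(v + 60.0) / 22.0)) + 5.0


def klt_w_inf_rm(v):
    return (1.0 + np.exp(-(v + 48.0) / 6.0)) ** -0.25


def klt_tau_w_rm(v):
    return 100.0 / (6.0 * np.exp((v + 60.0) / 6.0)
                    + 16.0 * np.exp(-(v + 60.0) / 45.0)) + 1.5


def klt_z_inf_rm(v, zeta=0.5):
    return zeta + (1.0 - zeta) / (1.0 + np.exp((v + 71.0) / 10.0))


def klt_tau_z_rm(v):
    return 1000.0 / (np.exp((v + 60.0) / 20.0)
                     + np.exp(-(v + 60.0) / 8.0)) + 50.0


def ih_r_inf_rm(v):
    return 1.0 / (1.0 + np.exp((v + 76.0) / 7.0))


def ih_tau_r_rm(v):
    return 1.0e5 / (237.0 * np.exp((v + 60.0) / 12.0)
                    + 17.0 * np.exp(-(v + 60.0) / 14.0)) + 25.0


# ------------------------------------------------------------ LUT builders

def _lut(dt, inf_fn, tau_fn, tau_scale=1.0):
    inf = inf_fn(V_GRID)
    tau = tau_fn(V_GRID) * tau_scale
    return inf, np.exp(-dt / tau)


def mso_luts(dt: float, temperature: float, na_speedup: float,
             klt_tau_scale: float, ih_v_half: float) -> np.ndarray:
    """Stacked (8, n_grid) LUT: inf and exp(-dt/tau) per MSO gate.

    Rows: m_inf, Em, h_inf, Eh, w_inf, Ew, r_inf, Er.  Sodium time
    constants carry the Q10 temperature factor; activation gets the extra
    fourfold speed-up.  KLT/Ih kinetics are physiological-temperature fits
    scaled only by their calibration constants.
    """
    k = temperature_factor(temperature)
    m = _lut(dt, na_m_inf, na_tau_m, 1.0 / (k * na_speedup))
    h = _lut(dt, na_h_inf, na_tau_h, 1.0 / k)
    w = _lut(dt, klt_w_inf_mso, klt_tau_w_mso, klt_tau_scale)
    r = _lut(dt, lambda v: ih_r_inf_mso(v, ih_v_half), ih_tau_r_mso)
    return np.ascontiguousarray(np.stack([*m, *h, *w, *r]))


def gbc_luts(dt: float, temperature: float) -> np.ndarray:
    """Stacked (14, n_grid) LUT for the Rothman-Manis type II gates.

    Rows: m, h, n, p, w, z, r (inf and decay factor each).  All rates carry
    the Q10=3 temperature factor from the 22 degC reference.
    """
    k = temperature_factor(temperature)
    s = 1.0 / k
    parts = [
        _lut(dt, na_m_inf, na_tau_m, s),
        _lut(dt, na_h_inf, na_tau_h, s),
        _lut(dt, kht_n_inf, kht_tau_n, s),
        _lut(dt, kht_p_inf, kht_tau_p, s),
        _lut(dt, klt_w_inf_rm, klt_tau_w_rm, s),
        _lut(dt, klt_z_inf_rm, klt_tau_z_rm, s),
        _lut(dt, ih_r_inf_rm, ih_tau_r_rm, s),
    ]
    return np.ascontiguousarray(np.vstack([a for p in parts for a in p]))


def biexp_peak_time(tau1: float, tau2: float) -> float:
    """Peak time of exp(-t/tau2) - exp(-t/tau1), tau2 > tau1."""
    return tau1 * tau2 / (tau2 - tau1) * np.log(tau2 / tau1)


def biexp_norm(tau1: float, tau2: float) -> float:
    """Scale factor making the bi-exponential difference peak at 1."""
    if tau1 >= tau2:
        raise ValueError("bi-exponential synapse requires tau2 > tau1")
    ts = biexp_peak_time(tau1, tau2)
    return 1.0 / (np.exp(-ts / tau2) - np.exp(-ts / tau1))
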