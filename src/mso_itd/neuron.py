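"""Single-compartment Hodgkin-Huxley models of MSO and GBC neurons.

The MSO compartment carries fast sodium, low-threshold potassium (KLT),
hyperpolarization-activated (Ih) and leak conductances; the globular bushy
cell (GBC) is a Rothman-Manis type II compartment driven by 40 fast,
non-depressing auditory-nerve synapses.  Integration uses exponential
Euler at a default step of 10 us; see `_kernels` for the scheme.

Membrane potentials are in mV, conductances in nS, capacitance in pF,
currents in pA, and internal time in ms; the public API exchanges spike
times and durations in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np

from . import _channels as ch
from ._kernels import mso_kernel, gbc_kernel

DT_DEFAULT = 1e-5
"""Default integration step, seconds (one 100 kHz sample)."""


@dataclass
class MSOParams:
    """MSO compartment parameters.

    The electrical constants default to the values of the model this
    package implements: Cm = 70 pF, resting potential -55.8 mV and the
    maximal conductances g_Na = 3.9 uS, g_KLT = 650 nS, g_h = 520 nS,
    g_leak = 13 nS, at 37 degC with the sodium activation sped up
    fourfold and the KLT inactivation fixed at 0.4.

    ``klt_tau_scale`` and ``ih_v_half`` are kinetic calibration constants
    (see docs/methods.md); the leak reversal is solved at construction so
    the stated resting potential is the compartment's fixed point.
    """

    cm: float = 70.0            # pF
    e_rest: float = -55.8       # mV
    e_na: float = 56.2
    e_k: float = -90.0
    e_h: float = -35.0
    e_e: float = 0.0
    e_i: float = -70.0
    g_na: float = 3900.0        # nS
    g_k: float = 650.0
    g_h: float = 520.0
    g_leak: float = 13.0
    temperature: float = 37.0   # degC
    na_speedup: float = 4.0
    klt_z_inf: float = 0.4
    klt_tau_scale: float = 0.60
    ih_v_half: float = -75.0
    spike_threshold: float = -20.0  # mV
    spike_lockout: float = 1e-3     # s
    e_leak: float = field(default=None)  # solved if None

    def __post_init__(self):
        if min(self.cm, self.g_leak) <= 0 or min(
                self.g_na, self.g_k, self.g_h) < 0:
            raise ValueError("capacitance and conductances must be positive")
        if self.e_leak is None:
            self.e_leak = self._solve_e_leak()

    def _solve_e_leak(self) -> float:
        """Leak reversal making V = e_rest a steady state."""
        v = self.e_rest
        i_na = self.g_na * ch.na_m_inf(v) ** 3 * ch.na_h_inf(v) * (v - self.e_na)
        i_klt = (self.g_k * ch.klt_w_inf_mso(v) ** 4 * self.klt_z_inf
                 * (v - self.e_k))
        i_h = (self.g_h * ch.ih_r_inf_mso(v, self.ih_v_half) * (v - self.e_h))
        return v + (i_na + i_klt + i_h) / self.g_leak

    def resting_state(self) -> dict:
        v = self.e_rest
        return dict(v=v, m=ch.na_m_inf(v), h=ch.na_h_inf(v),
                    w=ch.klt_w_inf_mso(v),
                    r=ch.ih_r_inf_mso(v, self.ih_v_half))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def load(cls, path) -> "MSOParams":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class GBCParams:
    """Rothman-Manis type II bushy-cell parameters (22 degC conductances)."""

    cm: float = 12.0
    e_na: float = 55.0
    e_k: float = -70.0
    e_h: float = -43.0
    e_leak: float = -65.0
    e_e: float = 0.0
    g_na: float = 1000.0
    g_kht: float = 150.0
    g_klt: float = 200.0
    g_h: float = 20.0
    g_leak: float = 2.0
    temperature: float = 37.0
    tau_syn: float = 0.2e-3    # s, alpha-function ANF synapse
    g_syn: float = 8.0         # nS per ANF input, calibrated
    n_inputs: int = 40
    spike_threshold: float = -20.0
    spike_lockout: float = 0.7e-3

    def resting_state(self) -> dict:
        # RM type II rests slightly above E_leak; start there and let the
        # first milliseconds settle.
        v = -63.6
        return dict(v=v, m=ch.na_m_inf(v), h=ch.na_h_inf(v),
                    n=ch.kht_n_inf(v), p=ch.kht_p_inf(v),
                    w=ch.klt_w_inf_rm(v), z=ch.klt_z_inf_rm(v),
                    r=ch.ih_r_inf_rm(v))


def channel_currents(state: dict, params: MSOParams) -> dict:
    """Instantaneous per-channel currents (pA) for a given MSO state.

    ``state`` maps 'v' (mV) and the gating variables m, h, w, r in [0,1].
    Positive values are outward.
    """
    for g in ("m", "h", "w", "r"):
        x = state[g]
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"gating variable {g}={x} outside [0,1]")
    v = state["v"]
    return {
        "na": params.g_na * state["m"] ** 3 * state["h"] * (v - params.e_na),
        "klt": (params.g_k * state["w"] ** 4 * params.klt_z_inf
                * (v - params.e_k)),
        "h": params.g_h * state["r"] * (v - params.e_h),
        "leak": params.g_leak * (v - params.e_leak),
    }


def _as_imp(events_per_neuron, n_steps, n, dt_s, weight):
    """Bin per-neuron event times (s) into a (n_steps, n) impulse array."""
    imp = np.zeros((n_steps, n), dtype=np.float32)
    for j, ev in enumerate(events_per_neuron):
        if len(ev) == 0:
            continue
        idx = np.floor(np.asarray(ev) / dt_s + 0.5).astype(np.int64)
        idx = idx[(idx >= 0) & (idx < n_steps)]
        np.add.at(imp[:, j], idx, weight)
    return imp


def run_mso_population(params: MSOParams, duration: float, *,
                       exc_imp=None, inh_imp=None, i_inj=None,
                       tau_e=0.17e-3, tau_i1=0.14e-3, tau_i2=1.6e-3,
                       n_neurons=None, dt: float = DT_DEFAULT,
                       record_v: bool = False):
    """Integrate a population of identical, unconnected MSO compartments.

    ``exc_imp``/``inh_imp`` are (n_steps, n) arrays of synaptic
    peak-conductance increments (nS) per step; ``i_inj`` is an (n_steps,)
    injected current (pA) shared by all neurons.  Returns
    (spike_times: list of arrays in s, v_traces or None).
    """
    n_steps = int(round(duration / dt))
    if n_neurons is None:
        for a in (exc_imp, inh_imp):
            if a is not None:
                n_neurons = a.shape[1]
                break
        else:
            n_neurons = 1
    if exc_imp is None:
        exc_imp = np.zeros((n_steps, n_neurons), dtype=np.float32)
    if inh_imp is None:
        inh_imp = np.zeros((n_steps, n_neurons), dtype=np.float32)
    if i_inj is None:
        i_inj = np.zeros(n_steps)
    if exc_imp.shape != (n_steps, n_neurons) or inh_imp.shape != (n_steps, n_neurons):
        raise ValueError("impulse arrays must have shape (n_steps, n_neurons)")

    dt_ms = dt * 1e3
    lut = ch.mso_luts(dt_ms, params.temperature, params.na_speedup,
                      params.klt_tau_scale, params.ih_v_half)
    rs = params.resting_state()
    v = np.full(n_neurons, rs["v"])
    m = np.full(n_neurons, rs["m"])
    h = np.full(n_neurons, rs["h"])
    w = np.full(n_neurons, rs["w"])
    r = np.full(n_neurons, rs["r"])
    max_spk = int(duration * 2000) + 16
    spike_steps = np.zeros((n_neurons, max_spk), dtype=np.int64)
    counts = np.zeros(n_neurons, dtype=np.int64)
    v_out = np.zeros((n_steps, n_neurons if record_v else 0))
    lockout_steps = int(round(params.spike_lockout / dt))
    t1, t2 = tau_i1 * 1e3, tau_i2 * 1e3
    mso_kernel(dt_ms, n_steps, lut, ch.V_MIN, 1.0 / ch.DV,
               v, m, h, w, r, params.klt_z_inf,
               params.cm, params.g_na, params.g_k, params.g_h, params.g_leak,
               params.e_na, params.e_k, params.e_h, params.e_leak,
               params.e_e, params.e_i,
               exc_imp, inh_imp, np.ascontiguousarray(i_inj, dtype=np.float64),
               tau_e * 1e3, np.exp(-dt_ms / t1), np.exp(-dt_ms / t2),
               ch.biexp_norm(t1, t2),
               params.spike_threshold, lockout_steps,
               spike_steps, counts, v_out, record_v)
    if np.any(~np.isfinite(v)):
        raise FloatingPointError("MSO integration diverged (non-finite Vm)")
    spikes = [spike_steps[j, :counts[j]] * dt for j in range(n_neurons)]
    return spikes, (v_out if record_v else None)


def integrate(params: MSOParams, duration: float, *, dt: float = DT_DEFAULT,
              exc_times=None, inh_times=None, g_e: float = 30.0,
              g_i: float = 10.0, i_inj=None, tau_e=0.17e-3,
              tau_i1=0.14e-3, tau_i2=1.6e-3):
    """Integrate a single MSO compartment and return its voltage trace.

    ``exc_times``/``inh_times`` are synaptic event times in seconds with
    per-event peak conductances ``g_e``/``g_i`` (nS); ``i_inj`` may be an
    (n_steps,) current array in pA.  Returns (t, v, spike_times), with t in
    seconds.
    """
    if dt > 2e-5:
        raise ValueError("dt must be <= 20 us for a stable HH integration")
    n_steps = int(round(duration / dt))
    exc_imp = _as_imp([np.asarray(exc_times if exc_times is not None else [])],
                      n_steps, 1, dt, g_e)
    inh_imp = _as_imp([np.asarray(inh_times if inh_times is not None else [])],
                      n_steps, 1, dt, g_i)
    spikes, v = run_mso_population(
        params, duration, exc_imp=exc_imp, inh_imp=inh_imp, i_inj=i_inj,
        tau_e=tau_e, tau_i1=tau_i1, tau_i2=tau_i2, dt=dt, record_v=True)
    t = np.arange(n_steps) * dt
    return t, v[:, 0], spikes[0]


def mso_rhs(t, y, params: MSOParams, i_fn):
    """Continuous-time right-hand side of the MSO ODEs (reference use).

    State y = [v, m, h, w, r]; ``i_fn(t_ms)`` returns injected current in
    pA.  Used by the high-accuracy reference integration that validates
    the exponential-Euler kernel; time in ms.
    """
    v, m, h, w, r = y
    k = ch.temperature_factor(params.temperature)
    i_na = params.g_na * m**3 * h * (v - params.e_na)
    i_klt = params.g_k * w**4 * params.klt_z_inf * (v - params.e_k)
    i_h = params.g_h * r * (v - params.e_h)
    i_leak = params.g_leak * (v - params.e_leak)
    dv = (-(i_na + i_klt + i_h + i_leak) + i_fn(t)) / params.cm
    dm = (ch.na_m_inf(v) - m) / (ch.na_tau_m(v) / (k * params.na_speedup))
    dh = (ch.na_h_inf(v) - h) / (ch.na_tau_h(v) / k)
    dw = (ch.klt_w_inf_mso(v) - w) / (ch.klt_tau_w_mso(v) * params.klt_tau_scale)
    dr = ((ch.ih_r_inf_mso(v, params.ih_v_half) - r) / ch.ih_tau_r_mso(v))
    return [dv, dm, dh, dw, dr]


def impedance_curve(params: MSOParams, freqs=None, *, amp_pa: float = 50.0,
                    f0: float = 10.0, f1: float = 1000.0,
                    duration: float = 10.0, dt: float = DT_DEFAULT):
    """Subthreshold impedance magnitude from a ZAP current injection.

    A low-amplitude exponential chirp current (``amp_pa`` pA, sweeping
    ``f0``..``f1`` Hz over ``duration`` s) is injected; the impedance is
    |FFT(V)/FFT(I)| evaluated inside the swept band.  Raises if the probe
    drives spikes or climbs within 5 mV of the spike threshold.

    Returns (freqs, impedance_MOhm, resonance_freq).
    """
    n_steps = int(round(duration / dt))
    t = np.arange(n_steps) * dt
    k_rate = np.log(f1 / f0) / duration
    phase = 2 * np.pi * f0 * (np.exp(k_rate * t) - 1.0) / k_rate
    i = amp_pa * np.sin(phase)
    spikes, v = run_mso_population(params, duration, i_inj=i, n_neurons=1,
                                   dt=dt, record_v=True)
    v = v[:, 0]
    if len(spikes[0]) or v.max() > params.spike_threshold - 5.0:
        raise ValueError("probe amplitude drove the neuron toward threshold; "
                         "lower amp_pa")
    f_axis = np.fft.rfftfreq(n_steps, d=dt)
    z = np.abs(np.fft.rfft(v - v.mean()) / np.fft.rfft(i))  # mV/pA = GOhm
    z_mohm = z * 1e3
    band = (f_axis >= f0 * 1.2) & (f_axis <= f1 * 0.8)
    fb, zb = f_axis[band], z_mohm[band]
    # light smoothing against FFT-bin noise
    kernel = np.ones(21) / 21.0
    zs = np.convolve(zb, kernel, mode="same")
    if freqs is not None:
        zq = np.interp(freqs, fb, zs)
        res = float(fb[np.argmax(zs)])
        return np.asarray(freqs), zq, res
    res = float(fb[np.argmax(zs)])
    return fb, zs, res


def run_gbc_population(params: GBCParams, duration: float, exc_imp,
                       *, dt: float = DT_DEFAULT, record_v: bool = False):
    """Integrate unconnected GBC compartments driven by ANF impulses."""
    n_steps, n = exc_imp.shape
    dt_ms = dt * 1e3
    lut = ch.gbc_luts(dt_ms, params.temperature)
    rs = params.resting_state()
    v = np.full(n, rs["v"])
    gates = {g: np.full(n, rs[g]) for g in "mhnpwzr"}
    max_spk = int(duration * 2000) + 16
    spike_steps = np.zeros((n, max_spk), dtype=np.int64)
    counts = np.zeros(n, dtype=np.int64)
    v_out = np.zeros((n_steps, n if record_v else 0))
    gbc_kernel(dt_ms, n_steps, lut, ch.V_MIN, 1.0 / ch.DV,
               v, gates["m"], gates["h"], gates["n"], gates["p"],
               gates["w"], gates["z"], gates["r"],
               params.cm, params.g_na, params.g_kht, params.g_klt,
               params.g_h, params.g_leak,
               params.e_na, params.e_k, params.e_h, params.e_leak, params.e_e,
               exc_imp, np.zeros(n_steps), params.tau_syn * 1e3,
               params.spike_threshold, int(round(params.spike_lockout / dt)),
               spike_steps, counts, v_out, record_v)
    if np.any(~np.isfinite(v)):
        raise FloatingPointError("GBC integration diverged (non-finite Vm)")
    spikes = [spike_steps[j, :counts[j]] * dt for j in range(n)]
    return spikes, (v_out if record_v else None)


def gbc_neuron(anf_inputs, duration: float, params: GBCParams | None = None,
               *, dt: float = DT_DEFAULT):
    """Drive one GBC with its 40 ANF input spike trains.

    ``anf_inputs`` is a sequence of ``params.n_inputs`` spike-time arrays
    (s).  Deterministic: identical inputs yield an identical output train.
    Returns the GBC spike times in seconds.
    """
    params = params or GBCParams()
    if len(anf_inputs) != params.n_inputs:
        raise ValueError(f"expected {params.n_inputs} ANF input trains, "
                         f"got {len(anf_inputs)}")
    n_steps = int(round(duration / dt))
    merged = np.sort(np.concatenate([np.asarray(a) for a in anf_inputs]))
    imp = _as_imp([merged], n_steps, 1, dt, params.g_syn)
    spikes, _ = run_gbc_population(params, duration, imp, dt=dt)
    return spikes[0]
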