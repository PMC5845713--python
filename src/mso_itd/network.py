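"""The binaural MSO circuit: ANF -> GBC -> MSO wiring and simulation.

Each hemisphere holds independent pools of ANF fibers, GBC neurons and MSO
neurons (500 each at full scale).  Every MSO neuron receives six
excitatory ANF inputs from each hemisphere (alpha-function conductance,
tau = 0.17 ms) and three inhibitory GBC inputs from each hemisphere
(peak-normalized bi-exponential, tau = 0.14/1.6 ms).  Contralateral
excitatory and inhibitory pathways carry a fixed 100 us axonal delay;
contralateral inhibition is additionally offset by 0.6 ms relative to the
excitation of its side, ipsilateral inhibition by 0 ms.  Input fibers are
drawn without replacement per neuron, independently across neurons, from
seeded streams, so a run is bit-reproducible from its master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .neuron import (DT_DEFAULT, GBCParams, MSOParams, _as_imp,
                     run_gbc_population, run_mso_population)
from .periphery import PeripheryConfig, SpikeTrains, anf_spikes
from .stimuli import BinauralStimulus


@dataclass
class NetworkConfig:
    """Wiring, synaptic and delay parameters of the MSO circuit.

    ``g_syn_e`` / ``g_syn_i`` are per-input peak conductances in nS; their
    defaults are fixed by the calibration described in docs/methods.md
    (the excitatory strength puts the cell in the coincidence-detector
    regime, the inhibitory strength places the 125 Hz best-ITD).
    ``inh_delay_additive`` selects whether the 0.6 ms contralateral
    inhibitory offset rides on top of the 100 us axonal delay.
    """

    n_per_population: int = 500
    n_exc_per_side: int = 6
    n_inh_per_side: int = 3
    g_syn_e: float = 20.0           # nS, calibrated
    g_syn_i: float = 30.0           # nS, calibrated
    tau_e: float = 0.17e-3          # s
    tau_i1: float = 0.14e-3
    tau_i2: float = 1.6e-3
    delay_contra_axonal: float = 100e-6
    delay_inh_contra: float = 0.6e-3
    delay_inh_ipsi: float = 0.0
    inh_delay_additive: bool = True
    cf: float = 500.0
    rng_seed: int = 0

    def __post_init__(self):
        if not self.tau_i2 > self.tau_i1 > 0:
            raise ValueError("need tau_i2 > tau_i1 > 0")
        if min(self.delay_contra_axonal, self.delay_inh_contra,
               self.delay_inh_ipsi) < 0:
            raise ValueError("delays must be non-negative")
        if min(self.n_per_population, self.n_exc_per_side,
               self.n_inh_per_side) <= 0:
            raise ValueError("population and fan-in counts must be positive")

    @property
    def contra_inh_delay_total(self) -> float:
        extra = self.delay_contra_axonal if self.inh_delay_additive else 0.0
        return extra + self.delay_inh_contra


@dataclass
class NetworkResult:
    """Spike trains of all six populations plus the run metadata."""

    anf: dict
    gbc: dict
    mso: dict
    config: NetworkConfig
    stim_duration: float
    stim_pad: float
    stim_core: float
    itd_applied: float

    @property
    def analysis_window(self) -> tuple[float, float]:
        """Default rate window: +25 ms after core onset to +25 ms after
        core offset (clipped to the recording)."""
        start = self.stim_pad + 0.025
        end = min(self.stim_pad + self.stim_core + 0.025, self.stim_duration)
        return (start, end)


def epsc_waveform(t, params: NetworkConfig | None = None):
    """Normalized excitatory alpha conductance (t/tau)*exp(1 - t/tau).

    Peaks at exactly 1 at t = tau_e; zero for t < 0.  Multiply by
    ``g_syn_e`` for the conductance in nS; the synaptic current is
    g_e(t) * (Vm - E_e).
    """
    tau = (params.tau_e if params is not None else 0.17e-3)
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, (t / tau) * np.exp(1.0 - t / tau), 0.0)
    return out


def ipsc_waveform(t, params: NetworkConfig | None = None):
    """Peak-normalized inhibitory bi-exponential conductance.

    g(t) = N * (exp(-t/tau_i2) - exp(-t/tau_i1)) with N chosen so the
    maximum equals 1; multiply by ``g_syn_i`` for nS.
    """
    from ._channels import biexp_norm
    p = params if params is not None else NetworkConfig()
    t1, t2 = p.tau_i1, p.tau_i2
    t = np.asarray(t, dtype=float)
    n = biexp_norm(t1, t2)
    return np.where(t >= 0, n * (np.exp(-t / t2) - np.exp(-t / t1)), 0.0)


def _fan_in(rng, pool_size, n_draw, n_neurons):
    """(n_neurons, n_draw) input indices drawn per neuron.

    Without replacement; scaled-down pools smaller than the fan-in fall
    back to drawing with replacement so the total synaptic drive per
    neuron is preserved.
    """
    replace = pool_size < n_draw
    return np.stack([rng.choice(pool_size, size=n_draw, replace=replace)
                     for _ in range(n_neurons)])


def _collect(trains, fan_idx, delay):
    """Per-target-neuron merged event lists with a pathway delay."""
    out = []
    for row in fan_idx:
        ev = [trains[i] + delay for i in row if len(trains[i])]
        out.append(np.sort(np.concatenate(ev)) if ev else np.empty(0))
    return out


def build_and_run(stim: BinauralStimulus, net: NetworkConfig | None = None,
                  mso: MSOParams | None = None,
                  gbc: GBCParams | None = None,
                  periphery: PeripheryConfig | None = None,
                  *, dt: float = DT_DEFAULT,
                  wiring_seed: int | None = None) -> NetworkResult:
    """Simulate the full circuit for one stimulus.

    Wiring and periphery noise derive deterministically from
    ``net.rng_seed``: the same seed and stimulus give bit-identical spike
    output.  ``wiring_seed`` fixes the fan-in draws independently of the
    periphery noise, so repeated runs can share one deterministic wiring
    while the spiking noise stays fresh (as the JND procedure requires).
    """
    net = net or NetworkConfig()
    mso = mso or MSOParams()
    gbc = gbc or GBCParams()
    n = net.n_per_population
    if periphery is None:
        periphery = PeripheryConfig(fiber_count=n, cf=net.cf,
                                    rng_seed=net.rng_seed)
    else:
        periphery = replace(periphery, fiber_count=n, cf=net.cf)
    if len(stim.left) != len(stim.right):
        raise ValueError("stimulus channels of unequal length")

    duration = stim.duration
    n_steps = int(round(duration / dt))
    # periphery noise streams derive from rng_seed with spawn keys (0,)/(1,)
    # inside anf_spikes; the wiring stream uses the disjoint key (2,)
    periphery = replace(periphery, rng_seed=net.rng_seed)
    anf = {h: anf_spikes(stim, periphery, h) for h in ("left", "right")}

    rng_w = np.random.default_rng(np.random.SeedSequence(
        net.rng_seed if wiring_seed is None else wiring_seed,
        spawn_key=(2,)))
    gbc_trains = {}
    for h in ("left", "right"):
        fan = _fan_in(rng_w, n, gbc.n_inputs, n)
        events = _collect(anf[h].trains, fan, 0.0)
        imp = _as_imp(events, n_steps, n, dt, gbc.g_syn)
        spikes, _ = run_gbc_population(gbc, duration, imp, dt=dt)
        gbc_trains[h] = SpikeTrains(spikes, "GBC", h, net.cf, duration)

    mso_trains = {}
    for h in ("left", "right"):
        contra = "right" if h == "left" else "left"
        exc_events = []
        inh_events = []
        fan_ei = _fan_in(rng_w, n, net.n_exc_per_side, n)
        fan_ec = _fan_in(rng_w, n, net.n_exc_per_side, n)
        fan_ii = _fan_in(rng_w, n, net.n_inh_per_side, n)
        fan_ic = _fan_in(rng_w, n, net.n_inh_per_side, n)
        e_ipsi = _collect(anf[h].trains, fan_ei, 0.0)
        e_contra = _collect(anf[contra].trains, fan_ec,
                            net.delay_contra_axonal)
        i_ipsi = _collect(gbc_trains[h].trains, fan_ii, net.delay_inh_ipsi)
        i_contra = _collect(gbc_trains[contra].trains, fan_ic,
                            net.contra_inh_delay_total)
        for j in range(n):
            exc_events.append(np.concatenate([e_ipsi[j], e_contra[j]]))
            inh_events.append(np.concatenate([i_ipsi[j], i_contra[j]]))
        exc_imp = _as_imp(exc_events, n_steps, n, dt, net.g_syn_e)
        inh_imp = _as_imp(inh_events, n_steps, n, dt, net.g_syn_i)
        spikes, _ = run_mso_population(
            mso, duration, exc_imp=exc_imp, inh_imp=inh_imp,
            tau_e=net.tau_e, tau_i1=net.tau_i1, tau_i2=net.tau_i2, dt=dt)
        mso_trains[h] = SpikeTrains(spikes, "MSO", h, net.cf, duration)

    return NetworkResult(anf=anf, gbc=gbc_trains, mso=mso_trains,
                         config=net, stim_duration=duration,
                         stim_pad=stim.pad, stim_core=stim.duration_core,
                         itd_applied=stim.itd_applied)


def itd_rate_curve(freq: float, itd_grid, net: NetworkConfig | None = None,
                   mso: MSOParams | None = None, *, duration: float = 0.1,
                   level: float = 50.0, dt: float = DT_DEFAULT):
    """Mean MSO population rate of both hemispheres at each ITD.

    Runs ``build_and_run`` once per ITD (fresh periphery noise per run,
    seeded from the network seed) and computes the population rate in the
    default analysis window.  Returns a pandas DataFrame with columns
    (itd, rate_left, rate_right).
    """
    import pandas as pd

    from .decoding import population_rate

    net = net or NetworkConfig(cf=freq)
    rows = []
    seeds = np.random.SeedSequence(net.rng_seed).generate_state(len(itd_grid))
    for itd, seed in zip(itd_grid, seeds):
        from .stimuli import make_tone
        stim = make_tone(freq, duration, level, itd=float(itd))
        res = build_and_run(stim, replace(net, rng_seed=int(seed) % 2**31),
                            mso=mso, dt=dt)
        w = res.analysis_window
        rows.append({
            "itd": float(itd),
            "rate_left": population_rate(res.mso["left"], w),
            "rate_right": population_rate(res.mso["right"], w),
        })
    return pd.DataFrame(rows)
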