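"""Auditory-nerve-fiber spike generation.

The default front end is a statistical surrogate of high-spontaneous-rate
ANF responses: a fourth-order gammatone filter at the characteristic
frequency, half-wave rectification, a low-pass cascade that rolls off
phase locking with frequency, a saturating (sigmoidal-in-dB) rate-level
stage, two multiplicative adaptation stages (rapid and short-term, giving
the onset overshoot), and per-fiber inhomogeneous Poisson sampling with an
absolute dead time.  The surrogate reproduces the response statistics that
drive the downstream circuit -- spontaneous and driven rates, vector
strength, interaural phase, onset adaptation -- not cochlear mechanics.

Any external cochlear model exposing the same ``anf_spikes`` signature
(stimulus, config, hemisphere -> SpikeTrains) can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.signal import lfilter

from .stimuli import BinauralStimulus, P_REF

CF_MIN = 120.0
CF_MAX = 1500.0


@dataclass
class SpikeTrains:
    """Spike times of one neuron population.

    ``trains`` holds one strictly-increasing array of spike times (s) per
    neuron; ``population`` is one of {"ANF", "GBC", "MSO"}.
    """

    trains: list
    population: str
    hemisphere: str
    cf: float
    duration: float

    @property
    def n_neurons(self) -> int:
        return len(self.trains)

    def pooled(self) -> np.ndarray:
        if not self.trains:
            return np.empty(0)
        return np.sort(np.concatenate(self.trains))

    def counts_in(self, start: float, end: float) -> np.ndarray:
        """Per-neuron spike counts inside [start, end)."""
        return np.array([np.count_nonzero((tr >= start) & (tr < end))
                         for tr in self.trains])

    def subset(self, idx) -> "SpikeTrains":
        return SpikeTrains([self.trains[i] for i in idx], self.population,
                           self.hemisphere, self.cf, self.duration)

    def validate(self, refractory: float = 0.0) -> None:
        for tr in self.trains:
            if len(tr) == 0:
                continue
            if tr[0] < 0 or tr[-1] > self.duration:
                raise ValueError("spike time outside [0, duration]")
            if len(tr) > 1:
                isi = np.diff(tr)
                if np.any(isi <= 0):
                    raise ValueError("spike times not strictly increasing")
                if refractory and np.any(isi < refractory - 1e-12):
                    raise ValueError("inter-spike interval below refractory")

    # -- serialization -------------------------------------------------
    def to_events(self, path) -> None:
        """Write a plain-text (time_s, neuron_id) event list."""
        with open(path, "w") as fh:
            fh.write(f"# population={self.population} "
                     f"hemisphere={self.hemisphere} cf={self.cf} "
                     f"duration={self.duration} n={self.n_neurons}\n")
            for j, tr in enumerate(self.trains):
                for t in tr:
                    fh.write(f"{t:.7f}\t{j}\n")

    @classmethod
    def from_events(cls, path) -> "SpikeTrains":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").split()
            meta = dict(kv.split("=") for kv in header)
            data = np.loadtxt(fh, ndmin=2)
        n = int(meta["n"])
        trains = [np.empty(0)] * n
        if data.size:
            ids = data[:, 1].astype(int)
            trains = [np.sort(data[ids == j, 0]) for j in range(n)]
        return cls(trains, meta["population"], meta["hemisphere"],
                   float(meta["cf"]), float(meta["duration"]))

    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            g = f.create_group("trains")
            for j, tr in enumerate(self.trains):
                g.create_dataset(str(j), data=np.asarray(tr))
            f.attrs.update(population=self.population,
                           hemisphere=self.hemisphere, cf=self.cf,
                           duration=self.duration, n=self.n_neurons)

    @classmethod
    def from_hdf5(cls, path) -> "SpikeTrains":
        import h5py
        with h5py.File(path, "r") as f:
            n = int(f.attrs["n"])
            trains = [f["trains"][str(j)][()] for j in range(n)]
            return cls(trains, str(f.attrs["population"]),
                       str(f.attrs["hemisphere"]), float(f.attrs["cf"]),
                       float(f.attrs["duration"]))


@dataclass
class PeripheryConfig:
    """Parameters of the ANF surrogate.

    Rates are in spikes/s; ``sat_rate`` is the unadapted driven rate at
    full saturation (onset rates approach it; fully adapted rates are
    lower by the product of the two depletion gains).
    ``rate_level_midpoint``/``spread`` place the sigmoidal rate-level
    function on the slow-envelope dB scale.  The two adaptation stages
    are (recovery time constant s, depletion strength).
    """

    fiber_count: int = 500
    cf: float = 500.0
    spont_rate: float = 60.0
    sat_rate: float = 1000.0
    rate_level_midpoint: float = 20.0   # dB SPL on the envelope scale
    rate_level_spread: float = 6.0      # dB
    phase_lock_cutoff: float = 1200.0   # Hz, one-pole cascade corner
    phase_lock_order: int = 4
    env_cutoff: float = 50.0            # Hz, envelope extractor
    duty_offset_db: float = 3.0         # fine-structure gate re envelope
    duty_spread_db: float = 1.0
    tau_rapid: float = 0.010            # s
    beta_rapid: float = 1.2
    tau_short: float = 0.080            # s
    beta_short: float = 0.4
    refractory: float = 0.75e-3         # s, absolute dead time
    rng_seed: int = 0

    def __post_init__(self):
        if not CF_MIN <= self.cf <= CF_MAX:
            raise ValueError(
                f"cf={self.cf} Hz outside surrogate filterbank range "
                f"[{CF_MIN:g}, {CF_MAX:g}] Hz")
        if min(self.spont_rate, self.sat_rate) < 0:
            raise ValueError("rates must be non-negative")


@njit(cache=True)
def _adaptation_gain(s, dt, tau, beta):
    """Exact stepwise solution of g' = (1 - g)/tau - beta*s*g/tau."""
    n = s.shape[0]
    g = np.empty(n)
    x = 1.0
    for i in range(n):
        a = (1.0 + beta * s[i]) / tau
        e = np.exp(-dt * a)
        x = x * e + (1.0 / tau) * (1.0 - e) / a
        g[i] = x
    return g


def erb(freq: float) -> float:
    """Equivalent rectangular bandwidth (Hz) of the auditory filter."""
    return 24.7 * (4.37 * freq / 1000.0 + 1.0)


def gammatone_filter(wave: np.ndarray, cf: float, fs: float,
                     order: int = 4) -> np.ndarray:
    """Fourth-order gammatone bandpass at ``cf``, unity gain at cf.

    Realized as a cascade of identical complex one-pole filters (the
    numerically stable form; a direct high-order polynomial realization
    is unstable at low cf relative to fs).  Returns the real part.
    """
    bw = 1.019 * erb(cf)
    pole = np.exp((-2 * np.pi * bw + 2j * np.pi * cf) / fs)
    y = wave.astype(complex)
    for _ in range(order):
        y = lfilter([1.0], [1.0, -pole], y)
    wc = 2 * np.pi * cf / fs
    gain = (1.0 / (1.0 - pole * np.exp(-1j * wc))) ** order
    return 2.0 * np.real(y / gain)


def instantaneous_rate(wave: np.ndarray, fs: float,
                       cfg: PeripheryConfig) -> np.ndarray:
    """Instantaneous firing rate (spikes/s) driven by one ear's waveform.

    The half-wave-rectified gammatone output is split into a slow
    envelope (one-pole at ``env_cutoff``) that sets the overall driven
    rate through a sigmoidal-in-dB rate-level function, and a fast
    fine-structure path (low-pass cascade at ``phase_lock_cutoff``) that
    gates firing to the depolarizing phase.  The gate threshold rides a
    few dB above the envelope, so phase locking is sharp at low
    frequencies and fades as the low-pass cascade flattens the fine
    structure -- the vector-strength roll-off of real ANFs.  Two
    multiplicative depletion stages add rapid and short-term adaptation.
    """
    x = gammatone_filter(wave, cfg.cf, fs)
    x = np.maximum(x, 0.0)
    d = x.copy()
    lp = np.exp(-2 * np.pi * cfg.phase_lock_cutoff / fs)
    for _ in range(cfg.phase_lock_order):
        d = lfilter([1.0 - lp], [1.0, -lp], d)
    le = np.exp(-2 * np.pi * cfg.env_cutoff / fs)
    env = lfilter([1.0 - le], [1.0, -le], x)
    db_d = 20.0 * np.log10(np.maximum(d, 1e-12) / P_REF)
    db_env = 20.0 * np.log10(np.maximum(env, 1e-12) / P_REF)
    s_rate = 1.0 / (1.0 + np.exp(-(db_env - cfg.rate_level_midpoint)
                                 / cfg.rate_level_spread))
    duty = 1.0 / (1.0 + np.exp(-(db_d - db_env - cfg.duty_offset_db)
                               / cfg.duty_spread_db))
    # mean-normalized gate: concentrates spikes into the depolarizing
    # phase without changing the mean driven rate, so synchrony fades at
    # high cf while the rate-level function is cf-independent
    mean_duty = lfilter([1.0 - le], [1.0, -le], duty)
    drive = duty / np.maximum(mean_duty, 0.05)
    dt = 1.0 / fs
    gain = (_adaptation_gain(s_rate, dt, cfg.tau_rapid, cfg.beta_rapid)
            * _adaptation_gain(s_rate, dt, cfg.tau_short, cfg.beta_short))
    # driven activity displaces spontaneous firing rather than adding to it
    return (cfg.spont_rate * (1.0 - s_rate)
            + cfg.sat_rate * s_rate * gain * drive)


def _sample_train(rate, dt, dead, rng) -> np.ndarray:
    """One inhomogeneous-Poisson train with absolute dead time."""
    cum = np.cumsum(rate) * dt
    total = cum[-1]
    n_draw = int(total + 4.0 * np.sqrt(total + 1.0) + 10)
    arr = np.cumsum(rng.exponential(size=n_draw))
    while arr[-1] < total:  # pragma: no cover - margin almost always enough
        arr = np.concatenate([arr, arr[-1] + np.cumsum(
            rng.exponential(size=n_draw))])
    arr = arr[arr < total]
    t_grid = (np.arange(len(rate)) + 1) * dt
    times = np.interp(arr, cum, t_grid)
    from ._kernels import enforce_dead_time
    return enforce_dead_time(times, dead)


def anf_spikes(stim: BinauralStimulus, cfg: PeripheryConfig,
               hemisphere: str) -> SpikeTrains:
    """Generate the ANF population response of one ear.

    Fibers are independent inhomogeneous point processes sharing the
    deterministic instantaneous-rate profile of their ear's waveform.
    Reproducible: the same (stimulus, config, hemisphere) triple yields
    identical trains.
    """
    if hemisphere not in ("left", "right"):
        raise ValueError("hemisphere must be 'left' or 'right'")
    wave = stim.left if hemisphere == "left" else stim.right
    rate = instantaneous_rate(wave, stim.fs, cfg)
    dt = 1.0 / stim.fs
    root = np.random.SeedSequence(cfg.rng_seed,
                                  spawn_key=(0 if hemisphere == "left" else 1,))
    trains = [
        _sample_train(rate, dt, cfg.refractory, np.random.default_rng(ss))
        for ss in root.spawn(cfg.fiber_count)
    ]
    return SpikeTrains(trains, "ANF", hemisphere, cfg.cf, stim.duration)


def vector_strength(spikes, freq: float) -> float:
    """Phase-locking strength of a spike train to ``freq`` (Hz), in [0,1]."""
    spikes = np.asarray(spikes)
    if spikes.size < 2:
        raise ValueError("vector strength needs at least 2 spikes")
    ph = 2 * np.pi * freq * spikes
    return float(np.abs(np.mean(np.exp(1j * ph))))


def mean_phase(spikes, freq: float) -> float:
    """Circular-mean phase (rad) of spike times w.r.t. ``freq``."""
    spikes = np.asarray(spikes)
    if spikes.size < 2:
        raise ValueError("mean phase needs at least 2 spikes")
    return float(np.angle(np.mean(np.exp(2j * np.pi * freq * spikes))))
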