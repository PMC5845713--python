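"""Binaural stimulus synthesis and conditioning.

All stimuli live at a fixed internal sampling rate of 100 kHz.  A conditioned
stimulus consists of a *core* signal (gated with 20 ms raised-cosine ramps)
surrounded by silent padding on both sides.  Levels are expressed in dB SPL
re 20 uPa and calibrated against the RMS of the ungated plateau, so the peak
amplitude of a tone at level L is sqrt(2) * 20e-6 * 10**(L/20) pascal.

Interaural time differences (ITDs) follow the convention: positive ITD means
the right-ear signal leads (the left channel is delayed).  Sub-sample ITDs
are imposed in the frequency domain by adding a linear phase to each channel
(+itd/2 delay on the left, -itd/2 on the right), which keeps the binaural
midpoint fixed and is exactly invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

FS = 100_000.0
"""Internal sampling rate (Hz)."""

P_REF = 20e-6
"""SPL reference pressure (Pa)."""

DEFAULT_GATE = 0.020
DEFAULT_PAD = 0.020


@dataclass
class BinauralStimulus:
    """Two synchronized pressure waveforms with calibration metadata.

    Attributes
    ----------
    left, right : ndarray
        Pressure waveforms in Pa, equal length, at sampling rate ``fs``.
    fs : float
        Sampling rate in Hz (100 kHz after conditioning).
    itd_applied : float
        Net ITD imposed on the pair, seconds.  Positive = right leading.
    level_db_spl : float
        Calibrated level of the ungated core plateau, dB SPL.
    duration_core : float
        Core signal duration in seconds (gating ramps included, padding
        excluded).
    pad : float
        Duration of the silent padding at each end, seconds.
    """

    left: np.ndarray
    right: np.ndarray
    fs: float
    itd_applied: float
    level_db_spl: float
    duration_core: float
    pad: float = DEFAULT_PAD

    def __post_init__(self):
        if len(self.left) != len(self.right):
            raise ValueError("left and right channels must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.left)

    @property
    def duration(self) -> float:
        """Total duration including padding, seconds."""
        return self.n_samples / self.fs

    @property
    def core_window(self) -> tuple[float, float]:
        """(start, end) of the core segment in seconds."""
        return (self.pad, self.pad + self.duration_core)

    def swapped(self) -> "BinauralStimulus":
        """Return the stimulus with left and right channels exchanged."""
        return replace(
            self,
            left=self.right.copy(),
            right=self.left.copy(),
            itd_applied=-self.itd_applied,
        )

    def save(self, path) -> None:
        np.savez(
            path,
            left=self.left,
            right=self.right,
            fs=self.fs,
            itd_applied=self.itd_applied,
            level_db_spl=self.level_db_spl,
            duration_core=self.duration_core,
            pad=self.pad,
        )

    @classmethod
    def load(cls, path) -> "BinauralStimulus":
        d = np.load(path)
        return cls(
            left=d["left"],
            right=d["right"],
            fs=float(d["fs"]),
            itd_applied=float(d["itd_applied"]),
            level_db_spl=float(d["level_db_spl"]),
            duration_core=float(d["duration_core"]),
            pad=float(d["pad"]),
        )


def _raised_cosine_gate(n_core: int, gate: float, fs: float) -> np.ndarray:
    n_gate = int(round(gate * fs))
    win = np.ones(n_core)
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_gate) / n_gate))
    win[:n_gate] = ramp
    win[n_core - n_gate:] = ramp[::-1]
    return win


def _condition(core: np.ndarray, level_db_spl: float, gate: float,
               pad: float, fs: float = FS) -> np.ndarray:
    """Calibrate, gate and pad a mono core signal.

    Calibration scales the signal so the RMS of the *ungated* core equals
    the target SPL; the raised-cosine ramps are applied afterwards.
    """
    rms = np.sqrt(np.mean(core**2))
    if rms <= 0:
        raise ValueError("cannot calibrate a zero-energy signal")
    target = P_REF * 10.0 ** (level_db_spl / 20.0)
    scaled = core * (target / rms)
    gated = scaled * _raised_cosine_gate(len(core), gate, fs)
    n_pad = int(round(pad * fs))
    return np.concatenate([np.zeros(n_pad), gated, np.zeros(n_pad)])


def _check_tone_args(freq: float, duration: float, gate: float) -> None:
    if duration <= 0:
        raise ValueError("duration must be positive")
    if freq <= 0 or freq >= FS / 2:
        raise ValueError(f"frequency must lie in (0, {FS / 2:g}) Hz")
    if duration < 2 * gate:
        raise ValueError("duration must cover both gating ramps")


def make_tone(freq: float, duration: float, level: float = 50.0, *,
              itd: float = 0.0, gate: float = DEFAULT_GATE,
              pad: float = DEFAULT_PAD) -> BinauralStimulus:
    """Synthesize a diotic pure tone, optionally with an imposed ITD.

    Parameters
    ----------
    freq : float
        Tone frequency, Hz (must be below Nyquist).
    duration : float
        Core duration in seconds, gating ramps included (>= 2 * gate).
    level : float
        Level of the ungated plateau, dB SPL.
    itd : float
        ITD in seconds applied after conditioning (positive = right leading).
    """
    _check_tone_args(freq, duration, gate)
    t = np.arange(int(round(duration * FS))) / FS
    core = np.sin(2 * np.pi * freq * t)
    ch = _condition(core, level, gate, pad)
    stim = BinauralStimulus(ch, ch.copy(), FS, 0.0, level, duration, pad)
    if itd != 0.0:
        stim = apply_itd(stim, itd)
    return stim


def make_am_tone(carrier: float, mod_rate: float, depth: float = 1.0,
                 duration: float = 1.0, level: float = 50.0, *,
                 itd: float = 0.0, gate: float = DEFAULT_GATE,
                 pad: float = DEFAULT_PAD) -> BinauralStimulus:
    """Sinusoidally amplitude-modulated tone (e.g. 400 Hz carrier, 2 Hz AM)."""
    _check_tone_args(carrier, duration, gate)
    if not 0.0 <= depth <= 1.0:
        raise ValueError("modulation depth must lie in [0, 1]")
    t = np.arange(int(round(duration * FS))) / FS
    env = 1.0 + depth * np.sin(2 * np.pi * mod_rate * t - np.pi / 2)
    core = env * np.sin(2 * np.pi * carrier * t)
    ch = _condition(core, level, gate, pad)
    stim = BinauralStimulus(ch, ch.copy(), FS, 0.0, level, duration, pad)
    if itd != 0.0:
        stim = apply_itd(stim, itd)
    return stim


def make_chirp(f0: float, f1: float, duration: float = 1.0,
               level: float = 50.0, *, itd_start: float = 0.0,
               itd_end: float = 0.0, gate: float = DEFAULT_GATE,
               pad: float = DEFAULT_PAD) -> BinauralStimulus:
    """Linear chirp with an optionally time-varying ITD.

    The right channel carries the plain chirp.  The time-varying ITD is
    realized as an instantaneous-phase offset on the left channel:
    phi_L(t) = phi(t) - 2*pi*f(t)*itd(t), which delays the left-ear fine
    structure by itd(t) (positive = right leading) for slowly varying
    trajectories.
    """
    _check_tone_args(min(f0, f1), duration, gate)
    if max(f0, f1) >= FS / 2:
        raise ValueError("chirp endpoint above Nyquist")
    n = int(round(duration * FS))
    t = np.arange(n) / FS
    f_inst = f0 + (f1 - f0) * t / duration
    phase = 2 * np.pi * (f0 * t + 0.5 * (f1 - f0) * t**2 / duration)
    itd_traj = itd_start + (itd_end - itd_start) * t / duration
    right = np.sin(phase)
    left = np.sin(phase - 2 * np.pi * f_inst * itd_traj)
    gate_win = _raised_cosine_gate(n, gate, FS)
    target = P_REF * 10.0 ** (level / 20.0)
    scale = target / np.sqrt(0.5)  # unit-amplitude sine RMS
    n_pad = int(round(pad * FS))
    z = np.zeros(n_pad)
    left = np.concatenate([z, left * gate_win * scale, z])
    right = np.concatenate([z, right * gate_win * scale, z])
    mean_itd = 0.5 * (itd_start + itd_end)
    stim = BinauralStimulus(left, right, FS, mean_itd, level, duration, pad)
    stim.itd_trajectory = itd_traj  # true per-sample ITD of the core
    return stim


def _fft_delay(x: np.ndarray, delay: float, fs: float) -> np.ndarray:
    """Delay a signal by an arbitrary (sub-sample) amount via linear phase."""
    n = len(x)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    return np.fft.irfft(spec * np.exp(-2j * np.pi * f * delay), n=n)


def apply_itd(stim: BinauralStimulus, itd: float) -> BinauralStimulus:
    """Impose an ITD by symmetric frequency-domain linear phase shifts.

    The left channel is delayed by +itd/2 and the right by -itd/2, so
    positive ``itd`` makes the right ear lead while the binaural midpoint
    stays fixed.  Energy per channel is preserved exactly (|FFT| unchanged)
    and the operation is invertible: ``apply_itd(apply_itd(s, t), -t)``
    recovers ``s``.
    """
    if abs(itd) / 2 >= stim.pad:
        raise ValueError("|itd|/2 must be smaller than the padding duration")
    left = _fft_delay(stim.left, +itd / 2, stim.fs)
    right = _fft_delay(stim.right, -itd / 2, stim.fs)
    return replace(stim, left=left, right=right,
                   itd_applied=stim.itd_applied + itd)


def load_audio(path, target_level: float = 50.0, *, itd: float = 0.0,
               gate: float = DEFAULT_GATE, pad: float = DEFAULT_PAD,
               max_duration: float | None = None) -> BinauralStimulus:
    """Load a WAV file, resample to 100 kHz, gate, pad and calibrate.

    Mono files are duplicated to both ears; stereo files keep their
    channels.  Resampling uses a band-limited polyphase filter (Kaiser
    window).  Integer PCM is scaled to [-1, 1] before calibration; the
    common calibration factor is derived from the two-channel RMS so any
    interaural level cue in the file is preserved.
    """
    rate, data = wavfile.read(path)
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 1:
        data = np.stack([data, data], axis=1)
    elif data.shape[1] > 2:
        raise ValueError("only mono or stereo WAV files are supported")
    if max_duration is not None:
        data = data[: int(max_duration * rate)]
    if not np.any(data):
        raise ValueError("audio file contains no signal")
    if rate != FS:
        up, down = (np.array([FS, rate]) /
                    np.gcd(int(FS), int(rate))).astype(int)
        data = resample_poly(data, up, down, axis=0, window=("kaiser", 5.0))
    rms = np.sqrt(np.mean(data**2))
    target = P_REF * 10.0 ** (target_level / 20.0)
    data *= target / rms
    n = data.shape[0]
    gate_win = _raised_cosine_gate(n, gate, FS)
    n_pad = int(round(pad * FS))
    z = np.zeros(n_pad)
    left = np.concatenate([z, data[:, 0] * gate_win, z])
    right = np.concatenate([z, data[:, 1] * gate_win, z])
    stim = BinauralStimulus(left, right, FS, 0.0, target_level, n / FS, pad)
    if itd != 0.0:
        stim = apply_itd(stim, itd)
    return stim
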