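"""Stimulus synthesis, calibration and sub-sample ITD imposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.io import wavfile

from mso_itd.stimuli import (FS, P_REF, BinauralStimulus, apply_itd,
                             load_audio, make_am_tone, make_chirp, make_tone)


def spectral_peak(x, fs):
    spec = np.abs(np.fft.rfft(x))
    return np.fft.rfftfreq(len(x), 1 / fs)[np.argmax(spec)]


class TestMakeTone:
    def test_total_length_includes_padding(self):
        s = make_tone(250.0, 0.1, 50.0)
        assert s.n_samples == 14000  # 20 + 100 + 20 ms at 100 kHz
        assert s.fs == 100000

    def test_plateau_amplitude_matches_spl(self):
        s = make_tone(250.0, 0.1, 50.0)
        plateau = s.left[5000:9000]
        expected_peak = np.sqrt(2) * P_REF * 10 ** (50 / 20)
        assert np.max(np.abs(plateau)) == pytest.approx(expected_peak,
                                                        rel=1e-3)
        rms_db = 20 * np.log10(np.sqrt(np.mean(plateau**2)) / P_REF)
        assert abs(rms_db - 50.0) < 0.1

    def test_spectral_peak_at_tone_frequency(self):
        s = make_tone(250.0, 0.1, 50.0)
        core = s.left[2000:12000]
        assert spectral_peak(core, s.fs) == pytest.approx(250.0, abs=10.0)

    def test_gating_leaves_plateau_untouched(self):
        s = make_tone(250.0, 0.1, 50.0)
        t = np.arange(10000) / FS
        raw = np.sin(2 * np.pi * 250 * t)
        raw *= np.sqrt(2) * P_REF * 10 ** (50 / 20)
        plateau = slice(2000 + 2000, 2000 + 8000)
        assert np.allclose(s.left[plateau], raw[2000:8000], atol=1e-12)

    @pytest.mark.parametrize("bad", [
        dict(freq=-10.0, duration=0.1),
        dict(freq=60000.0, duration=0.1),
        dict(freq=250.0, duration=0.0),
        dict(freq=250.0, duration=0.03),  # shorter than the two ramps
    ])
    def test_rejects_invalid_arguments(self, bad):
        with pytest.raises(ValueError):
            make_tone(level=50.0, **bad)


class TestApplyITD:
    def test_zero_itd_is_identity(self, tone_250):
        out = apply_itd(tone_250, 0.0)
        assert np.allclose(out.left, tone_250.left, atol=1e-12)

    def test_cross_correlation_peaks_at_applied_itd(self, tone_250):
        itd = 250e-6
        out = apply_itd(tone_250, itd)
        lags = np.arange(-100, 101)
        xc = [np.dot(out.left[5000:9000], out.right[5000 + k:9000 + k])
              for k in lags]
        # positive ITD = right leads = left delayed: left(t) ~ right(t - itd)
        assert lags[np.argmax(xc)] == pytest.approx(-itd * FS, abs=1)

    def test_mirror_symmetry(self, tone_250):
        plus = apply_itd(tone_250, 200e-6)
        minus = apply_itd(tone_250, -200e-6)
        assert np.allclose(plus.left, minus.right, atol=1e-9)
        assert np.allclose(plus.right, minus.left, atol=1e-9)

    def test_energy_preserved_per_channel(self, tone_250):
        out = apply_itd(tone_250, 330e-6)
        assert np.allclose(np.abs(np.fft.rfft(out.left)),
                           np.abs(np.fft.rfft(tone_250.left)), atol=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(itd=st.floats(min_value=-900e-6, max_value=900e-6))
    def test_round_trip_recovers_input(self, itd):
        s = make_tone(330.0, 0.06, 40.0)
        back = apply_itd(apply_itd(s, itd), -itd)
        scale = np.max(np.abs(s.left))
        assert np.allclose(back.left, s.left, atol=1e-9 * scale)
        assert np.allclose(back.right, s.right, atol=1e-9 * scale)

    def test_rejects_itd_larger_than_padding(self, tone_250):
        with pytest.raises(ValueError):
            apply_itd(tone_250, 45e-3)


class TestOtherStimuli:
    def test_am_tone_envelope_rate(self):
        s = make_am_tone(400.0, 4.0, 1.0, duration=0.5, level=50.0)
        env = np.abs(s.left[2000:52000])
        # count envelope minima: 4 Hz modulation over 0.5 s -> 2 cycles
        spec = np.abs(np.fft.rfft(env - env.mean()))
        f = np.fft.rfftfreq(len(env), 1 / FS)
        assert f[np.argmax(spec)] == pytest.approx(4.0, abs=1.0)

    def test_chirp_sweeps_frequency(self):
        s = make_chirp(125.0, 1000.0, duration=1.0, level=50.0)
        early = spectral_peak(s.left[3000:13000], FS)
        late = spectral_peak(s.left[90000:100000], FS)
        assert early < 350 and late > 700

    def test_chirp_time_varying_itd_tracks_trajectory(self):
        s = make_chirp(300.0, 300.0, duration=0.5, level=50.0,
                       itd_start=300e-6, itd_end=300e-6)
        # constant trajectory: left should lag right by ~300 us everywhere
        lags = np.arange(-60, 61)
        xc = [np.dot(s.left[20000:30000], s.right[20000 + k:30000 + k])
              for k in lags]
        assert lags[np.argmax(xc)] == pytest.approx(-30, abs=2)


class TestLoadAudio:
    def test_mono_file_resampled_and_duplicated(self, tmp_path):
        rate = 44100
        t = np.arange(rate) / rate
        wav = (0.5 * np.sin(2 * np.pi * 300 * t) * 32767).astype(np.int16)
        path = tmp_path / "tone.wav"
        wavfile.write(path, rate, wav)
        s = load_audio(path, 50.0)
        assert s.n_samples == 100000 + 2 * 2000
        assert np.allclose(s.left, s.right)
        assert spectral_peak(s.left[5000:95000], FS) == pytest.approx(
            300.0, abs=5.0)

    def test_silent_file_rejected(self, tmp_path):
        path = tmp_path / "silent.wav"
        wavfile.write(path, 44100, np.zeros(44100, dtype=np.int16))
        with pytest.raises(ValueError):
            load_audio(path, 50.0)


def test_save_load_round_trip(tmp_path, tone_250):
    p = tmp_path / "stim.npz"
    tone_250.save(p)
    back = BinauralStimulus.load(p)
    assert np.allclose(back.left, tone_250.left)
    assert back.level_db_spl == tone_250.level_db_spl
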