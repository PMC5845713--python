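"""MLP predictor: features, training-set construction, optimization."""

import numpy as np
import pytest

from mso_itd.ann import (FEATURE_COLS, MLPModel, extract_features,
                         generate_training_set, predict, split_by_tone,
                         train)
from mso_itd.network import NetworkConfig, NetworkResult
from mso_itd.periphery import SpikeTrains


def stub_result(duration=0.21, rate_mso_l=100.0, rate_mso_r=200.0,
                rate_anf=500.0, cf=400.0, n=10):
    """NetworkResult with constant-rate regular spike trains."""
    def pop(rate, label, hemi):
        trains = [np.arange(0.0, duration, 1.0 / rate) + j * 1e-5
                  for j in range(n)]
        return SpikeTrains(trains, label, hemi, cf, duration)
    return NetworkResult(
        anf={"left": pop(rate_anf, "ANF", "left"),
             "right": pop(rate_anf, "ANF", "right")},
        gbc={"left": pop(50.0, "GBC", "left"),
             "right": pop(50.0, "GBC", "right")},
        mso={"left": pop(rate_mso_l, "MSO", "left"),
             "right": pop(rate_mso_r, "MSO", "right")},
        config=NetworkConfig(n_per_population=n, cf=cf),
        stim_duration=duration, stim_pad=0.02, stim_core=duration - 0.04,
        itd_applied=0.0)


class TestExtractFeatures:
    def test_frame_count_is_floor_of_duration(self):
        df = extract_features(stub_result(duration=0.21))
        assert len(df) == 7  # floor(0.21 / 0.03)

    def test_constant_rates_give_identical_frames_after_first(self):
        df = extract_features(stub_result())
        body = df.iloc[1:][["mso_l", "mso_r", "anf"]]
        assert body.nunique().max() == 1
        assert df.iloc[0].first_frame
        assert df.iloc[0][["mso_l_prev", "mso_r_prev", "anf_prev"]].eq(
            0.0).all()

    def test_rates_match_population_rate(self):
        df = extract_features(stub_result(rate_mso_l=100.0))
        assert df.iloc[2].mso_l == pytest.approx(100.0, rel=0.05)

    def test_too_short_simulation_rejected(self):
        with pytest.raises(ValueError):
            extract_features(stub_result(duration=0.05))


@pytest.fixture(scope="module")
def tiny_set():
    return generate_training_set(n_tones=4, n_neurons=10, seed=6)


class TestTrainingSet:
    def test_fourteen_bins_per_tone(self, tiny_set):
        x, y, tid = tiny_set
        assert len(x) == 4 * 14  # (300 + 2*60) ms / 30 ms
        assert x.shape[1] == len(FEATURE_COLS) == 7

    def test_exists_labels_mark_edge_bins(self, tiny_set):
        _, y, tid = tiny_set
        for tone in np.unique(tid):
            exists = y[tid == tone, 1]
            assert list(exists[:2]) == [-1.0, -1.0]
            assert list(exists[-2:]) == [-1.0, -1.0]
            assert np.all(exists[2:-2] == 1.0)

    def test_itd_target_constant_within_tone(self, tiny_set):
        _, y, tid = tiny_set
        for tone in np.unique(tid):
            itds = y[tid == tone, 0]
            assert np.ptp(itds) == 0.0
            assert abs(itds[0]) <= 500e-6

    def test_generation_reproducible(self):
        a = generate_training_set(n_tones=2, n_neurons=8, seed=9)
        b = generate_training_set(n_tones=2, n_neurons=8, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_split_fractions(self):
        tid = np.repeat(np.arange(50), 14)
        tr, va, te = split_by_tone(tid, 0)
        assert tr.sum() + va.sum() + te.sum() == len(tid)
        assert len(np.unique(tid[tr])) == 40
        assert len(np.unique(tid[va])) == 5


def linear_toy(n=3000, seed=0):
    """Synthetic rate->ITD mapping the MLP must learn easily."""
    rng = np.random.default_rng(seed)
    itd = rng.uniform(-500e-6, 500e-6, n)
    base = rng.uniform(40, 80, n)
    x = np.column_stack([
        base - 2e4 * itd, base + 2e4 * itd, np.full(n, 150.0),
        base - 2e4 * itd, base + 2e4 * itd, np.full(n, 150.0),
        np.full(n, 400.0)])
    x += rng.normal(0, 0.5, x.shape)
    y = np.column_stack([itd, np.ones(n)])
    return x, y


class TestTraining:
    def test_learns_linear_mapping(self):
        x, y = linear_toy()
        model = train(x, y, seed=1, max_epochs=300)
        _, va, _ = split_by_tone(np.arange(len(x)), 1)
        pred = model.forward(x[va])
        resid = np.std(pred[:, 0] - y[va, 0])
        assert resid < 0.2 * np.std(y[va, 0])

    def test_training_is_deterministic(self):
        x, y = linear_toy(800)
        a = train(x, y, seed=2, max_epochs=40, patience=5)
        b = train(x, y, seed=2, max_epochs=40, patience=5)
        assert np.array_equal(a.w1, b.w1) and np.array_equal(a.w2, b.w2)

    def test_architecture_is_7_20_2(self):
        x, y = linear_toy(500)
        m = train(x, y, seed=3, max_epochs=10, patience=3)
        assert m.w1.shape == (7, 20) and m.w2.shape == (20, 2)

    def test_model_round_trip(self, tmp_path):
        x, y = linear_toy(500)
        m = train(x, y, seed=3, max_epochs=10, patience=3)
        p = tmp_path / "model.npz"
        m.save(p)
        back = MLPModel.load(p)
        assert np.array_equal(back.w1, m.w1)
        assert np.allclose(back.forward(x[:10]), m.forward(x[:10]))


class TestPredict:
    def test_untrained_model_rejected(self, tone_250):
        m = MLPModel(w1=None, b1=None, w2=None, b2=None,
                     x_mean=np.zeros(7), x_std=np.ones(7))
        with pytest.raises(ValueError):
            predict(m, tone_250)

    def test_cf_outside_trained_range_rejected(self, tone_250):
        x, y = linear_toy(500)
        m = train(x, y, seed=3, max_epochs=10, patience=3)
        with pytest.raises(ValueError):
            predict(m, tone_250, cf_grid=[2000.0], n_neurons=5)
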