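"""Multilayer-perceptron ITD predictor operating on population rates.

A small fully-connected network (7 inputs, one hidden layer of 20 tanh
units, 2 tanh outputs) regresses the ITD of a 30 ms signal frame from
the mean firing rates of the left and right MSO populations, the left
ANF population, the same three rates of the previous frame, and the
characteristic frequency of the simulated channel.  The first output is
the ITD estimate (scaled to [-1, 1] over +-1 ms); the second is a
signal-exists score trained to -1 on silent frames and +1 on frames
containing the tone, which gates unreliable predictions (score <= 0) at
inference so that cross-frequency averages only include channels that
actually carry signal energy.

Training data are pure tones with random level, frequency and ITD
processed through the full spiking network in the on-frequency channel
(cf = tone frequency); the cf input lets a single network serve the
whole 125-1000 Hz range.  Optimization is full-batch-shuffled
mini-batch Adam on the mean squared error with early stopping when the
relative improvement of the validation error stays below 0.01% for a
patience window.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .decoding import population_rate
from .network import NetworkConfig, build_and_run
from .stimuli import BinauralStimulus, make_tone

BIN_WIDTH = 0.030
N_HIDDEN = 20
CF_RANGE = (125.0, 1000.0)
ITD_SCALE = 1e-3
"""ITD mapped to [-1, 1] over +-1 ms for the tanh-bounded output."""


def extract_features(result, bin_width: float = BIN_WIDTH) -> pd.DataFrame:
    """Per-bin feature rows from one network run.

    Columns: t (bin start, s), mso_l, mso_r, anf (current-bin rates,
    spikes/s), mso_l_prev, mso_r_prev, anf_prev (previous bin; zero-filled
    and flagged on the first frame), cf.  The monaural ANF input is taken
    from the left hemisphere.
    """
    n_bins = int(np.floor(result.stim_duration / bin_width + 1e-9))
    if n_bins < 2:
        raise ValueError("simulation must cover at least two bins")
    rates = {}
    for key, trains in (("mso_l", result.mso["left"]),
                        ("mso_r", result.mso["right"]),
                        ("anf", result.anf["left"])):
        rates[key] = np.array([
            population_rate(trains, (b * bin_width, (b + 1) * bin_width))
            for b in range(n_bins)])
    rows = []
    for b in range(n_bins):
        prev = {k: (rates[k][b - 1] if b > 0 else 0.0) for k in rates}
        rows.append({
            "t": b * bin_width,
            "mso_l": rates["mso_l"][b], "mso_r": rates["mso_r"][b],
            "anf": rates["anf"][b],
            "mso_l_prev": prev["mso_l"], "mso_r_prev": prev["mso_r"],
            "anf_prev": prev["anf"],
            "cf": result.config.cf,
            "first_frame": b == 0,
        })
    return pd.DataFrame(rows)


FEATURE_COLS = ["mso_l", "mso_r", "anf", "mso_l_prev", "mso_r_prev",
                "anf_prev", "cf"]


def generate_training_set(n_tones: int = 2000, *, n_neurons: int = 500,
                          seed: int = 0, tone_duration: float = 0.3,
                          pad: float = 0.06, level_range=(30.0, 70.0),
                          freq_range=CF_RANGE, itd_max: float = 500e-6,
                          bin_width: float = BIN_WIDTH):
    """Simulate the tone corpus and return (features, targets, tone_id).

    Each tone is ``tone_duration`` long, padded with ``pad`` of silence,
    with level ~ U(level_range) dB SPL, frequency ~ U(freq_range) Hz and
    ITD ~ U(-itd_max, +itd_max); the network channel is tuned to the tone
    frequency.  Targets per frame are (itd_s, exists) with exists = -1
    for the two bins at each end of the signal (they contain silence)
    and +1 elsewhere.  The conventional split by tone is 80% train, 10%
    validation, 10% test (see ``split_by_tone``).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    feats, targs, tone_ids = [], [], []
    for tone in range(n_tones):
        freq = rng.uniform(*freq_range)
        level = rng.uniform(*level_range)
        itd = rng.uniform(-itd_max, itd_max)
        stim = make_tone(freq, tone_duration, level, itd=itd, pad=pad)
        net = NetworkConfig(n_per_population=n_neurons, cf=freq,
                            rng_seed=int(rng.integers(2**31)))
        res = build_and_run(stim, net)
        df = extract_features(res, bin_width)
        n_bins = len(df)
        exists = np.ones(n_bins)
        exists[:2] = -1.0
        exists[-2:] = -1.0
        feats.append(df[FEATURE_COLS].to_numpy())
        targs.append(np.column_stack([np.full(n_bins, itd), exists]))
        tone_ids.append(np.full(n_bins, tone))
    return (np.concatenate(feats), np.concatenate(targs),
            np.concatenate(tone_ids))


def split_by_tone(tone_ids, seed: int = 0):
    """Boolean masks (train, val, test) with an 80/10/10 split by tone."""
    tones = np.unique(tone_ids)
    rng = np.random.default_rng(np.random.SeedSequence(seed,
                                                       spawn_key=(7,)))
    perm = rng.permutation(tones)
    n = len(tones)
    n_train = int(round(0.8 * n))
    n_val = int(round(0.1 * n))
    sets = (set(perm[:n_train]), set(perm[n_train:n_train + n_val]),
            set(perm[n_train + n_val:]))
    return tuple(np.isin(tone_ids, sorted(s)) for s in sets)


@dataclass
class MLPModel:
    """Trained 7-20-2 tanh perceptron with its scaling parameters."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    cf_range: tuple = CF_RANGE
    itd_scale: float = ITD_SCALE
    loss_curve: np.ndarray = field(default_factory=lambda: np.empty(0))
    stop_epoch: int = 0
    seed: int = 0

    def _scale_x(self, x):
        x = np.asarray(x, dtype=float)
        z = (x - self.x_mean) / self.x_std
        lo, hi = self.cf_range
        z[:, 6] = 2.0 * (np.log(x[:, 6] / lo) / np.log(hi / lo)) - 1.0
        return z

    def forward(self, x_raw):
        """(itd_s, signal_score) for raw feature rows."""
        z = self._scale_x(x_raw)
        h = np.tanh(z @ self.w1 + self.b1)
        out = np.tanh(h @ self.w2 + self.b2)
        return np.column_stack([out[:, 0] * self.itd_scale, out[:, 1]])

    def save(self, path) -> None:
        np.savez(path, w1=self.w1, b1=self.b1, w2=self.w2, b2=self.b2,
                 x_mean=self.x_mean, x_std=self.x_std,
                 cf_range=np.array(self.cf_range),
                 itd_scale=self.itd_scale, loss_curve=self.loss_curve,
                 stop_epoch=self.stop_epoch, seed=self.seed)

    @classmethod
    def load(cls, path) -> "MLPModel":
        d = np.load(path)
        return cls(w1=d["w1"], b1=d["b1"], w2=d["w2"], b2=d["b2"],
                   x_mean=d["x_mean"], x_std=d["x_std"],
                   cf_range=tuple(d["cf_range"]),
                   itd_scale=float(d["itd_scale"]),
                   loss_curve=d["loss_curve"],
                   stop_epoch=int(d["stop_epoch"]), seed=int(d["seed"]))


def _scaled_targets(y):
    return np.column_stack([y[:, 0] / ITD_SCALE, y[:, 1]])


def train(features, targets, *, seed: int = 0, tone_ids=None,
          hidden: int = N_HIDDEN, lr: float = 3e-3, batch_size: int = 64,
          max_epochs: int = 1500, improvement_tol: float = 1e-4,
          patience: int = 20) -> MLPModel:
    """Train the MLP with Adam and validation-based early stopping.

    Stops once the relative improvement of the best validation MSE has
    stayed below ``improvement_tol`` (0.01%) for ``patience`` consecutive
    epochs, and returns the weights of the best validation epoch.
    Deterministic for fixed inputs and seed; raises on divergence.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if tone_ids is None:
        tone_ids = np.arange(len(x))
    tr, va, _ = split_by_tone(tone_ids, seed)
    if not (tr.any() and va.any()):
        raise ValueError("training and validation splits must be non-empty")

    model = MLPModel(w1=None, b1=None, w2=None, b2=None,
                     x_mean=x[tr].mean(axis=0), x_std=x[tr].std(axis=0),
                     seed=seed)
    model.x_std[model.x_std == 0] = 1.0
    z = model._scale_x(x)
    t = _scaled_targets(y)
    z_tr, t_tr, z_va, t_va = z[tr], t[tr], z[va], t[va]

    rng = np.random.default_rng(np.random.SeedSequence(seed,
                                                       spawn_key=(13,)))
    n_in = z.shape[1]
    w1 = rng.normal(0, 1.0 / np.sqrt(n_in), (n_in, hidden))
    b1 = np.zeros(hidden)
    w2 = rng.normal(0, 1.0 / np.sqrt(hidden), (hidden, 2))
    b2 = np.zeros(2)
    params = [w1, b1, w2, b2]
    adam_m = [np.zeros_like(p) for p in params]
    adam_v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    def val_mse():
        h = np.tanh(z_va @ w1 + b1)
        out = np.tanh(h @ w2 + b2)
        return float(np.mean((out - t_va) ** 2))

    best = np.inf
    best_params = None
    stale = 0
    curve = []
    n_tr = len(z_tr)
    for epoch in range(max_epochs):
        order = rng.permutation(n_tr)
        for start in range(0, n_tr, batch_size):
            idx = order[start:start + batch_size]
            zb, tb = z_tr[idx], t_tr[idx]
            h = np.tanh(zb @ w1 + b1)
            out = np.tanh(h @ w2 + b2)
            err = out - tb
            if not np.isfinite(err).all():
                raise FloatingPointError("training diverged (non-finite "
                                         f"loss at epoch {epoch})")
            d_out = (2.0 / err.size) * err * (1.0 - out**2)
            g_w2 = h.T @ d_out
            g_b2 = d_out.sum(axis=0)
            d_h = (d_out @ w2.T) * (1.0 - h**2)
            g_w1 = zb.T @ d_h
            g_b1 = d_h.sum(axis=0)
            step += 1
            for p, g, m_, v_ in zip(params, [g_w1, g_b1, g_w2, g_b2],
                                    adam_m, adam_v):
                m_ *= beta1
                m_ += (1 - beta1) * g
                v_ *= beta2
                v_ += (1 - beta2) * g * g
                mhat = m_ / (1 - beta1**step)
                vhat = v_ / (1 - beta2**step)
                p -= lr * mhat / (np.sqrt(vhat) + eps)
        mse = val_mse()
        curve.append(mse)
        if not np.isfinite(best) or best - mse > improvement_tol * best:
            best = mse
            best_params = [p.copy() for p in params]
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    model.w1, model.b1, model.w2, model.b2 = best_params
    model.loss_curve = np.asarray(curve)
    model.stop_epoch = len(curve)
    return model


@dataclass
class PredictionFrame:
    """One (time bin, frequency channel) prediction."""

    t: float
    cf: float
    itd_hat: float
    signal_score: float

    @property
    def reliable(self) -> bool:
        return self.signal_score > 0.0


def predict(model: MLPModel, stim: BinauralStimulus, *, cf_grid=None,
            n_neurons: int = 100, seed: int = 0,
            net: NetworkConfig | None = None,
            bin_width: float = BIN_WIDTH, gate: float = 0.0):
    """Frame-wise ITD predictions for a conditioned stimulus.

    Runs the spiking network once per channel of ``cf_grid`` (default 13
    log-spaced frequencies over the trained range), applies the MLP per
    30 ms bin, gates frames by the signal-exists score, and averages the
    reliable channels per bin into a cross-frequency estimate (bins with
    no reliable channel yield no estimate).

    Returns (frames DataFrame[t, cf, itd_hat, signal_score, reliable],
    track DataFrame[t, itd_hat, n_reliable]).
    """
    if model.w1 is None:
        raise ValueError("model has not been trained")
    lo, hi = model.cf_range
    cf_grid = np.geomspace(lo, hi, 13) if cf_grid is None else cf_grid
    rows = []
    base = net or NetworkConfig(n_per_population=n_neurons)
    seeds = np.random.SeedSequence(seed).generate_state(len(cf_grid))
    for cf, s in zip(np.asarray(cf_grid, float), seeds):
        if not lo <= cf <= hi:
            raise ValueError(f"cf {cf} Hz outside the trained range "
                             f"[{lo}, {hi}] Hz")
        res = build_and_run(stim, replace(base, cf=cf,
                                          n_per_population=n_neurons,
                                          rng_seed=int(s) % 2**31))
        df = extract_features(res, bin_width)
        out = model.forward(df[FEATURE_COLS].to_numpy())
        for i, row in df.iterrows():
            rows.append({"t": row["t"], "cf": cf, "itd_hat": out[i, 0],
                         "signal_score": out[i, 1],
                         "reliable": out[i, 1] > gate})
    frames = pd.DataFrame(rows)
    rel = frames[frames.reliable]
    track = (rel.groupby("t")
             .agg(itd_hat=("itd_hat", "mean"), n_reliable=("cf", "size"))
             .reset_index())
    return frames, track
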