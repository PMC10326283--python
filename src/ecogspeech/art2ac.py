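"""Articulatory-to-acoustic synthesizer network.

A feedforward network maps a short window of articulatory trajectories (10
past frames, the current frame and 1 future frame; 12 x 14 = 168 inputs) to
the 25 mel-cepstral coefficients of the current frame, adding only 10 ms of
look-ahead latency.  Defaults follow the real-time synthesizer design: 3
hidden layers of 512 tanh units, 25% dropout, Adam on mini-batches of 32,
early stopping with a patience of 20 epochs on a held-out validation split.

The network is trained on the reference speaker's paired EMA/mel corpus and
can then be fine-tuned, starting from the pretrained weights, to predict a
patient's mel cepstrum from articulatory trajectories decoded from neural
activity.

Implemented as a compact numpy MLP so training stays deterministic for a
given seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .lindec import ZScoreState, apply_zscore, fit_zscore, invert_zscore
from .tracks import FeatureTrack

N_EMA = 14
N_MEL = 25
PAST_FRAMES = 10
FUTURE_FRAMES = 1
CONTEXT_FRAMES = PAST_FRAMES + 1 + FUTURE_FRAMES  # 12


@dataclass
class SynthNetConfig:
    hidden: tuple[int, ...] = (512, 512, 512)
    dropout: float = 0.25
    batch_size: int = 32
    patience: int = 20
    max_epochs: int = 200
    learning_rate: float = 1e-3
    finetune_learning_rate: float = 1e-4
    train_frac: float = 0.8
    val_frac: float = 0.1  # remainder is a held-out evaluation split


@dataclass
class SynthNet:
    """Fitted synthesizer: layer weights, normalization state, history."""

    config: SynthNetConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_zscore: ZScoreState
    y_zscore: ZScoreState
    history: dict = field(default_factory=dict)

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    def copy(self) -> "SynthNet":
        return SynthNet(
            config=copy.deepcopy(self.config),
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            x_zscore=ZScoreState(self.x_zscore.mean.copy(), self.x_zscore.std.copy()),
            y_zscore=ZScoreState(self.y_zscore.mean.copy(), self.y_zscore.std.copy()),
            history=dict(self.history),
        )


def build_context(ema: np.ndarray) -> np.ndarray:
    """Stack 10 past + current + 1 future EMA frames per output frame
    (edge replication at sentence boundaries)."""
    n = ema.shape[0]
    if n < CONTEXT_FRAMES:
        raise ValueError(f"need at least {CONTEXT_FRAMES} frames")
    offsets = np.arange(-PAST_FRAMES, FUTURE_FRAMES + 1)
    idx = np.clip(np.arange(n)[:, None] + offsets[None, :], 0, n - 1)
    return ema[idx].reshape(n, -1)


def _forward(weights, biases, X, dropout_masks=None):
    """Forward pass; returns activations per layer (pre-output are tanh)."""
    acts = [X]
    h = X
    n_hidden = len(weights) - 1
    for layer in range(n_hidden):
        h = np.tanh(h @ weights[layer] + biases[layer])
        if dropout_masks is not None:
            h = h * dropout_masks[layer]
        acts.append(h)
    acts.append(h @ weights[-1] + biases[-1])
    return acts


def _init_params(dims: list[int], rng: np.random.Generator):
    weights, biases = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        # Glorot-style scale suits tanh units
        s = np.sqrt(6.0 / (d_in + d_out))
        weights.append(rng.uniform(-s, s, size=(d_in, d_out)))
        biases.append(np.zeros(d_out))
    return weights, biases


def _train_loop(
    weights, biases, X_tr, Y_tr, X_val, Y_val, cfg: SynthNetConfig,
    lr: float, rng: np.random.Generator,
):
    """Adam + dropout mini-batch training with early stopping (best-epoch
    weights restored).  Mutates weights/biases in place; returns history."""
    params = weights + biases
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n_hidden = len(weights) - 1
    keep = 1.0 - cfg.dropout

    best_val = np.inf
    best_state = None
    since_best = 0
    history = {"train_loss": [], "val_loss": []}
    n = X_tr.shape[0]
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X_tr[idx], Y_tr[idx]
            masks = [
                (rng.random((1, w.shape[1])) < keep) / keep for w in weights[:-1]
            ] if cfg.dropout > 0 else None
            acts = _forward(weights, biases, xb, masks)
            err = acts[-1] - yb
            ep_loss += float(np.sum(err**2))
            grad = 2.0 * err / (xb.shape[0] * yb.shape[1])
            grads_w = [None] * len(weights)
            grads_b = [None] * len(biases)
            delta = grad
            for layer in range(len(weights) - 1, -1, -1):
                grads_w[layer] = acts[layer].T @ delta
                grads_b[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = delta @ weights[layer].T
                    if masks is not None:
                        delta = delta * masks[layer - 1]
                    delta = delta * (1.0 - acts[layer] ** 2)  # tanh'
            step += 1
            lr_t = lr * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for k, g in enumerate(grads_w + grads_b):
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g**2
                params[k] -= lr_t * m[k] / (np.sqrt(v[k]) + eps)

        val_pred = _forward(weights, biases, X_val)[-1]
        val_loss = float(np.mean((val_pred - Y_val) ** 2))
        history["train_loss"].append(ep_loss / (n * Y_tr.shape[1]))
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = ([w.copy() for w in weights], [b.copy() for b in biases])
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if best_state is not None:
        for w, wb in zip(weights, best_state[0]):
            w[...] = wb
        for b, bb in zip(biases, best_state[1]):
            b[...] = bb
    history["best_val_loss"] = best_val
    return history


def _stack_pairs(pairs: list[tuple[FeatureTrack, FeatureTrack]]):
    X, Y = [], []
    for ema, mel in pairs:
        if ema.n_frames != mel.n_frames:
            raise ValueError("EMA and mel tracks must be frame-aligned")
        X.append(build_context(ema.data))
        Y.append(mel.data)
    return np.vstack(X), np.vstack(Y)


def train_synthesizer(
    pairs: list[tuple[FeatureTrack, FeatureTrack]],
    cfg: SynthNetConfig | None = None,
    seed: int = 0,
) -> SynthNet:
    """Train the articulatory-to-acoustic network on EMA -> mel pairs.

    Frames from all sentences are pooled and split at random into
    train/validation/evaluation fractions (80/10/10 by default); inputs and
    targets are z-scored with training-split statistics.
    """
    cfg = cfg or SynthNetConfig()
    X, Y = _stack_pairs(pairs)
    if X.shape[0] < 10 * CONTEXT_FRAMES:
        raise ValueError("corpus too short to train the synthesizer")
    rng = np.random.default_rng(seed)
    order = rng.permutation(X.shape[0])
    n_tr = int(round(cfg.train_frac * len(order)))
    n_val = int(round(cfg.val_frac * len(order)))
    tr, val = order[:n_tr], order[n_tr : n_tr + n_val]

    xz, yz = fit_zscore(X[tr]), fit_zscore(Y[tr])
    X_tr, Y_tr = apply_zscore(xz, X[tr]), apply_zscore(yz, Y[tr])
    X_val, Y_val = apply_zscore(xz, X[val]), apply_zscore(yz, Y[val])

    dims = [X.shape[1], *cfg.hidden, Y.shape[1]]
    weights, biases = _init_params(dims, rng)
    history = _train_loop(weights, biases, X_tr, Y_tr, X_val, Y_val, cfg,
                          cfg.learning_rate, rng)
    return SynthNet(cfg, weights, biases, xz, yz, history)


def fine_tune(
    net: SynthNet,
    pairs: list[tuple[FeatureTrack, FeatureTrack]],
    seed: int = 0,
    max_epochs: int | None = None,
) -> SynthNet:
    """Continue training from the pretrained weights on new EMA -> mel pairs.

    Typically the pairs are (decoded patient EMA, patient mel).  The input
    net is left unmodified; normalization statistics are inherited from
    pretraining so the transferred weights see inputs on the same scale.
    A smaller Adam step preserves the pretrained structure.
    """
    tuned = net.copy()
    if max_epochs is not None:
        tuned.config = copy.deepcopy(tuned.config)
        tuned.config.max_epochs = max_epochs
    if tuned.config.max_epochs == 0:
        tuned.history = {"train_loss": [], "val_loss": [], "best_val_loss": np.nan}
        return tuned
    if pairs and pairs[0][0].data.shape[1] * CONTEXT_FRAMES != net.input_dim:
        raise ValueError("architecture mismatch: input dimension differs")
    rng = np.random.default_rng(seed)
    cfg = tuned.config
    # early stopping validates on whole held-out sentences: fine-tuning
    # corpora are small, and frame-level random splits leak through the
    # strong within-sentence autocorrelation, hiding overfitting
    order = rng.permutation(len(pairs))
    n_val_sent = max(1, int(round(len(pairs) * cfg.val_frac)))
    val_ids = set(order[:n_val_sent].tolist())
    tr_pairs = [p for i, p in enumerate(pairs) if i not in val_ids]
    val_pairs = [p for i, p in enumerate(pairs) if i in val_ids]
    if not tr_pairs:
        raise ValueError("fine-tuning needs at least two sentences")
    X_tr_raw, Y_tr_raw = _stack_pairs(tr_pairs)
    X_val_raw, Y_val_raw = _stack_pairs(val_pairs)
    X_tr = apply_zscore(net.x_zscore, X_tr_raw)
    Y_tr = apply_zscore(net.y_zscore, Y_tr_raw)
    X_val = apply_zscore(net.x_zscore, X_val_raw)
    Y_val = apply_zscore(net.y_zscore, Y_val_raw)
    tuned.history = _train_loop(
        tuned.weights, tuned.biases, X_tr, Y_tr, X_val, Y_val, cfg,
        cfg.finetune_learning_rate, rng,
    )
    return tuned


def predict_mel(net: SynthNet, ema: FeatureTrack) -> FeatureTrack:
    """Predict a mel track from an EMA track (deterministic, no dropout)."""
    X = build_context(ema.data)
    if X.shape[1] != net.input_dim:
        raise ValueError("EMA dimensionality does not match the trained net")
    pred = _forward(net.weights, net.biases, apply_zscore(net.x_zscore, X))[-1]
    from .acoustics import MEL_LABELS

    out = invert_zscore(net.y_zscore, pred)
    labels = MEL_LABELS if out.shape[1] == len(MEL_LABELS) else [
        f"y{i}" for i in range(out.shape[1])
    ]
    return FeatureTrack(out, labels, ema.rate)


def validation_mse(net: SynthNet, pairs: list[tuple[FeatureTrack, FeatureTrack]]) -> float:
    """Mean squared error (z-scored target units) of the net on given pairs."""
    X, Y = _stack_pairs(pairs)
    pred = _forward(net.weights, net.biases, apply_zscore(net.x_zscore, X))[-1]
    return float(np.mean((pred - apply_zscore(net.y_zscore, Y)) ** 2))
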