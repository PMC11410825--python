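"""The two component predictors, written from scratch on numpy.

mRNN
    A single-cell LSTM that consumes a pair's feature vector as a length-T
    sequence of scalars (input size 1). Gates use the logistic function, the
    candidate state uses tanh, and the cell state follows the standard
    update c_t = f_t * c_{t-1} + i_t * g_t; the final hidden state passes
    through three dense layers (tanh, tanh, logistic) to a score in (0, 1).
    Training is SGD with momentum on the mean binary cross-entropy,
    mini-batch 70, 50 epochs by default.

DBN
    A stack of restricted Boltzmann machines pre-trained greedily with
    one-step contrastive divergence (momentum 0.5 for the first five epochs
    then 0.9, weight cost 2e-4), then fine-tuned end-to-end with a logistic
    output head on the same cross-entropy for 100 epochs. Inputs must be
    scaled to [0, 1].

Both trainers are deterministic given their seed, and both forward passes
are pure functions of parameters and input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

EPS = 1e-12


@dataclass
class TrainConfig:
    """Hyper-parameters for both predictors."""

    seed: int = 0
    # mRNN (single-cell LSTM + 3 dense layers)
    lstm_hidden: int = 16
    dense_sizes: tuple[int, int] = (16, 8)
    rnn_epochs: int = 50
    rnn_batch: int = 70
    rnn_lr: float = 0.01
    rnn_momentum: float = 0.9
    grad_clip: float = 1.0  # global-norm clip for the LSTM gradients (0 disables)
    # DBN
    dbn_hidden: tuple[int, ...] = (50,)
    pretrain_epochs: int = 50
    finetune_epochs: int = 100
    dbn_batch: int = 200
    dbn_lr: float = 0.01
    initial_momentum: float = 0.5
    final_momentum: float = 0.9
    momentum_switch_epoch: int = 5
    weight_cost: float = 0.0002
    dropout: float = 0.1  # fine-tuning dropout on the hidden layers

    def __post_init__(self) -> None:
        if self.rnn_lr < 0 or self.dbn_lr < 0:
            raise ValueError("learning rates must be non-negative")
        for m in (self.rnn_momentum, self.initial_momentum, self.final_momentum):
            if not 0 <= m < 1:
                raise ValueError("momentum must be in [0, 1)")


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def cross_entropy(labels, scores) -> float:
    """Mean binary cross-entropy with scores clipped to [eps, 1 - eps]."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal lengths")
    s = np.clip(scores, EPS, 1.0 - EPS)
    return float(-np.mean(labels * np.log(s) + (1.0 - labels) * np.log(1.0 - s)))


# ---------------------------------------------------------------------------
# mRNN: single-cell LSTM


@dataclass
class LstmParams:
    """Gate and head parameters; gate blocks are stacked [forget, input, cell, output]."""

    w_x: np.ndarray  # (4H,)
    w_h: np.ndarray  # (4H, H)
    b: np.ndarray  # (4H,)
    dense: list[tuple[np.ndarray, np.ndarray]]  # [(W, b), ...] H->d1->d2->1

    @property
    def hidden(self) -> int:
        return self.w_h.shape[1]

    def named_arrays(self):
        yield "w_x", self.w_x
        yield "w_h", self.w_h
        yield "b", self.b
        for i, (w, bias) in enumerate(self.dense):
            yield f"dense_w{i}", w
            yield f"dense_b{i}", bias

    @classmethod
    def zeros(cls, hidden: int, dense_sizes=(16, 8)) -> "LstmParams":
        sizes = [hidden, *dense_sizes, 1]
        dense = [
            (np.zeros((sizes[i], sizes[i + 1])), np.zeros(sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        return cls(np.zeros(4 * hidden), np.zeros((4 * hidden, hidden)), np.zeros(4 * hidden), dense)

    @classmethod
    def init(cls, hidden: int, dense_sizes, rng: np.random.Generator) -> "LstmParams":
        p = cls.zeros(hidden, dense_sizes)
        p.w_x = rng.normal(0.0, 0.2, 4 * hidden)
        p.w_h = rng.normal(0.0, 0.1 / np.sqrt(hidden), (4 * hidden, hidden))
        p.b[:hidden] = 1.0  # open forget gates initially so state persists
        sizes = [hidden, *dense_sizes, 1]
        p.dense = [
            (
                rng.normal(0.0, 1.0 / np.sqrt(sizes[i]), (sizes[i], sizes[i + 1])),
                np.zeros(sizes[i + 1]),
            )
            for i in range(len(sizes) - 1)
        ]
        return p


def _lstm_run(params: LstmParams, x: np.ndarray, keep_cache: bool):
    n, t_len = x.shape
    hid = params.hidden
    h = np.zeros((n, hid))
    c = np.zeros((n, hid))
    cache = []
    for t in range(t_len):
        xt = x[:, t]
        z = xt[:, None] * params.w_x[None, :] + h @ params.w_h.T + params.b[None, :]
        f = sigmoid(z[:, :hid])
        i = sigmoid(z[:, hid : 2 * hid])
        g = np.tanh(z[:, 2 * hid : 3 * hid])
        o = sigmoid(z[:, 3 * hid :])
        c_prev, h_prev = c, h
        c = f * c_prev + i * g
        h = o * np.tanh(c)
        if keep_cache:
            cache.append((xt, h_prev, c_prev, f, i, g, o, c))
    acts = [h]
    for layer, (w, b) in enumerate(params.dense):
        z = acts[-1] @ w + b
        acts.append(sigmoid(z) if layer == len(params.dense) - 1 else np.tanh(z))
    score = acts[-1][:, 0]
    if not np.all(np.isfinite(score)):
        raise FloatingPointError("non-finite activation in LSTM forward pass")
    return score, cache, acts


def lstm_forward(params: LstmParams, feature_sequence) -> np.ndarray | float:
    """Score in (0, 1) for one feature vector (1-D input) or a batch (2-D)."""
    x = np.asarray(feature_sequence, dtype=float)
    single = x.ndim == 1
    score, _, _ = _lstm_run(params, np.atleast_2d(x), keep_cache=False)
    return float(score[0]) if single else score


def lstm_loss_and_grads(params: LstmParams, x: np.ndarray, y: np.ndarray):
    """Summed cross-entropy gradients over the batch (full BPTT).

    Returns the mean loss for reporting; the gradients are per-sample sums so
    the configured step ratio acts per sample, the convention the momentum /
    step-ratio hyper-parameter family comes from.
    """
    hid = params.hidden
    score, cache, acts = _lstm_run(params, x, keep_cache=True)
    loss = cross_entropy(y, score)

    grads = {name: np.zeros_like(arr) for name, arr in params.named_arrays()}
    # logistic output with cross-entropy gives delta = s - y
    delta = (score - y)[:, None]
    for layer in range(len(params.dense) - 1, -1, -1):
        w, _ = params.dense[layer]
        grads[f"dense_w{layer}"] += acts[layer].T @ delta
        grads[f"dense_b{layer}"] += delta.sum(axis=0)
        delta = delta @ w.T
        if layer > 0:
            delta = delta * (1.0 - acts[layer] ** 2)

    dh = delta
    dc = np.zeros((x.shape[0], hid))
    for t in range(x.shape[1] - 1, -1, -1):
        xt, h_prev, c_prev, f, i, g, o, c = cache[t]
        tanh_c = np.tanh(c)
        do = dh * tanh_c
        dct = dc + dh * o * (1.0 - tanh_c**2)
        df = dct * c_prev
        di = dct * g
        dg = dct * i
        dc = dct * f
        dz = np.hstack(
            [df * f * (1 - f), di * i * (1 - i), dg * (1 - g**2), do * o * (1 - o)]
        )
        grads["w_x"] += (dz * xt[:, None]).sum(axis=0)
        grads["w_h"] += dz.T @ h_prev
        grads["b"] += dz.sum(axis=0)
        dh = dz @ params.w_h
    return loss, grads


def train_mrnn(features, labels, config: TrainConfig):
    """Train the mRNN; returns (params, per-epoch loss trace).

    The trace has ``rnn_epochs + 1`` entries: the full-data loss before
    training and after each epoch. Deterministic given ``config.seed``.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.ndim != 2 or x.shape[0] != y.shape[0] or x.shape[0] == 0:
        raise ValueError("features must be (n, d) with one label per row")
    rng = np.random.default_rng(config.seed)
    params = LstmParams.init(config.lstm_hidden, config.dense_sizes, rng)
    velocity = {name: np.zeros_like(arr) for name, arr in params.named_arrays()}
    trace = [cross_entropy(y, lstm_forward(params, x))]
    n = x.shape[0]
    for epoch in range(config.rnn_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.rnn_batch):
            idx = order[start : start + config.rnn_batch]
            loss, grads = lstm_loss_and_grads(params, x[idx], y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"mRNN training diverged at epoch {epoch}")
            if config.grad_clip > 0:
                norm = math.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))
                if norm > config.grad_clip:
                    scale = config.grad_clip / norm
                    grads = {k: g * scale for k, g in grads.items()}
            arrays = dict(params.named_arrays())
            for name, arr in arrays.items():
                velocity[name] = config.rnn_momentum * velocity[name] - config.rnn_lr * grads[name]
                arr += velocity[name]
        trace.append(cross_entropy(y, lstm_forward(params, x)))
    return params, np.asarray(trace)


# ---------------------------------------------------------------------------
# RBM / DBN


@dataclass
class RbmParams:
    """Weights (visible x hidden) and the two bias vectors of one RBM."""

    w: np.ndarray  # (p, q)
    b_visible: np.ndarray  # (p,)
    b_hidden: np.ndarray  # (q,)

    @classmethod
    def init(cls, n_visible: int, n_hidden: int, rng: np.random.Generator) -> "RbmParams":
        return cls(rng.normal(0.0, 0.01, (n_visible, n_hidden)), np.zeros(n_visible), np.zeros(n_hidden))


def rbm_energy(params: RbmParams, v, h) -> float:
    """E(v, h) = -A.v - B.h - v W h for one configuration."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape != params.b_visible.shape or h.shape != params.b_hidden.shape:
        raise ValueError("v/h shapes do not match the RBM parameters")
    return float(-params.b_visible @ v - params.b_hidden @ h - v @ params.w @ h)


def prob_hidden(params: RbmParams, v: np.ndarray) -> np.ndarray:
    """P(h_j = 1 | v) = sigma(B_j + sum_i v_i W_ij)."""
    return sigmoid(np.atleast_2d(v) @ params.w + params.b_hidden)


def prob_visible(params: RbmParams, h: np.ndarray) -> np.ndarray:
    """P(v_r = 1 | h) = sigma(A_r + sum_j W_rj h_j)."""
    return sigmoid(np.atleast_2d(h) @ params.w.T + params.b_visible)


@dataclass
class _CdState:
    vw: np.ndarray
    vbv: np.ndarray
    vbh: np.ndarray

    @classmethod
    def zeros(cls, params: RbmParams) -> "_CdState":
        return cls(np.zeros_like(params.w), np.zeros_like(params.b_visible), np.zeros_like(params.b_hidden))


def cd1_epoch(
    params: RbmParams,
    data_batch: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator,
    epoch: int = 0,
    state: _CdState | None = None,
) -> float:
    """One CD-1 sweep over a batch; updates ``params`` in place.

    The positive statistics use the data and hidden probabilities, the
    negative statistics the mean-field reconstruction; momentum switches
    from its initial to its final value after ``momentum_switch_epoch``
    epochs and the weight cost decays the weights. As everywhere in this
    module the learning rate acts per sample (summed batch statistics).
    Returns the mean squared reconstruction error.
    """
    v0 = np.asarray(data_batch, dtype=float)
    if v0.ndim != 2 or v0.shape[0] == 0:
        raise ValueError("data batch must be a non-empty 2-D array")
    if state is None:
        state = _CdState.zeros(params)
    momentum = (
        config.initial_momentum if epoch < config.momentum_switch_epoch else config.final_momentum
    )
    h0_prob = prob_hidden(params, v0)
    h0_sample = (rng.random(h0_prob.shape) < h0_prob).astype(float)
    v1_prob = prob_visible(params, h0_sample)
    h1_prob = prob_hidden(params, v1_prob)
    dw = (v0.T @ h0_prob - v1_prob.T @ h1_prob) - config.weight_cost * params.w
    dbv = (v0 - v1_prob).sum(axis=0)
    dbh = (h0_prob - h1_prob).sum(axis=0)
    state.vw = momentum * state.vw + config.dbn_lr * dw
    state.vbv = momentum * state.vbv + config.dbn_lr * dbv
    state.vbh = momentum * state.vbh + config.dbn_lr * dbh
    params.w += state.vw
    params.b_visible += state.vbv
    params.b_hidden += state.vbh
    return float(np.mean((v0 - v1_prob) ** 2))


def train_rbm(data: np.ndarray, n_hidden: int, config: TrainConfig, rng: np.random.Generator):
    """Greedy pre-training of one RBM; returns (params, per-epoch recon-error trace)."""
    data = np.asarray(data, dtype=float)
    params = RbmParams.init(data.shape[1], n_hidden, rng)
    state = _CdState.zeros(params)
    batch = max(1, min(config.dbn_batch, data.shape[0]))
    trace = []
    for epoch in range(config.pretrain_epochs):
        order = rng.permutation(data.shape[0])
        errors = []
        for start in range(0, data.shape[0], batch):
            idx = order[start : start + batch]
            errors.append(cd1_epoch(params, data[idx], config, rng, epoch, state))
        trace.append(float(np.mean(errors)))
    return params, np.asarray(trace)


@dataclass
class DbnModel:
    """Pre-trained RBM stack plus the supervised logistic head."""

    rbms: list[RbmParams]
    head_w: np.ndarray
    head_b: float
    finetune_trace: np.ndarray = field(default=None, repr=False)
    pretrain_traces: list[np.ndarray] = field(default_factory=list, repr=False)


def dbn_forward(model: DbnModel, features: np.ndarray) -> np.ndarray:
    """Mean-field pass through the stack, then the logistic head; scores in (0, 1)."""
    a = np.atleast_2d(np.asarray(features, dtype=float))
    for rbm in model.rbms:
        a = sigmoid(a @ rbm.w + rbm.b_hidden)
    return sigmoid(a @ model.head_w + model.head_b)


def train_dbn_predict(features, labels, config: TrainConfig):
    """Pre-train the RBM stack, fine-tune with the logistic head, return scores.

    Returns ``(model, scores_on_training_data)``. Inputs must already lie in
    [0, 1] (min-max normalize upstream); out-of-range input raises.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.min() < 0.0 or x.max() > 1.0:
        raise ValueError("DBN input must be scaled to [0, 1]")
    rng = np.random.default_rng(config.seed)
    rbms: list[RbmParams] = []
    pre_traces = []
    layer_input = x
    for n_hidden in config.dbn_hidden:
        params, trace = train_rbm(layer_input, n_hidden, config, rng)
        rbms.append(params)
        pre_traces.append(trace)
        layer_input = sigmoid(layer_input @ params.w + params.b_hidden)
    head_w = rng.normal(0.0, 0.01, config.dbn_hidden[-1])
    model = DbnModel(rbms=rbms, head_w=head_w, head_b=0.0, pretrain_traces=pre_traces)

    batch = max(1, min(config.dbn_batch, x.shape[0]))
    momentum = config.final_momentum
    vel = {
        "head_w": np.zeros_like(model.head_w),
        "head_b": 0.0,
        **{f"w{i}": np.zeros_like(r.w) for i, r in enumerate(rbms)},
        **{f"bh{i}": np.zeros_like(r.b_hidden) for i, r in enumerate(rbms)},
    }
    trace = [cross_entropy(y, dbn_forward(model, x))]
    for epoch in range(config.finetune_epochs):
        order = rng.permutation(x.shape[0])
        for start in range(0, x.shape[0], batch):
            idx = order[start : start + batch]
            xb, yb = x[idx], y[idx]
            # forward with caches; inverted dropout on the hidden layers
            acts = [xb]
            pre_drop = [xb]
            masks = []
            for rbm in rbms:
                s = sigmoid(acts[-1] @ rbm.w + rbm.b_hidden)
                if config.dropout > 0:
                    mask = (rng.random(s.shape) >= config.dropout) / (1.0 - config.dropout)
                    a = s * mask
                else:
                    mask = None
                    a = s
                masks.append(mask)
                pre_drop.append(s)
                acts.append(a)
            scores = sigmoid(acts[-1] @ model.head_w + model.head_b)
            # per-sample summed gradients: the step ratio acts per sample
            delta = scores - yb
            g_head_w = acts[-1].T @ delta
            g_head_b = float(delta.sum())
            d_hidden = np.outer(delta, model.head_w)
            layer_grads = []
            for li in range(len(rbms) - 1, -1, -1):
                if masks[li] is not None:
                    d_hidden = d_hidden * masks[li]
                s = pre_drop[li + 1]
                dz = d_hidden * s * (1.0 - s)
                layer_grads.append((li, acts[li].T @ dz, dz.sum(axis=0)))
                d_hidden = dz @ rbms[li].w.T
            vel["head_w"] = momentum * vel["head_w"] - config.dbn_lr * g_head_w
            vel["head_b"] = momentum * vel["head_b"] - config.dbn_lr * g_head_b
            model.head_w += vel["head_w"]
            model.head_b += vel["head_b"]
            for li, gw, gb in layer_grads:
                vel[f"w{li}"] = momentum * vel[f"w{li}"] - config.dbn_lr * gw
                vel[f"bh{li}"] = momentum * vel[f"bh{li}"] - config.dbn_lr * gb
                rbms[li].w += vel[f"w{li}"]
                rbms[li].b_hidden += vel[f"bh{li}"]
        loss = cross_entropy(y, dbn_forward(model, x))
        if not np.isfinite(loss):
            raise FloatingPointError(f"DBN fine-tuning diverged at epoch {epoch}")
        trace.append(loss)
    model.finetune_trace = np.asarray(trace)
    return model, dbn_forward(model, x)
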