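"""Gait-cycle-to-knee-angle regression networks.

The core model is a fully connected four-layer perceptron
(100-250-150-100): hidden layer 1 with logistic activation, hidden layer 2
with ReLU, output layer with ELU.  Forward pass, analytic backpropagation and
the RMSprop update are written out explicitly in numpy so the equations are
auditable and the gradients can be checked against finite differences.

Training minimizes mean squared error on min-max-normalized cycles with
mini-batch RMSprop (learning rate 0.007), monitored with leave-one-subject-out
validation: each fold holds out one training subject, trains on the rest, and
records per-epoch train/validation losses.  Everything is deterministic given
the config seed.

A 1-D convolutional network (Conv 32 -> pool 2 -> Conv 64 -> pool 2 ->
dropout 0.5 -> dense -> linear out) is provided for comparison and trained
with the identical protocol.

Dataset assembly implements the six condition combinations: M1/M2/M3 are
single-shoe models (both speeds), M4/M5 are single-speed models (all shoes),
M6 uses every condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal
from scipy.special import expit

from .preprocessing import (GaitCycle, NormalizationParams, apply_minmax,
                            fit_minmax)

MODEL_IDS = ("M1", "M2", "M3", "M4", "M5", "M6")

#: shoe and speed combinations each model trains on
MODEL_CONDITIONS: Dict[str, Tuple[Tuple[str, ...], Tuple[str, ...]]] = {
    "M1": (("S1",), ("C", "F")),
    "M2": (("S2",), ("C", "F")),
    "M3": (("S3",), ("C", "F")),
    "M4": (("S1", "S2", "S3"), ("C",)),
    "M5": (("S1", "S2", "S3"), ("F",)),
    "M6": (("S1", "S2", "S3"), ("C", "F")),
}


@dataclass
class LabeledCyclePair:
    """One pressure cycle and its paired angle cycle, with condition labels."""

    subject: str
    shoe: str
    speed: str
    pressure: GaitCycle
    angle: GaitCycle
    cycle_index: int = 0


@dataclass
class Dataset:
    """Normalized training matrices for one model id."""

    model_id: str
    inputs: np.ndarray  # [n_cycles x 100], normalized pressure
    targets: np.ndarray  # [n_cycles x 100], normalized angle
    labels: pd.DataFrame  # subject, shoe, speed, cycle_index per row
    norm_input: NormalizationParams
    norm_target: NormalizationParams


def assemble_dataset(cycle_pairs: Sequence[LabeledCyclePair], model_id: str,
                     training_subjects: Sequence[str]) -> Dataset:
    """Select the model's conditions over the training subjects and scale.

    Min-max bounds are fitted on the selected rows only (one global pair of
    bounds per stream) and stored on the dataset.
    """
    if model_id not in MODEL_CONDITIONS:
        raise ValueError(f"unknown model id {model_id!r}")
    shoes, speeds = MODEL_CONDITIONS[model_id]
    training_subjects = list(training_subjects)
    present = {(p.subject, p.shoe, p.speed) for p in cycle_pairs}
    for subj in training_subjects:
        for shoe in shoes:
            for speed in speeds:
                if (subj, shoe, speed) not in present:
                    raise ValueError(
                        f"no cycles for required condition subject={subj} "
                        f"shoe={shoe} speed={speed} when assembling {model_id}")
    rows = [p for p in cycle_pairs
            if p.subject in training_subjects and p.shoe in shoes
            and p.speed in speeds]
    X = np.stack([p.pressure.values for p in rows])
    Y = np.stack([p.angle.values for p in rows])
    nin, ntg = fit_minmax(X), fit_minmax(Y)
    labels = pd.DataFrame({"subject": [p.subject for p in rows],
                           "shoe": [p.shoe for p in rows],
                           "speed": [p.speed for p in rows],
                           "cycle_index": [p.cycle_index for p in rows]})
    return Dataset(model_id=model_id, inputs=apply_minmax(X, nin),
                   targets=apply_minmax(Y, ntg), labels=labels,
                   norm_input=nin, norm_target=ntg)


# ---------------------------------------------------------------------------
# the four-layer perceptron

@dataclass
class MLPModel:
    """Explicit weights/biases of the input-h1-h2-output network."""

    layer_sizes: Tuple[int, int, int, int]
    w1: np.ndarray  # [Nh x Nl], input -> hidden 1
    b1: np.ndarray  # [Nh]
    w2: np.ndarray  # [Nz x Nh], hidden 1 -> hidden 2
    b2: np.ndarray  # [Nz]
    w3: np.ndarray  # [Nout x Nz], hidden 2 -> output
    b3: np.ndarray  # [Nout]
    elu_alpha: float = 1.0
    norm_input: NormalizationParams | None = None
    norm_target: NormalizationParams | None = None

    def params(self) -> List[np.ndarray]:
        return [self.w1, self.b1, self.w2, self.b2, self.w3, self.b3]


def init_mlp(seed: int,
             layer_sizes: Tuple[int, int, int, int] = (100, 250, 150, 100)
             ) -> MLPModel:
    """Glorot-uniform weights, zero biases; deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    nl, nh, nz, nout = layer_sizes

    def glorot(n_out, n_in):
        lim = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-lim, lim, size=(n_out, n_in))

    return MLPModel(layer_sizes=layer_sizes,
                    w1=glorot(nh, nl), b1=np.zeros(nh),
                    w2=glorot(nz, nh), b2=np.zeros(nz),
                    w3=glorot(nout, nz), b3=np.zeros(nout))


def _elu(x: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(x >= 0.0, x, alpha * (np.exp(np.minimum(x, 0.0)) - 1.0))


def _mlp_forward_cached(model: MLPModel, x: np.ndarray):
    h = x @ model.w1.T + model.b1
    y1 = expit(h)
    z = y1 @ model.w2.T + model.b2
    y2 = np.maximum(z, 0.0)
    y3 = y2 @ model.w3.T + model.b3
    out = _elu(y3, model.elu_alpha)
    return out, (x, y1, z, y2, y3)


def mlp_forward(model: MLPModel, x) -> np.ndarray:
    """Forward pass; accepts one cycle (1-D) or a batch (2-D)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xb = x[None, :] if single else x
    if xb.shape[1] != model.layer_sizes[0]:
        raise ValueError(f"input length {xb.shape[1]} does not match the "
                         f"network input size {model.layer_sizes[0]}")
    if not np.all(np.isfinite(xb)):
        raise ValueError("input contains non-finite values")
    out, _ = _mlp_forward_cached(model, xb)
    return out[0] if single else out


def _mlp_backward(model: MLPModel, cache, grad_out: np.ndarray
                  ) -> List[np.ndarray]:
    """Gradients of the loss w.r.t. params, given dL/d(output)."""
    x, y1, z, y2, y3 = cache
    a = model.elu_alpha
    dy3 = grad_out * np.where(y3 >= 0.0, 1.0,
                              a * np.exp(np.minimum(y3, 0.0)))
    gw3 = dy3.T @ y2
    gb3 = dy3.sum(axis=0)
    dy2 = dy3 @ model.w3
    dz = dy2 * (z > 0.0)
    gw2 = dz.T @ y1
    gb2 = dz.sum(axis=0)
    dy1 = dz @ model.w2
    dh = dy1 * y1 * (1.0 - y1)
    gw1 = dh.T @ x
    gb1 = dh.sum(axis=0)
    return [gw1, gb1, gw2, gb2, gw3, gb3]


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((pred - target) ** 2))


# ---------------------------------------------------------------------------
# RMSprop and the shared training loop

@dataclass
class TrainConfig:
    """Optimization protocol shared by the MLP and the CNN."""

    learning_rate: float = 0.007
    rho: float = 0.9  # squared-gradient decay
    epsilon: float = 1e-8
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


class RMSprop:
    """Keeps a moving average of squared gradients per parameter."""

    def __init__(self, params: List[np.ndarray], lr: float, rho: float,
                 epsilon: float) -> None:
        self.lr, self.rho, self.epsilon = lr, rho, epsilon
        self.cache = [np.zeros_like(p) for p in params]

    def step(self, params: List[np.ndarray], grads: List[np.ndarray]) -> None:
        for p, g, c in zip(params, grads, self.cache):
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(c) + self.epsilon)


def _loso_folds(subjects: np.ndarray) -> List[str]:
    uniq = sorted(pd.unique(subjects))
    if len(uniq) < 2:
        raise ValueError("leave-one-subject-out validation needs at least "
                         "two training subjects")
    return uniq


def _fit_once(model, state, forward_train, forward_eval, backward,
              Xtr, Ytr, Xva, Yva, config: TrainConfig, seed: int,
              records: list, fold_idx, val_subject) -> None:
    rng = np.random.default_rng(seed)
    opt = RMSprop(model.params(), config.learning_rate, config.rho,
                  config.epsilon)
    n = Xtr.shape[0]
    best_loss, best_params = np.inf, None
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        for lo in range(0, n, config.batch_size):
            sel = order[lo:lo + config.batch_size]
            xb, yb = Xtr[sel], Ytr[sel]
            pred, cache = forward_train(model, state, xb, rng)
            grad_out = 2.0 * (pred - yb) / pred.size
            grads = backward(model, state, cache, grad_out)
            opt.step(model.params(), grads)
        tr_loss = mse_loss(forward_eval(model, state, Xtr), Ytr)
        va_loss = (mse_loss(forward_eval(model, state, Xva), Yva)
                   if Xva is not None and Xva.shape[0] else np.nan)
        records.append({"fold": fold_idx, "val_subject": val_subject,
                        "epoch": epoch, "train_loss": tr_loss,
                        "val_loss": va_loss})
        if tr_loss < best_loss:
            best_loss = tr_loss
            best_params = [p.copy() for p in model.params()]
    # constant-rate RMSprop bounces around the optimum; keep the best
    # iterate found on the training objective (no validation involved)
    for p, b in zip(model.params(), best_params):
        p[...] = b


def _train_network(make_model, forward_train, forward_eval, backward,
                   dataset: Dataset, config: TrainConfig):
    """Generic LOSO-monitored training loop returning (model, history).

    One fold per training subject measures generalization: it holds that
    subject out, trains on the rest, and records per-epoch train/validation
    losses.  The returned model is then refit on all training subjects with
    the same protocol (fold ``final`` in the history) — cross-validation
    selects and monitors, the deployed model uses every training cycle.
    ``make_model(seed)`` builds a fresh model; ``forward_train`` and
    ``backward`` run one batch with caching; ``forward_eval`` is the
    deterministic inference pass.
    """
    if dataset.inputs.shape[0] == 0:
        raise ValueError("dataset is empty")
    subjects = dataset.labels["subject"].to_numpy()
    folds = _loso_folds(subjects)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
             ss.spawn(len(folds) + 1)]
    records: list = []
    for fold_idx, (val_subject, fold_seed) in enumerate(zip(folds, seeds)):
        val_mask = subjects == val_subject
        model, state = make_model(fold_seed)
        _fit_once(model, state, forward_train, forward_eval, backward,
                  dataset.inputs[~val_mask], dataset.targets[~val_mask],
                  dataset.inputs[val_mask], dataset.targets[val_mask],
                  config, fold_seed, records, fold_idx, val_subject)
    model, state = make_model(seeds[-1])
    _fit_once(model, state, forward_train, forward_eval, backward,
              dataset.inputs, dataset.targets, None, None,
              config, seeds[-1], records, "final", "")
    history = pd.DataFrame.from_records(records)
    return model, history


def train_mlp(dataset: Dataset, config: TrainConfig | None = None,
              layer_sizes: Tuple[int, int, int, int] = (100, 250, 150, 100)
              ) -> Tuple[MLPModel, pd.DataFrame]:
    """Train the four-layer perceptron under the LOSO protocol.

    Returns the last fold's model (with the dataset's normalization bounds
    attached) and the per-fold, per-epoch loss history.
    """
    config = config or TrainConfig()

    def make(seed):
        return init_mlp(seed, layer_sizes), None

    def fwd_train(model, _state, xb, _rng):
        return _mlp_forward_cached(model, xb)

    def fwd_eval(model, _state, xb):
        return _mlp_forward_cached(model, xb)[0]

    def bwd(model, _state, cache, grad_out):
        return _mlp_backward(model, cache, grad_out)

    model, history = _train_network(make, fwd_train, fwd_eval, bwd,
                                    dataset, config)
    model.norm_input = dataset.norm_input
    model.norm_target = dataset.norm_target
    return model, history


def predict_knee_angle(model, pressure_cycle,
                       smooth_cutoff: float = 0.2) -> GaitCycle:
    """Pressure cycle (kPa) -> knee angle cycle (deg).

    Normalizes with the stored input bounds, runs the network, inverts the
    target normalization, and smooths with a zero-phase 4th-order Butterworth
    at ``smooth_cutoff`` cycles/sample in the 100-point domain.
    """
    if model.norm_input is None or model.norm_target is None:
        raise ValueError("model has no stored normalization parameters; "
                         "train it (or attach params) before predicting")
    values = (pressure_cycle.values if isinstance(pressure_cycle, GaitCycle)
              else np.asarray(pressure_cycle, dtype=float))
    xn = apply_minmax(values, model.norm_input)
    yn = forward_any(model, xn)
    y = apply_minmax(yn, model.norm_target, invert=True)
    sos = signal.butter(4, smooth_cutoff / 0.5, btype="low", output="sos")
    smoothed = signal.sosfiltfilt(sos, y)
    return GaitCycle(values=smoothed, modality="angle",
                     source_index=getattr(pressure_cycle, "source_index", 0))


def forward_any(model, x) -> np.ndarray:
    """Inference pass for either network type (normalized domain)."""
    x = np.asarray(x, dtype=float)
    if isinstance(model, MLPModel):
        return mlp_forward(model, x)
    single = x.ndim == 1
    out = model.forward(np.atleast_2d(x), train=False)[0]
    return out[0] if single else out


# ---------------------------------------------------------------------------
# 1-D convolutional comparison network

@dataclass(frozen=True)
class CNNSpec:
    """Architecture of the comparison network."""

    conv1_filters: int = 32
    conv2_filters: int = 64
    kernel: int = 3
    pool: int = 2
    dropout: float = 0.5
    dense_units: int = 100
    n_input: int = 100
    n_output: int = 100


class CNNModel:
    """Conv1D(32, sigmoid) -> pool -> Conv1D(64, relu) -> pool -> dropout
    -> dense(ELU) -> linear output, with explicit numpy backprop."""

    def __init__(self, spec: CNNSpec, seed: int) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)

        def glorot(shape, fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape)

        k, c1, c2 = spec.kernel, spec.conv1_filters, spec.conv2_filters
        l1 = spec.n_input - k + 1
        p1 = l1 // spec.pool
        l2 = p1 - k + 1
        p2 = l2 // spec.pool
        self.flat = p2 * c2
        self.k1 = glorot((k, 1, c1), k, k * c1)
        self.cb1 = np.zeros(c1)
        self.k2 = glorot((k, c1, c2), k * c1, k * c2)
        self.cb2 = np.zeros(c2)
        self.wd = glorot((spec.dense_units, self.flat), self.flat,
                         spec.dense_units)
        self.bd = np.zeros(spec.dense_units)
        self.wo = glorot((spec.n_output, spec.dense_units), spec.dense_units,
                         spec.n_output)
        self.bo = np.zeros(spec.n_output)
        self.elu_alpha = 1.0
        self.norm_input: NormalizationParams | None = None
        self.norm_target: NormalizationParams | None = None

    def params(self) -> List[np.ndarray]:
        return [self.k1, self.cb1, self.k2, self.cb2, self.wd, self.bd,
                self.wo, self.bo]

    @staticmethod
    def _conv(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
        """Valid 1-D convolution: x [B,L,Cin], kernel [k,Cin,Cout]."""
        k = kernel.shape[0]
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        # win: [B, L-k+1, Cin, k] -> contract over (Cin, k)
        return np.einsum("blck,kco->blo", win, kernel, optimize=True)

    @staticmethod
    def _conv_backward(x, kernel, d_out):
        k = kernel.shape[0]
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        g_kernel = np.einsum("blck,blo->kco", win, d_out, optimize=True)
        dx = np.zeros_like(x)
        lout = d_out.shape[1]
        for off in range(k):
            dx[:, off:off + lout, :] += d_out @ kernel[off].T
        return g_kernel, dx

    def _pool(self, x: np.ndarray):
        p = self.spec.pool
        lp = x.shape[1] // p
        xr = x[:, :lp * p, :].reshape(x.shape[0], lp, p, x.shape[2])
        arg = xr.argmax(axis=2)
        out = np.take_along_axis(xr, arg[:, :, None, :], axis=2)[:, :, 0, :]
        return out, (arg, x.shape)

    def _pool_backward(self, d_out: np.ndarray, pool_cache) -> np.ndarray:
        arg, shape = pool_cache
        p = self.spec.pool
        lp = d_out.shape[1]
        dxr = np.zeros((shape[0], lp, p, shape[2]))
        np.put_along_axis(dxr, arg[:, :, None, :], d_out[:, :, None, :],
                          axis=2)
        dx = np.zeros(shape)
        dx[:, :lp * p, :] = dxr.reshape(shape[0], lp * p, shape[2])
        return dx

    def forward(self, x: np.ndarray, train: bool = False, rng=None):
        x3 = x[:, :, None]
        a1 = self._conv(x3, self.k1) + self.cb1
        s1 = expit(a1)
        q1, pc1 = self._pool(s1)
        a2 = self._conv(q1, self.k2) + self.cb2
        r2 = np.maximum(a2, 0.0)
        q2, pc2 = self._pool(r2)
        if train and self.spec.dropout > 0:
            keep = 1.0 - self.spec.dropout
            mask = (rng.random(q2.shape) < keep) / keep
        else:
            mask = np.ones_like(q2)
        q2d = q2 * mask
        flat = q2d.reshape(x.shape[0], -1)
        ad = flat @ self.wd.T + self.bd
        d = _elu(ad, self.elu_alpha)
        out = d @ self.wo.T + self.bo
        cache = (x3, a1, s1, pc1, q1, a2, pc2, mask, flat, ad, d)
        return out, cache

    def backward(self, cache, grad_out: np.ndarray) -> List[np.ndarray]:
        x3, a1, s1, pc1, q1, a2, pc2, mask, flat, ad, d = cache
        gwo = grad_out.T @ d
        gbo = grad_out.sum(axis=0)
        dd = grad_out @ self.wo
        dad = dd * np.where(ad >= 0.0, 1.0,
                            self.elu_alpha * np.exp(np.minimum(ad, 0.0)))
        gwd = dad.T @ flat
        gbd = dad.sum(axis=0)
        dflat = dad @ self.wd
        dq2d = dflat.reshape(mask.shape)
        dq2 = dq2d * mask
        dr2 = self._pool_backward(dq2, pc2)
        da2 = dr2 * (a2 > 0.0)
        gk2, dq1 = self._conv_backward(q1, self.k2, da2)
        gcb2 = da2.sum(axis=(0, 1))
        ds1 = self._pool_backward(dq1, pc1)
        da1 = ds1 * s1 * (1.0 - s1)
        gk1, _ = self._conv_backward(x3, self.k1, da1)
        gcb1 = da1.sum(axis=(0, 1))
        return [gk1, gcb1, gk2, gcb2, gwd, gbd, gwo, gbo]


def train_cnn(dataset: Dataset, spec: CNNSpec | None = None,
              config: TrainConfig | None = None
              ) -> Tuple[CNNModel, pd.DataFrame]:
    """Train the Conv1D comparison network with the same LOSO protocol."""
    spec = spec or CNNSpec()
    config = config or TrainConfig()

    def make(seed):
        return CNNModel(spec, seed), None

    def fwd_train(model, _state, xb, rng):
        return model.forward(xb, train=True, rng=rng)

    def fwd_eval(model, _state, xb):
        return model.forward(xb, train=False)[0]

    def bwd(model, _state, cache, grad_out):
        return model.backward(cache, grad_out)

    model, history = _train_network(make, fwd_train, fwd_eval, bwd,
                                    dataset, config)
    model.norm_input = dataset.norm_input
    model.norm_target = dataset.norm_target
    return model, history
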