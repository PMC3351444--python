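"""Per-sample stochastic gradient descent for the shared-weight network.

Training minimizes squared error plus a small weight-decay penalty, one
sample at a time.  The gradient is obtained by backward accumulation through
the T unrolled iterations of the chain dynamics; because cell weights are
shared per residue type, each weight collects contributions from every
position and every time step at which its type appears.  A direct
consequence — and a useful invariant — is that a gradient step leaves the
rows of residue types absent from the sample untouched (up to the decay
shrinkage when the penalty is active).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .alphabet import Peptide
from .errors import InvalidInputError
from .network import ACTIVATIONS, GNNModel, _chain_matrix

Assay = Literal["activity", "stability"]


@dataclass
class TrainingSample:
    """A (peptide, continuous label) pair.

    ``label`` is the value regressed on (typically a standardized log assay
    value, or a synthetic teacher output).  ``raw_label`` keeps the original
    assay measurement, in nM for activity (EC50) or minutes for half-life,
    when one exists.
    """

    peptide: Peptide
    label: float
    raw_label: Optional[float] = None
    property_name: Optional[Assay] = None

    def __post_init__(self):
        if not math.isfinite(self.label):
            raise InvalidInputError("label must be finite")
        if self.raw_label is not None and self.raw_label <= 0:
            raise InvalidInputError("raw assay values must be positive")


@dataclass
class TrainConfig:
    """Hyper-parameters of the stochastic gradient descent.

    The step size starts small (mu0, around 0.01) and decays by the constant
    factor ``lr_decay`` after every epoch, so the step at epoch e is
    mu0 * lr_decay**e — slow convergence of the shared weights is the point.
    ``weight_decay`` is the coefficient of the squared-norm penalty that
    pulls insignificant weights toward zero.
    """

    mu0: float = 0.01
    lr_decay: float = 0.999
    epochs: int = 1000
    weight_decay: float = 1e-4
    shuffle_seed: int = 0
    loss_name: str = "squared_error"

    def __post_init__(self):
        if self.mu0 <= 0:
            raise InvalidInputError("mu0 must be > 0")
        if not (0 < self.lr_decay <= 1):
            raise InvalidInputError("lr_decay must be in (0, 1]")
        if self.epochs < 1:
            raise InvalidInputError("epochs must be >= 1")
        if self.weight_decay < 0:
            raise InvalidInputError("weight_decay must be >= 0")
        if self.loss_name != "squared_error":
            raise InvalidInputError(f"unsupported loss {self.loss_name!r}")

    def step_size(self, epoch: int) -> float:
        return self.mu0 * self.lr_decay**epoch


@dataclass
class GradientVector:
    """Gradient with the same layout as the model's weight table."""

    phi: np.ndarray  # (M,)
    omega: np.ndarray  # (M, 2N+1)


def loss(prediction: float, label: float, model: GNNModel, lam: float) -> float:
    """Squared error plus weight decay: (pred - label)^2 + lam * ||Omega||^2."""
    if not (math.isfinite(prediction) and math.isfinite(label)):
        raise InvalidInputError("loss inputs must be finite")
    if lam < 0:
        raise InvalidInputError("lam must be >= 0")
    penalty = lam * (float(model.phi @ model.phi) + float((model.omega**2).sum()))
    return (prediction - label) ** 2 + penalty


def backprop_gradient(
    model: GNNModel, sample: TrainingSample, lam: float = 0.0
) -> GradientVector:
    """Exact gradient of the per-sample loss with respect to every weight.

    Backward accumulation through the unrolled iterations: with
    s(t+1) = b + W x(t), x(t+1) = act(s(t+1)) and g(t) = dL/dx(t),

        d(t)      = g(t) * act'(x(t))          (element-wise)
        d phi[a]  += sum over positions i of type a of d_i(t)
        d omega[a, j] += d_i(t) * x_{i+j}(t-1)
        g(t-1)    = W^T d(t)

    The coupling matrix W is constant in t, so it is built once.
    """
    grad, _ = _backprop(model, sample, lam)
    return grad


def _backprop(
    model: GNNModel, sample: TrainingSample, lam: float
) -> tuple[GradientVector, float]:
    """Gradient plus the forward prediction it was computed at."""
    model.check_peptide(sample.peptide)
    idx = sample.peptide.type_indices
    L = idx.size
    N = model.radius
    T = model.iterations
    K = 2 * N + 1
    act, act_deriv = ACTIVATIONS[model.activation]

    b = model.phi[idx]
    W = _chain_matrix(model, idx)
    # padded states make every neighbor window a contiguous slice
    padded = np.zeros((T + 1, L + 2 * N))
    states = padded[:, N : N + L]
    for t in range(T):
        states[t + 1] = act(b + W @ states[t])
    pred = states[T].sum() if model.output_mode == "sum" else states[T].mean()

    dL_dpred = 2.0 * (pred - sample.label)
    g = np.full(L, dL_dpred * (1.0 if model.output_mode == "sum" else 1.0 / L))

    # accumulate per-position contributions over time, scatter into the
    # shared rows once at the end (cells of one type share their weights)
    dsum = np.zeros(L)
    dxsum = np.zeros((L, K))
    windows = np.lib.stride_tricks.sliding_window_view(padded, K, axis=1)
    WT = W.T
    for t in range(T, 0, -1):
        d = g * act_deriv(states[t])
        dsum += d
        dxsum += d[:, None] * windows[t - 1]
        g = WT @ d

    M = model.phi.size
    gphi = np.bincount(idx, weights=dsum, minlength=M)
    col = np.arange(K)
    flat = (idx[:, None] * K + col).ravel()
    gomega = np.bincount(flat, weights=dxsum.ravel(), minlength=M * K).reshape(M, K)

    if lam > 0:
        gphi += 2.0 * lam * model.phi
        gomega += 2.0 * lam * model.omega
    return GradientVector(gphi, gomega), float(pred)


def sgd_step(
    model: GNNModel, sample: TrainingSample, mu: float, lam: float = 0.0
) -> GNNModel:
    """One stochastic update Omega <- Omega - mu * grad(loss_i); returns a new model."""
    if mu < 0:
        raise InvalidInputError("mu must be >= 0")
    grad = backprop_gradient(model, sample, lam)
    out = model.copy()
    out.phi -= mu * grad.phi
    out.omega -= mu * grad.omega
    return out


def train(
    data: Sequence[TrainingSample],
    config: TrainConfig,
    init_seed: int,
    model: Optional[GNNModel] = None,
    val_data: Optional[Sequence[TrainingSample]] = None,
) -> tuple[GNNModel, list[float]]:
    """Epoch-wise per-sample SGD over a shuffled pass of the data.

    If no starting ``model`` is given, one is initialized over the samples'
    alphabet with radius L_max - 1 (fully connected chain), T equal to the
    rounded mean sequence length, and sum output: regression targets are
    standardized, and the sum of L bounded cell states spans that label
    range where their mean (bounded by 1) cannot.  When ``val_data`` is
    supplied the
    weights with the best validation RMSE seen after any epoch are returned
    (early-stopping snapshot); otherwise the final weights are.

    Returns the trained model and the per-epoch training-error trace (mean
    per-sample loss over the epoch, evaluated as samples are visited).
    """
    if not data:
        raise InvalidInputError("empty training data")
    from .network import default_iterations, init_model  # cycle-free local import

    peptides = [s.peptide for s in data]
    alphabet = peptides[0].alphabet
    for p in peptides[1:]:
        if p.alphabet != alphabet:
            raise InvalidInputError("all training peptides must share one alphabet")

    if model is None:
        N = max(len(p) for p in peptides) - 1
        T = default_iterations(peptides)
        model = init_model(alphabet, N, T, seed=init_seed, output_mode="sum")
    else:
        model = model.copy()

    rng = np.random.default_rng(config.shuffle_seed)
    lam = config.weight_decay
    curve: list[float] = []
    best_val = math.inf
    best_weights: Optional[tuple[np.ndarray, np.ndarray]] = None
    order = np.arange(len(data))

    for epoch in range(config.epochs):
        mu = config.step_size(epoch)
        rng.shuffle(order)
        epoch_loss = 0.0
        for k in order:
            sample = data[k]
            grad, pred = _backprop(model, sample, lam)
            # track the pre-update loss of the visited sample
            epoch_loss += loss(pred, sample.label, model, lam)
            model.phi -= mu * grad.phi
            model.omega -= mu * grad.omega
        curve.append(epoch_loss / len(data))
        if val_data is not None:
            val_rmse = rmse(model, val_data)
            if val_rmse < best_val:
                best_val = val_rmse
                best_weights = (model.phi.copy(), model.omega.copy())

    if best_weights is not None:
        model.phi, model.omega = best_weights
    return model, curve


def _fast_forward(model: GNNModel, p: Peptide) -> float:
    """Forward pass without building a state trace (training hot path)."""
    idx = p.type_indices
    act, _ = ACTIVATIONS[model.activation]
    b = model.phi[idx]
    W = _chain_matrix(model, idx)
    x = np.zeros(idx.size)
    for _ in range(model.iterations):
        x = act(b + W @ x)
    return float(x.sum() if model.output_mode == "sum" else x.mean())


def rmse(model: GNNModel, data: Sequence[TrainingSample]) -> float:
    """Root-mean-square prediction error on a sample collection."""
    if not data:
        raise InvalidInputError("empty data")
    errs = [_fast_forward(model, s.peptide) - s.label for s in data]
    return float(np.sqrt(np.mean(np.square(errs))))


@dataclass
class LabelTransform:
    """Invertible map between raw assay values and regression labels.

    Labels are standardized log10 assay values; for activity the sign is
    flipped so that a *lower* EC50 (more potent) maps to a *larger* label.
    EC50 values in this problem span 0.2–10 nM and half-lives 13–1700 min,
    so log-scale regression is the natural conditioning choice.
    """

    assay: Assay
    mean: float
    std: float

    @property
    def sign(self) -> float:
        return -1.0 if self.assay == "activity" else 1.0

    @classmethod
    def fit(cls, raw: Sequence[float], assay: Assay) -> "LabelTransform":
        raw = np.asarray(raw, dtype=float)
        if raw.size == 0:
            raise InvalidInputError("no raw values")
        if np.any(raw <= 0):
            raise InvalidInputError("raw assay values must be positive")
        logs = np.log10(raw)
        std = float(np.std(logs))
        if std == 0.0:
            warnings.warn("zero variance in raw labels; labels all map to 0")
            std = 1.0
        return cls(assay=assay, mean=float(np.mean(logs)), std=std)

    def transform(self, raw) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        if np.any(raw <= 0):
            raise InvalidInputError("raw assay values must be positive")
        return self.sign * (np.log10(raw) - self.mean) / self.std

    def inverse_transform(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        return 10.0 ** (self.mean + self.sign * y * self.std)

    def to_dict(self) -> dict:
        return {"assay": self.assay, "mean": self.mean, "std": self.std}

    @classmethod
    def from_dict(cls, d: dict) -> "LabelTransform":
        return cls(assay=d["assay"], mean=d["mean"], std=d["std"])


def transform_labels(
    raw: Sequence[float], assay: Assay
) -> tuple[np.ndarray, LabelTransform]:
    """Standardized log10 labels, oriented so that larger = better."""
    tf = LabelTransform.fit(raw, assay)
    return tf.transform(raw), tf


def make_samples(
    peptides: Sequence[Peptide],
    raw_values: Sequence[float],
    assay: Assay,
) -> tuple[list[TrainingSample], LabelTransform]:
    """Bundle peptides and raw assay values into transformed training samples."""
    if len(peptides) != len(raw_values):
        raise InvalidInputError("peptides and raw_values must align")
    labels, tf = transform_labels(raw_values, assay)
    samples = [
        TrainingSample(p, float(y), raw_label=float(r), property_name=assay)
        for p, y, r in zip(peptides, labels, raw_values)
    ]
    return samples, tf
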