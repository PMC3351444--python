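"""The peptide-topology network: one elementary cell per amino acid.

A peptide of length L maps one-to-one onto a chain of L cells.  All cells of
the same residue type share one weight vector: an internal weight ``phi``, a
self-feedback weight ``omega[0]`` and neighbor weights ``omega[j]`` for
offsets j = -N..N.  The chain is iterated T time steps from a zero initial
state,

    x_i(t+1) = act( phi[a_i] + sum_j omega[a_i, j] * x_{i+j}(t) ),

with a_i the residue type at position i and states outside the chain treated
as zero, and the network output is the average (optionally the sum) of the
internal states after the final iteration.  Because weights are keyed by
residue type, a single trained weight table evaluates any sequence over the
alphabet — rearranging residues rearranges cells, not weights.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import json
import numpy as np

from .alphabet import Alphabet, Peptide
from .errors import InvalidInputError, ModelMismatchError

MODEL_SCHEMA = "pepgnn-model-v1"

# activation -> (function, derivative expressed in terms of the *output*)
ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "tanh": (np.tanh, lambda x: 1.0 - x * x),
    "logistic": (lambda s: 1.0 / (1.0 + np.exp(-s)), lambda x: x * (1.0 - x)),
    "identity": (lambda s: s, lambda x: np.ones_like(x)),
}


@dataclass
class StateTrace:
    """Cell states over time: row t of ``states`` is x(t), t = 0..T."""

    states: np.ndarray  # shape (T+1, L)

    @property
    def iterations(self) -> int:
        return self.states.shape[0] - 1

    @property
    def length(self) -> int:
        return self.states.shape[1]


@dataclass
class GNNModel:
    """Shared-weight cell table plus iteration dynamics.

    Parameters
    ----------
    alphabet
        Governing residue alphabet; its size M is the number of weight rows.
    phi
        Internal weights, shape (M,).
    omega
        Feedback and neighbor weights, shape (M, 2N+1); column N is the
        self-feedback weight omega_0, column N+j the weight to the neighbor
        j positions away.
    radius
        Neighborhood radius N >= 0.
    iterations
        Number of time steps T >= 1.
    activation
        One of "tanh", "logistic", "identity".
    output_mode
        "average" (mean of final states, default) or "sum".
    """

    alphabet: Alphabet
    phi: np.ndarray
    omega: np.ndarray
    radius: int
    iterations: int
    activation: str = "tanh"
    output_mode: str = "average"

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=np.float64)
        self.omega = np.asarray(self.omega, dtype=np.float64)
        M = self.alphabet.size
        if self.radius < 0:
            raise InvalidInputError(f"radius must be >= 0, got {self.radius}")
        if self.iterations < 1:
            raise InvalidInputError(f"iterations must be >= 1, got {self.iterations}")
        if self.phi.shape != (M,):
            raise InvalidInputError(f"phi must have shape ({M},), got {self.phi.shape}")
        if self.omega.shape != (M, 2 * self.radius + 1):
            raise InvalidInputError(
                f"omega must have shape ({M}, {2 * self.radius + 1}), got {self.omega.shape}"
            )
        if self.activation not in ACTIVATIONS:
            raise InvalidInputError(f"unknown activation {self.activation!r}")
        if self.output_mode not in ("average", "sum"):
            raise InvalidInputError(f"unknown output_mode {self.output_mode!r}")

    @property
    def n_weights(self) -> int:
        return self.phi.size + self.omega.size

    def copy(self) -> "GNNModel":
        return replace(self, phi=self.phi.copy(), omega=self.omega.copy())

    def check_peptide(self, p: Peptide) -> None:
        if p.alphabet != self.alphabet:
            raise ModelMismatchError("peptide alphabet differs from model alphabet")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": MODEL_SCHEMA,
            "alphabet": self.alphabet.to_pairs(),
            "radius": int(self.radius),
            "iterations": int(self.iterations),
            "activation": self.activation,
            "output_mode": self.output_mode,
            "phi": self.phi.tolist(),
            "omega": self.omega.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GNNModel":
        if d.get("schema") != MODEL_SCHEMA:
            raise InvalidInputError(f"unsupported model schema {d.get('schema')!r}")
        return cls(
            alphabet=Alphabet.from_pairs(d["alphabet"]),
            phi=np.array(d["phi"], dtype=np.float64),
            omega=np.array(d["omega"], dtype=np.float64),
            radius=d["radius"],
            iterations=d["iterations"],
            activation=d["activation"],
            output_mode=d["output_mode"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "GNNModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def init_model(
    alphabet: Alphabet,
    N: int,
    T: int,
    seed: int,
    activation: str = "tanh",
    output_mode: str = "average",
    scale: float = 0.1,
) -> GNNModel:
    """Random model with weights i.i.d. uniform on [-scale, +scale].

    The small default scale keeps a tanh network in its quasi-linear regime
    at the start of training.  Reproducible given ``seed``.
    """
    if N < 0 or T < 1:
        raise InvalidInputError(f"need N >= 0 and T >= 1, got N={N}, T={T}")
    rng = np.random.default_rng(seed)
    M = alphabet.size
    phi = rng.uniform(-scale, scale, size=M)
    omega = rng.uniform(-scale, scale, size=(M, 2 * N + 1))
    return GNNModel(alphabet, phi, omega, N, T, activation, output_mode)


def default_iterations(training_peptides: Sequence[Peptide]) -> int:
    """T is set to the average length of the sequences under study (min 1)."""
    if not training_peptides:
        raise InvalidInputError("empty peptide list")
    mean_len = float(np.mean([len(p) for p in training_peptides]))
    return max(1, int(round(mean_len)))


# index template for scattering omega rows into an L x L coupling matrix,
# cached per (chain length, radius) — it does not depend on the sequence
_CHAIN_PLANS: dict[tuple[int, int], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _chain_plan(L: int, N: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    key = (L, N)
    plan = _CHAIN_PLANS.get(key)
    if plan is None:
        i = np.arange(L)
        rows, cols, flat = [], [], []
        for j in range(-N, N + 1):
            iv = i[(i + j >= 0) & (i + j < L)]
            rows.append(iv)
            cols.append(np.full(iv.size, j + N))
            flat.append(iv * L + iv + j)
        plan = (np.concatenate(rows), np.concatenate(cols), np.concatenate(flat))
        _CHAIN_PLANS[key] = plan
    return plan


def _chain_matrix(model: GNNModel, idx: np.ndarray) -> np.ndarray:
    """Per-position coupling matrix W with W[i, i+j] = omega[a_i, j].

    Constant across time steps, so the iteration is x(t+1) = act(b + W x(t)).
    """
    L = idx.size
    K = 2 * model.radius + 1
    rows, cols, flat = _chain_plan(L, model.radius)
    W = np.zeros(L * L)
    W[flat] = model.omega.ravel()[idx[rows] * K + cols]
    return W.reshape(L, L)


def forward(model: GNNModel, p: Peptide) -> tuple[float, StateTrace]:
    """Run the iterated dynamics on one peptide.

    Returns the scalar prediction and the full state trace (row 0 is the
    zero initial state).  Deterministic: identical inputs give identical
    outputs bit-for-bit.
    """
    model.check_peptide(p)
    idx = p.type_indices
    L = idx.size
    act, _ = ACTIVATIONS[model.activation]
    b = model.phi[idx]
    W = _chain_matrix(model, idx)
    states = np.zeros((model.iterations + 1, L))
    x = states[0]
    for t in range(model.iterations):
        x = act(b + W @ x)
        states[t + 1] = x
    pred = float(x.sum() if model.output_mode == "sum" else x.mean())
    return pred, StateTrace(states)


def forward_batch(model: GNNModel, idx_matrix: np.ndarray) -> np.ndarray:
    """Predictions for a batch of equal-length peptides.

    ``idx_matrix`` has shape (B, L), rows are residue type indices.  Returns
    shape (B,).  Exactly equivalent to calling :func:`forward` row by row;
    used by the ensemble and the genetic algorithm where thousands of
    candidate sequences are scored per generation.
    """
    idx = np.asarray(idx_matrix, dtype=np.intp)
    if idx.ndim != 2:
        raise InvalidInputError("idx_matrix must be 2-D (batch, length)")
    B, L = idx.shape
    N = model.radius
    act, _ = ACTIVATIONS[model.activation]
    b = model.phi[idx]  # (B, L)
    W = np.zeros((B, L, L))
    i = np.arange(L)
    for j in range(-N, N + 1):
        valid = (i + j >= 0) & (i + j < L)
        iv = i[valid]
        W[:, iv, iv + j] = model.omega[idx[:, iv], j + N]
    x = np.zeros((B, L))
    for t in range(model.iterations):
        x = act(b + np.einsum("bij,bj->bi", W, x))
    return x.sum(axis=1) if model.output_mode == "sum" else x.mean(axis=1)
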