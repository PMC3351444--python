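"""Cross-validation-style ensembles of trained networks.

Each candidate model is trained on its own random train/validation split
with a fresh weight initialization; candidates are scored by validation
RMSE on the held-out points and only the best-scoring fraction is retained.
The ensemble predicts by plain arithmetic averaging of member outputs,
which by Jensen's inequality cannot do worse in mean squared error than the
average of its members.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .alphabet import Peptide
from .errors import InvalidInputError, ModelMismatchError
from .network import GNNModel, forward_batch
from .training import (
    LabelTransform,
    TrainConfig,
    TrainingSample,
    _fast_forward,
    rmse,
    train,
)

BUNDLE_SCHEMA = "pepgnn-ensemble-v1"


@dataclass
class EnsembleConfig:
    """Candidate count, split geometry and retention rule.

    ``n_candidates`` models are trained on independent random subsamples of
    fraction ``train_fraction``; the best ``keep_fraction`` of them (by
    validation RMSE, at least one) survive into the ensemble.
    """

    n_candidates: int = 20
    train_fraction: float = 0.8
    keep_fraction: float = 0.5
    split_seed: int = 0

    def __post_init__(self):
        if self.n_candidates < 1:
            raise InvalidInputError("n_candidates must be >= 1")
        if not (0 < self.train_fraction < 1):
            raise InvalidInputError("train_fraction must be in (0, 1)")
        if not (0 < self.keep_fraction <= 1):
            raise InvalidInputError("keep_fraction must be in (0, 1]")

    @property
    def n_keep(self) -> int:
        return max(1, math.ceil(self.n_candidates * self.keep_fraction))


class Ensemble:
    """Trained member models plus their validation scores.

    Optionally carries the label transform of the raw assay values, so that
    predictions can be reported back on the original nM / minute scale.
    """

    def __init__(
        self,
        members: Sequence[GNNModel],
        validation_scores: Sequence[float],
        label_transform: Optional[LabelTransform] = None,
    ):
        if not members:
            raise InvalidInputError("ensemble needs at least one member")
        if len(members) != len(validation_scores):
            raise InvalidInputError("one validation score per member required")
        if any(not math.isfinite(s) for s in validation_scores):
            raise InvalidInputError("validation scores must be finite")
        self.members = list(members)
        self.validation_scores = [float(s) for s in validation_scores]
        self.label_transform = label_transform

    @property
    def alphabet(self):
        return self.members[0].alphabet

    def predict(self, p: Peptide) -> float:
        """Mean of member outputs, on the transformed label scale."""
        if p.alphabet != self.alphabet:
            raise ModelMismatchError("peptide alphabet differs from ensemble alphabet")
        return float(np.mean([_fast_forward(m, p) for m in self.members]))

    def predict_batch(self, idx_matrix: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`predict` over rows of residue-type indices."""
        outs = [forward_batch(m, idx_matrix) for m in self.members]
        return np.mean(outs, axis=0)

    def predict_raw(self, p: Peptide) -> float:
        """Prediction mapped back to the raw assay scale (nM or minutes)."""
        if self.label_transform is None:
            raise InvalidInputError("ensemble carries no label transform")
        return float(self.label_transform.inverse_transform(self.predict(p)))

    # -- serialization ---------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write a bundle directory: member model files plus a manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        names = []
        for k, m in enumerate(self.members):
            name = f"member_{k:03d}.json"
            m.save(directory / name)
            names.append(name)
        manifest = {
            "schema": BUNDLE_SCHEMA,
            "members": names,
            "validation_scores": self.validation_scores,
            "label_transform": (
                self.label_transform.to_dict() if self.label_transform else None
            ),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "Ensemble":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        if manifest.get("schema") != BUNDLE_SCHEMA:
            raise InvalidInputError(f"unsupported bundle schema {manifest.get('schema')!r}")
        members = [GNNModel.load(directory / n) for n in manifest["members"]]
        tf = manifest.get("label_transform")
        return cls(
            members,
            manifest["validation_scores"],
            LabelTransform.from_dict(tf) if tf else None,
        )


def build_ensemble(
    data: Sequence[TrainingSample],
    train_cfg: TrainConfig,
    ens_cfg: EnsembleConfig,
    label_transform: Optional[LabelTransform] = None,
) -> Ensemble:
    """Train, score and select candidate models.

    Every candidate gets an independent random train/validation split
    (repeated random subsampling, not disjoint folds) and a fresh weight
    seed, both derived deterministically from ``ens_cfg.split_seed``.
    Candidates are ranked by RMSE on their own held-out points and the best
    ``n_keep`` are retained, ties broken by candidate order.
    """
    K = len(data)
    if K < 5:
        raise InvalidInputError(f"need at least 5 samples to split, got {K}")
    n_train = min(K - 1, max(1, round(ens_cfg.train_fraction * K)))

    ss = np.random.SeedSequence(ens_cfg.split_seed)
    children = ss.spawn(ens_cfg.n_candidates)
    candidates: list[tuple[float, int, GNNModel]] = []
    for c, child in enumerate(children):
        split_rng = np.random.default_rng(child)
        seeds = split_rng.integers(0, 2**31 - 1, size=2)
        perm = split_rng.permutation(K)
        train_idx, val_idx = perm[:n_train], perm[n_train:]
        train_data = [data[i] for i in train_idx]
        val_data = [data[i] for i in val_idx]
        cfg = TrainConfig(
            mu0=train_cfg.mu0,
            lr_decay=train_cfg.lr_decay,
            epochs=train_cfg.epochs,
            weight_decay=train_cfg.weight_decay,
            shuffle_seed=int(seeds[1]),
            loss_name=train_cfg.loss_name,
        )
        model, _ = train(train_data, cfg, init_seed=int(seeds[0]), val_data=val_data)
        candidates.append((rmse(model, val_data), c, model))

    candidates.sort(key=lambda t: (t[0], t[1]))
    kept = candidates[: ens_cfg.n_keep]
    return Ensemble(
        [m for _, _, m in kept],
        [s for s, _, _ in kept],
        label_transform=label_transform,
    )


def predict(ensemble: Ensemble, p: Peptide) -> float:
    """Module-level alias for :meth:`Ensemble.predict`."""
    return ensemble.predict(p)
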