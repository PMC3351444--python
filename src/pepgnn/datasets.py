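"""Packaged chemerin-9 assay data and synthetic teacher worlds.

Two data sources back the package's experiments:

* The chemerin-9 optimization table — 21 nonamer peptides (five per design
  cycle 0–3 plus the wild type YFPGQFAFS) with measured EC50 (intracellular
  Ca2+ mobilization, nM) and serum half-life (HPLC assay, minutes).  The
  half-life of the most stable cycle-3 peptide yLPsQYAFf is stored as
  1693 min; the table's own "169±291" entry is inconsistent with its SD and
  with the value's three other appearances in the study text, so the
  corrected reading is shipped.

* A *teacher world*: a pair of randomly drawn networks standing in for the
  activity and stability assays.  Labels generated from a known model let
  end-to-end experiments (training recovery, closed-loop design) run with a
  ground truth that wet-lab data cannot provide.  Teachers are synthetic
  statistical stand-ins, not biophysical models of receptor binding or
  protease cleavage.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alphabet import Alphabet, Peptide, default_alphabet, encode_peptide
from .errors import InvalidInputError
from .network import GNNModel, forward_batch, init_model
from .training import TrainingSample

FIXTURE_NAME = "chemerin9_cycles.csv"


@dataclass(frozen=True)
class AssayRecord:
    """One row of the chemerin-9 optimization table."""

    cycle: Optional[int]  # 0-3, or None for the wild-type row
    sequence: str
    ec50_nM: float
    ec50_sd: float
    thalf_min: float
    thalf_sd: float

    @property
    def is_wild_type(self) -> bool:
        return self.cycle is None


def load_chemerin9_table() -> list[AssayRecord]:
    """The 21 packaged records: five per cycle 0-3 plus wild-type chemerin-9."""
    with resources.files("pepgnn.data").joinpath(FIXTURE_NAME).open() as fh:
        df = pd.read_csv(fh, dtype={"cycle": str})
    records = []
    for row in df.itertuples(index=False):
        cycle = None if row.cycle == "wt" else int(row.cycle)
        records.append(
            AssayRecord(
                cycle=cycle,
                sequence=row.sequence,
                ec50_nM=float(row.ec50_nM),
                ec50_sd=float(row.ec50_sd),
                thalf_min=float(row.t_half_min),
                thalf_sd=float(row.t_half_sd),
            )
        )
    return records


def chemerin9_frame() -> pd.DataFrame:
    """The packaged table as a DataFrame (column layout of the source CSV)."""
    with resources.files("pepgnn.data").joinpath(FIXTURE_NAME).open() as fh:
        return pd.read_csv(fh, dtype={"cycle": str})


def fold_change(value: float, reference: float) -> float:
    """Ratio value/reference, e.g. half-life improvement over wild type."""
    if reference <= 0:
        raise InvalidInputError("reference must be > 0")
    return value / reference


@dataclass
class TeacherWorld:
    """A synthetic ground truth: two fixed networks emulating the assays.

    Teacher outputs are affinely calibrated (per teacher) to zero mean and
    unit variance over a reference draw of random peptides, so labels live
    on a standardized scale and ``noise_sd`` reads directly as a fraction
    of the signal spread — the default 0.1 is 10% measurement noise.
    Labels are deterministic given (world, peptide) at noise_sd = 0.
    """

    teacher_activity: GNNModel
    teacher_stability: GNNModel
    noise_sd: float = 0.1
    seed: int = 0
    # per-teacher output calibration (shift, scale); identity by default
    activity_cal: tuple[float, float] = (0.0, 1.0)
    stability_cal: tuple[float, float] = (0.0, 1.0)

    @property
    def alphabet(self) -> Alphabet:
        return self.teacher_activity.alphabet

    def true_scores(self, idx_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Noise-free (activity, stability) teacher outputs for a batch."""
        (am, asd), (sm, ssd) = self.activity_cal, self.stability_cal
        return (
            (forward_batch(self.teacher_activity, idx_matrix) - am) / asd,
            (forward_batch(self.teacher_stability, idx_matrix) - sm) / ssd,
        )

    def combined_objective(
        self, idx_matrix: np.ndarray, weights: tuple[float, float] = (0.5, 0.5)
    ) -> np.ndarray:
        """Weighted sum of the two noise-free teacher outputs."""
        a, s = self.true_scores(idx_matrix)
        return weights[0] * a + weights[1] * s


def make_teacher(
    alphabet: Alphabet,
    seed: int,
    sparsity: float = 0.5,
    length: int = 9,
    phi_scale: float = 1.0,
    omega_scale: float = 0.3,
    noise_sd: float = 0.1,
    calibration_size: int = 2000,
) -> TeacherWorld:
    """Draw a reproducible teacher world.

    Teacher internal weights are uniform on [-phi_scale, +phi_scale] and
    coupling weights on [-omega_scale, +omega_scale]; the smaller coupling
    scale gives a landscape dominated by per-residue main effects with
    milder neighbor interactions, the structure assay data such as the
    chemerin-9 table exhibits (single substitutions move stability
    50-fold).  A fraction ``sparsity`` of all weights is independently
    zeroed, controlling landscape roughness.  The chain is fully connected
    for the given peptide length (radius length-1) and iterated ``length``
    times, and each teacher's output is standardized over a reference draw
    of ``calibration_size`` random peptides.
    """
    if not (0 <= sparsity <= 1):
        raise InvalidInputError("sparsity must be in [0, 1]")
    ss = np.random.SeedSequence(seed)
    act_ss, stab_ss, mask_ss, cal_ss = ss.spawn(4)
    mask_rng = np.random.default_rng(mask_ss)

    def _draw(child_ss) -> GNNModel:
        child_seed = int(np.random.default_rng(child_ss).integers(0, 2**31 - 1))
        m = init_model(alphabet, N=length - 1, T=length, seed=child_seed, scale=1.0)
        m.phi *= phi_scale
        m.omega *= omega_scale
        m.phi *= mask_rng.random(m.phi.shape) >= sparsity
        m.omega *= mask_rng.random(m.omega.shape) >= sparsity
        return m

    def _calibrate(m: GNNModel) -> tuple[float, float]:
        cal = random_peptides(alphabet, calibration_size, length,
                              np.random.default_rng(cal_ss))
        out = forward_batch(m, cal)
        sd = float(out.std())
        return float(out.mean()), sd if sd > 0 else 1.0

    activity = _draw(act_ss)
    stability = _draw(stab_ss)
    return TeacherWorld(
        teacher_activity=activity,
        teacher_stability=stability,
        noise_sd=noise_sd,
        seed=seed,
        activity_cal=_calibrate(activity),
        stability_cal=_calibrate(stability),
    )


def random_peptides(
    alphabet: Alphabet, n: int, length: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform-random residue-type index matrix of shape (n, length)."""
    if n < 1 or length < 1:
        raise InvalidInputError("need n >= 1 and length >= 1")
    return rng.integers(0, alphabet.size, size=(n, length), dtype=np.intp)


def sample_dataset(
    world: TeacherWorld,
    n: int,
    length: int,
    rng: np.random.Generator,
    properties: Sequence[str] = ("activity", "stability"),
) -> list[TrainingSample]:
    """Draw n uniform-random peptides and label them by the teachers.

    Each peptide is labeled for every requested property with teacher output
    plus Gaussian noise of SD ``world.noise_sd``; the returned flat list
    holds one TrainingSample per (peptide, property).  Duplicated draws are
    allowed, as they would be in a random synthesis batch.
    """
    idx = random_peptides(world.alphabet, n, length, rng)
    return label_with_teacher(world, idx, rng, properties)


def label_with_teacher(
    world: TeacherWorld,
    idx_matrix: np.ndarray,
    rng: np.random.Generator,
    properties: Sequence[str] = ("activity", "stability"),
) -> list[TrainingSample]:
    """Teacher-label an existing batch of peptides (rows of type indices)."""
    activity_scores, stability_scores = world.true_scores(idx_matrix)
    scores = {"activity": activity_scores, "stability": stability_scores}
    samples: list[TrainingSample] = []
    for prop in properties:
        if prop not in scores:
            raise InvalidInputError(f"unknown property {prop!r}")
        y = scores[prop]
        if world.noise_sd > 0:
            y = y + rng.normal(0.0, world.noise_sd, size=y.shape)
        for row, label in zip(idx_matrix, y):
            samples.append(
                TrainingSample(
                    Peptide(world.alphabet, row.copy()),
                    float(label),
                    property_name=prop,  # type: ignore[arg-type]
                )
            )
    return samples


def split_by_property(
    samples: Sequence[TrainingSample],
) -> dict[str, list[TrainingSample]]:
    out: dict[str, list[TrainingSample]] = {}
    for s in samples:
        out.setdefault(s.property_name or "unlabeled", []).append(s)
    return out


def chemerin9_peptides(alphabet: Optional[Alphabet] = None) -> list[Peptide]:
    """All 21 packaged sequences encoded over the (default) alphabet."""
    alphabet = alphabet or default_alphabet()
    return [encode_peptide(r.sequence, alphabet) for r in load_chemerin9_table()]
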