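"""Simulated design cycles: train -> evolve -> assay -> retrain.

Mirrors the iterative optimization workflow — a start population is
assayed, per-property ensembles are trained on everything measured so far,
the genetic algorithm proposes a batch of unseen top-ranked candidates, the
batch is "assayed" (here: labeled by a teacher world with noise) and the
loop repeats.  Because the teacher's noise-free output is known, the true
quality of every proposed batch can be scored exactly, which is how
closed-loop improvement is measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import Peptide
from .datasets import TeacherWorld, label_with_teacher, random_peptides, split_by_property
from .ensemble import EnsembleConfig, build_ensemble
from .errors import InvalidInputError
from .ga import FitnessSpec, GAConfig, evolve, rank_for_synthesis
from .training import TrainConfig


@dataclass
class LoopResult:
    """Per-cycle bookkeeping of a simulated design campaign.

    ``batch_best`` holds, for the start population (index 0) and each design
    cycle, the best *noise-free* combined teacher objective within that
    batch; ``cumulative_best`` the running maximum over everything assayed.
    """

    batch_best: list[float] = field(default_factory=list)
    cumulative_best: list[float] = field(default_factory=list)
    batches: list[np.ndarray] = field(default_factory=list)


def run_design_loop(
    world: TeacherWorld,
    n_start: int = 30,
    batch_size: int = 34,
    cycles: int = 3,
    length: int = 9,
    seed: int = 0,
    weights: tuple[float, float] = (0.5, 0.5),
    train_cfg: TrainConfig | None = None,
    ens_cfg: EnsembleConfig | None = None,
    ga_cfg: GAConfig | None = None,
) -> LoopResult:
    """Run ``cycles`` rounds of model-guided design against a teacher world.

    Defaults follow the study's cycle geometry (30 starting sequences, 34
    designs per round, three rounds); smaller budgets can be passed for
    quick experiments.  All randomness derives from ``seed``.
    """
    if n_start < 5:
        raise InvalidInputError("need at least 5 starting sequences")
    if cycles < 1 or batch_size < 1:
        raise InvalidInputError("cycles and batch_size must be >= 1")
    train_cfg = train_cfg or TrainConfig(epochs=200)
    ens_cfg = ens_cfg or EnsembleConfig(n_candidates=6, keep_fraction=0.5)
    ga_cfg = ga_cfg or GAConfig(
        population_size=200, generations=100, elite_count=10, peptide_length=length
    )

    ss = np.random.SeedSequence(seed)
    assay_ss, seed_ss = ss.spawn(2)
    assay_rng = np.random.default_rng(assay_ss)
    sub_seeds = np.random.default_rng(seed_ss).integers(0, 2**31 - 1, size=3 * cycles)

    result = LoopResult()
    start = random_peptides(world.alphabet, n_start, length, assay_rng)
    assayed = start
    samples = label_with_teacher(world, start, assay_rng)
    _record(result, world, start, weights)

    for c in range(cycles):
        by_prop = split_by_property(samples)
        objectives = []
        for k, prop in enumerate(("activity", "stability")):
            cfg = EnsembleConfig(
                n_candidates=ens_cfg.n_candidates,
                train_fraction=ens_cfg.train_fraction,
                keep_fraction=ens_cfg.keep_fraction,
                split_seed=int(sub_seeds[3 * c + k]),
            )
            ens = build_ensemble(by_prop[prop], train_cfg, cfg)
            objectives.append((ens, weights[k]))
        fitness = FitnessSpec(objectives)

        cfg = GAConfig(
            population_size=ga_cfg.population_size,
            generations=ga_cfg.generations,
            elite_count=ga_cfg.elite_count,
            mutation_rate=ga_cfg.mutation_rate,
            crossover_rate=ga_cfg.crossover_rate,
            peptide_length=length,
            tournament_size=ga_cfg.tournament_size,
            seed=int(sub_seeds[3 * c + 2]),
        )
        ranked, _ = evolve(fitness, cfg)
        exclude = [Peptide(world.alphabet, row) for row in assayed]
        batch_peps = rank_for_synthesis(ranked, batch_size, exclude=exclude)
        batch = np.array([p.type_indices for p in batch_peps], dtype=np.intp)

        samples.extend(label_with_teacher(world, batch, assay_rng))
        assayed = np.concatenate([assayed, batch])
        _record(result, world, batch, weights)

    return result


def _record(
    result: LoopResult,
    world: TeacherWorld,
    batch: np.ndarray,
    weights: tuple[float, float],
) -> None:
    best = float(world.combined_objective(batch, weights).max())
    result.batches.append(batch)
    result.batch_best.append(best)
    prev = result.cumulative_best[-1] if result.cumulative_best else -np.inf
    result.cumulative_best.append(max(prev, best))
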