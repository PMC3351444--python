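"""Genetic algorithm over fixed-length peptide sequences.

The search operates directly on the string level: per-position point
mutation, 2-point crossover, tournament parent selection and elitist
survivor selection (the best individuals are copied unchanged into the next
generation, so the best fitness seen never decreases).  Trained ensembles
supply the fitness through :class:`FitnessSpec`, a weighted sum over
objectives; any callable scoring a peptide works as well, which is how the
search is validated against fitness landscapes with known optima.

The study-scale configuration is a population of 2000 evolving for 5000
generations; the defaults below reproduce that, and every test or example
passes smaller budgets explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .alphabet import Alphabet, Peptide, decode_peptide
from .ensemble import Ensemble
from .errors import InvalidInputError


@dataclass
class GAConfig:
    """Operator rates and budgets for the evolutionary search.

    ``mutation_rate`` is the per-position substitution probability; when
    None it defaults to 1/L so that one position mutates per offspring in
    expectation.  ``elite_count`` individuals are carried over unchanged.
    """

    population_size: int = 2000
    generations: int = 5000
    elite_count: int = 20
    mutation_rate: Optional[float] = None
    crossover_rate: float = 0.9
    peptide_length: int = 9
    tournament_size: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise InvalidInputError("population_size must be >= 2")
        if self.generations < 1:
            raise InvalidInputError("generations must be >= 1")
        if not (1 <= self.elite_count < self.population_size):
            raise InvalidInputError("need 1 <= elite_count < population_size")
        if self.mutation_rate is not None and not (0 <= self.mutation_rate <= 1):
            raise InvalidInputError("mutation_rate must be in [0, 1]")
        if not (0 <= self.crossover_rate <= 1):
            raise InvalidInputError("crossover_rate must be in [0, 1]")
        if self.peptide_length < 1:
            raise InvalidInputError("peptide_length must be >= 1")
        if self.tournament_size < 1:
            raise InvalidInputError("tournament_size must be >= 1")

    @property
    def effective_mutation_rate(self) -> float:
        return (
            self.mutation_rate
            if self.mutation_rate is not None
            else 1.0 / self.peptide_length
        )


class FitnessSpec:
    """Weighted-sum scalarization of ensemble predictions.

    Each objective is an ensemble whose outputs are on its own standardized
    label scale (larger = better by construction of the label transform),
    so a convex combination is directly meaningful.  Weights must sum to 1.
    """

    def __init__(self, objectives: Sequence[tuple[Ensemble, float]]):
        if not objectives:
            raise InvalidInputError("need at least one objective")
        weights = np.array([w for _, w in objectives], dtype=float)
        if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
            raise InvalidInputError("objective weights must be >= 0 and sum to 1")
        alphabet = objectives[0][0].alphabet
        for ens, _ in objectives[1:]:
            if ens.alphabet != alphabet:
                raise InvalidInputError("all objectives must share one alphabet")
        self.objectives = list(objectives)
        self.alphabet = alphabet

    def evaluate_batch(self, idx_matrix: np.ndarray) -> np.ndarray:
        total = np.zeros(idx_matrix.shape[0])
        for ens, w in self.objectives:
            total += w * ens.predict_batch(idx_matrix)
        return total

    def __call__(self, p: Peptide) -> float:
        return float(self.evaluate_batch(p.type_indices[None, :])[0])


Fitness = Union[FitnessSpec, Callable[[Peptide], float]]


def mutate(p: Peptide, rate: float, rng: np.random.Generator) -> Peptide:
    """Point mutation: each position is independently replaced, with
    probability ``rate``, by a uniformly drawn *different* residue type."""
    if not (0 <= rate <= 1):
        raise InvalidInputError("rate must be in [0, 1]")
    idx = _mutate_rows(p.type_indices[None, :].copy(), rate, p.alphabet.size, rng)
    return Peptide(p.alphabet, idx[0])


def _mutate_rows(
    rows: np.ndarray, rate: float, M: int, rng: np.random.Generator
) -> np.ndarray:
    """In-place per-position mutation of an integer population block."""
    mask = rng.random(rows.shape) < rate
    n = int(mask.sum())
    if n:
        # shifting by 1..M-1 modulo M is a uniform draw over the other symbols
        shift = rng.integers(1, M, size=n)
        rows[mask] = (rows[mask] + shift) % M
    return rows


def crossover_2pt(
    a: Peptide, b: Peptide, rng: np.random.Generator
) -> tuple[Peptide, Peptide]:
    """2-point crossover: swap the segment between two uniform cuts.

    Cut points c1 <= c2 are drawn uniformly from 0..L (inclusive); the
    children exchange positions [c1, c2).  Equal cuts reproduce the parents.
    """
    if len(a) != len(b):
        raise InvalidInputError("parents must have equal length")
    if a.alphabet != b.alphabet:
        raise InvalidInputError("parents must share one alphabet")
    L = len(a)
    c1, c2 = np.sort(rng.integers(0, L + 1, size=2))
    child_a = a.type_indices.copy()
    child_b = b.type_indices.copy()
    child_a[c1:c2], child_b[c1:c2] = b.type_indices[c1:c2], a.type_indices[c1:c2]
    return Peptide(a.alphabet, child_a), Peptide(b.alphabet, child_b)


def _evaluate(fitness: Fitness, pop: np.ndarray, alphabet: Alphabet) -> np.ndarray:
    if isinstance(fitness, FitnessSpec) or hasattr(fitness, "evaluate_batch"):
        return np.asarray(fitness.evaluate_batch(pop), dtype=float)
    return np.array([fitness(Peptide(alphabet, row)) for row in pop], dtype=float)


def evolve(
    fitness: Fitness,
    cfg: GAConfig,
    alphabet: Optional[Alphabet] = None,
    initial: Optional[Sequence[Peptide]] = None,
) -> tuple[list[tuple[Peptide, float]], list[float]]:
    """Run the evolutionary search.

    Starts from ``initial`` peptides if given (topped up with uniform-random
    sequences), otherwise from a fully random population.  Each generation:
    evaluate, copy the ``elite_count`` best unchanged, and fill the rest
    with tournament-selected parents undergoing 2-point crossover (with
    probability ``crossover_rate``) and point mutation.

    Returns the final population, deduplicated and sorted by descending
    fitness, and the per-generation best-fitness history (monotone
    non-decreasing thanks to elitism).
    """
    if alphabet is None:
        if isinstance(fitness, FitnessSpec):
            alphabet = fitness.alphabet
        elif initial:
            alphabet = initial[0].alphabet
        else:
            raise InvalidInputError("alphabet required for a bare-callable fitness")
    M = alphabet.size
    L = cfg.peptide_length
    P = cfg.population_size
    rate = cfg.effective_mutation_rate
    rng = np.random.default_rng(cfg.seed)

    pop = rng.integers(0, M, size=(P, L), dtype=np.intp)
    if initial:
        for k, p in enumerate(initial[:P]):
            if len(p) != L:
                raise InvalidInputError("initial peptides must have cfg.peptide_length")
            pop[k] = p.type_indices

    history: list[float] = []
    fit = _evaluate(fitness, pop, alphabet)
    for _ in range(cfg.generations):
        history.append(float(fit.max()))
        order = np.argsort(-fit, kind="stable")
        elites = pop[order[: cfg.elite_count]]

        n_children = P - cfg.elite_count
        # tournament selection: best of `tournament_size` uniform picks
        draws = rng.integers(0, P, size=(2 * n_children, cfg.tournament_size))
        winners = draws[np.arange(2 * n_children), np.argmax(fit[draws], axis=1)]
        pa, pb = pop[winners[:n_children]], pop[winners[n_children:]]

        child_a, child_b = pa.copy(), pb.copy()
        do_cross = rng.random(n_children) < cfg.crossover_rate
        cuts = np.sort(rng.integers(0, L + 1, size=(n_children, 2)), axis=1)
        cols = np.arange(L)
        seg = (cols >= cuts[:, :1]) & (cols < cuts[:, 1:]) & do_cross[:, None]
        child_a[seg], child_b[seg] = pb[seg], pa[seg]

        children = np.concatenate([child_a, child_b])[
            rng.permutation(2 * n_children)[:n_children]
        ]
        _mutate_rows(children, rate, M, rng)

        pop = np.concatenate([elites, children])
        fit = _evaluate(fitness, pop, alphabet)
    history.append(float(fit.max()))

    order = np.argsort(-fit, kind="stable")
    seen: set[bytes] = set()
    ranked: list[tuple[Peptide, float]] = []
    for k in order:
        key = pop[k].tobytes()
        if key in seen:
            continue
        seen.add(key)
        ranked.append((Peptide(alphabet, pop[k].copy()), float(fit[k])))
    return ranked, history


def rank_for_synthesis(
    ranked: Sequence[tuple[Peptide, float]],
    k: int,
    exclude: Sequence[Peptide] = (),
) -> list[Peptide]:
    """Top-k candidates for the next synthesis batch.

    Removes previously assayed sequences (exact string match) and
    duplicates; warns and returns everything available if fewer than ``k``
    distinct candidates survive.
    """
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    excluded = {decode_peptide(p) for p in exclude}
    out: list[Peptide] = []
    seen: set[str] = set()
    for p, _ in sorted(ranked, key=lambda t: -t[1]):
        s = decode_peptide(p)
        if s in excluded or s in seen:
            continue
        seen.add(s)
        out.append(p)
        if len(out) == k:
            return out
    warnings.warn(f"only {len(out)} distinct candidates available, requested {k}")
    return out
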