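# Methods

## The model

`pepgnn` models quantitative structure–activity relationships (QSAR) of
short peptides over a mixed L/D amino-acid alphabet.  Instead of computing
molecular descriptors, the peptide sequence itself defines the topology of
the learning machine: a peptide of length L maps one-to-one onto a chain of
L *elementary cells*, and all cells representing the same residue type
(letter + chirality) share a single weight vector.  Cell `i` of type `a_i`
carries an internal weight `phi[a_i]`, a self-feedback weight
`omega[a_i, 0]` and neighbor-coupling weights `omega[a_i, j]` for offsets
`j = -N..N`.  Starting from the zero state, the chain is iterated T steps:

    x_i(t+1) = act( phi[a_i] + sum_{j=-N..N} omega[a_i, j] * x_{i+j}(t) )

with out-of-chain states treated as zero and `act` a squashing function
(tanh by default; logistic and identity are available).  The network output
is the average of the final states, or optionally their sum.  T defaults to
the rounded mean length of the training sequences, and the radius N to
L−1, i.e. a fully connected chain for the common length.

Because weights are keyed by residue type, a trained weight table evaluates
*any* sequence over the alphabet: rearranging residues rearranges cells,
not weights.  That is what makes the model usable as a search objective
over sequence space.

### Average vs. sum output

The two output conventions differ only by the factor L for fixed-length
data, but they differ materially in range: an average of tanh-bounded
states lies in (−1, 1), while regression labels in this package are
standardized (unit variance, tails beyond ±2).  `init_model` defaults to
`average`; the training front end (`train` with no starting model)
initializes `sum`-output networks so that the output range spans the label
range.  In teacher-student experiments this choice moves held-out rank
correlation from ≈0.6 to ≈0.93; both modes are first-class and
serialized.

## Labels

Assay values span orders of magnitude (EC50 0.2–10 nM, half-life
13–1693 min), so raw-scale least squares is dominated by the largest
values.  `transform_labels` regresses on standardized log10 values,
sign-flipped for activity so that *larger is better* for every property
(lower EC50 = more potent).  The transform parameters are stored with each
ensemble and inverted when predictions are reported on the assay scale.
Zero-variance inputs map to all-zero labels with a warning.

## Training

Plain per-sample stochastic gradient descent.  The loss on sample i is
`(out(Omega, s_i) − y_i)^2 + lambda * ||Omega||^2`; the gradient is exact,
obtained by backward accumulation through the T unrolled iterations with
the chain-coupling matrix held fixed per sample (it depends only on the
sequence and current weights).  Weight sharing makes the update sparse:
only the rows of residue types present in the sample move (plus the decay
shrinkage when lambda > 0) — asserted as an invariant in the tests.

Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| `mu0` (initial step) | 0.01 | small steps; shared weights accumulate many per-sample updates |
| `lr_decay` (per epoch) | 0.999 | slow geometric decay; 0.995 collapses the step (0.995^500 ≈ 0.08) before noise-free fits converge |
| `weight_decay` | 1e-4 | pulls weights of residue types with little evidence toward zero |
| `epochs` | 1000 | generous ceiling; experiments here use 120–400 |
| init scale | U[−0.1, 0.1] | keeps tanh cells in their quasi-linear regime at start |

Sample order is reshuffled every epoch with a seeded generator; identical
seeds give bit-identical models.  When a validation split is supplied,
training returns the weight snapshot with the best validation RMSE.

## Ensembles

Generalization from ~20–100 assayed peptides needs variance reduction.
`build_ensemble` trains `n_candidates` models (default 20) on independent
random train/validation splits (repeated random subsampling, fraction 0.8)
with fresh weight seeds, scores each by validation RMSE on its own held-out
points, and keeps the best `keep_fraction` (default 0.5, at least one).
Prediction is the plain mean of member outputs, which under squared loss
cannot be worse than the average member — asserted numerically in the
tests.  Candidate seeds derive from one `SeedSequence`, so ensemble builds
are reproducible.

## Evolutionary design

The genetic algorithm searches fixed-length sequence space (35^9 ≈ 7.9e13
nonamers for the default alphabet) with the trained ensembles as fitness.
Operators: per-position point mutation (rate 1/L by default, replacement
always a *different* symbol), 2-point crossover (cuts uniform on 0..L,
probability 0.9), tournament-of-2 parent selection, and elitist survivor
selection (default 20 elites copied unchanged — best-so-far fitness is
therefore monotone, asserted on every run).  Config defaults keep the
study geometry (population 2000, 5000 generations); tests and the
simulated campaigns use population 150–200 over 60–100 generations, which
already recovers the analytic optimum of position-wise additive landscapes
in all 20 random instances checked.

Two assay objectives are scalarized as a weighted sum (default 0.5/0.5) of
per-objective ensemble predictions.  Each ensemble predicts on its own
standardized label scale with larger = better, so the convex combination
is directly meaningful.  This scalarization shapes everything downstream
and is exposed in `FitnessSpec` and the CLI `--weights` flag.  Candidates
for "synthesis" are the top-k distinct sequences after removing previously
assayed ones (exact string match).

## The synthetic teacher world

Wet-lab assays are emulated by a pair of fixed random networks (activity
and stability teachers) over the same alphabet.  Teacher internal weights
are drawn U[−1, 1] and couplings U[−0.3, 0.3]; the smaller coupling scale
yields a landscape dominated by per-residue main effects with milder
interactions — the structure the chemerin-9 table itself exhibits, where
single substitutions shift stability 50-fold.  Equal scales were examined
during design and produce an interaction-dominated landscape that no
student recovers from 80 samples; that regime is available by passing
`omega_scale=1.0` but is not the default condition.  Half of all teacher
weights are zeroed (`sparsity=0.5`), controlling roughness.

Each teacher's output is affinely standardized over a fixed reference draw
of 2000 random peptides, so labels live on a zero-mean, unit-SD scale and
the measurement noise `noise_sd=0.1` reads directly as 10% of the signal
spread.  Labels are deterministic at `noise_sd=0`.

What the teachers do *not* emulate: protease cleavage chemistry, receptor
binding, assay-specific censoring, batch effects, or any correlation
between activity and stability beyond what two independent random networks
share.  Passing teacher-world experiments therefore shows that the
training/ensembling/search machinery works when the ground truth is a
network of this family under moderate noise — not that real assay
landscapes are of this family.

## Experiments and their scales

* **Teacher-student recovery** — 80 noisy training labels, single student
  (400 epochs), 200 held-out random peptides; Spearman rank correlation
  with the noise-free teacher ≥ 0.8 required for a majority of 3 seeds.
  Observed ≈ 0.86–0.88.
* **Closed-loop design** — 24 random start peptides, three cycles of
  (train two 6-candidate ensembles → GA 200×80 → select 12 unseen
  candidates → teacher assay).  A campaign counts as successful when every
  designed batch contains a peptide at least as good (true combined
  objective) as the best random-start peptide and the campaign's best
  strictly improves on it.  Per-cycle batch bests are max-statistics of
  12 draws and not strictly monotone run by run (a cycle that finds a
  near-optimum early cannot be topped later, and re-proposing it is
  forbidden); the best-so-far objective is the monotone quantity and is
  asserted as such.  Observed: designed batches reach 2.4–5 SD of the
  objective from ≈1.3 SD starts; 9/10 seeded campaigns succeed.
* **Gradient verification** — backprop vs central differences (h=1e-6)
  over ≥50 random geometries including N=0 and T=1, per-component
  symmetric relative error with an additive floor of 1e-4 absorbing FD
  round-off (~1e-10 absolute) on near-zero components.
* **Forward-dynamics oracle** — vectorized evaluator vs an independently
  written nested-loop evaluator, 100 random cases, agreement to 1e-10.

These problem sizes are the package's standing experiment configuration;
the study-scale geometry (30 start sequences, batches of 34, GA
2000×5000) is the default of `run_design_loop` and `GAConfig` and runs
unchanged, just longer.

## Numerical notes and edge cases

* The chain-coupling matrix is constant over time steps and is built once
  per (model, sequence); index templates are cached per (length, radius).
* Gradient contributions are accumulated over time per position and
  scattered into the shared rows once per sample (`bincount`), keeping the
  per-sample cost ≈150 µs at L=T=9, N=8.
* Peptides of length 1 and radius 0 degenerate to independent cells; both
  are covered by the gradient and oracle tests.
* Ties in ensemble member selection break by candidate order; ties in GA
  ranking by population order (stable argsort).
* Model and ensemble serialization is JSON (shortest-round-trip floats),
  so write→read round-trips are bit-exact.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawning; no global RNG state is used.

## Known limitations

* Residues are symbolic types; no physicochemical descriptors, so nothing
  is shared between, say, Leu and Ile, and the model cannot extrapolate to
  residue types absent from training data (their weights stay near
  initialization — the weight decay then keeps their contribution small).
* One network per property; no multi-task coupling between activity and
  stability models.
* The weighted-sum scalarization cannot express preferences along a
  concave Pareto front; weights are a modeling choice, not a fit quantity.
* Variable-length design is untested territory: the GA operates at fixed
  length, although the network itself evaluates any length.
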