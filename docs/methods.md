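# Methods

## Model

The core object is a two-layer competitive network: an input layer with one
unit per sensor channel and an output (competitive) layer whose neurons hold
weight vectors acting as cluster prototypes. Presentation of a sample `x`
selects the winner by minimum Euclidean distance; only the winner updates,

    w' = w + η (x − w),

which contracts the winner-to-sample distance by exactly `(1 − η)`. The
per-epoch convergence statistic is the summed squared weight change
`Et = Σ_ij [w_ij(t) − w_ij(t+1)]²`.

The open-structure variant wraps this inner loop with structural edits per
epoch, in this order:

1. **Novelty check per presented sample.** If the cosine similarity
   ("comparability") of the sample to every prototype is below `λ`, a neuron
   is created at the sample. One threshold `λ` serves both novelty and
   merging; the data's class fingerprints differ in direction, which is what
   cosine measures, so a single angular threshold is coherent for both uses.
2. **Empty-neuron deletion** after each pass (a neuron that wins no samples
   carries no information).
3. **Davies–Bouldin (DB) monitoring.** The index is computed with the neuron
   weights as centers — the neurons *are* the model's centers and converge
   to member centroids anyway; a unit test verifies agreement with the
   centroid-based standard implementation when centers coincide with
   centroids. Fewer than two non-empty clusters leaves DB undefined and the
   structural check is skipped.
4. **Repair on DB deterioration.** If DB rose by more than `α` since the
   previous epoch, at most one repair is applied: merge the most comparable
   prototype pair if its cosine exceeds `λ` (size-weighted mean, conserving
   `n_i w_i + n_j w_j`), otherwise split the cluster with the largest mean
   squared member distance into `w ± θσ`. One repair per epoch keeps the
   trace interpretable and prevents oscillating edits.

Weight initialization sets every prototype to the componentwise mean of the
normalized data: all neurons start equally close to every sample, so early
competition separates them along the real class structure rather than
leaving stranded never-winning units (the known pathology of random
initialization, which the fixed baseline retains behind a flag).

### Learning-rate schedule

`η(t) = clip(sin(πt/T), η_min, η_max)` over the presentation counter `t`:
small at the start (prototypes are poorly placed; large steps would encode
noise), maximal mid-training (fast adaptation), decaying to `η_min` so the
network settles. A short-period cyclic variant
`sin(2π(t mod c)/(T·N))` is available via `HyperParams(schedule="cyclic")`
for comparison; it keeps `η` pinned near `η_min` and is not the default
because it cannot produce the rise-then-fall behavior the schedule exists
for.

### Stopping rule

Training stops at `t = T`, or when `Et < ε` with no structural change that
epoch — but the error test is honored only (a) after a DB comparison
between consecutive epochs was possible, and (b) in the decay phase of the
schedule (`t ≥ T/2`). Both guards matter: early in training `η` is tiny by
design, so a small `Et` reflects the step size rather than a settled
network, and stopping there would freeze the structure before it was ever
validated. With the guards, a degenerate single-cluster dataset still
terminates correctly: mid-phase large-`η` jitter perturbs DB, the resulting
rise triggers the merge of the two near-identical prototypes, and the run
converges with one neuron.

`Et` is not comparable across structure changes (the matrices differ in
shape); in epochs with an edit, the trace records the accumulated
per-update squared change instead, and the convergence test is suspended
for that epoch.

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| `θ` | split step, fraction of member spread | 0.1 | children at `w ± θσ` |
| `λ` | comparability threshold | 0.65 | merging and novelty |
| `α` | DB-rise tolerance | 0.028 | repairs trigger above it |
| `ε` | weight-change stop threshold | 0.001 | per epoch |
| `T` | training budget, presentations | 3000 | ≈ 50 epochs at 60 samples |
| `N_init` | initial neuron count | 2 | arbitrary by design |
| `η_min, η_max` | schedule clip bounds | 0.01, 0.9 | keep `η` usable at both ends |

`σ` is the componentwise standard deviation of the split cluster's members:
it keeps `θσ` in data units, so `θ = 0.1` displaces children by a tenth of
the cluster width (the squared, variance-based variant is available behind
`HyperParams(spread="variance")` but makes the offset unit-inconsistent).

Prototype counts after a split divide evenly (remainder to the `+` child);
the next epoch's reassignment corrects them.

## Normalization

Features are min–max rescaled per channel to [0, 1] before training;
constant channels map to 0. The parameters are stored in the model file and
re-applied at prediction time, where out-of-range inputs are deliberately
*not* clipped — an off-scale response is evidence for novelty, and clipping
would erase it.

## Synthetic data

No public dataset accompanies the method, so experiments run on generated
sensor-array features. The generator emulates an 8-channel array of
partially selective metal-oxide sensors bounded to 0–5 V: each analyte class
responds strongly (uniform 2.5–4.5 V) on a 3-channel fingerprint subset and
sits near the clean-air baseline (uniform 0.2–0.8 V) elsewhere; replicate
measurements scatter as a spherical Gaussian (sd 0.15 V, truncated to the
voltage range) around the class mean; 15 replicates per class. Class
placements are rejected until (a) pairwise mean distance is at least
`separation_ratio × spread` (default ratio 8), (b) fingerprint subsets
pairwise share at most one channel, and (c) pairwise cosine of the class
means, evaluated in the min–max frame of the training classes, is at most
0.55. Constraint (c) is the operative one: distinct analytes excite
distinct sensor subsets, i.e. differ in response *direction*, and the
comparability threshold `λ = 0.65` can only separate known from unknown
odors when that holds — the staged unknown-odor experiment presupposes an
odor that is actually distinguishable, as any real deployment of the method
would. The held-out class is excluded from the training file and normalized
with the training-time parameters at prediction.

What the generator does **not** emulate: response transients and sampling
protocol, sensor drift, temperature/humidity covariates, inter-channel
correlated noise, and class overlap. Passing tests therefore demonstrate
the algorithm's behavior under its own working assumptions (separable,
directionally distinct odor classes), not robustness to messy instrument
data.

## Problem sizes and determinism

The bundled experiments use 4 training classes × 15 samples × 8 channels
(T = 3000 ≈ 50 epochs) and a 20-seed battery for all rate estimates; the
DB cross-check uses 200 random instances with up to 6 clusters and 50
points. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); sample order is reshuffled each epoch under
the run's seed, and the whole simulate→fit→predict pipeline is reproducible
byte-for-byte for a fixed seed.

## Numerical choices and edge cases

- Winner ties break to the lowest neuron index; ranking by squared distance
  (used internally) is verified against true-distance ranking.
- Cosine of a zero-norm prototype is treated as 0 in aggregate checks; a
  zero-norm *sample* is an error for the novelty test and is routed to the
  plain winner update during training.
- Merging two empty neurons, splitting a point-mass cluster (zero spread),
  and deleting the last remaining neuron are refused.
- Coincident cluster centers give an infinite DB ratio, which correctly
  pressures the pair toward a merge.
- DB agreement with the brute-force definition is asserted to 1e−9; exact
  algebraic identities (merge conservation, split midpoint symmetry, the
  `(1 − η)` contraction) to 1e−12.

## Known limitations

- `λ` is a single global angular threshold: odor classes that differ only
  in magnitude (same sensors, stronger response) are invisible to the
  novelty test and will be absorbed.
- Cluster-count adaptation relies on DB *changes*; a structure that is
  stably suboptimal from the first epoch (DB monotonically improving toward
  a wrong local optimum) is only escaped through the stochastic jitter of
  the mid-training learning rate.
- The method assumes roughly spherical, comparable-scale clusters in the
  normalized space, inherited from the Euclidean winner rule and the DB
  index.
- At most one merge/split per epoch means structure converges in
  O(true classes) epochs at best; very short budgets `T` can end training
  mid-adaptation.
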