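# enosecnn

Open-structure competitive neural network clustering for electronic-nose
(e-nose) sensor arrays.

An e-nose pairs an array of partially selective gas sensors with a pattern
recognition algorithm: each odor sample becomes a feature vector of
steady-state sensor responses (here 8 channels, 0–5 V), and classification
means clustering those vectors. Classical competitive (winner-take-all)
networks do this simply and fast, but demand the number of odor categories
up front, are sensitive to random initial weights and a hand-picked constant
learning rate, and silently absorb never-seen odors into the nearest known
category. This package implements an open-structure variant that removes all
three limitations, alongside the classical network as a baseline.

## The model

A competitive network holds one weight vector (prototype) `w_i` per output
neuron. For an input `x`, the winner is the neuron minimizing the Euclidean
distance `d(w_i, x) = ||w_i − x||`, and only the winner moves:

    w' = w + η (x − w)

so its distance to `x` contracts by exactly `(1 − η)`. Training stops when
the summed squared weight change per epoch, `Et = Σ [w(t) − w(t+1)]²`, drops
below a threshold `ε`.

The open-structure network edits the prototype set while training:

- **Validity monitoring.** After each epoch the Davies–Bouldin index
  `DB = (1/n) Σ_i max_{j≠i} (d_i + d_j) / d(c_i, c_j)` is evaluated with the
  neuron weights as centers `c_i` and `d_i` the mean member distance; lower
  is better. A rise of more than `α` triggers one structural repair.
- **Merging.** The repair first looks for the most similar prototype pair
  under cosine similarity ("comparability"); if it exceeds `λ` the pair is
  replaced by its size-weighted mean `w = (n_i w_i + n_j w_j)/(n_i + n_j)`.
- **Splitting.** Otherwise the cluster with the largest mean squared member
  distance (its "super-ball volume") is split into `w ± θσ`, with `σ` the
  componentwise spread of its members.
- **Deletion.** Neurons that win no samples are removed each epoch.
- **Novelty.** A sample whose comparability to every prototype falls below
  `λ` spawns a new neuron at that sample — during training and, optionally,
  at prediction time, where it is reported as `NEW_CLASS`.
- **Learning-rate schedule.** `η(t) = clip(sin(πt/T), η_min, η_max)`: small
  while prototypes are poorly placed, largest mid-training, decaying so the
  network settles.

Reference defaults: `θ = 0.1`, `ε = 0.001`, `λ = 0.65`, `α = 0.028`, initial
cluster count `N = 2`, training budget `T = 3000` presentations.

Because no public sensor dataset accompanies the method, the package ships a
synthetic generator that emulates multi-class sensor-array features (distinct
response fingerprints per analyte, Gaussian replicate noise, 0–5 V range)
including a held-out "unknown odor" class; see `docs/methods.md`.

## Worked example

```python
from enosecnn import (AdaptiveCompetitiveNet, HyperParams, generate,
                      make_spec_separated, normalize_minmax)

spec = make_spec_separated(n_classes=4, seed=42)   # 4 odor classes, 8 sensors
X, labels, _ = generate(spec)                      # 60 samples, volts
Xn, params = normalize_minmax(X)                   # per-channel to [0, 1]

res = AdaptiveCompetitiveNet(Xn, HyperParams()).fit(seed=0)
print(res.summary())
```

```
Open-structure competitive network
============================================
samples               60
channels              8
initial neurons       2
final neurons         4
epochs run            49
final Et              4.574e-04
final DB value        0.1222
converged (Et<eps)    True
cluster sizes         [15, 15, 15, 15]
structural events     2
```

Starting from 2 neurons the network grew and settled at 4 — the true number
of classes — with each neuron capturing exactly one class (final DB 0.12;
the weight-change error crossed ε = 0.001 within the 3000-presentation
budget). `res.predict(new_samples, allow_new=True)` then labels samples of a
never-trained odor `NEW_CLASS` instead of forcing them into a known
category, and with `update=True` the first such sample becomes a new neuron.

The same pipeline is scriptable from the shell:

```sh
enosecnn simulate --n-classes 5 --holdout-class 4 --seed 3 --out-dir data/
enosecnn fit data/train.csv --has-labels --seed 3
enosecnn predict data/holdout.csv --has-labels --model model.json
enosecnn evaluate --pred predictions.csv --truth data/train.csv
```

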