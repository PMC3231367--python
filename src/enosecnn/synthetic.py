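"""Synthetic sensor-array feature data with controllable class structure.

Emulates the steady-state feature vectors of a metal-oxide gas-sensor array
(8 partially selective channels, responses bounded to 0-5 V). Each odor class
is modelled as a characteristic response fingerprint: a subset of channels
responds strongly (the analyte's chemistry excites those sensors) while the
rest sit near baseline. Within-class replicate measurements scatter as a
spherical Gaussian around the class mean, truncated to the physical voltage
range.

The fingerprint construction matters: distinct classes differ in *direction*
(which channels respond), not merely in magnitude, which is exactly the
structure the cosine-comparability machinery of the clustering network
assumes and what replicate measurements of chemically distinct headspaces
look like. A held-out class can be excluded from the training file to stage
the "unknown odor presented to a trained network" experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json
import numpy as np


from .io import FeatureMatrix

__all__ = ["SyntheticSpec", "make_spec_separated", "generate"]

V_MIN, V_MAX = 0.0, 5.0


class GenerationError(RuntimeError):
    """Raised when no class-mean placement satisfies the separation demand."""


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic dataset (deterministic given ``seed``)."""

    class_means: np.ndarray          # (n_classes, n_channels), volts in [0, 5]
    class_spreads: np.ndarray        # per-class within-class sd, volts
    n_per_class: np.ndarray          # samples per class
    holdout_class: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_means = np.atleast_2d(np.asarray(self.class_means, dtype=float))
        self.class_spreads = np.asarray(self.class_spreads, dtype=float).ravel()
        self.n_per_class = np.asarray(self.n_per_class, dtype=int).ravel()
        k = self.class_means.shape[0]
        if k < 1:
            raise ValueError("need at least one class")
        if self.class_spreads.size == 1:
            self.class_spreads = np.full(k, float(self.class_spreads[0]))
        if self.n_per_class.size == 1:
            self.n_per_class = np.full(k, int(self.n_per_class[0]))
        if self.class_spreads.size != k or self.n_per_class.size != k:
            raise ValueError("spreads and n_per_class must match the class count")
        if np.any(self.class_spreads < 0):
            raise ValueError("spreads must be nonnegative")
        if np.any(self.n_per_class < 1):
            raise ValueError("n_per_class must be positive")
        if np.any(self.class_means < V_MIN) or np.any(self.class_means > V_MAX):
            raise ValueError(f"class means must lie in [{V_MIN}, {V_MAX}] volts")
        if self.holdout_class is not None and not 0 <= self.holdout_class < k:
            raise ValueError("holdout_class out of range")

    @property
    def n_classes(self) -> int:
        return self.class_means.shape[0]

    @property
    def n_channels(self) -> int:
        return self.class_means.shape[1]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "class_means": self.class_means.tolist(),
            "class_spreads": self.class_spreads.tolist(),
            "n_per_class": self.n_per_class.tolist(),
            "holdout_class": self.holdout_class,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSpec":
        doc = json.loads(Path(path).read_text())
        return cls(
            class_means=np.array(doc["class_means"], dtype=float),
            class_spreads=np.array(doc["class_spreads"], dtype=float),
            n_per_class=np.array(doc["n_per_class"], dtype=int),
            holdout_class=doc.get("holdout_class"),
            seed=int(doc.get("seed", 0)),
        )


def _angularly_separated(means: np.ndarray, holdout_class: int | None,
                         cos_cap: float) -> bool:
    """Check pairwise cosine of class means in the normalized frame.

    Normalization at training time is per-channel min-max over the training
    classes only, so the check is done in that frame: a held-out class is
    excluded from the min/max but still compared against every other class.
    """
    k = means.shape[0]
    if k < 2:
        return True
    train = [c for c in range(k) if c != holdout_class]
    mins = means[train].min(axis=0)
    span = means[train].max(axis=0) - mins
    normed = np.zeros_like(means)
    nz = span > 0
    normed[:, nz] = (means[:, nz] - mins[nz]) / span[nz]
    norms = np.linalg.norm(normed, axis=1)
    if np.any(norms == 0):
        return False
    cos = (normed @ normed.T) / np.outer(norms, norms)
    np.fill_diagonal(cos, -1.0)
    return bool(cos.max() <= cos_cap)


def make_spec_separated(
    n_classes: int,
    n_channels: int = 8,
    separation_ratio: float = 8.0,
    seed: int = 0,
    spread: float = 0.15,
    n_per_class: int = 15,
    holdout_class: int | None = None,
    cos_cap: float = 0.55,
    max_tries: int = 500,
) -> SyntheticSpec:
    """Draw well-separated class fingerprints under a seed.

    Each class mean responds strongly (uniform 2.5-4.5 V) on a small random
    subset of channels and sits near the clean-air baseline (uniform
    0.2-0.8 V) on the rest. Placements are redrawn until every pair of means
    is at least ``separation_ratio * spread`` apart in Euclidean distance,
    responsive subsets barely overlap, and every pair of class means has
    cosine similarity at most ``cos_cap`` in the normalized frame the network
    sees, so fingerprints are distinct in direction as well as position.
    Deterministic
    given ``seed``; raises :class:`GenerationError` if the demand cannot be
    met within ``max_tries`` redraws.
    """
    if separation_ratio <= 0:
        raise ValueError("separation_ratio must be > 0")
    rng = np.random.default_rng(seed)
    # 3 of 8 channels respond per analyte, pairwise sharing at most 1: keeps
    # fingerprints distinct in direction (pairwise cosine well below typical
    # comparability thresholds), which is what chemically distinct headspaces
    # on a partially selective array look like.
    k_resp = max(1, (3 * n_channels) // 8)
    max_overlap = max(0, k_resp // 3)
    min_dist = separation_ratio * spread

    for _ in range(max_tries):
        means = np.empty((n_classes, n_channels))
        subsets: list[set[int]] = []
        ok = True
        for c in range(n_classes):
            placed = False
            for _ in range(max_tries):
                subset = set(rng.choice(n_channels, size=k_resp, replace=False).tolist())
                if any(len(subset & s) > max_overlap for s in subsets):
                    continue
                mean = rng.uniform(0.2, 0.8, size=n_channels)
                mean[list(subset)] = rng.uniform(2.5, 4.5, size=k_resp)
                if c > 0 and np.min(np.linalg.norm(means[:c] - mean, axis=1)) < min_dist:
                    continue
                means[c] = mean
                subsets.append(subset)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok and _angularly_separated(means, holdout_class, cos_cap):
            return SyntheticSpec(
                class_means=means,
                class_spreads=np.full(n_classes, spread),
                n_per_class=np.full(n_classes, n_per_class),
                holdout_class=holdout_class,
                seed=seed,
            )
    raise GenerationError(
        f"could not place {n_classes} class means with min distance {min_dist:.3g} V "
        f"in [{V_MIN}, {V_MAX}]^{n_channels}"
    )


def generate(spec: SyntheticSpec):
    """Sample a dataset from a spec.

    Per class, draws ``n_per_class`` replicates from a spherical Gaussian at
    the class mean with the class spread, clamped to the 0-5 V range. When a
    holdout class is set its samples are returned separately and excluded
    from the training matrix.

    Returns
    -------
    (FeatureMatrix, labels, holdout)
        ``holdout`` is ``(FeatureMatrix, labels)`` or ``None``.
    """
    rng = np.random.default_rng(spec.seed)
    train_rows, train_labels = [], []
    hold_rows, hold_labels = [], []
    for c in range(spec.n_classes):
        samples = rng.normal(
            loc=spec.class_means[c],
            scale=max(spec.class_spreads[c], 0.0) if spec.class_spreads[c] > 0 else 0.0,
            size=(spec.n_per_class[c], spec.n_channels),
        ) if spec.class_spreads[c] > 0 else np.tile(spec.class_means[c], (spec.n_per_class[c], 1))
        samples = np.clip(samples, V_MIN, V_MAX)
        if spec.holdout_class == c:
            hold_rows.append(samples)
            hold_labels.extend([c] * spec.n_per_class[c])
        else:
            train_rows.append(samples)
            train_labels.extend([c] * spec.n_per_class[c])
    X = FeatureMatrix(np.vstack(train_rows))
    holdout = None
    if hold_rows:
        holdout = (FeatureMatrix(np.vstack(hold_rows)), hold_labels)
    return X, train_labels, holdout
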