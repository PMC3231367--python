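"""Open-structure competitive network: DB-driven merge/split/delete, novelty.

The fixed baseline in :mod:`enosecnn.network` needs the cluster count chosen
up front and a hand-picked constant learning rate. The open-structure variant
removes both constraints:

* the learning rate follows a rise-then-fall schedule over the training
  budget, so prototypes move cautiously at first, adapt aggressively
  mid-training and settle at the end;
* the number of output neurons is edited during training, guided by the
  Davies-Bouldin (DB) cluster-validity index: when DB worsens (rises) by more
  than a threshold ``alpha``, the two most similar prototypes are merged if
  their cosine similarity ("comparability") exceeds ``lambda_sim``, otherwise
  the most dispersed cluster (largest mean squared member distance, the
  "super-ball volume") is split in two along its spread vector;
* neurons that capture no samples are deleted each epoch;
* a sample whose comparability to every prototype falls below ``lambda_sim``
  is treated as a new odor category and a neuron is created at that sample —
  the same test serves as new-class detection at prediction time.

Starting from an arbitrary initial neuron count (typically 2), the network
converges to the number of distinguishable odor classes present in the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import FeatureMatrix
from .network import (
    NetworkState,
    TrainingTrace,
    distance,
    find_winner,
    init_weights_uniform,
    update_winner,
    weight_change_error,
    _assign_all,
)

__all__ = [
    "NEW_CLASS",
    "HyperParams",
    "ClusterSummary",
    "PredictionResult",
    "learning_rate",
    "db_index",
    "comparability",
    "merge_neurons",
    "superball_volume",
    "split_neuron",
    "delete_empty",
    "check_novel",
    "add_neuron",
    "fit",
    "predict",
    "AdaptiveCompetitiveNet",
    "AdaptiveCompetitiveResults",
]

#: Sentinel label for "does not belong to any trained category".
NEW_CLASS = -1


class UndefinedDBError(ValueError):
    """DB index needs at least two non-empty clusters."""


class DegenerateVectorError(ValueError):
    """Cosine similarity is undefined for a zero-norm vector."""


@dataclass
class HyperParams:
    """All tunables of the open-structure network in one place.

    Parameters
    ----------
    theta : float in (0, 1)
        Split step: children land at w +/- theta * spread.
    lambda_sim : float in (0, 1]
        Comparability (cosine) threshold, used both for merging prototype
        pairs and for novelty detection.
    alpha : float > 0
        DB-increase threshold triggering a structural repair.
    epsilon : float > 0
        Weight-change error threshold for convergence.
    T : int > 0
        Total training budget in sample presentations.
    c : int > 0
        Presentations of each sample per epoch.
    n_init : int > 0
        Initial number of output neurons.
    eta_min, eta_max : float
        Clipping bounds of the learning-rate schedule.
    schedule : {"half_sine", "cyclic"}
        "half_sine" (default) rises from eta_min to eta_max at mid-training
        and falls back; "cyclic" is the literal short-period variant
        sin(2*pi*(t mod c)/(T*N)), kept for comparison.
    spread : {"std", "variance"}
        Whether the split offset vector is the componentwise standard
        deviation (default, same units as the data) or variance.
    """

    theta: float = 0.1
    lambda_sim: float = 0.65
    alpha: float = 0.028
    epsilon: float = 0.001
    T: int = 3000
    c: int = 1
    n_init: int = 2
    eta_min: float = 0.01
    eta_max: float = 0.9
    schedule: str = "half_sine"
    spread: str = "std"

    def __post_init__(self) -> None:
        if not 0 < self.theta < 1:
            raise ValueError("theta must be in (0, 1)")
        if not 0 < self.lambda_sim <= 1:
            raise ValueError("lambda_sim must be in (0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.T < 1 or self.c < 1 or self.n_init < 1:
            raise ValueError("T, c and n_init must be positive integers")
        if not 0 < self.eta_min <= self.eta_max <= 1:
            raise ValueError("require 0 < eta_min <= eta_max <= 1")
        if self.schedule not in ("half_sine", "cyclic"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.spread not in ("std", "variance"):
            raise ValueError(f"unknown spread {self.spread!r}")

    def to_dict(self) -> dict:
        return {
            "theta": self.theta, "lambda_sim": self.lambda_sim,
            "alpha": self.alpha, "epsilon": self.epsilon, "T": self.T,
            "c": self.c, "n_init": self.n_init, "eta_min": self.eta_min,
            "eta_max": self.eta_max, "schedule": self.schedule,
            "spread": self.spread,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HyperParams":
        return cls(**d)


@dataclass
class ClusterSummary:
    """Per-cluster statistics: center, scatter, dispersion, spread, size."""

    center: np.ndarray
    size: int
    mean_dist: float | None
    volume: float | None
    spread: np.ndarray | None

    @property
    def empty(self) -> bool:
        return self.size == 0


@dataclass
class PredictionResult:
    """Outcome of classifying one sample against a trained network."""

    label: int
    similarity: float
    distance: float

    @property
    def is_new(self) -> bool:
        return self.label == NEW_CLASS


def learning_rate(t: int, hp: HyperParams, n_current: int = 1) -> float:
    """Scheduled learning rate at presentation ``t``.

    The default half-sine schedule clip(sin(pi*t/T), eta_min, eta_max) is
    small at the start (cautious while prototypes are poorly placed), largest
    at mid-training, and decays to eta_min at the end so the network settles.
    The "cyclic" variant evaluates sin(2*pi*(t mod c)/(T*N)) instead.
    """
    if t < 0 or t > hp.T:
        raise ValueError(f"t must be in [0, T], got {t}")
    if hp.schedule == "half_sine":
        raw = math.sin(math.pi * t / hp.T)
    else:
        raw = math.sin(2.0 * math.pi * (t % hp.c) / (hp.T * max(n_current, 1)))
    return float(min(max(raw, hp.eta_min), hp.eta_max))


def comparability(w_i: np.ndarray, w_j: np.ndarray) -> float:
    """Cosine similarity between two vectors, the "comparability" measure."""
    w_i = np.asarray(w_i, dtype=float)
    w_j = np.asarray(w_j, dtype=float)
    if w_i.shape != w_j.shape:
        raise ValueError(f"shape mismatch: {w_i.shape} vs {w_j.shape}")
    ni = float(np.linalg.norm(w_i))
    nj = float(np.linalg.norm(w_j))
    if ni == 0.0 or nj == 0.0:
        raise DegenerateVectorError("comparability undefined for zero-norm vector")
    return float(np.dot(w_i, w_j) / (ni * nj))


def _safe_comparability(w_i: np.ndarray, w_j: np.ndarray) -> float:
    """Comparability with the zero-norm convention (similarity 0)."""
    try:
        return comparability(w_i, w_j)
    except DegenerateVectorError:
        return 0.0


def db_index(X_norm: FeatureMatrix | np.ndarray, assignments: np.ndarray,
             state: NetworkState) -> float:
    """Davies-Bouldin validity index with neuron weights as cluster centers.

    DB = (1/n) * sum_i max_{j != i} (d_i + d_j) / d(c_i, c_j)

    where d_i is the mean Euclidean distance of cluster i's members to its
    center c_i (the neuron's weight row). Lower is better; the minimum marks
    the best partition. Only non-empty clusters participate; fewer than two
    of them leaves the index undefined.
    """
    X = X_norm.values if isinstance(X_norm, FeatureMatrix) else np.asarray(X_norm, dtype=float)
    assignments = np.asarray(assignments)
    occupied = [k for k in range(state.n_clusters) if np.any(assignments == k)]
    if len(occupied) < 2:
        raise UndefinedDBError("DB index needs >= 2 non-empty clusters")
    centers = state.weights[occupied]
    d = np.array([
        float(np.mean(np.linalg.norm(X[assignments == k] - state.weights[k], axis=1)))
        for k in occupied
    ])
    n = len(occupied)
    total = 0.0
    for i in range(n):
        best = -np.inf
        for j in range(n):
            if j == i:
                continue
            sep = float(np.linalg.norm(centers[i] - centers[j]))
            ratio = np.inf if sep == 0.0 else (d[i] + d[j]) / sep
            best = max(best, ratio)
        total += best
    return float(total / n)


def merge_neurons(w_i: np.ndarray, w_j: np.ndarray, n_i: int, n_j: int) -> np.ndarray:
    """Size-weighted mean of two prototypes: (n_i*w_i + n_j*w_j)/(n_i + n_j)."""
    if n_i + n_j < 1:
        raise ValueError("cannot merge two empty neurons")
    w_i = np.asarray(w_i, dtype=float)
    w_j = np.asarray(w_j, dtype=float)
    return (n_i * w_i + n_j * w_j) / (n_i + n_j)


def superball_volume(members: np.ndarray, w_k: np.ndarray) -> float:
    """Mean squared Euclidean distance of a cluster's members to its center.

    The cluster with the largest volume is the split candidate.
    """
    members = np.atleast_2d(np.asarray(members, dtype=float))
    if members.shape[0] < 1 or members.size == 0:
        raise ValueError("super-ball volume undefined for an empty cluster")
    diff = members - np.asarray(w_k, dtype=float)
    return float(np.mean(np.einsum("ij,ij->i", diff, diff)))


def split_neuron(w_m: np.ndarray, sigma_k: np.ndarray, theta: float):
    """Split one prototype into two, offset +/- theta*sigma along the spread.

    Returns ``(w_m + theta*sigma_k, w_m - theta*sigma_k)``; their midpoint is
    exactly the parent.
    """
    if not 0 < theta < 1:
        raise ValueError("theta must be in (0, 1)")
    sigma_k = np.asarray(sigma_k, dtype=float)
    if np.any(sigma_k < 0):
        raise ValueError("spread vector must be componentwise nonnegative")
    if np.all(sigma_k == 0):
        raise ValueError("refusing to split a point-mass cluster (zero spread)")
    w_m = np.asarray(w_m, dtype=float)
    return w_m + theta * sigma_k, w_m - theta * sigma_k


def delete_empty(state: NetworkState, assignments: np.ndarray) -> NetworkState:
    """Remove every neuron with no assigned samples, preserving row order."""
    assignments = np.asarray(assignments)
    counts = np.bincount(assignments, minlength=state.n_clusters)
    keep = counts > 0
    if not np.any(keep):
        raise ValueError("deleting empty neurons would leave no neurons")
    return NetworkState(state.weights[keep], counts[keep])


def check_novel(x: np.ndarray, state: NetworkState, lambda_sim: float):
    """Novelty test: is ``x`` unlike every stored prototype?

    Returns ``(is_novel, best_similarity, best_index)``; novel iff the best
    comparability over all neurons falls below ``lambda_sim``.
    """
    if state.n_clusters < 1:
        raise ValueError("network has no output neurons")
    x = np.asarray(x, dtype=float)
    if np.linalg.norm(x) == 0.0:
        raise DegenerateVectorError("novelty check undefined for zero-norm sample")
    sims = np.array([_safe_comparability(x, w) for w in state.weights])
    best = int(np.argmax(sims))
    return bool(sims[best] < lambda_sim), float(sims[best]), best


def add_neuron(state: NetworkState, x_new: np.ndarray) -> NetworkState:
    """Append one neuron whose weights are exactly the novel sample."""
    x_new = np.asarray(x_new, dtype=float)
    if x_new.shape != (state.n_channels,):
        raise ValueError(
            f"sample length {x_new.shape} does not match channels {state.n_channels}"
        )
    return NetworkState(
        np.vstack([state.weights, x_new[None, :]]),
        np.concatenate([state.counts, [1]]),
    )


def cluster_summaries(X_norm, assignments: np.ndarray, state: NetworkState) -> list[ClusterSummary]:
    """Per-cluster center, scatter, super-ball volume and spread vector."""
    X = X_norm.values if isinstance(X_norm, FeatureMatrix) else np.asarray(X_norm, dtype=float)
    assignments = np.asarray(assignments)
    out = []
    for k in range(state.n_clusters):
        members = X[assignments == k]
        if members.shape[0] == 0:
            out.append(ClusterSummary(state.weights[k].copy(), 0, None, None, None))
        else:
            out.append(
                ClusterSummary(
                    center=state.weights[k].copy(),
                    size=int(members.shape[0]),
                    mean_dist=float(np.mean(np.linalg.norm(members - state.weights[k], axis=1))),
                    volume=superball_volume(members, state.weights[k]),
                    spread=members.std(axis=0),
                )
            )
    return out


def _try_repair(state: NetworkState, X: np.ndarray, assignments: np.ndarray,
                hp: HyperParams) -> tuple[NetworkState, str]:
    """One structural repair after a DB rise: merge the most comparable pair
    if it clears lambda_sim, else split the largest-volume cluster."""
    n = state.n_clusters
    # most similar prototype pair
    best_pair, best_sim = None, -np.inf
    for i in range(n):
        for j in range(i + 1, n):
            s = _safe_comparability(state.weights[i], state.weights[j])
            if s > best_sim:
                best_sim, best_pair = s, (i, j)
    if best_pair is not None and best_sim > hp.lambda_sim and n > 1:
        i, j = best_pair
        ni, nj = int(state.counts[i]), int(state.counts[j])
        if ni + nj >= 1:
            w_new = merge_neurons(state.weights[i], state.weights[j], ni, nj)
            keep = [k for k in range(n) if k not in (i, j)]
            weights = np.vstack([state.weights[keep], w_new[None, :]]) if keep else w_new[None, :]
            counts = np.concatenate([state.counts[keep], [ni + nj]])
            return NetworkState(weights, counts), "merge"
    # otherwise split the most dispersed cluster
    volumes = np.full(n, -np.inf)
    for k in range(n):
        members = X[assignments == k]
        if members.shape[0] > 0:
            volumes[k] = superball_volume(members, state.weights[k])
    m = int(np.argmax(volumes))
    members = X[assignments == m]
    if members.shape[0] == 0:
        return state, "none"
    sigma = members.std(axis=0)
    if hp.spread == "variance":
        sigma = sigma ** 2
    if np.all(sigma == 0):
        return state, "none"  # point-mass cluster, split refused
    w1, w2 = split_neuron(state.weights[m], sigma, hp.theta)
    nm = int(state.counts[m])
    keep = [k for k in range(n) if k != m]
    weights = np.vstack([state.weights[keep], w1[None, :], w2[None, :]]) if keep \
        else np.vstack([w1[None, :], w2[None, :]])
    counts = np.concatenate([state.counts[keep], [nm - nm // 2, nm // 2]])
    return NetworkState(weights, counts), "split"


def fit(X_norm: FeatureMatrix, hp: HyperParams, seed: int = 0):
    """Train the open-structure competitive network.

    Starting from ``hp.n_init`` neurons all initialized at the data mean, each
    epoch presents every sample ``hp.c`` times in a freshly shuffled order.
    A sample failing the novelty test spawns a neuron at its position;
    otherwise the nearest neuron moves toward it at the scheduled learning
    rate. After each pass, empty neurons are deleted and the DB index is
    evaluated; a DB rise exceeding ``hp.alpha`` triggers at most one repair
    (merge of the most comparable pair above ``hp.lambda_sim``, else split of
    the most dispersed cluster). Training stops when the epoch weight-change
    error drops below ``hp.epsilon`` with no structural change in that epoch,
    or when ``hp.T`` presentations are spent.

    Returns
    -------
    (NetworkState, TrainingTrace, assignments)
    """
    if not isinstance(X_norm, FeatureMatrix):
        X_norm = FeatureMatrix(np.asarray(X_norm, dtype=float))
    X = X_norm.values
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in feature matrix")
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    state = init_weights_uniform(hp.n_init, X_norm)

    trace = TrainingTrace()
    prev_db: float | None = None
    t = 0
    epoch = 0
    assignments = _assign_all(state, X)
    while t < hp.T:
        epoch += 1
        events: list[str] = []
        W_before = state.weights.copy()
        accum_sq = 0.0  # per-update fallback when the structure changes mid-epoch
        eta = hp.eta_min
        order = np.concatenate([rng.permutation(n) for _ in range(hp.c)])
        for idx in order:
            if t >= hp.T:
                break
            x = X[idx]
            eta = learning_rate(t, hp, state.n_clusters)
            try:
                novel, _, _ = check_novel(x, state, hp.lambda_sim)
            except DegenerateVectorError:
                novel = False
            if novel:
                state = add_neuron(state, x)
                events.append("add")
            else:
                win = find_winner(state, x)
                w_new = update_winner(state.weights[win], x, eta)
                accum_sq += float(np.sum((w_new - state.weights[win]) ** 2))
                state.weights[win] = w_new
            t += 1

        assignments = _assign_all(state, X)
        state.counts = np.bincount(assignments, minlength=state.n_clusters)
        if np.any(state.counts == 0) and np.any(state.counts > 0):
            state = delete_empty(state, assignments)
            assignments = _assign_all(state, X)
            state.counts = np.bincount(assignments, minlength=state.n_clusters)
            events.append("delete")

        try:
            db = db_index(X_norm, assignments, state)
        except UndefinedDBError:
            db = None
        compared = db is not None and prev_db is not None
        if compared and (db - prev_db) > hp.alpha:
            state, ev = _try_repair(state, X, assignments, hp)
            if ev != "none":
                events.append(ev)
                assignments = _assign_all(state, X)
                state.counts = np.bincount(assignments, minlength=state.n_clusters)
        prev_db = db

        structural = bool(events)
        # The error-based stop is only reachable after a DB comparison was
        # possible (or once DB is undefined outright, e.g. a single cluster),
        # and only in the decay phase of the learning-rate schedule: while
        # eta is still ramping up, a small Et reflects the small step size,
        # not a settled network.
        stoppable = (compared or (db is None and epoch >= 2)) and t >= hp.T // 2
        if state.weights.shape == W_before.shape and not structural:
            Et = weight_change_error(W_before, state.weights)
        else:
            Et = accum_sq
        for ev in ("merge", "split", "delete", "add"):
            if ev in events:
                event = ev
                break
        else:
            event = "none"
        trace.append(epoch, Et, db, state.n_clusters, eta, event)
        if stoppable and not structural and Et < hp.epsilon:
            break
    return state, trace, assignments


def predict(state: NetworkState, hp: HyperParams, x: np.ndarray,
            allow_new: bool = True) -> PredictionResult:
    """Classify one sample against a trained network.

    With ``allow_new``, a sample whose best comparability to every prototype
    falls below ``hp.lambda_sim`` is labelled :data:`NEW_CLASS`; otherwise the
    nearest neuron's index is returned regardless (the closed-world behavior
    of the fixed baseline, which absorbs unknown odors into the nearest
    existing category).
    """
    x = np.asarray(x, dtype=float)
    novel, best_sim, _ = check_novel(x, state, hp.lambda_sim)
    win = find_winner(state, x)
    dist = distance(state.weights[win], x)
    if allow_new and novel:
        return PredictionResult(NEW_CLASS, best_sim, dist)
    return PredictionResult(win, best_sim, dist)


# ---------------------------------------------------------------------------
# Model/Results interface


class AdaptiveCompetitiveNet:
    """Open-structure competitive network model.

    Parameters
    ----------
    X : FeatureMatrix or array-like
        Feature matrix, assumed normalized to roughly [0, 1].
    hp : HyperParams, optional
        Tunables; defaults are the reference settings (theta=0.1,
        lambda=0.65, alpha=0.028, epsilon=0.001, N_init=2, T=3000).
    """

    def __init__(self, X, hp: HyperParams | None = None):
        self.X = X if isinstance(X, FeatureMatrix) else FeatureMatrix(np.asarray(X, dtype=float))
        self.hp = hp or HyperParams()

    @classmethod
    def from_dataframe(cls, df, hp: HyperParams | None = None):
        return cls(
            FeatureMatrix(df.to_numpy(dtype=float), channel_ids=list(map(str, df.columns))),
            hp=hp,
        )

    def fit(self, seed: int = 0) -> "AdaptiveCompetitiveResults":
        state, trace, assignments = fit(self.X, self.hp, seed=seed)
        return AdaptiveCompetitiveResults(self, state, trace, assignments, seed)


class AdaptiveCompetitiveResults:
    """Fit results: final prototypes, assignments, per-epoch trace."""

    def __init__(self, model, state, trace, assignments, seed,
                 norm=None):
        self.model = model
        self.state = state
        self.trace = trace
        self.assignments = np.asarray(assignments)
        self.seed = seed
        self.norm = norm  # optional NormalizationParams for raw-volt inputs

    @property
    def hp(self) -> HyperParams:
        return self.model.hp

    @property
    def weights(self) -> np.ndarray:
        return self.state.weights

    @property
    def n_clusters(self) -> int:
        return self.state.n_clusters

    @property
    def converged(self) -> bool:
        return bool(
            self.trace.Et
            and self.trace.Et[-1] < self.hp.epsilon
            and self.trace.events[-1] == "none"
        )

    def cluster_summaries(self) -> list[ClusterSummary]:
        return cluster_summaries(self.model.X, self.assignments, self.state)

    def predict(self, X, allow_new: bool = True, update: bool = False):
        """Classify samples; optionally grow the network on novel ones.

        With ``update=True`` (online mode) each novel sample immediately
        becomes a new neuron, so subsequent samples of the same new odor are
        recognized as that category.
        """
        X = X.values if isinstance(X, FeatureMatrix) else np.atleast_2d(np.asarray(X, dtype=float))
        results = []
        for x in X:
            res = predict(self.state, self.hp, x, allow_new=allow_new)
            if update and res.is_new:
                self.state = add_neuron(self.state, x)
            results.append(res)
        return results

    def summary(self) -> str:
        db_final = next((v for v in reversed(self.trace.db) if v is not None), None)
        lines = [
            "Open-structure competitive network",
            "=" * 44,
            f"samples               {self.model.X.n_samples}",
            f"channels              {self.model.X.n_channels}",
            f"initial neurons       {self.hp.n_init}",
            f"final neurons         {self.n_clusters}",
            f"epochs run            {len(self.trace)}",
            f"final Et              {self.trace.Et[-1]:.3e}" if self.trace.Et else "final Et              n/a",
            f"final DB value        {'n/a' if db_final is None else f'{db_final:.4f}'}",
            f"converged (Et<eps)    {self.converged}",
            f"cluster sizes         {self.state.counts.tolist()}",
            f"structural events     {sum(e != 'none' for e in self.trace.events)}",
        ]
        return "\n".join(lines)
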