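"""Classic two-layer competitive (winner-take-all) network.

Output-layer neurons hold weight vectors acting as cluster prototypes.
Each input sample excites the neuron whose weights are nearest in Euclidean
distance; only that winner moves, by a fraction eta of its offset to the
sample:

    w' = w + eta * (x - w)

Training stops once the summed squared weight change over an epoch,

    Et = sum_ij [w_ij(t) - w_ij(t+1)]^2

drops below a threshold epsilon, or the iteration budget is spent. This
module provides the fixed-structure baseline (cluster count chosen in
advance, constant learning rate); the open-structure variant that edits the
prototype set during training lives in :mod:`enosecnn.adaptive`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import FeatureMatrix

__all__ = [
    "NetworkState",
    "TrainingTrace",
    "distance",
    "find_winner",
    "update_winner",
    "weight_change_error",
    "init_weights_uniform",
    "init_weights_random",
    "train_fixed",
    "FixedCompetitiveNet",
    "FixedCompetitiveResults",
]


@dataclass
class NetworkState:
    """Weights (one row per output neuron) and per-neuron assignment counts."""

    weights: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.weights.ndim != 2:
            raise ValueError("weights must be a 2-d matrix")
        if self.counts.shape != (self.weights.shape[0],):
            raise ValueError("counts length must equal the number of neurons")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_clusters(self) -> int:
        return self.weights.shape[0]

    @property
    def n_channels(self) -> int:
        return self.weights.shape[1]

    def copy(self) -> "NetworkState":
        return NetworkState(self.weights.copy(), self.counts.copy())


@dataclass
class TrainingTrace:
    """Per-epoch record of the training dynamics.

    Machine-readable twin of the usual convergence plots: weight-change error
    Et, cluster-validity (DB) value where defined, cluster count, learning
    rate, and any structural event in that epoch.
    """

    epochs: list[int] = field(default_factory=list)
    Et: list[float] = field(default_factory=list)
    db: list[float | None] = field(default_factory=list)
    n_clusters: list[int] = field(default_factory=list)
    eta: list[float] = field(default_factory=list)
    events: list[str] = field(default_factory=list)

    def append(self, epoch, Et, db, n_clusters, eta, event="none") -> None:
        if self.epochs and epoch <= self.epochs[-1]:
            raise ValueError("epoch index must be strictly increasing")
        if Et < 0:
            raise ValueError("Et must be nonnegative")
        self.epochs.append(int(epoch))
        self.Et.append(float(Et))
        self.db.append(None if db is None else float(db))
        self.n_clusters.append(int(n_clusters))
        self.eta.append(float(eta))
        self.events.append(str(event))

    def __len__(self) -> int:
        return len(self.epochs)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": self.epochs,
                "Et": self.Et,
                "DB": [np.nan if v is None else v for v in self.db],
                "n_clusters": self.n_clusters,
                "eta": self.eta,
                "event": self.events,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def distance(w: np.ndarray, x: np.ndarray) -> float:
    """Euclidean distance between a weight vector and a sample vector."""
    w = np.asarray(w, dtype=float)
    x = np.asarray(x, dtype=float)
    if w.shape != x.shape:
        raise ValueError(f"shape mismatch: {w.shape} vs {x.shape}")
    return float(np.sqrt(np.dot(w - x, w - x)))


def find_winner(state: NetworkState, x: np.ndarray) -> int:
    """Index of the neuron nearest to ``x``; ties broken by lowest index."""
    if state.n_clusters < 1:
        raise ValueError("network has no output neurons")
    x = np.asarray(x, dtype=float)
    diff = state.weights - x
    # argmin on squared distance: same winner as true distance (monotone map)
    return int(np.argmin(np.einsum("ij,ij->i", diff, diff)))


def update_winner(w: np.ndarray, x: np.ndarray, eta: float) -> np.ndarray:
    """Move the winner toward the sample: ``w + eta*(x - w)``.

    The winner-to-sample distance contracts by exactly the factor (1 - eta).
    """
    if not 0 < eta <= 1:
        raise ValueError(f"eta must be in (0, 1], got {eta}")
    w = np.asarray(w, dtype=float)
    x = np.asarray(x, dtype=float)
    if w.shape != x.shape:
        raise ValueError(f"shape mismatch: {w.shape} vs {x.shape}")
    return w + eta * (x - w)


def weight_change_error(W_prev: np.ndarray, W_next: np.ndarray) -> float:
    """Summed squared entrywise weight change Et between two snapshots.

    Only defined while the structure is unchanged; a row-count mismatch means
    neurons were added/removed in between and raises.
    """
    W_prev = np.asarray(W_prev, dtype=float)
    W_next = np.asarray(W_next, dtype=float)
    if W_prev.shape != W_next.shape:
        raise ValueError(
            f"weight matrices not comparable: {W_prev.shape} vs {W_next.shape} "
            "(structure changed)"
        )
    d = W_prev - W_next
    return float(np.sum(d * d))


def init_weights_uniform(n_clusters: int, X_norm: FeatureMatrix) -> NetworkState:
    """All neurons start at the same point: the componentwise mean of the data.

    Starting every prototype at the centre of the normalized feature cloud
    keeps the initial weights close to all samples, so the first competitive
    updates pull prototypes apart along the real class structure instead of
    leaving stranded neurons that never win.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if X_norm.n_samples < 1:
        raise ValueError("empty feature matrix")
    mean = X_norm.values.mean(axis=0)
    weights = np.tile(mean, (n_clusters, 1))
    return NetworkState(weights, np.zeros(n_clusters, dtype=int))


def init_weights_random(n_clusters: int, n_channels: int, rng: np.random.Generator) -> NetworkState:
    """Random initial weights in [0, 1], the textbook baseline initialization."""
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    weights = rng.uniform(0.0, 1.0, size=(n_clusters, n_channels))
    return NetworkState(weights, np.zeros(n_clusters, dtype=int))


def _assign_all(state: NetworkState, X: np.ndarray) -> np.ndarray:
    d2 = ((X[:, None, :] - state.weights[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def train_fixed(
    X_norm: FeatureMatrix,
    n_clusters: int,
    eta: float = 0.4,
    T: int = 3000,
    epsilon: float = 0.001,
    seed: int = 0,
    init: str = "random",
    initial_state: NetworkState | None = None,
):
    """Train a fixed-structure competitive network.

    Presents samples in a freshly shuffled order each epoch, updating only the
    winner at the constant rate ``eta``, until the per-epoch weight-change
    error Et falls below ``epsilon`` or ``T`` sample presentations have been
    spent.

    Parameters
    ----------
    init : {"random", "uniform"}
        "random" draws initial weights uniformly in [0, 1] (the textbook
        baseline, prone to slow convergence and dead units); "uniform" starts
        all neurons at the data mean.

    Returns
    -------
    (NetworkState, TrainingTrace)
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if not 0 < eta <= 1:
        raise ValueError("eta must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if initial_state is not None:
        if initial_state.n_clusters != n_clusters:
            raise ValueError("initial_state cluster count disagrees with n_clusters")
        state = initial_state.copy()
    elif init == "random":
        state = init_weights_random(n_clusters, X_norm.n_channels, rng)
    elif init == "uniform":
        state = init_weights_uniform(n_clusters, X_norm)
    else:
        raise ValueError(f"unknown init {init!r}")

    X = X_norm.values
    n = X.shape[0]
    trace = TrainingTrace()
    t = 0
    epoch = 0
    while t < T:
        epoch += 1
        W_before = state.weights.copy()
        order = rng.permutation(n)
        for idx in order:
            if t >= T:
                break
            win = find_winner(state, X[idx])
            state.weights[win] = update_winner(state.weights[win], X[idx], eta)
            t += 1
        Et = weight_change_error(W_before, state.weights)
        assignments = _assign_all(state, X)
        state.counts = np.bincount(assignments, minlength=state.n_clusters)
        trace.append(epoch, Et, None, state.n_clusters, eta)
        if Et < epsilon:
            break
    return state, trace


# ---------------------------------------------------------------------------
# Model/Results interface


class FixedCompetitiveNet:
    """Fixed-structure competitive network model (baseline).

    The cluster count is chosen in advance and never changes; the learning
    rate is constant. Serves as the reference the open-structure network is
    compared against.

    Parameters
    ----------
    X : FeatureMatrix or array-like
        Feature matrix, assumed already normalized to roughly [0, 1].
    n_clusters : int
        Number of output neurons, fixed for the whole run.
    eta : float
        Constant learning rate (default 0.4).
    """

    def __init__(self, X, n_clusters: int, eta: float = 0.4, T: int = 3000,
                 epsilon: float = 0.001, init: str = "random"):
        self.X = X if isinstance(X, FeatureMatrix) else FeatureMatrix(np.asarray(X, dtype=float))
        self.n_clusters = int(n_clusters)
        self.eta = float(eta)
        self.T = int(T)
        self.epsilon = float(epsilon)
        self.init = init

    @classmethod
    def from_dataframe(cls, df, **kwargs):
        return cls(FeatureMatrix(df.to_numpy(dtype=float), channel_ids=list(map(str, df.columns))), **kwargs)

    def fit(self, seed: int = 0) -> "FixedCompetitiveResults":
        state, trace = train_fixed(
            self.X, self.n_clusters, eta=self.eta, T=self.T,
            epsilon=self.epsilon, seed=seed, init=self.init,
        )
        assignments = _assign_all(state, self.X.values)
        return FixedCompetitiveResults(self, state, trace, assignments, seed)


class FixedCompetitiveResults:
    """Fit results of a :class:`FixedCompetitiveNet`."""

    def __init__(self, model, state, trace, assignments, seed):
        self.model = model
        self.state = state
        self.trace = trace
        self.assignments = np.asarray(assignments)
        self.seed = seed

    @property
    def weights(self) -> np.ndarray:
        return self.state.weights

    @property
    def converged(self) -> bool:
        return bool(self.trace.Et and self.trace.Et[-1] < self.model.epsilon)

    @property
    def n_epochs(self) -> int:
        return len(self.trace)

    def predict(self, X) -> np.ndarray:
        X = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
        return _assign_all(self.state, np.atleast_2d(X))

    def summary(self) -> str:
        lines = [
            "Fixed-structure competitive network",
            "=" * 44,
            f"samples              {self.model.X.n_samples}",
            f"channels             {self.model.X.n_channels}",
            f"output neurons       {self.state.n_clusters}",
            f"learning rate (eta)  {self.model.eta}",
            f"epochs run           {self.n_epochs}",
            f"final Et             {self.trace.Et[-1]:.3e}" if self.trace.Et else "final Et             n/a",
            f"converged (Et<eps)   {self.converged}",
            f"cluster sizes        {self.state.counts.tolist()}",
        ]
        return "\n".join(lines)
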