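"""Feature-matrix I/O, min-max normalization and model serialization.

The package consumes steady-state sensor-array feature vectors (one row per
odor sample, one column per sensor channel) supplied as delimited text.
Features are rescaled per channel to [0, 1] before training; the affine
parameters are stored with the model so that prediction applies exactly the
training-time transform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
from typing import Sequence


import pandas as pd

__all__ = [
    "FeatureMatrix",
    "NormalizationParams",
    "read_feature_csv",
    "normalize_minmax",
    "apply_normalization",
    "save_model",
    "load_model",
]


class ParseError(ValueError):
    """Raised when a feature file contains non-numeric or malformed cells."""


class DeserializationError(ValueError):
    """Raised when a saved model file cannot be decoded."""


@dataclass
class FeatureMatrix:
    """Samples x channels matrix of sensor responses.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_channels)
        Feature values; must be finite.
    sample_ids, channel_ids : sequence of str, optional
        Row / column identifiers carried through I/O.
    """

    values: np.ndarray
    sample_ids: list[str] | None = None
    channel_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-dimensional")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("feature matrix needs at least 1 sample and 1 channel")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        cols = self.channel_ids or [f"ch{j}" for j in range(self.n_channels)]
        return pd.DataFrame(self.values, columns=cols)


@dataclass
class NormalizationParams:
    """Per-channel minimum and maximum in original units (volts)."""

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if self.mins.shape != self.maxs.shape or self.mins.ndim != 1:
            raise ValueError("mins and maxs must be 1-d arrays of equal length")
        if np.any(self.maxs < self.mins):
            raise ValueError("per-channel max must be >= min")

    @property
    def n_channels(self) -> int:
        return self.mins.size


def read_feature_csv(path: str | Path, has_labels: bool = False):
    """Read a delimited feature file, optionally with a trailing label column.

    Comma-separated, "." decimal; an optional single header row is detected by
    a non-numeric first row. Returns ``(FeatureMatrix, labels-or-None)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = path.read_text().strip()
    if not raw:
        raise ParseError(f"{path}: empty input file")
    lines = [ln for ln in raw.splitlines() if ln.strip()]
    rows = [ln.split(",") for ln in lines]

    def _numeric(cell: str) -> bool:
        try:
            float(cell)
            return True
        except ValueError:
            return False

    header = None
    first_feats = rows[0][:-1] if has_labels else rows[0]
    if not all(_numeric(c) for c in first_feats):
        header = [c.strip() for c in rows[0]]
        rows = rows[1:]
        if not rows:
            raise ParseError(f"{path}: header only, no data rows")

    ncol = len(rows[0])
    labels: list[str] | None = [] if has_labels else None
    data = []
    for i, row in enumerate(rows):
        if len(row) != ncol:
            raise ParseError(f"{path}: row {i + 1} has {len(row)} fields, expected {ncol}")
        feats = row[:-1] if has_labels else row
        vals = []
        for j, cell in enumerate(feats):
            if not _numeric(cell):
                raise ParseError(
                    f"{path}: non-numeric feature cell {cell!r} at row {i + 1}, column {j + 1}"
                )
            vals.append(float(cell))
        data.append(vals)
        if has_labels:
            labels.append(row[-1].strip())
    channel_ids = None
    if header is not None:
        channel_ids = header[:-1] if has_labels else header
    X = FeatureMatrix(np.array(data, dtype=float), channel_ids=channel_ids)
    return X, labels


def write_feature_csv(
    path: str | Path,
    X: FeatureMatrix,
    labels: Sequence | None = None,
    header: bool = True,
) -> None:
    """Write a feature matrix (and optional trailing label column) as CSV."""
    path = Path(path)
    cols = X.channel_ids or [f"ch{j}" for j in range(X.n_channels)]
    with path.open("w") as fh:
        if header:
            head = list(cols) + (["label"] if labels is not None else [])
            fh.write(",".join(head) + "\n")
        for i in range(X.n_samples):
            cells = [repr(float(v)) for v in X.values[i]]
            if labels is not None:
                cells.append(str(labels[i]))
            fh.write(",".join(cells) + "\n")


def normalize_minmax(X: FeatureMatrix):
    """Rescale each channel to [0, 1] by (x - min) / (max - min).

    Constant channels map to 0. Returns the transformed matrix and the
    parameters needed to reapply the identical transform at prediction time.
    """
    mins = X.values.min(axis=0)
    maxs = X.values.max(axis=0)
    params = NormalizationParams(mins, maxs)
    return apply_normalization(X, params), params


def apply_normalization(X: FeatureMatrix, params: NormalizationParams) -> FeatureMatrix:
    """Apply stored per-channel affine rescaling.

    Out-of-range inputs map outside [0, 1] and are deliberately not clipped:
    an off-scale response is informative for novelty detection.
    """
    if X.n_channels != params.n_channels:
        raise ValueError(
            f"channel mismatch: matrix has {X.n_channels}, params have {params.n_channels}"
        )
    span = params.maxs - params.mins
    out = np.zeros_like(X.values)
    nz = span > 0
    out[:, nz] = (X.values[:, nz] - params.mins[nz]) / span[nz]
    return FeatureMatrix(out, sample_ids=X.sample_ids, channel_ids=X.channel_ids)


# ---------------------------------------------------------------------------
# Model serialization: one structured-text (JSON) file holding the weight
# matrix, per-neuron counts, hyperparameters and normalization parameters, so
# a trained network can be reloaded to classify later samples.

_FORMAT = "enosecnn-model-v1"


def save_model(path: str | Path, state, hyper=None, norm: NormalizationParams | None = None) -> None:
    """Serialize a trained network (weights, counts, params) as JSON text."""
    doc: dict = {
        "format": _FORMAT,
        "weights": np.asarray(state.weights, dtype=float).tolist(),
        "counts": np.asarray(state.counts, dtype=int).tolist(),
    }
    if hyper is not None:
        doc["hyper"] = hyper.to_dict()
    if norm is not None:
        doc["normalization"] = {"mins": norm.mins.tolist(), "maxs": norm.maxs.tolist()}
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path):
    """Inverse of :func:`save_model`.

    Returns ``(NetworkState, HyperParams-or-None, NormalizationParams-or-None)``
    reproducing every stored field bit-for-bit.
    """
    from .adaptive import HyperParams
    from .network import NetworkState

    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, OSError) as exc:
        raise DeserializationError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != _FORMAT:
        raise DeserializationError(f"{path}: not a recognized model file")
    try:
        state = NetworkState(
            weights=np.array(doc["weights"], dtype=float),
            counts=np.array(doc["counts"], dtype=int),
        )
    except (KeyError, ValueError) as exc:
        raise DeserializationError(f"{path}: malformed model payload: {exc}") from exc
    hyper = HyperParams.from_dict(doc["hyper"]) if "hyper" in doc else None
    norm = None
    if "normalization" in doc:
        norm = NormalizationParams(
            np.array(doc["normalization"]["mins"], dtype=float),
            np.array(doc["normalization"]["maxs"], dtype=float),
        )
    return state, hyper, norm
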