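"""Handcrafted statistical features and the neighborhoods built on them.

Seven statistics per channel — mean, population variance, standard deviation,
median, max, min and interquartile range — summarize each window; the variance
is the population form (1/W)*sum((r - mean)^2).  Quartiles use linear
interpolation between order statistics (numpy's default), applied consistently
here and in the test oracles.

Two neighborhood structures drive the consistency objectives: the temporal
set P_t = {t-radius .. t+radius} of a window within its own person's stream
(self included, clipped at stream boundaries), and the feature-space set Q_i
of the k nearest neighbors across the whole training set (self excluded,
Euclidean distance, ties broken by lower index).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_synth import SensorWindow

__all__ = [
    "STAT_NAMES", "FeatureVector", "NeighborhoodIndex",
    "extract_features", "features_matrix", "temporal_neighborhood",
    "feature_knn", "build_neighborhood_index", "FeatureScaler",
    "write_features_csv", "read_features_csv",
]

STAT_NAMES = ("mean", "var", "std", "median", "max", "min", "iqr")


@dataclass
class FeatureVector:
    values: np.ndarray  # (7*C,), channel-major
    t: int
    activity: int
    person: int


def _channel_stats(r: np.ndarray) -> np.ndarray:
    mean = r.mean()
    var = ((r - mean) ** 2).mean()  # population variance
    q1, q3 = np.percentile(r, [25, 75])  # linear-interpolation quartiles
    return np.array([mean, var, np.sqrt(var), np.median(r), r.max(), r.min(),
                     q3 - q1])


def extract_features(window: SensorWindow) -> FeatureVector:
    """Seven statistics per channel, computed separately for each axis."""
    if window.W < 1:
        raise ValueError("empty window")
    vals = np.concatenate([_channel_stats(window.values[:, c])
                           for c in range(window.n_channels)])
    return FeatureVector(vals, window.t, window.activity, window.person)


def features_matrix(windows: list[SensorWindow]) -> np.ndarray:
    """(N, 7*C) matrix of handcrafted features, one row per window."""
    return np.stack([extract_features(w).values for w in windows])


def feature_names(n_channels: int) -> list[str]:
    return [f"ch{c}_{s}" for c in range(n_channels) for s in STAT_NAMES]


def temporal_neighborhood(t: int, n_windows: int, radius: int = 2) -> np.ndarray:
    """Indices {t-radius .. t+radius} clipped to [0, n_windows); includes t."""
    if n_windows == 0:
        raise ValueError("empty window sequence")
    if not 0 <= t < n_windows:
        raise ValueError(f"t={t} outside [0, {n_windows})")
    lo = max(0, t - radius)
    hi = min(n_windows - 1, t + radius)
    return np.arange(lo, hi + 1)


def feature_knn(features: np.ndarray, k: int = 5,
                standardize: bool = True) -> dict[int, np.ndarray]:
    """Q_i = indices of the k nearest samples to i (self excluded).

    Distances are Euclidean in (optionally z-scored) feature space; ties are
    broken in favor of the lower index, so the result is deterministic.
    """
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if features.ndim == 1:
        features = features[:, None]
    n = features.shape[0]
    if n <= k:
        raise ValueError(f"dataset size {n} <= k={k}; lower k")
    x = FeatureScaler().fit(features).transform(features) if standardize else features
    # all-pairs squared distances; N is small enough for the dense matrix
    sq = (x ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.fill_diagonal(d2, np.inf)
    out: dict[int, np.ndarray] = {}
    for i in range(n):
        order = np.argsort(d2[i], kind="stable")  # stable: ties -> lower index
        out[i] = np.sort(order[:k])
    return out


@dataclass
class NeighborhoodIndex:
    """Temporal sets P (per global window index) and feature kNN sets Q."""

    temporal: dict[int, np.ndarray]
    feature: dict[int, np.ndarray]
    k: int
    radius: int


def build_neighborhood_index(windows: list[SensorWindow],
                             features: np.ndarray | None = None,
                             radius: int = 2, k: int = 5,
                             standardize: bool = True) -> NeighborhoodIndex:
    """Build P and Q over a window set.

    P is computed within each person's window sequence (temporal continuity is
    per stream) and mapped back to global indices; Q is computed across the
    whole set in handcrafted-feature space.
    """
    if features is None:
        features = features_matrix(windows)
    persons = np.array([w.person for w in windows])
    order_t = np.array([w.t for w in windows])
    temporal: dict[int, np.ndarray] = {}
    for person in np.unique(persons):
        idx = np.where(persons == person)[0]
        idx = idx[np.argsort(order_t[idx], kind="stable")]
        n = len(idx)
        for local, gi in enumerate(idx):
            temporal[int(gi)] = idx[temporal_neighborhood(local, n, radius)]
    feature = feature_knn(features, k=k, standardize=standardize)
    return NeighborhoodIndex(temporal, feature, k=k, radius=radius)


class FeatureScaler:
    """Per-feature z-scoring with training-set statistics; constant features
    are left unscaled (std treated as 1)."""

    def __init__(self):
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "FeatureScaler":
        x = np.asarray(x, dtype=np.float64)
        self.mean_ = x.mean(axis=0)
        std = x.std(axis=0)
        std[std == 0] = 1.0
        self.std_ = std
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("scaler not fitted")
        return (np.asarray(x, dtype=np.float64) - self.mean_) / self.std_

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        return self.fit(x).transform(x)


def write_features_csv(windows: list[SensorWindow], path: str | Path,
                       standardize: bool = False) -> None:
    """Feature table ``person,activity,t,feat_0..`` plus a sidecar naming
    each feature column ``ch{j}_{stat}``."""
    path = Path(path)
    feats = features_matrix(windows)
    if standardize:
        feats = FeatureScaler().fit_transform(feats)
    df = pd.DataFrame({
        "person": [w.person for w in windows],
        "activity": [w.activity for w in windows],
        "t": [w.t for w in windows],
    })
    for j in range(feats.shape[1]):
        df[f"feat_{j}"] = feats[:, j]
    df.to_csv(path, index=False)
    names = feature_names(windows[0].n_channels)
    pd.DataFrame({"column": [f"feat_{j}" for j in range(len(names))],
                  "name": names}).to_csv(
        path.with_suffix(".names.csv"), index=False)


def read_features_csv(path: str | Path):
    df = pd.read_csv(path)
    feat_cols = [c for c in df.columns if c.startswith("feat_")]
    return (df[feat_cols].to_numpy(dtype=np.float64),
            df["activity"].to_numpy(dtype=np.int64),
            df["person"].to_numpy(dtype=np.int64),
            df["t"].to_numpy(dtype=np.int64))
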