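"""The 1-D K-means feature: collapse a multi-feature table to one scalar.

The transform clusters the (min-max scaled) feature matrix with K-means
and replaces each sample by a single number derived from its assigned
centroid.  Two scalarizations are offered:

* ``centroid_mean`` (default) — the mean of the assigned centroid's
  coordinates, a single value that blends the information of every
  feature through the cluster structure;
* ``centroid_distance`` — the Euclidean distance from the (scaled) sample
  to its assigned centroid.

K-means itself is Lloyd's algorithm from k-means++ starts: minimize
sum_i sum_{x in C_i} ||x - mu_i||^2 over clusters C_i and centers mu_i,
with mu_i the mean of its members at convergence.  The number of clusters
can be chosen automatically by maximizing the mean silhouette over a
candidate range.

Clustering is run on features min-max scaled to [0, 1]: the HRV features
span several orders of magnitude (total power in the thousands of ms^2
against pNN50 fractions), so unscaled Euclidean distance would be
dominated by the largest-magnitude feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.metrics import silhouette_score

from .errors import ParameterError, SchemaError
from .io_core import FeatureTable

MAPPINGS = ("centroid_mean", "centroid_distance")


@dataclass
class KMeansFeatureModel:
    """A fitted K-means feature transform."""

    k: int
    centroids: np.ndarray  # k x d, in scaled space
    feature_names: list[str]
    scale_min: Optional[np.ndarray]  # None when fitted without scaling
    scale_range: Optional[np.ndarray]
    mapping: str = "centroid_mean"
    inertia: float = float("nan")
    inertia_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.k < 2:
            raise ParameterError("k must be at least 2")
        if self.mapping not in MAPPINGS:
            raise ParameterError(f"unknown mapping {self.mapping!r}")

    # scaled-space helpers -------------------------------------------------
    def scale(self, values: np.ndarray) -> np.ndarray:
        if self.scale_min is None:
            return np.asarray(values, dtype=float)
        return (values - self.scale_min) / self.scale_range

    def assign(self, values: np.ndarray) -> np.ndarray:
        x = self.scale(values)
        d2 = ((x[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)

    # serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": "kmeans_feature",
            "k": self.k,
            "centroids": self.centroids.tolist(),
            "feature_names": self.feature_names,
            "scale_min": None if self.scale_min is None else self.scale_min.tolist(),
            "scale_range": None if self.scale_range is None else self.scale_range.tolist(),
            "mapping": self.mapping,
            "inertia": self.inertia,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "KMeansFeatureModel":
        return cls(
            k=payload["k"],
            centroids=np.asarray(payload["centroids"], dtype=float),
            feature_names=list(payload["feature_names"]),
            scale_min=None
            if payload["scale_min"] is None
            else np.asarray(payload["scale_min"], dtype=float),
            scale_range=None
            if payload["scale_range"] is None
            else np.asarray(payload["scale_range"], dtype=float),
            mapping=payload.get("mapping", "centroid_mean"),
            inertia=payload.get("inertia", float("nan")),
        )


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = len(x)
    centers = [x[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(
            ((x[:, None, :] - np.asarray(centers)[None, :, :]) ** 2).sum(axis=2),
            axis=1,
        )
        total = d2.sum()
        if total <= 0:
            centers.append(x[rng.integers(n)])
        else:
            centers.append(x[rng.choice(n, p=d2 / total)])
    return np.asarray(centers, dtype=float)


def _lloyd(
    x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    centers = _kmeanspp_init(x, k, rng)
    assign = np.full(len(x), -1)
    history: list[float] = []
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_assign = np.argmin(d2, axis=1)
        history.append(float(d2[np.arange(len(x)), new_assign].sum()))
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            members = x[assign == j]
            if len(members):
                centers[j] = members.mean(axis=0)
            else:  # re-seed an empty cluster at the farthest point
                centers[j] = x[np.argmax(d2.min(axis=1))]
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    assign = np.argmin(d2, axis=1)
    inertia = float(d2[np.arange(len(x)), assign].sum())
    return centers, assign, inertia, history


def fit_kmeans(
    table: FeatureTable,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    scale: bool = True,
    mapping: str = "centroid_mean",
) -> KMeansFeatureModel:
    """Fit K-means on the (optionally min-max scaled) feature matrix.

    Runs ``n_init`` k-means++ starts and keeps the run with the lowest
    inertia.  The within-cluster objective is non-increasing across Lloyd
    iterations; the retained run's per-iteration values are exposed as
    ``inertia_history``.
    """
    if k > table.n_samples:
        raise ParameterError(f"k={k} exceeds the {table.n_samples} samples")
    if k < 2:
        raise ParameterError("k must be at least 2")
    values = table.values
    if scale:
        lo = values.min(axis=0)
        rng_ = values.max(axis=0) - lo
        rng_[rng_ == 0] = 1.0
        x = (values - lo) / rng_
    else:
        lo = rng_ = None
        x = values.astype(float)

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        centers, _, inertia, history = _lloyd(x, k, rng)
        if best is None or inertia < best[1]:
            best = (centers, inertia, history)
    centers, inertia, history = best
    return KMeansFeatureModel(
        k=k,
        centroids=centers,
        feature_names=list(table.feature_names),
        scale_min=lo,
        scale_range=rng_,
        mapping=mapping,
        inertia=inertia,
        inertia_history=history,
    )


def select_k(
    table: FeatureTable, k_range: range | tuple[int, int], seed: int = 0, n_init: int = 10
) -> int:
    """Pick k maximizing the mean silhouette over a candidate range
    (ties break toward the smallest k)."""
    if isinstance(k_range, tuple):
        k_range = range(k_range[0], k_range[1] + 1)
    ks = [k for k in k_range if 2 <= k <= table.n_samples - 1]
    if not ks:
        raise ParameterError("empty candidate range for k")
    if len(ks) == 1:
        return ks[0]
    best_k, best_score = None, -np.inf
    for k in ks:
        model = fit_kmeans(table, k, seed=seed, n_init=n_init)
        labels = model.assign(table.values)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(model.scale(table.values), labels)
        if score > best_score + 1e-12:
            best_k, best_score = k, score
    if best_k is None:
        raise ParameterError("no candidate k produced two or more clusters")
    return best_k


def transform_1d(model: KMeansFeatureModel, table: FeatureTable) -> FeatureTable:
    """Map every sample to its 1-D K-means feature value.

    Samples in the same cluster receive identical scalars, so the output
    takes at most k distinct values.
    """
    if list(table.feature_names) != list(model.feature_names):
        raise SchemaError(
            "feature names/order differ from those the model was fitted on"
        )
    assign = model.assign(table.values)
    if model.mapping == "centroid_mean":
        scalars = model.centroids.mean(axis=1)[assign]
    else:  # centroid_distance
        x = model.scale(table.values)
        scalars = np.linalg.norm(x - model.centroids[assign], axis=1)
    return FeatureTable(
        ["KMeansFeat"], scalars[:, None], table.labels, table.label_scheme
    )


def default_k(label_scheme: str) -> Optional[int]:
    """Study-aligned default cluster counts: 2 for binary labels, 5 for
    five-class labels, otherwise unknown (select over a range)."""
    return {"binary": 2, "five_class": 5}.get(label_scheme)
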