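"""Portable k-means: over-clustered fit, text serialization, blind reapplication.

The estimator is deliberately self-contained (Lloyd iterations, k-means++
seeding, best-of-restarts) so that the entire fitted state — cluster count,
feature list, normalization parameters and centroids — can be serialized to a
self-describing JSON file and reapplied, bit-for-bit, on any machine.  The
portability of that stored model across independent recordings is the whole
point: refitting k-means per dataset yields incomparable clusters.

Cluster identities are presentation-ordered into letters A, B, C, ... by
ascending mean ENMO of their member windows, so that low letters always mean
low movement intensity and purity tables are comparable across runs.
"""

from __future__ import annotations

import json
import string
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .features import MinMaxNormalizer

__all__ = [
    "PortableKMeans",
    "PortableModel",
    "kmeans_fit",
    "assign",
    "apply_model",
    "save_model",
    "load_model",
    "order_clusters",
    "cluster_letters",
]

MODEL_FORMAT_VERSION = "1"


def _pairwise_sq_dists(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    # (n, k) squared Euclidean distances; einsum keeps memory flat
    XX = np.einsum("ij,ij->i", X, X)[:, None]
    CC = np.einsum("ij,ij->i", C, C)[None, :]
    d = XX + CC - 2.0 * X @ C.T
    np.maximum(d, 0.0, out=d)
    return d


def _kpp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding by D^2 sampling."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = _pairwise_sq_dists(X, centers[:1]).ravel()
    for j in range(1, k):
        total = d2.sum()
        if total <= 0.0:  # all remaining points coincide with a centre
            centers[j] = X[rng.integers(n)]
            continue
        probs = d2 / total
        idx = rng.choice(n, p=probs)
        centers[j] = X[idx]
        d2 = np.minimum(d2, _pairwise_sq_dists(X, centers[j:j + 1]).ravel())
    return centers


class PortableKMeans(ClusterMixin, BaseEstimator):
    """K-means clusterer with over-clustering defaults and portable state.

    Parameters
    ----------
    n_clusters : number of clusters K.  Default 10: more clusters than the
        nine expected activity classes, so heterogeneous behaviours can split.
    init : "k-means++" (D^2 sampling) or "random" (uniform choice of rows).
    n_init : independent restarts; the run with the lowest within-cluster
        sum of squares wins.
    max_iter : Lloyd iteration cap per restart.
    random_state : seed; the fit is deterministic given it.

    Attributes
    ----------
    cluster_centers_ : (K, p) centroids in (normalized) feature space.
    labels_ : training assignments.
    inertia_ : total within-cluster sum of squared distances.
    n_iter_ : Lloyd iterations of the winning restart.
    """

    def __init__(self, n_clusters: int = 10, init: str = "k-means++",
                 n_init: int = 10, max_iter: int = 300,
                 random_state: int | None = None):
        self.n_clusters = n_clusters
        self.init = init
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    def _lloyd(self, X: np.ndarray, rng: np.random.Generator):
        k = self.n_clusters
        if self.init == "k-means++":
            C = _kpp_init(X, k, rng)
        elif self.init == "random":
            C = X[rng.choice(X.shape[0], size=k, replace=False)]
        else:
            raise ValueError(f"unknown init {self.init!r}")
        labels = None
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            d = _pairwise_sq_dists(X, C)
            new_labels = np.argmin(d, axis=1)  # argmin ties -> lowest index
            if labels is not None and np.array_equal(new_labels, labels):
                break  # C is already the member means of this assignment
            labels = new_labels
            for j in range(k):
                members = labels == j
                if members.any():
                    C[j] = X[members].mean(axis=0)
                else:
                    # reseed an emptied cluster at the point farthest from
                    # its assigned centroid
                    far = int(np.argmax(d[np.arange(len(labels)), labels]))
                    C[j] = X[far]
                    labels[far] = j
        d = _pairwise_sq_dists(X, C)
        labels = np.argmin(d, axis=1)
        inertia = float(d[np.arange(X.shape[0]), labels].sum())
        return C, labels, inertia, n_iter

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if X.shape[0] < self.n_clusters:
            raise ValueError(
                f"n_samples={X.shape[0]} < n_clusters={self.n_clusters}")
        root = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_init):
            rng = np.random.default_rng(root.integers(2 ** 31))
            C, labels, inertia, n_iter = self._lloyd(X, rng)
            if best is None or inertia < best[2]:
                best = (C, labels, inertia, n_iter)
        self.cluster_centers_, self.labels_, self.inertia_, self.n_iter_ = best
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.cluster_centers_.shape[1]:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects "
                f"{self.cluster_centers_.shape[1]}")
        return np.argmin(_pairwise_sq_dists(X, self.cluster_centers_), axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class PortableModel(BaseModel):
    """Everything needed to reapply the clustering blind, as plain text.

    Centroids live in min-max-normalized feature space; ``norm_min`` and
    ``norm_max`` are the training-data extrema used to reach that space.
    """

    version: str = MODEL_FORMAT_VERSION
    k: int = Field(ge=1)
    feature_names: list[str]
    norm_min: list[float]
    norm_max: list[float]
    centroids: list[list[float]]
    seed: int | None = None
    init: str = "k-means++"
    n_restarts: int = 10
    window_seconds: float = 10.0
    trim_seconds: float = 30.0
    created: str | None = None

    @field_validator("feature_names")
    @classmethod
    def _unique_names(cls, v):
        if len(set(v)) != len(v):
            raise ValueError("feature_names must be unique")
        return v

    @model_validator(mode="after")
    def _consistent(self):
        p = len(self.feature_names)
        if len(self.norm_min) != p or len(self.norm_max) != p:
            raise ValueError("norm_min/norm_max length must match feature_names")
        if any(hi < lo for lo, hi in zip(self.norm_min, self.norm_max)):
            raise ValueError("norm_max < norm_min for some feature")
        if len(self.centroids) != self.k:
            raise ValueError("number of centroids must equal k")
        for c in self.centroids:
            if len(c) != p:
                raise ValueError("centroid dimensionality must match feature_names")
        arr = np.asarray(self.centroids)
        for i in range(self.k):
            for j in range(i + 1, self.k):
                if np.array_equal(arr[i], arr[j]):
                    raise ValueError(f"centroids {i} and {j} coincide")
        return self

    def normalizer(self) -> MinMaxNormalizer:
        return MinMaxNormalizer.from_params(
            self.feature_names, self.norm_min, self.norm_max)

    def estimator(self) -> PortableKMeans:
        est = PortableKMeans(n_clusters=self.k, init=self.init,
                             n_init=self.n_restarts, random_state=self.seed)
        est.cluster_centers_ = np.asarray(self.centroids, dtype=float)
        est.n_features_in_ = len(self.feature_names)
        return est


def kmeans_fit(fm_norm: pd.DataFrame, k: int = 10, seed: int | None = None,
               n_restarts: int = 10, max_iter: int = 300,
               norm: MinMaxNormalizer | None = None,
               window_seconds: float = 10.0,
               trim_seconds: float = 30.0,
               created: str | None = None) -> PortableModel:
    """Fit k-means on a normalized feature matrix and package the state.

    ``fm_norm`` columns define the model's feature list; ``norm`` (if given)
    supplies the stored min/max so the model can renormalize raw features by
    itself.  Without it, identity normalization (min 0, max 1) is recorded.
    ``created`` is optional free-form provenance (e.g. an ISO timestamp);
    it is left unset by default so that identical fits yield identical files.
    """
    cols = list(fm_norm.columns)
    est = PortableKMeans(n_clusters=k, n_init=n_restarts, max_iter=max_iter,
                         random_state=seed)
    est.fit(fm_norm.to_numpy(dtype=float))
    if norm is not None:
        if list(norm.columns_) != cols:
            raise ValueError("normalizer columns do not match feature matrix")
        mins, maxs = norm.min_.tolist(), norm.max_.tolist()
    else:
        mins, maxs = [0.0] * len(cols), [1.0] * len(cols)
    return PortableModel(
        k=k,
        feature_names=cols,
        norm_min=mins,
        norm_max=maxs,
        centroids=est.cluster_centers_.tolist(),
        seed=seed,
        n_restarts=n_restarts,
        created=created,
        window_seconds=window_seconds,
        trim_seconds=trim_seconds,
    )


def assign(fm_norm: pd.DataFrame, model: PortableModel) -> np.ndarray:
    """Nearest-centroid assignment of normalized rows; ties -> lowest index."""
    if list(fm_norm.columns) != model.feature_names:
        raise ValueError(
            f"feature columns {list(fm_norm.columns)} do not match model "
            f"feature list {model.feature_names}")
    return model.estimator().predict(fm_norm.to_numpy(dtype=float))


def apply_model(fm_raw: pd.DataFrame, model: PortableModel) -> np.ndarray:
    """Blind application: normalize raw features with stored parameters, assign."""
    missing = [c for c in model.feature_names if c not in fm_raw.columns]
    if missing:
        raise ValueError(f"feature matrix lacks model features: {missing}")
    fm_norm = model.normalizer().transform(fm_raw)
    return assign(fm_norm, model)


def save_model(model: PortableModel, path: str | Path) -> None:
    """Write the model as self-describing JSON (full-precision floats)."""
    Path(path).write_text(json.dumps(model.model_dump(), indent=2) + "\n")


def load_model(path: str | Path) -> PortableModel:
    """Read and validate a model file; schema violations name the field."""
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"model file is not valid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise ValueError("model file must hold a JSON object")
    if data.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model version {data.get('version')!r}")
    return PortableModel.model_validate(data)


def cluster_letters(k: int) -> list[str]:
    if k > 26:
        raise ValueError("letter naming supports at most 26 clusters")
    return list(string.ascii_uppercase[:k])


def order_clusters(model: PortableModel, fm_raw: pd.DataFrame,
                   assignments: Sequence[int] | None = None) -> dict[int, str]:
    """Name clusters A, B, ... by ascending mean ENMO of member windows.

    ``fm_raw`` must carry the raw (denormalized) ``enmo_mean`` column; the
    intensity of a cluster is the mean of that column over its members.
    Clusters with no members sort last; ties break on the original index.
    Returns a mapping raw cluster index -> letter.
    """
    if "enmo_mean" not in fm_raw.columns:
        raise ValueError("feature matrix lacks an enmo_mean column")
    if assignments is None:
        assignments = apply_model(fm_raw, model)
    assignments = np.asarray(assignments)
    if len(assignments) != len(fm_raw):
        raise ValueError("assignments length does not match feature matrix")
    intensity = []
    e = fm_raw["enmo_mean"].to_numpy(dtype=float)
    for j in range(model.k):
        members = assignments == j
        mean_e = float(e[members].mean()) if members.any() else np.inf
        intensity.append((mean_e, j))
    order = [j for _, j in sorted(intensity, key=lambda t: (t[0], t[1]))]
    letters = cluster_letters(model.k)
    return {j: letters[rank] for rank, j in enumerate(order)}
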