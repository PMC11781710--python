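"""Atlas subgrouping by k-means on normalized volume-feature vectors.

Poor contour propagation in multi-atlas segmentation is usually driven by
large volume differences between atlas and target.  The subgrouping (SAGA)
step therefore partitions the atlas library into ``k`` clusters of
volumetrically similar subjects by minimizing the within-cluster sum of
squared feature distances

    argmin_C  sum_i sum_{x in C_i} || x - mu_i ||^2

and a target is later matched only against the subgroup whose centroid is
nearest to its own feature vector.

Lloyd's algorithm is implemented here directly (rather than delegating to
scikit-learn) so that initialization, restart policy, empty-cluster repair
and tie-breaking are exactly the documented, deterministic ones; the
scikit-learn implementation serves as an independent cross-check in the
test-suite.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .features import FeatureVector


def _pairwise_sq(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, shape (n_points, n_centroids)."""
    return ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)


class AtlasSubgrouper(ClusterMixin, BaseEstimator):
    """k-means partition of the atlas library in volume-feature space.

    Parameters
    ----------
    n_clusters : int, default 4
        Number of subgroups ``k``; four keeps per-cluster selection cheap on
        a ~70-atlas library without hurting segmentation quality.
    n_restarts : int, default 10
        Seeded re-initializations; the run with the lowest objective wins.
    max_iter : int, default 300
        Lloyd iteration cap per restart (assignment fixed point usually
        arrives much earlier).
    random_state : int, default 0
        Seed for the restart stream; the whole fit is deterministic in
        (data, n_clusters, n_restarts, random_state).

    Attributes
    ----------
    cluster_centers_ : ndarray (k, n_features)
    labels_ : ndarray (n_samples,)
    inertia_ : float
        Final within-cluster sum of squared distances.
    atlas_ids_ : tuple of str, only when fitted via :func:`fit_subgroups`.
    """

    def __init__(
        self,
        n_clusters: int = 4,
        n_restarts: int = 10,
        max_iter: int = 300,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.random_state = random_state

    # -- Lloyd internals ----------------------------------------------------

    @staticmethod
    def _assign(X: np.ndarray, C: np.ndarray) -> np.ndarray:
        # argmin breaks ties toward the lowest cluster index.
        return np.argmin(_pairwise_sq(X, C), axis=1)

    @staticmethod
    def _repair_empty(X: np.ndarray, C: np.ndarray, assign: np.ndarray) -> np.ndarray:
        """Re-seed each empty cluster from the point farthest from its centroid."""
        d = _pairwise_sq(X, C)
        point_d = d[np.arange(len(X)), assign].copy()
        for j in range(C.shape[0]):
            if not np.any(assign == j):
                far = int(np.argmax(point_d))
                C[j] = X[far]
                assign[far] = j
                point_d[far] = 0.0
        return assign

    def _lloyd(self, X: np.ndarray, C0: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        C = C0.copy()
        assign = self._assign(X, C)
        assign = self._repair_empty(X, C, assign)
        prev_obj = np.inf
        for _ in range(self.max_iter):
            for j in range(self.n_clusters):
                C[j] = X[assign == j].mean(axis=0)
            new_assign = self._assign(X, C)
            new_assign = self._repair_empty(X, C, new_assign)
            obj = float(_pairwise_sq(X, C)[np.arange(len(X)), new_assign].sum())
            # Lloyd's objective never increases at an update; guard anyway.
            if obj > prev_obj + 1e-9:  # pragma: no cover - theoretical guard
                break
            if np.array_equal(new_assign, assign):
                assign = new_assign
                prev_obj = obj
                break
            assign = new_assign
            prev_obj = obj
        return C, assign, prev_obj

    # -- Estimator API ------------------------------------------------------

    def fit(self, X: np.ndarray, y=None) -> "AtlasSubgrouper":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_atlases, n_features)")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature vectors must be finite")
        n = X.shape[0]
        if not 2 <= self.n_clusters <= n:
            raise ValueError(
                f"need 2 <= k <= N, got k={self.n_clusters} with N={n}"
            )
        rng = np.random.default_rng(self.random_state)
        best: tuple[float, np.ndarray, np.ndarray] | None = None
        # Initialize from k distinct data points (distinct *values* where
        # possible, so duplicated points do not collapse clusters).
        unique, uniq_idx = np.unique(X, axis=0, return_index=True)
        for _ in range(max(1, self.n_restarts)):
            if len(unique) >= self.n_clusters:
                pick = rng.choice(len(unique), size=self.n_clusters, replace=False)
                C0 = unique[pick].astype(float)
            else:
                pick = rng.choice(n, size=self.n_clusters, replace=False)
                C0 = X[pick].astype(float)
            C, assign, obj = self._lloyd(X, C0)
            if best is None or obj < best[0] - 1e-12:
                best = (obj, C, assign)
        obj, C, assign = best
        self.n_features_in_ = X.shape[1]
        self.cluster_centers_ = C
        self.labels_ = assign
        self.inertia_ = obj
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Nearest-centroid subgroup; ties go to the lowest cluster index."""
        check_is_fitted(self, "cluster_centers_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self._assign(X, self.cluster_centers_)

    # -- Persistence --------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        check_is_fitted(self, "cluster_centers_")
        payload = {
            "n_clusters": self.n_clusters,
            "n_restarts": self.n_restarts,
            "max_iter": self.max_iter,
            "random_state": self.random_state,
            "cluster_centers": self.cluster_centers_.tolist(),
            "labels": self.labels_.tolist(),
            "inertia": self.inertia_,
            "atlas_ids": list(getattr(self, "atlas_ids_", []) or []),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AtlasSubgrouper":
        try:
            is_file = Path(str(source)).exists()
        except OSError:
            is_file = False
        text = Path(source).read_text() if is_file else str(source)
        payload = json.loads(text)
        model = cls(
            n_clusters=payload["n_clusters"],
            n_restarts=payload["n_restarts"],
            max_iter=payload["max_iter"],
            random_state=payload["random_state"],
        )
        model.cluster_centers_ = np.asarray(payload["cluster_centers"], dtype=float)
        model.labels_ = np.asarray(payload["labels"], dtype=int)
        model.inertia_ = float(payload["inertia"])
        model.n_features_in_ = model.cluster_centers_.shape[1]
        if payload.get("atlas_ids"):
            model.atlas_ids_ = tuple(payload["atlas_ids"])
        return model

    @property
    def assignment_(self) -> dict[str, int]:
        """Atlas id -> cluster index (available after :func:`fit_subgroups`)."""
        check_is_fitted(self, "labels_")
        ids = getattr(self, "atlas_ids_", None)
        if ids is None:
            raise AttributeError("fitted from a bare array; no atlas ids attached")
        return {a: int(c) for a, c in zip(ids, self.labels_)}

    def members(self, cluster: int) -> list[str]:
        """Atlas ids belonging to one subgroup."""
        return [a for a, c in self.assignment_.items() if c == int(cluster)]


def fit_subgroups(
    vectors: dict[str, FeatureVector],
    k: int = 4,
    seed: int = 0,
    restarts: int = 10,
) -> AtlasSubgrouper:
    """Partition the atlas library into ``k`` volume-feature subgroups."""
    ids = tuple(vectors.keys())
    X = np.stack([vectors[a].values for a in ids])
    model = AtlasSubgrouper(
        n_clusters=k, n_restarts=restarts, random_state=seed
    ).fit(X)
    model.atlas_ids_ = ids
    return model


def assign_subgroup(target: FeatureVector | np.ndarray, model: AtlasSubgrouper) -> int:
    """Index of the subgroup whose centroid is nearest to the target."""
    vec = target.values if isinstance(target, FeatureVector) else np.asarray(target)
    return int(model.predict(vec[None, :])[0])
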