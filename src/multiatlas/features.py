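"""Per-structure volume features and their [0, 1] normalization.

The feature vector of an atlas (or target) is the ordered tuple of its
structure volumes in cc, e.g. ``(body, bladder, rectum, left femoral head,
right femoral head, bone marrow)``.  Because organ volumes live on very
different scales (a bladder spans hundreds of cc, a femoral head tens),
each structure is min-max scaled to [0, 1] over the *atlas* set before any
distance or clustering is computed; the identical affine map is then applied
to the target, whose values are deliberately left unclamped so that
out-of-range targets remain distinguishable in distance ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .imaging import Atlas, EmptyStructureError, volume_of_label

#: Structures of the default feature vector.  The contoured set includes the
#: body external contour alongside the five evaluated organs; restrict to
#: five via the ``structures`` argument where only organs are wanted.
DEFAULT_STRUCTURES: tuple[str, ...] = (
    "body",
    "bladder",
    "rectum",
    "left femoral head",
    "right femoral head",
    "bone marrow",
)

#: Canonical label integers used throughout the synthetic cohort.
DEFAULT_LABELS: dict[int, str] = {
    1: "bladder",
    2: "rectum",
    3: "left femoral head",
    4: "right femoral head",
    5: "bone marrow",
    6: "body",
}


@dataclass
class FeatureVector:
    """Ordered per-structure volumes of one subject.

    ``raw_cc`` is always present; ``normalized`` is filled by
    :func:`normalize` (atlas-set min-max scaling).
    """

    structure_order: tuple[str, ...]
    raw_cc: np.ndarray
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.structure_order = tuple(self.structure_order)
        self.raw_cc = np.asarray(self.raw_cc, dtype=float)
        if self.raw_cc.shape != (len(self.structure_order),):
            raise ValueError("raw_cc length must match structure_order")
        if np.any(self.raw_cc < 0):
            raise ValueError("volumes must be non-negative")
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)
            if self.normalized.shape != self.raw_cc.shape:
                raise ValueError("normalized length must match structure_order")

    @property
    def values(self) -> np.ndarray:
        """The normalized vector if available, else raw cc."""
        return self.raw_cc if self.normalized is None else self.normalized


class VolumeFeatureNormalizer(TransformerMixin, BaseEstimator):
    """Per-structure min-max scaler fitted on the atlas set.

    Equivalent to an unclipped min-max scaling to [0, 1] on the fitting set;
    transformed values outside the atlas range fall outside [0, 1] and are
    kept as such.  A structure whose volume is constant across atlases
    cannot be scaled and raises a degenerate-feature error at fit time.

    Attributes
    ----------
    data_min_, data_max_ : ndarray of shape (n_structures,)
        Per-structure atlas-set minimum and maximum in cc.
    structure_order_ : tuple of str
        Structure names, when fitted through :func:`fit_normalizer`.
    """

    def __init__(self, structure_order: tuple[str, ...] | None = None):
        self.structure_order = structure_order

    def fit(self, X: np.ndarray, y=None) -> "VolumeFeatureNormalizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D array with at least two atlases")
        if not np.all(np.isfinite(X)):
            raise ValueError("volumes must be finite")
        data_min = X.min(axis=0)
        data_max = X.max(axis=0)
        degenerate = np.nonzero(data_max <= data_min)[0]
        if degenerate.size:
            order = self.structure_order or tuple(
                f"structure[{j}]" for j in range(X.shape[1])
            )
            names = ", ".join(order[j] for j in degenerate)
            raise ValueError(
                f"degenerate feature(s) with constant volume across atlases: {names}"
            )
        self.n_features_in_ = X.shape[1]
        self.data_min_ = data_min
        self.data_max_ = data_max
        self.structure_order_ = (
            tuple(self.structure_order) if self.structure_order else None
        )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "data_min_")
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} structures, got {X.shape[-1]}"
            )
        return (X - self.data_min_) / (self.data_max_ - self.data_min_)

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "data_min_")
        X = np.asarray(X, dtype=float)
        return X * (self.data_max_ - self.data_min_) + self.data_min_


def extract_features(
    atlas: Atlas, structures: tuple[str, ...] = DEFAULT_STRUCTURES
) -> FeatureVector:
    """Raw per-structure volume vector of one atlas, in the given order."""
    raw = []
    for name in structures:
        try:
            label = atlas.contours.label_for(name)
        except KeyError as exc:
            raise KeyError(f"atlas {atlas.id}: unknown structure {name!r}") from exc
        v = volume_of_label(atlas.contours, label)
        if v == 0.0:
            raise EmptyStructureError(
                f"atlas {atlas.id}: structure {name!r} has zero volume"
            )
        raw.append(v)
    return FeatureVector(structures, np.array(raw))


def features_from_volumes(
    volumes: dict[str, float], structures: tuple[str, ...] = DEFAULT_STRUCTURES
) -> FeatureVector:
    """Build a FeatureVector from known volumes (e.g. a target's estimates)."""
    return FeatureVector(structures, np.array([volumes[s] for s in structures]))


def fit_normalizer(atlas_vectors: list[FeatureVector]) -> VolumeFeatureNormalizer:
    """Learn per-structure min/max from the atlas set (>= 2 atlases)."""
    if len(atlas_vectors) < 2:
        raise ValueError("need at least two atlases to fit the normalizer")
    order = atlas_vectors[0].structure_order
    for v in atlas_vectors[1:]:
        if v.structure_order != order:
            raise ValueError("all feature vectors must share structure_order")
    X = np.stack([v.raw_cc for v in atlas_vectors])
    return VolumeFeatureNormalizer(structure_order=order).fit(X)


def normalize(vector: FeatureVector, norm: VolumeFeatureNormalizer) -> FeatureVector:
    """Apply the atlas-fitted min-max map; out-of-range values unclamped."""
    if norm.structure_order_ is not None and (
        vector.structure_order != norm.structure_order_
    ):
        raise ValueError(
            f"structure order mismatch: {vector.structure_order} vs "
            f"{norm.structure_order_}"
        )
    return replace(vector, normalized=norm.transform(vector.raw_cc[None, :])[0])


def feature_table(vectors: dict[str, FeatureVector]) -> pd.DataFrame:
    """Tidy table of features: one row per atlas id (CSV-exportable)."""
    rows = {}
    for atlas_id, vec in vectors.items():
        row: dict[str, float] = {}
        for j, name in enumerate(vec.structure_order):
            row[f"{name}_cc"] = vec.raw_cc[j]
            if vec.normalized is not None:
                row[f"{name}_norm"] = vec.normalized[j]
        rows[atlas_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "atlas_id"
    return df
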