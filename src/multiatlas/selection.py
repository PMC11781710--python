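"""Atlas selection strategies: cMAS, SAGA, FASA, SIM and a random baseline.

Every strategy answers the same question — *which n atlases should be
deformably registered and fused for this target?* — but pays a different
cost and consults different information:

* **cMAS** deformably registers *every* atlas to the target and keeps the
  n with the highest post-registration image similarity (normalized
  cross-correlation).  Most expensive; the conventional baseline.
* **SAGA** first restricts candidates to the target's volume-feature
  subgroup (k-means, :mod:`multiatlas.subgrouping`), then ranks that
  subgroup exactly like cMAS.  Registration cost drops from N to the
  subgroup size.
* **FASA** ranks atlases by the Euclidean distance
  ``D = ||v_atlas - v_target||`` between normalized volume-feature vectors
  and registers only the n closest.  No image comparison at all.
* **SIM** ranks by Mattes-style mutual information after rigid
  registration, then registers the n best.  The intensity-similarity
  counterpart of FASA.
* **random** is the seeded uniform baseline.

Ties are always broken by lexicographic atlas id, so every strategy is
deterministic given its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .features import FeatureVector
from .imaging import Atlas, LabelMap, VolumeImage
from .registration import (
    DeformableConfig,
    DeformationField,
    RigidConfig,
    deformable_register,
    mattes_mi,
    normalized_cross_correlation,
    propagate_labels,
    resample_to_grid,
    rigid_register,
    apply_field,
)
from .subgrouping import AtlasSubgrouper, assign_subgroup

logger = logging.getLogger(__name__)

STRATEGIES = ("cmas", "saga", "fasa", "sim", "random")


@dataclass
class SelectionResult:
    """A ranked atlas shortlist produced by one strategy for one target."""

    strategy: str
    target_id: str
    ranked_atlases: tuple[str, ...]
    scores: dict[str, float] | None = None
    n_selected: int = 0

    def __post_init__(self) -> None:
        self.ranked_atlases = tuple(self.ranked_atlases)
        if len(set(self.ranked_atlases)) != len(self.ranked_atlases):
            raise ValueError("ranked atlas list contains duplicates")
        if self.target_id in self.ranked_atlases:
            raise ValueError("a target may not select itself as an atlas")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not self.n_selected:
            self.n_selected = len(self.ranked_atlases)


@dataclass
class RegisteredAtlas:
    """Outcome of deformably registering one atlas onto one target."""

    atlas_id: str
    ncc: float
    labels: LabelMap
    field: DeformationField | None = None


def register_atlas_to_target(
    atlas: Atlas,
    target: VolumeImage,
    deform_config: DeformableConfig | None = None,
    rigid_config: RigidConfig | None = None,
    do_rigid: bool = False,
    similarity_mask: np.ndarray | None = None,
) -> RegisteredAtlas:
    """Deformable registration + label propagation + NCC scoring.

    The NCC is evaluated between the target and the warped atlas image,
    optionally restricted to a mask (typically the target's body region so
    background air does not inflate the correlation).
    """
    init = rigid_register(target, atlas.image, rigid_config) if do_rigid else None
    field_ = deformable_register(target, atlas.image, init=init, config=deform_config)
    warped = apply_field(atlas.image, field_, order=1)
    ncc = normalized_cross_correlation(target, warped, mask=similarity_mask)
    labels = propagate_labels(atlas.contours, field_)
    return RegisteredAtlas(atlas.id, ncc, labels)


class _RankMixin:
    """Shared ranking helper: sort by score with lexicographic-id ties."""

    @staticmethod
    def _rank(scores: dict[str, float], ascending: bool, n: int) -> tuple[list, dict]:
        order = sorted(
            scores, key=lambda a: ((1 if ascending else -1) * scores[a], a)
        )
        top = order[:n]
        return top, {a: scores[a] for a in order}


class FasaSelector(_RankMixin, BaseEstimator):
    """Feature-distance atlas selection (MAS-FASA).

    Ranks atlases by the Euclidean distance between normalized volume
    feature vectors and keeps the ``n_select`` closest (lowest D first).
    """

    def __init__(self, n_select: int = 5):
        self.n_select = n_select

    def fit(self, atlas_vectors: dict[str, FeatureVector | np.ndarray], y=None):
        self.atlas_vectors_ = {
            a: (v.values if isinstance(v, FeatureVector) else np.asarray(v, float))
            for a, v in atlas_vectors.items()
        }
        dims = {v.shape for v in self.atlas_vectors_.values()}
        if len(dims) > 1:
            raise ValueError(f"atlas vectors disagree in dimension: {dims}")
        return self

    def select(
        self, target_vec: FeatureVector | np.ndarray, target_id: str = "target"
    ) -> SelectionResult:
        if not hasattr(self, "atlas_vectors_"):
            raise NotFittedError("call fit with the atlas vectors first")
        t = (
            target_vec.values
            if isinstance(target_vec, FeatureVector)
            else np.asarray(target_vec, float)
        )
        candidates = {a: v for a, v in self.atlas_vectors_.items() if a != target_id}
        if self.n_select > len(candidates):
            raise ValueError(
                f"n_select={self.n_select} exceeds {len(candidates)} candidates"
            )
        first = next(iter(candidates.values()))
        if t.shape != first.shape:
            raise ValueError(f"dimension mismatch: {t.shape} vs {first.shape}")
        d = {a: float(np.linalg.norm(v - t)) for a, v in candidates.items()}
        top, ordered = self._rank(d, ascending=True, n=self.n_select)
        return SelectionResult("fasa", target_id, tuple(top), ordered)


class SimSelector(_RankMixin, BaseEstimator):
    """Intensity-similarity atlas selection (MAS-SIM).

    Each atlas image is rigidly registered to the target and scored by
    mutual information on the overlap; the ``n_select`` highest-MI atlases
    are kept.
    """

    def __init__(
        self,
        n_select: int = 5,
        bins: int = 32,
        rigid_config: RigidConfig | None = None,
    ):
        self.n_select = n_select
        self.bins = bins
        self.rigid_config = rigid_config

    def fit(self, atlases: list[Atlas], y=None):
        self.atlases_ = {a.id: a for a in atlases}
        return self

    def score_one(self, target: VolumeImage, atlas: Atlas) -> float:
        transform = rigid_register(target, atlas.image, self.rigid_config)
        warped = resample_to_grid(atlas.image, target, transform, order=1)
        return mattes_mi(target, warped, bins=self.bins)

    def select(self, target: VolumeImage, target_id: str = "target") -> SelectionResult:
        if not hasattr(self, "atlases_"):
            raise NotFittedError("call fit with the atlas list first")
        candidates = {a: atl for a, atl in self.atlases_.items() if a != target_id}
        if self.n_select > len(candidates):
            raise ValueError(
                f"n_select={self.n_select} exceeds {len(candidates)} candidates"
            )
        mi: dict[str, float] = {}
        n_ok = 0
        for a, atlas in candidates.items():
            try:
                mi[a] = self.score_one(target, atlas)
                n_ok += 1
            except Exception as exc:  # registration failure: score -inf
                logger.warning("SIM: registration of atlas %s failed: %s", a, exc)
                mi[a] = float("-inf")
        if n_ok < self.n_select:
            raise RuntimeError(
                f"only {n_ok} atlases registered successfully; need {self.n_select}"
            )
        top, ordered = self._rank(mi, ascending=False, n=self.n_select)
        return SelectionResult("sim", target_id, tuple(top), ordered)


class CmasSelector(_RankMixin, BaseEstimator):
    """Conventional register-all selection (cMAS).

    Deformably registers every candidate atlas to the target and ranks by
    post-registration normalized cross-correlation.  An optional mutable
    ``cache`` (atlas id -> :class:`RegisteredAtlas`) lets callers reuse the
    expensive registrations across strategies.
    """

    def __init__(
        self,
        n_select: int = 5,
        deform_config: DeformableConfig | None = None,
        rigid_config: RigidConfig | None = None,
        do_rigid: bool = False,
    ):
        self.n_select = n_select
        self.deform_config = deform_config
        self.rigid_config = rigid_config
        self.do_rigid = do_rigid

    strategy_name = "cmas"

    def fit(self, atlases: list[Atlas], y=None):
        self.atlases_ = {a.id: a for a in atlases}
        return self

    def _candidate_ids(self, target_id: str, **kwargs) -> list[str]:
        return sorted(a for a in self.atlases_ if a != target_id)

    def _ensure_registered(
        self,
        atlas_id: str,
        target: VolumeImage,
        cache: dict[str, RegisteredAtlas],
        mask: np.ndarray | None,
    ) -> RegisteredAtlas:
        if atlas_id not in cache:
            cache[atlas_id] = register_atlas_to_target(
                self.atlases_[atlas_id],
                target,
                deform_config=self.deform_config,
                rigid_config=self.rigid_config,
                do_rigid=self.do_rigid,
                similarity_mask=mask,
            )
        return cache[atlas_id]

    def select(
        self,
        target: VolumeImage,
        target_id: str = "target",
        cache: dict[str, RegisteredAtlas] | None = None,
        similarity_mask: np.ndarray | None = None,
        **candidate_kwargs,
    ) -> SelectionResult:
        if not hasattr(self, "atlases_"):
            raise NotFittedError("call fit with the atlas list first")
        cache = cache if cache is not None else {}
        ids = self._candidate_ids(target_id, **candidate_kwargs)
        if self.n_select > len(ids):
            raise ValueError(
                f"n_select={self.n_select} exceeds {len(ids)} candidates"
            )
        ncc: dict[str, float] = {}
        n_ok = 0
        for a in ids:
            try:
                ncc[a] = self._ensure_registered(a, target, cache, similarity_mask).ncc
                n_ok += 1
            except Exception as exc:
                logger.warning("%s: registration of atlas %s failed: %s",
                               self.strategy_name, a, exc)
                ncc[a] = float("-inf")
        if n_ok < self.n_select:
            raise RuntimeError(
                f"only {n_ok} atlases registered successfully; need {self.n_select}"
            )
        top, ordered = self._rank(ncc, ascending=False, n=self.n_select)
        return SelectionResult(self.strategy_name, target_id, tuple(top), ordered)


class SagaSelector(CmasSelector):
    """Subgroup-restricted selection (MAS-SAGA).

    The target is assigned to its volume-feature subgroup, and only that
    subgroup's atlases compete, ranked by the same post-registration
    similarity as cMAS.
    """

    strategy_name = "saga"

    def __init__(
        self,
        n_select: int = 5,
        deform_config: DeformableConfig | None = None,
        rigid_config: RigidConfig | None = None,
        do_rigid: bool = False,
        subgrouper: AtlasSubgrouper | None = None,
    ):
        super().__init__(n_select, deform_config, rigid_config, do_rigid)
        self.subgrouper = subgrouper

    def _candidate_ids(self, target_id: str, target_vec=None) -> list[str]:
        if self.subgrouper is None:
            raise ValueError("SagaSelector needs a fitted subgrouper")
        if target_vec is None:
            raise ValueError("SagaSelector needs the target's feature vector")
        cluster = assign_subgroup(target_vec, self.subgrouper)
        members = [a for a in self.subgrouper.members(cluster)
                   if a in self.atlases_ and a != target_id]
        if len(members) < self.n_select:
            raise ValueError(
                f"assigned subgroup {cluster} has only {len(members)} atlases "
                f"(< n_select={self.n_select}); use a smaller n_select or fewer "
                "clusters k"
            )
        return sorted(members)

    def select(
        self,
        target: VolumeImage,
        target_vec: FeatureVector | np.ndarray = None,
        target_id: str = "target",
        cache: dict[str, RegisteredAtlas] | None = None,
        similarity_mask: np.ndarray | None = None,
    ) -> SelectionResult:
        return super().select(
            target,
            target_id=target_id,
            cache=cache,
            similarity_mask=similarity_mask,
            target_vec=target_vec,
        )


class RandomSelector(BaseEstimator):
    """Seeded uniform baseline: n atlases without replacement."""

    def __init__(self, n_select: int = 5, random_state: int = 0):
        self.n_select = n_select
        self.random_state = random_state

    def fit(self, atlas_ids: list[str], y=None):
        self.atlas_ids_ = tuple(atlas_ids)
        return self

    def select(self, target_id: str = "target", seed: int | None = None) -> SelectionResult:
        if not hasattr(self, "atlas_ids_"):
            raise NotFittedError("call fit with the atlas id list first")
        ids = [a for a in self.atlas_ids_ if a != target_id]
        if self.n_select > len(ids):
            raise ValueError(
                f"n_select={self.n_select} exceeds {len(ids)} candidates"
            )
        rng = np.random.default_rng(self.random_state if seed is None else seed)
        pick = rng.choice(len(ids), size=self.n_select, replace=False)
        return SelectionResult("random", target_id, tuple(ids[i] for i in pick), None)


# ---------------------------------------------------------------------------
# Thin functional wrappers


def select_fasa(
    target_vec, atlas_vecs: dict, n: int = 5, target_id: str = "target"
) -> SelectionResult:
    return FasaSelector(n_select=n).fit(atlas_vecs).select(target_vec, target_id)


def select_sim(
    target: VolumeImage,
    atlases: list[Atlas],
    n: int = 5,
    target_id: str = "target",
    rigid_config: RigidConfig | None = None,
) -> SelectionResult:
    sel = SimSelector(n_select=n, rigid_config=rigid_config).fit(atlases)
    return sel.select(target, target_id)


def select_cmas(
    target: VolumeImage,
    atlases: list[Atlas],
    n: int = 5,
    target_id: str = "target",
    deform_config: DeformableConfig | None = None,
    cache: dict | None = None,
    similarity_mask: np.ndarray | None = None,
) -> SelectionResult:
    sel = CmasSelector(n_select=n, deform_config=deform_config).fit(atlases)
    return sel.select(target, target_id, cache=cache, similarity_mask=similarity_mask)


def select_saga(
    target_vec,
    target: VolumeImage,
    model: AtlasSubgrouper,
    atlases: list[Atlas],
    n: int = 5,
    target_id: str = "target",
    deform_config: DeformableConfig | None = None,
    cache: dict | None = None,
    similarity_mask: np.ndarray | None = None,
) -> SelectionResult:
    sel = SagaSelector(
        n_select=n, deform_config=deform_config, subgrouper=model
    ).fit(atlases)
    return sel.select(
        target, target_vec, target_id, cache=cache, similarity_mask=similarity_mask
    )


def select_random(
    atlas_ids: list[str], n: int = 5, seed: int = 0, target_id: str = "target"
) -> SelectionResult:
    return RandomSelector(n_select=n, random_state=seed).fit(atlas_ids).select(target_id)


# ---------------------------------------------------------------------------
# Strategy-overlap analysis


@dataclass
class OverlapReport:
    """How often two strategies picked the same atlases for the same targets."""

    strategy_a: str
    strategy_b: str
    per_target: dict[str, int]
    total_coincidences: int
    total_selections: int
    #: shared picks / pooled two-strategy selections: 12 shared picks over
    #: 30 targets x 5 x 2 strategies = 12/300 = 4.0%
    coincidence_fraction: float
    #: shared picks / one strategy's selections (1.0 when the two
    #: strategies always pick the same atlases)
    agreement_fraction: float
    frequencies: pd.DataFrame  # per-atlas selection counts
    never_selected: tuple[str, ...]

    def to_csv(self, path) -> None:
        self.frequencies.to_csv(path)


def selection_overlap(
    a: dict[str, SelectionResult],
    b: dict[str, SelectionResult],
    atlas_ids: list[str] | None = None,
) -> OverlapReport:
    """Per-target intersections and overall coincidence fraction.

    The coincidence fraction is (sum of per-target intersection sizes) /
    (total selections over both strategies), e.g. 12 shared picks out of
    30 targets x 5 selections x 2 strategies = 12/300 = 4.0%.
    """
    if set(a) != set(b):
        raise ValueError("the two strategies ran on different target sets")
    if not a:
        raise ValueError("no targets")
    ns = {len(r.ranked_atlases) for r in list(a.values()) + list(b.values())}
    if len(ns) != 1:
        raise ValueError(f"selection sizes differ across results: {ns}")
    per_target = {
        t: len(set(a[t].ranked_atlases) & set(b[t].ranked_atlases)) for t in a
    }
    total = sum(per_target.values())
    total_selections = 2 * len(a) * ns.pop()
    name_a = next(iter(a.values())).strategy
    name_b = next(iter(b.values())).strategy

    counts: dict[str, dict[str, int]] = {}
    if atlas_ids is None:
        atlas_ids = sorted(
            {x for r in list(a.values()) + list(b.values()) for x in r.ranked_atlases}
        )
    for aid in atlas_ids:
        counts[aid] = {name_a: 0, name_b: 0, "both": 0}
    for t in a:
        sa, sb = set(a[t].ranked_atlases), set(b[t].ranked_atlases)
        for aid in sa:
            counts[aid][name_a] += 1
        for aid in sb:
            counts[aid][name_b] += 1
        for aid in sa & sb:
            counts[aid]["both"] += 1
    freq = pd.DataFrame.from_dict(counts, orient="index")
    freq.index.name = "atlas_id"
    never = tuple(
        aid for aid in atlas_ids if counts[aid][name_a] + counts[aid][name_b] == 0
    )
    return OverlapReport(
        strategy_a=name_a,
        strategy_b=name_b,
        per_target=per_target,
        total_coincidences=total,
        total_selections=total_selections,
        coincidence_fraction=total / total_selections,
        agreement_fraction=2 * total / total_selections,
        frequencies=freq,
        never_selected=never,
    )


def plot_overlap_grid(
    a: dict[str, SelectionResult],
    b: dict[str, SelectionResult],
    atlas_ids: list[str],
    path=None,
):
    """Targets x atlases grid colored by which strategy selected each atlas
    (the selection-agreement figure style: one row per target)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    targets = sorted(a)
    grid = np.zeros((len(targets), len(atlas_ids)), dtype=int)
    col = {aid: j for j, aid in enumerate(atlas_ids)}
    for i, t in enumerate(targets):
        sa, sb = set(a[t].ranked_atlases), set(b[t].ranked_atlases)
        for aid in sa - sb:
            grid[i, col[aid]] = 1
        for aid in sb - sa:
            grid[i, col[aid]] = 2
        for aid in sa & sb:
            grid[i, col[aid]] = 3
    cmap = ListedColormap(["#74c476", "#ffd92f", "#e41a1c", "#ff7f00"])
    fig, ax = plt.subplots(figsize=(10, 5))
    ax.imshow(grid, cmap=cmap, vmin=0, vmax=3, aspect="auto", interpolation="none")
    ax.set_xlabel("atlas")
    ax.set_ylabel("target")
    name_a = next(iter(a.values())).strategy
    name_b = next(iter(b.values())).strategy
    ax.set_title(f"selected by: {name_a} (yellow), {name_b} (red), both (orange)")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
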