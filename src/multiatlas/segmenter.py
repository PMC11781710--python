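"""A single fit/predict front door for the whole pipeline.

``MultiAtlasSegmenter`` wraps atlas-library fitting (feature extraction,
normalization, subgrouping) and per-target segmentation (selection,
deformable registration, label propagation, majority-vote fusion) behind
the familiar estimator interface::

    seg = MultiAtlasSegmenter(strategy="saga", n_select=5, k=4)
    seg.fit(atlases)
    fused = seg.predict(target_image, target_volumes={"bladder": 180.0, ...})
"""

from __future__ import annotations

from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .features import (
    DEFAULT_STRUCTURES,
    extract_features,
    features_from_volumes,
    fit_normalizer,
    normalize,
)
from .imaging import Atlas, LabelMap, VolumeImage
from .registration import DeformableConfig, RigidConfig, majority_vote
from .selection import (
    CmasSelector,
    FasaSelector,
    RandomSelector,
    SagaSelector,
    SelectionResult,
    SimSelector,
)
from .subgrouping import fit_subgroups


class MultiAtlasSegmenter(BaseEstimator):
    """Multi-atlas segmentation with a pluggable selection strategy.

    Parameters
    ----------
    strategy : {"cmas", "saga", "fasa", "sim", "random"}, default "saga"
    n_select : int, default 5
        Atlases fused per target.
    k : int, default 4
        Subgroups for the SAGA strategy.
    structures : tuple of str
        Feature-vector structure order (body plus the five organs by
        default).
    do_rigid : bool, default False
        Rigid pre-alignment before the deformable stage (synthetic cohorts
        share a frame; patient data should enable this).
    random_state : int, default 0
    """

    def __init__(
        self,
        strategy: str = "saga",
        n_select: int = 5,
        k: int = 4,
        structures: tuple[str, ...] = DEFAULT_STRUCTURES,
        deform_config: DeformableConfig | None = None,
        rigid_config: RigidConfig | None = None,
        do_rigid: bool = False,
        random_state: int = 0,
    ):
        self.strategy = strategy
        self.n_select = n_select
        self.k = k
        self.structures = structures
        self.deform_config = deform_config
        self.rigid_config = rigid_config
        self.do_rigid = do_rigid
        self.random_state = random_state

    def fit(self, atlases: list[Atlas], y=None) -> "MultiAtlasSegmenter":
        if self.strategy not in ("cmas", "saga", "fasa", "sim", "random"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        self.atlases_ = list(atlases)
        vectors_raw = {a.id: extract_features(a, self.structures) for a in atlases}
        self.normalizer_ = fit_normalizer(list(vectors_raw.values()))
        self.vectors_ = {
            aid: normalize(v, self.normalizer_) for aid, v in vectors_raw.items()
        }
        self.subgrouper_ = (
            fit_subgroups(self.vectors_, k=self.k, seed=self.random_state)
            if self.strategy == "saga"
            else None
        )
        if self.strategy == "cmas":
            self.selector_ = CmasSelector(
                self.n_select, self.deform_config, self.rigid_config, self.do_rigid
            ).fit(atlases)
        elif self.strategy == "saga":
            self.selector_ = SagaSelector(
                self.n_select,
                self.deform_config,
                self.rigid_config,
                self.do_rigid,
                self.subgrouper_,
            ).fit(atlases)
        elif self.strategy == "fasa":
            self.selector_ = FasaSelector(self.n_select).fit(self.vectors_)
        elif self.strategy == "sim":
            self.selector_ = SimSelector(
                self.n_select, rigid_config=self.rigid_config
            ).fit(atlases)
        else:
            self.selector_ = RandomSelector(self.n_select, self.random_state).fit(
                sorted(vectors_raw)
            )
        self._cache = {}
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "selector_"):
            raise NotFittedError("fit the segmenter on an atlas library first")

    def select(
        self,
        target: VolumeImage,
        target_volumes: dict[str, float] | None = None,
        target_id: str = "target",
    ) -> SelectionResult:
        """Run only the selection step for a target."""
        self._check_fitted()
        mask = target.voxels > -500.0
        if self.strategy in ("saga", "fasa"):
            if target_volumes is None:
                raise ValueError(
                    f"strategy {self.strategy!r} needs the target's structure "
                    "volumes (feature-based selection)"
                )
            tvec = normalize(
                features_from_volumes(target_volumes, self.structures),
                self.normalizer_,
            )
            if self.strategy == "fasa":
                return self.selector_.select(tvec, target_id)
            return self.selector_.select(
                target, tvec, target_id, cache=self._cache, similarity_mask=mask
            )
        if self.strategy == "cmas":
            return self.selector_.select(
                target, target_id, cache=self._cache, similarity_mask=mask
            )
        if self.strategy == "sim":
            return self.selector_.select(target, target_id)
        return self.selector_.select(target_id)

    def predict(
        self,
        target: VolumeImage,
        target_volumes: dict[str, float] | None = None,
        target_id: str = "target",
    ) -> LabelMap:
        """Segment a target image: select, register, propagate, fuse."""
        self._check_fitted()
        self._cache: dict = {}
        selection = self.select(target, target_volumes, target_id)
        self.last_selection_ = selection
        mask = target.voxels > -500.0
        registrar = (
            self.selector_
            if isinstance(self.selector_, CmasSelector)
            else CmasSelector(
                self.n_select, self.deform_config, self.rigid_config, self.do_rigid
            ).fit(self.atlases_)
        )
        candidates = [
            registrar._ensure_registered(a, target, self._cache, mask).labels
            for a in selection.ranked_atlases
        ]
        return majority_vote(candidates)
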