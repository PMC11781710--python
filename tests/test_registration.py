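"""Mutual information, rigid/deformable registration, propagation, fusion."""

import numpy as np
import pytest

from multiatlas import (
    DeformableConfig,
    DeformationField,
    LabelMap,
    RigidConfig,
    RigidTransform,
    VolumeImage,
    apply_field,
    deformable_register,
    majority_vote,
    mattes_mi,
    propagate_labels,
    rigid_register,
)
from multiatlas.registration import (
    _euler_matrix,
    _physical_grid,
    _sample_at_physical,
    resample_to_grid,
)

from conftest import image_like

FAST_RIGID = RigidConfig(levels=(4, 2), max_evaluations=(300, 120))
FAST_DEFORM = DeformableConfig(levels=(4, 2), iterations=(60, 30))


def shifted_copy(img: VolumeImage, offset_mm) -> VolumeImage:
    """moving(x) = fixed(x - offset): content translated by +offset."""
    pts = _physical_grid(img.shape, img.spacing, img.origin)
    data = _sample_at_physical(
        img, pts - np.asarray(offset_mm, dtype=float), order=1,
        cval=float(img.voxels.min()),
    )
    return VolumeImage(data, img.spacing, img.origin)


class TestMutualInformation:
    def test_self_information_is_marginal_entropy(self, coarse_phantom):
        img = coarse_phantom.image
        mi = mattes_mi(img, img, bins=32)
        hist, _ = np.histogram(img.voxels, bins=32)
        p = hist / hist.sum()
        entropy = -(p[p > 0] * np.log(p[p > 0])).sum()
        assert mi == pytest.approx(entropy, rel=1e-9)

    def test_symmetric(self, coarse_phantom):
        rng = np.random.default_rng(0)
        a = coarse_phantom.image
        b = VolumeImage(rng.normal(size=a.shape), a.spacing, a.origin)
        assert abs(mattes_mi(a, b) - mattes_mi(b, a)) < 1e-9

    def test_independent_noise_mi_below_bias_bound(self):
        # analytic chi-square bias for independent data: ~(bins-1)^2/(2 n)
        rng = np.random.default_rng(1)
        a = image_like(rng.uniform(size=(64, 64, 64)))
        b = image_like(rng.uniform(size=(64, 64, 64)))
        assert mattes_mi(a, b, bins=32) < 0.01

    def test_invariant_to_affine_intensity_rescale(self, coarse_phantom):
        a = coarse_phantom.image
        b = VolumeImage(a.voxels * 2.5 + 100.0, a.spacing, a.origin)
        assert mattes_mi(a, b, bins=32) == pytest.approx(
            mattes_mi(a, a, bins=32), rel=1e-9
        )

    def test_constant_image_warns_and_returns_zero(self):
        a = image_like(np.zeros((16, 16, 16)))
        b = image_like(np.random.default_rng(0).normal(size=(16, 16, 16)))
        with pytest.warns(UserWarning, match="constant"):
            assert mattes_mi(a, b) == 0.0

    def test_noise_image_mi_within_permutation_null(self):
        rng = np.random.default_rng(2)
        a = image_like(rng.uniform(size=(24, 24, 24)))
        b_data = rng.uniform(size=(24, 24, 24))
        mi = mattes_mi(a, image_like(b_data), bins=16)
        null = []
        for _ in range(20):
            perm = rng.permutation(b_data.ravel()).reshape(b_data.shape)
            null.append(mattes_mi(a, image_like(perm), bins=16))
        se = np.std(null, ddof=1) / np.sqrt(len(null))
        assert abs(mi - np.mean(null)) < 3 * se + 1e-3

    def test_too_few_bins_rejected(self, coarse_phantom):
        with pytest.raises(ValueError, match="bins"):
            mattes_mi(coarse_phantom.image, coarse_phantom.image, bins=4)


class TestRigidRegistration:
    def test_identity_for_identical_images(self, coarse_phantom):
        t = rigid_register(coarse_phantom.image, coarse_phantom.image, FAST_RIGID)
        assert np.linalg.norm(t.translation) < 1.0
        assert abs(np.trace(t.rotation) - 3.0) < 1e-3

    def test_translation_recovered_within_half_voxel(self, phantom):
        moving = shifted_copy(phantom.image, (10.0, 0.0, 0.0))
        t = rigid_register(phantom.image, moving, FAST_RIGID)
        err = np.linalg.norm(t.translation - np.array([10.0, 0.0, 0.0]))
        assert err < 0.5 * min(phantom.image.spacing)

    def test_small_rotation_recovered(self, phantom):
        rot = RigidTransform(
            _euler_matrix(0, 0, np.deg2rad(5.0)), np.zeros(3), np.zeros(3)
        )
        moving = resample_to_grid(phantom.image, phantom.image, rot, order=1)
        t = rigid_register(phantom.image, moving, FAST_RIGID)
        recovered_deg = np.rad2deg(np.arctan2(t.rotation[1, 0], t.rotation[0, 0]))
        assert recovered_deg == pytest.approx(-5.0, abs=0.5)

    def test_rotation_must_be_proper(self):
        with pytest.raises(ValueError, match="orthonormal"):
            RigidTransform(rotation=2 * np.eye(3))


class TestDeformableRegistration:
    def test_identity_input_gives_negligible_field(self, coarse_phantom):
        field = deformable_register(
            coarse_phantom.image, coarse_phantom.image, config=FAST_DEFORM
        )
        assert np.percentile(field.magnitude(), 99) < 0.1

    def test_msd_never_worse_than_initialization(self, phantom):
        from multiatlas import random_smooth_field

        img = phantom.image
        w = random_smooth_field(
            img.shape, img.spacing, img.origin, amplitude_mm=10.0, seed=13
        )
        moving = VolumeImage(apply_field(img, w).voxels, img.spacing, img.origin)
        field = deformable_register(img, moving, config=FAST_DEFORM)
        warped = apply_field(moving, field)
        msd_before = ((moving.voxels - img.voxels) ** 2).mean()
        msd_after = ((warped.voxels - img.voxels) ** 2).mean()
        assert msd_after <= msd_before

    def test_field_round_trips_through_nifti(self, tmp_path):
        from multiatlas.registration import read_field, write_field

        rng = np.random.default_rng(8)
        field = DeformationField(
            rng.normal(size=(6, 5, 4, 3)), (2.0, 2.0, 3.0), (-5.0, 0.0, 1.0)
        )
        write_field(field, tmp_path / "dvf.nii.gz")
        back = read_field(tmp_path / "dvf.nii.gz")
        np.testing.assert_allclose(back.displacement, field.displacement)
        assert back.spacing == field.spacing
        assert back.origin == field.origin

    def test_field_must_be_finite(self):
        bad = np.zeros((4, 4, 4, 3))
        bad[0, 0, 0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            DeformationField(bad, (1, 1, 1), (0, 0, 0))

    def test_self_registration_reproduces_contours(self, coarse_phantom):
        field = deformable_register(
            coarse_phantom.image, coarse_phantom.image, config=FAST_DEFORM
        )
        prop = propagate_labels(coarse_phantom.contours, field)
        from multiatlas import dice

        assert dice(prop, coarse_phantom.contours, 1) > 0.99


class TestPropagateLabels:
    def test_identity_field_preserves_labels(self, coarse_phantom):
        lab = coarse_phantom.contours
        field = DeformationField(
            np.zeros(lab.shape + (3,)), lab.spacing, lab.origin
        )
        out = propagate_labels(lab, field)
        np.testing.assert_array_equal(out.labels, lab.labels)

    def test_pure_translation_shifts_by_whole_voxels(self):
        rng = np.random.default_rng(3)
        data = rng.integers(0, 3, size=(12, 12, 12)).astype(np.int16)
        lab = LabelMap(data)  # 1 mm spacing
        disp = np.zeros((12, 12, 12, 3))
        disp[..., 0] = 5.0
        out = propagate_labels(lab, DeformationField(disp, (1, 1, 1), (0, 0, 0)))
        np.testing.assert_array_equal(out.labels[:7], data[5:])
        assert (out.labels[7:] == 0).all()  # outside maps to background

    def test_output_labels_subset_of_input(self, coarse_phantom):
        rng = np.random.default_rng(4)
        disp = rng.normal(0, 3, size=coarse_phantom.contours.shape + (3,))
        out = propagate_labels(
            coarse_phantom.contours,
            DeformationField(disp, coarse_phantom.contours.spacing,
                             coarse_phantom.contours.origin),
        )
        assert set(np.unique(out.labels)) <= (
            set(np.unique(coarse_phantom.contours.labels)) | {0}
        )


class TestMajorityVote:
    @staticmethod
    def _maps(arrays):
        return [LabelMap(np.asarray(a, dtype=np.int16)) for a in arrays]

    def test_three_of_five_wins(self):
        votes = [1, 1, 1, 0, 0]
        maps = self._maps([np.full((2, 2, 2), v) for v in votes])
        assert (majority_vote(maps).labels == 1).all()

    def test_identical_candidates_pass_through(self, coarse_phantom):
        fused = majority_vote([coarse_phantom.contours] * 5)
        np.testing.assert_array_equal(fused.labels, coarse_phantom.contours.labels)

    def test_two_two_tie_goes_to_background(self):
        maps = self._maps([np.full((2, 2, 2), v) for v in (1, 1, 2, 2)])
        assert (majority_vote(maps).labels == 0).all()

    def test_matches_per_voxel_mode_oracle(self):
        rng = np.random.default_rng(5)
        stacks = [rng.integers(0, 4, size=(16, 16, 16)) for _ in range(5)]
        fused = majority_vote(self._maps(stacks)).labels
        arr = np.stack(stacks)
        for idx in zip(*[rng.integers(0, 16, 40) for _ in range(3)]):
            votes = arr[(slice(None),) + idx]
            counts = np.bincount(votes, minlength=4)
            top = counts.max()
            winners = np.nonzero(counts == top)[0]
            expected = winners[0] if len(winners) == 1 else 0
            assert fused[idx] == expected

    def test_permutation_invariant(self):
        rng = np.random.default_rng(6)
        stacks = [rng.integers(0, 3, size=(8, 8, 8)) for _ in range(5)]
        maps = self._maps(stacks)
        f1 = majority_vote(maps).labels
        f2 = majority_vote(maps[::-1]).labels
        np.testing.assert_array_equal(f1, f2)

    def test_grid_mismatch_raises(self):
        a = LabelMap(np.zeros((4, 4, 4), dtype=np.int16), spacing=(1, 1, 1))
        b = LabelMap(np.zeros((4, 4, 4), dtype=np.int16), spacing=(2, 2, 2))
        with pytest.raises(ValueError, match="grid"):
            majority_vote([a, b])

    def test_needs_at_least_one_candidate(self):
        with pytest.raises(ValueError):
            majority_vote([])
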