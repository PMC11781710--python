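"""Atlas selection strategies: ranking oracles, tie rules, restriction
properties and the strategy-overlap analysis."""

import numpy as np
import pytest

from multiatlas import (
    DeformableConfig,
    FeatureVector,
    RigidConfig,
    SelectionResult,
    generate_phantom,
    select_fasa,
    select_random,
    selection_overlap,
    fit_subgroups,
)
from multiatlas.selection import (
    CmasSelector,
    SagaSelector,
    SimSelector,
    plot_overlap_grid,
)

from conftest import make_volumes, small_spec

FAST_RIGID = RigidConfig(levels=(4,), max_evaluations=(200,))
FAST_DEFORM = DeformableConfig(levels=(4, 2), iterations=(30, 15))


def vec(values) -> FeatureVector:
    values = np.atleast_1d(np.asarray(values, dtype=float))
    names = tuple(f"s{i}" for i in range(len(values)))
    return FeatureVector(names, np.abs(values), values)


class TestFasa:
    def test_identical_vector_ranked_first_with_zero_distance(self):
        rng = np.random.default_rng(0)
        atlas_vecs = {f"a{i:02d}": vec(rng.normal(size=3)) for i in range(10)}
        target = atlas_vecs["a07"].normalized.copy()
        res = select_fasa(vec(target), atlas_vecs, n=3)
        assert res.ranked_atlases[0] == "a07"
        assert res.scores["a07"] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_full_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        atlas_vecs = {f"a{i:02d}": vec(rng.normal(size=4)) for i in range(20)}
        target = vec(rng.normal(size=4))
        res = select_fasa(target, atlas_vecs, n=5)
        d = {
            a: np.linalg.norm(v.normalized - target.normalized)
            for a, v in atlas_vecs.items()
        }
        expected = sorted(d, key=lambda a: (d[a], a))[:5]
        assert list(res.ranked_atlases) == expected
        # scores ascend with the ranking
        ranked_d = [res.scores[a] for a in res.ranked_atlases]
        assert ranked_d == sorted(ranked_d)

    def test_equal_distance_breaks_ties_lexicographically(self):
        atlas_vecs = {
            "b": vec([1.0, 0.0]),
            "a": vec([-1.0, 0.0]),
            "c": vec([0.0, 5.0]),
        }
        res = select_fasa(vec([0.0, 0.0]), atlas_vecs, n=2)
        assert list(res.ranked_atlases) == ["a", "b"]

    def test_target_id_excluded_from_candidates(self):
        atlas_vecs = {"a": vec([0.0]), "b": vec([1.0])}
        res = select_fasa(vec([0.0]), atlas_vecs, n=1, target_id="a")
        assert res.ranked_atlases == ("b",)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            select_fasa(vec([0.0, 1.0]), {"a": vec([0.0])}, n=1)


class TestRandomBaseline:
    def test_seeded_rerun_identical(self):
        ids = [f"a{i}" for i in range(12)]
        r1 = select_random(ids, n=5, seed=3)
        r2 = select_random(ids, n=5, seed=3)
        assert r1.ranked_atlases == r2.ranked_atlases

    def test_selecting_all_is_a_permutation(self):
        ids = [f"a{i}" for i in range(8)]
        res = select_random(ids, n=8, seed=1)
        assert sorted(res.ranked_atlases) == sorted(ids)

    def test_uniform_selection_frequencies(self):
        ids = [f"a{i:02d}" for i in range(10)]
        n, draws = 3, 10_000
        counts = {a: 0 for a in ids}
        for d in range(draws):
            for a in select_random(ids, n=n, seed=d).ranked_atlases:
                counts[a] += 1
        p = n / len(ids)
        sigma = np.sqrt(draws * p * (1 - p))
        for a in ids:
            assert abs(counts[a] - draws * p) < 3 * sigma


@pytest.fixture(scope="module")
def tiny_library():
    """Five coarse noisy phantoms with graded bladder volumes + a target.

    CT-like noise matters here: without it the piecewise-constant phantoms
    are indistinguishable to a 32-bin joint histogram (all soft-tissue
    classes share one bin), which degenerates MI ranking.
    """
    atlases = []
    for i, bl in enumerate([100.0, 150.0, 200.0, 260.0, 330.0]):
        spec = small_spec(
            volumes_cc=make_volumes(bladder=bl), noise_sd=10.0, seed=20 + i
        )
        atlases.append(generate_phantom(spec, f"a{i:02d}"))
    target_atlas = generate_phantom(
        small_spec(volumes_cc=make_volumes(bladder=210.0), noise_sd=10.0, seed=99),
        "target",
    )
    return atlases, target_atlas


class TestSim:
    def test_exact_copy_of_target_ranked_first(self, tiny_library):
        atlases, target_atlas = tiny_library
        from multiatlas.imaging import Atlas

        clone = Atlas("clone", target_atlas.image, target_atlas.contours)
        sel = SimSelector(n_select=2, rigid_config=FAST_RIGID).fit(atlases + [clone])
        res = sel.select(target_atlas.image, "target")
        assert res.ranked_atlases[0] == "clone"
        # MI scores descend with ranking
        ranked = [res.scores[a] for a in res.ranked_atlases]
        assert ranked == sorted(ranked, reverse=True)

    def test_n_equals_all_is_full_sort(self, tiny_library):
        atlases, target_atlas = tiny_library
        sel = SimSelector(n_select=5, rigid_config=FAST_RIGID).fit(atlases)
        res = sel.select(target_atlas.image, "target")
        assert sorted(res.ranked_atlases) == sorted(a.id for a in atlases)


class TestCmas:
    def test_target_itself_ranked_first_with_similarity_one(self, tiny_library):
        atlases, target_atlas = tiny_library
        from multiatlas.imaging import Atlas

        clone = Atlas("clone", target_atlas.image, target_atlas.contours)
        sel = CmasSelector(n_select=2, deform_config=FAST_DEFORM).fit(
            atlases[:3] + [clone]
        )
        res = sel.select(target_atlas.image, "target")
        assert res.ranked_atlases[0] == "clone"
        assert res.scores["clone"] == pytest.approx(1.0, abs=1e-6)

    def test_selection_size_and_no_target(self, tiny_library):
        atlases, target_atlas = tiny_library
        sel = CmasSelector(n_select=3, deform_config=FAST_DEFORM).fit(atlases)
        cache = {}
        res = sel.select(target_atlas.image, "target", cache=cache)
        assert len(res.ranked_atlases) == 3
        assert "target" not in res.ranked_atlases
        assert len(cache) == len(atlases)  # register-all cost profile


class TestSaga:
    def test_selection_restricted_to_assigned_subgroup(self, tiny_library):
        atlases, target_atlas = tiny_library
        vectors = {
            a.id: vec([i]) for i, a in enumerate(atlases)
        }  # two obvious volume groups: {0,1} vs {3,4} with 2 in between
        model = fit_subgroups(vectors, k=2, seed=0)
        sel = SagaSelector(
            n_select=2, deform_config=FAST_DEFORM, subgrouper=model
        ).fit(atlases)
        tvec = vec([0.2])
        cluster = model.predict(np.array([[0.2]]))[0]
        members = set(model.members(cluster))
        res = sel.select(target_atlas.image, tvec, "target")
        assert set(res.ranked_atlases) <= members

    def test_subgroup_smaller_than_n_advises(self, tiny_library):
        atlases, target_atlas = tiny_library
        vectors = {a.id: vec([i]) for i, a in enumerate(atlases)}
        model = fit_subgroups(vectors, k=2, seed=0)
        sel = SagaSelector(n_select=4, subgrouper=model).fit(atlases)
        with pytest.raises(ValueError, match="smaller n_select or fewer"):
            sel.select(target_atlas.image, vec([0.0]), "target")


class TestSelectionResult:
    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicates"):
            SelectionResult("fasa", "t", ("a", "a"))

    def test_self_selection_rejected(self):
        with pytest.raises(ValueError, match="itself"):
            SelectionResult("fasa", "t", ("a", "t"))


def engineered_results(n_targets=30, n_pick=5, coincidences=12):
    """Two strategies over 70 atlases with an exact number of shared picks."""
    ids = [f"i{k:02d}" for k in range(70)]
    a, b = {}, {}
    remaining = coincidences
    for t in range(n_targets):
        tid = f"t{t:02d}"
        shared = min(remaining, n_pick) if remaining > 0 else 0
        shared = min(shared, 2)  # spread coincidences over targets
        remaining -= shared
        pick_a = ids[:shared] + ids[10:10 + n_pick - shared]
        pick_b = ids[:shared] + ids[30:30 + n_pick - shared]
        a[tid] = SelectionResult("fasa", tid, tuple(pick_a))
        b[tid] = SelectionResult("sim", tid, tuple(pick_b))
    assert remaining == 0
    return a, b, ids


class TestSelectionOverlap:
    def test_identical_results_give_full_agreement(self):
        a = {f"t{i}": SelectionResult("fasa", f"t{i}", ("x", "y")) for i in range(4)}
        b = {f"t{i}": SelectionResult("sim", f"t{i}", ("y", "x")) for i in range(4)}
        assert selection_overlap(a, b).agreement_fraction == 1.0

    def test_disjoint_results_give_fraction_zero(self):
        a = {"t": SelectionResult("fasa", "t", ("x", "y"))}
        b = {"t": SelectionResult("sim", "t", ("u", "v"))}
        report = selection_overlap(a, b)
        assert report.coincidence_fraction == 0.0
        assert report.agreement_fraction == 0.0

    def test_engineered_twelve_of_three_hundred(self):
        a, b, ids = engineered_results()
        report = selection_overlap(a, b, atlas_ids=ids)
        assert report.total_selections == 300
        assert report.total_coincidences == 12
        assert report.coincidence_fraction == pytest.approx(0.04)
        # atlases never chosen by either strategy are reported
        assert set(report.never_selected) == (
            set(ids) - {x for r in list(a.values()) + list(b.values())
                        for x in r.ranked_atlases}
        )

    def test_mismatched_targets_rejected(self):
        a = {"t1": SelectionResult("fasa", "t1", ("x",))}
        b = {"t2": SelectionResult("sim", "t2", ("x",))}
        with pytest.raises(ValueError, match="different target"):
            selection_overlap(a, b)

    def test_grid_figure_renders(self, tmp_path):
        a, b, ids = engineered_results(n_targets=5, coincidences=4)
        fig = plot_overlap_grid(a, b, ids, path=tmp_path / "grid.png")
        assert (tmp_path / "grid.png").exists()
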