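import itertools

import numpy as np
import pytest

from netarget.coord_eval import (
    ConditioningError,
    euclidean_distance,
    label_with_atlas,
    load_reference_set,
    pairwise_distance_summary,
    sensitivity_selectivity,
    talairach_mni,
    trilaterate_reference,
    wilcoxon_one_sample,
)
from netarget.image_model import GridImage
from netarget.tables import coordinates, distance_column


class TestEuclidean:
    def test_hand_computed_patient_pair(self):
        # first two parietal targets of the patient table: sqrt(216)
        d = euclidean_distance((-34, -80, 44), (-38, -66, 42))
        assert d == pytest.approx(np.sqrt(216), abs=1e-12)
        assert round(d, 2) == 14.70

    def test_identity_and_symmetry(self, rng):
        a, b = rng.normal(size=(2, 3))
        assert euclidean_distance(a, a) == 0.0
        assert euclidean_distance(a, b) == euclidean_distance(b, a)

    def test_space_mismatch_rejected(self):
        with pytest.raises(ValueError, match="space"):
            euclidean_distance((0, 0, 0), (1, 1, 1), "MNI", "native_T1")


class TestPairwiseSummary:
    def test_two_points_median_is_their_distance(self):
        s = pairwise_distance_summary([(0, 0, 0), (3, 4, 0)])
        assert s.median == pytest.approx(5.0)

    def test_matches_exhaustive_enumeration(self, rng):
        pts = rng.normal(scale=30, size=(4, 3))
        s = pairwise_distance_summary(pts)
        oracle = sorted(
            np.linalg.norm(pts[i] - pts[j]) for i, j in itertools.combinations(range(4), 2)
        )
        assert len(s.distances) == 6
        assert s.median == pytest.approx(np.median(oracle))
        assert s.q1 == pytest.approx(np.percentile(oracle, 25))
        assert s.q3 == pytest.approx(np.percentile(oracle, 75))

    def test_invariant_under_rigid_motion(self, rng):
        pts = rng.normal(scale=30, size=(7, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = pts @ q.T + rng.normal(scale=100, size=3)
        a = pairwise_distance_summary(pts)
        b = pairwise_distance_summary(moved)
        assert a.median == pytest.approx(b.median, abs=1e-9)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distance_summary([(0, 0, 0)])


def brute_force_wilcoxon(values, mu, alternative):
    """Full 2^n enumeration over sign assignments, conditional on |d|."""
    from scipy.stats import rankdata

    d = np.asarray(values, float) - mu
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.asarray(stats)
    p_greater = np.mean(stats >= w_obs - 1e-12)
    p_less = np.mean(stats <= w_obs + 1e-12)
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2 * min(p_greater, p_less))


class TestWilcoxon:
    def test_reproduces_published_parietal_p_values(self, ad_table):
        dists = distance_column(ad_table, "P3")
        p12 = wilcoxon_one_sample(dists, mu=12, alternative="greater")
        assert p12.exact
        assert p12.p_value == pytest.approx(0.0002, abs=5e-5)
        p20 = wilcoxon_one_sample(dists, mu=20, alternative="greater")
        assert p20.p_value == pytest.approx(0.342, abs=5e-4)

    def test_tiny_exact_case(self):
        res = wilcoxon_one_sample([1.0, 2.0, 3.0], mu=0.0, alternative="greater")
        assert res.p_value == pytest.approx(1.0 / 8.0)
        assert res.statistic == 6.0

    def test_all_values_below_mu_gives_p_near_one(self, rng):
        values = rng.uniform(0, 5, size=10)
        res = wilcoxon_one_sample(values, mu=10.0, alternative="greater")
        assert res.statistic == 0.0
        assert res.p_value >= 0.999

    @pytest.mark.parametrize("alternative", ["greater", "less", "two-sided"])
    @pytest.mark.parametrize("case", range(4))
    def test_matches_full_enumeration_oracle(self, alternative, case):
        rng = np.random.default_rng(400 + case)
        n = int(rng.integers(4, 10))
        values = np.round(rng.normal(1.0, 2.0, size=n), 1)  # rounding makes ties
        mu = 0.5
        if np.all(values == mu):
            values[0] += 1.0
        res = wilcoxon_one_sample(values, mu=mu, alternative=alternative)
        assert res.p_value == pytest.approx(
            brute_force_wilcoxon(values, mu, alternative), abs=1e-12
        )

    def test_statistic_bounds(self, rng):
        values = rng.normal(size=12)
        res = wilcoxon_one_sample(values, mu=0.0)
        n = res.n
        assert 0 <= res.statistic <= n * (n + 1) / 2
        assert 0 < res.p_value <= 1

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_one_sample([2.0, 2.0], mu=2.0)

    def test_large_n_uses_normal_approximation(self, rng):
        values = rng.normal(1.0, 1.0, size=40)
        res = wilcoxon_one_sample(values, mu=0.5)
        assert not res.exact
        exact = wilcoxon_one_sample(values, mu=0.5, exact_limit=50)
        assert res.p_value == pytest.approx(exact.p_value, abs=0.01)


def cohort_maps(n, containing, other_containing):
    """Binary maps on a shared grid; the reference lands at voxel (2,2,2)."""
    expected, others = [], []
    for i in range(n):
        e = np.zeros((5, 5, 5))
        o = np.zeros((5, 5, 5))
        if i in containing:
            e[2, 2, 2] = 1.0
        if i in other_containing:
            o[2, 2, 2] = 1.0
        expected.append(GridImage(e, np.eye(4)))
        others.append(GridImage(o, np.eye(4)))
    return expected, others


class TestSensitivitySelectivity:
    def test_mirrors_published_row_structure(self):
        # 13 subjects; inside 6 expected maps, 4 of which also contain it
        expected, others = cohort_maps(13, set(range(6)), {0, 1, 2, 3})
        res = sensitivity_selectivity((2.0, 2.0, 2.0), expected, others, 0.5)
        assert res.sensitivity == pytest.approx(6 / 13)
        assert round(res.sensitivity * 100) == 46
        assert res.selectivity == pytest.approx(2 / 6)
        assert round(res.selectivity * 100) == 33

    def test_disjoint_maps_are_fully_selective(self):
        expected, others = cohort_maps(5, {0, 1, 2}, set())
        res = sensitivity_selectivity((2.0, 2.0, 2.0), expected, others, 0.5)
        assert res.selectivity == 1.0

    def test_uncontained_coordinate_flags_selectivity_undefined(self):
        expected, others = cohort_maps(4, set(), set())
        res = sensitivity_selectivity((2.0, 2.0, 2.0), expected, others, 0.5)
        assert res.sensitivity == 0.0
        assert res.selectivity is None

    def test_out_of_fov_subject_excluded(self):
        expected, others = cohort_maps(3, {0, 1, 2}, set())
        res = sensitivity_selectivity((100.0, 2.0, 2.0), expected[:1] + [
            GridImage(np.ones((200, 5, 5)), np.eye(4))
        ] + expected[2:], others, 0.5)
        assert res.n_excluded == 2
        assert res.n_subjects == 1


class TestTalairachMni:
    @pytest.mark.parametrize(
        "convention", ["brett", "lancaster_spm", "lancaster_fsl"]
    )
    def test_round_trip_identity(self, convention, rng):
        for _ in range(10):
            p = rng.normal(scale=40, size=3)
            tal = talairach_mni(p, "mni2tal", convention)
            back = talairach_mni(tal, "tal2mni", convention)
            np.testing.assert_allclose(back, p, atol=1e-6)

    def test_lancaster_matches_direct_matrix_product(self):
        mat = np.array(
            [[0.9254, 0.0024, -0.0118, -1.0207],
             [-0.0048, 0.9316, -0.0871, -1.7667],
             [0.0152, 0.0883, 0.8924, 4.0926]]
        )
        p = np.array([-38.0, -66.0, 51.0])
        expected = mat[:, :3] @ p + mat[:, 3]
        np.testing.assert_allclose(
            talairach_mni(p, "mni2tal", "lancaster_spm"), expected, atol=1e-12
        )

    def test_brett_branches_agree_on_midline_plane(self):
        # the piecewise map is continuous across z=0 only where y=0
        for x in (-40.0, 0.0, 25.0):
            up = talairach_mni((x, 0.0, 1e-9), "mni2tal", "brett")
            down = talairach_mni((x, 0.0, -1e-9), "mni2tal", "brett")
            np.testing.assert_allclose(up, down, atol=1e-6)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            talairach_mni((0, 0, 0), "mni2tal", "mystery")


class TestTrilateration:
    def test_exact_recovery_from_consistent_distances(self, rng):
        ref = rng.normal(scale=30, size=3)
        pts = rng.normal(scale=30, size=(8, 3))
        d = np.linalg.norm(pts - ref, axis=1)
        fit = trilaterate_reference(pts, d)
        np.testing.assert_allclose(fit.reference_mm, ref, atol=1e-9)
        assert fit.rms_residual < 1e-9

    def test_published_parietal_column_is_consistent(self, ad_table):
        fit = trilaterate_reference(
            coordinates(ad_table, "ipl"), distance_column(ad_table, "P3")
        )
        assert fit.rms_residual <= 0.01

    def test_coplanar_points_rejected(self):
        pts = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)]
        with pytest.raises(ConditioningError):
            trilaterate_reference(pts, [1.0, 1.0, 1.0, 1.0])


class TestAtlasLabeling:
    @pytest.fixture
    def atlas(self):
        data = np.zeros((20, 20, 20), dtype=int)
        data[2:8, 2:8, 2:8] = 1
        data[12:18, 12:18, 12:18] = 2
        return GridImage(data, np.diag([2.0, 2.0, 2.0, 1.0])), {1: "A", 2: "B"}

    def test_containment(self, atlas):
        img, labels = atlas
        assert label_with_atlas((8.0, 8.0, 8.0), img, labels) == "A"

    def test_near_rule(self, atlas):
        img, labels = atlas
        # 2 mm outside box A in background
        assert label_with_atlas((18.0, 8.0, 8.0), img, labels) == "near:A"

    def test_far_background_is_none(self, atlas):
        img, labels = atlas
        assert label_with_atlas((38.0, 2.0, 38.0), img, labels) == "none"

    def test_outside_fov_rejected(self, atlas):
        img, labels = atlas
        with pytest.raises(ValueError):
            label_with_atlas((500.0, 0.0, 0.0), img, labels)

    def test_agrees_with_exhaustive_nearest_scan(self, atlas, rng):
        from netarget.image_model import voxel_to_world, world_to_voxel

        img, labels = atlas
        labeled = np.argwhere(img.data != 0)
        lworld = np.atleast_2d(voxel_to_world(img.affine, labeled.astype(float)))
        for _ in range(100):
            p = rng.uniform(0, 38, size=3)
            got = label_with_atlas(p, img, labels, near_radius_mm=5.0)
            vox = np.round(world_to_voxel(img.affine, p)).astype(int)
            snapped = np.atleast_1d(voxel_to_world(img.affine, vox.astype(float)))
            if img.data[tuple(vox)] != 0:
                assert got == labels[img.data[tuple(vox)]]
                continue
            dists = np.linalg.norm(lworld - snapped, axis=1)
            if dists.min() <= 5.0:
                expect = labels[img.data[tuple(labeled[np.argmin(dists)])]]
                assert got == f"near:{expect}"
            else:
                assert got == "none"


def test_reference_set_loads_names_and_shapes():
    refs = load_reference_set()
    assert {"P3", "IPL", "F3", "BA9", "BA46", "5cm", "BA8/9"} <= set(refs)
    assert all(v.shape == (3,) for v in refs.values())
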