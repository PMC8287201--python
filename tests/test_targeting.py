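from collections import deque

import numpy as np
import pytest

from netarget.image_model import BinaryMask, GridImage, voxel_to_world
from netarget.targeting import (
    NoValidTargetError,
    TargetCandidate,
    TargetingConfig,
    cluster_map,
    extract_target,
    local_maxima,
    scalp_cortex_distance,
    select_target,
)


def flood_fill_clusters(supra: np.ndarray, connectivity: int):
    """Brute-force BFS connected components oracle."""
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = sum(v != 0 for v in (di, dj, dk))
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((di, dj, dk))
    seen = np.zeros(supra.shape, dtype=bool)
    clusters = []
    for idx in np.argwhere(supra):
        idx = tuple(idx)
        if seen[idx]:
            continue
        comp = []
        queue = deque([idx])
        seen[idx] = True
        while queue:
            cur = queue.popleft()
            comp.append(cur)
            for off in offsets:
                nb = tuple(np.add(cur, off))
                if all(0 <= nb[d] < supra.shape[d] for d in range(3)):
                    if supra[nb] and not seen[nb]:
                        seen[nb] = True
                        queue.append(nb)
        clusters.append(frozenset(comp))
    return set(clusters)


def gaussian_blob(shape, affine, center_mm, sigma_mm, amp=10.0):
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    world = np.atleast_2d(voxel_to_world(affine, vox))
    d2 = np.sum((world - np.asarray(center_mm)) ** 2, axis=1)
    return (amp * np.exp(-d2 / (2 * sigma_mm**2))).reshape(shape)


class TestClusterMap:
    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        data = rng.normal(size=(12, 12, 12))
        zmap = GridImage(data, np.eye(4))
        config = TargetingConfig(z_threshold=1.0, connectivity=connectivity)
        clusters = cluster_map(zmap, config)
        ours = {frozenset(map(tuple, c.voxels)) for c in clusters}
        oracle = flood_fill_clusters(data > 1.0, connectivity)
        assert ours == oracle

    def test_two_distant_blobs_give_two_clusters(self):
        affine = np.diag([4.0, 4.0, 4.0, 1.0])
        data = gaussian_blob((20, 20, 20), affine, (20, 20, 20), 6.0) + gaussian_blob(
            (20, 20, 20), affine, (60, 20, 20), 6.0
        )
        clusters = cluster_map(GridImage(data, affine), TargetingConfig(z_threshold=3.0))
        assert len(clusters) == 2
        oracle = flood_fill_clusters(data > 3.0, 26)
        assert {frozenset(map(tuple, c.voxels)) for c in clusters} == oracle

    def test_subthreshold_map_gives_empty_list(self):
        zmap = GridImage(np.zeros((5, 5, 5)), np.eye(4))
        assert cluster_map(zmap, TargetingConfig(z_threshold=3.0)) == []

    def test_diagonal_touch_depends_on_connectivity(self):
        data = np.zeros((4, 4, 4))
        data[1, 1, 1] = 5.0
        data[2, 2, 2] = 5.0
        zmap = GridImage(data, np.eye(4))
        assert len(cluster_map(zmap, TargetingConfig(connectivity=26))) == 1
        assert len(cluster_map(zmap, TargetingConfig(connectivity=6))) == 2

    def test_clusters_partition_suprathreshold_set(self, rng):
        data = rng.normal(size=(10, 10, 10))
        zmap = GridImage(data, np.eye(4))
        clusters = cluster_map(zmap, TargetingConfig(z_threshold=0.5))
        all_vox = [tuple(v) for c in clusters for v in c.voxels]
        assert len(all_vox) == len(set(all_vox))
        assert len(all_vox) == int((data > 0.5).sum())
        for c in clusters:
            assert c.size == len(c.voxels)

    def test_threshold_monotonicity(self, rng):
        data = rng.normal(size=(10, 10, 10))
        zmap = GridImage(data, np.eye(4))
        counts = [
            sum(c.size for c in cluster_map(zmap, TargetingConfig(z_threshold=t)))
            for t in (0.5, 1.0, 1.5, 2.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_search_region_box_restricts_clusters(self):
        affine = np.diag([4.0, 4.0, 4.0, 1.0])
        data = gaussian_blob((20, 20, 20), affine, (20, 20, 20), 6.0) + gaussian_blob(
            (20, 20, 20), affine, (60, 20, 20), 6.0
        )
        config = TargetingConfig(
            z_threshold=3.0, search_region=((0, 0, 0), (40, 76, 76))
        )
        clusters = cluster_map(GridImage(data, affine), config)
        assert len(clusters) == 1
        assert tuple(clusters[0].peak.world_mm) == (20.0, 20.0, 20.0)


class TestLocalMaxima:
    def test_single_blob_single_peak(self):
        affine = np.diag([4.0, 4.0, 4.0, 1.0])
        data = gaussian_blob((16, 16, 16), affine, (28, 28, 28), 8.0)
        zmap = GridImage(data, affine)
        clusters = cluster_map(zmap, TargetingConfig(z_threshold=1.0))
        peaks = local_maxima(zmap, clusters[0], 8.0)
        assert len(peaks) == 1
        assert tuple(peaks[0].world_mm) == (28.0, 28.0, 28.0)

    def test_two_separated_gaussians_two_peaks(self):
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        data = gaussian_blob((32, 16, 16), affine, (10, 14, 14), 5.0) + gaussian_blob(
            (32, 16, 16), affine, (40, 14, 14), 5.0
        )
        zmap = GridImage(data, affine)
        clusters = cluster_map(zmap, TargetingConfig(z_threshold=0.5))
        peaks = [p for c in clusters for p in local_maxima(zmap, c, 8.0)]
        assert len(peaks) == 2

    def test_plateau_tie_breaks_to_lexicographic_minimum(self):
        data = np.zeros((6, 6, 6))
        data[2:4, 2:4, 2:4] = 5.0  # flat plateau of equal maxima
        zmap = GridImage(data, np.eye(4))
        clusters = cluster_map(zmap, TargetingConfig(z_threshold=1.0))
        peaks = local_maxima(zmap, clusters[0], 8.0)
        assert len(peaks) == 1
        assert peaks[0].voxel == (2, 2, 2)

    def test_every_peak_is_suprathreshold_neighborhood_max(self, rng):
        data = rng.normal(size=(12, 12, 12))
        zmap = GridImage(data, np.eye(4))
        config = TargetingConfig(z_threshold=0.1)
        for cluster in cluster_map(zmap, config):
            for peak in local_maxima(zmap, cluster, 0.0):
                i, j, k = peak.voxel
                assert data[i, j, k] > 0.1
                nb = data[max(i-1, 0):i+2, max(j-1, 0):j+2, max(k-1, 0):k+2]
                assert data[i, j, k] >= nb.max()


def spherical_head(radius_mm, voxel_mm=2.0):
    n = int(2 * radius_mm / voxel_mm) + 5
    affine = np.diag([voxel_mm] * 3 + [1.0])
    affine[:3, 3] = -(n - 1) / 2 * voxel_mm
    ii, jj, kk = np.meshgrid(*(np.arange(n),) * 3, indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    world = np.atleast_2d(voxel_to_world(affine, vox))
    mask = (np.linalg.norm(world, axis=1) <= radius_mm).reshape((n, n, n))
    return BinaryMask(mask.astype(np.uint8), affine)


class TestScalpDistance:
    def test_sphere_analytic_case(self):
        head = spherical_head(80.0, voxel_mm=4.0)
        d = scalp_cortex_distance((60.0, 0.0, 0.0), head)
        assert d == pytest.approx(20.0, abs=4.0 * np.sqrt(3))

    def test_boundary_point_is_near_zero(self):
        head = spherical_head(40.0, voxel_mm=2.0)
        # take an actual surface voxel centre on the +x axis
        xs = np.argwhere(head.bool_data)
        world = np.atleast_2d(voxel_to_world(head.affine, xs.astype(float)))
        surface_point = world[np.argmax(world[:, 0])]
        assert scalp_cortex_distance(surface_point, head) <= np.sqrt(3) * 2.0 / 2 + 1e-9

    def test_matches_exhaustive_boundary_scan(self, noisy_bundle):
        from scipy import ndimage

        head = noisy_bundle.head_mask
        inner = ndimage.binary_erosion(
            head.bool_data, ndimage.generate_binary_structure(3, 1), border_value=0
        )
        boundary = np.argwhere(head.bool_data & ~inner)
        bworld = np.atleast_2d(voxel_to_world(head.affine, boundary.astype(float)))
        for point in [(-30.0, -38.0, 22.0), (0.0, 0.0, 0.0), (-46.0, 0.0, 20.0)]:
            oracle = np.min(np.linalg.norm(bworld - np.asarray(point), axis=1))
            assert scalp_cortex_distance(point, head) == pytest.approx(oracle)

    def test_point_outside_head_rejected(self, noisy_bundle):
        with pytest.raises(ValueError, match="outside"):
            scalp_cortex_distance((200.0, 0.0, 0.0), noisy_bundle.head_mask)


def make_candidate(zmap, voxel):
    return TargetCandidate(
        voxel=voxel,
        world_mm=np.asarray(voxel_to_world(zmap.affine, np.asarray(voxel, float))),
        z_value=float(zmap.data[voxel]),
        cluster_id=1,
    )


class TestSelection:
    def test_shared_peak_rejected_specific_peak_chosen(self, noiseless_bundle):
        bundle = noiseless_bundle
        own = bundle.truth_maps["DMN"]
        own = GridImage(own.data / own.data.max() * 10.0, own.affine)
        other = bundle.truth_maps["FPN"]
        other = GridImage(other.data / other.data.max() * 10.0, other.affine)
        shared = bundle.truth_node("DMN", "shared_junction")
        specific = bundle.truth_node("DMN", "l_ipl")
        candidates = [
            make_candidate(own, shared.peak_voxel),
            make_candidate(own, specific.peak_voxel),
        ]
        sel = select_target(candidates, other, bundle.gm_mask, bundle.head_mask,
                            TargetingConfig(z_threshold=3.0), label="DMN")
        assert sel.chosen.voxel == specific.peak_voxel
        rejected = {c.voxel: c.rejected_by for c in sel.rejected}
        assert rejected[shared.peak_voxel] == "criterion_i_network_specificity"

    def test_candidate_outside_gray_matter_rejected(self, noiseless_bundle):
        bundle = noiseless_bundle
        own = bundle.truth_maps["DMN"]
        from netarget.image_model import world_to_voxel

        # head centre: inside the head but far below the gm shell
        deep_voxel = tuple(
            np.round(world_to_voxel(own.affine, np.zeros(3))).astype(int)
        )
        candidates = [
            make_candidate(own, deep_voxel),
            make_candidate(own, bundle.truth_node("DMN", "l_ipl").peak_voxel),
        ]
        sel = select_target(candidates, None, bundle.gm_mask, bundle.head_mask,
                            TargetingConfig())
        rejected = {c.voxel: c.rejected_by for c in sel.rejected}
        assert rejected[deep_voxel] == "criterion_ii_gray_matter"

    def test_shallower_of_two_survivors_wins(self, noiseless_bundle):
        bundle = noiseless_bundle
        own = bundle.truth_maps["DMN"]
        shallow = bundle.truth_node("DMN", "l_ipl").peak_voxel     # ~9 mm deep
        deep = bundle.truth_node("DMN", "precuneus").peak_voxel    # ~20 mm deep
        sel = select_target(
            [make_candidate(own, deep), make_candidate(own, shallow)],
            None, bundle.gm_mask, bundle.head_mask, TargetingConfig(),
        )
        assert sel.chosen.voxel == shallow
        assert sel.chosen.scalp_distance_mm < 15.0

    def test_all_rejected_raises_with_reasons(self, noiseless_bundle):
        bundle = noiseless_bundle
        own = bundle.truth_maps["DMN"]
        shared = bundle.truth_node("DMN", "shared_junction")
        other = GridImage(
            np.full(own.shape, 100.0), own.affine
        )  # everything falls in the other network
        with pytest.raises(NoValidTargetError) as err:
            select_target([make_candidate(own, shared.peak_voxel)], other,
                          bundle.gm_mask, bundle.head_mask, TargetingConfig())
        assert "criterion_i" in str(err.value)


class TestEndToEnd:
    def test_extract_target_on_truth_maps(self, noiseless_bundle):
        bundle = noiseless_bundle
        scale = 10.0 / bundle.truth_maps["DMN"].data.max()
        own = GridImage(bundle.truth_maps["DMN"].data * scale,
                        bundle.truth_maps["DMN"].affine)
        other = GridImage(bundle.truth_maps["FPN"].data * scale,
                          bundle.truth_maps["FPN"].affine)
        sel = extract_target(own, other, bundle.gm_mask, bundle.head_mask,
                             TargetingConfig(), label="DMN")
        expected = bundle.truth_node("DMN", "l_ipl").peak_mm
        assert np.linalg.norm(sel.chosen.world_mm - expected) <= 8.0
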