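"""Cluster decomposition, local maxima, and the three target-selection rules.

A selected network z-map is thresholded and decomposed into connected
clusters; each cluster's local maxima are candidate stimulation
coordinates. A final target must

(i)   be specific to its network — candidates also suprathreshold in the
      other network's map are excluded;
(ii)  lie in gray matter (gyral crown rather than sulcal depth);
(iii) minimize the scalp-to-cortex distance among the survivors, since
      stimulation efficacy falls off steeply with coil-to-target depth.

All tie-breaks are deterministic: z descending, then lexicographic voxel
index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .image_model import (
    BinaryMask,
    GridImage,
    value_at_world,
    voxel_to_world,
    world_to_voxel,
)


class NoValidTargetError(RuntimeError):
    """Every candidate was rejected; reasons are carried on the exception."""

    def __init__(self, reasons: dict):
        self.reasons = reasons
        lines = "; ".join(f"{k}: {v}" for k, v in reasons.items())
        super().__init__(f"no candidate satisfied the selection criteria ({lines})")


@dataclass
class TargetingConfig:
    z_threshold: float = 3.0
    connectivity: int = 26          # 6 | 18 | 26
    min_peak_separation_mm: float = 8.0
    other_network_threshold: float | None = None  # defaults to z_threshold
    other_network_radius_mm: float = 0.0  # 0: evaluate at the voxel itself
    gm_rule: str = "mask"           # mask | probability
    gm_probability: float = 0.5
    search_region: object = None    # optional BinaryMask or world-mm box

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    @property
    def other_threshold(self) -> float:
        return (
            self.z_threshold
            if self.other_network_threshold is None
            else self.other_network_threshold
        )


@dataclass
class TargetCandidate:
    voxel: tuple[int, int, int]
    world_mm: np.ndarray
    z_value: float
    cluster_id: int
    in_other_network: bool | None = None
    in_gm: bool | None = None
    scalp_distance_mm: float | None = None
    rejected_by: str | None = None


@dataclass
class Cluster:
    id: int
    voxels: np.ndarray            # (n, 3) integer indices
    size: int
    peak: TargetCandidate


@dataclass
class TargetSelection:
    label: str
    chosen: TargetCandidate
    rejected: list[TargetCandidate]
    config: TargetingConfig


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _region_mask(zmap: GridImage, region) -> np.ndarray | None:
    if region is None:
        return None
    if isinstance(region, BinaryMask):
        if not zmap.same_grid(region):
            raise ValueError("search region must share the z-map grid")
        return region.bool_data
    lo, hi = np.asarray(region[0], float), np.asarray(region[1], float)
    ii, jj, kk = np.meshgrid(
        *(np.arange(s) for s in zmap.shape), indexing="ij"
    )
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    world = np.atleast_2d(voxel_to_world(zmap.affine, vox))
    inside = np.all((world >= lo) & (world <= hi), axis=1)
    return inside.reshape(zmap.shape)


def cluster_map(zmap: GridImage, config: TargetingConfig | None = None) -> list[Cluster]:
    """Connected components of {z > threshold}, largest first.

    An optional search region (box in world mm or mask) restricts the
    suprathreshold set before decomposition — the reproducible stand-in for
    picking "the cluster in the region of interest" by eye.
    """
    config = config or TargetingConfig()
    supra = zmap.data > config.z_threshold
    region = _region_mask(zmap, config.search_region)
    if region is not None:
        supra &= region
    labels, n = ndimage.label(supra, structure=_STRUCTURES[config.connectivity])
    clusters: list[Cluster] = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        vals = zmap.data[tuple(vox.T)]
        best = np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0], -vals))[0]
        pv = tuple(int(v) for v in vox[best])
        peak = TargetCandidate(
            voxel=pv,
            world_mm=np.asarray(voxel_to_world(zmap.affine, np.asarray(pv, float))),
            z_value=float(zmap.data[pv]),
            cluster_id=lab,
        )
        clusters.append(Cluster(id=lab, voxels=vox, size=len(vox), peak=peak))
    clusters.sort(key=lambda c: (-c.size, c.id))
    return clusters


def local_maxima(
    zmap: GridImage, cluster: Cluster, min_separation_mm: float = 8.0
) -> list[TargetCandidate]:
    """26-neighborhood maxima of a cluster, greedily separated in mm.

    A voxel qualifies when its value is >= all 26 neighbors; qualifying
    voxels are visited by descending z (ties: lexicographic index) and kept
    only if at least ``min_separation_mm`` from every already-kept peak —
    so exactly one peak survives per flat plateau.
    """
    if cluster.size == 0:
        raise ValueError("cluster is empty")
    data = zmap.data
    maxfilt = ndimage.maximum_filter(
        data, footprint=np.ones((3, 3, 3)), mode="constant", cval=-np.inf
    )
    is_max = data >= maxfilt
    vox = cluster.voxels[is_max[tuple(cluster.voxels.T)]]
    vals = data[tuple(vox.T)]
    order = np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0], -vals))
    kept: list[TargetCandidate] = []
    kept_world: list[np.ndarray] = []
    for idx in order:
        world = np.asarray(voxel_to_world(zmap.affine, vox[idx].astype(float)))
        if kept_world and np.min(
            np.linalg.norm(np.asarray(kept_world) - world, axis=1)
        ) < min_separation_mm:
            continue
        kept.append(
            TargetCandidate(
                voxel=tuple(int(v) for v in vox[idx]),
                world_mm=world,
                z_value=float(vals[idx]),
                cluster_id=cluster.id,
            )
        )
        kept_world.append(world)
    return kept


def scalp_cortex_distance(point_mm, head_mask: BinaryMask) -> float:
    """Euclidean distance (mm) from a point to the outer scalp surface.

    The surface is the set of head voxels with a 6-neighbor outside the
    head; the "shortest perpendicular path" is operationalized as the
    distance to the nearest surface voxel centre (the foot of the
    perpendicular onto a locally planar scalp).
    """
    point_mm = np.asarray(point_mm, dtype=float)
    vox = np.round(world_to_voxel(head_mask.affine, point_mm)).astype(int)
    if (
        np.any(vox < 0)
        or np.any(vox >= np.asarray(head_mask.shape))
        or head_mask.data[tuple(vox)] == 0
    ):
        raise ValueError(f"point {tuple(point_mm)} lies outside the head mask")
    inner = ndimage.binary_erosion(
        head_mask.bool_data, structure=_STRUCTURES[6], border_value=0
    )
    boundary = np.argwhere(head_mask.bool_data & ~inner)
    bworld = np.atleast_2d(voxel_to_world(head_mask.affine, boundary.astype(float)))
    dist, _ = cKDTree(bworld).query(point_mm)
    return float(dist)


def _neighborhood_max(image: GridImage, point_mm, radius_mm: float) -> float:
    """Maximum image value over voxel centres within radius of a point."""
    point = np.asarray(point_mm, dtype=float)
    center = world_to_voxel(image.affine, point)
    vox_mm = np.linalg.norm(image.affine[:3, :3], axis=0)
    half = np.ceil(radius_mm / vox_mm).astype(int)
    lo = np.maximum(np.round(center).astype(int) - half, 0)
    hi = np.minimum(np.round(center).astype(int) + half + 1, image.shape)
    if np.any(lo >= hi):
        return -np.inf
    ranges = [np.arange(l, h) for l, h in zip(lo, hi)]
    ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    world = np.atleast_2d(voxel_to_world(image.affine, vox))
    inside = np.linalg.norm(world - point, axis=1) <= max(radius_mm, 1e-9)
    if not inside.any():
        return float(value_at_world(image, point, "nearest"))
    vals = image.data[tuple(vox[inside].astype(int).T)]
    return float(np.max(vals))


def audit_candidate(
    candidate: TargetCandidate,
    other_map: GridImage | None,
    gm_mask: BinaryMask,
    head_mask: BinaryMask,
    config: TargetingConfig,
) -> TargetCandidate:
    """Fill the per-criterion audit fields on a candidate (in place).

    Network-specificity (criterion i) asks whether the candidate falls
    within the other network's spatial map: by default the other map is
    evaluated at the candidate's voxel; a positive
    ``other_network_radius_mm`` instead takes the maximum over voxel
    centres within that radius (a tolerance for coarse grids).
    """
    if other_map is not None:
        if config.other_network_radius_mm > 0:
            other_val = _neighborhood_max(
                other_map, candidate.world_mm, config.other_network_radius_mm
            )
        else:
            other_val = value_at_world(other_map, candidate.world_mm, "nearest")
        candidate.in_other_network = bool(other_val > config.other_threshold)
    else:
        candidate.in_other_network = False
    gm_val = value_at_world(gm_mask, candidate.world_mm, "nearest")
    if config.gm_rule == "probability":
        candidate.in_gm = bool(gm_val >= config.gm_probability)
    else:
        candidate.in_gm = bool(gm_val >= 1)
    try:
        candidate.scalp_distance_mm = scalp_cortex_distance(
            candidate.world_mm, head_mask
        )
    except ValueError:
        candidate.scalp_distance_mm = np.inf
    return candidate


def select_target(
    candidates: list[TargetCandidate],
    other_map: GridImage | None,
    gm_mask: BinaryMask,
    head_mask: BinaryMask,
    config: TargetingConfig | None = None,
    label: str = "generic",
) -> TargetSelection:
    """Apply the three criteria and return the selected target with audit."""
    if not candidates:
        raise ValueError("candidates must be non-empty")
    config = config or TargetingConfig()
    survivors: list[TargetCandidate] = []
    rejected: list[TargetCandidate] = []
    for cand in candidates:
        audit_candidate(cand, other_map, gm_mask, head_mask, config)
        if cand.in_other_network:
            cand.rejected_by = "criterion_i_network_specificity"
            rejected.append(cand)
        elif not cand.in_gm:
            cand.rejected_by = "criterion_ii_gray_matter"
            rejected.append(cand)
        elif not np.isfinite(cand.scalp_distance_mm):
            cand.rejected_by = "outside_head"
            rejected.append(cand)
        else:
            survivors.append(cand)
    if not survivors:
        reasons = {
            f"candidate@{tuple(np.round(c.world_mm, 1))}": c.rejected_by
            for c in rejected
        }
        raise NoValidTargetError(reasons)
    survivors.sort(
        key=lambda c: (c.scalp_distance_mm, -c.z_value, c.voxel)
    )
    chosen = survivors[0]
    rejected.extend(survivors[1:])
    for c in survivors[1:]:
        c.rejected_by = "criterion_iii_deeper_than_chosen"
    return TargetSelection(label=label, chosen=chosen, rejected=rejected,
                           config=config)


def extract_target(
    zmap: GridImage,
    other_map: GridImage | None,
    gm_mask: BinaryMask,
    head_mask: BinaryMask,
    config: TargetingConfig | None = None,
    label: str = "generic",
) -> TargetSelection:
    """cluster -> local maxima -> criteria, end to end for one network."""
    config = config or TargetingConfig()
    clusters = cluster_map(zmap, config)
    if not clusters:
        raise NoValidTargetError({"clusters": "no suprathreshold voxels"})
    candidates: list[TargetCandidate] = []
    for cluster in clusters:
        candidates.extend(
            local_maxima(zmap, cluster, config.min_peak_separation_mm)
        )
    return select_target(candidates, other_map, gm_mask, head_mask, config, label)
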