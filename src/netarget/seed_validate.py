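"""Seed-based connectivity validation of selected targets.

A spherical ROI around a candidate coordinate defines a seed signal (the
unweighted mean time series over the ROI, or optionally its first
eigenvariate); the whole-brain Pearson correlation map of that signal is
then matched against the individual ICA network maps with the same
goodness-of-fit score used for template matching. A well-placed target's
seed map should match its own network's map best.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .image_model import BinaryMask, BoldSeries, GridImage, world_to_voxel, voxel_to_world
from .network_ica import NetworkTemplate, goodness_of_fit


@dataclass
class SeedRoi:
    center_mm: np.ndarray
    radius_mm: float
    mask: BinaryMask
    truncated: bool = False


@dataclass
class SeedMap:
    correlation: GridImage
    center_mm: np.ndarray
    radius_mm: float


@dataclass
class SeedMatch:
    best_label: str | None
    scores: dict[str, float]
    ambiguous: bool


def spherical_roi(center_mm, radius_mm: float, grid) -> SeedRoi:
    """Voxels whose centres lie within ``radius_mm`` of the centre point.

    The centre voxel is always included (so radius 0 yields exactly one
    voxel). A sphere clipped by the field of view yields a warning and the
    non-empty remainder.
    """
    center = np.asarray(center_mm, dtype=float)
    shape = grid.shape3d if isinstance(grid, BoldSeries) else grid.shape
    affine = grid.affine
    cvox = world_to_voxel(affine, center)
    if np.any(np.round(cvox) < 0) or np.any(np.round(cvox) >= np.asarray(shape)):
        raise ValueError(f"seed centre {tuple(center)} outside the field of view")

    vox_mm = np.linalg.norm(affine[:3, :3], axis=0)
    halfwidth = np.ceil(radius_mm / vox_mm).astype(int) + 1
    lo = np.maximum(np.round(cvox).astype(int) - halfwidth, 0)
    hi = np.minimum(np.round(cvox).astype(int) + halfwidth + 1, shape)
    mask = np.zeros(shape, dtype=np.uint8)
    ranges = [np.arange(l, h) for l, h in zip(lo, hi)]
    ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    world = np.atleast_2d(voxel_to_world(affine, vox))
    inside = np.linalg.norm(world - center, axis=1) <= radius_mm
    mask[tuple(vox[inside].astype(int).T)] = 1
    mask[tuple(np.round(cvox).astype(int))] = 1

    # truncated when the sphere extends past the grid of voxel centres
    margin = np.min(
        np.minimum(cvox * vox_mm, (np.asarray(shape) - 1 - cvox) * vox_mm)
    )
    truncated = bool(radius_mm > 0 and margin < radius_mm)
    if truncated:
        warnings.warn("seed sphere truncated by the field of view", UserWarning)
    return SeedRoi(center, float(radius_mm), BinaryMask(mask, affine, grid.space_tag),
                   truncated=truncated)


def seed_correlation_map(
    series: BoldSeries, roi: SeedRoi, signal: str = "mean"
) -> SeedMap:
    """Voxelwise Pearson correlation with the ROI's seed signal.

    Zero-variance voxels map to correlation 0 (not NaN) so downstream
    template matching is defined everywhere. The seed signal itself must
    have positive variance.
    """
    if series.n_frames < 3:
        raise ValueError("need at least 3 frames for a correlation map")
    if not np.allclose(series.affine, roi.mask.affine, atol=1e-6):
        raise ValueError("ROI must live on the series grid")
    data = series.data.astype(float)
    roi_ts = data[roi.mask.bool_data]
    if roi_ts.size == 0:
        raise ValueError("empty ROI")
    if signal == "mean":
        seed = roi_ts.mean(axis=0)
    elif signal == "eigenvariate":
        centered = roi_ts - roi_ts.mean(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        seed = vt[0]
        if np.corrcoef(seed, roi_ts.mean(axis=0))[0, 1] < 0:
            seed = -seed
    else:
        raise ValueError(f"unknown seed signal {signal!r}")
    seed = seed - seed.mean()
    seed_sd = seed.std()
    if seed_sd == 0:
        raise ValueError("seed signal has zero variance")

    flat = data.reshape(-1, series.n_frames)
    centered = flat - flat.mean(axis=1, keepdims=True)
    sds = centered.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (centered @ seed) / (series.n_frames * sds * seed_sd)
    corr[sds == 0] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    return SeedMap(
        correlation=GridImage(
            corr.reshape(series.shape3d), series.affine.copy(), series.space_tag
        ),
        center_mm=roi.center_mm,
        radius_mm=roi.radius_mm,
    )


def match_map_to_networks(
    seed_map: SeedMap,
    candidates: list[NetworkTemplate],
    analysis_mask: BinaryMask | None = None,
) -> SeedMatch:
    """Which network map does the seed map resemble most?

    Each candidate map is binarized at its threshold and scored with the
    same inside-minus-outside goodness of fit used for component
    classification. Exact score ties are flagged ambiguous.
    """
    if not candidates:
        raise ValueError("candidate maps must be non-empty")
    scores = {
        t.label: goodness_of_fit(seed_map.correlation, t, analysis_mask)
        for t in candidates
    }
    ordered = sorted(scores.items(), key=lambda kv: -kv[1])
    ambiguous = len(ordered) > 1 and ordered[0][1] == ordered[1][1]
    return SeedMatch(
        best_label=None if ambiguous else ordered[0][0],
        scores=scores,
        ambiguous=ambiguous,
    )
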