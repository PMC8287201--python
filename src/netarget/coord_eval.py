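"""Distance analyses, exact Wilcoxon focality tests, sensitivity/selectivity,
Talairach<->MNI transforms, atlas labeling, and a trilateration oracle.

The statistics here mirror how individualized stimulation coordinates are
compared against group-level coordinates from the literature: all pairwise
Euclidean distances summarize inter-subject spread; a one-sample Wilcoxon
signed-rank test (exact, one-sided "greater" by default) asks whether the
distance from a group coordinate exceeds an assumed stimulation focality
(conservative 12 mm, lenient 20 mm); sensitivity/selectivity quantify how
often a group coordinate falls inside the expected individual network map
and only there. Trilateration recovers an unprinted reference coordinate
from per-subject (coordinate, distance) pairs and doubles as a consistency
oracle for published distance tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy import ndimage, stats

from .image_model import GridImage, value_at_world, world_to_voxel


class ConditioningError(ValueError):
    """Geometry too degenerate (coplanar / ill-conditioned) to solve."""


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def euclidean_distance(a_mm, b_mm, space_a: str = "other", space_b: str = "other") -> float:
    a = np.asarray(a_mm, dtype=float)
    b = np.asarray(b_mm, dtype=float)
    if a.shape != (3,) or b.shape != (3,):
        raise ValueError("coordinates must be 3-vectors")
    if space_a != space_b and "other" not in (space_a, space_b):
        raise ValueError(f"space mismatch: {space_a!r} vs {space_b!r}")
    return float(np.linalg.norm(a - b))


@dataclass
class PairwiseSummary:
    median: float
    q1: float
    q3: float
    distances: np.ndarray


def pairwise_distance_summary(coordinates) -> PairwiseSummary:
    """All C(n,2) pairwise distances with linear-interpolation quartiles."""
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2 or coords.shape[1] != 3:
        raise ValueError("need at least two 3D coordinates")
    from scipy.spatial.distance import pdist

    d = pdist(coords)
    return PairwiseSummary(
        median=float(np.median(d)),
        q1=float(np.percentile(d, 25)),
        q3=float(np.percentile(d, 75)),
        distances=d,
    )


# ---------------------------------------------------------------------------
# Exact one-sample Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

@dataclass
class WilcoxonResult:
    n: int
    statistic: float        # W+ = sum of ranks of positive differences
    p_value: float
    alternative: str
    mu: float
    exact: bool


def wilcoxon_one_sample(
    values,
    mu: float = 0.0,
    alternative: str = "greater",
    exact_limit: int = 25,
) -> WilcoxonResult:
    """One-sample Wilcoxon signed-rank test against ``mu``.

    Zero differences are dropped; tied absolute differences receive average
    ranks. For n <= ``exact_limit`` the p-value is exact, computed from the
    full null distribution of W+ conditional on the observed |differences|
    (equivalent to enumerating all 2^n sign assignments, implemented as a
    subset-sum count over doubled ranks so ties cost nothing extra). Larger
    n uses the normal approximation with tie-corrected variance and
    continuity correction.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = np.asarray(values, dtype=float) - mu
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_limit:
        p_greater, p_less = _exact_tail_probs(ranks, w_plus)
        exact = True
    else:
        mean = n * (n + 1) / 4.0
        # variance with tie correction: sum(r^2)/4
        var = float(np.sum(ranks**2)) / 4.0
        sd = np.sqrt(var)
        p_greater = float(stats.norm.sf((w_plus - 0.5 - mean) / sd))
        p_less = float(stats.norm.cdf((w_plus + 0.5 - mean) / sd))
        exact = False

    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return WilcoxonResult(n=n, statistic=w_plus, p_value=float(min(p, 1.0)),
                          alternative=alternative, mu=mu, exact=exact)


def _exact_tail_probs(ranks: np.ndarray, w_plus: float) -> tuple[float, float]:
    """P(W+ >= w) and P(W+ <= w) under the exact conditional null."""
    r2 = np.round(2 * ranks).astype(int)  # doubled ranks are integers
    total = r2.sum()
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= 2.0 ** len(r2)
    w2 = int(round(2 * w_plus))
    return float(counts[w2:].sum()), float(counts[: w2 + 1].sum())


# ---------------------------------------------------------------------------
# Sensitivity / selectivity
# ---------------------------------------------------------------------------

@dataclass
class SensSpecResult:
    reference: str
    sensitivity: float
    selectivity: float | None   # None when sensitivity == 0
    n_contained: int
    n_subjects: int
    n_excluded: int = 0


def sensitivity_selectivity(
    reference_mm,
    expected_maps: list[GridImage],
    other_maps: list[GridImage],
    threshold: float,
    reference_name: str = "reference",
    transforms: list[np.ndarray] | None = None,
) -> SensSpecResult:
    """Containment of a group-level coordinate in individual network maps.

    sensitivity = fraction of subjects whose expected-network map contains
    the coordinate (map value at its voxel > threshold); selectivity =
    among contained subjects, the fraction NOT also inside the other
    network's map. Subjects whose field of view excludes the coordinate are
    dropped from the denominators and counted in ``n_excluded``. A per-
    subject 4x4 ``transform`` maps the reference into that subject's world
    frame.
    """
    if len(expected_maps) != len(other_maps):
        raise ValueError("expected_maps and other_maps must pair up")
    ref = np.asarray(reference_mm, dtype=float)
    contained = 0
    exclusive = 0
    excluded = 0
    for i, (exp_map, oth_map) in enumerate(zip(expected_maps, other_maps)):
        point = ref
        if transforms is not None and transforms[i] is not None:
            mat = np.asarray(transforms[i], float)
            point = mat[:3, :3] @ ref + mat[:3, 3]
        vox = np.round(world_to_voxel(exp_map.affine, point)).astype(int)
        if np.any(vox < 0) or np.any(vox >= np.asarray(exp_map.shape)):
            excluded += 1
            continue
        in_expected = exp_map.data[tuple(vox)] > threshold
        in_other = value_at_world(oth_map, point, "nearest") > threshold
        if in_expected:
            contained += 1
            if not in_other:
                exclusive += 1
    n = len(expected_maps) - excluded
    if n == 0:
        raise ValueError("reference outside every subject's field of view")
    sens = contained / n
    sel = (exclusive / contained) if contained else None
    return SensSpecResult(
        reference=reference_name,
        sensitivity=sens,
        selectivity=sel,
        n_contained=contained,
        n_subjects=n,
        n_excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Talairach <-> MNI
# ---------------------------------------------------------------------------

def _load_packaged_yaml(name: str) -> dict:
    with resources.files("netarget.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


_TRANSFORMS_CACHE: dict | None = None


def _transforms() -> dict:
    global _TRANSFORMS_CACHE
    if _TRANSFORMS_CACHE is None:
        _TRANSFORMS_CACHE = _load_packaged_yaml("transforms.yaml")
    return _TRANSFORMS_CACHE


def talairach_mni(
    coordinate,
    direction: str = "tal2mni",
    convention: str = "brett",
) -> np.ndarray:
    """Map a coordinate between Talairach and MNI space.

    ``lancaster_spm`` / ``lancaster_fsl``: a single affine (and its exact
    inverse). ``brett``: the classical piecewise affine, branching on the
    sign of the MNI z coordinate; its inverse selects the branch whose
    back-projected MNI z sign is consistent.
    """
    p = np.asarray(coordinate, dtype=float)
    if p.shape != (3,):
        raise ValueError("coordinate must be a 3-vector")
    if direction not in ("mni2tal", "tal2mni"):
        raise ValueError(f"unknown direction {direction!r}")
    cfg = _transforms()
    if convention in ("lancaster_spm", "lancaster_fsl"):
        mat = np.asarray(cfg[convention]["mni_to_tal"], dtype=float)
        if direction == "mni2tal":
            return mat[:3, :3] @ p + mat[:3, 3]
        return np.linalg.solve(mat, np.r_[p, 1.0])[:3]
    if convention == "brett":
        pos = np.asarray(cfg["brett"]["mni_to_tal_zpos"], dtype=float)
        neg = np.asarray(cfg["brett"]["mni_to_tal_zneg"], dtype=float)
        if direction == "mni2tal":
            return (pos if p[2] >= 0 else neg) @ p
        sol_pos = np.linalg.solve(pos, p)
        if sol_pos[2] >= 0:
            return sol_pos
        return np.linalg.solve(neg, p)
    raise ValueError(f"unknown convention {convention!r}")


# ---------------------------------------------------------------------------
# Trilateration
# ---------------------------------------------------------------------------

@dataclass
class TrilaterationResult:
    reference_mm: np.ndarray
    rms_residual: float
    residuals: np.ndarray


def trilaterate_reference(coordinates, distances) -> TrilaterationResult:
    """Least-squares recovery of x from |x - c_i| = d_i.

    Linearized by differencing the squared equations, then polished by
    Gauss-Newton. Requires >= 4 non-coplanar coordinates; near-coplanar
    geometry raises :class:`ConditioningError`.
    """
    C = np.asarray(coordinates, dtype=float)
    d = np.asarray(distances, dtype=float)
    if C.ndim != 2 or C.shape[1] != 3 or C.shape[0] < 4:
        raise ValueError("need at least four 3D coordinates")
    if len(d) != len(C):
        raise ValueError("one distance per coordinate required")
    A = 2.0 * (C[1:] - C[0])
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[-1] < 1e-8 * sv[0] or sv[-1] == 0:
        raise ConditioningError("coordinates are (nearly) coplanar")
    b = (d[0] ** 2 - d[1:] ** 2) + (np.sum(C[1:] ** 2, axis=1) - np.sum(C[0] ** 2))
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    for _ in range(50):
        diff = x - C
        r = np.linalg.norm(diff, axis=1)
        r[r == 0] = 1e-12
        J = diff / r[:, None]
        step, *_ = np.linalg.lstsq(J, -(r - d), rcond=None)
        x = x + step
        if np.linalg.norm(step) < 1e-12:
            break
    residuals = np.linalg.norm(x - C, axis=1) - d
    return TrilaterationResult(
        reference_mm=x,
        rms_residual=float(np.sqrt(np.mean(residuals**2))),
        residuals=residuals,
    )


# ---------------------------------------------------------------------------
# Atlas labeling
# ---------------------------------------------------------------------------

def label_with_atlas(
    coordinate_mm,
    atlas: GridImage,
    labels: dict[int, str],
    near_radius_mm: float = 5.0,
) -> str:
    """Anatomical label of the containing voxel.

    Background points report the nearest labeled voxel within
    ``near_radius_mm`` as ``near:<label>``, else ``"none"``.
    """
    point = np.asarray(coordinate_mm, dtype=float)
    vox = np.round(world_to_voxel(atlas.affine, point)).astype(int)
    if np.any(vox < 0) or np.any(vox >= np.asarray(atlas.shape)):
        raise ValueError("coordinate outside the atlas field of view")
    value = int(atlas.data[tuple(vox)])
    if value != 0:
        return labels.get(value, str(value))
    labeled = atlas.data != 0
    if not labeled.any():
        return "none"
    vox_mm = np.linalg.norm(atlas.affine[:3, :3], axis=0)
    dist, indices = ndimage.distance_transform_edt(
        ~labeled, sampling=vox_mm, return_indices=True
    )
    if dist[tuple(vox)] <= near_radius_mm:
        nearest = tuple(indices[:, vox[0], vox[1], vox[2]])
        value = int(atlas.data[nearest])
        return f"near:{labels.get(value, str(value))}"
    return "none"


# ---------------------------------------------------------------------------
# Packaged reference coordinates
# ---------------------------------------------------------------------------

def load_reference_set(name: str = "references.yaml") -> dict[str, np.ndarray]:
    """Named group-level MNI coordinates shipped as editable config."""
    raw = _load_packaged_yaml(name)
    out: dict[str, np.ndarray] = {}
    for key, entry in raw["references"].items():
        out[key] = np.asarray(entry["mni_mm"], dtype=float)
    return out
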