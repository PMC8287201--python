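"""Spatial ICA, template matching, and reliability selection across runs.

A 4D series is decomposed by spatial ICA: the data matrix (voxels x frames)
is whitened by principal components over the time dimension and unmixed by
a fixed-point (FastICA) algorithm, so the independent sources are spatial
maps and each map carries a paired time course. Maps are z-scored over the
analysis mask and sign-fixed to non-negative skewness (ICA is sign
indeterminate; the activation tail is conventionally positive).

Networks of interest are identified by template matching: the component
maximizing a goodness-of-fit score against a binary network template wins
that label. Reliability across repeated ICA runs is summarized by the
medoid map (the assigned component with maximal median absolute spatial
correlation to the other runs' assignments) and the classification
frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .image_model import BinaryMask, BoldSeries, GridImage

DEFAULT_N_RUNS = 10  # repeated decompositions for reliability assessment


@dataclass
class SpatialComponent:
    zmap: GridImage
    timecourse: np.ndarray
    run_index: int
    component_index: int
    sign_fixed: bool = True

    def masked_values(self, mask: BinaryMask) -> np.ndarray:
        return self.zmap.data[mask.bool_data]


@dataclass
class IcaRun:
    components: list[SpatialComponent]
    mask: BinaryMask
    seed: int
    n_components: int
    n_iter: int
    converged: bool


@dataclass
class NetworkTemplate:
    label: str
    map: GridImage
    threshold: float = 0.5

    def binarized(self) -> np.ndarray:
        supra = self.map.data > self.threshold
        if not supra.any():
            raise ValueError(
                f"template {self.label!r} has no suprathreshold voxel"
            )
        return supra


@dataclass
class NetworkAssignment:
    run_index: int
    label: str
    component_index: int
    gof_score: float


@dataclass
class ReliableSelection:
    label: str
    component: SpatialComponent
    frequency: float            # runs with an assignment / total runs
    n_assigned: int
    n_runs: int
    median_abs_correlation: float


@dataclass
class IcaConfig:
    n_components: int | str = "auto"
    n_runs: int = DEFAULT_N_RUNS
    fun: str = "logcosh"
    tol: float = 1e-4
    max_iter: int = 500
    auto_method: str = "mp"  # mp (noise-edge) | variance (cumulative < threshold)
    auto_variance_threshold: float = 0.90
    gof_method: str = "gof"  # gof | correlation


# ---------------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------------

def estimate_n_components(
    series: BoldSeries,
    mask: BinaryMask,
    method: str = "mp",
    variance_threshold: float = 0.90,
) -> int:
    """Data-driven component count, bounded to [2, frames/10] and the rank.

    ``mp`` (default): the number of covariance eigenvalues above the
    Marchenko-Pastur noise edge, with the noise level estimated from the
    median eigenvalue — the random-matrix analogue of the probabilistic-PCA
    dimensionality estimators used by ICA tooling. On noiseless data this
    reduces to the numerical rank.

    ``variance``: one more than the number of principal components whose
    cumulative explained variance stays below ``variance_threshold``. This
    simple rule is adequate at high SNR but saturates at the upper bound
    once noise dominates the spectrum.
    """
    X = _masked_matrix(series, mask)
    n_vox, n_frames = X.shape
    sv = np.linalg.svd(X, compute_uv=False)
    lam = sv**2 / n_vox
    rank = int(np.sum(sv > sv[0] * 1e-10))
    if method == "mp":
        gamma = n_frames / n_vox
        edge = np.median(lam) * (1.0 + np.sqrt(gamma)) ** 2
        edge = max(edge, lam[0] * 1e-9)  # guard for (near-)noiseless data
        n = int(np.sum(lam > edge))
    elif method == "variance":
        cum = np.cumsum(lam) / lam.sum()
        n = int(np.sum(cum < variance_threshold)) + 1
    else:
        raise ValueError(f"unknown auto method {method!r}")
    upper = max(2, series.n_frames // 10)
    return int(np.clip(n, 2, min(upper, rank)))


def _masked_matrix(series: BoldSeries, mask: BinaryMask) -> np.ndarray:
    """(voxels x frames) matrix of voxel-demeaned time series."""
    X = series.data[mask.bool_data].astype(float)
    return X - X.mean(axis=1, keepdims=True)


def fit_spatial_ica(
    series: BoldSeries,
    mask: BinaryMask,
    n_components: int | str = "auto",
    seed: int = 0,
    config: IcaConfig | None = None,
    run_index: int = 0,
) -> IcaRun:
    """One spatial ICA decomposition, deterministic given the seed."""
    config = config or IcaConfig()
    X = _masked_matrix(series, mask)
    n_vox, n_frames = X.shape
    if n_components == "auto":
        n_components = estimate_n_components(
            series, mask, config.auto_method, config.auto_variance_threshold
        )
    n_components = int(n_components)
    sv = np.linalg.svd(X, compute_uv=False)
    rank = int(np.sum(sv > sv[0] * 1e-10))
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds data rank {rank}"
        )
    if n_vox <= n_components or n_frames <= n_components:
        raise ValueError("mask voxels and frame count must exceed n_components")

    ica = FastICA(
        n_components=n_components,
        whiten="unit-variance",
        fun=config.fun,
        tol=config.tol,
        max_iter=config.max_iter,
        random_state=int(seed),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        sources = ica.fit_transform(X)  # (voxels, components): spatial maps
    mixing = ica.mixing_  # (frames, components): time courses
    converged = ica.n_iter_ < config.max_iter

    components: list[SpatialComponent] = []
    mbool = mask.bool_data
    for k in range(n_components):
        m = sources[:, k].copy()
        tc = mixing[:, k].copy()
        if stats.skew(m) < 0:
            m = -m
            tc = -tc
        m = (m - m.mean()) / m.std()
        full = np.zeros(series.shape3d)
        full[mbool] = m
        components.append(
            SpatialComponent(
                zmap=GridImage(full, series.affine.copy(), series.space_tag),
                timecourse=tc,
                run_index=run_index,
                component_index=k,
            )
        )
    return IcaRun(
        components=components,
        mask=mask,
        seed=int(seed),
        n_components=n_components,
        n_iter=int(ica.n_iter_),
        converged=bool(converged),
    )


def repeat_spatial_ica(
    series: BoldSeries,
    mask: BinaryMask,
    config: IcaConfig | None = None,
    seed: int = 0,
) -> list[IcaRun]:
    """Run the decomposition ``n_runs`` times with derived seeds."""
    config = config or IcaConfig()
    return [
        fit_spatial_ica(
            series,
            mask,
            config.n_components,
            seed=(int(seed) * 1000 + r) % (2**31 - 1),
            config=config,
            run_index=r,
        )
        for r in range(config.n_runs)
    ]


# ---------------------------------------------------------------------------
# Template matching
# ---------------------------------------------------------------------------

def goodness_of_fit(
    zmap: GridImage,
    template: NetworkTemplate,
    analysis_mask: BinaryMask | None = None,
    method: str = "gof",
) -> float:
    """Template-matching score.

    ``gof``: mean z inside the binarized template minus mean z outside it
    (within the analysis mask) — robust to template size imbalance.
    ``correlation``: Pearson correlation between map and template map over
    the analysis mask.
    """
    if not zmap.same_grid(template.map):
        raise ValueError("zmap and template must live on the same grid")
    inside = template.binarized()
    mask = (
        analysis_mask.bool_data
        if analysis_mask is not None
        else np.ones(zmap.shape, dtype=bool)
    )
    if method == "correlation":
        a = zmap.data[mask].astype(float)
        b = template.map.data[mask].astype(float)
        return float(np.corrcoef(a, b)[0, 1])
    vals_in = zmap.data[inside & mask]
    vals_out = zmap.data[~inside & mask]
    if vals_in.size == 0:
        raise ValueError("template is empty within the analysis mask")
    outside_mean = vals_out.mean() if vals_out.size else 0.0
    return float(vals_in.mean() - outside_mean)


def classify_components(
    run: IcaRun,
    templates: list[NetworkTemplate],
    analysis_mask: BinaryMask | None = None,
    method: str = "gof",
) -> dict[str, NetworkAssignment | None]:
    """Assign components to template labels, one winner per label.

    Greedy over descending score: a component may win at most one label;
    ties break toward higher score, then lower component index. Labels left
    without an eligible component map to None.
    """
    if not templates:
        raise ValueError("templates must be non-empty")
    if not run.components:
        raise ValueError("run has no components")
    mask = analysis_mask or run.mask
    scores = {
        (t.label, c.component_index): goodness_of_fit(c.zmap, t, mask, method)
        for t in templates
        for c in run.components
    }
    order = sorted(
        scores.items(), key=lambda kv: (-kv[1], kv[0][1], kv[0][0])
    )
    out: dict[str, NetworkAssignment | None] = {t.label: None for t in templates}
    used: set[int] = set()
    for (label, comp_idx), score in order:
        if out[label] is not None or comp_idx in used:
            continue
        run_index = run.components[comp_idx].run_index
        out[label] = NetworkAssignment(run_index, label, comp_idx, score)
        used.add(comp_idx)
    return out


def select_reliable_map(
    runs: list[IcaRun],
    label: str,
    templates: list[NetworkTemplate],
    analysis_mask: BinaryMask | None = None,
    method: str = "gof",
) -> ReliableSelection:
    """Medoid of the per-run components classified as ``label``.

    The medoid maximizes the median absolute spatial correlation with the
    other runs' assigned components (absolute: ICA sign indeterminacy).
    """
    if not runs:
        raise ValueError("runs must be non-empty")
    mask = analysis_mask or runs[0].mask
    chosen: list[SpatialComponent] = []
    for run in runs:
        assignment = classify_components(run, templates, mask, method)[label]
        if assignment is not None:
            chosen.append(run.components[assignment.component_index])
    if not chosen:
        raise ValueError(f"label {label!r} was assigned in zero runs")
    if len(chosen) == 1:
        return ReliableSelection(label, chosen[0], 1.0 / len(runs),
                                 1, len(runs), 1.0)
    vals = np.stack([c.masked_values(mask) for c in chosen])
    corr = np.abs(np.corrcoef(vals))
    med = np.array([
        np.median(np.delete(corr[i], i)) for i in range(len(chosen))
    ])
    best = int(np.argmax(med))  # argmax takes the lowest index on ties
    return ReliableSelection(
        label=label,
        component=chosen[best],
        frequency=len(chosen) / len(runs),
        n_assigned=len(chosen),
        n_runs=len(runs),
        median_abs_correlation=float(med[best]),
    )
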