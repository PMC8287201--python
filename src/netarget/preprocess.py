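"""BOLD preprocessing: frame trimming, realignment, high-pass, smoothing.

The stages mirror a conventional single-subject resting-state stream:
remove initial non-equilibrium frames, rigid-body motion correction,
temporal high-pass at 0.01 Hz, isotropic Gaussian smoothing at 4 mm FWHM.
Realignment here is a deliberately simple intensity-based re-implementation
(phase correlation for translations, Powell search for full rigid-body);
it is adequate for phantom data and small motions, not a drop-in for a
production motion corrector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage.registration import phase_cross_correlation

from .image_model import BoldSeries, GridImage

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PreprocConfig:
    n_drop: int = 10
    highpass_hz: float = 0.01
    smooth_fwhm_mm: float = 4.0
    realign: str = "translation"  # off | translation | rigid6
    highpass_method: str = "butterworth"  # butterworth | dct
    smooth_before_filter: bool = False

    def __post_init__(self) -> None:
        if self.n_drop < 0:
            raise ValueError("n_drop must be >= 0")
        if self.highpass_hz < 0:
            raise ValueError("highpass_hz must be >= 0")
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smooth_fwhm_mm must be >= 0")
        if self.realign not in ("off", "translation", "rigid6"):
            raise ValueError(f"unknown realign mode {self.realign!r}")
        if self.highpass_method not in ("butterworth", "dct"):
            raise ValueError(f"unknown highpass method {self.highpass_method!r}")


def trim_initial_frames(series: BoldSeries, n: int) -> BoldSeries:
    """Drop the first ``n`` frames (signal-equilibrium discard)."""
    if not 0 <= n < series.n_frames:
        raise ValueError(
            f"cannot drop {n} of {series.n_frames} frames"
        )
    return BoldSeries(
        series.data[..., n:].copy(),
        series.affine.copy(),
        series.tr_seconds,
        series.space_tag,
    )


# ---------------------------------------------------------------------------
# Realignment
# ---------------------------------------------------------------------------

def realign_rigid(
    series: BoldSeries, reference_index: int = 0, mode: str = "translation"
) -> tuple[BoldSeries, np.ndarray]:
    """Register every frame to the reference frame.

    Returns the realigned series and a motion trace with one parameter
    vector per frame: (tx, ty, tz) in mm for ``translation``, plus
    (rx, ry, rz) in degrees for ``rigid6``. Rotations are about the volume
    centre.
    """
    if mode not in ("translation", "rigid6"):
        raise ValueError(f"unknown realign mode {mode!r}")
    if not 0 <= reference_index < series.n_frames:
        raise ValueError("reference_index out of range")
    data = series.data.astype(float)
    stds = data.reshape(-1, series.n_frames).std(axis=0)
    if np.any(stds == 0):
        raise ValueError("constant (zero-variance) frames cannot be realigned")

    ref = data[..., reference_index]
    vox_mm = np.linalg.norm(series.affine[:3, :3], axis=0)
    n_par = 3 if mode == "translation" else 6
    trace = np.zeros((series.n_frames, n_par))
    out = np.empty_like(data)

    for t in range(series.n_frames):
        frame = data[..., t]
        if t == reference_index:
            out[..., t] = frame
            continue
        shift_vox, _, _ = phase_cross_correlation(
            ref, frame, upsample_factor=20, normalization=None
        )
        if mode == "translation":
            out[..., t] = ndimage.shift(frame, shift_vox, order=1, mode="constant")
            trace[t, :3] = shift_vox * vox_mm
        else:
            params = _fit_rigid6(ref, frame, np.asarray(shift_vox, float))
            out[..., t] = _apply_rigid6(frame, params)
            trace[t, :3] = params[:3] * vox_mm
            trace[t, 3:] = np.degrees(params[3:])
    return (
        BoldSeries(out, series.affine.copy(), series.tr_seconds, series.space_tag),
        trace,
    )


def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    mx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    my = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    mz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return mz @ my @ mx


def _apply_rigid6(frame: np.ndarray, params: np.ndarray) -> np.ndarray:
    # params: shifts (voxels) + rotations (radians); resample frame onto the
    # reference grid, i.e. apply the inverse map to output coordinates.
    center = (np.asarray(frame.shape) - 1) / 2.0
    rot = _rotation_matrix(*params[3:])
    inv = rot.T
    offset = center - inv @ (center + params[:3])
    return ndimage.affine_transform(
        frame, inv, offset=offset, order=1, mode="constant"
    )


def _fit_rigid6(ref: np.ndarray, frame: np.ndarray, shift0: np.ndarray) -> np.ndarray:
    from scipy.optimize import minimize

    mask = ref != 0

    def cost(p):
        moved = _apply_rigid6(frame, p)
        return float(np.mean((moved[mask] - ref[mask]) ** 2))

    x0 = np.r_[shift0, 0.0, 0.0, 0.0]
    res = minimize(cost, x0, method="Powell",
                   options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": 2000})
    return res.x


# ---------------------------------------------------------------------------
# Temporal filtering
# ---------------------------------------------------------------------------

def temporal_highpass(
    series: BoldSeries, cutoff_hz: float, method: str = "butterworth"
) -> BoldSeries:
    """Per-voxel high-pass filter; output is zero-mean per voxel.

    ``butterworth``: zero-phase (forward-backward) order-4 Butterworth.
    ``dct``: regression against the slow discrete-cosine basis, the
    classical fMRI drift model.
    """
    nyquist = 1.0 / (2.0 * series.tr_seconds)
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    data = series.data.astype(float)
    flat = data.reshape(-1, series.n_frames)
    if cutoff_hz <= 0:
        filtered = flat - flat.mean(axis=1, keepdims=True)
    elif method == "butterworth":
        sos = signal.butter(4, cutoff_hz / nyquist, btype="highpass", output="sos")
        filtered = signal.sosfiltfilt(sos, flat, axis=1)
        filtered -= filtered.mean(axis=1, keepdims=True)
    elif method == "dct":
        n = series.n_frames
        duration = n * series.tr_seconds
        n_basis = int(np.floor(2.0 * duration * cutoff_hz))
        t = (np.arange(n) + 0.5) / n
        basis = [np.ones(n)]
        for k in range(1, n_basis + 1):
            basis.append(np.cos(np.pi * k * t))
        X = np.column_stack(basis)
        beta, *_ = np.linalg.lstsq(X, flat.T, rcond=None)
        filtered = (flat.T - X @ beta).T
    else:
        raise ValueError(f"unknown highpass method {method!r}")
    return BoldSeries(
        filtered.reshape(series.data.shape),
        series.affine.copy(),
        series.tr_seconds,
        series.space_tag,
    )


# ---------------------------------------------------------------------------
# Spatial smoothing
# ---------------------------------------------------------------------------

def spatial_smooth(image_or_series, fwhm_mm: float):
    """Isotropic Gaussian smoothing specified in mm FWHM.

    The kernel width is converted per axis by the voxel size
    (sigma_vox = FWHM / (2 sqrt(2 ln 2)) / voxel_size); total image mass is
    preserved up to boundary truncation. ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    obj = image_or_series
    if fwhm_mm == 0:
        return obj.copy()
    vox_mm = np.linalg.norm(obj.affine[:3, :3], axis=0)
    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / vox_mm
    if isinstance(obj, BoldSeries):
        out = ndimage.gaussian_filter(
            obj.data.astype(float), sigma=(*sigma_vox, 0.0), mode="constant"
        )
        return BoldSeries(out, obj.affine.copy(), obj.tr_seconds, obj.space_tag)
    if isinstance(obj, GridImage):
        out = ndimage.gaussian_filter(
            obj.data.astype(float), sigma=sigma_vox, mode="constant"
        )
        return GridImage(out, obj.affine.copy(), obj.space_tag)
    raise TypeError(f"cannot smooth object of type {type(obj)!r}")


# ---------------------------------------------------------------------------
# Full stream
# ---------------------------------------------------------------------------

def run_preprocess(
    series: BoldSeries, config: PreprocConfig | None = None
) -> tuple[BoldSeries, np.ndarray | None]:
    """trim -> realign -> high-pass -> smooth (order configurable for the
    last two via ``smooth_before_filter``). Returns (series, motion trace)."""
    config = config or PreprocConfig()
    out = trim_initial_frames(series, config.n_drop)
    trace = None
    if config.realign != "off":
        out, trace = realign_rigid(out, 0, config.realign)
    steps = (
        ("smooth", "filter") if config.smooth_before_filter else ("filter", "smooth")
    )
    for step in steps:
        if step == "filter":
            out = temporal_highpass(out, config.highpass_hz, config.highpass_method)
        else:
            out = spatial_smooth(out, config.smooth_fwhm_mm)
    return out, trace
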