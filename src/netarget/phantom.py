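"""Synthetic resting-state phantom with planted DMN/FPN networks.

The phantom provides ground truth for every downstream stage: two spatial
networks built from Gaussian nodes inside an ellipsoidal head, band-limited
mutually orthogonal network time courses, i.i.d. Gaussian noise, and simple
head / gray-matter geometry. A node listed under both networks ("shared
node") lets tests exercise the network-specificity selection criterion.

The default scale (32x38x32 voxels at 4 mm, 200 frames, TR 1 s) is a
desk-scale stand-in for a multiband acquisition (2.1 mm isotropic, 600
volumes, TR 1 s); the full-size geometry can be requested through
:class:`PhantomSpec` but is not needed by the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import ndimage

from .image_model import BinaryMask, BoldSeries, GridImage, voxel_to_world

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class NodeSpec:
    name: str
    center_mm: tuple[float, float, float]
    fwhm_mm: float = 14.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        self.center_mm = tuple(float(v) for v in self.center_mm)


@dataclass
class NetworkSpec:
    label: str
    nodes: list[NodeSpec]


def default_networks() -> list[NetworkSpec]:
    """Two networks with one node planted in both (the "shared" node).

    Within each network the intended TMS-like target is the most
    superficial network-specific node; the shared node is more superficial
    still, so only the network-specificity criterion can reject it.

    The shared node carries 60% of the network-defining amplitude: strong
    enough to be robustly suprathreshold in both estimated network maps,
    weak enough that the two networks remain statistically identifiable —
    with a shared blob as strong as the defining nodes, the sum and
    difference of the networks are sparser than the networks themselves and
    no independence-based decomposition can recover them.
    """
    shared = NodeSpec("shared_junction", (-46.0, 0.0, 20.0), 14.0, 0.6)
    return [
        NetworkSpec(
            "DMN",
            [
                NodeSpec("l_ipl", (-30.0, -38.0, 22.0), 14.0, 1.0),
                NodeSpec("precuneus", (-5.0, -38.0, 24.0), 14.0, 0.9),
                shared,
            ],
        ),
        NetworkSpec(
            "FPN",
            [
                NodeSpec("l_dlpfc", (-30.0, 40.0, 18.0), 14.0, 1.0),
                NodeSpec("l_spl", (-20.0, -19.0, 28.0), 14.0, 0.9),
                shared,
            ],
        ),
    ]


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (32, 38, 32)
    voxel_size_mm: float = 4.0
    n_frames: int = 200
    tr_seconds: float = 1.0
    networks: list[NetworkSpec] = field(default_factory=default_networks)
    band_hz: tuple[float, float] = (0.01, 0.08)
    noise_sd: float = 0.5
    baseline_scale: float = 1.0  # static anatomy added to every frame
    head_radii_mm: tuple[float, float, float] = (56.0, 68.0, 54.0)
    gm_depth_mm: tuple[float, float] = (4.0, 20.0)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_frames < 2 * len(self.networks):
            raise ValueError("need at least 2 frames per network")
        for net in self.networks:
            for node in net.nodes:
                if node.fwhm_mm <= 0:
                    raise ValueError(f"node {node.name}: fwhm must be > 0")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = -(np.asarray(self.shape) - 1) / 2.0 * self.voxel_size_mm
        return aff

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["networks"] = [
            NetworkSpec(n["label"], [NodeSpec(**nd) for nd in n["nodes"]])
            for n in raw.get("networks", [])
        ]
        for key in ("shape", "band_hz", "head_radii_mm", "gm_depth_mm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class NodeTruth:
    network: str
    name: str
    center_mm: np.ndarray
    peak_mm: np.ndarray          # world coordinate of the arg-max voxel
    peak_voxel: tuple[int, int, int]
    shared: bool


@dataclass
class PhantomBundle:
    spec: PhantomSpec
    seed: int
    t1_like: GridImage
    head_mask: BinaryMask
    gm_mask: BinaryMask
    brain_mask: BinaryMask
    bold: BoldSeries
    truth_maps: dict[str, GridImage]
    truth_timecourses: dict[str, np.ndarray]
    truth_nodes: list[NodeTruth]

    def truth_node(self, network: str, name: str) -> NodeTruth:
        for node in self.truth_nodes:
            if node.network == network and node.name == name:
                return node
        raise KeyError(f"no node {name!r} in network {network!r}")


def band_limited_timecourses(
    n_frames: int,
    n_signals: int,
    tr_seconds: float,
    band_hz: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance, zero-mean, pairwise-orthogonal band-limited signals.

    White noise is restricted to the pass band in the frequency domain and
    the columns are then orthogonalized (QR), which leaves them band-limited
    (the pass band is a linear subspace) and exactly uncorrelated.
    """
    white = rng.standard_normal((n_frames, n_signals))
    freqs = np.fft.rfftfreq(n_frames, d=tr_seconds)
    keep = (freqs >= band_hz[0]) & (freqs <= band_hz[1]) & (freqs > 0)
    if keep.sum() < n_signals:
        raise ValueError("pass band too narrow for requested signal count")
    spectrum = np.fft.rfft(white, axis=0)
    spectrum[~keep] = 0.0
    sig = np.fft.irfft(spectrum, n=n_frames, axis=0)
    sig -= sig.mean(axis=0)
    q, r = np.linalg.qr(sig)
    q *= np.sign(np.diag(r))  # deterministic orientation
    q -= q.mean(axis=0)
    return q / q.std(axis=0)


def generate_phantom(spec: PhantomSpec, seed: int = 0) -> PhantomBundle:
    """Build the deterministic phantom bundle for a spec and seed."""
    rng = np.random.default_rng(seed)
    affine = spec.affine
    shape = tuple(spec.shape)

    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    world = np.atleast_2d(voxel_to_world(affine, vox))
    radii = np.asarray(spec.head_radii_mm, dtype=float)

    rho = np.linalg.norm(world / radii, axis=1).reshape(shape)
    head = (rho <= 1.0).astype(np.uint8)
    depth = ndimage.distance_transform_edt(
        head, sampling=[spec.voxel_size_mm] * 3
    )
    lo, hi = spec.gm_depth_mm
    gm = ((depth >= lo) & (depth <= hi)).astype(np.uint8)
    brain = (depth >= lo).astype(np.uint8)

    head_mask = BinaryMask(head, affine, "native_T1")
    gm_mask = BinaryMask(gm, affine, "native_T1")
    brain_mask = BinaryMask(brain, affine, "native_T1")
    t1 = GridImage(100.0 * head + 40.0 * gm + 20.0 * brain, affine, "native_T1")

    shared_names = _shared_node_names(spec)
    truth_maps: dict[str, GridImage] = {}
    truth_nodes: list[NodeTruth] = []
    maps = []
    for net in spec.networks:
        net_map = np.zeros(shape)
        for node in net.nodes:
            center = np.asarray(node.center_mm, dtype=float)
            if np.linalg.norm(center / radii) >= 1.0:
                raise ValueError(
                    f"node {node.name!r} center {tuple(center)} lies outside the head"
                )
            sigma = node.fwhm_mm * _FWHM_TO_SIGMA
            d2 = np.sum((world - center) ** 2, axis=1).reshape(shape)
            profile = node.amplitude * np.exp(-d2 / (2.0 * sigma**2))
            net_map += profile
            peak_voxel = np.unravel_index(np.argmax(profile), shape)
            truth_nodes.append(
                NodeTruth(
                    network=net.label,
                    name=node.name,
                    center_mm=center,
                    peak_mm=np.asarray(
                        voxel_to_world(affine, np.asarray(peak_voxel, float))
                    ),
                    peak_voxel=tuple(int(v) for v in peak_voxel),
                    shared=node.name in shared_names,
                )
            )
        truth_maps[net.label] = GridImage(net_map, affine, "native_T1")
        maps.append(net_map)

    tcs = band_limited_timecourses(
        spec.n_frames, len(spec.networks), spec.tr_seconds, spec.band_hz, rng
    )
    truth_tcs = {net.label: tcs[:, k] for k, net in enumerate(spec.networks)}

    signal = np.einsum("xyzk,tk->xyzt", np.stack(maps, axis=-1), tcs)
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, signal.shape)
    # static anatomical baseline: real BOLD frames are dominated by a
    # time-invariant image (fluctuations are a few percent); without it,
    # frame-to-frame registration has nothing to lock onto
    if spec.baseline_scale != 0:
        signal = signal + spec.baseline_scale * t1.data[..., None]
    bold = BoldSeries(
        signal.astype(np.float32), affine, spec.tr_seconds, "native_EPI"
    )

    return PhantomBundle(
        spec=spec,
        seed=seed,
        t1_like=t1,
        head_mask=head_mask,
        gm_mask=gm_mask,
        brain_mask=brain_mask,
        bold=bold,
        truth_maps=truth_maps,
        truth_timecourses=truth_tcs,
        truth_nodes=truth_nodes,
    )


def _shared_node_names(spec: PhantomSpec) -> set[str]:
    seen: dict[str, int] = {}
    for net in spec.networks:
        for node in net.nodes:
            seen[node.name] = seen.get(node.name, 0) + 1
    return {name for name, count in seen.items() if count > 1}


def inject_translation(
    series: BoldSeries, shift_vox, frame_indices
) -> BoldSeries:
    """Return a copy with a known voxel-space translation applied to frames.

    Used to create ground truth for realignment tests.
    """
    out = series.copy()
    shift_vox = np.asarray(shift_vox, dtype=float)
    for t in frame_indices:
        out.data[..., t] = ndimage.shift(
            series.data[..., t].astype(float), shift_vox, order=1, mode="constant"
        )
    return out


def write_truth_tsv(bundle: PhantomBundle, path) -> None:
    """Write per-node ground-truth peak coordinates as a TSV."""
    import pandas as pd

    rows = [
        {
            "network": n.network,
            "node": n.name,
            "x_mm": n.peak_mm[0],
            "y_mm": n.peak_mm[1],
            "z_mm": n.peak_mm[2],
            "shared": int(n.shared),
        }
        for n in bundle.truth_nodes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
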