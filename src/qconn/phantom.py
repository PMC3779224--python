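"""Known-truth fiber-bundle phantoms and simulated diffusion-weighted signals.

A phantom is a small voxel grid containing one or more cylindrical fiber
bundles.  Voxels within a bundle's radius of its centerline are white
matter and carry the local centerline tangent as a fiber direction; the
terminal ends of each bundle are capped by gray-matter ROI labels, so every
bundle connects exactly two ROIs ("true pairs").  The diffusion signal is a
standard multi-tensor mixture

    S(q) = S0 * sum_k f_k * exp(-b(q) * g^T D_k g)

with axially symmetric per-fiber tensors, corrupted by Rician noise
(magnitude of a complex Gaussian) and optionally averaged over repeats in
the complex or the magnitude domain.  Complex averaging reduces the noise
floor by sqrt(N); magnitude averaging does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schemes import QScheme

__all__ = [
    "BundleSpec",
    "PhantomConfig",
    "PhantomTruth",
    "DWIDataset",
    "build_phantom",
    "noiseless_signal",
    "simulate_dwi",
    "complex_average",
]

MAX_DIRS = 3  # most fiber populations a phantom voxel can carry

# typical adult white-matter tensor eigenvalues, mm^2/s
DEFAULT_AXIAL_D = 1.7e-3
DEFAULT_RADIAL_D = 0.3e-3
DEFAULT_GM_D = 0.8e-3
DEFAULT_BACKGROUND_D = 3.0e-3  # free-water-like surround


@dataclass
class BundleSpec:
    """One cylindrical fiber bundle: centerline polyline + radius + tensor."""

    centerline: np.ndarray  # (M, 3) mm
    radius: float  # mm
    weight: float = 1.0
    diffusivities: tuple[float, float] = (DEFAULT_AXIAL_D, DEFAULT_RADIAL_D)

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2:
            raise ValueError("centerline needs at least 2 points")
        if self.radius <= 0:
            raise ValueError(f"bundle radius must be positive, got {self.radius}")
        ax, rad = self.diffusivities
        if not (ax >= rad > 0):
            raise ValueError(f"need axial >= radial > 0, got {self.diffusivities}")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1).sum())


@dataclass
class PhantomConfig:
    """Named phantom geometry plus grid/voxel parameters."""

    geometry: str = "straight"  # straight | crossing | arc | three_bundle_crossing
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    radius: float = 3.0  # bundle radius, mm
    angle: float = 90.0  # crossing angle, degrees
    cap_length: float = 4.0  # terminal ROI cap extent along the bundle, mm
    margin: float = 2.0  # gap between bundle ends and grid faces, mm
    diffusivities: tuple[float, float] = (DEFAULT_AXIAL_D, DEFAULT_RADIAL_D)


@dataclass
class PhantomTruth:
    """Ground truth: geometry, masks, labels and per-voxel fiber directions."""

    bundles: list[BundleSpec]
    wm_mask: np.ndarray  # bool (X, Y, Z)
    roi_labels: np.ndarray  # int (X, Y, Z); 0 background
    voxel_size: np.ndarray  # (3,) mm
    true_pairs: set[tuple[int, int]]
    directions: np.ndarray  # (X, Y, Z, MAX_DIRS, 3) unit tangents, zero-padded
    fractions: np.ndarray  # (X, Y, Z, MAX_DIRS) volume fractions, zero-padded
    n_dirs: np.ndarray  # int (X, Y, Z)
    config: PhantomConfig | None = None

    def __post_init__(self) -> None:
        if np.any(self.wm_mask & (self.roi_labels > 0)):
            raise ValueError("white-matter mask and ROI labels must be disjoint")

    @property
    def n_rois(self) -> int:
        return int(self.roi_labels.max())

    @property
    def roi_ids(self) -> list[int]:
        return list(range(1, self.n_rois + 1))


@dataclass
class DWIDataset:
    """A simulated 4-D diffusion acquisition plus everything needed downstream."""

    signal: np.ndarray  # (X, Y, Z, n_samples), >= 0
    scheme: QScheme
    voxel_size: np.ndarray
    wm_mask: np.ndarray
    roi_labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.signal.shape[-1] != len(self.scheme):
            raise ValueError(
                f"signal has {self.signal.shape[-1]} volumes but scheme has "
                f"{len(self.scheme)} samples"
            )
        if not np.all(np.isfinite(self.signal)) or np.any(self.signal < 0):
            raise ValueError("signal must be finite and non-negative")


def _voxel_centers(grid_shape, voxel_size) -> np.ndarray:
    idx = np.indices(grid_shape).reshape(3, -1).T
    return (idx + 0.5) * np.asarray(voxel_size)


def _nearest_on_polyline(points: np.ndarray, line: np.ndarray):
    """Distance, arclength position and local tangent of the nearest
    centerline point, for every query point.  Vectorized over points."""
    best_d2 = np.full(len(points), np.inf)
    best_s = np.zeros(len(points))
    best_tan = np.zeros((len(points), 3))
    s0 = 0.0
    for a, b in zip(line[:-1], line[1:]):
        ab = b - a
        seg_len = float(np.linalg.norm(ab))
        if seg_len == 0:
            continue
        t = np.clip((points - a) @ ab / seg_len**2, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d2 = ((points - proj) ** 2).sum(axis=1)
        upd = d2 < best_d2
        best_d2[upd] = d2[upd]
        best_s[upd] = s0 + t[upd] * seg_len
        best_tan[upd] = ab / seg_len
        s0 += seg_len
    return np.sqrt(best_d2), best_s, best_tan


def _half_extent(center, direction, extent, margin) -> float:
    """Largest h with center ± h*direction at least `margin` inside the box."""
    lo = np.full(3, margin)
    hi = extent - margin
    t_hi = np.inf
    for i in range(3):
        if abs(direction[i]) < 1e-12:
            continue
        t1 = (lo[i] - center[i]) / direction[i]
        t2 = (hi[i] - center[i]) / direction[i]
        t_hi = min(t_hi, max(t1, t2))
    return float(t_hi)


def _line_bundle(center, direction, extent, cfg: PhantomConfig) -> BundleSpec:
    u = np.asarray(direction, dtype=float)
    u /= np.linalg.norm(u)
    h = _half_extent(center, u, extent, cfg.margin)
    line = np.stack([center - h * u, center + h * u])
    return BundleSpec(line, cfg.radius, diffusivities=cfg.diffusivities)


def _make_bundles(cfg: PhantomConfig) -> list[BundleSpec]:
    extent = np.asarray(cfg.grid_shape) * np.asarray(cfg.voxel_size)
    c = extent / 2.0
    if cfg.geometry == "straight":
        return [_line_bundle(c, (1, 0, 0), extent, cfg)]
    if cfg.geometry == "crossing":
        th = np.radians(cfg.angle)
        return [
            _line_bundle(c, (1, 0, 0), extent, cfg),
            _line_bundle(c, (np.cos(th), np.sin(th), 0), extent, cfg),
        ]
    if cfg.geometry == "three_bundle_crossing":
        return [
            _line_bundle(c, (np.cos(a), np.sin(a), 0), extent, cfg)
            for a in np.radians([0.0, 60.0, 120.0])
        ]
    if cfg.geometry == "arc":
        # quarter circle in the x-y plane
        r = min(extent[0], extent[1]) / 2.0 - cfg.margin - cfg.radius
        th = np.linspace(0, np.pi / 2, max(int(np.pi / 2 * r), 8))
        base = np.array([cfg.margin + cfg.radius, cfg.margin + cfg.radius, c[2]])
        line = base + np.stack(
            [r * np.cos(th), r * np.sin(th), np.zeros_like(th)], axis=1
        )
        return [BundleSpec(line, cfg.radius, diffusivities=cfg.diffusivities)]
    raise ValueError(f"unknown phantom geometry: {cfg.geometry!r}")


def build_phantom(cfg: PhantomConfig) -> PhantomTruth:
    """Rasterize the configured bundles into masks, labels and direction maps."""
    bundles = _make_bundles(cfg)
    shape = tuple(cfg.grid_shape)
    vs = np.asarray(cfg.voxel_size, dtype=float)
    centers = _voxel_centers(shape, vs)
    n_vox = len(centers)

    directions = np.zeros((n_vox, MAX_DIRS, 3))
    weights = np.zeros((n_vox, MAX_DIRS))
    n_dirs = np.zeros(n_vox, dtype=int)
    # cap membership per bundle end: (bundle index, end 0/1) -> voxel bool
    cap_masks = []
    for bundle in bundles:
        dist, s, tan = _nearest_on_polyline(centers, bundle.centerline)
        in_tube = dist <= bundle.radius
        L = bundle.length
        start_cap = in_tube & (s < cfg.cap_length)
        end_cap = in_tube & (s > L - cfg.cap_length)
        mid = in_tube & ~start_cap & ~end_cap
        cap_masks.append((start_cap, end_cap))
        for v in np.flatnonzero(mid):
            k = n_dirs[v]
            if k >= MAX_DIRS:
                continue
            directions[v, k] = tan[v]
            weights[v, k] = bundle.weight
            n_dirs[v] = k + 1

    wm = n_dirs > 0
    labels = np.zeros(n_vox, dtype=int)
    true_pairs: set[tuple[int, int]] = set()
    label = 0
    for start_cap, end_cap in cap_masks:
        pair = []
        for cap in (start_cap, end_cap):
            label += 1
            cap = cap & ~wm  # white matter wins where a tube overrides a cap
            clash = cap & (labels > 0)
            if np.any(clash):
                raise ValueError(
                    f"ROI cap of label {label} overlaps label(s) "
                    f"{sorted(set(labels[clash]))}"
                )
            if not np.any(cap):
                raise ValueError(f"ROI cap {label} rasterized to zero voxels")
            labels[cap] = label
            pair.append(label)
        true_pairs.add((min(pair), max(pair)))

    frac = np.zeros_like(weights)
    tot = weights.sum(axis=1)
    frac[wm] = weights[wm] / tot[wm, None]

    return PhantomTruth(
        bundles=bundles,
        wm_mask=wm.reshape(shape),
        roi_labels=labels.reshape(shape),
        voxel_size=vs,
        true_pairs=true_pairs,
        directions=directions.reshape(shape + (MAX_DIRS, 3)),
        fractions=frac.reshape(shape + (MAX_DIRS,)),
        n_dirs=n_dirs.reshape(shape),
        config=cfg,
    )


def noiseless_signal(
    truth: PhantomTruth,
    scheme: QScheme,
    S0: float = 100.0,
    gm_diffusivity: float = DEFAULT_GM_D,
    background_diffusivity: float = DEFAULT_BACKGROUND_D,
) -> np.ndarray:
    """Multi-tensor mixture signal, no noise.  Antipodally symmetric in q."""
    shape = truth.wm_mask.shape
    bvals = scheme.bvals  # (S,)
    grads = scheme.gradients  # (S, 3)
    frac = truth.fractions.reshape(-1, MAX_DIRS)
    dirs = truth.directions.reshape(-1, MAX_DIRS, 3)
    wm = truth.wm_mask.reshape(-1)
    roi = truth.roi_labels.reshape(-1) > 0

    sums = frac[wm].sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("white-matter volume fractions must sum to 1")

    sig = np.empty((len(wm), len(scheme)))
    # isotropic compartments
    sig[:] = S0 * np.exp(-bvals * background_diffusivity)[None, :]
    sig[roi] = S0 * np.exp(-bvals * gm_diffusivity)[None, :]
    # white matter: axially symmetric tensors, g^T D g = rd + (ad - rd)(g.u)^2
    ad, rd = truth.bundles[0].diffusivities if truth.bundles else (
        DEFAULT_AXIAL_D,
        DEFAULT_RADIAL_D,
    )
    cos2 = np.einsum("vkj,sj->vks", dirs[wm], grads) ** 2  # (V, K, S)
    att = np.exp(-bvals[None, None, :] * (rd + (ad - rd) * cos2))
    sig[wm] = S0 * np.einsum("vk,vks->vs", frac[wm], att)
    return sig.reshape(shape + (len(scheme),))


def complex_average(repeats) -> np.ndarray:
    """Magnitude of the voxelwise complex mean of repeated acquisitions.

    With N repeats of a zero-signal voxel the residual magnitude scales as
    1/sqrt(N) relative to a single repeat (the square-root law); N = 1 is
    the identity up to the magnitude operation.
    """
    arrays = [np.asarray(r) for r in repeats]
    if not arrays:
        raise ValueError("need at least one repeat")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("repeats must share shape and scheme")
    return np.abs(np.mean(arrays, axis=0))


def simulate_dwi(
    truth: PhantomTruth,
    scheme: QScheme,
    S0: float = 100.0,
    snr: float = np.inf,
    n_averages: int = 1,
    averaging: str = "complex",
    seed: int = 0,
    gm_diffusivity: float = DEFAULT_GM_D,
    background_diffusivity: float = DEFAULT_BACKGROUND_D,
) -> DWIDataset:
    """Simulate one acquisition of ``scheme`` on ``truth``.

    SNR is defined on the b0 signal: each repeat adds independent complex
    Gaussian noise with std ``S0/snr`` per channel and the magnitude is
    Rician.  ``averaging="complex"`` averages the complex repeats before
    taking the magnitude; ``"magnitude"`` averages the magnitudes.
    """
    if not (snr > 0):
        raise ValueError(f"snr must be positive (or inf for noiseless), got {snr}")
    if n_averages < 1:
        raise ValueError("n_averages must be >= 1")
    if averaging not in ("complex", "magnitude"):
        raise ValueError(f"unknown averaging mode: {averaging!r}")

    clean = noiseless_signal(
        truth, scheme, S0=S0,
        gm_diffusivity=gm_diffusivity,
        background_diffusivity=background_diffusivity,
    )
    if np.isinf(snr):
        signal = clean.copy()
    else:
        rng = np.random.default_rng(seed)
        sigma = S0 / snr
        repeats = [
            clean
            + sigma * rng.standard_normal(clean.shape)
            + 1j * sigma * rng.standard_normal(clean.shape)
            for _ in range(n_averages)
        ]
        if averaging == "complex":
            signal = complex_average(repeats)
        else:
            signal = np.mean([np.abs(r) for r in repeats], axis=0)

    return DWIDataset(
        signal=signal,
        scheme=scheme,
        voxel_size=truth.voxel_size,
        wm_mask=truth.wm_mask,
        roi_labels=truth.roi_labels,
        provenance={
            "scheme": scheme.name,
            "seed": seed,
            "snr": None if np.isinf(snr) else snr,
            "n_averages": n_averages,
            "averaging": averaging,
            "S0": S0,
        },
    )
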