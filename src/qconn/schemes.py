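"""Diffusion encoding schemes as explicit q-space sample sets.

Two families are supported, matching the acquisitions being compared:

* **Cartesian** (DSI-style): all integer lattice points inside a hemisphere
  of radius ``R`` lattice units, plus the q-space origin (b0).  At fixed
  diffusion time the b-value scales with ``|q|**2``, so a lattice point q
  carries ``b = b_max * |q|^2 / R^2``.
* **Shell** (HARDI/DTI-style): one b0 plus ``n-1`` unit directions
  quasi-uniformly spread over the sphere, all at the same b-value.

Schemes serialize to/from FSL-dialect ``bvals``/``bvecs`` text tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QSample",
    "QScheme",
    "cartesian_hemisphere_scheme",
    "uniform_sphere_scheme",
    "bvalue_of",
    "write_bvals_bvecs",
    "read_bvals_bvecs",
    "scheme_from_tables",
]

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class QSample:
    """A single q-space measurement: lattice vector / direction + b-value."""

    qvec: tuple[float, float, float]
    bval: float
    grad: tuple[float, float, float]
    is_b0: bool

    def __post_init__(self) -> None:
        if self.bval < 0:
            raise ValueError(f"negative b-value: {self.bval}")
        if self.is_b0 != (self.bval == 0):
            raise ValueError("is_b0 flag must be equivalent to bval == 0")
        if not self.is_b0:
            norm = float(np.linalg.norm(self.grad))
            if abs(norm - 1.0) > _UNIT_TOL:
                raise ValueError(f"gradient direction not unit-norm: |g| = {norm}")


@dataclass
class QScheme:
    """An ordered set of q-space samples defining one encoding scheme."""

    samples: list[QSample]
    kind: str  # "cartesian" | "shell"
    b_max: float
    lattice_radius: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("cartesian", "shell"):
            raise ValueError(f"unknown scheme kind: {self.kind!r}")
        qvecs = {s.qvec for s in self.samples}
        if len(qvecs) != len(self.samples):
            raise ValueError("duplicate qvec in scheme")
        if not any(s.is_b0 for s in self.samples):
            raise ValueError("scheme must contain at least one b0 sample")
        if self.kind == "shell":
            for s in self.samples:
                if not s.is_b0 and s.bval != self.b_max:
                    raise ValueError("shell scheme: all DW samples must sit at b_max")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def bvals(self) -> np.ndarray:
        return np.array([s.bval for s in self.samples], dtype=float)

    @property
    def gradients(self) -> np.ndarray:
        """(n, 3) unit gradient directions; zero rows for b0 samples."""
        g = np.array(
            [(0.0, 0.0, 0.0) if s.is_b0 else s.grad for s in self.samples], dtype=float
        )
        return g

    @property
    def qvecs(self) -> np.ndarray:
        return np.array([s.qvec for s in self.samples], dtype=float)

    @property
    def dw_mask(self) -> np.ndarray:
        return np.array([not s.is_b0 for s in self.samples], dtype=bool)

    @property
    def n_dw(self) -> int:
        return int(self.dw_mask.sum())


def _keep_hemisphere(q: tuple[int, int, int]) -> bool:
    """One representative per antipodal pair: z > 0, then y > 0, then x > 0."""
    x, y, z = q
    if z != 0:
        return z > 0
    if y != 0:
        return y > 0
    return x > 0


def bvalue_of(qvec, R: int, b_max: float) -> float:
    """b-value of a lattice point under the quadratic b–q relation."""
    q = np.asarray(qvec, dtype=float)
    q2 = float(q @ q)
    if q2 > R * R:
        raise ValueError(f"|q|^2 = {q2} exceeds lattice radius {R}")
    return b_max * q2 / (R * R)


def cartesian_hemisphere_scheme(R: int, b_max: float, name: str = "") -> QScheme:
    """Cubic-lattice hemisphere scheme of radius ``R`` lattice units.

    Contains the origin (b0) plus exactly one member of every antipodal pair
    of integer lattice points with ``|q|^2 <= R^2``.  R=5 yields 258 samples,
    R=4 yields 129.
    """
    if not (isinstance(R, (int, np.integer)) and R >= 1):
        raise ValueError(f"lattice radius must be a positive integer, got {R!r}")
    if b_max <= 0:
        raise ValueError(f"b_max must be positive, got {b_max}")
    pts = []
    rng = range(-R, R + 1)
    for x in rng:
        for y in rng:
            for z in rng:
                if x == y == z == 0:
                    continue
                if x * x + y * y + z * z <= R * R and _keep_hemisphere((x, y, z)):
                    pts.append((x, y, z))
    # stable order: by |q|^2 then lexicographic (z, y, x)
    pts.sort(key=lambda p: (p[0] ** 2 + p[1] ** 2 + p[2] ** 2, p[2], p[1], p[0]))
    samples = [QSample((0.0, 0.0, 0.0), 0.0, (0.0, 0.0, 0.0), True)]
    for p in pts:
        b = bvalue_of(p, R, b_max)
        g = np.asarray(p, dtype=float)
        g /= np.linalg.norm(g)
        samples.append(QSample(tuple(float(v) for v in p), b, tuple(g), False))
    return QScheme(samples, "cartesian", b_max, lattice_radius=R, name=name or f"DSIq{R}")


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _disperse_axes(points: np.ndarray, n_iter: int = 120, step: float = 0.05) -> np.ndarray:
    """Electrostatic-repulsion refinement treating each point and its
    antipode as a charge pair, so the *axial* arrangement is optimized."""
    x = points / np.linalg.norm(points, axis=1, keepdims=True)
    n = len(x)
    if n < 2:
        return x
    for _ in range(n_iter):
        diff = x[:, None, :] - x[None, :, :]
        anti = x[:, None, :] + x[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        a2 = np.einsum("ijk,ijk->ij", anti, anti)
        np.fill_diagonal(d2, np.inf)
        np.fill_diagonal(a2, np.inf)
        d2 = np.maximum(d2, 1e-12)
        a2 = np.maximum(a2, 1e-12)
        force = (diff / d2[..., None] ** 1.5).sum(axis=1)
        force += (anti / a2[..., None] ** 1.5).sum(axis=1)
        # project onto tangent plane and take a bounded step
        force -= np.einsum("ij,ij->i", force, x)[:, None] * x
        norms = np.linalg.norm(force, axis=1, keepdims=True)
        scale = step / np.maximum(norms.max(), 1e-12)
        x = x + scale * force
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    return x


def uniform_sphere_scheme(
    n_total: int, b: float, seed: int = 0, name: str = ""
) -> QScheme:
    """One b0 plus ``n_total - 1`` quasi-uniform unit directions at b-value ``b``.

    Directions come from a Fibonacci spiral refined by electrostatic repulsion
    on antipodally-symmetrized charges; the construction is deterministic for
    a given ``seed`` (the seed only rotates the final point set).
    """
    if n_total < 2:
        raise ValueError(f"n_total must be >= 2, got {n_total}")
    if b <= 0:
        raise ValueError(f"b must be positive, got {b}")
    n_dw = n_total - 1
    dirs = _disperse_axes(_fibonacci_sphere(n_dw))
    rng = np.random.default_rng(seed)
    # random rotation: uniformity is rotation-invariant, so the seed never
    # degrades the configuration
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    dirs = dirs @ q.T
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    samples = [QSample((0.0, 0.0, 0.0), 0.0, (0.0, 0.0, 0.0), True)]
    for d in dirs:
        t = tuple(float(v) for v in d)
        samples.append(QSample(t, float(b), t, False))
    return QScheme(samples, "shell", float(b), name=name or f"shell{n_total}")


def min_axial_angle_deg(directions: np.ndarray) -> float:
    """Smallest pairwise angle between axes (antipodally identified), degrees."""
    d = np.asarray(directions, dtype=float)
    dots = np.abs(d @ d.T)
    np.fill_diagonal(dots, 0.0)
    return float(np.degrees(np.arccos(np.clip(dots.max(), -1.0, 1.0))))


# --- FSL-dialect gradient tables ------------------------------------------


def write_bvals_bvecs(scheme: QScheme, bvals_path, bvecs_path) -> None:
    """One row of b-values; three rows of x/y/z components; b0 rows zero."""
    np.savetxt(bvals_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvecs_path, scheme.gradients.T, fmt="%.9g")


def read_bvals_bvecs(bvals_path, bvecs_path) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(bvals_path).reshape(-1)
    bvecs = np.loadtxt(bvecs_path)
    if bvecs.shape[0] == 3 and bvecs.ndim == 2:
        bvecs = bvecs.T
    if bvecs.shape[0] != bvals.shape[0]:
        raise ValueError(
            f"bvals has {bvals.shape[0]} entries but bvecs has {bvecs.shape[0]} rows"
        )
    return bvals, bvecs


def scheme_from_tables(
    bvals: np.ndarray, bvecs: np.ndarray, kind: str = "shell", name: str = ""
) -> QScheme:
    """Rebuild a QScheme from a gradient table (b0 rows detected by b = 0).

    Non-unit DW rows are renormalized.  For shell schemes read back from
    disk the qvec is taken to be the unit direction itself.
    """
    import warnings

    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    b_max = float(bvals.max())
    samples = []
    for b, g in zip(bvals, bvecs):
        if b == 0:
            samples.append(QSample((0.0, 0.0, 0.0), 0.0, (0.0, 0.0, 0.0), True))
            continue
        norm = float(np.linalg.norm(g))
        if abs(norm - 1.0) > 1e-6:
            warnings.warn(f"renormalizing non-unit gradient row {tuple(g)}")
        g = g / norm
        t = tuple(float(v) for v in g)
        samples.append(QSample(t, float(b), t, False))
    return QScheme(samples, kind, b_max, name=name)
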