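# Methods

## Encoding schemes

A Cartesian (DSI-style) scheme contains the q-space origin plus exactly one
member of every antipodal pair of integer lattice points with |q|² ≤ R².
The retained hemisphere is q_z > 0, falling back to q_y > 0 and then
q_x > 0 on the boundary planes; any antipodal selection is equivalent
because every reconstruction path symmetrizes over antipodes. At fixed
diffusion time the b-value is quadratic in |q|, so a lattice point carries
b = b_max·|q|²/R². R = 5 gives 258 samples and R = 4 gives 129, the
sample counts of the acquisitions being compared (both counts include the
single b0 at the origin — the lattice arithmetic forces that reading).

Shell schemes place one b0 plus n−1 directions at a single b-value.
Directions start on a Fibonacci spiral and are refined by electrostatic
repulsion acting on antipodally symmetrized charges (120 fixed iterations,
bounded step), which optimizes the *axial* arrangement relevant for
diffusion encoding. The construction is deterministic; the seed only
applies a random global rotation, which cannot change uniformity. A
regression property guards the axial resolution: minimum pairwise axial
angle ≥ 60°·√(2/n).

## Phantoms and signal simulation

Phantoms are cylindrical bundles (straight, two-bundle crossing at a
configurable angle, a quarter-circle arc, and a three-bundle 0°/60°/120°
in-plane crossing) rasterized on a small grid, 24³ voxels of 2 mm by
default. Voxels within one radius of a centerline are white matter and
carry the local tangent as a fiber direction; the terminal 4 mm of each
bundle becomes a gray-matter ROI cap instead, so white matter and ROIs are
disjoint and every bundle connects exactly two ROIs. The anisotropic
2.21×2.21×3 mm voxel geometry of the emulated protocol is available
through the configuration; the isotropic default keeps the desk-scale
experiments simple.

The noise-free signal is the standard multi-tensor mixture
S(q) = S0 Σₖ fₖ exp(−b(q)·gᵀDₖg) with axially symmetric tensors.
Defaults: axial/radial diffusivities 1.7×10⁻³ / 0.3×10⁻³ mm²/s (typical
adult white matter), S0 = 100, gray-matter ROIs isotropic at 0.8×10⁻³,
background isotropic at 3.0×10⁻³ (free-water-like). Noise is complex
Gaussian with per-channel standard deviation S0/SNR — SNR is defined on
the b0 signal and spatially uniform — and the magnitude is Rician.
Repeats are combined either by complex averaging (mean of complex values,
then magnitude; noise floor shrinks by √N) or magnitude averaging
(no floor reduction). Everything is reproducible from a single seed.

What the generator does **not** emulate: subject motion, eddy currents,
susceptibility distortion, coil-sensitivity inhomogeneity, partial-volume
T2 effects, axonal dispersion, and realistic cortical geometry. Passing
tests therefore demonstrate correctness of the processing chain and the
direction of model-capacity effects (crossings resolved vs collapsed),
not in vivo effect sizes.

## Reconstruction

**Tensor.** Log-linear least squares on ln(S/S0) over the
diffusion-weighted samples, with S/S0 floored at 10⁻⁴ before the log.
The fit is exact on noiseless consistent data; FA uses eigenvalues clamped
at zero, ADC is the eigenvalue mean. The principal eigenvector is the
single tracking direction; voxels whose two leading eigenvalues differ by
≤ 10⁻⁹ mm²/s are flagged degenerate (the eigendecomposition itself remains
deterministic).

**DSI.** Hemisphere samples and their mirrors are placed on a centered
cubic lattice, windowed by a Hanning taper ½(1 + cos(π|q|/(R+1))),
zero-padded into an odd N³ grid and Fourier transformed; the ODF is the
sum of the propagator magnitude along rays through the center, by
trilinear interpolation, optionally r²-weighted. The default grid is
N = 33 with radii 4–12 grid cells. A minimal N = 17 embedding with radii
2–6 — the smallest grid that contains an R = 5 lattice — was found to
flatten the saddle between the lobes of a 90° crossing into spurious
local maxima (trilinear interpolation at radii of only a few cells); the
two-fold zero-padding samples the same physical propagator range finely
enough that the crossing resolves into exactly its two true peaks. The
closed-form mixture ODF confirms there is no real maximum at the
45° bisector.

**QBI.** Real even spherical harmonics fit to S/S0 by least squares with
Laplace–Beltrami regularization (λ = 0.006), order 8 when the shell has
≥ 45 directions and otherwise the largest feasible even order; the
Funk–Radon transform is applied analytically by scaling degree-l
coefficients with 2π·P_l(0). The FRT of a constant is constant, which the
isotropic-input test asserts.

**Solid-angle ("corrected") QBI.** The same machinery applied to
ln(−ln S/S0) with the signal clamped into [10⁻⁴, 1−10⁻⁴]; degree-l
coefficients are scaled by −P_l(0)·l(l+1)/8π and the l = 0 term is the
constant 1/4π. Sharper than the standard q-ball by construction, which is
asserted on identical input.

**Peaks.** ODF values are min–max normalized per voxel; candidates must
dominate their 1-ring on the tessellation (icosahedron subdivision 3,
642 vertices, ≈ 9.4° edges) and reach a normalized value of 0.4;
antipodal duplicates merge; candidates are kept greedily by value subject
to ≥ 25° pairwise axial separation, up to 3 peaks. A constant ODF yields
zero peaks. These thresholds are exposed in the API because results
depend on them.

## Tractography

Deterministic streamlining in millimeter space: each white-matter voxel
with n_v direction vectors receives 32·n_v seeds uniform inside the voxel;
from each seed two walks start along ±the generating vector (the first
step has no incoming trajectory, so the seed's own vector defines it).
Each 1 mm step follows the current voxel's axial direction closest to the
incoming direction (nearest-neighbor lookup, no interpolation — the
FACT-style convention), sign-aligned with propagation; a walk aborts on
turns sharper than 60°/mm and ends one step after leaving the white-matter
mask, so the endpoint voxel is the first non-WM voxel and its label is the
endpoint label. Retained fibers are 5–200 mm long with both endpoint
labels nonzero. There is no FA or amplitude stopping criterion. All walks
advance in lockstep through vectorized state, and results are
bit-identical for a fixed seed.

## Connectome matrices

M(i,j) counts retained fibers per unordered ROI pair; self-pairs are
discarded (zero diagonal). The connection distance d(i,j) is the shortest
path between ROIs confined to the white matter: a 26-connected graph over
WM voxel centers with Euclidean edge weights, each ROI attached through a
zero-weight virtual node to the WM voxels 6-adjacent to it (6-adjacency
avoids diagonal leakage through corners), solved by multi-source Dijkstra.
Voxel centers rather than surface points define the metric; with 26
connectivity a corner path may take a diagonal, so an L-shaped corridor
with 5 mm legs measures 8+√2 ≈ 9.41 mm. Distance bins are half-open
[lo, hi) with the last bin closed.

## Statistics

Normalized connectivity divides a scan's connection count by the
per-subject mean of the reference replicates, so reference scans average
to exactly 1 per subject. All scan-column pairs get classical paired
t-tests (df = n−1); Bonferroni multiplies by the number of pairs (28 for
eight scans). Scan-rescan variability is the mean over subjects of the
per-subject sample (n−1) standard deviation across replicates — the n−1
convention reproduces the published σ = 229 exactly, so it is taken as
the source convention. The replicate spread is the max over subjects of
(max−min) of mean-normalized replicate counts, which reproduces the
published 5.2%; this is an interpretation, as is the inter-subject
variability (mean over replicates of the across-subject SD, ≈ 553 on the
shipped table), whose published value (533) is not recoverable under any
natural definition we tried and is therefore not asserted. Fiber
limitation subsamples every scheme's fiber set, uniformly without
replacement, to the per-subject minimum F_s before matrices are built.

## Problem sizes and design choices

Phantom experiments use 24³-voxel grids (≈ 700–900 white-matter voxels for
the three-bundle crossing), SNR 20, and ten RNG replicates for the
scheme-ordering check — sizes at which the full four-scheme pipeline runs
in a few seconds per replicate while keeping hundreds of fibers per true
bundle. The qualitative ordering (DSI ≥ QBI ≥ DTI in recovered true
connections, with matched fiber counts) is asserted in ≥ 8 of 10
replicates; the corrected-QBI excess of short (< 40 mm) spurious
connections is asserted in aggregate over the replicates on the raw
(unmatched) fiber sets, since matching removes precisely the seed-count
excess that drives it.

## Known limitations

- Peak directions are tessellation vertices; angular resolution is one
  edge (≈ 9.4° at subdivision 3). No quadratic refinement of maxima.
- The DSI radial projection and the q-ball transforms are unnormalized
  (min–max normalization at peak extraction absorbs scale), so ODF values
  are comparable within a voxel, not across methods.
- Tensor fitting is plain least squares; no weighting, no RESTORE-style
  outlier handling.
- The geodesic metric depends on the rasterized mask at 2 mm; distances
  carry O(voxel diagonal) discretization error.
- With three crossing bundles the center voxels hold three directions,
  the phantom's maximum; more complex configurations would need a larger
  per-voxel direction capacity.
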