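"""End-to-end experiment glue: scheme -> simulate -> reconstruct -> track -> matrices.

``TABLE1_SCHEMES`` mirrors the acquisition protocol being compared: a
full 5-shell Cartesian DSI lattice at b_max 8000 and 6400 s/mm2, a 4-shell
lattice at 6400 (2 averages), a 257-direction single shell at 3000
reconstructed by q-ball, and 65/21-direction DTI shells at 1000 with 4 and
3 averages respectively.  Scan time is emulated by the averaging counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig, SchemeEntry, stage_seed
from .connectome import (
    build_connection_matrix,
    count_connections,
    geodesic_distance_matrix,
)
from .phantom import DWIDataset, PhantomTruth, build_phantom, simulate_dwi
from .reconstruct import (
    csa_odf,
    default_sh_order,
    dsi_odf,
    extract_peaks,
    fit_tensor,
    qbi_odf,
    tensor_peaks,
)
from .schemes import QScheme, cartesian_hemisphere_scheme, uniform_sphere_scheme
from .stats import SchemeRunResult, fiber_limitation
from .tessellation import icosphere
from .tracking import TrackingParams, track_wholebrain

__all__ = [
    "TABLE1_SCHEMES",
    "make_scheme",
    "reconstruct_peaks",
    "run_scheme",
    "run_comparison",
]

TABLE1_SCHEMES: dict[str, SchemeEntry] = {
    e.name: e
    for e in [
        SchemeEntry("DSIq5b8000", "cartesian", "dsi", 8000.0, lattice_radius=5),
        SchemeEntry("DSIq5b6400", "cartesian", "dsi", 6400.0, lattice_radius=5),
        SchemeEntry("DSIq4", "cartesian", "dsi", 6400.0, lattice_radius=4,
                    n_averages=2),
        SchemeEntry("QBI", "shell", "qbi", 3000.0, n_directions=257),
        SchemeEntry("QBIcsa", "shell", "csa", 3000.0, n_directions=257),
        SchemeEntry("DTI65", "shell", "dti", 1000.0, n_directions=65, n_averages=4),
        SchemeEntry("DTI21", "shell", "dti", 1000.0, n_directions=21, n_averages=3),
    ]
}


def make_scheme(entry: SchemeEntry, seed: int = 0) -> QScheme:
    if entry.kind == "cartesian":
        if entry.lattice_radius is None:
            raise ValueError(f"scheme {entry.name}: cartesian needs lattice_radius")
        return cartesian_hemisphere_scheme(
            entry.lattice_radius, entry.b_max, name=entry.name
        )
    if entry.n_directions is None:
        raise ValueError(f"scheme {entry.name}: shell needs n_directions")
    return uniform_sphere_scheme(
        entry.n_directions, entry.b_max, seed=seed, name=entry.name
    )


def reconstruct_peaks(dwi: DWIDataset, method: str, tess=None, sh_order=None):
    """Dispatch to the reconstruction matching the scheme's model."""
    tess = tess or icosphere(3)
    if method == "dti":
        return tensor_peaks(fit_tensor(dwi))
    if method == "dsi":
        return extract_peaks(dsi_odf(dwi, tess))
    if method in ("qbi", "csa"):
        order = sh_order or default_sh_order(dwi.scheme.n_dw)
        odf = (qbi_odf if method == "qbi" else csa_odf)(dwi, tess, sh_order=order)
        return extract_peaks(odf)
    raise ValueError(f"unknown reconstruction method: {method!r}")


def run_scheme(
    truth: PhantomTruth,
    entry: SchemeEntry,
    snr: float,
    seed: int,
    params: TrackingParams | None = None,
    tess=None,
    sh_order=None,
    subject="phantom",
) -> SchemeRunResult:
    """Simulate, reconstruct and track one scheme on one phantom."""
    scheme = make_scheme(entry, seed=stage_seed(seed, f"dirs/{entry.name}"))
    dwi = simulate_dwi(
        truth, scheme, snr=snr,
        n_averages=entry.n_averages, averaging=entry.averaging,
        seed=stage_seed(seed, f"noise/{entry.name}"),
    )
    peaks = reconstruct_peaks(dwi, entry.method, tess=tess, sh_order=sh_order)
    params = params or TrackingParams()
    tracking = TrackingParams(
        step=params.step, max_turn=params.max_turn,
        seeds_per_vector=params.seeds_per_vector,
        min_len=params.min_len, max_len=params.max_len,
        rng_seed=stage_seed(seed, f"track/{entry.name}"),
    )
    sset = track_wholebrain(peaks, truth.wm_mask, truth.roi_labels, tracking)
    M = build_connection_matrix(sset, truth.roi_ids)
    return SchemeRunResult(
        scheme=entry.name,
        subject=subject,
        connection_count=count_connections(M),
        fiber_count=sset.count,
        matrix=M,
        streamlines=sset,
    )


def run_comparison(cfg: PipelineConfig, seed: int | None = None) -> dict:
    """Run every configured scheme on the phantom; optionally apply fiber
    limitation before matrices.  Returns runs, matrices and the distance
    matrix, all keyed by scheme name."""
    seed = cfg.rng_seed if seed is None else seed
    truth = build_phantom(cfg.phantom)
    tess = icosphere(3)
    runs = {
        e.name: run_scheme(truth, e, cfg.snr, seed, cfg.tracking, tess, cfg.sh_order)
        for e in cfg.schemes
    }
    if cfg.fiber_limit and len(runs) >= 2:
        limited = fiber_limitation(
            {k: r.streamlines for k, r in runs.items()},
            rng_seed=stage_seed(seed, "fiber_limitation"),
        )
        for k, r in runs.items():
            sset = limited[k]
            M = build_connection_matrix(sset, truth.roi_ids)
            r.streamlines = sset
            r.fiber_count = sset.count
            r.matrix = M
            r.connection_count = count_connections(M, cfg.n_f)
    D = geodesic_distance_matrix(truth.wm_mask, truth.roi_labels, truth.voxel_size)
    for r in runs.values():
        r.distances = D
    return {"truth": truth, "runs": runs, "distances": D, "seed": seed}
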