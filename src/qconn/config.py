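"""Pipeline configuration and reproducible seed derivation.

One top-level seed is fanned out to per-stage child seeds by stable
hashing of the stage name, so every randomized stage (sphere points,
noise, seeding, subsampling) is reproducible independently of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .phantom import PhantomConfig
from .tracking import TrackingParams

__all__ = ["PipelineConfig", "SchemeEntry", "stage_seed", "load_config"]


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic child seed for a named stage; always < 2**31."""
    ss = np.random.SeedSequence([int(base_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SchemeEntry:
    """One acquisition to simulate + the reconstruction applied to it."""

    name: str
    kind: str  # cartesian | shell
    method: str  # dsi | qbi | csa | dti
    b_max: float
    lattice_radius: int | None = None  # cartesian
    n_directions: int | None = None  # shell: total samples incl. b0
    n_averages: int = 1
    averaging: str = "complex"


@dataclass
class PipelineConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    schemes: list[SchemeEntry] = field(default_factory=list)
    snr: float = 20.0
    tracking: TrackingParams = field(default_factory=TrackingParams)
    reference: str = "DSIq5b8000"
    n_f: int = 1
    bins: tuple = (0.0, 50.0, 100.0, 200.0)
    rng_seed: int = 0
    sh_order: int | None = None  # None: largest feasible even order up to 8
    fiber_limit: bool = True

    def __post_init__(self) -> None:
        names = [s.name for s in self.schemes]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate scheme names in config: {names}")


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    if "phantom" in raw:
        ph = dict(raw["phantom"])
        for key in ("grid_shape", "voxel_size", "diffusivities"):
            if key in ph:
                ph[key] = tuple(ph[key])
        kwargs["phantom"] = PhantomConfig(**ph)
    if "schemes" in raw:
        kwargs["schemes"] = [SchemeEntry(**s) for s in raw["schemes"]]
    if "tracking" in raw:
        kwargs["tracking"] = TrackingParams(**raw["tracking"])
    for key in ("snr", "reference", "n_f", "rng_seed", "sh_order", "fiber_limit"):
        if key in raw:
            kwargs[key] = raw[key]
    if "bins" in raw:
        kwargs["bins"] = tuple(raw["bins"])
    return PipelineConfig(**kwargs)
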