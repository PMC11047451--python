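"""JSON configuration with full defaults and fail-fast validation.

Any key absent from a user file falls back to the default; unknown keys are
errors.  All coordinates and thresholds are SI; the seed makes every
downstream computation reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class ForwardConfig:
    model: str = "three_shell_sphere"  # {homogeneous, three_shell_sphere, imported}
    conductivities: tuple = (0.33, 0.0042, 0.33)  # S/m: brain, skull, scalp
    radii: tuple = (0.079, 0.082, 0.088, 0.092)  # m: cortex..scalp fixtures
    n_terms: int = 60
    constrain_normals: bool = True


@dataclass
class QCConfig:
    sensor_corr_threshold: float = 0.7
    source_corr_threshold: float = 0.33
    min_distance_m: float = 0.002
    max_iterations: int = 3
    flag_mode: str = "any"  # {any, all}


@dataclass
class SpectralConfig:
    fmax_hz: float = 50.0
    df_hz: float = 0.5
    bandwidth_hz: float = 1.0
    segment_length: int = 400
    transform: str = "bfht"  # {fft, gfht, bfht}


@dataclass
class InverseConfig:
    method: str = "sssbl"  # {sssbl, eloreta, lcmv}
    type2: str = "hglasso"  # {hglasso, hgridge}
    alpha1: float = 1.0  # quasinorm (sqrt) penalty weight
    alpha2: float = 0.0  # nuclear (linear) penalty weight
    alpha_graph: float = 0.1
    noise_variance: float | None = None  # None: estimated from the data
    max_iter: int = 500
    tolerance: float = 1e-6
    support_threshold: float = 0.95


@dataclass
class PriorsConfig:
    field: bool = False
    curvature: bool = False
    laplacian: bool = False
    parcellation: bool = False
    slope_gyri: float = 0.5
    intercept_gyri: float = 1.0
    slope_sulci: float = 0.5
    intercept_sulci: float = 1.0
    laplacian_deformation: float = 1e-3


@dataclass
class ComparisonConfig:
    n_permutations: int = 1000
    alpha: float = 0.01
    statistic: str = "mean_diff"  # {mean_diff, t_like}


@dataclass
class Config:
    forward: ForwardConfig = field(default_factory=ForwardConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    inverse: InverseConfig = field(default_factory=InverseConfig)
    priors: PriorsConfig = field(default_factory=PriorsConfig)
    comparison: ComparisonConfig = field(default_factory=ComparisonConfig)
    seed: int = 0

    def validate(self) -> None:
        qc = self.qc
        for name in ("sensor_corr_threshold", "source_corr_threshold"):
            v = getattr(qc, name)
            if not (0 < v <= 1):
                raise ValueError(f"qc.{name} must be in (0, 1]")
        if qc.max_iterations < 1:
            raise ValueError("qc.max_iterations must be >= 1")
        sp = self.spectral
        if sp.fmax_hz <= 0 or sp.df_hz <= 0 or sp.bandwidth_hz <= 0:
            raise ValueError("spectral frequencies must be positive")
        if self.comparison.alpha <= 0 or self.comparison.alpha >= 1:
            raise ValueError("comparison.alpha must be in (0, 1)")
        if self.comparison.n_permutations < 1:
            raise ValueError("comparison.n_permutations must be >= 1")
        fwd = self.forward
        if any(c <= 0 for c in fwd.conductivities):
            raise ValueError("conductivities must be positive")
        if any(b <= a for a, b in zip(fwd.radii, fwd.radii[1:])):
            raise ValueError("forward.radii must be strictly ascending")


def _merge(dc, data: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(dc)}
    for key, val in data.items():
        if key not in names:
            raise KeyError(f"unknown configuration key {path}{key!r}")
        cur = getattr(dc, key)
        if dataclasses.is_dataclass(cur) and isinstance(val, dict):
            _merge(cur, val, f"{path}{key}.")
        elif isinstance(cur, tuple) and isinstance(val, (list, tuple)):
            setattr(dc, key, tuple(val))
        else:
            setattr(dc, key, val)


def load_config(path: str | None = None, overrides: dict | None = None) -> Config:
    """Build a configuration: defaults, optionally updated from a JSON file
    and/or an overrides mapping.  Unknown keys raise."""
    cfg = Config()
    if path is not None:
        with open(path) as fh:
            data = json.load(fh)
        _merge(cfg, data, "")
    if overrides:
        _merge(cfg, overrides, "")
    cfg.validate()
    return cfg


def dump_config(cfg: Config, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=1)
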