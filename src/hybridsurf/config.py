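"""Run configuration: every stage parameter with its default, in one place.

Configs load from TOML or YAML; unknown keys are rejected so a typo cannot
silently fall back to a default.  The effective configuration is echoed into
every report for full provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class SmoothingConfig:
    """Taubin smoothing of the marching-cubes mesh (staircase removal)."""

    enabled: bool = True
    iterations: int = 20
    lamb: float = 0.5
    mu: float = -0.53


@dataclass
class MPUConfig:
    """MPU implicit parameters.

    ``tol`` (mm) is the smoothness/accuracy knob; ``resolution`` (mm) is the
    polygonization grid step (None: half the smallest voxel spacing).
    """

    tol: float = 0.5
    max_depth: int = 8
    alpha: float = 0.75
    n_min: int = 15
    resolution: float | None = None


@dataclass
class HybridConfig:
    """Selection/merge/refit parameters.

    ``weld_tol`` (mm) merges shared vertices (None: 1e-6 x bounding-box
    diagonal); ``refit_tol`` (mm) is the final MPU tolerance (None: a
    quarter of the smallest voxel spacing — the merged cloud is dense, so a
    very small tolerance suffices); ties in the selection go to ``tie_rule``
    ("fe" by default); ``symmetric`` adds the FE -> MPU matching direction.
    """

    weld_tol: float | None = None
    refit_tol: float | None = None
    tie_rule: str = "fe"
    symmetric: bool = False


@dataclass
class MetricsConfig:
    thresholds: tuple[float, ...] = (0.5, 1.0)
    sampling_density: float = 10.0  # Hausdorff samples per mm^2


@dataclass
class RunConfig:
    """Full pipeline configuration."""

    isovalue: float = 0.5
    pad_mask: bool = True
    normal_sigma: float = 1.0  # voxels, Gaussian width for normal estimation
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    mpu: MPUConfig = field(default_factory=MPUConfig)
    hybrid: HybridConfig = field(default_factory=HybridConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls()
        _apply(cfg, data, path="")
        return cfg

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text) or {}
        elif path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(text)
        else:
            raise ValueError(f"unsupported config format {path.suffix!r} (use TOML or YAML)")
        return cls.from_dict(data)


def _apply(obj, data: dict, path: str) -> None:
    if not isinstance(data, dict):
        raise ValueError(f"config section {path or '<root>'} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in fields:
            raise ValueError(f"unknown config key {path + key!r}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current):
            _apply(current, value, path=f"{path}{key}.")
        else:
            if key == "thresholds":
                value = tuple(float(v) for v in value)
            setattr(obj, key, value)
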