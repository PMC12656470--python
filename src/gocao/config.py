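"""Pipeline configuration: defaults, TOML/YAML loading, validation.

Every knob of the registration pipeline lives here with its default; a config
file (TOML or YAML) may override any subset, and unknown keys are rejected by
name so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

from .exceptions import ConfigError

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class GaborConfig:
    n_orientations: int = 8
    sigmas: tuple = (2.0, 4.0, 8.0)
    ir_sigmas: tuple = (8.0, 12.0)  # coarser bank for the low-resolution side
    gamma: float = 0.5


@dataclass
class OrdinalConfig:
    omega: float = 3.0        # flank-lobe offset, px
    sigma_p: float = 1.0      # center-lobe scale, px
    sigma_n: float = 1.0      # flank-lobe scale, px


@dataclass
class ContourConfig:
    threshold_rule: str = "zero-crossing"
    percentile: float = 98.0
    min_length: int = 40
    css_sigmas: tuple = (2.0, 4.0, 6.0)
    curvature_threshold: float = 0.05  # px^-1
    nms_separation: int = 5
    arm_length: int = 20


@dataclass
class DescriptorConfig:
    vis_radii: tuple = (24.0, 32.0, 48.0)
    ir_radius: float = 32.0
    smooth_sigma: float = 8.0  # map smoothing before descriptor gradients, px
    ratio: float = 1.0  # nearest/second-nearest threshold; 1.0 = mutual-NN only


@dataclass
class RansacConfig:
    iterations: int = 2000
    tol: float = 5.0  # inlier reprojection tolerance, px (visible scale)
    seed: int = 0
    min_inliers: int = 4


@dataclass
class RefineConfig:
    window: int = 10        # search half-width, px
    patch_radius: int = 16  # ZNCC template half-width, px
    smooth_sigma: float = 4.0  # map smoothing before correlation, px
    iterations: int = 2     # refine/refit sweeps


@dataclass
class PipelineConfig:
    gabor: GaborConfig = field(default_factory=GaborConfig)
    ordinal: OrdinalConfig = field(default_factory=OrdinalConfig)
    contours: ContourConfig = field(default_factory=ContourConfig)
    descriptors: DescriptorConfig = field(default_factory=DescriptorConfig)
    ransac: RansacConfig = field(default_factory=RansacConfig)
    refine: RefineConfig = field(default_factory=RefineConfig)
    metric_radius: float = 5.0  # correct-match rule, px
    normalize_maps: bool = True

    def validate(self) -> "PipelineConfig":
        checks = [
            (self.metric_radius > 0, "metric_radius must be > 0"),
            (all(s > 0 for s in self.gabor.sigmas), "gabor.sigmas must be > 0"),
            (self.gabor.n_orientations >= 1, "gabor.n_orientations must be >= 1"),
            (self.ordinal.sigma_p > 0 and self.ordinal.sigma_n > 0, "ordinal sigmas must be > 0"),
            (self.contours.min_length >= 3, "contours.min_length must be >= 3"),
            (self.contours.curvature_threshold > 0, "contours.curvature_threshold must be > 0"),
            (self.contours.arm_length >= 1, "contours.arm_length must be >= 1"),
            (0 < self.descriptors.ratio <= 1 or self.descriptors.ratio == 0,
             "descriptors.ratio must be in [0, 1]"),
            (self.ransac.iterations >= 1, "ransac.iterations must be >= 1"),
            (self.ransac.tol > 0, "ransac.tol must be > 0"),
            (self.refine.window >= 1, "refine.window must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)
        return self

    def as_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "gabor": GaborConfig,
    "ordinal": OrdinalConfig,
    "contours": ContourConfig,
    "descriptors": DescriptorConfig,
    "ransac": RansacConfig,
    "refine": RefineConfig,
}
_SCALARS = {"metric_radius", "normalize_maps"}


def _apply(cfg: PipelineConfig, data: dict) -> PipelineConfig:
    for key, value in data.items():
        if key in _SCALARS:
            setattr(cfg, key, value)
        elif key in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a table/mapping")
            section = getattr(cfg, key)
            valid = {f.name for f in fields(section)}
            for sub, subval in value.items():
                if sub not in valid:
                    raise ConfigError(f"unknown config key {key}.{sub!r}")
                if isinstance(subval, list):
                    subval = tuple(subval)
                setattr(section, sub, subval)
        else:
            raise ConfigError(f"unknown config key {key!r}")
    return cfg


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Defaults, optionally merged with a TOML/YAML file and a flat override
    mapping ("section.key" -> value, applied last)."""
    cfg = PipelineConfig()
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        if path.suffix.lower() == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        elif path.suffix.lower() in (".yml", ".yaml"):
            import yaml

            data = yaml.safe_load(path.read_text()) or {}
        else:
            raise ConfigError(f"unsupported config format: {path.suffix}")
        _apply(cfg, data)
    if overrides:
        nested: dict = {}
        for dotted, value in overrides.items():
            parts = dotted.split(".")
            if len(parts) == 1:
                nested[parts[0]] = value
            elif len(parts) == 2:
                nested.setdefault(parts[0], {})[parts[1]] = value
            else:
                raise ConfigError(f"bad override key {dotted!r}")
        _apply(cfg, nested)
    return cfg.validate()
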