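"""Run configuration: tunable parameters, defaults, validation, YAML loading.

Every knob of the pipeline lives here so that a single YAML file (or a
single :class:`TrackerConfig` instance) fully determines a run.  Ranges are
checked eagerly; a bad value raises :class:`ConfigError` naming the key and
its legal range.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """A configuration value is missing, unknown, or out of range."""


@dataclass
class IoConfig:
    #: detections with confidence below this floor are dropped at ingest
    conf_floor: float = 0.1

    def validate(self) -> None:
        if not 0.0 <= self.conf_floor <= 1.0:
            raise ConfigError(f"io.conf_floor={self.conf_floor}: legal range is [0, 1]")


@dataclass
class KalmanConfig:
    #: position noise weight (dimensionless, scales with box size)
    w_p: float = 1.0 / 20.0
    #: velocity noise weight (dimensionless)
    w_v: float = 1.0 / 160.0
    #: fading-memory (forgetting-factor) bounds
    lambda_min: float = 0.6
    lambda_max: float = 1.0
    #: residual sensitivity of the forgetting factor, px^-2
    gamma: float = 0.01
    #: divide the squared residual by trace(H C- H^T + S) before the
    #: forgetting factor (scale-invariant variant); off = raw pixel^2 norm
    residual_normalized: bool = False
    #: initialize the covariance with distinct per-component sigmas instead
    #: of the isotropic summed sigma_p^2 / sigma_v^2 blocks
    per_component_init: bool = False

    def validate(self) -> None:
        if not (0.0 < self.lambda_min <= self.lambda_max <= 1.0):
            raise ConfigError(
                f"kalman.lambda_min={self.lambda_min}, kalman.lambda_max={self.lambda_max}: "
                "legal range is 0 < lambda_min <= lambda_t <= lambda_max <= 1"
            )
        if self.gamma < 0:
            raise ConfigError(f"kalman.gamma={self.gamma}: legal range is gamma >= 0")
        if self.w_p <= 0 or self.w_v <= 0:
            raise ConfigError(
                f"kalman.w_p={self.w_p}, kalman.w_v={self.w_v}: weights must be > 0"
            )


@dataclass
class RansacConfig:
    max_iters: int = 100
    inlier_tol: float = 3.0  # px
    min_samples: int = 3
    min_inlier_frac: float = 0.5

    def validate(self) -> None:
        if self.max_iters < 1:
            raise ConfigError(f"camera.ransac.max_iters={self.max_iters}: must be >= 1")
        if self.inlier_tol <= 0:
            raise ConfigError(f"camera.ransac.inlier_tol={self.inlier_tol}: must be > 0")
        if self.min_samples < 3:
            raise ConfigError(f"camera.ransac.min_samples={self.min_samples}: must be >= 3")
        if not 0.0 < self.min_inlier_frac <= 1.0:
            raise ConfigError(
                f"camera.ransac.min_inlier_frac={self.min_inlier_frac}: legal range is (0, 1]"
            )


@dataclass
class CameraConfig:
    #: apply camera-motion compensation to predicted boxes
    enabled: bool = True
    #: correspondence source: "sidecar" (file only), "detections"
    #: (mutual-nearest-neighbour detection centres), or "auto" (sidecar when
    #: present, detection centres otherwise)
    source: str = "auto"
    #: divide width/height by the scale factors instead of multiplying
    #: (dimensionally consistent variant under zoom)
    inverse_scale: bool = False
    ransac: RansacConfig = field(default_factory=RansacConfig)

    def validate(self) -> None:
        if self.source not in ("sidecar", "detections", "auto"):
            raise ConfigError(
                f"camera.source={self.source!r}: legal values are sidecar|detections|auto"
            )
        self.ransac.validate()


@dataclass
class AssocConfig:
    #: spatial gate: IoU distances above this are inadmissible
    theta_iou: float = 0.7
    #: appearance gate: cosine distances above this veto appearance fusion
    theta_reid: float = 0.25
    #: fused costs above this demote a solved match to unmatched
    match_gate: float = 0.8
    #: EMA smoothing coefficient for track appearance features
    alpha: float = 0.9
    #: drop appearance-vetoed pairs entirely instead of falling back to IoU
    strict_reid_filter: bool = False

    def validate(self) -> None:
        if not 0.0 < self.theta_iou <= 1.0:
            raise ConfigError(f"assoc.theta_iou={self.theta_iou}: legal range is (0, 1]")
        if self.theta_reid < 0:
            raise ConfigError(f"assoc.theta_reid={self.theta_reid}: must be >= 0")
        if self.match_gate <= 0:
            raise ConfigError(f"assoc.match_gate={self.match_gate}: must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"assoc.alpha={self.alpha}: legal range is 0 < alpha < 1")


@dataclass
class LifecycleConfig:
    #: consecutive hits before a tentative track is confirmed
    n_init: int = 3
    #: consecutive misses before a lost track is removed (30 frames = 3 s at 10 fps)
    max_age: int = 30
    #: optional second association stage on low-confidence detections
    two_stage: bool = False
    #: confidence split between the stages when two_stage is on
    high_conf: float = 0.6

    def validate(self) -> None:
        if self.n_init < 1:
            raise ConfigError(f"tracker.n_init={self.n_init}: must be >= 1")
        if self.max_age < 1:
            raise ConfigError(f"tracker.max_age={self.max_age}: must be >= 1")
        if not 0.0 <= self.high_conf <= 1.0:
            raise ConfigError(f"tracker.high_conf={self.high_conf}: legal range is [0, 1]")


@dataclass
class TrackerConfig:
    """Complete, validated parameter set for a tracking run."""

    io: IoConfig = field(default_factory=IoConfig)
    kalman: KalmanConfig = field(default_factory=KalmanConfig)
    camera: CameraConfig = field(default_factory=CameraConfig)
    assoc: AssocConfig = field(default_factory=AssocConfig)
    tracker: LifecycleConfig = field(default_factory=LifecycleConfig)
    seed: int = 0

    def validate(self) -> "TrackerConfig":
        for section in (self.io, self.kalman, self.camera, self.assoc, self.tracker):
            section.validate()
        return self


_SECTIONS = {
    "io": IoConfig,
    "kalman": KalmanConfig,
    "camera": CameraConfig,
    "assoc": AssocConfig,
    "tracker": LifecycleConfig,
}


def _build(cls, mapping: dict, prefix: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in mapping.items():
        if key not in fields:
            raise ConfigError(f"unknown config key {prefix}{key}")
        if key == "ransac":
            if not isinstance(value, dict):
                raise ConfigError(f"{prefix}ransac must be a mapping")
            kwargs[key] = _build(RansacConfig, value, prefix + "ransac.")
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc


def config_from_dict(data: dict | None) -> TrackerConfig:
    """Build and validate a :class:`TrackerConfig` from a nested dict."""
    data = dict(data or {})
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.pop(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"config section {name!r} must be a mapping")
        kwargs[name] = _build(cls, section, name + ".")
    if "seed" in data:
        kwargs["seed"] = int(data.pop("seed"))
    if data:
        raise ConfigError(f"unknown config section(s): {sorted(data)}")
    return TrackerConfig(**kwargs).validate()


def load_config(path: str | Path | None) -> TrackerConfig:
    """Load a YAML run configuration, filling defaults and checking ranges.

    ``None`` or an empty file yields the full default parameter set.
    """
    if path is None:
        return TrackerConfig().validate()
    raw = Path(path).read_text()
    data = yaml.safe_load(raw)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a YAML mapping")
    return config_from_dict(data)
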