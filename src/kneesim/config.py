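"""Configuration loading, validation and results serialization.

One YAML file configures the whole pipeline.  Every section mirrors a
model component; omitted fields fall back to the documented defaults
(strain limit 0.03, friction 0.01, 70 kg / 1.72 m, 1 s cycle, 0.02 s
step, 0.01 mm / 0.1 deg tolerances; geometry, stiffness and PCSA tables
are literature-typical calibration values — see docs/methods.md).
Unknown keys are rejected with the offending field path.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dynamics import ContactParams, SimulationResult
from .errors import ConfigError, ResultIOError
from .experiments import (ANALYSIS_WINDOW_DEFAULT, HAMSTRING_FACTORS_DEFAULT,
                          PCL_FACTORS_DEFAULT, ModelBundle)
from .gait import GaitCycle, GaitGenParams, generate_gait_cycle
from .geometry import BodyParams, KneeGeometry, default_geometry
from .ligaments import (DEFAULT_LIGAMENT_STIFFNESS, DEFAULT_STRAIN_LIMIT,
                        default_ligament_set)
from .muscles import DEFAULT_PCSA, default_muscle_set

__all__ = [
    "RunConfig",
    "load_config",
    "write_config",
    "default_config",
    "build_bundle",
    "build_gait",
    "write_result",
    "read_result",
]

_DATA = Path(__file__).parent / "data"


@dataclass
class GaitConfig:
    n_samples: int = 100
    body_mass: float = 70.0
    stance_knee_peak: float = 18.0
    swing_knee_peak: float = 64.0
    knee_min: float = 3.0
    toe_off_fraction: float = 0.60
    noise_sd: float = 0.5
    seed: int = 0


@dataclass
class GeometryConfig:
    condyle_radius: float = 25.0
    dish_radius: float = 35.0
    dish_rim_slope: float = 0.095
    plateau_slope: float = 0.0
    thigh_length: float = 420.0
    sites: dict = field(default_factory=dict)  # name -> [x, y] overrides


@dataclass
class BodyConfig:
    body_mass: float = 70.0
    height: float = 1.72
    shank_mass_fraction: float = 0.0465
    foot_mass_fraction: float = 0.0145
    shank_length_fraction: float = 0.246
    thigh_length_fraction: float = 0.245
    shank_com_fraction: float = 0.433
    shank_gyration_fraction: float = 0.302
    foot_com_offset: float = 0.05
    gravity: float = 9.81


@dataclass
class LigamentConfig:
    strain_limit: float = DEFAULT_STRAIN_LIMIT
    toe_transition: str = "at_limit"
    stiffness: dict = field(default_factory=dict)         # per-ligament overrides
    reference_strain: dict = field(default_factory=dict)  # per-bundle overrides


@dataclass
class MuscleConfig:
    pcsa: dict = field(default_factory=dict)  # per-muscle overrides


@dataclass
class ContactConfig:
    friction_mu: float = 0.01
    restitution: float = 0.0
    contact_stiffness: float = 4.0e4
    contact_damping_ratio: float = 1.0
    slip_velocity: float = 1.0
    tissue_damping: float = 0.8


@dataclass
class IntegratorConfig:
    dt: float = 0.02
    n_cycles: int = 2
    tolerance_translation: float = 0.01
    tolerance_rotation: float = 0.1


@dataclass
class SweepConfig:
    pcl_factors: list = field(default_factory=lambda: list(PCL_FACTORS_DEFAULT))
    hamstring_factors: list = field(
        default_factory=lambda: list(HAMSTRING_FACTORS_DEFAULT))
    pcl_residual: float = 0.15
    window: list = field(default_factory=lambda: list(ANALYSIS_WINDOW_DEFAULT))
    trend_degree: int = 2


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "results"
    gait: GaitConfig = field(default_factory=GaitConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    body: BodyConfig = field(default_factory=BodyConfig)
    ligaments: LigamentConfig = field(default_factory=LigamentConfig)
    muscles: MuscleConfig = field(default_factory=MuscleConfig)
    contact: ContactConfig = field(default_factory=ContactConfig)
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)


_SECTIONS = {
    "gait": GaitConfig, "geometry": GeometryConfig, "body": BodyConfig,
    "ligaments": LigamentConfig, "muscles": MuscleConfig,
    "contact": ContactConfig, "integrator": IntegratorConfig,
    "sweep": SweepConfig,
}

_RANGES = {
    # field path -> (low, high, low_inclusive, high_inclusive)
    "gait.toe_off_fraction": (0.0, 1.0, False, False),
    "gait.noise_sd": (0.0, None, True, True),
    "gait.n_samples": (50, None, True, True),
    "geometry.condyle_radius": (0.0, None, False, True),
    "geometry.dish_rim_slope": (0.0, None, False, True),
    "body.body_mass": (0.0, None, False, True),
    "body.height": (0.0, None, False, True),
    "ligaments.strain_limit": (0.0, None, False, True),
    "contact.friction_mu": (0.0, None, True, True),
    "contact.contact_stiffness": (0.0, None, False, True),
    "contact.tissue_damping": (0.0, None, True, True),
    "integrator.dt": (0.0, None, False, True),
    "integrator.n_cycles": (1, None, True, True),
    "integrator.tolerance_translation": (0.0, None, False, True),
    "sweep.pcl_residual": (0.0, 1.0, False, True),
    "sweep.trend_degree": (0, None, True, True),
}


def _check_range(path: str, value) -> None:
    spec = _RANGES.get(path)
    if spec is None:
        return
    lo, hi, lo_inc, hi_inc = spec
    ok = True
    if lo is not None:
        ok &= (value >= lo) if lo_inc else (value > lo)
    if hi is not None:
        ok &= (value <= hi) if hi_inc else (value < hi)
    if not ok:
        bounds = f"[{lo}, {hi}]" if lo_inc and hi_inc else f"({lo}, {hi})"
        raise ConfigError(f"value {value!r} outside allowed range {bounds}",
                          field=path)


def _build_section(cls, mapping: dict, path: str):
    obj = cls()
    known = set(obj.__dataclass_fields__)
    for key, value in (mapping or {}).items():
        if key not in known:
            raise ConfigError(f"unknown key (known: {sorted(known)})",
                              field=f"{path}.{key}")
        _check_range(f"{path}.{key}", value)
        setattr(obj, key, value)
    return obj


def _config_from_mapping(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    cfg = RunConfig()
    known_top = set(cfg.__dataclass_fields__)
    for key, value in raw.items():
        if key not in known_top:
            raise ConfigError(f"unknown key (known: {sorted(known_top)})",
                              field=key)
        if key in _SECTIONS:
            setattr(cfg, key, _build_section(_SECTIONS[key], value, key))
        else:
            setattr(cfg, key, value)
    _cross_validate(cfg)
    return cfg


def _cross_validate(cfg: RunConfig) -> None:
    if cfg.geometry.dish_radius <= cfg.geometry.condyle_radius:
        raise ConfigError("dish_radius must exceed condyle_radius",
                          field="geometry.dish_radius")
    unknown = set(cfg.ligaments.stiffness) - set(DEFAULT_LIGAMENT_STIFFNESS)
    if unknown:
        raise ConfigError(f"unknown ligaments {sorted(unknown)}",
                          field="ligaments.stiffness")
    unknown = set(cfg.muscles.pcsa) - set(DEFAULT_PCSA)
    if unknown:
        raise ConfigError(f"unknown muscles {sorted(unknown)}",
                          field="muscles.pcsa")
    if cfg.ligaments.toe_transition not in ("at_limit", "double_limit"):
        raise ConfigError("must be at_limit|double_limit",
                          field="ligaments.toe_transition")
    lo, hi = cfg.sweep.window
    if not (0.0 <= lo < hi <= 1.0):
        raise ConfigError("window must satisfy 0 <= lo < hi <= 1",
                          field="sweep.window")
    for f in list(cfg.sweep.pcl_factors) + list(cfg.sweep.hamstring_factors):
        if not (0.0 < f <= 1.0):
            raise ConfigError(f"sweep factor {f} outside (0, 1]",
                              field="sweep")


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: cannot parse YAML: {exc}") from exc
    return _config_from_mapping(raw or {})


def write_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a configuration; load(write(cfg)) round-trips."""
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))


def default_config() -> RunConfig:
    """The shipped default configuration."""
    return load_config(_DATA / "default_config.yaml")


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

def build_gait(cfg: RunConfig) -> GaitCycle:
    g = cfg.gait
    params = GaitGenParams(
        body_mass=g.body_mass, stance_knee_peak=g.stance_knee_peak,
        swing_knee_peak=g.swing_knee_peak, knee_min=g.knee_min,
        toe_off_fraction=g.toe_off_fraction, noise_sd=g.noise_sd,
        seed=g.seed if g.seed is not None else cfg.seed)
    return generate_gait_cycle(params, g.n_samples)


def build_bundle(cfg: RunConfig, gait: GaitCycle | None = None) -> ModelBundle:
    """Assemble the full model from a validated configuration."""
    geo_c = cfg.geometry
    geometry = default_geometry()
    geometry.condyle_radius = geo_c.condyle_radius
    geometry.dish_radius = geo_c.dish_radius
    geometry.dish_rim_slope = geo_c.dish_rim_slope
    geometry.plateau_slope = geo_c.plateau_slope
    geometry.thigh_length = geo_c.thigh_length
    if geo_c.sites:
        geometry = geometry.with_sites(**{k: tuple(v) for k, v in geo_c.sites.items()})

    body = BodyParams(**asdict(cfg.body))
    ligaments = default_ligament_set(
        geometry,
        stiffness_table=cfg.ligaments.stiffness or None,
        strain_limit=cfg.ligaments.strain_limit,
        reference_strain=cfg.ligaments.reference_strain or None,
        toe_transition=cfg.ligaments.toe_transition)
    muscles = default_muscle_set(pcsa_table=cfg.muscles.pcsa or None)
    contact = ContactParams(
        friction_mu=cfg.contact.friction_mu,
        restitution=cfg.contact.restitution,
        contact_stiffness=cfg.contact.contact_stiffness,
        contact_damping_ratio=cfg.contact.contact_damping_ratio,
        slip_velocity=cfg.contact.slip_velocity,
        tissue_damping=cfg.contact.tissue_damping,
        config_tolerance_translation=cfg.integrator.tolerance_translation,
        config_tolerance_rotation=cfg.integrator.tolerance_rotation)
    if gait is None:
        gait = build_gait(cfg)
    return ModelBundle(geometry=geometry, ligaments=ligaments, muscles=muscles,
                       gait=gait, body=body, contact=contact,
                       n_cycles=cfg.integrator.n_cycles, dt=cfg.integrator.dt)


# ---------------------------------------------------------------------------
# Results I/O
# ---------------------------------------------------------------------------

def write_result(result: SimulationResult, path: str | Path) -> None:
    """Write a simulation as tidy CSV plus a JSON metadata sidecar
    (``<path>.meta.json``)."""
    path = Path(path)
    frame = result.to_frame()
    if frame.empty:
        raise ResultIOError("refusing to write an empty result")
    try:
        frame.to_csv(path, index=False, float_format="%.10g")
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(result.metadata, indent=2, default=str))
    except OSError as exc:
        raise ResultIOError(f"cannot write {path}: {exc}") from exc


def read_result(path: str | Path):
    """Read back a tidy results CSV and its metadata sidecar as
    (wide DataFrame indexed by cycle_fraction, metadata dict)."""
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise ResultIOError(f"results file not found: {path}")
    frame = pd.read_csv(path)
    needed = {"cycle_fraction", "variable", "value", "units"}
    if not needed.issubset(frame.columns):
        raise ResultIOError(f"{path}: missing columns {sorted(needed - set(frame.columns))}")
    wide = frame.pivot(index="cycle_fraction", columns="variable", values="value")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return wide, meta
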