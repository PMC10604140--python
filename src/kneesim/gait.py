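"""Synthetic gait-cycle generator.

Produces the driving signals for the knee model: sagittal joint angles
(hip, knee, ankle) and ground-reaction-force components over one
time-normalized stride of 1 s, with the canonical structure of level
walking — stance ending at toe-off near 60 % of the cycle, a small
knee-flexion wave in stance and a large one in swing, a double-bump
vertical GRF, and a braking-then-propulsion anteroposterior GRF.

Waveforms are built from periodic von-Mises bumps.  A wrapped bump
``exp(kappa*(cos(2*pi*(t-c)) - 1))`` is smooth, 1-periodic and unimodal,
so a knee curve made of two well-separated bumps has exactly two local
maxima by construction — the structural feature the downstream
experiments rely on (hamstring demand arises from braking the large
swing wave).  Stochastic variability is injected as amplitude/baseline
jitter rather than additive white noise, so the waveform topology
survives any noise draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ParameterError, ResultIOError

__all__ = [
    "GaitGenParams",
    "GaitCycle",
    "generate_gait_cycle",
    "resample_cycle",
    "write_gait_file",
    "read_gait_file",
    "count_local_maxima",
]

_GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class GaitGenParams:
    """Parameters of the synthetic stride.

    Angles in degrees, mass in kg, times as cycle fractions.

    ``noise_sd`` is the standard deviation (degrees) of the jitter applied
    to the angular waveform amplitudes and baselines; 0 gives the
    deterministic normative template.
    """

    body_mass: float = 70.0
    stance_knee_peak: float = 18.0
    swing_knee_peak: float = 64.0
    knee_min: float = 3.0
    toe_off_fraction: float = 0.60
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.toe_off_fraction < 1.0):
            raise ParameterError(
                f"toe_off_fraction must lie in (0, 1), got {self.toe_off_fraction}"
            )
        if not (self.swing_knee_peak > self.stance_knee_peak > 0.0):
            raise ParameterError(
                "need swing_knee_peak > stance_knee_peak > 0, got "
                f"{self.swing_knee_peak} / {self.stance_knee_peak}"
            )
        if self.body_mass <= 0.0:
            raise ParameterError(f"body_mass must be positive, got {self.body_mass}")
        if self.noise_sd < 0.0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.knee_min < 0.0:
            raise ParameterError(f"knee_min must be >= 0, got {self.knee_min}")


@dataclass
class GaitCycle:
    """One time-normalized stride (duration fixed at 1 s).

    Signals are sampled on the uniform grid ``t = arange(n)/n`` of cycle
    fractions in [0, 1).  Angles in degrees, forces in newtons.
    """

    t: np.ndarray
    hip_flexion: np.ndarray
    knee_flexion: np.ndarray
    ankle_flexion: np.ndarray
    grf_vertical: np.ndarray
    grf_anteroposterior: np.ndarray
    toe_off_fraction: float
    duration: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def validate(self) -> "GaitCycle":
        n = self.n_samples
        for name in ("hip_flexion", "knee_flexion", "ankle_flexion",
                     "grf_vertical", "grf_anteroposterior"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ParameterError(f"{name} has length {len(arr)}, expected {n}")
            if not np.all(np.isfinite(arr)):
                raise ParameterError(f"{name} contains non-finite values")
        if not np.allclose(self.t, np.arange(n) / n):
            raise ParameterError("t must be the uniform grid arange(n)/n")
        if self.duration != 1.0:
            raise ParameterError("duration is fixed at 1.0 s")
        if not (0.0 < self.toe_off_fraction < 1.0):
            raise ParameterError("toe_off_fraction must lie in (0, 1)")
        if np.any(self.grf_vertical < 0.0):
            raise ParameterError("grf_vertical must be non-negative")
        swing = self.t >= self.toe_off_fraction
        if np.any(self.grf_vertical[swing] != 0.0):
            raise ParameterError("grf_vertical must vanish during swing")
        n_max = count_local_maxima(self.knee_flexion)
        if n_max != 2:
            raise ParameterError(
                f"knee_flexion must have exactly two local maxima, found {n_max}"
            )
        return self


def count_local_maxima(signal: np.ndarray, prominence: float = 0.5) -> int:
    """Number of local maxima of a periodic signal, ignoring wiggles of
    prominence below ``prominence`` (same units as the signal)."""
    from scipy.signal import find_peaks

    x = np.asarray(signal, dtype=float)
    # wrap so peaks at the cycle boundary are counted once
    ext = np.concatenate([x, x, x])
    peaks, _ = find_peaks(ext, prominence=prominence)
    n = len(x)
    return int(np.sum((peaks >= n) & (peaks < 2 * n)))


def _vm_bump(t: np.ndarray, center: float, kappa: float) -> np.ndarray:
    """Periodic unit-peak bump (von Mises shape)."""
    return np.exp(kappa * (np.cos(2.0 * np.pi * (t - center)) - 1.0))


def generate_gait_cycle(params: GaitGenParams, n_samples: int) -> GaitCycle:
    """Generate one synthetic stride.

    Deterministic for identical ``(params, n_samples)``: the RNG is seeded
    from ``params.seed`` alone.
    """
    if not isinstance(n_samples, (int, np.integer)) or n_samples < 50:
        raise ParameterError(f"n_samples must be an integer >= 50, got {n_samples}")

    rng = np.random.default_rng(params.seed)
    jit = lambda: float(rng.normal(0.0, params.noise_sd))  # noqa: E731

    t = np.arange(n_samples) / n_samples

    # --- knee: small stance wave + large swing wave -------------------
    base = params.knee_min + jit() * 0.3
    base = max(base, 0.0)
    a_stance = max(params.stance_knee_peak + jit() - base, 1.0)
    a_swing = max(params.swing_knee_peak + jit() - base, a_stance + 1.0)
    knee = (base
            + a_stance * _vm_bump(t, 0.15, 10.0)
            + a_swing * _vm_bump(t, 0.72, 3.3))

    # --- hip: single near-sinusoidal wave, peak in terminal swing -----
    hip_mean = 12.0 + jit()
    hip_amp = 15.5 + jit()
    hip = hip_mean + hip_amp * np.cos(2.0 * np.pi * (t - 0.92))

    # --- ankle: dorsiflexion through stance, push-off plantarflexion --
    ankle = (2.0 + jit() * 0.5
             + 8.0 * _vm_bump(t, 0.40, 8.0)
             - 18.0 * _vm_bump(t, params.toe_off_fraction + 0.03, 40.0))

    # --- GRF: double-bump vertical, braking/propulsion AP -------------
    bw = params.body_mass * _GRAVITY
    s = np.clip(t / params.toe_off_fraction, 0.0, 1.0)
    c1 = 1.10 * (1.0 + 0.005 * jit())
    grf_v = bw * (c1 * np.sin(np.pi * s) + 0.12 * np.sin(2.0 * np.pi * s)
                  + 0.33 * np.sin(3.0 * np.pi * s))
    grf_v = np.clip(grf_v, 0.0, None)
    grf_ap = bw * (-0.12 * np.sin(2.0 * np.pi * s))
    swing = t >= params.toe_off_fraction
    grf_v[swing] = 0.0
    grf_ap[swing] = 0.0

    cycle = GaitCycle(
        t=t,
        hip_flexion=hip,
        knee_flexion=knee,
        ankle_flexion=ankle,
        grf_vertical=grf_v,
        grf_anteroposterior=grf_ap,
        toe_off_fraction=params.toe_off_fraction,
        meta={"seed": params.seed, "body_mass": params.body_mass,
              "noise_sd": params.noise_sd},
    )
    return cycle.validate()


def resample_cycle(cycle: GaitCycle, n_out: int) -> GaitCycle:
    """Periodic linear interpolation of every signal onto a uniform grid
    of ``n_out`` samples.

    Linear (rather than trigonometric) interpolation preserves
    non-negativity of the vertical GRF and introduces no ringing at the
    toe-off kink.  The swing-phase GRF is re-zeroed exactly so the
    swing invariant survives grid changes.
    """
    if not isinstance(n_out, (int, np.integer)) or n_out < 2:
        raise ParameterError(f"n_out must be an integer >= 2, got {n_out}")

    t_new = np.arange(n_out) / n_out

    def interp(sig: np.ndarray) -> np.ndarray:
        return np.interp(t_new, cycle.t, sig, period=1.0)

    grf_v = interp(cycle.grf_vertical)
    grf_ap = interp(cycle.grf_anteroposterior)
    swing = t_new >= cycle.toe_off_fraction
    grf_v[swing] = 0.0
    grf_ap[swing] = 0.0

    out = GaitCycle(
        t=t_new,
        hip_flexion=interp(cycle.hip_flexion),
        knee_flexion=interp(cycle.knee_flexion),
        ankle_flexion=interp(cycle.ankle_flexion),
        grf_vertical=grf_v,
        grf_anteroposterior=grf_ap,
        toe_off_fraction=cycle.toe_off_fraction,
        meta=dict(cycle.meta),
    )
    return out.validate()


_COLUMNS = ("t", "hip_flexion", "knee_flexion", "ankle_flexion", "grf_v", "grf_ap")


def write_gait_file(cycle: GaitCycle, path: str | Path) -> None:
    """Write a stride as delimited text: comment header with scalar
    metadata, then one named column per signal."""
    import pandas as pd

    path = Path(path)
    df = pd.DataFrame({
        "t": cycle.t,
        "hip_flexion": cycle.hip_flexion,
        "knee_flexion": cycle.knee_flexion,
        "ankle_flexion": cycle.ankle_flexion,
        "grf_v": cycle.grf_vertical,
        "grf_ap": cycle.grf_anteroposterior,
    })
    with open(path, "w") as fh:
        fh.write(f"# toe_off_fraction = {cycle.toe_off_fraction!r}\n")
        fh.write(f"# duration = {cycle.duration!r}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_gait_file(path: str | Path) -> GaitCycle:
    """Read a stride written by :func:`write_gait_file` (or user-supplied
    text with the same column layout)."""
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise ResultIOError(f"gait file not found: {path}")
    toe_off = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "toe_off_fraction" in line:
                toe_off = float(line.split("=")[1])
    if toe_off is None:
        raise ResultIOError(f"{path}: missing '# toe_off_fraction = ...' header")
    df = pd.read_csv(path, comment="#")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ResultIOError(f"{path}: missing columns {sorted(missing)}")
    cycle = GaitCycle(
        t=df["t"].to_numpy(),
        hip_flexion=df["hip_flexion"].to_numpy(),
        knee_flexion=df["knee_flexion"].to_numpy(),
        ankle_flexion=df["ankle_flexion"].to_numpy(),
        grf_vertical=df["grf_v"].to_numpy(),
        grf_anteroposterior=df["grf_ap"].to_numpy(),
        toe_off_fraction=toe_off,
    )
    return cycle.validate()


def with_toe_off(cycle: GaitCycle, toe_off_fraction: float) -> GaitCycle:
    """Return a copy with a different annotated toe-off fraction (it must
    still be consistent with the swing-phase GRF)."""
    return replace(cycle, toe_off_fraction=toe_off_fraction).validate()
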