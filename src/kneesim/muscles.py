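"""Knee-crossing muscle actuators and the Min/Max force-sharing solver.

Ten actuators cross the joint: four quadriceps (via an effective
patella point and the shared patellar-tendon insertion), four
hamstrings and the two gastrocnemii.  Each is a straight force
generator between its femur-frame origin site and its tibia-frame
insertion site.

Force sharing follows the Min/Max criterion: at each sample, minimize
the largest muscle stress (force over physiological cross-sectional
area, PCSA) subject to the knee-moment equality and non-negative
forces,

    min sigma  s.t.  F_i <= pcsa_i * sigma,  F_i >= 0,
                     sum_i r_i F_i = M(t)

with ``r_i`` the flexor-positive moment arm of muscle i about the knee
center.  At the optimum every agonist works at the common stress and
antagonists are silent, which is also how the solution is verified
against a solver-independent oracle in the test-suite.

Lever arms are estimated by moment probing: apply a probe force along
the muscle's line of action at its tibial insertion and divide the
resulting moment about the knee axis by the probe magnitude; the result
is independent of the probe by linearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog

from .errors import GeometryError, InfeasibleError, LookupError_, ParameterError
from .geometry import KneeGeometry, KneeState, site_position

__all__ = [
    "MUSCLE_NAMES",
    "MUSCLE_GROUPS",
    "MuscleActuator",
    "MuscleSet",
    "MomentDemand",
    "default_muscle_set",
    "lever_arm",
    "muscle_direction",
    "minmax_forces",
    "solve_muscle_forces_cycle",
    "scale_group",
]

MUSCLE_GROUPS: dict[str, tuple[str, ...]] = {
    "quadriceps": ("Vastus Lateralis", "Vastus Medialis", "Vastus Intermedius",
                   "Rectus Femoris"),
    "hamstrings": ("Semitendinosus", "Semimembranosus",
                   "Biceps Femoris long head", "Biceps Femoris short head"),
    "gastrocnemius": ("Gastrocnemius Lateralis", "Gastrocnemius Medialis"),
}

MUSCLE_NAMES: tuple[str, ...] = tuple(
    m for members in MUSCLE_GROUPS.values() for m in members
)

#: PCSA defaults in mm^2 (standard anatomy-table values, documented as
#: non-subject-specific calibration parameters).
DEFAULT_PCSA: dict[str, float] = {
    "Vastus Lateralis": 3500.0,
    "Vastus Medialis": 2400.0,
    "Vastus Intermedius": 2800.0,
    "Rectus Femoris": 1400.0,
    "Semitendinosus": 500.0,
    "Semimembranosus": 1900.0,
    "Biceps Femoris long head": 1100.0,
    "Biceps Femoris short head": 500.0,
    "Gastrocnemius Lateralis": 970.0,
    "Gastrocnemius Medialis": 2100.0,
}

_MUSCLE_SITES: dict[str, tuple[str, str]] = {
    "Vastus Lateralis": ("fem_patella_vl", "tib_patellar_tendon"),
    "Vastus Medialis": ("fem_patella_vm", "tib_patellar_tendon"),
    "Vastus Intermedius": ("fem_patella_vi", "tib_patellar_tendon"),
    "Rectus Femoris": ("fem_patella_rf", "tib_patellar_tendon"),
    "Semitendinosus": ("pel_st", "tib_st"),
    "Semimembranosus": ("pel_sm", "tib_sm"),
    "Biceps Femoris long head": ("pel_bfl", "tib_bfl"),
    "Biceps Femoris short head": ("fem_bfs", "tib_bfs"),
    "Gastrocnemius Lateralis": ("fem_gl", "tib_gl"),
    "Gastrocnemius Medialis": ("fem_gm", "tib_gm"),
}


@dataclass(frozen=True)
class MuscleActuator:
    name: str
    group: str
    origin_site: str     # femur or pelvis frame (pelvis = biarticular)
    insertion_site: str  # tibia frame
    pcsa: float          # mm^2
    scale: float = 1.0   # residual-force factor in [0, 1]

    def __post_init__(self) -> None:
        if self.pcsa <= 0:
            raise ParameterError(f"{self.name}: pcsa must be positive")
        if not (0.0 <= self.scale <= 1.0):
            raise ParameterError(f"{self.name}: scale must lie in [0, 1]")
        if self.group not in MUSCLE_GROUPS:
            raise ParameterError(f"{self.name}: unknown group {self.group!r}")


@dataclass
class MuscleSet:
    muscles: dict[str, MuscleActuator]

    def __post_init__(self) -> None:
        if set(self.muscles) != set(MUSCLE_NAMES):
            raise ParameterError("MuscleSet must contain exactly the 10 named actuators")

    def __iter__(self):
        return (self.muscles[n] for n in MUSCLE_NAMES)

    def muscle(self, name: str) -> MuscleActuator:
        try:
            return self.muscles[name]
        except KeyError:
            raise LookupError_(f"unknown muscle: {name!r}") from None

    def group_members(self, group: str) -> tuple[str, ...]:
        try:
            return MUSCLE_GROUPS[group]
        except KeyError:
            raise LookupError_(f"unknown muscle group: {group!r}") from None

    def scales(self) -> np.ndarray:
        return np.array([m.scale for m in self])


@dataclass
class MomentDemand:
    """Per-sample knee flexion(+)/extension(-) moment over the cycle, N*m."""

    t: np.ndarray       # cycle fractions, uniform grid
    moment: np.ndarray  # N*m, flexor positive

    def __post_init__(self) -> None:
        if len(self.t) != len(self.moment):
            raise ParameterError("t and moment must have equal length")
        if not np.all(np.isfinite(self.moment)):
            raise ParameterError("moment contains non-finite values")


def default_muscle_set(pcsa_table: dict[str, float] | None = None) -> MuscleSet:
    table = dict(DEFAULT_PCSA)
    if pcsa_table:
        unknown = set(pcsa_table) - set(table)
        if unknown:
            raise ParameterError(f"unknown muscles in PCSA table: {sorted(unknown)}")
        table.update(pcsa_table)
    group_of = {m: g for g, members in MUSCLE_GROUPS.items() for m in members}
    muscles = {
        name: MuscleActuator(
            name=name, group=group_of[name],
            origin_site=_MUSCLE_SITES[name][0],
            insertion_site=_MUSCLE_SITES[name][1],
            pcsa=table[name],
        )
        for name in MUSCLE_NAMES
    }
    return MuscleSet(muscles=muscles)


def muscle_direction(muscle: MuscleActuator, geometry: KneeGeometry,
                     state: KneeState) -> np.ndarray:
    """Unit vector of the pull on the tibia (insertion toward origin)."""
    o = site_position(geometry, muscle.origin_site, state)
    i = site_position(geometry, muscle.insertion_site, state)
    v = o - i
    n = float(np.hypot(*v))
    if n < 1e-9:
        raise GeometryError(f"{muscle.name}: degenerate (zero-length) path")
    return v / n


def lever_arm(muscle: MuscleActuator, geometry: KneeGeometry,
              state: KneeState, probe_force: float = 100.0) -> float:
    """Flexor-positive moment arm (mm) by moment probing.

    The probe force acts along the muscle's line of action at the tibial
    insertion; the moment about the knee center divided by the probe
    magnitude is the lever arm.  Flexion of this planar knee is a
    clockwise rotation of the tibia (negative z), so flexor-positive
    means the negated z moment.
    """
    if probe_force <= 0:
        raise ParameterError(f"probe_force must be positive, got {probe_force}")
    u = muscle_direction(muscle, geometry, state)
    p = site_position(geometry, muscle.insertion_site, state)  # about knee center
    fx, fy = probe_force * u
    moment_z = p[0] * fy - p[1] * fx  # N*mm
    return -moment_z / probe_force    # mm, flexor positive


def minmax_forces(demand: float, muscles: list[MuscleActuator],
                  lever_arms_m: np.ndarray) -> np.ndarray:
    """Solve the Min/Max sharing problem at one sample.

    demand in N*m (flexor positive), lever arms in meters (flexor
    positive).  Returns per-muscle forces (N).
    """
    lever = np.asarray(lever_arms_m, dtype=float)
    n = len(muscles)
    if lever.shape != (n,):
        raise ParameterError("lever_arms must match the muscle list")
    if demand == 0.0:
        return np.zeros(n)
    agonists = lever * np.sign(demand) > 0.0
    if not np.any(agonists):
        raise InfeasibleError(
            f"no muscle can produce a moment of the demanded sign ({demand:+.3f} N*m)"
        )
    pcsa = np.array([m.pcsa for m in muscles])
    # variables: [F_1..F_n, sigma]
    c = np.zeros(n + 1)
    c[-1] = 1.0
    a_ub = np.hstack([np.eye(n), -pcsa[:, None]])
    b_ub = np.zeros(n)
    a_eq = np.hstack([lever, [0.0]])[None, :]
    b_eq = [demand]
    res = linprog(c, A_ub=a_ub, b_ub=b_ub, A_eq=a_eq, b_eq=b_eq,
                  bounds=[(0, None)] * (n + 1), method="highs")
    if not res.success:
        raise InfeasibleError(f"Min/Max LP failed: {res.message}")
    forces = np.clip(res.x[:n], 0.0, None)
    return forces


def solve_muscle_forces_cycle(
    demand: MomentDemand,
    muscles: MuscleSet,
    geometry: KneeGeometry,
    states: list[KneeState],
) -> np.ndarray:
    """Per-sample Min/Max solution over a cycle.

    ``states`` carry the prescribed flexion used for the state-dependent
    lever arms (free dof at their reference values).  Returns an array
    of shape (n_samples, 10) in ``MUSCLE_NAMES`` order, before any
    group scaling.
    """
    if len(states) != len(demand.t):
        raise ParameterError("states must be sampled on the demand grid")
    mlist = list(muscles)
    n_s = len(demand.t)
    forces = np.zeros((n_s, len(mlist)))
    for j, (m_j, state) in enumerate(zip(demand.moment, states)):
        lever_mm = np.array([lever_arm(m, geometry, state) for m in mlist])
        try:
            forces[j] = minmax_forces(float(m_j), mlist, lever_mm * 1e-3)
        except InfeasibleError as exc:
            raise InfeasibleError(f"sample {j} (t={demand.t[j]:.3f}): {exc}") from exc
    return forces


def scale_group(muscles: MuscleSet, group: str, factor: float) -> MuscleSet:
    """Set the residual-force scale of every member of a group.

    The scale is applied multiplicatively to whatever scale the member
    already carries, so repeated application composes.
    """
    if not (0.0 <= factor <= 1.0):
        raise ParameterError(f"group factor must lie in [0, 1], got {factor}")
    members = muscles.group_members(group)
    new = dict(muscles.muscles)
    for name in members:
        m = new[name]
        new[name] = replace(m, scale=m.scale * factor)
    return MuscleSet(muscles=new)
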