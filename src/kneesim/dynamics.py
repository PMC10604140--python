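"""Forward dynamics of the tibia relative to the femur during gait.

The knee model prescribes flexion from the driving gait cycle and leaves
the two sagittal translations of the tibia (anteroposterior ``ap`` and
joint-axis ``comp``) free.  Their dynamics under ligament tensions,
muscle pulls, frictional unilateral condyle-plateau contact, gravity,
ground reaction and the inertia of the shank+foot segment are integrated
with an adaptive Kutta-Merson scheme (4th-order embedded Runge-Kutta)
over two gait cycles; the second cycle is the analyzed, steady-state one.

The driving model (trunk/pelvis/hip) is not simulated as rigid bodies:
its only effects on the knee — prescribed flexion, ground reaction force
and segment inertia — enter directly, through the gait record and an
inverse-dynamics pass over the shank+foot segment.

Internal unit system: N, mm, s, deg (so masses appear as kg/1000).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import EquilibriumError, IntegrationError, ParameterError
from .gait import GaitCycle
from .geometry import (BodyParams, KneeGeometry, KneeState, SegmentProperties,
                       flexion_rotation, segment_properties)
from .ligaments import BUNDLE_NAMES, LIGAMENT_GROUPS, LigamentSet, bundle_tension
from .muscles import (MUSCLE_NAMES, MomentDemand, MuscleSet,
                      solve_muscle_forces_cycle)

__all__ = [
    "ContactParams",
    "SimulationResult",
    "inverse_dynamics_knee",
    "contact_force",
    "kutta_merson_step",
    "integrate_adaptive",
    "integrate_step",
    "simulate_gait",
    "passive_drawer_test",
    "KneeModel",
]


@dataclass(frozen=True)
class ContactParams:
    """Contact, damping and integration-tolerance parameters.

    The condyle-plateau interaction is a penalty law: normal force
    proportional to penetration depth plus an inelastic (restitution 0)
    damping term, and regularized Coulomb friction with coefficient
    ``friction_mu`` (default 0.01).  ``tissue_damping`` is a small
    joint-level viscosity standing in for unmodelled soft tissue; it
    provides the dissipation that drives the simulation to its periodic
    steady state.
    """

    friction_mu: float = 0.01
    restitution: float = 0.0          # fixed: inelastic contact
    contact_stiffness: float = 4.0e4  # N/mm penetration
    contact_damping_ratio: float = 1.0
    slip_velocity: float = 1.0        # mm/s, friction regularization
    tissue_damping: float = 0.8      # N s/mm on both free dof
    config_tolerance_translation: float = 0.01  # mm, integrator target
    config_tolerance_rotation: float = 0.1      # deg (prescription check)

    def __post_init__(self) -> None:
        if self.friction_mu < 0:
            raise ParameterError("friction_mu must be >= 0")
        if self.restitution != 0.0:
            raise ParameterError("contact is inelastic: restitution must be 0")
        if self.contact_stiffness <= 0:
            raise ParameterError("contact_stiffness must be positive")
        if self.config_tolerance_translation <= 0:
            raise ParameterError("config_tolerance_translation must be positive")


# ---------------------------------------------------------------------------
# Inverse dynamics of the shank+foot segment
# ---------------------------------------------------------------------------

def _segment_kinematics(gait: GaitCycle, body: BodyParams):
    """World-frame kinematics of the shank+foot segment.

    The shank hangs from a knee point carried by the thigh: the hip
    center translates uniformly (pelvis at constant walking velocity),
    the thigh orientation follows hip flexion, the shank orientation is
    ``hip - knee`` flexion from the vertical.  Returns (phi, phi_ddot,
    a_knee, a_com) with accelerations in m/s^2.
    """
    seg = segment_properties(body)
    t_s = gait.t * gait.duration
    phi = np.radians(gait.hip_flexion - gait.knee_flexion)
    hip = np.radians(gait.hip_flexion)
    l_thigh = body.thigh_length_fraction * body.height

    def ddot(sig):
        return np.gradient(np.gradient(sig, t_s, edge_order=2), t_s, edge_order=2)

    ddphi = ddot(phi)
    # knee point carried by the thigh (hip pull-through / braking)
    a_knee = np.column_stack([ddot(l_thigh * np.sin(hip)),
                              ddot(-l_thigh * np.cos(hip))])
    d = seg.com_distance
    a_rel = np.column_stack([ddot(d * np.sin(phi)), ddot(-d * np.cos(phi))])
    a_com = a_knee + a_rel
    return phi, ddphi, a_knee, a_com


def inverse_dynamics_knee(gait: GaitCycle, body: BodyParams,
                          cop_heel: float = -0.04,
                          cop_toe: float = 0.10) -> MomentDemand:
    """Knee moment demand (N*m, flexor positive) by Newton-Euler balance
    of the shank+foot segment about the (accelerating) knee point.

        tau_muscle = I_com*phi_dd + (r_com x m*a_com) - (r_com x m*g)
                     - (r_cop x F_grf)

    all moments about the knee, z out of the sagittal plane (x forward,
    y up), extension positive z; the returned demand is flexor positive.
    The GRF acts at a center of pressure progressing linearly from
    ``cop_heel`` to ``cop_toe`` (m, anterior of the ankle) over stance.
    """
    seg = segment_properties(body)
    phi, ddphi, _a_knee, a_com = _segment_kinematics(gait, body)
    m, d, L = seg.total_mass, seg.com_distance, seg.shank_length
    inertia_com = seg.inertia_about_knee - m * d ** 2
    g = body.gravity

    r_com = np.column_stack([d * np.sin(phi), -d * np.cos(phi)])
    tau_inertial = inertia_com * ddphi + m * (
        r_com[:, 0] * a_com[:, 1] - r_com[:, 1] * a_com[:, 0])
    tau_grav = -m * g * d * np.sin(phi)  # (r_com x m*g)_z with g = (0, -g)

    s = np.clip(gait.t / gait.toe_off_fraction, 0.0, 1.0)
    cop_x = L * np.sin(phi) + np.where(gait.t < gait.toe_off_fraction,
                                       cop_heel + (cop_toe - cop_heel) * s, 0.0)
    cop_y = -L * np.cos(phi) - 0.08
    tau_grf = cop_x * gait.grf_vertical - cop_y * gait.grf_anteroposterior

    tau_muscle = tau_inertial - tau_grav - tau_grf
    return MomentDemand(t=gait.t, moment=-tau_muscle)  # flexor positive


def external_joint_load(gait: GaitCycle, body: BodyParams) -> np.ndarray:
    """Non-muscular, non-articular load on the tibia segment, expressed in
    the knee (tibia-aligned) frame, N, shape (n, 2) = (anterior, proximal).

    Sum of gravity, ground reaction and the inertial force of the
    prescribed segment motion (including the knee point carried by the
    thigh); together with the ligament, muscle and contact forces it
    closes the force balance of the free dof.
    """
    seg = segment_properties(body)
    phi, _ddphi, _a_knee, a_com = _segment_kinematics(gait, body)
    m = seg.total_mass
    lx = gait.grf_anteroposterior - m * a_com[:, 0]
    ly = gait.grf_vertical - m * (body.gravity + a_com[:, 1])
    # world -> knee frame (x anterior = forward normal of the shank axis)
    c, s = np.cos(phi), np.sin(phi)
    return np.column_stack([c * lx + s * ly, -s * lx + c * ly])


# ---------------------------------------------------------------------------
# Contact
# ---------------------------------------------------------------------------

_N_CONTACT_GRID = 81
_CONTACT_HALFSPAN = 10.0  # mm; the contact point stays within this span
                          # because the rim slope caps the surface gradient


def _surface_height(xi: np.ndarray, geometry: KneeGeometry) -> np.ndarray:
    """Plateau height (tibia frame) above its lowest point, with the
    parabolic well flattening to the rim slope."""
    rd = geometry.dish_radius
    s_max = geometry.dish_rim_slope
    xi0 = rd * s_max
    axi = np.abs(xi)
    return np.where(axi <= xi0, xi ** 2 / (2.0 * rd),
                    xi0 ** 2 / (2.0 * rd) + s_max * (axi - xi0))


def _surface_slope(xi: float, geometry: KneeGeometry) -> float:
    rd = geometry.dish_radius
    s_max = geometry.dish_rim_slope
    return float(np.clip(xi / rd, -s_max, s_max))


def _contact_geometry(ap: float, comp: float, geometry: KneeGeometry):
    """Penetration depth (mm, >0 in contact) and surface slope at the
    deepest point of the condyle circle into the plateau well."""
    rc = geometry.condyle_radius
    tan_a = math.tan(math.radians(geometry.plateau_slope))
    x = np.linspace(-_CONTACT_HALFSPAN, _CONTACT_HALFSPAN, _N_CONTACT_GRID)
    y_cond = -np.sqrt(rc ** 2 - x ** 2)
    xi = x - ap
    y_surf = -rc + comp + tan_a * xi + _surface_height(xi, geometry)
    gap = y_cond - y_surf
    j = int(np.argmin(gap))
    # quadratic refinement around the grid minimum for smoothness
    if 0 < j < len(x) - 1:
        g0, g1, g2 = gap[j - 1], gap[j], gap[j + 1]
        denom = g0 - 2.0 * g1 + g2
        if abs(denom) > 1e-12:
            frac = 0.5 * (g0 - g2) / denom
            frac = float(np.clip(frac, -0.5, 0.5))
            h = x[1] - x[0]
            x_star = x[j] + frac * h
            gap_min = g1 - 0.25 * (g0 - g2) * frac
        else:
            x_star, gap_min = x[j], gap[j]
    else:
        x_star, gap_min = x[j], gap[j]
    slope = tan_a + _surface_slope(x_star - ap, geometry)
    return -float(gap_min), slope  # penetration, surface slope


def contact_force(state: KneeState, geometry: KneeGeometry,
                  params: ContactParams,
                  effective_mass_kg: float = 4.27) -> tuple[float, float]:
    """Normal and friction force magnitudes (N) at a knee state.

    Normal force is zero whenever the surfaces are separated and never
    negative; friction magnitude never exceeds ``friction_mu * normal``.
    The friction value is signed (positive = anterior force on the tibia).
    """
    vec, info = _contact_force_vector(
        state.ap, state.comp, state.ap_velocity, state.comp_velocity,
        geometry, params, effective_mass_kg / 1000.0)
    return info["normal"], info["friction"]


def _contact_force_vector(ap, comp, ap_vel, comp_vel, geometry, params, m_eff):
    pen, slope = _contact_geometry(ap, comp, geometry)
    if pen <= 0.0:
        return np.zeros(2), {"normal": 0.0, "friction": 0.0, "penetration": pen,
                             "slope": slope}
    c_n = 2.0 * params.contact_damping_ratio * math.sqrt(
        params.contact_stiffness * m_eff)
    pen_rate = comp_vel - slope * ap_vel
    normal = params.contact_stiffness * pen + c_n * pen_rate
    normal = max(normal, 0.0)
    root = math.sqrt(1.0 + slope * slope)
    n_hat = np.array([-slope, 1.0]) / root   # outward surface normal
    t_hat = np.array([1.0, slope]) / root
    v_slip = (ap_vel + slope * comp_vel) / root
    friction = -params.friction_mu * normal * math.tanh(v_slip / params.slip_velocity)
    force = -normal * n_hat + friction * t_hat
    return force, {"normal": normal, "friction": friction, "penetration": pen,
                   "slope": slope}


# ---------------------------------------------------------------------------
# Kutta-Merson integration
# ---------------------------------------------------------------------------

def kutta_merson_step(f, t: float, y: np.ndarray, h: float):
    """One Kutta-Merson step: 4th-order solution and an embedded local
    error estimate."""
    k1 = f(t, y)
    k2 = f(t + h / 3.0, y + h * k1 / 3.0)
    k3 = f(t + h / 3.0, y + h * (k1 + k2) / 6.0)
    k4 = f(t + h / 2.0, y + h * (k1 + 3.0 * k3) / 8.0)
    k5 = f(t + h, y + h * (k1 - 3.0 * k3 + 4.0 * k4) / 2.0)
    y_new = y + h * (k1 + 4.0 * k4 + k5) / 6.0
    err = h * (2.0 * k1 - 9.0 * k3 + 8.0 * k4 - k5) / 30.0
    return y_new, err


def integrate_adaptive(f, t0: float, t1: float, y0: np.ndarray,
                       tol: np.ndarray, h0: float,
                       min_h: float = 1e-8) -> np.ndarray:
    """Advance y from t0 to t1 with adaptive Kutta-Merson sub-stepping.

    ``tol`` gives the per-component local error target; steps are halved
    until the estimate meets it and grown (at most doubled) when the
    error is comfortably below target.
    """
    if t1 <= t0:
        return np.asarray(y0, dtype=float)
    t, y = t0, np.asarray(y0, dtype=float)
    h = min(h0, t1 - t0)
    while t < t1 - 1e-12:
        h = min(h, t1 - t)
        y_new, err = kutta_merson_step(f, t, y, h)
        ratio = float(np.max(np.abs(err) / tol))
        if not np.isfinite(ratio) or ratio > 1.0:
            h *= 0.5
            if h < min_h:
                raise IntegrationError("step-size underflow", time=t)
            continue
        t += h
        y = y_new
        if ratio < 0.05:
            h = min(2.0 * h, h0)
        else:
            h = min(h * min(2.0, 0.9 * ratio ** -0.2), h0)
    return y


def integrate_step(state: KneeState, force, dt: float,
                   effective_mass_kg: float,
                   flexion_at=None,
                   tolerance: float = 0.01) -> KneeState:
    """Advance the free translations by ``dt`` under a force law.

    ``force`` maps a KneeState to the net (anterior, proximal) force in N.
    ``flexion_at`` optionally re-prescribes flexion as a function of time
    (degrees); otherwise flexion is held.  Adaptive sub-stepping targets
    ``tolerance`` (mm) per step.
    """
    if dt <= 0:
        raise ParameterError(f"dt must be positive, got {dt}")
    m_eff = effective_mass_kg / 1000.0  # N per mm/s^2

    def rhs(t, y):
        th = state.flexion if flexion_at is None else float(flexion_at(t))
        st = KneeState(flexion=th, ap=y[0], comp=y[1],
                       ap_velocity=y[2], comp_velocity=y[3], time=t)
        fx, fy = force(st)
        return np.array([y[2], y[3], fx / m_eff, fy / m_eff])

    y0 = np.array([state.ap, state.comp, state.ap_velocity, state.comp_velocity])
    tol = np.array([tolerance, tolerance, tolerance * 1e3, tolerance * 1e3])
    y = integrate_adaptive(rhs, state.time, state.time + dt, y0, tol, h0=dt)
    th1 = state.flexion if flexion_at is None else float(flexion_at(state.time + dt))
    return KneeState(flexion=th1, ap=y[0], comp=y[1],
                     ap_velocity=y[2], comp_velocity=y[3], time=state.time + dt)


# ---------------------------------------------------------------------------
# The assembled knee model
# ---------------------------------------------------------------------------

class KneeModel:
    """Precompiled right-hand side of the free-dof dynamics for one gait
    condition (fixed geometry, ligament scaling and muscle force series)."""

    def __init__(self, geometry: KneeGeometry, ligaments: LigamentSet,
                 muscles: MuscleSet, gait: GaitCycle, body: BodyParams,
                 contact: ContactParams,
                 muscle_forces: np.ndarray | None = None):
        self.geometry = geometry
        self.ligaments = ligaments
        self.muscles = muscles
        self.gait = gait
        self.body = body
        self.contact = contact
        self.segment = segment_properties(body)
        self.m_eff = self.segment.total_mass / 1000.0  # N per mm/s^2

        self._fem, self._tib, self._L0, self._k, self._eps_l = ligaments.arrays(geometry)
        mus = list(muscles)
        self._orig = np.array([geometry.site(m.origin_site).xy for m in mus])
        self._orig_pelvis = np.array(
            [geometry.site(m.origin_site).body == "pelvis" for m in mus])
        self._ins = np.array([geometry.site(m.insertion_site).xy for m in mus])
        self._hip_center = np.array([0.0, geometry.thigh_length])

        if muscle_forces is None:
            demand = inverse_dynamics_knee(gait, body)
            states = [KneeState(flexion=th, hip_flexion=h)
                      for th, h in zip(gait.knee_flexion, gait.hip_flexion)]
            muscle_forces = solve_muscle_forces_cycle(demand, muscles, geometry, states)
        self.base_muscle_forces = np.asarray(muscle_forces)
        self.muscle_forces = self.base_muscle_forces * muscles.scales()[None, :]
        self._load = external_joint_load(gait, body)

        # periodic interpolation tables on an extended grid
        self._tgrid = np.concatenate([gait.t, [1.0]])
        self._theta = np.concatenate([gait.knee_flexion, gait.knee_flexion[:1]])
        self._hip = np.concatenate([gait.hip_flexion, gait.hip_flexion[:1]])
        self._ftab = np.vstack([self.muscle_forces, self.muscle_forces[:1]])
        self._ltab = np.vstack([self._load, self._load[:1]])

    # -- interpolants ---------------------------------------------------
    def _frac(self, t: float) -> float:
        return t / self.gait.duration % 1.0

    def flexion(self, t: float) -> float:
        return float(np.interp(self._frac(t), self._tgrid, self._theta))

    def hip_flexion(self, t: float) -> float:
        return float(np.interp(self._frac(t), self._tgrid, self._hip))

    def muscle_forces_at(self, t: float) -> np.ndarray:
        x = self._frac(t)
        j = min(int(x * self.gait.n_samples), self.gait.n_samples - 1)
        w = x * self.gait.n_samples - j
        return (1.0 - w) * self._ftab[j] + w * self._ftab[j + 1]

    def load_at(self, t: float) -> np.ndarray:
        x = self._frac(t)
        j = min(int(x * self.gait.n_samples), self.gait.n_samples - 1)
        w = x * self.gait.n_samples - j
        return (1.0 - w) * self._ltab[j] + w * self._ltab[j + 1]

    # -- force assembly -------------------------------------------------
    def ligament_forces(self, theta: float, ap: float, comp: float):
        """Net ligament force on the tibia (N, 2) and per-bundle tensions."""
        rot = flexion_rotation(theta)
        fem = self._fem @ rot.T
        v = fem - (self._tib + np.array([ap, comp]))
        length = np.hypot(v[:, 0], v[:, 1])
        eps = (length - self._L0) / self._L0
        tension = bundle_tension(eps, self._k, self._eps_l,
                                 self.ligaments.toe_transition)
        force = (tension / length) @ v
        return force, tension

    def muscle_force_vector(self, t: float, theta: float, hip: float,
                            ap: float, comp: float):
        rot = flexion_rotation(theta)
        orig = self._orig.copy()
        if np.any(self._orig_pelvis):
            pel = self._orig[self._orig_pelvis] @ flexion_rotation(-hip).T
            orig[self._orig_pelvis] = self._hip_center + pel
        orig = orig @ rot.T
        v = orig - (self._ins + np.array([ap, comp]))
        length = np.hypot(v[:, 0], v[:, 1])
        mags = self.muscle_forces_at(t)
        return (mags / length) @ v

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        ap, comp, apv, compv = y
        theta = self.flexion(t)
        hip = self.hip_flexion(t)
        f_lig, _ = self.ligament_forces(theta, ap, comp)
        f_mus = self.muscle_force_vector(t, theta, hip, ap, comp)
        f_con, _ = _contact_force_vector(ap, comp, apv, compv,
                                         self.geometry, self.contact, self.m_eff)
        f_ext = self.load_at(t)
        f_damp = -self.contact.tissue_damping * np.array([apv, compv])
        f = f_lig + f_mus + f_con + f_ext + f_damp
        return np.array([apv, compv, f[0] / self.m_eff, f[1] / self.m_eff])


@dataclass
class SimulationResult:
    """Per-sample outputs of the analyzed (final) cycle plus condition
    metadata."""

    t: np.ndarray                      # cycle fractions
    flexion: np.ndarray                # deg
    ap: np.ndarray                     # mm, anterior positive
    comp: np.ndarray                   # mm
    ap_velocity: np.ndarray            # mm/s
    comp_velocity: np.ndarray          # mm/s
    bundle_tensions: np.ndarray        # (n, 15) N, BUNDLE_NAMES order
    ligament_tensions: dict[str, np.ndarray]  # per anatomical ligament, N
    contact_normal: np.ndarray         # N
    contact_friction: np.ndarray       # N, signed
    penetration: np.ndarray            # mm
    muscle_forces: np.ndarray          # (n, 10) N, MUSCLE_NAMES order
    metadata: dict = field(default_factory=dict)

    @property
    def contact_bw(self) -> np.ndarray:
        """Contact force normalized to body weight."""
        return self.contact_normal / self.metadata["body_weight"]

    def validate(self) -> "SimulationResult":
        if np.any(self.contact_normal < 0):
            raise ParameterError("contact force must be non-negative")
        if np.any(self.bundle_tensions < 0):
            raise ParameterError("ligament tensions must be non-negative")
        return self

    def to_frame(self):
        """Tidy long-format DataFrame (cycle_fraction, variable, value, units)."""
        import pandas as pd

        rows = []

        def add(name, values, units):
            rows.append(pd.DataFrame({
                "cycle_fraction": self.t, "variable": name,
                "value": values, "units": units,
            }))

        add("knee_flexion", self.flexion, "deg")
        add("ap_displacement", self.ap, "mm")
        add("compression", self.comp, "mm")
        add("contact_force", self.contact_normal, "N")
        add("contact_force_bw", self.contact_bw, "BW")
        add("contact_friction", self.contact_friction, "N")
        add("penetration", self.penetration, "mm")
        for lig, series in self.ligament_tensions.items():
            add(f"tension_{lig}", series, "N")
        for j, name in enumerate(BUNDLE_NAMES):
            add(f"bundle_{name}", self.bundle_tensions[:, j], "N")
        for j, name in enumerate(MUSCLE_NAMES):
            add(f"muscle_{name}", self.muscle_forces[:, j], "N")
        return pd.concat(rows, ignore_index=True)


def simulate_gait(
    geometry: KneeGeometry,
    ligaments: LigamentSet,
    muscles: MuscleSet,
    gait: GaitCycle,
    body: BodyParams,
    contact: ContactParams,
    n_cycles: int = 2,
    dt: float = 0.02,
    muscle_forces: np.ndarray | None = None,
    condition: str = "intact",
) -> SimulationResult:
    """Run ``n_cycles`` periodic repetitions of the stride and report the
    final cycle on the driving grid.

    ``muscle_forces`` (n_samples x 10, unscaled) may be supplied to reuse
    the intact-condition Min/Max solution across conditions; group scale
    factors of ``muscles`` are applied on top.
    """
    if n_cycles < 1:
        raise ParameterError("n_cycles must be >= 1")
    model = KneeModel(geometry, ligaments, muscles, gait, body, contact,
                      muscle_forces=muscle_forces)
    n = gait.n_samples
    grid_dt = gait.duration / n
    tol_t = contact.config_tolerance_translation
    tol = np.array([tol_t, tol_t, tol_t * 50.0, tol_t * 50.0])
    # cap the sub-step below the explicit stability limit of the stiff
    # contact mode, so the penalty dof is resolved rather than ringing
    omega_contact = math.sqrt(contact.contact_stiffness / model.m_eff)
    h0 = min(dt, grid_dt, 1.8 / omega_contact)

    y = np.zeros(4)
    t = 0.0
    # cycles before the last: integrate through without recording
    for _ in range(n_cycles - 1):
        for _j in range(n):
            try:
                y = integrate_adaptive(model.rhs, t, t + grid_dt, y, tol, h0)
            except IntegrationError as exc:
                raise IntegrationError(
                    f"condition {condition!r}: {exc}", time=t) from exc
            t += grid_dt

    # final (analyzed) cycle: record at each grid node
    states = np.zeros((n, 4))
    for j in range(n):
        states[j] = y
        try:
            y = integrate_adaptive(model.rhs, t, t + grid_dt, y, tol, h0)
        except IntegrationError as exc:
            raise IntegrationError(f"condition {condition!r}: {exc}", time=t) from exc
        t += grid_dt

    theta = gait.knee_flexion
    bundle_t = np.zeros((n, len(BUNDLE_NAMES)))
    normal = np.zeros(n)
    friction = np.zeros(n)
    penetr = np.zeros(n)
    mus = np.zeros((n, len(MUSCLE_NAMES)))
    t_cycle = (n_cycles - 1) * gait.duration
    for j in range(n):
        ap, comp, apv, compv = states[j]
        _, tension = model.ligament_forces(theta[j], ap, comp)
        bundle_t[j] = tension
        _, info = _contact_force_vector(ap, comp, apv, compv, geometry,
                                        contact, model.m_eff)
        normal[j], friction[j] = info["normal"], info["friction"]
        penetr[j] = info["penetration"]
        mus[j] = model.muscle_forces_at(t_cycle + gait.t[j] * gait.duration)

    lig_t = {
        lig: bundle_t[:, [BUNDLE_NAMES.index(b) for b in members]].sum(axis=1)
        for lig, members in LIGAMENT_GROUPS.items()
    }
    result = SimulationResult(
        t=gait.t.copy(), flexion=theta.copy(),
        ap=states[:, 0], comp=states[:, 1],
        ap_velocity=states[:, 2], comp_velocity=states[:, 3],
        bundle_tensions=bundle_t, ligament_tensions=lig_t,
        contact_normal=normal, contact_friction=friction,
        penetration=penetr, muscle_forces=mus,
        metadata={
            "condition": condition,
            "pcl_factor": ligaments.scales["PCL-al"],
            "hamstring_factor": muscles.muscle("Semitendinosus").scale,
            "n_cycles": n_cycles, "dt": dt,
            "tolerance_translation": contact.config_tolerance_translation,
            "body_weight": body.body_weight,
            "seed": gait.meta.get("seed"),
        },
    )
    return result.validate()


# ---------------------------------------------------------------------------
# Passive drawer test
# ---------------------------------------------------------------------------

def passive_drawer_test(
    geometry: KneeGeometry,
    ligaments: LigamentSet,
    contact: ContactParams,
    flexion: float,
    applied_ap_force: float,
    preload: float = 100.0,
    max_force: float = 500.0,
    effective_mass_kg: float = 4.27,
) -> float:
    """Quasi-static AP drawer displacement (mm) at a fixed flexion angle.

    The tibia is seated with a compressive ``preload`` (N), the AP force
    is ramped quasi-statically (numerical continuation in 25 N steps) and
    the equilibrium displacement is measured from the unloaded (0 N)
    equilibrium.  Positive force/displacement = anterior.
    """
    from scipy.optimize import minimize

    if abs(applied_ap_force) > max_force:
        raise ParameterError(
            f"|applied_ap_force| must be <= {max_force} N, got {applied_ap_force}")
    m_eff = effective_mass_kg / 1000.0

    fem, tib, L0, k_arr, eps_l = ligaments.arrays(geometry)
    rot = flexion_rotation(flexion)
    fem_rot = fem @ rot.T

    toe = ligaments.toe_transition

    def elastic_energy(eps):
        """Per-unit-L0 strain energy of the toe/linear law (N)."""
        if toe == "at_limit":
            toe_e = k_arr * eps ** 3 / (6.0 * eps_l)
            lin_e = k_arr * (eps_l ** 2 / 6.0 + 0.5 * (eps ** 2 - eps_l ** 2)
                             - 0.5 * eps_l * (eps - eps_l))
            return np.where(eps <= 0.0, 0.0,
                            np.where(eps <= eps_l, toe_e, lin_e))
        toe_e = k_arr * eps ** 3 / (12.0 * eps_l)
        lin_e = k_arr * (2.0 * eps_l ** 2 / 3.0 + 0.5 * eps ** 2 - eps_l * eps)
        return np.where(eps <= 0.0, 0.0,
                        np.where(eps <= 2.0 * eps_l, toe_e, lin_e))

    def potential(y, f_ap):
        """Total potential (N*mm); friction-free statics is conservative."""
        ap, comp = y
        v = fem_rot - (tib + np.array([ap, comp]))
        length = np.hypot(v[:, 0], v[:, 1])
        eps = (length - L0) / L0
        e_lig = float(np.sum(L0 * elastic_energy(eps)))
        pen, _ = _contact_geometry(ap, comp, geometry)
        e_con = 0.5 * contact.contact_stiffness * max(pen, 0.0) ** 2
        return e_lig + e_con - f_ap * ap + preload * comp

    def residual(y, f_ap):
        ap, comp = y
        v = fem_rot - (tib + np.array([ap, comp]))
        length = np.hypot(v[:, 0], v[:, 1])
        eps = (length - L0) / L0
        tension = bundle_tension(eps, k_arr, eps_l, toe)
        f_lig = (tension / length) @ v
        f_con, _ = _contact_force_vector(ap, comp, 0.0, 0.0, geometry,
                                         contact, m_eff)
        return f_lig + f_con + np.array([f_ap, -preload])

    def solve(f_ap, guess):
        # the force residual is the exact negative gradient of the potential
        sol = minimize(potential, guess, args=(f_ap,), method="BFGS",
                       jac=lambda y, fa: -residual(y, fa),
                       options={"gtol": 1e-8, "maxiter": 500})
        y = sol.x
        if np.max(np.abs(residual(y, f_ap))) > 1.0:
            pol = minimize(potential, y, args=(f_ap,), method="Powell",
                           options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": 400})
            if np.max(np.abs(residual(pol.x, f_ap))) < np.max(
                    np.abs(residual(y, f_ap))):
                y = pol.x
        if np.max(np.abs(residual(y, f_ap))) > 1.0:  # N; ~0.02 mm at joint stiffness
            raise EquilibriumError(
                f"drawer equilibrium did not converge at flexion={flexion} deg, "
                f"force={f_ap} N (residual {np.max(np.abs(residual(y, f_ap))):.3g} N)")
        return y

    y0 = solve(0.0, np.array([0.0, preload / contact.contact_stiffness]))
    n_steps = max(1, int(math.ceil(abs(applied_ap_force) / 25.0)))
    y = y0
    for frac in np.linspace(1.0 / n_steps, 1.0, n_steps):
        y = solve(applied_ap_force * frac, y)
    return float(y[0] - y0[0])
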