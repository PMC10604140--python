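"""Parametric sagittal-plane knee geometry.

The model is a planar reduction of the knee: the femoral condyles are
approximated by a single circular sagittal profile, the tibial plateau by
a shallow dish (a parabolic well with a finite rim slope, standing in for
the articular congruence that a 3D surface pair provides), and every
ligament/muscle attachment by a 2D point tagged with the body it belongs
to.

Frames and conventions
----------------------
The laboratory frame is aligned with the tibia: +x anterior, +y proximal,
origin at the knee joint center.  Knee flexion is prescribed and rotates
the femur-fixed sites about the origin (at 90 degrees flexion the femoral
shaft points posteriorly, i.e. a femoral +x offset maps to +y).  The two
free degrees of freedom translate the tibia-fixed sites: ``ap`` (mm,
anterior positive) and ``comp`` (mm, proximal positive, i.e. compression
of the joint).  At the zero state the transformation is the identity.

Attachment coordinates are not subject-specific measurements: they are
literature-typical sagittal positions, shipped as documented calibration
defaults (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError, LookupError_, ParameterError

__all__ = [
    "Site",
    "KneeGeometry",
    "BodyParams",
    "SegmentProperties",
    "KneeState",
    "default_geometry",
    "segment_properties",
    "site_position",
    "flexion_rotation",
]

FEMUR = "femur"
TIBIA = "tibia"
PELVIS = "pelvis"


@dataclass(frozen=True)
class Site:
    """One attachment point: (x, y) in mm in its body frame.

    Pelvis-frame sites (biarticular muscle origins) are stored as offsets
    from the hip center; their laboratory position depends on both the
    knee flexion and the hip flexion of the state.
    """

    name: str
    body: str  # "femur" | "tibia" | "pelvis"
    xy: tuple[float, float]

    def __post_init__(self) -> None:
        if self.body not in (FEMUR, TIBIA, PELVIS):
            raise ParameterError(
                f"site {self.name}: body must be femur|tibia|pelvis, got {self.body}")


@dataclass(frozen=True)
class KneeState:
    """Prescribed flexion plus the free sagittal translations of the tibia.

    flexion/hip_flexion in degrees; ap/comp in mm (anterior / proximal
    positive); velocities in mm/s.  hip_flexion only matters for
    pelvis-frame (biarticular origin) sites.
    """

    flexion: float = 0.0
    ap: float = 0.0
    comp: float = 0.0
    ap_velocity: float = 0.0
    comp_velocity: float = 0.0
    time: float = 0.0
    hip_flexion: float = 0.0


@dataclass
class KneeGeometry:
    """Condyle/plateau profile and the attachment-site table.

    condyle_radius
        Radius (mm) of the circular femoral condyle profile, centered at
        the knee center so that flexion leaves the contact geometry
        unchanged.
    dish_radius
        Sagittal radius (mm) of the tibial plateau well; must exceed the
        condyle radius.  The relative curvature ``1/(dish - condyle)``
        sets how strongly compressive load centers the tibia.
    dish_rim_slope
        Maximum surface slope of the well (dimensionless); beyond the
        matching offset the plateau flattens to this slope, so the
        centering force saturates at ``slope * normal_force``.
    plateau_slope
        Posterior inclination of the plateau (degrees, posterior-down
        positive).
    """

    condyle_radius: float = 25.0
    dish_radius: float = 35.0
    dish_rim_slope: float = 0.095
    plateau_slope: float = 0.0
    thigh_length: float = 420.0  # mm; hip center at (0, thigh_length) femur frame
    sites: dict[str, Site] = field(default_factory=dict)
    patellar_tendon_insertion: str = "tib_patellar_tendon"

    def __post_init__(self) -> None:
        if self.condyle_radius <= 0:
            raise ParameterError("condyle_radius must be positive")
        if self.dish_radius <= self.condyle_radius:
            raise ParameterError("dish_radius must exceed condyle_radius")
        if self.dish_rim_slope <= 0:
            raise ParameterError("dish_rim_slope must be positive")

    def site(self, name: str) -> Site:
        try:
            return self.sites[name]
        except KeyError:
            raise LookupError_(f"unknown attachment site: {name!r}") from None

    def with_sites(self, **updates: tuple[float, float]) -> "KneeGeometry":
        """Copy with some site coordinates replaced (same body tags)."""
        sites = dict(self.sites)
        for name, xy in updates.items():
            old = self.site(name)
            sites[name] = replace(old, xy=tuple(xy))
        return replace(self, sites=sites)


def flexion_rotation(flexion_deg: float) -> np.ndarray:
    """Rotation applied to femur-frame coordinates at a given flexion.

    Counter-clockwise in the (x anterior, y proximal) plane: the femoral
    shaft (+y) tilts posteriorly as the knee flexes.
    """
    th = math.radians(flexion_deg)
    c, s = math.cos(th), math.sin(th)
    return np.array([[c, -s], [s, c]])


def site_position(geometry: KneeGeometry, site: str, state: KneeState) -> np.ndarray:
    """Laboratory-frame position (mm) of a named site at a knee state."""
    st = geometry.site(site)
    xy = np.asarray(st.xy, dtype=float)
    if st.body == FEMUR:
        return flexion_rotation(state.flexion) @ xy
    if st.body == PELVIS:
        hip_center = np.array([0.0, geometry.thigh_length])
        thigh_frame = hip_center + flexion_rotation(-state.hip_flexion) @ xy
        return flexion_rotation(state.flexion) @ thigh_frame
    return xy + np.array([state.ap, state.comp])


# ---------------------------------------------------------------------------
# Anthropometrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BodyParams:
    """Whole-body parameters and the anthropometric fractions used to
    derive segment properties (Dempster-type defaults, documented as
    non-subject-specific calibration values)."""

    body_mass: float = 70.0          # kg
    height: float = 1.72             # m
    shank_mass_fraction: float = 0.0465
    foot_mass_fraction: float = 0.0145
    shank_length_fraction: float = 0.246   # of height
    thigh_length_fraction: float = 0.245   # of height
    shank_com_fraction: float = 0.433      # of shank length, from knee
    shank_gyration_fraction: float = 0.302 # of shank length, about COM
    foot_com_offset: float = 0.05          # m beyond the ankle, along the shank
    gravity: float = 9.81            # m/s^2

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ParameterError(f"body_mass must be positive, got {self.body_mass}")
        if self.height <= 0:
            raise ParameterError(f"height must be positive, got {self.height}")
        if self.shank_mass_fraction <= 0 or self.foot_mass_fraction <= 0:
            raise ParameterError("segment mass fractions must be positive")
        if self.shank_mass_fraction + self.foot_mass_fraction >= 1.0:
            raise ParameterError("shank+foot mass must be below body mass")

    @property
    def body_weight(self) -> float:
        """Body weight in newtons (normalizer for contact forces)."""
        return self.body_mass * self.gravity


@dataclass(frozen=True)
class SegmentProperties:
    """Shank+foot lumped-segment properties about the knee."""

    shank_mass: float        # kg
    foot_mass: float         # kg
    total_mass: float        # kg
    shank_length: float      # m
    com_distance: float      # m, from the knee along the segment
    inertia_about_knee: float  # kg m^2


def segment_properties(body: BodyParams) -> SegmentProperties:
    """Masses, COM and moment of inertia of the shank+foot segment.

    Masses scale linearly with body mass; inertias follow from the
    configured radii of gyration.  The foot is lumped as a point mass
    just beyond the ankle.
    """
    m_s = body.shank_mass_fraction * body.body_mass
    m_f = body.foot_mass_fraction * body.body_mass
    L = body.shank_length_fraction * body.height
    d_s = body.shank_com_fraction * L
    d_f = L + body.foot_com_offset
    rg = body.shank_gyration_fraction * L
    inertia = m_s * (rg ** 2 + d_s ** 2) + m_f * d_f ** 2
    com = (m_s * d_s + m_f * d_f) / (m_s + m_f)
    return SegmentProperties(
        shank_mass=m_s, foot_mass=m_f, total_mass=m_s + m_f,
        shank_length=L, com_distance=com, inertia_about_knee=inertia,
    )


# ---------------------------------------------------------------------------
# Default attachment layout (mm, knee center at the origin)
# ---------------------------------------------------------------------------

_DEFAULT_SITES: dict[str, tuple[str, tuple[float, float]]] = {
    # cruciates (femoral PCL posterior to femoral ACL; tibial likewise);
    # femoral sites sit close to the flexion axis for near-isometry
    "fem_acl_a": (FEMUR, (-1.5, -0.5)),
    "fem_acl_p": (FEMUR, (-2.5, -1.5)),
    "tib_acl_a": (TIBIA, (11.0, -30.0)),
    "tib_acl_p": (TIBIA, (8.0, -31.0)),
    "fem_pcl_al": (FEMUR, (-5.5, -4.0)),
    "fem_pcl_pm": (FEMUR, (-6.5, -3.5)),
    "tib_pcl_al": (TIBIA, (-14.0, -32.0)),
    "tib_pcl_pm": (TIBIA, (-16.0, -31.0)),
    # lateral collateral, three fascicles (sagittal projection); vertical
    # at neutral: dormant until several mm of AP slide, then recruited
    # with large tension per unit AP restraint
    "fem_lcl_ant": (FEMUR, (2.0, 2.0)),
    "fem_lcl_int": (FEMUR, (0.0, 2.0)),
    "fem_lcl_post": (FEMUR, (-2.0, 2.0)),
    "tib_lcl_ant": (TIBIA, (2.0, -36.0)),
    "tib_lcl_int": (TIBIA, (0.0, -36.0)),
    "tib_lcl_post": (TIBIA, (-2.0, -36.0)),
    # superficial MCL, three long fascicles
    "fem_smcl_ant": (FEMUR, (3.0, 3.0)),
    "fem_smcl_int": (FEMUR, (1.0, 3.0)),
    "fem_smcl_post": (FEMUR, (-1.0, 3.0)),
    "tib_smcl_ant": (TIBIA, (3.0, -48.0)),
    "tib_smcl_int": (TIBIA, (1.0, -50.0)),
    "tib_smcl_post": (TIBIA, (-1.0, -48.0)),
    # deep MCL, two short vertical fascicles
    "fem_dmcl_1": (FEMUR, (-2.0, 1.0)),
    "fem_dmcl_2": (FEMUR, (-4.0, 0.0)),
    "tib_dmcl_1": (TIBIA, (-6.0, -27.0)),
    "tib_dmcl_2": (TIBIA, (-8.0, -24.0)),
    # capsule bundles (small femoral radii for near-isometry; the
    # posterior bundles slacken with flexion)
    "fem_cap_ant_l": (FEMUR, (4.0, 1.5)),
    "tib_cap_ant_l": (TIBIA, (4.0, -22.0)),
    "fem_cap_post_l": (FEMUR, (-7.0, 0.5)),
    "tib_cap_post_l": (TIBIA, (-7.0, -22.0)),
    "fem_cap_post_m": (FEMUR, (-7.0, 1.5)),
    "tib_cap_post_m": (TIBIA, (-7.0, -23.0)),
    # quadriceps: effective inferior-pole patella points (femur frame) and
    # the shared patellar-tendon insertion on the tibial tuberosity; the
    # anterior patella offset reproduces the anterior tendon tilt near
    # extension that pulls the tibia forward in stance
    "fem_patella_vl": (FEMUR, (47.0, 4.0)),
    "fem_patella_vm": (FEMUR, (48.0, 5.0)),
    "fem_patella_vi": (FEMUR, (48.0, 7.0)),
    "fem_patella_rf": (FEMUR, (49.0, 9.0)),
    "tib_patellar_tendon": (TIBIA, (35.0, -48.0)),
    # hamstrings: the three biarticular heads originate at the ischial
    # tuberosity (pelvis frame: offset from the hip center), so their
    # posterior obliquity on the tibia grows with hip flexion — large in
    # late swing, small in stance; the uniarticular short head stays on
    # the femoral shaft
    "pel_st": (PELVIS, (-66.0, -18.0)),
    "pel_sm": (PELVIS, (-70.0, -22.0)),
    "pel_bfl": (PELVIS, (-74.0, -18.0)),
    "fem_bfs": (FEMUR, (-12.0, 180.0)),
    "tib_st": (TIBIA, (-12.0, -30.0)),
    "tib_sm": (TIBIA, (-20.0, -20.0)),
    "tib_bfl": (TIBIA, (-20.0, -22.0)),
    "tib_bfs": (TIBIA, (-20.0, -22.0)),
    # gastrocnemii: posterior femoral condyle origins, calcaneal insertion
    "fem_gl": (FEMUR, (-18.0, 4.0)),
    "fem_gm": (FEMUR, (-16.0, 6.0)),
    "tib_gl": (TIBIA, (-55.0, -400.0)),
    "tib_gm": (TIBIA, (-50.0, -400.0)),
}


def default_geometry() -> KneeGeometry:
    """Literature-typical sagittal knee geometry.

    Invariants checked at construction: positive condyle radius, dish
    wider than condyle, cruciate AP ordering (femoral and tibial PCL
    sites posterior to the respective ACL sites).
    """
    sites = {name: Site(name, body, xy) for name, (body, xy) in _DEFAULT_SITES.items()}
    geo = KneeGeometry(sites=sites)
    _check_cruciate_ordering(geo)
    return geo


def _check_cruciate_ordering(geo: KneeGeometry) -> None:
    """Cruciate AP ordering: every PCL site posterior to every ACL site
    on the same body."""
    for body in ("fem", "tib"):
        pcl_x = max(geo.site(f"{body}_pcl_al").xy[0], geo.site(f"{body}_pcl_pm").xy[0])
        acl_x = min(geo.site(f"{body}_acl_a").xy[0], geo.site(f"{body}_acl_p").xy[0])
        if not pcl_x < acl_x:
            raise GeometryError(
                f"{body}: PCL sites must be posterior to ACL sites "
                f"(max PCL x={pcl_x}, min ACL x={acl_x})"
            )
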