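"""Ligament bundle set and the nonlinear force-strain law.

Fifteen elastic fascicles span the joint: two bundles each for the
cruciates (ACL, PCL) and the deep MCL, three each for the LCL and the
superficial MCL, and three capsule bundles.  Each fascicle is a straight
line-of-sight spring between a femoral and a tibial site with a toe
region: force rises quadratically with engineering strain up to a strain
limit (default 0.03) and linearly beyond, with value and slope continuous
at the limit:

    f(eps) = 0                         eps <= 0        (slack)
           = k * eps^2 / (2*eps_l)     0 < eps <= eps_l
           = k * (eps - eps_l/2)       eps >  eps_l

``k`` is the stiffness in newtons per unit strain.  Ligaments modelled by
several fascicles share the anatomical ligament's stiffness equally
(``split_stiffness``).  Reference lengths are calibrated so that every
bundle is exactly slack at the full-extension neutral state; per-bundle
reference-strain offsets are configurable.

PCL injury is modelled by scaling the stiffness of the two PCL bundles
by a common residual factor in [0, 1] — the law is linear in k, so
tension at fixed strain scales by exactly that factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import LookupError_, ParameterError
from .geometry import KneeGeometry, KneeState, flexion_rotation, site_position

__all__ = [
    "BUNDLE_NAMES",
    "LIGAMENT_GROUPS",
    "DEFAULT_LIGAMENT_STIFFNESS",
    "LigamentBundle",
    "LigamentSet",
    "bundle_strain",
    "bundle_tension",
    "split_stiffness",
    "scale_pcl_stiffness",
    "total_ligament_tension",
    "default_ligament_set",
]

#: the 15 fascicles, grouped per anatomical ligament
LIGAMENT_GROUPS: dict[str, tuple[str, ...]] = {
    "ACL": ("ACL-a", "ACL-p"),
    "PCL": ("PCL-al", "PCL-pm"),
    "LCL": ("LCL-ant", "LCL-int", "LCL-post"),
    "sMCL": ("sMCL-ant", "sMCL-int", "sMCL-post"),
    "dMCL": ("dMCL-1", "dMCL-2"),
    "Capsule": ("Cap-Ant-L", "Cap-Post-L", "Cap-Post-M"),
}

BUNDLE_NAMES: tuple[str, ...] = tuple(
    b for bundles in LIGAMENT_GROUPS.values() for b in bundles
)

#: per-ligament stiffness (N per unit strain) before bundle splitting.
#: Literature-typical calibration defaults (the model is not
#: subject-specific); see docs/methods.md.
DEFAULT_LIGAMENT_STIFFNESS: dict[str, float] = {
    "ACL": 10000.0,
    "PCL": 18000.0,
    "LCL": 6000.0,
    "sMCL": 8250.0,
    "dMCL": 5000.0,
    "Capsule": 9000.0,
}

_BUNDLE_SITES: dict[str, tuple[str, str]] = {
    "ACL-a": ("fem_acl_a", "tib_acl_a"),
    "ACL-p": ("fem_acl_p", "tib_acl_p"),
    "PCL-al": ("fem_pcl_al", "tib_pcl_al"),
    "PCL-pm": ("fem_pcl_pm", "tib_pcl_pm"),
    "LCL-ant": ("fem_lcl_ant", "tib_lcl_ant"),
    "LCL-int": ("fem_lcl_int", "tib_lcl_int"),
    "LCL-post": ("fem_lcl_post", "tib_lcl_post"),
    "sMCL-ant": ("fem_smcl_ant", "tib_smcl_ant"),
    "sMCL-int": ("fem_smcl_int", "tib_smcl_int"),
    "sMCL-post": ("fem_smcl_post", "tib_smcl_post"),
    "dMCL-1": ("fem_dmcl_1", "tib_dmcl_1"),
    "dMCL-2": ("fem_dmcl_2", "tib_dmcl_2"),
    "Cap-Ant-L": ("fem_cap_ant_l", "tib_cap_ant_l"),
    "Cap-Post-L": ("fem_cap_post_l", "tib_cap_post_l"),
    "Cap-Post-M": ("fem_cap_post_m", "tib_cap_post_m"),
}

DEFAULT_STRAIN_LIMIT = 0.03


@dataclass(frozen=True)
class LigamentBundle:
    """One elastic fascicle."""

    name: str
    femur_site: str
    tibia_site: str
    rest_length: float          # L0, mm
    stiffness: float            # k, N per unit strain
    strain_limit: float = DEFAULT_STRAIN_LIMIT

    def __post_init__(self) -> None:
        if self.rest_length <= 0:
            raise ParameterError(f"{self.name}: rest_length must be positive")
        if self.stiffness < 0:
            raise ParameterError(f"{self.name}: stiffness must be >= 0")
        if self.strain_limit <= 0:
            raise ParameterError(f"{self.name}: strain_limit must be positive")


def split_stiffness(k_ligament: float, n_bundles: int) -> float:
    """Per-bundle stiffness: the anatomical ligament's stiffness divided
    equally over its bundles."""
    if not isinstance(n_bundles, (int, np.integer)) or n_bundles < 1:
        raise ParameterError(f"n_bundles must be an integer >= 1, got {n_bundles}")
    return k_ligament / n_bundles


def bundle_strain(geometry: KneeGeometry, bundle: LigamentBundle,
                  state: KneeState) -> float:
    """Engineering strain (L - L0)/L0 at a knee state; negative = slack."""
    f = site_position(geometry, bundle.femur_site, state)
    t = site_position(geometry, bundle.tibia_site, state)
    length = float(np.hypot(*(f - t)))
    return (length - bundle.rest_length) / bundle.rest_length


def bundle_tension(strain, k, strain_limit=DEFAULT_STRAIN_LIMIT,
                   transition: str = "at_limit"):
    """Tension (N) of the quadratic-toe / linear spring law.

    Accepts scalars or arrays in ``strain``.  Zero (never negative) when
    slack.  Two C1 parameterizations of where the toe ends:

    ``at_limit`` (default)
        quadratic up to the strain limit itself, linear beyond:
        ``k*eps^2/(2*eps_l)`` then ``k*(eps - eps_l/2)``.
    ``double_limit``
        the classical formulation with the transition at twice the
        limit: ``k*eps^2/(4*eps_l)`` then ``k*(eps - eps_l)``.
    """
    if np.any(np.asarray(k) < 0):
        raise ParameterError("stiffness must be >= 0")
    if np.any(np.asarray(strain_limit) <= 0):
        raise ParameterError("strain_limit must be positive")
    eps = np.asarray(strain, dtype=float)
    if transition == "at_limit":
        toe = k * eps ** 2 / (2.0 * strain_limit)
        lin = k * (eps - strain_limit / 2.0)
        out = np.where(eps <= 0.0, 0.0,
                       np.where(eps <= strain_limit, toe, lin))
    elif transition == "double_limit":
        toe = k * eps ** 2 / (4.0 * strain_limit)
        lin = k * (eps - strain_limit)
        out = np.where(eps <= 0.0, 0.0,
                       np.where(eps <= 2.0 * strain_limit, toe, lin))
    else:
        raise ParameterError(
            f"toe transition must be at_limit|double_limit, got {transition!r}")
    if np.ndim(strain) == 0:
        return float(out)
    return out


@dataclass
class LigamentSet:
    """The ordered 15-bundle collection with per-bundle scaling factors.

    ``scales`` multiply stiffness (hence tension at fixed strain);
    ``scale_pcl_stiffness`` uses them to model residual PCL stiffness.
    """

    bundles: dict[str, LigamentBundle]
    scales: dict[str, float] = field(default_factory=dict)
    toe_transition: str = "at_limit"  # see bundle_tension

    def __post_init__(self) -> None:
        if set(self.bundles) != set(BUNDLE_NAMES):
            missing = set(BUNDLE_NAMES) - set(self.bundles)
            extra = set(self.bundles) - set(BUNDLE_NAMES)
            raise ParameterError(
                f"LigamentSet must contain exactly the 15 named bundles; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        self.scales = {name: self.scales.get(name, 1.0) for name in BUNDLE_NAMES}

    def __iter__(self):
        return iter(self.bundles.values())

    def bundle(self, name: str) -> LigamentBundle:
        try:
            return self.bundles[name]
        except KeyError:
            raise LookupError_(f"unknown bundle: {name!r}") from None

    def effective_stiffness(self, name: str) -> float:
        return self.bundle(name).stiffness * self.scales[name]

    # -- vectorized access used by the dynamics inner loop -------------
    def arrays(self, geometry: KneeGeometry):
        """(femur_xy[15,2], tibia_xy[15,2], L0[15], k_eff[15], eps_l[15])
        in the order of ``BUNDLE_NAMES``."""
        fem = np.array([geometry.site(self.bundles[n].femur_site).xy for n in BUNDLE_NAMES])
        tib = np.array([geometry.site(self.bundles[n].tibia_site).xy for n in BUNDLE_NAMES])
        L0 = np.array([self.bundles[n].rest_length for n in BUNDLE_NAMES])
        k = np.array([self.effective_stiffness(n) for n in BUNDLE_NAMES])
        eps_l = np.array([self.bundles[n].strain_limit for n in BUNDLE_NAMES])
        return fem, tib, L0, k, eps_l


def default_ligament_set(
    geometry: KneeGeometry,
    stiffness_table: dict[str, float] | None = None,
    strain_limit: float = DEFAULT_STRAIN_LIMIT,
    reference_strain: dict[str, float] | None = None,
    toe_transition: str = "at_limit",
) -> LigamentSet:
    """Build the 15-bundle set on a geometry.

    Rest lengths are set so each bundle is just slack (strain 0) at the
    full-extension neutral state, shifted by the optional per-bundle
    ``reference_strain`` (positive = pretension: L0 shortened so the
    neutral-state strain equals the given value).
    """
    table = dict(DEFAULT_LIGAMENT_STIFFNESS)
    if stiffness_table:
        unknown = set(stiffness_table) - set(table)
        if unknown:
            raise ParameterError(f"unknown ligaments in stiffness table: {sorted(unknown)}")
        table.update(stiffness_table)
    ref = reference_strain or {}
    neutral = KneeState()
    bundles: dict[str, LigamentBundle] = {}
    for lig, members in LIGAMENT_GROUPS.items():
        k_each = split_stiffness(table[lig], len(members))
        for name in members:
            fem_site, tib_site = _BUNDLE_SITES[name]
            f = site_position(geometry, fem_site, neutral)
            t = site_position(geometry, tib_site, neutral)
            length = float(np.hypot(*(f - t)))
            eps0 = ref.get(name, 0.0)
            bundles[name] = LigamentBundle(
                name=name, femur_site=fem_site, tibia_site=tib_site,
                rest_length=length / (1.0 + eps0),
                stiffness=k_each, strain_limit=strain_limit,
            )
    return LigamentSet(bundles=bundles, toe_transition=toe_transition)


def scale_pcl_stiffness(liga: LigamentSet, factor: float) -> LigamentSet:
    """Residual-PCL model: multiply both PCL bundle stiffness scales by
    ``factor`` in [0, 1]; every other bundle is untouched."""
    if not (0.0 <= factor <= 1.0):
        raise ParameterError(f"PCL residual factor must lie in [0, 1], got {factor}")
    scales = dict(liga.scales)
    for name in LIGAMENT_GROUPS["PCL"]:
        scales[name] = scales[name] * factor
    return replace(liga, scales=scales)


def total_ligament_tension(
    liga: LigamentSet, geometry: KneeGeometry, state: KneeState
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-ligament tensions (bundles summed) and per-bundle detail (N)."""
    per_bundle: dict[str, float] = {}
    for name in BUNDLE_NAMES:
        b = liga.bundles[name]
        eps = bundle_strain(geometry, b, state)
        per_bundle[name] = bundle_tension(eps, liga.effective_stiffness(name),
                                          b.strain_limit, liga.toe_transition)
    per_ligament = {
        lig: sum(per_bundle[n] for n in members)
        for lig, members in LIGAMENT_GROUPS.items()
    }
    return per_ligament, per_bundle
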