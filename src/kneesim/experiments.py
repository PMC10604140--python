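"""The two in-silico experiments and their outcome statistics.

Experiment 1 (PCL sweep): a progressive PCL injury is simulated by
scaling the stiffness of the two PCL bundles from 100 % down in 10 %
steps to 20 %, plus a most-critical 15 % condition, re-running the gait
simulation in each condition with identical driving data and muscle
forces.

Experiment 2 (hamstring sweep): starting from the 15 %-PCL knee, the
force of the four hamstring actuators is scaled to 90/80/70/60 % of the
Min/Max solution, probing hamstring relaxation as a compensation
strategy.

Outcomes are summarized per condition as the mean difference from the
reference curve over the late-swing analysis window (default 76-100 %
of the cycle, closed at both ends), and as windowed peaks with their
timing.  A least-squares polynomial (default degree 2) summarizes the
trend of the windowed mean difference across sweep factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import ContactParams, SimulationResult, simulate_gait
from .errors import AlignmentError, IntegrationError, ParameterError
from .gait import GaitCycle
from .geometry import BodyParams, KneeGeometry
from .ligaments import LigamentSet, scale_pcl_stiffness
from .muscles import MuscleSet, scale_group

__all__ = [
    "PCL_FACTORS_DEFAULT",
    "HAMSTRING_FACTORS_DEFAULT",
    "ANALYSIS_WINDOW_DEFAULT",
    "SweepSpec",
    "ConditionSummary",
    "SweepResult",
    "ModelBundle",
    "window_mean_diff",
    "window_mean",
    "peak_metric",
    "fit_trend",
    "run_pcl_sweep",
    "run_hamstring_sweep",
    "summary_table",
]

PCL_FACTORS_DEFAULT = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.15)
HAMSTRING_FACTORS_DEFAULT = (1.0, 0.9, 0.8, 0.7, 0.6)
ANALYSIS_WINDOW_DEFAULT = (0.76, 1.00)

#: variables summarized per condition
SUMMARY_VARIABLES = ("ap_displacement", "contact_force", "tension_ACL",
                     "tension_PCL", "tension_LCL", "tension_sMCL",
                     "tension_dMCL", "tension_Capsule")


@dataclass(frozen=True)
class SweepSpec:
    """Which sweep to run and how to summarize it."""

    experiment: str  # "pcl_sweep" | "hamstring_sweep"
    factors: tuple[float, ...] = ()
    analysis_window: tuple[float, float] = ANALYSIS_WINDOW_DEFAULT
    pcl_residual: float = 0.15       # hamstring sweep: fixed PCL condition
    trend_degree: int = 2

    def __post_init__(self) -> None:
        if self.experiment not in ("pcl_sweep", "hamstring_sweep"):
            raise ParameterError(
                f"experiment must be pcl_sweep|hamstring_sweep, got {self.experiment!r}")
        factors = self.factors or (
            PCL_FACTORS_DEFAULT if self.experiment == "pcl_sweep"
            else HAMSTRING_FACTORS_DEFAULT)
        object.__setattr__(self, "factors", tuple(factors))
        for f in self.factors:
            if not (0.0 < f <= 1.0):
                raise ParameterError(f"sweep factors must lie in (0, 1], got {f}")
        lo, hi = self.analysis_window
        if not (0.0 <= lo < hi <= 1.0):
            raise ParameterError(
                f"analysis_window must satisfy 0 <= lo < hi <= 1, got {self.analysis_window}")
        if 1.0 not in self.factors:
            raise ParameterError("the reference condition (factor 1.0) must be swept")


@dataclass
class ModelBundle:
    """Everything needed to simulate one knee: geometry, ligaments,
    muscles, driving gait, body and contact parameters."""

    geometry: KneeGeometry
    ligaments: LigamentSet
    muscles: MuscleSet
    gait: GaitCycle
    body: BodyParams
    contact: ContactParams
    n_cycles: int = 2
    dt: float = 0.02


@dataclass
class ConditionSummary:
    """Windowed statistics of one condition against the sweep reference."""

    label: str
    factor: float
    mean_diff: dict[str, float]          # variable -> windowed mean difference
    peak: dict[str, tuple[float, float]]  # variable -> (extreme, cycle fraction)


@dataclass
class SweepResult:
    spec: SweepSpec
    reference_label: str
    summaries: list[ConditionSummary]
    results: dict[str, SimulationResult]
    trend: dict[str, np.ndarray] = field(default_factory=dict)
    intact_contact: np.ndarray | None = None  # hamstring sweep only


# ---------------------------------------------------------------------------
# Windowed statistics
# ---------------------------------------------------------------------------

def _window_mask(t: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if not lo < hi:
        raise ParameterError(f"empty analysis window {window}")
    mask = (t >= lo - 1e-12) & (t <= hi + 1e-12)
    if not np.any(mask):
        raise ParameterError(f"analysis window {window} contains no samples")
    return mask


def window_mean_diff(series: np.ndarray, reference: np.ndarray,
                     t: np.ndarray, window=ANALYSIS_WINDOW_DEFAULT) -> float:
    """Mean of (series - reference) over the closed window of cycle
    fractions; the two series must share the sampling grid."""
    series = np.asarray(series, float)
    reference = np.asarray(reference, float)
    if series.shape != reference.shape or series.shape != np.shape(t):
        raise AlignmentError(
            f"series ({series.shape}), reference ({reference.shape}) and grid "
            f"({np.shape(t)}) must share one sampling grid")
    mask = _window_mask(np.asarray(t), window)
    return float(np.mean(series[mask] - reference[mask]))


def window_mean(series: np.ndarray, t: np.ndarray,
                window=ANALYSIS_WINDOW_DEFAULT) -> float:
    """Mean of a series over the closed window."""
    mask = _window_mask(np.asarray(t), window)
    return float(np.mean(np.asarray(series, float)[mask]))


def peak_metric(series: np.ndarray, t: np.ndarray,
                window=ANALYSIS_WINDOW_DEFAULT,
                sense: str = "max") -> tuple[float, float]:
    """Windowed extreme and the cycle fraction where it occurs.

    Ties are broken by the earliest sample.
    """
    if sense not in ("max", "min"):
        raise ParameterError(f"sense must be max|min, got {sense!r}")
    t = np.asarray(t)
    mask = _window_mask(t, window)
    vals = np.asarray(series, float)[mask]
    ts = t[mask]
    j = int(np.argmax(vals)) if sense == "max" else int(np.argmin(vals))
    return float(vals[j]), float(ts[j])


def fit_trend(factors, mean_diffs, degree: int = 2):
    """Least-squares polynomial over (factor, mean difference) pairs.

    Returns (coefficients highest-power-first, fitted values).
    """
    factors = np.asarray(factors, float)
    mean_diffs = np.asarray(mean_diffs, float)
    if degree < 0:
        raise ParameterError("trend degree must be >= 0")
    if len(factors) < degree + 1:
        raise ParameterError(
            f"need at least degree+1={degree + 1} points, got {len(factors)}")
    coeffs = np.polyfit(factors, mean_diffs, degree)
    return coeffs, np.polyval(coeffs, factors)


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

def _variables(result: SimulationResult) -> dict[str, np.ndarray]:
    out = {"ap_displacement": result.ap, "contact_force": result.contact_normal}
    for lig, series in result.ligament_tensions.items():
        out[f"tension_{lig}"] = series
    return out


def _summarize(label: str, factor: float, result: SimulationResult,
               reference: SimulationResult, window) -> ConditionSummary:
    vars_c = _variables(result)
    vars_r = _variables(reference)
    mean_diff = {
        name: window_mean_diff(vars_c[name], vars_r[name], result.t, window)
        for name in SUMMARY_VARIABLES
    }
    peak = {
        name: peak_metric(vars_c[name], result.t, window,
                          sense="min" if name == "ap_displacement" else "max")
        for name in SUMMARY_VARIABLES
    }
    return ConditionSummary(label=label, factor=factor,
                            mean_diff=mean_diff, peak=peak)


def _intact_muscle_forces(bundle: ModelBundle) -> np.ndarray:
    """Min/Max solution on the intact driving kinematics; computed once
    and reused across conditions (muscle forces are an experiment input,
    not re-optimized per condition)."""
    from .dynamics import KneeModel

    model = KneeModel(bundle.geometry, bundle.ligaments, bundle.muscles,
                      bundle.gait, bundle.body, bundle.contact)
    return model.base_muscle_forces


def run_pcl_sweep(bundle: ModelBundle, spec: SweepSpec | None = None) -> SweepResult:
    """Simulate every PCL residual-stiffness condition and summarize it
    against the intact (factor 1.0) reference."""
    spec = spec or SweepSpec(experiment="pcl_sweep")
    if spec.experiment != "pcl_sweep":
        raise ParameterError("spec.experiment must be 'pcl_sweep'")
    forces = _intact_muscle_forces(bundle)
    results: dict[str, SimulationResult] = {}
    labels = {}
    for f in spec.factors:
        label = f"PCL-{f * 100:g}%"
        labels[f] = label
        liga = scale_pcl_stiffness(bundle.ligaments, f)
        try:
            results[label] = simulate_gait(
                bundle.geometry, liga, bundle.muscles, bundle.gait, bundle.body,
                bundle.contact, n_cycles=bundle.n_cycles, dt=bundle.dt,
                muscle_forces=forces, condition=label)
        except IntegrationError as exc:
            raise IntegrationError(
                f"PCL sweep aborted at condition {label!r}; completed "
                f"conditions: {sorted(results)}: {exc}") from exc
    ref_label = labels[1.0]
    reference = results[ref_label]
    summaries = [
        _summarize(labels[f], f, results[labels[f]], reference,
                   spec.analysis_window)
        for f in spec.factors
    ]
    trend = _fit_sweep_trends(spec, summaries)
    return SweepResult(spec=spec, reference_label=ref_label,
                       summaries=summaries, results=results, trend=trend)


def run_hamstring_sweep(bundle: ModelBundle,
                        spec: SweepSpec | None = None) -> SweepResult:
    """Simulate hamstring residual-force conditions on the PCL-deficient
    knee (residual stiffness ``spec.pcl_residual``), referenced to the
    full-force condition; the intact-knee contact curve is attached for
    comparison."""
    spec = spec or SweepSpec(experiment="hamstring_sweep")
    if spec.experiment != "hamstring_sweep":
        raise ParameterError("spec.experiment must be 'hamstring_sweep'")
    forces = _intact_muscle_forces(bundle)
    liga_def = scale_pcl_stiffness(bundle.ligaments, spec.pcl_residual)
    results: dict[str, SimulationResult] = {}
    labels = {}
    for f in spec.factors:
        label = f"PCL{spec.pcl_residual * 100:g}%-Ham{f * 100:g}%"
        labels[f] = label
        muscles = scale_group(bundle.muscles, "hamstrings", f)
        try:
            results[label] = simulate_gait(
                bundle.geometry, liga_def, muscles, bundle.gait, bundle.body,
                bundle.contact, n_cycles=bundle.n_cycles, dt=bundle.dt,
                muscle_forces=forces, condition=label)
        except IntegrationError as exc:
            raise IntegrationError(
                f"hamstring sweep aborted at condition {label!r}; completed "
                f"conditions: {sorted(results)}: {exc}") from exc
    ref_label = labels[1.0]
    reference = results[ref_label]
    summaries = [
        _summarize(labels[f], f, results[labels[f]], reference,
                   spec.analysis_window)
        for f in spec.factors
    ]
    intact = simulate_gait(
        bundle.geometry, bundle.ligaments, bundle.muscles, bundle.gait,
        bundle.body, bundle.contact, n_cycles=bundle.n_cycles, dt=bundle.dt,
        muscle_forces=forces, condition="IntactKnee")
    trend = _fit_sweep_trends(spec, summaries)
    return SweepResult(spec=spec, reference_label=ref_label,
                       summaries=summaries, results=results, trend=trend,
                       intact_contact=intact.contact_normal)


def _fit_sweep_trends(spec: SweepSpec, summaries) -> dict[str, np.ndarray]:
    factors = [s.factor for s in summaries]
    trend = {}
    for name in SUMMARY_VARIABLES:
        diffs = [s.mean_diff[name] for s in summaries]
        coeffs, _fitted = fit_trend(factors, diffs, spec.trend_degree)
        trend[name] = coeffs
    return trend


def summary_table(sweep: SweepResult):
    """Long-format DataFrame of the per-condition windowed statistics."""
    import pandas as pd

    rows = []
    for s in sweep.summaries:
        for name in SUMMARY_VARIABLES:
            peak_val, peak_t = s.peak[name]
            rows.append({
                "condition": s.label,
                "factor": s.factor,
                "variable": name,
                "window_mean_diff": s.mean_diff[name],
                "peak_value": peak_val,
                "peak_cycle_fraction": peak_t,
                "reference": sweep.reference_label,
                "window_lo": sweep.spec.analysis_window[0],
                "window_hi": sweep.spec.analysis_window[1],
            })
    return pd.DataFrame(rows)
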