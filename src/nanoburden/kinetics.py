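"""Inhalation dosimetry and first-order lung clearance kinetics.

Deposited dose bookkeeping for a nose-only rat inhalation study:

* ventilation rate = 0.8 L/min per kg body weight (the standard allometric
  coefficient for rats);
* total applied (inhaled) mass [mg] = exposure time [min] × ventilation
  rate [L/min] × aerosol concentration [mg/m³] / 1000;
* deposition fraction = retained lung burden / applied mass × 100;
* clearance of poorly soluble particles is treated as first-order,
  ``N(t) = N0 · exp(−λ t)`` with retention half-time t½ = ln 2 / λ, fitted
  per phase when the time course is biphasic (fast tracheobronchial phase,
  slow alveolar phase — the latter prolonged under lung overload).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExposureScenario",
    "BurdenObservation",
    "ClearancePhase",
    "ClearanceFit",
    "ventilation_rate",
    "total_applied_mass",
    "deposition_fraction",
    "clearance_fit",
    "overload_check",
    "MPPD_PREDICTED_DEPOSITION_PCT",
]

#: Pulmonary deposition fractions (%) predicted by the MPPD software for the
#: two study aerosols — comparison constants, not recomputed here.
MPPD_PREDICTED_DEPOSITION_PCT = {"PS-NR": 6.8, "PA-6": 6.9}

#: Morrow lung-overload threshold for poorly soluble unit-density particles
OVERLOAD_THRESHOLD_MG_PER_G = 1.0


@dataclass(frozen=True)
class ExposureScenario:
    """A repeated nose-only exposure: concentration × schedule × animal."""

    concentration_mg_m3: float
    minutes_per_day: float = 360.0
    exposure_days: int = 20  # 5 days/week over 4 weeks
    body_weight_kg: float = 0.270
    ventilation_coeff_l_min_kg: float = 0.8

    def __post_init__(self) -> None:
        if self.concentration_mg_m3 <= 0 or self.minutes_per_day <= 0:
            raise ValueError("concentration and daily minutes must be positive")
        if self.exposure_days < 0:
            raise ValueError("exposure days must be >= 0")
        if self.body_weight_kg <= 0 or self.ventilation_coeff_l_min_kg < 0:
            raise ValueError("body weight must be positive, coefficient >= 0")


@dataclass(frozen=True)
class BurdenObservation:
    """Mean organ burden of one sacrifice group."""

    day: float
    burden: float
    organ: str = "lung"
    n: int = 1
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("day must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class ClearancePhase:
    start_day: float
    end_day: float
    lam_per_day: float
    half_time_days: float
    n_points: int


@dataclass
class ClearanceFit:
    """Phase-wise first-order clearance fit.

    ``n0`` is the burden at day 0 (the fitted intercept of the first
    phase); each phase satisfies t½ × λ = ln 2 and ``predict`` is
    continuous across phase boundaries.
    """

    n0: float
    phases: list[ClearancePhase] = field(default_factory=list)
    days_used: list[float] = field(default_factory=list)

    def predict(self, day: float) -> float:
        if day < 0:
            raise ValueError("day must be >= 0")
        value, t = self.n0, 0.0
        for phase in self.phases:
            seg_end = phase.end_day
            if day <= seg_end or phase is self.phases[-1]:
                return value * math.exp(-phase.lam_per_day * (day - t))
            value *= math.exp(-phase.lam_per_day * (seg_end - t))
            t = seg_end
        return value


def ventilation_rate(body_weight_kg: float,
                     coeff_l_min_kg: float = 0.8) -> float:
    """Lung ventilation rate (L/min), unrounded: coefficient × body weight.

    A zero coefficient is degenerate (no ventilation) and flagged with a
    warning rather than rejected."""
    if body_weight_kg <= 0:
        raise ValueError("body weight must be positive")
    if coeff_l_min_kg < 0:
        raise ValueError("ventilation coefficient must be >= 0")
    if coeff_l_min_kg == 0:
        warnings.warn("ventilation coefficient is 0; rate degenerates to 0")
    return coeff_l_min_kg * body_weight_kg


def total_applied_mass(scenario: ExposureScenario) -> float:
    """Total inhaled mass (mg) over the whole exposure schedule.

    Uses the unrounded ventilation rate internally; rounding the rate for
    display (e.g. 0.216 → 0.22 L/min) is presentation only."""
    minutes = scenario.minutes_per_day * scenario.exposure_days
    rate = ventilation_rate(scenario.body_weight_kg,
                            scenario.ventilation_coeff_l_min_kg)
    return minutes * rate * scenario.concentration_mg_m3 / 1000.0


def deposition_fraction(lung_burden_mg: float, applied_mass_mg: float) -> float:
    """Retained lung burden as percent of the total applied mass."""
    if applied_mass_mg <= 0:
        raise ValueError("applied mass must be positive")
    if lung_burden_mg < 0:
        raise ValueError("burden must be >= 0")
    return 100.0 * lung_burden_mg / applied_mass_mg


def _fit_segment(days: np.ndarray, burdens: np.ndarray) -> tuple[float, float]:
    """Log-linear fit of one clearance segment.

    Returns (λ per day, burden at segment start).  With exactly two points
    this reduces to the closed form λ = ln(N_start/N_end) / Δt."""
    logs = np.log(burdens)
    if days.size == 2:
        lam = (logs[0] - logs[1]) / (days[1] - days[0])
        return float(lam), float(burdens[0])
    slope, intercept = np.polyfit(days, logs, 1)
    return float(-slope), float(np.exp(intercept + slope * days[0]))


def clearance_fit(observations, phase_boundaries=None) -> ClearanceFit:
    """Fit first-order clearance to a burden time course.

    ``observations`` is a list of :class:`BurdenObservation` (or
    ``(day, burden)`` pairs).  Without ``phase_boundaries`` one global
    phase is fitted; with boundaries (interior sampling days, e.g. the
    5-week sacrifice at day 35) each consecutive interval is fitted
    separately, which is the interval-wise biphasic convention.  Two
    points per phase give the closed-form λ; more give a log-linear
    least-squares fit.  An increasing burden yields a negative λ with a
    warning (growth, not clearance).
    """
    obs = [o if isinstance(o, BurdenObservation) else BurdenObservation(*o)
           for o in observations]
    obs.sort(key=lambda o: o.day)
    days = np.array([o.day for o in obs], dtype=float)
    burdens = np.array([o.burden for o in obs], dtype=float)
    if days.size < 2:
        raise ValueError("at least two timepoints required")
    if (burdens <= 0).any():
        raise ValueError("burdens must be positive for a log-linear fit")

    bounds = sorted(phase_boundaries) if phase_boundaries else []
    edges = [days[0], *[b for b in bounds if days[0] < b < days[-1]], days[-1]]
    phases: list[ClearancePhase] = []
    n0 = None
    for start, end in zip(edges[:-1], edges[1:]):
        sel = (days >= start) & (days <= end)
        if sel.sum() < 2:
            raise ValueError(f"phase [{start}, {end}] has fewer than 2 timepoints")
        lam, n_start = _fit_segment(days[sel], burdens[sel])
        if lam <= 0:
            warnings.warn(f"burden increases over [{start}, {end}]; "
                          "negative clearance constant reported (growth)")
            half = math.inf if lam == 0 else math.log(2.0) / lam
        else:
            half = math.log(2.0) / lam
        phases.append(ClearancePhase(start_day=float(start), end_day=float(end),
                                     lam_per_day=lam, half_time_days=half,
                                     n_points=int(sel.sum())))
        if n0 is None:
            n0 = n_start
    return ClearanceFit(n0=float(n0), phases=phases, days_used=list(days))


def overload_check(burden_mg: float, lung_weight_g: float,
                   threshold_mg_per_g: float = OVERLOAD_THRESHOLD_MG_PER_G,
                   ) -> tuple[float, bool]:
    """Lung-overload screen against the ~1 mg/g threshold for poorly
    soluble low-toxicity particles.

    Returns (burden/weight ratio in mg/g, flag).  The flag uses a strict
    inequality: exactly at threshold is not flagged."""
    if lung_weight_g <= 0:
        raise ValueError("lung weight must be positive")
    ratio = burden_mg / lung_weight_g
    return ratio, ratio > threshold_mg_per_g
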