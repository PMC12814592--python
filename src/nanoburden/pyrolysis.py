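"""Polymer mass quantification from Py-GC/MS marker-fragment peak areas.

Organ burdens of an unlabelled polymer (PA-6, via its caprolactam marker
fragment, m/z 113 — metadata only, the chromatography itself is not
modelled) are obtained by external calibration: a dilution series of
polymer standards is pyrolysed, the peak area regressed on analyte mass,
and sample crucible masses back-calculated and scaled to the whole organ
by the extract-to-aliquot dilution factor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationCurve",
    "PyroSample",
    "DetectionLimits",
    "fit_calibration",
    "quantify_organ",
    "detection_limits",
    "spike_recovery",
    "calibration_standard_mass",
    "censored_mean",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted external calibration line ``area = intercept + slope × mass``.

    ``replicates`` holds the calibration table (mass_ng, peak_area) used;
    ``lowest_mass_ng`` and ``lowest_mass_sd_ng`` summarise the replicate
    scatter at the lowest standard, expressed on the mass scale, for
    detection-limit estimation.
    """

    slope: float
    intercept: float
    residual_sd: float
    mass_range_ng: tuple
    lowest_mass_ng: float
    lowest_mass_sd_ng: float | None = None
    replicates: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("a valid calibration has positive slope")
        if self.mass_range_ng[0] <= 0:
            raise ValueError("calibrated range must start above zero")


@dataclass(frozen=True)
class PyroSample:
    """One organ sample: peak area of the aliquot pyrolysed from the
    organ's solvent extract."""

    peak_area: float
    aliquot_ul: float
    extract_ml: float
    organ_wet_mass_g: float | None = None
    organ: str = "lung"

    def __post_init__(self) -> None:
        if self.aliquot_ul <= 0 or self.extract_ml <= 0:
            raise ValueError("aliquot and extract volumes must be positive")
        if self.aliquot_ul > self.extract_ml * 1000.0:
            raise ValueError("aliquot cannot exceed the extract volume")
        if self.organ_wet_mass_g is not None and self.organ_wet_mass_g <= 0:
            raise ValueError("organ wet mass must be positive")

    @property
    def dilution_factor(self) -> float:
        """Extract volume over aliquot volume (crucible → organ scale-up)."""
        return self.extract_ml * 1000.0 / self.aliquot_ul


@dataclass(frozen=True)
class DetectionLimits:
    """Organ-scale detection and quantification limits (µg/organ)."""

    lod_ug: float
    loq_ug: float
    dilution_factor: float

    def __post_init__(self) -> None:
        if not (0 < self.lod_ug <= self.loq_ug):
            raise ValueError("need 0 < LOD <= LOQ")


def calibration_standard_mass(stock_mg: float, flask_ml: float = 25.0,
                              transfer_ul: float = 50.0, final_ml: float = 10.0,
                              pipetted_ul: float = 3.0) -> float:
    """Analyte mass (ng) in one calibration crucible prepared by the
    two-step dilution scheme: ``stock_mg`` polymer in ``flask_ml`` solvent,
    ``transfer_ul`` of stock diluted to ``final_ml``, and ``pipetted_ul``
    of the working solution evaporated in the crucible."""
    conc_ng_ul = stock_mg / flask_ml * 1e6 / 1000.0  # mg/mL -> ng/µL
    working = conc_ng_ul * transfer_ul / (final_ml * 1000.0)
    return working * pipetted_ul


def fit_calibration(masses_ng, areas) -> CalibrationCurve:
    """Ordinary least-squares line through the calibration series.

    The intercept is free (it absorbs instrument baseline); the residual
    SD uses n − 2 degrees of freedom.  At least 3 distinct masses are
    required.
    """
    m = np.asarray(masses_ng, dtype=float)
    a = np.asarray(areas, dtype=float)
    if m.shape != a.shape or m.ndim != 1:
        raise ValueError("masses and areas must be matching 1-D sequences")
    if np.unique(m).size < 3:
        raise ValueError("need at least 3 distinct calibration masses")
    slope, intercept = np.polyfit(m, a, 1)
    resid = a - (intercept + slope * m)
    dof = m.size - 2
    residual_sd = float(np.sqrt((resid**2).sum() / dof)) if dof > 0 else 0.0
    if slope <= 0:
        raise ValueError("calibration slope is not positive; invalid curve")
    lowest = float(m.min())
    at_lowest = a[m == lowest]
    sd_mass = float(at_lowest.std(ddof=1) / slope) if at_lowest.size > 1 else None
    return CalibrationCurve(
        slope=float(slope), intercept=float(intercept), residual_sd=residual_sd,
        mass_range_ng=(lowest, float(m.max())), lowest_mass_ng=lowest,
        lowest_mass_sd_ng=sd_mass,
        replicates=pd.DataFrame({"mass_ng": m, "peak_area": a}),
    )


def quantify_organ(sample: PyroSample, curve: CalibrationCurve) -> dict:
    """Back-calculate the polymer burden of one organ.

    crucible mass [ng] = (area − intercept) / slope; organ mass scales by
    the dilution factor (extract volume / aliquot volume); the per-gram
    value divides by the wet organ mass.  Areas below the intercept are
    reported as 0 with ``below_range=True`` rather than as negative mass.
    """
    crucible_ng = (sample.peak_area - curve.intercept) / curve.slope
    below = crucible_ng < 0
    if below:
        crucible_ng = 0.0
    organ_ug = crucible_ng * sample.dilution_factor / 1000.0
    out = {
        "organ": sample.organ,
        "crucible_mass_ng": crucible_ng,
        "mass_per_organ_ug": organ_ug,
        "below_range": bool(below),
    }
    if sample.organ_wet_mass_g is not None:
        out["mass_per_g_mg"] = organ_ug / 1000.0 / sample.organ_wet_mass_g
    return out


def detection_limits(curve: CalibrationCurve, dilution_factor: float,
                     k: float | None = None) -> DetectionLimits:
    """Organ-scale LOD/LOQ from the lowest calibration standard.

    LOQ = lowest calibrated mass × dilution factor.  LOD subtracts a
    replicate-scatter margin before scaling:
    ``LOD = (lowest − k × SD_lowest) × dilution``.  When ``k`` is omitted
    the margin defaults to 20% of the lowest mass (the convention that
    makes LOD/LOQ ratios of ~0.8 internally consistent); when no replicate
    SD is available LOD falls back to LOQ with a warning.
    """
    if dilution_factor <= 0:
        raise ValueError("dilution factor must be positive")
    loq_ug = curve.lowest_mass_ng * dilution_factor / 1000.0
    if k is None:
        margin = 0.2 * curve.lowest_mass_ng
    elif curve.lowest_mass_sd_ng is None:
        warnings.warn("no replicate SD at the lowest standard; LOD set to LOQ")
        margin = 0.0
    else:
        margin = k * curve.lowest_mass_sd_ng
    margin = min(margin, 0.999 * curve.lowest_mass_ng)  # keep LOD positive
    lod_ug = (curve.lowest_mass_ng - margin) * dilution_factor / 1000.0
    return DetectionLimits(lod_ug=lod_ug, loq_ug=loq_ug,
                           dilution_factor=dilution_factor)


def spike_recovery(measured_ug: float, spiked_ug: float,
                   endogenous_ug: float = 0.0) -> float:
    """Spike recovery in percent: 100 × (measured − endogenous) / spiked."""
    if spiked_ug <= 0:
        raise ValueError("spiked amount must be positive")
    return 100.0 * (measured_ug - endogenous_ug) / spiked_ug


def censored_mean(values_ug, lod_ug: float, substitute: str = "half_lod") -> float:
    """Group mean over results censored at the detection limit.

    Values below ``lod_ug`` are substituted with LOD/2 (``"half_lod"``,
    default) or dropped (``"exclude"``) before averaging — censored
    animals are never counted as zero.
    """
    v = np.asarray(values_ug, dtype=float)
    censored = v < lod_ug
    if substitute == "half_lod":
        v = np.where(censored, lod_ug / 2.0, v)
    elif substitute == "exclude":
        v = v[~censored]
        if v.size == 0:
            raise ValueError("all values censored; no mean available")
    else:
        raise ValueError(f"unknown substitution rule: {substitute!r}")
    return float(v.mean())
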