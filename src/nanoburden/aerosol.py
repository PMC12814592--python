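"""Aerosol metrics: gravimetric concentration and impactor MMAD/GSD.

The exposure atmosphere is characterised two ways: filter samples drawn at
a known flow give the gravimetric mass concentration, and an 8-stage
Marple personal cascade impactor partitions the aerosol by aerodynamic
diameter.  For a lognormal aerosol the cumulative undersize mass fraction
at cutoff ``c`` is ``Φ((ln c − ln MMAD)/ln GSD)``, so probit-transformed
cumulative fractions regressed on ``ln c`` recover MMAD and GSD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FilterSample",
    "ImpactorRun",
    "AerosolSummary",
    "gravimetric_concentration",
    "summarize_filters",
    "fit_mmad_gsd",
]


@dataclass(frozen=True)
class FilterSample:
    """One gravimetric filter sample."""

    mass_gain_mg: float
    flow_l_min: float = 3.0
    sampling_min: float = 40.0

    def __post_init__(self) -> None:
        if self.mass_gain_mg < 0:
            raise ValueError("mass gain must be >= 0")
        if not (self.flow_l_min > 0 and self.sampling_min > 0):
            raise ValueError("flow and sampling time must be positive")

    @property
    def sampled_volume_m3(self) -> float:
        return self.flow_l_min * self.sampling_min / 1000.0


@dataclass(frozen=True)
class ImpactorRun:
    """Cascade impactor stage masses with their effective cutoff diameters
    (µm, strictly decreasing) plus the backup-filter mass."""

    cutoffs_um: tuple
    stage_masses_mg: tuple
    filter_mass_mg: float = 0.0

    #: effective aerodynamic cutoff diameters of the 8-stage Marple impactor
    MARPLE_CUTOFFS_UM = (21.0, 15.0, 10.0, 6.5, 3.5, 1.0, 0.7, 0.4)

    def __post_init__(self) -> None:
        cut = np.asarray(self.cutoffs_um, float)
        if cut.size < 4:
            raise ValueError("at least 4 stages required")
        if not (np.diff(cut) < 0).all():
            raise ValueError("cutoffs must be strictly decreasing")
        if len(self.stage_masses_mg) != cut.size:
            raise ValueError("one mass per stage required")
        if (np.asarray(self.stage_masses_mg, float) < 0).any() or self.filter_mass_mg < 0:
            raise ValueError("stage masses must be >= 0")

    @property
    def total_mass_mg(self) -> float:
        return float(np.sum(self.stage_masses_mg) + self.filter_mass_mg)

    def cumulative_undersize(self) -> pd.DataFrame:
        """Fraction of total mass below each cutoff (the backup filter is
        counted as the sub-range below the last cutoff, closing the mass
        balance)."""
        stage = np.asarray(self.stage_masses_mg, float)
        total = self.total_mass_mg
        if total <= 0:
            raise ValueError("run contains no mass")
        tail = np.cumsum(stage[::-1])[:-1]
        below = np.concatenate((tail[::-1], [0.0])) + self.filter_mass_mg
        return pd.DataFrame({
            "cutoff_um": np.asarray(self.cutoffs_um, float),
            "undersize_fraction": below / total,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ImpactorRun":
        """Build a run from a table with ``cutoff_um`` and ``mass_mg``
        columns; a row with missing cutoff is the backup filter."""
        is_filter = df["cutoff_um"].isna()
        stages = df[~is_filter].sort_values("cutoff_um", ascending=False)
        filt = float(df.loc[is_filter, "mass_mg"].sum())
        return cls(cutoffs_um=tuple(stages["cutoff_um"]),
                   stage_masses_mg=tuple(stages["mass_mg"]),
                   filter_mass_mg=filt)


@dataclass(frozen=True)
class AerosolSummary:
    """Atmosphere summary: gravimetric concentration, impactor MMAD/GSD and
    the SMPS pass-through statistics (total count concentration and
    geometric mean diameter are instrument means, not refit here)."""

    mean_concentration_mg_m3: float
    sd_concentration_mg_m3: float
    mmad_um: float
    gsd: float
    tcc_n_cm3: float | None = None
    gmd_nm: float | None = None

    def __post_init__(self) -> None:
        if self.gsd < 1:
            raise ValueError("GSD must be >= 1")
        if self.mmad_um <= 0:
            raise ValueError("MMAD must be positive")


def gravimetric_concentration(sample: FilterSample) -> float:
    """Aerosol mass concentration (mg/m³) from one filter sample."""
    vol = sample.sampled_volume_m3
    if vol <= 0:
        raise ValueError("sampled volume must be positive")
    return sample.mass_gain_mg / vol


def summarize_filters(samples) -> tuple[float, float]:
    """Mean ± SD concentration (mg/m³) over replicate filter samples."""
    conc = np.array([gravimetric_concentration(s) for s in samples])
    if conc.size == 0:
        raise ValueError("no filter samples")
    sd = float(conc.std(ddof=1)) if conc.size > 1 else 0.0
    return float(conc.mean()), sd


def fit_mmad_gsd(run: ImpactorRun) -> tuple[float, float]:
    """Estimate (MMAD µm, GSD) by log-probit regression.

    Probit-transformed cumulative undersize fractions are regressed,
    unweighted, on ln(cutoff); endpoints at exactly 0 or 1 are excluded
    (the probit is undefined there).  MMAD = exp(−intercept/slope),
    GSD = exp(1/slope).
    """
    stage = np.asarray(run.stage_masses_mg, float)
    total = run.total_mass_mg
    if total <= 0:
        raise ValueError("run contains no mass")
    # Tail fractions accumulated from the small side of each tail to avoid
    # cancellation: the probit of a fraction near 1 is evaluated through
    # the (accurately known) opposite tail.
    oversize = np.cumsum(stage) / total
    # mass below each cutoff, accumulated small-side-first (no subtraction
    # through the dominant stage, which would cancel catastrophically)
    tail = np.cumsum(stage[::-1])[:-1]
    under_tail = np.concatenate((tail[::-1], [0.0]))
    undersize = (under_tail + run.filter_mass_mg) / total
    interior = (undersize > 0) & (oversize > 0)
    if interior.sum() < 3:
        raise ValueError(
            "degenerate impactor run: need >= 3 cumulative points strictly "
            "between 0 and 1 (all mass on one stage, or monodisperse aerosol)"
        )
    x = np.log(np.asarray(run.cutoffs_um, float)[interior])
    u = undersize[interior]
    v = oversize[interior]
    y = np.where(u <= 0.5, stats.norm.ppf(u), -stats.norm.ppf(v))
    fit = stats.linregress(x, y)
    if fit.slope <= 0:
        raise ValueError("non-increasing size distribution; cannot fit MMAD/GSD")
    mmad = math.exp(-fit.intercept / fit.slope)
    gsd = math.exp(1.0 / fit.slope)
    return mmad, gsd
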