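"""Bundled measurements from a 28-day nose-only rat inhalation study of
two nanoplastics: Nile-Red labelled polystyrene (PS-NR, quantified by
confocal microscopy) and polyamide-6 (PA-6, quantified by Py-GC/MS).

These small published summary tables are the real-data entry points of
the pipeline: per-animal confocal particle counts and mass concentrations,
group-mean organ burdens over the post-exposure period, the aerosol
characterisation, and the study design constants.  Exposure groups: MG =
main group (sacrificed one day after the last exposure), PEG1/PEG2 =
post-exposure observation groups (~5 and ~13 weeks later).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "confocal_particle_table",
    "pa6_lung_burden_by_concentration",
    "pa6_burden_timecourse",
    "aerosol_summary_table",
    "study_design",
    "CONFOCAL_LOQ_AGGLOMERATE_UM3",
    "CONFOCAL_SCANNED_VOLUME_MM3",
    "PS_PEG1_LUNG_HALF_TIME_PRINTED_DAYS",
]

#: smallest quantifiable single agglomerate volume in the confocal workflow
CONFOCAL_LOQ_AGGLOMERATE_UM3 = 0.0004
#: total tissue volume examined per organ in the confocal workflow (mm³)
CONFOCAL_SCANNED_VOLUME_MM3 = 0.43
#: the study's reported PS lung retention half-time (days), computed there
#: from unrounded group means; recomputation from the rounded table below
#: gives ~50.6 d (see docs/methods.md)
PS_PEG1_LUNG_HALF_TIME_PRINTED_DAYS = 46.0


def confocal_particle_table() -> pd.DataFrame:
    """Per-animal confocal counts and mass concentrations (PS-NR, 50 mg/m³).

    Columns: group, animal, organ, particles (absolute number detected),
    mass_ng_per_100um3 (polymer mass per (100 µm)³ of scanned tissue).
    """
    rows = [
        ("MG", 266, "lung", 6073, 0.24), ("MG", 266, "LN", 17012, 0.66),
        ("MG", 279, "lung", 9131, 0.31), ("MG", 279, "LN", 14194, 0.74),
        ("MG", 281, "lung", 12261, 0.72), ("MG", 281, "LN", 1702, 0.04),
        ("PEG1", 311, "lung", 10258, 0.40), ("PEG1", 311, "LN", 14, 0.01),
        ("PEG1", 321, "lung", 1701, 0.12), ("PEG1", 321, "LN", 3445, 0.14),
    ]
    return pd.DataFrame(rows, columns=["group", "animal", "organ",
                                       "particles", "mass_ng_per_100um3"])


def pa6_lung_burden_by_concentration() -> pd.DataFrame:
    """Main-group PA-6 lung burdens vs aerosol concentration.

    Columns: concentration_mg_m3, lung_burden_mg (mean per lung, wet
    weight), lung_weight_g (group mean), n (animals)."""
    rows = [(2.0, 0.26, 0.91, 5), (10.0, 1.2, 0.94, 5), (50.0, 3.8, 1.05, 5)]
    return pd.DataFrame(rows, columns=["concentration_mg_m3", "lung_burden_mg",
                                       "lung_weight_g", "n"])


def pa6_burden_timecourse() -> pd.DataFrame:
    """PA-6 group-mean burdens over the post-exposure period (50 mg/m³).

    Lung burdens in mg, lymph-node (LN) burdens in µg per node.  The
    day-35 lung value (2.74 mg) is not tabulated in the study report; it
    is back-calculated from the 226-day slow-phase half-time and the
    2.31 mg endpoint and flagged ``derived``.
    """
    rows = [
        ("lung", 0.0, 3.8, "mg", 5, False),
        ("lung", 35.0, 2.74, "mg", 5, True),
        ("lung", 91.0, 2.31, "mg", 5, False),
        ("LN", 0.0, 2.95, "ug", 5, False),
        ("LN", 91.0, 126.29, "ug", 5, False),
    ]
    return pd.DataFrame(rows, columns=["organ", "day", "burden", "unit",
                                       "n", "derived"])


def aerosol_summary_table() -> pd.DataFrame:
    """Measured atmospheres: gravimetric concentration mean ± SD,
    impactor MMAD/GSD, SMPS total count concentration and geometric mean
    diameter (instrument averages of four determinations)."""
    cols = ["particle", "target_mg_m3", "mean_mg_m3", "sd_mg_m3",
            "mmad_um", "gsd", "tcc_n_cm3", "gmd_nm"]
    rows = [
        ("PS-NR", 5.0, 5.2, 0.4, 1.39, 2.43, 19408, 220),
        ("PS-NR", 50.0, 50.7, 2.3, 1.32, 2.11, 39541, 253),
        ("PA-6", 2.0, 2.1, 0.2, 0.77, 2.68, 31069, 139),
        ("PA-6", 10.0, 10.3, 0.6, 1.24, 2.20, 35325, 206),
        ("PA-6", 50.0, 50.9, 3.1, 1.51, 2.04, 47772, 285),
    ]
    return pd.DataFrame(rows, columns=cols)


def study_design() -> dict:
    """Exposure design and organ constants used in the dosimetry."""
    return {
        "minutes_per_day": 360.0,          # 6 h/day
        "exposure_days": 20,               # 5 days/week for 4 weeks
        "body_weight_kg": {"PS-NR": 0.270, "PA-6": 0.200},
        "ventilation_coeff_l_min_kg": 0.8,
        "high_concentration_mg_m3": 50.0,
        "lung_volume_ml": 10.0,
        "ln_volume_ml": 0.03,
        "ps_lung_weight_g": 1.63,
        "sacrifice_days": {"MG": 0.0, "PEG1": 35.0, "PEG2": 91.0},
        "filter_sampling_min": {"low": 120.0, "high": 40.0},
        "filter_flow_l_min": 3.0,
    }
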