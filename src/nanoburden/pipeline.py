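"""End-to-end study orchestration: synthetic study → organ burdens →
clearance kinetics → summary table.

A single YAML config describes one polymer's study arm (exposure
scenario, analysis mode, organ constants, generator settings, master
seed).  ``run_study`` executes the stages, writes per-stage CSV artifacts
plus ``summary.json``/``summary.csv`` and a run log, and returns a
:class:`StudySummary`.  All randomness derives from the master seed via
per-stage spawned seeds, so repeated runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aerosol import fit_mmad_gsd
from .confocal import (PolymerSpec, extract_objects, filter_noise,
                       lod_volume_fraction, objects_to_frame, organ_burden,
                       segment, tissue_concentration)
from .kinetics import (ExposureScenario, clearance_fit, deposition_fraction,
                       overload_check, total_applied_mass)
from .pyrolysis import (PyroSample, detection_limits, fit_calibration,
                        quantify_organ)
from .stack import ImageGrid, PsfModel
from .synthetic import (Agglomerate, BurdenPhase, BurdenTimecourseSpec,
                        GroundTruthScene, generate_burden_timecourse,
                        generate_impactor_run, generate_pyro_run,
                        generate_stack, lognormal_diameters, scatter_centers)

__all__ = ["StudyConfig", "StudySummary", "run_study"]

log = logging.getLogger("nanoburden")


@dataclass
class StudyConfig:
    """One study arm. See ``StudyConfig.demo()`` for a complete example."""

    polymer: PolymerSpec
    exposure: ExposureScenario
    mode: str  # "confocal" | "pyro"
    seed: int = 0
    output_dir: Path = Path("nanoburden_out")
    imaging: dict = field(default_factory=dict)
    organs: dict = field(default_factory=dict)
    clearance: dict = field(default_factory=dict)
    pyro: dict = field(default_factory=dict)
    aerosol: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("confocal", "pyro"):
            raise ValueError("analysis mode must be 'confocal' or 'pyro'")
        self.output_dir = Path(self.output_dir)

    @classmethod
    def demo(cls, mode: str = "confocal", seed: int = 0,
             output_dir: str | Path = "nanoburden_out") -> "StudyConfig":
        """A small, fast study arm with PS-like parameters."""
        return cls(
            polymer=PolymerSpec("PS-NR", density_g_cm3=1.05, packing=0.64),
            exposure=ExposureScenario(concentration_mg_m3=50.0,
                                      body_weight_kg=0.270),
            mode=mode,
            seed=seed,
            output_dir=output_dir,
            imaging={"nx": 192, "ny": 192, "nz": 40, "dx": 0.12, "dz": 0.30,
                     "n_agglomerates": 12, "diameter_median_um": 0.9,
                     "diameter_gsd": 1.3, "intensity": 200.0,
                     "background": 20.0, "shot_scale": 1.0,
                     "read_noise_sd": 2.0, "min_voxels": 6,
                     "min_detectable_volume_um3": 0.0004},
            organs={"lung_volume_ml": 10.0, "lung_weight_g": 1.63,
                    "ln_volume_ml": 0.03},
            clearance={"half_times_days": [46.0], "boundaries_days": [],
                       "sampling_days": [0.0, 35.0], "cv": 0.0,
                       "animals_per_day": 3},
            pyro={"slope": 2.0, "intercept": 50.0, "noise_sd": 0.0,
                  "cal_masses_ng": [37, 150, 600, 1500, 3700],
                  "cal_replicates": 3, "aliquot_ul": 20.0, "extract_ml": 20.0},
            aerosol={"mmad_um": 1.32, "gsd": 2.11},
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            polymer=PolymerSpec(**raw["polymer"]),
            exposure=ExposureScenario(**raw["exposure"]),
            mode=raw["mode"],
            seed=int(raw.get("seed", 0)),
            output_dir=Path(raw.get("output_dir", "nanoburden_out")),
            imaging=raw.get("imaging", {}),
            organs=raw.get("organs", {}),
            clearance=raw.get("clearance", {}),
            pyro=raw.get("pyro", {}),
            aerosol=raw.get("aerosol", {}),
        )

    def to_dict(self) -> dict:
        d = {
            "polymer": asdict(self.polymer),
            "exposure": asdict(self.exposure),
            "mode": self.mode,
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "imaging": self.imaging,
            "organs": self.organs,
            "clearance": self.clearance,
            "pyro": self.pyro,
            "aerosol": self.aerosol,
        }
        return d


@dataclass
class StudySummary:
    """Per-polymer study findings (one row of a study summary table)."""

    polymer: str
    applied_mass_mg: float
    lung_burden_mg: float
    ln_burden_ug: float | None
    deposition_pct: float
    half_times_days: list
    mmad_um: float | None
    gsd: float | None
    lod: float | None
    loq: float | None
    overload_ratio_mg_per_g: float | None
    overload: bool | None

    def to_dict(self) -> dict:
        return asdict(self)


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    """Deterministic per-stage seeds derived from one master seed."""
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _confocal_stage(config: StudyConfig, seed: int, outdir: Path) -> dict:
    p = config.imaging
    grid = ImageGrid(nx=p["nx"], ny=p["ny"], nz=p["nz"],
                     dx=p.get("dx", 0.12), dy=p.get("dx", 0.12),
                     dz=p.get("dz", 0.30))
    rng = np.random.default_rng(seed)
    n = p["n_agglomerates"]
    diam = lognormal_diameters(n, p["diameter_median_um"], p["diameter_gsd"],
                               rng=rng)
    margin = float(diam.max()) / 2 + 1.0
    centers = scatter_centers(grid, n, min_spacing_um=float(diam.max()) + 2.0,
                              margin_um=margin,
                              z_range_um=(margin, grid.depth - margin), rng=rng)
    scene = GroundTruthScene(
        agglomerates=[Agglomerate(x, y, z, d, p["intensity"])
                      for (x, y, z), d in zip(centers, diam)],
        background=p["background"], fade_length_um=1e6,
        shot_scale=p["shot_scale"], read_noise_sd=p["read_noise_sd"],
        seed=seed)
    stack, _ = generate_stack(grid, scene, PsfModel())
    labels = segment(stack, method="otsu")
    objects = filter_noise(extract_objects(labels, stack),
                           min_voxels=p.get("min_voxels", 6))
    objects_to_frame(objects).to_csv(outdir / "objects.csv", index=False)
    result = tissue_concentration(objects, grid.volume, config.polymer)
    lung = organ_burden(result, config.organs["lung_volume_ml"],
                        config.organs.get("lung_weight_g"))
    scanned = result.scanned_volume_um3
    frac = lod_volume_fraction(p.get("min_detectable_volume_um3", 0.0004), scanned)
    log.info("confocal: %d objects kept, %.3g ng/(100 µm)³",
             result.objects_kept, result.mass_ng_per_100um3)
    return {"lung_burden_mg": lung.total_mass_mg,
            "lung_per_g": lung.mass_per_g_mg,
            "ln_burden_ug": None,
            "lod": frac, "loq": frac}


def _pyro_stage(config: StudyConfig, seed: int, outdir: Path) -> dict:
    p = config.pyro
    masses = np.repeat(np.asarray(p["cal_masses_ng"], float),
                       p.get("cal_replicates", 3))
    cal = generate_pyro_run(masses, p["slope"], p["intercept"],
                            p.get("noise_sd", 0.0), seed=seed)
    cal.to_csv(outdir / "calibration.csv", index=False)
    curve = fit_calibration(cal["mass_ng"], cal["peak_area"])
    true_burden_ug = p.get("true_lung_burden_ug", 3800.0)
    dilution = p["extract_ml"] * 1000.0 / p["aliquot_ul"]
    crucible_ng = true_burden_ug * 1000.0 / dilution
    run = generate_pyro_run([crucible_ng], p["slope"], p["intercept"],
                            p.get("noise_sd", 0.0), seed=seed + 1)
    sample = PyroSample(peak_area=float(run["peak_area"].iloc[0]),
                        aliquot_ul=p["aliquot_ul"], extract_ml=p["extract_ml"],
                        organ_wet_mass_g=config.organs.get("lung_weight_g"))
    result = quantify_organ(sample, curve)
    limits = detection_limits(curve, dilution)
    log.info("pyro: %.1f µg/organ (dilution %.0f)",
             result["mass_per_organ_ug"], dilution)
    return {"lung_burden_mg": result["mass_per_organ_ug"] / 1000.0,
            "lung_per_g": result.get("mass_per_g_mg"),
            "ln_burden_ug": p.get("true_ln_burden_ug"),
            "lod": limits.lod_ug, "loq": limits.loq_ug}


def run_study(config: StudyConfig) -> StudySummary:
    """Execute one study arm end to end and write all artifacts."""
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        cfg_text = json.dumps(config.to_dict(), sort_keys=True)
        log.info("nanoburden %s on python %s; config sha256 %s; master seed %d",
                 __version__, platform.python_version(),
                 hashlib.sha256(cfg_text.encode()).hexdigest()[:16], config.seed)
        seeds = _stage_seeds(config.seed)
        log.info("stage seeds: %s", seeds)

        if config.mode == "confocal":
            stage = _confocal_stage(config, seeds[0], outdir)
        else:
            stage = _pyro_stage(config, seeds[0], outdir)

        applied = total_applied_mass(config.exposure)
        deposition = deposition_fraction(stage["lung_burden_mg"], applied)

        cl = config.clearance
        tc_spec = BurdenTimecourseSpec(
            n0_mg=stage["lung_burden_mg"],
            phases=_phases_from_config(cl),
            cv=cl.get("cv", 0.0),
            sampling_days=cl.get("sampling_days", [0.0, 35.0]),
            animals_per_day=cl.get("animals_per_day", 3),
            seed=seeds[1])
        tc = generate_burden_timecourse(tc_spec)
        tc.to_csv(outdir / "timecourse.csv", index=False)
        means = tc.groupby("day")["burden_mg"].mean().reset_index()
        fit = clearance_fit(list(zip(means["day"], means["burden_mg"])),
                            phase_boundaries=cl.get("boundaries_days") or None)
        half_times = [ph.half_time_days for ph in fit.phases]

        mmad = gsd = None
        if config.aerosol:
            run = generate_impactor_run(config.aerosol["mmad_um"],
                                        config.aerosol["gsd"],
                                        total_mass_mg=10.0, seed=seeds[2],
                                        noise=config.aerosol.get("noise", 0.0))
            mmad, gsd = fit_mmad_gsd(run)

        ratio = flag = None
        if config.organs.get("lung_weight_g"):
            ratio, flag = overload_check(stage["lung_burden_mg"],
                                         config.organs["lung_weight_g"])

        summary = StudySummary(
            polymer=config.polymer.name,
            applied_mass_mg=applied,
            lung_burden_mg=stage["lung_burden_mg"],
            ln_burden_ug=stage["ln_burden_ug"],
            deposition_pct=deposition,
            half_times_days=half_times,
            mmad_um=mmad, gsd=gsd,
            lod=stage["lod"], loq=stage["loq"],
            overload_ratio_mg_per_g=ratio, overload=flag)

        (outdir / "summary.json").write_text(
            json.dumps(summary.to_dict(), indent=1, sort_keys=True))
        pd.DataFrame([summary.to_dict()]).to_csv(outdir / "summary.csv",
                                                 index=False)
        log.info("summary: %s", summary.to_dict())
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()


def _phases_from_config(cl: dict) -> list[BurdenPhase]:
    halves = cl.get("half_times_days", [46.0])
    bounds = list(cl.get("boundaries_days", []))
    ends = bounds + [None]
    if len(ends) != len(halves):
        raise ValueError("need one boundary fewer than half-times")
    return [BurdenPhase(end_day=e, half_time_days=h)
            for e, h in zip(ends, halves)]
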