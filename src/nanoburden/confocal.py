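"""Quantification of fluorescent nanoparticle agglomerates in 3D stacks.

The workflow mirrors semi-automatic confocal quantification of Nile-Red
labelled polystyrene in fixed tissue: segment the fluorescence contrast in
3D, size each connected object (voxel count → physical volume → equivalent
sphere diameter), drop sub-resolution noise objects (≤ 5 voxels) and
objects touching the stack faces, convert envelope volume to polymer mass
via a packing density and the bulk density, and scale the per-volume
concentrations to whole-organ burdens.

Because the point-spread function inflates apparent object size, each
segmented object is re-thresholded at a fixed relative height between the
local background and its peak before sizing (0.5 recovers a blurred flat
edge exactly; the default 0.4 is calibrated for spheres near the PSF
scale), which keeps volume — and hence mass — estimates close to the
geometric truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure
from sklearn.ensemble import RandomForestClassifier

from .stack import ImageGrid, ImageStack

__all__ = [
    "SegmentedObject",
    "PolymerSpec",
    "TissueScanResult",
    "BurdenEstimate",
    "PixelClassifier",
    "segment",
    "extract_objects",
    "filter_noise",
    "object_mass",
    "tissue_concentration",
    "organ_burden",
    "size_histogram",
    "equivalent_sphere_diameter",
    "lod_volume_fraction",
    "scanned_volume",
    "objects_to_frame",
]

#: voxels per (100 µm)³ reporting volume
REPORT_VOLUME_UM3 = 1.0e6
#: default noise rule — objects spanning <= 5 voxels are background noise
DEFAULT_MIN_VOXELS = 6


def equivalent_sphere_diameter(volume_um3: float) -> float:
    """Diameter of the sphere with the same volume, ``(6V/π)^(1/3)`` (µm)."""
    if volume_um3 < 0:
        raise ValueError("volume must be >= 0")
    return (6.0 * volume_um3 / math.pi) ** (1.0 / 3.0)


@dataclass(frozen=True)
class SegmentedObject:
    """One connected fluorescent object after segmentation."""

    label: int
    voxels: int
    volume_um3: float
    eq_diameter_um: float
    mean_intensity: float
    deepest_z_um: float
    touches_edge: bool

    def __post_init__(self) -> None:
        if self.voxels < 1:
            raise ValueError("an object must span at least one voxel")


@dataclass(frozen=True)
class PolymerSpec:
    """Polymer identity plus the two constants of the volume→mass model:
    bulk density (g/cm³) and agglomerate packing density (solid fraction of
    the envelope volume; 0.64 for random close packing)."""

    name: str
    density_g_cm3: float
    packing: float = 0.64

    def __post_init__(self) -> None:
        if not 0 < self.packing <= 1:
            raise ValueError("packing density must be in (0, 1]")
        if not self.density_g_cm3 > 0:
            raise ValueError("density must be positive")


#: Nile-Red labelled polystyrene: helium-pycnometry density, random close packing
POLYSTYRENE = PolymerSpec("PS-NR", density_g_cm3=1.05, packing=0.64)
POLYAMIDE_6 = PolymerSpec("PA-6", density_g_cm3=1.13, packing=0.64)


@dataclass(frozen=True)
class TissueScanResult:
    """Concentrations over a scanned tissue volume, reported per (100 µm)³."""

    objects_kept: int
    scanned_volume_um3: float
    number_per_100um3: float
    mass_ng_per_100um3: float
    total_mass_g: float = 0.0

    def __post_init__(self) -> None:
        if self.number_per_100um3 < 0 or self.mass_ng_per_100um3 < 0:
            raise ValueError("concentrations must be >= 0")


@dataclass(frozen=True)
class BurdenEstimate:
    """Whole-organ burden extrapolated from a tissue concentration."""

    organ: str
    organ_volume_ml: float
    total_mass_mg: float
    organ_weight_g: float | None = None
    mass_per_g_mg: float | None = None


# ---------------------------------------------------------------------------
# segmentation backends


class PixelClassifier:
    """Small trained pixel classifier over multi-scale Gaussian features.

    Emulates an interactively trained voxel classifier: features are the
    raw intensity, Gaussian-smoothed intensity at several spatial scales
    (axially rescaled for anisotropic voxels) and a gradient magnitude,
    fed to a random forest.  Training labels are 1 = background,
    2 = foreground, 0 = unlabeled.
    """

    def __init__(self, scales=(1.0, 2.0, 4.0), n_estimators: int = 20,
                 max_depth: int = 12, max_background_voxels: int = 200_000,
                 seed: int = 0):
        self.scales = tuple(scales)
        self.max_background_voxels = max_background_voxels
        self._forest = RandomForestClassifier(
            n_estimators=n_estimators, max_depth=max_depth,
            random_state=seed, n_jobs=1)
        self._fitted = False

    def _features(self, stack: ImageStack) -> np.ndarray:
        data = stack.data.astype(np.float32)
        aniso = stack.grid.dx / stack.grid.dz  # axial sigma in voxel units
        feats = [data]
        for s in self.scales:
            feats.append(ndimage.gaussian_filter(data, sigma=(s * aniso, s, s)))
        grad = ndimage.gaussian_gradient_magnitude(
            data, sigma=(self.scales[0] * aniso, self.scales[0], self.scales[0]))
        feats.append(grad)
        return np.stack([f.ravel() for f in feats], axis=1)

    def fit(self, stack: ImageStack, labels: np.ndarray,
            rng: np.random.Generator | None = None) -> "PixelClassifier":
        labels = np.asarray(labels)
        if labels.shape != stack.data.shape:
            raise ValueError("label volume must match the stack shape")
        rng = rng or np.random.default_rng(0)
        X = self._features(stack)
        y = labels.ravel()
        fg = np.flatnonzero(y == 2)
        bg = np.flatnonzero(y == 1)
        if fg.size == 0 or bg.size == 0:
            raise ValueError("training labels must include both classes")
        if bg.size > self.max_background_voxels:
            bg = rng.choice(bg, size=self.max_background_voxels, replace=False)
        idx = np.concatenate([fg, bg])
        self._forest.fit(X[idx], y[idx])
        self._fitted = True
        return self

    def predict_mask(self, stack: ImageStack) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("classifier has not been trained")
        X = self._features(stack)
        return (self._forest.predict(X) == 2).reshape(stack.data.shape)


def segment(stack: ImageStack, method: str = "otsu", threshold: float | None = None,
            classifier: PixelClassifier | None = None) -> np.ndarray:
    """3D segmentation of the fluorescence contrast into labelled objects.

    ``method``: ``"otsu"`` (global Otsu threshold), ``"absolute"`` (fixed
    ``threshold``) or ``"classifier"`` (a trained :class:`PixelClassifier`).
    Connected foreground regions are labelled with 26-connectivity; 0 is
    background.  An all-background stack yields an empty labelling.
    """
    data = stack.data
    if np.isnan(data).any():
        raise ValueError("stack contains NaN voxels")
    if method == "otsu":
        if np.ptp(data) == 0:
            return np.zeros(data.shape, dtype=np.int32)
        # Foreground is a tiny volume fraction, so a plain global Otsu
        # collapses into the background mode; restrict the histogram to
        # voxels above a robust background floor (median + 3 MAD) first.
        med = float(np.median(data))
        mad = float(np.median(np.abs(data - med)))
        floor = med + 3.0 * 1.4826 * mad
        candidates = data[data > floor]
        if candidates.size < 16 or np.ptp(candidates) == 0:
            return np.zeros(data.shape, dtype=np.int32)
        mask = data > filters.threshold_otsu(candidates)
    elif method == "absolute":
        if threshold is None:
            raise ValueError("absolute thresholding requires a threshold")
        mask = data > threshold
    elif method == "classifier":
        if classifier is None:
            raise ValueError("classifier method requires a trained PixelClassifier")
        mask = classifier.predict_mask(stack)
    else:
        raise ValueError(f"unknown segmentation method: {method!r}")
    return measure.label(mask, connectivity=3).astype(np.int32)


# ---------------------------------------------------------------------------
# object extraction and filtering


def extract_objects(labels: np.ndarray, stack: ImageStack,
                    grid: ImageGrid | None = None,
                    refine_halfmax: bool = True,
                    refine_height: float = 0.4,
                    background: float | None = None) -> list[SegmentedObject]:
    """Per-object metrics from a label field.

    Volume is voxel count × voxel volume; the equivalent sphere diameter
    follows from the volume; the deepest z location is recorded; objects
    with any voxel on one of the six stack faces are flagged
    ``touches_edge`` (they are kept in the list but excluded from
    concentration totals downstream).

    With ``refine_halfmax`` (default) each object's voxels are re-selected
    at ``background + refine_height × (object peak − background)`` within
    the object, correcting PSF-driven size inflation; ``background``
    defaults to the median intensity outside all labels.  For a blurred
    flat edge the unbiased height is 0.5; for spheres near the PSF scale
    the surface sits below half-max because the boundary curves away, so
    the default height of 0.4 was calibrated on synthetic spheres spanning
    0.6–1.8 µm at the reference PSF (see the methods documentation).
    """
    if not 0 < refine_height < 1:
        raise ValueError("refine_height must be in (0, 1)")
    grid = grid or stack.grid
    labels = np.asarray(labels)
    if labels.shape != stack.data.shape:
        raise ValueError("labels must match stack shape")
    data = stack.data
    if refine_halfmax and background is None:
        outside = data[labels == 0]
        background = float(np.median(outside)) if outside.size else 0.0
    nz, ny, nx = labels.shape
    objects: list[SegmentedObject] = []
    for region in measure.regionprops(labels, intensity_image=data):
        z0, y0, x0, z1, y1, x1 = region.bbox
        touches = (z0 == 0 or y0 == 0 or x0 == 0 or z1 == nz or y1 == ny or x1 == nx)
        sub = region.image
        vals = region.image_intensity[sub]
        if refine_halfmax:
            thr = background + refine_height * (float(vals.max()) - background)
            keep = region.image_intensity >= thr
            refined = sub & keep
            if refined.any():
                sub = refined
                vals = region.image_intensity[sub]
        count = int(sub.sum())
        volume = count * grid.voxel_volume
        zmax = z0 + int(np.max(np.nonzero(sub.any(axis=(1, 2)))[0]))
        objects.append(SegmentedObject(
            label=int(region.label),
            voxels=count,
            volume_um3=volume,
            eq_diameter_um=equivalent_sphere_diameter(volume),
            mean_intensity=float(vals.mean()),
            deepest_z_um=(zmax + 0.5) * grid.dz,
            touches_edge=bool(touches),
        ))
    return objects


def filter_noise(objects, min_voxels: int = DEFAULT_MIN_VOXELS):
    """Drop noise objects: only objects spanning at least ``min_voxels``
    voxels are kept (default 6, i.e. objects of ≤ 5 voxels are excluded as
    background noise).  Order is preserved; idempotent."""
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    return [o for o in objects if o.voxels >= min_voxels]


def object_mass(obj: SegmentedObject, polymer: PolymerSpec) -> float:
    """Polymer mass (g) of one agglomerate: envelope volume × packing
    density × bulk density, with the µm³ → cm³ conversion (10⁻¹²)."""
    if polymer is None:
        raise ValueError("a PolymerSpec is required")
    return obj.volume_um3 * polymer.packing * polymer.density_g_cm3 * 1e-12


def tissue_concentration(objects, scanned_volume_um3: float,
                         polymer: PolymerSpec) -> TissueScanResult:
    """Number and mass concentrations per (100 µm)³ of scanned tissue.

    Edge-touching objects are excluded; the input is expected to be
    noise-filtered already.
    """
    if not scanned_volume_um3 > 0:
        raise ValueError("scanned volume must be positive")
    kept = [o for o in objects if not o.touches_edge]
    total_mass_g = float(sum(object_mass(o, polymer) for o in kept))
    blocks = scanned_volume_um3 / REPORT_VOLUME_UM3
    return TissueScanResult(
        objects_kept=len(kept),
        scanned_volume_um3=scanned_volume_um3,
        number_per_100um3=len(kept) / blocks,
        mass_ng_per_100um3=total_mass_g * 1e9 / blocks,
        total_mass_g=total_mass_g,
    )


def organ_burden(result: TissueScanResult, organ_volume_ml: float,
                 organ_weight_g: float | None = None,
                 organ: str = "lung") -> BurdenEstimate:
    """Extrapolate a tissue concentration to a whole organ.

    1 mL = 10¹² µm³ = 10⁶ reporting blocks of (100 µm)³, so
    ``total mass [ng] = concentration [ng/(100 µm)³] × organ mL × 10⁶``.
    """
    if not organ_volume_ml > 0:
        raise ValueError("organ volume must be positive")
    if organ_weight_g is not None and organ_weight_g <= 0:
        raise ValueError("organ weight must be positive")
    total_ng = result.mass_ng_per_100um3 * organ_volume_ml * 1e6
    total_mg = total_ng / 1e6
    per_g = total_mg / organ_weight_g if organ_weight_g else None
    return BurdenEstimate(organ=organ, organ_volume_ml=organ_volume_ml,
                          total_mass_mg=total_mg, organ_weight_g=organ_weight_g,
                          mass_per_g_mg=per_g)


def size_histogram(objects, bin_edges_um) -> pd.DataFrame:
    """Relative-frequency histogram of equivalent sphere diameters.

    Returns a table with ``bin_left_um, bin_right_um, frequency``;
    frequencies sum to 1 (empty input → empty table)."""
    edges = np.asarray(bin_edges_um, dtype=float)
    diameters = np.array([o.eq_diameter_um for o in objects])
    if diameters.size == 0:
        return pd.DataFrame(columns=["bin_left_um", "bin_right_um", "frequency"])
    if diameters.min() < edges[0] or diameters.max() > edges[-1]:
        raise ValueError("bin edges must cover all observed diameters")
    counts, _ = np.histogram(diameters, bins=edges)
    return pd.DataFrame({
        "bin_left_um": edges[:-1],
        "bin_right_um": edges[1:],
        "frequency": counts / counts.sum(),
    })


def lod_volume_fraction(min_detectable_volume_um3: float,
                        scanned_volume_um3: float) -> float:
    """Detection limit expressed as a volume fraction: the smallest
    quantifiable agglomerate volume over the total scanned tissue volume."""
    if scanned_volume_um3 <= 0 or min_detectable_volume_um3 <= 0:
        raise ValueError("volumes must be positive")
    return min_detectable_volume_um3 / scanned_volume_um3


def scanned_volume(grid: ImageGrid, mode: str = "nominal",
                   objects=None) -> float:
    """Scanned tissue volume of one stack (µm³).

    ``"nominal"`` uses the configured stack extent; ``"detected"``
    truncates the depth at the deepest retained object (useful when the
    usable depth is limited by fading contrast)."""
    if mode == "nominal":
        return grid.volume
    if mode == "detected":
        if not objects:
            warnings.warn("no objects to bound the detected depth; "
                          "falling back to the nominal extent")
            return grid.volume
        depth = max(o.deepest_z_um for o in objects)
        return grid.field_x * grid.field_y * depth
    raise ValueError(f"unknown scanned-volume mode: {mode!r}")


def objects_to_frame(objects) -> pd.DataFrame:
    """Tabulate objects for the per-object CSV export."""
    return pd.DataFrame([{
        "label": o.label,
        "voxels": o.voxels,
        "volume_um3": o.volume_um3,
        "eq_diameter_um": o.eq_diameter_um,
        "mean_intensity": o.mean_intensity,
        "deepest_z_um": o.deepest_z_um,
        "edge_flag": o.touches_edge,
    } for o in objects])
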