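"""Image-stack geometry and containers for 3D confocal data.

Confocal xyz stacks are stored as (z, y, x) intensity arrays with an
explicit anisotropic voxel geometry: the lateral voxel pitch is set by the
scan zoom (120 nm in the reference acquisition) while the axial pitch is
the z-step of the piezo stage (300 nm, or 150 nm in the high-sensitivity
mode used for remote organs).  All physical quantities are in micrometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = ["ImageGrid", "PsfModel", "ImageStack", "write_stack", "read_stack"]

#: FWHM -> Gaussian sigma conversion, 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class ImageGrid:
    """Voxel lattice of a confocal stack.

    Parameters
    ----------
    nx, ny, nz
        Voxel counts along x, y (lateral) and z (axial).
    dx, dy
        Lateral voxel size in µm; must be equal (square pixels).
    dz
        Axial voxel size (z-step) in µm.
    """

    nx: int
    ny: int
    nz: int
    dx: float = 0.12
    dy: float = 0.12
    dz: float = 0.30

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("voxel counts must be >= 1")
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError("voxel sizes must be positive")
        if not np.isclose(self.dx, self.dy):
            raise ValueError("lateral voxels must be square (dx == dy)")

    @property
    def field_x(self) -> float:
        """Lateral physical extent along x (µm)."""
        return self.nx * self.dx

    @property
    def field_y(self) -> float:
        return self.ny * self.dy

    @property
    def depth(self) -> float:
        """Axial physical extent (µm)."""
        return self.nz * self.dz

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel (µm³)."""
        return self.dx * self.dy * self.dz

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape in (z, y, x) order."""
        return (self.nz, self.ny, self.nx)

    @property
    def volume(self) -> float:
        """Nominal scanned volume of the full stack (µm³)."""
        return self.field_x * self.field_y * self.depth

    def to_dict(self) -> dict:
        return {
            "nx": self.nx, "ny": self.ny, "nz": self.nz,
            "dx": self.dx, "dy": self.dy, "dz": self.dz,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImageGrid":
        return cls(**{k: d[k] for k in ("nx", "ny", "nz", "dx", "dy", "dz")})


def reference_grid() -> ImageGrid:
    """The standard acquisition geometry: 246 µm × 246 µm lateral field at
    120 nm lateral pitch, ~100 µm axial range at 300 nm z-step."""
    return ImageGrid(nx=2050, ny=2050, nz=333, dx=0.12, dy=0.12, dz=0.30)


@dataclass(frozen=True)
class PsfModel:
    """Separable anisotropic Gaussian surrogate for the confocal PSF.

    Defaults match the resolution of a 1.40 NA oil-immersion objective,
    roughly 200 nm laterally and 500 nm axially (FWHM).
    """

    lateral_fwhm_um: float = 0.20
    axial_fwhm_um: float = 0.50

    def __post_init__(self) -> None:
        if not (self.lateral_fwhm_um > 0):
            raise ValueError("lateral FWHM must be positive")
        if self.axial_fwhm_um < self.lateral_fwhm_um:
            raise ValueError("axial FWHM must be >= lateral FWHM")

    @property
    def lateral_sigma_um(self) -> float:
        return self.lateral_fwhm_um / FWHM_TO_SIGMA

    @property
    def axial_sigma_um(self) -> float:
        return self.axial_fwhm_um / FWHM_TO_SIGMA


@dataclass
class ImageStack:
    """A 3D intensity field plus its voxel geometry.

    ``data`` is indexed (z, y, x); intensities are non-negative arbitrary
    units.  ``channel`` distinguishes the Nile-Red fluorescence contrast
    from the scattering (tissue-structure) contrast.
    """

    data: np.ndarray
    grid: ImageGrid
    channel: str = "fluorescence"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3D (z, y, x)")
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid {self.grid.shape}"
            )
        finite = self.data[np.isfinite(self.data)]
        if finite.size and finite.min() < 0:
            raise ValueError("intensities must be >= 0")


def write_stack(stack: ImageStack, path: str | Path, ground_truth: dict | None = None) -> None:
    """Write a stack as a multi-page 16-bit TIFF (one page per z-slice) with
    a YAML grid sidecar and, optionally, a JSON ground-truth sidecar."""
    path = Path(path)
    data = stack.data
    peak = float(data.max()) if data.size else 0.0
    scale = 65535.0 / peak if peak > 0 else 1.0
    tifffile.imwrite(path, np.clip(data * scale, 0, 65535).astype(np.uint16))
    sidecar = {"grid": stack.grid.to_dict(), "channel": stack.channel,
               "intensity_scale": scale}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))
    if ground_truth is not None:
        path.with_suffix(".truth.json").write_text(json.dumps(ground_truth, indent=1))


def read_stack(path: str | Path) -> ImageStack:
    """Read a multi-page TIFF written by :func:`write_stack` (or any TIFF,
    if a YAML grid sidecar sits next to it)."""
    path = Path(path)
    data = tifffile.imread(path).astype(np.float64)
    sidecar = yaml.safe_load(path.with_suffix(".yaml").read_text())
    scale = float(sidecar.get("intensity_scale", 1.0))
    if scale > 0:
        data = data / scale
    grid = ImageGrid.from_dict(sidecar["grid"])
    return ImageStack(data=data, grid=grid, channel=sidecar.get("channel", "fluorescence"))
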