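"""Core voxel-grid containers shared across the pipeline.

All physical coordinates are in micrometres (μm); refractive index (RI) is
dimensionless.  Volumes are reported in femtolitres (1 fL = 1 μm³).  Arrays
are stored in ``(z, y, x)`` order, matching the page layout of a multi-page
TIFF stack, while user-facing fields such as ``shape_xyz`` and
``voxel_size_xyz`` are given in ``(x, y, z)`` order as a microscopist would
quote them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

__all__ = ["GridSpec", "Tomogram", "TimeLapse", "HeightMap"]

#: Refractive index of water at λ = 520 nm; zero point of the Hb scale.
N_WATER = 1.333
#: Refractive-index increment of haemoglobin, dL/g, at λ = 520 nm.
ALPHA_HB = 0.001983
#: Refractive index of the PBS imaging medium (slightly above pure water).
N_PBS = 1.334


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a tomographic acquisition volume.

    The default field of view is 90 × 90 × 30 μm at isotropic 0.2 μm
    voxels, i.e. a 450 × 450 × 150 grid, with a PBS background medium.
    """

    shape_xyz: Tuple[int, int, int] = (450, 450, 150)
    voxel_size_xyz: Tuple[float, float, float] = (0.2, 0.2, 0.2)
    background_ri: float = N_PBS

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.shape_xyz):
            raise ValueError(f"grid shape must be positive, got {self.shape_xyz}")
        if any(v <= 0 for v in self.voxel_size_xyz):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_xyz}")
        if not (1.30 <= self.background_ri <= 1.40):
            raise ValueError(
                f"background RI {self.background_ri} outside plausible medium range [1.30, 1.40]"
            )

    @property
    def shape_zyx(self) -> Tuple[int, int, int]:
        nx, ny, nz = self.shape_xyz
        return (nz, ny, nx)

    @property
    def extent_um(self) -> Tuple[float, float, float]:
        """Physical size of the field of view, (x, y, z) in μm."""
        return tuple(n * v for n, v in zip(self.shape_xyz, self.voxel_size_xyz))

    @property
    def voxel_volume_fl(self) -> float:
        vx, vy, vz = self.voxel_size_xyz
        return vx * vy * vz

    def axes_um(self):
        """Voxel-centre coordinate vectors (x, y, z) in μm."""
        return tuple(
            (np.arange(n) + 0.5) * v
            for n, v in zip(self.shape_xyz, self.voxel_size_xyz)
        )


@dataclass
class Tomogram:
    """A 3D refractive-index map with physical voxel spacing.

    ``data`` is indexed ``[z, y, x]``.
    """

    data: np.ndarray
    voxel_size_xyz: Tuple[float, float, float]
    background_ri: float = N_PBS
    timestamp_s: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"tomogram must be 3D, got shape {self.data.shape}")
        if any(v <= 0 for v in self.voxel_size_xyz):
            raise ValueError("voxel sizes must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("tomogram contains non-finite RI values")
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < 1.2 or hi > 1.6:
            raise ValueError(f"RI values [{lo:.3f}, {hi:.3f}] outside physical range [1.2, 1.6]")

    @property
    def shape_zyx(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_fl(self) -> float:
        vx, vy, vz = self.voxel_size_xyz
        return vx * vy * vz

    @property
    def voxel_size_zyx(self) -> Tuple[float, float, float]:
        vx, vy, vz = self.voxel_size_xyz
        return (vz, vy, vx)


@dataclass
class TimeLapse:
    """An ordered sequence of tomograms on a common grid."""

    frames: list
    frame_interval_s: float = 2.0

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be positive")
        if len(self.frames) >= 2:
            shp = self.frames[0].shape_zyx
            if any(f.shape_zyx != shp for f in self.frames):
                raise ValueError("all frames must share one grid")

    def __len__(self) -> int:
        return len(self.frames)

    def times_s(self) -> np.ndarray:
        return np.arange(len(self.frames)) * self.frame_interval_s


@dataclass
class HeightMap:
    """A 2D AFM-style topography grid; heights in nm, pixel size in nm."""

    heights_nm: np.ndarray
    pixel_size_nm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights_nm = np.asarray(self.heights_nm, dtype=np.float64)
        if self.heights_nm.ndim != 2:
            raise ValueError("height map must be 2D")
        if not np.all(np.isfinite(self.heights_nm)):
            raise ValueError("height map contains non-finite values")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self):
        return self.heights_nm.shape
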