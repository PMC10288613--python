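"""Synthetic phantom generator for RI tomograms, time-lapses and height maps.

Every phantom is a geometric refractive-index map: voxels inside the cell
carry ``RI = n_H2O + α · Hb`` (the inverse of the haemoglobin retrieval
formula), voxels outside carry the medium RI.  No optical forward model is
applied — no diffraction, no missing-cone artefacts.

The healthy discocyte uses the Evans–Fung biconcave profile

    z(ρ) = ± sqrt(1 − (ρ/R)²) · ½ [C0 + C2 (ρ/R)² + C4 (ρ/R)⁴]

with canonical average-cell coefficients R = 3.91 μm, C0 = 0.81 μm,
C2 = 7.83 μm, C4 = −4.39 μm (diameter ≈ 7.82 μm, volume ≈ 94 fL).
Spiculated shapes (echinocyte, acanthocyte) are star-convex radius fields:
an oblate-spheroid body plus radially oriented Gaussian bumps at
quasi-uniform surface directions, with spicule heights of 0.1–0.3 μm by
default.  Every generated cell is recorded in a ground-truth structure
holding its true label, centre, analytic volume/area where a closed form or
quadrature exists, and its true spicule inventory.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import integrate
from scipy.spatial.transform import Rotation

from .grids import ALPHA_HB, N_WATER, GridSpec, HeightMap, TimeLapse, Tomogram

__all__ = [
    "CELL_CLASSES",
    "PhantomSpec",
    "PhantomGroundTruth",
    "CellRecord",
    "SpiculeRec",
    "ShapeTrajectory",
    "make_cell_phantom",
    "make_bead_phantom",
    "make_scene",
    "make_timelapse",
    "make_height_map",
    "evans_fung_half_thickness",
    "evans_fung_volume_fl",
    "evans_fung_area_um2",
    "low_dose_trajectory",
    "high_dose_trajectory",
]

CELL_CLASSES = (
    "normocyte",
    "stomatocyte",
    "echinocyte",
    "acanthocyte",
    "spherocyte",
    "ovalocyte",
    "helmet",
    "sickle",
    "teardrop",
)

#: silica calibration microbead RI (well above any RBC value)
BEAD_RI = 1.43

# Evans–Fung coefficients for the average human RBC (μm)
EF_R = 3.91
EF_C0 = 0.81
EF_C2 = 7.83
EF_C4 = -4.39
EF_DIAMETER = 2 * EF_R
# maximum of the full-thickness profile C(t)·sqrt(1-t²); found numerically once
EF_MAX_THICKNESS = 2.5649


class PhantomError(ValueError):
    """Invalid phantom specification."""


class OutOfBoundsError(PhantomError):
    """Requested shape does not fit inside the voxel grid."""


class UnsupportedClassError(PhantomError):
    """Cell class outside the nine-label vocabulary."""


# ---------------------------------------------------------------------------
# specification


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic cell.

    Geometry defaults depend on ``cell_class`` and are filled by
    :meth:`for_class`; lengths in μm, Hb concentration in g/dL.
    """

    cell_class: str
    diameter_um: float = EF_DIAMETER
    thickness_um: Optional[float] = None
    spicule_count: int = 0
    spicule_height_um: float = 0.3
    spicule_width_um: float = 0.35
    dimple_depth_um: float = 0.0
    elongation: float = 1.0
    hb_concentration_g_dl: float = 33.0
    center_um: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation_deg: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_class not in CELL_CLASSES and self.cell_class != "bead":
            raise UnsupportedClassError(
                f"unknown cell class {self.cell_class!r}; expected one of {CELL_CLASSES}"
            )
        if self.diameter_um <= 0:
            raise PhantomError("diameter must be positive")
        if self.hb_concentration_g_dl < 0:
            raise PhantomError("Hb concentration must be non-negative")
        if self.elongation < 1.0:
            raise PhantomError("elongation is major/minor >= 1")
        if self.spicule_count > 0 and not (0.05 <= self.spicule_height_um <= 0.5):
            raise PhantomError(
                f"spicule height {self.spicule_height_um} μm outside default range [0.05, 0.5]"
            )

    @classmethod
    def for_class(cls, cell_class: str, **overrides) -> "PhantomSpec":
        """A spec with field-realistic default geometry for ``cell_class``."""
        defaults = dict(_CLASS_DEFAULTS.get(cell_class, {}))
        defaults.update(overrides)
        return cls(cell_class=cell_class, **defaults)


_CLASS_DEFAULTS = {
    "normocyte": dict(diameter_um=EF_DIAMETER),
    "ovalocyte": dict(diameter_um=7.2, elongation=1.45),
    "sickle": dict(diameter_um=5.0, elongation=2.2, thickness_um=1.8),
    "spherocyte": dict(diameter_um=4.7),
    "stomatocyte": dict(diameter_um=6.2, dimple_depth_um=1.3),
    "echinocyte": dict(
        diameter_um=6.4, thickness_um=3.6, spicule_count=12,
        spicule_height_um=0.3, spicule_width_um=0.35,
    ),
    "acanthocyte": dict(
        diameter_um=5.2, thickness_um=4.2, spicule_count=8,
        spicule_height_um=0.5, spicule_width_um=0.45,
    ),
    "helmet": dict(diameter_um=6.0),
    "teardrop": dict(diameter_um=5.2),
    "bead": dict(diameter_um=5.0, hb_concentration_g_dl=0.0),
}


@dataclass
class SpiculeRec:
    """Ground-truth membrane protrusion: unit direction, height, width."""

    direction: np.ndarray
    height_um: float
    width_um: float
    spicule_id: int = 0


@dataclass
class CellRecord:
    """Ground truth for one generated cell."""

    label: str
    center_um: Tuple[float, float, float]
    volume_fl: Optional[float]
    area_um2: Optional[float]
    spicule_count: int
    hb_concentration_g_dl: float
    interior_ri: float
    spicules: List[SpiculeRec] = field(default_factory=list)
    diameter_um: Optional[float] = None


@dataclass
class PhantomGroundTruth:
    """Ground truth for a generated scene or time-lapse."""

    cells: List[CellRecord]
    background_ri: float
    # time-lapse only:
    frame_labels: Optional[List[str]] = None
    frame_spicule_counts: Optional[List[int]] = None
    events: Optional[List[dict]] = None
    frame_interval_s: Optional[float] = None
    frame_centers_um: Optional[List[Tuple[float, float, float]]] = None


# ---------------------------------------------------------------------------
# Evans–Fung discocyte profile


def evans_fung_half_thickness(rho_um, R=EF_R, c0=EF_C0, c2=EF_C2, c4=EF_C4):
    """Half-thickness z(ρ) of the biconcave profile; 0 outside the rim."""
    rho = np.asarray(rho_um, dtype=float)
    t2 = np.clip((rho / R) ** 2, 0.0, 1.0)
    z = 0.5 * np.sqrt(1.0 - t2) * (c0 + c2 * t2 + c4 * t2 * t2)
    return np.where(rho <= R, np.maximum(z, 0.0), 0.0)


def evans_fung_volume_fl(lateral_scale=1.0, axial_scale=1.0):
    """Volume of the (possibly rescaled) Evans–Fung disc by quadrature."""
    f = lambda rho: 4.0 * math.pi * rho * evans_fung_half_thickness(rho)
    v, _ = integrate.quad(f, 0.0, EF_R, limit=200)
    return v * lateral_scale**2 * axial_scale


def evans_fung_area_um2(lateral_scale=1.0, axial_scale=1.0):
    """Surface area of the rescaled disc (surface of revolution quadrature).

    Only valid for isotropic lateral scaling; the rim singularity
    (dz/dρ → ∞) is integrable and handled by the substitution ρ = R sin u.
    """
    a, b = lateral_scale, axial_scale

    def integrand(u):
        rho = EF_R * math.sin(u)
        drho = EF_R * math.cos(u)
        eps = 1e-6
        dz = (evans_fung_half_thickness(rho + eps) - evans_fung_half_thickness(max(rho - eps, 0.0))) / (2 * eps)
        # scaled profile: ρ' = a ρ, z' = b z
        return 2.0 * 2.0 * math.pi * (a * rho) * math.hypot(a * drho, b * dz * drho)

    area, _ = integrate.quad(integrand, 0.0, math.pi / 2 - 1e-9, limit=400)
    return area


# ---------------------------------------------------------------------------
# shape primitives (all work in the cell's local frame, μm)


class _Shape:
    bounding_radius: float

    def inside(self, pts: np.ndarray) -> np.ndarray:  # (N, 3) -> (N,) bool
        raise NotImplementedError

    def volume_fl(self) -> Optional[float]:
        return None

    def area_um2(self) -> Optional[float]:
        return None

    @property
    def half_extents(self) -> np.ndarray:
        """Axis-aligned bounding half-widths (x, y, z) in the local frame."""
        return np.array([self.bounding_radius] * 3)


class _Sphere(_Shape):
    def __init__(self, radius: float):
        self.r = radius
        self.bounding_radius = radius

    def inside(self, pts):
        return np.einsum("ij,ij->i", pts, pts) <= self.r**2

    def volume_fl(self):
        return 4.0 / 3.0 * math.pi * self.r**3

    def area_um2(self):
        return 4.0 * math.pi * self.r**2


class _Discocyte(_Shape):
    """Evans–Fung disc, optionally elongated in x and bent (sickle)."""

    def __init__(self, diameter, thickness=None, elongation=1.0, bend_curvature=0.0):
        self.sl = diameter / EF_DIAMETER
        self.sz = (thickness / EF_MAX_THICKNESS) if thickness else self.sl
        self.e = elongation
        self.kappa = bend_curvature
        half_len = 0.5 * diameter * elongation
        half_z = EF_MAX_THICKNESS * self.sz / 2 + abs(bend_curvature) * half_len**2
        self.bounding_radius = math.hypot(half_len, half_z) * 1.02
        self._half_extents = np.array([half_len * 1.02, 0.5 * diameter * 1.02, half_z * 1.02])

    @property
    def half_extents(self) -> np.ndarray:
        return self._half_extents

    def inside(self, pts):
        x = pts[:, 0] / self.e
        y = pts[:, 1]
        z = pts[:, 2]
        if self.kappa:
            z = z - self.kappa * pts[:, 0] ** 2  # bend about the long axis
        rho = np.hypot(x, y) / self.sl
        half = evans_fung_half_thickness(rho) * self.sz
        return (rho <= EF_R) & (np.abs(z) <= half)

    def volume_fl(self):
        # bending is volume-preserving (shear along z)
        return evans_fung_volume_fl(self.sl, self.sz) * self.e

    def area_um2(self):
        if self.e == 1.0 and self.kappa == 0.0:
            return evans_fung_area_um2(self.sl, self.sz)
        return None


class _RadialShape(_Shape):
    """Star-convex body: spheroid radius field plus signed Gaussian bumps."""

    def __init__(self, a, c, bumps: Sequence[SpiculeRec]):
        self.a = a  # equatorial semi-axis (x, y)
        self.c = c  # polar semi-axis (z)
        self.bumps = list(bumps)
        extra = max((b.height_um for b in self.bumps if b.height_um > 0), default=0.0)
        self.bounding_radius = max(a, c) + extra + 0.1
        self._half_extents = np.array([a + extra + 0.1, a + extra + 0.1, c + extra + 0.1])

    @property
    def half_extents(self) -> np.ndarray:
        return self._half_extents

    def base_radius(self, units: np.ndarray) -> np.ndarray:
        ux, uy, uz = units[:, 0], units[:, 1], units[:, 2]
        return 1.0 / np.sqrt((ux**2 + uy**2) / self.a**2 + uz**2 / self.c**2)

    def radius(self, units: np.ndarray) -> np.ndarray:
        r = self.base_radius(units)
        for b in self.bumps:
            cosang = np.clip(units @ b.direction, -1.0, 1.0)
            ang = np.arccos(cosang)
            sigma = b.width_um / max(self.a, 1e-6)  # angular width
            r = r + b.height_um * np.exp(-0.5 * (ang / sigma) ** 2)
        return r

    def inside(self, pts):
        d = np.linalg.norm(pts, axis=1)
        ok = d > 1e-9
        out = np.ones(len(pts), bool)
        units = pts[ok] / d[ok, None]
        out[ok] = d[ok] <= self.radius(units)
        return out

    def volume_fl(self):
        # exact for star-convex shapes: V = ∮ r(u)³/3 dΩ, quasi-MC on directions
        u = _fibonacci_directions(20000)
        return float(np.mean(self.radius(u) ** 3) * 4.0 * math.pi / 3.0)

    def area_um2(self):
        if not self.bumps:
            a, c = self.a, self.c
            if abs(a - c) < 1e-9:
                return 4 * math.pi * a**2
            if a > c:  # oblate
                e = math.sqrt(1 - c**2 / a**2)
                return 2 * math.pi * a**2 * (1 + (1 - e**2) / e * math.atanh(e))
            e = math.sqrt(1 - a**2 / c**2)  # prolate
            return 2 * math.pi * a**2 * (1 + c / (a * e) * math.asin(e))
        return None


class _Helmet(_Shape):
    """Sphere with a spherical 'bite' removed — the schistocyte-like helmet."""

    def __init__(self, radius, bite_radius=None, bite_offset=None):
        self.r = radius
        self.rb = bite_radius if bite_radius is not None else 0.75 * radius
        # bite centre beyond the surface so a concave face is carved out
        self.d = bite_offset if bite_offset is not None else radius + 0.35 * self.rb
        self.bounding_radius = radius

    def inside(self, pts):
        in_main = np.einsum("ij,ij->i", pts, pts) <= self.r**2
        dz = pts[:, 2] - self.d
        in_bite = pts[:, 0] ** 2 + pts[:, 1] ** 2 + dz**2 <= self.rb**2
        return in_main & ~in_bite

    def volume_fl(self):
        return 4.0 / 3.0 * math.pi * self.r**3 - _sphere_lens_volume(self.r, self.rb, self.d)


def _sphere_lens_volume(R, r, d):
    """Volume of the intersection of two spheres (radii R, r, centres d apart)."""
    if d >= R + r:
        return 0.0
    if d <= abs(R - r):
        rr = min(R, r)
        return 4.0 / 3.0 * math.pi * rr**3
    return (
        math.pi
        * (R + r - d) ** 2
        * (d**2 + 2 * d * r - 3 * r**2 + 2 * d * R + 6 * r * R - 3 * R**2)
        / (12 * d)
    )


def _fibonacci_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (1 + math.sqrt(5)) * i
    z = 1 - 2 * i / n
    rho = np.sqrt(np.clip(1 - z * z, 0, 1))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _spicule_layout(count, height, width, rng, jitter_deg=6.0,
                    height_jitter=0.0) -> List[SpiculeRec]:
    """Quasi-uniform spicule directions with seeded angular jitter."""
    if count <= 0:
        return []
    dirs = _fibonacci_directions(count)
    jit = rng.normal(0.0, math.radians(jitter_deg), size=(count, 3))
    dirs = dirs + jit
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    heights = height * (1.0 + height_jitter * rng.standard_normal(count))
    return [
        SpiculeRec(direction=d, height_um=float(max(h, 0.0)), width_um=width, spicule_id=i)
        for i, (d, h) in enumerate(zip(dirs, heights))
    ]


def _build_shape(spec: PhantomSpec, spicules: Optional[List[SpiculeRec]] = None) -> Tuple[_Shape, List[SpiculeRec]]:
    rng = np.random.default_rng(spec.rng_seed)
    cls = spec.cell_class
    r = spec.diameter_um / 2.0

    if cls == "bead":
        return _Sphere(r), []
    if cls == "spherocyte":
        return _Sphere(r), []
    if cls in ("normocyte", "ovalocyte"):
        return _Discocyte(spec.diameter_um, spec.thickness_um, spec.elongation), []
    if cls == "sickle":
        kappa = 0.10  # 1/μm; crescent curvature of the long axis
        return _Discocyte(spec.diameter_um, spec.thickness_um, spec.elongation, bend_curvature=kappa), []
    if cls == "helmet":
        return _Helmet(r), []
    if cls == "stomatocyte":
        depth = spec.dimple_depth_um or 0.2 * spec.diameter_um
        cup = [SpiculeRec(np.array([0.0, 0.0, 1.0]), -depth, 0.45 * r, 0)]
        return _RadialShape(r, 0.85 * r, cup), []
    if cls in ("echinocyte", "acanthocyte"):
        if spicules is None:
            hj = 0.25 if cls == "acanthocyte" else 0.0
            spicules = _spicule_layout(
                spec.spicule_count, spec.spicule_height_um, spec.spicule_width_um,
                rng, jitter_deg=(15.0 if cls == "acanthocyte" else 6.0), height_jitter=hj,
            )
        a = spec.diameter_um / 2.0
        c = (spec.thickness_um or 0.55 * spec.diameter_um) / 2.0
        return _RadialShape(a, c, spicules), spicules
    if cls == "teardrop":
        tail = [SpiculeRec(np.array([1.0, 0.0, 0.0]), 0.45 * spec.diameter_um, 0.5 * r, 0)]
        return _RadialShape(r, 0.8 * r, tail), []
    raise UnsupportedClassError(cls)


# ---------------------------------------------------------------------------
# rasterisation


def _rasterize(shape: _Shape, spec_center, orientation_deg, grid: GridSpec,
               mask_out: np.ndarray) -> int:
    """OR the voxelised shape into ``mask_out`` (z, y, x); returns voxel count."""
    xs, ys, zs = grid.axes_um()
    cx, cy, cz = spec_center
    he = np.asarray(shape.half_extents, dtype=float)
    if any(orientation_deg):
        rot = Rotation.from_euler("zyx", orientation_deg, degrees=True)
        # conservative world-frame AABB of the rotated local box, never
        # worse than the isotropic bounding sphere
        he = np.minimum(np.abs(rot.as_matrix()) @ he,
                        shape.bounding_radius)
    ext = grid.extent_um
    for c, h, e, name in zip(spec_center, he, ext, "xyz"):
        if c - h < -1e-9 or c + h > e + 1e-9:
            raise OutOfBoundsError(
                f"shape of half-extent {h:.2f} μm at {name}={c:.2f} μm "
                f"exceeds the {e:.1f} μm grid extent"
            )
    ix = np.flatnonzero(np.abs(xs - cx) <= he[0] + grid.voxel_size_xyz[0])
    iy = np.flatnonzero(np.abs(ys - cy) <= he[1] + grid.voxel_size_xyz[1])
    iz = np.flatnonzero(np.abs(zs - cz) <= he[2] + grid.voxel_size_xyz[2])
    if len(ix) == 0 or len(iy) == 0 or len(iz) == 0:
        return 0
    X, Y, Z = np.meshgrid(xs[ix] - cx, ys[iy] - cy, zs[iz] - cz, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    if any(orientation_deg):
        rot = Rotation.from_euler("zyx", orientation_deg, degrees=True)
        pts = pts @ rot.as_matrix()  # rotate points into the local frame
    ins = shape.inside(pts).reshape(X.shape)
    # local block is (x, y, z); volume array is (z, y, x)
    block = np.transpose(ins, (2, 1, 0))
    sub = mask_out[np.ix_(iz, iy, ix)]
    mask_out[np.ix_(iz, iy, ix)] = sub | block
    return int(block.sum())


def interior_ri(hb_concentration_g_dl: float) -> float:
    """Inverse of the Hb retrieval formula: RI carried by cytoplasm voxels."""
    return N_WATER + ALPHA_HB * hb_concentration_g_dl


def _default_center(grid: GridSpec, z_um: float = None):
    ex, ey, ez = grid.extent_um
    return (ex / 2, ey / 2, z_um if z_um is not None else ez / 2)


def make_cell_phantom(spec: PhantomSpec, grid: GridSpec = None,
                      noise_sigma: float = 0.0):
    """Voxelise a single cell into a tomogram with its ground truth.

    Returns ``(Tomogram, PhantomGroundTruth)``.  The tomogram carries the
    medium RI outside the cell and ``n_H2O + α·Hb`` inside; optional
    additive Gaussian RI noise (off by default).
    """
    if grid is None:
        grid = GridSpec()
    if spec.center_um == (0.0, 0.0, 0.0):
        spec = replace(spec, center_um=_default_center(grid))
    tom, gt = make_scene([spec], grid, noise_sigma=noise_sigma)
    return tom, gt


def make_bead_phantom(diameter_um: float, grid: GridSpec = None,
                      center_um=None, ri: float = BEAD_RI):
    """Uniform-RI silica calibration bead; closed-form ground truth."""
    if diameter_um <= 0:
        raise PhantomError("bead diameter must be positive")
    if grid is None:
        grid = GridSpec()
    if center_um is None:
        center_um = _default_center(grid)
    mask = np.zeros(grid.shape_zyx, dtype=bool)
    shape = _Sphere(diameter_um / 2.0)
    _rasterize(shape, center_um, (0, 0, 0), grid, mask)
    data = np.full(grid.shape_zyx, grid.background_ri, dtype=np.float32)
    data[mask] = ri
    rec = CellRecord(
        label="bead", center_um=tuple(center_um),
        volume_fl=shape.volume_fl(), area_um2=shape.area_um2(),
        spicule_count=0, hb_concentration_g_dl=0.0, interior_ri=ri,
        diameter_um=diameter_um,
    )
    tom = Tomogram(data, grid.voxel_size_xyz, background_ri=grid.background_ri)
    return tom, PhantomGroundTruth(cells=[rec], background_ri=grid.background_ri)


def make_scene(specs: Sequence[PhantomSpec], grid: GridSpec = None,
               noise_sigma: float = 0.0, noise_seed: int = 0,
               background_gradient: float = 0.0):
    """Voxelise several cells into one tomogram.

    Overlapping cells take the larger RI voxelwise.  ``noise_sigma`` adds
    seeded Gaussian RI noise; ``background_gradient`` adds a smooth linear
    RI ramp along x of the given total amplitude.
    """
    if grid is None:
        grid = GridSpec()
    data = np.full(grid.shape_zyx, grid.background_ri, dtype=np.float32)
    occupied = np.zeros(grid.shape_zyx, dtype=bool)
    records = []
    for spec in specs:
        shape, spicules = _build_shape(spec)
        mask = np.zeros(grid.shape_zyx, dtype=bool)
        _rasterize(shape, spec.center_um, spec.orientation_deg, grid, mask)
        # silica beads carry their material RI, cells the Hb-mapped RI
        ri = BEAD_RI if spec.cell_class == "bead" else interior_ri(spec.hb_concentration_g_dl)
        fresh = mask & ~occupied
        data[fresh] = np.float32(ri)  # cytoplasm may sit below the medium RI
        overlap = mask & occupied
        if overlap.any():
            data[overlap] = np.maximum(data[overlap], np.float32(ri))
        occupied |= mask
        records.append(CellRecord(
            label=spec.cell_class, center_um=spec.center_um,
            volume_fl=shape.volume_fl(), area_um2=shape.area_um2(),
            spicule_count=len(spicules),
            hb_concentration_g_dl=spec.hb_concentration_g_dl,
            interior_ri=ri, spicules=spicules, diameter_um=spec.diameter_um,
        ))
    if background_gradient:
        nx = grid.shape_xyz[0]
        ramp = np.linspace(0, background_gradient, nx, dtype=np.float32)
        data += ramp[None, None, :]
    if noise_sigma:
        rng = np.random.default_rng(noise_seed)
        data += rng.normal(0.0, noise_sigma, size=data.shape).astype(np.float32)
        np.clip(data, 1.2, 1.6, out=data)
    tom = Tomogram(data, grid.voxel_size_xyz, background_ri=grid.background_ri)
    return tom, PhantomGroundTruth(cells=records, background_ri=grid.background_ri)


def make_population_scene(cell_class: str, n_cells: int, grid: GridSpec = None,
                          rng_seed: int = 0, z_um: float = None,
                          jitter_frac: float = 0.03, **spec_overrides):
    """A field of ``n_cells`` same-class cells on a jittered lattice.

    Cells sediment to a common z plane, keep clear of the XY borders and of
    each other, and receive small seeded geometry jitter (fractional sd
    ``jitter_frac`` on the diameter) plus per-cell orientation about z.
    Returns ``(Tomogram, PhantomGroundTruth)``.
    """
    if grid is None:
        grid = GridSpec()
    rng = np.random.default_rng(rng_seed)
    base = PhantomSpec.for_class(cell_class, **spec_overrides)
    shape, _ = _build_shape(base)
    he = shape.half_extents
    margin = float(max(he[0], he[1])) * 1.35 + 0.5
    ex, ey, ez = grid.extent_um
    pitch = 2.0 * margin * 0.85
    cols = int((ex - 2 * margin) // pitch) + 1
    rows = int((ey - 2 * margin) // pitch) + 1
    if cols * rows < n_cells:
        raise PhantomError(
            f"cannot place {n_cells} cells of class {cell_class!r} in a "
            f"{ex:.0f}×{ey:.0f} μm field without contact"
        )
    if z_um is None:
        z_um = min(float(he[2]) + 0.6, ez / 2)
    positions = [(margin + i * pitch, margin + j * pitch)
                 for j in range(rows) for i in range(cols)]
    order = rng.permutation(len(positions))[:n_cells]
    specs = []
    for k in order:
        px, py = positions[k]
        jx, jy = rng.uniform(-0.1, 0.1, 2) * margin
        d = base.diameter_um * (1 + jitter_frac * rng.standard_normal())
        specs.append(replace(
            base,
            diameter_um=float(max(d, 0.5)),
            center_um=(float(px + jx), float(py + jy), float(z_um)),
            orientation_deg=(float(rng.uniform(0, 360)), 0.0, 0.0),
            rng_seed=int(rng.integers(2**31 - 1)),
        ))
    return make_scene(specs, grid)


# ---------------------------------------------------------------------------
# time-lapse generation


@dataclass
class ShapeTrajectory:
    """Keyframed single-cell morphology with a spicule event schedule.

    ``keyframes`` is an ordered list of ``(time_s, PhantomSpec)``; numeric
    geometry is interpolated linearly between keyframes and the class label
    switches at the midpoint of each transition.  ``events`` schedules
    discrete spicule dynamics: ``(time_s, kind)`` with kind one of
    ``spicule_form | spicule_merge | spicule_split | spicule_dissolve``.
    """

    keyframes: List[Tuple[float, PhantomSpec]]
    frame_interval_s: float = 2.0
    events: List[Tuple[float, str]] = field(default_factory=list)

    EVENT_KINDS = ("spicule_form", "spicule_merge", "spicule_split", "spicule_dissolve")

    def __post_init__(self) -> None:
        if len(self.keyframes) < 2:
            raise PhantomError("a trajectory needs at least two keyframes")
        times = [t for t, _ in self.keyframes]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise PhantomError("keyframe times must be strictly increasing")
        if self.frame_interval_s <= 0:
            raise PhantomError("frame interval must be positive")
        t0, t1 = times[0], times[-1]
        for t, kind in self.events:
            if kind not in self.EVENT_KINDS:
                raise PhantomError(f"unknown event kind {kind!r}")
            if not (t0 <= t <= t1):
                raise PhantomError(f"event at t={t} s outside trajectory range [{t0}, {t1}] s")

    @property
    def duration_s(self) -> float:
        return self.keyframes[-1][0] - self.keyframes[0][0]


_INTERP_FIELDS = (
    "diameter_um", "spicule_height_um", "spicule_width_um",
    "dimple_depth_um", "elongation", "hb_concentration_g_dl",
)


def _interp_spec(sa: PhantomSpec, sb: PhantomSpec, f: float) -> PhantomSpec:
    kw = {}
    for name in _INTERP_FIELDS:
        kw[name] = (1 - f) * getattr(sa, name) + f * getattr(sb, name)
    ta = sa.thickness_um if sa.thickness_um is not None else _implied_thickness(sa)
    tb = sb.thickness_um if sb.thickness_um is not None else _implied_thickness(sb)
    kw["thickness_um"] = (1 - f) * ta + f * tb
    kw["center_um"] = tuple((1 - f) * a + f * b for a, b in zip(sa.center_um, sb.center_um))
    label = sa.cell_class if f < 0.5 else sb.cell_class
    base = sa if f < 0.5 else sb
    return replace(base, cell_class=label, spicule_count=base.spicule_count,
                   rng_seed=base.rng_seed, orientation_deg=base.orientation_deg, **kw)


def _implied_thickness(spec: PhantomSpec) -> float:
    if spec.cell_class in ("normocyte", "ovalocyte", "sickle"):
        return EF_MAX_THICKNESS * spec.diameter_um / EF_DIAMETER
    if spec.cell_class in ("echinocyte", "acanthocyte"):
        return 0.55 * spec.diameter_um
    return spec.diameter_um


def _spicule_envelope(sa: PhantomSpec, sb: PhantomSpec, f: float) -> float:
    """Spicule visibility g ∈ {0, 1} for the morphing field.

    Spicule onset is rendered as a rapid switch at the class midpoint
    rather than a slow ramp: echinocytic spicules form within tens of
    seconds, fast against the minute-scale shape relaxation, and a slow
    ramp would spend many frames hovering at the detection threshold,
    which no real membrane does.
    """
    ga = 1.0 if sa.spicule_count > 0 else 0.0
    gb = 1.0 if sb.spicule_count > 0 else 0.0
    return ga if f < 0.5 else gb


def make_timelapse(trajectory: ShapeTrajectory, grid: GridSpec = None,
                   noise_sigma: float = 0.0):
    """Render a keyframed trajectory into a frame sequence with ground truth.

    Scheduled spicule events edit an explicit spicule inventory at their
    stated times: formation adds one spicule at a fresh direction, a split
    replaces one spicule by two slightly separated daughters, a merge fuses
    the two closest spicules, and dissolution removes one.  The per-frame
    ground truth records the class label, the live spicule count and the
    frame index of every realised event.
    """
    if grid is None:
        grid = GridSpec()
    traj = trajectory
    t0 = traj.keyframes[0][0]
    n_frames = int(round(traj.duration_s / traj.frame_interval_s)) + 1
    ktimes = np.array([t for t, _ in traj.keyframes])
    rng = np.random.default_rng(traj.keyframes[0][1].rng_seed + 12345)

    # initial spicule inventory from the first spiculated keyframe
    inventory: List[SpiculeRec] = []
    next_id = 0
    for _, s in traj.keyframes:
        if s.spicule_count > 0:
            layout_rng = np.random.default_rng(s.rng_seed)
            inventory = _spicule_layout(s.spicule_count, s.spicule_height_um,
                                        s.spicule_width_um, layout_rng)
            next_id = len(inventory)
            break

    events_sorted = sorted(traj.events, key=lambda e: e[0])
    ev_idx = 0
    realized_events: List[dict] = []

    frames, labels, counts, centers = [], [], [], []
    for k in range(n_frames):
        t = t0 + k * traj.frame_interval_s
        # apply events scheduled up to and including this frame time
        while ev_idx < len(events_sorted) and events_sorted[ev_idx][0] <= t + 1e-9:
            ev_t, kind = events_sorted[ev_idx]
            ev_idx += 1
            next_id, ev_rec = _apply_event(kind, inventory, rng, next_id, k)
            realized_events.append(ev_rec)

        # bracket keyframes
        j = int(np.clip(np.searchsorted(ktimes, t, side="right") - 1, 0, len(ktimes) - 2))
        ta, sa = traj.keyframes[j]
        tb, sb = traj.keyframes[j + 1]
        f = float(np.clip((t - ta) / (tb - ta), 0.0, 1.0))
        spec = _interp_spec(sa, sb, f)
        g = _spicule_envelope(sa, sb, f)

        rendered = [
            SpiculeRec(s.direction, s.height_um * g, s.width_um, s.spicule_id)
            for s in inventory
        ] if g > 0 else []
        live = sum(1 for s in rendered if s.height_um > 0.05)

        if rendered and live:
            a = spec.diameter_um / 2.0
            c = (spec.thickness_um or 0.55 * spec.diameter_um) / 2.0
            shape: _Shape = _RadialShape(a, c, rendered)
        else:
            base_spec = replace(spec, spicule_count=0,
                                cell_class=spec.cell_class
                                if spec.cell_class not in ("echinocyte", "acanthocyte")
                                else "spherocyte")
            shape, _ = _build_shape(base_spec)

        mask = np.zeros(grid.shape_zyx, dtype=bool)
        _rasterize(shape, spec.center_um, spec.orientation_deg, grid, mask)
        data = np.full(grid.shape_zyx, grid.background_ri, dtype=np.float32)
        data[mask] = interior_ri(spec.hb_concentration_g_dl)
        if noise_sigma:
            data += rng.normal(0, noise_sigma, size=data.shape).astype(np.float32)
            np.clip(data, 1.2, 1.6, out=data)
        frames.append(Tomogram(data, grid.voxel_size_xyz, grid.background_ri,
                               timestamp_s=t))
        labels.append(spec.cell_class)
        counts.append(live)
        centers.append(spec.center_um)

    first = traj.keyframes[0][1]
    rec = CellRecord(
        label=first.cell_class, center_um=first.center_um,
        volume_fl=None, area_um2=None, spicule_count=len(inventory),
        hb_concentration_g_dl=first.hb_concentration_g_dl,
        interior_ri=interior_ri(first.hb_concentration_g_dl),
        spicules=inventory,
    )
    gt = PhantomGroundTruth(
        cells=[rec], background_ri=grid.background_ri,
        frame_labels=labels, frame_spicule_counts=counts,
        events=realized_events, frame_interval_s=traj.frame_interval_s,
        frame_centers_um=centers,
    )
    return TimeLapse(frames, traj.frame_interval_s), gt


def _apply_event(kind: str, inventory: List[SpiculeRec], rng, next_id: int, frame: int):
    if kind == "spicule_form":
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        h = float(np.mean([s.height_um for s in inventory])) if inventory else 0.25
        w = float(np.mean([s.width_um for s in inventory])) if inventory else 0.55
        inventory.append(SpiculeRec(d, h, w, next_id))
        return next_id + 1, {"kind": "formation", "frame": frame, "spicules": [next_id]}
    if kind == "spicule_dissolve":
        if not inventory:
            raise PhantomError("cannot dissolve: no spicules alive")
        s = inventory.pop(rng.integers(len(inventory)))
        return next_id, {"kind": "dissolution", "frame": frame, "spicules": [s.spicule_id]}
    if kind == "spicule_split":
        if not inventory:
            raise PhantomError("cannot split: no spicules alive")
        i = int(rng.integers(len(inventory)))
        parent = inventory.pop(i)
        axis = np.cross(parent.direction, [0.0, 0.0, 1.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.array([1.0, 0.0, 0.0])
        axis /= np.linalg.norm(axis)
        children = []
        for sign in (+1, -1):
            rot = Rotation.from_rotvec(sign * math.radians(13.0) * axis)
            d = rot.apply(parent.direction)
            children.append(SpiculeRec(d / np.linalg.norm(d), parent.height_um,
                                       parent.width_um * 0.8, next_id))
            next_id += 1
        inventory.extend(children)
        return next_id, {"kind": "split", "frame": frame,
                         "spicules": [parent.spicule_id] + [c.spicule_id for c in children]}
    if kind == "spicule_merge":
        if len(inventory) < 2:
            raise PhantomError("cannot merge: fewer than two spicules alive")
        best, pair = None, None
        for i in range(len(inventory)):
            for j in range(i + 1, len(inventory)):
                ang = math.acos(float(np.clip(
                    inventory[i].direction @ inventory[j].direction, -1, 1)))
                if best is None or ang < best:
                    best, pair = ang, (i, j)
        i, j = pair
        b = inventory.pop(j)
        a = inventory.pop(i)
        d = a.direction + b.direction
        d /= np.linalg.norm(d)
        merged = SpiculeRec(d, max(a.height_um, b.height_um),
                            (a.width_um + b.width_um) * 0.7, next_id)
        inventory.append(merged)
        return next_id + 1, {"kind": "merge", "frame": frame,
                             "spicules": [a.spicule_id, b.spicule_id, merged.spicule_id]}
    raise PhantomError(f"unknown event kind {kind!r}")


# ---------------------------------------------------------------------------
# canned dose-response scenarios (single cell, centred)


def _scenario_specs(grid: GridSpec, hb=33.0, seed=0):
    c = _default_center(grid, z_um=grid.extent_um[2] / 2)
    norm = PhantomSpec.for_class("normocyte", hb_concentration_g_dl=hb,
                                 center_um=c, rng_seed=seed)
    echin = PhantomSpec.for_class("echinocyte", hb_concentration_g_dl=hb + 1.5,
                                  center_um=c, rng_seed=seed)
    return norm, echin


def low_dose_trajectory(grid: GridSpec = None, frame_interval_s=2.0, seed=0,
                        duration_s=1200.0, events=()):
    """Reversible echinocytosis: normocyte → echinocyte → normocyte in 20 min."""
    if grid is None:
        grid = GridSpec()
    norm, echin = _scenario_specs(grid, seed=seed)
    return ShapeTrajectory(
        keyframes=[(0.0, norm), (0.3 * duration_s, echin),
                   (0.6 * duration_s, echin), (duration_s, norm)],
        frame_interval_s=frame_interval_s, events=list(events),
    )


def high_dose_trajectory(grid: GridSpec = None, frame_interval_s=2.0, seed=0,
                         duration_s=1200.0, events=()):
    """Persistent spheroechinocytosis: the normocyte shape never recovers."""
    if grid is None:
        grid = GridSpec()
    norm, echin = _scenario_specs(grid, seed=seed)
    sphero = replace(echin, diameter_um=5.6, thickness_um=4.6,
                     spicule_height_um=0.25,
                     hb_concentration_g_dl=echin.hb_concentration_g_dl + 1.0)
    return ShapeTrajectory(
        keyframes=[(0.0, norm), (0.25 * duration_s, echin),
                   (0.5 * duration_s, sphero), (duration_s, sphero)],
        frame_interval_s=frame_interval_s, events=list(events),
    )


# ---------------------------------------------------------------------------
# AFM-style height maps


def make_height_map(kind: str, params: dict = None, rng_seed: int = 0) -> HeightMap:
    """Synthetic AFM topograph.

    kinds:
      ``flat``           — constant zero height (optionally tilted via
                           ``tilt_x_nm_per_px`` / ``tilt_y_nm_per_px``).
      ``normocyte``      — dried biconcave disc profile (smooth).
      ``echinocyte``     — dome plus Gaussian bumps of ``bump_amplitude_nm``.
      ``particle_field`` — hemispherical caps on a flat substrate with
                           diameters drawn from ``lognormal(median_nm,
                           sigma_log)``.
    """
    p = dict(params or {})
    rng = np.random.default_rng(rng_seed)
    size_px = int(p.pop("size_px", 256))
    pixel_nm = float(p.pop("pixel_size_nm", 50.0))
    yy, xx = np.mgrid[0:size_px, 0:size_px] * pixel_nm  # nm
    cx = cy = size_px * pixel_nm / 2.0

    if kind == "flat":
        h = np.zeros((size_px, size_px))
        h += p.pop("tilt_x_nm_per_px", 0.0) * (xx / pixel_nm)
        h += p.pop("tilt_y_nm_per_px", 0.0) * (yy / pixel_nm)
        return HeightMap(h, pixel_nm, meta={"kind": kind})

    if kind in ("normocyte", "echinocyte"):
        diameter_nm = float(p.pop("diameter_nm", 7820.0))
        # air-dried smear cells collapse to a few hundred nm; the biconcave
        # footprint survives but the dome is far flatter than in suspension
        max_height_nm = float(p.pop("max_height_nm", 400.0))
        rho = np.hypot(xx - cx, yy - cy) / 1000.0  # μm
        scale = EF_DIAMETER * 1000.0 / diameter_nm  # map the cell rim onto EF_R
        base = evans_fung_half_thickness(rho * scale) * 2.0
        base *= max_height_nm / (base.max() if base.max() > 0 else 1.0)
        if kind == "normocyte":
            return HeightMap(base, pixel_nm, meta={"kind": kind})
        amp = float(p.pop("bump_amplitude_nm", 200.0))
        n_bumps = int(p.pop("n_bumps", 20))
        sigma_nm = float(p.pop("bump_sigma_nm", 300.0))
        if amp < 0 or sigma_nm <= 0:
            raise PhantomError("bump amplitude must be non-negative and width positive")
        # spicules sit on the body annulus, where the dried dome is near its
        # maximum; bumps combine by max so the tallest protrusion rises by
        # the stated amplitude, not by a sum of overlaps
        r_cell = diameter_nm / 2.0
        ang = rng.uniform(0, 2 * math.pi, n_bumps)
        rad = rng.uniform(0.55 * r_cell, 0.85 * r_cell, n_bumps)
        bx, by = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
        bumps = np.zeros_like(base)
        for x0, y0 in zip(bx, by):
            np.maximum(
                bumps,
                amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma_nm**2)),
                out=bumps,
            )
        return HeightMap(base + bumps, pixel_nm,
                         meta={"kind": kind, "bump_amplitude_nm": amp})

    if kind == "particle_field":
        n = int(p.pop("n_particles", 200))
        median_nm = float(p.pop("median_nm", 13.0))
        sigma_log = float(p.pop("sigma_log", 0.2))
        if median_nm <= 0 or sigma_log < 0:
            raise PhantomError("particle size parameters must be positive")
        sizes = draw_particle_sizes(n, median_nm, sigma_log, rng)
        h = np.zeros((size_px, size_px))
        px, py = rng.uniform(0, size_px * pixel_nm, n), rng.uniform(0, size_px * pixel_nm, n)
        for x0, y0, d in zip(px, py, sizes):
            r = d / 2.0
            r2 = (xx - x0) ** 2 + (yy - y0) ** 2
            cap = np.sqrt(np.clip(r**2 - r2, 0.0, None))
            np.maximum(h, cap, out=h)
        return HeightMap(h, pixel_nm, meta={"kind": kind, "true_sizes_nm": sizes.tolist(),
                                            "true_mean_nm": float(np.mean(sizes))})

    raise PhantomError(f"unknown height-map kind {kind!r}")


def draw_particle_sizes(n: int, median_nm: float, sigma_log: float, rng) -> np.ndarray:
    """Right-skewed (lognormal) particle diameters; mean = median·exp(σ²/2)."""
    return median_nm * np.exp(sigma_log * rng.standard_normal(n))
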