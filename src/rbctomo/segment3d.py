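"""3D segmentation of RI tomograms into single cells.

The chain mirrors a standard holotomography workflow: crop away empty
z-slices, apply a fixed 3×3×3 median filter, estimate and subtract the
background RI level (histogram mode — the medium dominates the field of
view), threshold automatically (Otsu), label connected components under a
26-neighbourhood, and discard cells that touch the lateral image border or
fall outside a volume gate.  Touching cells are not split; they are flagged
as suspected merges and removed by the filter, matching a workflow that
discards overlapping cells rather than watershedding them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .grids import Tomogram

__all__ = ["SegmentedCell", "SegmentationConfig", "preprocess", "segment", "filter_cells"]


@dataclass
class SegmentationConfig:
    """Tunable parameters of the segmentation chain."""

    #: fallback threshold above background when Otsu degenerates (RI units)
    fallback_threshold: float = 0.01
    #: z-slices with max(RI) − background below this many noise sigmas are cropped
    zcrop_nsigma: float = 2.0
    #: minimal absolute z-crop margin in RI units (guards the noise-free case)
    zcrop_min_excess: float = 0.003
    #: volume gate [fL]; cells outside are discarded by filter_cells
    volume_gate_fl: Tuple[float, float] = (20.0, 200.0)
    #: components larger than this multiple of the scene median volume are
    #: flagged as suspected merges
    merge_volume_factor: float = 1.6
    #: 3D connectivity (3 = 26-neighbourhood)
    connectivity: int = 3


@dataclass
class SegmentedCell:
    """One labelled cell: voxel mask on the parent grid plus QC flags."""

    cell_id: int
    mask: np.ndarray  # boolean, full-grid (z, y, x)
    voxel_size_xyz: Tuple[float, float, float]
    bbox: Tuple[slice, slice, slice]
    touches_border: bool = False
    suspected_merge: bool = False
    frame: Optional[int] = None

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_fl(self) -> float:
        vx, vy, vz = self.voxel_size_xyz
        return self.voxel_count * vx * vy * vz

    @property
    def centroid_um(self) -> np.ndarray:
        """(x, y, z) centroid in μm."""
        zc, yc, xc = ndimage.center_of_mass(self.mask)
        vx, vy, vz = self.voxel_size_xyz
        return np.array([(xc + 0.5) * vx, (yc + 0.5) * vy, (zc + 0.5) * vz])


def estimate_background(tom: Tomogram, bin_width: float = 5e-4) -> Tuple[float, float]:
    """Mode of the RI histogram and a robust noise sigma (MAD of the mode bin's
    neighbourhood)."""
    data = tom.data
    lo, hi = float(data.min()), float(data.max())
    nbins = max(int((hi - lo) / bin_width), 1)
    hist, edges = np.histogram(data, bins=nbins)
    k = int(np.argmax(hist))
    mode = 0.5 * (edges[k] + edges[k + 1])
    near = data[np.abs(data - mode) < 10 * bin_width]
    sigma = float(1.4826 * np.median(np.abs(near - np.median(near)))) if near.size else 0.0
    return mode, sigma


def preprocess(tom: Tomogram, cfg: SegmentationConfig = None,
               zcrop: bool = True) -> Tomogram:
    """z-crop empty slices, then apply the fixed 3×3×3 median filter.

    An all-background volume is returned cropped to zero slices (an empty
    tomogram signals "nothing to segment"; no exception is raised).
    ``zcrop=False`` keeps the full z-range — used for time-lapses, where
    every frame must stay on one grid.
    """
    cfg = cfg or SegmentationConfig()
    background, sigma = estimate_background(tom)
    excess = max(cfg.zcrop_nsigma * sigma, cfg.zcrop_min_excess)
    slice_max = tom.data.max(axis=(1, 2))
    keep = np.flatnonzero(slice_max > background + excess)
    if keep.size == 0:
        return _empty_like(tom)
    if not zcrop:
        keep = np.arange(tom.data.shape[0])
    z0, z1 = keep.min(), keep.max() + 1
    cropped = tom.data[z0:z1]
    filtered = ndimage.median_filter(cropped, size=3, mode="nearest")
    return Tomogram(filtered, tom.voxel_size_xyz, tom.background_ri, tom.timestamp_s)


def _empty_like(tom: Tomogram) -> Tomogram:
    out = Tomogram.__new__(Tomogram)
    out.data = np.empty((0,) + tom.data.shape[1:], dtype=np.float32)
    out.voxel_size_xyz = tom.voxel_size_xyz
    out.background_ri = tom.background_ri
    out.timestamp_s = tom.timestamp_s
    return out


def segment(tom: Tomogram, cfg: SegmentationConfig = None) -> List[SegmentedCell]:
    """Background subtraction, automatic threshold, connected components.

    Returns one :class:`SegmentedCell` per component with ``touches_border``
    (XY faces only) and ``suspected_merge`` (volume > ``merge_volume_factor``
    × scene median) flags set.  An empty list signals no foreground.
    """
    cfg = cfg or SegmentationConfig()
    if tom.data.size == 0:
        return []
    background, sigma = estimate_background(tom)
    sub = tom.data - np.float32(background)
    if float(sub.max()) - float(sub.min()) < 1e-5:
        return []
    floor = max(3.0 * sigma, cfg.zcrop_min_excess)
    if float(sub.max()) < cfg.fallback_threshold:
        warnings.warn(
            "degenerate (unimodal) RI histogram; using fallback threshold",
            stacklevel=2,
        )
        thr = cfg.fallback_threshold
    else:
        try:
            thr = float(threshold_otsu(sub))
        except ValueError:
            thr = cfg.fallback_threshold
        # with a clean, strongly imbalanced histogram Otsu can land inside
        # the background spike; the noise floor guards against that
        thr = max(thr, floor)
    fg = sub > thr
    if not fg.any():
        return []
    structure = ndimage.generate_binary_structure(3, cfg.connectivity)
    labels, n = ndimage.label(fg, structure=structure)
    if n == 0:
        return []
    objects = ndimage.find_objects(labels)
    cells: List[SegmentedCell] = []
    counts = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
    vx, vy, vz = tom.voxel_size_xyz
    volumes = counts * (vx * vy * vz)
    # leave-largest-out median: a single merged pair must not drag the
    # reference volume up in small scenes
    if n > 1:
        rest = np.sort(volumes)[:-1]
        median_v = float(np.median(rest))
    else:
        median_v = float(volumes[0])
    nz, ny, nx = tom.data.shape
    for i in range(n):
        sl = objects[i]
        mask = np.zeros_like(fg)
        mask[sl] = labels[sl] == (i + 1)
        touches = (
            sl[1].start == 0 or sl[1].stop == ny or sl[2].start == 0 or sl[2].stop == nx
        )
        merged = volumes[i] > cfg.merge_volume_factor * median_v and n > 1
        cells.append(SegmentedCell(
            cell_id=i + 1, mask=mask, voxel_size_xyz=tom.voxel_size_xyz,
            bbox=sl, touches_border=bool(touches), suspected_merge=bool(merged),
        ))
    return cells


def filter_cells(cells: List[SegmentedCell], cfg: SegmentationConfig = None) -> List[SegmentedCell]:
    """Drop XY-border cells, out-of-gate volumes, and suspected merges.

    Touching the z faces is allowed: sedimented cells legitimately rest on
    the dish bottom.  May return an empty list.
    """
    cfg = cfg or SegmentationConfig()
    lo, hi = cfg.volume_gate_fl
    kept = []
    for c in cells:
        if c.touches_border or c.suspected_merge:
            continue
        if not (lo <= c.volume_fl <= hi):
            continue
        kept.append(c)
    return kept
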