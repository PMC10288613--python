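"""AFM-style height-map analysis.

Standard scanning-probe post-processing — plane leveling and scan-line
correction — followed by the three quantities used to characterise RBC
membranes and drug aggregates: line profiles, RMS roughness (Sq) in
non-overlapping 1 μm² windows, and particle-size statistics with a
percentile-bootstrap 95% confidence interval of the mean (the particle
size distribution is right-skewed, so a Gaussian interval would be wrong).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .grids import HeightMap

__all__ = [
    "ParticleStats",
    "level",
    "line_profile",
    "rms_roughness",
    "particle_size_stats",
    "bootstrap_ci_mean",
]


@dataclass
class ParticleStats:
    """Particle population summary: mean diameter with bootstrap 95% CI."""

    n: int
    mean_nm: float
    ci_low_nm: float
    ci_high_nm: float
    sizes_nm: np.ndarray

    def __post_init__(self) -> None:
        if self.n != len(self.sizes_nm):
            raise ValueError("n must equal the number of sizes")
        if not (self.ci_low_nm <= self.mean_nm <= self.ci_high_nm):
            raise ValueError("CI must bracket the mean")


def level(hm: HeightMap) -> HeightMap:
    """Remove the best-fit plane, then per-row median offsets.

    Mirrors the usual AFM '2D leveling + scan line correction' step; the
    result is idempotent up to floating-point noise.
    """
    h = hm.heights_nm
    ny, nx = h.shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    A = np.column_stack([xx.ravel(), yy.ravel(), np.ones(h.size)])
    coef, *_ = np.linalg.lstsq(A, h.ravel(), rcond=None)
    flat = h - (A @ coef).reshape(h.shape)
    flat = flat - np.median(flat, axis=1, keepdims=True)
    return HeightMap(flat, hm.pixel_size_nm, meta=dict(hm.meta, leveled=True))


def line_profile(hm: HeightMap, row: Optional[int] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Height profile h(x) along one scan line (centre row by default).

    Returns (x_nm, heights_nm).
    """
    if row is None:
        row = hm.shape[0] // 2
    x = np.arange(hm.shape[1]) * hm.pixel_size_nm
    return x, hm.heights_nm[row].copy()


def rms_roughness(hm: HeightMap, window_um2: float = 1.0) -> np.ndarray:
    """Sq per non-overlapping window of ``window_um2`` μm².

    Sq = sqrt(mean((h − mean h)²)) within each square window; windows are
    tiled from the top-left corner and partial edge windows are discarded.
    """
    if window_um2 <= 0:
        raise ValueError("window area must be positive")
    side_nm = np.sqrt(window_um2) * 1000.0
    w = int(round(side_nm / hm.pixel_size_nm))
    ny, nx = hm.shape
    if w > min(ny, nx):
        raise ValueError(
            f"window side of {w} px exceeds the {min(ny, nx)} px map"
        )
    if w < 1:
        raise ValueError("window smaller than one pixel")
    sq = []
    for iy in range(ny // w):
        for ix in range(nx // w):
            tile = hm.heights_nm[iy * w:(iy + 1) * w, ix * w:(ix + 1) * w]
            sq.append(np.sqrt(np.mean((tile - tile.mean()) ** 2)))
    return np.asarray(sq)


def bootstrap_ci_mean(values: np.ndarray, n_boot: int = 10_000,
                      rng_seed: int = 0, level_pct: float = 95.0,
                      batch: int = 1000) -> Tuple[float, float]:
    """Percentile bootstrap CI of the mean of ``values``."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = np.random.default_rng(rng_seed)
    n = values.size
    means = np.empty(n_boot)
    done = 0
    while done < n_boot:
        b = min(batch, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        means[done:done + b] = values[idx].mean(axis=1)
        done += b
    a = (100.0 - level_pct) / 2.0
    lo, hi = np.percentile(means, [a, 100.0 - a])
    return float(lo), float(hi)


def detect_particles(hm: HeightMap, threshold_nm: Optional[float] = None,
                     min_pixels: int = 2) -> np.ndarray:
    """Equivalent-circle diameters (nm) of connected above-threshold regions.

    The default threshold is 3× the background Sq (roughness of the
    below-median half of the heights), suited to sparse particles on an
    atomically flat substrate.
    """
    h = hm.heights_nm
    if threshold_nm is None:
        background = h[h <= np.median(h)]
        sq_bg = float(np.sqrt(np.mean((background - background.mean()) ** 2)))
        threshold_nm = 3.0 * sq_bg if sq_bg > 0 else 0.5
    labels, n = ndimage.label(h > threshold_nm)
    if n == 0:
        return np.empty(0)
    areas_px = ndimage.sum_labels(np.ones_like(h), labels, index=np.arange(1, n + 1))
    areas_px = areas_px[areas_px >= min_pixels]
    areas_nm2 = areas_px * hm.pixel_size_nm**2
    return 2.0 * np.sqrt(areas_nm2 / np.pi)


def particle_size_stats(hm: HeightMap, threshold_nm: Optional[float] = None,
                        n_boot: int = 10_000, rng_seed: int = 0,
                        min_pixels: int = 2) -> Optional[ParticleStats]:
    """Particle detection plus bootstrap mean-size statistics.

    Returns ``None`` when no particles are found (the empty-stats signal).
    """
    sizes = detect_particles(hm, threshold_nm=threshold_nm, min_pixels=min_pixels)
    if sizes.size == 0:
        return None
    mean = float(sizes.mean())
    lo, hi = bootstrap_ci_mean(sizes, n_boot=n_boot, rng_seed=rng_seed)
    # the point estimate always lies inside its own percentile interval up
    # to resampling noise; guard the dataclass invariant explicitly
    lo, hi = min(lo, mean), max(hi, mean)
    return ParticleStats(n=int(sizes.size), mean_nm=mean,
                         ci_low_nm=lo, ci_high_nm=hi, sizes_nm=sizes)
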