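"""4D tracking and spicule dynamics.

Cells are linked across frames by greedy nearest-centroid assignment under
a displacement gate (sedimented RBCs barely move between 2 s frames, so no
appearance model is needed).  Membrane spicules are detected on the cell
surface mesh by fitting a smooth base surface — a low-degree spherical-
harmonic expansion of the per-vertex radius field about the centroid — and
extracting connected patches of positive radial residual.  Frame-to-frame
spicule correspondence by apex direction then yields the four event types
observed during echinocytosis: formation, merge, split and dissolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.special import sph_harm_y

from .segment3d import SegmentedCell

__all__ = [
    "CellTrack",
    "Spicule",
    "SpiculeEvent",
    "SpiculeConfig",
    "link_cells",
    "detect_spicules",
    "radius_residuals",
    "spicule_events",
    "reversibility",
    "ReversibilityResult",
]


@dataclass
class CellTrack:
    """One cell's identity through a time-lapse."""

    track_id: int
    entries: List[Tuple[int, int]] = field(default_factory=list)  # (frame, cell_id)
    features: Dict[int, object] = field(default_factory=dict)  # frame -> CellFeatures
    labels: Dict[int, str] = field(default_factory=dict)  # frame -> class label
    centroids: Dict[int, np.ndarray] = field(default_factory=dict)
    gap_count: int = 0

    @property
    def frames(self) -> List[int]:
        return [f for f, _ in self.entries]

    def label_series(self) -> List[Tuple[int, str]]:
        return sorted(self.labels.items())


@dataclass
class Spicule:
    """A detected membrane protrusion on one frame's mesh."""

    apex_um: np.ndarray
    direction: np.ndarray  # unit vector from the cell centroid
    height_um: float
    basal_radius_um: float
    frame: int = 0
    spicule_id: int = 0


@dataclass
class SpiculeEvent:
    """A discrete change in the spicule population."""

    kind: str  # formation | merge | split | dissolution
    frame: int
    parents: List[int] = field(default_factory=list)
    children: List[int] = field(default_factory=list)


@dataclass
class SpiculeConfig:
    """Detection and linking parameters."""

    #: spherical-harmonic degree of the base-surface expansion
    lmax: int = 12
    #: roughness-penalty weight of the base fit (spectral smoothing; larger
    #: values give a stiffer base surface)
    penalty: float = 5e-6
    #: minimal residual height for a spicule, μm (below the ~0.1 μm of the
    #: smallest reported protrusions)
    h_min_um: float = 0.08
    #: residual threshold seeding the first-pass spicule candidates, μm
    h_seed_um: float = 0.05
    #: minimal number of mesh vertices in a spicule patch (smaller patches
    #: are voxelization ripple, not membrane structure)
    min_patch_vertices: int = 8
    #: lower bound for first-pass candidate patches: over-excluding a few
    #: ripple vertices from the base refit is harmless, while failing to
    #: exclude a partially-absorbed spicule loses it entirely
    min_seed_vertices: int = 3
    #: candidate patches wider than this angular extent are body features
    #: (rims, folds), not spicules
    max_patch_extent_deg: float = 40.0
    #: candidate patches covering more than this vertex fraction are body
    max_patch_fraction: float = 0.06
    #: graph-dilation rings applied to candidate patches before the refit
    exclusion_dilation: int = 3
    #: frame-to-frame apex linking gate, degrees on the unit sphere
    link_gate_deg: float = 20.0


# ---------------------------------------------------------------------------
# cell linking


def link_cells(frames: Sequence[Sequence[SegmentedCell]], max_disp_um: float = 2.0,
               max_gap_frames: int = 1) -> List[CellTrack]:
    """Greedy nearest-centroid linking of segmented cells across frames.

    Unmatched cells start new tracks; tracks missing a match survive up to
    ``max_gap_frames`` frames (with a proportionally enlarged gate) before
    being terminated.  Frames must share one grid.
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames to track")
    shapes = {c.mask.shape for fr in frames for c in fr}
    if len(shapes) > 1:
        raise ValueError("frames have inconsistent grids")

    tracks: List[CellTrack] = []
    # active: list of (track, last_frame, last_centroid)
    active: List[List] = []
    next_id = 0
    for fi, cells in enumerate(frames):
        cents = [c.centroid_um for c in cells]
        unmatched = set(range(len(cells)))
        # candidate pairs sorted by distance
        pairs = []
        for ai, (tr, lf, lc) in enumerate(active):
            gap = fi - lf
            if gap > max_gap_frames + 1:
                continue
            gate = max_disp_um * gap
            for ci in unmatched:
                d = float(np.linalg.norm(cents[ci] - lc))
                if d <= gate:
                    pairs.append((d, ai, ci))
        pairs.sort()
        taken_tracks, taken_cells = set(), set()
        for d, ai, ci in pairs:
            if ai in taken_tracks or ci in taken_cells:
                continue
            taken_tracks.add(ai)
            taken_cells.add(ci)
            tr, lf, _ = active[ai]
            if fi - lf > 1:
                tr.gap_count += fi - lf - 1
            tr.entries.append((fi, cells[ci].cell_id))
            tr.centroids[fi] = cents[ci]
            active[ai] = [tr, fi, cents[ci]]
        unmatched -= taken_cells
        # retire tracks that exceeded the gap allowance
        active = [a for a in active if fi - a[1] <= max_gap_frames]
        for ci in sorted(unmatched):
            tr = CellTrack(track_id=next_id)
            next_id += 1
            tr.entries.append((fi, cells[ci].cell_id))
            tr.centroids[fi] = cents[ci]
            tracks.append(tr)
            active.append([tr, fi, cents[ci]])
    return tracks


# ---------------------------------------------------------------------------
# spicule detection


def _real_sh_basis(units: np.ndarray, lmax: int) -> np.ndarray:
    """Real spherical-harmonic design matrix for unit directions."""
    x, y, z = units[:, 0], units[:, 1], units[:, 2]
    theta = np.arccos(np.clip(z, -1.0, 1.0))  # polar
    phi = np.arctan2(y, x)  # azimuth
    cols = []
    for l in range(lmax + 1):
        for m in range(l + 1):
            ylm = sph_harm_y(l, m, theta, phi)
            cols.append(ylm.real)
            if m > 0:
                cols.append(ylm.imag)
    return np.column_stack(cols)


def _sh_penalty_diag(lmax: int) -> np.ndarray:
    """Thin-plate-style roughness penalty (l(l+1))² per basis column."""
    d = []
    for l in range(lmax + 1):
        for m in range(l + 1):
            d.append((l * (l + 1)) ** 2)
            if m > 0:
                d.append((l * (l + 1)) ** 2)
    return np.array(d, dtype=float)


def _penalized_fit(basis, radii, penalty_diag, lam, weights=None) -> np.ndarray:
    """Ridge solution of the penalized radius-field fit."""
    if weights is None:
        weights = np.ones(len(radii))
    bw = basis * weights[:, None]
    A = bw.T @ basis + lam * weights.sum() * np.diag(penalty_diag)
    return np.linalg.solve(A, bw.T @ radii)


def radius_residuals(mesh, lmax: int = 12, penalty: float = 5e-6):
    """Per-vertex radius residuals after a penalized spherical-harmonic fit.

    The base surface is a smoothing-spline-on-the-sphere expansion of the
    per-vertex radius field about the centroid: degree-``lmax`` real
    spherical harmonics with an (l(l+1))² roughness penalty, so broad body
    features are followed while narrow protrusions are left in the
    residual.  Returns ``(residuals_um, units, radii_um, centroid_um)``.
    """
    verts = np.asarray(mesh.vertices, dtype=float)
    centroid = verts.mean(axis=0)
    rel = verts - centroid
    radii = np.linalg.norm(rel, axis=1)
    if np.any(radii < 1e-9):
        raise ValueError("degenerate mesh: vertex at the centroid")
    units = rel / radii[:, None]
    basis = _real_sh_basis(units, lmax)
    coef = _penalized_fit(basis, radii, _sh_penalty_diag(lmax), penalty)
    return radii - basis @ coef, units, radii, centroid


def _residual_patches(mesh, above: np.ndarray) -> List[np.ndarray]:
    """Connected components of above-threshold vertices on the mesh graph."""
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    pos = {v: i for i, v in enumerate(idx)}
    edges = mesh.edges_unique
    e = edges[above[edges[:, 0]] & above[edges[:, 1]]]
    n = len(idx)
    if len(e):
        rows = [pos[v] for v in e[:, 0]]
        cols = [pos[v] for v in e[:, 1]]
        g = sparse.coo_matrix((np.ones(len(e)), (rows, cols)), shape=(n, n))
        n_comp, lab = connected_components(g, directed=False)
    else:
        n_comp, lab = n, np.arange(n)
    return [idx[lab == k] for k in range(n_comp)]


def _dilate_selection(mesh, sel: np.ndarray, rings: int) -> np.ndarray:
    edges = mesh.edges_unique
    for _ in range(rings):
        m = sel[edges[:, 0]] | sel[edges[:, 1]]
        sel = sel.copy()
        sel[edges[m][:, 0]] = True
        sel[edges[m][:, 1]] = True
    return sel


def _is_spicule_patch(patch: np.ndarray, units: np.ndarray, n_vertices: int,
                      cfg: SpiculeConfig, min_vertices: int = None) -> bool:
    """A spicule patch is compact: small angular extent, small vertex share.

    Ring-shaped residual bands (discocyte rims, cup edges) fail the extent
    test and are treated as body, not spicules.
    """
    if len(patch) < (min_vertices if min_vertices is not None else cfg.min_patch_vertices):
        return False
    if len(patch) > cfg.max_patch_fraction * n_vertices:
        return False
    gram = units[patch] @ units[patch].T
    extent = math.degrees(math.acos(float(np.clip(gram.min(), -1.0, 1.0))))
    return extent <= cfg.max_patch_extent_deg


def detect_spicules(mesh, cfg: SpiculeConfig = None, frame: int = 0) -> List[Spicule]:
    """Detect membrane spicules as compact positive-residual patches.

    Two passes: (1) a penalized spherical-harmonic base fit of the radius
    field flags candidate protrusions — compact connected patches above the
    seed threshold; (2) the base is refitted with the candidates (dilated a
    few rings to cover their skirts) excluded, so spicule heights are
    measured against a body surface not biased by the spicules themselves.
    Each accepted patch contributes one spicule with its apex at the
    maximal-residual vertex.
    """
    cfg = cfg or SpiculeConfig()
    verts = np.asarray(mesh.vertices, dtype=float)
    centroid = verts.mean(axis=0)
    rel = verts - centroid
    radii = np.linalg.norm(rel, axis=1)
    if np.any(radii < 1e-9):
        raise ValueError("degenerate mesh: vertex at the centroid")
    units = rel / radii[:, None]
    basis = _real_sh_basis(units, cfg.lmax)
    pen = _sh_penalty_diag(cfg.lmax)

    res = radii - basis @ _penalized_fit(basis, radii, pen, cfg.penalty)
    exclude = np.zeros(len(radii), dtype=bool)
    for patch in _residual_patches(mesh, res > cfg.h_seed_um):
        if _is_spicule_patch(patch, units, len(radii), cfg,
                             min_vertices=cfg.min_seed_vertices):
            exclude[patch] = True
    exclude = _dilate_selection(mesh, exclude, cfg.exclusion_dilation)
    weights = (~exclude).astype(float)
    if weights.sum() < 2 * basis.shape[1]:
        weights = np.ones(len(radii))
    res = radii - basis @ _penalized_fit(basis, radii, pen, cfg.penalty, weights)

    spicules: List[Spicule] = []
    sid = 0
    for patch in _residual_patches(mesh, res > cfg.h_min_um):
        if not _is_spicule_patch(patch, units, len(radii), cfg):
            continue
        apex = patch[np.argmax(res[patch])]
        spread = np.linalg.norm(verts[patch] - verts[apex], axis=1)
        spicules.append(Spicule(
            apex_um=verts[apex].copy(),
            direction=units[apex].copy(),
            height_um=float(res[apex]),
            basal_radius_um=float(np.percentile(spread, 90)) if len(patch) > 1 else 0.0,
            frame=frame,
            spicule_id=sid,
        ))
        sid += 1
    return spicules


# ---------------------------------------------------------------------------
# event calling


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    return math.degrees(math.acos(float(np.clip(u @ v, -1.0, 1.0))))


def spicule_events(per_frame: Sequence[Sequence[Spicule]],
                   cfg: SpiculeConfig = None) -> List[SpiculeEvent]:
    """Call formation/merge/split/dissolution events from per-frame spicules.

    Spicules in consecutive frames are matched greedily by apex direction
    within the angular gate.  A leftover previous spicule adjacent to a
    matched current one is a merge; a leftover current spicule adjacent to
    a matched previous one is a split; otherwise they are dissolutions and
    formations.  The first frame defines the initial population (no events).
    """
    cfg = cfg or SpiculeConfig()
    if len(per_frame) < 2:
        raise ValueError("need at least two frames of spicules")
    gate = cfg.link_gate_deg
    events: List[SpiculeEvent] = []
    for fi in range(1, len(per_frame)):
        prev, curr = list(per_frame[fi - 1]), list(per_frame[fi])
        pairs = []
        for i, p in enumerate(prev):
            for j, c in enumerate(curr):
                a = _angle_deg(p.direction, c.direction)
                if a <= gate:
                    pairs.append((a, i, j))
        pairs.sort()
        match_p: Dict[int, int] = {}
        match_c: Dict[int, int] = {}
        for a, i, j in pairs:
            if i in match_p or j in match_c:
                continue
            match_p[i] = j
            match_c[j] = i
        # leftover previous spicules: merge into a matched current, else dissolve
        for i, p in enumerate(prev):
            if i in match_p:
                continue
            target = None
            for j, c in enumerate(curr):
                if j in match_c and _angle_deg(p.direction, c.direction) <= gate:
                    target = j
                    break
            if target is not None:
                other = match_c[target]
                events.append(SpiculeEvent(
                    kind="merge", frame=fi,
                    parents=sorted([prev[other].spicule_id, p.spicule_id]),
                    children=[curr[target].spicule_id],
                ))
                match_p[i] = target  # consumed by the merge
            else:
                events.append(SpiculeEvent(kind="dissolution", frame=fi,
                                           parents=[p.spicule_id]))
        # leftover current spicules: split from a matched previous, else form
        for j, c in enumerate(curr):
            if j in match_c:
                continue
            source = None
            for i, p in enumerate(prev):
                if i in match_p and _angle_deg(p.direction, c.direction) <= gate:
                    source = i
                    break
            if source is not None:
                sib = match_p[source]
                events.append(SpiculeEvent(
                    kind="split", frame=fi,
                    parents=[prev[source].spicule_id],
                    children=sorted([curr[sib].spicule_id, c.spicule_id]),
                ))
                match_c[j] = source
            else:
                events.append(SpiculeEvent(kind="formation", frame=fi,
                                           children=[c.spicule_id]))
    return events


def event_balance(initial_count: int, events: Sequence[SpiculeEvent],
                  n_frames: int) -> List[int]:
    """Spicule count implied by the event ledger at each frame.

    count(t) = initial + formations + splits − merges − dissolutions up to t;
    used to check conservation against directly counted spicules.
    """
    delta = {"formation": +1, "split": +1, "merge": -1, "dissolution": -1}
    counts = []
    c = initial_count
    by_frame: Dict[int, List[SpiculeEvent]] = {}
    for e in events:
        by_frame.setdefault(e.frame, []).append(e)
    for f in range(n_frames):
        for e in by_frame.get(f, []):
            c += delta[e.kind]
        counts.append(c)
    return counts


# ---------------------------------------------------------------------------
# reversibility


@dataclass
class ReversibilityResult:
    status: str  # reversible | persistent | indeterminate
    left_frame: Optional[int] = None
    return_frame: Optional[int] = None
    no_transition: bool = False


def reversibility(track: CellTrack, frame_interval_s: float,
                  window_s: float = 1200.0,
                  baseline: str = "normocyte") -> ReversibilityResult:
    """Score a track's morphology as reversible or persistent.

    Reversible iff the per-frame class label leaves ``baseline`` and
    returns to it within ``window_s``.  A track that never leaves the
    baseline is reversible by convention (flagged ``no_transition``); a
    track shorter than the window that has left and not returned is
    indeterminate.
    """
    series = track.label_series()
    if not series:
        raise ValueError("track has no class labels")
    left = None
    for f, lab in series:
        if left is None:
            if lab != baseline:
                left = f
        else:
            if lab == baseline and (f - left) * frame_interval_s <= window_s:
                return ReversibilityResult("reversible", left_frame=left, return_frame=f)
    if left is None:
        return ReversibilityResult("reversible", no_transition=True)
    track_span_s = (series[-1][0] - series[0][0]) * frame_interval_s
    if track_span_s < window_s:
        # observation shorter than the recovery window: cannot rule out a
        # later return to the baseline morphology
        return ReversibilityResult("indeterminate", left_frame=left)
    return ReversibilityResult("persistent", left_frame=left)
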