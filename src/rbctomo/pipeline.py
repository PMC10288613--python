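"""End-to-end orchestration: tomogram → cells → features → classes → tracks.

Thin glue over the analysis modules; both the command-line interface and
the reproduction script drive the pipeline through these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import Classifier, DescriptorVector, predict, shape_descriptors
from .config import PipelineConfig
from .grids import TimeLapse, Tomogram
from .morphometry import CellFeatures, MeshingError, measure_cell, mesh_cell
from .segment3d import SegmentedCell, filter_cells, preprocess, segment
from .track4d import (
    CellTrack,
    ReversibilityResult,
    Spicule,
    SpiculeEvent,
    detect_spicules,
    link_cells,
    reversibility,
    spicule_events,
)

__all__ = ["SceneResult", "TimelapseResult", "analyze_tomogram", "analyze_timelapse"]


@dataclass
class SceneResult:
    """One tomogram's analysis output."""

    cells: List[SegmentedCell]
    features: List[CellFeatures]
    labels: Optional[List[str]] = None

    def table(self) -> pd.DataFrame:
        from .io import features_to_frame

        return features_to_frame(self.features, self.labels)


@dataclass
class TimelapseResult:
    """A time-lapse analysis: tracks, spicule dynamics, reversibility."""

    tracks: List[CellTrack]
    frame_cells: List[List[SegmentedCell]]
    spicules_by_track: Dict[int, List[List[Spicule]]]
    events_by_track: Dict[int, List[SpiculeEvent]]
    reversibility_by_track: Dict[int, ReversibilityResult]
    frame_interval_s: float

    def track_table(self) -> pd.DataFrame:
        rows = []
        for tr in self.tracks:
            spicule_counts = {}
            if tr.track_id in self.spicules_by_track:
                per_frame = self.spicules_by_track[tr.track_id]
                for (f, _), sp in zip(tr.entries, per_frame):
                    spicule_counts[f] = len(sp)
            for f, cid in tr.entries:
                feats = tr.features.get(f)
                row = {"track_id": tr.track_id, "frame": f, "cell_id": cid,
                       "time_s": f * self.frame_interval_s}
                if feats is not None:
                    row.update(feats.as_dict())
                row["class"] = tr.labels.get(f)
                row["spicule_count"] = spicule_counts.get(f)
                rows.append(row)
        return pd.DataFrame(rows)

    def event_table(self) -> pd.DataFrame:
        rows = []
        for tid, events in self.events_by_track.items():
            for e in events:
                rows.append({
                    "track_id": tid, "frame": e.frame, "kind": e.kind,
                    "time_s": e.frame * self.frame_interval_s,
                    "parents": ";".join(map(str, e.parents)),
                    "children": ";".join(map(str, e.children)),
                })
        return pd.DataFrame(rows)


def analyze_tomogram(tom: Tomogram, cfg: PipelineConfig = None,
                     classifier: Optional[Classifier] = None,
                     keep_all: bool = False) -> SceneResult:
    """Preprocess, segment, filter, measure (and optionally classify).

    ``keep_all=True`` skips the border/volume filter — useful for scenes
    whose objects legitimately fall outside the RBC volume gate.
    """
    cfg = cfg or PipelineConfig()
    pre = preprocess(tom, cfg.segmentation)
    cells = segment(pre, cfg.segmentation)
    if not keep_all:
        cells = filter_cells(cells, cfg.segmentation)
    features, kept, descriptors = [], [], []
    for c in cells:
        try:
            mesh = mesh_cell(c)
        except MeshingError:
            continue
        features.append(measure_cell(c, pre, mesh=mesh))
        kept.append(c)
        if classifier is not None:
            descriptors.append(shape_descriptors(c, pre, mesh=mesh,
                                                 spicule_cfg=cfg.spicules))
    labels = predict(classifier, descriptors) if classifier is not None else None
    return SceneResult(cells=kept, features=features, labels=labels)


def analyze_timelapse(tl: TimeLapse, cfg: PipelineConfig = None,
                      classifier: Optional[Classifier] = None) -> TimelapseResult:
    """Per-frame segmentation and measurement, tracking, spicule events.

    Frames are median-filtered without z-cropping so all masks stay on one
    grid.  Each track's per-frame mesh feeds the spicule detector; events
    are called from the per-frame spicule populations, and the track is
    scored reversible or persistent from its per-frame class labels.
    """
    cfg = cfg or PipelineConfig()
    frame_cells: List[List[SegmentedCell]] = []
    frame_pre: List[Tomogram] = []
    for fi, tom in enumerate(tl.frames):
        pre = preprocess(tom, cfg.segmentation, zcrop=False)
        cells = filter_cells(segment(pre, cfg.segmentation), cfg.segmentation)
        for c in cells:
            c.frame = fi
        frame_cells.append(cells)
        frame_pre.append(pre)

    tracks = link_cells(frame_cells, cfg.tracking.max_disp_um,
                        cfg.tracking.max_gap_frames)

    spicules_by_track: Dict[int, List[List[Spicule]]] = {}
    events_by_track: Dict[int, List[SpiculeEvent]] = {}
    rev_by_track: Dict[int, ReversibilityResult] = {}
    for tr in tracks:
        per_frame_spicules: List[List[Spicule]] = []
        for f, cid in tr.entries:
            cell = next(c for c in frame_cells[f] if c.cell_id == cid)
            try:
                mesh = mesh_cell(cell)
            except MeshingError:
                per_frame_spicules.append([])
                continue
            feats = measure_cell(cell, frame_pre[f], mesh=mesh)
            tr.features[f] = feats
            spic = detect_spicules(mesh, cfg.spicules, frame=f)
            per_frame_spicules.append(spic)
            if classifier is not None:
                desc = shape_descriptors(cell, frame_pre[f], mesh=mesh,
                                         spicule_cfg=cfg.spicules)
                tr.labels[f] = predict(classifier, [desc])[0]
        spicules_by_track[tr.track_id] = per_frame_spicules
        if len(per_frame_spicules) >= 2:
            events_by_track[tr.track_id] = spicule_events(per_frame_spicules,
                                                          cfg.spicules)
        if tr.labels:
            rev_by_track[tr.track_id] = reversibility(
                tr, tl.frame_interval_s, cfg.tracking.reversibility_window_s)
    return TimelapseResult(
        tracks=tracks, frame_cells=frame_cells,
        spicules_by_track=spicules_by_track, events_by_track=events_by_track,
        reversibility_by_track=rev_by_track,
        frame_interval_s=tl.frame_interval_s,
    )
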