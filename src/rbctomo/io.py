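"""Volumetric and tabular I/O.

Tomograms travel as multi-page TIFF stacks (one page per z-slice) with the
voxel size and medium RI recorded as JSON in the TIFF description tag, so
a write→read round trip is lossless.  Time-lapses are one TIFF per frame
plus a ``manifest.json``; ground truth rides in a sidecar JSON file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import tifffile

from .grids import TimeLapse, Tomogram
from .phantoms import CellRecord, PhantomGroundTruth, SpiculeRec

__all__ = [
    "write_tomogram",
    "read_tomogram",
    "write_timelapse",
    "read_timelapse",
    "write_ground_truth",
    "read_ground_truth",
    "features_to_frame",
]


def write_tomogram(tom: Tomogram, path) -> None:
    meta = {
        "voxel_size_xyz_um": list(tom.voxel_size_xyz),
        "background_ri": tom.background_ri,
        "timestamp_s": tom.timestamp_s,
    }
    tifffile.imwrite(str(path), tom.data, photometric="minisblack",
                     description=json.dumps(meta))


def read_tomogram(path) -> Tomogram:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    try:
        meta = json.loads(desc)
        voxel = tuple(meta["voxel_size_xyz_um"])
        bg = float(meta.get("background_ri", 1.334))
        ts = meta.get("timestamp_s")
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(
            f"{path} carries no voxel-size metadata; pass a Tomogram built "
            "with an explicit voxel size instead"
        ) from exc
    if data.ndim == 2:
        data = data[None]
    return Tomogram(data, voxel, background_ri=bg, timestamp_s=ts)


def write_timelapse(tl: TimeLapse, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for i, frame in enumerate(tl.frames):
        name = f"frame_{i:04d}.tif"
        write_tomogram(frame, out / name)
        names.append(name)
    manifest = {"frame_interval_s": tl.frame_interval_s, "frames": names}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_timelapse(in_dir) -> TimeLapse:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    frames = [read_tomogram(in_dir / name) for name in manifest["frames"]]
    return TimeLapse(frames, frame_interval_s=manifest["frame_interval_s"])


# ---------------------------------------------------------------------------
# ground truth sidecar


def _cell_to_json(c: CellRecord) -> dict:
    return {
        "label": c.label,
        "center_um": list(c.center_um),
        "volume_fl": c.volume_fl,
        "area_um2": c.area_um2,
        "spicule_count": c.spicule_count,
        "hb_concentration_g_dl": c.hb_concentration_g_dl,
        "interior_ri": c.interior_ri,
        "diameter_um": c.diameter_um,
        "spicules": [
            {"direction": list(map(float, s.direction)), "height_um": s.height_um,
             "width_um": s.width_um, "spicule_id": s.spicule_id}
            for s in c.spicules
        ],
    }


def write_ground_truth(gt: PhantomGroundTruth, path) -> None:
    blob = {
        "background_ri": gt.background_ri,
        "cells": [_cell_to_json(c) for c in gt.cells],
        "frame_labels": gt.frame_labels,
        "frame_spicule_counts": gt.frame_spicule_counts,
        "events": gt.events,
        "frame_interval_s": gt.frame_interval_s,
        "frame_centers_um": [list(c) for c in gt.frame_centers_um] if gt.frame_centers_um else None,
    }
    Path(path).write_text(json.dumps(blob, indent=2))


def read_ground_truth(path) -> PhantomGroundTruth:
    blob = json.loads(Path(path).read_text())
    cells = []
    for c in blob["cells"]:
        cells.append(CellRecord(
            label=c["label"], center_um=tuple(c["center_um"]),
            volume_fl=c["volume_fl"], area_um2=c["area_um2"],
            spicule_count=c["spicule_count"],
            hb_concentration_g_dl=c["hb_concentration_g_dl"],
            interior_ri=c["interior_ri"], diameter_um=c.get("diameter_um"),
            spicules=[
                SpiculeRec(np.array(s["direction"]), s["height_um"],
                           s["width_um"], s["spicule_id"])
                for s in c.get("spicules", [])
            ],
        ))
    return PhantomGroundTruth(
        cells=cells, background_ri=blob["background_ri"],
        frame_labels=blob.get("frame_labels"),
        frame_spicule_counts=blob.get("frame_spicule_counts"),
        events=blob.get("events"),
        frame_interval_s=blob.get("frame_interval_s"),
        frame_centers_um=[tuple(c) for c in blob["frame_centers_um"]]
        if blob.get("frame_centers_um") else None,
    )


def features_to_frame(features: List, labels: Optional[List[str]] = None) -> pd.DataFrame:
    """One row per cell; feature names and units fixed by the column header."""
    rows = [f.as_dict() for f in features]
    df = pd.DataFrame(rows)
    if labels is not None:
        df["predicted_class"] = labels
    return df
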