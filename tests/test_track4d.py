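"""Tracking, spicule detection, event calling and reversibility."""

import numpy as np
import pytest

from rbctomo.config import PipelineConfig
from rbctomo.grids import GridSpec
from rbctomo.phantoms import (
    PhantomSpec,
    ShapeTrajectory,
    low_dose_trajectory,
    make_population_scene,
    make_timelapse,
)
from rbctomo.pipeline import analyze_timelapse
from rbctomo.segment3d import SegmentationConfig, filter_cells, preprocess, segment
from rbctomo.morphometry import mesh_cell
from rbctomo.track4d import (
    CellTrack,
    Spicule,
    detect_spicules,
    event_balance,
    link_cells,
    reversibility,
    spicule_events,
)


def _segment_frames(tl):
    out = []
    for fi, tom in enumerate(tl.frames):
        cells = filter_cells(segment(preprocess(tom, zcrop=False)))
        for c in cells:
            c.frame = fi
        out.append(cells)
    return out


@pytest.fixture(scope="module")
def event_lapse(small_grid):
    """Low-dose echinocytosis with one scheduled split and one dissolution."""
    traj = low_dose_trajectory(small_grid, frame_interval_s=20.0, seed=3,
                               events=[(400.0, "spicule_split"),
                                       (520.0, "spicule_dissolve")])
    tl, gt = make_timelapse(traj, small_grid)
    res = analyze_timelapse(tl, PipelineConfig())
    return tl, gt, res


class TestLinking:
    def test_static_scene_tracks(self):
        grid = GridSpec(shape_xyz=(200, 200, 40), voxel_size_xyz=(0.2, 0.2, 0.2))
        tom, _ = make_population_scene("spherocyte", 3, grid, rng_seed=1)
        cells = filter_cells(segment(preprocess(tom, zcrop=False)))
        frames = [cells] * 5
        tracks = link_cells(frames)
        assert len(tracks) == 3
        assert all(len(t.entries) == 5 and t.gap_count == 0 for t in tracks)

    def test_translating_cell_single_track(self, small_grid):
        c0 = (4.5, 7.0, 5.0)
        c1 = (4.5 + 0.5 * 9, 7.0, 5.0)  # 0.5 μm per 2 s frame, 10 frames
        a = PhantomSpec.for_class("spherocyte", center_um=c0)
        b = PhantomSpec.for_class("spherocyte", center_um=c1)
        traj = ShapeTrajectory(keyframes=[(0.0, a), (18.0, b)], frame_interval_s=2.0)
        tl, _ = make_timelapse(traj, small_grid)
        frames = _segment_frames(tl)
        tracks = link_cells(frames)
        assert len(tracks) == 1
        tr = tracks[0]
        steps = [np.linalg.norm(tr.centroids[f + 1] - tr.centroids[f])
                 for f in range(9)]
        assert np.mean(steps) == pytest.approx(0.5, abs=0.21)

    def test_jump_beyond_gate_breaks_track(self):
        grid = GridSpec(shape_xyz=(200, 200, 40), voxel_size_xyz=(0.2, 0.2, 0.2))
        a, _ = make_population_scene("spherocyte", 1, grid, rng_seed=1)
        cells_a = filter_cells(segment(preprocess(a, zcrop=False)))
        spec = PhantomSpec.for_class(
            "spherocyte", center_um=(float(cells_a[0].centroid_um[0] + 12.0),
                                     float(cells_a[0].centroid_um[1]), 3.0))
        from rbctomo.phantoms import make_scene
        b, _ = make_scene([spec], grid)
        cells_b = filter_cells(segment(preprocess(b, zcrop=False)))
        tracks = link_cells([cells_a, cells_b, cells_b], max_disp_um=2.0)
        # the 12 μm jump exceeds the gate: old track ends, new one starts
        assert len(tracks) == 2

    def test_inconsistent_grids_rejected(self):
        g1 = GridSpec(shape_xyz=(100, 100, 30), voxel_size_xyz=(0.2, 0.2, 0.2))
        g2 = GridSpec(shape_xyz=(120, 120, 30), voxel_size_xyz=(0.2, 0.2, 0.2))
        t1, _ = make_population_scene("spherocyte", 1, g1, rng_seed=1)
        t2, _ = make_population_scene("spherocyte", 1, g2, rng_seed=1)
        c1 = segment(preprocess(t1, zcrop=False))
        c2 = segment(preprocess(t2, zcrop=False))
        with pytest.raises(ValueError):
            link_cells([c1, c2])


class TestSpiculeDetection:
    def test_smooth_discocyte_none(self, discocyte_mesh):
        assert detect_spicules(discocyte_mesh) == []

    def test_twelve_spicules_recovered(self, echinocyte_mesh):
        sp = detect_spicules(echinocyte_mesh)
        assert abs(len(sp) - 12) <= 2
        mean_h = np.mean([s.height_um for s in sp])
        assert 0.2 <= mean_h <= 0.35

    def test_subthreshold_heights_ignored(self, small_grid):
        spec = PhantomSpec.for_class("echinocyte", spicule_height_um=0.05)
        from rbctomo.phantoms import make_cell_phantom
        tom, _ = make_cell_phantom(spec, small_grid)
        cell = segment(preprocess(tom))[0]
        assert detect_spicules(mesh_cell(cell)) == []


def _spic(direction, frame=0, sid=0):
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    return Spicule(apex_um=d * 3.0, direction=d, height_um=0.3,
                   basal_radius_um=0.4, frame=frame, spicule_id=sid)


class TestEvents:
    def test_static_no_events(self):
        frame = [_spic([1, 0, 0], sid=0), _spic([0, 1, 0], sid=1)]
        assert spicule_events([frame, frame, frame]) == []

    def test_scheduled_split_called(self, event_lapse):
        tl, gt, res = event_lapse
        tid = res.tracks[0].track_id
        called = res.events_by_track[tid]
        scheduled = next(e for e in gt.events if e["kind"] == "split")
        frames = [e.frame for e in called if e.kind == "split"]
        assert any(abs(f - scheduled["frame"]) <= 1 for f in frames)

    def test_scheduled_dissolution_called(self, event_lapse):
        tl, gt, res = event_lapse
        tid = res.tracks[0].track_id
        called = res.events_by_track[tid]
        scheduled = next(e for e in gt.events if e["kind"] == "dissolution")
        frames = [e.frame for e in called if e.kind == "dissolution"]
        assert any(abs(f - scheduled["frame"]) <= 1 for f in frames)

    def test_event_conservation(self, event_lapse):
        tl, gt, res = event_lapse
        tid = res.tracks[0].track_id
        counts = [len(s) for s in res.spicules_by_track[tid]]
        implied = event_balance(counts[0], res.events_by_track[tid], len(counts))
        assert implied == counts

    def test_tracking_identity_on_static_lapse(self, event_lapse):
        _, _, res = event_lapse
        assert len(res.tracks) == 1
        assert res.tracks[0].gap_count == 0


def _label_track(labels, interval=20.0):
    tr = CellTrack(track_id=0)
    for f, lab in enumerate(labels):
        tr.entries.append((f, 1))
        tr.labels[f] = lab
    return tr


class TestReversibility:
    def test_reversible_round_trip(self):
        labels = ["normocyte"] * 5 + ["echinocyte"] * 20 + ["normocyte"] * 36
        r = reversibility(_label_track(labels), 20.0, window_s=1200.0)
        assert r.status == "reversible" and not r.no_transition

    def test_persistent_spheroechinocyte(self):
        labels = ["normocyte"] * 5 + ["echinocyte"] * 56
        r = reversibility(_label_track(labels), 20.0, window_s=1200.0)
        assert r.status == "persistent"

    def test_never_left_is_reversible_with_flag(self):
        r = reversibility(_label_track(["normocyte"] * 61), 20.0)
        assert r.status == "reversible" and r.no_transition

    def test_short_track_indeterminate(self):
        labels = ["normocyte", "echinocyte", "echinocyte"]
        r = reversibility(_label_track(labels), 20.0, window_s=1200.0)
        assert r.status == "indeterminate"


class TestDoseSignatures:
    def test_low_dose_diameter_dips_then_recovers(self, event_lapse):
        _, _, res = event_lapse
        tr = res.tracks[0]
        d = [tr.features[f].diameter_um for f, _ in tr.entries if f in tr.features]
        start, mid, end = d[0], min(d), d[-1]
        assert mid < start - 0.4           # echinocytic shrinkage
        assert end > mid + 0.4             # recovery toward the disc

    def test_sphericity_rises_during_echinocytosis(self, event_lapse):
        _, _, res = event_lapse
        tr = res.tracks[0]
        psi = [tr.features[f].sphericity for f, _ in tr.entries if f in tr.features]
        assert max(psi[10:50]) > psi[0] + 0.1
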