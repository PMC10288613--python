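"""Generator correctness: analytic ground truth, determinism, time-lapses."""

import math

import numpy as np
import pytest

from rbctomo.grids import ALPHA_HB, N_WATER, GridSpec
from rbctomo.phantoms import (
    PhantomError,
    PhantomSpec,
    OutOfBoundsError,
    ShapeTrajectory,
    UnsupportedClassError,
    _build_shape,
    _fibonacci_directions,
    draw_particle_sizes,
    make_bead_phantom,
    make_cell_phantom,
    make_height_map,
    make_population_scene,
    make_scene,
    make_timelapse,
)


class TestValidation:
    def test_unknown_class_rejected(self):
        with pytest.raises(UnsupportedClassError):
            PhantomSpec(cell_class="megalocyte")

    @pytest.mark.parametrize("kw", [
        dict(diameter_um=0.0),
        dict(diameter_um=-3.0),
        dict(hb_concentration_g_dl=-1.0),
        dict(elongation=0.5),
        dict(spicule_count=6, spicule_height_um=0.7),
    ])
    def test_bad_geometry_rejected(self, kw):
        with pytest.raises(PhantomError):
            PhantomSpec(cell_class="normocyte", **kw)

    def test_bead_zero_diameter_rejected(self):
        with pytest.raises(PhantomError):
            make_bead_phantom(0.0)

    def test_background_ri_range(self):
        with pytest.raises(ValueError):
            GridSpec(background_ri=1.5)

    def test_shape_exceeding_grid(self):
        tiny = GridSpec(shape_xyz=(20, 20, 20), voxel_size_xyz=(0.2, 0.2, 0.2))
        with pytest.raises(OutOfBoundsError):
            make_cell_phantom(PhantomSpec.for_class("normocyte"), tiny)


class TestVoxelization:
    def test_sphere_volume_analytic(self):
        # 6 μm spherocyte: V = (4/3)π·3³ = 113.10 fL
        grid = GridSpec(shape_xyz=(60, 60, 50), voxel_size_xyz=(0.2, 0.2, 0.2))
        spec = PhantomSpec.for_class("spherocyte", diameter_um=6.0)
        tom, gt = make_cell_phantom(spec, grid)
        true_v = 4.0 / 3.0 * math.pi * 27.0
        assert gt.cells[0].volume_fl == pytest.approx(true_v, rel=1e-6)
        vox_v = (tom.data > tom.background_ri).sum() * grid.voxel_volume_fl
        assert vox_v == pytest.approx(true_v, rel=0.02)

    def test_bead_closed_forms(self):
        grid = GridSpec(shape_xyz=(60, 60, 50), voxel_size_xyz=(0.2, 0.2, 0.2))
        _, gt = make_bead_phantom(5.0, grid)
        assert gt.cells[0].volume_fl == pytest.approx(65.45, abs=0.01)
        assert gt.cells[0].area_um2 == pytest.approx(78.54, abs=0.01)

    def test_small_bead_voxel_volume(self):
        grid = GridSpec(shape_xyz=(40, 40, 30), voxel_size_xyz=(0.2, 0.2, 0.2))
        # generic (off-lattice) centre: exact half-lattice alignment is a
        # measure-zero worst case for the voxel counter
        tom, gt = make_bead_phantom(2.0, grid, center_um=(4.07, 3.93, 3.11))
        vox_v = (tom.data > tom.background_ri).sum() * grid.voxel_volume_fl
        assert vox_v == pytest.approx(4.19, rel=0.05)

    def test_zero_hb_interior_is_water(self):
        grid = GridSpec(shape_xyz=(60, 60, 40), voxel_size_xyz=(0.2, 0.2, 0.2))
        spec = PhantomSpec.for_class("normocyte", hb_concentration_g_dl=0.0)
        tom, _ = make_cell_phantom(spec, grid)
        interior = tom.data[tom.data != np.float32(grid.background_ri)]
        assert interior.size > 0
        assert np.all(interior == np.float32(1.333))

    def test_inverse_formula_consistency(self):
        grid = GridSpec(shape_xyz=(60, 60, 40), voxel_size_xyz=(0.2, 0.2, 0.2))
        spec = PhantomSpec.for_class("normocyte", hb_concentration_g_dl=34.4)
        tom, gt = make_cell_phantom(spec, grid)
        interior = tom.data[tom.data > grid.background_ri]
        assert float(interior.mean()) == pytest.approx(N_WATER + ALPHA_HB * 34.4, abs=1e-6)
        assert gt.cells[0].interior_ri == pytest.approx(N_WATER + ALPHA_HB * 34.4)

    def test_volumetric_convergence(self):
        true_v = 4.0 / 3.0 * math.pi * 27.0
        errors = []
        for v in (0.4, 0.2, 0.1):
            n = int(10.0 / v)
            grid = GridSpec(shape_xyz=(n, n, n), voxel_size_xyz=(v, v, v))
            spec = PhantomSpec.for_class("spherocyte", diameter_um=6.0,
                                         center_um=(5.03, 4.97, 5.01))
            tom, _ = make_cell_phantom(spec, grid)
            vox_v = (tom.data > tom.background_ri).sum() * grid.voxel_volume_fl
            errors.append(abs(vox_v - true_v))
        assert errors[0] > errors[1] > errors[2]

    def test_echinocyte_ground_truth_consistency(self):
        spec = PhantomSpec.for_class("echinocyte", spicule_count=12,
                                     spicule_height_um=0.3)
        shape, spicules = _build_shape(spec)
        assert len(spicules) == 12
        u = _fibonacci_directions(20000)
        dev = shape.radius(u) - shape.base_radius(u)
        assert 0.25 <= float(dev.max()) <= 0.35

    def test_determinism(self, small_grid):
        c = tuple(e / 2 for e in small_grid.extent_um)
        spec = PhantomSpec.for_class("echinocyte", rng_seed=9, center_um=c)
        a, _ = make_scene([spec], small_grid, noise_sigma=0.001, noise_seed=5)
        b, _ = make_scene([spec], small_grid, noise_sigma=0.001, noise_seed=5)
        assert np.array_equal(a.data, b.data)

    def test_ground_truth_completeness(self):
        grid = GridSpec(shape_xyz=(200, 200, 40), voxel_size_xyz=(0.2, 0.2, 0.2))
        tom, gt = make_population_scene("spherocyte", 6, grid, rng_seed=3)
        assert len(gt.cells) == 6
        assert all(c.label == "spherocyte" for c in gt.cells)
        centers = {tuple(np.round(c.center_um, 3)) for c in gt.cells}
        assert len(centers) == 6  # one distinct record per generated cell


class TestTimelapse:
    def _static_traj(self, grid, n_frames=10):
        c = tuple(e / 2 for e in grid.extent_um)
        spec = PhantomSpec.for_class("normocyte", center_um=c)
        return ShapeTrajectory(
            keyframes=[(0.0, spec), ((n_frames - 1) * 2.0, spec)],
            frame_interval_s=2.0,
        )

    def test_static_frames_identical(self, small_grid):
        tl, _ = make_timelapse(self._static_traj(small_grid), small_grid)
        assert len(tl) == 10
        for f in tl.frames[1:]:
            assert np.array_equal(f.data, tl.frames[0].data)

    def test_label_transitions(self, small_grid):
        c = tuple(e / 2 for e in small_grid.extent_um)
        norm = PhantomSpec.for_class("normocyte", center_um=c)
        echin = PhantomSpec.for_class("echinocyte", center_um=c)
        traj = ShapeTrajectory(
            keyframes=[(0.0, norm), (60.0, echin), (118.0, norm)],
            frame_interval_s=2.0,
        )
        tl, gt = make_timelapse(traj, small_grid)
        labels = gt.frame_labels
        transitions = sum(1 for a, b in zip(labels, labels[1:]) if a != b)
        assert transitions == 2

    def test_split_increments_count(self, small_grid):
        c = tuple(e / 2 for e in small_grid.extent_um)
        echin = PhantomSpec.for_class("echinocyte", center_um=c)
        traj = ShapeTrajectory(
            keyframes=[(0.0, echin), (120.0, echin)],
            frame_interval_s=2.0,
            events=[(60.0, "spicule_split")],
        )
        _, gt = make_timelapse(traj, small_grid)
        counts = gt.frame_spicule_counts
        assert counts[29] == 12 and counts[30] == 13
        assert gt.events[0]["kind"] == "split" and gt.events[0]["frame"] == 30

    def test_event_outside_range_rejected(self, small_grid):
        traj_kw = dict(keyframes=self._static_traj(small_grid).keyframes,
                       frame_interval_s=2.0)
        with pytest.raises(PhantomError):
            ShapeTrajectory(events=[(999.0, "spicule_form")], **traj_kw)
        with pytest.raises(PhantomError):
            ShapeTrajectory(events=[(4.0, "spicule_teleport")], **traj_kw)

    def test_single_keyframe_rejected(self, small_grid):
        spec = PhantomSpec.for_class("normocyte")
        with pytest.raises(PhantomError):
            ShapeTrajectory(keyframes=[(0.0, spec)])


class TestHeightMaps:
    def test_flat_is_flat(self):
        hm = make_height_map("flat", dict(size_px=64))
        assert np.all(hm.heights_nm == 0.0)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(PhantomError):
            make_height_map("echinocyte", dict(bump_amplitude_nm=-10.0))

    def test_echinocyte_bump_amplitude(self):
        base = make_height_map("normocyte", dict(size_px=260))
        for seed in (1, 2, 3):
            hm = make_height_map("echinocyte",
                                 dict(size_px=260, bump_amplitude_nm=300.0),
                                 rng_seed=seed)
            excess = hm.heights_nm.max() - base.heights_nm.max()
            assert 250.0 <= excess <= 300.0

    def test_particle_sizes_match_distribution(self):
        rng = np.random.default_rng(0)
        sizes = draw_particle_sizes(500, 13.0, 0.2, rng)
        true_mean = 13.0 * math.exp(0.2**2 / 2)
        assert sizes.mean() == pytest.approx(true_mean, rel=0.10)

    def test_unknown_kind(self):
        with pytest.raises(PhantomError):
            make_height_map("volcano")
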