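"""Morphometric features and the RI→haemoglobin formulas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rbctomo.grids import GridSpec
from rbctomo.morphometry import (
    MeshingError,
    hb_concentration,
    hb_content,
    measure_cell,
    mesh_cell,
    sphericity,
)
from rbctomo.phantoms import (
    CELL_CLASSES,
    PhantomSpec,
    evans_fung_volume_fl,
    make_bead_phantom,
    make_cell_phantom,
)
from rbctomo.segment3d import SegmentedCell, preprocess, segment


class TestSphericity:
    @given(st.floats(min_value=0.5, max_value=50.0))
    @settings(max_examples=30, deadline=None)
    def test_sphere_is_one(self, r):
        v = 4.0 / 3.0 * math.pi * r**3
        a = 4.0 * math.pi * r**2
        assert sphericity(v, a) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("volume, area, expected", [
        (79.53, 119.75, 0.75),   # SCT normocyte means
        (86.88, 129.58, 0.73),   # SCA normocyte means
        (77.70, 100.00, 0.88),   # healthy echinocyte means
        (52.84, 79.78, 0.85),    # SCA spherocyte means
        (43.94, 72.35, 0.83),    # SCT acanthocyte means
    ])
    def test_printed_class_means(self, volume, area, expected):
        assert round(sphericity(volume, area), 2) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sphericity(0.0, 10.0)
        with pytest.raises(ValueError):
            sphericity(10.0, -1.0)


class TestHaemoglobin:
    def test_water_is_zero(self):
        assert hb_concentration(1.333) == 0.0

    def test_known_concentration(self):
        assert hb_concentration(1.40298) == pytest.approx(35.3, abs=0.1)

    def test_below_water_warns_but_returns(self):
        with pytest.warns(UserWarning):
            c = hb_concentration(1.330)
        assert c < 0

    def test_affine_slope(self):
        c1, c2 = hb_concentration(1.35), hb_concentration(1.37)
        assert (c2 - c1) / 0.02 == pytest.approx(1 / 0.001983, rel=1e-9)

    @pytest.mark.parametrize("volume, conc, expected", [
        (96.29, 35.2, 33.9),  # healthy normocyte means
        (86.88, 34.4, 29.9),  # SCA normocyte means
    ])
    def test_content_printed_means(self, volume, conc, expected):
        assert round(hb_content(volume, conc), 1) == expected

    def test_content_zero_concentration(self):
        assert hb_content(90.0, 0.0) == 0.0

    def test_content_invalid(self):
        with pytest.raises(ValueError):
            hb_content(-5.0, 30.0)
        with pytest.raises(ValueError):
            hb_content(90.0, -1.0)


class TestMeshing:
    def test_bead_area_close(self, bead5):
        cell, _, _ = bead5
        mesh = mesh_cell(cell)
        assert mesh.area == pytest.approx(78.54, rel=0.03)

    def test_mesh_volume_matches_voxel_volume(self, bead5, discocyte):
        for cell in (bead5[0], discocyte[0]):
            mesh = mesh_cell(cell)
            assert mesh.volume == pytest.approx(cell.volume_fl, rel=0.05)

    def test_discocyte_volume_analytic(self, discocyte):
        mesh = mesh_cell(discocyte[0])
        assert mesh.volume == pytest.approx(evans_fung_volume_fl(), rel=0.03)

    def test_single_voxel_mask_raises(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[5, 5, 5] = True
        cell = SegmentedCell(cell_id=1, mask=mask, voxel_size_xyz=(0.2, 0.2, 0.2),
                             bbox=(slice(5, 6), slice(5, 6), slice(5, 6)))
        with pytest.raises(MeshingError):
            mesh_cell(cell)

    def test_watertight(self, echinocyte):
        assert mesh_cell(echinocyte[0]).is_watertight


class TestMeasureCell:
    def test_bead_features(self, bead5):
        cell, pre, _ = bead5
        f = measure_cell(cell, pre)
        assert f.diameter_um == pytest.approx(5.0, abs=0.2)
        assert f.thickness_um == pytest.approx(5.0, abs=0.2)
        assert f.sphericity >= 0.97
        assert f.sv_ratio_per_um == pytest.approx(f.surface_area_um2 / f.volume_fl)

    def test_bead_benchmarking_both_sizes(self):
        grid = GridSpec(shape_xyz=(60, 60, 50), voxel_size_xyz=(0.2, 0.2, 0.2))
        for d in (2.0, 5.0):
            tom, _ = make_bead_phantom(d, grid)
            pre = preprocess(tom)
            f = measure_cell(segment(pre)[0], pre)
            nominal_v = math.pi * d**3 / 6
            nominal_a = math.pi * d**2
            assert f.diameter_um == pytest.approx(d, rel=0.05)
            assert f.volume_fl == pytest.approx(nominal_v, rel=0.05)
            assert f.surface_area_um2 == pytest.approx(nominal_a, rel=0.05)

    def test_discocyte_features(self, discocyte):
        cell, pre, _ = discocyte
        f = measure_cell(cell, pre)
        assert f.diameter_um == pytest.approx(7.82, rel=0.05)
        assert 0.70 <= f.sphericity <= 0.85

    def test_hb_round_trip_through_pipeline(self, small_grid):
        spec = PhantomSpec.for_class("normocyte", hb_concentration_g_dl=34.4)
        tom, _ = make_cell_phantom(spec, small_grid)
        pre = preprocess(tom)
        f = measure_cell(segment(pre)[0], pre)
        assert f.hb_concentration_g_dl == pytest.approx(34.4, abs=0.2)
        assert f.hb_content_pg == pytest.approx(
            0.01 * f.volume_fl * f.hb_concentration_g_dl, rel=1e-9)

    def test_echinocyte_rounder_than_discocyte(self, discocyte, echinocyte):
        fd = measure_cell(discocyte[0], discocyte[1])
        fe = measure_cell(echinocyte[0], echinocyte[1])
        assert fe.sphericity > fd.sphericity
        assert fe.sv_ratio_per_um < fd.sv_ratio_per_um

    def test_isoperimetric_bound_all_classes(self, small_grid):
        for cls in CELL_CLASSES:
            tom, _ = make_cell_phantom(PhantomSpec.for_class(cls), small_grid)
            pre = preprocess(tom)
            f = measure_cell(segment(pre)[0], pre)
            assert 0.0 < f.sphericity <= 1.0, cls

    def test_scale_equivariance(self):
        feats = {}
        for k in (0.5, 1.0, 2.0):
            d = 4.0 * k
            n = int(d / 0.2) + 20
            grid = GridSpec(shape_xyz=(n, n, n), voxel_size_xyz=(0.2, 0.2, 0.2))
            tom, _ = make_bead_phantom(d, grid)
            pre = preprocess(tom)
            feats[k] = measure_cell(segment(pre)[0], pre)
        base = feats[1.0]
        for k in (0.5, 2.0):
            f = feats[k]
            assert f.diameter_um == pytest.approx(base.diameter_um * k, rel=0.06)
            assert f.thickness_um == pytest.approx(base.thickness_um * k, rel=0.08)
            assert f.surface_area_um2 == pytest.approx(base.surface_area_um2 * k**2, rel=0.08)
            assert f.volume_fl == pytest.approx(base.volume_fl * k**3, rel=0.08)
            assert f.sphericity == pytest.approx(base.sphericity, abs=0.03)
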