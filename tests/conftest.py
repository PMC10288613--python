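import numpy as np
import pytest

from rbctomo.grids import GridSpec
from rbctomo.morphometry import mesh_cell
from rbctomo.phantoms import PhantomSpec, make_bead_phantom, make_cell_phantom
from rbctomo.segment3d import preprocess, segment


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(shape_xyz=(70, 70, 50), voxel_size_xyz=(0.2, 0.2, 0.2))


def _single_cell(spec, grid):
    tom, gt = make_cell_phantom(spec, grid)
    pre = preprocess(tom)
    cells = segment(pre)
    assert len(cells) == 1
    return cells[0], pre, gt


@pytest.fixture(scope="session")
def bead5(small_grid):
    """5 μm calibration bead: (cell, preprocessed tomogram, ground truth)."""
    tom, gt = make_bead_phantom(5.0, small_grid)
    pre = preprocess(tom)
    cells = segment(pre)
    assert len(cells) == 1
    return cells[0], pre, gt


@pytest.fixture(scope="session")
def discocyte(small_grid):
    return _single_cell(PhantomSpec.for_class("normocyte"), small_grid)


@pytest.fixture(scope="session")
def echinocyte(small_grid):
    return _single_cell(PhantomSpec.for_class("echinocyte"), small_grid)


@pytest.fixture(scope="session")
def discocyte_mesh(discocyte):
    return mesh_cell(discocyte[0])


@pytest.fixture(scope="session")
def echinocyte_mesh(echinocyte):
    return mesh_cell(echinocyte[0])


@pytest.fixture(scope="session")
def benchmark_small():
    """Nine-class labelled descriptor set, 8 cells per class (shared)."""
    from rbctomo.classify import make_benchmark

    return make_benchmark(8, rng_seed=42)
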