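"""Random-forest classification of RBC morphology.

Each segmented cell is reduced to a descriptor vector combining the
morphometric features (diameter, area, volume, thickness, sphericity, S/V,
Hb) with shape descriptors that separate the nine canonical RBC classes:
spicule count and mean spicule height (echinocyte, acanthocyte), radial
residual RMS (membrane texture), XY elongation (ovalocyte, sickle),
biconcavity depth (discocyte dimple) and convexity (stomatocyte, helmet).

Training follows a 33/67 stratified train–test split: the forest is fitted
on the 33% split and the held-out 67% is reserved for evaluation.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split

from .grids import GridSpec, Tomogram
from .morphometry import CellFeatures, measure_cell, mesh_cell
from .phantoms import CELL_CLASSES, PhantomSpec, make_cell_phantom
from .segment3d import SegmentedCell, SegmentationConfig, filter_cells, preprocess, segment
from .track4d import SpiculeConfig, detect_spicules, radius_residuals

__all__ = [
    "DescriptorVector",
    "Classifier",
    "shape_descriptors",
    "train_classifier",
    "predict",
    "evaluate",
    "make_benchmark",
    "save_classifier",
    "load_classifier",
]

FEATURE_NAMES = (
    "diameter_um",
    "surface_area_um2",
    "volume_fl",
    "thickness_um",
    "sphericity",
    "sv_ratio_per_um",
    "hb_concentration_g_dl",
    "hb_content_pg",
    "spicule_count",
    "mean_spicule_height_um",
    "radial_rms_um",
    "elongation_xy",
    "biconcavity",
    "convexity",
)


@dataclass
class DescriptorVector:
    """Feature vector consumed by the classifier."""

    features: CellFeatures
    spicule_count: int
    mean_spicule_height_um: float
    radial_rms_um: float
    elongation_xy: float
    biconcavity: float
    convexity: float
    label: Optional[str] = None

    def to_array(self) -> np.ndarray:
        f = self.features
        return np.array([
            f.diameter_um, f.surface_area_um2, f.volume_fl, f.thickness_um,
            f.sphericity, f.sv_ratio_per_um, f.hb_concentration_g_dl,
            f.hb_content_pg, float(self.spicule_count),
            self.mean_spicule_height_um, self.radial_rms_um,
            self.elongation_xy, self.biconcavity, self.convexity,
        ])


def _elongation_xy(mask: np.ndarray, voxel_size_xyz) -> float:
    """Major/minor axis ratio of the XY projection (second moments)."""
    proj = mask.any(axis=0)
    ys, xs = np.nonzero(proj)
    pts = np.column_stack([xs * voxel_size_xyz[0], ys * voxel_size_xyz[1]])
    pts = pts - pts.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    ev = np.sort(np.linalg.eigvalsh(cov))
    if ev[0] <= 1e-12:
        return float("inf")
    return float(np.sqrt(ev[1] / ev[0]))


def _biconcavity(mask: np.ndarray) -> float:
    """Centre-to-rim columnar height ratio of the z-column profile.

    ≈ 0.3 for a biconcave disc (thin dimple over a thick rim), ≈ 1 for a
    sphere or any shape whose thickest column passes near the centroid.
    """
    heights = mask.sum(axis=0).astype(float)
    if heights.max() == 0:
        return 1.0
    ys, xs = np.nonzero(heights)
    cy = int(round(np.average(ys, weights=heights[ys, xs])))
    cx = int(round(np.average(xs, weights=heights[ys, xs])))
    # average over a small centre patch to dodge single-column noise
    patch = heights[max(cy - 1, 0):cy + 2, max(cx - 1, 0):cx + 2]
    centre = float(patch[patch > 0].mean()) if (patch > 0).any() else 0.0
    return centre / float(heights.max())


def _convexity(mask: np.ndarray, voxel_size_xyz, volume_fl: float) -> float:
    """Voxel volume over convex-hull volume, clipped to (0, 1]."""
    surf = mask & ~ndimage.binary_erosion(mask)
    zs, ys, xs = np.nonzero(surf)
    vx, vy, vz = voxel_size_xyz
    pts = np.column_stack([xs * vx, ys * vy, zs * vz])
    if len(pts) < 5:
        return 1.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 1.0
    # hull of voxel centres slightly underestimates the true hull; the
    # voxel-count volume is measured on the same lattice, so the ratio is fair
    return float(min(volume_fl / hull.volume, 1.0)) if hull.volume > 0 else 1.0


def shape_descriptors(cell: SegmentedCell, tom: Tomogram,
                      mesh=None, spicule_cfg: SpiculeConfig = None,
                      label: Optional[str] = None) -> DescriptorVector:
    """Full descriptor vector for one measured cell."""
    if mesh is None:
        mesh = mesh_cell(cell)
    feats = measure_cell(cell, tom, mesh=mesh)
    spicules = detect_spicules(mesh, spicule_cfg)
    res, *_ = radius_residuals(mesh, (spicule_cfg or SpiculeConfig()).lmax)
    return DescriptorVector(
        features=feats,
        spicule_count=len(spicules),
        mean_spicule_height_um=float(np.mean([s.height_um for s in spicules])) if spicules else 0.0,
        radial_rms_um=float(np.sqrt(np.mean(res**2))),
        elongation_xy=_elongation_xy(cell.mask, cell.voxel_size_xyz),
        biconcavity=_biconcavity(cell.mask),
        convexity=_convexity(cell.mask, cell.voxel_size_xyz, feats.volume_fl),
        label=label,
    )


# ---------------------------------------------------------------------------
# training / prediction


@dataclass
class Classifier:
    """A trained forest plus its descriptor schema and held-out split."""

    model: RandomForestClassifier
    feature_names: Tuple[str, ...]
    classes: Tuple[str, ...]
    X_test: np.ndarray
    y_test: np.ndarray
    train_accuracy: float

    @property
    def schema_fingerprint(self) -> str:
        return "|".join(self.feature_names)


def _stack(labeled: Sequence[DescriptorVector], feature_names=FEATURE_NAMES,
           drop: Sequence[str] = ()) -> Tuple[np.ndarray, np.ndarray]:
    keep = [i for i, n in enumerate(FEATURE_NAMES) if n not in drop]
    X = np.stack([d.to_array()[keep] for d in labeled])
    y = np.array([d.label for d in labeled])
    return X, y


def train_classifier(labeled: Sequence[DescriptorVector],
                     split_fraction: float = 0.33, rng_seed: int = 0,
                     n_estimators: int = 200,
                     drop_features: Sequence[str] = ()) -> Classifier:
    """Fit a random forest on a stratified ``split_fraction`` of the data.

    The remaining cells are stored on the returned classifier for
    :func:`evaluate`.  Raises on single-class input.  ``drop_features``
    supports ablation experiments.
    """
    X, y = _stack(labeled, drop=drop_features)
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split_fraction, stratify=y, random_state=rng_seed,
    )
    model = RandomForestClassifier(
        n_estimators=n_estimators, max_features="sqrt",
        random_state=rng_seed, n_jobs=1,
    )
    model.fit(X_tr, y_tr)
    names = tuple(n for n in FEATURE_NAMES if n not in drop_features)
    return Classifier(
        model=model, feature_names=names, classes=classes,
        X_test=X_te, y_test=y_te,
        train_accuracy=float(model.score(X_tr, y_tr)),
    )


def predict(clf: Classifier, cells: Sequence[DescriptorVector]) -> List[str]:
    """Class label for each descriptor vector (empty in → empty out)."""
    if not cells:
        return []
    drop = tuple(n for n in FEATURE_NAMES if n not in clf.feature_names)
    X, _ = _stack(cells, drop=drop)
    if X.shape[1] != len(clf.feature_names):
        raise ValueError("descriptor schema does not match the classifier")
    return list(clf.model.predict(X))


def evaluate(clf: Classifier, X: np.ndarray = None, y: np.ndarray = None):
    """Confusion matrix (rows = true labels) and per-class accuracy on the
    held-out split (or on explicit arrays)."""
    if X is None:
        X, y = clf.X_test, clf.y_test
    pred = clf.model.predict(X)
    labels = list(clf.classes)
    cm = confusion_matrix(y, pred, labels=labels)
    row_sums = cm.sum(axis=1)
    per_class = {
        lab: (cm[i, i] / row_sums[i] if row_sums[i] else float("nan"))
        for i, lab in enumerate(labels)
    }
    accuracy = float(np.trace(cm) / cm.sum())
    return cm, per_class, accuracy


def save_classifier(clf: Classifier, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump({"fingerprint": clf.schema_fingerprint, "clf": clf}, fh)


def load_classifier(path) -> Classifier:
    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    clf = blob["clf"]
    if blob["fingerprint"] != clf.schema_fingerprint:
        raise ValueError("classifier file schema fingerprint mismatch")
    return clf


# ---------------------------------------------------------------------------
# phantom benchmark


_JITTER = dict(diameter=0.04, thickness=0.05, hb=1.5)


def _single_cell_grid(spec: PhantomSpec) -> GridSpec:
    """A compact grid holding one centred cell with comfortable margins."""
    from scipy.spatial.transform import Rotation

    from .phantoms import _build_shape

    shape, _ = _build_shape(spec)
    he = np.asarray(shape.half_extents, dtype=float)
    if any(spec.orientation_deg):
        rot = Rotation.from_euler("zyx", spec.orientation_deg, degrees=True)
        he = np.abs(rot.as_matrix()) @ he
    v = 0.2
    nx = int(np.ceil((2 * max(he[0], he[1]) + 3.0) / v / 2)) * 2
    nz = int(np.ceil((2 * he[2] + 2.0) / v / 2)) * 2
    return GridSpec(shape_xyz=(nx, nx, nz), voxel_size_xyz=(v, v, v))


def descriptor_from_spec(spec: PhantomSpec, seg_cfg: SegmentationConfig = None,
                         spicule_cfg: SpiculeConfig = None) -> DescriptorVector:
    """Generate a phantom, run the segmentation chain, return its descriptors."""
    grid = _single_cell_grid(spec)
    c = (grid.extent_um[0] / 2, grid.extent_um[1] / 2, grid.extent_um[2] / 2)
    from dataclasses import replace
    spec = replace(spec, center_um=c)
    tom, _ = make_cell_phantom(spec, grid)
    pre = preprocess(tom, seg_cfg)
    cells = segment(pre, seg_cfg)
    cfg = seg_cfg or SegmentationConfig(volume_gate_fl=(5.0, 400.0))
    kept = filter_cells(cells, cfg) or cells
    cell = max(kept, key=lambda cc: cc.voxel_count)
    return shape_descriptors(cell, pre, spicule_cfg=spicule_cfg, label=spec.cell_class)


def make_benchmark(n_per_class: int, rng_seed: int = 0,
                   classes: Sequence[str] = CELL_CLASSES) -> List[DescriptorVector]:
    """Balanced labelled phantom set with within-class geometry jitter.

    Each cell's defining parameters are perturbed around the class defaults
    (±4% diameter, ±5% thickness, Hb ~ N(33, 1.5) g/dL, spicule count ±2,
    random in-plane rotation and up to 15° tilt) so classes overlap the way
    a real field of view does, without erasing their separability.
    """
    rng = np.random.default_rng(rng_seed)
    out: List[DescriptorVector] = []
    for cls in classes:
        for i in range(n_per_class):
            base = PhantomSpec.for_class(cls)
            kw: Dict = dict(
                diameter_um=base.diameter_um * (1 + _JITTER["diameter"] * rng.standard_normal()),
                hb_concentration_g_dl=float(np.clip(
                    rng.normal(33.0, _JITTER["hb"]), 25.0, 38.0)),
                orientation_deg=(rng.uniform(0, 360), rng.uniform(-15, 15), 0.0),
                rng_seed=int(rng.integers(2**31 - 1)),
            )
            if base.thickness_um is not None:
                kw["thickness_um"] = base.thickness_um * (1 + _JITTER["thickness"] * rng.standard_normal())
            if base.spicule_count > 0:
                kw["spicule_count"] = int(max(3, base.spicule_count + rng.integers(-2, 3)))
                kw["spicule_height_um"] = float(np.clip(
                    base.spicule_height_um * (1 + 0.15 * rng.standard_normal()), 0.1, 0.5))
            if base.elongation > 1.0:
                kw["elongation"] = base.elongation * (1 + 0.08 * rng.standard_normal())
            spec = PhantomSpec.for_class(cls, **kw)
            out.append(descriptor_from_spec(spec))
    return out
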