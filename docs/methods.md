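# Methods

This note documents the models, estimators and numerical choices behind
`rbctomo`, and what the synthetic phantoms do and do not emulate.

## Phantom geometry

All phantoms are geometric RI maps: a voxel is inside or outside a
continuous shape, inside voxels carry `n_H2O + α·Hb` (or the silica RI
1.43 for calibration beads), outside voxels carry the medium RI
(PBS, 1.334). There is no optical forward model — no diffraction, no
missing-cone anisotropy, no speckle. Optional additive Gaussian RI noise
(default off, σ = 0.001 when enabled) and a smooth background gradient are
the only corruption models. Consequently, pipeline accuracies measured on
phantoms are upper bounds for real acquisitions; what the tests establish
is the correctness of the geometry, chemistry and bookkeeping of the
analysis chain, not robustness to instrument artefacts.

**Discocyte.** The healthy RBC uses the Evans–Fung biconcave profile

    z(ρ) = ± sqrt(1 − (ρ/R)²) · ½ [C0 + C2 (ρ/R)² + C4 (ρ/R)⁴]

with R = 3.91 μm, C0 = 0.81 μm, C2 = 7.83 μm, C4 = −4.39 μm: diameter
7.82 μm, volume 94.1 fL, surface area 134.1 μm² (both by quadrature),
maximum thickness 2.565 μm. These sit within 5% of the textbook reference
values (8 μm, 90 fL, 130 μm²). Ovalocytes stretch the disc laterally
(axis ratio 1.45); sickle cells stretch it further (2.2) and shear it
along an arc (curvature 0.10 μm⁻¹), which preserves volume.

**Spiculated shapes.** Echinocytes and acanthocytes are star-convex radius
fields: an oblate-spheroid body plus radially oriented Gaussian bumps at
quasi-uniform (golden-spiral) directions with seeded angular jitter. The
spheroid body — rather than a biconcave disc with bumps — keeps every
spiculated shape star-convex, so the radius field about the centroid is
single-valued and the spicule analysis is well defined; morphologically it
matches the rounded body of a real echinocyte. Defaults: echinocyte
6.4 × 3.6 μm body, 12 spicules of height 0.3 μm and lateral width
σ = 0.35 μm; acanthocyte 5.2 × 4.2 μm, 8 irregular spicules of height
0.5 μm, width 0.45 μm. Spicule heights are constrained to 0.05–0.5 μm,
bracketing the ~0.1–0.3 μm protrusions seen on real membranes, and the
widths follow the ~0.5–1 μm basal footprints of AFM line profiles.
Stomatocytes are spheres with one Gaussian cup, teardrops a sphere with a
single broad tail, helmets a sphere with a spherical bite removed (the one
non-star-convex class).

**Ground truth.** Every generated cell is recorded with its class, centre,
spicule inventory, and analytic volume/area where a closed form or
quadrature exists (spheres, spheroids, discocytes; star-convex shapes get
volumes from the exact solid-angle integral V = ∮ r(u)³/3 dΩ evaluated on
20 000 quasi-uniform directions).

**Voxelization.** Default grid: 90 × 90 × 30 μm field of view at isotropic
0.2 μm voxels (the instrument's spacing is not published; 0.2 μm is
consistent with the sub-micrometre features it resolves and is
configurable). A voxel is inside if its centre is inside the continuous
shape; voxelized volumes converge to the analytic values as the voxel
shrinks (tested at 0.4/0.2/0.1 μm). Exact half-lattice alignment of a
sphere centre is a worst case for the voxel counter (~5% at 10 voxels
across); generic placements sit well inside 2%.

**Time-lapses.** A trajectory is a list of keyframed cell specifications;
numeric geometry (diameter, thickness, Hb, centre, ...) interpolates
linearly between keyframes and the class label switches at the segment
midpoint. Spicules live in an explicit inventory edited by scheduled
events: formation adds a spicule at a fresh direction, a split replaces
one spicule by two daughters ±13° apart, a merge fuses the closest pair,
dissolution removes one. Spicule visibility switches on/off at the class
midpoint rather than ramping: real spicules form within tens of seconds
(fast against the minute-scale shape relaxation), and a slow ramp would
hold the membrane at the detection threshold for many frames, which no
real cell does. The default frame interval is 2 s, matching the
instrument's best temporal resolution; the packaged 20-minute scenarios
are rendered at 20–40 s intervals (31–61 frames) to keep test and
reproduction runs fast — a problem-size choice, not a claim about the
instrument.

## Segmentation

Background is estimated as the mode of the RI histogram (0.0005-wide
bins) — valid because medium dominates the field of view — with a robust
noise σ from the MAD around the mode. z-slices whose maximum RI exceeds
the background by less than max(2σ, 0.003) are cropped (the 0.003 floor
guards the noise-free case). The fixed 3×3×3 median filter follows.
Thresholding is Otsu on the background-subtracted volume with a noise
floor of max(3σ, 0.003): with clean, strongly imbalanced histograms Otsu
can land inside the background spike, and the floor prevents that. A
unimodal histogram (no foreground) triggers a warning and a configurable
fallback threshold. Components are labelled under 26-connectivity (the
most inclusive choice; avoids splitting thin spicules). Filters drop
cells touching the XY borders (z contact is allowed — sedimented cells
rest on the dish), cells outside a configurable volume gate (default
20–200 fL), and suspected merges: components larger than 1.6× the
leave-largest-out scene median volume. Touching cells are discarded, not
watershed-split.

## Morphometry

- **Volume** = voxel count × voxel volume (fL = μm³).
- **Surface area** from a marching-cubes mesh of the mask, contoured at
  0.5 after Gaussian pre-smoothing with σ = 0.6 voxel. The smoothing
  suppresses the staircase area inflation; σ was calibrated on the
  closed-form sphere (area error ≈ +1.2% at 0.2 μm voxels) and kept small
  enough that 0.3 μm spicules survive meshing. Meshes are watertight
  (repaired if needed).
- **Diameter** = maximum Feret diameter of the XY projection over the
  convex hull of pixel centres, plus half a mean pixel (the extreme pixel
  centres of a curved silhouette sit a fraction of a pixel inside the true
  boundary; the correction is calibrated on spheres and lands within 1%).
- **Thickness** = maximal z-extent of the mask. This makes a spherocyte's
  thickness equal its diameter; a mean-columnar-height alternative is a
  one-line change but the max-extent convention is the default.
- **Sphericity** ψ = π^(1/3)(6V)^(2/3)/A, evaluated on the mesh's own
  (volume, area) pair: for any closed surface the isoperimetric
  inequality then guarantees ψ ≤ 1, which a mixed (voxel volume, mesh
  area) pair cannot. The reported volume feature and S/V ratio use the
  voxel-count volume.
- **Haemoglobin**: Hb = (n̄ − 1.333)/0.001983 g/dL from the mask-mean RI;
  content = 0.01·V·Hb pg. A mean RI below water yields a negative
  concentration: the value is reported and the cell flagged, never
  silently clamped.

## Spicule detection

The base (body) surface is a penalized spherical-harmonic fit of the
per-vertex radius field about the centroid: degree 12 with an (l(l+1))²
roughness penalty (λ = 5·10⁻⁶) — a smoothing spline on the sphere. Two
passes: the first residual flags candidate protrusions as connected
patches above 0.05 μm that are *compact* (angular extent ≤ 40°, at most
6% of vertices); the second fit excludes the candidates (dilated 3 rings
to cover their skirts) so spicule heights are measured against an
unbiased body surface. Final spicules are compact patches with residual
> h_min = 0.08 μm (below the smallest ~0.1 μm protrusions of interest)
and ≥ 8 vertices (smaller patches are voxelization ripple). The
compactness test is what rejects the ring-shaped residual bands a
biconcave rim or cup edge produces — rings are body, not spicules. On the
default 12-spicule echinocyte phantom the detector recovers 12 ± 2
spicules with mean height 0.21 μm for a true height of 0.30 μm; the
deficit is meshing attenuation of sub-half-micrometre features and is
stable across seeds. Strongly non-convex bodies (helmet bite rims,
teardrop tails) can contribute one or two residual patches; for
classification these are a usable per-class signature, but spicule counts
on such shapes should not be read as membrane spicules.

## Tracking and events

Cells link frame-to-frame by greedy nearest-centroid assignment, gated at
2 μm per frame (sedimented cells barely move at 2 s framing), with
≤ 1-frame gaps bridged. Spicules link by apex direction within 20° per
frame; an unmatched old spicule adjacent to a matched new one is a merge,
an unmatched new spicule adjacent to a matched old one is a split, and
the remainder are dissolutions and formations. This bookkeeping makes the
conservation identity — alive(t) = initial + formations + splits −
merges − dissolutions — hold exactly against the per-frame detected
counts. Near-threshold spicules (during shape transitions) flicker in and
out of detection and generate formation/dissolution chatter; a
persistence filter would suppress it but is deliberately out of scope, so
event tables from transition frames should be read statistically.
Reversibility: a track is *reversible* if its per-frame class label
leaves the baseline (normocyte) and returns within the window (default
1200 s — the 20-minute observation), *persistent* if it never returns
within an observation at least as long as the window, *indeterminate* if
the observation is shorter, and reversible-with-flag if it never left.

## Classification

Descriptors per cell: the morphometric features plus spicule count, mean
spicule height, radius-residual RMS, XY elongation (second-moment axis
ratio), biconcavity (centre-to-peak columnar height ratio, ≈ 0.3 for
discs, ≈ 1 for spheres) and convexity (voxel volume over convex-hull
volume). The forest uses 200 trees, √p features per split, no depth cap,
seeded. Training follows a stratified 33% train / 67% test split;
stratification keeps rare classes represented. The phantom benchmark
jitters each class's generating parameters (±4% diameter, ±5% thickness,
Hb ~ N(33, 1.5) g/dL, spicule count ±2, random orientation with ≤ 15°
tilt); with 20 cells per class the held-out nine-class accuracy is ≈ 0.95.
Phantom classes are cleaner than real morphology continua (no
intermediate echinocyte stages, no debris), so these accuracies
characterise the descriptor pipeline, not expected clinical performance.

## AFM analysis

Height maps are leveled by best-fit-plane removal followed by per-row
median (scan-line) correction. Sq is the RMS height deviation in
non-overlapping 1 μm² windows, tiled from the corner, partial windows
discarded. The dried-cell phantoms scale the biconcave footprint to a
400 nm dome (air-dried cells collapse), with echinocyte bumps combined by
maximum so the tallest protrusion rises by exactly the stated amplitude.
Particles are connected regions above a threshold (default 3× the
background Sq, suited to atomically flat substrates); size is the
equivalent-circle diameter of the region's lateral extent — the
lateral-width reading of "particle size", chosen over peak height because
tip-convolved lateral extent is what line sections measure; peak heights
remain accessible from the maps. The 95% CI of the mean size is a
percentile bootstrap (default 10 000 resamples, seeded), chosen because
the size distribution is right-skewed; coverage of the true mean on
lognormal fields is ≥ 93% over 200 seeded replicates at n = 500.

## Degenerate inputs and error policy

Empty (all-background) volumes crop to zero slices and segment to an
empty list — a signal, not an exception. Shapes that do not fit the grid,
unknown class names, non-positive geometry, events scheduled outside a
trajectory, and windows larger than a height map raise typed errors.
Masks under 8 voxels refuse to mesh. Config files reject unknown keys.

## Known limitations

- No optical forward model: resolution anisotropy, missing-cone
  elongation and RI quantisation of real tomograms are not emulated.
- Spicule heights are systematically ~0.05–0.1 μm low at 0.2 μm voxels;
  finer grids recover them at proportional cost.
- Event calling has no temporal persistence filter (see above).
- Touching cells are discarded rather than split; dense fields lose
  throughput.
- The classifier is trained and evaluated on phantoms only; applying it
  to real exports requires retraining on annotated data.
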