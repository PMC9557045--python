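# Methods

`kneefit` selects total-knee-replacement (TKR) implant sizes from a pair of
segmented knee radiograph silhouettes. The pipeline has four stages:
silhouette-to-surface reconstruction, virtual implant fitting, metric-based
size selection, and cohort-level evaluation. A synthetic bone generator
provides reproducible data for training and benchmarking.

## Coordinate conventions

All geometry lives in a canonical right-knee frame:

- **X** — medio-lateral (ML), +X lateral
- **Y** — antero-posterior (AP), +Y anterior
- **Z** — long axis of the limb, +Z proximal

Left knees are mirrored about the X = 0 plane on ingest (`Mesh3D.mirrored`,
and `mask_to_contour` flips left AP masks; lateral views are
mirror-invariant). Units are millimetres throughout.

## Size charts and implant component models

`kneefit/data/size_charts.csv` holds 73 catalogue entries — (manufacturer,
model, component, size id, ML, AP) — across five commercial TKR systems
(NexGen, Sigma, Legion, Freedom, Scorpio), 35 femoral and 38 tibial sizes.

Each entry is turned into a geometric component by anisotropically scaling a
template to the catalogue (ML, AP):

- **Femoral component**: a labelled sagittal profile (inner J-shaped mating
  polyline of five planar cuts plus an outer articular curve) extruded across
  the ML width with rounded ends. Fitting uses ~2,400 uniform samples of the
  articular surface; overhang uses the boundary rim of the mating surface.
  Scaled component extents reproduce the catalogue (ML, AP) within 0.05 mm.
- **Tibial baseplate**: a 2-D kidney-shaped plate profile (two posterior
  lobes, flat posterior edge, intercondylar notch). Two variants are kept:
  a closed fitting ring with the notch replaced by its chord (area-faithful
  for ICP), and an open overhang edge set with the notch arc dropped (the
  notch is interior to the resection section by design and would otherwise
  register a constant false overhang).

## Fit metrics

- **Global RMSE** (`rmse_points_to_surface`, `rmse_points_to_polyline`): root
  mean square of closest-point distances from the component's sample points
  to the bone surface (3-D, femur) or from the plate profile to the bone
  resection-section outline (2-D, tibia).
- **Maximum over/underhang (max OUH)** (`directed_hausdorff`): directed
  Hausdorff distance from the component rim to the bone outline — the largest
  unsigned rim-to-bone mismatch, capturing both overhang and underhang.
  Polyline inputs are densified to ≤ 0.2 mm spacing before the point-set
  maximin; raw point arrays are compared as given.

Per chart and metric, `select_best` scans sizes in ordinal order and returns
the first whose value is within `DOWNSIZE_TIEBREAK_TOL = 0.05` mm of the
minimum — ties break toward downsizing, the conservative surgical choice.
Overhang above `OVERHANG_SIGNIFICANT_MM = 3.0` mm is reported as clinically
significant.

## Virtual fitting

**Femur** (`fit_femur_component`): unconstrained 6-DOF rigid ICP of the
component's articular samples onto the distal femur. Initialization centres
the component box on the distal region of matching proximal extent; ICP runs
on a ~500-point subsample with `tol = 1e-2` mm and the final metrics are
evaluated on the full sample set.

**Tibia** (`tibia_resection_plane` + `fit_tibia_plate`): the tibial plateau
is detected as the vertices on the medial side (x < 0) whose outward normals
satisfy n·ẑ > 0.8 (at least 50 such vertices, otherwise the mesh is rejected
as shaft-only). A least-squares plane z = ax + by + c through those vertices
gives the resection normal; the plane is placed exactly 2.0 mm below the
widest medial plateau point along that normal. The bone's cross-section
outline on this plane is matched to the plate profile by 3-DOF 2-D rigid ICP.

`predict_sizes` fits every size of every requested chart, records per-size
failures, and returns one `SizePrediction` per chart with the best size under
each metric and the full fit table.

## Registration (ICP) details

`icp_rigid_3d` aligns a point cloud to a mesh in three stages:

1. **Initialization** (when no explicit init is given): candidate poses from
   centroid translation plus the four proper-rotation sign combinations of
   principal axes, each refined on a subsample until near convergence before
   scoring — flipped candidates converge to distant minima with similar early
   scores, so scoring too early picks the wrong basin.
2. **Main loop**: nearest neighbours in a dense deterministic surface
   sampling of the target (20,000 points) with Kabsch updates; the objective
   (RMS closest-point distance) is non-increasing and iteration stops when it
   improves by less than `tol`.
3. **Exact polish**: up to 15 Kabsch iterations against *exact* closest
   points on the triangulated surface, because the discrete sampling biases
   the converged pose by a fraction of the point spacing. Near
   tangential-sliding minima plain point-to-point updates converge at a rate
   near 1, so each accepted update is extrapolated along its screw axis
   (Besl–McKay accelerated ICP; multiples k = 2, 4, 8) and the best multiple
   kept. The same `tol` governs this stage, so loose-tolerance callers (the
   fitting engine) pay for only one or two exact-surface iterations while
   tight-tolerance registration reaches ~1e-3 mm recovery error.

Exact closest-point queries subdivide large triangles at build time (pure
refinement) and scan the K = 32 nearest face centroids with per-face reach
pruning; a numba kernel accelerates this when available, with a bit-identical
NumPy fallback.

## 2-D→3-D reconstruction

Shape is modelled by a **statistical shape model (SSM)**: point distribution
of correspondent meshes after generalized Procrustes alignment (similarity,
scale preserved in mm), PCA-reduced to `DEFAULT_SSM_MODES = 6` modes.
Correspondence projects a template mesh (the training mesh with ML extent
closest to the set mean) onto each training surface by closest points after
similarity pre-alignment.

Out-of-plane coordinates are modelled by per-view **profile depth models
(PDMs)**: each training silhouette contour is resampled to P = 200 points
from an anatomically stable start index, and the signed out-of-plane
coordinate of the silhouette generator (mid-depth) is recorded per point.
The PDM stores the mean depth and PCA modes; at inference the depths are
scaled by the ratio of the contour's Z extent to the training mean Z extent.

`reconstruct_bone`: the AP and lateral mask contours are extracted, aligned
into 3-D (`align_contours_3d` centres them and cross-checks Z extents —
a Z-extent ratio far from 1 is rejected as inconsistent views), lifted to 3-D
by the PDMs, and the SSM is fitted to the pooled points by alternating
similarity alignment (Umeyama) and clamped linear mode solves (|b_k| ≤ 3√λ_k),
returning the best iterate.

## Synthetic bone generator

`generate_bone(bone, ML, AP, shape_coeffs, noise_sd, seed, grid_mm=2.0)`
produces watertight meshes with **exact** requested (ML, AP) extents
(final anisotropic rescale):

- **Femur**: superellipse loft of a native sagittal articular profile —
  two condyles with a trochlear waist (1.5 % central shrink) and a shaft stub.
- **Tibia**: marching-cubes surface of a two-lobed plateau field tapered to a
  distal cut (height = 0.90 × AP).

Four smooth deformation modes (`deformation_basis`) modulate each bone:
condylar asymmetry, AP skew along Z, plateau doming, and waist/taper
modulation. Surface noise is Gaussian along vertex normals, tapered to zero
near all six bounding planes so the measured extents remain exact, with draws
clipped at ±3.5 σ.

`generate_subject` / `generate_population` sample demographics
(`DemographicsConfig`: sex-specific ML ranges, AP/ML aspect ratios, age,
side) with `numpy.random.default_rng([seed, index])` spawning — subjects are
independent of cohort size and fully determined by (seed, index). Each
subject carries femur/tibia meshes and four binary silhouette masks
(AP/lateral × femur/tibia) rendered at 0.5 mm/px by orthographic projection.

**Scope**: the generator covers ML, AP ∈ [40, 100] mm, smooth unimodal
plateau/condyle geometry, and isotropic Gaussian surface noise. It does not
model osteophytes, cortical/trabecular interior structure, segmentation
artefacts, perspective/magnification, or pathology (varus/valgus deformity,
bone loss).

## Evaluation

`score_predictions` compares predicted best sizes to ground-truth bests
(computed by fitting the true meshes) per (model, component, metric):
exact and ±1-size accuracy (overall and by sex), mean RMSE/OUH of predicted
and ground-truth sizes — with the predicted size's metrics looked up on the
ground-truth geometry — the share of subjects whose selected size keeps
overhang under 3 mm, and Spearman rank correlation of correctness against
age (NaN when undefined). Reports serialize to JSON and CSV.

## Numerical choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; file writes are atomic (temp file + rename) and reproducible runs
  are byte-identical.
- Kabsch/Umeyama via SVD with determinant correction; rank-deficient
  correspondence sets are rejected.
- PCA eigendecomposition via SVD of the centred data matrix; eigenvalues are
  non-increasing and modes orthonormal by construction.
- Plateau plane by linear least squares on z = ax + by + c (the plateau is
  near-horizontal by convention, so the graph form is well conditioned).
- Contours are traversed counter-clockwise with an anatomically anchored
  start index; the extremal-edge tie band is 5 % of the contour extent to
  keep the index stable across near-flat silhouette edges.

## Limitations

- Silhouettes are assumed pre-segmented and orthographic; no calibration,
  magnification, or pose-estimation stage is included.
- The SSM is trained on synthetic bones; accuracy numbers quantify pipeline
  consistency under the generator's assumptions, not clinical performance.
- The femoral fit is a surface-registration proxy: no flexion/extension gap
  balancing, rotational alignment rules, or soft-tissue considerations.
- The tibial fit operates on a single resection plane at a fixed 2 mm depth
  below the widest medial plateau point; surgeons vary resection depth and
  slope per patient.
- Size charts encode published (ML, AP) footprints only; actual implant
  geometries differ between systems in ways the scaled templates do not
  capture.
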