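# Methods

This note records the models, conventions and numerical choices behind
`laminamap`, and what the phantom-based validation does and does not show.

## Coordinate and label conventions

Grids are `(x, y, z)` indexed, 0-based; voxel index `i` maps to world
millimetres as `origin + i * spacing` (voxel centres).  Layer volumes use
labels `{0: background, 1: white matter, 2: granular (incl. Purkinje),
3: molecular}`; lobule volumes use positive ids with 0 = unassigned.  The
Purkinje sheet is one cell thick and is counted inside the granular label, so
"granular thickness" always includes it.  NIfTI-1 is the on-disk format
(spacing in the header zooms, origin in the affine translation, label
vocabulary in a JSON sidecar); NIfTI stores zooms as float32, and alignment
checks therefore use a 1e-6 mm tolerance.

## Thickness model

Thickness is a *closest-point* (nearest-neighbour) distance between interface
surfaces, not a Laplacian or streamline definition: for each vertex of the
carrier mesh, the exact Euclidean distance to the nearest point anywhere on
the target mesh.  Distances are taken to target *triangles*, not vertices — a
vertex-only search overestimates thickness by up to an edge length on coarse
meshes.  The implementation prunes candidates with two KD-trees (target
vertices for an upper bound, triangle centroids within bound + circumscribing
radius) and resolves the survivors with the exact Voronoi-region
point-to-triangle test, so the result equals the exhaustive minimum; ties in
the minimizer are irrelevant because the distance itself is unique.

Carrier conventions: granular thickness lives on the Purkinje surface with
the WM surface as target; molecular thickness on the Purkinje surface against
the pial surface; whole-cortex thickness on the pial surface against WM.

Undefined thickness is encoded as *invalid*, never as zero: genuine near-zero
values are an erosion artifact signature and must remain distinguishable from
"no measurement".

Two independent checks accompany the mesh measure:

* **2D slice-wise thickness** emulates histology-slide measurements: within
  each slice perpendicular to a chosen axis, layer voxels on the inner
  interface are measured to the nearest outside voxel beyond the outer
  interface of the *same* slice.  Both boundary sets sit half a voxel inside
  their respective tissues on opposite sides of the layer, so the half-voxel
  biases cancel and an axis-aligned slab of thickness *t* measures exactly
  *t*.  Oblique sectioning stretches the apparent width to *t*/sin α (α the
  angle between the layer normal and the slicing axis), which is why the 2D
  median is always ≥ the 3D median.
* **The voxel oracle** seeds an exact Euclidean distance transform at the
  inner-side voxels touching the layer and reads it at the layer voxels
  touching the outer side; the two half-voxel offsets again cancel.  On every
  phantom the mesh measure and the oracle agree within one voxel diagonal.

## Surface extraction

Interfaces are iso-surfaces (marching cubes, level 0.5) of the indicator of a
nested label set: WM surface from `{WM}`, Purkinje from `{WM, granular}`,
pial from `{WM, granular, molecular}`.  The binary indicator is anti-aliased
with a 1-voxel Gaussian before meshing: a raw 0/1 indicator pins every vertex
to an edge midpoint, and the resulting staircase inflates the area of a
digital ball by ~9% *independently of resolution*, whereas the smoothed level
set tracks the true interface to sub-voxel accuracy (displacement of order
σ²·curvature; measured ball-area error ≈ 0.3%).  `smoothing=0` restores the
raw behaviour.  No mesh-level smoothing or decimation is ever applied, and
connected-component filtering is opt-in and logged (phantom conservation
tests rely on nothing being silently discarded).

## Phantoms

The generator's role is to give every downstream stage a known answer.

* **Shell**: concentric spheres (WM radius r, granular band t_g, molecular
  band t_m).  Areas 4πr², shell volumes, constant thickness — all closed
  form.  Lobules are azimuthal sectors (n = 2 gives hemispheres), so
  per-lobule truth partitions the totals exactly.
* **Folia ribbon**: the WM top surface is the extruded sine
  z = h₀ + A·sin(2πx/w); layer labels are *bands of the Euclidean distance*
  to that curve (granular 0 < d ≤ t_g, molecular t_g < d ≤ t_g + t_m, above
  the curve).  The default folium width w = 0.9 mm matches the cerebellar
  folds this geometry emulates; the amplitude is a free parameter (the
  literature specifies fold width, not depth).  Because the layers are
  distance level sets, the closest-point granular thickness is *exactly* t_g
  at every Purkinje-surface point even where bands merge inside tight troughs
  (merging removes outer-interface area, as real sulci do, without changing
  the distance to WM).  A `strict_curvature` switch rejects geometries whose
  normal offsets self-intersect (offset ≥ trough radius of curvature
  (w/2π)²/A) for users who want the classical offset-surface regime.
  Interface areas and layer volumes come from marching-squares quadrature of
  the 2D distance field at 4× voxel resolution (contour length × ribbon
  width, cell counting × ribbon width); lobules are contiguous x-blocks and
  quadrature segments/cells are attributed by midpoint, so per-lobule values
  sum to totals by construction.  Interface areas use the (n_y − 1)-interval
  ribbon width a voxel mesh can actually carry; volumes use all n_y voxels.
* **Erosion** tears the molecular layer off a seeded fraction of out-facing
  crowns: crowns are plateaus of local maxima of the molecular height map
  under a maximum filter of half-width 0.45 mm (half a folium), and all
  molecular voxels in the dilated crown columns are relabelled background.
  WM and granular labels are never touched.  All randomness flows through one
  `numpy` generator per call, seeded explicitly.
* **Shrinkage** rescales the geometry by 1/λ about the volume centre
  (nearest-neighbour resampling on the same grid), so that measurement
  correction can be round-trip tested: λ = 1.245 shrinks areas by ≈ 1/1.245²
  and tissue volume by ≈ 1/1.931, and correction recovers the originals
  within discretization (≈ 0.7% area, ≈ 0.06% volume at 0.15 mm voxels).

What the phantoms do *not* emulate: staining intensity (the pipeline starts
from labels), anatomically realistic vermis/hemisphere topology, partial
voluming, and segmentation error.  Passing tests therefore validate the
geometry chain, not any segmentation.

## Statistics

* **Shrinkage correction** is purely multiplicative: λ, λ², λ³ for
  dimensionality 1, 2, 3.  The linear and volumetric factors are tied exactly
  (volume = λ³); the published linear factor 1.245 is itself a rounded
  number, which is why 1.245³ = 1.9298 reproduces the published volumetric
  1.931 only to ~0.002.
* **Artifact exclusion** invalidates vertices with thickness < ε; ε defaults
  to one voxel spacing because sub-voxel thickness is unmeasurable and the
  erosion spike sits at ≈ 0.  Retained values are never modified and the
  exclusion count is logged and reported.
* **Lobule aggregation** assigns carrier vertices and pial triangles to
  lobules by nearest labelled voxel within 2 voxel spacings (marching-cubes
  vertices sit between voxel centres); GM volume counts granular+molecular
  voxels per lobule id.  Totals are recomputed as sums and pooled
  (count-weighted) statistics rather than copied from rows, making the
  conservation identities exact.  Standard deviations use the population
  (n-divisor) convention.  Lobules without valid vertices are emitted flagged
  empty, never dropped.
* **Gamma MLE** (location fixed at 0) solves log k − ψ(k) = log(mean) −
  mean(log) by Newton iteration from the closed-form
  (3 − s + √((s−3)² + 24s))/(12s) start; the scale is mean/k.  Parameter
  recovery at n = 50,000 is within 5% and agrees with an independent
  constrained MLE to 4 decimals.
* **Gaussian mixture** fits K ∈ {1, 2} by EM with BIC selection
  (deterministic `random_state`, covariance floor 1e-12 so the forced-K=1 fit
  equals the sample mean/population std to 1e-9).  The largest-weight
  component is reported as the layer's Gaussian model; with erosion present,
  BIC selects K = 2 and the minority component captures the near-zero spike.
* **Histogram summaries** use Freedman–Diaconis bins (mode = centre of the
  peak bin) and the central 95% interval as [2.5th, 97.5th] percentiles.

## Conformal spherical maps

A genus-zero check (single closed component, Euler characteristic 2) is
followed by one sparse linear solve: the cotangent Laplacian with a complex
dipole right-hand side supported on a pole triangle (the gradients of the
triangle's hat functions in its own orthonormal frame), the vertex farthest
from the pole pinned to the origin (the system's nullspace is the constants,
and a constant offset is itself a Möbius transform of the image).  The
complex solution is scaled so the median modulus is 1 — any uniform scale is
Möbius, and this choice balances the image hemispheres — then carried to the
sphere by inverse stereographic projection and renormalized, so unit norm
holds to machine precision.  The pole triangle defaults to the one farthest
from the mesh centroid.  Open lobule patches are closed by centroid-fan
capping first; cap vertices are flagged so textures can mark them invalid.

Angle fidelity is measured per triangle as the ratio of singular values of
the linear map between the source triangle and its image (1 = conformal,
infinite for degenerate images).  Rotations of the sphere give exactly 1;
general Möbius transforms of a *discretely sampled* sphere are conformal only
in the refinement limit, and the diagnostic correspondingly decreases toward
1 under refinement (as it does for the flattening itself: median angle
distortion on an icosphere falls from 4° at 642 vertices to 0.5° at 40k).

## Pipeline and problem sizes

`run_pipeline` chains phantom/input → surfaces → thickness → exclusion →
lobule statistics → fits → report, writes NIfTI/VTP/CSV/JSON outputs plus a
provenance log (config, seed, versions, stage timings), and is bit-reproducible
for a fixed config and seed on one platform.  Validation uses desk-scale
problems — shells of radius 5 mm at 0.1 mm voxels (~2M voxels, ~150k-triangle
pial mesh) and folia ribbons of 2–4 periods at 0.05–0.1 mm voxels — chosen so
the full suite and the acceptance script each run in minutes on one CPU while
still resolving the thinnest layer with ≥ 3 voxels.

## Known limitations

* The closest-point definition is the measurement model here; curvature-
  corrected or streamline thickness would differ in tight folds, where the
  nearest point of the target surface may not lie along the local normal.
* In deeply merged troughs the *molecular* (Purkinje→pial) distance can
  exceed t_m where the pial surface has been consumed by band merging; the
  granular measure is immune (the carrier is a distance level set of WM).
* Anti-aliased extraction trades a ~9% staircase area bias for a small
  curvature-dependent displacement; at fold radii approaching one voxel the
  smoothed surface rounds sharp crests.
* Whether published cerebellar tables weight thickness means by vertex count
  or by lobule row is not stated in the sources this mirrors; totals here are
  always vertex-weighted, and printed row sums that disagree with printed
  totals are resolved in favour of recomputed sums.
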