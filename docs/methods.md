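# Methods

This note documents the models, numerical choices and limitations of
`niqa`: the automated sphere-localization and ROI pipeline for NEMA NU-2
image quality phantom PET/CT scans, and the synthetic phantom generator
used to validate it.

## Coordinate conventions

Voxel arrays are stored `(slice, row, column)`; all index vectors use the
same array order, world coordinates are DICOM patient coordinates in mm.
Index `(0, 0, 0)` is the **center** of the first voxel and fractional
indices are meaningful everywhere — every sub-voxel sphere center is a
fractional index or a mm point. The header isometry Φ_DICOM is the
identity on the shared patient frame (standard DICOM semantics for a
common frame of reference); any header misalignment is expressed through
each series' own origin and orientation. Volumes whose row/column
direction cosines are not signed unit vectors are rejected outright
rather than resampled.

## Matched filtering

Templates are rasterized by **binary center inclusion**: a voxel belongs
to a filled sphere iff its center is within or on the analytic boundary
(`distance² ≤ r²`, no floating tolerance — ties on the boundary are
included), and to a hollow shell iff `r_in < distance ≤ r_in + wall`.
The matched value space records the SUM (or the MEAN over non-excluded
voxels) of the covered voxels at every placement where the template fits;
edge placements are not populated. Scans are computed by FFT
convolution; the contract — equality with the direct sliding-window sum
to 1e-6 relative — is enforced by oracle tests. When several placements
tie for the maximum (within 1e-9 relative, which absorbs FFT round-off),
the first in lexicographic array order is chosen and a `MultipleMaxima`
warning is issued, keeping results deterministic.

Sub-voxel peaks come from an ordinary-least-squares fit of a full
N-variate quadratic (constant, linear, all pure and cross second-order
terms) and its analytic vertex. In 3D the fit box is the largest box
around the argmax whose axis profiles have strictly negative discrete
second differences at every interior point ("concave down"); a profile
failing this immediately at the argmax triggers a fall-back to the 3×3×3
box with a warning. If the fitted Hessian is not negative definite the
grid argmax is used, again with a warning.

## CT localization

Large spheres (22/28/37 mm) are found with shell templates in subvolumes
spanning two sphere diameters per axis; small spheres (10/13/17 mm) in
subvolumes spanning three diameters, predicted by reflecting the
large-sphere centers through the hexagon center `C_H = C4 + C6 − C5`
(exact for three consecutive vertices of a regular hexagon; the formula
is affine, hence exactly equivariant under rigid motions).

Small-sphere subvolumes are integer up-sampled (nearest-neighbor
replication, per-axis factor = smallest integer making the voxel
< 1 mm) because the ~1 mm walls are otherwise represented by too few
voxels, and the values are rescaled to `V ↦ −|V − μ_PSW|`, where μ_PSW
is the mean CT value of the wall voxels labeled on the three largest
spheres. Matching wall-likeness rather than raw intensity keeps the
small-sphere filter from chasing noise extremes. Up-sampled indices map
back to parent fractional indices as `(u + 0.5)/f − 0.5` (center-aligned
replication).

**Air bubbles.** Each subvolume is histogrammed into 10 equal-width bins
over [min, max]; if the most-populated bin lies in the upper half
(bins 6–10, 1-based; edge values go to the higher bin except the maximum)
the subvolume must contain values far below water, i.e. air, and every
voxel at or below `mean − 2·SD` (population SD of the whole subvolume) is
excluded from all matched-filter statistics. When no air is detected the
cheaper SUM statistic replaces the MEAN; the two paths coincide exactly
in that case (tested). Wall labeling is purely geometric: shell-template
voxels at the argmax minus air voxels, with no intensity gating.

## Registration

The initial isometry Φ_E maps CT sphere 6 exactly onto the coarse PET
estimate of sphere 6, the 6–5 line onto the 6–5 line, and the 6–5–4
plane onto the corresponding plane. The two two-fold symmetric branches
are resolved stepwise by minimizing the distance of the mapped point to
its PET counterpart; the result is always a proper rotation.

The 6-DOF search perturbs Φ_E on a 7⁶ grid: translations ±3 mm in 1 mm
steps along the world axes, rotations about the centroid of the mapped
centers with the increment chosen per axis as `Δθ = 1 mm / r_perp`,
where `r_perp` is the distance of the center farthest from that axis —
so no sphere moves more than 1 mm of arc per increment. Perturbations
compose as `Rx·Ry·Rz` about the centroid followed by the translation;
at these angles (≲3°) the ordering effect is far below the fit
resolution, but the order is fixed for determinism. The implementation
gathers each sphere's candidate PET voxels once, splits them into an
always-covered core and an uncertain shell, and re-tests only the shell
per node; the values equal a full template rebuild and direct sum to
round-off (spot-checked against that oracle). Nodes whose analytic
sphere extends past the voxel-center grid are flagged invalid and
excluded from the fit. The layout must keep spheres separated by more
than the perturbation travel (always true for the NEMA ring); otherwise
the per-sphere sum decomposition would double-count and the search
refuses to run.

**6D fit extent.** The quadratic is fitted over the ±2-node box around
the grid argmax, not the full ±3 range: the matched-value surface is
only locally quadratic, and fitting the full grid measurably biases the
vertex (up to ~1.5 mm on noiseless fixtures versus ≤0.2 mm for the local
box). Two nodes is also the scale at which a vertex is considered
untrustworthy (`VertexFarFromMax`).

**Re-centering.** Because the coarse PET estimates are integer voxel
positions, Φ_E can tilt enough that spheres on the far side of the ring
start 5–7 mm from their true positions — beyond the ±3 mm window — and a
peak near the edge of the fit box biases the quadratic vertex. The
search is therefore re-run centered on the current optimum until the
argmax is the central node (peak symmetric in the fit box) or
consecutive optima agree within 0.25 mm at every sphere, up to four
passes; each pass is the identical 7⁶ search. The final pass's warnings
are reported, plus `RecenteredSearch` when iteration occurred. A maximum
on a face of the final search grid still raises `BoundaryMax`. Finer
search steps were evaluated and rejected: the binary-template sum is
piecewise constant under sub-voxel shifts, so a finer grid samples the
staircase rather than a smoother surface and degrades the vertex.

The report deliberately carries no pass/fail verdict on misalignment:
the displacement norms ‖D_i‖ and their angular spread θ_D are reported
raw. θ_D is the maximum pairwise angle among the nonzero D_i; with fewer
than two nonzero vectors it is reported as 0 with a note.

## Synthetic phantom generator

The generator emulates the study conditions the pipeline is meant for:

| parameter | default | meaning |
| --- | --- | --- |
| inner diameters | 10/13/17/22/28/37 mm | NEMA sphere set, 1 mm walls |
| hexagon radius | 57.2 mm | sphere-center ring |
| ring orientation | 97°, winding configurable | deliberately off-axis (real phantoms land at arbitrary rotations; exact axis alignment would create unphysical mirror-tie artifacts) |
| phantom center | (1.1, −0.7, 0.6) mm | off-grid, like a real scan |
| body | cylinder r = 112 mm, half-height 40 mm | large enough that every CT search box stays inside water, as with the torso shell |
| CT values | water 0, plastic +120, air −1000 HU | |
| CT grid | 2.5 mm slices, 1.37 mm in-plane, 36×170×170 | clinical attenuation-correction CT |
| PET grid | 3.27 mm slices, 2.73 mm in-plane, 32×88×88 | typical whole-body reconstruction |
| PET contrast | 4:1 spheres over unit background, walls/bubbles cold | |
| blur | PET 6 mm FWHM, CT 0.7 mm FWHM | post-reconstruction smoothing / detector blur |
| noise | PET σ = 0.1 (10% of background), CT σ = 15 HU, entering **before** the blur | blurred white noise has the spatially correlated texture of post-filtered reconstructions; the order is configurable |
| bubbles | none by default | air spheres resting against the top (−y) of a sphere's interior |
| misalignment | none by default | rigid transform applied to the physical PET content while headers claim alignment |

Rendering is geometric: voxels are supersampled (4× per axis for CT, 3×
for PET) and box-averaged so walls and boundaries carry correct
partial-volume fractions, then blurred and degraded with seeded noise.
Output volumes are quantized to scanner-like integer storage (1 HU for
CT, background/5000 for PET), which also makes the DICOM write→load
round trip bit-exact. Total PET activity of the noiseless render matches
the analytic body+spheres integral to <1% (tested).

What the generator does **not** emulate: the lung insert, PSF-
reconstruction ringing around spheres, beam hardening or low-dose CT
artifacts, Poisson projection-domain noise, non-rigid phantom
deformation. Passing tests therefore demonstrate the pipeline's
geometric and statistical correctness under realistic blur/noise/bubble/
misalignment conditions, not robustness to every scanner artifact.

## Problem sizes in the validation suite

The repeatability studies use 50 seeded noisy realizations per condition
(CT localization repeatability in two phantom positions; ROI statistic
stability with fixed CT geometry), 20 random rigid offsets for the
recovery property (translations uniform in ±2.5 mm, rotations up to
2.5 mm of arc at the ring), and paired air-detection on/off runs on a
phantom with 4–8 mm bubbles in spheres 2–5. These sizes keep the full
suite and the acceptance script each within minutes on a single CPU.

## Known limitations

- Fixed sphere count (six) and hot-sphere polarity; cold-sphere variants
  and nonstandard layouts are out of scope (the search-box sizes are
  tuned to the NEMA diameters).
- The CT stage assumes the subvolume is mostly water; phantoms whose
  search boxes reach outside the body (or epoxy fills with wall-like
  attenuation) need the fixed-geometry input mode instead.
- No background ROIs and no NEMA percent-contrast computation — the
  deliverable is the sphere centers, their ROI statistics and the
  misalignment diagnostics.
- Localization *bias* (as opposed to repeatability) inherits the
  rasterization asymmetry of the voxel grid and is a few tenths of a
  millimeter at clinical spacings; the validation suite measures both.
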