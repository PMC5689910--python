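# Methods

## Coordinate model

All world coordinates are millimetres. A volume's geometry is a `Grid3D`
(origin, per-axis spacing, voxel counts, orthonormal 3×3 direction matrix).
Indexing is 0-based, voxel-centred: voxel `i` covers the half-open slab
`[origin + i·s − s/2, origin + i·s + s/2)` per axis in the grid's local
frame. Oblique (rotated/flipped) grids are accepted; sheared affines are
rejected because the slab model and the distance computations assume
orthogonal axes. Every source — full-body CT, 4D-CT, 4D-PET, planning CT,
delineations, dose — keeps its own grid; fusion happens by evaluating each
source at world points. Nothing is ever resampled onto another grid, which
is what lets a 4 mm PET and a 1 mm CT coexist without preprocessing and is
verified behaviorally (a native coarse render equals a pre-upsampled one at
coincident sample points).

Interpolation is trilinear for all scalar sources (image, dose, and the
{0,1} indicator of a delineation). Points outside a source's bounding box
contribute value 0 with an outside flag, and hence zero colour and opacity
during rendering. Mask membership is always a nearest-neighbour lookup:
masks are categorical and interpolation would invent geometry.

## Transfer functions and windowing

A transfer function is a piecewise-linear map value → RGBA with strictly
increasing control values and an opacity cap. The windowing-coupled
constructor mirrors how PET display windows anchor volume rendering:
opacity 0 at or below the lower window value, the cap (default 0.7 for PET)
at or above the upper value, and a **linear** ramp between them. Only the
endpoints are fixed by the display convention; the linear ramp is this
package's choice, as is applying the same constructor to any modality.

## Ray-casting and fusion

For each pixel the ray is clipped to the scene ROI — a fractional, closed
sub-box of the reference volume's bounding box (reference = planning CT by
convention); the six fractions are the programmatic equivalent of clip-plane
sliders, and the clipping applies equally to image layers, delineation
surfaces and iso-dose surfaces. Marching uses a fixed world step, by
default half the smallest voxel spacing among enabled sources. Sample
positions are `t_entry + (k + ½)·Δt`, so rendering is fully deterministic.

At each sample every enabled, mask-visible image layer is evaluated in its
own grid and mapped through its transfer function; per-layer opacities are
corrected for the step length relative to a 1 mm reference
(`α' = 1 − (1−α)^Δt`) so the integral is step-size independent. The fused
sample is the weighted linear combination of layer colours and opacities
with weights normalized to sum 1 (accumulation-level intermixing). A layer
with masks assigned is visible at a point iff the point lies inside at
least one of its masks (union semantics); this lets, e.g., CT show inside
the trachea while PET+CT show inside the ITV.

Compositing is front-to-back with the over operator
(`C += (1−A)αc`, `A += (1−A)α`), with optional early termination at
`A > 0.99` (disabled in all oracle comparisons; the truncation error is
bounded by the remaining transmittance).

## Surfaces

Delineation surfaces are the 0.5 level set of the trilinearly interpolated
binary indicator — smooth at subvoxel scale without mesh extraction —
and iso-dose surfaces are levels (Gy) of the interpolated dose field. A
crossing between consecutive samples is located by linear inverse
interpolation and inserted as an *extra* sample at its exact depth with the
surface's own colour and opacity ("exclusive opacity"): it replaces no
volume sample, so a transparent surface attenuates what lies behind it and
an opaque surface occludes it, always in correct depth order, including
several surfaces crossing within one step (sorted by depth fraction).
Normals are normalized negative central-difference gradients at half-voxel
offsets in the source's own grid; shading is Blinn-Phong
(ambient + diffuse·max(n·l,0) + specular·max(n·h,0)^shininess, clamped),
with the unshaded base colour returned for degenerate (zero-gradient)
normals. The first surface crossing per pixel fills the depth buffer, which
is what surface point picking reuses: a pick casts the pixel's exact ray
through the same machinery and converts the hit to reference-grid indices
for slice navigation, so pick depth and depth buffer agree by construction.

The camera is a pinhole model (vertical field of view, mm world units) with
an orthographic option; the over-operator surface semantics and the
normalized weights for >2 volumes are package choices where the interactive
original left them unstated.

## Structure sets and rasterization

Structure sets carry named, coloured stacks of closed planar contours (per
time bin). I/O: DICOM-RT Structure Set (read/write via pydicom) and a JSON
dialect (`docs/contour_schema.md`) so tests need no binary fixtures.
Rasterization assigns each contour to the nearest slice centre in z
(tolerance: half a slice spacing; farther contours are an error) and fills
with the even-odd (parity) rule tested at voxel centres; voxel centres
exactly on a contour edge count as inside — a deterministic tie-break.
Nested contours therefore produce holes. The fill rule and boundary
convention are declared choices, not inferred ones. Majority voting marks a
voxel foreground iff ≥ k of n input masks (identical grids required) are
foreground — k = 3 of 4 being the typical consensus of four physicians'
delineations.

## Metrics

Dice and Hausdorff comparisons require both masks on one grid — callers
rasterize/map everything onto the planning grid rather than resampling one
mask onto the other. Surface voxels are foreground voxels with at least one
background 6-neighbour, with the grid border counting as background;
directed distances are Euclidean mm between surface voxel centres
(anisotropic spacing respected, subvoxel/mesh distances out of scope). The
maximum, average and 95th-percentile Hausdorff statistics are all computed
on the pooled (symmetrized) directed lists, the percentile with linear
interpolation; pooling for the 95 % variant is a declared choice, tested
against a brute-force oracle under the same definition. The conformity
index is the mean **absolute** inter-rater rating difference (absolute
rather than signed is a declared choice), and a delineation is accepted iff
its rating on the 1 (excellent) – 5 (poor) scale is at most 3.

## DVH

Cumulative DVHs evaluate mask membership at dose-grid voxel centres
(nearest-neighbour across grids, no partial-volume weighting — a known
upward/downward bias for structures a few dose voxels across), with
`fraction(d) = #{voxels ≥ d}/#voxels` at bin edges 0…max dose, default bin
width 0.1 Gy. `Dmean` is the arithmetic voxel mean; `V_x` the fraction at
least x Gy; `D_x%` the smallest dose received by at least x % of the
structure, realized exactly on step DVHs as the lower-interpolation
quantile at 1 − x/100.

## Margins and location classification

Margin expansion is Euclidean: a voxel joins the margin volume iff its
centre lies within the margin distance of any foreground voxel centre
(computed via an exact Euclidean distance transform with the grid's
spacings). Defaults are 20 mm around the bronchial tree and 5 mm around the
mediastinum, both configurable. A lesion is **central** iff its ITV
overlaps any margin volume by a positive amount (overlap measured on the
ITV's grid, nearest-neighbour across grids), otherwise **peripheral**; the
any-positive-overlap rule is the automated stand-in for a clinician's
distance-tool judgement and is monotone in the margin by construction.

## Synthetic phantom

The phantom emulates the clinical multi-source layout at roughly one-fifth
extent so a full pipeline run takes seconds: body CT 2×2×4 mm,
4D-CT 1.2×1.2×2 mm, 4D-PET 4 mm isotropic with 10 bins, planning CT
1×1×3 mm (96×96×32), dose 3 mm — preserving the resolution *ratios* of a
clinical stack (PET ≈ 4× coarser than planning CT in-plane). A spherical
soft-tissue lesion (radius 8 mm) in lung-density background moves
sinusoidally in z, `d(t) = A·sin(2πt/B)`, default amplitude 10 mm over
B = 10 bins — cranio-caudal motion dominates lung tumour excursion;
hysteresis and deformation are deliberately absent. PET frames are a
Gaussian-blurred uptake blob (contrast 8× background, 4 mm blur) at the
same per-bin centres; CT noise is additive Gaussian (20 HU), PET noise
Gaussian with √intensity scaling (Poisson-like). OARs are a tube (airway)
and a slab (mediastinum), placed so the default lesion is peripheral at the
default margins. The ITV is the voxelwise union of per-bin lesion masks on
the planning grid; the dose is a logistic plateau
`D(p) = Rx·σ(−s(p)/λ)` around the ITV (signed distance s, falloff
λ = 4 mm, Rx = 54 Gy — an SBRT-like 3×18 Gy prescription). One seed fixes
all randomness; different seeds change only noise, never geometry. The
ground-truth manifest (true per-bin centres, volumes, dose coverage) is
what recovery tests and the acceptance script close the loop against.

What passing phantom tests do *not* show: behaviour under deformable
motion, realistic anatomy/texture, PET partial-volume and reconstruction
artefacts, or registration error between sources — all sources here share
one patient frame by construction.

## Numerical choices and limitations

* Ray step Δt = half the minimum enabled spacing; opacity reference step
  1 mm; early termination at A > 0.99 (off in oracles).
* Outside-grid samples: value 0, zero colour/opacity. Edge clamping between
  the outermost voxel centres and the box face.
* Nearest-neighbour index rounding uses banker's rounding at exact
  half-voxel ties (inherited from `np.rint`); deterministic.
* Rasterization boundary tolerance 1e-9 mm; contour-to-slice tolerance
  half a slice spacing.
* I/O: NIfTI via nibabel (the file's affine frame is the world frame),
  DICOM series via SimpleITK, RTSS via pydicom; 4D volumes as per-bin files
  plus a JSON manifest. NRRD is not supported.
* The DVH layer does no 4D dose accumulation over breathing phases — dose
  volumes are static 3D inputs, as in routine 3D planning.
* Renderer throughput is numpy-vectorized per step but still a software
  ray-caster: suitable for hundreds-of-pixels interactive checks and
  batch figure generation, not real-time use.
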