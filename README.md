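# fuse4d

**Desk-scale 4D multimodal PET/CT visualization and radiotherapy
structure/dose assessment.**

Radiotherapy of moving targets (lung SBRT in particular) works with a stack
of imaging sources that never share a grid: a full-body CT, a respiratory
4D-CT and 4D-PET with ten breathing phases, a planning CT, delineations of
target and organs at risk (OARs), and a 3D dose distribution in Gy.
Assessing an internal target volume (ITV) — the union of the tumour
positions over the breathing cycle — or a dose distribution against all of
that at once requires fused 3D/4D views plus quantitative contour metrics.

`fuse4d` provides both halves as a plain-Python toolkit:

* **A software ray-caster** that fuses mixed-resolution volumes in one world
  coordinate system *without resampling*: every image layer is sampled
  trilinearly in its own grid at each ray sample, colours/opacities come
  from per-source transfer functions (for PET, coupled to the display
  window: transparent below the lower window value, constant opacity 0.7
  above the upper one), and the fused sample is the normalized weighted
  linear combination `C = Σ ŵᵢCᵢ`, `α = Σ ŵᵢαᵢ` (accumulation-level
  intermixing). Delineation surfaces (0.5 level of the interpolated binary
  indicator) and iso-dose surfaces (levels in Gy) are inserted as
  Blinn-Phong-shaded samples at their exact crossing depth, so transparent
  surfaces attenuate and opaque ones occlude at the correct depth.
  Clipping to a fractional ROI of the reference volume, per-layer masking
  by delineations, time-bin navigation, a depth buffer and surface point
  picking for 3D→2D navigation are included.
* **A quantitative layer**: DICOM-RTSS/JSON structure-set I/O, even-odd
  contour rasterization at voxel centres, majority-vote (k-of-n) consensus
  masks, Dice coefficient `DC = 2|A∩B|/(|A|+|B|)`, average/maximum/95th
  percentile Hausdorff distances on surface-voxel distances, inter-rater
  conformity index (mean absolute rating difference), the rating ≤ 3
  acceptance rule, cumulative dose-volume histograms with `Dmean`, `V_x`,
  `D_x%` summaries, Euclidean margin expansion, and central/peripheral
  tumour-location classification by margin-volume overlap.
* **A seeded synthetic 4D breathing phantom** reproducing the multi-source
  layout (body CT, 4D-CT, 10-bin 4D-PET on a 4 mm grid, 1×1×3 mm planning
  CT, delineations, coarse dose grid) with a sinusoidally moving spherical
  lesion and a ground-truth manifest, so the whole pipeline is testable
  without patient data.

## Worked example

```python
import numpy as np
from fuse4d import (PhantomSpec, make_phantom, assess, dvh_stats,
                    classify_location, dilate, MarginVolume)
from fuse4d.dvh import in_mask_doses

bundle = make_phantom(PhantomSpec(seed=7))

# quality of the end-exhale lesion delineation vs the breathing-integrated ITV
report = assess(bundle.lesion_bins[0], bundle.itv)
print(f"DC = {report.dice:.3f}  HDavg = {report.hd_avg:.2f} mm  "
      f"HDmax = {report.hd_max:.2f} mm  HD95 = {report.hd_95:.2f} mm")

doses = in_mask_doses(bundle.dose, bundle.itv)
s = dvh_stats(doses, v_levels_gy=[27.0], d_levels_pct=[95.0])
print(f"ITV dose: Dmean = {s['Dmean']:.1f} Gy  D95% = {s['D_95%']:.1f} Gy  "
      f"V27Gy = {100*s['V_27Gy']:.1f}%")

margins = [MarginVolume("bronchial_tree", 20.0, dilate(bundle.airway, 20.0)),
           MarginVolume("mediastinum", 5.0, dilate(bundle.mediastinum, 5.0))]
location, overlaps = classify_location(bundle.itv, margins)
print(f"location: {location}  "
      f"(airway overlap {overlaps['bronchial_tree']['overlap_mm3']:.0f} mm^3)")
```

prints

```
DC = 0.531  HDavg = 3.87 mm  HDmax = 9.11 mm  HD95 = 9.06 mm
ITV dose: Dmean = 39.0 Gy  D95% = 36.7 Gy  V27Gy = 100.0%
location: peripheral  (airway overlap 0 mm^3)
```

A single breathing phase covers only half the ITV of a lesion breathing
with 10 mm amplitude (DC ≈ 0.53, maximum surface distance ≈ 9 mm — close
to the 10 mm excursion), the ITV sits entirely inside the half-prescription
(27 Gy) isodose of the synthetic 54 Gy plan, and the lesion lies farther
than 20 mm from the bronchial tree and 5 mm from the mediastinum, hence
"peripheral".

## Command line

```bash
fuse4d phantom  --out phantom/ --seed 7 --amplitude 10 --bins 10
fuse4d render   --scene scene.yaml --out img.png --time-bin 3
fuse4d assess   --test itv1.nii.gz --ref planning_itv.nii.gz --out metrics.json
fuse4d dvh      --dose dose.nii.gz --structures itv.nii.gz,oar.nii.gz \
                --out dvh.csv --plot dvh.png --v-levels 37.5
fuse4d classify --itv itv.nii.gz --airway airway.nii.gz \
                --mediastinum med.nii.gz --report report.json
fuse4d pick     --scene scene.yaml --pixel 312,205
```

The scene YAML/JSON format is documented in `fuse4d/cli.py`; the JSON
contour dialect in `docs/contour_schema.md`.

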