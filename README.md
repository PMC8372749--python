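# mmii — multimodal image integration for epilepsy presurgical evaluation

Localizing the epileptogenic zone (EZ) before resective or ablative epilepsy
surgery requires fusing every available localization study — structural MRI,
FDG-PET, ictal/interictal perfusion SPECT, MEG dipole solutions, CTA/MRA
vasculature, post-implant CT and post-operative MRI — into one anatomical
frame, then planning stereo-EEG (SEEG) trajectories and ultimately a
resection in that frame.  Clinically this workflow lives inside proprietary
GUI platforms; `mmii` re-implements it as an open, scriptable Python
toolkit, for epilepsy imaging researchers and methods developers who need
the same chain of operations reproducible, testable and automatable.

Every modality is carried as a 3D scalar grid with a voxel-to-world affine
(RAS+ millimetres, NIfTI convention); every derived annotation (MEG
dipoles, electrode contacts, pass markers) is a named point list in the
base frame.

## What it computes

* **Rigid co-registration** of any modality onto the T1 base volume by
  maximization of mutual information,
  `MI(A,B) = H(A) + H(B) − H(A,B)` from the joint intensity histogram —
  a coarse multi-resolution Mattes-MI stage followed by a deterministic
  full-resolution Powell polish.  Statistical maps that ride on a carrier
  anatomical volume (fMRI activations, morphometric z-maps, SISCOM output)
  are moved with the carrier's transformation matrix, never re-estimated.
* **SISCOM** (subtraction ictal SPECT co-registered to MRI): both perfusion
  volumes normalized to mean 100 within a brain mask, subtracted, and
  expressed as voxelwise z-scores
  `z = (d − μ_d) / σ_d` over the masked difference distribution, then
  thresholded (z ≥ 1.5 or 2) into 26-connected clusters.
* **Talairach proportional grid** from AC, PC and midsagittal landmarks:
  4 sagittal sectors (A–D) between the vertical-AC plane and the anterior
  brain boundary, 4 (F–I) behind the vertical-PC plane, sector E between
  the commissures; 8 level bands above the AC–PC plane and 4 below;
  4 coronal columns (a–d, mesial to lateral) per hemisphere.
* **SEEG trajectory planning**: straight entry–target segments, minimum
  distance to a vessel mask (with the first 15 mm from the entry reported
  separately), and coverage of localization targets.
* **Contact localization** from the post-implant CT: suprathreshold
  components, local-maxima splitting of merged metal blooms, centre of
  maximal intensity per contact, nearest-trajectory assignment and naming
  (`LA1` = deepest contact of electrode LA).
* **Resection planning**: pass markers → brush-stroke mask → voxel mesh,
  containment checks for ictal-onset contacts, and burned high-intensity
  export for neuronavigation hand-off.
* **Phantoms**: seeded generators for a T1 head, perfusion pairs with
  focal perfusion changes, an implant CT with known contacts, and vessel
  trees — every stage is testable without clinical data.

## Worked example

```python
import numpy as np
from mmii import (BrainBounds, build_frame, grid_cell, compute_siscom,
                  threshold_clusters)
from mmii.phantom import PhantomSpec, make_perfusion_pair

# Talairach grid on an axis-aligned frame (AC at the origin, PC 23 mm
# posterior, bounding box from the segmented brain)
frame = build_frame((0, 0, 0), (0, -23, 0), (0, 0, 40),
                    BrainBounds(anterior=70, posterior=80, superior=70,
                                inferior=45, left=65, right=65))
print(grid_cell((25.0, 40.0, 30.0), frame))

# SISCOM on a phantom pair with a +15% hyperperfusion sphere at (15, 0, 15)
spec = PhantomSpec(seed=0, blob_specs=[((15.0, 0.0, 15.0), 8.0, 0.15)])
ictal, interictal, mask, truth = make_perfusion_pair(spec)
zm = compute_siscom(ictal, interictal, mask, smooth_fwhm=6.0)
top = threshold_clusters(zm, z_thresh=2.0, min_voxels=10)[0]
print(f"top cluster: {top.voxel_count} voxels, peak z={top.peak_z:.1f}, "
      f"centroid {np.round(top.centroid, 1)}")
```

Output:

```
B5b/right
top cluster: 461 voxels, peak z=9.7, centroid [15.1 -0.4 14.7]
```

`B5b/right` reads: sagittal sector B (second quarter-band from the
anterior boundary), level 5 (fifth band down from the vertex), coronal
column b (second from the midline), right hemisphere.  The SISCOM cluster
centroid lands within a millimetre of the simulated seizure-onset blob.

The same workflow runs end to end from a case file:

```bash
mmii phantom --preset full-case --seed 7 --out case/
mmii run --config case.yaml          # register → SISCOM → grid → plan
                                     # → contacts → resection
mmii siscom --ictal I.nii.gz --interictal J.nii.gz --t1 T1.nii.gz --z 1.5
```

## Layout

| module | contents |
|---|---|
| `mmii.volumes_io` | `ImageVolume`, `RigidTransform`, `PointSet`, NIfTI/DICOM I/O, burn/extract round trip |
| `mmii.registration` | mutual information, rigid registration, resampling, carrier-map transfer |
| `mmii.siscom` | perfusion normalization, z maps, cluster tables |
| `mmii.talairach` | proportional grid frame, cell lookup, grid planes |
| `mmii.trajectory` | trajectory plans, vessel clearance, coverage, expected contacts |
| `mmii.contacts` | CT contact segmentation, assignment and naming |
| `mmii.resection` | pass markers → mask → voxel mesh → burned export |
| `mmii.phantom` | seeded ground-truthed synthetic cases |
| `mmii.pipeline` | whole-case orchestration with manifest and logs (`mmii run`) |

See `docs/methods.md` for the models, parameter choices and limitations.
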