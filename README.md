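# vertefem

Voxel finite-element analysis of vertebral cement augmentation
(vertebroplasty) on a three-vertebra spinal segment.

## What this package is for

Vertebroplasty injects bone cement (PMMA) into a fractured or at-risk
vertebral body. A recurring biomechanical question is how the procedure
changes the load path through the treated segment — in particular whether
the stiffened vertebra redistributes stress onto its untreated neighbours,
a suspected mechanism behind adjacent-level fractures. Because cadaver
experiments confound treatment factors (cement volume, number of augmented
levels) with patient factors (bone density, disc degeneration), image-based
finite-element models are the standard tool for separating them.

`vertefem` is a reusable pipeline for exactly that kind of study, written
for biomechanics researchers who want a desk-scale, fully scripted
equivalent of the specimen-specific workflow:

1. **phantom** — a synthetic quantitative-CT-style image and label map of a
   T12–L1–L2 segment: three elliptic-cylinder vertebral bodies (trabecular
   core + cortical shell), two discs (orthotropic annulus ring around an
   isotropic nucleus), potting housings at both ends, and an optional
   centrally seeded cement region at a configurable fill fraction
   (default 20% of vertebral-body volume),
2. **imaging** — threshold segmentation and greyscale→modulus mapping
   `E = max(a·g + b, E_min)`; the default phantom's trabecular field is
   constructed so the mapped modulus has mean 128.41 MPa and SD 66.20 MPa,
3. **fe_core** — a voxel hex8 linear-elasticity solver (2×2×2 Gauss,
   optional mean-dilatation variant), displacement-controlled axial
   compression through a rigid top plate with free rotations (ball-seat
   loading), segmental stiffness k = R/δ in N/mm,
4. **calibration** — inverse tuning of disc properties: all disc stiffness
   constants are scaled, preserving the annulus anisotropy ratios, until
   the model matches a measured pre-augmentation segmental stiffness
   (617 N/mm by default),
5. **treatment** — parametric operators: cement modulus (2040 MPa ×1, ×0.5,
   ×0.25, ×0.125), cement volume (×0.5/×2), bone quality (×0.5/×2), disc
   state (healthy/degenerated), augmentation pattern (L1, T12, T12+L1),
6. **study** — sweeps over treatment cells, with per-element von Mises
   stress changes between untreated and treated states compared at a
   common reaction force of 1000 N and histogrammed per vertebra.

## Worked example

```python
from vertefem.phantom import PhantomSpec, generate_phantom, add_cement_region
from vertefem.imaging import greyscale_to_modulus
from vertefem.fe_core import build_model, assemble_and_solve, segment_stiffness
from vertefem.calibration import DiscProperties, calibrate
from vertefem.treatment import apply_augmentation

spec = PhantomSpec()                      # 1.4 mm voxels, seed 42
image, labels = generate_phantom(spec)
modulus = greyscale_to_modulus(image, labels)

def builder(disc):
    return build_model(labels, modulus, annulus=disc.annulus, nucleus=disc.nucleus)

cal = calibrate(builder, target_k=617.0)  # tune discs to the measured stiffness
print(cal.annulus_factor, cal.achieved_k)

labels_aug = add_cement_region(labels, "L1", 0.2)
model = build_model(labels_aug, modulus,
                    annulus=cal.disc.annulus, nucleus=cal.disc.nucleus)
model = apply_augmentation(model, ("L1",))
res = assemble_and_solve(model, 0.5)      # 0.5 mm axial compression
print(segment_stiffness(res).k)
```

This prints (to the digits that are stable across platforms):

```
2.5318 616.96
639.64
```

meaning: the disc stiffness constants must be scaled ×2.53 from their
healthy literature values for the model to reproduce the 617 N/mm
pre-augmentation stiffness (the achieved value, 616.96 N/mm, is within the
0.1% calibration tolerance), and augmenting L1 with pure cement at 20%
fill raises the segmental stiffness to ≈640 N/mm — a few percent, because
the discs, not the bone, dominate the axial compliance of the segment.

The same pipeline is scriptable from the shell:

```bash
vertefem generate-phantom --seed 42 --cement-level L1 --cement-fill 0.2 --out-prefix pre
vertefem build-materials --image pre_image.nii.gz --labels pre_labels.nii.gz --out materials.nii.gz
vertefem solve --image pre_image.nii.gz --labels pre_labels.nii.gz --summary summary.csv
vertefem calibrate --image pre_image.nii.gz --labels pre_labels.nii.gz --target-k 617 --out cal.json
vertefem run-study --study stiffness-grid --out-dir results/
```

## Scope and limitations

The model is linear-elastic and displacement-controlled; it predicts
stiffness and relative stress redistribution, not strength or failure.
The phantom idealizes vertebrae as elliptic cylinders without posterior
elements or facet joints, which is adequate for axial compression only.
See `docs/methods.md` for the full model description, parameter defaults,
numerical choices and known limitations.
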