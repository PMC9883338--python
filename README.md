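# tract2dicom

Research neuroimaging pipelines produce neurosurgical workups as
coregistered NIfTI volumes (T1, FLAIR, FA maps), NIfTI mask/label images
(tumour delineations, fMRI activation maps) and MRtrix `.tck` streamline
files (white-matter tractography). Commercial surgical planning and
navigation suites cannot read any of these: they import DICOM.
`tract2dicom` bridges that gap for neurosurgeons and the imaging
scientists supporting them — it converts a complete workup into a
standards-conformant DICOM dataset that a navigation suite imports as if
the objects were created natively, so tracts and segmented structures can
be rotated, toggled and fused with the anatomy during planning and
surgery instead of being frozen into screenshots.

## What it writes

Every object of one conversion run shares a single Frame of Reference
UID, asserting that the inputs were already coregistered (no registration
is performed or checked):

- **MR series** — each structural NIfTI becomes a classic single-frame MR
  Image Storage series. The voxel-to-world affine `A` (RAS mm, voxel
  centers) is decomposed into DICOM slice geometry in LPS: direction
  cosines from the normalized columns of `A`, `PixelSpacing`/slice
  spacing from the column norms, per-slice `ImagePositionPatient` from
  `A·(0,0,k,1)` with the first two coordinates negated (RAS→LPS).
  Intensities are stored as 16-bit pixels under a rescale mapping
  `value = stored × slope + intercept`; integer-valued volumes with range
  < 2¹⁶ are stored losslessly, arbitrary float volumes with error ≤ slope/2.
- **Segmentation (SEG) objects** — each label image (up to 30 distinct
  nonzero integer values, each mapped to a distinct color) becomes one
  Segmentation object: one segment per label value, one frame per
  (segment, occupied slice), frames compressed with DICOM's packbits-style
  run-length encoding (RLE Lossless transfer syntax), each frame carrying
  a derivation reference to the structural series whose grid the label
  image matches exactly.
- **Surface objects** — each tractogram becomes a Surface Segmentation
  object holding one shared 32-bit point list (LPS mm) and one Line
  Sequence polyline primitive per streamline, indexed 1-based. Tract
  objects are marked as deriving from the *first* structural image listed.

Patient and institutional attributes are copied from a "template" DICOM
file of the session under a closed whitelist, so the converted objects
attach to the correct patient record without leaking acquisition
parameters that would misdescribe derived data.

## Worked example

Generate a synthetic workup (geometric phantoms with realistic geometry),
then convert it:

```sh
tract2dicom make-fixtures --output-dir demo --seed 42
importTractography \
    --dicom-template demo/template.dcm \
    --nifti demo/t1.nii.gz --nifti demo/fa.nii.gz \
    --tract-files demo/cst_left.tck --tract-files demo/or_left.tck \
    --label-files demo/tumour.nii.gz \
    --output-dir out
```

which logs:

```
INFO tract2dicom.mr_series_writer: demo/t1.nii.gz -> MR series ... (32 slices)
INFO tract2dicom.mr_series_writer: demo/fa.nii.gz -> MR series ... (32 slices)
INFO tract2dicom.surface_tract_writer: demo/cst_left.tck -> Surface object: 50 streamlines, 1023 points
INFO tract2dicom.surface_tract_writer: demo/or_left.tck -> Surface object: 40 streamlines, 879 points
INFO tract2dicom.seg_label_writer: demo/tumour.nii.gz -> SEG object with 3 segments, 31 frames
INFO tract2dicom: wrote 67 DICOM files to out
```

The two 32-slice volumes become 64 single-frame MR files, the two
tractograms become two Surface objects, and the three-label mask becomes
one SEG object with three distinctly colored segments and 31 RLE frames
(one per segment per occupied slice) — 67 Part-10 files plus
`out/manifest.json`, which records every input→output mapping, every UID
and every decision taken (affine source, slice-order flips, warnings).
All 67 objects carry the same Frame of Reference UID, so an importing
suite fuses them without registration.

Flags: `--dicom-template`, `--nifti` (repeatable; first one is the
derivation source for tracts), `--tract-files`, `--label-files`,
`--output-dir`, plus extensions `--seed` (deterministic UIDs),
`--strict/--lenient` (tck count-mismatch handling), `--new-study-uid`,
`--label-names` (JSON value→name map) and `--fixed-datetime`.
Exit codes: 0 success, 2 usage, 3 input format, 4 geometry.

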