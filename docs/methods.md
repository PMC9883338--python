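# Methods

## Problem and model

The converter maps a neurosurgical imaging workup produced by research
software — mutually coregistered 3D NIfTI volumes, NIfTI integer label
images, and MRtrix `.tck` streamline files in scanner-space millimetres —
onto three DICOM object families: classic single-frame MR Image Storage,
Segmentation (SEG) objects, and Surface Segmentation objects carrying
polylines. The central modelling assumption is taken from the workup
itself: **all inputs are already coregistered**. The converter therefore
never resamples, reorients or registers anything; it only re-expresses
the same geometry in DICOM terms and stamps every emitted object with one
shared Frame of Reference UID. Anything that would silently alter data
destined for surgical navigation (shear resampling, label rounding,
streamline truncation) is a hard error instead.

## Coordinate conventions

NIfTI affines map voxel indices to RAS millimetres with index (0,0,0) at
the first voxel's center; DICOM's patient coordinate system is LPS and
`ImagePositionPatient` addresses the center of the first transmitted
pixel. Both address voxel centers, so the conversion is exactly
RAS→LPS (negate the first two coordinates) with no half-voxel shift.

The affine decomposition assigns voxel axis 0 to the DICOM row direction
(increasing column index), axis 1 to the column direction and axis 2 to
the slice axis; no axis permutation is performed, which keeps the mapping
bijective and auditable. Axes must be orthogonal: the tolerance is
|dot(unit axes)| ≤ 1e-4, beyond which the grid is refused as sheared.
Left-handed grids (negative affine determinant) are exported by reversing
the in-memory slice order — one flip always restores right-handedness —
with the affine translation updated so every voxel's world position is
unchanged; the flip is recorded in the run manifest. sform is preferred
over qform when both are present, and the choice is logged.

## Intensity encoding

MR pixels are stored as unsigned 16-bit with a rescale mapping
`value = stored × slope + intercept`. Volumes whose finite values are all
integral with range < 2¹⁶ use slope 1 and intercept = min, so decoding is
exact — the common case for masks, label-derived maps and most structural
data. Other volumes map min→0, max→65535 (slope = range/65535,
intercept = min), bounding the decoding error by slope/2. A constant
volume stores zeros with slope 1 and intercept equal to the constant.
Non-finite voxels are mapped to the minimum and counted in a logged
warning. Slope and intercept are rounded to their DICOM DS string
representation *before* quantization so writer and reader use identical
values.

## Segmentation objects

Each distinct nonzero label value becomes one segment; segment numbers
are consecutive from 1 in ascending label-value order, which makes the
value→segment mapping stable under any permutation of voxel order. The
original label value is preserved machine-readably in
`SegmentDescription` (`label_value=N`) so the integer array can be
recomposed exactly. Display colors come from a fixed 30-entry palette
(golden-angle hue walk at two saturation/value levels, converted to
DICOM-scaled CIELab), deterministic across runs and sites; 31 or more
labels is an error, not a truncation.

Frames are binary masks stored one byte per pixel and compressed with the
DICOM packbits-style run-length codec (RLE Lossless transfer syntax):
literal runs use control bytes 0–127 (length−1), replicate runs use
257−length for lengths 2–128, payloads carry the standard 64-byte offset
header and are padded to even length. One byte per pixel is used because
this RLE operates on 8-bit samples and is incompatible with 1-bit packed
frames. Frames are emitted only for slices where a segment is non-empty,
with explicit per-frame plane positions and derivation references to the
matching MR instances.

A label image must match one structural image's grid — shape and full
voxel-to-world affine within 1e-3 mm. Matching the origin as well as
spacing and orientation is deliberate: it guarantees one-to-one slice
correspondence for the per-frame references. The first geometric match in
input order wins when several structurals qualify.

## Surface objects

Streamlines are written into a Surface Segmentation object: one shared
point list in LPS at 32-bit precision (the native tck precision — no
resampling, decimation or merging) and one Line Sequence primitive per
streamline whose 1-based indices form a contiguous run; the runs
partition the point list exactly. One object is written per tck file,
with a recommended display color drawn from the same palette in input
order (viewers that color by local streamline orientation will override
it). Tract objects reference the first structural series as their
derivation source, which is what navigation software uses to associate
them with an image before the shared frame of reference is accepted.
Surface Segmentation Storage was chosen as the SOP class because it is
the SEG-modality IOD that carries the Surface Mesh information entity.

## tck reading

The reader accepts Float32LE (the common case) plus Float32BE and
Float64LE/BE, converting to float64 internally; other datatypes are
rejected. NaN triplets delimit streamlines and the +Inf triplet ends the
stream; neither ever appears in point data, and a missing terminator is a
corrupt-file error. A mismatch between the header `count` and the stored
streamline count is an error by default and a warning under `--lenient` —
the strict default exists because silent truncation is the failure mode
that matters in this application. Header keys are preserved verbatim for
provenance. Single-point streamlines are kept.

## UIDs, studies, reproducibility

By default UIDs are UUID-derived under the `2.25.` root, globally unique
across runs. With `--seed`, UIDs come from a deterministic counter under
a registered prefix, and `--fixed-datetime` freezes date/time attributes;
together they make a run byte-reproducible, which the test suite checks.
The study UID is copied from the template so converted objects join the
original study — the behaviour implied by using a template from the
session being analysed — and `--new-study-uid` mints a fresh study for
sites that prefer separation. The template tag whitelist (patient
identity, study identity/description, accession, institution, referring
physician) is closed; nothing else is ever propagated.

## Synthetic data

The fixture generators emulate the *structure* of a workup, not its
anatomy: gradient/sphere/noise phantoms on configurable affines
(identity, anisotropic, rotated, left-handed), disjoint spherical label
blobs on a lattice (1–30 labels, plus an over-limit mode to exercise the
error path), analytic helical streamlines with closed-form coordinates,
and a minimal template DICOM. Everything is deterministic under a seed.
Passing tests on these fixtures demonstrates geometric, intensity and
topological fidelity of the conversion; they say nothing about anatomical
plausibility, scanner artefacts, or the behaviour of any particular
vendor's import module, which can only be assessed on site.

Problem sizes in the tests and the acceptance script (grids ≤ 64³,
≤ 100 streamlines per tractogram, 100-replicate geometry and round-trip
sweeps) were chosen so the whole suite completes in well under a minute
on a single CPU while still covering the full 30-label capacity and all
affine families.

## Numerical choices and degenerate inputs

- Orthogonality tolerance 1e-4 (dot of unit axes); geometry match
  tolerance 1e-3 mm; voxel-center reconstruction is verified to < 1e-3 mm
  and in practice is exact to ~1e-14.
- Direction cosines are re-normalized after the RAS→LPS flip to keep
  unit norm at 1e-6.
- Constant-valued volumes, single-voxel labels, single-point streamlines
  and empty tractograms all have defined behaviour (see above; the last
  is an error since an empty surface object is meaningless).
- All-zero label images are rejected: an empty segmentation is more
  likely a pipeline mistake than an intent.

## Known limitations

- Enhanced (multi-frame) MR, fractional/probability segmentations,
  overlapping segments beyond one frame set per segment, and triangulated
  tube meshes around streamlines are out of scope.
- The SEG frames store 8-bit samples under binary semantics to satisfy
  run-length compression; strict readers expecting 1-bit binary
  segmentations will see a benign type deviation.
- DICOM is written, never analysed: the template loader copies whitelisted
  tags and nothing more, and no DICOM→NIfTI path exists.
- No network transfer (C-STORE), no vendor-private tags, no GUI.
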