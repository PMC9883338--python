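"""DICOM Segmentation objects from integer label images.

Each distinct nonzero label value becomes one segment with a distinct,
deterministic display color; each (segment, occupied slice) pair becomes
one frame, run-length encoded with the DICOM packbits-style codec and
stored under the RLE Lossless transfer syntax.  Frames carry explicit
plane positions and derivation references to the geometry-matched MR
series, so navigation software can overlay the regions on the converted
images without registration.

Up to 30 labels are supported per image; more is an error rather than a
silent merge.  RLE operates on 8-bit samples, so segment masks are stored
one byte per pixel with binary (0/1) semantics — Annex-G RLE and 1-bit
packed frames are mutually exclusive.
"""

from __future__ import annotations

import colorsys
import logging
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pydicom.dataset import Dataset
from pydicom.encaps import encapsulate, generate_frames
from pydicom.sequence import Sequence
from pydicom.uid import RLELossless

from .errors import (
    CorruptFrameError,
    EmptyLabelMapError,
    InvalidInputError,
    NoMatchingReferenceError,
    TooManyLabelsError,
)
from .geometry import (
    ImageVolume,
    affine_to_slice_geometry,
    flip_to_right_handed,
    geometry_matches,
)
from .mr_series_writer import (
    SeriesContext,
    TemplateMetadata,
    new_derived_dataset,
)

logger = logging.getLogger(__name__)

SEGMENTATION_STORAGE = "1.2.840.10008.5.1.4.1.1.66.4"
MAX_LABELS = 30


# ---------------------------------------------------------------------------
# color palette

def _build_palette(n: int = MAX_LABELS):
    """Fixed palette of maximally separated colors: golden-angle hue walk
    at two saturation/value levels.  Deterministic across runs and sites."""
    colors = []
    golden = 0.6180339887498949
    h = 0.0
    for i in range(n):
        h = (h + golden) % 1.0
        s, v = (0.9, 0.95) if i % 2 == 0 else (0.65, 0.75)
        rgb = colorsys.hsv_to_rgb(h, s, v)
        colors.append(tuple(int(round(255 * c)) for c in rgb))
    return tuple(colors)


PALETTE = _build_palette()


def assign_segment_colors(n: int):
    """Return ``n`` pairwise-distinct RGB colors (deterministic)."""
    if n < 1:
        raise InvalidInputError(f"need at least one segment, got {n}")
    if n > MAX_LABELS:
        raise TooManyLabelsError(
            f"{n} labels requested; label images support up to "
            f"{MAX_LABELS} distinct nonzero values")
    return list(PALETTE[:n])


def rgb_to_cielab_scaled(rgb):
    """sRGB (0-255) -> CIELab, scaled to the 16-bit DICOM PCS encoding
    (L*: 0..65535 over 0..100; a*, b*: 0..65535 over -128..127)."""
    r, g, b = (c / 255.0 for c in rgb)

    def lin(c):
        return c / 12.92 if c <= 0.04045 else ((c + 0.055) / 1.055) ** 2.4

    rl, gl, bl = lin(r), lin(g), lin(b)
    # sRGB D65 reference white
    x = 0.4124564 * rl + 0.3575761 * gl + 0.1804375 * bl
    y = 0.2126729 * rl + 0.7151522 * gl + 0.0721750 * bl
    z = 0.0193339 * rl + 0.1191920 * gl + 0.9503041 * bl
    xn, yn, zn = 0.95047, 1.0, 1.08883

    def f(t):
        return t ** (1 / 3) if t > 0.008856 else 7.787 * t + 16.0 / 116.0

    fx, fy, fz = f(x / xn), f(y / yn), f(z / zn)
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    bb = 200.0 * (fy - fz)
    scale = lambda v, lo, hi: int(round(min(max((v - lo) / (hi - lo), 0), 1) * 65535))
    return (scale(L, 0.0, 100.0), scale(a, -128.0, 127.0), scale(bb, -128.0, 127.0))


@dataclass
class SegmentDescriptor:
    segment_number: int  # 1-based, consecutive in ascending label value order
    label_value: int
    color: tuple  # RGB 0-255
    cielab: tuple  # DICOM-scaled CIELab
    label_text: str


# ---------------------------------------------------------------------------
# Annex-G style RLE codec (packbits on 8-bit samples)

RLE_HEADER_SIZE = 64
MAX_RLE_SEGMENTS = 15


@dataclass
class RLEFrame:
    payload: bytes  # 64-byte header + encoded segment(s), even length
    segment_count: int
    decoded_length: int


def _packbits_encode(data: bytes) -> bytes:
    """Literal runs: control 0..127 = length-1 literal bytes follow.
    Replicate runs: control 257-length for run lengths 2..128."""
    out = bytearray()
    i = 0
    n = len(data)
    literal_start = None

    def flush_literal(end):
        nonlocal literal_start
        if literal_start is None:
            return
        j = literal_start
        while j < end:
            chunk = data[j:min(j + 128, end)]
            out.append(len(chunk) - 1)
            out.extend(chunk)
            j += len(chunk)
        literal_start = None

    while i < n:
        run = 1
        while i + run < n and run < 128 and data[i + run] == data[i]:
            run += 1
        if run >= 2:
            flush_literal(i)
            out.append(257 - run)
            out.append(data[i])
            i += run
        else:
            if literal_start is None:
                literal_start = i
            i += 1
    flush_literal(n)
    return bytes(out)


def _packbits_decode(data: bytes, expected: int | None = None) -> bytes:
    out = bytearray()
    i = 0
    n = len(data)
    while i < n:
        if expected is not None and len(out) >= expected:
            break  # remaining bytes are padding
        control = data[i]
        i += 1
        if control <= 127:
            count = control + 1
            if i + count > n:
                raise CorruptFrameError("payload ends mid literal run")
            out.extend(data[i:i + count])
            i += count
        elif control >= 129:
            if i >= n:
                raise CorruptFrameError("payload ends mid replicate run")
            out.extend(bytes([data[i]]) * (257 - control))
            i += 1
        # control == 128: no-op, reserved
    return bytes(out)


def rle_encode_frame(frame: bytes) -> RLEFrame:
    """Encode one frame of 8-bit samples as a single-segment RLE stream
    with the standard 64-byte offset header, padded to even length."""
    frame = bytes(frame)
    if len(frame) == 0:
        raise InvalidInputError("cannot RLE-encode an empty frame")
    encoded = _packbits_encode(frame)
    header = struct.pack("<16L", 1, RLE_HEADER_SIZE, *([0] * 14))
    payload = header + encoded
    if len(payload) % 2:
        payload += b"\x00"
    return RLEFrame(payload=payload, segment_count=1,
                    decoded_length=len(frame))


def rle_decode_frame(encoded, expected_length: int | None = None) -> bytes:
    """Decode an RLE frame (bytes or :class:`RLEFrame`) back to raw samples.

    Tolerates the trailing pad byte; malformed headers or control streams
    raise :class:`CorruptFrameError`.
    """
    if isinstance(encoded, RLEFrame):
        expected_length = expected_length or encoded.decoded_length
        encoded = encoded.payload
    data = bytes(encoded)
    if len(data) < RLE_HEADER_SIZE:
        raise CorruptFrameError("RLE frame shorter than its 64-byte header")
    offsets = struct.unpack("<16L", data[:RLE_HEADER_SIZE])
    n_segments = offsets[0]
    if not 1 <= n_segments <= MAX_RLE_SEGMENTS:
        raise CorruptFrameError(f"invalid RLE segment count {n_segments}")
    seg_offsets = [o for o in offsets[1:1 + n_segments]]
    for o in seg_offsets:
        if o < RLE_HEADER_SIZE or o > len(data):
            raise CorruptFrameError(f"RLE segment offset {o} out of range")
    per_segment = (None if expected_length is None
                   else expected_length // n_segments)
    out = b""
    for s, start in enumerate(seg_offsets):
        end = seg_offsets[s + 1] if s + 1 < n_segments else len(data)
        out += _packbits_decode(data[start:end], per_segment)
    if expected_length is not None and len(out) < expected_length:
        raise CorruptFrameError(
            f"decoded {len(out)} bytes, expected {expected_length}")
    return out


# ---------------------------------------------------------------------------
# label map -> SEG object

@dataclass
class LabelMap:
    """3D non-negative integer label image with its RAS affine."""

    data: np.ndarray
    affine: np.ndarray
    source_path: str = ""

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise InvalidInputError(
                f"{self.source_path or 'label map'}: label image must be 3D")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("label image contains non-finite values")
        if np.any(arr != np.rint(arr)):
            raise InvalidInputError(
                f"{self.source_path or 'label map'}: non-integer label values "
                "are rejected rather than rounded")
        arr = np.rint(arr).astype(np.int64)
        if arr.min() < 0:
            raise InvalidInputError("label values must be non-negative")
        if arr.max() >= 2**16:
            raise InvalidInputError("label values must fit in 16 bits")
        self.data = arr

    def label_values(self):
        vals = np.unique(self.data)
        return [int(v) for v in vals if v != 0]

    @classmethod
    def from_volume(cls, vol: ImageVolume) -> "LabelMap":
        return cls(data=vol.data, affine=vol.affine,
                   source_path=vol.source_path)


def describe_segments(values, names: dict | None = None):
    """Build :class:`SegmentDescriptor` objects: segment numbers are
    consecutive from 1 in ascending label-value order."""
    values = sorted(int(v) for v in values)
    if len(values) == 0:
        raise EmptyLabelMapError("label image contains no nonzero voxels")
    if len(values) > MAX_LABELS:
        raise TooManyLabelsError(
            f"{len(values)} distinct nonzero values; label images support "
            f"up to {MAX_LABELS} labels")
    colors = assign_segment_colors(len(values))
    descriptors = []
    for i, v in enumerate(values):
        text = (names or {}).get(v) or (names or {}).get(str(v)) or f"Label {v}"
        descriptors.append(SegmentDescriptor(
            segment_number=i + 1, label_value=v, color=colors[i],
            cielab=rgb_to_cielab_scaled(colors[i]), label_text=text))
    return descriptors


def _reference_geometry(reference):
    """Slice geometry implied by an emitted MR instance list."""
    inst = sorted(reference, key=lambda d: int(d.InstanceNumber))
    first = inst[0]
    return inst, np.asarray(first.ImageOrientationPatient, dtype=float), [
        np.asarray(ds.ImagePositionPatient, dtype=float) for ds in inst]


def labelmap_to_seg(labels: LabelMap, reference, meta: TemplateMetadata,
                    ctx: SeriesContext, names: dict | None = None) -> Dataset:
    """Convert a label map into one DICOM Segmentation object.

    ``reference`` is the MR instance list (from ``volume_to_mr_series``)
    whose grid the labels annotate; shape, spacing, orientation and origin
    must agree within 1e-3 or :class:`NoMatchingReferenceError` is raised.
    Frames are emitted only for slices where a segment is non-empty.
    """
    data, affine, _ = flip_to_right_handed(labels.data, labels.affine)
    geom = affine_to_slice_geometry(affine, data.shape)
    inst, ref_orient, ref_positions = _reference_geometry(reference)
    rows, columns, n_slices = geom.shape
    if (len(inst) != n_slices
            or int(inst[0].Rows) != rows or int(inst[0].Columns) != columns
            or np.max(np.abs(ref_orient - geom.orientation)) > 1e-3
            or max(np.max(np.abs(p - q)) for p, q in
                   zip(ref_positions, geom.positions)) > 1e-3
            or abs(float(inst[0].PixelSpacing[0]) - geom.pixel_spacing[0]) > 1e-3
            or abs(float(inst[0].PixelSpacing[1]) - geom.pixel_spacing[1]) > 1e-3):
        raise NoMatchingReferenceError(
            f"{labels.source_path or 'label map'}: grid does not match the "
            "reference series (voxel size, spacing and orientation must agree)")

    descriptors = describe_segments(np.unique(data[data != 0]), names)

    ds = new_derived_dataset(SEGMENTATION_STORAGE, "SEG", meta, ctx,
                             transfer_syntax=RLELossless)
    ds.SeriesInstanceUID = ctx.new_uid()
    ds.SeriesNumber = ctx.new_series_number()
    ds.SeriesDescription = (Path(labels.source_path).name
                            if labels.source_path else "label map")[:64]
    ds.InstanceNumber = 1
    ds.ImageType = ["DERIVED", "PRIMARY"]
    ds.ContentLabel = "SEGMENTATION"
    ds.ContentDescription = "Converted label image"
    ds.ContentCreatorName = "tract2dicom"
    ds.LossyImageCompression = "00"
    ds.SegmentationType = "BINARY"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows = rows
    ds.Columns = columns
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0

    ref_series = Dataset()
    ref_series.SeriesInstanceUID = inst[0].SeriesInstanceUID
    ref_series.ReferencedInstanceSequence = Sequence()
    for r in inst:
        item = Dataset()
        item.ReferencedSOPClassUID = r.SOPClassUID
        item.ReferencedSOPInstanceUID = r.SOPInstanceUID
        ref_series.ReferencedInstanceSequence.append(item)
    ds.ReferencedSeriesSequence = Sequence([ref_series])

    seg_seq = Sequence()
    for d in descriptors:
        s = Dataset()
        s.SegmentNumber = d.segment_number
        s.SegmentLabel = d.label_text
        s.SegmentDescription = f"label_value={d.label_value}"
        s.SegmentAlgorithmType = "SEMIAUTOMATIC"
        s.SegmentAlgorithmName = "external"
        s.RecommendedDisplayCIELabValue = list(d.cielab)
        cat = Dataset()
        cat.CodeValue = "T-D0050"
        cat.CodingSchemeDesignator = "SRT"
        cat.CodeMeaning = "Tissue"
        s.SegmentedPropertyCategoryCodeSequence = Sequence([cat])
        typ = Dataset()
        typ.CodeValue = "T-D0050"
        typ.CodingSchemeDesignator = "SRT"
        typ.CodeMeaning = "Tissue"
        s.SegmentedPropertyTypeCodeSequence = Sequence([typ])
        seg_seq.append(s)
    ds.SegmentSequence = seg_seq

    shared = Dataset()
    orient = Dataset()
    orient.ImageOrientationPatient = [float(v) for v in geom.orientation]
    shared.PlaneOrientationSequence = Sequence([orient])
    measures = Dataset()
    measures.PixelSpacing = [float(geom.pixel_spacing[0]),
                             float(geom.pixel_spacing[1])]
    measures.SliceThickness = float(geom.slice_spacing)
    measures.SpacingBetweenSlices = float(geom.slice_spacing)
    shared.PixelMeasuresSequence = Sequence([measures])
    ds.SharedFunctionalGroupsSequence = Sequence([shared])

    frames = []
    per_frame = Sequence()
    frame_size = rows * columns
    for d in descriptors:
        mask3d = (data == d.label_value)
        for k in range(n_slices):
            sl = mask3d[:, :, k]
            if not sl.any():
                continue
            frame_bytes = np.ascontiguousarray(
                sl.T.astype(np.uint8)).tobytes()
            assert len(frame_bytes) == frame_size
            frames.append(frame_bytes)

            fg = Dataset()
            deriv = Dataset()
            code = Dataset()
            code.CodeValue = "113076"
            code.CodingSchemeDesignator = "DCM"
            code.CodeMeaning = "Segmentation"
            deriv.DerivationCodeSequence = Sequence([code])
            src = Dataset()
            src.ReferencedSOPClassUID = inst[k].SOPClassUID
            src.ReferencedSOPInstanceUID = inst[k].SOPInstanceUID
            purpose = Dataset()
            purpose.CodeValue = "121322"
            purpose.CodingSchemeDesignator = "DCM"
            purpose.CodeMeaning = "Source image for image processing operation"
            src.PurposeOfReferenceCodeSequence = Sequence([purpose])
            deriv.SourceImageSequence = Sequence([src])
            fg.DerivationImageSequence = Sequence([deriv])
            fc = Dataset()
            fc.DimensionIndexValues = [d.segment_number, k + 1]
            fg.FrameContentSequence = Sequence([fc])
            pp = Dataset()
            pp.ImagePositionPatient = [float(v) for v in geom.positions[k]]
            fg.PlanePositionSequence = Sequence([pp])
            sid = Dataset()
            sid.ReferencedSegmentNumber = d.segment_number
            fg.SegmentIdentificationSequence = Sequence([sid])
            per_frame.append(fg)
    ds.PerFrameFunctionalGroupsSequence = per_frame
    ds.NumberOfFrames = len(frames)

    dim_org_uid = ctx.new_uid()
    org = Dataset()
    org.DimensionOrganizationUID = dim_org_uid
    ds.DimensionOrganizationSequence = Sequence([org])
    dims = Sequence()
    for pointer, group in ((0x00620004, 0x00620002), (0x00200032, 0x00209113)):
        d_item = Dataset()
        d_item.DimensionOrganizationUID = dim_org_uid
        d_item.DimensionIndexPointer = pointer
        d_item.FunctionalGroupPointer = group
        dims.append(d_item)
    ds.DimensionIndexSequence = dims

    encoded = [rle_encode_frame(f).payload for f in frames]
    ds.PixelData = encapsulate(encoded)
    ds["PixelData"].VR = "OB"
    logger.info("%s -> SEG object with %d segments, %d frames",
                labels.source_path or "label map", len(descriptors), len(frames))
    return ds


def seg_to_labelmap(ds: Dataset, reference, decoder=None) -> np.ndarray:
    """Recompose the integer label array from an emitted SEG object.

    Validation utility: frames are decoded with this module's RLE decoder
    by default (pass ``decoder`` to substitute an independent one), then
    placed by their plane position — located against the ``reference`` MR
    instances — and their segment number.  Original label values are
    recovered from the machine-readable SegmentDescription.
    """
    rows, columns = int(ds.Rows), int(ds.Columns)
    orientation = np.asarray(
        ds.SharedFunctionalGroupsSequence[0]
        .PlaneOrientationSequence[0].ImageOrientationPatient, dtype=float)
    value_of = {}
    for s in ds.SegmentSequence:
        desc = str(getattr(s, "SegmentDescription", ""))
        value = None
        if desc.startswith("label_value="):
            value = int(desc.split("=", 1)[1])
        value_of[int(s.SegmentNumber)] = (
            value if value is not None else int(s.SegmentNumber))

    inst = sorted(reference, key=lambda d: int(d.InstanceNumber))
    normal = np.cross(orientation[:3], orientation[3:])
    ref_offsets = [float(np.dot(np.asarray(d.ImagePositionPatient, dtype=float),
                                normal)) for d in inst]

    def slice_index(position):
        off = float(np.dot(position, normal))
        k = int(np.argmin([abs(off - r) for r in ref_offsets]))
        if abs(off - ref_offsets[k]) > 1e-3:
            raise CorruptFrameError(
                f"frame plane position {position} matches no reference slice")
        return k

    decode = decoder or (lambda b: rle_decode_frame(b, rows * columns))
    raw_frames = list(generate_frames(ds.PixelData,
                                      number_of_frames=int(ds.NumberOfFrames)))
    out = np.zeros((columns, rows, len(inst)), dtype=np.int64)
    for frame, fg in zip(raw_frames, ds.PerFrameFunctionalGroupsSequence):
        seg_no = int(fg.SegmentIdentificationSequence[0]
                     .ReferencedSegmentNumber)
        pos = np.asarray(fg.PlanePositionSequence[0].ImagePositionPatient,
                         dtype=float)
        decoded = decode(frame)[: rows * columns]
        mask = np.frombuffer(decoded, dtype=np.uint8).reshape(rows, columns).T
        out[:, :, slice_index(pos)][mask > 0] = value_of[seg_no]
    return out
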