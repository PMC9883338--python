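"""Minimal conformance checklist for the objects this package emits.

Re-reads emitted Part-10 files with pydicom and verifies that the
attributes required for each supported SOP class are present and
non-empty, that UIDs are well-formed, and that pixel-bearing objects can
actually be decoded.  This is a safety net for the export path, not a
general DICOM validator.
"""

from __future__ import annotations

import pydicom

from .errors import CorruptObjectError
from .mr_series_writer import MR_IMAGE_STORAGE, is_valid_uid
from .seg_label_writer import SEGMENTATION_STORAGE
from .surface_tract_writer import SURFACE_SEGMENTATION_STORAGE

_COMMON = (
    "SOPClassUID", "SOPInstanceUID", "StudyInstanceUID", "SeriesInstanceUID",
    "FrameOfReferenceUID", "Modality", "PatientName", "PatientID",
)

REQUIRED = {
    MR_IMAGE_STORAGE: _COMMON + (
        "ImageOrientationPatient", "ImagePositionPatient", "PixelSpacing",
        "Rows", "Columns", "BitsAllocated", "BitsStored", "HighBit",
        "SamplesPerPixel", "PhotometricInterpretation", "PixelData",
        "RescaleSlope", "RescaleIntercept", "ScanningSequence",
        "SequenceVariant", "InstanceNumber",
    ),
    SEGMENTATION_STORAGE: _COMMON + (
        "SegmentationType", "SegmentSequence", "NumberOfFrames",
        "SharedFunctionalGroupsSequence", "PerFrameFunctionalGroupsSequence",
        "Rows", "Columns", "PixelData", "ReferencedSeriesSequence",
    ),
    SURFACE_SEGMENTATION_STORAGE: _COMMON + (
        "SurfaceCount", "SurfaceSequence", "SegmentSequence",
        "ReferencedSeriesSequence",
    ),
}


def check_dataset(ds) -> list:
    """Return a list of conformance problems (empty == passes)."""
    problems = []
    sop_class = str(getattr(ds, "SOPClassUID", ""))
    required = REQUIRED.get(sop_class)
    if required is None:
        return [f"unexpected SOP class {sop_class!r}"]
    for keyword in required:
        if keyword not in ds:
            problems.append(f"missing {keyword}")
            continue
        value = ds[keyword].value
        if value is None or (isinstance(value, str) and value == ""):
            problems.append(f"empty {keyword}")
    for kw in ("SOPInstanceUID", "StudyInstanceUID", "SeriesInstanceUID",
               "FrameOfReferenceUID"):
        uid = str(getattr(ds, kw, ""))
        if uid and not is_valid_uid(uid):
            problems.append(f"malformed UID in {kw}: {uid!r}")
    if "PixelData" in ds:
        try:
            ds.pixel_array
        except Exception as exc:  # decoding failure of any kind
            problems.append(f"undecodable PixelData: {exc}")
    return problems


def check_file(path) -> list:
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:
        return [f"{path}: unreadable ({exc})"]
    return [f"{path}: {p}" for p in check_dataset(ds)]


def assert_conformant(paths) -> None:
    problems = []
    for p in paths:
        problems.extend(check_file(p))
    if problems:
        raise CorruptObjectError("; ".join(problems))
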