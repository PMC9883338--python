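"""Emit classic single-frame MR Image Storage series from NIfTI volumes.

Every converted object of one run — MR slices, segmentations, surface
objects — carries the same Frame of Reference UID so the navigation suite
treats them as spatially fused without further registration.  Patient and
institutional attributes come from a "template" DICOM file taken from the
session being analysed; the tag whitelist is explicit and closed so that
acquisition parameters which would misdescribe derived images are never
propagated.

Classic single-frame MR (one Part-10 file per slice) is written rather
than Enhanced MR because it is the representation most reliably imported
by commercial navigation suites.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import FormatError, InvalidInputError, UnsupportedInputError
from .geometry import (
    ImageVolume,
    affine_to_slice_geometry,
    flip_to_right_handed,
)

logger = logging.getLogger(__name__)

MR_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.4"

#: The closed whitelist of attributes copied from the template file.
TEMPLATE_WHITELIST = (
    "PatientName",
    "PatientID",
    "PatientBirthDate",
    "PatientSex",
    "StudyDate",
    "StudyTime",
    "StudyDescription",
    "AccessionNumber",
    "InstitutionName",
    "ReferringPhysicianName",
    "StudyInstanceUID",
)

#: Default deterministic UID prefix (pydicom's registered root); random
#: UIDs use the UUID-derived "2.25." scheme instead.
DEFAULT_UID_ROOT = "1.2.826.0.1.3680043.8.498."


@dataclass
class TemplateMetadata:
    """Whitelisted patient/study/institution attributes from the template."""

    attributes: dict = field(default_factory=dict)

    def apply(self, ds: Dataset) -> None:
        for keyword, value in self.attributes.items():
            if keyword == "StudyInstanceUID":
                continue  # study placement is the SeriesContext's decision
            setattr(ds, keyword, value)


def load_template(path) -> TemplateMetadata:
    """Copy the whitelisted attributes out of a template DICOM Part-10 file.

    Absent optional attributes are simply omitted; anything outside the
    whitelist — pixel data included — is never read into the result.
    """
    try:
        ds = pydicom.dcmread(str(path), stop_before_pixels=True)
    except (pydicom.errors.InvalidDicomError, ValueError, EOFError) as exc:
        raise FormatError(f"{path}: not a readable DICOM file ({exc})") from exc
    attrs = {}
    for keyword in TEMPLATE_WHITELIST:
        if keyword in ds and ds[keyword].value not in (None, ""):
            attrs[keyword] = ds[keyword].value
    return TemplateMetadata(attributes=attrs)


def is_valid_uid(uid: str) -> bool:
    if not uid or len(uid) > 64:
        return False
    parts = uid.split(".")
    for p in parts:
        if not p.isdigit():
            return False
        if len(p) > 1 and p[0] == "0":
            return False
    return True


@dataclass
class SeriesContext:
    """Study/frame-of-reference state shared by every object of one run.

    With ``rng_seed`` set, UIDs come from a deterministic counter under
    ``uid_root`` so repeated runs are reproducible (intended for testing);
    otherwise UUID-derived ``2.25.`` UIDs guarantee global uniqueness.
    ``fixed_datetime`` freezes the date/time attributes stamped on output,
    again for byte-reproducible test runs.
    """

    study_uid: str = ""
    frame_of_reference_uid: str = ""
    uid_root: str = DEFAULT_UID_ROOT
    rng_seed: int | None = None
    next_series_number: int = 1
    fixed_datetime: datetime.datetime | None = None
    _uid_counter: int = 0

    def new_uid(self) -> str:
        if self.rng_seed is None:
            uid = generate_uid(prefix=None)  # "2.25." + UUID integer
        else:
            self._uid_counter += 1
            uid = f"{self.uid_root}{abs(self.rng_seed)}.{self._uid_counter}"
        if not is_valid_uid(uid):
            raise InvalidInputError(f"generated invalid UID {uid!r}")
        return uid

    def new_series_number(self) -> int:
        n = self.next_series_number
        self.next_series_number += 1
        return n

    def timestamp(self):
        now = self.fixed_datetime or datetime.datetime.now()
        return now.strftime("%Y%m%d"), now.strftime("%H%M%S")

    @classmethod
    def create(
        cls,
        template: TemplateMetadata | None = None,
        rng_seed: int | None = None,
        new_study_uid: bool = False,
        fixed_datetime: datetime.datetime | None = None,
    ) -> "SeriesContext":
        ctx = cls(rng_seed=rng_seed, fixed_datetime=fixed_datetime)
        template_study = (template.attributes.get("StudyInstanceUID")
                          if template else None)
        if template_study and not new_study_uid:
            # join the original study so converted objects sit beside the
            # acquired series in the patient record
            ctx.study_uid = str(template_study)
        else:
            ctx.study_uid = ctx.new_uid()
        ctx.frame_of_reference_uid = ctx.new_uid()
        return ctx


@dataclass
class IntensityEncoding:
    """Affine mapping between stored 16-bit pixels and physical values.

    decoded = stored * slope + intercept.  Integer-valued volumes whose
    range fits in 16 bits use slope 1 so recovery is exact; arbitrary
    float volumes map min->0, max->65535 with error bounded by slope/2.
    """

    slope: float
    intercept: float
    stored_bits: int = 16
    nan_count: int = 0


def _ds_round(x: float) -> float:
    """Round to the precision of a DICOM DS string so the encoder and any
    reader use the identical value."""
    return float(f"{x:.10g}")


def compute_intensity_encoding(data: np.ndarray) -> tuple:
    """Derive the stored uint16 array and its :class:`IntensityEncoding`."""
    data = np.asarray(data, dtype=np.float64)
    nan_mask = ~np.isfinite(data)
    nan_count = int(nan_mask.sum())
    finite = data[~nan_mask]
    if finite.size == 0:
        raise InvalidInputError("volume has no finite voxels")
    lo = float(finite.min())
    hi = float(finite.max())
    if nan_count:
        logger.warning("%d non-finite voxels mapped to the minimum value %g",
                       nan_count, lo)
        data = np.where(nan_mask, lo, data)

    if hi == lo:
        enc = IntensityEncoding(slope=1.0, intercept=_ds_round(lo),
                                nan_count=nan_count)
        stored = np.zeros(data.shape, dtype=np.uint16)
        return stored, enc

    integral = bool(np.all(np.equal(np.mod(finite, 1.0), 0.0)))
    if integral and hi - lo < 2**16:
        slope, intercept = 1.0, _ds_round(lo)
    else:
        slope = _ds_round((hi - lo) / 65535.0)
        intercept = _ds_round(lo)
    stored = np.rint((data - intercept) / slope)
    stored = np.clip(stored, 0, 65535).astype(np.uint16)
    return stored, IntensityEncoding(slope=slope, intercept=intercept,
                                     nan_count=nan_count)


def _base_file_meta(sop_class_uid: str, sop_instance_uid: str,
                    transfer_syntax=ExplicitVRLittleEndian) -> FileMetaDataset:
    fm = FileMetaDataset()
    fm.MediaStorageSOPClassUID = sop_class_uid
    fm.MediaStorageSOPInstanceUID = sop_instance_uid
    fm.TransferSyntaxUID = transfer_syntax
    fm.ImplementationClassUID = pydicom.uid.PYDICOM_IMPLEMENTATION_UID
    return fm


def new_derived_dataset(sop_class_uid: str, modality: str,
                        meta: TemplateMetadata, ctx: SeriesContext,
                        transfer_syntax=ExplicitVRLittleEndian) -> Dataset:
    """Shared skeleton for every emitted object: template attributes,
    study/frame-of-reference placement, fresh SOP instance UID."""
    ds = Dataset()
    ds.SpecificCharacterSet = "ISO_IR 100"
    sop_uid = ctx.new_uid()
    ds.SOPClassUID = sop_class_uid
    ds.SOPInstanceUID = sop_uid
    ds.Modality = modality
    ds.Manufacturer = "tract2dicom"
    meta.apply(ds)
    ds.StudyInstanceUID = ctx.study_uid
    ds.FrameOfReferenceUID = ctx.frame_of_reference_uid
    ds.PositionReferenceIndicator = ""
    date, time = ctx.timestamp()
    ds.setdefault("StudyDate", date)
    ds.setdefault("StudyTime", time)
    ds.SeriesDate = date
    ds.SeriesTime = time
    ds.ContentDate = date
    ds.ContentTime = time
    for kw in ("PatientName", "PatientID", "PatientBirthDate", "PatientSex",
               "ReferringPhysicianName", "AccessionNumber", "StudyID"):
        ds.setdefault(kw, "")
    ds.file_meta = _base_file_meta(sop_class_uid, sop_uid, transfer_syntax)
    return ds


def volume_to_mr_series(vol: ImageVolume, meta: TemplateMetadata,
                        ctx: SeriesContext,
                        series_description: str = "") -> list:
    """Convert one 3D volume into a list of single-frame MR instances.

    One MR Image Storage dataset per slice, all sharing a fresh series UID
    and the context's frame-of-reference and study UIDs.  Instance numbers
    ascend along the slice axis consistently with the per-slice positions.
    Left-handed grids have their slice order reversed in memory first.
    """
    if vol.data.ndim != 3:
        raise UnsupportedInputError(
            "multiple component images, such as fMRI time series or raw "
            "diffusion data, are not supported")
    data, affine, flipped = flip_to_right_handed(vol.data, vol.affine)
    geom = affine_to_slice_geometry(affine, data.shape)
    stored, enc = compute_intensity_encoding(data)

    series_uid = ctx.new_uid()
    series_number = ctx.new_series_number()
    rows, columns, n_slices = geom.shape
    instances = []
    for k in range(n_slices):
        ds = new_derived_dataset(MR_IMAGE_STORAGE, "MR", meta, ctx)
        ds.SeriesInstanceUID = series_uid
        ds.SeriesNumber = series_number
        ds.SeriesDescription = (series_description or Path(
            vol.source_path).name or "converted volume")[:64]
        ds.InstanceNumber = k + 1
        ds.ImageType = ["DERIVED", "SECONDARY"]
        ds.ScanningSequence = "RM"
        ds.SequenceVariant = "NONE"
        ds.ScanOptions = ""
        ds.MRAcquisitionType = "3D"
        ds.RepetitionTime = ""
        ds.EchoTime = ""
        ds.EchoTrainLength = ""
        ds.PatientPosition = ""

        ds.ImageOrientationPatient = [float(v) for v in geom.orientation]
        ds.ImagePositionPatient = [float(v) for v in geom.positions[k]]
        ds.PixelSpacing = [float(geom.pixel_spacing[0]),
                           float(geom.pixel_spacing[1])]
        ds.SliceThickness = float(geom.slice_spacing)
        ds.SpacingBetweenSlices = float(geom.slice_spacing)

        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows = rows
        ds.Columns = columns
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = f"{enc.slope:.10g}"
        ds.RescaleIntercept = f"{enc.intercept:.10g}"
        ds.RescaleType = "US"
        # pixel array is rows x columns = voxel axes (1, 0)
        ds.PixelData = np.ascontiguousarray(stored[:, :, k].T).tobytes()
        instances.append(ds)
    logger.info("%s -> MR series %s (%d slices%s)", vol.source_path or "volume",
                series_uid, n_slices, ", slice order reversed" if flipped else "")
    return instances


def decode_mr_series(instances) -> tuple:
    """Re-assemble the physical-valued volume from emitted MR instances.

    Utility for validation: sorts by InstanceNumber, inverts the pixel
    layout and applies the rescale mapping.
    """
    inst = sorted(instances, key=lambda d: int(d.InstanceNumber))
    slices = []
    for ds in inst:
        arr = ds.pixel_array.astype(np.float64)
        arr = arr * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        slices.append(arr.T)  # back to (axis0, axis1)
    return np.stack(slices, axis=2), inst


def save_instances(instances, out_dir) -> list:
    """Write datasets as ``<series number>/<modality>.<instance>.dcm``."""
    out_dir = Path(out_dir)
    paths = []
    for ds in instances:
        sub = out_dir / str(ds.SeriesNumber)
        sub.mkdir(parents=True, exist_ok=True)
        number = int(getattr(ds, "InstanceNumber", 1) or 1)
        path = sub / f"{ds.Modality}.{number}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths
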