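"""Synthetic inputs shaped like a real neurosurgical workup.

A workup comprises coregistered structural NIfTI volumes, NIfTI label
images and MRtrix tck tractograms, plus a template DICOM file supplying
patient and institutional attributes.  Everything here is generated
deterministically from a seed so the full conversion pipeline can be
exercised with no external data.  The phantoms are geometric (balls,
gradients, helices), not anatomical: they probe grid geometry, intensity
and label fidelity, not tissue realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import InvalidInputError
from .geometry import ImageVolume, validate_affine
from .seg_label_writer import LabelMap
from .tck_io import Tractogram

MR_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.4"


@dataclass
class PhantomSpec:
    """Recipe for one deterministic phantom volume."""

    shape: tuple = (32, 32, 32)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    seed: int = 0
    content: str = "sphere"  # sphere | gradient | noise
    radius: float | None = None  # sphere radius in voxels; default min(shape)/4

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise InvalidInputError(f"shape must be a positive 3D extent, "
                                    f"got {self.shape}")
        self.affine = validate_affine(self.affine)


def make_phantom_volume(spec: PhantomSpec) -> ImageVolume:
    """Generate a reproducible test volume.

    * ``sphere`` — value 1000 inside the discrete ball of the given radius
      around the grid center ``c = (shape - 1) / 2`` (voxel (i,j,k) is
      inside iff ``(i-cx)^2 + (j-cy)^2 + (k-cz)^2 <= r^2``), 0 outside.
    * ``gradient`` — value at (i,j,k) is exactly ``i + 2*j + 3*k``.
    * ``noise`` — uniform integers in [0, 1000) from the seeded generator.
    """
    nx, ny, nz = spec.shape
    if spec.content == "sphere":
        r = spec.radius if spec.radius is not None else min(spec.shape) / 4.0
        c = (np.asarray(spec.shape, dtype=np.float64) - 1.0) / 2.0
        i, j, k = np.ogrid[:nx, :ny, :nz]
        inside = ((i - c[0]) ** 2 + (j - c[1]) ** 2 + (k - c[2]) ** 2) <= r * r
        data = np.where(inside, 1000.0, 0.0)
    elif spec.content == "gradient":
        i, j, k = np.ogrid[:nx, :ny, :nz]
        data = (i + 2 * j + 3 * k).astype(np.float64) + np.zeros(spec.shape)
    elif spec.content == "noise":
        rng = np.random.default_rng(spec.seed)
        data = rng.integers(0, 1000, size=spec.shape).astype(np.float64)
    else:
        raise InvalidInputError(f"unknown phantom content {spec.content!r}")
    return ImageVolume(data=data, affine=spec.affine, intent="structural",
                       source_path=f"phantom:{spec.content}")


def make_label_blobs(n_labels: int, spec: PhantomSpec,
                     values=None, over_limit: bool = False) -> LabelMap:
    """Place ``n_labels`` disjoint spherical blobs on the grid.

    Blob centers sit on a regular lattice and radii are kept below half
    the lattice pitch, so supports never intersect.  ``values`` overrides
    the stored label values (default 1..n).  ``over_limit=True`` permits
    n > 30 so the downstream too-many-labels error path can be exercised.
    """
    if n_labels < 1:
        raise InvalidInputError("need at least one label")
    if n_labels > 30 and not over_limit:
        raise InvalidInputError(
            "n_labels > 30 requires over_limit mode (valid label images "
            "carry at most 30 distinct values)")
    if values is None:
        values = list(range(1, n_labels + 1))
    values = [int(v) for v in values]
    if len(values) != n_labels or len(set(values)) != n_labels or 0 in values:
        raise InvalidInputError("values must be distinct nonzero, one per blob")

    per_axis = int(np.ceil(n_labels ** (1.0 / 3.0)))
    pitches = [s / per_axis for s in spec.shape]
    if min(pitches) < 2.0:
        raise InvalidInputError(
            f"{n_labels} blobs do not fit in grid {spec.shape}")
    radius = max(min(pitches) / 3.0, 0.55)  # >=0.55 guarantees >=1 voxel
    rng = np.random.default_rng(spec.seed)

    data = np.zeros(spec.shape, dtype=np.int64)
    nx, ny, nz = spec.shape
    i, j, k = np.ogrid[:nx, :ny, :nz]
    cells = [(a, b, c) for a in range(per_axis) for b in range(per_axis)
             for c in range(per_axis)][:n_labels]
    for value, (a, b, c) in zip(values, cells):
        jitter = rng.uniform(-0.1, 0.1, size=3)
        center = [(a + 0.5 + jitter[0]) * pitches[0],
                  (b + 0.5 + jitter[1]) * pitches[1],
                  (c + 0.5 + jitter[2]) * pitches[2]]
        inside = ((i - center[0]) ** 2 + (j - center[1]) ** 2
                  + (k - center[2]) ** 2) <= radius * radius
        if not inside.any():  # guarantee at least the nearest voxel
            nearest = tuple(int(round(min(max(c_, 0), s - 1)))
                            for c_, s in zip(center, spec.shape))
            data[nearest] = value
        else:
            data[inside] = value
    return LabelMap(data=data, affine=spec.affine,
                    source_path=f"phantom:blobs{n_labels}")


def make_helical_tracts(n_streamlines: int, seed: int = 0,
                        points_per_streamline: int = 40) -> Tractogram:
    """Analytic helical streamlines in RAS millimetres.

    Streamline ``s`` has points ``p_k = center_s + (r_s cos(phi_s + k d),
    r_s sin(phi_s + k d), c_s (phi_s + k d))`` with angular step
    ``d = 0.2`` rad; radius, pitch, phase and center are drawn from the
    seeded generator, so the coordinates are reproducible and closed-form.
    """
    if n_streamlines < 0:
        raise InvalidInputError("streamline count must be non-negative")
    rng = np.random.default_rng(seed)
    d = 0.2
    streamlines = []
    for _ in range(n_streamlines):
        r = rng.uniform(5.0, 25.0)
        c = rng.uniform(0.5, 3.0)
        phi = rng.uniform(0.0, 2 * np.pi)
        center = rng.uniform(-40.0, 40.0, size=3)
        n_pts = int(rng.integers(2, points_per_streamline + 1))
        theta = phi + d * np.arange(n_pts)
        pts = np.stack([center[0] + r * np.cos(theta),
                        center[1] + r * np.sin(theta),
                        center[2] + c * theta], axis=1)
        streamlines.append(pts)
    return Tractogram(streamlines=streamlines,
                      header={"timestamp": "0.0"},
                      source_path=f"phantom:helix{n_streamlines}")


def make_minimal_template_dicom(patient_fields: dict, path) -> Path:
    """Write the smallest Part-10 file carrying the template attributes.

    ``patient_fields`` maps DICOM keywords (PatientID, PatientName,
    StudyDate, ...) to values; a StudyInstanceUID is minted if absent.
    """
    ds = Dataset()
    ds.SpecificCharacterSet = "ISO_IR 100"
    sop_uid = generate_uid(prefix=None)
    ds.SOPClassUID = MR_IMAGE_STORAGE
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "MR"
    for keyword, value in patient_fields.items():
        setattr(ds, keyword, value)
    ds.setdefault("StudyInstanceUID", generate_uid(prefix=None))
    ds.setdefault("SeriesInstanceUID", generate_uid(prefix=None))

    ds.file_meta = FileMetaDataset()
    ds.file_meta.MediaStorageSOPClassUID = ds.SOPClassUID
    ds.file_meta.MediaStorageSOPInstanceUID = sop_uid
    ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta.ImplementationClassUID = pydicom.uid.PYDICOM_IMPLEMENTATION_UID
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds.save_as(str(path), enforce_file_format=True)
    return path


# affine families covering the geometry decision table ----------------------

def rotation_affine(angle: float, axis: int = 2,
                    spacing=(1.0, 1.0, 1.0),
                    translation=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Orthogonal affine: in-plane rotation x positive scaling + shift."""
    c, s = np.cos(angle), np.sin(angle)
    rot = np.eye(3)
    a, b = [x for x in range(3) if x != axis]
    rot[a, a] = c
    rot[a, b] = -s
    rot[b, a] = s
    rot[b, b] = c
    m = np.eye(4)
    m[:3, :3] = rot @ np.diag(spacing)
    m[:3, 3] = translation
    return m


def random_orthogonal_affine(rng: np.random.Generator) -> np.ndarray:
    """Random rotation x positive anisotropic scaling + translation."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    spacing = rng.uniform(0.5, 3.0, size=3)
    m = np.eye(4)
    m[:3, :3] = q @ np.diag(spacing)
    m[:3, 3] = rng.uniform(-100.0, 100.0, size=3)
    return m


def left_handed_affine(spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    m = np.eye(4)
    m[:3, :3] = np.diag([spacing[0], spacing[1], -spacing[2]])
    return m


def save_volume_nifti(vol, path) -> Path:
    """Write an ImageVolume or LabelMap as a NIfTI-1 file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(vol.data)
    if data.dtype == np.int64:
        data = data.astype(np.int16)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_sform(vol.affine, code=1)
    img.header.set_qform(vol.affine, code=1)
    nib.save(img, str(path))
    return path


def make_demo_workup(out_dir, seed: int = 42) -> dict:
    """Materialize a complete synthetic workup directory.

    Returns a dict of paths: template, structural images, label image and
    tract files — ready to feed to the conversion command.
    """
    from .tck_io import write_tck

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = rotation_affine(0.0, spacing=(1.0, 1.0, 1.5),
                             translation=(-31.5, -31.5, -23.0))
    spec = PhantomSpec(shape=(64, 64, 32), affine=affine, seed=seed,
                       content="gradient")
    t1 = make_phantom_volume(spec)
    fa = make_phantom_volume(PhantomSpec(shape=(64, 64, 32), affine=affine,
                                         seed=seed + 1, content="sphere"))
    labels = make_label_blobs(3, PhantomSpec(shape=(64, 64, 32), affine=affine,
                                             seed=seed + 2))
    paths = {
        "template": make_minimal_template_dicom(
            {"PatientID": "SYN01", "PatientName": "Synthetic^Phantom",
             "PatientBirthDate": "20100101", "PatientSex": "O",
             "StudyDate": "20220101", "StudyTime": "120000",
             "StudyDescription": "Synthetic workup",
             "InstitutionName": "Nowhere General"},
            out_dir / "template.dcm"),
        "structurals": [save_volume_nifti(t1, out_dir / "t1.nii.gz"),
                        save_volume_nifti(fa, out_dir / "fa.nii.gz")],
        "labels": [save_volume_nifti(labels, out_dir / "tumour.nii.gz")],
        "tracts": [],
    }
    for name, n, s in (("cst_left.tck", 50, seed + 3),
                       ("or_left.tck", 40, seed + 4)):
        tract = make_helical_tracts(n, seed=s)
        p = out_dir / name
        write_tck(tract, p)
        paths["tracts"].append(p)
    return paths
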