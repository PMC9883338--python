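"""Coordinate conventions shared by every writer.

NIfTI stores a voxel-to-world affine in RAS millimetres (index (0,0,0)
maps to the *center* of the first voxel); DICOM describes slice geometry
in LPS millimetres through ImageOrientationPatient / ImagePositionPatient
/ PixelSpacing, where ImagePositionPatient is the center of the first
transmitted pixel.  Both conventions address voxel centers, so the mapping
carries no half-voxel shift.

Axis convention used throughout: voxel axis 0 varies along a DICOM row
(i.e. with the column index), voxel axis 1 varies down a column (with the
row index) and voxel axis 2 is the slice axis.  No axis permutation is
ever performed; sheared affines are refused rather than resampled, since
silently resampling data destined for surgical navigation would be far
worse than a hard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import (
    InvalidInputError,
    UnsupportedGeometryError,
    UnsupportedInputError,
)

logger = logging.getLogger(__name__)

#: |dot(unit axis_a, unit axis_b)| above this is treated as shear
ORTHOGONALITY_TOL = 1e-4


def validate_affine(matrix: np.ndarray) -> np.ndarray:
    """Check the 4x4 voxel-to-world affine invariants and return it as float64."""
    m = np.asarray(matrix, dtype=np.float64)
    if m.shape != (4, 4):
        raise InvalidInputError(f"affine must be 4x4, got {m.shape}")
    if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0]):
        raise InvalidInputError("affine last row must be (0, 0, 0, 1)")
    if abs(np.linalg.det(m[:3, :3])) < 1e-12:
        raise InvalidInputError("affine upper-left 3x3 block is singular")
    return m


@dataclass
class ImageVolume:
    """A 3D scalar grid plus its voxel-to-world (RAS mm) affine."""

    data: np.ndarray
    affine: np.ndarray
    intent: str = "structural"  # "structural" | "label"
    source_path: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise UnsupportedInputError(
                f"{self.source_path or 'volume'}: expected a 3D single-component "
                f"image, got {self.data.ndim}D; multiple component images, such "
                "as fMRI time series or raw diffusion data, are not supported"
            )
        self.affine = validate_affine(self.affine)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class SliceGeometry:
    """Decomposed DICOM slice geometry (all quantities LPS)."""

    orientation: np.ndarray  # 6 direction cosines: row dir then column dir
    positions: np.ndarray  # (n_slices, 3) per-slice origins, mm
    pixel_spacing: tuple  # (between-rows, between-columns) mm
    slice_spacing: float  # mm
    shape: tuple  # (rows, columns, slices)

    @property
    def normal(self) -> np.ndarray:
        r = self.orientation[:3]
        c = self.orientation[3:]
        return np.cross(r, c)


def ras_to_lps_point(p):
    """Map a point (or an (n,3) array of points) from RAS mm to LPS mm.

    The conversion negates the left-right and anterior-posterior axes and
    is its own inverse.
    """
    pts = np.asarray(p, dtype=np.float64)
    if not np.all(np.isfinite(pts)):
        raise InvalidInputError("non-finite coordinate in RAS->LPS conversion")
    out = pts.copy()
    out[..., 0] *= -1.0
    out[..., 1] *= -1.0
    return out


#: alias — the map is an involution
lps_to_ras_point = ras_to_lps_point


def affine_to_slice_geometry(affine: np.ndarray, shape) -> SliceGeometry:
    """Decompose a voxel-to-world affine into DICOM slice geometry.

    Raises :class:`UnsupportedGeometryError` for sheared grids and
    :class:`InvalidInputError` for degenerate spacings.  For every voxel
    index the position reconstructed from the returned geometry equals
    ``ras_to_lps(affine @ index)`` to well under 1e-3 mm.
    """
    m = validate_affine(affine)
    if len(shape) != 3 or any(int(s) < 1 for s in shape):
        raise InvalidInputError(f"shape must be a positive 3D extent, got {shape}")
    cols = m[:3, :3]
    spacings = np.linalg.norm(cols, axis=0)
    if np.any(spacings <= 0) or not np.all(np.isfinite(spacings)):
        raise InvalidInputError(f"non-positive voxel spacing {spacings}")
    units = cols / spacings
    for a, b in ((0, 1), (0, 2), (1, 2)):
        d = abs(float(np.dot(units[:, a], units[:, b])))
        if d > ORTHOGONALITY_TOL:
            raise UnsupportedGeometryError(
                f"affine axes {a} and {b} are not orthogonal (|dot|={d:.2e}); "
                "sheared grids are refused rather than resampled"
            )

    row_dir = ras_to_lps_point(units[:, 0])  # direction of increasing column index
    col_dir = ras_to_lps_point(units[:, 1])  # direction of increasing row index
    row_dir /= np.linalg.norm(row_dir)
    col_dir /= np.linalg.norm(col_dir)
    n_slices = int(shape[2])
    idx = np.zeros((n_slices, 4))
    idx[:, 2] = np.arange(n_slices)
    idx[:, 3] = 1.0
    positions = ras_to_lps_point((m @ idx.T).T[:, :3])
    return SliceGeometry(
        orientation=np.concatenate([row_dir, col_dir]),
        positions=positions,
        pixel_spacing=(float(spacings[1]), float(spacings[0])),
        slice_spacing=float(spacings[2]),
        shape=(int(shape[1]), int(shape[0]), n_slices),
    )


def flip_to_right_handed(data: np.ndarray, affine: np.ndarray):
    """Reverse the in-memory slice order of a left-handed grid.

    Returns ``(data, affine, flipped)``.  Flipping the slice axis negates
    the determinant, so one flip always restores a right-handed grid; the
    affine is updated so voxel-to-world positions are unchanged.
    """
    m = validate_affine(affine)
    if np.linalg.det(m[:3, :3]) >= 0:
        return data, m, False
    n = data.shape[2]
    flip = np.eye(4)
    flip[2, 2] = -1.0
    flip[2, 3] = n - 1
    logger.info("left-handed grid: reversing slice order for export")
    return data[:, :, ::-1], m @ flip, True


def load_nifti(path, intent: str = "structural") -> ImageVolume:
    """Load a NIfTI-1 image as an :class:`ImageVolume`.

    A single trailing singleton dimension is squeezed; anything else
    non-3D is rejected.  nibabel's affine resolution is used (sform
    preferred over qform when both are present) and the choice is logged.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[:, :, :, 0]
    if data.ndim != 3:
        raise UnsupportedInputError(
            f"{path}: {data.ndim}D input; multiple component images, such as "
            "fMRI time series or raw diffusion data, are not supported"
        )
    sform_code = int(img.header["sform_code"])
    qform_code = int(img.header["qform_code"])
    which = "sform" if sform_code > 0 else ("qform" if qform_code > 0 else "base")
    logger.info("%s: using %s affine (sform=%d qform=%d)", path, which,
                sform_code, qform_code)
    return ImageVolume(
        data=np.asarray(data, dtype=np.float64),
        affine=img.affine,
        intent=intent,
        source_path=str(path),
    )


def geometry_matches(a_affine, a_shape, b_affine, b_shape, tol: float = 1e-3) -> bool:
    """True when two grids share shape and voxel-to-world affine within tol (mm).

    Used to pair each label image with the structural image it annotates;
    matching the full affine (spacing, orientation *and* origin) guarantees
    that slices correspond one-to-one between the two grids.
    """
    if tuple(a_shape) != tuple(b_shape):
        return False
    return bool(np.max(np.abs(np.asarray(a_affine) - np.asarray(b_affine))) <= tol)
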