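"""DICOM Surface objects from tractography streamlines.

Streamlines become polylines in a Surface Segmentation Storage object:
one shared point list (LPS millimetres, 32-bit floats — the native tck
precision) and one Line Sequence primitive per streamline indexing a
contiguous, consecutive run of that list (1-based).  The object is marked
as deriving from the *first* structural series of the conversion run, so
navigation software associates the tracts with that image until the
shared frame of reference is accepted.

Streamlines are stored exactly as read: no resampling, decimation,
merging or deduplication.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from pydicom.dataset import Dataset
from pydicom.sequence import Sequence

from .errors import CorruptObjectError, EmptyTractError, InvalidInputError
from .geometry import lps_to_ras_point, ras_to_lps_point
from .mr_series_writer import SeriesContext, TemplateMetadata, new_derived_dataset
from .seg_label_writer import assign_segment_colors, rgb_to_cielab_scaled
from .tck_io import Tractogram

logger = logging.getLogger(__name__)

SURFACE_SEGMENTATION_STORAGE = "1.2.840.10008.5.1.4.1.1.66.5"


def tractogram_to_surface(tracts: Tractogram, first_series,
                          meta: TemplateMetadata, ctx: SeriesContext,
                          color_index: int = 0,
                          label: str = "") -> Dataset:
    """Convert one tractogram into a Surface Segmentation object.

    ``first_series`` is the MR instance list of the first structural
    input; the emitted object references that series as its derivation
    source.  ``color_index`` selects the recommended display color from
    the shared deterministic palette.
    """
    if len(tracts) == 0:
        raise EmptyTractError(
            f"{tracts.source_path or 'tractogram'}: no streamlines to convert")
    if not first_series:
        raise InvalidInputError("a reference structural series is required")
    tracts.validate()

    lengths = [len(s) for s in tracts.streamlines]
    all_points = np.concatenate(
        [np.asarray(s, dtype=np.float64) for s in tracts.streamlines])
    lps = ras_to_lps_point(all_points).astype("<f4")

    color = assign_segment_colors(color_index % 30 + 1)[color_index % 30]
    cielab = rgb_to_cielab_scaled(color)
    name = label or Path(tracts.source_path).stem or "tractogram"

    ds = new_derived_dataset(SURFACE_SEGMENTATION_STORAGE, "SEG", meta, ctx)
    ds.SeriesInstanceUID = ctx.new_uid()
    ds.SeriesNumber = ctx.new_series_number()
    ds.SeriesDescription = name
    ds.InstanceNumber = 1
    ds.ImageType = ["DERIVED", "PRIMARY"]
    ds.ContentLabel = "TRACTS"
    ds.ContentDescription = "Converted streamline tractogram"
    ds.ContentCreatorName = "tract2dicom"

    inst = sorted(first_series, key=lambda d: int(d.InstanceNumber))
    ref_series = Dataset()
    ref_series.SeriesInstanceUID = inst[0].SeriesInstanceUID
    ref_series.ReferencedInstanceSequence = Sequence()
    for r in inst:
        item = Dataset()
        item.ReferencedSOPClassUID = r.SOPClassUID
        item.ReferencedSOPInstanceUID = r.SOPInstanceUID
        ref_series.ReferencedInstanceSequence.append(item)
    ds.ReferencedSeriesSequence = Sequence([ref_series])

    seg = Dataset()
    seg.SegmentNumber = 1
    seg.SegmentLabel = name
    seg.SegmentDescription = f"streamlines={len(tracts)}"
    seg.SegmentAlgorithmType = "SEMIAUTOMATIC"
    seg.SegmentAlgorithmName = "tractography"
    ref_surface = Dataset()
    ref_surface.ReferencedSurfaceNumber = 1
    seg.ReferencedSurfaceSequence = Sequence([ref_surface])
    ds.SegmentSequence = Sequence([seg])

    surface = Dataset()
    surface.SurfaceNumber = 1
    surface.SurfaceComments = f"{len(tracts)} streamlines"
    surface.SurfaceProcessing = "NO"
    surface.RecommendedDisplayGrayscaleValue = 0xFFFF
    surface.RecommendedDisplayCIELabValue = list(cielab)
    surface.RecommendedPresentationOpacity = 1.0
    surface.RecommendedPresentationType = "SURFACE"
    surface.FiniteVolume = "NO"
    surface.Manifold = "NO"

    points = Dataset()
    points.NumberOfSurfacePoints = int(lps.shape[0])
    points.PointCoordinatesData = lps.tobytes()
    surface.SurfacePointsSequence = Sequence([points])
    normals = Dataset()
    normals.NumberOfVectors = 0
    normals.VectorDimensionality = 3
    surface.SurfacePointsNormalsSequence = Sequence([normals])

    primitives = Dataset()
    primitives.LongTrianglePointIndexList = b""
    primitives.LongEdgePointIndexList = b""
    primitives.LongVertexPointIndexList = b""
    primitives.TriangleStripSequence = Sequence()
    primitives.TriangleFanSequence = Sequence()
    primitives.FacetSequence = Sequence()
    line_seq = Sequence()
    start = 1  # indices into the point list are 1-based
    for n in lengths:
        line = Dataset()
        idx = np.arange(start, start + n, dtype="<u4")
        line.LongPrimitivePointIndexList = idx.tobytes()
        line_seq.append(line)
        start += n
    primitives.LineSequence = line_seq
    surface.SurfaceMeshPrimitivesSequence = Sequence([primitives])

    ds.SurfaceCount = 1
    ds.SurfaceSequence = Sequence([surface])
    logger.info("%s -> Surface object: %d streamlines, %d points",
                tracts.source_path or "tractogram", len(tracts), lps.shape[0])
    return ds


def surface_to_tractogram(surface: Dataset) -> Tractogram:
    """Extract streamlines back out of an emitted Surface object.

    Inverse of :func:`tractogram_to_surface` up to float32 precision;
    raises :class:`CorruptObjectError` on out-of-range or 0-based indices.
    """
    try:
        surf = surface.SurfaceSequence[0]
        pts_item = surf.SurfacePointsSequence[0]
        n_points = int(pts_item.NumberOfSurfacePoints)
        raw = bytes(pts_item.PointCoordinatesData)
        line_seq = surf.SurfaceMeshPrimitivesSequence[0].LineSequence
    except (AttributeError, IndexError) as exc:
        raise CorruptObjectError(f"not a surface tract object: {exc}") from exc
    lps = np.frombuffer(raw, dtype="<f4").reshape(-1, 3)
    if lps.shape[0] != n_points:
        raise CorruptObjectError(
            f"point list holds {lps.shape[0]} points, header says {n_points}")
    if len(line_seq) < 1:
        raise CorruptObjectError("object contains no polyline primitives")
    ras = lps_to_ras_point(lps.astype(np.float64))

    streamlines = []
    for line in line_seq:
        idx = np.frombuffer(bytes(line.LongPrimitivePointIndexList),
                            dtype="<u4")
        if idx.size == 0:
            raise CorruptObjectError("empty polyline primitive")
        if idx.min() < 1 or idx.max() > n_points:
            raise CorruptObjectError(
                f"polyline index out of range [1, {n_points}]: "
                f"{int(idx.min())}..{int(idx.max())} (indices are 1-based)")
        streamlines.append(ras[idx - 1])
    return Tractogram(streamlines=streamlines,
                      header={"count": str(len(streamlines))},
                      source_path=str(getattr(surface, "SOPInstanceUID", "")))
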