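"""Reader/writer for MRtrix-format ``.tck`` streamline files.

The format is a text header of ``key: value`` lines opened by the magic
line ``mrtrix tracks`` and closed by ``END``, followed (at the byte offset
declared by the ``file`` entry) by raw binary coordinate triplets in
scanner-space millimetres (RAS).  A triplet of NaNs terminates a
streamline; a triplet of +Inf terminates the stream.

Coordinates are kept exactly as stored — no filtering, resampling or
reorientation.  Header keys are preserved verbatim and case-sensitively;
only ``datatype``, ``file`` and ``count`` are interpreted.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CorruptFileError,
    FormatError,
    InvalidInputError,
    UnsupportedEncodingError,
)

logger = logging.getLogger(__name__)

MAGIC = "mrtrix tracks"

#: datatype header value -> numpy dtype of the stored triplets
SUPPORTED_DATATYPES = {
    "Float32LE": np.dtype("<f4"),
    "Float32BE": np.dtype(">f4"),
    "Float64LE": np.dtype("<f8"),
    "Float64BE": np.dtype(">f8"),
}


@dataclass
class Tractogram:
    """Ordered streamlines plus the verbatim tck header they came with.

    ``streamlines`` is a list of ``(n_i, 3)`` float64 arrays, each a polyline
    in scanner RAS millimetres with ``n_i >= 1`` and every coordinate finite.
    """

    streamlines: list = field(default_factory=list)
    header: dict = field(default_factory=dict)
    source_path: str = ""

    def __len__(self) -> int:
        return len(self.streamlines)

    @property
    def total_points(self) -> int:
        return sum(len(s) for s in self.streamlines)

    def validate(self) -> None:
        for i, s in enumerate(self.streamlines):
            pts = np.asarray(s, dtype=np.float64)
            if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 1:
                raise InvalidInputError(
                    f"streamline {i} is not an (n>=1, 3) point array"
                )
            if not np.all(np.isfinite(pts)):
                raise InvalidInputError(
                    f"streamline {i} contains non-finite coordinates"
                )


def _parse_header(fh: io.BufferedReader, path: str):
    """Read the text header; return (header dict, binary offset)."""
    first = fh.readline().decode("ascii", errors="replace").strip()
    if first != MAGIC:
        raise FormatError(f"{path}: missing '{MAGIC}' magic line")
    header: dict = {}
    offset = None
    while True:
        raw = fh.readline()
        if not raw:
            raise CorruptFileError(f"{path}: header not terminated by END")
        line = raw.decode("ascii", errors="replace").rstrip("\n")
        if line.strip() == "END":
            break
        if ":" not in line:
            continue  # tolerate stray lines; provenance only
        key, value = line.split(":", 1)
        header[key.strip()] = value.strip()
    if "file" not in header:
        raise CorruptFileError(f"{path}: header lacks a 'file' entry")
    file_entry = header["file"].split()
    try:
        offset = int(file_entry[-1])
    except (ValueError, IndexError):
        raise CorruptFileError(f"{path}: unparseable file entry {header['file']!r}")
    if file_entry[0] != ".":
        raise UnsupportedEncodingError(
            f"{path}: external data files are not supported"
        )
    return header, offset


def read_tck(path, strict: bool = True) -> Tractogram:
    """Read a tck file into a :class:`Tractogram`.

    Parameters
    ----------
    path:
        Path to a tck file.
    strict:
        When True (default) a mismatch between the header ``count`` entry
        and the number of streamlines actually stored raises
        :class:`CorruptFileError`; when False it is downgraded to a warning.
        Silent truncation is the dangerous failure mode in a surgical
        context, hence strict by default.
    """
    path = str(path)
    with open(path, "rb") as fh:
        header, offset = _parse_header(fh, path)
        datatype = header.get("datatype", "Float32LE")
        if datatype not in SUPPORTED_DATATYPES:
            raise UnsupportedEncodingError(
                f"{path}: unsupported datatype {datatype!r}; "
                f"supported: {sorted(SUPPORTED_DATATYPES)}"
            )
        dtype = SUPPORTED_DATATYPES[datatype]
        fh.seek(offset)
        raw = fh.read()

    n_values = len(raw) // dtype.itemsize
    if n_values % 3:
        n_values -= n_values % 3
    values = np.frombuffer(raw[: n_values * dtype.itemsize], dtype=dtype)
    triplets = values.reshape(-1, 3).astype(np.float64)

    streamlines: list = []
    current_start = 0
    terminated = False
    for idx in range(len(triplets)):
        t = triplets[idx]
        nan_mask = np.isnan(t)
        inf_mask = np.isposinf(t)
        if nan_mask.all():
            if idx > current_start:
                streamlines.append(np.array(triplets[current_start:idx]))
            current_start = idx + 1
        elif inf_mask.all():
            if idx > current_start:
                # stream may end without a final NaN delimiter
                streamlines.append(np.array(triplets[current_start:idx]))
            terminated = True
            break
        elif nan_mask.any() or not np.all(np.isfinite(t)):
            raise CorruptFileError(
                f"{path}: non-finite coordinate inside point data at triplet {idx}"
            )
    if not terminated:
        raise CorruptFileError(
            f"{path}: binary section truncated before the Inf terminator"
        )

    if "count" in header:
        try:
            declared = int(header["count"])
        except ValueError:
            raise CorruptFileError(f"{path}: unparseable count {header['count']!r}")
        if declared != len(streamlines):
            msg = (
                f"{path}: header count {declared} != {len(streamlines)} "
                "streamlines stored"
            )
            if strict:
                raise CorruptFileError(msg)
            warnings.warn(msg, stacklevel=2)
            logger.warning(msg)

    tract = Tractogram(streamlines=streamlines, header=header, source_path=path)
    tract.validate()
    return tract


def write_tck(tractogram: Tractogram, path, datatype: str = "Float32LE") -> None:
    """Write a :class:`Tractogram` as an MRtrix tck file.

    The ``count``, ``datatype`` and ``file`` entries are recomputed; every
    other header key is carried over verbatim for provenance.
    """
    if datatype not in SUPPORTED_DATATYPES:
        raise UnsupportedEncodingError(f"cannot write datatype {datatype!r}")
    tractogram.validate()
    dtype = SUPPORTED_DATATYPES[datatype]

    lines = [MAGIC]
    for key, value in tractogram.header.items():
        if key in ("datatype", "file", "count"):
            continue
        lines.append(f"{key}: {value}")
    lines.append(f"datatype: {datatype}")
    lines.append(f"count: {len(tractogram.streamlines)}")

    # the file entry states the offset of the binary section, which depends
    # on the header length including the entry itself: fix-point iterate
    offset = 0
    for _ in range(8):
        header_text = "\n".join(lines + [f"file: . {offset}", "END"]) + "\n"
        new_offset = len(header_text.encode("ascii"))
        if new_offset == offset:
            break
        offset = new_offset
    header_text = "\n".join(lines + [f"file: . {offset}", "END"]) + "\n"

    chunks = []
    for s in tractogram.streamlines:
        chunks.append(np.asarray(s, dtype=np.float64))
        chunks.append(np.full((1, 3), np.nan))
    chunks.append(np.full((1, 3), np.inf))
    binary = np.concatenate(chunks).astype(dtype).tobytes()

    with open(str(path), "wb") as fh:
        fh.write(header_text.encode("ascii"))
        fh.write(binary)
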