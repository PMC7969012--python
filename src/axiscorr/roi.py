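"""Readers for axis traces and background regions.

Two on-disk forms are supported:

* ImageJ ROI records (``.roi`` single files or ``RoiSet.zip`` bundles)
  of the polygon / polyline / freehand / freeline families, including
  the sub-pixel-resolution variant.  Only the coordinate payload is
  decoded; colors, names and other display attributes are ignored.
* A plain-text fallback: one vertex per line,
  ``fragment_id<TAB>row<TAB>col``, grouped by fragment id in file order.

ImageJ stores coordinates as (x, y) = (column, row); everything here is
converted to this package's (row, col) convention on read.  A matching
minimal encoder is provided so synthetic traces can be written back out
(and so tests can build fixtures without binary files in the tree).
"""

from __future__ import annotations

import struct
import zipfile
from pathlib import Path

import numpy as np

from .profiles import AxisTrace

__all__ = [
    "read_imagej_roi",
    "write_imagej_roi",
    "read_roi_zip",
    "read_text_traces",
    "write_text_traces",
    "roi_to_trace",
]

_MAGIC = b"Iout"
# ImageJ type codes for the vertex-list ROI families we accept
_POLYGON, _FREELINE, _POLYLINE, _FREEHAND = 0, 4, 5, 7
_VERTEX_TYPES = {_POLYGON, _FREELINE, _POLYLINE, _FREEHAND}
_OPT_SUBPIXEL = 128
_HEADER_SIZE = 64


def read_imagej_roi(data: bytes) -> dict:
    """Decode one ImageJ ``.roi`` record into vertices and metadata.

    Returns ``{"vertices": (n, 2) float array of (row, col),
    "roi_type": str, "closed": bool}``.  Raises ``ValueError`` for
    non-ROI data or ROI types without a vertex list.
    """
    if len(data) < _HEADER_SIZE or data[:4] != _MAGIC:
        raise ValueError("not an ImageJ ROI record (bad magic)")
    roi_type = data[6]
    if roi_type not in _VERTEX_TYPES:
        raise ValueError(f"unsupported ROI type code {roi_type}")
    top, left = struct.unpack(">hh", data[8:12])
    (n,) = struct.unpack(">h", data[16:18])
    if n <= 0:
        raise ValueError("ROI has no coordinates")
    (options,) = struct.unpack(">h", data[50:52])

    int_block_end = _HEADER_SIZE + 4 * n
    if len(data) < int_block_end:
        raise ValueError("truncated ROI coordinate block")
    if options & _OPT_SUBPIXEL and len(data) >= int_block_end + 8 * n:
        # absolute float (x, y) pairs follow the integer block
        xs = np.frombuffer(data, dtype=">f4", count=n, offset=int_block_end)
        ys = np.frombuffer(data, dtype=">f4", count=n, offset=int_block_end + 4 * n)
    else:
        xs_rel = np.frombuffer(data, dtype=">i2", count=n, offset=_HEADER_SIZE)
        ys_rel = np.frombuffer(data, dtype=">i2", count=n, offset=_HEADER_SIZE + 2 * n)
        xs = xs_rel.astype(float) + left
        ys = ys_rel.astype(float) + top
    vertices = np.column_stack([ys.astype(float), xs.astype(float)])
    names = {_POLYGON: "polygon", _FREELINE: "freeline",
             _POLYLINE: "polyline", _FREEHAND: "freehand"}
    return {
        "vertices": vertices,
        "roi_type": names[roi_type],
        "closed": roi_type in (_POLYGON, _FREEHAND),
    }


def write_imagej_roi(
    vertices: np.ndarray, roi_type: str = "polyline", subpixel: bool = False
) -> bytes:
    """Encode (row, col) vertices as a minimal ImageJ ``.roi`` record."""
    codes = {"polygon": _POLYGON, "freeline": _FREELINE,
             "polyline": _POLYLINE, "freehand": _FREEHAND}
    if roi_type not in codes:
        raise ValueError(f"unsupported roi_type {roi_type!r}")
    v = np.atleast_2d(np.asarray(vertices, dtype=float))
    ys, xs = v[:, 0], v[:, 1]
    top, left = int(np.floor(ys.min())), int(np.floor(xs.min()))
    bottom, right = int(np.ceil(ys.max())), int(np.ceil(xs.max()))
    n = len(v)
    header = bytearray(_HEADER_SIZE)
    header[:4] = _MAGIC
    struct.pack_into(">h", header, 4, 228)  # version
    header[6] = codes[roi_type]
    struct.pack_into(">hhhh", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    options = _OPT_SUBPIXEL if subpixel else 0
    struct.pack_into(">h", header, 50, options)
    xs_rel = np.round(xs - left).astype(">i2")
    ys_rel = np.round(ys - top).astype(">i2")
    payload = xs_rel.tobytes() + ys_rel.tobytes()
    if subpixel:
        payload += xs.astype(">f4").tobytes() + ys.astype(">f4").tobytes()
    return bytes(header) + payload


def roi_to_trace(
    roi: dict, width_px: int = 5, cell_id: str = "", fragment_id: str = ""
) -> AxisTrace:
    """Turn a decoded polyline-family ROI into an :class:`AxisTrace`."""
    return AxisTrace(
        vertices=roi["vertices"],
        width_px=width_px,
        cell_id=cell_id,
        fragment_id=fragment_id,
    )


def read_roi_zip(path, width_px: int = 5, cell_id: str = "") -> list[AxisTrace]:
    """Read all polyline-family ROIs from an ImageJ RoiSet zip as traces."""
    traces = []
    with zipfile.ZipFile(path) as zf:
        for name in sorted(zf.namelist()):
            if not name.lower().endswith(".roi"):
                continue
            roi = read_imagej_roi(zf.read(name))
            traces.append(
                roi_to_trace(
                    roi,
                    width_px=width_px,
                    cell_id=cell_id,
                    fragment_id=Path(name).stem,
                )
            )
    if not traces:
        raise ValueError(f"no .roi entries found in {path}")
    return traces


def read_text_traces(path, width_px: int = 5, cell_id: str = "") -> list[AxisTrace]:
    """Read the plain-text trace format: ``fragment_id<TAB>row<TAB>col``.

    Blank lines and lines starting with ``#`` are ignored; vertices are
    grouped by fragment id in order of first appearance.
    """
    groups: dict[str, list] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 'fragment_id<TAB>row<TAB>col'"
                )
            frag, row, col = parts
            groups.setdefault(frag, []).append((float(row), float(col)))
    if not groups:
        raise ValueError(f"no vertices found in {path}")
    return [
        AxisTrace(
            vertices=np.array(verts),
            width_px=width_px,
            cell_id=cell_id,
            fragment_id=frag,
        )
        for frag, verts in groups.items()
    ]


def write_text_traces(traces, path) -> None:
    """Write traces in the plain-text vertex-per-line format."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# fragment_id\trow\tcol\n")
        for trace in traces:
            for row, col in trace.vertices:
                fh.write(f"{trace.fragment_id}\t{row:g}\t{col:g}\n")
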