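"""Region-of-interest containers and file formats.

Supports the binary ImageJ ``.roi`` format (polyline, polygon, line,
rectangle; with sub-pixel float coordinates), zip archives of them, and a
plain JSON dialect::

    {"type": "polyline", "points": [[x, y], ...],
     "stroke_width": 2.0, "z_range": [z0, z1]}

Coordinate convention: 0-based with pixel centers at integer coordinates
and y increasing downward.  ImageJ places pixel centers at half-integer
coordinates (the integer grid runs along pixel edges), so every read
subtracts 0.5 and every write adds 0.5.
"""

from __future__ import annotations

import json
import struct
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

_IJ_MAGIC = b"Iout"
_IJ_VERSION = 228
_TYPE_POLYGON = 0
_TYPE_RECT = 1
_TYPE_LINE = 3
_TYPE_POLYLINE = 5
_OPT_SUB_PIXEL = 128

_IJ_OFFSET = 0.5  # ImageJ pixel-edge grid vs our pixel-center grid


@dataclass
class PolylineRoi:
    """An ordered open or closed vertex chain in pixel units."""

    vertices: np.ndarray  # (N, 2) float, columns x, y
    stroke_width: float | None = None
    z_range: tuple[int, int] | None = None
    closed: bool = False
    name: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array of (x, y)")
        if len(self.vertices) < 2:
            raise ValueError("a ROI needs at least 2 vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("vertices must be finite")

    @property
    def length(self) -> float:
        """Polyline arc length in pixels (closing edge included if closed)."""
        v = self.vertices
        if self.closed:
            v = np.vstack([v, v[:1]])
        return float(np.sum(np.linalg.norm(np.diff(v, axis=0), axis=1)))

    @classmethod
    def rectangle(cls, x0: float, y0: float, x1: float, y1: float,
                  **kw) -> "PolylineRoi":
        pts = [[x0, y0], [x1, y0], [x1, y1], [x0, y1]]
        return cls(np.asarray(pts, float), closed=True, **kw)


# ---------------------------------------------------------------------------
# ImageJ binary format


def encode_imagej_roi(roi: PolylineRoi) -> bytes:
    """Serialize to ImageJ .roi bytes with sub-pixel float coordinates."""
    pts_ij = roi.vertices + _IJ_OFFSET
    n = len(pts_ij)
    left = int(np.floor(pts_ij[:, 0].min()))
    top = int(np.floor(pts_ij[:, 1].min()))
    right = int(np.ceil(pts_ij[:, 0].max()))
    bottom = int(np.ceil(pts_ij[:, 1].max()))
    roi_type = _TYPE_POLYGON if roi.closed else _TYPE_POLYLINE

    header = bytearray(64)
    header[0:4] = _IJ_MAGIC
    struct.pack_into(">h", header, 4, _IJ_VERSION)
    header[6] = roi_type
    struct.pack_into(">hhhh", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    if roi.stroke_width is not None:
        struct.pack_into(">h", header, 34, int(round(roi.stroke_width)))
    struct.pack_into(">h", header, 50, _OPT_SUB_PIXEL)  # options

    body = bytearray()
    for col in (0, 1):
        ref = left if col == 0 else top
        for v in pts_ij[:, col]:
            body += struct.pack(">h", int(np.floor(v)) - ref)
    for col in (0, 1):
        for v in pts_ij[:, col]:
            body += struct.pack(">f", v)
    return bytes(header) + bytes(body)


def decode_imagej_roi(data: bytes, name: str | None = None) -> PolylineRoi:
    """Parse ImageJ .roi bytes into a :class:`PolylineRoi`."""
    if data[0:4] != _IJ_MAGIC:
        raise ValueError("not an ImageJ ROI (missing 'Iout' magic)")
    version = struct.unpack_from(">h", data, 4)[0]
    roi_type = data[6]
    top, left, bottom, right = struct.unpack_from(">hhhh", data, 8)
    n = struct.unpack_from(">h", data, 16)[0]
    stroke = struct.unpack_from(">h", data, 34)[0]
    options = struct.unpack_from(">h", data, 50)[0]
    sub_pixel = bool(options & _OPT_SUB_PIXEL) and version >= 222

    if roi_type == _TYPE_RECT:
        pts = np.array([
            [left, top], [right, top], [right, bottom], [left, bottom]
        ], float)
        closed = True
    elif roi_type == _TYPE_LINE:
        x1, y1, x2, y2 = struct.unpack_from(">ffff", data, 18)
        pts = np.array([[x1, y1], [x2, y2]], float)
        closed = False
    elif roi_type in (_TYPE_POLYGON, _TYPE_POLYLINE, 4, 7, 8):
        if sub_pixel:
            off = 64 + 4 * n
            xs = struct.unpack_from(f">{n}f", data, off)
            ys = struct.unpack_from(f">{n}f", data, off + 4 * n)
            pts = np.column_stack([xs, ys]).astype(float)
        else:
            xs = struct.unpack_from(f">{n}h", data, 64)
            ys = struct.unpack_from(f">{n}h", data, 64 + 2 * n)
            pts = np.column_stack([xs, ys]).astype(float)
            pts[:, 0] += left
            pts[:, 1] += top
        closed = roi_type in (_TYPE_POLYGON, 7, 8)
    else:
        raise ValueError(f"unsupported ImageJ ROI type {roi_type}")

    return PolylineRoi(
        pts - _IJ_OFFSET,
        stroke_width=float(stroke) if stroke else None,
        closed=closed,
        name=name,
    )


# ---------------------------------------------------------------------------
# file-level API


def _roi_to_json_dict(roi: PolylineRoi) -> dict:
    d: dict = {
        "type": "polygon" if roi.closed else "polyline",
        "points": roi.vertices.tolist(),
    }
    if roi.stroke_width is not None:
        d["stroke_width"] = roi.stroke_width
    if roi.z_range is not None:
        d["z_range"] = list(roi.z_range)
    if roi.name:
        d["name"] = roi.name
    return d


def _roi_from_json_dict(d: dict) -> PolylineRoi:
    kind = d.get("type", "polyline")
    if kind == "rect":
        (x0, y0), (x1, y1) = d["points"]
        roi = PolylineRoi.rectangle(x0, y0, x1, y1)
    else:
        roi = PolylineRoi(np.asarray(d["points"], float),
                          closed=(kind == "polygon"))
    if "stroke_width" in d:
        roi.stroke_width = float(d["stroke_width"])
    if "z_range" in d:
        roi.z_range = tuple(int(v) for v in d["z_range"])
    roi.name = d.get("name")
    return roi


def read_rois(path: str | Path) -> list[PolylineRoi]:
    """Read ROIs from .roi, .zip (of .roi entries) or .json files."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".roi":
        return [decode_imagej_roi(path.read_bytes(), name=path.stem)]
    if suffix == ".zip":
        out = []
        with zipfile.ZipFile(path) as zf:
            for entry in sorted(zf.namelist()):
                if entry.lower().endswith(".roi"):
                    out.append(
                        decode_imagej_roi(zf.read(entry),
                                          name=Path(entry).stem)
                    )
        return out
    if suffix == ".json":
        payload = json.loads(path.read_text())
        items = payload if isinstance(payload, list) else payload["rois"]
        return [_roi_from_json_dict(d) for d in items]
    raise ValueError(f"unsupported ROI file format: {path.name}")


def write_rois(rois: list[PolylineRoi], path: str | Path) -> None:
    """Write ROIs as .roi (single), .zip (many) or .json."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".roi":
        if len(rois) != 1:
            raise ValueError(".roi holds exactly one ROI; use .zip")
        path.write_bytes(encode_imagej_roi(rois[0]))
    elif suffix == ".zip":
        with zipfile.ZipFile(path, "w") as zf:
            for i, roi in enumerate(rois):
                name = roi.name or f"roi_{i:04d}"
                zf.writestr(f"{name}.roi", encode_imagej_roi(roi))
    elif suffix == ".json":
        path.write_text(
            json.dumps([_roi_to_json_dict(r) for r in rois], indent=2)
        )
    else:
        raise ValueError(f"unsupported ROI file format: {path.name}")
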