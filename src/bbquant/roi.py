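"""Per-slice polygon ROIs and their rasterization to 3-D masks.

ROIs come from interactive tools in which an outline is hand-drawn on each
z-slice around an oocyte or a whole nest.  The internal model is a list of
named units, each holding ``(slice, polygon)`` pairs; two serializations are
supported: a plain JSON dialect (canonical) and ImageJ ``.roi`` polygon
archives (zip) for interoperability with hand-drawn outlines.

Coordinate convention: polygon vertices are in pixel units with integer
coordinates addressing pixel *centers*; a voxel belongs to the rasterized mask
iff its (x, y) center lies strictly inside that slice's polygon.
"""

from __future__ import annotations

import json
import struct
import zipfile
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.validation import explain_validity

from .errors import RoiValidationError

VALID_KINDS = ("oocyte", "nest")


@dataclass
class RoiUnit:
    """One analysis unit (a single oocyte or one nest) outlined slice by slice."""

    name: str
    kind: str = "oocyte"
    #: list of (slice_index, vertices) with vertices an (N, 2) array of (x, y)
    polygons: list[tuple[int, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise RoiValidationError(f"unknown ROI kind {self.kind!r}")
        self.polygons = [(int(z), np.asarray(v, dtype=float)) for z, v in self.polygons]
        for z, verts in self.polygons:
            if z < 0:
                raise RoiValidationError(f"unit {self.name!r}: negative slice index {z}")
            if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
                raise RoiValidationError(
                    f"unit {self.name!r}, slice {z}: polygon needs >=3 (x, y) vertices"
                )

    def slices(self) -> list[int]:
        return sorted({z for z, _ in self.polygons})


@dataclass
class RoiSet:
    """A collection of ROI units belonging to one image stack."""

    units: list[RoiUnit] = field(default_factory=list)

    def __iter__(self):
        return iter(self.units)

    def __len__(self) -> int:
        return len(self.units)

    def unit(self, name: str) -> RoiUnit:
        for u in self.units:
            if u.name == name:
                return u
        raise KeyError(name)


def _validated_polygon(verts: np.ndarray, name: str, z: int) -> Polygon:
    poly = Polygon(verts)
    if not poly.is_valid:
        raise RoiValidationError(
            f"unit {name!r}, slice {z}: polygon is not simple "
            f"({explain_validity(poly)})"
        )
    if poly.area == 0:
        raise RoiValidationError(f"unit {name!r}, slice {z}: polygon has zero area")
    return poly


def rasterize_unit(unit: RoiUnit, grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Rasterize a unit's per-slice polygons into a 3-D boolean mask.

    A voxel at index ``(z, y, x)`` is in-mask iff slice ``z`` carries a
    polygon whose interior contains the point ``(x, y)``.  Slices without a
    polygon are all-False.
    """
    nz, ny, nx = grid_shape
    mask = np.zeros(grid_shape, dtype=bool)
    for z, verts in unit.polygons:
        if z >= nz:
            raise RoiValidationError(
                f"unit {unit.name!r}: slice {z} outside stack of {nz} slices"
            )
        poly = _validated_polygon(verts, unit.name, z)
        x0 = max(int(np.floor(verts[:, 0].min())), 0)
        x1 = min(int(np.ceil(verts[:, 0].max())), nx - 1)
        y0 = max(int(np.floor(verts[:, 1].min())), 0)
        y1 = min(int(np.ceil(verts[:, 1].max())), ny - 1)
        if x1 < x0 or y1 < y0:
            continue
        ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
        inside = shapely.contains_xy(poly, xs.ravel(), ys.ravel()).reshape(xs.shape)
        mask[z, y0 : y1 + 1, x0 : x1 + 1] |= inside
    return mask


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def roiset_to_json(rois: RoiSet, path) -> None:
    doc = {
        "units": [
            {
                "name": u.name,
                "kind": u.kind,
                "polygons": [
                    {"slice": z, "vertices": v.tolist()} for z, v in u.polygons
                ],
            }
            for u in rois.units
        ]
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def roiset_from_json(path) -> RoiSet:
    with open(path) as fh:
        doc = json.load(fh)
    units = [
        RoiUnit(
            name=u["name"],
            kind=u.get("kind", "oocyte"),
            polygons=[(p["slice"], np.asarray(p["vertices"])) for p in u["polygons"]],
        )
        for u in doc["units"]
    ]
    return RoiSet(units)


# ---------------------------------------------------------------------------
# ImageJ .roi polygon archives
# ---------------------------------------------------------------------------
# Minimal codec for the ImageJ ROI binary format, polygon type only.  The
# 64-byte header stores "Iout", a version, the ROI type, the bounding box,
# the vertex count and (at offset 56) the 1-based slice position; vertex
# coordinates follow as int16 offsets from the bounding-box corner.

_ROI_POLYGON = 0


def _encode_roi(verts: np.ndarray, z: int) -> bytes:
    xs = np.round(verts[:, 0]).astype(int)
    ys = np.round(verts[:, 1]).astype(int)
    left, top = int(xs.min()), int(ys.min())
    right, bottom = int(xs.max()), int(ys.max())
    n = len(xs)
    header = bytearray(64)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, 228)  # version
    header[6] = _ROI_POLYGON
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    struct.pack_into(">i", header, 56, z + 1)  # 1-based slice position
    body = struct.pack(f">{n}h", *(xs - left)) + struct.pack(f">{n}h", *(ys - top))
    return bytes(header) + body


def _decode_roi(blob: bytes) -> tuple[int, np.ndarray]:
    if blob[0:4] != b"Iout":
        raise RoiValidationError("not an ImageJ ROI (bad magic)")
    roi_type = blob[6]
    if roi_type != _ROI_POLYGON:
        raise RoiValidationError(f"unsupported ImageJ ROI type {roi_type} (polygon only)")
    top, left, _bottom, _right = struct.unpack_from(">4h", blob, 8)
    (n,) = struct.unpack_from(">h", blob, 16)
    (position,) = struct.unpack_from(">i", blob, 56)
    xs = np.array(struct.unpack_from(f">{n}h", blob, 64)) + left
    ys = np.array(struct.unpack_from(f">{n}h", blob, 64 + 2 * n)) + top
    z = max(position - 1, 0)
    return z, np.stack([xs, ys], axis=1).astype(float)


def roiset_to_imagej_zip(rois: RoiSet, path) -> None:
    """Write each per-slice polygon as ``<unit>-<slice>.roi`` inside a zip."""
    with zipfile.ZipFile(path, "w") as zf:
        for u in rois.units:
            for z, verts in u.polygons:
                zf.writestr(f"{u.name}-{z:04d}.roi", _encode_roi(verts, z))


def roiset_from_imagej_zip(path, kind: str = "oocyte") -> RoiSet:
    """Read a zip of ImageJ polygon ROIs, grouping files by unit-name prefix.

    File names of the form ``<unit>-<digits>.roi`` group into one unit; other
    names each become their own unit.  The ROI kind is not representable in
    the ImageJ format and must be supplied.
    """
    groups: dict[str, list[tuple[int, np.ndarray]]] = {}
    with zipfile.ZipFile(path) as zf:
        for info in sorted(zf.infolist(), key=lambda i: i.filename):
            if not info.filename.lower().endswith(".roi"):
                continue
            z, verts = _decode_roi(zf.read(info))
            stem = info.filename[:-4]
            base, _, suffix = stem.rpartition("-")
            unit_name = base if base and suffix.isdigit() else stem
            groups.setdefault(unit_name, []).append((z, verts))
    units = [RoiUnit(name=n, kind=kind, polygons=p) for n, p in groups.items()]
    return RoiSet(units)
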