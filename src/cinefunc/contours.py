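"""Masks <-> epicardial/endocardial contour polylines, and the CON-TXT v1 file dialect.

Clinical CMR software stores LV segmentations as contour files rather than
masks: one closed endocardial polyline (blood pool-myocardium border) and
one epicardial polyline (outer myocardial border) per slice/phase. This
module converts between 3-class label masks and such polylines, and defines
CON-TXT v1, a documented plain-text contour container used wherever a scan's
segmentation must round-trip through files.

Coordinate convention (fixed for round trips): 0-based pixel indices,
vertices as (x=column, y=row) at pixel-center coordinates.

CON-TXT v1 layout (UTF-8, LF):

    #CONTXT 1
    scan <id>
    spacing <dx> <dy> <dz>
    contour <slice> <phase> <endo|epi> <n>
    <x> <y>            (n vertex lines)
    ...

Contours are ordered by slice, then phase, endo before epi.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage
from skimage import measure

logger = logging.getLogger(__name__)

_FORMAT_VERSION = 1


@dataclass
class ContourPair:
    """Optional endo- and epicardial closed polylines for one slice/phase.

    Polylines are arrays of (x, y) vertices; the last vertex is implicitly
    joined to the first. ``None`` means the boundary is absent (no label).
    """

    endo: np.ndarray | None = None
    epi: np.ndarray | None = None
    slice_index: int = 0
    phase_index: int = 0


@dataclass
class ContourFile:
    scan_id: str
    pixel_spacing_mm: tuple[float, float] = (0.4, 0.4)
    slice_thickness_mm: float = 6.0
    contours: list[ContourPair] = field(default_factory=list)


def _largest_component(region: np.ndarray, what: str) -> np.ndarray:
    labeled, n = measure.label(region, return_num=True, connectivity=1)
    if n <= 1:
        return region
    sizes = np.bincount(labeled.ravel())[1:]
    keep = int(np.argmax(sizes)) + 1
    logger.info("%s has %d connected components; keeping the largest", what, n)
    return labeled == keep


def _trace_boundary(region: np.ndarray) -> np.ndarray | None:
    """Closed boundary polyline of a binary region, (x, y) pixel-center coords.

    Iso-contour tracing at the 0.5 level of the region indicator; holes are
    filled first (papillary muscles belong to the blood pool, and the
    epicardial border must enclose the cavity).
    """
    if not region.any():
        return None
    filled = ndimage.binary_fill_holes(region)
    padded = np.pad(filled.astype(float), 1)
    paths = measure.find_contours(padded, 0.5)
    if not paths:
        return None
    path = max(paths, key=len)
    rc = path - 1.0  # undo padding; (row, col)
    xy = np.column_stack([rc[:, 1], rc[:, 0]])
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    return xy


def mask_to_contours(mask: np.ndarray, slice_index: int = 0,
                     phase_index: int = 0) -> ContourPair:
    """Extract the endocardial and epicardial boundaries of a 3-class mask.

    endo traces the cavity (label 1), epi the union cavity ∪ myocardium
    (labels 1 and 2). Absent regions give absent contours; multiple connected
    components reduce to the largest, with a log record.
    """
    mask = np.asarray(mask)
    if not np.isin(np.unique(mask), (0, 1, 2)).all():
        raise ValueError("mask labels must be within {0,1,2}")
    cavity = _largest_component(mask == 1, "cavity")
    union = mask > 0
    if union.any():
        union = _largest_component(union, "epicardial region")
    return ContourPair(
        endo=_trace_boundary(cavity),
        epi=_trace_boundary(union) if union.any() else None,
        slice_index=slice_index,
        phase_index=phase_index,
    )


def _fill_polygon(poly: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    # tiny positive radius keeps pixel centers lying exactly on the traced
    # 0.5-level boundary inside, which makes mask->contour->mask exact
    inside = MplPath(poly).contains_points(pts, radius=1e-9)
    return inside.reshape(shape)


def contours_to_mask(cp: ContourPair, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a contour pair: inside endo -> 1, inside epi but not endo -> 2.

    A pixel belongs to a region when its center lies inside the polygon.
    """
    mask = np.zeros(shape, dtype=np.uint8)
    epi_fill = _fill_polygon(np.asarray(cp.epi, float), shape) if cp.epi is not None else None
    endo_fill = _fill_polygon(np.asarray(cp.endo, float), shape) if cp.endo is not None else None
    if endo_fill is not None and epi_fill is not None:
        if np.any(endo_fill & ~epi_fill):
            raise ValueError("endocardial contour extends outside the epicardial contour")
    if epi_fill is not None:
        mask[epi_fill] = 2
    if endo_fill is not None:
        mask[endo_fill] = 1
    return mask


def polygon_area(poly: np.ndarray) -> float:
    """Shoelace area of a closed polygon given as (x, y) vertices."""
    p = np.asarray(poly, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class ContourParseError(ValueError):
    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def write_contour_file(cf: ContourFile, path: str | Path) -> None:
    """Serialize to CON-TXT v1 with deterministic ordering."""
    lines = [f"#CONTXT {_FORMAT_VERSION}",
             f"scan {cf.scan_id}",
             "spacing {:.17g} {:.17g} {:.17g}".format(
                 cf.pixel_spacing_mm[0], cf.pixel_spacing_mm[1], cf.slice_thickness_mm)]
    for cp in sorted(cf.contours, key=lambda c: (c.slice_index, c.phase_index)):
        for kind, poly in (("endo", cp.endo), ("epi", cp.epi)):
            if poly is None:
                continue
            poly = np.asarray(poly, dtype=float)
            lines.append(f"contour {cp.slice_index} {cp.phase_index} {kind} {len(poly)}")
            lines.extend("{:.17g} {:.17g}".format(x, y) for x, y in poly)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_contour_file(path: str | Path) -> ContourFile:
    """Parse a CON-TXT v1 file; malformed input raises with the line number."""
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise ContourParseError(1, "empty file")
    header = lines[0].split()
    if len(header) != 2 or header[0] != "#CONTXT":
        raise ContourParseError(1, f"not a CON-TXT file: {lines[0]!r}")
    if header[1] != str(_FORMAT_VERSION):
        raise ContourParseError(1, f"unsupported CON-TXT version {header[1]!r}")

    scan_id = None
    spacing = None
    pairs: dict[tuple[int, int], ContourPair] = {}
    order: list[tuple[int, int]] = []
    i = 1
    while i < len(lines):
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        if parts[0] == "scan":
            scan_id = " ".join(parts[1:])
        elif parts[0] == "spacing":
            if len(parts) != 4:
                raise ContourParseError(i + 1, "spacing needs three values")
            spacing = tuple(float(v) for v in parts[1:])
        elif parts[0] == "contour":
            if len(parts) != 5 or parts[3] not in ("endo", "epi"):
                raise ContourParseError(i + 1, f"malformed contour header: {lines[i]!r}")
            s, p, kind, n = int(parts[1]), int(parts[2]), parts[3], int(parts[4])
            verts = []
            for j in range(n):
                i += 1
                if i >= len(lines):
                    raise ContourParseError(i + 1, "unexpected end of file inside contour")
                xy = lines[i].split()
                if len(xy) != 2:
                    raise ContourParseError(i + 1, f"expected 'x y', got {lines[i]!r}")
                verts.append((float(xy[0]), float(xy[1])))
            key = (s, p)
            if key not in pairs:
                pairs[key] = ContourPair(slice_index=s, phase_index=p)
                order.append(key)
            setattr(pairs[key], kind, np.asarray(verts, dtype=float))
        else:
            raise ContourParseError(i + 1, f"unknown directive {parts[0]!r}")
        i += 1
    if scan_id is None or spacing is None:
        raise ContourParseError(len(lines), "missing scan or spacing header")
    return ContourFile(scan_id=scan_id,
                       pixel_spacing_mm=(spacing[0], spacing[1]),
                       slice_thickness_mm=spacing[2],
                       contours=[pairs[k] for k in order])


def masks_to_contour_file(masks: np.ndarray, scan_id: str,
                          pixel_spacing_mm: tuple[float, float],
                          slice_thickness_mm: float) -> ContourFile:
    """Extract contours for every labeled frame of a (slice, phase, ...) stack."""
    out = ContourFile(scan_id, pixel_spacing_mm, slice_thickness_mm)
    for s in range(masks.shape[0]):
        for p in range(masks.shape[1]):
            if not masks[s, p].any():
                continue
            out.contours.append(mask_to_contours(masks[s, p], s, p))
    return out
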