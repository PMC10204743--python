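"""Oriented-midrib geometry: components, convex hulls, minimum-area rectangles.

Each connected component of the ridge mask is reduced to its convex hull and
the minimum-area enclosing rectangle (rotating calipers: the optimal rectangle
has one side collinear with a hull edge).  The rectangle's long side gives the
midrib azimuth; folding against the row direction yields the row-relative
azimuth in [0, 90] used by every downstream statistic.

Coordinates are (x, y) = (column, row).  Angles are degrees; line orientations
are 180-degree periodic and reported in [0, 180).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

logger = logging.getLogger(__name__)

__all__ = [
    "Rect",
    "MidribRecord",
    "extract_components",
    "convex_hull",
    "min_area_rect",
    "relative_azimuth",
    "extract_midribs",
    "filter_rectangles",
    "midrib_table",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Rect:
    """Oriented rectangle: center, side lengths (length >= width), angle of the
    long side in [0, 180) degrees."""

    center: tuple[float, float]
    length: float
    width: float
    angle_deg: float

    @property
    def area(self) -> float:
        return self.length * self.width

    @property
    def aspect(self) -> float:
        """length/width; infinite for degenerate (zero-width) rectangles."""
        return float("inf") if self.width == 0 else self.length / self.width


@dataclass
class MidribRecord:
    """One detected midrib candidate and its derived orientation."""

    component_id: int
    pixels: np.ndarray            # (n, 2) int array of (row, col)
    hull: np.ndarray              # (m, 2) float array of (x, y), CCW
    rect: Rect
    azimuth_deg: float            # long-side orientation, [0, 180)
    rel_azimuth_deg: float        # folded against the row direction, [0, 90]
    kept: bool = True
    degenerate: bool = False

    @property
    def pixel_count(self) -> int:
        return len(self.pixels)


def extract_components(mask: np.ndarray) -> list[np.ndarray]:
    """8-connected components of a binary mask.

    Returns a list of (n, 2) integer arrays of (row, col) pixel coordinates,
    ordered by the row-major position of each component's first pixel (the
    order `scipy.ndimage.label` assigns), so output is deterministic.
    """
    mask = np.asarray(mask).astype(bool)
    labels, n = ndi.label(mask, structure=_STRUCT8)
    out = []
    for idx in ndi.value_indices(labels, ignore_value=0).values():
        out.append(np.column_stack(idx))
    assert len(out) == n
    return out


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Convex hull of 2-D points by Andrew's monotone chain.

    Returns hull vertices counter-clockwise with collinear interior points
    excluded.  Degenerate inputs are handled rather than rejected: all points
    identical gives a single vertex, collinear points give the two extreme
    endpoints (a segment).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("points must be a non-empty (n, 2) array")
    uniq = np.unique(pts, axis=0)            # sorts lexicographically (x, then y)
    if len(uniq) == 1:
        logger.debug("degenerate single-vertex hull")
        return uniq
    if len(uniq) == 2:
        return uniq

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    def half(seq):
        h: list[np.ndarray] = []
        for p in seq:
            while len(h) >= 2 and cross(h[-2], h[-1], p) <= 0:
                h.pop()
            h.append(p)
        return h

    lower = half(uniq)
    upper = half(uniq[::-1])
    hull = np.array(lower[:-1] + upper[:-1])
    if len(hull) == 2:
        logger.debug("degenerate collinear hull (segment)")
    return hull


def min_area_rect(hull: np.ndarray) -> Rect:
    """Minimum-area enclosing rectangle of a convex hull (rotating calipers).

    The optimal rectangle has a side collinear with some hull edge, so it
    suffices to scan the hull edges, computing for each the bounding box in
    the frame aligned with that edge, and keep the smallest.  A two-vertex
    hull yields a zero-width rectangle along the segment.

    Raises
    ------
    ValueError
        For a single-point hull (no orientation is defined).
    """
    hull = np.asarray(hull, dtype=float)
    if hull.ndim != 2 or hull.shape[1] != 2:
        raise ValueError("hull must be an (m, 2) array")
    if len(hull) < 2:
        raise ValueError("minimum-area rectangle undefined for a single point")

    edges = np.roll(hull, -1, axis=0) - hull
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    valid = lengths > 0
    if not valid.any():
        raise ValueError("hull has no extent")
    u = edges[valid] / lengths[valid, None]       # (k, 2) unit edge directions
    v = np.stack([-u[:, 1], u[:, 0]], axis=1)     # perpendiculars

    proj_u = hull @ u.T                           # (m, k)
    proj_v = hull @ v.T
    ext_u = proj_u.max(axis=0) - proj_u.min(axis=0)
    ext_v = proj_v.max(axis=0) - proj_v.min(axis=0)
    areas = ext_u * ext_v
    k = int(np.argmin(areas))

    cu = (proj_u[:, k].max() + proj_u[:, k].min()) / 2.0
    cv = (proj_v[:, k].max() + proj_v[:, k].min()) / 2.0
    center = cu * u[k] + cv * v[k]
    a, b = ext_u[k], ext_v[k]
    if a >= b:
        length, width, direction = a, b, u[k]
    else:
        length, width, direction = b, a, v[k]
    angle = np.degrees(np.arctan2(direction[1], direction[0])) % 180.0
    return Rect(center=(float(center[0]), float(center[1])),
                length=float(length), width=float(width),
                angle_deg=float(angle))


def relative_azimuth(azimuth_deg, row_azimuth_deg):
    """Fold a line orientation against the row direction into [0, 90] degrees.

    0 means parallel to the rows, 90 perpendicular.  Orientations are axial
    (180-degree periodic), so delta = |azimuth - row| mod 180 and the result
    is min(delta, 180 - delta).  Vectorised over either argument.
    """
    delta = np.abs(np.asarray(azimuth_deg, dtype=float)
                   - np.asarray(row_azimuth_deg, dtype=float)) % 180.0
    out = np.minimum(delta, 180.0 - delta)
    return float(out) if out.ndim == 0 else out


def extract_midribs(mask: np.ndarray, row_azimuth_deg: float,
                    min_aspect: float = 3.0,
                    iqr_factor: float = 1.5) -> list[MidribRecord]:
    """Full mask-to-midrib chain: components -> hull -> min-area rect ->
    row-relative azimuth -> rectangle denoising (kept flags)."""
    records: list[MidribRecord] = []
    for cid, pix in enumerate(extract_components(mask)):
        xy = pix[:, ::-1].astype(float)          # (row, col) -> (x, y)
        hull = convex_hull(xy)
        if len(hull) < 2:
            records.append(MidribRecord(
                component_id=cid, pixels=pix, hull=hull,
                rect=Rect((float(hull[0, 0]), float(hull[0, 1])), 0.0, 0.0, 0.0),
                azimuth_deg=np.nan, rel_azimuth_deg=np.nan,
                kept=False, degenerate=True))
            continue
        rect = min_area_rect(hull)
        az = rect.angle_deg
        records.append(MidribRecord(
            component_id=cid, pixels=pix, hull=hull, rect=rect,
            azimuth_deg=az,
            rel_azimuth_deg=relative_azimuth(az, row_azimuth_deg),
            degenerate=len(hull) == 2))
    return filter_rectangles(records, min_aspect=min_aspect,
                             iqr_factor=iqr_factor)


def filter_rectangles(records: list[MidribRecord], min_aspect: float = 3.0,
                      iqr_factor: float = 1.5) -> list[MidribRecord]:
    """Flag rectangle outliers caused by Hessian artifacts; nothing is deleted.

    A record is kept iff (a) its aspect ratio length/width >= ``min_aspect``
    (zero width counts as infinite aspect) and (b) its log-area lies inside
    the Tukey fence [Q1 - f*IQR, Q3 + f*IQR] of the per-image log-area
    distribution.  With fewer than 4 area values the fence is meaningless and
    only the aspect rule applies.
    """
    if not records:
        return records
    cand = [r for r in records if not (r.degenerate and len(r.hull) < 2)]
    areas = np.array([r.rect.area for r in cand])
    pos = areas[areas > 0]
    if len(pos) >= 4:
        logs = np.log(pos)
        q1, q3 = np.percentile(logs, [25, 75])
        fence = (q1 - iqr_factor * (q3 - q1), q3 + iqr_factor * (q3 - q1))
    else:
        fence = None
        logger.info("fewer than 4 positive-area rectangles; "
                    "IQR fence skipped, aspect rule only")
    for r in cand:
        ok = r.rect.aspect >= min_aspect
        if ok and fence is not None:
            la = np.log(r.rect.area) if r.rect.area > 0 else -np.inf
            ok = fence[0] <= la <= fence[1]
        r.kept = bool(ok)
    return records


def midrib_table(records: list[MidribRecord]) -> pd.DataFrame:
    """Tabulate midrib records (one row per component)."""
    rows = [{
        "component_id": r.component_id,
        "pixel_count": r.pixel_count,
        "center_x": r.rect.center[0],
        "center_y": r.rect.center[1],
        "length_px": r.rect.length,
        "width_px": r.rect.width,
        "azimuth_deg": r.azimuth_deg,
        "rel_azimuth_deg": r.rel_azimuth_deg,
        "kept": r.kept,
    } for r in records]
    cols = ["component_id", "pixel_count", "center_x", "center_y",
            "length_px", "width_px", "azimuth_deg", "rel_azimuth_deg", "kept"]
    return pd.DataFrame(rows, columns=cols)
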