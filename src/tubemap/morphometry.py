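"""Cell morphometry and classification on unwrapped 2D maps.

Coordinates are map micrometres: X circumferential (periodic with the
circumference ``C``), Y axial.  Contours traced on a duplicated map may
have X anywhere in ``[0, 2C)``; all measurements are invariant under theta
origin shifts and map duplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely import affinity

from .errors import ContourError

CATEGORY_EHT = "EHT"
CATEGORY_HEMOGENIC = "hemogenic"
CATEGORY_ENDOTHELIAL = "endothelial"
DEFAULT_NEIGHBOR_EPS = 0.5  # um


@dataclass
class MapFrame:
    """Circumferential landmarks of one map: floor, roof, medio-lateral axes."""

    circumference: float          # C, um
    floor_x: float                # ventral floor axis, um in [0, C)

    def __post_init__(self) -> None:
        if self.circumference <= 0:
            raise ContourError("circumference must be > 0")
        self.floor_x = float(np.mod(self.floor_x, self.circumference))

    @property
    def roof_x(self) -> float:
        return float(np.mod(self.floor_x + self.circumference / 2, self.circumference))

    @property
    def lateral_x(self) -> tuple[float, float]:
        c = self.circumference
        return (
            float(np.mod(self.floor_x - c / 4, c)),
            float(np.mod(self.floor_x + c / 4, c)),
        )


@dataclass
class CellRecord:
    id: object
    contour: np.ndarray
    category: str
    length: float       # um, axial extent
    width: float        # um, circumferential extent
    area: float         # um^2
    neighbor_ids: set = field(default_factory=set)


def _as_polygon(contour: np.ndarray) -> Polygon:
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[1] != 2 or contour.shape[0] < 3:
        raise ContourError("contour needs >= 3 (x, y) vertices")
    poly = Polygon(contour)
    if not poly.is_valid or poly.area == 0:
        raise ContourError("contour is self-intersecting or degenerate")
    return poly


def polygon_area(contour: np.ndarray, pixel_size: float = 1.0) -> float:
    """Shoelace area of a simple polygon, orientation independent.

    ``pixel_size`` scales pixel-unit contours to micrometres (areas scale by
    its square); contours already in micrometres use the default of 1.
    """
    _as_polygon(contour)  # simplicity check
    pts = np.asarray(contour, dtype=float) * pixel_size
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)


def bounding_rect(
    contour: np.ndarray, pixel_size: float = 1.0, rotated: bool = False
) -> tuple[float, float]:
    """Best-fit rectangle extents: ``(length, width)`` in um.

    Default is the axis-aligned bounding rectangle in map coordinates:
    length is the extent along Y (axial, parallel to the flow axis), width
    along X (circumferential).  With ``rotated=True`` the minimum-area
    rotated rectangle is used instead; its side most aligned with Y is
    reported as the length.
    """
    poly = _as_polygon(contour)
    poly = affinity.scale(poly, xfact=pixel_size, yfact=pixel_size, origin=(0, 0))
    if not rotated:
        minx, miny, maxx, maxy = poly.bounds
        return (maxy - miny, maxx - minx)
    rect = poly.minimum_rotated_rectangle
    coords = np.asarray(rect.exterior.coords)[:4]
    e1 = coords[1] - coords[0]
    e2 = coords[2] - coords[1]
    s1, s2 = np.linalg.norm(e1), np.linalg.norm(e2)
    # side whose direction leans more along Y is the length
    if s1 > 0 and abs(e1[1]) / s1 >= (abs(e2[1]) / s2 if s2 > 0 else 0):
        return (float(s1), float(s2))
    return (float(s2), float(s1))


def _circular_span(xs: np.ndarray, circumference: float) -> tuple[float, float]:
    """Occupied arc of vertex X positions on the circle: (start, extent).

    The occupied arc is the complement of the largest angular gap between
    consecutive (sorted, mod-C) vertex positions.
    """
    c = circumference
    u = np.sort(np.unique(np.mod(xs, c)))
    if u.size == 1:
        return float(u[0]), 0.0
    gaps = np.diff(np.concatenate([u, [u[0] + c]]))
    k = int(np.argmax(gaps))
    start = u[(k + 1) % u.size]
    extent = c - gaps[k]
    return float(start), float(extent)


def classify_cell(
    contour: np.ndarray,
    frame: MapFrame,
    eht_annotation: bool = False,
) -> str:
    """Assign EHT / hemogenic / endothelial from position on the map.

    EHT identity is morphological/temporal and therefore user-supplied via
    ``eht_annotation``.  Otherwise a cell is *hemogenic* when its
    circumferential span covers the ventral floor axis while staying
    strictly within the two medio-lateral axes; everything else is
    *endothelial*.  The result is invariant under theta-origin shifts.
    """
    contour = np.asarray(contour, dtype=float)
    c = frame.circumference
    raw_extent = contour[:, 0].max() - contour[:, 0].min()
    if raw_extent > c + 1e-9:
        raise ContourError(f"contour spans {raw_extent:.3g} um > circumference {c:.3g} um")
    if eht_annotation:
        return CATEGORY_EHT
    start, extent = _circular_span(contour[:, 0], c)
    # everything measured relative to the lower lateral axis (floor - C/4)
    lateral_lo = frame.floor_x - c / 4
    rel_start = np.mod(start - lateral_lo, c)
    within_laterals = rel_start > 0 and (rel_start + extent) < c / 2
    rel_floor = np.mod(frame.floor_x - start, c)
    covers_floor = rel_floor <= extent + 1e-9
    if covers_floor and within_laterals:
        return CATEGORY_HEMOGENIC
    return CATEGORY_ENDOTHELIAL


def count_neighbors(
    contours: dict,
    circumference: float | None = None,
    epsilon: float = DEFAULT_NEIGHBOR_EPS,
) -> dict:
    """Adjacency: two cells are neighbors iff their epsilon-dilated polygons
    overlap with positive area, taking circumferential wrap into account
    when ``circumference`` is given."""
    if epsilon < 0:
        raise ContourError("epsilon must be >= 0")
    polys = {cid: _as_polygon(v).buffer(epsilon) for cid, v in contours.items()}
    shifts = [0.0]
    if circumference is not None:
        shifts += [circumference, -circumference]
    neighbors: dict = {cid: set() for cid in contours}
    ids = list(contours)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            pa = polys[a]
            touching = False
            for s in shifts:
                pb = polys[b] if s == 0 else affinity.translate(polys[b], xoff=s)
                inter = pa.intersection(pb)
                if inter.area > 1e-12:
                    touching = True
                    break
            if touching:
                neighbors[a].add(b)
                neighbors[b].add(a)
    return neighbors


def measure_cells(
    contours: dict,
    frame: MapFrame,
    annotations: dict | None = None,
    epsilon: float = DEFAULT_NEIGHBOR_EPS,
    pixel_size: float = 1.0,
) -> pd.DataFrame:
    """Per-cell morphometrics + category + neighbor count as a DataFrame."""
    annotations = annotations or {}
    adj = count_neighbors(contours, circumference=frame.circumference, epsilon=epsilon)
    rows = []
    for cid, verts in contours.items():
        is_eht = str(annotations.get(cid, "")).strip().upper() == "EHT"
        length, width = bounding_rect(verts, pixel_size=pixel_size)
        rows.append(
            {
                "cell_id": cid,
                "category": classify_cell(
                    np.asarray(verts, float) * pixel_size, frame, eht_annotation=is_eht
                ),
                "length_um": length,
                "width_um": width,
                "area_um2": polygon_area(verts, pixel_size=pixel_size),
                "n_neighbors": len(adj[cid]),
            }
        )
    return pd.DataFrame(rows)


def group_stats(
    table: pd.DataFrame,
    value_cols: tuple[str, ...] = ("length_um", "width_um", "area_um2"),
    category_col: str = "category",
    map_col: str | None = None,
) -> pd.DataFrame:
    """Per-category mean +- SEM of morphometric columns.

    When ``map_col`` is given the statistics are computed over per-map means
    (n = number of maps); otherwise cells are pooled (n = number of cells).
    Both aggregations are labelled in the ``aggregation`` column.
    """
    def _stats(df: pd.DataFrame, aggregation: str) -> list[dict]:
        out = []
        for cat, grp in df.groupby(category_col):
            row = {"category": cat, "aggregation": aggregation, "n": len(grp)}
            for col in value_cols:
                vals = grp[col].to_numpy(float)
                row[f"{col}_mean"] = vals.mean()
                row[f"{col}_sem"] = (
                    vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
                )
            out.append(row)
        return out

    rows = _stats(table, "pooled_cells")
    if map_col is not None:
        per_map = (
            table.groupby([category_col, map_col])[list(value_cols)].mean().reset_index()
        )
        rows += _stats(per_map, "per_map_means")
    return pd.DataFrame(rows)
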