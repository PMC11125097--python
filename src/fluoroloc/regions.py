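"""Six-region frame partition and occlusion-case classification.

Each frame is divided into the central crop area (MC), four mirror areas
(TL, TR, BL, BR) and background (BG).  TL/BR and TR/BL are opposing mirror
pairs.  Which non-background regions contain fluorescence determines one of
16 localization cases (or NOT_FOUND), via the rule system:

* MC occupied                      -> Case 1 (direct extraction), always
* all four mirrors                 -> Case 2 (cross the two diagonals)
* three mirrors                    -> Cases 3-6 (diagonal x perpendicular)
* two non-opposite mirrors         -> Cases 7-10 (two perpendiculars)
* two opposite mirrors             -> Cases 11-12 (opposite-pair solver)
* one mirror                       -> Cases 13-16 (two-frame solver)
* nothing                          -> NOT_FOUND

The default layout puts MC as a centered axis-aligned rectangle, the mirror
areas as the four frame quadrants minus their MC overlap, and BG as a thin
border ring.  In the physical rig the mirror views fill most of the frame;
small corner patches could not contain the reflected images, whose offset
from the frame center grows like (b + 2d) * pixel_scale.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon, box
from shapely.prepared import prep

from .errors import InvalidLayoutError
from .pipeline import Blob

__all__ = [
    "CaseId",
    "RegionLayout",
    "RegionAssignment",
    "build_layout",
    "assign_blobs",
    "classify_case",
    "scenario_letter",
    "MIRRORS",
    "OPPOSITE",
    "ASSIGN_ORDER",
]

MIRRORS = ("TL", "TR", "BL", "BR")
INFORMATIVE = ("MC",) + MIRRORS
ASSIGN_ORDER = ("MC", "TL", "TR", "BL", "BR", "BG")
OPPOSITE = {"TL": "BR", "BR": "TL", "TR": "BL", "BL": "TR"}

_R2 = 1.0 / math.sqrt(2.0)
# Unit vector from the frame center toward each mirror corner, (col, row).
MIRROR_AXES = {
    "TL": np.array([-_R2, -_R2]),
    "TR": np.array([_R2, -_R2]),
    "BL": np.array([-_R2, _R2]),
    "BR": np.array([_R2, _R2]),
}


def edge_tangent(mirror: str) -> np.ndarray:
    """Unit direction of the mirror's bottom edge (90° CCW from its axis)."""
    w = MIRROR_AXES[mirror]
    return np.array([-w[1], w[0]])


class CaseId(enum.IntEnum):
    NOT_FOUND = 0
    CASE_1 = 1
    CASE_2 = 2
    CASE_3 = 3
    CASE_4 = 4
    CASE_5 = 5
    CASE_6 = 6
    CASE_7 = 7
    CASE_8 = 8
    CASE_9 = 9
    CASE_10 = 10
    CASE_11 = 11
    CASE_12 = 12
    CASE_13 = 13
    CASE_14 = 14
    CASE_15 = 15
    CASE_16 = 16


def scenario_letter(case: CaseId) -> str:
    """Scenario letter a-g for a case id."""
    if case == CaseId.CASE_1:
        return "a"
    if case == CaseId.CASE_2:
        return "b"
    if CaseId.CASE_3 <= case <= CaseId.CASE_6:
        return "c"
    if CaseId.CASE_7 <= case <= CaseId.CASE_10:
        return "e"
    if case in (CaseId.CASE_11, CaseId.CASE_12):
        return "d"
    if CaseId.CASE_13 <= case <= CaseId.CASE_16:
        return "f"
    return "g"


@dataclass(frozen=True)
class RegionLayout:
    """The six-region tiling of a frame plus the mirror edge lines.

    ``polygons`` maps region label to a shapely geometry; the six geometries
    tile the frame exactly.  ``mirror_edges`` maps each mirror to a segment
    of its bottom-edge line (used for the perpendicular constructions); the
    inward normal of that edge is ``-MIRROR_AXES[m]``.
    """

    width: int
    height: int
    polygons: dict
    mirror_edges: dict
    center: tuple[float, float]
    _prepared: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_prepared", {r: prep(p) for r, p in self.polygons.items()})

    def region_of(self, point: tuple[float, float]) -> str:
        """First region (in fixed order MC, TL, TR, BL, BR, BG) covering ``point``."""
        pt = Point(point)
        for region in ASSIGN_ORDER:
            if self._prepared[region].intersects(pt):
                return region
        return "BG"  # numerically outside every polygon: treat as background


def build_layout(
    width: int = 1024,
    height: int = 1024,
    mc_fraction: float = 0.3,
    margin_px: float = 8.0,
    edge_distance_px: float | None = None,
) -> RegionLayout:
    """Construct the default six-region tiling.

    ``mc_fraction`` is MC's side length as a fraction of the frame side;
    ``margin_px`` is the width of the BG border ring; ``edge_distance_px``
    places the (conceptual) mirror bottom-edge lines at that distance from
    the frame center along each corner diagonal (default: at MC's corner).
    """
    if width <= 0 or height <= 0:
        raise InvalidLayoutError("frame dimensions must be positive")
    if not 0 < mc_fraction < 1:
        raise InvalidLayoutError(f"mc_fraction must lie in (0, 1), got {mc_fraction}")
    if margin_px < 0 or 2 * margin_px >= min(width, height) * (1 - mc_fraction):
        raise InvalidLayoutError(f"margin_px {margin_px} leaves no room for mirror areas")
    cx, cy = width / 2.0, height / 2.0
    hw, hh = mc_fraction * width / 2.0, mc_fraction * height / 2.0
    if hw <= 0 or hh <= 0:
        raise InvalidLayoutError("MC rectangle is degenerate")
    m = margin_px
    frame = box(0, 0, width, height)
    inner = box(m, m, width - m, height - m)
    mc = box(cx - hw, cy - hh, cx + hw, cy + hh)
    quadrants = {
        "TL": box(m, m, cx, cy),
        "TR": box(cx, m, width - m, cy),
        "BL": box(m, cy, cx, height - m),
        "BR": box(cx, cy, width - m, height - m),
    }
    polygons = {name: quad.difference(mc) for name, quad in quadrants.items()}
    polygons["MC"] = mc
    polygons["BG"] = frame.difference(inner)
    _validate_tiling(polygons, width, height)

    if edge_distance_px is None:
        edge_distance_px = math.hypot(hw, hh)
    half = min(width, height) / 4.0
    edges = {}
    for mirror, w in MIRROR_AXES.items():
        foot = np.array([cx, cy]) + w * edge_distance_px
        t = edge_tangent(mirror)
        edges[mirror] = (tuple(foot - t * half), tuple(foot + t * half))
    return RegionLayout(
        width=width, height=height, polygons=polygons, mirror_edges=edges, center=(cx, cy)
    )


def _validate_tiling(polygons: dict, width: int, height: int) -> None:
    total = sum(p.area for p in polygons.values())
    if not math.isclose(total, width * height, rel_tol=1e-9):
        raise InvalidLayoutError(f"region areas sum to {total}, expected {width * height}")
    labels = list(polygons)
    for i, ri in enumerate(labels):
        for rj in labels[i + 1 :]:
            inter = polygons[ri].intersection(polygons[rj]).area
            if inter > 1e-6:
                raise InvalidLayoutError(f"regions {ri} and {rj} overlap (area {inter})")


@dataclass(frozen=True)
class RegionAssignment:
    """Blobs bucketed by region, with a per-region primary blob."""

    by_region: dict
    primary: dict

    def occupied(self) -> frozenset:
        """Informative (non-BG) regions containing at least one blob."""
        return frozenset(r for r in INFORMATIVE if self.by_region.get(r))


def assign_blobs(
    blobs: list[Blob], layout: RegionLayout, primary: str = "area"
) -> RegionAssignment:
    """Assign each blob to the region containing its centroid.

    Boundary centroids go to the first matching region in the fixed order
    MC, TL, TR, BL, BR, BG.  The per-region primary blob is the largest by
    area (``primary="area"``) or the brightest (``primary="brightness"``).
    """
    if primary not in ("area", "brightness"):
        raise ValueError(f"primary must be 'area' or 'brightness', got {primary!r}")
    by_region: dict[str, list[Blob]] = {r: [] for r in ASSIGN_ORDER}
    for blob in blobs:
        by_region[layout.region_of(blob.centroid)].append(blob)
    key = (lambda b: b.area) if primary == "area" else (lambda b: b.max_intensity)
    primaries = {r: max(bs, key=key) for r, bs in by_region.items() if bs}
    return RegionAssignment(by_region=by_region, primary=primaries)


# Case tables, straight from the rule listing.
_THREE_MIRROR_CASES = {
    frozenset({"TL", "BR", "TR"}): CaseId.CASE_3,
    frozenset({"TL", "BR", "BL"}): CaseId.CASE_4,
    frozenset({"TR", "BL", "TL"}): CaseId.CASE_5,
    frozenset({"TR", "BL", "BR"}): CaseId.CASE_6,
}
_TWO_MIRROR_CASES = {
    frozenset({"TR", "BR"}): CaseId.CASE_7,
    frozenset({"TL", "BL"}): CaseId.CASE_8,
    frozenset({"TL", "TR"}): CaseId.CASE_9,
    frozenset({"BL", "BR"}): CaseId.CASE_10,
    frozenset({"BL", "TR"}): CaseId.CASE_11,
    frozenset({"BR", "TL"}): CaseId.CASE_12,
}
_ONE_MIRROR_CASES = {
    frozenset({"TL"}): CaseId.CASE_13,
    frozenset({"BL"}): CaseId.CASE_14,
    frozenset({"TR"}): CaseId.CASE_15,
    frozenset({"BR"}): CaseId.CASE_16,
}


def classify_case(assign: RegionAssignment | frozenset) -> CaseId:
    """Map a region occupancy to its localization case.

    Accepts either a :class:`RegionAssignment` or a plain set of occupied
    region labels.  MC occupancy always dispatches to Case 1, matching the
    IF-ordering of the rule listing.
    """
    occupied = assign.occupied() if isinstance(assign, RegionAssignment) else frozenset(assign)
    if "MC" in occupied:
        return CaseId.CASE_1
    mirrors = frozenset(m for m in MIRRORS if m in occupied)
    if len(mirrors) == 4:
        return CaseId.CASE_2
    if len(mirrors) == 3:
        return _THREE_MIRROR_CASES[mirrors]
    if len(mirrors) == 2:
        return _TWO_MIRROR_CASES[mirrors]
    if len(mirrors) == 1:
        return _ONE_MIRROR_CASES[mirrors]
    return CaseId.NOT_FOUND
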