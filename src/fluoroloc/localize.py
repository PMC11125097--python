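"""Plant-center computation for the 16 occlusion cases.

Construction cases (1-10) use only blob centroids and line algebra: diagonal
connections between opposing-mirror blobs and perpendiculars dropped from a
blob onto its mirror's edge direction.  Solver cases (11-16) convert blob
positions to mirror-view coordinates along the pair axis, invert the
projection equations to recover the plant's lateral position ``a`` and height
``b``, and fuse the result back into a 2-D pixel center:

* the cross-edge pixel coordinate is ``a * pixel_scale`` along the pair axis
  through the frame center;
* the along-edge coordinate is taken from the blob centroid component
  parallel to the mirror edge, which a planar reflection preserves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateObservationError,
    FluorolocError,
    MissingSecondFrameError,
    ParallelLinesError,
)
from .geometry import FluorPoint, MirrorObservation, RigGeometry, solve_opposite, solve_single_mirror
from .regions import (
    MIRROR_AXES,
    CaseId,
    RegionAssignment,
    RegionLayout,
    classify_case,
    edge_tangent,
)

__all__ = [
    "LineSeg",
    "LocalizationResult",
    "intersect_lines",
    "perpendicular_through",
    "locate_center",
]

# For the solver cases the pair axis points toward the *top* mirror of the
# pair; the top mirror supplies the first (Eq.-3-form) coordinate.
_OPPOSITE_PAIRS = {CaseId.CASE_11: ("TR", "BL"), CaseId.CASE_12: ("TL", "BR")}
_SINGLE_MIRROR = {
    CaseId.CASE_13: "TL",
    CaseId.CASE_14: "BL",
    CaseId.CASE_15: "TR",
    CaseId.CASE_16: "BR",
}
_THREE_MIRROR = {
    CaseId.CASE_3: (("TL", "BR"), "TR"),
    CaseId.CASE_4: (("TL", "BR"), "BL"),
    CaseId.CASE_5: (("TR", "BL"), "TL"),
    CaseId.CASE_6: (("TR", "BL"), "BR"),
}
_TWO_MIRROR = {
    CaseId.CASE_7: ("TR", "BR"),
    CaseId.CASE_8: ("TL", "BL"),
    CaseId.CASE_9: ("TL", "TR"),
    CaseId.CASE_10: ("BL", "BR"),
}


@dataclass(frozen=True)
class LineSeg:
    """A segment (or infinite line) through two distinct pixel points."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    infinite: bool = True

    def __post_init__(self) -> None:
        if np.allclose(self.p0, self.p1):
            raise ValueError("LineSeg endpoints must be distinct")

    @property
    def direction(self) -> np.ndarray:
        d = np.asarray(self.p1, float) - np.asarray(self.p0, float)
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class LocalizationResult:
    """Outcome of one localization attempt.

    ``center_px`` is present iff the case is not NOT_FOUND and no degeneracy
    occurred; an out-of-frame intersection is flagged in ``status`` rather
    than clipped.
    """

    case_id: CaseId
    center_px: tuple[float, float] | None
    solver_output: FluorPoint | None = None
    status: str = "ok"
    diagnostics: dict = field(default_factory=dict)

    @property
    def success(self) -> bool:
        return self.status == "ok" and self.center_px is not None


def intersect_lines(l1: LineSeg, l2: LineSeg, angular_epsilon: float = 1e-6) -> tuple[float, float]:
    """Intersection point of the infinite extensions of two lines."""
    p = np.asarray(l1.p0, float)
    q = np.asarray(l2.p0, float)
    d1 = l1.direction
    d2 = l2.direction
    cross = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(cross) < angular_epsilon:  # |sin| of the angle between unit vectors
        raise ParallelLinesError("construction lines are parallel within epsilon")
    rhs = q - p
    t = (rhs[0] * d2[1] - rhs[1] * d2[0]) / cross
    pt = p + t * d1
    return (float(pt[0]), float(pt[1]))


def perpendicular_through(p: tuple[float, float], edge: LineSeg) -> LineSeg:
    """Infinite line through ``p`` perpendicular to a mirror edge."""
    d = edge.direction
    normal = np.array([-d[1], d[0]])
    q = (p[0] + normal[0], p[1] + normal[1])
    return LineSeg(p0=tuple(map(float, p)), p1=(float(q[0]), float(q[1])), infinite=True)


def _axis_line(p: tuple[float, float], axis: np.ndarray) -> LineSeg:
    return LineSeg(p0=tuple(map(float, p)), p1=(p[0] + axis[0], p[1] + axis[1]), infinite=True)


def _mirror_coord(centroid, center, axis) -> float:
    """Signed pixel offset of a blob centroid from the frame center along an axis."""
    rel = np.asarray(centroid, float) - np.asarray(center, float)
    return float(rel @ axis)


def locate_center(
    assign: RegionAssignment,
    layout: RegionLayout,
    g: RigGeometry,
    second_frame_assign: RegionAssignment | None = None,
    l: float | None = None,
) -> LocalizationResult:
    """Run the case dispatch and return the estimated plant center.

    ``second_frame_assign`` and ``l`` (travel distance, cm) are required for
    the single-mirror cases 13-16.  Degeneracies surface as a typed ``status``
    with the failing case recorded; no case fabricates a center.
    """
    case = classify_case(assign)
    try:
        center, solver_out, diag = _dispatch(case, assign, layout, g, second_frame_assign, l)
    except MissingSecondFrameError as exc:
        return LocalizationResult(case, None, status="missing_second_frame", diagnostics={"reason": str(exc)})
    except ParallelLinesError as exc:
        return LocalizationResult(case, None, status="parallel_lines", diagnostics={"reason": str(exc)})
    except (DegenerateObservationError, FluorolocError) as exc:
        return LocalizationResult(case, None, status="degenerate", diagnostics={"reason": str(exc)})
    if center is None:
        return LocalizationResult(case, None, status="not_found", diagnostics=diag)
    status = "ok"
    if not (0 <= center[0] <= layout.width and 0 <= center[1] <= layout.height):
        status = "out_of_frame"
    return LocalizationResult(case, center, solver_output=solver_out, status=status, diagnostics=diag)


def _dispatch(case, assign, layout, g, second, l):
    prim = assign.primary
    if case == CaseId.NOT_FOUND:
        return None, None, {"reason": "no fluorescence in any informative region"}
    if case == CaseId.CASE_1:
        return prim["MC"].centroid, None, {"blobs": ["MC"]}
    if case == CaseId.CASE_2:
        l1 = LineSeg(prim["TL"].centroid, prim["BR"].centroid)
        l2 = LineSeg(prim["TR"].centroid, prim["BL"].centroid)
        return intersect_lines(l1, l2), None, {"lines": ["TL-BR", "TR-BL"]}
    if case in _THREE_MIRROR:
        (m_a, m_b), extra = _THREE_MIRROR[case]
        diag_line = LineSeg(prim[m_a].centroid, prim[m_b].centroid)
        perp = _axis_line(prim[extra].centroid, MIRROR_AXES[extra])
        return (
            intersect_lines(diag_line, perp),
            None,
            {"lines": [f"{m_a}-{m_b}", f"perp@{extra}"]},
        )
    if case in _TWO_MIRROR:
        m1, m2 = _TWO_MIRROR[case]
        p1 = _axis_line(prim[m1].centroid, MIRROR_AXES[m1])
        p2 = _axis_line(prim[m2].centroid, MIRROR_AXES[m2])
        return intersect_lines(p1, p2), None, {"lines": [f"perp@{m1}", f"perp@{m2}"]}
    if case in _OPPOSITE_PAIRS:
        return _solve_opposite_case(case, prim, layout, g)
    if case in _SINGLE_MIRROR:
        if second is None or l is None:
            raise MissingSecondFrameError(
                f"case {int(case)} needs a second frame and travel distance"
            )
        return _solve_single_case(case, prim, second, layout, g, l)
    raise FluorolocError(f"unhandled case {case!r}")  # pragma: no cover


def _solve_opposite_case(case, prim, layout, g):
    top, bottom = _OPPOSITE_PAIRS[case]
    w = MIRROR_AXES[top]
    t = edge_tangent(top)
    s = g.pixel_scale
    d = g.mirror_offset_cm
    c_top = prim[top].centroid
    c_bot = prim[bottom].centroid
    x = _mirror_coord(c_top, layout.center, w) / s - d
    o_bot = _mirror_coord(c_bot, layout.center, w)
    if g.eq4_variant == "printed":
        x1 = o_bot / s + d
    else:
        x1 = -o_bot / s - d
    sol = solve_opposite(MirrorObservation(x=x, x1=x1), g)
    tau = 0.5 * (_mirror_coord(c_top, layout.center, t) + _mirror_coord(c_bot, layout.center, t))
    center = np.asarray(layout.center) + w * (sol.a * s) + t * tau
    diag = {"pair": f"{top}-{bottom}", "x": x, "x1": x1}
    return (float(center[0]), float(center[1])), sol, diag


def _solve_single_case(case, prim, second, layout, g, l):
    mirror = _SINGLE_MIRROR[case]
    w = MIRROR_AXES[mirror]
    t = edge_tangent(mirror)
    s = g.pixel_scale
    d = g.mirror_offset_cm
    blob1 = prim[mirror]
    candidates = second.by_region.get(mirror, [])
    if not candidates:
        raise DegenerateObservationError(f"no blob in {mirror} in the second frame")
    c1 = np.asarray(blob1.centroid, float)
    blob2 = min(candidates, key=lambda b: float(np.hypot(*(np.asarray(b.centroid) - c1))))
    x1 = _mirror_coord(blob1.centroid, layout.center, w) / s - d
    x2 = _mirror_coord(blob2.centroid, layout.center, w) / s - d
    sol = solve_single_mirror(MirrorObservation(x1=x1, x2=x2, frame_travel_l=l), g)
    tau = _mirror_coord(blob1.centroid, layout.center, t)
    center = np.asarray(layout.center) + w * (sol.a * s) + t * tau
    diag = {"mirror": mirror, "x1": x1, "x2": x2, "l": l}
    return (float(center[0]), float(center[1])), sol, diag
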