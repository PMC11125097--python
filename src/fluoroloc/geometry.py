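"""Mirror-view projection geometry.

The imaging chamber views the plant from above (central area) and through four
inclined planar mirrors (corner areas).  Along the axis of a mirror pair the
apparent position ``x`` of a fluorescent point in a mirror view depends on the
point's lateral position ``a`` and height ``b`` above the reference plane, the
camera height ``c`` and the mirror-edge offset ``d`` (all in cm):

    x  = (b + d)(c + d) / (-a + b + c + 2 d)          (single view)
    x1 = (b + d)(c + d) / (b - a - c)                 (opposing view)

For a static plant observed in one mirror across two frames separated by a
camera travel ``l`` at mirror angle ``theta``:

    x1 = N / (-a1 + b + c + 2 d),   x2 = N / (-a2 + b + c + 2 d),
    a2 = a1 + l sin(theta),         N = (b + d)(c + d).

This module implements the forward maps and their closed-form inversions.  The
two opposing-view equations are implemented exactly as printed; note that the
second is *not* the mirror image of the first (its denominator lacks the
``+2d`` term).  A ``symmetric`` variant with denominator ``a + b + c + 2d`` is
available for physical-plausibility experiments; the synthetic renderer always
uses the same variant the solver inverts, so the pair is self-consistent either
way.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from .errors import (
    ConfigurationError,
    DegenerateObservationError,
    SingularGeometryError,
)

__all__ = [
    "RigGeometry",
    "FluorPoint",
    "MirrorObservation",
    "forward_single_view",
    "forward_opposite_pair",
    "solve_opposite",
    "forward_two_frames",
    "solve_single_mirror",
    "convert_coords",
]


@dataclass(frozen=True)
class RigGeometry:
    """World-unit parameters of the imaging rig.

    Parameters
    ----------
    camera_height_cm
        Height ``c`` of the camera above the reference (bed) plane.
    mirror_offset_cm
        Distance ``d`` from the bottom edge of each mirror to the chamber
        center, measured in the reference plane.
    mirror_angle_deg
        Angle ``theta`` between the mirror and the direction of travel.
    pixel_scale
        Pixels per centimeter in the image plane.  87 px/cm corresponds to
        the full-resolution sensor; desk-scale simulations use a smaller
        value.
    travel_axis
        Unit direction of camera motion in the image plane, (col, row).
    eq4_variant
        ``"printed"`` uses the opposing-view equation exactly as published;
        ``"symmetric"`` replaces its denominator by ``a + b + c + 2d``.
    parallax_epsilon
        Minimum coordinate separation (cm) below which a solve is rejected
        as degenerate.
    singular_epsilon
        Minimum |denominator| (cm) for the forward projections.
    """

    camera_height_cm: float = 150.0
    mirror_offset_cm: float = 18.0
    mirror_angle_deg: float = 45.0
    pixel_scale: float = 87.0
    travel_axis: tuple[float, float] = (1.0, 0.0)
    eq4_variant: str = "printed"
    parallax_epsilon: float = 1e-6
    singular_epsilon: float = 1e-9

    def __post_init__(self) -> None:
        if not self.camera_height_cm > 0:
            raise ConfigurationError("camera_height_cm must be > 0")
        if not self.mirror_offset_cm > 0:
            raise ConfigurationError("mirror_offset_cm must be > 0")
        if not 0 < self.mirror_angle_deg < 180:
            raise ConfigurationError("mirror_angle_deg must lie in (0, 180)")
        if not self.pixel_scale > 0:
            raise ConfigurationError("pixel_scale must be > 0")
        if self.eq4_variant not in ("printed", "symmetric"):
            raise ConfigurationError(
                f"eq4_variant must be 'printed' or 'symmetric', got {self.eq4_variant!r}"
            )

    @property
    def c(self) -> float:
        return self.camera_height_cm

    @property
    def d(self) -> float:
        return self.mirror_offset_cm

    @property
    def sin_theta(self) -> float:
        return math.sin(math.radians(self.mirror_angle_deg))

    # -- config file round trip -------------------------------------------
    _KEYMAP = {
        "camera_height_cm": "camera_height_cm",
        "mirror_offset_cm": "mirror_offset_cm",
        "mirror_angle_deg": "mirror_angle_deg",
        "pixel_scale_px_per_cm": "pixel_scale",
        "travel_axis": "travel_axis",
        "eq4_variant": "eq4_variant",
        "parallax_epsilon": "parallax_epsilon",
    }

    @classmethod
    def from_dict(cls, data: dict) -> "RigGeometry":
        kwargs = {}
        for file_key, attr in cls._KEYMAP.items():
            if file_key in data:
                value = data[file_key]
                if attr == "travel_axis":
                    value = tuple(float(v) for v in value)
                kwargs[attr] = value
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RigGeometry":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "camera_height_cm": self.camera_height_cm,
            "mirror_offset_cm": self.mirror_offset_cm,
            "mirror_angle_deg": self.mirror_angle_deg,
            "pixel_scale_px_per_cm": self.pixel_scale,
            "travel_axis": list(self.travel_axis),
            "eq4_variant": self.eq4_variant,
            "parallax_epsilon": self.parallax_epsilon,
        }

    def replace(self, **kwargs) -> "RigGeometry":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FluorPoint:
    """A fluorescent point along a mirror-pair axis.

    ``a`` is the signed lateral position (cm) and ``b`` the height (cm) above
    the reference plane.  Physical scenes have ``b >= 0``; solver outputs may
    be any finite real and are validity-checked by the caller.
    """

    a: float
    b: float


@dataclass(frozen=True)
class MirrorObservation:
    """Mirror-view coordinates (cm) feeding a solver.

    For the opposite-pair solve, ``x`` and ``x1`` are the coordinates in the
    two opposing mirrors of a single frame.  For the two-frame solve, ``x1``
    and ``x2`` are the coordinates in the same mirror in consecutive frames
    and ``frame_travel_l`` is the camera displacement between them.
    """

    x: float | None = None
    x1: float | None = None
    x2: float | None = None
    frame_travel_l: float | None = None

    def __post_init__(self) -> None:
        for name in ("x", "x1", "x2", "frame_travel_l"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ConfigurationError(f"observation field {name} must be finite")
        if self.frame_travel_l is not None and not self.frame_travel_l > 0:
            raise ConfigurationError("frame_travel_l must be > 0")


def _numerator(b: float, g: RigGeometry) -> float:
    # (b + d)(c + d) == bc + dc + bd + d^2 exactly
    return (b + g.d) * (g.c + g.d)


def _checked_div(num: float, den: float, eps: float) -> float:
    if abs(den) < eps:
        raise SingularGeometryError(f"projection denominator {den!r} below epsilon {eps!r}")
    return num / den


def forward_single_view(p: FluorPoint, g: RigGeometry) -> float:
    """Project a fluorescent point into its mirror-view coordinate ``x``."""
    den = -p.a + p.b + g.c + 2 * g.d
    return _checked_div(_numerator(p.b, g), den, g.singular_epsilon)


def forward_opposite_pair(p: FluorPoint, g: RigGeometry) -> tuple[float, float]:
    """Project a point into both mirrors of an opposing pair, ``(x, x1)``."""
    x = forward_single_view(p, g)
    if g.eq4_variant == "printed":
        den1 = p.b - p.a - g.c
    else:
        den1 = p.a + p.b + g.c + 2 * g.d
    x1 = _checked_div(_numerator(p.b, g), den1, g.singular_epsilon)
    return x, x1


def solve_opposite(obs: MirrorObservation, g: RigGeometry) -> FluorPoint:
    """Invert the opposing-pair projection: ``(x, x1) -> (a, b)``.

    With ``N = (b+d)(c+d)``, the printed denominators differ by ``2(c+d)``,
    so ``N/x - N/x1 = 2(c+d)`` gives ``b`` directly, then ``a`` follows from
    the single-view equation.
    """
    if obs.x is None or obs.x1 is None:
        raise DegenerateObservationError("opposite solve requires both x and x1")
    x, x1 = obs.x, obs.x1
    if abs(x1 - x) < g.parallax_epsilon:
        raise DegenerateObservationError("x and x1 coincide: system unsolvable")
    if x == 0.0 or x1 == 0.0:
        raise DegenerateObservationError("zero mirror coordinate: N/x undefined")
    if g.eq4_variant == "printed":
        b = 2.0 * x * x1 / (x1 - x) - g.d
    else:
        # N/x + N/x1 = 2(b + c + 2d) with N = (b+d)(c+d)
        s = (x + x1) / (x * x1)
        den = (g.c + g.d) * s - 2.0
        if abs(den) < g.parallax_epsilon:
            raise DegenerateObservationError("symmetric solve is singular for these inputs")
        b = (2.0 * (g.c + 2 * g.d) - g.d * (g.c + g.d) * s) / den
    n = _numerator(b, g)
    a = b + g.c + 2 * g.d - n / x
    return FluorPoint(a=a, b=b)


def forward_two_frames(p: FluorPoint, g: RigGeometry, l: float) -> tuple[float, float]:
    """Project a static point into one mirror before/after camera travel ``l``."""
    if l < 0:
        raise ConfigurationError("travel distance l must be >= 0")
    a2 = p.a + l * g.sin_theta
    x1 = forward_single_view(p, g)
    x2 = forward_single_view(FluorPoint(a=a2, b=p.b), g)
    return x1, x2


def solve_single_mirror(obs: MirrorObservation, g: RigGeometry) -> FluorPoint:
    """Invert the two-frame projection: ``(x1, x2, l) -> (a1, b)``.

    The two denominators differ by ``l sin(theta)``, so
    ``N = l sin(theta) x1 x2 / (x2 - x1)``.
    """
    if obs.x1 is None or obs.x2 is None or obs.frame_travel_l is None:
        raise DegenerateObservationError("two-frame solve requires x1, x2 and frame_travel_l")
    if abs(g.sin_theta) < g.singular_epsilon:
        raise ConfigurationError("sin(theta) = 0: travel has no mirror-normal component")
    x1, x2, l = obs.x1, obs.x2, obs.frame_travel_l
    if abs(x2 - x1) < g.parallax_epsilon:
        raise DegenerateObservationError("insufficient parallax: x1 and x2 coincide")
    if x1 == 0.0 or x2 == 0.0:
        raise DegenerateObservationError("zero mirror coordinate: N/x undefined")
    n = l * g.sin_theta * x1 * x2 / (x2 - x1)
    b = n / (g.c + g.d) - g.d
    a1 = b + g.c + 2 * g.d - n / x1
    return FluorPoint(a=a1, b=b)


def convert_coords(
    point: float | Iterable[float] | np.ndarray,
    g: RigGeometry,
    direction: str,
    origin_px: tuple[float, float] | float = 0.0,
) -> np.ndarray | float:
    """Linear conversion between pixel and world coordinates.

    ``direction`` is ``"px_to_world"`` or ``"world_to_px"``.  The scaling is
    about ``origin_px`` (given in pixels), so the two directions compose to
    the identity.  Accepts scalars or arrays.
    """
    if direction not in ("px_to_world", "world_to_px"):
        raise ConfigurationError(f"unknown direction {direction!r}")
    arr = np.asarray(point, dtype=float)
    origin = np.asarray(origin_px, dtype=float)
    if direction == "world_to_px":
        out = arr * g.pixel_scale + origin
    else:
        out = (arr - origin) / g.pixel_scale
    if np.ndim(point) == 0 and np.ndim(out) == 0:
        return float(out)
    return out
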