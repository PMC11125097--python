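"""Forward simulation of the dark-box imaging chamber.

A scene is a single fluorescent seedling at a ground-truth bed position and
height, imaged from above.  Depending on the occlusion scenario, its
fluorescence shows up in the central area and/or in mirror areas; mirror-view
blob positions are computed with the same forward projection equations the
solvers invert, so solver-facing scenes are geometrically consistent by
construction.  Frames are rendered as isotropic Gaussian blobs on a near-zero
background with additive Gaussian sensor noise, quantized to 8 bits.

Scenario occupancy (which mirrors are blocked by canopy) is *sampled*, not
biophysically modeled; occluders are represented only through region
occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Config
from .errors import ConfigurationError
from .geometry import FluorPoint, forward_opposite_pair, forward_single_view, forward_two_frames
from .pipeline import GrayFrame
from .regions import MIRROR_AXES, RegionLayout, edge_tangent

__all__ = [
    "SCENARIOS",
    "DEFAULT_COUNTS",
    "SyntheticScene",
    "BenchmarkSet",
    "sample_scene",
    "render_frames",
    "make_benchmark",
]

SCENARIOS = ("central", "four", "three", "two_nonopposite", "two_opposite", "one")
# Benchmark case mix: central, four, three, two non-opposite, two opposite, one.
DEFAULT_COUNTS = (32, 67, 54, 65, 44, 38)

_PAIRS = (("TL", "BR"), ("TR", "BL"))
_NONOPPOSITE = (("TR", "BR"), ("TL", "BL"), ("TL", "TR"), ("BL", "BR"))
_EDGE_MARGIN_PX = 20.0


@dataclass(frozen=True)
class SyntheticScene:
    """Ground truth plus per-frame blob placements for one scene."""

    scene_id: str
    scenario: str
    truth_center_px: tuple[float, float]
    a_cm: float | None
    b_cm: float
    occupied_regions: frozenset
    frame_blobs: tuple  # one tuple of (region, (col, row)) per frame
    travel_cm: float | None
    noise_seed: int

    @property
    def n_frames(self) -> int:
        return len(self.frame_blobs)


def _rel(p, center) -> np.ndarray:
    return np.asarray(p, float) - np.asarray(center, float)


def _mirror_blob(center, mirror, plant_px, b, g) -> tuple[float, float]:
    """Forward-project the plant into one mirror view (own-axis equation)."""
    w = MIRROR_AXES[mirror]
    t = edge_tangent(mirror)
    s = g.pixel_scale
    rel = _rel(plant_px, center)
    a_m = float(rel @ w) / s
    x = forward_single_view(FluorPoint(a=a_m, b=b), g)
    pos = np.asarray(center) + w * ((g.d + x) * s) + t * float(rel @ t)
    return (float(pos[0]), float(pos[1]))


def _opposite_blobs(center, pair, plant_px, b, g):
    """Blob positions in an opposing pair via the paired projection equations."""
    top, bottom = pair
    w = MIRROR_AXES[top]
    t = edge_tangent(top)
    s = g.pixel_scale
    rel = _rel(plant_px, center)
    a = float(rel @ w) / s
    tau = float(rel @ t)
    x, x1 = forward_opposite_pair(FluorPoint(a=a, b=b), g)
    pos_top = np.asarray(center) + w * ((g.d + x) * s) + t * tau
    if g.eq4_variant == "printed":
        o_b = (x1 - g.d) * s
    else:
        o_b = -(g.d + x1) * s
    pos_bot = np.asarray(center) + w * o_b + t * tau
    return a, (top, (float(pos_top[0]), float(pos_top[1]))), (bottom, (float(pos_bot[0]), float(pos_bot[1])))


def _two_frame_blobs(center, mirror, plant_px, b, g, travel_cm):
    w = MIRROR_AXES[mirror]
    t = edge_tangent(mirror)
    s = g.pixel_scale
    rel = _rel(plant_px, center)
    a1 = float(rel @ w) / s
    tau = float(rel @ t)
    x1, x2 = forward_two_frames(FluorPoint(a=a1, b=b), g, travel_cm)
    out = []
    for x in (x1, x2):
        pos = np.asarray(center) + w * ((g.d + x) * s) + t * tau
        out.append((mirror, (float(pos[0]), float(pos[1]))))
    return a1, out[0], out[1]


def _scene_valid(layout: RegionLayout, frame_blobs) -> bool:
    for frame in frame_blobs:
        for region, (col, row) in frame:
            if not (
                _EDGE_MARGIN_PX <= col <= layout.width - _EDGE_MARGIN_PX
                and _EDGE_MARGIN_PX <= row <= layout.height - _EDGE_MARGIN_PX
            ):
                return False
            if layout.region_of((col, row)) != region:
                return False
    return True


def sample_scene(
    scenario: str,
    layout: RegionLayout,
    config: Config,
    rng: np.random.Generator,
    scene_id: str = "scene",
    max_tries: int = 500,
) -> SyntheticScene:
    """Draw one geometrically consistent scene of the given scenario.

    The plant center is drawn uniformly in a disc of ``plant_radius_cm``
    about the bed center and its height uniformly in ``b_range_cm``; draws
    whose mirror images would leave their regions (or the frame) are
    rejected and resampled.
    """
    if scenario not in SCENARIOS:
        raise ConfigurationError(f"unknown scenario {scenario!r}")
    g = config.rig
    sim = config.sim
    center = np.asarray(layout.center)
    radius_px = sim.plant_radius_cm * g.pixel_scale
    for _ in range(max_tries):
        u, phi = rng.uniform(), rng.uniform(0.0, 2.0 * math.pi)
        r = radius_px * math.sqrt(u)
        plant = (float(center[0] + r * math.cos(phi)), float(center[1] + r * math.sin(phi)))
        b = float(rng.uniform(*sim.b_range_cm))
        a_cm: float | None = None
        travel: float | None = None
        if scenario == "central":
            frames = (((("MC"), plant),),)
            regions = frozenset({"MC"})
        elif scenario == "four":
            frames = (tuple((m, _mirror_blob(center, m, plant, b, g)) for m in MIRROR_AXES),)
            regions = frozenset(MIRROR_AXES)
        elif scenario == "three":
            pair = _PAIRS[int(rng.integers(2))]
            other = _PAIRS[1] if pair == _PAIRS[0] else _PAIRS[0]
            extra = other[int(rng.integers(2))]
            mirrors = (*pair, extra)
            frames = (tuple((m, _mirror_blob(center, m, plant, b, g)) for m in mirrors),)
            regions = frozenset(mirrors)
        elif scenario == "two_nonopposite":
            mirrors = _NONOPPOSITE[int(rng.integers(4))]
            frames = (tuple((m, _mirror_blob(center, m, plant, b, g)) for m in mirrors),)
            regions = frozenset(mirrors)
        elif scenario == "two_opposite":
            pair = _PAIRS[int(rng.integers(2))]
            a_cm, blob_top, blob_bot = _opposite_blobs(center, pair, plant, b, g)
            frames = ((blob_top, blob_bot),)
            regions = frozenset(pair)
        else:  # one
            mirror = tuple(MIRROR_AXES)[int(rng.integers(4))]
            travel = sim.travel_cm
            a_cm, blob1, blob2 = _two_frame_blobs(center, mirror, plant, b, g, travel)
            frames = ((blob1,), (blob2,))
            regions = frozenset({mirror})
        if _scene_valid(layout, frames):
            return SyntheticScene(
                scene_id=scene_id,
                scenario=scenario,
                truth_center_px=plant,
                a_cm=a_cm,
                b_cm=b,
                occupied_regions=regions,
                frame_blobs=frames,
                travel_cm=travel,
                noise_seed=int(rng.integers(0, 2**31 - 1)),
            )
    raise ConfigurationError(
        f"could not sample a valid {scenario!r} scene in {max_tries} tries; "
        "check rig/layout parameters"
    )


def render_frames(
    scene: SyntheticScene,
    config: Config,
    noise_sigma: float | None = None,
) -> list[GrayFrame]:
    """Render the scene's frame(s): background + Gaussian blobs + noise.

    Rendering is deterministic given the scene (the noise stream is seeded
    by ``scene.noise_seed``).  ``noise_sigma`` overrides the configured
    sensor noise, e.g. 0 for noise-free renders.
    """
    sim = config.sim
    sigma_n = sim.noise_sigma if noise_sigma is None else noise_sigma
    rng = np.random.default_rng(scene.noise_seed)
    out = []
    for i, blobs in enumerate(scene.frame_blobs):
        img = np.full((sim.frame_height, sim.frame_width), float(sim.background))
        for _, (col, row) in blobs:
            _add_gaussian(img, col, row, sim.peak, sim.blob_sigma_px)
        if sigma_n > 0:
            img += rng.normal(0.0, sigma_n, size=img.shape)
        px = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
        out.append(GrayFrame(pixels=px, frame_id=f"{scene.scene_id}_f{i}"))
    return out


def _add_gaussian(img: np.ndarray, col: float, row: float, peak: float, sigma: float) -> None:
    h, w = img.shape
    half = int(math.ceil(5 * sigma))
    c0, c1 = max(0, int(col) - half), min(w, int(col) + half + 1)
    r0, r1 = max(0, int(row) - half), min(h, int(row) + half + 1)
    if c0 >= c1 or r0 >= r1:
        return
    cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    img[r0:r1, c0:c1] += peak * np.exp(
        -((cc - col) ** 2 + (rr - row) ** 2) / (2.0 * sigma**2)
    )


@dataclass(frozen=True)
class BenchmarkSet:
    """A seeded, reproducible collection of scenes with a manifest."""

    scenes: tuple
    counts: tuple
    seed: int
    config: Config = field(repr=False)

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "scene_id": s.scene_id,
                "scenario": s.scenario,
                "truth_col": s.truth_center_px[0],
                "truth_row": s.truth_center_px[1],
                "a_cm": s.a_cm if s.a_cm is not None else float("nan"),
                "b_cm": s.b_cm,
                "n_frames": s.n_frames,
                "travel_cm": s.travel_cm if s.travel_cm is not None else float("nan"),
            }
            for s in self.scenes
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "scene_id", "scenario", "truth_col", "truth_row",
                "a_cm", "b_cm", "n_frames", "travel_cm",
            ],
        )

    def iter_rendered(self, noise_sigma: float | None = None):
        """Yield ``(scene, [frames])`` pairs, rendering lazily."""
        for scene in self.scenes:
            yield scene, render_frames(scene, self.config, noise_sigma=noise_sigma)


def make_benchmark(
    counts: tuple = DEFAULT_COUNTS,
    seed: int = 0,
    config: Config | None = None,
) -> BenchmarkSet:
    """Build the benchmark case mix (default 32/67/54/65/44/38, total 300)."""
    if len(counts) != len(SCENARIOS):
        raise ConfigurationError(f"counts must have {len(SCENARIOS)} entries")
    if any(c < 0 for c in counts):
        raise ConfigurationError("scenario counts must be >= 0")
    config = config or Config.default()
    layout = config.layout()
    total = int(sum(counts))
    children = np.random.SeedSequence(seed).spawn(max(total, 1))
    scenes = []
    idx = 0
    for scenario, count in zip(SCENARIOS, counts):
        for _ in range(int(count)):
            rng = np.random.default_rng(children[idx])
            scenes.append(
                sample_scene(scenario, layout, config, rng, scene_id=f"scene_{idx:04d}")
            )
            idx += 1
    return BenchmarkSet(scenes=tuple(scenes), counts=tuple(counts), seed=seed, config=config)
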