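"""Success-radius scoring and the per-scenario accuracy report.

A localization counts as a success when the true plant center lies within
the success radius (default 43.5 px, i.e. 0.5 cm at the full-resolution
pixel scale) of the estimated center, boundary inclusive.  Absent estimates
are failures, not errors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import KeyMismatchError

__all__ = ["DEFAULT_RADIUS_PX", "score_localization", "evaluate", "EvaluationReport"]

DEFAULT_RADIUS_PX = 43.5


def score_localization(
    estimate: tuple[float, float] | None,
    truth: tuple[float, float],
    radius_px: float = DEFAULT_RADIUS_PX,
) -> bool:
    """True iff the estimate is within ``radius_px`` of the truth (inclusive)."""
    if not radius_px > 0:
        raise ValueError("radius_px must be > 0")
    if estimate is None:
        return False
    return math.hypot(estimate[0] - truth[0], estimate[1] - truth[1]) <= radius_px


@dataclass(frozen=True)
class EvaluationReport:
    """Per-scenario and overall localization accuracy."""

    per_scenario: pd.DataFrame  # scenario, count, successes, accuracy
    overall_count: int
    overall_successes: int
    success_radius_px: float
    failures: pd.DataFrame  # scene_id, scenario, case_id, status, distance_px

    @property
    def overall_accuracy(self) -> float:
        if self.overall_count == 0:
            return float("nan")
        return self.overall_successes / self.overall_count

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "success_radius_px": self.success_radius_px,
            "overall": {
                "count": self.overall_count,
                "successes": self.overall_successes,
                "accuracy": None if self.overall_count == 0 else self.overall_accuracy,
            },
            "per_scenario": self.per_scenario.to_dict(orient="records"),
            "failures": self.failures.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path: str | Path) -> None:
        self.per_scenario.to_csv(path, index=False)


def evaluate(
    results: pd.DataFrame,
    truths: pd.DataFrame,
    radius_px: float = DEFAULT_RADIUS_PX,
) -> EvaluationReport:
    """Join results to truths on ``scene_id`` and score every scene.

    ``results`` needs columns scene_id, center_col, center_row (NaN when no
    center was produced), case_id, status; ``truths`` needs scene_id,
    scenario, truth_col, truth_row.  The report is invariant to row order.
    """
    if not radius_px > 0:
        raise ValueError("radius_px must be > 0")
    if set(results["scene_id"]) != set(truths["scene_id"]):
        raise KeyMismatchError("results and truths carry different scene_id sets")
    if results["scene_id"].duplicated().any() or truths["scene_id"].duplicated().any():
        raise KeyMismatchError("scene_id values must be unique")
    merged = truths.merge(results, on="scene_id", how="inner").sort_values("scene_id")
    dist = (
        (merged["center_col"] - merged["truth_col"]) ** 2
        + (merged["center_row"] - merged["truth_row"]) ** 2
    ) ** 0.5
    ok_status = merged["status"] == "ok"
    merged = merged.assign(
        distance_px=dist, success=(dist <= radius_px) & dist.notna() & ok_status
    )
    rows = []
    for scenario, grp in merged.groupby("scenario", sort=False):
        rows.append(
            {
                "scenario": scenario,
                "count": int(len(grp)),
                "successes": int(grp["success"].sum()),
                "accuracy": float(grp["success"].mean()),
            }
        )
    per_scenario = pd.DataFrame(rows, columns=["scenario", "count", "successes", "accuracy"])
    fail_cols = ["scene_id", "scenario", "case_id", "status", "distance_px"]
    failures = (
        merged.loc[~merged["success"], [c for c in fail_cols if c in merged.columns]]
        .reset_index(drop=True)
    )
    return EvaluationReport(
        per_scenario=per_scenario,
        overall_count=int(len(merged)),
        overall_successes=int(merged["success"].sum()),
        success_radius_px=radius_px,
        failures=failures,
    )
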