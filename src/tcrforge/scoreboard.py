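"""Composite scoring and ranking of TCR construction methods.

Six aspects enter the score: accuracy and sensitivity (per-sample
weighted means of the CDR3/V/J proportions with weights 0.5/0.3/0.2,
averaged over samples), adaptability and usability point scores, and
computational cost expressed as log2(1/time_s) and log2(1/memory_kB).
Each aspect is min-max scaled to [1, 10] across methods and combined
with weights 0.2 (accuracy), 0.2 (sensitivity) and 0.1 for each of the
other four. The weights sum to 0.8 by design and are not renormalized,
so the best possible overall score is 8.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRIPLET_WEIGHTS = (0.5, 0.3, 0.2)  # CDR3, V, J
ASPECTS = ("accuracy", "sensitivity", "adaptability", "usability", "time", "memory")
ASPECT_WEIGHTS = {
    "accuracy": 0.2,
    "sensitivity": 0.2,
    "adaptability": 0.1,
    "usability": 0.1,
    "time": 0.1,
    "memory": 0.1,
}


@dataclass
class RawAspects:
    """Raw per-method inputs to the scoreboard.

    ``accuracy`` / ``sensitivity`` are per-sample (CDR3, V, J) triplets of
    proportions; time is in seconds, memory in kB; adaptability and the
    two usability components are points assigned externally.
    """

    method: str
    accuracy: list[tuple[float, float, float]]
    sensitivity: list[tuple[float, float, float]]
    time_s: float
    memory_kb: float
    adaptability_points: float
    output_file_points: float  # 0-4, one per supported output file
    friendliness_points: float  # 0-5, subjective input

    def __post_init__(self) -> None:
        if self.time_s <= 0 or self.memory_kb <= 0:
            raise ValueError(f"{self.method}: time and memory must be positive")
        if not 0 <= self.output_file_points <= 4:
            raise ValueError(f"{self.method}: output-file points outside [0, 4]")
        if not 0 <= self.friendliness_points <= 5:
            raise ValueError(f"{self.method}: friendliness points outside [0, 5]")


def min_max_scale(values: list[float], a: float = 1.0, b: float = 10.0) -> list[float]:
    """x_i = a + (X_i - X_min)(b - a)/(X_max - X_min).

    When all values coincide the scale is undefined; they map to the
    midpoint (a + b)/2.
    """
    if b <= a:
        raise ValueError("need b > a")
    if not values:
        raise ValueError("empty input")
    lo, hi = min(values), max(values)
    if hi == lo:
        return [(a + b) / 2.0] * len(values)
    return [a + (x - lo) * (b - a) / (hi - lo) for x in values]


def _weighted_triplet_mean(triplets: list[tuple[float, float, float]]) -> float:
    if not triplets:
        raise ValueError("need at least one per-sample triplet")
    per_sample = [
        sum(w * x for w, x in zip(TRIPLET_WEIGHTS, t)) for t in triplets
    ]
    return float(np.mean(per_sample))


def aspect_scores(raw: RawAspects) -> dict[str, float]:
    """The six unscaled aspect values for one method."""
    return {
        "accuracy": _weighted_triplet_mean(raw.accuracy),
        "sensitivity": _weighted_triplet_mean(raw.sensitivity),
        "adaptability": float(raw.adaptability_points),
        "usability": float(raw.output_file_points + raw.friendliness_points),
        "time": -math.log2(raw.time_s),
        "memory": -math.log2(raw.memory_kb),
    }


def overall_ranking(raws: list[RawAspects], a: float = 1.0, b: float = 10.0) -> pd.DataFrame:
    """Scale aspects across methods, combine with the fixed weights, rank.

    Returns a frame indexed by method with the six scaled scores, the
    overall score and a dense-style rank (descending by overall; ties
    share the smaller rank). Needs at least two methods for the min-max
    spread to be meaningful.
    """
    if len(raws) < 2:
        raise ValueError(
            "min-max scaling needs >= 2 methods; supply a comparison set"
        )
    methods = [r.method for r in raws]
    if len(set(methods)) != len(methods):
        raise ValueError("duplicated method names")
    unscaled = {r.method: aspect_scores(r) for r in raws}
    table = pd.DataFrame(index=methods)
    for aspect in ASPECTS:
        scaled = min_max_scale([unscaled[m][aspect] for m in methods], a, b)
        table[aspect] = scaled
    table["overall"] = sum(
        ASPECT_WEIGHTS[aspect] * table[aspect] for aspect in ASPECTS
    )
    table["rank"] = (
        table["overall"].rank(method="min", ascending=False).astype(int)
    )
    return table.sort_values(["overall", "rank"], ascending=[False, True])


def raw_aspects_from_tables(
    metrics: pd.DataFrame, points: pd.DataFrame
) -> list[RawAspects]:
    """Assemble RawAspects from tidy input tables.

    ``metrics``: columns method, sample, metric (accuracy|sensitivity),
    cdr3, v, j. ``points``: columns method, adaptability, output_files,
    friendliness, time_s, memory_kb.
    """
    raws = []
    points = points.set_index("method")
    for method, group in metrics.groupby("method", sort=True):
        triplets = {"accuracy": [], "sensitivity": []}
        for row in group.itertuples(index=False):
            triplets[str(row.metric)].append(
                (float(row.cdr3), float(row.v), float(row.j))
            )
        p = points.loc[method]
        raws.append(
            RawAspects(
                method=str(method),
                accuracy=triplets["accuracy"],
                sensitivity=triplets["sensitivity"],
                time_s=float(p["time_s"]),
                memory_kb=float(p["memory_kb"]),
                adaptability_points=float(p["adaptability"]),
                output_file_points=float(p["output_files"]),
                friendliness_points=float(p["friendliness"]),
            )
        )
    return raws
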