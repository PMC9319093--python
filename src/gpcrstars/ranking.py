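"""Secondary V1/V2/V3 star ranking of GPCR models.

After the preliminary star totals, each model receives three coarse star
grades: V1 bins the weighted star total, V2 bins the ionic-lock
hydrogen-bond distance (R3.50 side chain to S6.33 OG, Å), and V3 bins the
enrichment-test AUC.  The V1+V2+V3 sum, sorted descending, is the final
model ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

__all__ = [
    "v1_stars",
    "v2_stars",
    "v3_stars",
    "SecondaryScore",
    "score_secondary",
    "rank_models",
    "load_secondary_table",
]

# Published bin floors: (3-star, 2-star, 1-star).
V1_BOUNDS = (27.0, 20.0, 13.0)   # total stars, higher is better
V2_BOUNDS = (2.5, 3.5, 4.5)      # lock distance in Å, lower is better
V3_BOUNDS = (0.79, 0.77, 0.75)   # AUC, higher is better


def _bin(value: float, bounds: tuple[float, float, float], lower_better: bool) -> int:
    t3, t2, t1 = bounds
    meets = (lambda v, t: v <= t) if lower_better else (lambda v, t: v >= t)
    for stars, bound in ((3, t3), (2, t2), (1, t1)):
        if meets(value, bound):
            return stars
    return 0


def v1_stars(total_stars: float) -> int:
    """Bin a weighted star total (≥27 → 3, ≥20 → 2, ≥13 → 1, else 0)."""
    if total_stars < 0:
        raise ValueError("total stars must be nonnegative")
    return _bin(total_stars, V1_BOUNDS, lower_better=False)


def v2_stars(lock_distance: float) -> int:
    """Bin an ionic-lock distance in Å (≤2.5 → 3, ≤3.5 → 2, ≤4.5 → 1, else 0)."""
    if lock_distance <= 0:
        raise ValueError("lock distance must be positive")
    return _bin(lock_distance, V2_BOUNDS, lower_better=True)


def v3_stars(auc: float) -> int:
    """Bin an enrichment AUC (≥0.79 → 3, ≥0.77 → 2, ≥0.75 → 1, else 0)."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    return _bin(auc, V3_BOUNDS, lower_better=False)


@dataclass(frozen=True)
class SecondaryScore:
    """One model's secondary grades and their inputs."""

    model_id: str
    total_stars: float
    lock_distance: float
    auc: float
    v1: int = field(init=False)
    v2: int = field(init=False)
    v3: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "v1", v1_stars(self.total_stars))
        object.__setattr__(self, "v2", v2_stars(self.lock_distance))
        object.__setattr__(self, "v3", v3_stars(self.auc))

    @property
    def sum(self) -> int:
        return self.v1 + self.v2 + self.v3


def score_secondary(
    model_id: str, total_stars: float, lock_distance: float, auc: float
) -> SecondaryScore:
    return SecondaryScore(model_id, total_stars, lock_distance, auc)


def rank_models(scores: Sequence[SecondaryScore]) -> pd.DataFrame:
    """Rank models by V1+V2+V3 descending.

    Ties break by total stars (desc), then lock distance (asc), then
    model id — a deterministic order the coarse sums alone cannot fix.
    Returns a frame with a 1-based ``rank`` column.
    """
    if not scores:
        raise ValueError("no scores to rank")
    ids = [s.model_id for s in scores]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate model_id(s): {sorted({i for i in ids if ids.count(i) > 1})}")
    ordered = sorted(
        scores,
        key=lambda s: (-s.sum, -s.total_stars, s.lock_distance, s.model_id),
    )
    df = pd.DataFrame(
        {
            "model_id": [s.model_id for s in ordered],
            "total_stars": [s.total_stars for s in ordered],
            "v1": [s.v1 for s in ordered],
            "lock_distance": [s.lock_distance for s in ordered],
            "v2": [s.v2 for s in ordered],
            "auc": [s.auc for s in ordered],
            "v3": [s.v3 for s in ordered],
            "v1_v2_v3": [s.sum for s in ordered],
        }
    )
    df.insert(0, "rank", range(1, len(df) + 1))
    return df


def load_secondary_table(path: Union[str, Path]) -> list[SecondaryScore]:
    """Read a CSV with columns model_id,total_stars,lock_distance,auc."""
    df = pd.read_csv(path)
    required = {"model_id", "total_stars", "lock_distance", "auc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"secondary table missing columns: {sorted(missing)}")
    return [
        SecondaryScore(r.model_id, float(r.total_stars), float(r.lock_distance), float(r.auc))
        for r in df.itertuples()
    ]
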