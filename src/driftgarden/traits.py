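"""Derived seedling trait scores for the common-garden experiment.

Three composite traits are computed from raw greenhouse observations:

* **Bud Break Score** — sum of two phenology scores (each 1-5) recorded at
  consecutive spring dates; higher values mean earlier bud break.
* **Growth Increment** — height difference between fall and spring in mm;
  negative values (dieback) are preserved and flagged.
* **Water Stress Score** — drought-response scores (0-3) recorded at a short
  series of early-summer dates, combined with inverse-log-Julian-date weights
  so that earlier responses (the most drought-sensitive seedlings) carry
  strictly more weight.  The weights are normalised to sum to one, so the
  score stays on the 0-3 scale of the raw observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StressObservation:
    """A single drought-stress scoring of one seedling."""

    individual_id: str
    julian_date: int  # day of year
    score: int  # 0 (hardy) .. 3 (sensitive)

    def __post_init__(self) -> None:
        if self.score not in (0, 1, 2, 3):
            raise ValueError(f"stress score must be in 0..3, got {self.score}")
        if not 1 <= self.julian_date <= 366:
            raise ValueError(f"julian_date out of range: {self.julian_date}")


def bud_break_score(score_date1: int, score_date2: int) -> int:
    """Sum of the two yearly phenology scores; range 2..10, higher = earlier."""
    for s in (score_date1, score_date2):
        if not (isinstance(s, (int, np.integer)) and 1 <= s <= 5):
            raise ValueError(f"bud break scores must be integers in 1..5, got {s!r}")
    return int(score_date1) + int(score_date2)


def growth_increment(height_spring: float, height_fall: float) -> tuple[float, bool]:
    """Fall minus spring height in mm; returns (increment, dieback flag).

    The increment may be <= 0 (shoot dieback); the sign is preserved and the
    second element flags it for reporting.
    """
    if height_spring < 0 or height_fall < 0:
        raise ValueError("heights must be non-negative")
    inc = float(height_fall) - float(height_spring)
    return inc, inc <= 0


def water_stress_weights(julian_dates) -> np.ndarray:
    """Inverse-log-date weights, normalised to sum to 1.

    ``w_i = (1/ln JD_i) / sum_k (1/ln JD_k)``; earlier dates get strictly
    larger weights.
    """
    jd = np.asarray(julian_dates, dtype=float)
    inv = 1.0 / np.log(jd)
    return inv / inv.sum()


def water_stress_score(obs: list[StressObservation]) -> float:
    """Weighted sum of stress scores; bounded in [0, 3].

    Accepts 1-6 observations with strictly increasing Julian dates.  All
    scores 0 gives 0; all scores 3 gives exactly 3 (the weights sum to one).
    Increasing any single score never decreases the result.
    """
    if not 1 <= len(obs) <= 6:
        raise ValueError("expected 1-6 stress observations")
    dates = np.array([o.julian_date for o in obs], dtype=float)
    scores = np.array([o.score for o in obs], dtype=float)
    if len(obs) > 1 and not (np.diff(dates) > 0).all():
        raise ValueError("Julian dates must be strictly increasing")
    w = water_stress_weights(dates)
    return float(scores @ w)


def score_table(raw: pd.DataFrame) -> pd.DataFrame:
    """Compute weighted Water Stress Scores from a long table of raw scores.

    ``raw`` needs columns ``individual_id, julian_date, score``; returns one
    row per individual with columns ``individual_id, trait, value``.
    """
    out = []
    for ind, grp in raw.sort_values("julian_date").groupby("individual_id", sort=False):
        obs = [StressObservation(str(ind), int(r.julian_date), int(r.score))
               for r in grp.itertuples()]
        out.append({"individual_id": str(ind), "trait": "water_stress_score",
                    "value": water_stress_score(obs)})
    return pd.DataFrame(out, columns=["individual_id", "trait", "value"])
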