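"""Locality-quantile suitability thresholds and the four-class scheme.

The present-day logistic scores at all unique presence localities define
three cutoffs so that 68%, 95% and 100% of the localities score at or above
them.  Any score then classifies into:

    optimal       score >= tau_optimal       (the best 68% of localities)
    intermediate  score >= tau_intermediate  (suboptimal)
    marginal      score >= tau_marginal      (extreme environments)
    unsuitable    otherwise

For level ``l`` with ``n`` localities the cutoff is the score of the
k-th highest locality, ``k = ceil(l * n)``; ties at the cutoff join the
better class, so at baseline exactly k localities are optimal when scores
are distinct, every locality is suitable, and a set of all-equal scores is
entirely optimal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CLASSES = ("unsuitable", "marginal", "intermediate", "optimal")
CLASS_CODES = {name: code for code, name in enumerate(CLASSES)}
MASKED_CODE = 255


@dataclass(frozen=True)
class ThresholdSet:
    """The three suitability cutoffs, on the logistic score scale."""

    tau_optimal: float
    tau_intermediate: float
    tau_marginal: float
    levels: tuple[float, ...] = (0.68, 0.95, 1.00)
    n_localities: int = 0
    # localities at or above each tau; can exceed ceil(l*n) under ties
    attained_counts: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (self.tau_optimal >= self.tau_intermediate
                >= self.tau_marginal >= 0):
            raise ValueError(
                f"thresholds must be ordered and non-negative, got "
                f"{self.tau_optimal}, {self.tau_intermediate}, {self.tau_marginal}")

    @property
    def taus(self) -> tuple[float, float, float]:
        return (self.tau_optimal, self.tau_intermediate, self.tau_marginal)

    def to_dict(self) -> dict:
        return {"tau_optimal": self.tau_optimal,
                "tau_intermediate": self.tau_intermediate,
                "tau_marginal": self.tau_marginal,
                "levels": list(self.levels),
                "n_localities": self.n_localities,
                "attained_counts": list(self.attained_counts)}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdSet":
        return cls(tau_optimal=d["tau_optimal"],
                   tau_intermediate=d["tau_intermediate"],
                   tau_marginal=d["tau_marginal"],
                   levels=tuple(d.get("levels", (0.68, 0.95, 1.00))),
                   n_localities=d.get("n_localities", 0),
                   attained_counts=tuple(d.get("attained_counts", ())))


def derive_thresholds(scores: np.ndarray,
                      levels: tuple[float, ...] = (0.68, 0.95, 1.00)) -> ThresholdSet:
    """Derive the cutoffs from present-day scores at all unique localities.

    ``levels`` must be strictly increasing with the last equal to 1.0 (the
    all-inclusive marginal level).  Ties that make a level unattainable
    exactly are resolved from above and recorded in ``attained_counts``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("scores must be non-empty")
    if np.any(scores < 0):
        raise ValueError("scores must be non-negative")
    if len(levels) != 3 or any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("levels must be 3 strictly increasing values")
    if levels[-1] != 1.0:
        raise ValueError("last level must be 1.0 (include every locality)")
    n = scores.size
    desc = np.sort(scores)[::-1]
    taus, attained = [], []
    for lev in levels:
        k = math.ceil(lev * n)
        tau = float(desc[k - 1])
        taus.append(tau)
        attained.append(int(np.sum(scores >= tau)))
    return ThresholdSet(tau_optimal=taus[0], tau_intermediate=taus[1],
                        tau_marginal=taus[2], levels=tuple(levels),
                        n_localities=n, attained_counts=tuple(attained))


def classify(score: float, thresholds: ThresholdSet) -> str:
    """Classify one logistic score into the four-class scheme."""
    if score < 0:
        raise ValueError(f"suitability score must be >= 0, got {score}")
    if score >= thresholds.tau_optimal:
        return "optimal"
    if score >= thresholds.tau_intermediate:
        return "intermediate"
    if score >= thresholds.tau_marginal:
        return "marginal"
    return "unsuitable"


def classify_codes(scores: np.ndarray, thresholds: ThresholdSet) -> np.ndarray:
    """Vectorised classification to integer codes
    (0 unsuitable, 1 marginal, 2 intermediate, 3 optimal)."""
    scores = np.asarray(scores, dtype=float)
    if np.any(scores < 0):
        raise ValueError("suitability scores must be >= 0")
    codes = np.zeros(scores.shape, dtype=np.uint8)
    codes[scores >= thresholds.tau_marginal] = CLASS_CODES["marginal"]
    codes[scores >= thresholds.tau_intermediate] = CLASS_CODES["intermediate"]
    codes[scores >= thresholds.tau_optimal] = CLASS_CODES["optimal"]
    return codes
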