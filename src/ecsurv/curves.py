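"""Monthly recurrence-probability curves on the five-year surveillance grid.

The whole pipeline works on a common representation of recurrence timing: an
unconditional probability ``p_m`` of the *first* recurrence falling in month
``m`` for m = 1..60 after surgery, together with the cumulative incidence
``F(m) = sum_{j<=m} p_j``.  Visit scheduling inverts ``F``; the Markov model
converts ``p_m`` back to conditional hazards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Number of months in the surveillance horizon (five years).
GRID_MONTHS = 60


@dataclass(frozen=True)
class HazardCurve:
    """Unconditional monthly first-recurrence probabilities over months 1..60.

    Parameters
    ----------
    monthly_prob : array-like of length 60
        ``monthly_prob[m-1]`` is the probability that the first recurrence
        occurs in month ``m``.  Nonnegative; the total mass may not exceed 1.
    group : str, optional
        Risk-group label (I..IV) the curve belongs to.
    """

    monthly_prob: np.ndarray
    group: Optional[str] = None

    def __post_init__(self) -> None:
        p = np.asarray(self.monthly_prob, dtype=float)
        if p.shape != (GRID_MONTHS,):
            raise ValueError(
                f"monthly_prob must have length {GRID_MONTHS}, got shape {p.shape}"
            )
        if np.any(p < -1e-12):
            raise ValueError("monthly probabilities must be nonnegative")
        p = np.clip(p, 0.0, None)
        if p.sum() > 1.0 + 1e-9:
            raise ValueError("total recurrence mass exceeds 1")
        object.__setattr__(self, "monthly_prob", p)

    @property
    def months(self) -> np.ndarray:
        return np.arange(1, GRID_MONTHS + 1)

    @property
    def cumulative(self) -> np.ndarray:
        """Cumulative incidence F(m) for m = 1..60."""
        return np.cumsum(self.monthly_prob)

    def cum_at(self, month: int) -> float:
        """F(month); F(0) = 0 by convention."""
        if month <= 0:
            return 0.0
        return float(self.cumulative[min(month, GRID_MONTHS) - 1])

    def survival_at(self, month: int) -> float:
        """Recurrence-free probability S(month) = 1 - F(month)."""
        return 1.0 - self.cum_at(month)

    @property
    def peak_month(self) -> int:
        """Month with the largest monthly recurrence probability."""
        return int(np.argmax(self.monthly_prob)) + 1

    def smoothed_peak_month(self, window: int = 5) -> int:
        """Peak month of a centred moving average of the monthly masses.

        Step-function estimators (ensemble cumulative hazards differenced to
        monthly masses) carry month-to-month noise comparable to the true
        differences near a broad peak, so the raw argmax is unstable; a short
        moving average localises the mode without refitting.
        """
        kernel = np.ones(window) / window
        return int(np.argmax(np.convolve(self.monthly_prob, kernel, mode="same"))) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": self.months,
                "monthly_prob": self.monthly_prob,
                "cumulative": self.cumulative,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, group: Optional[str] = None) -> "HazardCurve":
        frame = frame.sort_values("month")
        if not np.array_equal(frame["month"].to_numpy(), np.arange(1, GRID_MONTHS + 1)):
            raise ValueError("curve frame must cover months 1..60 exactly")
        return cls(frame["monthly_prob"].to_numpy(dtype=float), group=group)

    def to_json(self) -> str:
        return json.dumps(
            {"group": self.group, "monthly_prob": self.monthly_prob.tolist()}
        )

    @classmethod
    def from_json(cls, text: str) -> "HazardCurve":
        obj = json.loads(text)
        return cls(np.asarray(obj["monthly_prob"], dtype=float), group=obj.get("group"))


def flat_curve(total: float, group: Optional[str] = None) -> HazardCurve:
    """A uniform curve placing ``total`` recurrence mass evenly over 60 months."""
    return HazardCurve(np.full(GRID_MONTHS, total / GRID_MONTHS), group=group)
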