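"""Follow-up schedule encoding and cumulative-risk-based design.

Guideline protocols are fixed month sets; risk-adaptive schedules place the
j-th of k visits at the first month where cumulative recurrence incidence
reaches j/k of its five-year total, so that every inter-visit interval
carries (approximately) equal recurrence mass.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .curves import GRID_MONTHS, HazardCurve

#: Published per-year visit counts of the recommended group schedules.
RECOMMENDED_YEARLY: Dict[str, Tuple[int, ...]] = {
    "I": (3, 3, 3, 2, 1),
    "II": (4, 4, 1, 1, 2),
    "III": (4, 4, 2, 1, 1),
    "IV": (4, 4, 1, 1, 1),
}

_ALIASES = {
    "5010": "NEOCRT5010",
    "OEO2": "NEOCRT5010",
    "NCT03001596": "NCT1596",
}


@dataclass(frozen=True)
class FollowUpSchedule:
    """Sorted distinct integer visit months within the five-year horizon."""

    label: str
    visit_months: Tuple[int, ...]

    def __post_init__(self):
        months = tuple(int(m) for m in self.visit_months)
        if not months:
            raise ValueError("schedule must contain at least one visit")
        if sorted(set(months)) != list(months):
            raise ValueError("visit months must be strictly increasing")
        if months[0] < 1 or months[-1] > GRID_MONTHS:
            raise ValueError("visit months must lie in [1, 60]")
        object.__setattr__(self, "visit_months", months)

    @property
    def n_visits(self) -> int:
        return len(self.visit_months)

    def to_json(self) -> str:
        return json.dumps({"label": self.label, "visit_months": list(self.visit_months)})

    @classmethod
    def from_json(cls, text: str) -> "FollowUpSchedule":
        obj = json.loads(text)
        return cls(label=obj["label"], visit_months=tuple(obj["visit_months"]))


def _protocol_catalog() -> Dict[str, List[int]]:
    text = resources.files("ecsurv.data").joinpath("protocols.json").read_text()
    return json.loads(text)


def protocol_schedule(name: str) -> FollowUpSchedule:
    """One of the fixed comparison protocols (CROSS, NEOCRT5010, NCCN,
    NCT1596), by name or common alias."""
    catalog = _protocol_catalog()
    key = _ALIASES.get(name.upper(), name.upper())
    if key not in catalog:
        raise ValueError(
            f"unknown protocol {name!r}; available: {sorted(catalog)}"
        )
    return FollowUpSchedule(label=key, visit_months=tuple(catalog[key]))


def uniform_schedule(k: int, label: Optional[str] = None) -> FollowUpSchedule:
    """k visits evenly spaced over the 60-month horizon, ending at month 60."""
    months = tuple(int(round(GRID_MONTHS * j / k)) for j in range(1, k + 1))
    return FollowUpSchedule(label=label or f"uniform_{k}", visit_months=months)


def design_schedule(curve: HazardCurve, k: int, label: Optional[str] = None) -> FollowUpSchedule:
    """Equal-cumulative-risk schedule with ``k`` visits.

    Visit j is placed at the smallest month where F(m) >= (j/k) F(60);
    collisions advance to the next unused month, and month 60 is always the
    final visit so every in-horizon event has a coming visit.
    """
    if not (5 <= k <= 20):
        raise ValueError("visit count k must lie in [5, 20]")
    F = curve.cumulative
    F60 = F[-1]
    if F60 <= 0:
        warnings.warn("curve has no recurrence mass; falling back to uniform spacing",
                      stacklevel=2)
        return uniform_schedule(k, label=label or f"risk_{k}")
    used: set[int] = set()
    for j in range(1, k + 1):
        target = (j / k) * F60
        m = int(np.searchsorted(F, target - 1e-12) + 1)
        m = min(m, GRID_MONTHS)
        while m in used and m < GRID_MONTHS:
            m += 1
        while m in used:
            m -= 1
        used.add(m)
    if GRID_MONTHS not in used:
        used.discard(max(used))
        used.add(GRID_MONTHS)
    months = tuple(sorted(used))
    return FollowUpSchedule(label=label or f"risk_{k}", visit_months=months)


def recommended_schedule(
    curve: HazardCurve, group: str, label: Optional[str] = None
) -> FollowUpSchedule:
    """Recommended group schedule: published per-year visit counts with
    months placed within each year by the equal-risk rule restricted to that
    year's recurrence mass."""
    if group not in RECOMMENDED_YEARLY:
        raise ValueError(f"unknown group {group!r}; expected one of {sorted(RECOMMENDED_YEARLY)}")
    counts = RECOMMENDED_YEARLY[group]
    F = np.concatenate([[0.0], curve.cumulative])  # F[m] for m = 0..60
    months: List[int] = []
    for year, c in enumerate(counts, start=1):
        start, end = 12 * (year - 1), 12 * year
        mass = F[end] - F[start]
        used: set[int] = set()
        for j in range(1, c + 1):
            if mass > 0:
                target = F[start] + (j / c) * mass
                rel = int(np.searchsorted(F[start + 1 : end + 1], target - 1e-12))
                m = start + 1 + min(rel, 11)
            else:
                m = start + int(round(12 * j / c))
            while m in used and m < end:
                m += 1
            while m in used:
                m -= 1
            used.add(m)
        months.extend(sorted(used))
    return FollowUpSchedule(
        label=label or f"recommended_{group}", visit_months=tuple(sorted(months))
    )


@dataclass(frozen=True)
class SelectionResult:
    schedule: FollowUpSchedule
    median_ddt: float
    reference_median: float
    dominates: bool


def select_recommended(
    curve: HazardCurve,
    event_months: Sequence[float],
    reference: FollowUpSchedule,
) -> SelectionResult:
    """Fewest-visit designed schedule whose median delayed detection time on
    ``event_months`` does not exceed the reference schedule's.

    If no designed schedule (k = 5..20) matches the reference, the k = 20
    schedule is returned flagged as non-dominating.
    """
    from .evaluate import compute_ddt

    events = np.asarray(event_months, dtype=float)
    if events.size == 0:
        raise ValueError("event_months must be nonempty")
    ref_median = compute_ddt(events, reference).median
    last = None
    for k in range(5, 21):
        cand = design_schedule(curve, k)
        med = compute_ddt(events, cand).median
        last = (cand, med)
        if med <= ref_median:
            return SelectionResult(cand, med, ref_median, dominates=True)
    cand, med = last
    warnings.warn("no designed schedule matches the reference median DDT", stacklevel=2)
    return SelectionResult(cand, med, ref_median, dominates=False)


def yearly_counts(schedule: FollowUpSchedule) -> Tuple[int, int, int, int, int]:
    """Visit counts per follow-up year ((0,12], (12,24], ..., (48,60])."""
    months = np.asarray(schedule.visit_months)
    return tuple(
        int(np.sum((months > 12 * (y - 1)) & (months <= 12 * y))) for y in range(1, 6)
    )
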