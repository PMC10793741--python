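"""Markov cohort cost-effectiveness model for surveillance strategies.

Four health states: DiseaseFree, RecurrenceUndetected, RecurrenceDetected,
Death (absorbing).  Recurrence follows the group's monthly curve (converted
to a conditional hazard) within the five-year horizon and a flat tail hazard
after; an undetected recurrence is found with certainty at a scheduled visit
(configurable sensitivity) and with a symptomatic-detection probability in
between; mortality after detection is scaled by a linear penalty in the
detection delay, which is how schedules differ in effectiveness.  Costs and
utilities are per-cycle and discounted at an annual rate.

All rates, costs, and utilities are configurable placeholders: the model's
absolute outputs are not calibrated to any published cost table — only the
incremental-cost / incremental-effectiveness arithmetic of
:func:`icer_table` is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .curves import GRID_MONTHS, HazardCurve
from .schedule import FollowUpSchedule

STATES = ("DiseaseFree", "RecurrenceUndetected", "RecurrenceDetected", "Death")


@dataclass(frozen=True)
class MarkovSpec:
    """State-transition model parameters.

    Probabilities are per cycle (default: monthly); utilities are on the
    annual [0, 1] scale and accrue as ``u * cycle_months / 12`` per cycle.
    """

    recurrence_curve: HazardCurve
    cycle_months: int = 1
    horizon_cycles: int = 480
    tail_recurrence_per_cycle: float = 0.002
    symptomatic_detection_prob_per_cycle: float = 0.08
    background_mortality_per_cycle: float = 0.001
    undetected_mortality_per_cycle: float = 0.030
    post_detection_mortality_per_cycle: float = 0.020
    delay_beta: float = 0.02  # mortality multiplier slope per month of delay
    visit_sensitivity: float = 1.0
    c_visit: float = 150.0
    c_salvage: float = 8000.0
    c_terminal: float = 5000.0
    u_df: float = 0.85
    u_detected: float = 0.60
    u_undetected: float = 0.55
    annual_discount: float = 0.03

    def __post_init__(self):
        probs = (
            self.tail_recurrence_per_cycle,
            self.symptomatic_detection_prob_per_cycle,
            self.background_mortality_per_cycle,
            self.undetected_mortality_per_cycle,
            self.post_detection_mortality_per_cycle,
            self.visit_sensitivity,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("per-cycle probabilities must lie in [0, 1]")
        if self.undetected_mortality_per_cycle < self.post_detection_mortality_per_cycle:
            raise ValueError("undetected mortality must be >= detected mortality")
        if not (0.0 <= self.u_undetected <= self.u_detected <= self.u_df <= 1.0):
            raise ValueError("utilities must satisfy 0 <= u_undetected <= u_detected <= u_df <= 1")
        if self.delay_beta < 0:
            raise ValueError("delay_beta must be nonnegative")
        if self.cycle_months < 1 or self.horizon_cycles < 0:
            raise ValueError("invalid cycle/horizon")


@dataclass
class CEAResult:
    strategy: str
    total_cost: float
    total_qaly: float
    incremental_cost: Optional[float] = None
    incremental_effectiveness: Optional[float] = None
    icer: Optional[float] = None
    dominated: bool = False
    is_reference: bool = False

    @property
    def icer_rounded(self) -> Optional[int]:
        return None if self.icer is None else int(round(self.icer))


def _recurrence_prob(spec: MarkovSpec, cycle: int) -> float:
    """Conditional per-cycle recurrence probability for a disease-free
    patient at the given cycle (0-based; cycle c covers month c+1)."""
    month = cycle * spec.cycle_months + 1
    if month <= GRID_MONTHS:
        curve = spec.recurrence_curve
        p_m = float(curve.monthly_prob[month - 1])
        s_prev = curve.survival_at(month - 1)
        q = p_m / s_prev if s_prev > 0 else 0.0
        return min(max(q, 0.0), 1.0)
    return spec.tail_recurrence_per_cycle


def _visit_cycles(spec: MarkovSpec, schedule: FollowUpSchedule) -> set:
    return {(m - 1) // spec.cycle_months for m in schedule.visit_months}


def build_transition(
    spec: MarkovSpec, schedule: FollowUpSchedule, cycle: int
) -> Dict[str, Dict[str, float]]:
    """Per-state transition probabilities for one cycle (base rates; the
    delay-dependent mortality scaling is applied by :func:`run_markov`).

    Death competes first within a cycle; each row's remainder is the
    self-transition, so rows sum to 1 exactly.
    """
    if cycle >= spec.horizon_cycles:
        raise ValueError("cycle beyond the model horizon")
    q = _recurrence_prob(spec, cycle)
    b = spec.background_mortality_per_cycle
    u = spec.undetected_mortality_per_cycle
    d = spec.post_detection_mortality_per_cycle
    det = (
        spec.visit_sensitivity
        if cycle in _visit_cycles(spec, schedule)
        else spec.symptomatic_detection_prob_per_cycle
    )
    rows = {
        "DiseaseFree": {
            "Death": b,
            "RecurrenceUndetected": (1.0 - b) * q,
            "DiseaseFree": (1.0 - b) * (1.0 - q),
        },
        "RecurrenceUndetected": {
            "Death": u,
            "RecurrenceDetected": (1.0 - u) * det,
            "RecurrenceUndetected": (1.0 - u) * (1.0 - det),
        },
        "RecurrenceDetected": {
            "Death": d,
            "RecurrenceDetected": 1.0 - d,
        },
        "Death": {"Death": 1.0},
    }
    for state, row in rows.items():
        total = sum(row.values())
        if abs(total - 1.0) > 1e-9 or any(not (0 <= p <= 1) for p in row.values()):
            raise ValueError(f"invalid transition row for {state} at cycle {cycle}")
    return rows


def run_markov(
    spec: MarkovSpec,
    schedule: FollowUpSchedule,
    label: Optional[str] = None,
    return_trace: bool = False,
):
    """Deterministic cohort-trace evaluation from DiseaseFree mass 1.

    Undetected mass is tracked by its recurrence cycle and detected mass by
    its detection delay, so the linear delay penalty on post-detection
    mortality is exact.  Per-cycle discounted costs (visit, salvage at
    detection, terminal at death) and utilities accumulate into a
    :class:`CEAResult`.
    """
    label = label or schedule.label
    horizon = spec.horizon_cycles
    visit_cycles = _visit_cycles(spec, schedule)
    disc_rate = 1.0 + spec.annual_discount
    b = spec.background_mortality_per_cycle
    u_mort = spec.undetected_mortality_per_cycle
    d_mort = spec.post_detection_mortality_per_cycle

    df_mass = 1.0
    undetected: Dict[int, float] = {}  # entry cycle -> mass
    detected: Dict[int, float] = {}  # delay (cycles) -> mass
    dead = 0.0
    cost = 0.0
    qaly = 0.0
    trace_rows = []

    for c in range(horizon):
        q = _recurrence_prob(spec, c)
        det_prob = (
            spec.visit_sensitivity
            if c in visit_cycles
            else spec.symptomatic_detection_prob_per_cycle
        )
        disc = disc_rate ** (-(c * spec.cycle_months) / 12.0)

        undet_mass = sum(undetected.values())
        det_mass = sum(detected.values())
        if return_trace:
            trace_rows.append(
                {
                    "cycle": c,
                    "DiseaseFree": df_mass,
                    "RecurrenceUndetected": undet_mass,
                    "RecurrenceDetected": det_mass,
                    "Death": dead,
                }
            )

        # utilities accrue on start-of-cycle occupancy
        qaly += (
            disc
            * (spec.cycle_months / 12.0)
            * (
                spec.u_df * df_mass
                + spec.u_undetected * undet_mass
                + spec.u_detected * det_mass
            )
        )
        if c in visit_cycles:
            cost += disc * spec.c_visit * (df_mass + undet_mass + det_mass)

        new_dead = 0.0
        # disease-free transitions
        df_dead = df_mass * b
        df_recur = df_mass * (1.0 - b) * q
        df_mass = df_mass * (1.0 - b) * (1.0 - q)
        new_dead += df_dead

        # undetected transitions
        newly_detected = 0.0
        next_undetected: Dict[int, float] = {}
        for entry, mass in undetected.items():
            died = mass * u_mort
            found = mass * (1.0 - u_mort) * det_prob
            stays = mass * (1.0 - u_mort) * (1.0 - det_prob)
            new_dead += died
            if found > 0:
                delay = c - entry
                detected[delay] = detected.get(delay, 0.0) + found
                newly_detected += found
            if stays > 0:
                next_undetected[entry] = stays
        undetected = next_undetected
        if df_recur > 0:
            undetected[c] = undetected.get(c, 0.0) + df_recur

        # detected transitions with linear delay penalty on mortality
        for delay in list(detected):
            mass = detected[delay]
            mort = min(1.0, d_mort * (1.0 + spec.delay_beta * delay * spec.cycle_months))
            new_dead += mass * mort
            detected[delay] = mass * (1.0 - mort)

        cost += disc * spec.c_salvage * newly_detected
        cost += disc * spec.c_terminal * new_dead
        dead += new_dead

    result = CEAResult(strategy=label, total_cost=cost, total_qaly=qaly)
    if return_trace:
        return result, pd.DataFrame(trace_rows)
    return result


def icer_table(results: Sequence[CEAResult], reference: str) -> List[CEAResult]:
    """Fill incremental cost, incremental effectiveness, and ICER versus the
    named reference strategy.

    ICER is reported as incremental cost over incremental QALYs (rounded to
    whole dollars for display); strategies with nonpositive incremental
    effectiveness at nonnegative incremental cost are flagged dominated,
    and a zero effectiveness difference leaves the ICER undefined.
    """
    by_label = {r.strategy: r for r in results}
    if reference not in by_label:
        raise ValueError(f"reference strategy {reference!r} not among results")
    ref = by_label[reference]
    out: List[CEAResult] = []
    for r in results:
        if r.strategy == reference:
            out.append(replace(r, incremental_cost=None,
                               incremental_effectiveness=None, icer=None,
                               dominated=False, is_reference=True))
            continue
        ic = r.total_cost - ref.total_cost
        ie = r.total_qaly - ref.total_qaly
        icer = ic / ie if ie != 0 else None
        dominated = ie <= 0 and ic >= 0
        out.append(
            replace(r, incremental_cost=ic, incremental_effectiveness=ie,
                    icer=icer, dominated=dominated, is_reference=False)
        )
    return out


def cea_frame(results: Sequence[CEAResult]) -> pd.DataFrame:
    """Results as a table mirroring the usual CEA column layout."""
    rows = []
    for r in results:
        rows.append(
            {
                "strategy": r.strategy,
                "cost": round(r.total_cost, 2),
                "incremental_cost": None
                if r.incremental_cost is None
                else round(r.incremental_cost, 2),
                "effectiveness_qaly": round(r.total_qaly, 3),
                "incremental_effectiveness": None
                if r.incremental_effectiveness is None
                else round(r.incremental_effectiveness, 3),
                "icer_per_qaly": r.icer_rounded,
                "dominated": r.dominated,
                "reference": r.is_reference,
            }
        )
    return pd.DataFrame(rows)
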