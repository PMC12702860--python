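"""Perspective-specific costing of cohort traces.

Two perspectives are supported:

* **payer** -- 5-year horizon, monetary basis is billed hospital charges per
  day for in-hospital states plus per-event costs for home infections, NGT
  discharges, and rehospitalizations.
* **hospital** -- 1-year horizon, charges converted to incurred costs via the
  cost-to-charge ratio, home-event costs excluded, staff time for NNS training
  included; NICU costs split into pre-training vs. training & follow-up and
  reported per FOF (Markov 1) / non-FOF (Markov 2) group.

Costs accumulate in full precision; rounding happens only at report rendering.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import (
    HOSPITAL_STATES,
    PRE,
    TRAIN,
    WARD,
    Arm,
    CohortTrace,
    stratify,
)
from .parameters import ParameterError, ParameterSet, charge_to_cost


class Perspective(str, enum.Enum):
    payer = "payer"
    hospital = "hospital"

    @property
    def horizon_days(self) -> float:
        return 5 * 365.0 if self is Perspective.payer else 365.0

    @property
    def months(self) -> int:
        return 60 if self is Perspective.payer else 12


PAYER_CATEGORIES = (
    "NICU",
    "Lower acuity ward",
    "Infection (in hospital)",
    "Discharged with NGT",
    "Infection (at home)",
    "Rehospitalizations",
)

HOSPITAL_CATEGORIES = (
    "FOF group: Pre NNS training NICU",
    "FOF group: NNS training and follow up",
    "FOF group: Staff time for training",
    "Non-FOF group: Pre NNS training NICU",
    "Non-FOF group: NNS training and follow up",
    "Non-FOF group: Staff time for training",
)


@dataclass(frozen=True)
class CostBreakdown:
    """Per-arm costs by care-setting category for one perspective."""

    arm: Arm
    perspective: Perspective
    categories: dict[str, float]

    @property
    def total(self) -> float:
        # single accumulation path: the total is always fsum of the categories
        return math.fsum(self.categories.values())

    def share(self, category: str) -> float:
        return self.categories[category] / self.total


@dataclass(frozen=True)
class BudgetImpact:
    """Arm differences per category (intervention minus comparator)."""

    perspective: Perspective
    categories: dict[str, float]
    arm_totals: dict[str, float]

    @property
    def total_difference(self) -> float:
        return math.fsum(self.categories.values())

    @property
    def saving(self) -> float:
        """Positive when the intervention arm costs less."""
        return -self.total_difference


@dataclass(frozen=True)
class CoveredLives:
    prop_women_reproductive_age: float
    fertility_rate: float
    prop_preterm_25_30: float
    lives: int


def _require(ps: ParameterSet, name: str, category: str) -> float:
    if name not in ps:
        raise ParameterError(f"missing unit cost {name!r} for category {category!r}")
    return ps.value(name)


def _capped_days(trace: CohortTrace, markov_id: int, state_slot: int, cap_days: float) -> float:
    """Person-days in one hospital state up to ``cap_days``, exact within cycles."""
    total = 0.0
    state = HOSPITAL_STATES[state_slot]
    for i, cyc in enumerate(trace.grid):
        if cyc.start_day >= cap_days:
            break
        m_days = min(cyc.length, cap_days - cyc.start_day)
        occ = trace.occupancy[i, markov_id, state]
        if occ == 0.0:
            continue
        d = trace.hosp_exit_daily[i, markov_id, state_slot]
        total += occ * (m_days if d <= 0 else -math.expm1(math.log1p(-d) * m_days) / d)
    return total


def _capped_tally(trace: CohortTrace, name: str, markov_id: int | None, cap_days: float) -> float:
    """Cumulative event tally up to ``cap_days`` (marginal cycle prorated)."""
    total = 0.0
    arr = trace.tallies[name]
    for i, cyc in enumerate(trace.grid):
        if cyc.start_day >= cap_days:
            break
        w = min(1.0, (cap_days - cyc.start_day) / cyc.length)
        total += w * (arr[i].sum() if markov_id is None else arr[i, markov_id])
    return total


def staff_time_cost(ps: ParameterSet, arm: Arm, group: int) -> float:
    """Hands-on staff cost of NNS training for one arm and FOF group.

    ``patients x sessions x minutes/session x wage / 60``; the non-FOF group's
    session count is scaled by the non-FOF staff factor (longer training
    attempts without FOF achievement).
    """
    if group not in (0, 1):
        raise ValueError("group must be 0 (FOF) or 1 (non-FOF)")
    sessions = ps.value(f"sessions_per_patient_{arm.value}")
    minutes = ps.value("staff_min_per_session")
    wage = ps.value("staff_wage_per_hour")
    if min(sessions, minutes, wage) < 0:
        raise ParameterError("staff-time inputs must be >= 0")
    split = stratify(ps, arm)
    # NNS-at-birth infants need no training sessions
    patients = split.mass_train_success if group == 0 else split.mass_train_failure
    if group == 1:
        sessions *= ps.value("nonfof_staff_factor")
    return patients * sessions * minutes * wage / 60.0


def attach_costs(trace: CohortTrace, ps: ParameterSet, persp: Perspective) -> CostBreakdown:
    """Cost a cohort trace under one perspective."""
    if trace.grid.horizon_days < persp.horizon_days - 1e-9:
        raise ValueError(
            f"trace horizon {trace.grid.horizon_days} d is shorter than the "
            f"{persp.value} perspective horizon {persp.horizon_days} d"
        )
    cap = persp.horizon_days
    arm = trace.arm

    if persp is Perspective.payer:
        cats = {
            "NICU": (
                _capped_days(trace, 0, 0, cap) + _capped_days(trace, 1, 0, cap)
                + _capped_days(trace, 0, 1, cap) + _capped_days(trace, 1, 1, cap)
            ) * _require(ps, "nicu_charge_per_day", "NICU"),
            "Lower acuity ward": (
                _capped_days(trace, 0, 2, cap) + _capped_days(trace, 1, 2, cap)
            ) * _require(ps, "ward_charge_per_day", "Lower acuity ward"),
            "Infection (in hospital)": _capped_tally(trace, "hosp_infections", None, cap)
            * _require(ps, "cost_infection_hosp", "Infection (in hospital)"),
            "Discharged with NGT": _capped_tally(trace, "ngt_discharges", None, cap)
            * _require(ps, "cost_ngt_discharge", "Discharged with NGT"),
            "Infection (at home)": _capped_tally(trace, "home_infections", None, cap)
            * _require(ps, "cost_home_infection", "Infection (at home)"),
            "Rehospitalizations": _capped_tally(trace, "rehosp_events", None, cap)
            * _require(ps, "cost_rehospitalization", "Rehospitalizations"),
        }
        assert tuple(cats) == PAYER_CATEGORIES
        return CostBreakdown(arm=arm, perspective=persp, categories=cats)

    ccr = _require(ps, "charge_to_cost_ratio", "hospital conversion")
    nicu = _require(ps, "nicu_charge_per_day", "NICU")
    ward = _require(ps, "ward_charge_per_day", "Lower acuity ward")
    c_inf = _require(ps, "cost_infection_hosp", "Infection (in hospital)")
    cats = {}
    for m, label in ((0, "FOF group"), (1, "Non-FOF group")):
        pre_charge = _capped_days(trace, m, 0, cap) * nicu
        train_charge = (
            _capped_days(trace, m, 1, cap) * nicu
            + _capped_days(trace, m, 2, cap) * ward
            + _capped_tally(trace, "hosp_infections", m, cap) * c_inf
        )
        cats[f"{label}: Pre NNS training NICU"] = charge_to_cost(pre_charge, ccr)
        cats[f"{label}: NNS training and follow up"] = charge_to_cost(train_charge, ccr)
        cats[f"{label}: Staff time for training"] = staff_time_cost(ps, arm, m)
    cats = {k: cats[k] for k in HOSPITAL_CATEGORIES}
    return CostBreakdown(arm=arm, perspective=persp, categories=cats)


def compare(b_intervention: CostBreakdown, b_comparator: CostBreakdown) -> BudgetImpact:
    """Per-category and total arm differences (negative = saving)."""
    if b_intervention.perspective is not b_comparator.perspective:
        raise ValueError("cannot compare breakdowns from different perspectives")
    if tuple(b_intervention.categories) != tuple(b_comparator.categories):
        raise ValueError("category sets differ between breakdowns")
    diffs = {
        k: b_intervention.categories[k] - b_comparator.categories[k]
        for k in b_intervention.categories
    }
    return BudgetImpact(
        perspective=b_intervention.perspective,
        categories=diffs,
        arm_totals={
            b_intervention.arm.value: b_intervention.total,
            b_comparator.arm.value: b_comparator.total,
        },
    )


def covered_lives(ps: ParameterSet) -> CoveredLives:
    """Insured population size that generates the modelled cohort of births.

    ``lives = round(n_patients / (prop_women x fertility x prop_preterm))``.
    """
    pw = ps.value("prop_women_reproductive_age")
    fr = ps.value("fertility_rate_annual")
    pp = ps.value("prop_births_preterm_25_30")
    denom = pw * fr * pp
    if denom <= 0:
        raise ParameterError("covered-lives denominator must be > 0")
    return CoveredLives(
        prop_women_reproductive_age=pw,
        fertility_rate=fr,
        prop_preterm_25_30=pp,
        lives=int(round(ps.n_patients / denom)),
    )


def pmpm(total_cost: float, lives: int, months: int) -> float:
    """Cost per member per month (full precision; round at display)."""
    if lives <= 0 or months <= 0:
        raise ValueError("lives and months must be > 0")
    return total_cost / (lives * months)
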