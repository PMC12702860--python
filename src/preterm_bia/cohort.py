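"""Decision tree + dual Markov cohort engine.

The care pathway for a cohort of preterm infants (gestational age at birth
25--30 weeks) is modelled as a decision tree that pre-stratifies the cohort by
predicted achievement of full oral feeding (FOF), followed by two structurally
identical Markov models evolved on a non-uniform time grid: daily cycles up to
day 180, half-monthly cycles thereafter, over a 5-year horizon.

* Markov 1 holds infants who achieve FOF in the NICU (non-nutritive sucking
  already developed at birth, or developed through training).
* Markov 2 holds infants whose training does not lead to FOF in the NICU; they
  are discharged home with a naso-/orogastric tube (NGT) and their NICU
  discharge probability is scaled by the time-to-discharge (TTD) factor
  (base case 0.8, i.e. slower discharge than the FOF group).

States: pre-training NICU, NICU training & follow-up, lower-acuity ward, and
home states (healthy / home-managed infection / rehospitalized) replicated in
five one-year clusters, plus an absorbing dead state.  Death is reachable from
every living state.  At each 365-day boundary home-cluster occupancy migrates
to the next year's cluster, which carries that year's infection,
rehospitalization, and mortality risks.

Numerical conventions
---------------------
* Per-cycle probabilities come from constant-hazard compounding
  (:func:`to_cycle_prob`), so daily and half-monthly cycles are consistent.
* Within a cycle, death takes precedence, then discharge, then events; the
  residual mass remains in state, so rows are exactly stochastic.
* NICU/ward patient-days are tallied at daily resolution inside each cycle
  (closed form under the constant hazard), so a cohort with constant daily
  discharge probability p accrues a mean stay of exactly 1/p days.
* Event tallies (infections, discharges, rehospitalizations, deaths) resolve
  at cycle end; in-hospital infections are costed tallies that do not alter
  transitions (any length-of-stay effect is absorbed in the calibrated
  discharge hazards).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .parameters import ParameterError, ParameterSet

HORIZON_DAYS = 5 * 365
DAILY_PHASE_END = 180
HALF_MONTH = 15
N_YEARS = 5

# state indices
PRE = 0
TRAIN = 1
WARD = 2
HOME = 3            # HOME + y, y in 0..4
HOME_INF = 8        # HOME_INF + y
REHOSP = 13         # REHOSP + y
DEAD = 18
N_STATES = 19

HOSPITAL_STATES = (PRE, TRAIN, WARD)
STATE_NAMES = (
    ["nicu_pre_training", "nicu_training_followup", "lower_acuity_ward"]
    + [f"home_healthy_y{y + 1}" for y in range(N_YEARS)]
    + [f"home_infection_y{y + 1}" for y in range(N_YEARS)]
    + [f"rehospitalized_y{y + 1}" for y in range(N_YEARS)]
    + ["dead"]
)

TALLY_NAMES = (
    "nicu_pre_days",
    "nicu_train_days",
    "ward_days",
    "hosp_infections",
    "nicu_discharges",
    "ngt_discharges",
    "home_infections",
    "rehosp_events",
    "deaths",
)


class Arm(str, enum.Enum):
    PFOS = "pfos"
    SOC = "soc"


class EngineError(RuntimeError):
    """Raised when the cohort iteration violates a structural invariant."""


# ---------------------------------------------------------------------------
# time grid


@dataclass(frozen=True)
class Cycle:
    index: int
    start_day: float
    length: float
    phase: str          # "daily" | "half_monthly"
    year_cluster: int   # 0-based home-year cluster


@dataclass(frozen=True)
class TimeGrid:
    horizon_days: float
    cycles: tuple[Cycle, ...]

    def __len__(self) -> int:
        return len(self.cycles)

    def __iter__(self):
        return iter(self.cycles)


def build_time_grid(horizon_days: float = HORIZON_DAYS) -> TimeGrid:
    """Daily cycles up to day 180, then 15-day cycles, tiling [0, horizon]."""
    if horizon_days < 1:
        raise ValueError(f"horizon_days must be >= 1, got {horizon_days}")
    cycles: list[Cycle] = []
    day = 0.0
    idx = 0
    while day < horizon_days - 1e-9:
        if day < DAILY_PHASE_END:
            length = min(1.0, horizon_days - day)
            phase = "daily"
        else:
            length = min(float(HALF_MONTH), horizon_days - day)
            phase = "half_monthly"
        cluster = min(int(day // 365), N_YEARS - 1)
        cycles.append(Cycle(idx, day, length, phase, cluster))
        day += length
        idx += 1
    return TimeGrid(horizon_days=float(horizon_days), cycles=tuple(cycles))


# ---------------------------------------------------------------------------
# elementary probability plumbing


def to_cycle_prob(p: float, source_period_days: float, cycle_days: float) -> float:
    """Rescale a probability between periods under a constant hazard.

    ``1 - (1 - p) ** (cycle_days / source_period_days)``; identity when the
    periods coincide, monotone in both ``p`` and ``cycle_days``.
    """
    if source_period_days <= 0 or cycle_days <= 0:
        raise ValueError("periods must be > 0")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must be in [0, 1], got {p}")
    if p == 1.0:
        if cycle_days < source_period_days:
            raise ValueError("cannot rescale a certain event to a shorter cycle (hazard undefined)")
        return 1.0
    return -math.expm1(math.log1p(-p) * cycle_days / source_period_days)


def apply_ttd(p_discharge_fof: float, ttd: float) -> float:
    """Scale the FOF-group discharge probability by the TTD factor (capped at 1)."""
    if ttd <= 0:
        raise ValueError(f"TTD factor must be > 0, got {ttd}")
    if not 0.0 <= p_discharge_fof <= 1.0:
        raise ValueError(f"probability must be in [0, 1], got {p_discharge_fof}")
    return min(ttd * p_discharge_fof, 1.0)


def weighted_rehosp_rate(
    rate_gab_24_27: float, rate_gab_28_31: float, prop_younger: float
) -> float:
    """Rehospitalization risk for the mixed cohort, weighted by the GAB split."""
    if rate_gab_24_27 < 0 or rate_gab_28_31 < 0:
        raise ValueError("rates must be >= 0")
    if not 0.0 <= prop_younger <= 1.0:
        raise ValueError(f"proportion must be in [0, 1], got {prop_younger}")
    return prop_younger * rate_gab_24_27 + (1.0 - prop_younger) * rate_gab_28_31


def _odds_scale(p: float, odds_ratio: float) -> float:
    if p <= 0.0:
        return 0.0
    if p >= 1.0:
        return 1.0
    odds = p / (1.0 - p) * odds_ratio
    return odds / (1.0 + odds)


# ---------------------------------------------------------------------------
# decision tree


@dataclass(frozen=True)
class DecisionTreeSplit:
    """Cohort masses entering each Markov entry state for one arm."""

    arm: Arm
    mass_nns_at_birth: float      # -> Markov 1, achieved-FOF (training/follow-up) state
    mass_train_success: float     # -> Markov 1, pre-training NICU state
    mass_train_failure: float     # -> Markov 2, pre-training NICU state

    @property
    def total(self) -> float:
        return self.mass_nns_at_birth + self.mass_train_success + self.mass_train_failure

    @property
    def markov_mass(self) -> tuple[float, float]:
        return (self.mass_nns_at_birth + self.mass_train_success, self.mass_train_failure)


def stratify(ps: ParameterSet, arm: Arm) -> DecisionTreeSplit:
    """Decision-tree pre-stratification by predicted FOF achievement."""
    n = ps.n_patients
    f_birth = ps.value("prop_nns_at_birth")
    f_success = ps.value(f"prop_train_success_{arm.value}")
    for name, f in (("prop_nns_at_birth", f_birth), (f"prop_train_success_{arm.value}", f_success)):
        if not 0.0 <= f <= 1.0:
            raise ParameterError(f"{name} must be a fraction in [0, 1], got {f}")
    split = DecisionTreeSplit(
        arm=arm,
        mass_nns_at_birth=n * f_birth,
        mass_train_success=n * (1.0 - f_birth) * f_success,
        mass_train_failure=n * (1.0 - f_birth) * (1.0 - f_success),
    )
    if abs(split.total - n) > 1e-9 * max(n, 1.0):
        raise ParameterError("decision-tree branch masses do not sum to the cohort size")
    return split


# ---------------------------------------------------------------------------
# transition matrices


def _discharge_prob_daily(ps: ParameterSet, arm: Arm, markov_id: int) -> float:
    """Per-day NICU discharge probability for the given Markov."""
    ttf = ps.value(f"time_to_fof_{arm.value}")
    if ttf <= 0:
        raise ParameterError(f"time_to_fof_{arm.value} must be > 0")
    p = min(1.0 / ttf, 1.0)
    if markov_id == 1:
        p = apply_ttd(p, ps.value("ttd"))
    return p


def build_transition_matrix(
    ps: ParameterSet, arm: Arm, markov_id: int, cycle: Cycle
) -> np.ndarray:
    """Row-stochastic one-cycle transition matrix for (arm, Markov, cycle).

    Home rows carry the year-cluster-specific infection / rehospitalization /
    mortality risks; the Markov-2 NICU discharge probability passes through the
    TTD factor; residual mass stays in state.  Death takes within-cycle
    precedence, then discharge, then events.
    """
    if markov_id not in (0, 1):
        raise ValueError("markov_id must be 0 (FOF) or 1 (non-FOF)")
    L = cycle.length
    M = np.zeros((N_STATES, N_STATES))

    p_die_hosp = to_cycle_prob(ps.value("mort_hospital_daily"), 1.0, L)

    # pre-training NICU: held until the training-start transfer (run loop)
    M[PRE, DEAD] = p_die_hosp
    M[PRE, PRE] = 1.0 - p_die_hosp

    # NICU training & follow-up: discharge home or to the lower-acuity ward
    p_dis = to_cycle_prob(_discharge_prob_daily(ps, arm, markov_id), 1.0, L)
    f_ward = ps.value("prop_discharge_to_ward")
    dis_eff = (1.0 - p_die_hosp) * p_dis
    M[TRAIN, DEAD] = p_die_hosp
    M[TRAIN, WARD] = dis_eff * f_ward
    M[TRAIN, HOME + cycle.year_cluster] = dis_eff * (1.0 - f_ward)
    M[TRAIN, TRAIN] = 1.0 - p_die_hosp - dis_eff

    # lower-acuity ward
    p_ward_exit = to_cycle_prob(min(1.0 / ps.value("ward_los_days"), 1.0), 1.0, L)
    exit_eff = (1.0 - p_die_hosp) * p_ward_exit
    M[WARD, DEAD] = p_die_hosp
    M[WARD, HOME + cycle.year_cluster] = exit_eff
    M[WARD, WARD] = 1.0 - p_die_hosp - exit_eff

    prop_younger = ps.value("prop_gab_25_28")
    for y in range(N_YEARS):
        mort_annual = ps.value("mort_home_annual_y1" if y == 0 else "mort_home_annual_later")
        p_die_home = to_cycle_prob(mort_annual, 365.0, L)

        p_inf_annual = ps.value(f"home_infection_annual_y{y + 1}")
        if markov_id == 1 and y == 0:  # NGT at home raises year-1 infection odds
            p_inf_annual = _odds_scale(p_inf_annual, ps.value("ngt_home_infection_or"))
        p_inf = to_cycle_prob(p_inf_annual, 365.0, L)

        r = weighted_rehosp_rate(
            ps.value(f"rehosp_rate_24_27_y{y + 1}"),
            ps.value(f"rehosp_rate_28_31_y{y + 1}"),
            prop_younger,
        )
        if markov_id == 1 and y == 0:
            r = min(r * ps.value("m2_rehosp_factor"), 1.0)
        p_reh = to_cycle_prob(min(r, 1.0), 365.0, L)

        h, hi, rh = HOME + y, HOME_INF + y, REHOSP + y
        live = 1.0 - p_die_home
        M[h, DEAD] = p_die_home
        M[h, hi] = live * p_inf
        M[h, rh] = live * p_reh
        M[h, h] = 1.0 - p_die_home - live * (p_inf + p_reh)

        # home-managed infection: 1-cycle transient, back to healthy
        M[hi, DEAD] = p_die_home
        M[hi, h] = live

        # rehospitalized: inpatient stay of configurable mean length
        p_rh_exit = to_cycle_prob(min(1.0 / ps.value("rehosp_los_days"), 1.0), 1.0, L)
        rh_exit = (1.0 - p_die_hosp) * p_rh_exit
        M[rh, DEAD] = p_die_hosp
        M[rh, h] = rh_exit
        M[rh, rh] = 1.0 - p_die_hosp - rh_exit

    M[DEAD, DEAD] = 1.0

    rowsum_err = np.abs(M.sum(axis=1) - 1.0).max()
    if rowsum_err > 1e-9:
        raise EngineError(f"transition-matrix row sums off by {rowsum_err:.2e}")
    if (M < -1e-15).any() or (M > 1.0 + 1e-12).any():
        raise EngineError("transition-matrix entries outside [0, 1]")
    return M


# ---------------------------------------------------------------------------
# cohort trace


@dataclass
class CohortTrace:
    """State occupancy and per-cycle event tallies for one arm (both Markovs)."""

    arm: Arm
    grid: TimeGrid
    entering_mass: np.ndarray            # (2,) mass entering each Markov
    occupancy: np.ndarray                # (n_cycles + 1, 2, N_STATES), cycle-start mass
    tallies: dict[str, np.ndarray]       # name -> (n_cycles, 2) per-cycle increments
    hosp_exit_daily: np.ndarray          # (n_cycles, 2, 3) per-day exit prob of PRE/TRAIN/WARD

    def total(self, name: str, markov_id: int | None = None, through_cycle: int | None = None):
        arr = self.tallies[name][: through_cycle if through_cycle is not None else len(self.grid)]
        return float(arr.sum() if markov_id is None else arr[:, markov_id].sum())

    @property
    def nicu_days(self) -> float:
        return self.total("nicu_pre_days") + self.total("nicu_train_days")

    @property
    def mean_nicu_los(self) -> float:
        return self.nicu_days / float(self.entering_mass.sum())


def _expected_days(occ: np.ndarray, exit_daily: np.ndarray, n_days: float) -> np.ndarray:
    """Person-days accrued over the first ``n_days`` of a cycle.

    Under a constant per-day exit probability d, an occupant present at cycle
    start contributes (1 - (1-d)^m) / d days over m days (m if d == 0).
    """
    out = np.empty_like(occ)
    zero = exit_daily <= 0.0
    out[zero] = occ[zero] * n_days
    d = exit_daily[~zero]
    out[~zero] = occ[~zero] * -np.expm1(np.log1p(-d) * n_days) / d
    return out


def run_cohort(
    ps: ParameterSet, arm: Arm, horizon_days: float = HORIZON_DAYS
) -> CohortTrace:
    """Evolve the decision tree + dual Markov cohort over the full grid."""
    grid = build_time_grid(horizon_days)
    split = stratify(ps, arm)
    t0 = ps.value("training_start_day")

    n_cyc = len(grid)
    occ = np.zeros((2, N_STATES))
    occ[0, TRAIN] = split.mass_nns_at_birth
    occ[0, PRE] = split.mass_train_success
    occ[1, PRE] = split.mass_train_failure
    entering = occ.sum(axis=1).copy()

    occupancy = np.zeros((n_cyc + 1, 2, N_STATES))
    tallies = {name: np.zeros((n_cyc, 2)) for name in TALLY_NAMES}
    hosp_exit_daily = np.zeros((n_cyc, 2, 3))

    matrices: dict[tuple, np.ndarray] = {}
    p_inf_daily = ps.value("p_infection_hosp_daily")
    home_slice = slice(HOME, HOME + N_YEARS)

    for i, cyc in enumerate(grid):
        # deterministic training start: pre-training mass transfers at cycle start
        if cyc.start_day >= t0:
            for m in (0, 1):
                if occ[m, PRE] > 0.0:
                    occ[m, TRAIN] += occ[m, PRE]
                    occ[m, PRE] = 0.0
        occupancy[i] = occ

        p_inf_cycle = to_cycle_prob(p_inf_daily, 1.0, cyc.length)
        for m in (0, 1):
            key = (m, cyc.length, cyc.year_cluster)
            M = matrices.get(key)
            if M is None:
                M = matrices[key] = build_transition_matrix(ps, arm, m, cyc)

            o = occ[m]
            # person-days at daily resolution (exact under the constant hazard)
            for j, s in enumerate(HOSPITAL_STATES):
                q = 1.0 - M[s, s]
                d = -math.expm1(math.log1p(-min(q, 1.0 - 1e-15)) / cyc.length)
                hosp_exit_daily[i, m, j] = d
            days = _expected_days(
                o[list(HOSPITAL_STATES)], hosp_exit_daily[i, m], cyc.length
            )
            tallies["nicu_pre_days"][i, m] = days[0]
            tallies["nicu_train_days"][i, m] = days[1]
            tallies["ward_days"][i, m] = days[2]
            tallies["hosp_infections"][i, m] = (
                o[[PRE, TRAIN, WARD]].sum() * p_inf_cycle
            )

            flows = o[:, None] * M
            discharges = flows[TRAIN, WARD] + flows[TRAIN, home_slice].sum()
            tallies["nicu_discharges"][i, m] = discharges
            if m == 1:
                tallies["ngt_discharges"][i, m] = discharges
            tallies["home_infections"][i, m] = flows[home_slice, HOME_INF : HOME_INF + N_YEARS].sum()
            tallies["rehosp_events"][i, m] = flows[home_slice, REHOSP : REHOSP + N_YEARS].sum()
            tallies["deaths"][i, m] = flows[:, DEAD].sum() - o[DEAD]

            occ[m] = o @ M
            if abs(occ[m].sum() - entering[m]) > 1e-9 * max(entering[m], 1.0):
                raise EngineError(
                    f"mass conservation violated at cycle {i} (markov {m}): "
                    f"{occ[m].sum():.12g} != {entering[m]:.12g}"
                )

        # year-cluster migration at 365-day boundaries
        if i + 1 < n_cyc and grid.cycles[i + 1].year_cluster > cyc.year_cluster:
            c = cyc.year_cluster
            for m in (0, 1):
                for base in (HOME, HOME_INF, REHOSP):
                    occ[m, base + c + 1] += occ[m, base + c]
                    occ[m, base + c] = 0.0

    occupancy[n_cyc] = occ
    return CohortTrace(
        arm=arm,
        grid=grid,
        entering_mass=entering,
        occupancy=occupancy,
        tallies=tallies,
        hosp_exit_daily=hosp_exit_daily,
    )


# ---------------------------------------------------------------------------
# outcome extraction


OUTCOME_KEYS = (
    "nicu_days",
    "hosp_infections",
    "ngt_discharges",
    "home_infections",
    "rehosp_events",
    "ward_days",
    "deaths",
)


def extract_outcomes(
    trace: CohortTrace, other: CohortTrace | None = None
) -> dict[str, float] | dict[str, dict[str, float]]:
    """Clinical/resource summary of a trace; with ``other``, also differences.

    With two traces the result maps ``{trace.arm: ..., other.arm: ...,
    "difference": ...}`` where differences are ``trace - other`` per category.
    """
    def summary(t: CohortTrace) -> dict[str, float]:
        out = {"nicu_days": t.nicu_days}
        for key in OUTCOME_KEYS[1:]:
            out[key] = t.total(key)
        return out

    if other is None:
        return summary(trace)
    a, b = summary(trace), summary(other)
    return {
        trace.arm.value: a,
        other.arm.value: b,
        "difference": {k: a[k] - b[k] for k in a},
    }


def trace_to_frame(trace: CohortTrace):
    """Long-format occupancy export (cycle, markov, state, mass)."""
    import pandas as pd

    rows = []
    for i, cyc in enumerate(trace.grid):
        for m in (0, 1):
            for s, name in enumerate(STATE_NAMES):
                rows.append(
                    {
                        "cycle": i,
                        "start_day": cyc.start_day,
                        "arm": trace.arm.value,
                        "markov": m + 1,
                        "state": name,
                        "mass": trace.occupancy[i, m, s],
                    }
                )
    return pd.DataFrame(rows, columns=["cycle", "start_day", "arm", "markov", "state", "mass"])
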