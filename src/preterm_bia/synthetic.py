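"""Default calibrated parameter fixture and synthetic parameter sets.

The original supplementary input tables behind this model are not distributed
with the package; this module builds a structurally faithful stand-in.  Every
value is either anchored to a figure printed in the published analysis (length
of stay, covered lives, cost-category magnitudes), back-solved so that the
base-case run reproduces such a figure, or a documented plausible placeholder.
The fixture is therefore *calibrated*, not transcribed: no claim is made that
individual unit costs equal the original supplementary inputs.

Calibration targets shipped with the fixture (checked by the test suite):

* mean NICU length of stay 65.8 days (SoC) / 59.8 days (PFOS), the per-arm
  model inputs, within 0.1 day;
* covered insurance lives exactly 982,791;
* NICU share of payer costs ~92%;
* NGT discharges per 100 infants near 5.94 (SoC) / 6.42 (PFOS);
* NICU-day difference per 100 infants near 577 (loose tolerance: the printed
  clinical table and the printed LOS inputs are not mutually consistent, and
  the fixture follows the LOS inputs).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.optimize import brentq

from .cohort import Arm, run_cohort
from .costing import Perspective, attach_costs, covered_lives
from .parameters import ParameterSet, dump_parameters, load_parameters, perturb

# published reference magnitudes the fixture is calibrated against
LOS_TARGET = {Arm.SOC: 65.8, Arm.PFOS: 59.8}          # days, model inputs
COVERED_LIVES_TARGET = 982_791                         # insured lives
SOC_NICU_CATEGORY_USD = 22_182_414.0                   # payer NICU category, SoC arm
NGT_DISCHARGE_TARGET = {Arm.SOC: 5.94, Arm.PFOS: 6.42}  # per 100 infants
NICU_SHARE_TARGET = 0.919                              # NICU share of payer costs
NICU_DAY_DIFF_TARGET = 577.0                           # SoC minus PFOS, per 100

# subgroup LOS inputs (days): the older GAB group carries nearly all of the
# arm gap, consistent with the trial pattern the published subgroup table shows
SUBGROUP_LOS = {
    "gab_25_28": {Arm.SOC: 75.0, Arm.PFOS: 73.8},
    "gab_29_30": {Arm.SOC: 56.6, Arm.PFOS: 45.8},
}


@dataclass(frozen=True)
class CalibrationTarget:
    name: str
    target: float
    tolerance: float


DEFAULT_TARGETS = (
    CalibrationTarget("mean_nicu_los_soc", LOS_TARGET[Arm.SOC], 0.1),
    CalibrationTarget("mean_nicu_los_pfos", LOS_TARGET[Arm.PFOS], 0.1),
    CalibrationTarget("covered_lives", COVERED_LIVES_TARGET, 0.5),
    CalibrationTarget("nicu_share_payer", NICU_SHARE_TARGET, 0.02),
    CalibrationTarget("ngt_discharges_soc", NGT_DISCHARGE_TARGET[Arm.SOC], 0.6),
    CalibrationTarget("ngt_discharges_pfos", NGT_DISCHARGE_TARGET[Arm.PFOS], 0.6),
    CalibrationTarget("nicu_day_difference", NICU_DAY_DIFF_TARGET, 60.0),
)


class CalibrationError(RuntimeError):
    """Raised when a calibration root cannot be bracketed or a target fails."""


def calibrate_discharge_prob(target_mean_los_days: float, mortality: float = 0.0) -> float:
    """Per-day NICU discharge probability reproducing a target mean stay.

    With zero mortality the mean of the day-resolved geometric stay is exactly
    ``1/p``, so the closed form ``p = 1/target`` applies.  With a competing
    daily death probability the exit process has per-day intensity
    ``1 - (1-p)(1-m)`` and the discharge probability is found by root-finding
    on the mean-stay equation, bracketed in (0, 1).
    """
    if target_mean_los_days <= 1.0:
        raise ValueError(f"target mean LOS must exceed 1 day, got {target_mean_los_days}")
    if not 0.0 <= mortality < 1.0:
        raise ValueError(f"mortality must be in [0, 1), got {mortality}")
    if mortality == 0.0:
        return 1.0 / target_mean_los_days

    def mean_stay(p: float) -> float:
        return 1.0 / (1.0 - (1.0 - p) * (1.0 - mortality))

    if mean_stay(0.0) < target_mean_los_days:
        raise CalibrationError(
            f"no discharge probability in (0, 1) reaches mean stay {target_mean_los_days} d "
            f"under daily mortality {mortality}"
        )
    return float(brentq(lambda p: mean_stay(p) - target_mean_los_days, 0.0, 1.0, xtol=1e-14))


def los_validation_run(target_mean_los_days: float, mortality: float = 0.0) -> float:
    """Round-trip check of the calibration against the engine.

    Sets a single-branch cohort (everyone trains successfully, training from
    day 0, no ward stop, no events) with the constant daily discharge
    probability returned by :func:`calibrate_discharge_prob`, evolves the full
    5-year grid, and returns cumulative NICU patient-days divided by the
    entering mass.  With zero mortality this reproduces the target exactly.
    """
    p = calibrate_discharge_prob(target_mean_los_days, mortality)
    ps = default_fixture()
    for name, value in {
        "prop_nns_at_birth": 0.0,
        "prop_train_success_soc": 1.0,
        "training_start_day": 0.0,
        "ttd": 1.0,
        "prop_discharge_to_ward": 0.0,
        "mort_hospital_daily": mortality,
        "mort_home_annual_y1": 0.0,
        "mort_home_annual_later": 0.0,
        "p_infection_hosp_daily": 0.0,
        "time_to_fof_soc": 1.0 / p,
    }.items():
        ps = ps.with_value(name, value)
    return run_cohort(ps, Arm.SOC).mean_nicu_los


def _base_entries() -> dict[str, dict]:
    """Raw fixture registry before the calibration passes."""
    prob = lambda v, note="", frac=None, period=365.0: {
        "value": v, "kind": "probability", "period_days": period, "note": note,
        **({"uncertainty_frac": frac} if frac is not None else {}),
    }
    charge = lambda v, note="": {
        "value": v, "kind": "charge", "year_of_value": 2024, "note": note,
    }
    cost = lambda v, note="": {
        "value": v, "kind": "cost", "year_of_value": 2024, "note": note,
    }
    return {
        # cohort structure
        "n_patients": {
            "value": 100, "kind": "count", "uncertainty_frac": 0.0,
            "note": "published: 100 hypothetical preterm infants, GAB 25-30 weeks",
        },
        "prop_nns_at_birth": prob(
            0.02, "placeholder: small fraction with NNS already developed at birth"
        ),
        "prop_train_success_soc": prob(
            0.9384, "back-solved: yields ~5.9 NGT discharges per 100 (SoC)"
        ),
        "prop_train_success_pfos": prob(
            0.9336, "back-solved: yields ~6.4 NGT discharges per 100 (PFOS)"
        ),
        "prop_gab_25_28": prob(0.5, "placeholder: GAB mix for weighted rehospitalization risk"),
        # engine dynamics (time_to_fof_* re-calibrated in build_default_fixture)
        "time_to_fof_soc": {
            "value": 45.0, "kind": "count", "bounds": [2.0, 1.0e9],
            "note": "back-solved: mean days in training state; calibrated to 65.8 d arm LOS",
        },
        "time_to_fof_pfos": {
            "value": 40.0, "kind": "count", "bounds": [2.0, 1.0e9],
            "note": "back-solved: calibrated to 59.8 d arm LOS",
        },
        "training_start_day": {
            "value": 21.0, "kind": "count", "bounds": [0.0, 180.0],
            "note": "placeholder: oral stimulation typically starts ~3 weeks after birth",
        },
        "ttd": {
            "value": 0.8, "kind": "factor", "bounds": [0.05, 5.0],
            "note": "published base case: time-to-discharge factor for the non-FOF group",
        },
        "prop_discharge_to_ward": prob(
            0.10, "placeholder: share of NICU discharges via a lower-acuity ward"
        ),
        "ward_los_days": {
            "value": 10.0, "kind": "count", "bounds": [1.5, 120.0],
            "note": "placeholder: mean lower-acuity ward stay",
        },
        "rehosp_los_days": {
            "value": 9.0, "kind": "count", "bounds": [1.5, 90.0],
            "note": "placeholder: mean rehospitalization stay",
        },
        "mort_hospital_daily": prob(
            0.0002, "placeholder: in-hospital background mortality", period=1.0
        ),
        "mort_home_annual_y1": prob(0.010, "placeholder: first-year at-home mortality"),
        "mort_home_annual_later": prob(0.003, "placeholder: later-year at-home mortality"),
        "p_infection_hosp_daily": prob(
            0.0012, "back-solved: ~7-8 NGT infections per 100 over the NICU stay", period=1.0
        ),
        "home_infection_annual_y1": prob(0.12, "placeholder: declining home-infection risk"),
        "home_infection_annual_y2": prob(0.10, "placeholder"),
        "home_infection_annual_y3": prob(0.08, "placeholder"),
        "home_infection_annual_y4": prob(0.07, "placeholder"),
        "home_infection_annual_y5": prob(0.06, "placeholder"),
        "ngt_home_infection_or": {
            "value": 2.0, "kind": "odds_ratio",
            "note": "placeholder: elevated year-1 infection odds with an NGT at home",
        },
        "m2_rehosp_factor": {
            "value": 1.3, "kind": "factor", "bounds": [0.2, 5.0],
            "note": "placeholder: elevated year-1 rehospitalization risk with an NGT at home",
        },
        # annual rehospitalization risks by GAB group (weighted by prop_gab_25_28)
        "rehosp_rate_24_27_y1": {"value": 0.51, "kind": "rate", "period_days": 365.0,
                                 "note": "back-solved: GAB 24-27 rehospitalization risk, year 1; "
                                         "levels chosen so the mixed cohort accrues ~123 "
                                         "rehospitalizations per 100 over 5 years"},
        "rehosp_rate_24_27_y2": {"value": 0.32, "kind": "rate", "period_days": 365.0, "note": "back-solved"},
        "rehosp_rate_24_27_y3": {"value": 0.21, "kind": "rate", "period_days": 365.0, "note": "back-solved"},
        "rehosp_rate_24_27_y4": {"value": 0.16, "kind": "rate", "period_days": 365.0, "note": "back-solved"},
        "rehosp_rate_24_27_y5": {"value": 0.13, "kind": "rate", "period_days": 365.0, "note": "back-solved"},
        "rehosp_rate_28_31_y1": {"value": 0.34, "kind": "rate", "period_days": 365.0,
                                 "note": "back-solved: GAB 28-31 rehospitalization risk, year 1"},
        "rehosp_rate_28_31_y2": {"value": 0.22, "kind": "rate", "period_days": 365.0, "note": "back-solved"},
        "rehosp_rate_28_31_y3": {"value": 0.145, "kind": "rate", "period_days": 365.0, "note": "back-solved"},
        "rehosp_rate_28_31_y4": {"value": 0.11, "kind": "rate", "period_days": 365.0, "note": "back-solved"},
        "rehosp_rate_28_31_y5": {"value": 0.085, "kind": "rate", "period_days": 365.0, "note": "back-solved"},
        # unit costs / charges (nicu_charge_per_day re-calibrated)
        "nicu_charge_per_day": charge(
            3350.0, "back-solved: SoC payer NICU category matches the published magnitude"
        ),
        "ward_charge_per_day": charge(985.0, "placeholder: lower-acuity (level I) daily charge"),
        "cost_infection_hosp": charge(2263.0, "placeholder: per in-hospital NGT infection"),
        "cost_ngt_discharge": cost(3852.0, "placeholder: per discharge home with an NGT"),
        "cost_home_infection": cost(1049.0, "placeholder: per home-managed infection"),
        "cost_rehospitalization": cost(13900.0, "placeholder: per rehospitalization episode"),
        "charge_to_cost_ratio": {
            "value": 0.44, "kind": "factor", "bounds": [0.05, 1.5],
            "note": "placeholder: scalar hospital cost-to-charge ratio",
        },
        "staff_wage_per_hour": cost(60.0, "placeholder: loaded nursing wage"),
        "staff_min_per_session": {
            "value": 15.0, "kind": "count", "bounds": [1.0, 120.0],
            "note": "placeholder: hands-on minutes per training session",
        },
        "sessions_per_patient_soc": {
            "value": 57.0, "kind": "count", "bounds": [0.0, 500.0],
            "note": "placeholder: manual oral-stimulation sessions per SoC patient",
        },
        "sessions_per_patient_pfos": {
            "value": 48.0, "kind": "count", "bounds": [0.0, 500.0],
            "note": "placeholder: fewer hands-on sessions with the pulsed-pacifier device",
        },
        "nonfof_staff_factor": {
            "value": 1.3, "kind": "factor", "bounds": [0.2, 5.0],
            "note": "placeholder: extra training effort in the non-FOF group",
        },
        # covered-lives demographics (prop_births_preterm_25_30 back-solved)
        "prop_women_reproductive_age": prob(
            0.1925, "placeholder: share of insured population who are women of reproductive age"
        ),
        "fertility_rate_annual": {
            "value": 0.0565, "kind": "rate", "period_days": 365.0,
            "note": "placeholder: births per woman-year",
        },
        "prop_births_preterm_25_30": prob(
            0.00936, "back-solved below: covered lives exactly 982,791"
        ),
    }


def _calibrate_ttf(ps: ParameterSet, arm: Arm, target_los: float) -> float:
    """Root-find the training-state mean (days) so the arm mean NICU LOS hits target."""
    name = f"time_to_fof_{arm.value}"

    def err(ttf: float) -> float:
        return run_cohort(ps.with_value(name, ttf), arm).mean_nicu_los - target_los

    lo, hi = 3.0, 350.0
    if err(lo) > 0 or err(hi) < 0:
        raise CalibrationError(f"cannot bracket time-to-FOF for {arm.value} at LOS {target_los}")
    return float(brentq(err, lo, hi, xtol=1e-9))


def build_default_fixture(validate: bool = True) -> ParameterSet:
    """Construct the calibrated default fixture from scratch.

    Runs three calibration passes: (1) the covered-lives denominator is
    back-solved so rounding yields exactly the target lives; (2) per-arm
    training-state means are root-found against the engine so the base-case
    arm mean NICU LOS equals the published per-arm inputs; (3) the NICU daily
    charge is back-solved so the SoC payer NICU category matches the published
    magnitude.
    """
    ps = load_parameters({"label": "default-calibrated", "parameters": _base_entries()})

    pw = ps.value("prop_women_reproductive_age")
    fr = ps.value("fertility_rate_annual")
    pp = ps.n_patients / (COVERED_LIVES_TARGET * pw * fr)
    ps = ps.with_value("prop_births_preterm_25_30", pp)

    for arm in (Arm.SOC, Arm.PFOS):
        ps = ps.with_value(f"time_to_fof_{arm.value}", _calibrate_ttf(ps, arm, LOS_TARGET[arm]))

    soc_days = run_cohort(ps, Arm.SOC).nicu_days
    ps = ps.with_value("nicu_charge_per_day", SOC_NICU_CATEGORY_USD / soc_days)

    if validate:
        failures = [
            f"{name}: {value:.4f} vs {t.target} (tol {t.tolerance})"
            for name, value, t in check_calibration(ps)
            if abs(value - t.target) > t.tolerance
        ]
        if failures:
            raise CalibrationError("fixture fails its calibration targets: " + "; ".join(failures))
    return ps


def check_calibration(ps: ParameterSet) -> list[tuple[str, float, CalibrationTarget]]:
    """Evaluate every shipped calibration target on a parameter set."""
    traces = {arm: run_cohort(ps, arm) for arm in Arm}
    payer_soc = attach_costs(traces[Arm.SOC], ps, Perspective.payer)
    values = {
        "mean_nicu_los_soc": traces[Arm.SOC].mean_nicu_los,
        "mean_nicu_los_pfos": traces[Arm.PFOS].mean_nicu_los,
        "covered_lives": float(covered_lives(ps).lives),
        "nicu_share_payer": payer_soc.share("NICU"),
        "ngt_discharges_soc": traces[Arm.SOC].total("ngt_discharges"),
        "ngt_discharges_pfos": traces[Arm.PFOS].total("ngt_discharges"),
        "nicu_day_difference": traces[Arm.SOC].nicu_days - traces[Arm.PFOS].nicu_days,
    }
    return [(t.name, values[t.name], t) for t in DEFAULT_TARGETS]


@functools.lru_cache(maxsize=1)
def _load_shipped_fixture() -> ParameterSet:
    text = resources.files("preterm_bia.data").joinpath("default_parameters.yaml").read_text()
    return load_parameters(text)


def default_fixture() -> ParameterSet:
    """The shipped, pre-calibrated default parameter set."""
    return _load_shipped_fixture().model_copy(deep=True)


def subgroup_fixtures() -> tuple[ParameterSet, ParameterSet]:
    """Parameter sets for the GAB 25--28 and 29--30 subgroups (50 infants each).

    Each subgroup uses its own GAB-specific rehospitalization risks (the mixed
    weighting collapses to one group) and arm LOS inputs re-calibrated to the
    subgroup pattern: the older group carries nearly the whole arm gap.
    """
    base = default_fixture()
    out = []
    for label, prop_younger in (("gab_25_28", 1.0), ("gab_29_30", 0.0)):
        ps = base.model_copy(update={"label": label})
        ps = ps.with_value("n_patients", base.n_patients / 2.0)
        ps = ps.with_value("prop_gab_25_28", prop_younger)
        for arm in (Arm.SOC, Arm.PFOS):
            ps = ps.with_value(
                f"time_to_fof_{arm.value}",
                _calibrate_ttf(ps, arm, SUBGROUP_LOS[label][arm]),
            )
        out.append(ps)
    return out[0], out[1]


def random_paramset(seed: int, jitter: float = 0.1) -> ParameterSet:
    """Fixture with every non-structural parameter jittered within +/- jitter.

    Deterministic per seed; bounds respected via clamping.  Intended as a
    property-test input generator, not a study condition.
    """
    if not 0.0 <= jitter <= 0.5:
        raise ValueError(f"jitter must be in [0, 0.5], got {jitter}")
    ps = default_fixture()
    rng = np.random.default_rng(seed)
    structural = {"n_patients", "training_start_day"}
    for name in ps.names():
        if name in structural:
            continue
        factor = 1.0 + jitter * float(rng.uniform(-1.0, 1.0))
        ps = perturb(ps, name, factor)
    return ps.model_copy(update={"label": f"jittered-{seed}"})


def write_fixture(path) -> None:
    """Generate the calibrated fixture and write it as YAML (make-fixture)."""
    from pathlib import Path

    Path(path).write_text(dump_parameters(build_default_fixture()))
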