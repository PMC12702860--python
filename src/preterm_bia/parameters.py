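"""Parameter registry for the budget-impact model.

Every model input lives in a :class:`ParameterSet`: a named collection of
scalar :class:`Parameter` values with their kind (probability, cost, charge,
odds ratio, ...), the calendar year a monetary value refers to, admissible
bounds, and a relative uncertainty fraction used by the probabilistic
sensitivity analysis.  The module also owns the PSA distribution-assignment
rules, charge/cost conversion, inflation to the model's currency year, and
deterministic perturbation/sampling of whole parameter sets.

Distribution assignment follows the conventions of probabilistic budget-impact
modelling: gamma for costs and charges, lognormal for odds ratios, normal for
mid-range proportions (10%--90%) and other continuous inputs, beta for
proportions near the extremes.  All families are moment-matched so that the
sampled mean equals the base value and the standard deviation equals
``value * uncertainty_frac``.
"""

from __future__ import annotations

import csv
import enum
import hashlib
import io
import json
import logging
import math
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

logger = logging.getLogger(__name__)

#: currency year all monetary inputs are normalized to
CURRENCY_YEAR = 2024

#: relative-sd defaults by kind: 20% for costs/charges, 10% otherwise
DEFAULT_UNCERTAINTY = {"cost": 0.20, "charge": 0.20}
GENERAL_UNCERTAINTY = 0.10


class ParameterError(ValueError):
    """Raised for invalid, missing, or out-of-bounds parameters."""


class Kind(str, enum.Enum):
    probability = "probability"
    rate = "rate"
    cost = "cost"
    charge = "charge"
    odds_ratio = "odds_ratio"
    count = "count"
    factor = "factor"


class Parameter(BaseModel):
    """A single named scalar model input."""

    model_config = ConfigDict(frozen=True)

    name: str
    value: float
    kind: Kind
    period_days: float | None = None
    year_of_value: int | None = None
    uncertainty_frac: float | None = None
    bounds: tuple[float, float] | None = None
    note: str = ""

    @model_validator(mode="after")
    def _check(self) -> "Parameter":
        lo, hi = self.effective_bounds
        if not lo <= self.value <= hi:
            raise ParameterError(
                f"parameter {self.name!r}: value {self.value} outside bounds [{lo}, {hi}]"
            )
        if self.uncertainty_frac is not None and self.uncertainty_frac < 0:
            raise ParameterError(f"parameter {self.name!r}: uncertainty_frac must be >= 0")
        if self.period_days is not None and self.period_days <= 0:
            raise ParameterError(f"parameter {self.name!r}: period_days must be > 0")
        if self.kind in (Kind.probability, Kind.rate) and self.period_days is None:
            raise ParameterError(
                f"parameter {self.name!r}: kind {self.kind.value} requires period_days"
            )
        return self

    @property
    def effective_bounds(self) -> tuple[float, float]:
        if self.bounds is not None:
            return self.bounds
        if self.kind is Kind.probability:
            return (0.0, 1.0)
        if self.kind in (Kind.cost, Kind.charge, Kind.rate, Kind.count):
            return (0.0, math.inf)
        if self.kind is Kind.odds_ratio:
            return (1e-12, math.inf)
        return (-math.inf, math.inf)

    @property
    def frac(self) -> float:
        if self.uncertainty_frac is not None:
            return self.uncertainty_frac
        return DEFAULT_UNCERTAINTY.get(self.kind.value, GENERAL_UNCERTAINTY)


class Family(str, enum.Enum):
    normal = "normal"
    beta = "beta"
    lognormal = "lognormal"
    gamma = "gamma"
    degenerate = "degenerate"


class DistributionSpec(BaseModel):
    """A sampling distribution with moment parameters matched to a Parameter.

    ``mean`` always equals the base value; ``sd`` equals value * frac except
    for the degenerate family.  ``bounds`` are enforced at draw time by
    resampling (up to 1,000 rounds) and finally clamping.
    """

    model_config = ConfigDict(frozen=True)

    family: Family
    mean: float
    sd: float = 0.0
    bounds: tuple[float, float] = (-math.inf, math.inf)

    def draw(self, rng: np.random.Generator, size: int | None = None) -> float | np.ndarray:
        n = 1 if size is None else size
        if self.family is Family.degenerate:
            out = np.full(n, self.mean)
        elif self.family is Family.normal:
            out = rng.normal(self.mean, self.sd, n)
        elif self.family is Family.gamma:
            shape = (self.mean / self.sd) ** 2
            scale = self.sd**2 / self.mean
            out = rng.gamma(shape, scale, n)
        elif self.family is Family.lognormal:
            sigma2 = math.log1p((self.sd / self.mean) ** 2)
            mu = math.log(self.mean) - sigma2 / 2.0
            out = rng.lognormal(mu, math.sqrt(sigma2), n)
        elif self.family is Family.beta:
            a, b = _beta_moments(self.mean, self.sd)
            out = rng.beta(a, b, n)
        else:  # pragma: no cover
            raise ParameterError(f"unknown family {self.family}")
        lo, hi = self.bounds
        for _ in range(1000):
            bad = (out < lo) | (out > hi)
            if not bad.any():
                break
            out[bad] = self.draw_raw(rng, int(bad.sum()))
        out = np.clip(out, lo, hi)
        return float(out[0]) if size is None else out

    def draw_raw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        spec = self.model_copy(update={"bounds": (-math.inf, math.inf)})
        return np.atleast_1d(spec.draw(rng, n))


def _beta_moments(mean: float, sd: float) -> tuple[float, float]:
    if not 0.0 < mean < 1.0:
        raise ParameterError(f"beta distribution requires mean in (0,1), got {mean}")
    if sd**2 >= mean * (1.0 - mean):
        raise ParameterError(f"beta distribution infeasible: sd {sd} too large for mean {mean}")
    common = mean * (1.0 - mean) / sd**2 - 1.0
    return mean * common, (1.0 - mean) * common


def assign_distribution(p: Parameter) -> DistributionSpec:
    """PSA distribution for one parameter.

    Costs/charges -> gamma; odds ratios -> lognormal; probabilities in
    [0.10, 0.90] -> normal, outside -> beta; all other continuous inputs ->
    normal.  A zero uncertainty fraction (or a zero/boundary base value that
    admits no spread) yields a degenerate distribution.
    """
    frac = p.frac
    v = p.value
    sd = abs(v) * frac
    bounds = p.effective_bounds
    if frac == 0.0 or sd == 0.0:
        return DistributionSpec(family=Family.degenerate, mean=v, sd=0.0, bounds=bounds)
    if p.kind in (Kind.cost, Kind.charge):
        return DistributionSpec(family=Family.gamma, mean=v, sd=sd, bounds=bounds)
    if p.kind is Kind.odds_ratio:
        return DistributionSpec(family=Family.lognormal, mean=v, sd=sd, bounds=bounds)
    if p.kind is Kind.probability:
        if 0.10 <= v <= 0.90:
            return DistributionSpec(family=Family.normal, mean=v, sd=sd, bounds=bounds)
        if not 0.0 < v < 1.0:
            return DistributionSpec(family=Family.degenerate, mean=v, sd=0.0, bounds=bounds)
        if sd**2 >= v * (1.0 - v):  # spread infeasible for a beta this extreme
            sd = 0.5 * math.sqrt(v * (1.0 - v))
        return DistributionSpec(family=Family.beta, mean=v, sd=sd, bounds=bounds)
    return DistributionSpec(family=Family.normal, mean=v, sd=sd, bounds=bounds)


def charge_to_cost(charge: float, ratio: float) -> float:
    """Convert a billed charge to an incurred cost via a cost-to-charge ratio."""
    if ratio <= 0:
        raise ParameterError(f"cost-to-charge ratio must be > 0, got {ratio}")
    if charge < 0:
        raise ParameterError(f"charge must be >= 0, got {charge}")
    return charge * ratio


def cost_to_charge(cost: float, ratio: float) -> float:
    if ratio <= 0:
        raise ParameterError(f"cost-to-charge ratio must be > 0, got {ratio}")
    return cost / ratio


def inflate_to_2024(
    value: float, year_of_value: int, index: Mapping[int, float], target_year: int = CURRENCY_YEAR
) -> float:
    """Inflate a monetary value to the model currency year using an index table."""
    for year in (year_of_value, target_year):
        if year not in index:
            raise ParameterError(f"inflation index has no entry for year {year}")
    return value * index[target_year] / index[year_of_value]


def default_inflation_index() -> dict[int, float]:
    """Medical-care price index shipped with the package (editable fixture)."""
    text = resources.files("preterm_bia.data").joinpath("inflation_index.csv").read_text()
    out: dict[int, float] = {}
    for row in csv.DictReader(io.StringIO(text)):
        out[int(row["year"])] = float(row["index"])
    return out


# ---------------------------------------------------------------------------
# ParameterSet

#: parameters every downstream module depends on; load_parameters enforces these
MANDATORY_PARAMETERS = (
    "n_patients",
    "prop_nns_at_birth",
    "prop_train_success_soc",
    "prop_train_success_pfos",
    "prop_gab_25_28",
    "time_to_fof_soc",
    "time_to_fof_pfos",
    "training_start_day",
    "ttd",
    "prop_discharge_to_ward",
    "ward_los_days",
    "rehosp_los_days",
    "mort_hospital_daily",
    "mort_home_annual_y1",
    "mort_home_annual_later",
    "p_infection_hosp_daily",
    "home_infection_annual_y1",
    "home_infection_annual_y2",
    "home_infection_annual_y3",
    "home_infection_annual_y4",
    "home_infection_annual_y5",
    "ngt_home_infection_or",
    "m2_rehosp_factor",
    "rehosp_rate_24_27_y1",
    "rehosp_rate_24_27_y2",
    "rehosp_rate_24_27_y3",
    "rehosp_rate_24_27_y4",
    "rehosp_rate_24_27_y5",
    "rehosp_rate_28_31_y1",
    "rehosp_rate_28_31_y2",
    "rehosp_rate_28_31_y3",
    "rehosp_rate_28_31_y4",
    "rehosp_rate_28_31_y5",
    "nicu_charge_per_day",
    "ward_charge_per_day",
    "cost_infection_hosp",
    "cost_ngt_discharge",
    "cost_home_infection",
    "cost_rehospitalization",
    "charge_to_cost_ratio",
    "staff_wage_per_hour",
    "staff_min_per_session",
    "sessions_per_patient_soc",
    "sessions_per_patient_pfos",
    "nonfof_staff_factor",
    "prop_women_reproductive_age",
    "fertility_rate_annual",
    "prop_births_preterm_25_30",
)


class ParameterSet(BaseModel):
    """Validated, currency-normalized registry of all model inputs."""

    parameters: dict[str, Parameter]
    currency_year: int = CURRENCY_YEAR
    inflation_index: dict[int, float] = Field(default_factory=dict)
    label: str = "default"

    def __contains__(self, name: str) -> bool:
        return name in self.parameters

    def __getitem__(self, name: str) -> Parameter:
        try:
            return self.parameters[name]
        except KeyError:
            raise ParameterError(f"unknown parameter {name!r}") from None

    def value(self, name: str) -> float:
        return self[name].value

    @property
    def n_patients(self) -> float:
        return self.value("n_patients")

    def names(self) -> list[str]:
        return sorted(self.parameters)

    def with_value(self, name: str, value: float, clamp: bool = False) -> "ParameterSet":
        """Copy of the set with one parameter replaced (optionally clamped)."""
        p = self[name]
        lo, hi = p.effective_bounds
        if clamp and not lo <= value <= hi:
            clamped = min(max(value, lo), hi)
            logger.warning(
                "parameter %s: value %.6g clamped to bounds [%g, %g] -> %.6g",
                name, value, lo, hi, clamped,
            )
            value = clamped
        new = dict(self.parameters)
        new[name] = p.model_copy(update={"value": value})
        new[name].model_validate(new[name])
        return self.model_copy(update={"parameters": new})

    def distributions(self) -> dict[str, DistributionSpec]:
        return {name: assign_distribution(self.parameters[name]) for name in self.names()}

    def content_hash(self) -> str:
        """Stable hash of the registry for report provenance."""
        payload = json.dumps(
            {n: self.parameters[n].model_dump(mode="json") for n in self.names()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_frame(self):
        """Registry as a pandas DataFrame (audit export)."""
        import pandas as pd

        rows = []
        for name in self.names():
            p = self.parameters[name]
            lo, hi = p.effective_bounds
            rows.append(
                {
                    "name": name,
                    "value": p.value,
                    "kind": p.kind.value,
                    "period_days": p.period_days,
                    "year_of_value": p.year_of_value,
                    "uncertainty_frac": p.frac,
                    "lower": lo,
                    "upper": hi,
                    "note": p.note,
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def schema_description(cls) -> dict:
        """JSON-schema-style description of the parameter file format."""
        return {
            "type": "object",
            "properties": {
                "label": {"type": "string"},
                "currency_year": {"type": "integer"},
                "inflation_index": {"type": "object"},
                "parameters": {
                    "type": "object",
                    "additionalProperties": Parameter.model_json_schema(),
                },
            },
            "required": ["parameters"],
        }


def perturb(ps: ParameterSet, name: str, factor: float) -> ParameterSet:
    """One-way perturbation: scale a single parameter, clamped to its bounds."""
    return ps.with_value(name, ps.value(name) * factor, clamp=True)


def sample(ps: ParameterSet, seed: int | np.random.Generator) -> ParameterSet:
    """One joint independent PSA draw of every parameter (deterministic per seed)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    new = dict(ps.parameters)
    for name in ps.names():
        spec = assign_distribution(new[name])
        if spec.family is Family.degenerate:
            continue
        new[name] = new[name].model_copy(update={"value": float(spec.draw(rng))})
    return ps.model_copy(update={"parameters": new})


def load_parameters(source: str | Path | Mapping) -> ParameterSet:
    """Load and validate a parameter file (YAML path, YAML text, or mapping).

    Monetary values carrying an earlier ``year_of_value`` are inflated to the
    set's currency year; charge-kind inputs keep their kind tag so that the
    hospital perspective can convert them later.
    """
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        s = str(source)
        if "\n" in s:
            text = s
        else:
            path = Path(s)
            if not path.exists():
                raise ParameterError(f"parameter file not found: {s}")
            text = path.read_text()
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "parameters" not in doc:
        raise ParameterError("parameter file must be a mapping with a 'parameters' section")

    currency_year = int(doc.get("currency_year", CURRENCY_YEAR))
    index = {int(k): float(v) for k, v in (doc.get("inflation_index") or {}).items()}
    if not index:
        index = default_inflation_index()

    params: dict[str, Parameter] = {}
    errors: list[str] = []
    for name, entry in dict(doc["parameters"]).items():
        try:
            p = Parameter(name=name, **entry)
            if (
                p.kind in (Kind.cost, Kind.charge)
                and p.year_of_value is not None
                and p.year_of_value != currency_year
            ):
                v = inflate_to_2024(p.value, p.year_of_value, index, currency_year)
                p = p.model_copy(update={"value": v, "year_of_value": currency_year})
            params[name] = p
        except (ParameterError, ValueError) as exc:
            errors.append(str(exc))
    missing = [n for n in MANDATORY_PARAMETERS if n not in params]
    if missing:
        errors.append(f"missing mandatory parameters: {', '.join(missing)}")
    if errors:
        raise ParameterError("; ".join(errors))
    return ParameterSet(
        parameters=params,
        currency_year=currency_year,
        inflation_index=index,
        label=str(doc.get("label", "default")),
    )


def dump_parameters(ps: ParameterSet) -> str:
    """Serialize a ParameterSet back to YAML (inverse of load_parameters)."""
    entries = {}
    for name in ps.names():
        p = ps.parameters[name]
        e: dict = {"value": p.value, "kind": p.kind.value}
        if p.period_days is not None:
            e["period_days"] = p.period_days
        if p.year_of_value is not None:
            e["year_of_value"] = p.year_of_value
        if p.uncertainty_frac is not None:
            e["uncertainty_frac"] = p.uncertainty_frac
        if p.bounds is not None:
            e["bounds"] = list(p.bounds)
        if p.note:
            e["note"] = p.note
        entries[name] = e
    doc = {
        "label": ps.label,
        "currency_year": ps.currency_year,
        "inflation_index": {int(y): float(v) for y, v in sorted(ps.inflation_index.items())},
        "parameters": entries,
    }
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=None)
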