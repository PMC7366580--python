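"""Canonical gross drug budget-impact engine.

A gross drug budget impact contains only the acquisition cost of the new
drug: eligible patient population -> treated patients -> drug consumption
-> annual cost, over a finite horizon (default five model years). Cost
offsets from displaced comparators, rebates, pharmacist fees and VAT are
deliberately out of scope; everything is valued at the publicly available
list price.

Applicant-submitted models are confidential and heterogeneous, so a single
canonical *multiplicative cohort* engine is defined here. It is
deterministic and monotone in every parameter, which is all the downstream
validation and probabilistic sensitivity analysis stages require, and it
can express any combination of the documented modelling features
(incidence, prevalence, population growth, adherence, discontinuation,
duration of treatment) and parameter-category profile.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

SCHEMA_VERSION = "1"

#: Fixed days-per-year convention used to annualise daily dosing.
DAYS_PER_YEAR = 365.25

Category = Literal["population", "market_share", "dosage", "acquisition_cost"]


class Parameter(BaseModel):
    """A single named model input, categorised for the parameter census.

    Categories follow the four standard blocks of an applicant budget-impact
    model: 'population' (eligible-population assumptions), 'market_share'
    (uptake percentages), 'dosage' (pack/vial requirements per patient-year)
    and 'acquisition_cost' (drug cost). ``psa_vary`` marks whether the
    probabilistic sensitivity analysis may perturb the value; the agreed
    list price is the one parameter that never varies.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    category: Category
    value: Union[float, list[float]]
    unit: str = ""
    psa_vary: bool = True

    @field_validator("value")
    @classmethod
    def _nonnegative(cls, v):
        vals = v if isinstance(v, list) else [v]
        if any(x < 0 for x in vals):
            raise ValueError("parameter values must be nonnegative")
        return v


class FeatureFlags(BaseModel):
    """Which of the six optional modelling features a model includes."""

    model_config = ConfigDict(extra="forbid")

    incidence: bool = False
    prevalence: bool = True
    population_growth: bool = False
    adherence: bool = False
    discontinuation: bool = False
    duration_of_treatment: bool = False

    @model_validator(mode="after")
    def _has_source_population(self):
        if not (self.incidence or self.prevalence):
            raise ValueError(
                "a model must have a source population: at least one of "
                "incidence/prevalence must be enabled"
            )
        return self


def _factor_list_validator(category: Category, fraction: bool):
    def check(params: list[Parameter]) -> list[Parameter]:
        for p in params:
            if p.category != category:
                raise ValueError(f"expected category {category!r}, got {p.category!r}")
            if isinstance(p.value, list):
                raise ValueError("extra factors must be scalar")
            if fraction and not (0.0 <= p.value <= 1.0):
                raise ValueError(f"{category} factors must lie in [0, 1]")
            if not fraction and p.value <= 0:
                raise ValueError(f"{category} factors must be positive")
        return params

    return check


class ModelSpec(BaseModel):
    """One drug/indication's gross budget-impact model.

    The engine is multiplicative: eligible population x market share gives
    treated patients; packs per patient-year x unit price gives cost per
    treated person-year. Optional cohort tracking (discontinuation and/or a
    duration-of-treatment cap) makes earlier start cohorts persist into
    later years.

    Disabled features are pinned to their neutral values so that a spec and
    its feature flags can never disagree (growth_rate=0, adherence=1,
    discontinuation_rate=0, duration unbounded, and a zero incident inflow
    or prevalent pool as appropriate).

    ``extra_*_factors`` hold additional multiplicative assumptions in each
    category (e.g. diagnosis/eligibility fractions under population,
    comparator-switching fractions under market share, wastage or
    vial-sharing adjustments under dosage and cost); they exist because real
    applicant models differ widely in how many parameters each category
    contains, and every one of them is an independent target for the PSA.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    schema_version: str = SCHEMA_VERSION
    drug_id: str
    horizon_years: int = Field(default=5, ge=1)
    features: FeatureFlags = Field(default_factory=FeatureFlags)

    prevalent_pool: float = Field(default=0.0, ge=0)
    incident_inflow: float = Field(default=0.0, ge=0)
    growth_rate: float = Field(default=0.0, ge=-1)
    market_share: list[float]
    adherence: float = Field(default=1.0, gt=0, le=1)
    discontinuation_rate: float = Field(default=0.0, ge=0, lt=1)
    max_duration_years: Optional[int] = Field(default=None, ge=1)

    units_per_day: float = Field(gt=0)
    pack_size: float = Field(default=1.0, gt=0)
    list_price: float = Field(gt=0)

    extra_population_factors: list[Parameter] = Field(default_factory=list)
    extra_share_factors: list[Parameter] = Field(default_factory=list)
    extra_dosage_factors: list[Parameter] = Field(default_factory=list)
    extra_cost_factors: list[Parameter] = Field(default_factory=list)

    pack_rounding: Literal["none", "ceil_per_patient"] = "none"

    _check_pop = field_validator("extra_population_factors")(
        _factor_list_validator("population", fraction=True)
    )
    _check_share = field_validator("extra_share_factors")(
        _factor_list_validator("market_share", fraction=True)
    )
    _check_dose = field_validator("extra_dosage_factors")(
        _factor_list_validator("dosage", fraction=False)
    )
    _check_cost = field_validator("extra_cost_factors")(
        _factor_list_validator("acquisition_cost", fraction=False)
    )

    @field_validator("market_share")
    @classmethod
    def _share_in_unit_interval(cls, v):
        if any(not (0.0 <= s <= 1.0) for s in v):
            raise ValueError("market_share entries must lie in [0, 1]")
        return v

    @field_validator("schema_version")
    @classmethod
    def _known_schema(cls, v):
        if v != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {v!r}")
        return v

    @model_validator(mode="after")
    def _consistent(self):
        if len(self.market_share) != self.horizon_years:
            raise ValueError(
                f"market_share must have horizon_years={self.horizon_years} entries, "
                f"got {len(self.market_share)}"
            )
        f = self.features
        if not f.incidence and self.incident_inflow != 0:
            raise ValueError("incidence feature off requires incident_inflow = 0")
        if not f.prevalence and self.prevalent_pool != 0:
            raise ValueError("prevalence feature off requires prevalent_pool = 0")
        if not f.population_growth and self.growth_rate != 0:
            raise ValueError("population_growth feature off requires growth_rate = 0")
        if not f.adherence and self.adherence != 1:
            raise ValueError("adherence feature off requires adherence = 1")
        if not f.discontinuation and self.discontinuation_rate != 0:
            raise ValueError("discontinuation feature off requires discontinuation_rate = 0")
        if not f.duration_of_treatment and self.max_duration_years is not None:
            raise ValueError(
                "duration_of_treatment feature off requires unbounded max_duration_years"
            )
        if f.duration_of_treatment and self.max_duration_years is None:
            raise ValueError("duration_of_treatment feature on requires max_duration_years")
        return self

    # ------------------------------------------------------------------
    # parameter census view
    # ------------------------------------------------------------------
    def parameters(self) -> list[Parameter]:
        """Flatten the spec into categorised :class:`Parameter` records.

        This is the view the parameter census counts. The market-share
        vector contributes one record per horizon year (the conventional
        "one percentage per year" layout); a pack size of exactly 1 means
        the price is already per unit and is not counted as an applicant
        assumption.
        """
        f = self.features
        out: list[Parameter] = []
        if f.prevalence:
            out.append(Parameter(name="prevalent_pool", category="population",
                                 value=self.prevalent_pool, unit="persons"))
        if f.incidence:
            out.append(Parameter(name="incident_inflow", category="population",
                                 value=self.incident_inflow, unit="persons/year"))
        if f.population_growth:
            out.append(Parameter(name="growth_rate", category="population",
                                 value=max(self.growth_rate, 0.0), unit="/year"))
        out.extend(self.extra_population_factors)
        for y, s in enumerate(self.market_share, start=1):
            out.append(Parameter(name=f"market_share_y{y}", category="market_share",
                                 value=s, unit="fraction"))
        out.extend(self.extra_share_factors)
        out.append(Parameter(name="units_per_day", category="dosage",
                             value=self.units_per_day, unit="units/day"))
        if self.pack_size != 1.0:
            out.append(Parameter(name="pack_size", category="dosage",
                                 value=self.pack_size, unit="units/pack"))
        if f.adherence:
            out.append(Parameter(name="adherence", category="dosage",
                                 value=self.adherence, unit="fraction"))
        out.extend(self.extra_dosage_factors)
        out.append(Parameter(name="list_price", category="acquisition_cost",
                             value=self.list_price, unit="currency/pack", psa_vary=False))
        out.extend(self.extra_cost_factors)
        return out

    # ------------------------------------------------------------------
    # serialisation
    # ------------------------------------------------------------------
    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = self.model_dump_json(indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "ModelSpec":
        """Load a spec from a JSON file path or a JSON string.

        Unknown keys are rejected (``extra='forbid'``) so schema drift
        fails loudly rather than being silently ignored.
        """
        p = Path(source) if not str(source).lstrip().startswith("{") else None
        text = p.read_text() if p is not None else str(source)
        return cls.model_validate(json.loads(text))


class GrossImpactResult(BaseModel):
    """Deterministic per-year output of the gross budget-impact engine."""

    model_config = ConfigDict(extra="forbid")

    drug_id: str
    per_year_cost: list[float]
    per_year_treated: list[float]
    per_year_packs: list[float]


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------

def _check_year(spec: ModelSpec, year: int) -> None:
    if not 1 <= year <= spec.horizon_years:
        raise ValueError(
            f"year must be in 1..{spec.horizon_years}, got {year}"
        )


def eligible_population(spec: ModelSpec, year: int) -> float:
    """Eligible patient population in a given model year (1-based).

    The source population (prevalent pool and/or annual incident inflow,
    per the feature flags) is compounded by the population growth rate and
    scaled by every extra multiplicative population factor (diagnosis
    rates, eligibility fractions, ...).
    """
    _check_year(spec, year)
    f = spec.features
    base = spec.prevalent_pool * f.prevalence + spec.incident_inflow * f.incidence
    growth = (1.0 + spec.growth_rate) ** (year - 1)
    factor = math.prod(p.value for p in spec.extra_population_factors)
    out = base * growth * factor
    if out < 0:
        raise ValueError("eligible population became negative")
    return out


def _effective_share(spec: ModelSpec, year: int) -> float:
    s = spec.market_share[year - 1] * math.prod(
        p.value for p in spec.extra_share_factors
    )
    return min(max(s, 0.0), 1.0)


def _cohort_mode(spec: ModelSpec) -> bool:
    f = spec.features
    return f.discontinuation or f.duration_of_treatment


def treated_person_years(spec: ModelSpec, year: int) -> float:
    """Person-years on treatment in a given model year.

    Market share is point-in-year penetration: with neither
    discontinuation nor a duration cap modelled, the treated population in
    year y is simply eligible(y) x share(y). When either cohort feature is
    on, each year's eligible(y) x share(y) enters treatment as a new start
    cohort, and the cohort that started in year s contributes
    (1 - discontinuation_rate)^(y - s) person-years in year y for as long
    as y - s is below the duration cap.
    """
    _check_year(spec, year)
    if not _cohort_mode(spec):
        return eligible_population(spec, year) * _effective_share(spec, year)
    d = spec.discontinuation_rate
    cap = spec.max_duration_years or math.inf
    total = 0.0
    for s in range(1, year + 1):
        age = year - s
        if age >= cap:
            continue
        starters = eligible_population(spec, s) * _effective_share(spec, s)
        total += starters * (1.0 - d) ** age
    return total


def packs_per_patient_year(spec: ModelSpec, days_per_year: float = DAYS_PER_YEAR) -> float:
    """Packs (or vials) required by one patient in a year of treatment.

    units_per_day x days_per_year / pack_size, scaled by adherence and any
    extra dosage factors. Fractional packs are retained by default: at the
    population level the expectation is the relevant quantity; set
    ``pack_rounding='ceil_per_patient'`` on the spec to round each
    patient's annual requirement up to whole packs instead.
    """
    packs = spec.units_per_day * days_per_year / spec.pack_size * spec.adherence
    packs *= math.prod(p.value for p in spec.extra_dosage_factors)
    if spec.pack_rounding == "ceil_per_patient":
        packs = float(math.ceil(packs))
    return packs


def effective_unit_price(spec: ModelSpec) -> float:
    """List price per pack, scaled by any extra acquisition-cost factors."""
    return spec.list_price * math.prod(p.value for p in spec.extra_cost_factors)


def gross_budget_impact(spec: ModelSpec) -> GrossImpactResult:
    """Evaluate the full gross drug budget impact over the model horizon.

    per_year_cost[y] = treated_person_years(y) x packs_per_patient_year x
    unit price. The map from any single parameter to every year's cost is
    monotone (nondecreasing for population, share, dosage, adherence and
    price; nonincreasing for the discontinuation rate), which the PSA
    corner-enumeration oracle relies on.
    """
    years = range(1, spec.horizon_years + 1)
    treated = [treated_person_years(spec, y) for y in years]
    ppy = packs_per_patient_year(spec)
    price = effective_unit_price(spec)
    packs = [t * ppy for t in treated]
    cost = [p * price for p in packs]
    return GrossImpactResult(
        drug_id=spec.drug_id,
        per_year_cost=cost,
        per_year_treated=treated,
        per_year_packs=packs,
    )


def gross_impact_frame(result: GrossImpactResult):
    """Per-year results as a tidy DataFrame (year, treated, packs, cost)."""
    import pandas as pd

    n = len(result.per_year_cost)
    return pd.DataFrame(
        {
            "year": np.arange(1, n + 1),
            "treated": result.per_year_treated,
            "packs": result.per_year_packs,
            "cost": result.per_year_cost,
        }
    )
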