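"""Gross budget-impact engine: worked examples and structural properties."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pydantic import ValidationError

from biaval import (
    FeatureFlags,
    ModelSpec,
    Parameter,
    eligible_population,
    gross_budget_impact,
    packs_per_patient_year,
    treated_person_years,
)
from conftest import TWELVE_PACKS, make_spec


def pop_factor(value, name="f"):
    return Parameter(name=name, category="population", value=value)


class TestEligiblePopulation:
    def test_identity_case(self, toy_spec):
        assert eligible_population(toy_spec, 1) == 1000

    def test_single_compounding_step(self):
        spec = make_spec(
            features=FeatureFlags(prevalence=True, population_growth=True),
            growth_rate=0.10,
        )
        assert eligible_population(spec, 2) == pytest.approx(1100)

    def test_combined_sources_growth_and_factors(self):
        # hand-computed: (800 + 100) * 1.05^2 * (0.5 * 0.8) = 396.90
        spec = make_spec(
            features=FeatureFlags(prevalence=True, incidence=True, population_growth=True),
            prevalent_pool=800.0,
            incident_inflow=100.0,
            growth_rate=0.05,
            extra_population_factors=[pop_factor(0.5, "a"), pop_factor(0.8, "b")],
        )
        assert eligible_population(spec, 3) == pytest.approx(396.90)

    @pytest.mark.parametrize("year", [0, 6, -1])
    def test_year_out_of_range(self, toy_spec, year):
        with pytest.raises(ValueError, match="year"):
            eligible_population(toy_spec, year)


class TestTreatedPersonYears:
    def test_features_off_is_direct_product(self, toy_spec):
        assert treated_person_years(toy_spec, 1) == pytest.approx(100)

    def test_one_survival_step(self):
        spec = make_spec(
            features=FeatureFlags(prevalence=True, discontinuation=True),
            discontinuation_rate=0.5,
            market_share=[0.1, 0, 0, 0, 0],
        )
        assert treated_person_years(spec, 2) == pytest.approx(50)

    def test_duration_cap_expires_cohort(self):
        # cohorts of 100 (year 1) and 200 (year 2), 20% discontinuation,
        # 2-year cap: in year 3 only the year-2 cohort survives, 200*0.8
        spec = make_spec(
            features=FeatureFlags(
                prevalence=True, discontinuation=True, duration_of_treatment=True
            ),
            discontinuation_rate=0.2,
            max_duration_years=2,
            market_share=[0.1, 0.2, 0, 0, 0],
        )
        assert treated_person_years(spec, 3) == pytest.approx(160)
        assert treated_person_years(spec, 2) == pytest.approx(200 + 80)

    def test_share_validation(self):
        with pytest.raises(ValidationError):
            make_spec(market_share=[1.5] * 5)


class TestPacksPerPatientYear:
    def test_identity(self):
        spec = make_spec(units_per_day=1.0, pack_size=365.25)
        assert packs_per_patient_year(spec) == pytest.approx(1.0)

    def test_arithmetic(self):
        spec = make_spec(units_per_day=2.0, pack_size=28.0)
        assert packs_per_patient_year(spec) == pytest.approx(2 * 365.25 / 28)

    def test_adherence_scales_linearly(self):
        spec = make_spec(
            features=FeatureFlags(prevalence=True, adherence=True),
            units_per_day=2.0,
            pack_size=28.0,
            adherence=0.8,
        )
        assert packs_per_patient_year(spec) == pytest.approx(0.8 * 2 * 365.25 / 28)

    def test_ceil_rounding_option(self):
        spec = make_spec(units_per_day=2.0, pack_size=28.0, pack_rounding="ceil_per_patient")
        assert packs_per_patient_year(spec) == 27.0

    def test_nonpositive_dosage_rejected(self):
        with pytest.raises(ValidationError):
            make_spec(units_per_day=0.0)
        with pytest.raises(ValidationError):
            make_spec(pack_size=-1.0)


class TestGrossBudgetImpact:
    def test_toy_product(self, toy_spec):
        res = gross_budget_impact(toy_spec)
        assert res.per_year_cost[0] == pytest.approx(120_000)
        assert res.per_year_packs[0] == pytest.approx(1200)

    def test_zero_share_annihilates(self):
        res = gross_budget_impact(make_spec(market_share=[0.0] * 5))
        assert res.per_year_cost == [0.0] * 5

    def test_linearity_in_price(self, toy_spec):
        base = gross_budget_impact(toy_spec).per_year_cost
        doubled = gross_budget_impact(make_spec(list_price=200.0)).per_year_cost
        assert np.allclose(doubled, 2 * np.asarray(base))

    def test_cost_equals_packs_times_price(self, toy_spec):
        res = gross_budget_impact(toy_spec)
        assert np.allclose(
            res.per_year_cost, np.asarray(res.per_year_packs) * toy_spec.list_price
        )


# ----------------------------------------------------------------------
# invariants
# ----------------------------------------------------------------------

share_vec = st.lists(st.floats(0, 1), min_size=5, max_size=5)


@given(pool=st.floats(1, 1e6), k=st.floats(0.1, 10), shares=share_vec)
@settings(max_examples=50, deadline=None)
def test_homogeneity_in_pool_and_price(pool, k, shares):
    base = np.asarray(
        gross_budget_impact(make_spec(prevalent_pool=pool, market_share=shares)).per_year_cost
    )
    scaled_pool = np.asarray(
        gross_budget_impact(
            make_spec(prevalent_pool=pool * k, market_share=shares)
        ).per_year_cost
    )
    scaled_price = np.asarray(
        gross_budget_impact(
            make_spec(prevalent_pool=pool, market_share=shares, list_price=100.0 * k)
        ).per_year_cost
    )
    assert np.allclose(scaled_pool, k * base, rtol=1e-12)
    assert np.allclose(scaled_price, k * base, rtol=1e-12)


@given(shares=share_vec, pool=st.floats(1, 1e5))
@settings(max_examples=50, deadline=None)
def test_feature_off_closed_form(shares, pool):
    """With only prevalence on, cost reduces to pool*share*packs*price."""
    spec = make_spec(prevalent_pool=pool, market_share=shares)
    res = gross_budget_impact(spec)
    expected = pool * np.asarray(shares) * 12.0 * 100.0
    assert np.allclose(res.per_year_cost, expected, rtol=1e-9)


@pytest.mark.parametrize(
    "field,low,high",
    [
        ("prevalent_pool", 1000.0, 1500.0),
        ("units_per_day", 1.0, 2.0),
        ("list_price", 100.0, 130.0),
    ],
)
def test_monotone_nondecreasing_parameters(field, low, high):
    spec_lo = make_spec(**{field: low})
    spec_hi = make_spec(**{field: high})
    lo = np.asarray(gross_budget_impact(spec_lo).per_year_cost)
    hi = np.asarray(gross_budget_impact(spec_hi).per_year_cost)
    assert (hi >= lo).all()


def test_discontinuation_monotone_nonincreasing():
    def cost(d):
        spec = make_spec(
            features=FeatureFlags(prevalence=True, discontinuation=True),
            discontinuation_rate=d,
            market_share=[0.1, 0.2, 0.3, 0.3, 0.3],
        )
        return np.asarray(gross_budget_impact(spec).per_year_cost)

    assert (cost(0.4) <= cost(0.1)).all()


@given(
    shares=st.lists(st.floats(0, 0.5), min_size=5, max_size=5),
    d=st.floats(0, 0.9),
    cap=st.integers(1, 5),
)
@settings(max_examples=50, deadline=None)
def test_cohort_conservation(shares, d, cap):
    """Each cohort's person-years never exceed starters x capped duration,
    and yearly starters equal eligible x share exactly."""
    spec = make_spec(
        features=FeatureFlags(
            prevalence=True, discontinuation=True, duration_of_treatment=True
        ),
        discontinuation_rate=d,
        max_duration_years=cap,
        market_share=shares,
    )
    total_py = sum(treated_person_years(spec, y) for y in range(1, 6))
    starters = [eligible_population(spec, y) * shares[y - 1] for y in range(1, 6)]
    bound = sum(s * min(cap, 5 - y) for y, s in enumerate(starters, start=0))
    assert total_py <= bound + 1e-6 * max(bound, 1.0)


# ----------------------------------------------------------------------
# validation and serialisation
# ----------------------------------------------------------------------

class TestSpecValidation:
    def test_needs_source_population(self):
        with pytest.raises(ValidationError, match="source population"):
            FeatureFlags(prevalence=False, incidence=False)

    def test_disabled_features_pin_neutral_values(self):
        with pytest.raises(ValidationError, match="growth_rate"):
            make_spec(growth_rate=0.1)
        with pytest.raises(ValidationError, match="discontinuation"):
            make_spec(discontinuation_rate=0.2)
        with pytest.raises(ValidationError, match="incident_inflow"):
            make_spec(incident_inflow=5.0)

    def test_share_length_must_match_horizon(self):
        with pytest.raises(ValidationError, match="horizon"):
            make_spec(market_share=[0.1] * 4)

    def test_json_round_trip(self, toy_spec, tmp_path):
        path = tmp_path / "spec.json"
        toy_spec.to_json(path)
        assert ModelSpec.from_json(path) == toy_spec

    def test_unknown_keys_rejected(self, toy_spec, tmp_path):
        payload = json.loads(toy_spec.to_json())
        payload["surprise"] = 1
        with pytest.raises(ValidationError):
            ModelSpec.model_validate(payload)

    def test_unknown_schema_version_rejected(self, toy_spec):
        payload = json.loads(toy_spec.to_json())
        payload["schema_version"] = "99"
        with pytest.raises(ValidationError, match="schema_version"):
            ModelSpec.model_validate(payload)

    def test_parameter_records_cover_fields(self, toy_spec):
        params = toy_spec.parameters()
        cats = {p.category for p in params}
        assert cats == {"population", "market_share", "dosage", "acquisition_cost"}
        price = [p for p in params if p.category == "acquisition_cost" and not p.psa_vary]
        assert len(price) == 1 and price[0].name == "list_price"
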