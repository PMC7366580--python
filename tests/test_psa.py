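"""Monte-Carlo PSA: sampling support, determinism, oracles, coverage."""

import itertools

import numpy as np
import pytest

from biaval import (
    CoverageStatus,
    PsaConfig,
    RealisedSeries,
    YearStatus,
    classify_coverage,
    gross_budget_impact,
    run_psa,
    sample_spec,
)
from conftest import make_spec


def corner_costs(spec, r, fields):
    """Independent oracle: evaluate all 2^k specs with each field at
    value*(1-r) or value*(1+r) and return the min/max year-1 cost.
    Valid because the engine is monotone in every single parameter."""
    costs = []
    for signs in itertools.product((-1, 1), repeat=len(fields)):
        update = {}
        for s, f in zip(signs, fields):
            v = getattr(spec, f)
            scaled = [x * (1 + s * r) for x in v] if isinstance(v, list) else v * (1 + s * r)
            update[f] = scaled
        costs.append(gross_budget_impact(spec.model_copy(update=update)).per_year_cost[0])
    return min(costs), max(costs)


class TestSampleSpec:
    def test_zero_range_is_identity(self, toy_spec):
        cfg = PsaConfig(range_fraction=0.0, seed=1)
        assert sample_spec(toy_spec, cfg, 0) == toy_spec

    @pytest.mark.parametrize("dist", ["uniform", "triangular", "normal_truncated"])
    def test_support_bounds(self, dist):
        spec = make_spec(prevalent_pool=10.0)
        cfg = PsaConfig(range_fraction=0.2, distribution=dist, seed=7)
        pools = [sample_spec(spec, cfg, i).prevalent_pool for i in range(300)]
        assert all(8.0 <= p <= 12.0 for p in pools)
        assert min(pools) < 9.0 < 11.0 < max(pools)  # support actually explored

    def test_fractions_clamped(self):
        spec = make_spec(market_share=[0.95] * 5)
        cfg = PsaConfig(range_fraction=0.2, seed=3)
        for i in range(200):
            shares = sample_spec(spec, cfg, i).market_share
            assert all(s <= 1.0 for s in shares)

    def test_list_price_fixed_by_default(self, toy_spec):
        cfg = PsaConfig(range_fraction=0.2, seed=5)
        assert all(
            sample_spec(toy_spec, cfg, i).list_price == toy_spec.list_price
            for i in range(50)
        )

    def test_list_price_varies_when_requested(self, toy_spec):
        cfg = PsaConfig(range_fraction=0.2, seed=5, vary_list_price=True)
        prices = {sample_spec(toy_spec, cfg, i).list_price for i in range(20)}
        assert len(prices) > 1
        assert all(80.0 <= p <= 120.0 for p in prices)


class TestRunPsa:
    def test_zero_range_collapses_to_point(self, toy_spec):
        res = run_psa(toy_spec, PsaConfig(range_fraction=0.0, n_simulations=20, seed=2))
        point = gross_budget_impact(toy_spec).per_year_cost
        assert res.per_year_min == pytest.approx(point)
        assert res.per_year_max == pytest.approx(point)

    def test_seed_reproducibility(self, toy_spec):
        cfg = PsaConfig(n_simulations=100, seed=11)
        a, b = run_psa(toy_spec, cfg), run_psa(toy_spec, cfg)
        assert np.array_equal(a.per_year_draws, b.per_year_draws)
        assert a.per_year_min == b.per_year_min

    def test_substreams_stable_when_n_grows(self, toy_spec):
        small = run_psa(toy_spec, PsaConfig(n_simulations=10, seed=4))
        large = run_psa(toy_spec, PsaConfig(n_simulations=40, seed=4))
        assert np.array_equal(large.per_year_draws[:10], small.per_year_draws)

    def test_corner_oracle_containment(self):
        # purely multiplicative year-1 model: pool, dosage, pack size and
        # share vary; corners of the +/-20% box bound every draw
        spec = make_spec(horizon_years=1, market_share=[0.1])
        cfg = PsaConfig(n_simulations=1000, range_fraction=0.2, seed=9)
        res = run_psa(spec, cfg)
        lo, hi = corner_costs(
            spec, 0.2, ["prevalent_pool", "units_per_day", "pack_size", "market_share"]
        )
        assert lo <= res.per_year_min[0] <= res.per_year_max[0] <= hi

    def test_point_estimate_inside_bounds(self, toy_spec):
        res = run_psa(toy_spec, PsaConfig(n_simulations=1000, seed=13))
        point = gross_budget_impact(toy_spec).per_year_cost
        for y in range(5):
            assert res.per_year_min[y] <= point[y] <= res.per_year_max[y]

    def test_bound_nesting_in_range_fraction(self, toy_spec):
        bounds = {}
        for r in (0.05, 0.10, 0.20):
            res = run_psa(toy_spec, PsaConfig(n_simulations=1000, range_fraction=r, seed=21))
            bounds[r] = (np.asarray(res.per_year_min), np.asarray(res.per_year_max))
        for small, big in ((0.05, 0.10), (0.10, 0.20)):
            assert (bounds[big][0] <= bounds[small][0]).all()
            assert (bounds[big][1] >= bounds[small][1]).all()

    def test_mean_between_min_and_max(self, toy_spec):
        res = run_psa(toy_spec, PsaConfig(n_simulations=200, seed=17))
        for lo, m, hi in zip(res.per_year_min, res.per_year_mean, res.per_year_max):
            assert lo <= m <= hi

    def test_percentile_bounds_narrower_than_minmax(self, toy_spec):
        minmax = run_psa(toy_spec, PsaConfig(n_simulations=500, seed=8))
        pct = run_psa(
            toy_spec, PsaConfig(n_simulations=500, seed=8, bound_type="percentile")
        )
        assert all(p >= m for p, m in zip(pct.per_year_min, minmax.per_year_min))
        assert all(p <= m for p, m in zip(pct.per_year_max, minmax.per_year_max))


class TestClassifyCoverage:
    def _psa(self, spec, seed=3):
        return run_psa(spec, PsaConfig(n_simulations=500, seed=seed))

    def test_mean_is_inside(self, toy_spec):
        psa = self._psa(toy_spec)
        realised = RealisedSeries(
            drug_id="X",
            reimbursement_start=None,
            per_year_realised=list(psa.per_year_mean),
            full_year_mask=[True] * 5,
        )
        assert classify_coverage(psa, realised).per_year == [YearStatus.INSIDE] * 5

    def test_zero_realised_is_outside(self, toy_spec):
        psa = self._psa(toy_spec)
        realised = RealisedSeries(
            drug_id="X",
            reimbursement_start=None,
            per_year_realised=[0.0] * 5,
            full_year_mask=[True] * 5,
        )
        assert classify_coverage(psa, realised).per_year == [YearStatus.OUTSIDE] * 5

    def test_short_series_gives_not_available(self, toy_spec):
        psa = self._psa(toy_spec)
        realised = RealisedSeries(
            drug_id="X",
            reimbursement_start=None,
            per_year_realised=[psa.per_year_mean[0]],
            full_year_mask=[True],
        )
        status = classify_coverage(psa, realised)
        assert status.per_year[0] == YearStatus.INSIDE
        assert status.per_year[1:] == [YearStatus.NOT_AVAILABLE] * 4

    def test_bounds_are_inclusive(self, toy_spec):
        psa = self._psa(toy_spec)
        realised = RealisedSeries(
            drug_id="X",
            reimbursement_start=None,
            per_year_realised=list(psa.per_year_min),
            full_year_mask=[True] * 5,
        )
        assert classify_coverage(psa, realised).per_year == [YearStatus.INSIDE] * 5

    def test_drug_mismatch_raises(self, toy_spec):
        psa = self._psa(toy_spec)
        realised = RealisedSeries(
            drug_id="Y", reimbursement_start=None,
            per_year_realised=[1.0], full_year_mask=[True],
        )
        with pytest.raises(ValueError, match="mismatch"):
            classify_coverage(psa, realised)


def test_all_available_inside_requires_data():
    empty = CoverageStatus(drug_id="Z", per_year=[YearStatus.NOT_AVAILABLE] * 5)
    assert not empty.all_available_inside()
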