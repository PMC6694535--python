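import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvdsim.cvd_engine import (
    GROUP_FACTORS,
    GROUPS,
    CvdState,
    RiskEngineParams,
    adjusted_probability,
    age_adjusted_incidence,
    compute_events,
    cvd_probability,
    group_risk_multiplier,
    partition_risk_groups,
    probability_grid,
    update_post_cvd,
)
from cvdsim.grids import AGES, GRID_SHAPE, CohortGrid


def engine_params(**kw):
    defaults = dict(
        beta0={g: 0.0 for g in GROUPS},
        beta_age=0.0,
        beta_diabetes=0.0,
        beta_hypertension=0.0,
        beta_smoking=0.0,
    )
    defaults.update(kw)
    return RiskEngineParams(**defaults)


@pytest.fixture
def table_params(config):
    return config.risk_engine_params()


class TestPartition:
    def test_independence_products(self):
        shares = partition_risk_groups(0.2, 0.5, 0.1)
        assert np.allclose(shares["DHS"], 0.2 * 0.5 * 0.1)
        assert np.allclose(shares["none"], 0.8 * 0.5 * 0.9)
        assert np.allclose(shares["DH"], 0.2 * 0.5 * 0.9)
        assert np.allclose(shares.share.sum(axis=0), 1.0)

    def test_zero_prevalence_empties_factor_groups(self):
        shares = partition_risk_groups(0.0, 0.3, 0.2)
        for g in ("D", "DH", "DS", "DHS"):
            assert np.allclose(shares[g], 0.0)

    def test_degenerate_all_ones(self):
        shares = partition_risk_groups(1.0, 1.0, 1.0)
        assert np.allclose(shares["DHS"], 1.0)
        for g in GROUPS[:-1]:
            assert np.allclose(shares[g], 0.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            partition_risk_groups(1.2, 0.1, 0.1)

    def test_even_split_matches_marginals(self):
        shares = partition_risk_groups(0.15, 0.25, 0.1, mode="even_split")
        share = shares.share
        for fi, prev in enumerate((0.15, 0.25, 0.1)):
            marg = sum(share[gi] for gi, g in enumerate(GROUPS) if GROUP_FACTORS[g][fi])
            assert np.allclose(marg, prev, atol=1e-8)
        assert np.allclose(share.sum(axis=0), 1.0)

    @given(
        pd_=st.floats(0.0, 1.0),
        ph=st.floats(0.0, 1.0),
        ps=st.floats(0.0, 1.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_shares_sum_to_one(self, pd_, ph, ps):
        shares = partition_risk_groups(pd_, ph, ps)
        assert np.allclose(shares.share.sum(axis=0), 1.0)
        assert shares.share.min() >= 0


class TestCvdProbability:
    def test_logistic_at_zero(self):
        p = engine_params()
        for g in GROUPS:
            assert cvd_probability(g, 50, "male", p) == pytest.approx(0.5)

    def test_female_none_at_80(self, table_params):
        # direct evaluation with the packaged constants
        p = cvd_probability("none", 80, "female", table_params)
        assert p == pytest.approx(1.0 / (1.0 + np.exp(6.376)), rel=1e-6)
        assert p == pytest.approx(0.001697, rel=2e-3)

    def test_male_diabetes_only_at_60(self, table_params):
        p = cvd_probability("D", 60, "male", table_params)
        assert p == pytest.approx(1.0 / (1.0 + np.exp(2.25603)), rel=1e-9)
        assert p == pytest.approx(0.0948, rel=5e-3)

    def test_monotone_in_age(self, table_params):
        probs = cvd_probability("DH", AGES, "female", table_params)
        assert np.all(np.diff(probs) > 0)
        assert np.all((probs > 0) & (probs < 1))

    def test_age_bounds(self, table_params):
        with pytest.raises(ValueError):
            cvd_probability("none", 17, "male", table_params)
        with pytest.raises(ValueError):
            cvd_probability("none", 101, "male", table_params)

    def test_unknown_group(self, table_params):
        with pytest.raises(ValueError):
            cvd_probability("XYZ", 50, "male", table_params)

    @given(b2=st.floats(-2.0, 2.0))
    @settings(max_examples=20, deadline=None)
    def test_monotone_in_diabetes_beta(self, b2):
        lo = engine_params(beta_diabetes=b2)
        hi = engine_params(beta_diabetes=b2 + 0.5)
        assert cvd_probability("D", 60, "female", hi) > cvd_probability("D", 60, "female", lo)


class TestAdjustedProbability:
    def test_zero_coverage_limit(self):
        assert adjusted_probability(0.1, 0.0, 0.8) == pytest.approx(0.1)

    def test_full_coverage_limit(self):
        assert adjusted_probability(0.1, 1.0, 0.8) == pytest.approx(0.08)

    def test_half_coverage(self):
        assert adjusted_probability(0.1, 0.5, 0.5) == pytest.approx(0.075)

    def test_literal_mode(self):
        # treated fraction's risk multiplied by (1 - rr) instead of rr
        assert adjusted_probability(0.1, 1.0, 0.8, eq10_literal=True) == pytest.approx(0.02)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            adjusted_probability(1.2, 0.5, 0.8)
        with pytest.raises(ValueError):
            adjusted_probability(0.1, -0.1, 0.8)
        with pytest.raises(ValueError):
            adjusted_probability(0.1, 0.5, 0.0)

    @given(p=st.floats(0.0, 1.0), cov=st.floats(0.0, 1.0),
           rr=st.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_never_exceeds_untreated(self, p, cov, rr):
        ap = adjusted_probability(p, cov, rr)
        assert ap <= p + 1e-15
        if p > 1e-12 and cov > 1e-12 and rr < 1 - 1e-12:
            assert ap < p


class TestComputeEvents:
    def test_product(self):
        pop = np.full((1,) + GRID_SHAPE, 0.0)
        pop[0, 0, 0] = 10_000.0
        p = np.full((1,) + GRID_SHAPE, 0.01)
        assert compute_events(pop, p).sum() == pytest.approx(100.0)

    def test_zero_population(self):
        pop = np.zeros((8,) + GRID_SHAPE)
        p = np.full((8,) + GRID_SHAPE, 0.5)
        assert compute_events(pop, p).sum() == 0.0

    def test_two_cells(self):
        pop = np.zeros((1,) + GRID_SHAPE)
        p = np.zeros((1,) + GRID_SHAPE)
        pop[0, 0, 0], p[0, 0, 0] = 1000.0, 0.02
        pop[0, 1, 0], p[0, 1, 0] = 500.0, 0.04
        assert compute_events(pop, p).sum() == pytest.approx(40.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            compute_events(np.zeros((2, 2)), np.zeros((3, 2)))


class TestBruteForceOracle:
    def test_vectorized_equals_per_person_sum(self, table_params, config):
        """3-cohort toy: engine totals equal scalar group-by-group summation."""
        cells = [(40, "female", 10_000.0), (60, "male", 5_000.0), (80, "female", 2_000.0)]
        prev = {"d": 0.12, "h": 0.25, "s": 0.14}
        cov = {"diabetes": 0.4, "hypertension": 0.3, "smoking": 0.2}

        pop = np.zeros(GRID_SHAPE)
        from cvdsim.grids import age_index, sex_index
        for age, sex, n in cells:
            pop[age_index(age), sex_index(sex)] = n

        shares = partition_risk_groups(prev["d"], prev["h"], prev["s"])
        pop_by_group = shares.share * pop[np.newaxis]
        mult = group_risk_multiplier(cov, table_params)
        vec_total = compute_events(pop_by_group, probability_grid(table_params) * mult).sum()

        # independent brute force: python loops, scalar calls only
        brute = 0.0
        for age, sex, n in cells:
            for g in GROUPS:
                d, h, s = GROUP_FACTORS[g]
                share = (
                    (prev["d"] if d else 1 - prev["d"])
                    * (prev["h"] if h else 1 - prev["h"])
                    * (prev["s"] if s else 1 - prev["s"])
                )
                p = cvd_probability(g, age, sex, table_params)
                for factor, flag in zip(("diabetes", "hypertension", "smoking"), (d, h, s)):
                    if flag:
                        p = adjusted_probability(p, cov[factor], table_params.rr_for(factor))
                brute += n * share * p
        assert vec_total == pytest.approx(brute, rel=1e-12)


class TestUpdatePostCvd:
    def test_event_death_split(self, table_params):
        state = CvdState(CohortGrid.zeros())
        events = CohortGrid.single(70, "male", 100.0)
        nxt = update_post_cvd(state, events, table_params, 0.0)
        assert nxt.annual_event_deaths == pytest.approx(20.0)
        assert nxt.post_cvd.total() == pytest.approx(80.0)

    def test_zero_death_rate_all_survive(self):
        p = engine_params(event_death_rate=0.0)
        state = CvdState(CohortGrid.zeros())
        events = CohortGrid.filled(1.0)
        nxt = update_post_cvd(state, events, p, 0.0)
        assert nxt.post_cvd.total() == pytest.approx(events.total())
        assert nxt.annual_event_deaths == 0.0

    def test_chained_mortality_multipliers(self, table_params):
        state = CvdState(CohortGrid.single(80, "female", 1000.0))
        nxt = update_post_cvd(state, 0.0, table_params, 0.01)
        assert nxt.annual_post_cvd_deaths == pytest.approx(1000 * 0.01 * 1.6 * 0.87)
        assert nxt.post_cvd.total() == pytest.approx(1000 - 13.92)

    def test_telescoping_conservation(self, table_params):
        state = CvdState(CohortGrid.filled(10.0))
        start = state.post_cvd.total()
        survivors_sum = deaths_sum = 0.0
        rng = np.random.default_rng(3)
        for _ in range(50):
            events = CohortGrid(rng.uniform(0, 2, GRID_SHAPE))
            state = update_post_cvd(state, events, table_params, 0.02)
            survivors_sum += events.total() * (1 - table_params.event_death_rate)
            deaths_sum += state.annual_post_cvd_deaths
        assert state.post_cvd.total() == pytest.approx(
            start + survivors_sum - deaths_sum, rel=1e-9)


class TestAgeAdjustedIncidence:
    def test_uniform_rate_invariant_to_standard(self):
        pop = CohortGrid.filled(100.0)
        events = CohortGrid.filled(1.0)  # rate 0.01 everywhere
        skew = np.linspace(1, 5, 83)[:, None] * np.ones(GRID_SHAPE)
        assert age_adjusted_incidence(events, pop, CohortGrid(skew)) == pytest.approx(0.01)

    def test_equal_weights_average(self):
        pop = np.zeros(GRID_SHAPE)
        ev = np.zeros(GRID_SHAPE)
        pop[0, 0], ev[0, 0] = 100.0, 1.0  # rate 0.01
        pop[1, 0], ev[1, 0] = 100.0, 3.0  # rate 0.03
        std = np.zeros(GRID_SHAPE)
        std[0, 0] = std[1, 0] = 50.0
        assert age_adjusted_incidence(ev, pop, std) == pytest.approx(0.02)

    def test_weighted_sum(self):
        pop = np.zeros(GRID_SHAPE)
        ev = np.zeros(GRID_SHAPE)
        pop[0, 0], ev[0, 0] = 100.0, 1.0
        pop[1, 0], ev[1, 0] = 100.0, 3.0
        std = np.zeros(GRID_SHAPE)
        std[0, 0], std[1, 0] = 75.0, 25.0
        assert age_adjusted_incidence(ev, pop, std) == pytest.approx(0.015)

    def test_empty_cells_excluded_with_warning(self):
        pop = np.zeros(GRID_SHAPE)
        ev = np.zeros(GRID_SHAPE)
        pop[0, 0], ev[0, 0] = 100.0, 1.0
        std = np.full(GRID_SHAPE, 1.0)
        with pytest.warns(RuntimeWarning, match="excluded"):
            out = age_adjusted_incidence(ev, pop, std)
        assert out == pytest.approx(0.01)

    def test_zero_standard_rejected(self):
        with pytest.raises(ValueError):
            age_adjusted_incidence(CohortGrid.zeros(), CohortGrid.filled(1.0),
                                   CohortGrid.zeros())


class TestGroupMultiplier:
    def test_coverage_monotone_event_response(self, table_params):
        pop_by_group = np.full((8,) + GRID_SHAPE, 10.0)
        p = probability_grid(table_params)
        lo = group_risk_multiplier({"diabetes": 0.2}, table_params)
        hi = group_risk_multiplier({"diabetes": 0.6}, table_params)
        assert compute_events(pop_by_group, p * hi).sum() < compute_events(
            pop_by_group, p * lo).sum()

    def test_multi_factor_product(self, table_params):
        cov = {"diabetes": 1.0, "hypertension": 1.0, "smoking": 0.0}
        mult = group_risk_multiplier(cov, table_params)
        gi = GROUPS.index("DH")
        assert np.allclose(mult[gi], 0.8 * 0.5)
        assert np.allclose(mult[GROUPS.index("none")], 1.0)
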