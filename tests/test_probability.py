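"""Competing-risk probability engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_hazard_grid, riemann_cumulative_incidence
from fracrisk.hazard import HazardGrid, apply_relative_risk
from fracrisk.probability import (
    competing_decomposition,
    cumulative_incidence,
    lifetime_probability,
    probability_curve,
    ten_year_probability,
)


def constant_grid(f, d, start=50.0, years=60, step=0.25, sex="female"):
    n = int(years / step)
    return HazardGrid(sex, start, step, np.full(n, f), np.full(n, d))


class TestClosedForms:
    def test_zero_fracture_hazard_gives_zero(self):
        grid = constant_grid(0.0, 0.05)
        assert cumulative_incidence(grid, 50, 10) == 0.0

    def test_no_competing_risk_closed_form(self):
        grid = constant_grid(0.01, 0.0)
        want = 1 - np.exp(-0.1)
        assert cumulative_incidence(grid, 50, 10) == pytest.approx(want, abs=1e-12)

    def test_competing_risk_closed_form(self):
        # P = f/(f+d) · (1 − e^{−(f+d)T})
        grid = constant_grid(0.01, 0.05)
        want = (0.01 / 0.06) * (1 - np.exp(-0.6))
        assert cumulative_incidence(grid, 50, 10) == pytest.approx(want, abs=1e-12)

    def test_partial_cells(self):
        grid = constant_grid(0.02, 0.03, step=1.0)
        want = (0.02 / 0.05) * (1 - np.exp(-0.05 * 2.5))
        assert cumulative_incidence(grid, 50.25, 2.5) == pytest.approx(want, abs=1e-12)

    def test_domain_errors(self):
        grid = constant_grid(0.01, 0.01)
        with pytest.raises(ValueError):
            cumulative_incidence(grid, 50, -1)
        with pytest.raises(ValueError, match="missing"):
            cumulative_incidence(grid, 50, 80)
        with pytest.raises(ValueError, match="missing"):
            cumulative_incidence(grid, 30, 10)


class TestOracleEquivalence:
    def test_random_grids_match_riemann_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            grid = random_hazard_grid(rng)
            start = 50.0 + rng.uniform(0, 2)
            horizon = rng.uniform(1, 12)
            got = cumulative_incidence(grid, start, horizon)
            want = riemann_cumulative_incidence(grid, start, horizon)
            assert got == pytest.approx(want, abs=1e-6)

    def test_partition_of_unity(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            grid = random_hazard_grid(rng)
            pf, pd_, s = competing_decomposition(grid, 50.0, 14.0)
            assert pf + pd_ + s == pytest.approx(1.0, abs=1e-10)

    def test_grid_step_convergence(self, survey_results, life_tables):
        from fracrisk.probability import FractureRiskModel

        coarse = FractureRiskModel(survey_results, life_tables, grid_step=1 / 12).fit()
        fine = FractureRiskModel(survey_results, life_tables, grid_step=1 / 24).fit()
        for age in (55, 70, 85):
            a = coarse.ten_year_probability("female", age).probability
            b = fine.ten_year_probability("female", age).probability
            assert abs(a - b) < 1e-4


class TestMonotonicity:
    def test_rr_increases_probability(self, risk_results):
        grid = risk_results.grid("female", "hip")
        p1 = ten_year_probability(grid, 70).probability
        p18 = ten_year_probability(grid, 70, rr_frac=1.8).probability
        assert p18 > p1

    def test_higher_mortality_lowers_fracture_probability(self, risk_results):
        grid = risk_results.grid("female", "hip")
        doubled = apply_relative_risk(grid, 1.0, 2.0)
        for age in (50, 65, 80):
            assert (cumulative_incidence(doubled, age, 10)
                    < cumulative_incidence(grid, age, 10))

    def test_lifetime_exceeds_fixed_horizon(self, risk_results):
        grid = risk_results.grid("male", "hip")
        life = lifetime_probability(grid, 50).probability
        ten = ten_year_probability(grid, 50).probability
        assert life >= ten

    def test_zero_mortality_limit(self, risk_results):
        grid = risk_results.grid("female", "hip")
        no_death = HazardGrid(grid.sex, grid.start_age, grid.step,
                              grid.h_frac, np.zeros(grid.n_cells))
        p = cumulative_incidence(no_death, 60, 10)
        w = np.diff(np.clip(grid.edges, 60.0, 70.0))
        want = 1 - np.exp(-np.sum(grid.h_frac * w))
        assert p == pytest.approx(want, abs=1e-12)


class TestCurves:
    def test_singleton_curve_equals_scalar(self, risk_results):
        grid = risk_results.grid("female", "hip")
        curve = probability_curve(grid, [70.0])
        scalar = ten_year_probability(grid, 70.0)
        assert curve[0].probability == pytest.approx(scalar.probability)

    def test_female_mof_curve_unimodal_peak_near_70(self, risk_results):
        """Ten-year MOF probability rises to ~70 then falls: the competing
        effect of steeply rising late-life mortality."""
        ages = np.arange(50, 91, 5)
        df = risk_results.probability_curve("female", ages, outcome="mof")
        p = df["probability"].to_numpy()
        peak = ages[np.argmax(p)]
        assert 65 <= peak <= 75
        d = np.diff(p)
        turn = np.argmax(p)
        assert np.all(d[:turn] > 0) and np.all(d[turn:] < 0)

    def test_rr_curve_dominates_pointwise(self, risk_results):
        ages = np.arange(50, 91, 5)
        base = risk_results.probability_curve("female", ages, outcome="mof")
        prior = risk_results.probability_curve("female", ages, outcome="mof",
                                               rr_frac=1.8)
        assert np.all(prior["probability"].to_numpy()
                      >= base["probability"].to_numpy())

    def test_assessment_range_enforced(self, risk_results):
        grid = risk_results.grid("female", "hip")
        with pytest.raises(ValueError, match="assessment age"):
            ten_year_probability(grid, 95)


class TestLifetime:
    def test_constant_hazard_closed_form(self):
        grid = constant_grid(0.004, 0.0, start=50.0, years=55)
        p = lifetime_probability(grid, 50).probability
        assert p == pytest.approx(1 - np.exp(-0.004 * 55), abs=1e-8)

    def test_low_fracture_high_mortality_halves_risk(self):
        """Same fracture hazard, much higher late-life mortality → roughly
        half the lifetime risk, mirroring cross-country comparisons."""
        base = constant_grid(0.004, 0.02, start=50.0, years=55)
        high_mort = constant_grid(0.004, 0.055, start=50.0, years=55)
        p_low = lifetime_probability(base, 50).probability
        p_high = lifetime_probability(high_mort, 50).probability
        assert p_high < p_low
        assert p_high / p_low == pytest.approx(0.5, abs=0.15)

    def test_probabilities_in_unit_interval(self, risk_results):
        for sex in ("female", "male"):
            for outcome in ("hip", "mof"):
                p = risk_results.lifetime_probability(sex, 50, outcome).probability
                assert 0 <= p <= 1


@settings(max_examples=40, deadline=None)
@given(
    f=st.floats(0, 0.2), d=st.floats(0, 0.5),
    horizon=st.floats(0.5, 30),
)
def test_probability_bounded_and_consistent(f, d, horizon):
    grid = constant_grid(f, d, start=40.0, years=70)
    p = cumulative_incidence(grid, 45.0, horizon)
    assert 0 <= p <= 1
    tot = f + d
    if tot > 0:
        want = f / tot * (1 - np.exp(-tot * horizon))
        assert p == pytest.approx(want, abs=1e-10)
    else:
        assert p == 0.0
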