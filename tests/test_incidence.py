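"""Rates, exact Poisson intervals and the between-sex comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from fracrisk import datasets
from fracrisk.incidence import (
    AgeBand,
    IncidenceModel,
    compute_rate,
    display_rate,
    exact_poisson_ci,
    rate_ratio_test,
)


def poisson_ci_by_root_finding(events, person_years, level=0.95):
    """Oracle: invert the Poisson CDF tails numerically (no chi-square)."""
    alpha = 1 - level
    if events == 0:
        low = 0.0
    else:
        low = optimize.brentq(
            lambda mu: stats.poisson.sf(events - 1, mu) - alpha / 2,
            1e-12, 10 * events + 50,
        )
    high = optimize.brentq(
        lambda mu: stats.poisson.cdf(events, mu) - alpha / 2,
        1e-12, 10 * events + 50,
    )
    return low / person_years * 1e5, high / person_years * 1e5


class TestRateAndRounding:
    def test_survey_band_rate(self):
        # 21 events on 57,212 persons over two years displays as 18
        assert display_rate(compute_rate(21, 57212, 2)) == 18

    def test_zero_events(self):
        assert compute_rate(0, 10000, 2) == 0.0

    def test_crude_female_rate(self):
        assert round(compute_rate(388, 250339, 2), 1) == 77.5

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            compute_rate(1, 0, 2)
        with pytest.raises(ValueError):
            compute_rate(1, 100, 0)
        with pytest.raises(ValueError):
            compute_rate(-1, 100, 2)


class TestExactCI:
    def test_small_count_interval(self):
        low, high = exact_poisson_ci(4, 143466)
        assert (display_rate(low), display_rate(high)) == (0.8, 7.1)

    def test_zero_events_lower_bound_zero(self):
        low, high = exact_poisson_ci(0, 50000)
        assert low == 0.0 and high > 0

    def test_matches_root_finding_oracle(self):
        py = 23934.0
        for k in [0, 1, 4, 21, 48, 117, 200]:
            got = exact_poisson_ci(k, py)
            want = poisson_ci_by_root_finding(k, py)
            assert got == pytest.approx(want, abs=1e-8)

    def test_level_widens_interval(self):
        l95, h95 = exact_poisson_ci(10, 1000)
        l99, h99 = exact_poisson_ci(10, 1000, level=0.99)
        assert l99 < l95 and h99 > h95

    def test_scales_inversely_with_person_years(self):
        l1, h1 = exact_poisson_ci(7, 1000)
        l2, h2 = exact_poisson_ci(7, 2000)
        assert l2 == pytest.approx(l1 / 2) and h2 == pytest.approx(h1 / 2)

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            exact_poisson_ci(1, 100, level=1.2)

    def test_coverage_on_simulated_poisson(self):
        # exact intervals are conservative: coverage >= nominal within MC error
        rng = np.random.default_rng(42)
        true_rate = 50.0  # per 1e5
        py = 80000.0
        mu = true_rate * py / 1e5
        events = rng.poisson(mu, size=10000)
        ks = np.unique(events)
        covered = {}
        for k in ks:
            lo, hi = exact_poisson_ci(int(k), py)
            covered[k] = lo <= true_rate <= hi
        frac = np.mean([covered[k] for k in events])
        assert frac >= 0.95 - 3 * np.sqrt(0.95 * 0.05 / 10000)


class TestRateRatioTest:
    def test_symmetric_null_gives_p_one(self):
        assert rate_ratio_test(10, 1000, 10, 1000) == 1.0

    def test_p_value_capped_and_symmetric(self):
        p_ab = rate_ratio_test(5, 700, 9, 1300)
        p_ba = rate_ratio_test(9, 1300, 5, 700)
        assert 0 < p_ab <= 1
        assert p_ab == pytest.approx(p_ba)

    def test_agrees_with_binomial_tail_oracle(self):
        # direct tail summation of the conditional binomial
        xa, pya, xb, pyb = 32, 81974.0, 19, 89248.0
        n, p0 = xa + xb, pya / (pya + pyb)
        pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
        upper = pmf[xa:].sum()
        lower = pmf[: xa + 1].sum()
        want = min(1.0, 2 * min(upper, lower))
        assert rate_ratio_test(xa, pya, xb, pyb) == pytest.approx(want, rel=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rate_ratio_test(1, 0, 1, 100)
        with pytest.raises(ValueError):
            rate_ratio_test(0, 100, 0, 100)


class TestAgeBand:
    def test_midpoint_of_closed_band(self):
        assert AgeBand(50, 54).midpoint == 52.5

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            AgeBand(60, 55)


class TestIncidenceModel:
    def test_crude_rates_and_ratio(self, survey_results):
        crude = survey_results.crude_rates
        assert round(crude["female"], 1) == 77.5
        assert round(crude["male"], 1) == 56.8
        assert round(survey_results.female_male_ratio, 1) == 1.4

    def test_events_conserved_per_sex(self, survey_results):
        totals = survey_results.table.groupby("sex")["events"].sum()
        assert totals["male"] == 296 and totals["female"] == 388

    def test_symmetric_table_ratio_one(self):
        counts = pd.DataFrame({
            "sex": ["female", "female", "male", "male"],
            "band_start": [50, 55] * 2, "band_end": [54, 59] * 2,
            "events": [10, 20, 10, 20],
        })
        pop = counts.rename(columns={"events": "population"}).assign(
            population=[1000, 2000, 1000, 2000])
        res = IncidenceModel(counts, pop).fit()
        assert res.female_male_ratio == pytest.approx(1.0)

    def test_doubled_female_rates_double_ratio(self):
        counts = pd.DataFrame({
            "sex": ["female", "female", "male", "male"],
            "band_start": [50, 55] * 2, "band_end": [54, 59] * 2,
            "events": [20, 40, 10, 20],
        })
        pop = counts.assign(population=[1000, 2000, 1000, 2000]).drop(columns="events")
        res = IncidenceModel(counts, pop).fit()
        assert res.female_male_ratio == pytest.approx(2.0)

    def test_undefined_ratio_when_no_male_events(self):
        counts = pd.DataFrame({
            "sex": ["female", "male"], "band_start": [50, 50],
            "band_end": [54, 54], "events": [5, 0],
        })
        pop = counts.assign(population=1000).drop(columns="events")
        res = IncidenceModel(counts, pop).fit()
        assert res.female_male_ratio is None
        assert "undefined" in res.summary()

    def test_rejects_nonpositive_population(self):
        counts = pd.DataFrame({"sex": ["male"], "band_start": [50],
                               "band_end": [54], "events": [1]})
        pop = counts.assign(population=0).drop(columns="events")
        with pytest.raises(ValueError):
            IncidenceModel(counts, pop)


@settings(max_examples=60, deadline=None)
@given(k=st.integers(0, 500), py=st.floats(100, 1e7))
def test_ci_brackets_rate(k, py):
    low, high = exact_poisson_ci(k, py)
    rate = k / py * 1e5
    assert low <= rate <= high
    if k == 0:
        assert low == 0.0
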