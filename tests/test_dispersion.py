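import numpy as np
import pandas as pd
import pytest

from lifedisp.dispersion import (
    cv_across_populations,
    e_dagger,
    gini_lifetable,
    keyfitz_entropy,
    quadrant_analysis,
    threshold_age,
)
from lifedisp.lifetable import build_lifetable

AGES_1Y = np.arange(0, 111)


def death_atoms(lt):
    """Ages at death implied by the table's deaths distribution."""
    ages = lt.ages.astype(float)
    at = np.append(ages[:-1] + lt.ax[:-1], ages[-1] + lt.ex[-1])
    return at, lt.dx


def gini_pairwise_oracle(lt):
    """Brute-force Gini: mean absolute pairwise difference of ages at death
    over twice the mean age at death, on the dx atoms."""
    at, w = death_atoms(lt)
    mad = w @ np.abs(at[:, None] - at[None, :]) @ w
    return mad / (2.0 * (w @ at))


def edagger_quadrature_oracle(a, b, max_age=200.0, step=0.01):
    """Fine-grid evaluation of e-dagger = integral d(x) e(x) dx for a
    Gompertz hazard mu = a e^{bx}."""
    x = np.arange(0.0, max_age + step, step)
    l = np.exp(-a / b * (np.exp(b * x) - 1.0))
    e = np.array(
        [np.trapezoid(l[i:], x[i:]) for i in range(len(x))]
    ) / np.where(l > 0, l, 1.0)
    d = a * np.exp(b * x) * l
    return np.trapezoid(d * e, x)


class TestEDagger:
    def test_constant_hazard_equals_life_expectancy(self, constant_hazard_fine):
        assert e_dagger(constant_hazard_fine) == pytest.approx(50.0, abs=0.5)

    def test_all_deaths_in_open_interval_single_atom(self):
        mx = np.zeros(111)
        mx[-1] = 0.05
        lt = build_lifetable(mx, AGES_1Y)
        assert e_dagger(lt) == pytest.approx(1.0 / 0.05, abs=1e-12)

    def test_gompertz_matches_quadrature_oracle(self):
        a, b = 1e-4, 0.1
        mids = np.append(AGES_1Y[:-1] + 0.5, 110.5)
        lt = build_lifetable(a * np.exp(b * mids), AGES_1Y, a0_rule="midpoint")
        assert e_dagger(lt) == pytest.approx(
            edagger_quadrature_oracle(a, b), abs=0.1
        )

    def test_invariant_to_prepending_deathfree_ages(self, cee_lifetable):
        lt = cee_lifetable
        ages = np.concatenate([np.arange(-5, 0), lt.ages])
        mx = np.concatenate([np.zeros(5), lt.mx])
        extended = build_lifetable(mx, ages, a0_rule="midpoint")
        lt_mid = build_lifetable(lt.mx, lt.ages, a0_rule="midpoint")
        assert e_dagger(extended) == pytest.approx(e_dagger(lt_mid), abs=1e-9)


class TestThresholdAge:
    def test_cee_schedule_threshold_in_plausible_band(self, cee_lifetable):
        a_dagger = threshold_age(cee_lifetable)
        assert 55.0 < a_dagger < 75.0

    def test_sensitivity_vanishes_at_threshold(self, cee_lifetable):
        from lifedisp.dispersion import _band_factors, e0_edagger_matrix

        lt = cee_lifetable
        a_dagger = threshold_age(lt)
        factors = _band_factors(lt.ages, a_dagger, 1.0, 0.01)
        _, ed = e0_edagger_matrix(lt.mx * factors, lt.ages)
        assert abs(float(ed[0]) - e_dagger(lt)) < 1e-6

    def test_reductions_below_compress_above_expand(self, cee_lifetable):
        lt = cee_lifetable
        a_dagger = threshold_age(lt)
        base = e_dagger(lt)
        below = lt.mx * np.where(lt.ages < a_dagger, 0.99, 1.0)
        above = lt.mx * np.where(lt.ages > a_dagger, 0.99, 1.0)
        assert e_dagger(build_lifetable(below, lt.ages)) < base
        assert e_dagger(build_lifetable(above, lt.ages)) > base

    def test_schedule_without_threshold_raises(self):
        lt = build_lifetable(np.full(111, 0.02), AGES_1Y)
        # a constant hazard only expands: reductions anywhere raise e-dagger
        with pytest.raises(ValueError, match="no sign change|no threshold"):
            threshold_age(lt)


class TestEntropyGini:
    def test_constant_hazard_entropy_near_one(self, constant_hazard_fine):
        assert keyfitz_entropy(constant_hazard_fine) == pytest.approx(1.0, abs=0.02)

    def test_rectangular_survival_entropy_near_zero(self):
        mx = np.zeros(111)
        mx[-1] = 10.0
        lt = build_lifetable(mx, AGES_1Y)
        assert keyfitz_entropy(lt) < 0.01

    def test_entropy_identity_with_edagger(self, schedule_bank):
        for lt in schedule_bank:
            h = keyfitz_entropy(lt)
            assert abs(h - e_dagger(lt) / lt.e0) < 0.01

    def test_constant_hazard_gini_half(self, constant_hazard_fine):
        assert gini_lifetable(constant_hazard_fine) == pytest.approx(0.5, abs=0.02)

    def test_rectangular_survival_gini_near_zero(self):
        mx = np.zeros(111)
        mx[-1] = 10.0
        lt = build_lifetable(mx, AGES_1Y)
        assert gini_lifetable(lt) < 0.01

    def test_gini_matches_pairwise_oracle(self, schedule_bank):
        for lt in schedule_bank:
            assert abs(gini_lifetable(lt) - gini_pairwise_oracle(lt)) < 0.01

    def test_gini_and_entropy_rank_dispersion_identically(self):
        # three schedules with known dispersion ordering:
        # near-rectangular < Gompertz < constant hazard
        rect = np.where(AGES_1Y < 80, 1e-5, 2.0).astype(float)
        mids = np.append(AGES_1Y[:-1] + 0.5, 110.5)
        gomp = 1e-4 * np.exp(0.1 * mids)
        const = np.full(111, 0.02)
        tables = [build_lifetable(m, AGES_1Y) for m in (rect, gomp, const)]
        ginis = [gini_lifetable(t) for t in tables]
        entropies = [keyfitz_entropy(t) for t in tables]
        assert np.argsort(ginis).tolist() == np.argsort(entropies).tolist() == [0, 1, 2]


class TestCV:
    def test_identical_values_zero(self):
        assert cv_across_populations([7.0, 7.0, 7.0]) == 0.0

    def test_two_values_population_sd_convention(self):
        assert cv_across_populations([10.0, 20.0]) == pytest.approx(1.0 / 3.0)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            cv_across_populations([-1.0, 1.0])

    def test_single_value_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            cv_across_populations([5.0])


class TestQuadrants:
    def test_strictly_decreasing_series_all_down_down(self):
        years = np.arange(2000, 2011)
        e0 = pd.DataFrame({"A": 70 - 0.5 * np.arange(11)}, index=years)
        ed = pd.DataFrame({"A": 15 - 0.1 * np.arange(11)}, index=years)
        (q,) = quadrant_analysis(e0, ed, [(2000, 2011, "all")])
        assert q.proportions["down_down"] == 1.0
        assert q.ci_high["down_down"] == 1.0
        assert q.n_pairs == 10

    def test_independent_signs_give_quarter_shares(self):
        rng = np.random.default_rng(42)
        n_years = 401
        years = np.arange(n_years)
        steps_e0 = rng.choice([-1.0, 1.0], size=n_years - 1)
        steps_ed = rng.choice([-1.0, 1.0], size=n_years - 1)
        e0 = pd.DataFrame({"A": 500 + np.concatenate([[0], np.cumsum(steps_e0)])}, index=years)
        ed = pd.DataFrame({"A": 500 + np.concatenate([[0], np.cumsum(steps_ed)])}, index=years)
        (q,) = quadrant_analysis(e0, ed, [(0, n_years, "all")])
        assert q.n_pairs == 400
        for name, p in q.proportions.items():
            half = 1.96 * np.sqrt(p * (1 - p) / q.n_pairs)
            assert abs(p - 0.25) <= half + 1e-12, name

    def test_relative_scale_divides_by_previous_value(self):
        years = [2000, 2001]
        e0 = pd.DataFrame({"A": [50.0, 55.0]}, index=years)
        ed = pd.DataFrame({"A": [10.0, 9.0]}, index=years)
        (q_abs,) = quadrant_analysis(e0, ed, [(2000, 2001, "p")], scale="absolute")
        (q_rel,) = quadrant_analysis(e0, ed, [(2000, 2001, "p")], scale="relative")
        assert q_abs.counts["up_down"] == q_rel.counts["up_down"] == 1

    def test_short_period_yields_empty_summary(self):
        years = [2000, 2001]
        e0 = pd.DataFrame({"A": [50.0, 55.0]}, index=years)
        ed = pd.DataFrame({"A": [10.0, 9.0]}, index=years)
        (q,) = quadrant_analysis(e0, ed, [(1990, 1991, "empty")])
        assert q.n_pairs == 0 and np.isnan(q.proportions["up_up"])

    def test_zero_differences_excluded_by_default_but_togglable(self):
        years = np.arange(2000, 2004)
        e0 = pd.DataFrame({"A": [50.0, 50.0, 51.0, 52.0]}, index=years)
        ed = pd.DataFrame({"A": [10.0, 9.0, 8.0, 7.0]}, index=years)
        (q,) = quadrant_analysis(e0, ed, [(2000, 2004, "p")])
        assert q.n_pairs == 2 and q.n_zero_excluded == 1
        (q2,) = quadrant_analysis(e0, ed, [(2000, 2004, "p")], drop_zero=False)
        assert q2.n_pairs == 3
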