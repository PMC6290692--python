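import numpy as np
import pandas as pd
import pytest

from lifedisp.decomposition import (
    decompose_by_age,
    decompose_by_age_cause,
    horiuchi_decompose,
    lifetable_functional,
)
from lifedisp.dispersion import threshold_age
from lifedisp.causes import CAUSE_CATEGORIES, CauseProportionTable, split_rates_by_cause
from lifedisp.lifetable import MortalitySurface
from lifedisp.synthetic import (
    CEE_MALE_PARAMS,
    abridged_grid,
    default_cause_profiles,
    flat_schedule,
    make_cause_table,
    make_surface,
)

TOY_AGES = np.array([0, 50, 100])
TOY_START = np.array([0.005, 0.02, 0.4])
TOY_END = np.array([0.0048, 0.021, 0.38])  # year-over-year-sized changes


def two_year_surface(mx1, mx2, ages):
    return MortalitySurface(
        population_id="t",
        sex="male",
        ages=ages,
        years=np.array([2000, 2001]),
        mx=np.column_stack([mx1, mx2]),
        open_age=int(ages[-1]),
    )


class TestHoriuchi:
    def test_zero_path_gives_zero_contributions(self):
        f = lifetable_functional("e0", TOY_AGES)
        res = horiuchi_decompose(f, TOY_START, TOY_START, n_steps=7)
        assert np.all(res.contributions.to_numpy() == 0.0)
        assert res.total == 0.0 and res.residual == 0.0

    @pytest.mark.parametrize("n_steps", [1, 3, 20])
    def test_linear_functional_exact_at_any_step_count(self, n_steps):
        slopes = np.array([2.0, -1.0, 0.5])

        def f(x):
            x = np.atleast_2d(x.T).T
            return slopes @ x

        res = horiuchi_decompose(f, TOY_START, TOY_END, n_steps=n_steps)
        expected = slopes * (TOY_END - TOY_START)
        assert np.allclose(res.contributions.to_numpy(), expected, atol=1e-14)
        assert res.residual < 1e-14

    @pytest.mark.parametrize("functional", ["e0", "e_dagger"])
    def test_toy_table_matches_dense_path_reference(self, functional):
        f = lifetable_functional(functional, TOY_AGES)
        res = horiuchi_decompose(f, TOY_START, TOY_END, n_steps=20)
        ref = horiuchi_decompose(f, TOY_START, TOY_END, n_steps=10_000)
        assert np.allclose(
            res.contributions.to_numpy(), ref.contributions.to_numpy(), atol=1e-6
        )

    def test_label_mismatch_rejected(self):
        f = lifetable_functional("e0", TOY_AGES)
        with pytest.raises(ValueError, match="labels"):
            horiuchi_decompose(f, TOY_START, TOY_END, labels=["a", "b"])

    def test_nonfinite_functional_reported_with_step(self):
        def f(x):
            return np.full(x.shape[1] if x.ndim == 2 else 1, np.nan)

        with pytest.raises(ValueError, match="non-finite"):
            horiuchi_decompose(f, TOY_START, TOY_END, n_steps=5)

    def test_residual_shrinks_quadratically_with_steps(self, cee_surface):
        big = make_surface(
            CEE_MALE_PARAMS, flat_schedule(years=[2000]), years=[2000]
        ).mx[:, 0] * 1.4
        f = lifetable_functional("e_dagger", cee_surface.ages)
        r = {
            n: horiuchi_decompose(f, cee_surface.mx[:, 0], big, n_steps=n).residual
            for n in (5, 20, 80)
        }
        assert r[5] > r[20] > r[80]
        assert r[5] / r[20] > 8.0  # ~16 for quadratic convergence
        assert r[20] / r[80] > 8.0

    def test_symmetry_reversing_endpoints_negates_contributions(self, cee_surface):
        f = lifetable_functional("e_dagger", cee_surface.ages)
        x1 = cee_surface.mx[:, 0]
        x2 = x1 * 1.1
        fwd = horiuchi_decompose(f, x1, x2, n_steps=20)
        bwd = horiuchi_decompose(f, x2, x1, n_steps=20)
        assert np.allclose(
            fwd.contributions.to_numpy(), -bwd.contributions.to_numpy(), atol=1e-10
        )


class TestDecomposeByAge:
    def test_uniform_reduction_splits_sign_at_threshold(self, cee_lifetable, cee_surface):
        a_dagger = threshold_age(cee_lifetable)
        mx1 = cee_surface.mx[:, 0]
        surf = two_year_surface(mx1, mx1 * 0.99, cee_surface.ages)
        res = decompose_by_age(surf, 2000, 2001, functional="e_dagger")
        contrib = res.contributions
        ages = contrib.index.to_numpy()
        young = contrib[(ages >= 1) & (ages < a_dagger - 1)]
        old = contrib[(ages > a_dagger + 1) & (ages <= 100)]
        assert np.all(young.to_numpy() < 0)
        assert np.all(old.to_numpy() > 0)

    def test_change_confined_to_one_age_is_local(self, cee_surface):
        mx1 = cee_surface.mx[:, 0]
        mx2 = mx1.copy()
        mx2[40] *= 1.3
        surf = two_year_surface(mx1, mx2, cee_surface.ages)
        res = decompose_by_age(surf, 2000, 2001, functional="e_dagger")
        others = res.contributions.drop(index=40)
        assert abs(res.contributions.loc[40] - res.total) < 1e-8
        assert np.all(np.abs(others.to_numpy()) < 1e-8)

    def test_adult_crisis_expands_young_compresses_old(self, cee_lifetable, cee_surface):
        # mortality increases spanning ages 20-80 (the stagnation pattern):
        # expansion from increases below the threshold age, compression from
        # increases above it
        ages = cee_surface.ages
        mx1 = cee_surface.mx[:, 0]
        mx2 = mx1 * np.where((ages >= 20) & (ages < 80), 1.3, 1.0)
        surf = two_year_surface(mx1, mx2, ages)
        res = decompose_by_age(surf, 2000, 2001, functional="e_dagger")
        contrib = res.contributions
        # the threshold age moves along the integration path, so bracket the
        # sign change with the thresholds of the two endpoint tables
        from lifedisp.lifetable import build_lifetable

        a1 = threshold_age(cee_lifetable)
        a2 = threshold_age(build_lifetable(mx2, ages))
        lo, hi = min(a1, a2), max(a1, a2)
        young = contrib[(ages >= 20) & (ages < lo - 1)]
        old = contrib[(ages > hi + 1) & (ages < 80)]
        assert np.all(young.to_numpy() > 0)
        assert np.all(old.to_numpy() < 0)


def uniform_props(year=2000):
    grid = abridged_grid()
    props = pd.DataFrame(
        np.full((len(grid), 7), 1.0 / 7.0), index=grid, columns=list(CAUSE_CATEGORIES)
    )
    return CauseProportionTable(year=year, props=props)


class TestCauseSplit:
    def test_single_cause_carries_full_rate(self):
        grid = abridged_grid()
        props = pd.DataFrame(0.0, index=grid, columns=list(CAUSE_CATEGORIES))
        props["circulatory"] = 1.0
        table = CauseProportionTable(year=2000, props=props)
        mx = np.linspace(0.001, 0.2, len(grid))
        out = split_rates_by_cause(mx, grid, table)
        assert np.allclose(out["circulatory"].to_numpy()[:-1], mx[:-1])
        # open group mass is rerouted to the residual category
        assert out.loc[grid[-1], "rest"] == mx[-1]

    def test_equal_sevenths(self):
        grid = abridged_grid()
        mx = np.linspace(0.001, 0.2, len(grid))
        out = split_rates_by_cause(mx, grid, uniform_props())
        assert np.allclose(out.to_numpy()[:-1], (mx[:-1] / 7.0)[:, None])

    def test_cause_sums_conserve_all_cause_exactly(self):
        profiles = default_cause_profiles()
        grid = abridged_grid()
        table = make_cause_table(profiles, 1995)
        mx = np.geomspace(1e-4, 0.15, len(grid))
        out = split_rates_by_cause(mx, grid, table)
        assert np.array_equal(out.sum(axis=1).to_numpy(), mx) or np.allclose(
            out.sum(axis=1).to_numpy(), mx, rtol=0, atol=np.finfo(float).eps * 4
        )

    def test_misaligned_grids_rejected(self):
        with pytest.raises(ValueError, match="align"):
            split_rates_by_cause(np.ones(10), np.arange(0, 50, 5), uniform_props())


class TestDecomposeByAgeCause:
    def make_abridged_surface(self, mx1, mx2):
        grid = abridged_grid()
        return MortalitySurface(
            population_id="t",
            sex="male",
            ages=grid,
            years=np.array([1994, 2000]),
            mx=np.column_stack([mx1, mx2]),
            open_age=85,
        )

    def test_no_change_gives_zero_totals(self):
        grid = abridged_grid()
        mx = np.geomspace(5e-4, 0.15, len(grid))
        surf = self.make_abridged_surface(mx, mx)
        res, totals = decompose_by_age_cause(
            surf, uniform_props(1994), uniform_props(2000), 1994, 2000
        )
        assert np.all(totals.to_numpy() == 0.0) and res.total == 0.0

    def test_transport_only_change_is_local_to_transport(self):
        grid = abridged_grid()
        mx1 = np.geomspace(5e-4, 0.15, len(grid))
        p1 = uniform_props(1994)
        # raise only the transport component at ages 20-49
        m_split = p1.props.mul(mx1, axis=0).copy()
        band = (grid >= 20) & (grid < 50)
        m_split.loc[band, "transport"] *= 1.8
        mx2 = m_split.sum(axis=1).to_numpy()
        p2 = CauseProportionTable(
            year=2000, props=m_split.div(m_split.sum(axis=1), axis=0)
        )
        surf = self.make_abridged_surface(mx1, mx2)
        res, totals = decompose_by_age_cause(surf, p1, p2, 1994, 2000)
        others = totals.drop("transport")
        assert abs(totals["transport"] - res.total) < 1e-6
        assert np.all(np.abs(others.to_numpy()) < 1e-6 * max(1, abs(res.total)))
        # and at least 99.9% of the total lands on the perturbed cause
        assert abs(totals["transport"]) / np.abs(totals).sum() > 0.999

    def test_cause_totals_match_age_only_decomposition(self):
        grid = abridged_grid()
        mx1 = np.geomspace(5e-4, 0.15, len(grid))
        mx2 = mx1 * np.where((grid >= 20) & (grid < 60), 1.25, 0.95)
        profiles = default_cause_profiles()
        surf = self.make_abridged_surface(mx1, mx2)
        res_cause, totals = decompose_by_age_cause(
            surf, make_cause_table(profiles, 1994), make_cause_table(profiles, 2000),
            1994, 2000,
        )
        res_age = decompose_by_age(surf, 1994, 2000, functional="e_dagger")
        assert totals.sum() == pytest.approx(res_age.total, abs=1e-4)
        age_from_cause = res_cause.contributions.groupby(level="age").sum()
        assert np.allclose(
            age_from_cause.to_numpy(), res_age.contributions.to_numpy(), atol=1e-4
        )
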