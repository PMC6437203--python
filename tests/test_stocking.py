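import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from seabream.stocking import (
    ReleaseCohortSeries,
    ReplacementParams,
    compare_decay_rates,
    cumulative_recapture_rate,
    equilibrium_surface,
    estimate_hatchery_fraction,
    expand_catch,
    fit_exponential_decay,
    fitness_reduction_per_generation,
    generations_to_threshold,
    pool_hatchery_fraction,
    replacement_step,
    replacement_trajectory,
    wild_gene_growth_factor,
    wild_gene_proportion,
)


def cohort_series(recaptures, n_released=1000, effort=None, start=2000):
    rows = []
    for k, rec in enumerate(recaptures):
        row = {"release_year": start + k, "n_released": n_released}
        for age in range(1, 9):
            row[f"age{age}"] = rec[age - 1] if age <= len(rec) else 0.0
        rows.append(row)
    years = np.arange(start + 1, start + len(recaptures) + 9)
    if effort is None:
        effort = pd.Series(1.0, index=years)
    return ReleaseCohortSeries(pd.DataFrame(rows), effort)


class TestHatcheryFraction:
    def test_zero_marked(self):
        e = estimate_hatchery_fraction(100, 0)
        assert e.p_h == 0.0 and e.se == 0.0

    def test_binomial_arithmetic(self):
        e = estimate_hatchery_fraction(100, 50, q=1.0)
        assert e.p_h == pytest.approx(0.5)
        assert e.se == pytest.approx(0.05)

    def test_mark_rate_expansion(self):
        e = estimate_hatchery_fraction(100, 45, q=0.9)
        assert e.p_h == pytest.approx(0.5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            estimate_hatchery_fraction(100, 50, q=0.0)
        with pytest.raises(ValueError):
            estimate_hatchery_fraction(0, 0)

    def test_landings_weighted_pooling(self):
        a = estimate_hatchery_fraction(100, 80, stratum="inner")
        b = estimate_hatchery_fraction(100, 10, stratum="outer")
        pooled = pool_hatchery_fraction([a, b], [300.0, 100.0])
        assert pooled.p_h == pytest.approx(0.75 * 0.8 + 0.25 * 0.1)


class TestExpandCatch:
    def test_no_hatchery_means_all_wild(self):
        comp = pd.Series([0.6, 0.4], index=[1, 2])
        w = pd.Series([2.0, 4.0], index=[1, 2])
        out = expand_catch(100.0, 0.0, w, comp)
        assert out["numbers_hatchery"].sum() == 0
        assert out["mass_wild"].sum() == pytest.approx(100.0)

    def test_two_age_hand_computation_and_mass_conservation(self):
        comp = pd.Series([0.6, 0.4], index=[1, 2])
        w = pd.Series([2.0, 4.0], index=[1, 2])
        out = expand_catch(100.0, 0.3, w, comp)
        assert out["numbers_total"].tolist() == pytest.approx([30.0, 10.0])
        assert (
            out["mass_hatchery"].sum() + out["mass_wild"].sum()
        ) == pytest.approx(100.0)

    def test_mismatched_ages_rejected(self):
        comp = pd.Series([1.0], index=[1])
        w = pd.Series([2.0, 4.0], index=[1, 2])
        with pytest.raises(ValueError):
            expand_catch(10.0, 0.1, w, comp)


class TestRecaptureRates:
    def test_flat_effort_equals_uncorrected(self):
        c = cohort_series([(50, 30, 20)])
        corrected = cumulative_recapture_rate(c, 3)
        raw = cumulative_recapture_rate(c, 3, corrected=False)
        assert corrected.iloc[0] == pytest.approx(raw.iloc[0])
        assert corrected.iloc[0] == pytest.approx(0.10)

    def test_halved_effort_doubles_that_years_contribution(self):
        years = np.arange(2001, 2012)
        effort = pd.Series(1.0, index=years)
        effort[2002] = 0.5  # age-2 catch year of the single cohort
        c = cohort_series([(50, 30, 20)], effort=effort)
        rate = cumulative_recapture_rate(c, 3, effort_reference_year=2001)
        assert rate.iloc[0] == pytest.approx((50 + 60 + 20) / 1000)

    def test_zero_effort_rejected(self):
        years = np.arange(2001, 2012)
        effort = pd.Series(1.0, index=years)
        c = cohort_series([(50, 30, 20)], effort=effort)
        with pytest.raises(ValueError):
            cumulative_recapture_rate(c, 3, effort_reference_year=1999)

    def test_max_age_bounds(self):
        c = cohort_series([(50, 30, 20)])
        with pytest.raises(ValueError):
            cumulative_recapture_rate(c, 9)


class TestDecayFit:
    def test_exact_data_recovered_to_high_precision(self):
        x = np.arange(20, dtype=float)
        y = 2.0 * np.exp(-0.1 * x)
        fit = fit_exponential_decay(x, y)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-8)
        assert fit.rate == pytest.approx(0.1, abs=1e-8)
        assert fit.p_value < 1e-10

    def test_flat_data_has_no_decline(self):
        x = np.arange(15, dtype=float)
        rng = np.random.default_rng(1)
        y = 5.0 + rng.normal(0, 0.1, x.size)
        fit = fit_exponential_decay(x, y)
        # the estimated rate is within its own sampling noise of zero
        assert abs(fit.rate) < 3 * fit.se_rate
        assert fit.p_value > 0.05

    def test_positive_input_required(self):
        with pytest.raises(ValueError):
            fit_exponential_decay([0, 1, 2], [1.0, -0.5, 0.2])


class TestRateComparison:
    def test_identical_fits(self):
        c = compare_decay_rates(0.1, 0.01, 0.1, 0.01)
        assert c.z == 0.0
        assert c.p_one_sided == pytest.approx(0.5)

    def test_published_pair_average(self):
        c = compare_decay_rates(0.1222, 0.018, 0.1565, 0.017)
        assert c.mean_simple == pytest.approx(0.13935)

    def test_pooled_mean_weighted_by_precision(self):
        c = compare_decay_rates(0.1, 0.01, 0.2, 0.03)
        # the precise estimate dominates
        assert c.mean_pooled < 0.12


class TestFitnessConversion:
    def test_closed_forms(self):
        assert fitness_reduction_per_generation(0.0, 4.8).value == 0.0
        assert fitness_reduction_per_generation(math.log(2), 1.0).value == (
            pytest.approx(0.5)
        )

    def test_delta_method_formula(self):
        red = fitness_reduction_per_generation(0.2, 3.0, se_rate=0.05)
        assert red.se == pytest.approx(3.0 * math.exp(-0.6) * 0.05)
        assert red.se_linear == pytest.approx(0.15)

    def test_invalid_generation_time(self):
        with pytest.raises(ValueError):
            fitness_reduction_per_generation(0.1, 0.0)


class TestReplacementModel:
    def test_neutral_fitness_closed_form_trajectory(self):
        # f = 1 has the exact solution p_t = (1+R)^(-t)
        params = ReplacementParams(f=1.0, R=0.1)
        traj = replacement_trajectory(params, n_generations=100)
        expected = 1.1 ** -np.arange(101)
        assert np.allclose(traj.wild_gene, expected, atol=1e-12)

    def test_no_stocking_neutral_is_stationary(self):
        params = ReplacementParams(f=1.0, R=0.0)
        state = np.array([0.25, 0.5, 0.25])
        nxt = replacement_step(state, params)
        assert np.allclose(nxt, state, atol=1e-15)

    def test_extinct_wild_gene_is_absorbing(self):
        for f, R in [(0.0, 0.5), (0.5, 0.1), (1.0, 0.0)]:
            state = np.array([0.0, 0.0, 1.0])
            nxt = replacement_step(state, ReplacementParams(f=f, R=R))
            assert wild_gene_proportion(nxt) == 0.0

    @given(
        st.floats(0.0, 1.0),
        st.floats(0.0, 1.0),
        st.floats(0.0, 1.0),
    )
    def test_step_preserves_the_simplex(self, f, R, p0):
        params = ReplacementParams(f=f, R=R, p0=p0)
        state = params.initial_state()
        for _ in range(5):
            state = replacement_step(state, params)
            assert state.min() >= -1e-12
            assert state.sum() == pytest.approx(1.0, abs=1e-9)

    def test_persistence_boundary_predicts_iteration_outcome(self):
        # the sign of the growth factor minus one must agree with whether
        # iteration ever drives the wild gene below 1%
        for f in np.linspace(0.1, 1.0, 8):
            for R in np.linspace(0.05, 1.0, 8):
                params = ReplacementParams(f=float(f), R=float(R))
                factor = wild_gene_growth_factor(params)
                if abs(factor - 1) < 0.02:
                    continue  # numerically near the boundary
                gens = generations_to_threshold(params, 0.01, max_generations=20000)
                if factor > 1:
                    assert gens is None
                else:
                    assert gens is not None

    def test_equilibrium_surface_properties(self):
        f = np.linspace(0.0, 1.0, 6)
        R = np.linspace(0.0, 0.5, 6)
        surf = equilibrium_surface(f, R)
        # no stocking keeps the wild gene fixed at 1
        assert np.allclose(surf[0.0], 1.0)
        # equilibrium is non-increasing in the stocking rate at fixed f
        vals = surf.to_numpy()
        assert (np.diff(vals, axis=1) <= 1e-9).all()

    def test_interior_equilibrium_matches_growth_factor(self):
        # f=0.6, R=0.3 persists; iterate to the interior equilibrium
        params = ReplacementParams(f=0.6, R=0.3)
        traj = replacement_trajectory(params)
        assert traj.converged
        assert traj.equilibrium > 0.01
        assert generations_to_threshold(params, 0.01) is None

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            generations_to_threshold(ReplacementParams(1.0, 0.1), 1.5)
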