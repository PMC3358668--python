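"""Bundled models: coefficient algebra, deterministic limits, benchmarks."""

import numpy as np
import pytest

from sdesmc.bayes import check_fairness
from sdesmc.bltl import Until, parse_formula
from sdesmc.models import (
    ImmunogenicParams,
    LefeverGarayParams,
    PRESETS,
    biased_success_prob,
    brownian_barrier_model,
    get_preset,
    immunogenic,
    lefever_garay,
    toy_fixture,
    toy_posterior_pair,
)
from sdesmc.sde import SimulationGrid, simulate, simulate_batch


class TestLefeverGaray:
    def test_zero_state_is_absorbing(self):
        model = lefever_garay(LefeverGarayParams())
        state = np.array([[0.0]])
        for t in (0.0, 1.3, 7.0):
            assert model.drift(t, state)[0, 0] == 0.0
            assert model.diffusion(t, state)[0, 0, 0] == 0.0

    def test_noise_vanishes_at_carrying_capacity(self):
        p = LefeverGarayParams(K=10.0)
        model = lefever_garay(p)
        state = np.array([[10.0]])
        assert model.diffusion(0.0, state)[0, 0, 0] == pytest.approx(0.0)

    def test_drift_matches_formula_at_sample_point(self):
        p = LefeverGarayParams(r0=1.2, K=5.0, beta=0.7, A0=0.4, omega=2.0)
        model = lefever_garay(p)
        x, t = 2.0, 0.9
        logistic = x * (1 - x / p.K)
        expected = (
            p.r0 * logistic
            - p.beta * x**2 / (1 + x**2)
            + logistic * p.A0 * np.cos(p.omega * t)
        )
        assert model.drift(t, np.array([[x]]))[0, 0] == pytest.approx(expected)

    def test_noise_free_limit_follows_logistic_growth(self):
        """With beta = A0 = 0 and noise suppressed, Euler tracks the logistic ODE."""
        p = LefeverGarayParams(r0=1.0, K=1.0, beta=0.0, A0=0.0, x0=0.01)
        model = lefever_garay(p)
        grid = SimulationGrid(10.0, 1e-3)
        # suppress noise by simulating with zero Brownian increments: use the
        # drift-only difference equation directly
        finals, _, _ = simulate_batch(
            model, grid, np.zeros((1, 1)), _ZeroRng(), return_states=False
        )
        t, x0 = 10.0, 0.01
        logistic_exact = x0 * np.exp(t) / (1 + x0 * (np.exp(t) - 1))
        assert finals[0, 0] == pytest.approx(logistic_exact, abs=5e-3)

    def test_trajectories_stay_nonnegative_and_finite(self):
        model = lefever_garay(LefeverGarayParams())
        grid = SimulationGrid(1.0, 1e-3)
        rng = np.random.default_rng(99)
        states, _, _ = simulate_batch(model, grid, np.zeros((500, 1)), rng)
        assert np.all(states >= 0.0)
        assert np.all(np.isfinite(states))


class _ZeroRng:
    """Stand-in generator producing zero increments (drift-only integration)."""

    def standard_normal(self, shape):
        return np.zeros(shape)


class TestImmunogenic:
    def test_noise_vanishes_at_equilibrium(self):
        p = ImmunogenicParams()
        model = immunogenic(p)
        state = np.array([[p.x1_eq, p.y1_eq]])
        assert np.allclose(model.diffusion(0.0, state), 0.0)

    def test_tumor_extinction_absorbing_in_y(self):
        model = immunogenic(ImmunogenicParams())
        for x in (0.0, 0.5, 3.0):
            drift = model.drift(0.0, np.array([[x, 0.0]]))
            assert drift[0, 1] == 0.0

    def test_default_equilibrium_lies_on_y_nullcline(self):
        p = ImmunogenicParams()
        # interior fixed point satisfies b1 (1 - b2 y) = x
        assert p.b1 * (1 - p.b2 * p.y1_eq) == pytest.approx(p.x1_eq)
        # and the x-equation a1 - a2 x + a3 x y = 0
        assert p.a1 - p.a2 * p.x1_eq + p.a3 * p.x1_eq * p.y1_eq == pytest.approx(
            0.0, abs=1e-12
        )

    def test_noise_free_interior_fixed_point_found_by_simulation(self):
        p = ImmunogenicParams(b11=0.0, b12=0.0, b21=0.0, b22=0.0, x0=1.0, y0=1.0)
        model = immunogenic(p)
        finals, _, _ = simulate_batch(
            model, SimulationGrid(200.0, 1e-2), np.zeros((1, 2)), _ZeroRng(),
            return_states=False,
        )
        x_fix, y_fix = finals[0]
        if y_fix > 1e-6:  # interior attractor: check the nullcline relation
            assert p.b1 * (1 - p.b2 * y_fix) == pytest.approx(x_fix, rel=1e-3)

    def test_trajectories_stay_nonnegative_and_finite(self):
        model = immunogenic(ImmunogenicParams())
        rng = np.random.default_rng(7)
        states, _, _ = simulate_batch(
            model, SimulationGrid(1.0, 1e-3), np.zeros((500, 2)), rng
        )
        assert np.all(states >= 0.0)
        assert np.all(np.isfinite(states))


class TestBrownianBarrier:
    def test_analytic_probability_values(self):
        _, _, p1 = brownian_barrier_model(1.0, 1.0)
        assert p1 == pytest.approx(0.3173, abs=5e-4)
        _, _, p3 = brownian_barrier_model(3.0, 1.0)
        assert p3 == pytest.approx(0.0027, abs=1e-4)

    def test_probability_vanishes_for_distant_barrier(self):
        _, _, p = brownian_barrier_model(50.0, 1.0)
        assert p < 1e-100

    def test_formula_is_bounded_eventually(self):
        _, formula, _ = brownian_barrier_model(2.0, 5.0)
        assert isinstance(formula, Until)
        assert formula.bound == 5.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            brownian_barrier_model(-1.0, 1.0)
        with pytest.raises(ValueError):
            brownian_barrier_model(1.0, 0.0)


class TestToyFixture:
    def test_identity_when_c_is_one(self):
        pair = toy_fixture(1.0, 0.01)
        np.testing.assert_allclose(pair.p_natural, pair.p_biased)

    def test_rare_mass_boosted_by_c(self):
        pair = toy_fixture(10.0, 1e-3)
        assert pair.p_biased[0] == pytest.approx(1e-2)
        assert pair.ratios[0] == pytest.approx(10.0)

    def test_boost_capped_at_half(self):
        pair = toy_fixture(10.0, 0.2)
        assert pair.p_biased[0] == pytest.approx(0.5)

    def test_expected_hitting_time_drops_geometrically(self):
        pair = toy_fixture(10.0, 1e-3)
        rng = np.random.default_rng(0)
        nat = pair.sample(rng, 200000, biased=False)
        bia = pair.sample(rng, 200000, biased=True)
        # mean waiting time for the rare outcome ~ 1/p: 1000 vs 100
        assert 1 / max(np.mean(nat == 0), 1e-9) == pytest.approx(1000, rel=0.25)
        assert 1 / np.mean(bia == 0) == pytest.approx(100, rel=0.15)

    def test_empirical_frequency_ratio_matches_declared_derivative(self):
        pair = toy_fixture(5.0, 0.01)
        rng = np.random.default_rng(3)
        nat = pair.sample(rng, 400000, biased=False)
        bia = pair.sample(rng, 400000, biased=True)
        empirical = np.mean(bia == 0) / np.mean(nat == 0)
        assert empirical == pytest.approx(pair.ratios[0], rel=0.15)

    def test_fairness_check_on_explicit_derivatives(self):
        pair = toy_fixture(2.0, 0.1)
        rng = np.random.default_rng(11)
        outcomes = pair.sample(rng, 400, biased=True)
        factors = pair.ratios[outcomes]
        # systematically biased stream: geometric mean ~ ratio, needs eta >= it
        assert check_fairness(factors, eta=2.0)
        alternating = np.concatenate([factors, 1.0 / factors])
        assert check_fairness(alternating, eta=1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            toy_fixture(0.5, 0.01)
        with pytest.raises(ValueError):
            toy_fixture(2.0, 0.7)


class TestBiasedFamily:
    def test_derivatives_bounded_by_c_everywhere(self):
        for c in (1.5, 2.0, 10.0):
            u = np.linspace(1e-6, 1 - 1e-6, 2001)
            q = biased_success_prob(u, c)
            assert np.all(q / u <= c + 1e-9)
            assert np.all(q / u >= 1 / c - 1e-9)
            assert np.all((1 - q) / (1 - u) <= c + 1e-9)
            assert np.all((1 - q) / (1 - u) >= 1 / c - 1e-9)

    def test_rare_events_boosted_linearly(self):
        assert biased_success_prob(1e-3, 10.0) == pytest.approx(1e-2)

    def test_posterior_pair_reduces_to_identity_at_c_one(self):
        p, q = toy_posterior_pair([True, False, False], 0.3, 1.0)
        assert q == pytest.approx(p, rel=1e-8)


class TestPresets:
    def test_registry_contents(self):
        assert {"lefever", "lefever_rare", "immunogenic", "immuno_rare",
                "brownian_barrier"} <= set(PRESETS)

    def test_headline_properties_parse(self):
        for name in ("lefever_rare", "immuno_rare"):
            preset = get_preset(name)
            formula = parse_formula(preset.formula)
            assert formula is not None
            assert preset.theta0 == 0.01

    def test_rare_preset_initial_states(self):
        model = get_preset("lefever_rare").build()
        assert model.initial_state[0] == pytest.approx(1e9)
        model = get_preset("immuno_rare").build()
        np.testing.assert_allclose(model.initial_state, [0.1, 0.1])

    def test_overrides_flow_through(self):
        model = get_preset("lefever").build(r0=2.5, x0=4.0)
        assert model.initial_state[0] == 4.0

    def test_unknown_preset_raises(self):
        with pytest.raises(KeyError):
            get_preset("nonexistent")
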