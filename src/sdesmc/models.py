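"""Bundled models: two tumor SDE systems, analytic benchmarks, and a discrete
two-outcome fixture with an explicit change of measure.

The tumor models ship with *placeholder* default parameters: the original
studies they come from fix their coefficients elsewhere, so the defaults here
are chosen only to produce plausible dynamics at desk scale and are clearly
not calibrated values.  Every coefficient is overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import sqrt
from typing import Optional

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm

from .bltl import parse_formula
from .sde import SDEModel, SimulationGrid

__all__ = [
    "LefeverGarayParams",
    "ImmunogenicParams",
    "ToyMeasurePair",
    "lefever_garay",
    "immunogenic",
    "brownian_barrier_model",
    "toy_fixture",
    "biased_success_prob",
    "toy_posterior_pair",
    "PRESETS",
    "Preset",
    "get_preset",
]


# ---------------------------------------------------------------------------
# Lefever–Garay: tumor growth under immune surveillance and chemotherapy


@dataclass(frozen=True)
class LefeverGarayParams:
    """One-dimensional tumor model
    dx = [r₀x(1−x/K) − βx²/(1+x²) + x(1−x/K)A₀cos(ωt)] dt + x(1−x/K) dW.

    r0 : linear per-capita birth rate of tumor cells.
    K : carrying capacity of the environment (cells).
    beta : strength of immune-cell predation (saturating in x).
    A0, omega : amplitude and angular frequency of the periodic chemotherapy
        term.
    x0 : initial tumor burden (cells).

    Defaults are uncalibrated placeholders at desk scale.
    """

    r0: float = 1.0
    K: float = 10.0
    beta: float = 2.0
    A0: float = 0.3
    omega: float = 1.0
    x0: float = 1.0

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("carrying capacity K must be positive")
        if self.x0 < 0 or self.beta < 0 or self.A0 < 0:
            raise ValueError("x0, beta and A0 must be non-negative")


def lefever_garay(params: LefeverGarayParams = LefeverGarayParams()) -> SDEModel:
    """Build the Lefever–Garay SDE; multiplicative noise ``x(1−x/K) dW``.

    The drift and diffusion share the logistic factor, so both the empty
    state x = 0 and the carrying capacity are noise-free; x = 0 is absorbing.
    """
    p = params

    def drift(t: float, state: np.ndarray) -> np.ndarray:
        x = state[..., 0]
        logistic = x * (1.0 - x / p.K)
        dx = (
            p.r0 * logistic
            - p.beta * x**2 / (1.0 + x**2)
            + logistic * p.A0 * np.cos(p.omega * t)
        )
        return dx[..., None]

    def diffusion(t: float, state: np.ndarray) -> np.ndarray:
        x = state[..., 0]
        return (x * (1.0 - x / p.K))[..., None, None]

    return SDEModel(
        dim_state=1,
        dim_noise=1,
        drift=drift,
        diffusion=diffusion,
        initial_state=np.array([p.x0]),
        variable_names=("x",),
        clamp_nonnegative=True,
    )


# ---------------------------------------------------------------------------
# Immunogenic tumor model: immune cells x vs tumor cells y


def _immuno_equilibrium(a1, a2, a3, b1, b2):
    """Interior fixed point of the noise-free system.

    The y-nullcline gives x = b₁(1 − b₂ y); substituting into the x-equation
    a₁ − a₂x + a₃xy = 0 yields a quadratic in y, whose smaller root is taken.
    """
    # (a2 - a3 y) * b1 (1 - b2 y) = a1
    # a3 b1 b2 y² - b1(a2 b2 + a3) y + (a2 b1 - a1) = 0
    qa = a3 * b1 * b2
    qb = -b1 * (a2 * b2 + a3)
    qc = a2 * b1 - a1
    disc = qb * qb - 4 * qa * qc
    if qa == 0 or disc < 0:
        raise ValueError("parameters admit no interior equilibrium")
    y_eq = (-qb - sqrt(disc)) / (2 * qa)
    x_eq = b1 * (1.0 - b2 * y_eq)
    return x_eq, y_eq


@dataclass(frozen=True)
class ImmunogenicParams:
    """Two-dimensional immunogenic tumor model

    dx = (a₁ − a₂x + a₃xy) dt + [b₁₁(x−x₁) + b₁₂(y−y₁)] dW₁
    dy = (b₁y(1−b₂y) − xy) dt + [b₂₁(x−x₁) + b₂₂(y−y₁)] dW₂

    with x the immune-cell and y the tumor-cell amount (dimensionless
    "units").  Noise grows with the distance to the stochastic equilibrium
    (x₁, y₁) and vanishes exactly there.  Defaults are uncalibrated
    placeholders; by default (x₁, y₁) is the interior fixed point of the
    deterministic drift.
    """

    a1: float = 0.5
    a2: float = 1.0
    a3: float = 0.2
    b1: float = 2.0
    b2: float = 0.25
    b11: float = 0.1
    b12: float = 0.0
    b21: float = 0.0
    b22: float = 0.1
    x1_eq: Optional[float] = None
    y1_eq: Optional[float] = None
    x0: float = 0.1
    y0: float = 0.1

    def __post_init__(self) -> None:
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("initial amounts must be non-negative")
        if self.x1_eq is None or self.y1_eq is None:
            x_eq, y_eq = _immuno_equilibrium(
                self.a1, self.a2, self.a3, self.b1, self.b2
            )
            if self.x1_eq is None:
                object.__setattr__(self, "x1_eq", x_eq)
            if self.y1_eq is None:
                object.__setattr__(self, "y1_eq", y_eq)
        if not (np.isfinite(self.x1_eq) and np.isfinite(self.y1_eq)):
            raise ValueError("equilibrium point must be finite")


def immunogenic(params: ImmunogenicParams = ImmunogenicParams()) -> SDEModel:
    """Build the immunogenic tumor SDE with two independent Brownian motions."""
    p = params

    def drift(t: float, state: np.ndarray) -> np.ndarray:
        x = state[..., 0]
        y = state[..., 1]
        dx = p.a1 - p.a2 * x + p.a3 * x * y
        dy = p.b1 * y * (1.0 - p.b2 * y) - x * y
        return np.stack([dx, dy], axis=-1)

    def diffusion(t: float, state: np.ndarray) -> np.ndarray:
        x = state[..., 0]
        y = state[..., 1]
        dx1 = p.b11 * (x - p.x1_eq) + p.b12 * (y - p.y1_eq)
        dy2 = p.b21 * (x - p.x1_eq) + p.b22 * (y - p.y1_eq)
        zero = np.zeros_like(x)
        row_x = np.stack([dx1, zero], axis=-1)
        row_y = np.stack([zero, dy2], axis=-1)
        return np.stack([row_x, row_y], axis=-2)

    return SDEModel(
        dim_state=2,
        dim_noise=2,
        drift=drift,
        diffusion=diffusion,
        initial_state=np.array([p.x0, p.y0]),
        variable_names=("x", "y"),
        clamp_nonnegative=True,
    )


# ---------------------------------------------------------------------------
# Analytic benchmark: Brownian barrier crossing


def brownian_barrier_model(barrier: float, horizon: float):
    """Standard Brownian motion against the barrier-crossing property.

    Returns ``(model, formula, analytic_probability)`` for ``dX = dW``,
    ``X₀ = 0`` and ``F[horizon](x > barrier)``.  By the reflection principle
    the continuous-time crossing probability is ``2 (1 − Φ(a/√t))``; a
    discretely monitored estimate undershoots it slightly because excursions
    between grid points go unseen.
    """
    if barrier <= 0 or horizon <= 0:
        raise ValueError("barrier and horizon must be positive")

    def drift(t: float, state: np.ndarray) -> np.ndarray:
        return np.zeros_like(state)

    def diffusion(t: float, state: np.ndarray) -> np.ndarray:
        return np.ones(state.shape[:-1] + (1, 1))

    model = SDEModel(
        dim_state=1,
        dim_noise=1,
        drift=drift,
        diffusion=diffusion,
        initial_state=np.array([0.0]),
        variable_names=("x",),
    )
    formula = parse_formula(f"F[{horizon!r}](x > {barrier!r})")
    probability = float(2.0 * norm.sf(barrier / sqrt(horizon)))
    return model, formula, probability


# ---------------------------------------------------------------------------
# Discrete two-outcome fixture with explicit measures


@dataclass(frozen=True)
class ToyMeasurePair:
    """Two equivalent measures on a finite outcome set, rare outcome first.

    ``c`` bounds the outcome-wise Radon–Nikodym derivative
    ``p_biased / p_natural`` within [1/c, c].
    """

    p_natural: np.ndarray
    p_biased: np.ndarray
    satisfying: np.ndarray
    c: float

    def __post_init__(self) -> None:
        p_nat = np.asarray(self.p_natural, dtype=float)
        p_bia = np.asarray(self.p_biased, dtype=float)
        sat = np.asarray(self.satisfying, dtype=bool)
        object.__setattr__(self, "p_natural", p_nat)
        object.__setattr__(self, "p_biased", p_bia)
        object.__setattr__(self, "satisfying", sat)
        if not (np.isclose(p_nat.sum(), 1.0) and np.isclose(p_bia.sum(), 1.0)):
            raise ValueError("both measures must sum to 1")
        if np.any((p_nat > 0) != (p_bia > 0)):
            raise ValueError("measures must be equivalent (same support)")
        support = p_nat > 0
        ratio = p_bia[support] / p_nat[support]
        if np.any(ratio > self.c * (1 + 1e-12)) or np.any(
            ratio < (1 + 1e-12) ** -1 / self.c
        ):
            raise ValueError("Radon–Nikodym ratio violates the declared bound c")

    @property
    def ratios(self) -> np.ndarray:
        """Outcome-wise Radon–Nikodym derivatives dQ/dP."""
        out = np.zeros_like(self.p_natural)
        support = self.p_natural > 0
        out[support] = self.p_biased[support] / self.p_natural[support]
        return out

    def sample(self, rng: np.random.Generator, n: int, biased: bool = True):
        """Draw outcome indices i.i.d. from one of the two measures."""
        p = self.p_biased if biased else self.p_natural
        return rng.choice(len(p), size=n, p=p)


def toy_fixture(c: float, p_rare: float) -> ToyMeasurePair:
    """Two-outcome fixture: a rare satisfying outcome boosted by a factor ≤ c.

    Natural measure (p_rare, 1 − p_rare); biased measure moves the rare mass
    to min(c·p_rare, 1/2).
    """
    if c < 1:
        raise ValueError("c must be at least 1")
    if not 0.0 < p_rare < 0.5:
        raise ValueError("p_rare must lie in (0, 1/2)")
    q_rare = min(c * p_rare, 0.5)
    return ToyMeasurePair(
        p_natural=np.array([p_rare, 1.0 - p_rare]),
        p_biased=np.array([q_rare, 1.0 - q_rare]),
        satisfying=np.array([True, False]),
        c=c,
    )


def biased_success_prob(u, c: float):
    """Success probability of the c-bounded biased Bernoulli family.

    For a natural success probability ``u``, the biased family samples
    success with probability ``q(u) = min(c·u, 1 − (1−u)/c)``.  Both
    outcome-wise derivatives, ``q/u`` and ``(1−q)/(1−u)``, then stay within
    [1/c, c] for every u in [0, 1] — the family realizes the bounded change
    of measure on the Bernoulli likelihood itself, which makes the posterior
    distortion bound directly computable.
    """
    if c < 1:
        raise ValueError("c must be at least 1")
    u = np.asarray(u, dtype=float)
    q = np.minimum(c * u, 1.0 - (1.0 - u) / c)
    return q if q.shape else float(q)


def toy_posterior_pair(
    outcomes,
    theta0: float,
    c: float,
    prior_alpha: float = 1.0,
    prior_beta: float = 1.0,
):
    """Posterior P(ρ < θ₀ | outcomes) under the natural and biased likelihoods.

    ``outcomes`` is a boolean sequence.  The natural posterior uses the
    Bernoulli(u) likelihood; the biased posterior uses Bernoulli(q(u)) with
    q from :func:`biased_success_prob`, integrating both by adaptive
    quadrature.  Returns ``(p_natural, q_biased)``.
    """
    outcomes = np.asarray(outcomes, dtype=bool)
    x = int(outcomes.sum())
    n = int(outcomes.size)

    def posterior(success_prob_fn):
        def integrand(u):
            q = success_prob_fn(u)
            return (
                q**x
                * (1.0 - q) ** (n - x)
                * u ** (prior_alpha - 1.0)
                * (1.0 - u) ** (prior_beta - 1.0)
            )

        kink = 1.0 / (c + 1.0)  # where the biased family switches branch
        below = quad(integrand, 0.0, theta0, points=[min(kink, theta0)], limit=200)[0]
        total = below + quad(integrand, theta0, 1.0, points=[max(kink, theta0)], limit=200)[0]
        return below / total

    natural = posterior(lambda u: u)
    biased = posterior(lambda u: biased_success_prob(u, c))
    return natural, biased


# ---------------------------------------------------------------------------
# Preset registry


@dataclass(frozen=True)
class Preset:
    """A named bundle: model, property, threshold and simulation grid."""

    name: str
    description: str
    model_factory: object
    formula: str
    theta0: float
    grid: SimulationGrid
    analytic_probability: Optional[float] = None

    def build(self, **overrides) -> SDEModel:
        return self.model_factory(**overrides)


def _lefever_factory(**overrides) -> SDEModel:
    return lefever_garay(replace(LefeverGarayParams(), **overrides))


def _lefever_rare_factory(**overrides) -> SDEModel:
    # Rare-growth demonstration: carrying capacity below the 1e11 barrier so
    # only a noise excursion can cross it.  Placeholder coefficients.
    params = LefeverGarayParams(
        r0=0.3, K=8e10, beta=0.0, A0=0.1, omega=np.pi, x0=1e9
    )
    return lefever_garay(replace(params, **overrides))


def _immuno_factory(**overrides) -> SDEModel:
    return immunogenic(replace(ImmunogenicParams(), **overrides))


def _barrier_factory(barrier: float = 1.0, horizon: float = 1.0) -> SDEModel:
    return brownian_barrier_model(barrier, horizon)[0]


PRESETS: dict[str, Preset] = {
    "lefever": Preset(
        name="lefever",
        description="Lefever-Garay tumor model, desk-scale placeholder defaults",
        model_factory=_lefever_factory,
        formula="F[10](x > 8)",
        theta0=0.01,
        grid=SimulationGrid(t_end=10.0, dt=1e-3),
    ),
    "lefever_rare": Preset(
        name="lefever_rare",
        description=(
            "Lefever-Garay rare-growth property: from a billion cells, does "
            "the tumor reach 1e11 cells within 10 time units with "
            "probability at least 1%?"
        ),
        model_factory=_lefever_rare_factory,
        formula="F[10](x > 1e11)",
        theta0=0.01,
        grid=SimulationGrid(t_end=10.0, dt=1e-3),
    ),
    "immunogenic": Preset(
        name="immunogenic",
        description="Immunogenic tumor model, desk-scale placeholder defaults",
        model_factory=_immuno_factory,
        formula="F[10](x > 3.3)",
        theta0=0.01,
        grid=SimulationGrid(t_end=10.0, dt=1e-3),
    ),
    "immuno_rare": Preset(
        name="immuno_rare",
        description=(
            "Immunogenic rare-growth property: from 0.1 units each, does the "
            "monitored variable exceed 3.3 units within 10 time units with "
            "probability at least 1%?  The headline property is stated on "
            "variable x; pass formula='F[10](y > 3.3)' to monitor the tumor "
            "variable y instead (see the methods note)."
        ),
        model_factory=_immuno_factory,
        formula="F[10](x > 3.3)",
        theta0=0.01,
        grid=SimulationGrid(t_end=10.0, dt=1e-3),
    ),
    "brownian_barrier": Preset(
        name="brownian_barrier",
        description=(
            "Standard Brownian motion vs F[1](x > 1); analytic crossing "
            "probability 2(1 - Phi(1)) ~ 0.3173 by the reflection principle"
        ),
        model_factory=_barrier_factory,
        formula="F[1](x > 1)",
        theta0=0.1,
        grid=SimulationGrid(t_end=1.0, dt=1e-3),
        analytic_probability=float(2.0 * norm.sf(1.0)),
    ),
}


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
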