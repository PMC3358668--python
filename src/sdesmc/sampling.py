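"""Outcome samplers feeding the sequential test.

The non-i.i.d. policy draws, for every trajectory, a fresh constant drift
shift θ uniformly from the symmetric box [−θ_max, +θ_max]^dim_noise and
simulates the SDE under the corresponding Girsanov-shifted measure.  The
symmetry of the draw is the constructive fairness argument: biases for and
against any event are applied equally often in the long run, so the
geometric mean of the implied Radon–Nikodym derivatives is driven toward 1.
The fairness bound η that licenses the Bayes-factor correction is asserted
by the user, since the implied derivatives of SDE path events are not
computable in closed form.

Trajectories are generated in fixed-size chunks, each chunk from its own
counter-derived random stream, so the outcome sequence is reproducible from
the root seed alone regardless of how many samples the test consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .bayes import SampleOutcome
from .bltl import Formula, Trace, formula_variables, satisfies
from .sde import SDEModel, SimulationGrid, simulate_batch

__all__ = [
    "derive_rng",
    "TrajectorySampler",
    "bernoulli_sampler",
    "biased_bernoulli_sampler",
    "monte_carlo_probability",
]


def derive_rng(root_seed: int, stream_index: int) -> np.random.Generator:
    """Independent, reproducible stream ``stream_index`` of a root seed."""
    ss = np.random.SeedSequence(entropy=abs(int(root_seed)), spawn_key=(int(stream_index),))
    return np.random.default_rng(ss)


def _check_formula(model: SDEModel, formula: Formula) -> None:
    unknown = formula_variables(formula) - set(model.variable_names)
    if unknown:
        raise LookupError(
            f"formula references unknown variables {sorted(unknown)}; "
            f"model provides {model.variable_names}"
        )


@dataclass
class TrajectorySampler:
    """Iterable of monitored SDE trajectories, optionally measure-perturbed.

    mode "off" simulates every path under the natural measure; mode
    "symmetric_uniform" draws θ ~ U[−θ_max, θ_max]^dim_noise per path.
    """

    model: SDEModel
    grid: SimulationGrid
    formula: Formula
    theta_max: float = 0.0
    mode: str = "off"
    root_seed: int = 0
    batch_size: int = 256

    def __post_init__(self) -> None:
        if self.mode not in ("off", "symmetric_uniform"):
            raise ValueError("mode must be 'off' or 'symmetric_uniform'")
        if self.mode == "off":
            self.theta_max = 0.0
        if self.theta_max < 0:
            raise ValueError("theta_max must be non-negative")
        _check_formula(self.model, self.formula)

    def __iter__(self) -> Iterator[SampleOutcome]:
        m = self.model.dim_noise
        chunk = 0
        while True:
            rng = derive_rng(self.root_seed, chunk)
            if self.mode == "symmetric_uniform" and self.theta_max > 0:
                thetas = rng.uniform(-self.theta_max, self.theta_max, (self.batch_size, m))
            else:
                thetas = np.zeros((self.batch_size, m))
            states, log_weights, _ = simulate_batch(self.model, self.grid, thetas, rng)
            durations = np.diff(self.grid.times, append=self.grid.times[-1])
            for i in range(self.batch_size):
                trace = Trace(
                    states=states[i],
                    durations=durations,
                    variable_names=self.model.variable_names,
                )
                yield SampleOutcome(
                    satisfied=satisfies(self.formula, trace),
                    theta=thetas[i].copy(),
                    log_weight=float(log_weights[i]),
                )
            chunk += 1


def bernoulli_sampler(p: float, root_seed: int) -> Iterator[SampleOutcome]:
    """I.i.d. Bernoulli(p) outcome stream (analytic test harness)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a probability")
    chunk = 0
    while True:
        rng = derive_rng(root_seed, chunk)
        draws = rng.random(1024) < p
        for d in draws:
            yield SampleOutcome(satisfied=bool(d))
        chunk += 1


def biased_bernoulli_sampler(p: float, c: float, root_seed: int) -> Iterator[SampleOutcome]:
    """Bernoulli stream under the c-bounded biased measure.

    Samples success with probability q(p) = min(c·p, 1 − (1−p)/c); the
    outcome-wise Radon–Nikodym derivative is bounded by c, so asserting
    η = c makes the stream η-fair in the worst case.
    """
    from .models import biased_success_prob

    q = float(biased_success_prob(p, c))
    log_ratio_success = np.log(q / p) if p > 0 else 0.0
    log_ratio_failure = np.log((1 - q) / (1 - p)) if p < 1 else 0.0
    chunk = 0
    while True:
        rng = derive_rng(root_seed, chunk)
        draws = rng.random(1024) < q
        for d in draws:
            yield SampleOutcome(
                satisfied=bool(d),
                log_weight=-(log_ratio_success if d else log_ratio_failure),
            )
        chunk += 1


def monte_carlo_probability(
    model: SDEModel,
    grid: SimulationGrid,
    formula: Formula,
    n_paths: int,
    root_seed: int = 0,
    batch_size: int = 1000,
) -> float:
    """Plain i.i.d. Monte-Carlo estimate of Pr(σ ⊨ φ) under the natural measure."""
    _check_formula(model, formula)
    sampler = TrajectorySampler(
        model=model,
        grid=grid,
        formula=formula,
        mode="off",
        root_seed=root_seed,
        batch_size=batch_size,
    )
    hits = 0
    for i, outcome in enumerate(sampler):
        if i >= n_paths:
            break
        hits += int(outcome.satisfied)
    return hits / n_paths
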