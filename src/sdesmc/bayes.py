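"""Bayesian sequential hypothesis testing on Bernoulli satisfaction outcomes.

The statistical model-checking question "does the model satisfy φ with
probability at least θ₀?" is cast as a choice between the composite
hypotheses H₀: ρ ≥ θ₀ and H₁: ρ < θ₀, where ρ is the unknown satisfaction
probability.  With a Beta(α, β) prior g on ρ and data x successes in n
Bernoulli trials, the Bayes factor is the ratio of prior-weighted
likelihood masses

    B = ∫_{θ₀}^1 u^x (1−u)^{n−x} g(u) du  /  ∫_0^{θ₀} u^x (1−u)^{n−x} g(u) du,

available in closed form through the regularized incomplete beta function:
with I = I_{θ₀}(α + x, β + n − x), B = (1 − I) / I.

When samples are drawn under per-sample *perturbed* probability measures
(non-i.i.d. sampling), the running Bayes factor computed from the biased
outcomes can differ from the natural-measure one.  If the sampling strategy
is η-fair — the geometric mean of the per-sample Radon–Nikodym derivatives
stays within [1/η, η] — the distortion of the posterior after n samples is
bounded by a factor η^{2n}, so the sequential test shrinks the Bayes factor
toward 1 by η^{2n} before comparing it with the decision threshold.  All
arithmetic is done on log B so the test survives n in the thousands.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from scipy.special import betainc

__all__ = [
    "TestSpec",
    "TestState",
    "TestResult",
    "SampleOutcome",
    "bayes_factor",
    "log_bayes_factor",
    "posterior_prob_below",
    "adjust_bayes_factor",
    "check_fairness",
    "eventually_fair",
    "sequential_verify",
]


@dataclass(frozen=True)
class TestSpec:
    """Parameters of the sequential test.

    theta0 : probability threshold of H₀: ρ ≥ θ₀.
    prior_alpha, prior_beta : Beta prior on ρ (default the flat Beta(1, 1)).
    bayes_threshold : decision threshold T > 1; accept H₀ once the adjusted
        Bayes factor exceeds T, accept H₁ once it drops below 1/T.
    eta : asserted fairness bound of the sampling strategy (η = 1 means
        i.i.d. sampling and disables the correction).
    concentration_b : optional posterior-concentration rate constant used by
        :func:`eventually_fair`; it is supplied by the user, not estimated.
    max_samples : budget after which the test returns ``undecided``.
    """

    __test__ = False  # not a pytest class

    theta0: float
    prior_alpha: float = 1.0
    prior_beta: float = 1.0
    bayes_threshold: float = 100.0
    eta: float = 1.0
    concentration_b: Optional[float] = None
    max_samples: int = 10**6

    def __post_init__(self) -> None:
        if not 0.0 < self.theta0 < 1.0:
            raise ValueError("theta0 must lie strictly between 0 and 1")
        if self.prior_alpha <= 0 or self.prior_beta <= 0:
            raise ValueError("Beta prior parameters must be positive")
        if self.bayes_threshold <= 1:
            raise ValueError("bayes_threshold must exceed 1")
        if self.eta < 1:
            raise ValueError("eta must be at least 1")
        if self.concentration_b is not None and self.concentration_b <= 0:
            raise ValueError("concentration_b must be positive")
        if self.max_samples < 0:
            raise ValueError("max_samples must be non-negative")


@dataclass
class TestState:
    """Running counters of the sequential test."""

    __test__ = False  # not a pytest class

    n: int = 0
    x: int = 0
    log_bayes_factor: float = 0.0
    history: Optional[list] = None


@dataclass
class TestResult:
    __test__ = False  # not a pytest class

    decision: str  # accept_H0 | accept_H1 | undecided
    n_samples: int
    satisfied_count: int
    raw_log_bayes_factor: float
    adjusted_log_bayes_factor: float

    def to_dict(self) -> dict:
        return {
            "decision": self.decision,
            "n_samples": self.n_samples,
            "satisfied_count": self.satisfied_count,
            "raw_log_bf": self.raw_log_bayes_factor,
            "adjusted_log_bf": self.adjusted_log_bayes_factor,
        }


@dataclass(frozen=True)
class SampleOutcome:
    """One monitored sample: the verdict plus its perturbation metadata."""

    satisfied: bool
    theta: Optional[np.ndarray] = None
    log_weight: float = 0.0


def log_bayes_factor(x: int, n: int, spec: TestSpec) -> float:
    """log B for x successes in n trials; ±inf when one side underflows.

    Both posterior tails are computed directly with the regularized
    incomplete beta function (the upper tail through its complement
    identity), so neither side loses precision to cancellation.
    """
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    a = spec.prior_alpha + x
    b = spec.prior_beta + n - x
    below = betainc(a, b, spec.theta0)  # posterior mass on [0, θ₀)
    above = betainc(b, a, 1.0 - spec.theta0)  # posterior mass on (θ₀, 1]
    if below == 0.0:
        return math.inf
    if above == 0.0:
        return -math.inf
    return math.log(above) - math.log(below)


def bayes_factor(x: int, n: int, spec: TestSpec) -> float:
    """Bayes factor B = (1 − I)/I with I the posterior CDF at θ₀.

    Saturates to ±infinity/0 when the log Bayes factor leaves the range
    representable in double precision.
    """
    try:
        return math.exp(log_bayes_factor(x, n, spec))
    except OverflowError:
        return math.inf


def posterior_prob_below(x: int, n: int, theta0: float, spec: TestSpec) -> float:
    """Posterior probability P(ρ < θ₀ | x, n) = I_{θ₀}(α + x, β + n − x)."""
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    if not 0.0 < theta0 < 1.0:
        raise ValueError("theta0 must lie strictly between 0 and 1")
    return float(betainc(spec.prior_alpha + x, spec.prior_beta + n - x, theta0))


def adjust_bayes_factor(log_b: float, eta: float, n: int) -> float:
    """Shrink log B toward 0 by the η-fairness penalty 2 n log η.

    The correction divides B by η^{2n} when B > 1 and multiplies it by
    η^{2n} when B < 1; it is clamped so that it never crosses zero (the
    penalty may neutralize the evidence, never reverse it).
    """
    if eta < 1:
        raise ValueError("eta must be at least 1")
    if n < 0:
        raise ValueError("n must be non-negative")
    penalty = 2.0 * n * math.log(eta)
    if log_b > 0:
        return max(log_b - penalty, 0.0)
    if log_b < 0:
        return min(log_b + penalty, 0.0)
    return 0.0


def check_fairness(bias_factors: Sequence[float], eta: float) -> bool:
    """Is the geometric mean of the per-sample bias factors within [1/η, η]?

    ``bias_factors`` are explicit Radon–Nikodym derivatives, available only
    for models with tractable measures (e.g. the discrete two-outcome
    fixture).  An empty history is vacuously fair (with a warning).
    """
    if eta < 1:
        raise ValueError("eta must be at least 1")
    factors = np.asarray(list(bias_factors), dtype=float)
    if factors.size == 0:
        warnings.warn("empty bias history: fairness is vacuously true")
        return True
    if np.any(factors <= 0):
        raise ValueError("bias factors must be positive")
    mean_log = float(np.mean(np.log(factors)))
    return abs(mean_log) <= math.log(eta) + 1e-12


def eventually_fair(eta: float, concentration_b: float) -> bool:
    """Termination condition for the corrected test: η⁴ < e^b (strictly)."""
    if eta < 1:
        raise ValueError("eta must be at least 1")
    if concentration_b <= 0:
        raise ValueError("concentration_b must be positive")
    return 4.0 * math.log(eta) < concentration_b


def sequential_verify(
    sampler: Iterable,
    spec: TestSpec,
    keep_history: bool = False,
    audit: Optional[list] = None,
) -> TestResult:
    """Run the sequential test until a hypothesis is accepted or the budget ends.

    Parameters
    ----------
    sampler
        Iterable of outcomes; each item is a bool or a :class:`SampleOutcome`.
        Exhaustion of the iterable before a decision counts as running out
        of budget.
    keep_history
        Retain per-sample records on the returned state (memory-heavy).
    audit
        Optional list that receives one dict per sample
        (index, outcome, theta, log_weight, running log Bayes factors).

    The loop per sample: update (n, x); compute the raw log Bayes factor;
    shrink it by the η^{2n} penalty; accept H₀ when the adjusted factor
    exceeds T, H₁ when it drops below 1/T (strict comparisons — a tie keeps
    sampling).
    """
    log_t = math.log(spec.bayes_threshold)
    state = TestState(history=[] if keep_history else None)
    raw = log_bayes_factor(0, 0, spec)
    adjusted = adjust_bayes_factor(raw, spec.eta, 0)

    iterator: Iterator = iter(sampler)
    while state.n < spec.max_samples:
        try:
            item = next(iterator)
        except StopIteration:
            break
        outcome = item if isinstance(item, SampleOutcome) else SampleOutcome(bool(item))
        state.n += 1
        state.x += int(outcome.satisfied)
        raw = log_bayes_factor(state.x, state.n, spec)
        adjusted = adjust_bayes_factor(raw, spec.eta, state.n)
        state.log_bayes_factor = raw
        if state.history is not None:
            state.history.append(outcome)
        if audit is not None:
            theta = outcome.theta
            audit.append(
                {
                    "sample_index": state.n,
                    "outcome": int(outcome.satisfied),
                    "theta": None if theta is None else np.asarray(theta).tolist(),
                    "log_weight": outcome.log_weight,
                    "running_log_bf": raw,
                    "running_adjusted_log_bf": adjusted,
                }
            )
        if adjusted > log_t:
            return TestResult("accept_H0", state.n, state.x, raw, adjusted)
        if adjusted < -log_t:
            return TestResult("accept_H1", state.n, state.x, raw, adjusted)
    return TestResult("undecided", state.n, state.x, raw, adjusted)
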