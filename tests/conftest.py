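"""Shared generators for randomized monitor tests."""

import numpy as np
import pytest

from sdesmc.bltl import And, Atom, Not, Or, Trace, Until

VARIABLES = ("x", "y")


def random_formula(rng: np.random.Generator, depth: int):
    """Random formula over VARIABLES with nesting depth at most ``depth``.

    Thresholds are drawn from a small integer set so that equality atoms
    have a real chance of being true on integer-valued traces.
    """
    kinds = ["atom"] if depth <= 0 else ["atom", "not", "and", "or", "until"]
    kind = kinds[rng.integers(len(kinds))]
    if kind == "atom":
        return Atom(
            variable=VARIABLES[rng.integers(len(VARIABLES))],
            relation="<>="[rng.integers(3)],
            threshold=float(rng.integers(0, 5)),
        )
    if kind == "not":
        return Not(random_formula(rng, depth - 1))
    left = random_formula(rng, depth - 1)
    if kind == "and":
        return And(left, random_formula(rng, depth - 1))
    if kind == "or":
        return Or(left, random_formula(rng, depth - 1))
    return Until(left, random_formula(rng, depth - 1), bound=float(rng.integers(0, 8)))


def random_trace(rng: np.random.Generator, max_states: int = 8) -> Trace:
    """Random integer-valued trace with small integer durations."""
    n = int(rng.integers(1, max_states + 1))
    states = rng.integers(0, 5, size=(n, len(VARIABLES))).astype(float)
    durations = rng.integers(0, 4, size=n).astype(float)
    durations[-1] = 0.0
    return Trace(states=states, durations=durations, variable_names=VARIABLES)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
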