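"""Bounded Linear Temporal Logic over finite timed traces.

A trace is an alternating sequence of states and durations,
``σ = (s₀, Δ₀), (s₁, Δ₁), …``.  Formulas are built from numeric atoms
``x ~ v`` (``~`` one of ``<``, ``>``, ``=``), Boolean connectives, and the bounded
Until ``φ₁ U[t] φ₂``:  ``σ^k ⊨ φ₁ U[t] φ₂`` iff some witness index ``k+i``
satisfies ``φ₂``, every strictly earlier index from ``k`` satisfies ``φ₁``,
and the elapsed time to *reach* the witness, ``Σ_{0≤l<i} Δ_{k+l}``, is at
most ``t``.  ``F[t] φ`` ("eventually within t") and ``G[t] φ`` ("always
within t") are derived operators, desugared at parse time.

Semantics on a finite trace are two-valued: a bounded Until with no witness
inside the trace is false.

Two evaluators are provided: :func:`satisfies`, which evaluates each subtree
as a vector over all start indices in linear time, and
:func:`brute_force_satisfies`, a deliberately naive recursive transcription
of the semantic rules kept as an independent test oracle.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "Trace",
    "Formula",
    "Atom",
    "Not",
    "And",
    "Or",
    "Until",
    "FormulaSyntaxError",
    "parse_formula",
    "satisfies",
    "brute_force_satisfies",
    "formula_variables",
    "formula_time_bound",
]


@dataclass(frozen=True)
class Trace:
    """Finite timed trace: one duration per state (the last is typically 0)."""

    states: np.ndarray
    durations: np.ndarray
    variable_names: tuple[str, ...]

    def __post_init__(self) -> None:
        states = np.atleast_2d(np.asarray(self.states, dtype=float))
        durations = np.atleast_1d(np.asarray(self.durations, dtype=float))
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "durations", durations)
        object.__setattr__(self, "variable_names", tuple(self.variable_names))
        if len(states) != len(durations) or len(states) < 1:
            raise ValueError("need equal, positive numbers of states and durations")
        if np.any(durations < 0) or not np.all(np.isfinite(durations)):
            raise ValueError("durations must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())

    def values(self, name: str) -> np.ndarray:
        """Column of variable ``name``; V(σ, ·, name)."""
        try:
            j = self.variable_names.index(name)
        except ValueError:
            raise LookupError(
                f"unknown variable {name!r}; trace has {self.variable_names}"
            ) from None
        return self.states[:, j]


# ---------------------------------------------------------------------------
# Abstract syntax


@dataclass(frozen=True)
class Atom:
    variable: str
    relation: str  # one of < > =
    threshold: float

    def __str__(self) -> str:
        return f"{self.variable} {self.relation} {self.threshold:g}"


@dataclass(frozen=True)
class Not:
    child: "Formula"

    def __str__(self) -> str:
        return f"!({self.child})"


@dataclass(frozen=True)
class And:
    left: "Formula"
    right: "Formula"

    def __str__(self) -> str:
        return f"({self.left}) & ({self.right})"


@dataclass(frozen=True)
class Or:
    left: "Formula"
    right: "Formula"

    def __str__(self) -> str:
        return f"({self.left}) | ({self.right})"


@dataclass(frozen=True)
class Until:
    left: "Formula"
    right: "Formula"
    bound: float

    def __post_init__(self) -> None:
        if self.bound < 0:
            raise ValueError("Until bound must be non-negative")

    def __str__(self) -> str:
        return f"({self.left}) U[{self.bound:g}] ({self.right})"


Formula = Union[Atom, Not, And, Or, Until]


def formula_variables(formula: Formula) -> set[str]:
    """All variable names referenced by atoms of ``formula``."""
    if isinstance(formula, Atom):
        return {formula.variable}
    if isinstance(formula, Not):
        return formula_variables(formula.child)
    return formula_variables(formula.left) | formula_variables(formula.right)


def formula_time_bound(formula: Formula) -> float:
    """Largest nesting-accumulated time bound (horizon needed to monitor)."""
    if isinstance(formula, Atom):
        return 0.0
    if isinstance(formula, Not):
        return formula_time_bound(formula.child)
    inner = max(formula_time_bound(formula.left), formula_time_bound(formula.right))
    if isinstance(formula, Until):
        return formula.bound + inner
    return inner


# ---------------------------------------------------------------------------
# Parser (recursive descent)
#
# formula := or ;  or := and ('|' and)* ;  and := unary ('&' unary)*
# unary   := '!' unary | atom | group | 'F[' num ']' group | 'G[' num ']' group
# group   := '(' formula ')'  [ 'U[' num ']' group ]      (Until needs parens)
# atom    := ident ('<'|'>'|'=') number


class FormulaSyntaxError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN = re.compile(
    r"\s*(?:(?P<num>[0-9]+(?:\.[0-9]*)?(?:[eE][+-]?[0-9]+)?|\.[0-9]+(?:[eE][+-]?[0-9]+)?)"
    r"|(?P<ident>[A-Za-z_][A-Za-z_0-9]*)"
    r"|(?P<op>[!&|()<>=\[\]]))"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise FormulaSyntaxError(f"unexpected character {text[pos]!r}", pos)
        pos = m.end()
        for kind in ("num", "ident", "op"):
            tok = m.group(kind)
            if tok is not None:
                tokens.append((kind, tok, m.start(kind)))
                break
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None, len(self.text))

    def _next(self):
        tok = self._peek()
        self.i += 1
        return tok

    def _expect(self, value: str):
        kind, tok, pos = self._next()
        if tok != value:
            raise FormulaSyntaxError(f"expected {value!r}, found {tok!r}", pos)

    def parse(self) -> Formula:
        node = self._or()
        kind, tok, pos = self._peek()
        if kind is not None:
            raise FormulaSyntaxError(f"trailing input {tok!r}", pos)
        return node

    def _or(self) -> Formula:
        node = self._and()
        while self._peek()[1] == "|":
            self._next()
            node = Or(node, self._and())
        return node

    def _and(self) -> Formula:
        node = self._unary()
        while self._peek()[1] == "&":
            self._next()
            node = And(node, self._unary())
        return node

    def _bound(self) -> float:
        self._expect("[")
        kind, tok, pos = self._next()
        if kind != "num":
            raise FormulaSyntaxError(f"expected a numeric bound, found {tok!r}", pos)
        self._expect("]")
        return float(tok)

    def _group(self) -> Formula:
        self._expect("(")
        node = self._or()
        self._expect(")")
        return node

    def _unary(self) -> Formula:
        kind, tok, pos = self._peek()
        if tok == "!":
            self._next()
            return Not(self._unary())
        if kind == "ident" and tok in ("F", "G") and self._lookahead_is_bound():
            self._next()
            bound = self._bound()
            child = self._group()
            if tok == "F":
                return _eventually(child, bound)
            return _always(child, bound)
        if tok == "(":
            node = self._group()
            if self._peek()[1] == "U":
                self._next()
                bound = self._bound()
                right = self._group()
                return Until(node, right, bound)
            return node
        if kind == "ident":
            return self._atom()
        raise FormulaSyntaxError(f"unexpected token {tok!r}", pos)

    def _lookahead_is_bound(self) -> bool:
        nxt = self.tokens[self.i + 1] if self.i + 1 < len(self.tokens) else None
        return nxt is not None and nxt[1] == "["

    def _atom(self) -> Atom:
        kind, name, pos = self._next()
        if kind != "ident":
            raise FormulaSyntaxError(f"expected a variable name, found {name!r}", pos)
        kind, rel, pos = self._next()
        if rel not in ("<", ">", "="):
            raise FormulaSyntaxError(
                f"expected a relation (<, >, =) after {name!r}, found {rel!r}", pos
            )
        kind, num, pos = self._next()
        if kind != "num":
            raise FormulaSyntaxError(f"expected a number, found {num!r}", pos)
        return Atom(name, rel, float(num))


def _eventually(child: Formula, bound: float) -> Until:
    # F[t] φ  ≡  (φ ∨ ¬φ) U[t] φ  — the left side is a tautology built from φ.
    return Until(Or(child, Not(child)), child, bound)


def _always(child: Formula, bound: float) -> Not:
    # G[t] φ  ≡  ¬ F[t] ¬φ
    return Not(_eventually(Not(child), bound))


def parse_formula(text: str) -> Formula:
    """Parse a formula string into its syntax tree.

    Precedence ``!`` > ``&`` > ``|``; Until is non-associative and both of
    its operands must be parenthesized, e.g. ``(x > 0) U[5] (y < 1)``.
    """
    return _Parser(text).parse()


# ---------------------------------------------------------------------------
# Evaluation


def _evaluate_all(formula: Formula, trace: Trace, elapsed: np.ndarray) -> np.ndarray:
    """Verdict of ``formula`` at every start index, as a boolean vector.

    ``elapsed[i]`` is the cumulative duration of states ``0 … i−1``, so the
    time needed to reach index ``m`` from ``k`` is ``elapsed[m] − elapsed[k]``.
    The Until verdict uses the earliest admissible witness: since durations
    are non-negative, elapsed time to any later witness can only be larger,
    so if the earliest witness misses the bound every witness does.
    """
    n = len(trace)
    if isinstance(formula, Atom):
        column = trace.values(formula.variable)
        if formula.relation == "<":
            return column < formula.threshold
        if formula.relation == ">":
            return column > formula.threshold
        return column == formula.threshold
    if isinstance(formula, Not):
        return ~_evaluate_all(formula.child, trace, elapsed)
    if isinstance(formula, And):
        return _evaluate_all(formula.left, trace, elapsed) & _evaluate_all(
            formula.right, trace, elapsed
        )
    if isinstance(formula, Or):
        return _evaluate_all(formula.left, trace, elapsed) | _evaluate_all(
            formula.right, trace, elapsed
        )
    # Until
    left = _evaluate_all(formula.left, trace, elapsed)
    right = _evaluate_all(formula.right, trace, elapsed)
    witness = _next_true_index(right)  # earliest m ≥ k with φ₂
    break_at = _next_true_index(~left)  # earliest m ≥ k with ¬φ₁
    has_witness = witness < n
    safe = np.minimum(witness, n - 1)
    within = (elapsed[safe] - elapsed) <= formula.bound
    return has_witness & (break_at >= witness) & within


def _next_true_index(mask: np.ndarray) -> np.ndarray:
    """For each position k, the smallest index m ≥ k with mask[m], else n."""
    n = len(mask)
    idx = np.where(mask, np.arange(n), n)
    return np.minimum.accumulate(idx[::-1])[::-1]


def satisfies(formula: Formula, trace: Trace, k: int = 0) -> bool:
    """Decide ``σ^k ⊨ φ`` on a finite trace."""
    n = len(trace)
    if not 0 <= k < n:
        raise IndexError(f"start index {k} outside trace of length {n}")
    elapsed = np.concatenate(([0.0], np.cumsum(trace.durations[:-1])))
    return bool(_evaluate_all(formula, trace, elapsed)[k])


def brute_force_satisfies(formula: Formula, trace: Trace, k: int = 0) -> bool:
    """Independent oracle: literal recursion over the semantic rules.

    No sharing, no vectorization, no early exit beyond what the quantifiers
    themselves require; used to cross-check :func:`satisfies` in tests.
    """
    n = len(trace)
    if not 0 <= k < n:
        raise IndexError(f"start index {k} outside trace of length {n}")
    if isinstance(formula, Atom):
        value = float(trace.values(formula.variable)[k])
        if formula.relation == "<":
            return value < formula.threshold
        if formula.relation == ">":
            return value > formula.threshold
        return value == formula.threshold
    if isinstance(formula, Not):
        return not brute_force_satisfies(formula.child, trace, k)
    if isinstance(formula, And):
        return brute_force_satisfies(formula.left, trace, k) and brute_force_satisfies(
            formula.right, trace, k
        )
    if isinstance(formula, Or):
        return brute_force_satisfies(formula.left, trace, k) or brute_force_satisfies(
            formula.right, trace, k
        )
    for i in range(n - k):
        time_to_reach = float(np.sum(trace.durations[k : k + i]))
        if (
            time_to_reach <= formula.bound
            and brute_force_satisfies(formula.right, trace, k + i)
            and all(
                brute_force_satisfies(formula.left, trace, k + j) for j in range(i)
            )
        ):
            return True
    return False
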