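"""Shared fixtures and independent oracles for the test suite.

The naive recursive BLTL evaluator below is written directly from the
semantic clauses and deliberately shares no code with the package's
memoized bottom-up monitor, so the two can check each other.
"""

from __future__ import annotations

import operator

import numpy as np
import pytest

from smcsynth.logic import Formula, Kind, State, Trace

_OPS = {"<=": operator.le, ">=": operator.ge, "<": operator.lt,
        ">": operator.gt, "==": operator.eq, "!=": operator.ne}


def naive_evaluate(trace: Trace, f: Formula, i: int) -> bool:
    """Direct recursion over the semantic clauses (independent oracle)."""
    if f.kind is Kind.ATOM:
        if f.atom is not None:
            return f.atom in trace[i].labels
        var, op, val = f.comparison
        return _OPS[op](trace[i].valuation[var], val)
    if f.kind is Kind.NOT:
        return not naive_evaluate(trace, f.children[0], i)
    if f.kind is Kind.AND:
        return naive_evaluate(trace, f.children[0], i) and naive_evaluate(trace, f.children[1], i)
    if f.kind is Kind.OR:
        return naive_evaluate(trace, f.children[0], i) or naive_evaluate(trace, f.children[1], i)
    if f.kind is Kind.FINALLY:
        return any(naive_evaluate(trace, f.children[0], i + l) for l in range(f.bound + 1))
    if f.kind is Kind.GLOBALLY:
        return all(naive_evaluate(trace, f.children[0], i + l) for l in range(f.bound + 1))
    # UNTIL: exists l <= d with phi2 at i+l and phi1 at all j < l
    a, b = f.children
    for l in range(f.bound + 1):
        if naive_evaluate(trace, b, i + l):
            if all(naive_evaluate(trace, a, i + j) for j in range(l)):
                return True
    return False


def label_trace(labels_per_step, alphabet=("a", "b")) -> Trace:
    """Build a trace from per-step label collections (no valuations needed)."""
    states = []
    for labels in labels_per_step:
        labels = frozenset(labels)
        states.append(State(valuation={x: float(x in labels) for x in alphabet},
                            labels=labels))
    return Trace(states=states)


def random_formula(rng: np.random.Generator, atoms=("a", "b"), depth: int = 3,
                   max_bound: int = 3) -> Formula:
    """Random BLTL AST for fuzzing the monitor (seeded, depth-limited)."""
    if depth == 0 or rng.random() < 0.3:
        return Formula.atom_(str(rng.choice(atoms)))
    kind = rng.choice(["not", "and", "or", "until", "finally", "globally"])
    bound = int(rng.integers(0, max_bound + 1))
    if kind == "not":
        return Formula.not_(random_formula(rng, atoms, depth - 1, max_bound))
    if kind in ("and", "or"):
        left = random_formula(rng, atoms, depth - 1, max_bound)
        right = random_formula(rng, atoms, depth - 1, max_bound)
        return Formula.and_(left, right) if kind == "and" else Formula.or_(left, right)
    if kind == "until":
        left = random_formula(rng, atoms, depth - 1, max_bound)
        right = random_formula(rng, atoms, depth - 1, max_bound)
        return Formula.until(bound, left, right)
    child = random_formula(rng, atoms, depth - 1, max_bound)
    return (Formula.finally_(bound, child) if kind == "finally"
            else Formula.globally(bound, child))


def random_trace(rng: np.random.Generator, length: int, atoms=("a", "b")) -> Trace:
    steps = []
    for _ in range(length):
        steps.append([x for x in atoms if rng.random() < 0.5])
    return label_trace(steps, atoms)


@pytest.fixture
def bernoulli_fixture():
    from smcsynth.models import build_fixture

    return build_fixture("bernoulli")


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
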