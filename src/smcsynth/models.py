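"""Parameterized stochastic models and trace sampling.

A parameterized discrete-time Markov chain (ParDTMC) has a transition kernel
``P(s, s', omega)`` that depends on a real parameter vector ``omega`` drawn
from a bounded box (the :class:`ParameterSpace`).  Agent-based models whose
joint agent state evolves by a per-step stochastic update rule induce a
ParDTMC over joint states and are handled through the same sampler contract:
all the statistical machinery downstream only ever needs labeled traces.

Exhaustive path enumeration (and with it the exact satisfaction probability
``u = P(sigma |= phi)``) is provided purely as a small-instance oracle for
testing the sampling path; production verification is sampling-only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Hashable, Mapping, Optional, Sequence

import numpy as np

from .logic import AtomicProposition, Formula, State, Trace, required_horizon, evaluate

__all__ = [
    "ParameterSpace",
    "ParDTMC",
    "AgentModel",
    "PathDistribution",
    "Fixture",
    "sample_trace",
    "enumerate_paths",
    "exact_satisfaction_probability",
    "build_fixture",
    "trace_to_csv",
    "trace_from_csv",
    "FIXTURE_NAMES",
]

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class ParameterSpace:
    """Axis-aligned box of admissible parameter vectors."""

    names: tuple[str, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.lower) == len(self.upper)):
            raise ValueError("names/lower/upper length mismatch")
        if len(self.names) < 1:
            raise ValueError("parameter space must have dimension >= 1")
        if len(set(self.names)) != len(self.names):
            raise ValueError("parameter names must be unique")
        for name, lo, hi in zip(self.names, self.lower, self.upper):
            if not lo < hi:
                raise ValueError(f"bound for {name!r} must satisfy lower < upper")

    @property
    def dimension(self) -> int:
        return len(self.names)

    def validate(self, omega: Sequence[float]) -> np.ndarray:
        """Return omega as an array, or raise if out of bounds."""
        w = np.asarray(omega, dtype=float)
        if w.shape != (self.dimension,):
            raise ValueError(f"parameter point must have shape ({self.dimension},), got {w.shape}")
        lo = np.asarray(self.lower)
        hi = np.asarray(self.upper)
        if np.any(w < lo) or np.any(w > hi):
            bad = [self.names[i] for i in range(self.dimension) if not lo[i] <= w[i] <= hi[i]]
            raise ValueError(f"parameter(s) out of bounds: {bad}")
        return w

    def clip(self, omega: Sequence[float]) -> np.ndarray:
        return np.clip(np.asarray(omega, dtype=float), self.lower, self.upper)

    def sample_uniform(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lower, self.upper)

    def as_dict(self, omega: Sequence[float]) -> dict[str, float]:
        return dict(zip(self.names, map(float, omega)))


@dataclass
class ParDTMC:
    """Explicit-state parameterized DTMC with a proposition registry.

    ``transition(state, omega)`` returns the categorical successor
    distribution as a mapping; ``valuation(state)`` exposes the variables the
    propositions are predicates over.
    """

    states: Sequence[Hashable]
    init: Mapping[Hashable, float]
    transition: Callable[[Hashable, np.ndarray], Mapping[Hashable, float]]
    propositions: tuple[AtomicProposition, ...]
    space: ParameterSpace
    valuation: Callable[[Hashable], Mapping[str, float]] = field(
        default=lambda s: {"s": float(s)})
    name: str = "pardtmc"

    def __post_init__(self) -> None:
        total = float(sum(self.init.values()))
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"initial distribution sums to {total}, not 1")
        names = [p.name for p in self.propositions]
        if len(set(names)) != len(names):
            raise ValueError("proposition names must be unique")

    def label_state(self, state: Hashable) -> State:
        valuation = dict(self.valuation(state))
        labels = frozenset(p.name for p in self.propositions if p.holds(valuation))
        return State(valuation=valuation, labels=labels)


@dataclass
class AgentModel:
    """Agent-based model reducible to a ParDTMC over joint agent states.

    ``initial(omega, rng)`` draws the joint state; ``step(state, omega, rng)``
    advances it one tick.  The induced joint-state process is Markov because
    the update depends only on the current joint state.
    """

    n_agents: int
    initial: Callable[[np.ndarray, np.random.Generator], Hashable]
    step: Callable[[Hashable, np.ndarray, np.random.Generator], Hashable]
    propositions: tuple[AtomicProposition, ...]
    space: ParameterSpace
    valuation: Callable[[Hashable], Mapping[str, float]] = field(
        default=lambda s: {"s": float(s)})
    name: str = "agent-model"

    def label_state(self, state: Hashable) -> State:
        valuation = dict(self.valuation(state))
        labels = frozenset(p.name for p in self.propositions if p.holds(valuation))
        return State(valuation=valuation, labels=labels)


def _draw_categorical(dist: Mapping[Hashable, float], rng: np.random.Generator,
                      context: str) -> Hashable:
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    total = probs.sum()
    if abs(total - 1.0) > _ROW_TOL or np.any(probs < -_ROW_TOL):
        raise ValueError(f"non-normalized distribution in {context}: sums to {total}")
    # cumulative inverse transform keeps a single uniform per draw,
    # byte-reproducible across platforms
    u = rng.random()
    c = np.cumsum(probs)
    idx = int(np.searchsorted(c, u, side="right"))
    return keys[min(idx, len(keys) - 1)]


def sample_trace(model: ParDTMC | AgentModel, omega: Sequence[float],
                 horizon: int, rng: np.random.Generator) -> Trace:
    """Draw one labeled trace of ``horizon + 1`` states.

    ``s_0`` comes from the initial distribution; each successive state from
    the transition kernel at ``omega``.  Deterministic given the generator
    state.
    """
    if horizon < 0:
        raise ValueError("horizon must be nonnegative")
    w = model.space.validate(omega)
    meta = {"model": model.name, "omega": [float(x) for x in w]}
    if isinstance(model, AgentModel):
        state = model.initial(w, rng)
        raw = [state]
        for _ in range(horizon):
            state = model.step(state, w, rng)
            raw.append(state)
    else:
        state = _draw_categorical(model.init, rng, "init")
        raw = [state]
        for _ in range(horizon):
            state = _draw_categorical(model.transition(state, w), rng,
                                      f"transition from {state!r}")
            raw.append(state)
    return Trace(states=[model.label_state(s) for s in raw], meta=meta)


@dataclass
class PathDistribution:
    """Exact finite-horizon path law: (state sequence, probability) pairs."""

    paths: list[tuple[tuple[Hashable, ...], float]]

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.paths)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"path probabilities sum to {total}, not 1")

    def __len__(self) -> int:
        return len(self.paths)


def enumerate_paths(model: ParDTMC, omega: Sequence[float], horizon: int,
                    cap: int = 10**6) -> PathDistribution:
    """Exhaustive fixed-horizon path enumeration (oracle only).

    Refuses outright when the path count bound ``|support(init)| * max
    out-degree ** horizon`` exceeds ``cap`` — this is deliberately not a
    production code path.
    """
    w = model.space.validate(omega)
    support = [s for s, p in model.init.items() if p > 0]
    max_deg = 1
    for s in model.states:
        max_deg = max(max_deg, sum(1 for p in model.transition(s, w).values() if p > 0))
    if len(support) * max_deg ** max(horizon, 0) > cap:
        raise ValueError(f"enumeration bound exceeds cap {cap}; refuse (oracle only)")

    frontier: list[tuple[tuple[Hashable, ...], float]] = [
        ((s,), float(model.init[s])) for s in support]
    for _ in range(horizon):
        nxt = []
        for path, prob in frontier:
            dist = model.transition(path[-1], w)
            row_sum = float(sum(dist.values()))
            if abs(row_sum - 1.0) > _ROW_TOL:
                raise ValueError(f"transition row from {path[-1]!r} sums to {row_sum}")
            for s, p in dist.items():
                if p > 0:
                    nxt.append((path + (s,), prob * float(p)))
        frontier = nxt
    return PathDistribution(paths=frontier)


def exact_satisfaction_probability(model: ParDTMC, omega: Sequence[float],
                                   formula: Formula, cap: int = 10**6) -> float:
    """Exact ``u(omega) = P(sigma |= phi)`` by path enumeration at the
    formula's horizon; desk-scale oracle for the statistical checker."""
    horizon = required_horizon(formula)
    dist = enumerate_paths(model, omega, horizon, cap=cap)
    total = 0.0
    for path, prob in dist.paths:
        trace = Trace(states=[model.label_state(s) for s in path])
        if evaluate(trace, formula, 0):
            total += prob
    return total


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    """A ParDTMC with a canonical formula and the closed-form u(omega)."""

    model: ParDTMC
    formula: Formula
    true_probability: Callable[[Sequence[float]], float]


def _three_state_bernoulli(p_of: Callable[[np.ndarray], float],
                           space: ParameterSpace, name: str) -> ParDTMC:
    # states: 0 = start, 1 = success, 2 = fail; success/fail absorbing
    def transition(state, omega):
        if state == 0:
            p = float(p_of(omega))
            return {1: p, 2: 1.0 - p}
        return {state: 1.0}

    return ParDTMC(
        states=[0, 1, 2],
        init={0: 1.0},
        transition=transition,
        propositions=(AtomicProposition("success", lambda v: v["s"] == 1.0),),
        space=space,
        name=name,
    )


FIXTURE_NAMES = ("bernoulli", "logistic-bernoulli", "small-chain")


def build_fixture(name: str, **settings) -> Fixture:
    """Built-in ParDTMC fixtures with documented closed-form satisfaction
    probabilities.

    - ``bernoulli``: 1-D omega in [0,1]; canonical formula ``F[1](success)``
      with u(omega) = omega exactly.
    - ``logistic-bernoulli``: 2-D omega in [-3,3]^2; u(omega) =
      sigmoid(omega_0 + omega_1); u = 1/2 at the midpoint (0, 0).
    - ``small-chain``: fixed 3-state kernel, rows (0.5,0.5,0), (0,0.2,0.8),
      (0,0,1); canonical formula ``F[2](terminal)`` with u = 0.4 for every
      omega (the single dummy parameter is unused).
    """
    if name == "bernoulli":
        space = ParameterSpace(("p",), (0.0,), (1.0,))
        model = _three_state_bernoulli(lambda w: w[0], space, "bernoulli")
        from .logic import parse_formula
        return Fixture(model, parse_formula("F[1](success)"),
                       lambda w: float(np.asarray(w, dtype=float)[0]))
    if name == "logistic-bernoulli":
        space = ParameterSpace(("w0", "w1"), (-3.0, -3.0), (3.0, 3.0))

        def u(w):
            w = np.asarray(w, dtype=float)
            return float(1.0 / (1.0 + math.exp(-(w[0] + w[1]))))

        model = _three_state_bernoulli(lambda w: u(w), space, "logistic-bernoulli")
        from .logic import parse_formula
        return Fixture(model, parse_formula("F[1](success)"), u)
    if name == "small-chain":
        space = ParameterSpace(("unused",), (0.0,), (1.0,))
        kernel = {0: {0: 0.5, 1: 0.5}, 1: {1: 0.2, 2: 0.8}, 2: {2: 1.0}}
        model = ParDTMC(
            states=[0, 1, 2],
            init={0: 1.0},
            transition=lambda s, w: kernel[s],
            propositions=(AtomicProposition("terminal", lambda v: v["s"] == 2.0),),
            space=space,
            name="small-chain",
        )
        from .logic import parse_formula
        # reach state 2 within 2 steps from 0: only path 0->1->2, 0.5 * 0.8
        return Fixture(model, parse_formula("F[2](terminal)"), lambda w: 0.4)
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


# ---------------------------------------------------------------------------
# Trace CSV I/O
# ---------------------------------------------------------------------------

def trace_to_csv(trace: Trace, path) -> None:
    """Write ``step,<var1>,<var2>,...`` rows; labels are not stored (they are
    recomputed from registered propositions on load)."""
    import csv

    variables = sorted(trace[0].valuation.keys())
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["step"] + variables)
        for i, state in enumerate(trace.states):
            writer.writerow([i] + [repr(float(state.valuation[v])) for v in variables])


def trace_from_csv(path, propositions: Sequence[AtomicProposition] = ()) -> Trace:
    """Read a trace CSV, recomputing labels from the given propositions."""
    import csv

    states = []
    with open(path, "r", newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            valuation = {k: float(v) for k, v in row.items() if k != "step"}
            labels = frozenset(p.name for p in propositions if p.holds(valuation))
            states.append(State(valuation=valuation, labels=labels))
    return Trace(states=states, meta={"source": str(path)})
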