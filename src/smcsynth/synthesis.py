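"""Simulated-annealing parameter synthesis driven by checker sample counts.

The search looks for a parameter point omega at which the model satisfies a
PBLTL specification P_{>= theta}(phi).  Every candidate is submitted to the
Bayesian sequential checker; an accept ends the search immediately.  When the
candidate is rejected, the *number of samples the checker needed to reject*
is used as the fitness signal: rejection takes more samples the closer the
point's true satisfaction probability is to theta, so "hard to reject" is a
proxy for "close to the satisfying region".  The annealer moves greedily to
candidates with larger sample counts and accepts worse candidates with
Metropolis probability exp(-(n - n') / t) under a strictly decreasing
temperature schedule.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .checking import (BetaPrior, Decision, IndifferenceRegion, PBLTLSpec,
                       Prior, TestResult, bsmc_verify, model_sampler)
from .models import ParameterSpace

__all__ = [
    "AnnealingSchedule",
    "NeighborhoodPolicy",
    "SynthesisResult",
    "TrajectoryRecord",
    "neighbor",
    "accept_move",
    "synthesize",
]


@dataclass(frozen=True)
class AnnealingSchedule:
    """Geometric cooling t_k = t_start * gamma^k, stopping below t_stop.

    Any strictly decreasing positive schedule is admissible; override
    ``cooling`` with a custom callable of the iteration count if geometric
    decay does not fit.
    """

    t_start: float = 100.0
    t_stop: float = 1.0
    gamma: float = 0.95
    cooling: Optional[Callable[[int], float]] = None

    def __post_init__(self) -> None:
        if self.t_start <= 0 or not 0 < self.t_stop <= self.t_start:
            raise ValueError("need 0 < t_stop <= t_start")
        if self.cooling is None and not 0 < self.gamma < 1:
            raise ValueError("geometric cooling needs 0 < gamma < 1")

    def temperature(self, lcount: int) -> float:
        if self.cooling is not None:
            return float(self.cooling(lcount))
        return self.t_start * self.gamma ** lcount


@dataclass(frozen=True)
class NeighborhoodPolicy:
    """Gaussian proposal: per-dimension sd = scale * (upper - lower), either
    perturbing one uniformly chosen coordinate or all of them; out-of-box
    proposals are clipped back to the bounds."""

    scale: float = 0.1
    mode: str = "all"  # "all" | "one"

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("scale must be nonnegative")
        if self.mode not in ("all", "one"):
            raise ValueError("mode must be 'all' or 'one'")


def neighbor(omega: Sequence[float], space: ParameterSpace,
             policy: NeighborhoodPolicy, rng: np.random.Generator) -> np.ndarray:
    """Random in-bounds neighbor of omega under the policy (symmetric
    Gaussian step before clipping)."""
    w = space.validate(omega)
    ranges = np.asarray(space.upper) - np.asarray(space.lower)
    if policy.scale == 0.0:
        return w.copy()
    if policy.mode == "one":
        step = np.zeros_like(w)
        i = int(rng.integers(space.dimension))
        step[i] = rng.normal(0.0, policy.scale * ranges[i])
    else:
        step = rng.normal(0.0, policy.scale * ranges)
    return space.clip(w + step)


def accept_move(n_current: int, n_candidate: int, temperature: float,
                rng: np.random.Generator) -> bool:
    """Annealing move rule on the sample-count fitness.

    Larger candidate counts are always taken (greedy uphill); equal or worse
    counts are taken with Metropolis probability exp(-(n - n') / t), so ties
    are always accepted and high temperature tolerates worse moves.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if n_candidate > n_current:
        return True
    return rng.random() < math.exp(-(n_current - n_candidate) / temperature)


@dataclass
class TrajectoryRecord:
    iteration: int
    omega: tuple[float, ...]
    decision: str
    n: int
    z: int
    temperature: float
    accepted: bool


@dataclass
class SynthesisResult:
    """Outcome of one annealing search.

    ``found`` status is backed by the final checker call recorded in the
    trajectory having accepted H0 at ``omega``; ``not_found`` means the
    temperature fell below the stop temperature with no accept.
    """

    status: str  # "found" | "not_found"
    omega: Optional[tuple[float, ...]]
    trajectory: list[TrajectoryRecord] = field(default_factory=list)
    checker_calls: int = 0
    final_result: Optional[TestResult] = None

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "omega": list(self.omega) if self.omega is not None else None,
            "checker_calls": self.checker_calls,
            "final_result": self.final_result.to_dict() if self.final_result else None,
        }

    def to_json(self, path) -> None:
        payload = self.to_dict()
        payload["trajectory"] = [vars(r) | {"omega": list(r.omega)} for r in self.trajectory]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    def trajectory_frame(self):
        import pandas as pd

        rows = []
        for r in self.trajectory:
            row = {"iteration": r.iteration, "decision": r.decision, "n": r.n,
                   "z": r.z, "temperature": r.temperature, "accepted": r.accepted}
            for j, x in enumerate(r.omega):
                row[f"omega_{j}"] = x
            rows.append(row)
        return pd.DataFrame(rows)


def synthesize(model, spec: PBLTLSpec, *,
               schedule: AnnealingSchedule = AnnealingSchedule(),
               prior_family: Callable[[np.ndarray], Prior] = lambda w: BetaPrior(),
               bayes_threshold: float = 100.0,
               indifference: IndifferenceRegion = IndifferenceRegion.symmetric(0.05),
               policy: NeighborhoodPolicy = NeighborhoodPolicy(),
               max_samples: int = 10**4,
               max_iterations: int = 10**4,
               sampler_factory: Optional[Callable] = None,
               rng: Union[int, np.random.SeedSequence] = 0,
               ) -> SynthesisResult:
    """Search the model's parameter box for a point satisfying the spec.

    Starts from a uniform random point; returns on the first checker accept.
    Otherwise anneals: propose a neighbor, check it, move by
    :func:`accept_move` on the checker's sample count (a ``budget_exhausted``
    call counts as a non-accepting result with n = cap, logged distinctly),
    cool, and stop when the temperature drops below ``schedule.t_stop`` or
    after ``max_iterations`` proposals.

    ``prior_family`` maps the candidate point to the checker prior (the
    parameterized prior h(.)); ``sampler_factory(omega)``, when given,
    overrides the default per-point trace sampler — the hook the agent-based
    demo uses to bind dosing experiments.
    """
    if bayes_threshold <= 1.0:
        raise ValueError("bayes threshold L must exceed 1")
    space: ParameterSpace = model.space
    ss = (rng if isinstance(rng, np.random.SeedSequence)
          else np.random.SeedSequence(int(rng)))
    move_rng = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))

    def make_sampler(w: np.ndarray):
        if sampler_factory is not None:
            return sampler_factory(w)
        return model_sampler(model, w, spec.horizon)

    def check(w: np.ndarray) -> TestResult:
        return bsmc_verify(make_sampler(w), spec,
                           bayes_threshold=bayes_threshold,
                           prior=prior_family(w),
                           indifference=indifference,
                           max_samples=max_samples,
                           rng=ss.spawn(1)[0])

    trajectory: list[TrajectoryRecord] = []

    def log(iteration: int, w: np.ndarray, res: TestResult, t: float,
            accepted: bool) -> None:
        trajectory.append(TrajectoryRecord(
            iteration=iteration, omega=tuple(float(x) for x in w),
            decision=res.decision.value, n=res.n, z=res.z,
            temperature=t, accepted=accepted))

    omega = space.sample_uniform(move_rng)
    result = check(omega)
    t = schedule.t_start
    log(0, omega, result, t, True)
    if result.decision is Decision.ACCEPT_H0:
        return SynthesisResult("found", tuple(float(x) for x in omega),
                               trajectory, checker_calls=1, final_result=result)
    n_fitness = result.n

    lcount = 0
    calls = 1
    while lcount < max_iterations:
        lcount += 1
        t = schedule.temperature(lcount)
        if t < schedule.t_stop:
            break
        candidate = neighbor(omega, space, policy, move_rng)
        cand_result = check(candidate)
        calls += 1
        if cand_result.decision is Decision.ACCEPT_H0:
            log(lcount, candidate, cand_result, t, True)
            return SynthesisResult("found", tuple(float(x) for x in candidate),
                                   trajectory, checker_calls=calls,
                                   final_result=cand_result)
        accepted = accept_move(n_fitness, cand_result.n, t, move_rng)
        log(lcount, candidate, cand_result, t, accepted)
        if accepted:
            omega = candidate
            n_fitness = cand_result.n
    return SynthesisResult("not_found", None, trajectory,
                           checker_calls=calls, final_result=result)
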