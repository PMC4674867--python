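"""Sequential statistical model checking of PBLTL specifications.

Decides "does the model satisfy phi with probability at least theta?" by
drawing i.i.d. traces, monitoring each against the BLTL formula, and
sequentially testing

    H0: u >= theta + eps2     vs     H1: u <= theta - eps1

where ``u`` is the (unknown) satisfaction probability and
``[theta - eps1, theta + eps2]`` is the indifference region in which either
answer is acceptable.  The Bayesian test stops when the Bayes factor

    B = P(x_1..x_n | H0) / P(x_1..x_n | H1)
      = int_{theta+eps2}^{1} u^z (1-u)^(n-z) g(u) du
        / int_{0}^{theta-eps1} u^z (1-u)^(n-z) g(u) du

crosses L (accept H0) or 1/L (reject H0).  For a conjugate Beta(a, b) prior
the Beta-function normalizers cancel and

    B = (1 - I_{theta+eps2}(z+a, n-z+b)) / I_{theta-eps1}(z+a, n-z+b)

with I the regularized incomplete beta function; an arbitrary tabulated prior
falls back to adaptive quadrature.  A Wald SPRT with the same indifference
region serves as the classical baseline.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy import integrate, special

from .logic import Formula, Trace, evaluate, required_horizon

__all__ = [
    "Decision",
    "PBLTLSpec",
    "IndifferenceRegion",
    "BetaPrior",
    "TabulatedPrior",
    "SPRTConfig",
    "TestResult",
    "bayes_factor",
    "bsmc_verify",
    "sprt_verify",
    "sample_count_profile",
    "model_sampler",
]


class Decision(enum.Enum):
    ACCEPT_H0 = "accept_H0"
    REJECT_H0 = "reject_H0"
    BUDGET_EXHAUSTED = "budget_exhausted"


@dataclass(frozen=True)
class PBLTLSpec:
    """A BLTL formula plus a probability threshold theta."""

    formula: Formula
    theta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")

    @property
    def horizon(self) -> int:
        return required_horizon(self.formula)


@dataclass(frozen=True)
class IndifferenceRegion:
    """Half-widths (eps1 below theta, eps2 above); [u_l, u_r] around theta."""

    eps1: float
    eps2: float

    def __post_init__(self) -> None:
        if self.eps1 <= 0 or self.eps2 <= 0:
            raise ValueError("eps1 and eps2 must be positive")

    def bounds(self, theta: float) -> tuple[float, float]:
        u_l, u_r = theta - self.eps1, theta + self.eps2
        if u_l < 0 or u_r > 1:
            raise ValueError(
                f"indifference region [{u_l}, {u_r}] leaves [0, 1]; shrink eps")
        return u_l, u_r

    @staticmethod
    def symmetric(eps: float) -> "IndifferenceRegion":
        return IndifferenceRegion(eps, eps)


@dataclass(frozen=True)
class BetaPrior:
    """Conjugate Beta(a, b) prior on the unknown satisfaction probability."""

    a: float = 1.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta shapes must be positive")


@dataclass(frozen=True)
class TabulatedPrior:
    """Arbitrary prior density tabulated on a grid over [0, 1].

    Linearly interpolated between knots; normalized to integrate to 1 at
    construction (tolerance 1e-6 before renormalization is not enforced —
    any positive integrable table is accepted and scaled).
    """

    grid: tuple[float, ...]
    density: tuple[float, ...]

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        d = np.asarray(self.density)
        if g.ndim != 1 or g.shape != d.shape or g.size < 2:
            raise ValueError("grid and density must be matching 1-D arrays, size >= 2")
        if g[0] < 0 or g[-1] > 1 or np.any(np.diff(g) <= 0):
            raise ValueError("grid must be increasing within [0, 1]")
        if np.any(d < 0):
            raise ValueError("density must be nonnegative")
        mass = float(np.trapezoid(d, g))
        if not mass > 0:
            raise ValueError("density integrates to 0")
        if abs(mass - 1.0) > 1e-6:
            object.__setattr__(self, "density", tuple(float(x) / mass for x in d))

    def __call__(self, u: float) -> float:
        return float(np.interp(u, self.grid, self.density, left=0.0, right=0.0))


Prior = Union[BetaPrior, TabulatedPrior]


@dataclass(frozen=True)
class SPRTConfig:
    """Type-1 (alpha) and type-2 (beta) error bounds for the Wald SPRT."""

    alpha: float = 0.01
    beta: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise ValueError("alpha and beta must lie in (0, 1)")


@dataclass
class TestResult:
    """Outcome of one sequential test.

    ``statistic`` is the final Bayes factor (BSMC) or likelihood ratio
    (SPRT); ``log10_trajectory`` records log10 of the statistic after each
    sample.  ``satisfied`` translates the decision to the PBLTL question:
    H0 accepted means the model meets P_{>= theta}(phi).
    """

    decision: Decision
    n: int
    z: int
    statistic: float
    log10_trajectory: list[float] = field(default_factory=list)
    method: str = "bsmc"
    vacuous_h1: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.z <= self.n:
            raise ValueError("need 0 <= z <= n")

    @property
    def satisfied(self) -> Optional[bool]:
        if self.decision is Decision.ACCEPT_H0:
            return True
        if self.decision is Decision.REJECT_H0:
            return False
        return None

    def to_dict(self) -> dict:
        return {
            "decision": self.decision.value,
            "satisfied": self.satisfied,
            "n": self.n,
            "z": self.z,
            "statistic": self.statistic,
            "method": self.method,
            "vacuous_h1": self.vacuous_h1,
            "log10_trajectory": self.log10_trajectory,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Bayes factor
# ---------------------------------------------------------------------------

def _log_marginal_tabulated(n: int, z: int, lo: float, hi: float,
                            prior: TabulatedPrior) -> float:
    """log of int_lo^hi u^z (1-u)^(n-z) g(u) du, stabilized around the
    integrand's mode."""
    if hi <= lo:
        return -math.inf

    def log_kernel(u: float) -> float:
        if u <= 0.0:
            return 0.0 if z == 0 else -math.inf
        if u >= 1.0:
            return 0.0 if z == n else -math.inf
        return z * math.log(u) + (n - z) * math.log1p(-u)

    mode = min(max(z / n if n else 0.5, lo), hi)
    shift = log_kernel(mode) if math.isfinite(log_kernel(mode)) else 0.0

    def integrand(u: float) -> float:
        lk = log_kernel(u)
        return math.exp(lk - shift) * prior(u) if math.isfinite(lk) else 0.0

    val, _ = integrate.quad(integrand, lo, hi, limit=200)
    if val <= 0:
        return -math.inf
    return math.log(val) + shift


def bayes_factor(n: int, z: int, theta: float, eps1: float, eps2: float,
                 prior: Prior = BetaPrior()) -> float:
    """Bayes factor of H0: u >= theta+eps2 against H1: u <= theta-eps1 after
    observing z satisfactions in n Bernoulli trials.

    Returns ``inf`` when the H1 integral is exactly zero (theta - eps1 = 0:
    H1 is vacuous), which forces immediate H0 acceptance upstream.
    """
    if not 0 <= z <= n:
        raise ValueError("need 0 <= z <= n")
    u_l, u_r = theta - eps1, theta + eps2
    if u_l < 0 or u_r > 1:
        raise ValueError("indifference region leaves [0, 1]")
    if n == 0:
        pass  # prior mass ratio; handled by the same formulas below

    if isinstance(prior, BetaPrior):
        a, b = z + prior.a, n - z + prior.b
        # numerator: upper tail of Beta(a,b) beyond u_r, via the exact
        # complement to avoid 1 - (1 - tiny) cancellation
        num = float(special.betaincc(a, b, u_r)) if u_r < 1 else 0.0
        den = float(special.betainc(a, b, u_l)) if u_l > 0 else 0.0
    else:
        log_num = _log_marginal_tabulated(n, z, u_r, 1.0, prior)
        log_den = _log_marginal_tabulated(n, z, 0.0, u_l, prior)
        num = math.exp(log_num) if math.isfinite(log_num) else 0.0
        den = math.exp(log_den) if math.isfinite(log_den) else 0.0
        if math.isfinite(log_num) and math.isfinite(log_den):
            return math.exp(log_num - log_den)

    if den == 0.0:
        return math.inf
    return num / den


# ---------------------------------------------------------------------------
# Sequential procedures
# ---------------------------------------------------------------------------

TraceSampler = Callable[[np.random.Generator], Trace]


def model_sampler(model, omega, horizon: int) -> TraceSampler:
    """Bind a model and parameter point into the per-trace sampler contract."""
    from .models import sample_trace

    def sampler(rng: np.random.Generator) -> Trace:
        return sample_trace(model, omega, horizon, rng)

    return sampler


def _resolve_streams(rng) -> np.random.SeedSequence:
    """Normalize a seed / SeedSequence / Generator into a SeedSequence so the
    test can spawn one independent child stream per sampled trace."""
    if isinstance(rng, np.random.SeedSequence):
        return rng
    if isinstance(rng, np.random.Generator):
        # derive a child sequence from the generator deterministically
        return np.random.SeedSequence(int(rng.integers(0, 2**31 - 1)))
    return np.random.SeedSequence(int(rng))


def _log10_clip(x: float) -> float:
    if x == 0.0:
        return -math.inf
    if math.isinf(x):
        return math.inf
    return math.log10(x)


def bsmc_verify(sampler: TraceSampler, spec: PBLTLSpec, *,
                bayes_threshold: float = 100.0,
                prior: Prior = BetaPrior(),
                indifference: IndifferenceRegion = IndifferenceRegion.symmetric(0.05),
                max_samples: int = 10**5,
                rng: Union[int, np.random.SeedSequence, np.random.Generator] = 0,
                ) -> TestResult:
    """Bayesian sequential statistical model checking.

    Draws traces i.i.d. (one spawned RNG stream per trace), monitors each
    against ``spec.formula``, recomputes the Bayes factor after every draw,
    and stops at B > L (accept H0), B < 1/L (reject H0), or the sample cap
    (``budget_exhausted`` — a distinct outcome, never coerced to a verdict;
    the actual probability may lie inside the indifference region, where
    the test is allowed to run forever).
    """
    if bayes_threshold <= 1.0:
        raise ValueError("bayes threshold L must exceed 1")
    if max_samples < 1:
        raise ValueError("max_samples must be >= 1")
    u_l, u_r = indifference.bounds(spec.theta)
    ss = _resolve_streams(rng)
    n = z = 0
    trajectory: list[float] = []
    vacuous = u_l <= 0.0
    while n < max_samples:
        child = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))
        trace = sampler(child)
        n += 1
        if evaluate(trace, spec.formula, 0):
            z += 1
        B = bayes_factor(n, z, spec.theta, indifference.eps1, indifference.eps2, prior)
        trajectory.append(_log10_clip(B))
        if B > bayes_threshold:
            return TestResult(Decision.ACCEPT_H0, n, z, B, trajectory,
                              method="bsmc", vacuous_h1=vacuous)
        if B < 1.0 / bayes_threshold:
            return TestResult(Decision.REJECT_H0, n, z, B, trajectory,
                              method="bsmc", vacuous_h1=vacuous)
    return TestResult(Decision.BUDGET_EXHAUSTED, n, z, B, trajectory,
                      method="bsmc", vacuous_h1=vacuous)


def sprt_verify(sampler: TraceSampler, spec: PBLTLSpec, *,
                indifference: IndifferenceRegion = IndifferenceRegion.symmetric(0.05),
                errors: SPRTConfig = SPRTConfig(),
                max_samples: int = 10**5,
                rng: Union[int, np.random.SeedSequence, np.random.Generator] = 0,
                ) -> TestResult:
    """Wald sequential probability ratio test baseline.

    Tests H1: u <= u_l against H0: u >= u_r with the likelihood ratio
    Lambda_n = u_l^z (1-u_l)^(n-z) / (u_r^z (1-u_r)^(n-z)) in log space;
    accepts H1 (rejects H0) at Lambda >= (1-beta)/alpha and accepts H0 at
    Lambda <= beta/(1-alpha).
    """
    u_l, u_r = indifference.bounds(spec.theta)
    if not (0.0 < u_l and u_r < 1.0):
        raise ValueError("SPRT needs 0 < theta - eps1 and theta + eps2 < 1")
    upper = math.log((1.0 - errors.beta) / errors.alpha)
    lower = math.log(errors.beta / (1.0 - errors.alpha))
    step_sat = math.log(u_l / u_r)              # x_i = 1
    step_unsat = math.log((1.0 - u_l) / (1.0 - u_r))  # x_i = 0
    ss = _resolve_streams(rng)
    n = z = 0
    log_lambda = 0.0
    trajectory: list[float] = []
    while n < max_samples:
        child = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))
        trace = sampler(child)
        n += 1
        if evaluate(trace, spec.formula, 0):
            z += 1
            log_lambda += step_sat
        else:
            log_lambda += step_unsat
        trajectory.append(log_lambda / math.log(10.0))
        if log_lambda >= upper:
            return TestResult(Decision.REJECT_H0, n, z, math.exp(log_lambda),
                              trajectory, method="sprt")
        if log_lambda <= lower:
            return TestResult(Decision.ACCEPT_H0, n, z, math.exp(log_lambda),
                              trajectory, method="sprt")
    return TestResult(Decision.BUDGET_EXHAUSTED, n, z, math.exp(log_lambda),
                      trajectory, method="sprt")


# ---------------------------------------------------------------------------
# Sample-count profiles (efficiency curves)
# ---------------------------------------------------------------------------

def sample_count_profile(fixture, spec_theta: float, omegas: Sequence[Sequence[float]],
                         *, runs: int = 200, method: str = "bsmc",
                         bayes_threshold: float = 100.0,
                         prior: Prior = BetaPrior(),
                         indifference: IndifferenceRegion = IndifferenceRegion.symmetric(0.05),
                         errors: SPRTConfig = SPRTConfig(),
                         max_samples: int = 10**4,
                         rng: Union[int, np.random.SeedSequence] = 0):
    """Mean sample count versus true satisfaction probability on a fixture
    grid — the efficiency curve showing n blowing up as u(omega) approaches
    the threshold theta.

    Returns a pandas DataFrame with columns
    ``omega, u, mean_n, sd_n, accept_frac, exhausted_frac``.
    """
    import pandas as pd

    ss = _resolve_streams(rng)
    spec_cache: dict = {}
    rows = []
    for omega in omegas:
        w = fixture.model.space.validate(omega)
        spec = spec_cache.setdefault("spec", PBLTLSpec(fixture.formula, spec_theta))
        sampler = model_sampler(fixture.model, w, spec.horizon)
        counts = np.empty(runs)
        accepts = 0
        exhausted = 0
        for r in range(runs):
            child = ss.spawn(1)[0]
            if method == "bsmc":
                res = bsmc_verify(sampler, spec, bayes_threshold=bayes_threshold,
                                  prior=prior, indifference=indifference,
                                  max_samples=max_samples, rng=child)
            elif method == "sprt":
                res = sprt_verify(sampler, spec, indifference=indifference,
                                  errors=errors, max_samples=max_samples, rng=child)
            else:
                raise ValueError(f"unknown method {method!r}")
            counts[r] = res.n
            accepts += res.decision is Decision.ACCEPT_H0
            exhausted += res.decision is Decision.BUDGET_EXHAUSTED
        rows.append({
            "omega": ",".join(f"{x:g}" for x in w),
            "u": fixture.true_probability(w),
            "mean_n": float(counts.mean()),
            "sd_n": float(counts.std(ddof=1)) if runs > 1 else 0.0,
            "accept_frac": accepts / runs,
            "exhausted_frac": exhausted / runs,
        })
    return pd.DataFrame(rows)
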