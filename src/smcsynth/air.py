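"""Desk-scale agent-based model of the acute inflammatory response (AIR).

A discrete-time stochastic model of the response to lipopolysaccharide (LPS)
endotoxin dosing: resting macrophages activate on exposure to LPS,
pro-inflammatory mediators and tissue damage; active macrophages secrete a
pro-inflammatory mediator (the inflammation readout) and an anti-inflammatory
mediator that suppresses further activation and secretion and, above a
threshold, heals damage; damage is produced by the pro-mediator and feeds
back into both activation and mediator production; LPS and all mediators
decay by first-order evaporation.

The model exposes exactly the 28 named parameters of the published roster:
14 core rate/threshold parameters plus 14 dosing-schedule parameters for the
four endotoxin experiments (single low dose, single high dose, and two
double-dose schedules).  It is an explicitly labeled *interpretation* of the
original SPARK agent-based model, whose update rules are not public: each
parameter's name and role is honored, numeric fidelity to the original is a
non-goal, and the parameter box is chosen so that all four qualitative
behaviors — resolving inflammation, non-resolving inflammation, priming and
desensitization — are reachable somewhere inside it.

Four expert behavioral specifications in BLTL are encoded against threshold
atoms over the observables:

1. ``D_L -> F[d1](I & F[d2](N))``          (low dose, inflammation resolves)
2. ``D_H -> F[d3](G[d4](I_H))``            (high dose, never resolves)
3. ``D -> F[d5](I_L & F[d6](D -> F[d7](I_H)))``  (second response augmented)
4. ``D -> F[d8](I_H & F[d9](D -> F[d10](I_L)))`` (second response reduced)

The published numbered list labels formula 3 "desensitization" while the
results text pairs it with *priming* (an augmented second response, which is
what the formula literally says: I_L first, I_H after the second dose).  The
code keys everything by formula number, not by label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .checking import (BetaPrior, IndifferenceRegion, PBLTLSpec, bsmc_verify)
from .logic import AtomicProposition, Formula, State, Trace, parse_formula, evaluate
from .models import ParameterSpace
from .synthesis import (AnnealingSchedule, NeighborhoodPolicy, SynthesisResult,
                        synthesize)

__all__ = [
    "PARAMETER_NAMES",
    "AIRParameters",
    "SpecThresholds",
    "AIRModel",
    "default_parameter_space",
    "simulate_air",
    "build_propositions",
    "encode_specs",
    "guarded_formula",
    "run_case_study",
    "plot_traces",
]

#: The 28 parameter names of the published roster, in roster order.
PARAMETER_NAMES: tuple[str, ...] = (
    "LPS-evap", "mac-act-LPS", "mac-act-pro", "mac-regen", "mac-age",
    "mac-act-dam", "max-pro-dam", "pro-dam-thresh", "damage-evap",
    "anti-heal-thresh", "mac-anti", "anti-evap", "pro-evap", "mac-prop",
    "exp1-dose-time", "exp1-dose-duration", "exp1-dose-amount",
    "exp2-dose-time", "exp2-dose-duration", "exp2-dose-amount",
    "exp3-1st-dose-time", "exp3-2nd-dose-time", "exp3-doses-duration",
    "exp3-doses-amount",
    "exp4-1st-dose-time", "exp4-2nd-dose-time", "exp4-doses-duration",
    "exp4-doses-amount",
)

_EVAP_NAMES = ("LPS-evap", "damage-evap", "anti-evap", "pro-evap")

# Fixed internal constants of the interpretation (not synthesized):
_K_PRO = 1.0     # pro-mediator secreted per active macrophage per step
_K_DAM = 0.15    # damage produced per unit pro-mediator per step
_HEAL_FRAC = 0.5  # extra damage removal fraction when anti > anti-heal-thresh
_CAPACITY_PER_PROP = 10.0  # macrophage pool capacity per unit mac-prop


@dataclass(frozen=True)
class AIRParameters:
    """The 28-parameter vector, keyed exactly by the published names."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        got = tuple(self.values.keys())
        if set(got) != set(PARAMETER_NAMES) or len(got) != 28:
            missing = set(PARAMETER_NAMES) - set(got)
            extra = set(got) - set(PARAMETER_NAMES)
            raise ValueError(f"parameter roster mismatch: missing={sorted(missing)}, "
                             f"extra={sorted(extra)}")
        for name in _EVAP_NAMES:
            if not 0.0 <= self.values[name] <= 1.0:
                raise ValueError(f"{name} must be an evaporation fraction in [0, 1]")
        for name, v in self.values.items():
            if v < 0:
                raise ValueError(f"{name} must be nonnegative")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    @staticmethod
    def from_vector(omega: Sequence[float]) -> "AIRParameters":
        w = np.asarray(omega, dtype=float)
        if w.shape != (28,):
            raise ValueError("AIR parameter vector must have 28 entries")
        return AIRParameters(dict(zip(PARAMETER_NAMES, map(float, w))))

    def to_vector(self) -> np.ndarray:
        return np.array([self.values[n] for n in PARAMETER_NAMES])

    def doses(self, experiment: int) -> list[tuple[float, float, float]]:
        """(start time, duration, total amount) events for experiment 1-4."""
        v = self.values
        if experiment == 1:
            return [(v["exp1-dose-time"], v["exp1-dose-duration"], v["exp1-dose-amount"])]
        if experiment == 2:
            return [(v["exp2-dose-time"], v["exp2-dose-duration"], v["exp2-dose-amount"])]
        if experiment == 3:
            return [(v["exp3-1st-dose-time"], v["exp3-doses-duration"], v["exp3-doses-amount"]),
                    (v["exp3-2nd-dose-time"], v["exp3-doses-duration"], v["exp3-doses-amount"])]
        if experiment == 4:
            return [(v["exp4-1st-dose-time"], v["exp4-doses-duration"], v["exp4-doses-amount"]),
                    (v["exp4-2nd-dose-time"], v["exp4-doses-duration"], v["exp4-doses-amount"])]
        raise ValueError("experiment must be 1..4")


def default_parameter_space() -> ParameterSpace:
    """Search box for the 28 parameters (roster order).

    Rates and thresholds span ranges on the scale of the model's internal
    units (mediator units per macrophage per step); dose times are early in
    the trace so the dose atoms can anchor the monitored specifications.
    """
    bounds = {
        "LPS-evap": (0.05, 0.95),
        "mac-act-LPS": (0.01, 1.0),
        "mac-act-pro": (0.0, 0.5),
        "mac-regen": (0.0, 5.0),
        "mac-age": (2.0, 60.0),
        "mac-act-dam": (0.0, 0.5),
        "max-pro-dam": (0.0, 20.0),
        "pro-dam-thresh": (0.1, 10.0),
        "damage-evap": (0.01, 0.9),
        "anti-heal-thresh": (0.5, 10.0),
        "mac-anti": (0.0, 1.0),
        "anti-evap": (0.01, 0.9),
        "pro-evap": (0.05, 0.9),
        "mac-prop": (1.0, 10.0),
        "exp1-dose-time": (0.0, 3.0),
        "exp1-dose-duration": (1.0, 5.0),
        "exp1-dose-amount": (0.0, 60.0),
        "exp2-dose-time": (0.0, 3.0),
        "exp2-dose-duration": (1.0, 10.0),
        "exp2-dose-amount": (0.0, 300.0),
        "exp3-1st-dose-time": (0.0, 3.0),
        "exp3-2nd-dose-time": (5.0, 14.0),
        "exp3-doses-duration": (1.0, 5.0),
        "exp3-doses-amount": (0.0, 60.0),
        "exp4-1st-dose-time": (0.0, 3.0),
        "exp4-2nd-dose-time": (5.0, 14.0),
        "exp4-doses-duration": (1.0, 5.0),
        "exp4-doses-amount": (0.0, 60.0),
    }
    return ParameterSpace(
        names=PARAMETER_NAMES,
        lower=tuple(bounds[n][0] for n in PARAMETER_NAMES),
        upper=tuple(bounds[n][1] for n in PARAMETER_NAMES),
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _dose_at(doses: list[tuple[float, float, float]], t: int) -> float:
    """LPS administered during step t: each event spreads its total amount
    uniformly over ceil(duration) steps starting at floor(start time)."""
    total = 0.0
    for start, duration, amount in doses:
        first = int(math.floor(start))
        nsteps = max(int(math.ceil(duration)), 1)
        if first <= t < first + nsteps:
            total += amount / nsteps
    return total


def simulate_air(params: AIRParameters, horizon: int,
                 rng: Optional[np.random.Generator] = None, *,
                 experiment: int = 1, deterministic: bool = False,
                 initial_damage: float = 0.0) -> Trace:
    """Simulate one trace of ``horizon + 1`` states for a dosing experiment.

    State ``s_t`` records the observables *entering* step t together with
    ``dose``, the LPS administered during step t — so a dose scheduled at
    time 0 is visible at trace position 0, where the dose atoms anchor the
    behavioral specifications.  In deterministic mode every stochastic draw
    is replaced by its expectation (used for monotonicity/decay tests only).
    """
    if horizon < 0:
        raise ValueError("horizon must be nonnegative")
    if rng is None and not deterministic:
        raise ValueError("stochastic simulation needs an rng")
    v = params.values
    doses = params.doses(experiment)
    capacity = max(round(_CAPACITY_PER_PROP * v["mac-prop"]), 1)

    lps = 0.0
    m_rest: float = float(capacity)
    m_act: float = 0.0
    pro = 0.0
    anti = 0.0
    damage = float(initial_damage)

    def snapshot(t: int) -> dict[str, float]:
        return {
            "dose": _dose_at(doses, t),
            "LPS": lps,
            "mac_active": m_act,
            "pro": pro,
            "anti": anti,
            "damage": damage,
        }

    valuations = [snapshot(0)]
    for t in range(horizon):
        dose = _dose_at(doses, t)
        lps = lps + dose

        # macrophage activation: hazard from LPS, pro-mediator and damage,
        # suppressed by the anti-inflammatory mediator
        drive = (v["mac-act-LPS"] * lps + v["mac-act-pro"] * pro
                 + v["mac-act-dam"] * damage) / (1.0 + anti)
        p_act = -math.expm1(-drive)
        if deterministic:
            newly_active = m_rest * p_act
            retiring = m_act / v["mac-age"]
            recruited = min(max(capacity - m_rest - m_act + retiring, 0.0),
                            v["mac-regen"])
        else:
            newly_active = float(rng.binomial(int(m_rest), p_act))
            retiring = float(rng.binomial(int(m_act), min(1.0 / v["mac-age"], 1.0)))
            deficit = max(capacity - int(m_rest) - int(m_act) + retiring, 0.0)
            recruited = float(min(rng.poisson(v["mac-regen"]), deficit))
        m_rest = m_rest - newly_active + recruited
        m_act = m_act + newly_active - retiring

        # mediator secretion (anti-suppressed) and damage kinetics
        hill = damage / (damage + v["pro-dam-thresh"]) if damage > 0 else 0.0
        secretion = (_K_PRO * m_act + v["max-pro-dam"] * hill) / (1.0 + anti)
        pro = pro * (1.0 - v["pro-evap"]) + secretion
        anti = anti * (1.0 - v["anti-evap"]) + v["mac-anti"] * m_act
        damage = damage * (1.0 - v["damage-evap"]) + _K_DAM * pro
        if anti > v["anti-heal-thresh"]:
            damage *= (1.0 - _HEAL_FRAC)

        # first-order endotoxin clearance
        lps = lps * (1.0 - v["LPS-evap"])
        valuations.append(snapshot(t + 1))

    props = build_propositions()
    states = [State(valuation=val,
                    labels=frozenset(p.name for p in props if p.holds(val)))
              for val in valuations]
    return Trace(states=states, meta={"model": "air", "experiment": experiment})


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpecThresholds:
    """Step bounds d1..d10 and the numeric thresholds behind the atoms.

    The dose atoms compare the per-step administered dose; the inflammation
    atoms compare the pro-inflammatory mediator level.  None of these values
    are published — they are configuration, not claims.
    """

    deltas: tuple[int, ...] = (5, 8, 3, 6, 4, 10, 4, 4, 10, 4)
    dose_low_max: float = 10.0    # D_L: 0 < dose <= this
    dose_high_min: float = 20.0   # D_H: dose >= this
    inflammation: float = 5.0     # I: pro > this
    baseline: float = 1.0         # N: pro <= this
    level_low: float = 3.0        # I_L: pro > this
    level_high: float = 10.0      # I_H: pro > this

    def __post_init__(self) -> None:
        if len(self.deltas) != 10 or any(d < 0 for d in self.deltas):
            raise ValueError("need 10 nonnegative step bounds d1..d10")
        if not self.dose_low_max < self.dose_high_min:
            raise ValueError("low-dose threshold must be below high-dose threshold")
        if not self.level_low < self.level_high:
            raise ValueError("I_L level must be below I_H level")


def build_propositions(thresholds: SpecThresholds = SpecThresholds()
                       ) -> tuple[AtomicProposition, ...]:
    """Threshold atoms over the AIR observables."""
    th = thresholds
    return (
        AtomicProposition("D", lambda v: v["dose"] > 0.0),
        AtomicProposition("D_L", lambda v: 0.0 < v["dose"] <= th.dose_low_max),
        AtomicProposition("D_H", lambda v: v["dose"] >= th.dose_high_min),
        AtomicProposition("I", lambda v: v["pro"] > th.inflammation),
        AtomicProposition("N", lambda v: v["pro"] <= th.baseline),
        AtomicProposition("I_L", lambda v: v["pro"] > th.level_low),
        AtomicProposition("I_H", lambda v: v["pro"] > th.level_high),
    )


#: antecedent dose atom of each behavioral specification, keyed by number
_ANTECEDENTS = {1: "D_L", 2: "D_H", 3: "D", 4: "D"}


def encode_specs(thresholds: SpecThresholds = SpecThresholds(),
                 theta: float = 0.8) -> list[PBLTLSpec]:
    """The four expert behavioral properties as PBLTL specifications."""
    d = thresholds.deltas
    texts = [
        f"D_L -> F[{d[0]}](I & F[{d[1]}](N))",
        f"D_H -> F[{d[2]}](G[{d[3]}](I_H))",
        f"D -> F[{d[4]}](I_L & F[{d[5]}](D -> F[{d[6]}](I_H)))",
        f"D -> F[{d[7]}](I_H & F[{d[8]}](D -> F[{d[9]}](I_L)))",
    ]
    return [PBLTLSpec(parse_formula(t), theta) for t in texts]


def guarded_formula(spec_number: int, spec: PBLTLSpec) -> Formula:
    """Non-vacuity guard: conjoin the spec's antecedent dose atom.

    The published formulas are implications, so a schedule that never doses
    satisfies all four vacuously; the case study searches for schedules that
    *exhibit* the behaviors, so synthesis monitors ``D_x & phi`` instead.
    """
    return Formula.and_(Formula.atom_(_ANTECEDENTS[spec_number]), spec.formula)


# ---------------------------------------------------------------------------
# End-to-end case study
# ---------------------------------------------------------------------------

@dataclass
class AIRModel:
    """Binds the simulator, parameter box and thresholds for synthesis."""

    space: ParameterSpace = field(default_factory=default_parameter_space)
    thresholds: SpecThresholds = SpecThresholds()
    name: str = "air"

    def sampler(self, omega: Sequence[float], horizon: int, experiment: int):
        params = AIRParameters.from_vector(self.space.validate(omega))

        def sample(rng: np.random.Generator) -> Trace:
            return simulate_air(params, horizon, rng, experiment=experiment)

        return sample


def run_case_study(*, spec_numbers: Sequence[int] = (1, 2, 3, 4),
                   theta: float = 0.8,
                   thresholds: SpecThresholds = SpecThresholds(),
                   space: Optional[ParameterSpace] = None,
                   joint: bool = False,
                   schedule: AnnealingSchedule = AnnealingSchedule(t_start=50.0, t_stop=1.0, gamma=0.9),
                   policy: NeighborhoodPolicy = NeighborhoodPolicy(scale=0.1, mode="all"),
                   bayes_threshold: float = 100.0,
                   indifference: IndifferenceRegion = IndifferenceRegion.symmetric(0.05),
                   max_samples: int = 500,
                   max_iterations: int = 200,
                   seed: int = 0) -> dict[int, SynthesisResult]:
    """Synthesize dosing schedules making the AIR model exhibit the selected
    behavioral specifications.

    Per-spec mode (default) runs one annealing search per specification,
    each monitoring its own experiment's traces against its guarded formula.
    Joint mode runs a single search whose per-sample Bernoulli outcome is
    the conjunction over all selected specs, each monitored on a trace of
    its own experiment.

    Returns ``{spec number: SynthesisResult}`` (joint mode uses key 0).
    """
    model = AIRModel(space=space or default_parameter_space(), thresholds=thresholds)
    specs = encode_specs(thresholds, theta)
    ss = np.random.SeedSequence(seed)

    def make_single(k: int):
        spec = specs[k - 1]
        monitored = PBLTLSpec(guarded_formula(k, spec), theta)

        def factory(omega):
            return model.sampler(omega, monitored.horizon, experiment=k)

        return monitored, factory

    if not joint:
        out: dict[int, SynthesisResult] = {}
        for k in spec_numbers:
            monitored, factory = make_single(k)
            out[k] = synthesize(
                model, monitored,
                schedule=schedule, policy=policy,
                bayes_threshold=bayes_threshold, indifference=indifference,
                max_samples=max_samples, max_iterations=max_iterations,
                sampler_factory=factory, rng=ss.spawn(1)[0])
        return out

    # joint mode: one Bernoulli trial = all specs hold, each on its own trace.
    # Encoded as a synthetic single-state trace carrying the conjunction so
    # the sequential checker machinery is reused unchanged.
    monitored_list = [(k,) + make_single(k) for k in spec_numbers]
    conj_atom = AtomicProposition("all_specs", lambda v: v["ok"] > 0.5)

    def joint_factory(omega):
        samplers = [(m, f(omega)) for _, m, f in monitored_list]

        def sample(rng: np.random.Generator) -> Trace:
            ok = all(evaluate(s(rng), m.formula, 0) for m, s in samplers)
            val = {"ok": 1.0 if ok else 0.0}
            labels = frozenset(["all_specs"]) if ok else frozenset()
            return Trace(states=[State(valuation=val, labels=labels)])

        return sample

    joint_spec = PBLTLSpec(Formula.atom_("all_specs"), theta)
    result = synthesize(
        model, joint_spec,
        schedule=schedule, policy=policy,
        bayes_threshold=bayes_threshold, indifference=indifference,
        max_samples=max_samples, max_iterations=max_iterations,
        sampler_factory=joint_factory, rng=ss.spawn(1)[0])
    return {0: result}


def verify_found(result: SynthesisResult, spec_number: int, *,
                 theta: float = 0.8,
                 thresholds: SpecThresholds = SpecThresholds(),
                 space: Optional[ParameterSpace] = None,
                 n_traces: int = 50, seed: int = 12345) -> float:
    """Fresh-trace satisfaction fraction of a found point against its
    guarded specification (re-verification on new seeds)."""
    if result.status != "found":
        raise ValueError("can only re-verify a found result")
    model = AIRModel(space=space or default_parameter_space(), thresholds=thresholds)
    spec = encode_specs(thresholds, theta)[spec_number - 1]
    monitored = PBLTLSpec(guarded_formula(spec_number, spec), theta)
    sampler = model.sampler(np.asarray(result.omega), monitored.horizon,
                            experiment=spec_number)
    ss = np.random.SeedSequence(seed)
    hits = 0
    for child in ss.spawn(n_traces):
        rng = np.random.Generator(np.random.PCG64(child))
        hits += evaluate(sampler(rng), monitored.formula, 0)
    return hits / n_traces


def plot_traces(params: AIRParameters, horizon: int, *, experiment: int = 1,
                n_traces: int = 10, seed: int = 0, path=None):
    """Overlay stochastic observable traces for one experiment (PNG when
    ``path`` given); returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ss = np.random.SeedSequence(seed)
    observables = ["LPS", "mac_active", "pro", "anti", "damage"]
    fig, axes = plt.subplots(len(observables), 1, figsize=(7, 10), sharex=True)
    for child in ss.spawn(n_traces):
        rng = np.random.Generator(np.random.PCG64(child))
        trace = simulate_air(params, horizon, rng, experiment=experiment)
        for ax, obs in zip(axes, observables):
            ax.plot([s.valuation[obs] for s in trace.states], alpha=0.5, lw=1)
    for ax, obs in zip(axes, observables):
        ax.set_ylabel(obs)
    axes[-1].set_xlabel("step")
    fig.suptitle(f"AIR experiment {experiment}")
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
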