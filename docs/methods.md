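# Methods

`smcsynth` decides probabilistic temporal-logic properties of stochastic
biological models by sequential hypothesis testing on simulated traces, and
searches a model's parameter space for property-satisfying points by
simulated annealing. This note records the models and procedures, the
tunable parameters and their defaults, the numerical choices, and what the
synthetic fixtures and the inflammation demo do and do not establish.

## Bounded linear temporal logic and monitoring

Specifications are bounded LTL (BLTL) formulas over atomic propositions:

    phi ::= a | phi & phi | phi "|" phi | !phi | phi U[d] phi

with derived operators `F[d] p = true U[d] p` (eventually within d steps)
and `G[d] p = !F[d] !p` (always for d steps), and `p -> q` as sugar for
`!p | q`. Every temporal operator carries a nonnegative integer step bound
`d`, so each formula has a finite *horizon*

    h(atom) = 0,   h(!p) = h(p),   h(p op q) = max(h(p), h(q)),
    h(p U[d] q) = h(F[d] p) = h(G[d] p) = d + max over children,

and a trace with at least `h + 1` states starting at the evaluation
position always decides the formula. The monitor exploits this: it refuses
(raises) on shorter traces rather than returning a three-valued "unknown",
because every caller in the package derives its simulation length from the
horizon in the first place.

The bounded until `p U[d] q` holds at position `i` iff there is an
`l <= d` with `q` true at `i + l` and `p` true at all positions strictly
before that. Two deliberate readings of corner cases:

- The semantic clause is sometimes printed with the witness position fixed
  at `i + 1`; we implement the standard `i + l` quantification — the
  `i + 1` form would make the operator's bound meaningless.
- `l = 0` is admitted, so `F[0] q = q` and `p U[0] q = q`.

Evaluation is a memoized bottom-up pass: one boolean table per distinct
subformula over its decidable positions, linear in `|phi| * |trace|`. The
test suite checks it against an independently written naive recursion,
exhaustively over all 4^6 label sequences for an `U[4]` formula and on
1,000 random formula/trace pairs.

`rewrite_derived` eliminates `F`/`G` by the identities above; `true` is
encoded as `a | !a` over the first atom of the rewritten operand so no
foreign proposition is introduced. The rewrite preserves both semantics
(property-tested) and horizon.

## Parameterized models and sampling

A parameterized discrete-time Markov chain (ParDTMC) couples a state set,
an initial distribution, a transition kernel `P(s, s' ; omega)` depending
on a parameter vector `omega` in a bounded box, and a registry of named
propositions over state valuations. Agent-based models enter through the
same contract — anything that can draw an initial joint state and advance
it one step induces a ParDTMC over joint states — because the checker only
ever consumes labeled traces.

Sampling draws one categorical successor per step by inverse-transform on
a single uniform, which keeps traces byte-reproducible across platforms.
Each sampled trace gets its own RNG stream spawned from the master seed
(`numpy.random.SeedSequence`), so draws are i.i.d. and a run is
reproducible regardless of evaluation order. Transition rows are checked
to sum to 1 within 1e-9 at use; a non-normalized row is a model bug and is
reported, never renormalized silently.

Exact machinery exists only as a desk-scale oracle: `enumerate_paths`
multiplies kernel probabilities along every fixed-horizon path (refusing
beyond a configurable 10^6-path cap) and `exact_satisfaction_probability`
sums the probability of the monitored-true paths. Production verification
never touches it; tests use it to cross-check the sampler and the checker.

Three fixtures with closed-form satisfaction probability `u(omega)` back
the statistical tests: `bernoulli` (u = omega on [0,1], the identity),
`logistic-bernoulli` (u = sigmoid(w0 + w1) on [-3,3]^2, midpoint 1/2) and
`small-chain` (fixed 3-state kernel, u = 0.4 identically).

## Bayesian sequential checking

The probabilistic question "does the model satisfy `phi` with probability
at least theta" is relaxed with an indifference region
`[theta - eps1, theta + eps2]` to the test of

    H0: u >= theta + eps2     against     H1: u <= theta - eps1.

Monitoring each sampled trace yields a Bernoulli outcome; after `n` draws
with `z` satisfactions the Bayes factor of H0 against H1 under a prior
`g` on `u` is

    B = int_{theta+eps2}^{1} u^z (1-u)^(n-z) g(u) du
      / int_{0}^{theta-eps1} u^z (1-u)^(n-z) g(u) du,

and sampling stops at `B > L` (accept H0), `B < 1/L` (reject), or a sample
cap. The cap is reported as a distinct third outcome, never coerced to a
verdict: when `u` falls inside the indifference region the sequential test
may legitimately run forever, and there either answer would be acceptable
— we decline to fabricate one.

Numerical choices:

- Default prior Beta(1, 1); for any Beta(a, b) the normalizers cancel and
  `B = (1 - I_{theta+eps2}(z+a, n-z+b)) / I_{theta-eps1}(z+a, n-z+b)` with
  `I` the regularized incomplete beta function. The numerator uses the
  exact complement (`betaincc`) to avoid `1 - (1 - tiny)` cancellation, so
  the sequential loop is O(1) per draw and stable at large `n`.
- Arbitrary priors are supported as tabulated densities; those integrals
  are evaluated by adaptive quadrature of the log-scaled integrand.
- `theta - eps1 = 0` makes H1 vacuous and the denominator literally zero;
  `B = +inf` is returned with a flag and forces immediate acceptance,
  rather than raising.
- The per-step statistic trajectory is logged as log10(B), since B spans
  many orders of magnitude.
- Defaults: L = 100, eps1 = eps2 = 0.05, cap 10^5 samples.

The closed form is verified against adaptive quadrature of the defining
integrals at relative error 1e-8 over a ~2,000-case grid, and the
stopping behavior against hand-derivable special cases: with a uniform
prior, theta = 0.5 and eps = 0.1, an always-satisfying sampler gives
`B_n = (1 - 0.6^(n+1)) / 0.4^(n+1)`, which first exceeds 100 at n = 5, so
the checker accepts after exactly 5 samples (and rejects a
never-satisfying sampler at n = 5 by the symmetric form).

A Wald SPRT over the same indifference region is the classical baseline:
log-space likelihood ratio `Lambda_n = u_l^z (1-u_l)^(n-z) / (u_r^z
(1-u_r)^(n-z))` with thresholds `(1-beta)/alpha` and `beta/(1-alpha)`,
defaults alpha = beta = 0.01. At the matched settings the Bayesian test
needs markedly fewer samples when the model is far from the threshold
(e.g. the always-satisfying case: 5 vs 12); the profile utility
(`sample_count_profile`) tabulates mean sample count against true `u` and
reproduces the characteristic blow-up of both tests as `u` approaches
theta. Because the publication behind this method does not state the
theta, L, alpha, beta or grid of its efficiency figure, these curves are
asserted as *ordering* properties (peak adjacent to theta; SPRT >= Bayes
for |u - theta| >= 0.3), not value matches.

## Annealing synthesis

`synthesize` searches the parameter box for a point the checker accepts.
The fitness signal is the checker's sample count `n`: rejecting a point
takes more samples the closer its true satisfaction probability is to
theta, so "expensive to reject" marks proximity to the satisfying region
(this premise is itself tested on the identity fixture). The loop:

1. uniform random initial point; check; return immediately on accept;
2. otherwise propose a neighbor (Gaussian step, per-dimension sd =
   `scale x range`, default scale 0.1, perturb-all or perturb-one modes,
   clipped to the box), check it, and return on accept;
3. move to the candidate if its `n` is larger; if not, move anyway with
   Metropolis probability `exp(-(n - n')/t)` — ties are always accepted;
4. cool geometrically `t_k = t_start * gamma^k` (defaults 100 -> 1 at
   gamma = 0.95) and stop below `t_stop` or at an iteration guard.

Two printed-algorithm repairs are made deliberately: the published
worse-move rule accepts when `rand(0,1) > exp(-(n'-n)/t)`, which for a
worse candidate compares against a value >= 1 and can never fire,
contradicting the stated purpose of annealing — we use the standard
Metropolis form above; and the checker prior for a candidate `omega'` is
evaluated at `omega'` (the printed call passes the previous point's
prior). A `budget_exhausted` check counts as a non-accepting result with
fitness `n = cap`, logged distinctly.

A found result is backed by the recorded accepting call; re-verification
with fresh seeds is part of the test battery (accept frequency >= 0.9
when the found point's true `u` clears `theta + eps2`). Every checker
call is logged (iteration, point, decision, n, temperature, move flag),
the log has exactly one row per call, and a full run is reproducible from
the master seed.

## The acute-inflammation demo

The demonstration target is a small agent-based model of the acute
inflammatory response to LPS endotoxin. The original model this emulates
is a SPARK-framework program whose update rules are not published; this
implementation is therefore an explicitly labeled interpretation that
honors the name and role of each of the 28 published parameters (14 core
rates/thresholds + 14 dosing-schedule parameters across four
experiments). Numeric fidelity to the published synthesized values is a
non-goal — they are the output of one stochastic search on an unavailable
model.

Dynamics per discrete step (macrophage counts integer in stochastic mode;
mediators continuous): scheduled LPS injection (each dose spreads its
amount uniformly over its duration); resting macrophages activate with
hazard `mac-act-LPS * LPS + mac-act-pro * pro + mac-act-dam * damage`,
suppressed by `1/(1 + anti)` (binomial draw); active macrophages retire
at rate `1/mac-age`; the resting pool is replenished at rate `mac-regen`
toward capacity `10 * mac-prop`; active macrophages secrete
pro-inflammatory mediator (1 unit each) plus a damage-driven term
saturating at `max-pro-dam` with half-saturation `pro-dam-thresh`, again
anti-suppressed; anti is produced at `mac-anti` per active macrophage;
damage grows with pro (0.15 per unit), decays at `damage-evap`, and is
halved when anti exceeds `anti-heal-thresh`; LPS, pro and anti decay by
their `-evap` fractions. Fixed internal constants (secretion 1.0, damage
coupling 0.15, healing fraction 0.5, capacity 10 per unit `mac-prop`)
were chosen once so that all four qualitative behaviors are reachable in
the default box, and are not exposed as parameters.

Structural guarantees (tested): with zero dosing and zero initial insult
every inflammatory observable is exactly 0 at every step; in
deterministic mode (all draws replaced by expectations — used only for
tests) the peak pro-inflammatory response is monotone in the dose amount,
and after the last dose with activation off LPS decays geometrically at
`(1 - LPS-evap)` per step to closed form.

The four behavioral specifications use threshold atoms over the
observables — `D`/`D_L`/`D_H` on the per-step administered dose and
`I`/`N`/`I_L`/`I_H` on the pro-mediator level — with configurable levels
and step bounds d1..d10, none of which are published; the defaults
(e.g. I at pro > 5, I_H at pro > 10, d = (5,8,3,6,4,10,4,4,10,4)) are
configuration, not claims. A trace's state at position t records the
observables entering step t plus the dose administered during it, so a
dose scheduled at time 0 is visible at the formula's evaluation position.

Non-vacuity guard: the published formulas are implications `D_x -> ...`,
so a schedule that never doses satisfies all four vacuously. Since the
case study's point is to *discover schedules that exhibit* the behaviors,
synthesis and re-verification monitor `D_x & phi` (the antecedent dose
event must occur at the evaluation position); `encode_specs` still
returns the published formulas verbatim. With dosing forced to zero the
guarded non-resolving-inflammation spec is correctly unsatisfiable.

Specs can be synthesized per-spec (default: one annealing run per
specification, each on its own dosing experiment) or jointly (one run
whose Bernoulli outcome is the conjunction across specs, each monitored
on a trace of its own experiment); the source publication does not say
which mode produced its parameter set, so both are provided.

Known limitations: the interpretation's mediator kinetics are first-order
caricatures with no spatial structure; discretizing the continuous
mediators (required for an exact ParDTMC reduction) is not attempted —
the exact oracles stop at explicit-state fixtures; "low" and "high" dose
magnitudes are conventions of the default thresholds. A green demo test
establishes that the pipeline finds and re-verifies satisfying schedules
in this stated world, not that the schedule values mean anything
clinically.

## Test scaling

All stochastic assertions use seeded streams and 3-sigma (or frequency-
threshold) tolerances computed from the actual replication count. Two
simulations are scaled down from their natural size for suite runtime,
with tolerances widened accordingly by the binomial formula: the
sampler-vs-enumeration cross-check uses 2x10^4 traces (not 10^5), and the
demo synthesis runs use a 300-sample checker cap with ~150 annealing
iterations. The whole suite runs in well under a minute on one CPU.
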