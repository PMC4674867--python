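"""Bayes factor, sequential Bayesian checker, SPRT baseline, profiles."""

import math

import numpy as np
import pytest
from scipy import integrate, special

from smcsynth.checking import (BetaPrior, Decision, IndifferenceRegion,
                               PBLTLSpec, SPRTConfig, TabulatedPrior,
                               bayes_factor, bsmc_verify, model_sampler,
                               sample_count_profile, sprt_verify)
from smcsynth.models import build_fixture


def quadrature_bayes_factor(n, z, theta, eps1, eps2, a=1.0, b=1.0):
    """Independent oracle: numerator/denominator of the Bayes factor by
    adaptive quadrature of the defining integrals, stabilized by scaling the
    integrand by its maximum over [0, 1].

    The posterior kernel is u^(z+a-1) (1-u)^(n-z+b-1) up to the prior's
    normalizer, which cancels in the ratio; the log Beta-pdf constant is
    kept so each integral individually matches the definition.
    """
    log_const = -special.betaln(a, b)
    az, bz = z + a - 1.0, n - z + b - 1.0

    def log_integrand(u):
        if u <= 0.0:
            return -np.inf if az > 0 else (np.inf if az < 0 else log_const)
        if u >= 1.0:
            return -np.inf if bz > 0 else (np.inf if bz < 0 else log_const)
        return az * math.log(u) + bz * math.log1p(-u) + log_const

    # mode of the kernel (interior when both exponents positive)
    if az > 0 and bz > 0:
        shift = log_integrand(az / (az + bz))
    else:
        grid = np.linspace(1e-9, 1 - 1e-9, 513)
        shift = float(np.max(az * np.log(grid) + bz * np.log1p(-grid) + log_const))

    def integrand(u):
        lv = log_integrand(u)
        return math.exp(lv - shift) if np.isfinite(lv) else 0.0

    num, _ = integrate.quad(integrand, theta + eps2, 1.0, limit=300)
    den, _ = integrate.quad(integrand, 0.0, theta - eps1, limit=300)
    if den == 0.0:
        return math.inf
    return num / den


class TestBayesFactor:
    def test_no_data_uniform_prior_symmetric(self):
        # with n = 0 the factor is the prior mass ratio of the two tails
        assert bayes_factor(0, 0, 0.5, 0.1, 0.1) == pytest.approx(1.0)
        assert bayes_factor(0, 0, 0.5, 1e-9, 1e-9) == pytest.approx(1.0)

    def test_all_successes_closed_form_identity(self):
        # Beta(1,1), z = n: I_x(k, 1) = x^k, so
        # B = (1 - 0.6^(n+1)) / 0.4^(n+1); at n = 6 that is ~593.27
        got = bayes_factor(6, 6, 0.5, 0.1, 0.1)
        assert got == pytest.approx((1 - 0.6**7) / 0.4**7, rel=1e-12)

    def test_matches_quadrature_oracle(self):
        cases = []
        for n in (1, 4, 9, 17, 30, 50):
            for z in sorted({0, n // 3, n // 2, n}):
                for theta in (0.3, 0.5, 0.8):
                    for a, b in ((1, 1), (2, 2), (5, 1)):
                        cases.append((n, z, theta, a, b))
        for n, z, theta, a, b in cases:
            got = bayes_factor(n, z, theta, 0.05, 0.05, BetaPrior(a, b))
            want = quadrature_bayes_factor(n, z, theta, 0.05, 0.05, a, b)
            if math.isinf(want):
                assert math.isinf(got)
            else:
                assert got == pytest.approx(want, rel=1e-7)

    def test_monotone_in_z(self):
        # more satisfying traces is always more evidence for H0
        for n in (1, 5, 12, 30):
            values = [bayes_factor(n, z, 0.5, 0.1, 0.1) for z in range(n + 1)]
            assert all(b > a for a, b in zip(values, values[1:]))

    def test_vacuous_h1_returns_infinity(self):
        assert math.isinf(bayes_factor(3, 1, 0.05, 0.05, 0.05))

    def test_extreme_n_no_nan(self):
        b = bayes_factor(5000, 4990, 0.5, 0.1, 0.1)
        assert math.isfinite(b) or math.isinf(b)
        assert not math.isnan(b)

    def test_tabulated_uniform_matches_beta11(self):
        tab = TabulatedPrior(tuple(np.linspace(0, 1, 201)), tuple(np.ones(201)))
        for n, z in ((5, 3), (12, 12), (20, 4)):
            assert bayes_factor(n, z, 0.5, 0.1, 0.1, tab) == pytest.approx(
                bayes_factor(n, z, 0.5, 0.1, 0.1, BetaPrior(1, 1)), rel=1e-5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bayes_factor(3, 4, 0.5, 0.1, 0.1)
        with pytest.raises(ValueError):
            bayes_factor(3, 1, 0.99, 0.05, 0.05)  # region leaves [0, 1]


def _samplers(fixture, spec):
    always = model_sampler(fixture.model, [1.0], spec.horizon)
    never = model_sampler(fixture.model, [0.0], spec.horizon)
    return always, never


class TestBSMC:
    def test_deterministic_stopping_times(self, bernoulli_fixture):
        # closed-form recurrence (independent oracle): with every draw
        # satisfying, B_n = (1 - 0.6^(n+1)) / 0.4^(n+1); first n with
        # B_n > 100 and, symmetrically, first n with the never-satisfying
        # B_n = 0.4^(n+1) / (1 - 0.6^(n+1)) < 1/100
        def first_crossing(up):
            n = 0
            while True:
                n += 1
                b_up = (1 - 0.6 ** (n + 1)) / 0.4 ** (n + 1)
                b_dn = 0.4 ** (n + 1) / (1 - 0.6 ** (n + 1))
                if up and b_up > 100:
                    return n
                if not up and b_dn < 0.01:
                    return n

        spec = PBLTLSpec(bernoulli_fixture.formula, 0.5)
        eps = IndifferenceRegion.symmetric(0.1)
        always, never = _samplers(bernoulli_fixture, spec)
        res_a = bsmc_verify(always, spec, bayes_threshold=100, indifference=eps, rng=0)
        res_n = bsmc_verify(never, spec, bayes_threshold=100, indifference=eps, rng=0)
        assert (res_a.decision, res_a.n) == (Decision.ACCEPT_H0, first_crossing(True))
        assert (res_n.decision, res_n.n) == (Decision.REJECT_H0, first_crossing(False))
        assert res_a.n == 5 and res_n.n == 5  # frozen from the recurrence
        assert res_a.z == res_a.n and res_n.z == 0

    def test_sequential_consistency_same_seed(self, bernoulli_fixture):
        spec = PBLTLSpec(bernoulli_fixture.formula, 0.6)
        sampler = model_sampler(bernoulli_fixture.model, [0.75], spec.horizon)
        runs = [bsmc_verify(sampler, spec, bayes_threshold=100,
                            indifference=IndifferenceRegion.symmetric(0.05),
                            rng=123) for _ in range(2)]
        assert (runs[0].decision, runs[0].n, runs[0].z) \
            == (runs[1].decision, runs[1].n, runs[1].z)

    def test_budget_exhaustion_distinct_outcome(self, bernoulli_fixture):
        # true probability dead inside the indifference region, tiny cap
        spec = PBLTLSpec(bernoulli_fixture.formula, 0.5)
        sampler = model_sampler(bernoulli_fixture.model, [0.5], spec.horizon)
        res = bsmc_verify(sampler, spec, bayes_threshold=10**6,
                          indifference=IndifferenceRegion(0.001, 0.001),
                          max_samples=30, rng=0)
        assert res.decision is Decision.BUDGET_EXHAUSTED
        assert res.satisfied is None and res.n == 30

    def test_vacuous_h1_flagged_and_accepts(self, bernoulli_fixture):
        spec = PBLTLSpec(bernoulli_fixture.formula, 0.05)
        sampler = model_sampler(bernoulli_fixture.model, [0.5], spec.horizon)
        res = bsmc_verify(sampler, spec, bayes_threshold=100,
                          indifference=IndifferenceRegion(0.05, 0.05), rng=0)
        assert res.vacuous_h1 and res.decision is Decision.ACCEPT_H0 and res.n == 1

    def test_decision_correctness_two_eps_separation(self, bernoulli_fixture):
        # u >= theta + 2 eps: accept frequency at least 95% (50-run version;
        # the 200-run experiment lives in the acceptance suite)
        spec = PBLTLSpec(bernoulli_fixture.formula, 0.7)
        eps = IndifferenceRegion.symmetric(0.05)
        sampler = model_sampler(bernoulli_fixture.model, [0.9], spec.horizon)
        accepts = sum(
            bsmc_verify(sampler, spec, bayes_threshold=100, indifference=eps,
                        rng=seed).decision is Decision.ACCEPT_H0
            for seed in range(50))
        assert accepts >= 48

    def test_log_trajectory_one_entry_per_sample(self, bernoulli_fixture):
        spec = PBLTLSpec(bernoulli_fixture.formula, 0.5)
        always, _ = _samplers(bernoulli_fixture, spec)
        res = bsmc_verify(always, spec, bayes_threshold=100,
                          indifference=IndifferenceRegion.symmetric(0.1), rng=0)
        assert len(res.log10_trajectory) == res.n
        assert res.log10_trajectory[-1] == pytest.approx(math.log10(res.statistic))


class TestSPRT:
    def test_always_satisfying_accepts_at_twelve(self, bernoulli_fixture):
        # Lambda_n = (u_l/u_r)^n = (2/3)^n; first n with (2/3)^n <= 0.01/0.99
        # is 12 (hand iteration: (2/3)^11 = 0.0116 > 0.0101 > (2/3)^12 = 0.0077)
        spec = PBLTLSpec(bernoulli_fixture.formula, 0.5)
        always, never = _samplers(bernoulli_fixture, spec)
        eps = IndifferenceRegion.symmetric(0.1)
        errors = SPRTConfig(0.01, 0.01)
        res = sprt_verify(always, spec, indifference=eps, errors=errors, rng=0)
        assert (res.decision, res.n) == (Decision.ACCEPT_H0, 12)
        # mirrored bound for the never-satisfying sampler at the same n
        res_n = sprt_verify(never, spec, indifference=eps, errors=errors, rng=0)
        assert (res_n.decision, res_n.n) == (Decision.REJECT_H0, 12)

    def test_requires_interior_indifference_region(self, bernoulli_fixture):
        spec = PBLTLSpec(bernoulli_fixture.formula, 0.05)
        always, _ = _samplers(bernoulli_fixture, spec)
        with pytest.raises(ValueError):
            sprt_verify(always, spec, indifference=IndifferenceRegion(0.05, 0.05))

    def test_needs_more_samples_than_bayes_when_far(self, bernoulli_fixture):
        # |u - theta| >= 0.3: SPRT mean sample count >= BSMC mean (100 runs
        # here; the 200-run grid comparison is in the acceptance suite)
        spec = PBLTLSpec(bernoulli_fixture.formula, 0.5)
        eps = IndifferenceRegion.symmetric(0.05)
        for u in (0.1, 0.9):
            sampler = model_sampler(bernoulli_fixture.model, [u], spec.horizon)
            ns_b = [bsmc_verify(sampler, spec, bayes_threshold=100,
                                indifference=eps, rng=s).n for s in range(100)]
            ns_s = [sprt_verify(sampler, spec, indifference=eps,
                                errors=SPRTConfig(0.01, 0.01), rng=s).n
                    for s in range(100)]
            assert np.mean(ns_s) >= np.mean(ns_b)


class TestProfile:
    def test_columns_and_peak_location(self, bernoulli_fixture):
        grid = [[u] for u in (0.2, 0.45, 0.5, 0.55, 0.8)]
        frame = sample_count_profile(bernoulli_fixture, 0.5, grid, runs=40,
                                     max_samples=2000, rng=9)
        assert list(frame.columns) == ["omega", "u", "mean_n", "sd_n",
                                       "accept_frac", "exhausted_frac"]
        peak_u = frame.loc[frame.mean_n.idxmax(), "u"]
        assert abs(peak_u - 0.5) <= 0.05

    def test_exhaustion_fraction_peaks_at_theta(self, bernoulli_fixture):
        # u = theta exactly with a tiny indifference region: the cap bites
        # hardest at theta
        grid = [[u] for u in (0.2, 0.5, 0.8)]
        frame = sample_count_profile(
            bernoulli_fixture, 0.5, grid, runs=30,
            indifference=IndifferenceRegion(0.005, 0.005),
            max_samples=100, rng=10)
        assert frame.exhausted_frac.idxmax() == 1

    def test_doubling_threshold_never_cheapens(self, bernoulli_fixture):
        # stochastic monotonicity of the mean sample count in L
        grid = [[0.65]]
        means = []
        for L in (100, 200):
            frame = sample_count_profile(bernoulli_fixture, 0.5, grid, runs=200,
                                         bayes_threshold=L, max_samples=2000,
                                         rng=11)
            means.append(frame.mean_n[0])
        assert means[1] >= means[0]


class TestResultSerialization:
    def test_json_round_trip(self, bernoulli_fixture, tmp_path):
        import json

        spec = PBLTLSpec(bernoulli_fixture.formula, 0.5)
        always, _ = _samplers(bernoulli_fixture, spec)
        res = bsmc_verify(always, spec, bayes_threshold=100,
                          indifference=IndifferenceRegion.symmetric(0.1), rng=0)
        path = tmp_path / "result.json"
        res.to_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["decision"] == "accept_H0"
        assert loaded["n"] == res.n and loaded["z"] == res.z
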