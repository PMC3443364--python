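"""Route-probability kernels: degenerate closed forms, the constant-hazard
matrix-exponential oracle, density properness, conservation and the
likelihood contract."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import quad

from semicr import (
    Covariates,
    IndividualRecord,
    ModelParams,
    State,
    WeibullParams,
    alive_continuation,
    death_density,
    log_likelihood,
    route_probability,
)
from semicr.likelihood import RouteLikelihood
from semicr.model import FREE_TRANSITIONS, LIVE_STATES
from semicr.simulate import default_params, simulate_cohort

import helpers

X = Covariates(0.0, 1)
TINY = 1e-12


def tiny_except(**rates) -> ModelParams:
    """Parameter set with all transition rates negligible except the given
    ones (exponential shapes, no covariate effects)."""
    weib = {
        m: WeibullParams(rates.get(f"m{m}", TINY), 1.0, np.zeros(2))
        for m in FREE_TRANSITIONS
    }
    return ModelParams(weib, baseline_logit=np.array([-40.0, 0.0, 0.0]))


def rec(**kw):
    kw.setdefault("id", 0)
    kw.setdefault("x", X)
    kw.setdefault("end_time", 10.0)
    return IndividualRecord(**kw)


class TestAliveContinuation:
    def test_boundary_is_one(self, gen_params):
        for st in LIVE_STATES:
            assert alive_continuation(st, 3.0, 3.0, X, gen_params) == pytest.approx(1.0)

    def test_no_death_rates_gives_one(self):
        p = tiny_except(m2=0.3, m4=0.2, m8=0.5)  # deaths negligible
        for st in LIVE_STATES:
            assert alive_continuation(st, 0.0, 15.0, X, p) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("T", [2.0, 6.0, 12.0])
    def test_matches_matrix_exponential(self, exp_params, T):
        for st in LIVE_STATES:
            a = alive_continuation(st, 0.0, T, X, exp_params)
            b = helpers.occupancy(exp_params, X, st, T)[:4].sum()
            assert a == pytest.approx(b, abs=1e-6)

    def test_death_state_rejected(self, gen_params):
        with pytest.raises(ValueError):
            alive_continuation(State.D, 0.0, 1.0, X, gen_params)


class TestDeathDensity:
    def test_single_path_degenerate(self):
        # only the direct death exit is active: S(s,d) * hazard(d) exactly
        p = tiny_except(m1=0.2)
        d = death_density(State.H, 1.0, 4.0, X, p)
        assert d == pytest.approx(np.exp(-0.2 * 3.0) * 0.2, rel=1e-9)
        p3 = tiny_except(m3=0.4)
        d3 = death_density(State.CI, 0.5, 2.5, X, p3)
        assert d3 == pytest.approx(np.exp(-0.4 * 2.0) * 0.4, rel=1e-9)

    def test_direct_only_flag(self, gen_params):
        s, d = 1.0, 6.0
        from semicr.model import hazard, sojourn_survival

        expected = sojourn_survival(State.H, s, d, X, gen_params) * hazard(
            1, d, X, gen_params
        )
        got = death_density(State.H, s, d, X, gen_params, direct_only=True)
        assert got == pytest.approx(float(expected), rel=1e-10)

    def test_density_is_proper(self, exp_params):
        tot, _ = quad(
            lambda u: death_density(State.H, 0.0, u, X, exp_params), 0, 500, limit=300
        )
        assert tot == pytest.approx(1.0, abs=1e-6)

    def test_domain(self, gen_params):
        with pytest.raises(ValueError):
            death_density(State.H, 3.0, 3.0, X, gen_params)


class TestRouteKernels:
    def test_route1_with_negligible_exits_is_one(self):
        p = tiny_except()
        r = rec(baseline_state=State.H, last_healthy_time=4.0)
        assert route_probability(r, p) == pytest.approx(1.0, abs=1e-9)

    def test_route4_exponential_illness_death_closed_form(self):
        # no LTF: two-path convolution through the impaired state
        # (rates chosen with l1 + l2 != l3, away from the removable pole)
        l1, l2, l3 = 0.06, 0.11, 0.21
        p = tiny_except(m1=l1, m2=l2, m3=l3)
        a, d = 2.0, 7.0
        t = d - a
        expected = np.exp(-(l1 + l2) * a) * (
            np.exp(-(l1 + l2) * t) * l1
            + l2 / (l1 + l2 - l3) * (np.exp(-l3 * t) - np.exp(-(l1 + l2) * t)) * l3
        )
        r = rec(baseline_state=State.H, last_healthy_time=a, death_time=d)
        got = route_probability(r, p, two_year_rule=False)
        assert got == pytest.approx(expected, rel=1e-8)

    def test_ltf_window_shrinks_continuously_to_zero(self, gen_params):
        widths = [2.0, 0.5, 0.1, 0.01, 1e-4]
        vals = []
        for w in widths:
            r = rec(
                baseline_state=State.H,
                last_healthy_time=2.0,
                ltf_lower=2.0,
                ltf_upper=2.0 + w,
            )
            vals.append(route_probability(r, gen_params))
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] < 1e-4

    def test_conservation_two_interview_schedule(self, gen_params):
        total = helpers.conservation_total(gen_params, X, interview=2.0, T=4.0)
        assert total == pytest.approx(1.0, abs=1e-3)


class TestLogLikelihood:
    def test_empty_dataset(self, gen_params):
        assert log_likelihood([], gen_params) == 0.0

    def test_single_certain_subject(self):
        p = tiny_except()  # screen probability of impairment ~ 0
        r = rec(baseline_state=State.H, last_healthy_time=4.0)
        assert log_likelihood([r], p) == pytest.approx(0.0, abs=1e-8)

    def test_order_invariance_and_determinism(self, gen_params):
        sim = simulate_cohort(gen_params, 120, seed=55)
        ll = log_likelihood(sim.records, gen_params)
        ll_rev = log_likelihood(list(reversed(sim.records)), gen_params)
        ll_again = log_likelihood(sim.records, gen_params)
        assert ll == ll_again
        assert ll == pytest.approx(ll_rev, rel=1e-12)

    def test_two_year_rule_changes_death_kernels(self, gen_params):
        r = rec(baseline_state=State.H, last_healthy_time=4.0, death_time=5.0)
        full = route_probability(r, gen_params, two_year_rule=False)
        direct = route_probability(r, gen_params, two_year_rule=True)
        assert direct < full  # latent CI/LTF detours are suppressed

    def test_generating_parameters_dominate_perturbed_ones(self, gen_params):
        inflated = ModelParams(
            {
                m: dataclasses.replace(w, tau=1.5 * w.tau)
                for m, w in gen_params.weibull.items()
            },
            k=gen_params.k,
            baseline_logit=gen_params.baseline_logit,
        )
        wins = 0
        for rep in range(20):
            sim = simulate_cohort(gen_params, 200, seed=500 + rep)
            eng = RouteLikelihood(sim.records, quad_nodes=8, two_year_rule=False)
            if eng.loglik(gen_params) > eng.loglik(inflated):
                wins += 1
        assert wins >= 19

    def test_batched_evaluation_consistent(self, gen_params):
        sim = simulate_cohort(gen_params, 60, seed=9)
        eng = RouteLikelihood(sim.records, quad_nodes=8, two_year_rule=False)
        single = eng.loglik(gen_params)
        k2 = gen_params.with_k(2.0)
        batch = eng.loglik_many([gen_params, k2, gen_params])
        assert batch[0] == pytest.approx(single, rel=1e-12)
        assert batch[2] == pytest.approx(single, rel=1e-12)
        assert batch[1] != pytest.approx(single)

    def test_quadrature_order_converged(self, gen_params):
        sim = simulate_cohort(gen_params, 150, seed=21)
        lls = [
            RouteLikelihood(sim.records, quad_nodes=q, two_year_rule=False).loglik(
                gen_params
            )
            for q in (8, 16, 32)
        ]
        # 8-node result already within a per-subject tolerance of the 32-node one
        assert abs(lls[0] - lls[2]) < 1e-3
        assert abs(lls[1] - lls[2]) < 1e-4
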