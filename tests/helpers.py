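"""Shared independent oracles for the test suite.

These deliberately avoid the package's quadrature machinery: the
constant-hazard limit is solved with a matrix exponential of the five-state
generator, and conservation sums enumerate observable patterns by hand.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from semicr import (
    Covariates,
    IndividualRecord,
    ModelParams,
    State,
    WeibullParams,
    integrated_death_probability,
    route_probability,
)
from semicr.model import TRANSITIONS

STATE_ORDER = [State.H, State.CI, State.LTF, State.CILTF, State.D]


def exponential_params(rates=None, baseline_logit=(0.0, 0.0, 0.0)) -> ModelParams:
    """A constant-hazard (all shapes = 1, no covariate effects) parameter set."""
    rates = rates or {1: 0.05, 2: 0.08, 3: 0.12, 4: 0.10, 5: 0.07, 8: 0.20}
    weib = {m: WeibullParams(r, 1.0, np.zeros(2)) for m, r in rates.items()}
    return ModelParams(weib, k=1.0, baseline_logit=np.asarray(baseline_logit, float))


def generator_matrix(p: ModelParams, x: Covariates) -> np.ndarray:
    """5x5 intensity matrix of the constant-hazard model (shapes must be 1)."""
    Q = np.zeros((5, 5))
    for m, (o, d) in TRANSITIONS.items():
        w = p.weibull_for(m)
        assert np.isclose(w.alpha, 1.0)
        Q[STATE_ORDER.index(o), STATE_ORDER.index(d)] = w.tau * np.exp(
            x.vector @ w.beta
        )
    for i in range(5):
        Q[i, i] = -Q[i].sum()
    return Q


def occupancy(p: ModelParams, x: Covariates, start: State, t: float) -> np.ndarray:
    """State-occupancy probabilities at time t from ``start`` at 0."""
    P = expm(generator_matrix(p, x) * t)
    return P[STATE_ORDER.index(start)]


def conservation_total(
    p: ModelParams, x: Covariates, interview: float = 2.0, T: float = 4.0
) -> float:
    """Total probability of all observable patterns under the two-interview
    schedule (screen at 0, one follow-up), death kernels integrated over the
    death time.  Should equal 1."""

    def rec(**kw):
        return IndividualRecord(id=0, x=x, end_time=T, **kw)

    s = interview
    alive = [
        rec(baseline_state=State.H, last_healthy_time=s),
        rec(baseline_state=State.H, last_healthy_time=0.0, ci_first_time=s, ci_last_time=s),
        rec(baseline_state=State.H, last_healthy_time=0.0, ltf_lower=0.0, ltf_upper=s),
        rec(baseline_state=State.CI, ci_last_time=s),
        rec(baseline_state=State.CI, ci_last_time=0.0, ltf_lower=0.0, ltf_upper=s),
    ]
    total = sum(route_probability(r, p, two_year_rule=False) for r in alive)
    mid_early, mid_late = 0.5 * s, 0.5 * (s + T)
    death_specs = [
        (rec(baseline_state=State.H, last_healthy_time=0.0, death_time=mid_early), 0.0, s),
        (rec(baseline_state=State.H, last_healthy_time=s, death_time=mid_late), s, T),
        (
            rec(
                baseline_state=State.H,
                last_healthy_time=0.0,
                ci_first_time=s,
                ci_last_time=s,
                death_time=mid_late,
            ),
            s,
            T,
        ),
        (
            rec(
                baseline_state=State.H,
                last_healthy_time=0.0,
                ltf_lower=0.0,
                ltf_upper=s,
                death_time=mid_late,
            ),
            s,
            T,
        ),
        (rec(baseline_state=State.CI, ci_last_time=0.0, death_time=mid_early), 0.0, s),
        (rec(baseline_state=State.CI, ci_last_time=s, death_time=mid_late), s, T),
        (
            rec(
                baseline_state=State.CI,
                ci_last_time=0.0,
                ltf_lower=0.0,
                ltf_upper=s,
                death_time=mid_late,
            ),
            s,
            T,
        ),
    ]
    for r, lo, hi in death_specs:
        total += integrated_death_probability(r, lo, hi, p)
    return total


def pattern_record(route: int, x: Covariates, end_time: float, row) -> IndividualRecord:
    """Rebuild the representative record of a Monte-Carlo pattern row."""

    def opt(v):
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

    base = State.H if route in (1, 2, 3, 4, 5, 6, 9, 10) else State.CI
    return IndividualRecord(
        id=0,
        x=x,
        baseline_state=base,
        end_time=end_time,
        last_healthy_time=opt(row.a),
        ci_first_time=opt(row.b),
        ci_last_time=opt(row.b_last),
        ltf_lower=opt(row.l0),
        ltf_upper=opt(row.l1),
    )
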