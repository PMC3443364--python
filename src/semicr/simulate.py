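"""Latent-trajectory simulation and interview-schedule observation.

Generates complete five-state trajectories by exact inversion of each
competing Weibull cumulative hazard on the global clock, then collapses them
through an interview schedule into the interval-censored records the
likelihood consumes.  The simulator doubles as a Monte-Carlo oracle: observed
pattern frequencies must match the quadrature route probabilities, and latent
state occupancies must match matrix-exponential results in the
constant-hazard limit.

The default generating configuration emulates a single-centre ageing cohort:
baseline ages truncated-normal on [64, 103] years (median about 74), roughly
63 per cent female, a prevalence screen at entry with logistic baseline
impairment, follow-up interviews at 2, 4, 7 and 10 years, and administrative
end of follow-up at 12 years.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .likelihood import IndividualRecord, classify_route
from .model import (
    TRANSITIONS,
    EXITS,
    Covariates,
    ModelParams,
    State,
    WeibullParams,
    baseline_ci_probability,
)


@dataclass(frozen=True)
class Schedule:
    """Interview times (years; the first is the prevalence screen at 0) and
    the administrative end of follow-up."""

    times: tuple[float, ...]
    end_time: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if len(t) == 0 or t[0] != 0.0:
            raise ValueError("schedule must start with the prevalence screen at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("interview times must be strictly increasing")
        if np.any(t > self.end_time):
            raise ValueError("interview times must not exceed end_time")


def default_schedule() -> Schedule:
    return Schedule((0.0, 2.0, 4.0, 7.0, 10.0), 12.0)


def default_params(k: float = 1.0) -> ModelParams:
    """Illustrative cohort-scale generating parameters.

    Death-transition intercepts, shapes and covariate effects use published
    cohort magnitudes for this kind of ageing study; the non-death intercepts
    and shapes are chosen to reproduce the qualitative pattern of such data
    (early-decaying drop-out hazard, a large early CI->CI(LTF) rate) at
    plausible event counts.  Illustrative, not ground truth.
    """
    weib = {
        1: WeibullParams(0.052, 1.156, np.array([0.082, -0.602])),  # H -> D
        2: WeibullParams(0.020, 1.200, np.array([0.133, 0.455])),   # H -> CI
        3: WeibullParams(0.094, 1.321, np.array([0.053, -0.328])),  # CI -> D
        4: WeibullParams(0.100, 0.750, np.array([0.014, 0.404])),   # H -> LTF
        5: WeibullParams(0.024, 1.636, np.array([0.087, -0.552])),  # LTF -> D
        8: WeibullParams(0.350, 0.600, np.array([-0.023, 0.096])),  # CI -> CI(LTF)
    }
    return ModelParams(
        weib,
        k=k,
        baseline_logit=np.array([-2.4, 0.10, 0.50]),
        age_center=74.0,
    )


@dataclass
class LatentTrajectory:
    """A complete simulated state path: (state, entry time) pairs starting at
    time 0, plus the exact death time when death occurred in follow-up."""

    path: list[tuple[State, float]]
    death_time: Optional[float]
    x: Covariates

    def state_at(self, t: float) -> State:
        if self.death_time is not None and t >= self.death_time:
            return State.D
        current = self.path[0][0]
        for state, entry in self.path:
            if entry <= t:
                current = state
            else:
                break
        return current

    def entered(self, states: Sequence[State], by: float) -> bool:
        """Did the trajectory enter any of ``states`` at or before ``by``?"""
        return any(s in states and e <= by for s, e in self.path)


def _exit_rates(p: ModelParams, x: Covariates) -> tuple[dict, dict]:
    xv = x.vector
    c, a = {}, {}
    for m in range(1, 9):
        w = p.weibull_for(m)
        c[m] = w.tau * np.exp(xv @ w.beta)
        a[m] = w.alpha
    return c, a


def sample_trajectory(
    p: ModelParams,
    x: Covariates,
    T: float,
    rng: np.random.Generator,
) -> LatentTrajectory:
    """Exact simulation of one latent trajectory up to time T.

    The baseline state is Bernoulli in the logistic screen probability; from a
    state occupied at time s each competing exit time solves
    ``c_m * (t**alpha_m - s**alpha_m) = E`` with ``E ~ Exp(1)`` and the
    earliest candidate wins.
    """
    if T <= 0:
        raise ValueError("need T > 0")
    c, a = _exit_rates(p, x)
    return _sample_with_rates(p, x, T, rng, c, a)


def _sample_with_rates(p, x, T, rng, c, a) -> LatentTrajectory:
    pi = baseline_ci_probability(x, p)
    state = State.CI if rng.random() < pi else State.H
    t = 0.0
    path = [(state, 0.0)]
    death = None
    while True:
        best_t = np.inf
        best_m = None
        for m in EXITS[state]:
            e = rng.exponential()
            tm = (t ** a[m] + e / c[m]) ** (1.0 / a[m])
            if tm < best_t:
                best_t = tm
                best_m = m
        if best_t > T:
            break
        t = best_t
        state = TRANSITIONS[best_m][1]
        if state is State.D:
            death = t
            break
        path.append((state, t))
    return LatentTrajectory(path, death, x)


def observe(
    traj: LatentTrajectory,
    schedule: Schedule,
    id: object = 0,
) -> IndividualRecord:
    """Collapse a latent trajectory into an interval-censored record.

    A subject attends an interview iff latently healthy or impaired at that
    time; the first missed interview defines the LTF interval and ends
    observation; exact death times are always recorded (registry flagging).
    """
    T = schedule.end_time
    base = traj.path[0][0]
    a = b = bp = l0 = l1 = None
    last_attended = 0.0
    for s_j in schedule.times:
        if traj.death_time is not None and traj.death_time <= s_j:
            break
        st = traj.state_at(s_j)
        if st is State.H:
            a = s_j
            last_attended = s_j
        elif st is State.CI:
            if base is State.H and b is None:
                b = s_j
            bp = s_j
            last_attended = s_j
        else:
            l0 = last_attended
            l1 = s_j
            break
    death = traj.death_time if (traj.death_time is not None and traj.death_time <= T) else None
    if base is State.CI:
        a = None  # impairment known from entry; no healthy interview exists
    return IndividualRecord(
        id=id,
        x=traj.x,
        baseline_state=base,
        end_time=T,
        last_healthy_time=a,
        ci_first_time=b,
        ci_last_time=bp,
        ltf_lower=l0,
        ltf_upper=l1,
        death_time=death,
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def default_covariate_generator(
    rng: np.random.Generator, n: int, age_center: float = 74.0
) -> np.ndarray:
    """Baseline covariates mimicking an elderly screening cohort: ages
    truncated-normal(75, 7) on [64, 103] years, 63 per cent female.  Returns
    an (n, 2) array of (centred age, sex)."""
    lo, hi = (64.0 - 75.0) / 7.0, (103.0 - 75.0) / 7.0
    ages = stats.truncnorm.rvs(lo, hi, loc=75.0, scale=7.0, size=n, random_state=rng)
    sex = (rng.random(n) < 0.63).astype(int)
    return np.column_stack([ages - age_center, sex])


@dataclass
class CohortSim:
    """Observed records plus the latent truths behind them."""

    records: list[IndividualRecord]
    trajectories: list[LatentTrajectory]
    params: ModelParams
    schedule: Schedule
    seed: int

    @property
    def latent_frame(self) -> pd.DataFrame:
        rows = []
        for i, tr in enumerate(self.trajectories):
            for st, e in tr.path:
                rows.append({"id": i, "state": st.value, "entry_time": e})
            if tr.death_time is not None:
                rows.append({"id": i, "state": "D", "entry_time": tr.death_time})
        return pd.DataFrame(rows, columns=["id", "state", "entry_time"])


def simulate_cohort(
    p: ModelParams,
    n: int,
    schedule: Optional[Schedule] = None,
    covariate_generator: Optional[Callable] = None,
    seed: int = 0,
) -> CohortSim:
    """Simulate ``n`` subjects (reproducible given ``seed``)."""
    if n < 1:
        raise ValueError("need n >= 1")
    schedule = schedule or default_schedule()
    rng = np.random.default_rng(seed)
    gen = covariate_generator or (
        lambda r, m: default_covariate_generator(r, m, p.age_center)
    )
    X = np.asarray(gen(rng, n), dtype=float)
    records, trajs = [], []
    for i in range(n):
        x = Covariates(float(X[i, 0]), int(X[i, 1]))
        c, a = _exit_rates(p, x)
        tr = _sample_with_rates(p, x, schedule.end_time, rng, c, a)
        records.append(observe(tr, schedule, id=i))
        trajs.append(tr)
    return CohortSim(records, trajs, p, schedule, seed)


# ---------------------------------------------------------------------------
# Monte-Carlo pattern frequencies (the likelihood oracle)
# ---------------------------------------------------------------------------


def _pattern_key(rec: IndividualRecord, death_bin_edges) -> tuple:
    rnd = lambda v: None if v is None else round(v, 6)
    key = [
        classify_route(rec).route_id,
        rnd(rec.last_healthy_time),
        rnd(rec.ci_first_time),
        rnd(rec.ci_last_time),
        rnd(rec.ltf_lower),
        rnd(rec.ltf_upper),
    ]
    if rec.death_time is None:
        key.extend([None, None])
    else:
        if death_bin_edges is None:
            key.extend([0.0, rec.end_time])
        else:
            j = int(np.searchsorted(death_bin_edges, rec.death_time, side="right")) - 1
            j = min(max(j, 0), len(death_bin_edges) - 2)
            key.extend([float(death_bin_edges[j]), float(death_bin_edges[j + 1])])
    return tuple(key)


def mc_route_probabilities(
    p: ModelParams,
    x: Covariates,
    schedule: Schedule,
    n: int,
    seed: int = 0,
    death_bin_edges: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Empirical frequencies of the realizable observed patterns for a fixed
    covariate profile, with binomial Monte-Carlo standard errors.

    Patterns are keyed by route and the defining interview times; deaths are
    binned on the death time (by ``death_bin_edges`` when given, otherwise a
    single bin spanning follow-up).  Frequencies sum to one exactly.
    """
    rng = np.random.default_rng(seed)
    c, a = _exit_rates(p, x)
    counts: dict[tuple, int] = {}
    for _ in range(n):
        tr = _sample_with_rates(p, x, schedule.end_time, rng, c, a)
        rec = observe(tr, schedule)
        key = _pattern_key(rec, death_bin_edges)
        counts[key] = counts.get(key, 0) + 1
    rows = []
    for key, cnt in sorted(counts.items(), key=lambda kv: (kv[0][0], str(kv[0]))):
        freq = cnt / n
        rows.append(
            {
                "route": key[0],
                "a": key[1],
                "b": key[2],
                "b_last": key[3],
                "l0": key[4],
                "l1": key[5],
                "d_lo": key[6],
                "d_hi": key[7],
                "count": cnt,
                "freq": freq,
                "se": np.sqrt(freq * (1.0 - freq) / n),
            }
        )
    return pd.DataFrame(rows)
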