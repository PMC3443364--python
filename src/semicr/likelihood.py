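"""Observed-route likelihood for the five-state model.

A subject's interval-censored history collapses into one of 12 observable
routes (healthy throughout, healthy-then-impaired, impaired-then-dead, ...).
Each route probability sums over every latent trajectory compatible with the
observations, which turns into at most doubly-nested time integrals of
Weibull sojourn survivals and intensities.  The integrals are evaluated with
fixed-order Gauss-Legendre quadrature so the likelihood is smooth and
deterministic, as a quasi-Newton optimiser requires.  Integrals whose lower
endpoint is the time origin are computed after the power substitution
``z = t**alpha`` of the attached intensity, which removes the integrable
``t**(alpha-1)`` singularity of shapes below one.

Routes are numbered

====  =====================  ====  =====================
 1    H -> H                  7    CI -> CI
 2    H -> CI                 8    CI -> D
 3    H -> CI -> D            9    H -> CI -> CI(LTF)
 4    H -> D                 10    H -> CI -> CI(LTF) -> D
 5    H -> LTF               11    CI -> CI(LTF)
 6    H -> LTF -> D          12    CI -> CI(LTF) -> D
====  =====================  ====  =====================

Routes 1-6, 9, 10 start from a healthy prevalence screen, the others from an
impaired one.  Observable LTF means a missed interview; the latent entry time
into the LTF states is only known to lie in the interval between the last
attended interview and the missed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import expit

from .model import (
    EXITS,
    Covariates,
    ModelParams,
    State,
)

DEFAULT_QUAD_NODES = 16

#: deaths this close (years) to the last observation are assumed to involve no
#: latent CI/LTF transition in between (boundary included)
TWO_YEAR_WINDOW = 2.0

#: floor applied to a route probability before taking logs; a record hitting
#: the floor is reported as effectively impossible under the parameters
PROB_FLOOR = 1e-300

ROUTES_BASELINE_H = (1, 2, 3, 4, 5, 6, 9, 10)
ROUTES_BASELINE_CI = (7, 8, 11, 12)
DEATH_ROUTES = (3, 4, 6, 8, 10, 12)


class RecordError(ValueError):
    """An individual record violates the observation-scheme invariants."""


class LikelihoodNumericalError(RuntimeError):
    """A route kernel evaluated to a non-finite value."""


@dataclass
class IndividualRecord:
    """One subject's interval-censored observation history.

    Times are years since study entry.  ``last_healthy_time`` is the last
    attended interview at which the subject was healthy; ``ci_first_time`` /
    ``ci_last_time`` bracket the attended interviews at which impairment was
    recorded (for a subject impaired at the prevalence screen only
    ``ci_last_time`` is set, and plays the role of the last attended
    interview).  A missed interview defines the loss-to-followup interval
    ``(ltf_lower, ltf_upper]`` with ``ltf_lower`` the last attended interview
    time.  Death times are exact; a subject without one is alive at
    ``end_time``.
    """

    id: object
    x: Covariates
    baseline_state: State
    end_time: float
    last_healthy_time: Optional[float] = None
    ci_first_time: Optional[float] = None
    ci_last_time: Optional[float] = None
    ltf_lower: Optional[float] = None
    ltf_upper: Optional[float] = None
    death_time: Optional[float] = None

    # -- helpers ------------------------------------------------------------

    @property
    def last_attended_time(self) -> float:
        if self.ci_last_time is not None:
            return self.ci_last_time
        if self.last_healthy_time is not None:
            return self.last_healthy_time
        raise RecordError(f"record {self.id}: no attended interview recorded")

    @property
    def last_observation_time(self) -> float:
        t = self.last_attended_time
        if self.ltf_upper is not None:
            t = max(t, self.ltf_upper)
        return t

    def validate(self) -> None:
        rid = self.id

        def err(msg: str):
            raise RecordError(f"record {rid}: {msg}")

        if self.baseline_state not in (State.H, State.CI):
            err(f"baseline state must be H or CI, got {self.baseline_state}")
        for name in (
            "last_healthy_time",
            "ci_first_time",
            "ci_last_time",
            "ltf_lower",
            "ltf_upper",
            "death_time",
            "end_time",
        ):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v < 0):
                err(f"{name} must be a finite nonnegative time, got {v}")
        if self.baseline_state is State.CI:
            if self.last_healthy_time is not None or self.ci_first_time is not None:
                err("baseline-CI subjects carry no healthy or first-CI times")
            if self.ci_last_time is None:
                err("baseline-CI subjects need a last attended interview time")
        else:
            if self.last_healthy_time is None:
                err("baseline-H subjects need a last healthy interview time")
            if (self.ci_first_time is None) != (self.ci_last_time is None):
                err("ci_first_time and ci_last_time must be present together")
            if self.ci_first_time is not None:
                if not (self.last_healthy_time < self.ci_first_time):
                    err("need last_healthy_time < ci_first_time")
                if not (self.ci_first_time <= self.ci_last_time):
                    err("need ci_first_time <= ci_last_time")
        if (self.ltf_lower is None) != (self.ltf_upper is None):
            err("LTF interval needs both endpoints")
        if self.ltf_lower is not None:
            if not (self.ltf_lower < self.ltf_upper):
                err("need ltf_lower < ltf_upper")
            if not np.isclose(self.ltf_lower, self.last_attended_time):
                err("ltf_lower must equal the last attended interview time")
        if self.death_time is not None:
            lo = self.ltf_lower if self.ltf_lower is not None else self.last_attended_time
            if not (self.death_time > lo):
                err("death must follow the last attended interview")
            if self.death_time > self.end_time:
                err("death_time cannot exceed end_time")
        obs = [
            t
            for t in (
                self.last_healthy_time,
                self.ci_last_time,
                self.ltf_upper,
                self.death_time,
            )
            if t is not None
        ]
        if obs and max(obs) > self.end_time + 1e-9:
            err("end_time must bound every observation time")


@dataclass(frozen=True)
class RoutePattern:
    """An observable route with its defining times."""

    route_id: int
    times: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.route_id not in range(1, 13):
            raise ValueError(f"route_id must be in 1..12, got {self.route_id}")


def classify_route(r: IndividualRecord) -> RoutePattern:
    """Deterministically map a valid record to one of the 12 routes."""
    r.validate()
    dead = r.death_time is not None
    ltf = r.ltf_lower is not None
    if r.baseline_state is State.H:
        ci = r.ci_first_time is not None
        if not ci and not ltf:
            rid = 4 if dead else 1
        elif ci and not ltf:
            rid = 3 if dead else 2
        elif not ci and ltf:
            rid = 6 if dead else 5
        else:
            rid = 10 if dead else 9
    else:
        if ltf:
            rid = 12 if dead else 11
        else:
            rid = 8 if dead else 7
    times = {
        "a": r.last_healthy_time,
        "b": r.ci_first_time,
        "b_last": r.ci_last_time,
        "l0": r.ltf_lower,
        "l1": r.ltf_upper,
        "d": r.death_time,
        "T": r.end_time,
    }
    return RoutePattern(rid, {k: v for k, v in times.items() if v is not None})


def apply_two_year_rule(r: IndividualRecord, route: RoutePattern) -> str:
    """Path restriction for deaths shortly after the last observation.

    A death within ``TWO_YEAR_WINDOW`` years of the last attended interview is
    assumed to involve no latent CI/LTF transition in between.  Returns one of

    * ``"none"`` -- no restriction;
    * ``"direct"`` -- routes 3, 4, 8: only the direct death path is kept;
    * ``"ltf_direct"`` -- route 6: only the observed H->LTF->D path is kept
      (the observed LTF cannot be annulled, but the latent CI branches are
      suppressed).

    Routes 10 and 12 already admit a single latent structure, so the rule
    leaves them unchanged.
    """
    if route.route_id not in DEATH_ROUTES:
        raise ValueError("the rule applies to death routes only")
    gap = r.death_time - r.last_attended_time
    if gap > TWO_YEAR_WINDOW:
        return "none"
    if route.route_id in (3, 4, 8):
        return "direct"
    if route.route_id == 6:
        return "ltf_direct"
    return "none"


# ---------------------------------------------------------------------------
# vectorised hazard/quadrature engine
# ---------------------------------------------------------------------------


def _bt(arr: np.ndarray, shape) -> np.ndarray:
    """Broadcast a leading-dims array to ``shape`` by appending node axes."""
    return np.broadcast_to(arr.reshape(arr.shape + (1,) * (len(shape) - arr.ndim)), shape)


class _Hazards:
    """Closed-form hazards for a batch of covariate profiles and (optionally)
    a batch of parameter sets.

    For each transition ``m`` the cumulative hazard over ``(s, t]`` is
    ``c_m * (t**alpha_m - s**alpha_m)`` with per-subject constant
    ``c_m = tau_m * exp(x . beta_m)`` (the derived LTF->CILTF transition is
    itself of this form with effective shape ``alpha2 + alpha5 - alpha1``).
    Arrays carry a leading (parameter-set, subject) pair of axes -- the
    parameter axis lets finite-difference gradients and Hessians evaluate
    many perturbed parameter vectors in one vectorised pass -- and quadrature
    nodes append trailing axes.  Time arrays enter with shape (1, n).
    """

    def __init__(self, params, X, quad_nodes: int = DEFAULT_QUAD_NODES):
        plist = [params] if isinstance(params, ModelParams) else list(params)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.n = X.shape[0]
        self.n_params = len(plist)
        xi, om = leggauss(quad_nodes)
        self._xi = xi
        self._om = om
        self.alpha: dict[int, np.ndarray] = {}
        self.c: dict[int, np.ndarray] = {}
        for m in range(1, 9):
            ws = [p.weibull_for(m) for p in plist]
            self.alpha[m] = np.array([[w.alpha] for w in ws])  # (P, 1)
            B = np.stack([w.beta for w in ws])  # (P, 2)
            tau = np.array([w.tau for w in ws])  # (P,)
            self.c[m] = tau[:, None] * np.exp(X @ B.T).T  # (P, n)

    @staticmethod
    def _e(arr: np.ndarray, ndim: int) -> np.ndarray:
        """Append singleton node axes so a (P, n)- or (P, 1)-shaped constant
        broadcasts against node-expanded time arrays."""
        return arr.reshape(arr.shape + (1,) * (ndim - arr.ndim))

    def cumhaz(self, m: int, s, t):
        nd = np.ndim(t)
        a = self._e(self.alpha[m], nd)
        return self._e(self.c[m], nd) * (t**a - s**a)

    def haz(self, m: int, t):
        nd = np.ndim(t)
        a = self._e(self.alpha[m], nd)
        return self._e(self.c[m], nd) * a * t ** (a - 1.0)

    def surv(self, state: State, s, t):
        tot = sum(self.cumhaz(m, s, t) for m in EXITS[state])
        return np.exp(-tot)

    def nodes(self, a, b, m: int):
        """Gauss-Legendre nodes/weights for ``int_a^b f(u) du`` after the
        substitution ``z = u**alpha_m`` (plain rule when alpha_m == 1)."""
        g = self._e(self.alpha[m], max(np.ndim(a), 2))
        ag = a**g
        bg = b**g
        half = 0.5 * (bg - ag)
        mid = 0.5 * (bg + ag)
        z = mid[..., None] + half[..., None] * self._xi
        ge = g[..., None]
        with np.errstate(divide="ignore", invalid="ignore"):
            u = z ** (1.0 / ge)
            w = self._om * half[..., None] * u / (ge * z)
        empty = z <= 0.0
        if np.any(empty):
            u = np.where(empty, 1e-12, u)
            w = np.where(empty, 0.0, w)
        return u, w

    # -- probability of any live state at T given `state` at s --------------

    def alive(self, state: State, s, T):
        if state is State.CILTF:
            return self.surv(State.CILTF, s, T)
        if state is State.LTF:
            u, w = self.nodes(s, T, 6)
            Te = _bt(T, u.shape)
            f = self.surv(State.LTF, s[..., None], u) * self.haz(6, u)
            f = f * self.surv(State.CILTF, u, Te)
            return self.surv(State.LTF, s, T) + (w * f).sum(-1)
        if state is State.CI:
            u, w = self.nodes(s, T, 8)
            Te = _bt(T, u.shape)
            f = self.surv(State.CI, s[..., None], u) * self.haz(8, u)
            f = f * self.surv(State.CILTF, u, Te)
            return self.surv(State.CI, s, T) + (w * f).sum(-1)
        if state is State.H:
            out = self.surv(State.H, s, T)
            u, w = self.nodes(s, T, 2)
            Te = _bt(T, u.shape)
            f = self.surv(State.H, s[..., None], u) * self.haz(2, u)
            out = out + (w * f * self.alive(State.CI, u, Te)).sum(-1)
            u, w = self.nodes(s, T, 4)
            Te = _bt(T, u.shape)
            f = self.surv(State.H, s[..., None], u) * self.haz(4, u)
            out = out + (w * f * self.alive(State.LTF, u, Te)).sum(-1)
            return out
        raise ValueError("death is absorbing; no alive continuation")

    # -- sub-density of death at exact time d given `state` at s ------------

    def death(self, state: State, s, d, direct: bool = False):
        if state is State.CILTF:
            return self.surv(State.CILTF, s, d) * self.haz(7, d)
        if state is State.CI:
            out = self.surv(State.CI, s, d) * self.haz(3, d)
            if not direct:
                u, w = self.nodes(s, d, 8)
                de = _bt(d, u.shape)
                f = self.surv(State.CI, s[..., None], u) * self.haz(8, u)
                f = f * self.surv(State.CILTF, u, de)
                out = out + (w * f).sum(-1) * self.haz(7, d)
            return out
        if state is State.LTF:
            out = self.surv(State.LTF, s, d) * self.haz(5, d)
            if not direct:
                u, w = self.nodes(s, d, 6)
                de = _bt(d, u.shape)
                f = self.surv(State.LTF, s[..., None], u) * self.haz(6, u)
                f = f * self.surv(State.CILTF, u, de)
                out = out + (w * f).sum(-1) * self.haz(7, d)
            return out
        if state is State.H:
            out = self.surv(State.H, s, d) * self.haz(1, d)
            if not direct:
                u, w = self.nodes(s, d, 2)
                de = _bt(d, u.shape)
                f = self.surv(State.H, s[..., None], u) * self.haz(2, u)
                out = out + (w * f * self.death(State.CI, u, de)).sum(-1)
                u, w = self.nodes(s, d, 4)
                de = _bt(d, u.shape)
                f = self.surv(State.H, s[..., None], u) * self.haz(4, u)
                out = out + (w * f * self.death(State.LTF, u, de)).sum(-1)
            return out
        raise ValueError("death density starts from a live state")

    # -- detection bracket: H at a, CI observed first at b -------------------

    def detect_ci(self, a, b):
        u, w = self.nodes(a, b, 2)
        be = _bt(b, u.shape)
        f = self.surv(State.H, a[..., None], u) * self.haz(2, u)
        f = f * self.surv(State.CI, u, be)
        return (w * f).sum(-1)

    # -- LTF-window integrals -------------------------------------------------

    def ltf_entry_alive(self, l0, up, T):
        """CI occupant at l0 enters CI(LTF) in (l0, up], any live state at T."""
        u, w = self.nodes(l0, up, 8)
        Te = _bt(T, u.shape)
        f = self.surv(State.CI, l0[..., None], u) * self.haz(8, u)
        f = f * self.surv(State.CILTF, u, Te)
        return (w * f).sum(-1)

    def ltf_entry_death(self, l0, up, d):
        """CI occupant at l0 enters CI(LTF) in (l0, up], dies at d."""
        u, w = self.nodes(l0, up, 8)
        de = _bt(d, u.shape)
        f = self.surv(State.CI, l0[..., None], u) * self.haz(8, u)
        f = f * self.surv(State.CILTF, u, de)
        return (w * f).sum(-1) * self.haz(7, d)


# ---------------------------------------------------------------------------
# route kernels
# ---------------------------------------------------------------------------


def _kernel(route: int, directive: str, hz: _Hazards, t: dict) -> np.ndarray:
    """Route kernel (likelihood factor beyond the baseline-state factor) for a
    group of subjects sharing route and path restriction."""
    H, CI, LTF, Q = State.H, State.CI, State.LTF, State.CILTF
    zero = np.zeros_like(t["T"])
    direct = directive == "direct"

    if route == 1:
        return hz.surv(H, zero, t["a"]) * hz.alive(H, t["a"], t["T"])
    if route == 2:
        occ = hz.surv(CI, t["b"], t["b_last"])
        return (
            hz.surv(H, zero, t["a"])
            * hz.detect_ci(t["a"], t["b"])
            * occ
            * hz.alive(CI, t["b_last"], t["T"])
        )
    if route == 3:
        occ = hz.surv(CI, t["b"], t["b_last"])
        return (
            hz.surv(H, zero, t["a"])
            * hz.detect_ci(t["a"], t["b"])
            * occ
            * hz.death(CI, t["b_last"], t["d"], direct=direct)
        )
    if route == 4:
        return hz.surv(H, zero, t["a"]) * hz.death(H, t["a"], t["d"], direct=direct)
    if route in (5, 6):
        l0 = t["l0"]
        if route == 5:
            up = t["l1"]
            horizon = t["T"]
        else:
            up = np.minimum(t["l1"], t["d"])
            horizon = t["d"]
        # branch 1: H -> LTF at w in (l0, up]
        u, w = hz.nodes(l0, up, 4)
        he = _bt(horizon, u.shape)
        f = hz.surv(H, l0[..., None], u) * hz.haz(4, u)
        if route == 5:
            f = f * hz.alive(LTF, u, he)
        else:
            f = f * hz.death(LTF, u, he, direct=(directive == "ltf_direct"))
        term1 = (w * f).sum(-1)
        if directive == "ltf_direct":
            return hz.surv(H, zero, l0) * term1
        # branch 2: H -> CI at u, CI -> CI(LTF) at v, l0 < u < v <= up
        u2, w2 = hz.nodes(l0, up, 2)
        upe = _bt(up, u2.shape)
        g = hz.surv(H, l0[..., None], u2) * hz.haz(2, u2)
        if route == 5:
            inner = hz.ltf_entry_alive(u2, upe, _bt(horizon, u2.shape))
        else:
            inner = hz.ltf_entry_death(u2, upe, _bt(horizon, u2.shape))
        term2 = (w2 * g * inner).sum(-1)
        return hz.surv(H, zero, l0) * (term1 + term2)
    if route == 7:
        return hz.surv(CI, zero, t["b_last"]) * hz.alive(CI, t["b_last"], t["T"])
    if route == 8:
        return hz.surv(CI, zero, t["b_last"]) * hz.death(
            CI, t["b_last"], t["d"], direct=direct
        )
    if route == 9:
        occ = hz.surv(CI, t["b"], t["b_last"])
        return (
            hz.surv(H, zero, t["a"])
            * hz.detect_ci(t["a"], t["b"])
            * occ
            * hz.ltf_entry_alive(t["l0"], t["l1"], t["T"])
        )
    if route == 10:
        occ = hz.surv(CI, t["b"], t["b_last"])
        up = np.minimum(t["l1"], t["d"])
        return (
            hz.surv(H, zero, t["a"])
            * hz.detect_ci(t["a"], t["b"])
            * occ
            * hz.ltf_entry_death(t["l0"], up, t["d"])
        )
    if route == 11:
        return hz.surv(CI, zero, t["b_last"]) * hz.ltf_entry_alive(
            t["l0"], t["l1"], t["T"]
        )
    if route == 12:
        up = np.minimum(t["l1"], t["d"])
        return hz.surv(CI, zero, t["b_last"]) * hz.ltf_entry_death(
            t["l0"], up, t["d"]
        )
    raise ValueError(f"unknown route {route}")


# ---------------------------------------------------------------------------
# dataset-level engine
# ---------------------------------------------------------------------------

_TIME_FIELDS = ("a", "b", "b_last", "l0", "l1", "d", "T")


class RouteLikelihood:
    """Vectorised log-likelihood over a dataset of individual records.

    Classification, validation, the two-year-rule directives and the grouping
    of subjects by (route, restriction) are done once at construction; every
    call to :meth:`loglik` only re-evaluates the closed-form hazard algebra
    and the quadrature sums.
    """

    def __init__(
        self,
        records: Sequence[IndividualRecord],
        quad_nodes: int = DEFAULT_QUAD_NODES,
        two_year_rule: bool = True,
    ):
        self.records = list(records)
        self.quad_nodes = quad_nodes
        self.two_year_rule = two_year_rule
        n = len(self.records)
        self.n = n
        self.X = np.empty((n, 2))
        self.routes = np.empty(n, dtype=int)
        times = {f: np.full(n, np.nan) for f in _TIME_FIELDS}
        groups: dict[tuple[int, str], list[int]] = {}
        for i, r in enumerate(self.records):
            pat = classify_route(r)
            self.routes[i] = pat.route_id
            self.X[i] = r.x.vector
            for f in _TIME_FIELDS:
                v = pat.times.get(f)
                if v is not None:
                    times[f][i] = v
            directive = "none"
            if two_year_rule and pat.route_id in DEATH_ROUTES:
                directive = apply_two_year_rule(r, pat)
            groups.setdefault((pat.route_id, directive), []).append(i)
        self._times = times
        self.groups = {k: np.asarray(v, dtype=int) for k, v in groups.items()}

    def route_probabilities_many(self, params: Sequence[ModelParams]) -> np.ndarray:
        """Per-subject likelihood contributions for a batch of parameter
        sets, shape (n_params, n_subjects)."""
        plist = list(params)
        P = len(plist)
        out = np.empty((P, self.n))
        G = np.stack([p.baseline_logit for p in plist])  # (P, 3)
        pi = expit(G[:, :1] + G[:, 1:] @ self.X.T)  # (P, n)
        for (route, directive), idx in self.groups.items():
            hz = _Hazards(plist, self.X[idx], self.quad_nodes)
            t = {f: self._times[f][idx][None, :] for f in _TIME_FIELDS}
            q = _kernel(route, directive, hz, t)
            base = pi[:, idx] if route in ROUTES_BASELINE_CI else 1.0 - pi[:, idx]
            q = base * q
            if not np.all(np.isfinite(q)):
                bad = idx[~np.all(np.isfinite(q), axis=0)]
                ids = [self.records[i].id for i in bad[:5]]
                raise LikelihoodNumericalError(
                    f"non-finite likelihood on route {route} for subjects {ids}"
                )
            out[:, idx] = q
        return out

    def route_probabilities(self, p: ModelParams) -> np.ndarray:
        """Per-subject likelihood contribution Q (probability for alive
        routes, density in the death time for death routes)."""
        return self.route_probabilities_many([p])[0]

    def subject_log_probs(self, p: ModelParams, strict: bool = False) -> np.ndarray:
        q = self.route_probabilities(p)
        zero = q <= 0.0
        if np.any(zero):
            ids = [self.records[i].id for i in np.nonzero(zero)[0][:10]]
            msg = f"zero route probability for subjects {ids}"
            if strict:
                raise LikelihoodNumericalError(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
        return np.log(np.maximum(q, PROB_FLOOR))

    def loglik(self, p: ModelParams, strict: bool = False) -> float:
        if self.n == 0:
            return 0.0
        return float(self.subject_log_probs(p, strict=strict).sum())

    def loglik_many(self, params: Sequence[ModelParams]) -> np.ndarray:
        """Log-likelihood for each parameter set in one vectorised pass
        (zero-probability records silently floored; meant for optimisation
        internals)."""
        if self.n == 0:
            return np.zeros(len(list(params)))
        q = self.route_probabilities_many(params)
        return np.log(np.maximum(q, PROB_FLOOR)).sum(axis=1)


# ---------------------------------------------------------------------------
# scalar convenience API
# ---------------------------------------------------------------------------


def _single(p: ModelParams, x: Covariates, quad_nodes: int) -> _Hazards:
    return _Hazards(p, x.vector[None, :], quad_nodes)


def alive_continuation(
    state: State,
    s: float,
    T: float,
    x: Covariates,
    p: ModelParams,
    quad_nodes: int = DEFAULT_QUAD_NODES,
) -> float:
    """Probability of occupying any live state at T given ``state`` at s."""
    if state is State.D:
        raise ValueError("death is absorbing")
    if not (0 <= s <= T):
        raise ValueError("need 0 <= s <= T")
    hz = _single(p, x, quad_nodes)
    return float(hz.alive(state, np.array([[s]]), np.array([[T]]))[0, 0])


def death_density(
    state: State,
    s: float,
    d: float,
    x: Covariates,
    p: ModelParams,
    direct_only: bool = False,
    quad_nodes: int = DEFAULT_QUAD_NODES,
) -> float:
    """Sub-density of death at exact time d given ``state`` at s < d."""
    if state is State.D:
        raise ValueError("death density starts from a live state")
    if not (0 <= s < d):
        raise ValueError("need 0 <= s < d")
    hz = _single(p, x, quad_nodes)
    return float(
        hz.death(state, np.array([[s]]), np.array([[d]]), direct=direct_only)[0, 0]
    )


def route_probability(
    r: IndividualRecord,
    p: ModelParams,
    quad_nodes: int = DEFAULT_QUAD_NODES,
    two_year_rule: bool = True,
) -> float:
    """Likelihood contribution of a single record."""
    eng = RouteLikelihood([r], quad_nodes=quad_nodes, two_year_rule=two_year_rule)
    return float(eng.route_probabilities(p)[0])


def log_likelihood(
    dataset: Iterable[IndividualRecord],
    p: ModelParams,
    quad_nodes: int = DEFAULT_QUAD_NODES,
    two_year_rule: bool = True,
    strict: bool = False,
) -> float:
    """Sum of log route probabilities over the dataset (0 when empty)."""
    eng = RouteLikelihood(list(dataset), quad_nodes=quad_nodes, two_year_rule=two_year_rule)
    return eng.loglik(p, strict=strict)


def integrated_death_probability(
    r: IndividualRecord,
    d_lo: float,
    d_hi: float,
    p: ModelParams,
    quad_nodes: int = DEFAULT_QUAD_NODES,
    two_year_rule: bool = False,
    d_nodes: int = 32,
) -> float:
    """Probability mass of a death route's pattern with the death time
    anywhere in ``(d_lo, d_hi]`` -- the route kernel (a density in d)
    integrated over the bin.  Used for conservation checks and for comparing
    against binned Monte-Carlo death-pattern frequencies."""
    from dataclasses import replace as _replace

    if not (d_lo < d_hi):
        raise ValueError("need d_lo < d_hi")
    xi, om = leggauss(d_nodes)
    mid, half = 0.5 * (d_hi + d_lo), 0.5 * (d_hi - d_lo)
    total = 0.0
    for z, w in zip(xi, om):
        d = mid + half * z
        rr = _replace(r, death_time=float(d), end_time=max(r.end_time, float(d)))
        total += half * w * route_probability(
            rr, p, quad_nodes=quad_nodes, two_year_rule=two_year_rule
        )
    return float(total)
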