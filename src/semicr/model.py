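"""Five-state semi-competing-risks model with Weibull transition intensities.

The state space describes an ageing cohort followed for cognitive decline and
death: healthy (H), cognitively impaired (CI), lost to follow-up while healthy
(LTF), cognitively impaired and lost to follow-up (CILTF), and death (D).
Death times are recorded exactly (mortality registry flagging); the illness and
drop-out processes are only seen at scheduled interviews, so their transition
times are interval-censored and the two LTF states are partially latent.

Eight transitions connect the states.  Six carry free Weibull
proportional-hazards parameter sets; two are derived through identifiability
constraints:

* transition 7 (CILTF -> D) is tied parameter-for-parameter to transition 3
  (CI -> D): death of an impaired participant does not depend on whether they
  have dropped out;
* transition 6 (LTF -> CILTF) is the ratio form
  ``lambda6 = k * lambda2 * lambda5 / lambda1``,
  i.e. the ratio of the death hazard to the impairment hazard before drop-out
  is ``k`` times the same ratio after drop-out.  ``k`` is not identifiable and
  is treated as a fixed sensitivity constant.

All hazards run on the global study clock (time since study entry), so the
process is Markov.  Each free transition ``m`` has intensity

    lambda_m(t | x) = tau_m * alpha_m * t**(alpha_m - 1) * exp(x . beta_m)

with rate-scale ``tau_m > 0``, shape ``alpha_m > 0`` and log-hazard-ratio
vector ``beta_m`` over the covariates (centred age in years, female sex
indicator).  Initial impairment at the prevalence screen follows a logistic
model in the same covariates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
from scipy.special import expit


class State(str, Enum):
    """The five states of the model."""

    H = "H"
    CI = "CI"
    LTF = "LTF"
    CILTF = "CILTF"
    D = "D"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"State.{self.name}"


#: transition index -> (origin, destination)
TRANSITIONS: dict[int, tuple[State, State]] = {
    1: (State.H, State.D),
    2: (State.H, State.CI),
    3: (State.CI, State.D),
    4: (State.H, State.LTF),
    5: (State.LTF, State.D),
    6: (State.LTF, State.CILTF),
    7: (State.CILTF, State.D),
    8: (State.CI, State.CILTF),
}

FREE_TRANSITIONS: tuple[int, ...] = (1, 2, 3, 4, 5, 8)
DERIVED_TRANSITIONS: tuple[int, ...] = (6, 7)

#: transitions leaving each live state
EXITS: dict[State, tuple[int, ...]] = {
    State.H: (1, 2, 4),
    State.CI: (3, 8),
    State.LTF: (5, 6),
    State.CILTF: (7,),
}

LIVE_STATES: tuple[State, ...] = (State.H, State.CI, State.LTF, State.CILTF)

#: default centring constant for baseline age (years)
DEFAULT_AGE_CENTER = 74.0

N_COVARIATES = 2  # centred age, sex


class DegenerateConstraintError(ValueError):
    """The derived LTF->CILTF hazard is not integrable (effective shape <= 0)."""


@dataclass(frozen=True)
class StateGraph:
    """The transition graph of the model.

    A small structural object used for validation and reporting; the numeric
    machinery indexes transitions directly.
    """

    states: tuple[State, ...] = tuple(State)
    transitions: Mapping[int, tuple[State, State]] = field(
        default_factory=lambda: dict(TRANSITIONS)
    )
    free: tuple[int, ...] = FREE_TRANSITIONS
    derived: tuple[int, ...] = DERIVED_TRANSITIONS

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def validate(self) -> None:
        """Check the structural invariants of the graph.

        Uses :mod:`networkx` for the path/acyclicity checks.
        """
        import networkx as nx

        if len(self.states) != 5:
            raise ValueError("model requires exactly 5 states")
        if len(self.transitions) != 8:
            raise ValueError("model requires exactly 8 transitions")
        if set(self.free) != {1, 2, 3, 4, 5, 8} or set(self.derived) != {6, 7}:
            raise ValueError("free/derived partition is fixed by the constraints")
        g = nx.DiGraph()
        g.add_nodes_from(self.states)
        g.add_edges_from(self.transitions.values())
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("transition graph must be acyclic")
        if g.out_degree(State.D) != 0:
            raise ValueError("death must be absorbing")
        for s in self.states:
            if s is State.D:
                continue
            if not nx.has_path(g, s, State.D):
                raise ValueError(f"no path from {s} to death")


@dataclass(frozen=True)
class Covariates:
    """Per-subject covariates: centred baseline age (years) and sex.

    ``sex`` is coded 0 = male (reference), 1 = female.  ``age_c`` is baseline
    age minus the cohort centring constant, so ``age_c = 0`` is "mean study
    age".
    """

    age_c: float
    sex: int

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be 0 or 1, got {self.sex}")
        if not np.isfinite(self.age_c):
            raise ValueError("age_c must be finite")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.age_c, float(self.sex)])


@dataclass(frozen=True)
class WeibullParams:
    """Weibull proportional-hazards parameters for one transition."""

    tau: float
    alpha: float
    beta: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        if not (self.tau > 0):
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.beta.shape != (N_COVARIATES,) or not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be a finite vector of length 2 (age, sex)")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set: six free Weibull triples, the sensitivity constant
    ``k``, and the baseline-impairment logistic coefficients.

    ``k`` is fixed, never estimated; the free-parameter vector has
    ``6 * 4 + 3 = 27`` entries in the default two-covariate configuration.
    """

    weibull: Mapping[int, WeibullParams]
    k: float = 1.0
    baseline_logit: np.ndarray = field(
        default_factory=lambda: np.zeros(1 + N_COVARIATES)
    )
    age_center: float = DEFAULT_AGE_CENTER

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "baseline_logit", np.asarray(self.baseline_logit, dtype=float)
        )
        if not (self.k > 0):
            raise ValueError(f"sensitivity constant k must be positive, got {self.k}")
        if set(self.weibull) != set(FREE_TRANSITIONS):
            raise ValueError(
                f"weibull must carry exactly the free transitions {FREE_TRANSITIONS}"
            )
        if self.baseline_logit.shape != (1 + N_COVARIATES,):
            raise ValueError("baseline_logit must be (gamma0, gamma_age, gamma_sex)")

    # -- derived transitions ------------------------------------------------

    def weibull_for(self, m: int) -> WeibullParams:
        """Weibull triple for any transition, deriving 6 and 7 from the
        constraints."""
        if m in self.weibull:
            return self.weibull[m]
        if m == 7:
            return self.weibull[3]
        if m == 6:
            w1, w2, w5 = self.weibull[1], self.weibull[2], self.weibull[5]
            a6 = w2.alpha + w5.alpha - w1.alpha
            if a6 <= 0:
                raise DegenerateConstraintError(
                    f"effective LTF->CILTF shape alpha2+alpha5-alpha1 = {a6:.4g} <= 0"
                )
            tau6 = self.k * (w2.tau * w2.alpha * w5.tau * w5.alpha) / (
                w1.tau * w1.alpha * a6
            )
            return WeibullParams(tau6, a6, w2.beta + w5.beta - w1.beta)
        raise ValueError(f"unknown transition index {m}")

    @property
    def n_free(self) -> int:
        return len(FREE_TRANSITIONS) * (2 + N_COVARIATES) + (1 + N_COVARIATES)

    # -- free-vector packing ------------------------------------------------

    def to_vector(self) -> np.ndarray:
        """Pack the free parameters on the unconstrained optimisation scale
        (log tau, log alpha, beta_age, beta_sex per transition, then the
        logistic coefficients)."""
        out: list[float] = []
        for m in FREE_TRANSITIONS:
            w = self.weibull[m]
            out.extend([np.log(w.tau), np.log(w.alpha), *w.beta])
        out.extend(self.baseline_logit)
        return np.array(out)

    @classmethod
    def from_vector(
        cls,
        theta: np.ndarray,
        k: float = 1.0,
        age_center: float = DEFAULT_AGE_CENTER,
    ) -> "ModelParams":
        theta = np.asarray(theta, dtype=float)
        blk = 2 + N_COVARIATES
        expect = len(FREE_TRANSITIONS) * blk + 1 + N_COVARIATES
        if theta.shape != (expect,):
            raise ValueError(f"expected free vector of length {expect}")
        weib = {}
        for i, m in enumerate(FREE_TRANSITIONS):
            b = theta[i * blk : (i + 1) * blk]
            weib[m] = WeibullParams(np.exp(b[0]), np.exp(b[1]), b[2:])
        gamma = theta[len(FREE_TRANSITIONS) * blk :]
        return cls(weib, k=k, baseline_logit=gamma, age_center=age_center)

    def with_k(self, k: float) -> "ModelParams":
        return replace(self, k=k)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "age_center": self.age_center,
            "baseline_logit": list(map(float, self.baseline_logit)),
            "weibull": {
                str(m): {
                    "tau": w.tau,
                    "alpha": w.alpha,
                    "beta": list(map(float, w.beta)),
                }
                for m, w in sorted(self.weibull.items())
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParams":
        weib = {
            int(m): WeibullParams(v["tau"], v["alpha"], np.asarray(v["beta"]))
            for m, v in d["weibull"].items()
        }
        return cls(
            weib,
            k=float(d.get("k", 1.0)),
            baseline_logit=np.asarray(d["baseline_logit"], dtype=float),
            age_center=float(d.get("age_center", DEFAULT_AGE_CENTER)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


#: ordered names of the free parameters (optimisation scale)
def free_parameter_names(
    free: Iterable[int] = FREE_TRANSITIONS,
) -> list[str]:
    names = []
    for m in free:
        names.extend(
            [f"log_tau_{m}", f"log_alpha_{m}", f"beta_age_{m}", f"beta_sex_{m}"]
        )
    names.extend(["gamma_0", "gamma_age", "gamma_sex"])
    return names


# ---------------------------------------------------------------------------
# hazard primitives (scalar / array over t; single covariate profile)
# ---------------------------------------------------------------------------


def hazard(m: int, t, x: Covariates, p: ModelParams):
    """Transition intensity lambda_m(t | x); ``t`` may be an array, t > 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("hazard requires t > 0")
    w = p.weibull_for(m)
    return w.tau * w.alpha * t ** (w.alpha - 1.0) * np.exp(x.vector @ w.beta)


def cumulative_hazard(m: int, s, t, x: Covariates, p: ModelParams):
    """Integrated intensity over (s, t], closed form for every transition
    (the derived ratio hazard is itself Weibull-type)."""
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(s < 0) or np.any(t < s):
        raise ValueError("cumulative_hazard requires 0 <= s <= t")
    w = p.weibull_for(m)
    return w.tau * np.exp(x.vector @ w.beta) * (t**w.alpha - s**w.alpha)


def sojourn_survival(state: State, s, t, x: Covariates, p: ModelParams):
    """Probability of no exit from ``state`` over (s, t]."""
    if state is State.D:
        raise ValueError("death is absorbing; sojourn survival is undefined")
    total = sum(cumulative_hazard(m, s, t, x, p) for m in EXITS[state])
    return np.exp(-total)


def baseline_ci_probability(x: Covariates, p: ModelParams):
    """Logistic probability of being impaired at the prevalence screen."""
    g = p.baseline_logit
    return float(expit(g[0] + g[1] * x.age_c + g[2] * x.sex))
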