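"""Model-based survival and cumulative-incidence curves.

The survival curve marginalises over the baseline screen state:
``P(alive at t) = pi(x) A(CI, 0, t) + (1 - pi(x)) A(H, 0, t)`` where ``A`` is
the all-live-states continuation probability.  The impairment cumulative
incidence is the sub-distribution probability of having entered either
impaired state (observed CI or latent post-LTF CI) by t starting healthy,
with death acting as a competing risk through the path construction:

    F(t) = int_0^t [ S_H(0,u) lambda2(u)
                     + int_0^u S_H(0,w) lambda4(w) S_LTF(w,u) lambda6(u) dw ] du.

Because ``lambda6`` carries the sensitivity constant ``k``, the incidence
curve -- unlike the regression coefficients -- is genuinely sensitive to k.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .likelihood import DEFAULT_QUAD_NODES, _Hazards, _bt
from .model import Covariates, ModelParams, State, baseline_ci_probability


@dataclass(frozen=True)
class CurveSpec:
    """A curve request: covariate profile, time grid (years, starting at 0),
    curve kind and the sensitivity constant used."""

    x: Covariates
    grid: tuple[float, ...]
    kind: str
    k: float

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if len(g) == 0 or g[0] != 0.0 or np.any(np.diff(g) <= 0):
            raise ValueError("grid must be strictly increasing and start at 0")
        if self.kind not in ("survival", "ci_incidence"):
            raise ValueError("kind must be 'survival' or 'ci_incidence'")


def _grid_hazards(p: ModelParams, x: Covariates, n: int, quad_nodes: int) -> _Hazards:
    X = np.tile(x.vector, (n, 1))
    return _Hazards(p, X, quad_nodes)


def survival_curve(
    p: ModelParams,
    x: Covariates,
    grid,
    quad_nodes: int = DEFAULT_QUAD_NODES,
) -> np.ndarray:
    """P(alive at t) on the grid, marginalised over the screen state."""
    grid = np.asarray(grid, dtype=float)[None, :]
    hz = _grid_hazards(p, x, grid.shape[1], quad_nodes)
    zero = np.zeros_like(grid)
    pi = baseline_ci_probability(x, p)
    out = pi * hz.alive(State.CI, zero, grid) + (1.0 - pi) * hz.alive(
        State.H, zero, grid
    )
    return out[0]


def ci_cumulative_incidence(
    p: ModelParams,
    x: Covariates,
    grid,
    k: Optional[float] = None,
    quad_nodes: int = DEFAULT_QUAD_NODES,
) -> np.ndarray:
    """Sub-distribution probability of impairment (observed or latent
    post-LTF) by each grid time, starting healthy at entry.  ``k`` overrides
    the sensitivity constant carried by ``p``."""
    if k is not None:
        p = p.with_k(k)
    grid = np.asarray(grid, dtype=float)[None, :]
    hz = _grid_hazards(p, x, grid.shape[1], quad_nodes)
    zero = np.zeros_like(grid)
    # direct H -> CI entries
    u, w = hz.nodes(zero, grid, 2)
    direct = (w * hz.surv(State.H, zero[..., None], u) * hz.haz(2, u)).sum(-1)
    # latent path H -> LTF -> CI(LTF): outer over the CI(LTF) entry time v
    v, wv = hz.nodes(zero, grid, 6)
    zz = np.zeros_like(v)
    uw, ww = hz.nodes(zz, v, 4)
    inner = (
        ww
        * hz.surv(State.H, _bt(zz, uw.shape), uw)
        * hz.haz(4, uw)
        * hz.surv(State.LTF, uw, _bt(v, uw.shape))
    ).sum(-1)
    latent = (wv * hz.haz(6, v) * inner).sum(-1)
    return (direct + latent)[0]


def curve_sensitivity_report(
    fits: Mapping[float, Union[ModelParams, "object"]],
    x: Covariates,
    grid,
    quad_nodes: int = DEFAULT_QUAD_NODES,
):
    """Survival and impairment-incidence curves for each fitted k, plus the
    maximum pairwise vertical discrepancy of each curve family.

    ``fits`` maps k to either a ``ModelParams`` or an object with a
    ``params`` attribute (a fit result).  Returns ``(frame, summary)`` where
    ``frame`` is tidy (t, k, kind, value) and ``summary`` holds
    ``ci_incidence_max_divergence`` and ``survival_max_divergence``.
    """
    grid = np.asarray(grid, dtype=float)
    rows = []
    curves: dict[str, dict[float, np.ndarray]] = {"survival": {}, "ci_incidence": {}}
    for k, obj in sorted(fits.items()):
        p = obj if isinstance(obj, ModelParams) else obj.params
        p = p.with_k(k)
        sv = survival_curve(p, x, grid, quad_nodes)
        ci = ci_cumulative_incidence(p, x, grid, quad_nodes=quad_nodes)
        curves["survival"][k] = sv
        curves["ci_incidence"][k] = ci
        for t, s, c in zip(grid, sv, ci):
            rows.append({"t": t, "k": k, "kind": "survival", "value": s})
            rows.append({"t": t, "k": k, "kind": "ci_incidence", "value": c})
    summary = {}
    for kind, by_k in curves.items():
        ks = sorted(by_k)
        gap = 0.0
        for i in range(len(ks)):
            for j in range(i + 1, len(ks)):
                gap = max(gap, float(np.abs(by_k[ks[i]] - by_k[ks[j]]).max()))
        summary[f"{kind}_max_divergence"] = gap
    return pd.DataFrame(rows), summary
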