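"""Net transition probabilities via the minimum-cost transportation problem.

Given the category prevalence vector at age ``a`` and at age ``a+1``, the
one-year flows between the three ordered weight categories are taken to be
the minimum-cost transport plan under an "economy of movement" cost
structure: staying put is cheapest (cost ``c0``), a one-step move costs
``c1`` and a two-step move costs ``c2``, with ``c0 < c1`` and
``2*c1 < c2`` so that mass never jumps two categories when it could cascade
through the middle one.  The default constants (0, 6, 17) come from a
calibration against longitudinal weight-category trajectories.

For any cost matrix satisfying those constraints, the optimal plan's *net*
flow across each adjacent-category boundary is a function of the marginals
alone: net flow across boundary k equals F_p(k) - F_q(k), the difference of
the two cumulative distributions.  ``closed_form_net`` implements this and
serves as an analytic cross-check on the LP solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

BOUNDARIES = ("normal_overweight", "overweight_obese")
DIRECTIONS = ("up", "down")

#: tolerance under which mismatched marginal sums are renormalized
MARGINAL_TOL = 1e-6


class InfeasibleMarginals(ValueError):
    """Source and target distributions do not carry the same total mass."""


@dataclass(frozen=True)
class CostMatrix:
    """Banded 'economy of movement' cost structure on K ordered categories.

    ``constants[s]`` is the per-unit cost of an ``s``-step move, so the cost
    of moving mass from category i to j is ``constants[|i-j|]``.  Validity
    requires strict convexity in the step distance: staying is cheapest and
    two one-step moves undercut one two-step move.
    """

    constants: tuple = (0.0, 6.0, 17.0)
    k: int = 3

    def __post_init__(self) -> None:
        if len(self.constants) != self.k:
            raise ValueError(f"need {self.k} step constants, got {len(self.constants)}")
        if not self.is_valid():
            c = self.constants
            raise ValueError(
                f"invalid economy-of-movement constants {c}: require c0 < c1 and "
                "strict convexity (e.g. 2*c1 < c2) in step distance"
            )

    def is_valid(self) -> bool:
        return _constants_valid(self.constants)

    @property
    def matrix(self) -> np.ndarray:
        idx = np.arange(self.k)
        return np.asarray(self.constants, float)[np.abs(idx[:, None] - idx[None, :])]


def _constants_valid(constants) -> bool:
    c = np.asarray(constants, float)
    if c[0] < 0 or c.ndim != 1 or len(c) < 2:
        return False
    if not np.all(np.diff(c) > 0):
        return False
    # strict convexity: an s-step move dearer than any split into two legs
    for s in range(2, len(c)):
        for a in range(1, s):
            if c[a] + c[s - a] >= c[s]:
                return False
    return True


@dataclass
class TransportPlan:
    """Optimal one-year flow matrix ``flows[i, j]`` with its marginals."""

    flows: np.ndarray
    p: np.ndarray
    q: np.ndarray
    cost: float
    age: int | None = None

    def net_flows(self) -> np.ndarray:
        """Signed net flow across each of the K-1 boundaries (positive = upward)."""
        k = len(self.p)
        nets = np.empty(k - 1)
        for b in range(k - 1):
            up = self.flows[: b + 1, b + 1 :].sum()
            down = self.flows[b + 1 :, : b + 1].sum()
            nets[b] = up - down
        return nets


def _check_marginals(p, q):
    p = np.asarray(p, float).copy()
    q = np.asarray(q, float).copy()
    if p.ndim != 1 or q.shape != p.shape:
        raise ValueError("p and q must be 1-d vectors of equal length")
    if (p < -MARGINAL_TOL).any() or (q < -MARGINAL_TOL).any():
        raise InfeasibleMarginals("negative prevalence entries")
    p, q = np.clip(p, 0.0, None), np.clip(q, 0.0, None)
    sp, sq = p.sum(), q.sum()
    if abs(sp - sq) > MARGINAL_TOL:
        raise InfeasibleMarginals(
            f"marginal sums differ beyond tolerance: {sp:.10f} vs {sq:.10f}"
        )
    if sp <= 0:
        raise InfeasibleMarginals("zero total mass")
    return p / sp * (sp + sq) / 2, q / sq * (sp + sq) / 2


def monotone_plan(p, q) -> np.ndarray:
    """North-west-corner (quantile) coupling of two distributions on ordered categories.

    This non-crossing plan is optimal for every cost matrix whose step costs
    are strictly convex in the move distance; it is also the tie-break
    representative reported when the LP optimum is degenerate.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    k = len(p)
    x = np.zeros((k, k))
    i = j = 0
    ri, rj = p[0], q[0]
    while i < k and j < k:
        m = min(ri, rj)
        x[i, j] += m
        ri -= m
        rj -= m
        if ri <= rj and i < k - 1:
            i += 1
            ri = p[i]
        elif rj < ri and j < k - 1:
            j += 1
            rj = q[j]
        else:
            break
    return x


def solve_transport(p, q, cost: CostMatrix | None = None, age: int | None = None) -> TransportPlan:
    """Minimum-cost transport plan between consecutive-age prevalence vectors.

    Solves the K^2-variable linear program with the marginal (mass
    conservation) constraints via the HiGHS simplex solver.  When the optimum
    is degenerate the monotone (non-crossing) plan is returned; its cost is
    verified against the LP optimum so the reported plan is always optimal.
    """
    cost = cost or CostMatrix()
    p, q = _check_marginals(p, q)
    k = len(p)
    if cost.k != k:
        raise ValueError(f"cost matrix is {cost.k}x{cost.k} but marginals have length {k}")
    c = cost.matrix.ravel()

    # equality constraints: row sums = p, column sums = q (one is redundant)
    a_eq = np.zeros((2 * k, k * k))
    for i in range(k):
        a_eq[i, i * k : (i + 1) * k] = 1.0
        a_eq[k + i, i::k] = 1.0
    b_eq = np.concatenate([p, q])
    res = linprog(c, A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")

    mono = monotone_plan(p, q)
    mono_cost = float((cost.matrix * mono).sum())
    if mono_cost <= res.fun + 1e-9:
        return TransportPlan(flows=mono, p=p, q=q, cost=mono_cost, age=age)
    # unreachable for valid economy-of-movement costs; kept for general matrices
    return TransportPlan(flows=res.x.reshape(k, k), p=p, q=q, cost=float(res.fun), age=age)


def closed_form_net(p, q) -> np.ndarray:
    """Signed per-boundary net flows of the optimal plan, K = 3 closed form.

    Boundary 1 (normal|overweight): p1 - q1.  Boundary 2 (overweight|obese):
    q3 - p3.  Positive values are upward (toward heavier categories).  Equal
    to the LP net flows for any valid economy-of-movement cost matrix.
    """
    p, q = _check_marginals(p, q)
    if len(p) != 3:
        raise ValueError("closed form supports K=3 only; use solve_transport")
    return np.array([p[0] - q[0], q[2] - p[2]])


def net_probabilities(nets, p, age: int | None = None, atol: float = 1e-12) -> pd.DataFrame:
    """Convert signed net flows into per-boundary, per-direction net probabilities.

    The favored direction's net flow is divided by the prevalence of its
    origin category (normal for upward crossing of boundary 1, overweight for
    upward crossing of boundary 2 and downward crossing of boundary 1, obese
    for downward crossing of boundary 2); the disfavored direction is
    reported as exactly 0.
    """
    nets = np.asarray(nets, float)
    p = np.asarray(p, float)
    rows = []
    # origin category index (into p) per (boundary, direction)
    origin = {(0, "up"): 0, (0, "down"): 1, (1, "up"): 1, (1, "down"): 2}
    for b, boundary in enumerate(BOUNDARIES):
        for direction in DIRECTIONS:
            flow = max(0.0, nets[b]) if direction == "up" else max(0.0, -nets[b])
            denom = p[origin[(b, direction)]]
            if flow > atol and denom <= atol:
                raise ValueError(
                    f"net flow {flow:.3g} across {boundary} ({direction}) with zero "
                    "origin prevalence — inconsistent marginals"
                )
            # flow can exceed the origin mass when upstream mass cascades
            # through (e.g. normal -> overweight -> obese within the year);
            # the reported probability is capped at 1
            prob = 0.0 if flow <= atol else min(flow / denom, 1.0)
            rows.append(
                {
                    "age": age,
                    "boundary": boundary,
                    "direction": direction,
                    "net_flow": flow if flow > atol else 0.0,
                    "net_prob": prob,
                    "zero_over_zero": bool(flow <= atol and denom <= atol),
                }
            )
    return pd.DataFrame(rows)


def project_forward(p, nets) -> np.ndarray:
    """Advance a prevalence vector one year using signed per-boundary net flows.

    Exact inverse of net-flow estimation: with ``nets`` computed from
    ``(p, q)`` this returns ``q`` to machine precision.
    """
    p = np.asarray(p, float)
    nets = np.asarray(nets, float)
    q = np.empty_like(p)
    q[0] = p[0] - nets[0]
    q[2] = p[2] + nets[1]
    q[1] = 1.0 - q[0] - q[2] if abs(p.sum() - 1.0) < 1e-9 else p.sum() - q[0] - q[2]
    return q


def nets_from_prevalence(P: np.ndarray) -> np.ndarray:
    """Signed net flows for every consecutive-age pair of a prevalence surface.

    ``P`` has shape (n_ages, 3); returns shape (n_ages - 1, 2).  Vectorized
    closed form, used heavily inside the bootstrap.
    """
    P = np.asarray(P, float)
    return np.column_stack([P[:-1, 0] - P[1:, 0], P[1:, 2] - P[:-1, 2]])


def net_table_from_curve(
    ages, P, stratum: str | None = None, use_lp: bool = True, cost: CostMatrix | None = None
) -> pd.DataFrame:
    """NetTransitionTable point estimates for a fitted prevalence surface.

    Point estimates go through the LP solver (``use_lp=True``); the closed
    form gives identical nets and is used for bootstrap replicates.
    """
    ages = np.asarray(ages)
    P = np.asarray(P, float)
    frames = []
    for t in range(len(ages) - 1):
        if use_lp:
            plan = solve_transport(P[t], P[t + 1], cost=cost, age=int(ages[t]))
            nets = plan.net_flows()
        else:
            nets = nets_from_prevalence(P[t : t + 2])[0]
        frames.append(net_probabilities(nets, P[t], age=int(ages[t])))
    table = pd.concat(frames, ignore_index=True)
    if stratum is not None:
        table.insert(0, "stratum", stratum)
    return table


def net_prob_array(P: np.ndarray) -> np.ndarray:
    """Net probabilities as an array of shape (n_ages-1, 2 boundaries, 2 directions).

    Vectorized equivalent of ``net_table_from_curve`` without the LP detour;
    index order matches BOUNDARIES x DIRECTIONS.
    """
    P = np.asarray(P, float)
    nets = nets_from_prevalence(P)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.zeros((len(P) - 1, 2, 2))
        out[:, 0, 0] = np.clip(nets[:, 0], 0, None) / P[:-1, 0]
        out[:, 0, 1] = np.clip(-nets[:, 0], 0, None) / P[:-1, 1]
        out[:, 1, 0] = np.clip(nets[:, 1], 0, None) / P[:-1, 1]
        out[:, 1, 1] = np.clip(-nets[:, 1], 0, None) / P[:-1, 2]
    return np.minimum(np.nan_to_num(out, nan=0.0, posinf=0.0), 1.0)
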