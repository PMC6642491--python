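"""Slack-based DEA efficiency and radial distance functions.

Implements the non-oriented slack-based measure (SBM) of efficiency, its
super-efficiency extension (super-SBM, evaluated against the peer set with
the unit under evaluation removed), and the input-oriented Farrell radial
distance, all under constant (CRS) or variable (VRS) returns to scale.

The SBM program for DMU k with inputs x_k and outputs y_k is the fractional
problem

    min ρ = (1 − (1/m) Σ_i s_i⁻/x_ik) / (1 + (1/q) Σ_r s_r⁺/y_rk)
    s.t.  X λ + s⁻ = x_k,   Y λ − s⁺ = y_k,   λ, s⁻, s⁺ ≥ 0
          (and Σ λ = 1 under VRS)

solved exactly as a linear program via the Charnes–Cooper transformation:
a scale variable t > 0 multiplies all slacks and intensities, the
denominator is normalized to 1, and the optimal (λ, s⁻, s⁺) are recovered
by dividing through by the optimal t. The super-SBM program replaces the
slack signs (reference point dominates the unit: x̄ = x_k + s⁻ ≥ X λ,
ȳ = y_k − s⁺ ≤ Y λ over peers j ≠ k) and has objective

    min δ = (1 + (1/m) Σ_i s_i⁻/x_ik) / (1 − (1/q) Σ_r s_r⁺/y_rk),

which is ≥ 1 whenever DMU k is SBM-efficient and the program is feasible;
under VRS the program can be infeasible, which is reported in the result's
status rather than raised.

All scores are units-invariant: rescaling any input or output row together
with the evaluated point leaves them unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = [
    "DEATechnology",
    "EfficiencyResult",
    "sbm_score",
    "super_sbm_score",
    "radial_distance",
    "evaluate_cross_section",
    "SLACK_TOL",
]

#: a DMU counts as SBM-efficient when its score is within this of 1
#: (equivalently its maximal slack is below it)
SLACK_TOL = 1e-7

_T_MIN = 1e-9  # lower bound keeping the Charnes-Cooper scale strictly positive


@dataclass(frozen=True)
class DEATechnology:
    """One cross-section's production possibilities.

    X is the m × n input matrix and Y the q × n output matrix over the n
    peer DMUs; ``rts`` selects constant or variable returns to scale (VRS
    adds the convexity constraint Σλ = 1).
    """

    X: np.ndarray
    Y: np.ndarray
    rts: str = "crs"
    dmu_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        if self.rts not in ("crs", "vrs"):
            raise ValueError(f"rts must be 'crs' or 'vrs', got {self.rts!r}")
        if X.shape[1] != Y.shape[1]:
            raise ValueError("X and Y must have the same number of DMU columns")
        if X.shape[1] < 1 or X.shape[0] < 1 or Y.shape[0] < 1:
            raise ValueError("need at least one DMU, one input and one output")
        if np.any(X <= 0) or np.any(Y <= 0):
            raise ValueError("DEA requires strictly positive inputs and outputs")
        if not self.dmu_ids:
            object.__setattr__(self, "dmu_ids",
                               tuple(f"DMU{j + 1:02d}" for j in range(X.shape[1])))
        elif len(self.dmu_ids) != X.shape[1]:
            raise ValueError("dmu_ids length mismatch")

    @property
    def n(self) -> int:
        return self.X.shape[1]

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def q(self) -> int:
        return self.Y.shape[0]


@dataclass
class EfficiencyResult:
    """Solved efficiency program for one DMU."""

    score: float
    input_slacks: np.ndarray
    output_slacks: np.ndarray
    lambdas: np.ndarray
    status: str  # optimal | infeasible | unbounded | numeric_failure
    model: str  # SBM | superSBM | radial
    rts: str
    dmu: str = ""
    message: str = ""

    @property
    def is_efficient(self) -> bool:
        return self.status == "optimal" and self.score >= 1.0 - SLACK_TOL

    @property
    def max_slack(self) -> float:
        if self.input_slacks.size + self.output_slacks.size == 0:
            return 0.0
        return float(max(self.input_slacks.max(initial=0.0),
                         self.output_slacks.max(initial=0.0)))


_STATUS = {0: "optimal", 1: "numeric_failure", 2: "infeasible",
           3: "unbounded", 4: "numeric_failure"}


def _solve(c, A_eq=None, b_eq=None, A_ub=None, b_ub=None, bounds=None):
    return linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                   bounds=bounds, method="highs")


def sbm_score(k: int, tech: DEATechnology) -> EfficiencyResult:
    """Non-oriented SBM efficiency of DMU ``k`` against the full peer set.

    Returns a score in (0, 1]; the score is 1 exactly when all optimal
    slacks vanish (to within :data:`SLACK_TOL`).
    """
    X, Y, n, m, q = tech.X, tech.Y, tech.n, tech.m, tech.q
    if not 0 <= k < n:
        raise IndexError(f"DMU index {k} out of range [0, {n})")
    xk, yk = X[:, k], Y[:, k]

    # variables: [t, Lam(n), Sm(m), Sp(q)] with Lam = t*lambda etc.
    nv = 1 + n + m + q
    c = np.zeros(nv)
    c[0] = 1.0
    c[1 + n:1 + n + m] = -1.0 / (m * xk)

    rows, rhs = [], []
    # denominator normalization: t + (1/q) sum Sp/y = 1
    r = np.zeros(nv)
    r[0] = 1.0
    r[1 + n + m:] = 1.0 / (q * yk)
    rows.append(r); rhs.append(1.0)
    # X Lam + Sm - t x_k = 0
    for i in range(m):
        r = np.zeros(nv)
        r[0] = -xk[i]
        r[1:1 + n] = X[i]
        r[1 + n + i] = 1.0
        rows.append(r); rhs.append(0.0)
    # Y Lam - Sp - t y_k = 0
    for s in range(q):
        r = np.zeros(nv)
        r[0] = -yk[s]
        r[1:1 + n] = Y[s]
        r[1 + n + m + s] = -1.0
        rows.append(r); rhs.append(0.0)
    if tech.rts == "vrs":
        r = np.zeros(nv)
        r[0] = -1.0
        r[1:1 + n] = 1.0
        rows.append(r); rhs.append(0.0)

    bounds = [(_T_MIN, None)] + [(0, None)] * (n + m + q)
    res = _solve(c, A_eq=np.array(rows), b_eq=np.array(rhs), bounds=bounds)
    status = _STATUS.get(res.status, "numeric_failure")
    if status != "optimal":
        return EfficiencyResult(np.nan, np.full(m, np.nan), np.full(q, np.nan),
                                np.full(n, np.nan), status, "SBM", tech.rts,
                                tech.dmu_ids[k], res.message)
    t = res.x[0]
    lam = res.x[1:1 + n] / t
    sm = res.x[1 + n:1 + n + m] / t
    sp = res.x[1 + n + m:] / t
    score = float(res.fun)
    # rounding guard: scores within SLACK_TOL of 1 are exactly efficient
    score = min(max(score, _T_MIN), 1.0)
    if score > 1.0 - SLACK_TOL:
        score = 1.0
    return EfficiencyResult(score, sm, sp, lam, "optimal", "SBM", tech.rts,
                            tech.dmu_ids[k])


def super_sbm_score(k: int, tech: DEATechnology) -> EfficiencyResult:
    """Super-efficiency SBM of DMU ``k`` against the peer set excluding it.

    The reference point (x_k + s⁻, y_k − s⁺) must be producible by the
    remaining peers, so δ ≥ 1 for SBM-efficient units; under VRS with no
    dominating convex combination the program is infeasible and the result
    carries ``status='infeasible'``.
    """
    X, Y, n, m, q = tech.X, tech.Y, tech.n, tech.m, tech.q
    if not 0 <= k < n:
        raise IndexError(f"DMU index {k} out of range [0, {n})")
    xk, yk = X[:, k], Y[:, k]
    peers = [j for j in range(n) if j != k]
    if not peers:
        return EfficiencyResult(np.nan, np.full(m, np.nan), np.full(q, np.nan),
                                np.array([]), "infeasible", "superSBM", tech.rts,
                                tech.dmu_ids[k], "no peers")
    Xp, Yp = X[:, peers], Y[:, peers]
    npeers = len(peers)

    # variables: [t, Lam(npeers), Sm(m), Sp(q)]
    nv = 1 + npeers + m + q
    c = np.zeros(nv)
    c[0] = 1.0
    c[1 + npeers:1 + npeers + m] = 1.0 / (m * xk)

    eq_rows, eq_rhs, ub_rows, ub_rhs = [], [], [], []
    # denominator: t - (1/q) sum Sp/y = 1
    r = np.zeros(nv)
    r[0] = 1.0
    r[1 + npeers + m:] = -1.0 / (q * yk)
    eq_rows.append(r); eq_rhs.append(1.0)
    # Xp Lam - Sm - t x_k <= 0  (reference input t*x_k + Sm covers peers)
    for i in range(m):
        r = np.zeros(nv)
        r[0] = -xk[i]
        r[1:1 + npeers] = Xp[i]
        r[1 + npeers + i] = -1.0
        ub_rows.append(r); ub_rhs.append(0.0)
    # -Yp Lam - Sp + t y_k <= 0  (reference output t*y_k - Sp within peers)
    for s in range(q):
        r = np.zeros(nv)
        r[0] = yk[s]
        r[1:1 + npeers] = -Yp[s]
        r[1 + npeers + m + s] = -1.0
        ub_rows.append(r); ub_rhs.append(0.0)
    # reference outputs stay nonnegative: Sp <= t y_k
    for s in range(q):
        r = np.zeros(nv)
        r[0] = -yk[s]
        r[1 + npeers + m + s] = 1.0
        ub_rows.append(r); ub_rhs.append(0.0)
    if tech.rts == "vrs":
        r = np.zeros(nv)
        r[0] = -1.0
        r[1:1 + npeers] = 1.0
        eq_rows.append(r); eq_rhs.append(0.0)

    bounds = [(_T_MIN, None)] + [(0, None)] * (npeers + m + q)
    res = _solve(c, A_eq=np.array(eq_rows), b_eq=np.array(eq_rhs),
                 A_ub=np.array(ub_rows), b_ub=np.array(ub_rhs), bounds=bounds)
    status = _STATUS.get(res.status, "numeric_failure")
    if status != "optimal":
        return EfficiencyResult(np.nan, np.full(m, np.nan), np.full(q, np.nan),
                                np.full(n, np.nan), status, "superSBM", tech.rts,
                                tech.dmu_ids[k], res.message)
    t = res.x[0]
    lam = np.zeros(n)
    lam[peers] = res.x[1:1 + npeers] / t
    sm = res.x[1 + npeers:1 + npeers + m] / t
    sp = res.x[1 + npeers + m:] / t
    return EfficiencyResult(float(res.fun), sm, sp, lam, "optimal", "superSBM",
                            tech.rts, tech.dmu_ids[k])


def radial_distance(x0: np.ndarray, y0: np.ndarray, tech: DEATechnology) -> EfficiencyResult:
    """Input-oriented Farrell distance of an arbitrary point to a technology.

    θ = min {θ : X λ ≤ θ x0, Y λ ≥ y0 (, Σλ = 1 under VRS), λ ≥ 0}. The
    point need not belong to the technology, so θ may exceed 1; under VRS a
    cross-period point can be infeasible, flagged in ``status``.
    """
    X, Y, n, m, q = tech.X, tech.Y, tech.n, tech.m, tech.q
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    if x0.shape != (m,) or y0.shape != (q,):
        raise ValueError("point dimensions do not match the technology")
    if np.any(x0 <= 0) or np.any(y0 <= 0):
        raise ValueError("evaluated point must be strictly positive")

    # variables: [theta, lambda(n)]
    nv = 1 + n
    c = np.zeros(nv)
    c[0] = 1.0
    ub_rows, ub_rhs = [], []
    for i in range(m):  # X lam - theta x0 <= 0
        r = np.zeros(nv)
        r[0] = -x0[i]
        r[1:] = X[i]
        ub_rows.append(r); ub_rhs.append(0.0)
    for s in range(q):  # -Y lam <= -y0
        r = np.zeros(nv)
        r[1:] = -Y[s]
        ub_rows.append(r); ub_rhs.append(-y0[s])
    A_eq = b_eq = None
    if tech.rts == "vrs":
        r = np.zeros(nv)
        r[1:] = 1.0
        A_eq, b_eq = np.array([r]), np.array([1.0])

    bounds = [(0, None)] * nv
    res = _solve(c, A_eq=A_eq, b_eq=b_eq, A_ub=np.array(ub_rows),
                 b_ub=np.array(ub_rhs), bounds=bounds)
    status = _STATUS.get(res.status, "numeric_failure")
    if status != "optimal":
        return EfficiencyResult(np.nan, np.zeros(m), np.zeros(q), np.full(n, np.nan),
                                status, "radial", tech.rts, message=res.message)
    return EfficiencyResult(float(res.fun), np.zeros(m), np.zeros(q),
                            res.x[1:].copy(), "optimal", "radial", tech.rts)


def evaluate_cross_section(dataset, period, rts: str = "vrs",
                           super_efficiency: bool = True) -> pd.DataFrame:
    """Score every DMU of one period's cross-section.

    Each DMU is first scored by SBM; SBM-efficient units (score 1 within
    tolerance) are re-scored by super-SBM so that efficient units can be
    ranked above 1. An infeasible super-SBM program falls back to a
    reported score of 1.0 with ``superSBM_infeasible`` flagged in the
    status column.

    Returns a DataFrame with columns dmu, period, model, rts, score,
    status, sbm_score, and per-indicator slack columns.
    """
    X, Y = dataset.input_output(period)
    tech = DEATechnology(X, Y, rts=rts, dmu_ids=tuple(dataset.dmu_ids))
    rows = []
    for k, dmu in enumerate(dataset.dmu_ids):
        base = sbm_score(k, tech)
        rec = {"dmu": dmu, "period": period, "rts": rts,
               "model": "SBM", "status": base.status,
               "sbm_score": base.score, "score": base.score}
        if super_efficiency and base.is_efficient:
            sup = super_sbm_score(k, tech)
            if sup.status == "optimal":
                rec.update(model="superSBM", score=sup.score, status="optimal")
                base = sup
            else:
                rec.update(model="superSBM", score=1.0,
                           status="superSBM_infeasible")
        for i, code in enumerate(dataset.input_codes):
            rec[f"slack_in_{code}"] = base.input_slacks[i]
        for r, code in enumerate(dataset.output_codes):
            rec[f"slack_out_{code}"] = base.output_slacks[r]
        rows.append(rec)
    return pd.DataFrame(rows)
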