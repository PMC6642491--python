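"""Independent oracles used by the test suite.

These deliberately avoid the library's LP path: the SBM oracle optimizes
the fractional objective directly by dense search over the intensity
simplex plus local refinement, and the KMO oracle inverts a 3×3 matrix by
explicit cofactors.
"""

import itertools

import numpy as np
from scipy.optimize import minimize


def sbm_objective(lam, x0, y0, X, Y):
    """Fractional SBM objective at intensity vector lam (slacks implied)."""
    sm = x0 - X @ lam
    sp = Y @ lam - y0
    num = 1.0 - np.mean(sm / x0)
    den = 1.0 + np.mean(sp / y0)
    return num / den


def _feasible(lam, x0, y0, X, Y, tol=1e-9):
    return (np.all(X @ lam <= x0 + tol) and np.all(Y @ lam >= y0 - tol)
            and np.all(lam >= -tol))


def _simplex_grid(n, step):
    k = int(round(1.0 / step))
    for c in itertools.combinations(range(k + n - 1), n - 1):
        parts = np.diff([-1, *c, k + n - 1]) - 1
        yield np.asarray(parts, float) / k


def sbm_fractional_oracle(k, X, Y, rts="crs", step=0.05, n_refine=5):
    """Global minimum of the fractional SBM program by grid + refinement.

    Only intended for tiny instances (n <= 4, m, q <= 2). For CRS the
    intensity vector is written as s * mu with mu on the unit simplex; for
    fixed mu the objective is a ratio of affine functions of s, so the
    optimum over s lies at an endpoint of the feasible interval.
    """
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    n = X.shape[1]
    x0, y0 = X[:, k], Y[:, k]

    candidates = []
    for mu in _simplex_grid(n, step):
        Xm, Ym = X @ mu, Y @ mu
        if rts == "vrs":
            if _feasible(mu, x0, y0, X, Y):
                candidates.append(mu)
            continue
        if np.any(Xm <= 0):
            continue
        s_hi = np.min(x0 / Xm)
        s_lo = np.max(y0 / np.where(Ym > 0, Ym, np.inf))
        if s_lo <= s_hi:
            for s in (s_lo, s_hi, 0.5 * (s_lo + s_hi)):
                candidates.append(s * mu)
    # the unit itself is always feasible (rho = 1)
    e = np.zeros(n)
    e[k] = 1.0
    candidates.append(e)

    vals = [(sbm_objective(lam, x0, y0, X, Y), lam) for lam in candidates
            if _feasible(lam, x0, y0, X, Y)]
    vals.sort(key=lambda t: t[0])
    best = vals[0][0]

    cons = [{"type": "ineq", "fun": lambda l: x0 - X @ l},
            {"type": "ineq", "fun": lambda l: Y @ l - y0}]
    if rts == "vrs":
        cons.append({"type": "eq", "fun": lambda l: np.sum(l) - 1.0})
    for _, lam0 in vals[:n_refine]:
        res = minimize(sbm_objective, lam0, args=(x0, y0, X, Y),
                       method="SLSQP", bounds=[(0, None)] * n,
                       constraints=cons,
                       options={"maxiter": 200, "ftol": 1e-12})
        if res.success and _feasible(res.x, x0, y0, X, Y, tol=1e-7):
            best = min(best, sbm_objective(res.x, x0, y0, X, Y))
    return best


def kmo_3x3_oracle(R):
    """KMO of a 3×3 correlation matrix via an explicit cofactor inverse."""
    R = np.asarray(R, float)
    det = (R[0, 0] * (R[1, 1] * R[2, 2] - R[1, 2] * R[2, 1])
           - R[0, 1] * (R[1, 0] * R[2, 2] - R[1, 2] * R[2, 0])
           + R[0, 2] * (R[1, 0] * R[2, 1] - R[1, 1] * R[2, 0]))
    cof = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            minor = np.delete(np.delete(R, i, axis=0), j, axis=1)
            cof[i, j] = (-1) ** (i + j) * (minor[0, 0] * minor[1, 1]
                                           - minor[0, 1] * minor[1, 0])
    inv = cof.T / det
    r2 = q2 = 0.0
    for i in range(3):
        for j in range(3):
            if i == j:
                continue
            r2 += R[i, j] ** 2
            q2 += (-inv[i, j] / np.sqrt(inv[i, i] * inv[j, j])) ** 2
    return r2 / (r2 + q2)


def pearson_pair_oracle(x, y):
    """Pearson r by the direct covariance / sd formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2)))
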