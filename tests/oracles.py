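"""Independent oracles used by unit and acceptance tests.

Each function here recomputes a quantity by a route deliberately
different from the implementation under test: constrained quadratic
programming for the SVM primal, O(n²) pair counting for the AUC, and
the closed-form beta-quantile bound for exact binomial intervals.
"""

import numpy as np
from scipy.optimize import minimize


def svm_primal_oracle(X, y01, cost, n_starts=5, seed=0):
    """Globally minimize ½‖w‖² + C Σ ξ s.t. ξ ≥ 0, ξ ≥ 1 − y(w·x+b).

    The soft-margin primal is an equivalent smooth convex QP in
    (w, b, ξ); SLSQP from several starts recovers its global optimum on
    small instances.  Returns the best objective value found.
    """
    X = np.asarray(X, dtype=float)
    ypm = 2 * np.asarray(y01) - 1
    n, d = X.shape

    def objective(z):
        w, xi = z[:d], z[d + 1 :]
        return 0.5 * np.dot(w, w) + cost * xi.sum()

    def grad(z):
        g = np.zeros_like(z)
        g[:d] = z[:d]
        g[d + 1 :] = cost
        return g

    def margin_con(z):
        w, b, xi = z[:d], z[d], z[d + 1 :]
        return xi - (1.0 - ypm * (X @ w + b))

    constraints = [{"type": "ineq", "fun": margin_con}]
    bounds = [(None, None)] * (d + 1) + [(0.0, None)] * n
    rng = np.random.default_rng(seed)
    best = np.inf
    starts = [np.zeros(d + 1 + n)] + [
        np.concatenate([rng.normal(0, 1, d + 1), np.ones(n)])
        for _ in range(n_starts - 1)
    ]
    for z0 in starts:
        z0 = z0.copy()
        z0[d + 1 :] = np.maximum(z0[d + 1 :], 1.0)
        res = minimize(
            objective,
            z0,
            jac=grad,
            bounds=bounds,
            constraints=constraints,
            method="SLSQP",
            options={"maxiter": 2000, "ftol": 1e-12},
        )
        if res.fun < best:
            best = float(res.fun)
    return best


def auc_pair_counting(scores, y01):
    """AUC as the fraction of (positive, negative) pairs ranked correctly.

    Ties count one half.  O(n²) by construction.
    """
    scores = np.asarray(scores, dtype=float)
    y01 = np.asarray(y01)
    pos = scores[y01 == 1]
    neg = scores[y01 == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def clopper_pearson_lower_all_successes(n, alpha=0.05):
    """Closed-form CP lower bound when every trial succeeds: (α/2)^(1/n)."""
    return (alpha / 2.0) ** (1.0 / n)
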