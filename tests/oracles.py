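"""Independent reference implementations used only to cross-check results.

These deliberately avoid the library's own code paths: the distance oracle is
a branch-and-bound exhaustive enumeration of left-to-right edit scripts (no
tabulation), and the logistic oracle maximizes the log-likelihood with a
quasi-Newton gradient routine instead of IRLS.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from carenet.name_match import CostTable

_INF = float("inf")


def oracle_distance(word: str, target: str, costs: CostTable) -> int:
    """Minimal edit-script cost by exhaustive recursion over op sequences."""
    w, t = word.lower(), target.lower()
    nw, nt = len(w), len(t)
    best = [_INF]

    def go(i: int, j: int, acc: float) -> None:
        if acc >= best[0]:
            return
        if i == nw and j == nt:
            best[0] = acc
            return
        if i < nw and j < nt:
            go(i + 1, j + 1, acc + (0 if w[i] == t[j] else costs.replace))
            if (
                i + 1 < nw
                and j + 1 < nt
                and w[i] == t[j + 1]
                and w[i + 1] == t[j]
                and w[i] != w[i + 1]
            ):
                go(i + 2, j + 2, acc + costs.adjacent_transposition)
        if j < nt:
            go(i, j + 1, acc + (costs.append_at_end if i == nw else costs.insert))
        if i < nw:
            go(i + 1, j, acc + (costs.truncate_at_end if j == nt else costs.delete))

    go(0, 0, 0)
    return int(best[0])


def oracle_logit_loglik(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Max log-likelihood of a logit fit via BFGS on the analytic gradient."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xd = np.hstack([np.ones((X.shape[0], 1)), X])

    def negll(beta):
        eta = Xd @ beta
        return -(y @ eta - np.logaddexp(0.0, eta).sum())

    def grad(beta):
        eta = np.clip(Xd @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        return -(Xd.T @ (y - mu))

    res = minimize(negll, np.zeros(Xd.shape[1]), jac=grad, method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    return res.x, -res.fun
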