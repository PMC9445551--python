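"""Shared censored-likelihood maximisation machinery.

Both the Weibull and the power generalised Weibull fits maximise a
right-censored log-likelihood over log-parameters (which enforces
positivity without constraints) and build Wald confidence intervals on
the log scale from a numerically inverted Hessian, back-transformed to
the natural scale.  Any numerical failure — optimiser non-convergence,
non-finite or ill-conditioned Hessian, non-positive variance — is
downgraded to flags on the fit result, never an exception: downstream
decision rules translate a flagged fit into "no signal".
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_hess

#: box for the log-parameters; exp(±20) is far outside any plausible fit
LOG_BOUND = 20.0
#: Hessians with a larger condition number count as singular
MAX_CONDITION = 1e12
#: objective value returned where the likelihood is non-finite
BIG = 1e10


def maximise(nll_grad, x0, fallback_starts=(), maxiter: int = 500):
    """Minimise a negative log-likelihood with gradient over log-parameters.

    Runs L-BFGS-B from ``x0``; only if that fails are the
    ``fallback_starts`` tried, keeping the best successful solution.

    Returns ``(x_hat, loglik, converged)``.
    """

    def run(x):
        return minimize(
            nll_grad,
            np.asarray(x, dtype=float),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-LOG_BOUND, LOG_BOUND)] * len(x),
            options={"maxiter": maxiter},
        )

    def ok(res):
        # a solution pinned to the box edge is a runaway (e.g. a shape
        # parameter drifting to 0 or infinity), not a converged MLE
        at_bound = np.any(np.abs(res.x) >= LOG_BOUND - 1e-8)
        return bool(res.success and np.isfinite(res.fun) and not at_bound)

    best = run(x0)
    if not ok(best):
        for start in fallback_starts:
            cand = run(start)
            if not ok(cand):
                continue
            if not ok(best) or cand.fun < best.fun:
                best = cand
    return np.asarray(best.x, dtype=float), float(-best.fun), ok(best)


def wald_log_intervals(nll, x_hat, conf_level: float):
    """Wald intervals for exp(x) from the Hessian of the negative log-likelihood.

    Returns ``((lower, upper), True)`` with arrays on the natural
    (positive) scale, or ``(None, False)`` when the Hessian is
    non-finite, ill-conditioned, or yields a non-positive variance.
    """
    x_hat = np.asarray(x_hat, dtype=float)
    try:
        hess = approx_hess(x_hat, nll)
    except Exception:  # numerical breakdown inside the differencer
        return None, False
    if not np.all(np.isfinite(hess)) or np.linalg.cond(hess) > MAX_CONDITION:
        return None, False
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None, False
    var = np.diag(cov)
    if not np.all(np.isfinite(var)) or np.any(var <= 0):
        return None, False
    z = norm.ppf(0.5 + conf_level / 2.0)
    se = np.sqrt(var)
    with np.errstate(over="ignore"):  # an unbounded upper limit is legitimate
        return (np.exp(x_hat - z * se), np.exp(x_hat + z * se)), True
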