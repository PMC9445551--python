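"""Signal-detection decision rules for single-arm exposed cohorts.

All four tests share one idea: adverse events unrelated to the drug
occur at a constant background hazard (exponential times), while a drug
reaction makes the hazard time-dependent.  Each test fits a parametric
hazard and raises a signal when the fitted shape is incompatible with
constancy:

* **WSP** — fit a two-parameter Weibull, hazard λ(t) = (α/θ^α) t^(α−1);
  signal if the confidence interval for the shape α excludes 1.
* **dWSP** — the WSP applied twice, once on the full window and once on
  the data administratively censored at half the window (which breaks
  the symmetry that blinds the plain WSP to mid-period reactions), each
  component at level 0.025; signal if either fires.
* **pWSP** — fit the power generalised Weibull; signal only if the
  intervals for *both* shape parameters ν and γ exclude 1
  (intersection–union rule for H0: ν = 1 or γ = 1).
* **combined** — pWSP OR dWSP at their own levels; recommended because
  the two are complementary (pWSP is strong for early reactions, dWSP
  for mid- and late-period ones).

A fit that fails to converge or has an unusable Hessian never fires:
estimation failure means "no signal".  Interval endpoints exactly at 1
also mean no signal (closed-interval convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _mle
from .events import EventTable, EventTableError
from .pgw import PgWFit, pgw_fit

__all__ = [
    "WeibullFit",
    "TestComponent",
    "SignalResult",
    "ci_excludes_one",
    "weibull_fit",
    "wsp_test",
    "dwsp_test",
    "pwsp_test",
    "combined_test",
]

_NAN_CI = (float("nan"), float("nan"))


@dataclass(frozen=True)
class WeibullFit:
    """Censored MLE of the two-parameter Weibull (shape α, scale θ)."""

    shape: float
    scale: float
    ci_shape: tuple
    ci_scale: tuple
    loglik: float
    converged: bool
    hessian_valid: bool
    conf_level: float

    def to_dict(self) -> dict:
        return {
            "shape": self.shape,
            "scale": self.scale,
            "ci_shape_low": self.ci_shape[0],
            "ci_shape_high": self.ci_shape[1],
            "ci_scale_low": self.ci_scale[0],
            "ci_scale_high": self.ci_scale[1],
            "loglik": self.loglik,
            "converged": self.converged,
            "hessian_valid": self.hessian_valid,
            "conf_level": self.conf_level,
        }


@dataclass(frozen=True)
class TestComponent:
    """One elementary CI-excludes-1 check inside a decision rule."""

    label: str
    alpha_level: float
    fired: bool
    ci: tuple
    fit: object

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "alpha_level": self.alpha_level,
            "fired": self.fired,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "fit": self.fit.to_dict() if self.fit is not None else None,
        }


@dataclass(frozen=True)
class SignalResult:
    """Verdict of a signal test plus the evidence behind it."""

    test_name: str
    signal: bool
    components: tuple
    subtests: tuple = field(default=())

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "signal": self.signal,
            "components": [c.to_dict() for c in self.components],
            "subtests": [s.to_dict() for s in self.subtests],
        }

    def verdict_line(self) -> str:
        mark = "SIGNAL" if self.signal else "no signal"
        parts = ", ".join(
            f"{c.label}: CI=({c.ci[0]:.6g}, {c.ci[1]:.6g})"
            f"{' *' if c.fired else ''}"
            for c in self.components
        )
        return f"{self.test_name}: {mark} [{parts}]"


def ci_excludes_one(ci) -> bool:
    """Closed-interval convention: an endpoint exactly at 1 does not fire."""
    low, high = ci
    if not (np.isfinite(low) and np.isfinite(high)):
        return False
    return low > 1.0 or high < 1.0


# ---------------------------------------------------------------------------
# Weibull censored MLE


def _weibull_nll_grad(log_te, sum_log_te, log_tc, wc):
    """Negative Weibull log-likelihood and gradient over (log θ, log α)."""
    n_e = log_te.size
    zero = np.zeros(2)

    def nll_grad(x):
        a_, b_ = x
        alpha = math.exp(b_)
        with np.errstate(over="ignore", invalid="ignore"):
            z_e = alpha * (log_te - a_)
            z_c = alpha * (log_tc - a_)
            e_e = np.exp(z_e)
            e_c = np.exp(z_c)
            ll = (
                n_e * (b_ - alpha * a_)
                + (alpha - 1.0) * sum_log_te
                - e_e.sum()
                - (wc * e_c).sum()
            )
            if not np.isfinite(ll):
                return _mle.BIG, zero
            g_a = alpha * (-n_e + e_e.sum() + (wc * e_c).sum())
            g_b = n_e + z_e.sum() - (e_e * z_e).sum() - (wc * e_c * z_c).sum()
            grad = -np.array([g_a, g_b])
        if not np.all(np.isfinite(grad)):
            return _mle.BIG, zero
        return -ll, grad

    return nll_grad


def weibull_fit(
    data: EventTable, conf_level: float = 0.95, zero_eps: float = 1e-9
) -> WeibullFit:
    """Censored maximum-likelihood Weibull fit with a log-scale Wald CI for α.

    Starts from the exponential submodel (α = 1, θ = total follow-up
    per event); α ∈ {0.5, 2} restarts are tried only if the first start
    fails.  α = 1 identifies a constant hazard, which is what the WSP
    family tests.  Failures downgrade to flags, never exceptions.
    """
    if data.n_events == 0:
        raise EventTableError("fitting requires at least one observed event")
    te = data.event_times.copy()
    zero = te == 0.0
    if zero.any():
        te[zero] = zero_eps * data.window_end
    tc, wc = np.unique(data.censoring_times, return_counts=True)
    keep = tc > 0
    tc, wc = tc[keep], wc[keep].astype(float)
    log_te = np.log(te)
    with np.errstate(divide="ignore"):
        log_tc = np.log(tc)
    nll_grad = _weibull_nll_grad(log_te, log_te.sum(), log_tc, wc)

    theta0 = (te.sum() + (tc * wc).sum()) / te.size
    x0 = np.array([math.log(theta0), 0.0])
    grid = [np.array([x0[0], math.log(a)]) for a in (0.5, 2.0)]
    x_hat, loglik, converged = _mle.maximise(nll_grad, x0, fallback_starts=grid)

    ci_scale = ci_shape = _NAN_CI
    hessian_valid = False
    if converged:
        intervals, hessian_valid = _mle.wald_log_intervals(
            lambda x: nll_grad(x)[0], x_hat, conf_level
        )
        if hessian_valid:
            lower, upper = intervals
            ci_scale = (float(lower[0]), float(upper[0]))
            ci_shape = (float(lower[1]), float(upper[1]))
    scale, shape = np.exp(x_hat)
    return WeibullFit(
        shape=shape,
        scale=scale,
        ci_shape=ci_shape,
        ci_scale=ci_scale,
        loglik=loglik,
        converged=converged,
        hessian_valid=hessian_valid,
        conf_level=conf_level,
    )


# ---------------------------------------------------------------------------
# decision rules


def _component_fires(fit) -> bool:
    return bool(fit.converged and fit.hessian_valid)


def wsp_test(data: EventTable, alpha_level: float = 0.05) -> SignalResult:
    """Weibull shape parameter test: signal iff the CI for α excludes 1."""
    fit = weibull_fit(data, conf_level=1.0 - alpha_level)
    fired = _component_fires(fit) and ci_excludes_one(fit.ci_shape)
    comp = TestComponent("alpha", alpha_level, fired, fit.ci_shape, fit)
    return SignalResult("WSP", fired, (comp,))


def dwsp_test(data: EventTable, component_alpha: float = 0.025) -> SignalResult:
    """Double WSP: full window plus administrative censoring at T/2.

    Each component runs at level ``component_alpha`` (Bonferroni for an
    overall 5%); a signal is raised if either fires.  A half-window
    component with no remaining events cannot fire.
    """
    components = []
    full = weibull_fit(data, conf_level=1.0 - component_alpha)
    fired_full = _component_fires(full) and ci_excludes_one(full.ci_shape)
    components.append(
        TestComponent("alpha_full", component_alpha, fired_full, full.ci_shape, full)
    )
    half_table = data.censored_at(data.window_end / 2.0)
    if half_table.n_events > 0:
        half = weibull_fit(half_table, conf_level=1.0 - component_alpha)
        fired_half = _component_fires(half) and ci_excludes_one(half.ci_shape)
        components.append(
            TestComponent(
                "alpha_half", component_alpha, fired_half, half.ci_shape, half
            )
        )
    signal = any(c.fired for c in components)
    return SignalResult("dWSP", signal, tuple(components))


def pwsp_test(data: EventTable, alpha_level: float = 0.05) -> SignalResult:
    """PgW shape test: signal iff the CIs for BOTH ν and γ exclude 1.

    Intersection–union rule for H0: ν = 1 or γ = 1 against
    H1: ν ≠ 1 and γ ≠ 1; estimation failure means no signal.
    """
    fit = pgw_fit(data, conf_level=1.0 - alpha_level)
    usable = _component_fires(fit)
    fired_nu = usable and ci_excludes_one(fit.ci_nu)
    fired_gamma = usable and ci_excludes_one(fit.ci_gamma)
    components = (
        TestComponent("nu", alpha_level, fired_nu, fit.ci_nu, fit),
        TestComponent("gamma", alpha_level, fired_gamma, fit.ci_gamma, fit),
    )
    return SignalResult("pWSP", fired_nu and fired_gamma, components)


def combined_test(
    data: EventTable,
    pwsp_alpha: float = 0.05,
    dwsp_component_alpha: float = 0.025,
) -> SignalResult:
    """Recommended rule: signal iff pWSP or dWSP raises one.

    The two subtests run at their own published levels with no further
    multiplicity adjustment; the levels are configurable.
    """
    p = pwsp_test(data, alpha_level=pwsp_alpha)
    d = dwsp_test(data, component_alpha=dwsp_component_alpha)
    return SignalResult(
        "combined",
        p.signal or d.signal,
        p.components + d.components,
        subtests=(p, d),
    )
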