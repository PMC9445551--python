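"""Power generalised Weibull distribution: closed forms, identities,
sampling, censored likelihood, and maximum-likelihood fitting."""

import math

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from wspsignal.events import EventTable, EventTableError
from wspsignal.pgw import (
    PgWParams,
    pgw_density,
    pgw_fit,
    pgw_hazard,
    pgw_loglik,
    pgw_quantile,
    pgw_sample,
    pgw_survival,
)

# hazard-shape exemplars: bathtub (A, B), near-flat bathtub (C), rising (D)
PANEL_A = PgWParams(0.5, 5.0, 700.0)
PANEL_B = PgWParams(0.5, 3.0, 700.0)
PANEL_C = PgWParams(0.5, 3.0, 800.0)
PANEL_D = PgWParams(167.0, 1.0, 1.5)

log_params = st.floats(-1.5, 1.5)


class TestClosedForms:
    def test_survival_at_zero_is_one(self):
        for p in (PANEL_A, PANEL_D, PgWParams(1, 1, 1)):
            assert pgw_survival(0.0, p) == 1.0

    def test_exponential_submodel_survival(self):
        assert pgw_survival(2.0, PgWParams(2, 1, 1)) == pytest.approx(
            math.exp(-1.0), rel=1e-12
        )

    def test_survival_against_arbitrary_precision(self):
        # S(0.5; theta=0.5, nu=5, gamma=700) = exp(1 - 2**(1/700))
        expected = float(sympy.N(sympy.exp(1 - 2 ** sympy.Rational(1, 700)), 30))
        assert pgw_survival(0.5, PANEL_A) == pytest.approx(expected, rel=1e-12)

    def test_nonfinite_time_rejected(self):
        with pytest.raises(ValueError):
            pgw_survival(np.nan, PANEL_A)
        with pytest.raises(ValueError):
            pgw_hazard(-1.0, PANEL_A)

    def test_exponential_hazard_constant(self):
        grid = np.logspace(-3, 2, 25)
        assert np.allclose(pgw_hazard(grid, PgWParams(167, 1, 1)), 1 / 167, rtol=1e-12)

    def test_weibull_submodel_hazard(self):
        # gamma = 1 collapses to the Weibull hazard alpha t^(alpha-1)
        grid = np.linspace(0.1, 3, 20)
        assert np.allclose(pgw_hazard(grid, PgWParams(1, 2, 1)), 2 * grid, rtol=1e-12)

    def test_hazard_pole_at_origin(self):
        assert pgw_hazard(0.0, PgWParams(1, 0.5, 1)) == np.inf
        assert pgw_hazard(0.0, PgWParams(1, 2, 1)) == 0.0

    @pytest.mark.parametrize("params", [PANEL_A, PANEL_B, PANEL_C, PANEL_D,
                                        PgWParams(0.5, 3, 0.5)])
    def test_hazard_density_survival_identity(self, params):
        grid = np.logspace(-2, 0.5, 40)
        lam = pgw_hazard(grid, params)
        f = pgw_density(grid, params)
        s = pgw_survival(grid, params)
        assert np.all(f >= 0)
        keep = f > 1e-250  # avoid 0/0 deep in the tail
        assert np.allclose(lam[keep], f[keep] / s[keep], rtol=1e-10)

    def test_density_integrates_to_one(self):
        params = PgWParams(0.5, 3, 0.5)
        total, _ = integrate.quad(lambda t: pgw_density(t, params), 0, 100, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_survival_matches_integrated_hazard(self):
        params = PgWParams(0.5, 3, 0.5)
        for t in (0.3, 1.0, 2.5):
            cum, _ = integrate.quad(lambda u: pgw_hazard(u, params), 0, t, limit=200)
            assert pgw_survival(t, params) == pytest.approx(math.exp(-cum), rel=1e-6)

    @pytest.mark.parametrize("bad", [(0, 1, 1), (1, -2, 1), (1, 1, np.inf)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            PgWParams(*bad)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(lt=log_params, ln=log_params, lg=log_params)
def test_survival_monotone_and_bounded(lt, ln, lg):
    params = PgWParams(math.exp(lt), math.exp(ln), math.exp(lg))
    s = pgw_survival(np.logspace(-3, 1.5, 60), params)
    assert np.all((0 <= s) & (s <= 1))
    assert np.all(np.diff(s) <= 1e-15)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(lt=log_params, ln=log_params)
def test_gamma_one_collapses_to_weibull(lt, ln):
    theta, nu = math.exp(lt), math.exp(ln)
    grid = np.logspace(-2, 1, 30)
    ours = pgw_survival(grid, PgWParams(theta, nu, 1.0))
    ref = stats.weibull_min.sf(grid, nu, scale=theta)
    assert np.allclose(ours, ref, rtol=1e-12)


def test_both_shapes_one_collapse_to_exponential():
    grid = np.logspace(-2, 1, 30)
    ours = pgw_survival(grid, PgWParams(0.7, 1.0, 1.0))
    assert np.allclose(ours, stats.expon.sf(grid, scale=0.7), rtol=1e-12)


class TestSampling:
    def test_quantile_inverts_survival(self):
        # U = S(1) = exp(1 - 2) for the unit-exponential submodel gives t = 1
        u = math.exp(-1.0)
        assert pgw_quantile(1 - u, PgWParams(1, 1, 1)) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("params", [PANEL_D, PgWParams(0.5, 3, 0.5)])
    def test_quantile_round_trip(self, params):
        p = np.linspace(0.01, 0.99, 25)
        t = pgw_quantile(p, params)
        assert np.allclose(1 - pgw_survival(t, params), p, rtol=1e-9, atol=1e-12)

    def test_exponential_sample_mean(self):
        theta = 2.5
        draws = pgw_sample(10_000, PgWParams(theta, 1, 1), rng=1)
        se = theta / math.sqrt(draws.size)
        assert abs(draws.mean() - theta) < 3 * se

    @pytest.mark.parametrize(
        "params", [PgWParams(1, 1, 1), PgWParams(0.5, 3, 0.5), PANEL_D, PANEL_A]
    )
    def test_sampler_agrees_with_survival(self, params):
        draws = pgw_sample(10_000, params, rng=7)
        res = stats.kstest(draws, lambda t: 1 - pgw_survival(t, params))
        assert res.pvalue > 0.01

    def test_sampler_reproducible(self):
        a = pgw_sample(50, PANEL_D, rng=3)
        assert np.array_equal(a, pgw_sample(50, PANEL_D, rng=3))


class TestLoglik:
    def test_single_event_exponential(self):
        data = EventTable(np.array([1.0]), np.array([1]), 1.0)
        assert pgw_loglik(data, PgWParams(1, 1, 1)) == pytest.approx(-1.0, rel=1e-12)

    def test_single_censored_exponential(self):
        data = EventTable(np.array([1.0]), np.array([0]), 1.0)
        assert pgw_loglik(data, PgWParams(1, 1, 1)) == pytest.approx(-1.0, rel=1e-12)

    def test_matches_term_by_term_recomputation(self):
        rng = np.random.default_rng(5)
        times = rng.uniform(0.01, 2.0, size=50)
        events = rng.integers(0, 2, size=50)
        data = EventTable(times, events, 2.0)
        theta, nu, gamma = 0.8, 1.7, 0.6
        total = 0.0
        for t, d in zip(times, events):
            a = math.log1p((t / theta) ** nu)
            log_s = 1 - math.exp(a / gamma)
            if d:
                log_lam = (
                    math.log(nu) - math.log(gamma) - nu * math.log(theta)
                    + (nu - 1) * math.log(t) + (1 / gamma - 1) * a
                )
                total += log_lam + log_s
            else:
                total += log_s
        assert pgw_loglik(data, PgWParams(theta, nu, gamma)) == pytest.approx(
            total, rel=1e-12
        )

    def test_zero_time_event_reported_as_minus_inf(self):
        data = EventTable(np.array([0.0, 0.5]), np.array([1, 1]), 1.0)
        assert pgw_loglik(data, PgWParams(1, 2, 1)) == -np.inf


class TestFit:
    def test_requires_events(self):
        data = EventTable(np.array([1.0, 1.0]), np.array([0, 0]), 1.0)
        with pytest.raises(EventTableError):
            pgw_fit(data)

    def test_parameter_recovery_exponential(self):
        draws = pgw_sample(5000, PgWParams(1, 1, 1), rng=11)
        events = draws < 3.0  # ~5% administratively censored
        data = EventTable(np.where(events, draws, 3.0), events.astype(int), 3.0)
        fit = pgw_fit(data)
        assert fit.converged and fit.hessian_valid
        z = stats.norm.ppf(0.975)
        for est, ci, truth in [
            (fit.params.nu, fit.ci_nu, 1.0),
            (fit.params.gamma, fit.ci_gamma, 1.0),
            (fit.params.theta, fit.ci_theta, 1.0),
        ]:
            se_log = (math.log(ci[1]) - math.log(ci[0])) / (2 * z)
            assert abs(math.log(est) - math.log(truth)) < 3 * se_log
            assert ci[0] <= est <= ci[1]

    def test_loglik_beats_local_grid(self):
        draws = pgw_sample(400, PgWParams(0.5, 3, 0.5), rng=13)
        data = EventTable(draws, np.ones(draws.size, int), draws.max())
        fit = pgw_fit(data)
        assert fit.converged
        best = fit.params
        for dl in np.linspace(-0.3, 0.3, 5):
            for dn in np.linspace(-0.3, 0.3, 5):
                for dg in np.linspace(-0.3, 0.3, 5):
                    cand = PgWParams(
                        best.theta * math.exp(dl),
                        best.nu * math.exp(dn),
                        best.gamma * math.exp(dg),
                    )
                    assert pgw_loglik(data, cand) <= fit.loglik + 1e-6

    def test_degenerate_data_flagged_not_raised(self):
        data = EventTable(np.full(30, 0.5), np.ones(30, int), 1.0)
        fit = pgw_fit(data)
        assert not (fit.converged and fit.hessian_valid)

    def test_zero_time_events_nudged_with_warning(self):
        data = EventTable(np.array([0.0, 0.4, 0.9]), np.array([1, 1, 1]), 1.0)
        with pytest.warns(UserWarning, match="nudged"):
            fit = pgw_fit(data)
        assert np.isfinite(fit.loglik)


def test_analytic_gradient_matches_finite_differences():
    from wspsignal.pgw import _compressed, _pgw_nll_grad

    rng = np.random.default_rng(17)
    draws = pgw_sample(150, PgWParams(0.7, 2.0, 0.6), rng=rng)
    events = draws < 1.5
    data = EventTable(np.where(events, draws, 1.5), events.astype(int), 1.5)
    te, tc, wc = _compressed(data, 1e-9)
    nll = _pgw_nll_grad(np.log(te), np.log(te).sum(), np.log(tc), wc)
    x = np.array([0.2, -0.3, 0.4])
    _, grad = nll(x)
    eps = 1e-6
    for i in range(3):
        step = eps * np.eye(3)[i]
        numeric = (nll(x + step)[0] - nll(x - step)[0]) / (2 * eps)
        assert grad[i] == pytest.approx(numeric, rel=1e-5)
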