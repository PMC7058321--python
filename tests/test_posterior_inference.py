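"""Sampler correctness (moment identities, determinism, contracts) and
posterior-predictive averaging."""

import math

import numpy as np
import pytest
from scipy.special import expit

import trialhte as t
from trialhte.horseshoe_model import HorseshoeConfig
from trialhte.posterior_inference import sample_polya_gamma
from trialhte.trial_data import DesignMatrix, TrialSchema

EMPTY_SCHEMA = TrialSchema(predictors=())


def make_design(X, y):
    X = np.asarray(X, dtype=float)
    return DesignMatrix(
        X=X, y=np.asarray(y, dtype=int),
        column_names=tuple(f"x{i}" for i in range(X.shape[1])),
        level_maps={}, standardizer=None, schema=EMPTY_SCHEMA,
    )


# ---------------------------------------------------------------------------
# Polya-Gamma kernel
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("c", [0.0, 0.5, 2.0, 5.0])
def test_polya_gamma_mean_identity(c):
    """E[PG(1,c)] = tanh(c/2)/(2c), with the c->0 limit 1/4."""
    n = 200_000
    x = sample_polya_gamma(np.full(n, c), seed=int(10 * c) + 1)
    expected = 0.25 if c == 0.0 else math.tanh(c / 2) / (2 * c)
    assert x.mean() == pytest.approx(expected, abs=4 * x.std() / math.sqrt(n))
    assert np.all(x > 0)


def test_polya_gamma_variance_at_zero():
    x = sample_polya_gamma(np.zeros(200_000), seed=3)
    assert x.var() == pytest.approx(1.0 / 24.0, rel=0.02)


# ---------------------------------------------------------------------------
# Sampler contracts
# ---------------------------------------------------------------------------

def intercept_only_design(n=100, successes=30):
    y = np.zeros(n, dtype=int)
    y[:successes] = 1
    return make_design(np.empty((n, 0)), y)


def test_seed_determinism():
    design = intercept_only_design()
    config = HorseshoeConfig(p0=1, K=0, N=100, tau0=1.0)
    a = t.sample_posterior(design, config, n_draws=200, seed=42)
    b = t.sample_posterior(design, config, n_draws=200, seed=42)
    assert np.array_equal(a.beta0_draws, b.beta0_draws)
    c = t.sample_posterior(design, config, n_draws=200, seed=43)
    assert not np.array_equal(a.beta0_draws, c.beta0_draws)


def test_degenerate_design_rejected():
    X = np.ones((30, 1))  # constant column
    design = make_design(X, np.r_[np.ones(10), np.zeros(20)])
    config = HorseshoeConfig(p0=1, K=1, N=30, tau0=1.0)
    with pytest.raises(ValueError, match="degenerate"):
        t.sample_posterior(design, config, n_draws=10, seed=0)


def test_diagnostics_populated():
    design = intercept_only_design()
    config = HorseshoeConfig(p0=1, K=0, N=100, tau0=1.0)
    draws = t.sample_posterior(design, config, n_draws=400, seed=1)
    assert "beta0" in draws.diagnostics
    assert draws.diagnostics["beta0"]["ess_bulk"] > 50
    assert draws.s == 400


def test_multiple_chains_supported():
    design = intercept_only_design()
    config = HorseshoeConfig(p0=1, K=0, N=100, tau0=1.0)
    draws = t.sample_posterior(design, config, n_draws=150, seed=1, n_chains=2)
    assert draws.s == 300
    assert draws.diagnostics["beta0"]["rhat"] < 1.05


# ---------------------------------------------------------------------------
# Quadrature oracles
# ---------------------------------------------------------------------------

def test_intercept_only_matches_quadrature():
    """Posterior mean abstinence probability for a 30/100 outcome under the
    Student-t intercept prior, against a dense 1-D grid integration."""
    from trialhte.horseshoe_model import _student_t_logpdf

    design = intercept_only_design()
    config = HorseshoeConfig(p0=1, K=0, N=100, tau0=1.0)

    grid = np.linspace(-6.0, 6.0, 6001)
    log_post = np.array([_student_t_logpdf(b, 7.0, 2.5) for b in grid])
    log_post += 30 * grid - 100 * np.logaddexp(0.0, grid)
    w = np.exp(log_post - log_post.max())
    w /= w.sum()
    oracle = float(np.sum(expit(grid) * w))

    draws = t.sample_posterior(design, config, n_draws=4000, seed=7)
    p_draws = expit(draws.beta0_draws)
    mcse = p_draws.std() / math.sqrt(draws.diagnostics["beta0"]["ess_bulk"])
    assert np.mean(p_draws) == pytest.approx(oracle, abs=3 * mcse)


def test_two_parameter_matches_quadrature():
    """Intercept + one coefficient with the scales clamped at 1: posterior
    means and 90% intervals against a dense 2-D grid integration."""
    from scipy.stats import norm

    from trialhte.horseshoe_model import _student_t_logpdf

    rng = np.random.default_rng(3)
    n = 50
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    y = (rng.random(n) < expit(-0.5 + 1.0 * x)).astype(int)
    design = make_design(x[:, None], y)
    config = HorseshoeConfig(p0=1, K=1, N=n, tau0=1.0)

    g0 = np.linspace(-4, 4, 801)
    g1 = np.linspace(-4, 4, 801)
    B0, B1 = np.meshgrid(g0, g1, indexing="ij")
    eta = B0[..., None] + B1[..., None] * x[None, None, :]
    log_post = (y * eta - np.logaddexp(0.0, eta)).sum(axis=-1)
    log_post += np.array([_student_t_logpdf(b, 7.0, 2.5) for b in g0])[:, None]
    log_post += norm.logpdf(g1)[None, :]
    w = np.exp(log_post - log_post.max())
    w /= w.sum()
    m0, m1 = w.sum(axis=1), w.sum(axis=0)

    def grid_quantile(g, m, q):
        return float(np.interp(q, np.cumsum(m), g))

    draws = t.sample_posterior(
        design, config, n_draws=6000, seed=11, fixed_tau=1.0, fixed_lam=1.0
    )
    for samples, grid, marg, name in (
        (draws.beta0_draws, g0, m0, "beta0"),
        (draws.beta_draws[:, 0], g1, m1, "beta[x0]"),
    ):
        mcse = samples.std() / math.sqrt(draws.diagnostics[name]["ess_bulk"])
        assert samples.mean() == pytest.approx(float((grid * marg).sum()), abs=3 * mcse)
        for q in (0.05, 0.95):
            # quantile MCSE is of the same order as the mean's here
            assert np.quantile(samples, q) == pytest.approx(
                grid_quantile(grid, marg, q), abs=5 * mcse
            )
    assert np.all(draws.tau_draws == 1.0)
    assert np.all(draws.lam_draws == 1.0)


# ---------------------------------------------------------------------------
# Posterior-predictive probabilities
# ---------------------------------------------------------------------------

def test_predictive_probability_trivials(stub_draws):
    zero = stub_draws(0.0, np.zeros((1, 11)))
    assert t.predictive_probability(zero, np.zeros(11)) == pytest.approx(0.5)

    single = stub_draws(math.log(3), np.zeros((1, 11)))
    assert t.predictive_probability(single, np.zeros(11)) == pytest.approx(0.75)

    # two draws giving per-draw probabilities 0.2 and 0.6 -> mean 0.4
    from scipy.special import logit

    two = stub_draws(np.array([logit(0.2), logit(0.6)]), np.zeros((2, 11)))
    assert t.predictive_probability(two, np.zeros(11)) == pytest.approx(0.4)


def test_predictive_probability_dimension_mismatch(stub_draws):
    draws = stub_draws(0.0, np.zeros((1, 11)))
    with pytest.raises(ValueError, match="shape"):
        t.predictive_probability(draws, np.zeros(4))


def test_prediction_averages_probabilities_not_linear_predictor(stub_draws):
    """Jensen gap: the posterior-predictive mean of invlogit(eta) differs
    from invlogit of the mean eta on a spread-out draw set."""
    draws = stub_draws(np.array([-3.0, 3.0]), np.zeros((2, 11)))
    p = t.predictive_probability(draws, np.zeros(11))
    assert p == pytest.approx(0.5)
    plugin = expit(np.mean([-3.0, 3.0]))
    spread = stub_draws(np.array([-1.0, 3.0]), np.zeros((2, 11)))
    p_spread = t.predictive_probability(spread, np.zeros(11))
    assert abs(p_spread - expit(1.0)) > 0.05  # mean of probs != prob of mean


def test_draws_frame_export(stub_draws):
    draws = stub_draws(0.0, np.zeros((3, 11)))
    frame = t.draws_to_frame(draws)
    assert frame.shape == (3, 2 + 2 * 11)
    assert "beta[group]" in frame.columns
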