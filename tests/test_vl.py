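"""Variational Laplace: conjugate oracles, monotonicity, Occam penalty."""

import numpy as np
import pytest

from gaindcm.vl import (
    Hyperparameters,
    Prior,
    Settings,
    evidence,
    free_energy,
    invert,
)


def conjugate_problem(seed=0, n=20, p=3, sigma=0.3):
    """Bayesian linear regression with closed-form posterior and evidence."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    theta = rng.normal(0, 0.5, p)
    y = X @ theta + rng.normal(0, sigma, n)
    m0 = np.zeros(p)
    S0 = np.diag(np.linspace(0.5, 2.0, p))
    Sn = np.linalg.inv(X.T @ X / sigma**2 + np.linalg.inv(S0))
    mn = Sn @ (X.T @ y / sigma**2)
    C = sigma**2 * np.eye(n) + X @ S0 @ X.T
    resid = y - X @ m0
    logZ = -0.5 * (
        n * np.log(2 * np.pi)
        + np.linalg.slogdet(C)[1]
        + resid @ np.linalg.solve(C, resid)
    )
    return X, y, Prior(m0, S0), np.log(1 / sigma**2), mn, Sn, logZ


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_matches_conjugate_posterior_and_evidence(seed):
    X, y, prior, lam, mn, Sn, logZ = conjugate_problem(seed)
    post = invert(y, lambda th: th @ X.T, prior, Hyperparameters(fixed=lam))
    assert np.max(np.abs(post.mean - mn)) <= 1e-6 * max(1.0, np.abs(mn).max())
    assert np.allclose(post.cov, Sn, rtol=1e-6, atol=1e-12)
    assert post.free_energy == pytest.approx(logZ, abs=1e-3)


def test_free_energy_terms_are_audit_consistent():
    X, y, prior, lam, *_ = conjugate_problem(3)
    J = X
    theta = prior.mean
    r = y - X @ theta
    terms = free_energy(r, J, theta, prior, lam, Hyperparameters(fixed=lam))
    assert terms.total == pytest.approx(
        terms.accuracy - terms.complexity_theta - terms.complexity_lambda
    )
    # posterior-at-prior with zero residuals has zero theta complexity
    t0 = free_energy(
        np.zeros_like(y), J * 0.0, theta, prior, lam, Hyperparameters(fixed=lam)
    )
    assert t0.complexity_theta == pytest.approx(0.0, abs=1e-12)


def test_doubling_residuals_lowers_free_energy():
    X, y, prior, lam, *_ = conjugate_problem(4)
    r = y - X @ prior.mean
    f1 = free_energy(r, X, prior.mean, prior, lam, Hyperparameters(fixed=lam))
    f2 = free_energy(2 * r, X, prior.mean, prior, lam, Hyperparameters(fixed=lam))
    assert f2.total < f1.total


def test_lambda_estimation_recovers_noise_precision():
    rng = np.random.default_rng(5)
    n, p, sigma = 400, 3, 0.5
    X = rng.standard_normal((n, p))
    y = X @ np.array([0.3, -0.2, 0.1]) + rng.normal(0, sigma, n)
    prior = Prior(np.zeros(p), np.eye(p))
    post = invert(y, lambda th: th @ X.T, prior, Hyperparameters(mean=4.0, var=1.0))
    assert post.lam == pytest.approx(np.log(1 / sigma**2), abs=0.3)
    assert post.lam_var > 0


def test_trace_monotone_and_deterministic_on_nonlinear_model():
    rng = np.random.default_rng(6)
    t = np.linspace(0, 1, 40)
    theta_true = np.array([0.4, -0.6])

    def fwd(thetas):
        thetas = np.atleast_2d(thetas)
        return np.exp(thetas[:, [0]]) * np.sin(
            2 * np.pi * (1 + thetas[:, [1]]) * t[None, :]
        )

    y = fwd(theta_true[None])[0] + rng.normal(0, 0.05, t.size)
    prior = Prior(np.zeros(2), 0.25 * np.eye(2))
    p1 = invert(y, fwd, prior, Hyperparameters())
    p2 = invert(y, fwd, prior, Hyperparameters())
    assert np.all(np.diff(p1.trace) >= 0)
    assert p1.free_energy == p2.free_energy  # determinism
    assert np.array_equal(p1.mean, p2.mean)
    # recovers the generating parameters reasonably
    assert np.max(np.abs(p1.mean - theta_true)) < 0.1


def test_self_consistency_zero_noise_recovers_truth():
    """Data generated at a prior-plausible theta, no noise: posterior
    lands within two prior SDs and residuals vanish."""
    t = np.linspace(0, 1, 60)

    def fwd(thetas):
        thetas = np.atleast_2d(thetas)
        return np.exp(thetas[:, [0]] * t[None, :]) - thetas[:, [1]] * t[None, :]

    theta_true = np.array([0.3, -0.2])
    y = fwd(theta_true[None])[0]
    prior = Prior(np.zeros(2), np.diag([1 / 16, 1 / 16]))
    post = invert(y, fwd, prior, Hyperparameters())
    sd = np.sqrt(np.diag(prior.cov))
    assert np.all(np.abs(post.mean - theta_true) < 2 * sd)
    resid = y - fwd(post.mean[None])[0]
    assert np.var(resid) < 1e-6 * np.var(y)


def test_occam_irrelevant_parameter_does_not_raise_evidence():
    X, y, prior3, lam, *_ = conjugate_problem(7)
    post3 = invert(y, lambda th: th @ X.T, prior3, Hyperparameters(fixed=lam))
    # extra parameter with no effect on the prediction
    prior4 = Prior(np.zeros(4), np.diag(np.append(np.diag(prior3.cov), 1.0)))
    post4 = invert(
        y, lambda th: th[:, :3] @ X.T, prior4, Hyperparameters(fixed=lam)
    )
    assert post4.free_energy <= post3.free_energy + 1e-6
    # nested-model margin stays within the Occam band
    assert post3.free_energy - post4.free_energy < 3.0


def test_evidence_extraction_and_units():
    X, y, prior, lam, _, _, logZ = conjugate_problem(8)
    post = invert(
        y, lambda th: th @ X.T, prior, Hyperparameters(fixed=lam),
        model_id="m1", subject_id="s1",
    )
    ev = evidence(post)
    assert ev.value == post.free_energy
    assert ev.model_id == "m1" and ev.subject_id == "s1"
    assert ev.log10 == pytest.approx(ev.value / np.log(10))


def test_nonfinite_data_rejected():
    prior = Prior(np.zeros(2), np.eye(2))
    with pytest.raises(ValueError, match="finite"):
        invert(np.array([1.0, np.nan]), lambda th: th, prior)


def test_singular_prior_rejected():
    with pytest.raises(ValueError, match="positive definite"):
        Prior(np.zeros(2), np.zeros((2, 2)))
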