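"""Variational Laplace inversion of nonlinear evoked-response models.

Fits a Gaussian approximate posterior ``q(theta) = N(mu, Sigma)`` over
log-scale model parameters, together with a log noise precision
``lambda`` (IID Gaussian observation noise in mode space), by maximising
the variational free energy

    F = <log p(y | theta, lambda)>_q - KL(q(theta) || p(theta))
                                     - KL(q(lambda) || p(lambda))

which is a lower-bound approximation to the log model evidence and is
the quantity used for Bayesian model comparison.  The posterior mean is
updated by Gauss-Newton steps on finite-difference sensitivities with
Levenberg-Marquardt damping; a step is accepted only if it improves the
best free energy attained so far, so the recorded free-energy trace is
non-decreasing by construction.  The noise precision is re-optimised by
a bounded one-dimensional search after every accepted step.

For linear-Gaussian models with fixed noise precision the attained free
energy equals the closed-form log marginal likelihood, which is used as
an exactness oracle in the tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np
from scipy import linalg as sla
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class Prior:
    """Gaussian prior over the free parameters (log-scale factors)."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        cov = np.asarray(self.cov, dtype=float)
        if cov.ndim == 1:
            cov = np.diag(cov)
        if cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("prior covariance shape mismatch")
        self.cov = cov
        try:
            self._chol = sla.cho_factor(self.cov, lower=True)
        except sla.LinAlgError as e:
            raise ValueError("prior covariance must be positive definite") from e
        self.logdet = 2.0 * float(np.sum(np.log(np.diag(self._chol[0]))))
        self.inv = sla.cho_solve(self._chol, np.eye(self.mean.size))

    @classmethod
    def from_variances(cls, mean: np.ndarray, variances: np.ndarray) -> "Prior":
        return cls(mean=np.asarray(mean, dtype=float), cov=np.asarray(variances, dtype=float))


@dataclass
class Hyperparameters:
    """Prior over the log noise precision ``lambda``.

    Noise covariance is ``exp(-lambda) * I`` over all mode-space samples.
    ``fixed`` pins lambda at a known value (no hyperparameter search and
    no lambda KL term) — used by the conjugate oracles.
    """

    mean: float = 4.0
    var: float = 1.0
    fixed: Optional[float] = None


@dataclass
class Settings:
    """Inversion controls (all deterministic)."""

    max_iter: int = 64
    tol_nats: float = 0.05
    converge_count: int = 3
    fd_step: float = 1e-3
    max_step_trials: int = 8
    initial_damping: float = 1e-3
    lambda_search_halfwidth: float = 12.0
    fd_dtype: type = np.float64


@dataclass
class FreeEnergyTerms:
    """Audit decomposition of the variational free energy (nats)."""

    accuracy: float
    complexity_theta: float
    complexity_lambda: float

    @property
    def total(self) -> float:
        return self.accuracy - self.complexity_theta - self.complexity_lambda


@dataclass
class Posterior:
    """Gaussian approximate posterior plus the attained free energy."""

    mean: np.ndarray
    cov: np.ndarray
    lam: float
    lam_var: float
    free_energy: float
    terms: FreeEnergyTerms
    trace: List[float]
    converged: bool
    n_iter: int
    param_names: Optional[List[str]] = None
    model_id: Optional[str] = None
    subject_id: Optional[str] = None


@dataclass
class LogEvidence:
    """Free-energy approximation to log model evidence (nats)."""

    value: float
    model_id: Optional[str] = None
    subject_id: Optional[str] = None

    @property
    def log10(self) -> float:
        return self.value / float(np.log(10.0))


def evidence(posterior: Posterior) -> LogEvidence:
    """Extract the attained free energy with provenance."""
    return LogEvidence(
        value=posterior.free_energy,
        model_id=posterior.model_id,
        subject_id=posterior.subject_id,
    )


# ---------------------------------------------------------------------------
# free energy


def _posterior_precision(JtJ: np.ndarray, lam: float, prior: Prior) -> np.ndarray:
    return np.exp(lam) * JtJ + prior.inv


def free_energy(
    residuals: np.ndarray,
    J: np.ndarray,
    theta: np.ndarray,
    prior: Prior,
    lam: float,
    hyper: Hyperparameters,
    JtJ: Optional[np.ndarray] = None,
) -> FreeEnergyTerms:
    """Free energy of ``q(theta) = N(theta, Sigma_p)`` at the GN curvature.

    ``Sigma_p`` is the Gauss-Newton posterior covariance implied by the
    sensitivities ``J`` and noise precision ``exp(lam)``; the accuracy
    term carries the expected log likelihood under ``q`` and the
    complexity terms the KL divergences to the priors.
    """
    r = np.asarray(residuals, dtype=float).ravel()
    N = r.size
    if JtJ is None:
        JtJ = J.T @ J
    H = _posterior_precision(JtJ, lam, prior)
    try:
        cho = sla.cho_factor(H, lower=True)
    except sla.LinAlgError as e:
        raise np.linalg.LinAlgError("singular posterior precision") from e
    logdet_H = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    Sigma_p = sla.cho_solve(cho, np.eye(H.shape[0]))
    elam = np.exp(lam)
    tr_data = elam * float(np.trace(JtJ @ Sigma_p))
    d = np.asarray(theta, dtype=float).ravel() - prior.mean
    rr = float(r @ r)

    accuracy = -0.5 * N * LOG2PI + 0.5 * N * lam - 0.5 * elam * rr - 0.5 * tr_data
    kl_theta = 0.5 * (
        float(np.trace(prior.inv @ Sigma_p))
        + float(d @ prior.inv @ d)
        - d.size
        + prior.logdet
        - (-logdet_H)
    )
    if hyper.fixed is not None:
        kl_lam = 0.0
    else:
        # Laplace posterior variance of lambda from the curvature of F
        curv = 0.5 * elam * (rr + tr_data / elam) + 1.0 / hyper.var
        v_post = 1.0 / curv
        kl_lam = (lam - hyper.mean) ** 2 / (2.0 * hyper.var) + 0.5 * (
            v_post / hyper.var - 1.0 - np.log(v_post / hyper.var)
        )
    return FreeEnergyTerms(
        accuracy=accuracy,
        complexity_theta=kl_theta,
        complexity_lambda=float(kl_lam),
    )


def _optimise_lambda(
    hyper: Hyperparameters,
    lam0: float,
    halfwidth: float,
    terms_fn,
) -> float:
    """Bounded 1-D maximisation of F over lambda (theta, J fixed).

    ``terms_fn(lam)`` must return the :class:`FreeEnergyTerms` at that
    lambda; the current value ``lam0`` is kept if the search does not
    improve on it, so F never decreases through a lambda update.
    """
    if hyper.fixed is not None:
        return float(hyper.fixed)

    def neg_f(lam: float) -> float:
        return -terms_fn(lam).total

    lo = hyper.mean - halfwidth
    hi = hyper.mean + halfwidth
    res = minimize_scalar(neg_f, bounds=(lo, hi), method="bounded", options={"xatol": 1e-4})
    return float(res.x) if -res.fun >= -neg_f(lam0) else float(lam0)


# ---------------------------------------------------------------------------
# inversion


def _fd_jacobian(
    forward_flat: Callable[[np.ndarray], np.ndarray],
    theta: np.ndarray,
    fd_step: float,
    dtype=np.float64,
) -> np.ndarray:
    """Central finite-difference sensitivities of the flattened prediction."""
    p = theta.size
    steps = np.eye(p) * fd_step
    batch = np.vstack([theta + steps, theta - steps]).astype(dtype)
    pred = np.asarray(forward_flat(batch), dtype=float)
    J = (pred[:p] - pred[p:]).T / (2.0 * fd_step)
    return J


def invert(
    data: np.ndarray,
    forward_flat: Callable[[np.ndarray], np.ndarray],
    prior: Prior,
    hyper: Optional[Hyperparameters] = None,
    settings: Optional[Settings] = None,
    param_names: Optional[List[str]] = None,
    model_id: Optional[str] = None,
    subject_id: Optional[str] = None,
) -> Posterior:
    """Invert a generative model given flattened response data.

    ``forward_flat`` maps a (B, p) batch of parameter vectors to (B, N)
    flattened predictions.  Returns the best-free-energy state; if the
    scheme hits the iteration cap without meeting the tolerance the
    posterior is flagged ``converged=False`` (best state still
    returned).
    """
    hyper = hyper or Hyperparameters()
    settings = settings or Settings()
    y = np.asarray(data, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("data contain non-finite values")

    theta = prior.mean.copy()
    lam = float(hyper.fixed) if hyper.fixed is not None else float(hyper.mean)

    g0 = np.asarray(forward_flat(theta[None, :]), dtype=float)[0]
    if not np.all(np.isfinite(g0)):
        raise ValueError("model is not simulable at the prior mean")
    r = y - g0

    trace: List[float] = []
    best_F = -np.inf
    best = None
    damping = settings.initial_damping
    n_small = 0
    converged = False
    n_iter = 0

    for n_iter in range(1, settings.max_iter + 1):
        J = _fd_jacobian(forward_flat, theta, settings.fd_step, settings.fd_dtype)
        JtJ = J.T @ J

        def terms_at(lam_v, rr_vec=r, th=theta):
            return free_energy(rr_vec, J, th, prior, lam_v, hyper, JtJ=JtJ)

        lam = _optimise_lambda(
            hyper, lam, settings.lambda_search_halfwidth, terms_at
        )
        F_curr = terms_at(lam).total
        if F_curr > best_F:
            best_F = F_curr
            best = (theta.copy(), lam, J, r.copy())
            if not trace:
                trace.append(best_F)

        # Levenberg-Marquardt trial steps against the best F so far
        elam = np.exp(lam)
        grad = elam * (J.T @ r) - prior.inv @ (theta - prior.mean)
        H = elam * JtJ + prior.inv
        dH = np.diag(np.diag(H))
        accepted = False
        for _ in range(settings.max_step_trials):
            try:
                dtheta = np.linalg.solve(H + damping * dH, grad)
            except np.linalg.LinAlgError:
                damping *= 4.0
                continue
            theta_t = theta + dtheta
            try:
                g_t = np.asarray(forward_flat(theta_t[None, :]), dtype=float)[0]
            except RuntimeError:  # divergent trajectory: reject this step
                g_t = np.full_like(y, np.nan)
            if np.all(np.isfinite(g_t)):
                r_t = y - g_t
                lam_t = _optimise_lambda(
                    hyper, lam, settings.lambda_search_halfwidth,
                    lambda lv: free_energy(r_t, J, theta_t, prior, lv, hyper, JtJ=JtJ),
                )
                F_t = free_energy(r_t, J, theta_t, prior, lam_t, hyper, JtJ=JtJ).total
            else:
                F_t = -np.inf
            if F_t > best_F:
                dF = F_t - best_F
                theta, r, lam = theta_t, r_t, lam_t
                best_F = F_t
                best = (theta.copy(), lam, J, r.copy())
                trace.append(best_F)
                logger.debug(
                    "iter %d: F=%.4f (dF=%.4g, lambda=%.3f, damping=%.2g)",
                    n_iter, best_F, dF, lam, damping,
                )
                damping = max(damping / 2.0, 1e-8)
                accepted = True
                n_small = n_small + 1 if dF < settings.tol_nats else 0
                break
            damping *= 4.0
        if not accepted:
            converged = True
            break
        if n_small >= settings.converge_count:
            converged = True
            break

    if best is None:  # pragma: no cover - defensive
        raise RuntimeError("free energy could not be evaluated")
    theta_b, lam_b, J_b, r_b = best
    JtJ_b = J_b.T @ J_b
    H_b = _posterior_precision(JtJ_b, lam_b, prior)
    Sigma_p = np.linalg.inv(H_b)
    terms = free_energy(r_b, J_b, theta_b, prior, lam_b, hyper, JtJ=JtJ_b)
    if hyper.fixed is not None:
        lam_var = 0.0
    else:
        rr = float(r_b @ r_b)
        tr_data = float(np.trace(JtJ_b @ Sigma_p))
        lam_var = 1.0 / (0.5 * np.exp(lam_b) * (rr + tr_data) + 1.0 / hyper.var)
    if not converged:
        logger.warning(
            "inversion hit max_iter=%d without convergence (model=%s subject=%s)",
            settings.max_iter, model_id, subject_id,
        )
    return Posterior(
        mean=theta_b,
        cov=Sigma_p,
        lam=lam_b,
        lam_var=lam_var,
        free_energy=terms.total,
        terms=terms,
        trace=trace,
        converged=converged,
        n_iter=n_iter,
        param_names=param_names,
        model_id=model_id,
        subject_id=subject_id,
    )
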