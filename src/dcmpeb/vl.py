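"""Generic variational Laplace: Gaussian posteriors by free-energy ascent.

Fits the model

    y = g(theta) + e,    e ~ N(0, exp(-lambda) I)
    theta ~ N(eta, P_theta^-1),    lambda ~ N(mu_l, v_l)

for an arbitrary differentiable forward map ``g`` by Gauss-Newton ascent
on the Laplace free energy

    F = accuracy - complexity
      = E_q[ln p(y | theta, lambda)] - KL(q(theta) || p(theta))
                                     - KL(q(lambda) || p(lambda))

with Levenberg-Marquardt damping of the step size.  Rejected steps
restore the previous state, so the trace of accepted free energies is
non-decreasing by construction.  For a linear ``g`` and fixed noise the
scheme terminates at the exact conjugate Gaussian posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import linalg

from .beliefs import GaussianBelief

__all__ = ["VLResult", "variational_laplace", "finite_difference_jacobian", "default_noise_hyperprior"]

FD_STEP = 1e-4


def default_noise_hyperprior() -> GaussianBelief:
    """Weakly-informative hyperprior over the observation log-precision."""
    return GaussianBelief(np.zeros(1), np.array([[16.0]]), label="log-precision")


def finite_difference_jacobian(
    forward: Callable[[np.ndarray], np.ndarray],
    theta: np.ndarray,
    f0: np.ndarray | None = None,
    step: float = FD_STEP,
) -> np.ndarray:
    """Central finite-difference Jacobian dg/dtheta, (n_data, n_params).

    Falls back to a one-sided difference when a perturbed evaluation is
    not finite (e.g. a perturbation crossing a stability boundary).
    """
    theta = np.asarray(theta, dtype=float)
    if f0 is None:
        f0 = forward(theta)
    cols = []
    for i in range(theta.size):
        dp = np.zeros_like(theta)
        dp[i] = step
        fp = forward(theta + dp)
        fm = forward(theta - dp)
        ok_p, ok_m = np.all(np.isfinite(fp)), np.all(np.isfinite(fm))
        if ok_p and ok_m:
            cols.append((fp - fm) / (2 * step))
        elif ok_p:
            cols.append((fp - f0) / step)
        elif ok_m:
            cols.append((f0 - fm) / step)
        else:
            cols.append(np.zeros_like(f0))
    return np.column_stack(cols)


@dataclass
class VLResult:
    """Converged state of a variational Laplace run."""

    posterior: GaussianBelief
    F: float
    accuracy: float
    complexity: float
    log_precision: float
    log_precision_var: float
    trace: list[float] = field(default_factory=list)
    n_iter: int = 0


def _gaussian_kl(m_q: float, v_q: float, m_p: float, v_p: float) -> float:
    return 0.5 * (v_q / v_p + (m_q - m_p) ** 2 / v_p - 1.0 + np.log(v_p / v_q))


def variational_laplace(
    forward: Callable[[np.ndarray], np.ndarray],
    prior: GaussianBelief,
    data: np.ndarray,
    noise_hyperprior: GaussianBelief | None = None,
    max_iter: int = 64,
    tol: float = 0.01,
    n_converge: int = 4,
    fd_step: float = FD_STEP,
    jacobian_fn=None,
) -> VLResult:
    """Invert ``data = forward(theta) + noise`` under Gaussian priors.

    Parameters
    ----------
    forward : callable
        Maps a parameter vector to a predicted feature vector.  May
        return non-finite values for infeasible parameters; such
        candidate steps are rejected.
    prior : GaussianBelief
        Prior over theta.
    data : array
        Observed feature vector.
    noise_hyperprior : GaussianBelief, optional
        1-D belief over the observation log-precision lambda (noise
        precision is exp(lambda) * I).  A zero-variance hyperprior fixes
        lambda.  Defaults to the weakly-informative N(0, 16).
    jacobian_fn : callable, optional
        ``jacobian_fn(theta, f0)`` returning dg/dtheta; defaults to
        central finite differences of `forward`.

    Returns
    -------
    VLResult
        Posterior, free energy, its accuracy/complexity split, the
        posterior over lambda and the accepted free-energy trace.
    """
    y = np.asarray(data, dtype=float).ravel()
    if noise_hyperprior is None:
        noise_hyperprior = default_noise_hyperprior()
    mu_l = float(noise_hyperprior.mean[0])
    v_l = float(noise_hyperprior.cov[0, 0])
    fixed_noise = v_l <= 0.0

    n = y.size
    eta = prior.mean.copy()
    P_th = prior.precision(jitter=1e-10)

    g0 = np.asarray(forward(eta), dtype=float).ravel()
    if g0.size != n:
        raise ValueError(f"forward map returns {g0.size} features, data has {n}")
    if not np.all(np.isfinite(g0)):
        raise ValueError("forward map is not finite at the prior mean")

    mu = eta.copy()
    lam = mu_l
    s_l = v_l if not fixed_noise else 0.0

    def state_F(mu_c, lam_c, g_c, J_c):
        """Free energy and posterior covariance at a candidate state."""
        r = y - g_c
        Pe = np.exp(lam_c)
        H = Pe * (J_c.T @ J_c) + P_th
        Sigma = linalg.inv(H)
        sse = float(r @ r) + float(np.trace(Sigma @ (J_c.T @ J_c)))
        acc = 0.5 * n * (lam_c - np.log(2 * np.pi)) - 0.5 * Pe * sse
        post = GaussianBelief(mu_c, Sigma, label="posterior")
        comp = post.kl_from(prior)
        if not fixed_noise:
            s_l_c = 1.0 / (0.5 * Pe * sse + 1.0 / v_l)
            comp += _gaussian_kl(lam_c, s_l_c, mu_l, v_l)
        else:
            s_l_c = 0.0
        return acc - comp, acc, comp, post, s_l_c, sse

    def update_lambda(lam_c, sse):
        """Damped Newton steps on the log-precision at fixed theta."""
        for _ in range(8):
            Pe = np.exp(lam_c)
            grad = 0.5 * n - 0.5 * Pe * sse - (lam_c - mu_l) / v_l
            hess = -0.5 * Pe * sse - 1.0 / v_l
            step = np.clip(-grad / hess, -2.0, 2.0)
            lam_c += step
            if abs(step) < 1e-6:
                break
        return lam_c

    if jacobian_fn is None:
        jacobian_fn = lambda th, f0: finite_difference_jacobian(forward, th, f0=f0, step=fd_step)
    g = g0
    J = jacobian_fn(mu, g)
    F, acc, comp, post, s_l, sse = state_F(mu, lam, g, J)
    trace = [F]
    rho = 1e-6  # LM damping: start near a full Newton step (exact for linear g)
    n_small = 0
    n_accept = 0
    any_finite_candidate = False

    for it in range(max_iter):
        Pe = np.exp(lam)
        r = y - g
        grad = Pe * (J.T @ r) - P_th @ (mu - eta)
        H = Pe * (J.T @ J) + P_th

        accepted = False
        while rho < 1e10:
            try:
                d_mu = linalg.solve(H + rho * np.diag(np.diag(H)), grad, assume_a="pos")
            except linalg.LinAlgError:
                d_mu = linalg.lstsq(H + rho * np.eye(H.shape[0]), grad)[0]
            mu_c = mu + d_mu
            g_c = np.asarray(forward(mu_c), dtype=float).ravel()
            if np.all(np.isfinite(g_c)):
                any_finite_candidate = True
                J_c = jacobian_fn(mu_c, g_c)
                lam_c = lam
                if not fixed_noise:
                    # E-step residual at the candidate mean
                    r_c = y - g_c
                    Sg = linalg.inv(np.exp(lam) * (J_c.T @ J_c) + P_th)
                    sse_c = float(r_c @ r_c) + float(np.trace(Sg @ (J_c.T @ J_c)))
                    lam_c = update_lambda(lam, sse_c)
                F_c, acc_c, comp_c, post_c, s_l_c, sse = state_F(mu_c, lam_c, g_c, J_c)
                if np.isfinite(F_c) and F_c >= F:
                    dF = F_c - F
                    mu, lam, g, J = mu_c, lam_c, g_c, J_c
                    F, acc, comp, post, s_l = F_c, acc_c, comp_c, post_c, s_l_c
                    trace.append(F)
                    rho = max(rho / 2.0, 1e-8)
                    accepted = True
                    n_accept += 1
                    n_small = n_small + 1 if dF < tol else 0
                    break
            rho *= 8.0
        if not accepted:
            break  # damping exhausted: no ascent direction left
        if n_small >= n_converge:
            break

    if n_accept == 0 and not any_finite_candidate:
        raise RuntimeError("variational Laplace failed to take any step: forward map not finite for every candidate")
    return VLResult(
        posterior=post,
        F=float(F),
        accuracy=float(acc),
        complexity=float(comp),
        log_precision=float(lam),
        log_precision_var=float(s_l),
        trace=trace,
        n_iter=len(trace) - 1,
    )
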