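"""Per-window model inversion and iterative empirical-prior refinement.

``invert_window`` fits the neural-mass cross-spectral model to one
window's observed CSD by variational Laplace, with the non-redundant
Hermitian stacking of the CSD matrices as the feature vector and a
single estimated log-precision as the feature noise model.

``peb_fit`` guards against local minima: windows are inverted
independently, a constant-only PEB estimates the between-window mean,
and the windows are re-inverted under the empirical shrinkage prior
centred on that mean, iterating while the hierarchical free energy
improves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beliefs import GaussianBelief
from .features import CrossSpectralData, explained_variance
from .networks import NetworkSpec
from .nmm import CsdModel, ErpConstants, ErpParameters, StabilityError, predict_csd
from .peb import _peb_core, bayesian_model_reduction, default_beta_prior, Q0_SCALE
from .vl import VLResult, variational_laplace

__all__ = ["DCMPosterior", "invert_window", "peb_fit"]


@dataclass
class DCMPosterior:
    """Posterior over one window's parameters, with fit diagnostics."""

    belief: GaussianBelief
    F: float
    explained_variance: float
    window: int = 0
    log_precision: float = 0.0
    trace: list[float] = field(default_factory=list)


def invert_window(
    csd: CrossSpectralData,
    spec: NetworkSpec,
    prior: GaussianBelief,
    gain: np.ndarray,
    constants: ErpConstants | None = None,
    noise_hyperprior: GaussianBelief | None = None,
    band: tuple[float, float] = (1.0, 45.0),
    max_iter: int = 64,
    tol: float = 0.01,
) -> DCMPosterior:
    """Fit the network model to one window's cross-spectral data.

    The window's frequency grid must lie inside the modelled band.
    Raises :class:`~dcmpeb.nmm.StabilityError` via the engine if the
    prior mean itself is unstable.
    """
    gain = np.atleast_2d(np.asarray(gain, dtype=float))
    if gain.shape != (csd.n_modes, spec.n_sources):
        raise ValueError(
            f"gain shape {gain.shape} does not match {csd.n_modes} modes x {spec.n_sources} sources"
        )
    if prior.dim != spec.n_params:
        raise ValueError(f"prior dimension {prior.dim} != B = {spec.n_params}")
    if csd.freqs.min() < band[0] - 1e-9 or csd.freqs.max() > band[1] + 1e-9:
        raise ValueError(
            f"window frequency grid [{csd.freqs.min():g}, {csd.freqs.max():g}] Hz "
            f"outside the modelled band {band}"
        )
    constants = constants or ErpConstants()
    model = CsdModel(spec, gain, csd.freqs, constants)
    res: VLResult = variational_laplace(
        model.features,
        prior,
        csd.likelihood_features(),
        noise_hyperprior=noise_hyperprior,
        max_iter=max_iter,
        tol=tol,
        jacobian_fn=model.jacobian,
    )
    params = ErpParameters.from_vector(res.posterior.mean, spec, constants)
    try:
        ev = explained_variance(csd, predict_csd(params, spec, gain, csd.freqs))
    except StabilityError:  # pragma: no cover - posterior mean is an accepted (stable) point
        ev = float("nan")
    return DCMPosterior(
        belief=res.posterior,
        F=res.F,
        explained_variance=ev,
        window=csd.window,
        log_precision=res.log_precision,
        trace=res.trace,
    )


def peb_fit(
    windows: list[CrossSpectralData],
    spec: NetworkSpec,
    prior: GaussianBelief,
    gain: np.ndarray,
    max_iter: int = 8,
    tol: float = 1.0 / 8.0,
    constants: ErpConstants | None = None,
    vl_max_iter: int = 64,
    return_trace: bool = False,
    return_prior: bool = False,
    **invert_kwargs,
) -> list[DCMPosterior]:
    """Iteratively re-invert windows under empirical shrinkage priors.

    Alternates (i) inversion of every window under the current prior
    and (ii) replacement of the prior mean by the PEB-estimated
    between-window mean (constant-only design, covariance kept at the
    original prior covariance).  A round is accepted only if the
    hierarchical free energy (sum of window free energies plus the PEB
    correction) improves; iteration stops when the improvement falls
    below `tol` or after `max_iter` rounds.
    """
    if not windows:
        raise ValueError("need at least one window")

    def invert_all(p: GaussianBelief) -> list[DCMPosterior]:
        return [
            invert_window(w, spec, p, gain, constants=constants, max_iter=vl_max_iter, **invert_kwargs)
            for w in windows
        ]

    # empirical shrinkage applies to the connectivity field only; spectral
    # and noise parameters keep their original priors (re-centring nuisance
    # parameters lets them drift between rounds)
    gidx = np.arange(spec.n_edges)

    def constant_peb(posteriors: list[DCMPosterior], p: GaussianBelief):
        beliefs = [d.belief.marginal(gidx) for d in posteriors]
        pg = p.marginal(gidx)
        Q0 = Q0_SCALE * np.eye(pg.dim)
        Q1 = 16.0 * pg.precision(jitter=1e-12)
        X = np.ones((len(beliefs), 1))
        bp = default_beta_prior(pg, 1)
        post, g_hat, _, F_peb = _peb_core(beliefs, pg, X, Q0, Q1, bp)
        V = np.linalg.inv(Q0 + np.exp(-g_hat) * Q1)
        return post.mean, V, F_peb

    def hierarchical_F(posteriors: list[DCMPosterior], p: GaussianBelief) -> tuple[float, np.ndarray]:
        mean, _, F_peb = constant_peb(posteriors, p)
        return sum(d.F for d in posteriors) + F_peb, mean

    def recenter(p: GaussianBelief, gain_mean: np.ndarray, gain_cov: np.ndarray | None = None) -> GaussianBelief:
        mean = prior.mean.copy()
        mean[gidx] = gain_mean
        cov = prior.cov.copy()
        if gain_cov is not None:
            cov[np.ix_(gidx, gidx)] = gain_cov
        return GaussianBelief(mean, cov, label="empirical-prior")

    current_prior = prior
    posteriors = invert_all(current_prior)
    F, mean = hierarchical_F(posteriors, current_prior)
    trace = [F]
    for _ in range(max_iter - 1):
        trial_prior = recenter(prior, mean)
        trial = invert_all(trial_prior)
        F_trial, mean_trial = hierarchical_F(trial, trial_prior)
        if F_trial <= F + tol:
            if F_trial > F:
                posteriors, F = trial, F_trial
                trace.append(F)
            break
        posteriors, F, mean = trial, F_trial, mean_trial
        trace.append(F)
        current_prior = trial_prior

    # final empirical-Bayes shrinkage of the connectivity block: replace its
    # prior by the estimated between-window model N(mean, V) and reduce
    # analytically (the other blocks keep the prior they were fitted under)
    mean_hat, V, _ = constant_peb(posteriors, current_prior)
    emp_prior = recenter(current_prior, mean_hat, V)
    refined = []
    for d in posteriors:
        try:
            _, q = bayesian_model_reduction(d.belief, current_prior, emp_prior)
        except np.linalg.LinAlgError:
            q = d.belief
        refined.append(
            DCMPosterior(
                belief=q,
                F=d.F,
                explained_variance=d.explained_variance,
                window=d.window,
                log_precision=d.log_precision,
                trace=d.trace,
            )
        )
    extras = []
    if return_trace:
        extras.append(trace)
    if return_prior:
        extras.append(emp_prior)
    if extras:
        return (refined, *extras)
    return refined
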