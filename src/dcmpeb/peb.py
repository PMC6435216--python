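"""Parametric empirical Bayes over window (and subject) posteriors.

The hierarchy treats lower-level parameter vectors as draws from a
linear model at the level above:

    theta = (X kron I_B) beta + eps,   eps  ~ N(0, Sigma(gamma))
    beta  = eta + xi,                  beta ~ N(0, Xi)

with a single log-precision ``gamma`` scaling the random-effects
precision, Sigma(gamma)^-1 = I_W kron (Q0 + exp(-gamma) Q1).  Because
each lower level is summarised by a Gaussian prior/posterior pair, the
upper level never touches the data: Bayesian model reduction (BMR)
replaces each unit's prior with the empirical prior implied by
``beta``, and the change in log evidence is analytic.  For fixed gamma
the problem is conjugate, so ``beta`` has a closed-form posterior and
only the scalar gamma needs numerical optimisation; the evidence is
completed with a Laplace correction over gamma.

The same machinery runs at two levels: windows within a subject
(second level) and subject effects within the group (third level, a
constant-only design).  On top of it sit model-space enumeration over
temporal basis functions, fixed-effects pooling of evidence over
subjects, greedy pruning with an exhaustive final sweep, Bayesian model
averaging, and trajectory prediction with credible bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.special import softmax

from .beliefs import GaussianBelief
from .design import DesignMatrix

__all__ = [
    "PEBResult",
    "ModelSpace",
    "BMAResult",
    "Trajectories",
    "bayesian_model_reduction",
    "peb_estimate",
    "group_peb",
    "enumerate_reduced_models",
    "score_reduced_models",
    "bmc_over_subjects",
    "greedy_search_bma",
    "predict_trajectories",
]

#: precision floor on random effects (lower bound of Sigma(gamma)^-1)
Q0_SCALE = 1e-4
#: prior over the random-effects log-precision offset gamma; with a single
#: precision component, gamma must be free to soak unmodelled lower-level
#: estimation error, or it masquerades as temporal structure
GAMMA_PRIOR_VAR = 1.0
#: prior variance used to switch a parameter off in a reduced model
PRUNED_VARIANCE = 1e-8


# -------------------------------------------------------------------------
# Bayesian model reduction
# -------------------------------------------------------------------------


def _prec(cov: np.ndarray) -> np.ndarray:
    try:
        return linalg.inv(cov)
    except linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("singular covariance in Bayesian model reduction") from err


def bayesian_model_reduction(
    full_posterior: GaussianBelief,
    full_prior: GaussianBelief,
    reduced_prior: GaussianBelief,
) -> tuple[float, GaussianBelief]:
    """Evidence change and posterior implied by swapping the prior.

    Given a posterior estimated under ``full_prior``, returns the change
    in log evidence ``dF`` and the posterior that would have been
    obtained under ``reduced_prior``, using the Gaussian identity on
    precisions and precision-weighted means; no data are revisited.
    """
    if not (full_posterior.dim == full_prior.dim == reduced_prior.dim):
        raise ValueError("dimension mismatch in Bayesian model reduction")
    Pq = _prec(full_posterior.cov)
    P0 = _prec(full_prior.cov)
    P1 = _prec(reduced_prior.cov)
    mq, m0, m1 = full_posterior.mean, full_prior.mean, reduced_prior.mean

    P1q = Pq - P0 + P1
    S1q = _prec(P1q)
    u = Pq @ mq - P0 @ m0 + P1 @ m1
    m1q = S1q @ u

    def _ld(M: np.ndarray) -> float:
        sign, ld = np.linalg.slogdet(M)
        if sign <= 0:
            raise np.linalg.LinAlgError("non-positive-definite matrix in BMR")
        return float(ld)

    dF = 0.5 * (_ld(Pq) - _ld(P1q) + _ld(P1) - _ld(P0))
    dF += 0.5 * (u @ m1q - m1 @ P1 @ m1 + m0 @ P0 @ m0 - mq @ Pq @ mq)
    reduced_posterior = GaussianBelief(m1q, 0.5 * (S1q + S1q.T), label=full_posterior.label)
    return float(dF), reduced_posterior


# -------------------------------------------------------------------------
# PEB estimation
# -------------------------------------------------------------------------


@dataclass
class PEBResult:
    """Posterior over second-level effects for one unit group.

    ``beta`` is ordered regressor-major: block p holds the B
    coefficients of regressor p, matching ``theta = (X kron I_B) beta``.
    """

    beta: GaussianBelief
    gamma: float
    gamma_var: float
    F: float
    design: DesignMatrix
    field_name: str
    Q0: np.ndarray
    Q1: np.ndarray
    beta_prior: GaussianBelief
    n_units: int
    param_labels: list[str] = field(default_factory=list)

    @property
    def B(self) -> int:
        return self.beta.dim // self.design.P

    def coefficient_labels(self) -> list[str]:
        base = self.param_labels or [f"p{b}" for b in range(self.B)]
        return [f"{reg}:{b}" for reg in self.design.labels for b in base]


def _field_indices(field_sel, dim: int, spec=None) -> np.ndarray:
    if field_sel is None or (isinstance(field_sel, str) and field_sel == "all"):
        return np.arange(dim)
    if isinstance(field_sel, str):
        if spec is None:
            raise ValueError("selecting a connection type by name requires the network spec")
        return np.asarray(spec.edge_indices(field_sel), dtype=int)
    return np.asarray(field_sel, dtype=int)


def _peb_core(
    posteriors: list[GaussianBelief],
    unit_prior: GaussianBelief,
    X: np.ndarray,
    Q0: np.ndarray,
    Q1: np.ndarray,
    beta_prior: GaussianBelief,
    gamma_prior_mean: float = 0.0,
    gamma_prior_var: float = GAMMA_PRIOR_VAR,
) -> tuple[GaussianBelief, float, float, float]:
    """Maximise the hierarchical free energy; closed form in beta, scalar search in gamma.

    Returns (beta posterior, gamma, gamma posterior variance, F).
    """
    W, P = X.shape
    B = unit_prior.dim
    P0 = unit_prior.precision(jitter=1e-12)
    eta0 = unit_prior.mean
    Pq = [linalg.inv(q.cov) for q in posteriors]
    cq = [Pq[i] @ posteriors[i].mean - P0 @ eta0 for i in range(W)]
    ld_q = [q.logdet() for q in posteriors]
    ld_0 = unit_prior.logdet()
    quad_q = [posteriors[i].mean @ Pq[i] @ posteriors[i].mean for i in range(W)]
    quad_0 = eta0 @ P0 @ eta0
    Xi_inv = beta_prior.precision(jitter=1e-12)
    ld_Xi = beta_prior.logdet()

    def evaluate(gamma: float) -> tuple[float, np.ndarray, np.ndarray]:
        """F(gamma) after analytically maximising/marginalising beta."""
        Pi = Q0 + np.exp(-gamma) * Q1  # random-effects precision
        sign, ld_Pi = np.linalg.slogdet(Pi)
        if sign <= 0:
            return -np.inf, None, None
        A = Xi_inv.copy()
        b = np.zeros(B * P)
        const = 0.0
        for i in range(W):
            P1q = Pq[i] - P0 + Pi
            try:
                S1q = linalg.inv(P1q)
            except linalg.LinAlgError:
                return -np.inf, None, None
            sign_i, ld_1q = np.linalg.slogdet(S1q)
            if sign_i <= 0:
                return -np.inf, None, None
            # quadratic form of dF_i in the empirical prior mean m_i = (x_i^T kron I_B) beta
            PiS = Pi @ S1q
            R = Pi - PiS @ Pi  # curvature of dF_i in m_i
            s = PiS @ cq[i]  # gradient of dF_i at m_i = 0
            const += 0.5 * (ld_1q - ld_q[i] - ld_0 + ld_Pi)
            const += 0.5 * (cq[i] @ S1q @ cq[i] - quad_q[i] + quad_0)
            x = X[i]
            A += np.kron(np.outer(x, x), R)
            b += np.kron(x, s)
        try:
            Sb = linalg.inv(A)
        except linalg.LinAlgError:
            return -np.inf, None, None
        beta_hat = Sb @ b
        sign_A, ld_A = np.linalg.slogdet(A)
        if sign_A <= 0:
            return -np.inf, None, None
        F = const + 0.5 * (b @ beta_hat) - 0.5 * ld_Xi - 0.5 * ld_A
        if gamma_prior_var > 0:
            F += -0.5 * np.log(2 * np.pi * gamma_prior_var) - 0.5 * (gamma - gamma_prior_mean) ** 2 / gamma_prior_var
        return float(F), beta_hat, Sb

    if gamma_prior_var <= 0:
        g_hat = gamma_prior_mean
        s_g = 0.0
        F_hat, beta_hat, Sb = evaluate(g_hat)
    else:
        res = optimize.minimize_scalar(
            lambda g: -evaluate(g)[0], bounds=(-6.0, 6.0), method="bounded", options={"xatol": 1e-4}
        )
        g_hat = float(res.x)
        F_hat, beta_hat, Sb = evaluate(g_hat)
        h = 1e-3
        d2 = (evaluate(g_hat + h)[0] - 2 * F_hat + evaluate(g_hat - h)[0]) / h**2
        s_g = -1.0 / d2 if d2 < 0 else gamma_prior_var
        F_hat += 0.5 * np.log(2 * np.pi * max(s_g, 1e-12))  # Laplace over gamma
    post = GaussianBelief(beta_hat, 0.5 * (Sb + Sb.T), label="beta")
    return post, g_hat, s_g, float(F_hat)


def default_beta_prior(unit_prior: GaussianBelief, P: int) -> GaussianBelief:
    """Zero-mean prior over beta: I_P kron pC, one pC-scale block per regressor."""
    cov = np.kron(np.eye(P), unit_prior.cov)
    return GaussianBelief(np.zeros(unit_prior.dim * P), cov, label="beta-prior")


def peb_estimate(
    window_posteriors: list[GaussianBelief],
    window_prior: GaussianBelief,
    X: DesignMatrix,
    field_sel=None,
    spec=None,
    gamma_prior: GaussianBelief | None = None,
    field_name: str = "all",
    bmr_prior: GaussianBelief | None = None,
) -> PEBResult:
    """Second-level PEB over per-window posteriors.

    Parameters
    ----------
    window_posteriors, window_prior : GaussianBelief
        Posterior per window and the prior those posteriors were
        estimated under (full parameter vector; `field_sel` extracts
        the modelled subset).
    X : DesignMatrix
        W x P temporal design; W must equal the number of windows.
    field_sel : None, "all", str or index sequence
        Connection-type selector: an edge-type name (with `spec`), an
        explicit index list, or all parameters.
    gamma_prior : GaussianBelief, optional
        1-D prior over gamma; zero variance fixes gamma.
    bmr_prior : GaussianBelief, optional
        The prior the posteriors were actually estimated under, when it
        differs from `window_prior` (e.g. after empirical-shrinkage
        refinement); Bayesian model reduction divides this one out,
        while `window_prior` keeps setting the random-effects and beta
        prior scales.

    Random effects between windows carry covariance exp(gamma) * pC/16:
    a priori, window-to-window fluctuations are 1/16 of the prior
    standard deviation of the parameters.
    """
    W = len(window_posteriors)
    if W == 0:
        raise ValueError("need at least one window posterior")
    if X.W != W:
        raise ValueError(f"design has {X.W} rows but {W} window posteriors given")
    idx = _field_indices(field_sel, window_prior.dim, spec)
    if isinstance(field_sel, str) and field_sel != "all":
        field_name = field_sel
    sub_post = [q.marginal(idx) for q in window_posteriors]
    sub_prior = window_prior.marginal(idx)
    sub_ref = (bmr_prior or window_prior).marginal(idx)
    B = idx.size
    Q0 = Q0_SCALE * np.eye(B)
    Q1 = 16.0 * sub_prior.precision()  # random-effects covariance = pC/16
    beta_prior = default_beta_prior(sub_prior, X.P)
    g_mean, g_var = (0.0, GAMMA_PRIOR_VAR)
    if gamma_prior is not None:
        g_mean, g_var = float(gamma_prior.mean[0]), float(gamma_prior.cov[0, 0])
    post, g_hat, s_g, F = _peb_core(sub_post, sub_ref, X.matrix, Q0, Q1, beta_prior, g_mean, g_var)
    labels = [f"theta{j}" for j in idx] if spec is None else [spec.param_labels()[j] for j in idx]
    return PEBResult(
        beta=post,
        gamma=g_hat,
        gamma_var=s_g,
        F=F,
        design=X,
        field_name=field_name,
        Q0=Q0,
        Q1=Q1,
        beta_prior=beta_prior,
        n_units=W,
        param_labels=labels,
    )


def group_peb(subject_pebs: list[PEBResult], gamma_prior: GaussianBelief | None = None) -> PEBResult:
    """Third-level PEB: conserved (group-mean) second-level effects.

    Subjects' beta posteriors enter a constant-only design, so the
    third-level coefficients are the between-window effects conserved
    over subjects.  Between-subject random effects carry the full prior
    covariance Xi (subjects are a priori as variable as the prior
    allows), scaled by exp(gamma).
    """
    if not subject_pebs:
        raise ValueError("need at least one subject")
    ref = subject_pebs[0]
    for p in subject_pebs[1:]:
        if p.design.labels != ref.design.labels or p.design.W != ref.design.W:
            raise ValueError("subjects must share the second-level design")
        if p.field_name != ref.field_name or p.beta.dim != ref.beta.dim:
            raise ValueError("subjects must share the connection-type field")
    N = len(subject_pebs)
    X3 = DesignMatrix(np.ones((N, 1)), ["constant"]) if N > 1 else DesignMatrix(np.ones((1, 1)), ["constant"])
    posts = [p.beta for p in subject_pebs]
    prior = ref.beta_prior
    dim = prior.dim
    Q0 = Q0_SCALE * np.eye(dim)
    Q1 = prior.precision(jitter=1e-12)  # between-subject covariance = Xi
    g_mean, g_var = (0.0, GAMMA_PRIOR_VAR)
    if gamma_prior is not None:
        g_mean, g_var = float(gamma_prior.mean[0]), float(gamma_prior.cov[0, 0])
    post, g_hat, s_g, F = _peb_core(posts, prior, X3.matrix, Q0, Q1, prior, g_mean, g_var)
    out = PEBResult(
        beta=post,
        gamma=g_hat,
        gamma_var=s_g,
        F=F,
        design=ref.design,  # the within-subject temporal design the coefficients refer to
        field_name=ref.field_name,
        Q0=Q0,
        Q1=Q1,
        beta_prior=prior,
        n_units=N,
        param_labels=ref.param_labels,
    )
    return out


# -------------------------------------------------------------------------
# Model space, comparison, averaging
# -------------------------------------------------------------------------


@dataclass
class ModelSpace:
    """All on/off combinations of the optional (non-constant) regressors.

    Model 1 switches every optional regressor on; the last model is the
    constant-only null.  Probabilities are softmax of pooled log
    evidence (fixed-effects pooling over subjects).
    """

    inclusion: np.ndarray  # (n_models, n_optional) bool
    regressor_labels: list[str]
    per_subject_logev: np.ndarray | None = None  # (n_subjects, n_models)
    pooled_logev: np.ndarray | None = None
    probabilities: np.ndarray | None = None

    @property
    def n_models(self) -> int:
        return self.inclusion.shape[0]

    @property
    def null_index(self) -> int:
        return int(np.flatnonzero(~self.inclusion.any(axis=1))[0])

    def winner(self) -> int:
        if self.pooled_logev is None:
            raise ValueError("no pooled evidence yet; run bmc_over_subjects")
        return int(np.argmax(self.pooled_logev))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.inclusion.astype(int), columns=self.regressor_labels)
        df.insert(0, "model", np.arange(1, self.n_models + 1))
        if self.pooled_logev is not None:
            df["pooled_logev"] = self.pooled_logev
        if self.probabilities is not None:
            df["probability"] = self.probabilities
        return df


def enumerate_reduced_models(n_optional: int, labels: list[str] | None = None) -> ModelSpace:
    """Scaffold of all 2**n combinations; the constant is always on.

    Reduction is implemented downstream by shrinking the prior variance
    of switched-off regressors' coefficients to (effectively) zero.
    """
    if n_optional < 0:
        raise ValueError("regressor count must be non-negative")
    rows = [np.array(bits, dtype=bool) for bits in product([True, False], repeat=n_optional)]
    inclusion = np.array(rows, dtype=bool).reshape(2**n_optional, n_optional)
    labels = labels or [f"regressor{i + 1}" for i in range(n_optional)]
    return ModelSpace(inclusion=inclusion, regressor_labels=list(labels))


def _reduced_beta_prior(peb: PEBResult, regressor_on: np.ndarray) -> GaussianBelief:
    """Beta prior with switched-off regressor blocks pinned to zero."""
    B, P = peb.B, peb.design.P
    cov = peb.beta_prior.cov.copy()
    for p in range(1, P):  # constant (p = 0) always on
        if not regressor_on[p - 1]:
            sl = slice(p * B, (p + 1) * B)
            cov[sl, :] = 0.0
            cov[:, sl] = 0.0
            cov[sl, sl] = PRUNED_VARIANCE * np.eye(B)
    return GaussianBelief(peb.beta_prior.mean, cov, label="reduced-beta-prior")


def score_reduced_models(peb: PEBResult, models: ModelSpace) -> np.ndarray:
    """Log evidence (relative to the full model) of each reduced model."""
    if models.inclusion.shape[1] != peb.design.P - 1:
        raise ValueError("model space does not match the design's optional regressors")
    out = np.empty(models.n_models)
    for m in range(models.n_models):
        dF, _ = bayesian_model_reduction(peb.beta, peb.beta_prior, _reduced_beta_prior(peb, models.inclusion[m]))
        out[m] = dF
    return out


def bmc_over_subjects(per_subject_logev: np.ndarray, models: ModelSpace | None = None) -> ModelSpace:
    """Fixed-effects Bayesian model comparison: sum log evidences over subjects."""
    lev = np.atleast_2d(np.asarray(per_subject_logev, dtype=float))
    if not np.all(np.isfinite(lev)):
        raise ValueError("log evidences must be finite")
    if models is None:
        # infer a plain scaffold sized to the evidence matrix
        n_models = lev.shape[1]
        n_opt = int(np.log2(n_models))
        if 2**n_opt != n_models:
            raise ValueError("cannot infer model space; pass the ModelSpace scaffold")
        models = enumerate_reduced_models(n_opt)
    if lev.shape[1] != models.n_models:
        raise ValueError("evidence matrix does not match the model space")
    pooled = lev.sum(axis=0)
    return ModelSpace(
        inclusion=models.inclusion,
        regressor_labels=models.regressor_labels,
        per_subject_logev=lev,
        pooled_logev=pooled,
        probabilities=softmax(pooled),
    )


@dataclass
class BMAResult:
    """Bayesian model average over a pruned model set.

    ``mean``/``cov`` are moments of the evidence-weighted Gaussian
    mixture; ``Pp[j]`` is the summed posterior probability of the
    models in which parameter j is switched on.
    """

    mean: np.ndarray
    cov: np.ndarray
    Pp: np.ndarray
    model_inclusion: np.ndarray  # (n_models, n_params) bool
    model_logev: np.ndarray
    model_prob: np.ndarray
    param_labels: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        labels = self.param_labels or [f"beta{j}" for j in range(self.mean.size)]
        return pd.DataFrame({"parameter": labels, "bma_mean": self.mean, "Pp": self.Pp})


def _reduced_prior_for_mask(peb: PEBResult, on: np.ndarray) -> GaussianBelief:
    cov = peb.beta_prior.cov.copy()
    off = np.flatnonzero(~on)
    cov[off, :] = 0.0
    cov[:, off] = 0.0
    cov[off, off] = PRUNED_VARIANCE
    return GaussianBelief(peb.beta_prior.mean, cov)


def greedy_search_bma(peb: PEBResult, final_sweep_size: int = 8) -> BMAResult:
    """Prune redundant second-level parameters, then model-average.

    Single parameters are pruned greedily whenever pinning them to zero
    does not decrease the free energy (ties go to the lowest index);
    the search finishes with an exhaustive sweep over all on/off
    combinations of the `final_sweep_size` parameters contributing
    least evidence, and a Bayesian model average over that final model
    set, weighted by model evidence.
    """
    n = peb.beta.dim
    on = np.ones(n, dtype=bool)

    def score(mask: np.ndarray) -> float:
        dF, _ = bayesian_model_reduction(peb.beta, peb.beta_prior, _reduced_prior_for_mask(peb, mask))
        return dF

    current = score(on)
    while True:
        best_j, best_dF = -1, -np.inf
        for j in np.flatnonzero(on):
            trial = on.copy()
            trial[j] = False
            dF = score(trial)
            if dF > best_dF + 1e-12:  # strictly better; ties keep the lowest index
                best_j, best_dF = j, dF
        if best_j < 0 or best_dF < current:
            break  # no pruning leaves F non-decreasing
        on[best_j] = False
        current = best_dF

    # contribution of each parameter = evidence lost when toggled from its state
    contrib = np.empty(n)
    for j in range(n):
        trial = on.copy()
        trial[j] = not trial[j]
        contrib[j] = abs(current - score(trial))
    k = min(final_sweep_size, n)
    sweep = np.sort(np.argsort(contrib, kind="stable")[:k])

    masks, logev, posts = [], [], []
    for bits in product([True, False], repeat=k):
        mask = on.copy()
        mask[sweep] = bits
        dF, post = bayesian_model_reduction(peb.beta, peb.beta_prior, _reduced_prior_for_mask(peb, mask))
        masks.append(mask)
        logev.append(dF)
        posts.append(post)
    masks = np.array(masks)
    logev = np.array(logev)
    prob = softmax(logev)

    mean = np.zeros(n)
    second = np.zeros((n, n))
    for w, post in zip(prob, posts):
        mean += w * post.mean
        second += w * (post.cov + np.outer(post.mean, post.mean))
    cov = second - np.outer(mean, mean)
    cov = 0.5 * (cov + cov.T)
    Pp = np.clip((prob[:, None] * masks).sum(axis=0), 0.0, 1.0)
    mean[~masks.any(axis=0)] = 0.0  # parameters off in every averaged model
    return BMAResult(
        mean=mean,
        cov=cov,
        Pp=Pp,
        model_inclusion=masks,
        model_logev=logev,
        model_prob=prob,
        param_labels=peb.coefficient_labels(),
    )


# -------------------------------------------------------------------------
# Trajectories
# -------------------------------------------------------------------------


@dataclass
class Trajectories:
    """Per-connection temporal trajectories on the log-gain scale."""

    values: np.ndarray  # (W, B)
    lower: np.ndarray
    upper: np.ndarray
    level: float = 0.90
    connection_labels: list[str] = field(default_factory=list)


def predict_trajectories(group_bma: BMAResult, X: DesignMatrix, level: float = 0.90) -> Trajectories:
    """Posterior-predictive trajectories X @ beta with credible bands.

    The band half-width at window n is z * sqrt(x_n^T Sigma_b x_n) per
    connection, with z the two-sided normal quantile of `level`
    (1.645 posterior standard deviations for a 90% band).
    """
    from scipy.stats import norm

    BP = group_bma.mean.size
    P = X.P
    if BP % P != 0:
        raise ValueError("BMA dimension incompatible with the design's regressor count")
    B = BP // P
    beta_mat = group_bma.mean.reshape(P, B)  # regressor-major blocks
    values = X.matrix @ beta_mat  # (W, B)
    z = norm.ppf(0.5 + level / 2.0)
    half = np.empty_like(values)
    for b in range(B):
        idx = np.arange(P) * B + b
        Sb = group_bma.cov[np.ix_(idx, idx)]
        half[:, b] = z * np.sqrt(np.einsum("wp,pq,wq->w", X.matrix, Sb, X.matrix))
    labels = [lab.split(":", 1)[1] for lab in group_bma.param_labels[:B]] if group_bma.param_labels else []
    return Trajectories(values=values, lower=values - half, upper=values + half, level=level, connection_labels=labels)
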