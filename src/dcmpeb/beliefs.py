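"""Gaussian beliefs: the mean/covariance pairs passed between all levels.

Every prior and posterior in the hierarchy -- window-level neuronal
parameters, second-level regression coefficients, group-level effects --
is a multivariate Gaussian.  :class:`GaussianBelief` is the single
container for them, with the small amount of linear algebra (precisions,
log-determinants, KL divergences, marginals) the inversion and
model-reduction machinery needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg


def _as_cov(cov: np.ndarray, n: int) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.ndim == 1:
        cov = np.diag(cov)
    if cov.shape != (n, n):
        raise ValueError(f"covariance shape {cov.shape} does not match mean length {n}")
    if not np.allclose(cov, cov.T, atol=1e-10 * max(1.0, np.abs(cov).max())):
        raise ValueError("covariance must be symmetric")
    return 0.5 * (cov + cov.T)


@dataclass
class GaussianBelief:
    """A Gaussian density N(mean, cov) over a parameter vector.

    Parameters
    ----------
    mean : (n,) array
    cov : (n, n) array or (n,) diagonal
        Symmetric positive semidefinite covariance.
    label : str
        Free-form tag ("prior", "posterior", parameter names, ...).
    """

    mean: np.ndarray
    cov: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = _as_cov(self.cov, self.mean.size)
        w = np.linalg.eigvalsh(self.cov)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError("covariance must be positive semidefinite")

    @property
    def dim(self) -> int:
        return self.mean.size

    def precision(self, jitter: float = 0.0) -> np.ndarray:
        """Inverse covariance (optionally ridge-stabilised)."""
        c = self.cov
        if jitter:
            c = c + jitter * np.eye(self.dim)
        return linalg.inv(c)

    def logdet(self) -> float:
        sign, ld = np.linalg.slogdet(self.cov)
        if sign <= 0:
            raise np.linalg.LinAlgError("covariance is singular; log-determinant undefined")
        return float(ld)

    def kl_from(self, prior: "GaussianBelief") -> float:
        """KL(self || prior); the complexity term of a free energy."""
        if prior.dim != self.dim:
            raise ValueError("dimension mismatch in KL divergence")
        p_prec = prior.precision()
        d = self.mean - prior.mean
        tr = float(np.trace(p_prec @ self.cov))
        quad = float(d @ p_prec @ d)
        return 0.5 * (tr + quad - self.dim + prior.logdet() - self.logdet())

    def marginal(self, idx: np.ndarray | list[int]) -> "GaussianBelief":
        idx = np.asarray(idx, dtype=int)
        return GaussianBelief(self.mean[idx], self.cov[np.ix_(idx, idx)], self.label)

    def copy(self) -> "GaussianBelief":
        return GaussianBelief(self.mean.copy(), self.cov.copy(), self.label)
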