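"""Multi-subject synthetic cross-spectral datasets with known trajectories.

The generator emulates the structure the hierarchical analysis is built
to detect: every subject's extrinsic log-gains follow smooth temporal
trajectories X @ beta' composed of a group-conserved mono-exponential
decay component plus subject-specific DCT components, with additive
window-to-window noise on the log-gains; window CSD matrices come from
the same neural mass forward model the inversion fits, plus sensor
noise on the stacked spectral features.  Ground truth (per-window
parameter matrices and subject coefficients) is stored alongside the
data so every pipeline stage can be scored.

Generation happens at the CSD-feature level: raw EEG time series with
realistic artefacts are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import DesignMatrix, build_design
from .features import CrossSpectralData, hermitian_features, hermitian_from_features
from .networks import NetworkSpec
from .nmm import ErpConstants, ErpParameters, StabilityError, predict_csd, transfer_matrices

__all__ = ["GroundTruth", "SubjectData", "SyntheticDataset", "default_ground_truth", "make_trajectories", "simulate_subject", "simulate_group", "random_gain"]

SUBJECT_SEED_STRIDE = 10_000


@dataclass
class GroundTruth:
    """Data-generating conditions for one synthetic cohort.

    ``beta`` is (n_edges, P): group-level coefficients of each temporal
    regressor per extrinsic connection (log-gain scale).  ``dispersion``
    is (P,): between-subject standard deviation of each regressor's
    coefficients (0 = fully conserved over subjects).
    """

    spec: NetworkSpec
    design: DesignMatrix
    beta: np.ndarray
    dispersion: np.ndarray
    window_noise_sd: float = 0.05
    obs_noise_sd: float = 0.02
    fs: float = 160.0
    freqs: np.ndarray | None = None
    constants: ErpConstants = field(default_factory=ErpConstants)
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.dispersion = np.atleast_1d(np.asarray(self.dispersion, dtype=float))
        if self.beta.shape != (self.spec.n_edges, self.design.P):
            raise ValueError(f"beta must be (n_edges={self.spec.n_edges}, P={self.design.P})")
        if self.dispersion.size != self.design.P:
            raise ValueError("one dispersion per regressor required")
        if self.freqs is None:
            self.freqs = np.arange(4.0, 41.0, 4.0)
        self.freqs = np.asarray(self.freqs, dtype=float)


def default_ground_truth(
    spec: NetworkSpec,
    n_windows: int = 20,
    decay_effect: float = -0.4,
    dct_dispersion: float = 0.2,
    seed: int = 0,
    **kwargs,
) -> GroundTruth:
    """Study conditions mirroring the systematic group finding.

    A conserved negative decay coefficient on every forward connection
    (monotonically increasing forward coupling), zero group-mean DCT
    coefficients with subject-specific dispersion, and window noise on
    the log-gains.
    """
    X = build_design(n_windows)
    beta = np.zeros((spec.n_edges, X.P))
    beta[spec.edge_indices("forward"), X.labels.index("decay")] = decay_effect
    dispersion = np.zeros(X.P)
    for k, lab in enumerate(X.labels):
        if lab.startswith("dct"):
            dispersion[k] = dct_dispersion
    return GroundTruth(spec=spec, design=X, beta=beta, dispersion=dispersion, seed=seed, **kwargs)


def make_trajectories(beta: np.ndarray, X: DesignMatrix) -> np.ndarray:
    """Noiseless log-gain trajectories X @ beta^T, (W, n_connections)."""
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    if beta.shape[1] != X.P:
        raise ValueError(f"beta has {beta.shape[1]} regressor columns, design has {X.P}")
    return X.matrix @ beta.T


def random_gain(n_modes: int, n_sources: int, seed: int = 0) -> np.ndarray:
    """Seeded random observation matrix with orthonormal unit-norm columns.

    Columns are drawn Haar-uniformly (QR of a Gaussian matrix), so every
    source has a unit-norm sensor topography and no two sources project
    to near-collinear patterns -- the degenerate mixing a real lead
    field of spatially separated cortical patches does not exhibit.
    """
    if n_modes < n_sources:
        raise ValueError("need at least as many modes as sources for distinct topographies")
    rng = np.random.default_rng(seed)
    Q, R = np.linalg.qr(rng.standard_normal((n_modes, n_sources)))
    return Q * np.sign(np.diag(R))[None, :]


@dataclass
class SubjectData:
    """One subject's windows plus the ground truth that generated them."""

    windows: list[CrossSpectralData]
    window_params: np.ndarray  # (W, B) full parameter vectors actually used
    beta: np.ndarray  # (n_edges, P) subject coefficients
    seed: int


@dataclass
class SyntheticDataset:
    truth: GroundTruth
    subjects: list[SubjectData]
    gain: np.ndarray
    seed: int

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def _stable_window_params(
    truth: GroundTruth, base: np.ndarray, gains_w: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Log-gains plus window noise, redrawn until the model is stable."""
    ne = truth.spec.n_edges
    for _ in range(100):
        theta = base.copy()
        theta[:ne] = gains_w + rng.standard_normal(ne) * truth.window_noise_sd
        params = ErpParameters.from_vector(theta, truth.spec, truth.constants)
        try:
            transfer_matrices(params, truth.spec, truth.freqs[:1])
        except StabilityError:
            continue
        return theta
    raise StabilityError("no stable window parameters found in 100 rejection attempts")


def simulate_subject(truth: GroundTruth, subject_beta: np.ndarray, seed: int, gain: np.ndarray) -> SubjectData:
    """Generate one subject's W windows of cross-spectral data.

    Per window: extrinsic log-gains follow the subject trajectory plus
    zero-mean window noise (stability enforced by rejection), the CSD
    is the forward prediction at those parameters, and iid Gaussian
    observation noise is added to the stacked real/imaginary features
    (re-Hermitized).  Bit-for-bit reproducible from the seed.
    """
    rng = np.random.default_rng(seed)
    traj = make_trajectories(subject_beta, truth.design)  # (W, n_edges)
    W = truth.design.W
    base = ErpParameters.prior_mean(truth.spec, truth.constants).to_vector()
    windows: list[CrossSpectralData] = []
    params_out = np.empty((W, truth.spec.n_params))
    m = gain.shape[0]
    for w in range(W):
        theta = _stable_window_params(truth, base, traj[w], rng)
        params_out[w] = theta
        pred = predict_csd(ErpParameters.from_vector(theta, truth.spec, truth.constants), truth.spec, gain, truth.freqs)
        S = pred.total
        if truth.obs_noise_sd > 0:
            # iid noise in the non-redundant Hermitian feature space
            feats = hermitian_features(S)
            feats = feats + rng.standard_normal(feats.size) * truth.obs_noise_sd
            S = hermitian_from_features(feats, truth.freqs.size, m)
        windows.append(CrossSpectralData(freqs=truth.freqs, csd=S, fs=truth.fs, window=w))
    return SubjectData(windows=windows, window_params=params_out, beta=np.array(subject_beta), seed=seed)


def simulate_group(truth: GroundTruth, n_subjects: int, seed: int | None = None) -> SyntheticDataset:
    """Generate a cohort with conserved and subject-specific components.

    Subject coefficients are the group beta plus zero-mean Gaussian
    deviations with the per-regressor dispersion; subject s is generated
    with derived seed ``seed + (s + 1) * 10_000``.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    gain = random_gain(truth.spec.n_modes, truth.spec.n_sources, seed=seed)
    subjects = []
    for s in range(n_subjects):
        dev = rng.standard_normal(truth.beta.shape) * truth.dispersion[None, :]
        sub_beta = truth.beta + dev
        sub_seed = seed + (s + 1) * SUBJECT_SEED_STRIDE
        subjects.append(simulate_subject(truth, sub_beta, sub_seed, gain))
    return SyntheticDataset(truth=truth, subjects=subjects, gain=gain, seed=seed)
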