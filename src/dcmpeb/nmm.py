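"""Convolution-based neural mass model and its cross-spectral prediction.

Each source contains three neuronal subpopulations -- spiny stellate
cells, inhibitory interneurons and pyramidal cells -- coupled by intrinsic
gains.  Every synaptic connection is a second-order kernel

    v'' = H * kappa * u - 2 * kappa * v' - kappa**2 * v

driven by presynaptic firing ``u``; firing is a sigmoid of membrane
potential, linearized here at the operating point (constant slope), so
the whole network is a linear state-space system and its spectral
response is available in closed form.

Extrinsic (between-source) connections are typed by the cortical
hierarchy and target different subpopulations:

* forward   -> spiny stellate cells
* backward  -> pyramidal cells and inhibitory interneurons
* lateral   -> all three subpopulations

Each extrinsic connection carries a free log-gain ``g``; the effective
coupling is ``baseline * exp(g)``, which keeps every extrinsic
connection strictly excitatory.  Endogenous neuronal fluctuations
("innovations") drive the stellate population of every source with a
white + 1/f spectrum; channel noise adds a white + 1/f floor at the
sensors.  The predicted cross-spectral density over observation modes is

    S(f) = L T(f) G_u(f) T(f)^H L^T + G_n(f)

with ``L`` the (modes x sources) gain matrix and ``T(f)`` the transfer
function from innovations to pyramidal depolarization.  Conduction
delays (intrinsic and extrinsic) are folded into the Jacobian by a
first-order Taylor correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beliefs import GaussianBelief
from .networks import EDGE_TYPES, NetworkSpec

__all__ = [
    "ErpConstants",
    "ErpParameters",
    "CsdPrediction",
    "StabilityError",
    "default_frequencies",
    "default_priors",
    "jacobian",
    "transfer_matrix",
    "transfer_matrices",
    "predict_csd",
]

N_STATES = 8  # per source: (v, v') for stellate, pyramidal-E, pyramidal-I, inhibitory

# state offsets within a source block
_VS, _DVS, _VPE, _DVPE, _VPI, _DVPI, _VI, _DVI = range(N_STATES)


class StabilityError(ValueError):
    """The linearized system has a non-decaying mode (Re eigenvalue >= 0)."""


@dataclass(frozen=True)
class ErpConstants:
    """Fixed biophysical constants of the three-population source model.

    Values are conventional for convolution-based mass models of EEG;
    they are not estimated.
    """

    H_e: float = 4.0  # excitatory synaptic gain (mV)
    H_i: float = 32.0  # inhibitory synaptic gain (mV)
    kappa_e: float = 1000.0 / 8.0  # excitatory rate constant (1/s), tau_e = 8 ms
    kappa_i: float = 1000.0 / 16.0  # inhibitory rate constant (1/s), tau_i = 16 ms
    gamma: tuple[float, float, float, float] = (128.0, 102.4, 32.0, 32.0)  # intrinsic gains
    #: extrinsic coupling before exp(log-gain) scaling, per connection type:
    #: strong driving forward connections, weaker modulatory backward/lateral
    baselines: tuple[float, float, float] = (64.0, 16.0, 4.0)  # (forward, backward, lateral)
    slope: float = 0.2  # sigmoid slope at the operating point (unitless)
    drive: float = 16.0  # innovation input amplitude (unit convention)

    def baseline(self, edge_type: str) -> float:
        return self.baselines[EDGE_TYPES.index(edge_type)]
    delay_intrinsic: float = 2e-3  # s
    delay_extrinsic: float = 16e-3  # s


@dataclass
class ErpParameters:
    """Free parameters of the network model for one window.

    The free vector, in order: one extrinsic log-gain per edge (forward,
    backward, lateral blocks), one innovation log-amplitude per source,
    the shared innovation 1/f log-amplitude, and the white and 1/f
    observation-noise log-amplitudes.
    """

    log_gains: np.ndarray
    a0: np.ndarray  # innovation log-amplitude per source
    a1: float = 0.0  # shared innovation 1/f log-amplitude
    b0: float = -2.0  # observation noise, white log-amplitude
    b1: float = -2.0  # observation noise, 1/f log-amplitude
    constants: ErpConstants = field(default_factory=ErpConstants)

    def __post_init__(self) -> None:
        self.log_gains = np.atleast_1d(np.asarray(self.log_gains, dtype=float))
        self.a0 = np.atleast_1d(np.asarray(self.a0, dtype=float))

    @classmethod
    def from_vector(cls, theta: np.ndarray, spec: NetworkSpec, constants: ErpConstants | None = None) -> "ErpParameters":
        theta = np.asarray(theta, dtype=float)
        if theta.size != spec.n_params:
            raise ValueError(f"parameter vector length {theta.size} != B = {spec.n_params}")
        ne, ns = spec.n_edges, spec.n_sources
        return cls(
            log_gains=theta[:ne],
            a0=theta[ne : ne + ns],
            a1=float(theta[ne + ns]),
            b0=float(theta[ne + ns + 1]),
            b1=float(theta[ne + ns + 2]),
            constants=constants or ErpConstants(),
        )

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.log_gains, self.a0, [self.a1, self.b0, self.b1]])

    @classmethod
    def prior_mean(cls, spec: NetworkSpec, constants: ErpConstants | None = None) -> "ErpParameters":
        return cls(
            log_gains=np.zeros(spec.n_edges),
            a0=np.zeros(spec.n_sources),
            constants=constants or ErpConstants(),
        )


@dataclass
class CsdPrediction:
    """Predicted cross-spectral density over observation modes.

    ``total = neuronal + noise`` at every frequency; each per-frequency
    matrix is Hermitian with non-negative real diagonal.
    """

    freqs: np.ndarray
    neuronal: np.ndarray  # (F, m, m) complex
    noise: np.ndarray  # (F, m, m) complex

    @property
    def total(self) -> np.ndarray:
        return self.neuronal + self.noise

    @property
    def n_modes(self) -> int:
        return self.neuronal.shape[1]


def default_frequencies() -> np.ndarray:
    """1-45 Hz in 1 Hz steps, the modelled band of band-passed EEG."""
    return np.arange(1.0, 46.0, 1.0)


def default_priors(spec: NetworkSpec, constants: ErpConstants | None = None) -> GaussianBelief:
    """Shrinkage priors over the free parameter vector.

    Extrinsic log-gains: mean 0 (baseline coupling unscaled), variance
    1/16.  Spectral and observation-noise log-amplitudes: weakly
    informative, variance 1/8, with the noise floor centred below the
    neuronal spectrum.
    """
    mean = ErpParameters.prior_mean(spec, constants).to_vector()
    var = np.empty(spec.n_params)
    var[: spec.n_edges] = 1.0 / 16.0
    var[spec.n_edges :] = 1.0 / 8.0
    return GaussianBelief(mean, np.diag(var), label="erp-prior")


def _edge_targets(edge_type: str) -> tuple[int, ...]:
    """Second-order kernels an extrinsic connection drives in the target source."""
    if edge_type == "forward":
        return (_VS,)
    if edge_type == "backward":
        return (_VPE, _VI)
    return (_VS, _VPE, _VI)  # lateral


def jacobian(params: ErpParameters, spec: NetworkSpec, with_delays: bool = True) -> np.ndarray:
    """Delay-corrected Jacobian of the linearized network (n x n, n = 8 * sources)."""
    c = params.constants
    ns = spec.n_sources
    n = N_STATES * ns
    J = np.zeros((n, n))
    D = np.zeros((n, n))
    s = c.slope
    g1, g2, g3, g4 = c.gamma

    def kernel(block: int, src: int, kappa: float) -> None:
        i = N_STATES * src + block
        J[i, i + 1] = 1.0
        J[i + 1, i] = -kappa * kappa
        J[i + 1, i + 1] = -2.0 * kappa

    for src in range(ns):
        off = N_STATES * src
        for blk, kap in ((_VS, c.kappa_e), (_VPE, c.kappa_e), (_VPI, c.kappa_i), (_VI, c.kappa_e)):
            kernel(blk, src, kap)
        ke_He = c.kappa_e * c.H_e
        ki_Hi = c.kappa_i * c.H_i

        def couple(to_blk: int, from_blk: int, gain: float, drive: float, delay: float) -> None:
            # presynaptic firing ~ slope * v; pyramidal potential is v_pe - v_pi
            J[off + to_blk + 1, off + from_blk] += gain * drive * s
            D[off + to_blk + 1, off + from_blk] = delay

        # intrinsic loops (pyramidal potential enters as v_pe - v_pi)
        for vp_blk, sign in ((_VPE, 1.0), (_VPI, -1.0)):
            couple(_VS, vp_blk, sign * g1, ke_He, c.delay_intrinsic)
            couple(_VI, vp_blk, sign * g3, ke_He, c.delay_intrinsic)
        couple(_VPE, _VS, g2, ke_He, c.delay_intrinsic)
        couple(_VPI, _VI, g4, ki_Hi, c.delay_intrinsic)

    for e, g in zip(spec.edges, params.log_gains):
        isrc, itgt = spec.node_index(e.source), spec.node_index(e.target)
        strength = c.baseline(e.type) * np.exp(g)
        osrc, otgt = N_STATES * isrc, N_STATES * itgt
        for blk in _edge_targets(e.type):
            kap_H = c.kappa_i * c.H_i if blk == _VPI else c.kappa_e * c.H_e
            for vp_blk, sign in ((_VPE, 1.0), (_VPI, -1.0)):
                J[otgt + blk + 1, osrc + vp_blk] += sign * strength * kap_H * s
                D[otgt + blk + 1, osrc + vp_blk] = c.delay_extrinsic

    if with_delays:
        # first-order Taylor: x(t - d) ~ x(t) - d x'(t)  =>  (I + J.D) x' = J x
        J = np.linalg.solve(np.eye(n) + J * D, J)
    return J


def _check_stable(J: np.ndarray) -> None:
    lam = np.linalg.eigvals(J)
    mx = float(lam.real.max())
    if mx >= 0.0:
        raise StabilityError(f"unstable linearized system: max Re(eig) = {mx:.4g} >= 0")


def _io_projections(params: ErpParameters, spec: NetworkSpec) -> tuple[np.ndarray, np.ndarray]:
    ns = spec.n_sources
    n = N_STATES * ns
    c = params.constants
    B = np.zeros((n, ns))  # innovations drive the stellate kernel
    C = np.zeros((ns, n))  # observed: pyramidal depolarization v_pe - v_pi
    for src in range(ns):
        off = N_STATES * src
        B[off + _DVS, src] = c.kappa_e * c.H_e * c.drive
        C[src, off + _VPE] = 1.0
        C[src, off + _VPI] = -1.0
    return B, C


def transfer_matrices(params: ErpParameters, spec: NetworkSpec, freqs: np.ndarray) -> np.ndarray:
    """Frequency response innovations -> pyramidal depolarization.

    Returns a (F, sources, sources) complex array
    ``T(f) = C (i 2 pi f I - J)^-1 B``.  Raises :class:`StabilityError`
    if the delay-corrected Jacobian has a non-negative eigenvalue.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    J = jacobian(params, spec)
    _check_stable(J)
    Bp, Cp = _io_projections(params, spec)
    n = J.shape[0]
    iw = 2j * np.pi * freqs
    A = iw[:, None, None] * np.eye(n)[None] - J[None]
    X = np.linalg.solve(A, np.broadcast_to(Bp, (freqs.size, *Bp.shape)))
    return Cp @ X


def transfer_matrix(params: ErpParameters, spec: NetworkSpec, f: float) -> np.ndarray:
    """Single-frequency transfer matrix (sources x sources)."""
    return transfer_matrices(params, spec, np.array([f]))[0]


def innovation_spectrum(params: ErpParameters, freqs: np.ndarray) -> np.ndarray:
    """Per-source innovation power G_u(f) = exp(a0) * (1 + exp(a1)/f); (F, sources)."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    return np.exp(params.a0)[None, :] * (1.0 + np.exp(params.a1) / freqs[:, None])


def noise_spectrum(params: ErpParameters, n_modes: int, freqs: np.ndarray) -> np.ndarray:
    """Channel-noise CSD G_n(f) = (exp(b0) + exp(b1)/f) I; (F, m, m)."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    amp = np.exp(params.b0) + np.exp(params.b1) / freqs
    return amp[:, None, None] * np.eye(n_modes)[None].astype(complex)


class CsdModel:
    """Preassembled forward model for fast repeated evaluation.

    Caches the intrinsic Jacobian structure of a fixed network, so that
    during inversion only the extrinsic log-gain entries are refreshed;
    perturbed parameter sets are evaluated in one batched resolvent
    solve, and spectral/noise parameters (which leave the dynamics
    untouched) reuse the base transfer function.  Numerically identical
    to :func:`predict_csd`.
    """

    def __init__(
        self,
        spec: NetworkSpec,
        gain: np.ndarray,
        freqs: np.ndarray | None = None,
        constants: ErpConstants | None = None,
    ) -> None:
        self.spec = spec
        self.constants = constants or ErpConstants()
        self.gain = np.atleast_2d(np.asarray(gain, dtype=float))
        if self.gain.shape[1] != spec.n_sources:
            raise ValueError(f"gain has {self.gain.shape[1]} columns, expected {spec.n_sources} sources")
        self.freqs = np.atleast_1d(np.asarray(default_frequencies() if freqs is None else freqs, dtype=float))
        zero = ErpParameters(np.full(spec.n_edges, -np.inf), np.zeros(spec.n_sources), constants=self.constants)
        self._J0 = jacobian(zero, spec, with_delays=False)  # intrinsic part only
        self._D = self._delay_matrix()
        self._Bp, self._Cp = _io_projections(zero, spec)
        c = self.constants
        self._edge_baselines = np.array([c.baseline(e.type) for e in spec.edges])
        # per-edge list of (row, col, signed kappa*H*slope) Jacobian increments
        self._edge_entries: list[list[tuple[int, int, float]]] = []
        for e in spec.edges:
            isrc, itgt = spec.node_index(e.source), spec.node_index(e.target)
            osrc, otgt = N_STATES * isrc, N_STATES * itgt
            entries = []
            for blk in _edge_targets(e.type):
                kap_H = c.kappa_i * c.H_i if blk == _VPI else c.kappa_e * c.H_e
                for vp_blk, sign in ((_VPE, 1.0), (_VPI, -1.0)):
                    entries.append((otgt + blk + 1, osrc + vp_blk, sign * kap_H * c.slope))
            self._edge_entries.append(entries)

    def _delay_matrix(self) -> np.ndarray:
        full = jacobian(
            ErpParameters(np.zeros(self.spec.n_edges), np.zeros(self.spec.n_sources), constants=self.constants),
            self.spec,
            with_delays=False,
        )
        c = self.constants
        ns = self.spec.n_sources
        D = np.zeros_like(full)
        kernel = np.zeros_like(full, dtype=bool)
        for src in range(ns):
            off = N_STATES * src
            for blk in (_VS, _VPE, _VPI, _VI):
                kernel[off + blk, off + blk + 1] = True
                kernel[off + blk + 1, off + blk] = True
                kernel[off + blk + 1, off + blk + 1] = True
        coupling = (full != 0) & ~kernel
        for i in range(D.shape[0]):
            for j in range(D.shape[1]):
                if coupling[i, j]:
                    D[i, j] = c.delay_intrinsic if i // N_STATES == j // N_STATES else c.delay_extrinsic
        return D

    @property
    def n_features(self) -> int:
        # non-redundant Hermitian stacking: m^2 real numbers per frequency
        return self.freqs.size * self.gain.shape[0] ** 2

    def _assemble(self, log_gains: np.ndarray) -> np.ndarray:
        J = self._J0.copy()
        strengths = self._edge_baselines * np.exp(log_gains)
        for s, entries in zip(strengths, self._edge_entries):
            for r, cidx, coeff in entries:
                J[r, cidx] += s * coeff
        return J

    def transfer_batch(self, log_gain_stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Batched transfer functions; returns (T (K,F,ns,ns), stable (K,))."""
        K = log_gain_stack.shape[0]
        n = self._J0.shape[0]
        Js = np.empty((K, n, n))
        for k in range(K):
            Js[k] = self._assemble(log_gain_stack[k])
        eye = np.eye(n)
        Js = np.linalg.solve(eye[None] + Js * self._D[None], Js)  # delay correction
        stable = np.linalg.eigvals(Js).real.max(axis=1) < 0.0
        iw = 2j * np.pi * self.freqs
        A = iw[None, :, None, None] * eye[None, None] - Js[:, None]
        X = np.linalg.solve(A, np.broadcast_to(self._Bp, (K, self.freqs.size, *self._Bp.shape)))
        return self._Cp @ X, stable

    def _spectra(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = ErpParameters.from_vector(theta, self.spec, self.constants)
        return innovation_spectrum(p, self.freqs), noise_spectrum(p, self.gain.shape[0], self.freqs)

    def _features_from_T(self, T: np.ndarray, theta: np.ndarray) -> np.ndarray:
        from .features import hermitian_features

        Gu, Gn = self._spectra(theta)
        M = self.gain[None] @ T
        S = (M * Gu[:, None, :]) @ M.conj().transpose(0, 2, 1) + Gn
        S = 0.5 * (S + S.conj().transpose(0, 2, 1))
        return hermitian_features(S)

    def features(self, theta: np.ndarray) -> np.ndarray:
        """Non-redundant Hermitian CSD feature vector; NaN if unstable."""
        theta = np.asarray(theta, dtype=float)
        ne = self.spec.n_edges
        T, stable = self.transfer_batch(theta[None, :ne])
        if not stable[0]:
            return np.full(self.n_features, np.nan)
        return self._features_from_T(T[0], theta)

    def jacobian(self, theta: np.ndarray, f0: np.ndarray | None = None, step: float = 1e-4) -> np.ndarray:
        """Central-difference feature Jacobian, batching the dynamics solves.

        Log-gain columns need fresh transfer functions (batched in one
        call); spectral and noise columns reuse the base transfer
        function since they do not enter the dynamics.
        """
        theta = np.asarray(theta, dtype=float)
        ne, B = self.spec.n_edges, theta.size
        stack = [theta[:ne]]
        for j in range(ne):
            for sgn in (1.0, -1.0):
                g = theta[:ne].copy()
                g[j] += sgn * step
                stack.append(g)
        T, stable = self.transfer_batch(np.array(stack))
        if not stable[0]:
            raise StabilityError("unstable at the expansion point")
        if f0 is None:
            f0 = self._features_from_T(T[0], theta)
        cols = []
        for j in range(ne):
            ip, im = 1 + 2 * j, 2 + 2 * j
            if stable[ip] and stable[im]:
                fp = self._features_from_T(T[ip], theta)
                fm = self._features_from_T(T[im], theta)
                cols.append((fp - fm) / (2 * step))
            elif stable[ip]:
                cols.append((self._features_from_T(T[ip], theta) - f0) / step)
            elif stable[im]:
                cols.append((f0 - self._features_from_T(T[im], theta)) / step)
            else:
                cols.append(np.zeros_like(f0))
        for j in range(ne, B):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += step
            tm[j] -= step
            fp = self._features_from_T(T[0], tp)
            fm = self._features_from_T(T[0], tm)
            cols.append((fp - fm) / (2 * step))
        return np.column_stack(cols)


def predict_csd(
    params: ErpParameters,
    spec: NetworkSpec,
    gain: np.ndarray,
    freqs: np.ndarray | None = None,
) -> CsdPrediction:
    """Predicted channel-level CSD for one parameter setting.

    Parameters
    ----------
    gain : (modes, sources) array
        Linear observation (lead-field) matrix.
    freqs : array, optional
        Frequency grid in Hz; defaults to 1-45 Hz.
    """
    if freqs is None:
        freqs = default_frequencies()
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    gain = np.atleast_2d(np.asarray(gain, dtype=float))
    if gain.shape[1] != spec.n_sources:
        raise ValueError(f"gain has {gain.shape[1]} columns, expected {spec.n_sources} sources")
    if freqs.min() <= 0:
        raise ValueError("frequencies must be positive")

    T = transfer_matrices(params, spec, freqs)  # (F, ns, ns)
    Gu = innovation_spectrum(params, freqs)  # (F, ns)
    M = gain[None] @ T  # (F, m, ns)
    neuronal = (M * Gu[:, None, :]) @ M.conj().transpose(0, 2, 1)
    neuronal = 0.5 * (neuronal + neuronal.conj().transpose(0, 2, 1))
    noise = noise_spectrum(params, gain.shape[0], freqs)
    return CsdPrediction(freqs=freqs, neuronal=neuronal, noise=noise)
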