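"""From multichannel time series to per-window cross-spectral features.

The analysis never fits raw time series: each recording is cut into
consecutive non-overlapping windows, reduced to a small number of
spatial modes, and summarised per window by a parametric (multivariate
autoregressive) estimate of the complex cross-spectral density on a
fixed frequency grid.  Those per-window CSD matrices are the data the
generative model is fitted to.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .nmm import CsdPrediction

__all__ = [
    "CrossSpectralData",
    "segment_windows",
    "project_modes",
    "mar_csd",
    "explained_variance",
    "stack_features",
    "hermitian_features",
    "hermitian_from_features",
    "read_edf",
    "save_csd_bundle",
    "load_csd_bundle",
]


@dataclass
class CrossSpectralData:
    """Observed complex CSD matrices for one window.

    ``csd`` has shape (F, m, m), Hermitian at each frequency.  The noise
    model for the stacked real feature vector is a single log-precision
    times identity; ``log_precision`` records an estimate when one is
    available (it is refined during inversion).
    """

    freqs: np.ndarray
    csd: np.ndarray
    fs: float
    window: int = 0
    log_precision: float | None = None

    def __post_init__(self) -> None:
        self.freqs = np.atleast_1d(np.asarray(self.freqs, dtype=float))
        self.csd = np.asarray(self.csd, dtype=complex)
        if self.csd.ndim != 3 or self.csd.shape[0] != self.freqs.size:
            raise ValueError("csd must be (F, m, m) matching the frequency grid")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.freqs[0] <= 0 or (self.fs > 0 and self.freqs[-1] >= self.fs / 2):
            raise ValueError("frequencies must lie in (0, Nyquist)")
        if not np.allclose(self.csd, self.csd.conj().transpose(0, 2, 1), atol=1e-8):
            raise ValueError("per-frequency CSD matrices must be Hermitian")

    @property
    def n_modes(self) -> int:
        return self.csd.shape[1]

    def features(self) -> np.ndarray:
        """Stacked real then imaginary parts of all entries and frequencies."""
        return stack_features(self.csd)

    def likelihood_features(self) -> np.ndarray:
        """Non-redundant Hermitian stacking used as the inversion data vector."""
        return hermitian_features(self.csd)


def stack_features(csd: np.ndarray) -> np.ndarray:
    csd = np.asarray(csd)
    return np.concatenate([csd.real.ravel(), csd.imag.ravel()])


def unstack_features(vec: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    n = int(np.prod(shape))
    return vec[:n].reshape(shape) + 1j * vec[n:].reshape(shape)


def hermitian_features(csd: np.ndarray) -> np.ndarray:
    """Non-redundant real feature vector of a stack of Hermitian matrices.

    Per frequency: real upper triangle including the diagonal, then the
    imaginary strictly-upper triangle.  Unlike stacking every entry,
    this counts each independent degree of freedom exactly once, which
    is what an iid feature-noise model requires.
    """
    csd = np.asarray(csd)
    m = csd.shape[-1]
    iu, ju = np.triu_indices(m)
    ius, jus = np.triu_indices(m, k=1)
    out = [csd[..., iu, ju].real.reshape(csd.shape[0], -1)]
    if ius.size:
        out.append(csd[..., ius, jus].imag.reshape(csd.shape[0], -1))
    return np.concatenate(out, axis=1).ravel()


def hermitian_from_features(vec: np.ndarray, n_freqs: int, m: int) -> np.ndarray:
    """Inverse of :func:`hermitian_features`."""
    iu, ju = np.triu_indices(m)
    ius, jus = np.triu_indices(m, k=1)
    per = iu.size + ius.size
    blocks = np.asarray(vec, dtype=float).reshape(n_freqs, per)
    S = np.zeros((n_freqs, m, m), dtype=complex)
    S[:, iu, ju] = blocks[:, : iu.size]
    S[:, ju, iu] = blocks[:, : iu.size]
    if ius.size:
        S[:, ius, jus] += 1j * blocks[:, iu.size :]
        S[:, jus, ius] -= 1j * blocks[:, iu.size :]
    return S


def n_hermitian_features(n_freqs: int, m: int) -> int:
    return n_freqs * m * m  # m(m+1)/2 real + m(m-1)/2 imaginary per frequency


def segment_windows(series: np.ndarray, fs: float, win_s: float = 1.0) -> list[np.ndarray]:
    """Cut a (channels, samples) array into consecutive non-overlapping windows.

    Windows have exactly ``round(fs * win_s)`` samples; a trailing
    remainder shorter than one window is dropped; order is preserved.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.size == 0:
        raise ValueError("empty series")
    nw = int(round(fs * win_s))
    if nw < 2:
        raise ValueError("window must contain at least 2 samples")
    if series.shape[1] < nw:
        raise ValueError(f"window of {nw} samples longer than recording ({series.shape[1]} samples)")
    n_win = series.shape[1] // nw
    return [series[:, i * nw : (i + 1) * nw] for i in range(n_win)]


def project_modes(series: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Project channels onto the top-m principal spatial components.

    Returns ``(projected, P)`` with ``projected = P @ series`` and ``P``
    an (m, channels) matrix with orthonormal rows (leading eigenvectors
    of the channel covariance).
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    n_chan = series.shape[0]
    if not 1 <= m <= n_chan:
        raise ValueError(f"mode count {m} out of range [1, {n_chan}]")
    x = series - series.mean(axis=1, keepdims=True)
    cov = (x @ x.T) / x.shape[1]
    w, v = np.linalg.eigh(cov)
    P = v[:, ::-1][:, :m].T
    return P @ series, P


def mar_csd(
    window: np.ndarray,
    order: int = 8,
    freqs: np.ndarray | None = None,
    fs: float = 1.0,
    window_index: int = 0,
) -> CrossSpectralData:
    """Cross-spectral density of one window via a multivariate AR model.

    Coefficients are estimated by least squares on the lagged regression
    x[t] = sum_k A_k x[t-k] + e[t]; the spectral matrix is

        S(f) = A(f)^-1  Sigma_e  A(f)^-H,
        A(f) = I - sum_k A_k exp(-i 2 pi f k / fs)

    A ridge of 1e-6 * trace is added only if the normal equations are
    singular.
    """
    x = np.atleast_2d(np.asarray(window, dtype=float))
    m, n = x.shape
    if n <= order * m:
        raise ValueError(f"{n} samples cannot identify MAR({order}) in {m} modes")
    if freqs is None:
        freqs = np.arange(1.0, fs / 2.0, 1.0)
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))

    # design: rows = time points, cols = stacked lags
    Y = x[:, order:].T  # (n - order, m)
    Z = np.hstack([x[:, order - k : n - k].T for k in range(1, order + 1)])  # (n - order, m * order)
    G = Z.T @ Z
    try:
        coef = np.linalg.solve(G, Z.T @ Y)
    except np.linalg.LinAlgError:
        ridge = 1e-6 * np.trace(G) / G.shape[0]
        G = G + ridge * np.eye(G.shape[0])
        coef = np.linalg.solve(G, Z.T @ Y)
    if not np.all(np.isfinite(coef)):
        raise np.linalg.LinAlgError("singular MAR fit")
    resid = Y - Z @ coef
    sigma = resid.T @ resid / resid.shape[0]
    A_k = coef.T.reshape(m, order, m).transpose(1, 0, 2)  # (order, m, m)

    phase = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, order + 1)) / fs)  # (F, order)
    A_f = np.eye(m)[None] - np.einsum("fk,kij->fij", phase, A_k)
    Ainv = np.linalg.inv(A_f)
    S = Ainv @ sigma @ Ainv.conj().transpose(0, 2, 1)
    S = 0.5 * (S + S.conj().transpose(0, 2, 1))
    return CrossSpectralData(freqs=freqs, csd=S, fs=fs, window=window_index)


def explained_variance(observed: CrossSpectralData, predicted: CsdPrediction) -> float:
    """Percent variance of the observed CSD explained by a prediction.

    Computed as 100 * (1 - SS_res / SS_tot) over the stacked real and
    imaginary parts of every matrix entry at every frequency; SS_tot is
    taken about zero so an all-zero prediction scores 0%.
    """
    if observed.freqs.shape != predicted.freqs.shape or not np.allclose(observed.freqs, predicted.freqs):
        raise ValueError("frequency grids of observed and predicted CSD do not match")
    if observed.csd.shape != predicted.total.shape:
        raise ValueError("mode dimensions of observed and predicted CSD do not match")
    y = observed.features()
    yhat = stack_features(predicted.total)
    ss_tot = float(y @ y)
    if ss_tot == 0.0:
        return 100.0
    ss_res = float((y - yhat) @ (y - yhat))
    return 100.0 * (1.0 - ss_res / ss_tot)


def read_edf(path: str) -> tuple[np.ndarray, float]:
    """Thin EDF+ adapter: returns (channels x samples, sampling rate).

    Requires the optional ``mne`` dependency; EEG recordings such as the
    64-channel, 160 Hz motor-imagery resting runs load directly.
    """
    try:
        import mne
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF files requires the optional 'mne' dependency") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data(), float(raw.info["sfreq"])


# -- portable container ----------------------------------------------------


def save_csd_bundle(path: str, windows: list[CrossSpectralData], attrs: dict | None = None) -> None:
    """Serialize a list of window CSDs (one subject) to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["n_windows"] = len(windows)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v
        for w in windows:
            g = f.create_group(f"window_{w.window:04d}")
            g.create_dataset("freqs", data=w.freqs)
            g.create_dataset("csd", data=w.csd)
            g.attrs["fs"] = w.fs
            g.attrs["window"] = w.window
            if w.log_precision is not None:
                g.attrs["log_precision"] = w.log_precision


def load_csd_bundle(path: str) -> tuple[list[CrossSpectralData], dict]:
    with h5py.File(path, "r") as f:
        attrs = dict(f.attrs)
        out = []
        for name in sorted(k for k in f.keys() if k.startswith("window_")):
            g = f[name]
            out.append(
                CrossSpectralData(
                    freqs=g["freqs"][()],
                    csd=g["csd"][()],
                    fs=float(g.attrs["fs"]),
                    window=int(g.attrs["window"]),
                    log_precision=float(g.attrs["log_precision"]) if "log_precision" in g.attrs else None,
                )
            )
    return out, attrs
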