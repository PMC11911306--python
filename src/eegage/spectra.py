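"""Power-spectrum estimation and transforms.

Two estimation back-ends are provided, matching the two arms of the
analysis:

* an autoregressive (AR) estimate using the covariance method (non-windowed
  least squares) of model order 256, evaluated on a fixed 0.1-45 Hz grid at
  0.1 Hz resolution -- used by the N-/D-/M-PAF estimators;
* Welch's method with a 4096 ms Hamming window and 50% overlap -- used by
  the Corcoran and Klimesch estimators after normalisation and
  Savitzky-Golay smoothing.

Power is converted to the log2-amplitude scale, 0.5*log2(power), before any
peak analysis, and multichannel spectra are summarised by the first
component of an SVD of the channel-by-frequency matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal


@dataclass(frozen=True)
class FrequencyGrid:
    """Fixed evaluation grid, default 0.1 to 45 Hz in 0.1 Hz steps (450 points)."""

    start: float = 0.1
    stop: float = 45.0
    step: float = 0.1

    def __post_init__(self) -> None:
        if self.start <= 0 or self.stop <= self.start or self.step <= 0:
            raise ValueError("frequency grid requires 0 < start < stop and step > 0")

    @property
    def count(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def values(self) -> np.ndarray:
        n0 = int(round(self.start / self.step))
        return np.arange(n0, n0 + self.count) * self.step


@dataclass
class Spectrum:
    """Spectral values on a grid; ``source`` records the estimation path."""

    freqs: np.ndarray
    values: np.ndarray  # per channel: (n_channels, n_freqs) or 1-D
    source: str  # "ar" | "welch" | "welch_smoothed"
    units: str = "log2-amplitude"
    labels: list[str] = field(default_factory=list)


@dataclass
class SvdSummary:
    """Leading singular triplet of a channel-by-frequency matrix."""

    component_spectrum: np.ndarray  # sigma_1 * v_1, per frequency
    channel_weights: np.ndarray  # u_1, unit norm
    variance_fraction: float  # sigma_1^2 / sum sigma_j^2


def _covariance_normal_equations(x: np.ndarray, order: int):
    """Exact covariance-method normal equations via O(N p + p^2) recursions.

    Returns (C, d, e0) with C[j-1,k-1] = sum_{n=p}^{N-1} x[n-j] x[n-k],
    d[j-1] = sum_{n=p}^{N-1} x[n] x[n-j] and e0 = sum_{n=p}^{N-1} x[n]^2.
    """
    p, n = order, x.size
    d = np.empty(p)
    col1 = np.empty(p)  # C[j, 1]
    w1 = x[p - 1 : n - 1]
    w0 = x[p:n]
    for j in range(1, p + 1):
        seg = x[p - j : n - j]
        d[j - 1] = seg @ w0
        col1[j - 1] = seg @ w1
    c_mat = np.empty((p, p))
    # fill lower-triangle diagonals with the shift recursion
    # C[j+1, k+1] = C[j, k] + x[p-1-j] x[p-1-k] - x[N-1-j] x[N-1-k]
    for lag in range(p):
        steps = p - lag - 1
        start = col1[lag]
        if steps > 0:
            t = np.arange(steps)
            inc = x[p - 2 - lag - t] * x[p - 2 - t] - x[n - 2 - lag - t] * x[n - 2 - t]
            diag = np.concatenate(([start], start + np.cumsum(inc)))
        else:
            diag = np.array([start])
        idx = np.arange(p - lag)
        c_mat[lag + idx, idx] = diag
        c_mat[idx, lag + idx] = diag
    e0 = w0 @ w0
    return c_mat, d, e0


def ar_coefficients_covariance(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """AR(p) fit by the covariance (non-windowed least squares) method.

    Minimises sum_{n=p}^{N-1} (x[n] + sum_k a_k x[n-k])^2 and returns the
    coefficient vector ``a`` (length p) and the driving-noise variance
    estimate SSE/(N-p).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size <= 2 * order:
        raise ValueError(f"signal length {x.size} must exceed 2*order = {2 * order}")
    c_mat, d, e0 = _covariance_normal_equations(x, order)
    try:
        a = np.linalg.solve(c_mat, -d)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological input
        cond = np.linalg.cond(c_mat)
        raise np.linalg.LinAlgError(
            f"covariance normal equations singular (condition number {cond:.3g})"
        ) from exc
    sse = e0 + d @ a
    var = max(sse, 0.0) / (x.size - order)
    return a, var


def ar_psd_covariance(
    x: np.ndarray,
    order: int = 256,
    fs: float = 500.0,
    grid: FrequencyGrid | None = None,
) -> Spectrum:
    """One-sided AR power spectral density on the fixed frequency grid."""
    grid = grid or FrequencyGrid()
    a, var = ar_coefficients_covariance(x, order)
    freqs = grid.values
    # A(f) = 1 + sum_k a_k exp(-i 2 pi f k / fs)
    phases = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, order + 1)) / fs)
    denom = np.abs(1.0 + phases @ a) ** 2
    psd = 2.0 * var / (fs * denom)
    return Spectrum(freqs=freqs, values=psd, source="ar", units="power-density")


def power_to_log2amplitude(psd: np.ndarray) -> np.ndarray:
    """log2 of the amplitude spectrum: 0.5 * log2(power)."""
    psd = np.asarray(psd, dtype=float)
    if np.any(psd <= 0):
        raise ValueError("power values must be strictly positive")
    return 0.5 * np.log2(psd)


def welch_psd(
    x: np.ndarray,
    fs: float = 500.0,
    window_ms: float = 4096.0,
    overlap: float = 0.5,
) -> Spectrum:
    """Welch PSD with a Hamming-tapered window (default 4096 ms, 50% overlap)."""
    x = np.asarray(x, dtype=float).ravel()
    nperseg = int(round(window_ms / 1000.0 * fs))
    if x.size < nperseg:
        raise ValueError(f"signal length {x.size} shorter than the {nperseg}-sample window")
    freqs, psd = sp_signal.welch(
        x,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        detrend=False,
        scaling="density",
    )
    return Spectrum(freqs=freqs, values=psd, source="welch", units="power-density")


def normalize_and_smooth(
    psd: np.ndarray,
    freqs: np.ndarray,
    band: tuple[float, float] = (0.1, 45.0),
    window_bins: int = 11,
    order: int = 5,
) -> np.ndarray:
    """Normalise a PSD by its mean over the analysis band, then SG-smooth.

    This is the pre-processing applied before the Corcoran and Klimesch
    alpha-peak estimators: division by mean power over 0.1-45 Hz followed by
    a 5th-order, 11-bin Savitzky-Golay filter.
    """
    psd = np.asarray(psd, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if psd.size < window_bins:
        raise ValueError(f"need at least {window_bins} frequency bins")
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    mean_power = psd[in_band].mean()
    if mean_power <= 0:
        raise ValueError("mean power over the analysis band must be positive")
    return sp_signal.savgol_filter(psd / mean_power, window_bins, order)


def svd_first_component(spectra: np.ndarray) -> SvdSummary:
    """First singular triplet of the channel-by-frequency matrix.

    The summary spectrum is sigma_1 * v_1 (a variance-weighted consensus
    across channels), with the sign fixed so that the mean channel loading
    is positive.
    """
    x = np.asarray(spectra, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two channels")
    if not np.all(np.isfinite(x)):
        raise ValueError("spectra must be finite")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if s[0] <= 0:
        raise ValueError("rank-0 input: all-zero spectra")
    u1, v1 = u[:, 0], vt[0]
    if u1.mean() < 0:
        u1, v1 = -u1, -v1
    return SvdSummary(
        component_spectrum=s[0] * v1,
        channel_weights=u1,
        variance_fraction=float(s[0] ** 2 / np.sum(s**2)),
    )
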