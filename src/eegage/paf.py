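"""Five peak-alpha-frequency (PAF) estimators.

* N-PAF: per channel, the highest-amplitude local maximum of the AR
  log2-amplitude spectrum in 7-13 Hz; the summary is the unweighted channel
  mean.
* D-PAF: the same peak rule applied once, to the first SVD component of the
  channel-by-frequency matrix.
* M-PAF: the alpha-band Gaussian centre of the parametric spectral model
  (aperiodic + five Gaussians) fitted to the SVD component by
  bound-constrained non-linear least squares with multi-start.
* C-PAF: per-channel peaks of the smoothed Welch spectrum, admitting only
  channels whose alpha peak rises one residual SD above a log-log
  regression of the background, combined by SNR weights.
* K-PAF: per-channel centre of gravity over an individually defined alpha
  band (bounded by the nearest enclosing local minima), averaged with equal
  channel weight.

Estimators return an explicit missing state rather than fabricating a value
when no admissible peak exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import model as sm
from .spectra import SvdSummary

ALPHA_BAND = (7.0, 13.0)


@dataclass
class PafEstimate:
    method: str  # one of N, D, M, C, K
    value: float | None
    per_channel: dict[str, float | None] = field(default_factory=dict)
    per_channel_amplitude: dict[str, float] = field(default_factory=dict)
    channel_weights: dict[str, float] = field(default_factory=dict)
    n_channels_used: int = 0

    @property
    def missing(self) -> bool:
        return self.value is None


def find_alpha_peaks(
    values: np.ndarray, freqs: np.ndarray, band: tuple[float, float] = ALPHA_BAND
) -> list[tuple[float, float]]:
    """Local maxima (strict neighbour comparison) strictly inside ``band``.

    A grid point is a peak when its value exceeds both neighbours; band
    endpoints are never peaks.  Returns (frequency, amplitude) pairs in
    ascending frequency.
    """
    values = np.asarray(values, dtype=float).ravel()
    freqs = np.asarray(freqs, dtype=float).ravel()
    idx = np.arange(1, freqs.size - 1)
    f = freqs[idx]
    in_band = (
        (f > band[0] - 1e-9) & (f < band[1] + 1e-9)
        & ~np.isclose(f, band[0]) & ~np.isclose(f, band[1])
    )
    is_peak = (values[idx] > values[idx - 1]) & (values[idx] > values[idx + 1])
    keep = idx[in_band & is_peak]
    return [(float(freqs[i]), float(values[i])) for i in keep]


def _highest_peak(peaks: list[tuple[float, float]]) -> tuple[float, float] | None:
    """Highest-amplitude peak; equal amplitudes break toward the lower frequency."""
    if not peaks:
        return None
    amps = np.array([a for _, a in peaks])
    return peaks[int(np.argmax(amps))]  # peaks are frequency-ascending; argmax takes first


def naive_paf(
    spectra: np.ndarray,
    freqs: np.ndarray,
    labels: list[str] | None = None,
    band: tuple[float, float] = ALPHA_BAND,
) -> PafEstimate:
    """N-PAF: channel-wise highest alpha peak, averaged over channels with one."""
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    labels = labels or [f"ch{i}" for i in range(spectra.shape[0])]
    per_channel: dict[str, float | None] = {}
    per_amp: dict[str, float] = {}
    for lab, row in zip(labels, spectra):
        best = _highest_peak(find_alpha_peaks(row, freqs, band))
        per_channel[lab] = None if best is None else best[0]
        if best is not None:
            per_amp[lab] = best[1]
    found = [v for v in per_channel.values() if v is not None]
    return PafEstimate(
        method="N",
        value=float(np.mean(found)) if found else None,
        per_channel=per_channel,
        per_channel_amplitude=per_amp,
        n_channels_used=len(found),
    )


def direct_paf(
    svd: SvdSummary, freqs: np.ndarray, band: tuple[float, float] = ALPHA_BAND
) -> PafEstimate:
    """D-PAF: highest alpha peak of the first SVD component spectrum."""
    best = _highest_peak(find_alpha_peaks(svd.component_spectrum, freqs, band))
    return PafEstimate(
        method="D",
        value=None if best is None else best[0],
        n_channels_used=svd.channel_weights.size,
    )


# ---------------------------------------------------------------------------
# Parametric spectral model fit (M-PAF)
# ---------------------------------------------------------------------------

_N_PARAMS = 3 + 3 * len(sm.BAND_NAMES)


def _fit_bounds() -> tuple[np.ndarray, np.ndarray]:
    lo = [0.0, -10.0, -100.0]
    hi = [1000.0, -1e-9, 100.0]
    for (mlo, mhi), smax in zip(sm.MU_BOUNDS, sm.SIGMA_MAX):
        lo.extend([sm.AMP_BOUNDS[0], mlo, sm.SIGMA_MIN])
        hi.extend([sm.AMP_BOUNDS[1], mhi, smax])
    return np.asarray(lo), np.asarray(hi)


def _heuristic_start(values: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Aperiodic-only fit, then band amplitudes from the residual maxima."""

    def resid(theta):
        return sm.aperiodic(freqs, *theta) - values

    ap = least_squares(resid, x0=[1.0, -0.5, float(values[-10:].mean())],
                       bounds=([0.0, -10.0, -100.0], [1000.0, -1e-9, 100.0]))
    residual = values - sm.aperiodic(freqs, *ap.x)
    x0 = list(ap.x)
    for (mlo, mhi), smax in zip(sm.MU_BOUNDS, sm.SIGMA_MAX):
        sel = (freqs > mlo) & (freqs < mhi)
        if sel.any():
            j = np.argmax(residual[sel])
            amp = float(np.clip(residual[sel][j], 0.05, sm.AMP_BOUNDS[1]))
            mu = float(freqs[sel][j])
        else:  # band outside the grid (gamma extends past 45 Hz)
            amp, mu = 0.05, 0.5 * (mlo + min(mhi, freqs[-1]))
        mu = float(np.clip(mu, mlo + 0.05, mhi - 0.05))
        x0.extend([amp, mu, min(2.0, smax)])
    return np.asarray(x0)


def _random_start(rng: np.random.Generator) -> np.ndarray:
    x0 = [rng.uniform(0.5, 8.0), rng.uniform(-1.5, -0.1), rng.uniform(-5.0, 5.0)]
    for (mlo, mhi), smax in zip(sm.MU_BOUNDS, sm.SIGMA_MAX):
        x0.extend([
            rng.uniform(0.0, 3.0),
            rng.uniform(mlo + 0.1, mhi - 0.1),
            rng.uniform(0.5, min(4.0, smax)),
        ])
    return np.asarray(x0)


def fit_spectral_model(
    values: np.ndarray,
    freqs: np.ndarray | None = None,
    n_starts: int = 10,
    seed: int = 0,
) -> sm.SpectralModelParams:
    """Bound-constrained least-squares fit of the spectral model.

    ``n_starts`` random initialisations plus one heuristic start (band
    amplitudes seeded from the residual over an aperiodic-only fit); the
    lowest-SSE solution wins.  Raises if every start fails.
    """
    from .spectra import FrequencyGrid

    values = np.asarray(values, dtype=float).ravel()
    freqs = FrequencyGrid().values if freqs is None else np.asarray(freqs, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("spectrum must be finite")
    lo, hi = _fit_bounds()
    rng = np.random.default_rng(seed)

    def resid(theta):
        return sm.model_from_vector(theta, freqs) - values

    def jac(theta):
        return sm.model_jacobian(theta, freqs)

    starts = [_heuristic_start(values, freqs)]
    starts += [_random_start(rng) for _ in range(n_starts)]
    best, best_sse, failures = None, np.inf, []
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            sol = least_squares(resid, x0=x0, jac=jac, bounds=(lo, hi),
                                ftol=1e-10, xtol=1e-10, max_nfev=300)
        except Exception as exc:  # pragma: no cover - optimizer pathology
            failures.append(str(exc))
            continue
        sse = float(2.0 * sol.cost)
        if sse < best_sse:
            best, best_sse = sol, sse
    if best is None:
        raise RuntimeError(f"spectral model fit failed on all starts: {failures}")
    n, p = values.size, _N_PARAMS
    tss = float(np.sum((values - values.mean()) ** 2))
    r2 = 1.0 - best_sse / tss if tss > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    return sm.SpectralModelParams.from_vector(best.x, adj_r2=float(adj_r2), sse=best_sse)


def modeled_paf(params: sm.SpectralModelParams) -> PafEstimate:
    """M-PAF: the fitted alpha-band Gaussian centre."""
    return PafEstimate(method="M", value=float(params.alpha.mu))


# ---------------------------------------------------------------------------
# Welch-based estimators (Corcoran and Klimesch)
# ---------------------------------------------------------------------------


def corcoran_paf(
    spectra: np.ndarray,
    freqs: np.ndarray,
    labels: list[str] | None = None,
    min_channels: int = 3,
    alpha_band: tuple[float, float] = ALPHA_BAND,
    background_band: tuple[float, float] = (1.0, 40.0),
) -> PafEstimate:
    """C-PAF: SNR-weighted mean of admissible channel alpha peaks.

    Admissibility: a channel's alpha peak (log power) must exceed the value
    predicted by a log-log linear regression of the non-alpha background by
    at least one residual standard deviation.  Fewer than ``min_channels``
    admissible channels yields an explicit missing estimate.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    freqs = np.asarray(freqs, dtype=float)
    labels = labels or [f"ch{i}" for i in range(spectra.shape[0])]
    bg = (
        (freqs >= background_band[0]) & (freqs <= background_band[1])
        & ~((freqs >= alpha_band[0]) & (freqs <= alpha_band[1]))
    )
    log_f_bg = np.log(freqs[bg])
    design = np.column_stack([np.ones(log_f_bg.size), log_f_bg])
    per_channel: dict[str, float | None] = {}
    snr: dict[str, float] = {}
    for lab, row in zip(labels, spectra):
        log_p = np.log(np.maximum(row, 1e-12))
        best = _highest_peak(find_alpha_peaks(row, freqs, alpha_band))
        if best is None:
            per_channel[lab] = None
            continue
        f_peak, amp = best
        coef, *_ = np.linalg.lstsq(design, log_p[bg], rcond=None)
        resid_sd = float(np.std(log_p[bg] - design @ coef))
        predicted = coef[0] + coef[1] * np.log(f_peak)
        q = float(np.log(max(amp, 1e-12)) - predicted)
        if q > resid_sd:
            per_channel[lab] = f_peak
            snr[lab] = q
        else:
            per_channel[lab] = None
    admitted = [lab for lab, v in per_channel.items() if v is not None]
    if len(admitted) < min_channels:
        return PafEstimate(method="C", value=None, per_channel=per_channel,
                           n_channels_used=len(admitted))
    total = sum(snr[lab] for lab in admitted)
    weights = {lab: snr[lab] / total for lab in admitted}
    value = sum(weights[lab] * per_channel[lab] for lab in admitted)
    return PafEstimate(
        method="C", value=float(value), per_channel=per_channel,
        channel_weights=weights, n_channels_used=len(admitted),
    )


def _nearest_minimum(values: np.ndarray, start: int, stop: int, step: int) -> int:
    """Index of the first strict local minimum walking from start toward stop.

    Falls back to ``stop`` (the search-window edge) if no enclosing minimum
    exists before it.
    """
    i = start + step
    while (step > 0 and i < stop) or (step < 0 and i > stop):
        if values[i] < values[i - 1] and values[i] < values[i + 1]:
            return i
        i += step
    return stop


def klimesch_paf(
    spectra: np.ndarray,
    freqs: np.ndarray,
    labels: list[str] | None = None,
    alpha_band: tuple[float, float] = ALPHA_BAND,
    search_window: tuple[float, float] = (5.0, 15.0),
) -> PafEstimate:
    """K-PAF: centre of gravity over an individually defined alpha band.

    The band around the channel's alpha peak is delimited by the nearest
    enclosing local minima within the search window (window edges when no
    minimum exists); the CoG is amplitude-weighted within channel, and
    channels are averaged with equal weight.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    freqs = np.asarray(freqs, dtype=float)
    labels = labels or [f"ch{i}" for i in range(spectra.shape[0])]
    win = np.flatnonzero((freqs >= search_window[0]) & (freqs <= search_window[1]))
    per_channel: dict[str, float | None] = {}
    for lab, row in zip(labels, spectra):
        best = _highest_peak(find_alpha_peaks(row, freqs, alpha_band))
        if best is None or win.size < 3:
            per_channel[lab] = None
            continue
        ip = int(np.argmin(np.abs(freqs - best[0])))
        lo = _nearest_minimum(row, ip, max(int(win[0]), 1), -1)
        hi = _nearest_minimum(row, ip, min(int(win[-1]), freqs.size - 2), +1)
        weights = np.maximum(row[lo : hi + 1], 0.0)
        if weights.sum() <= 0:
            per_channel[lab] = None
            continue
        per_channel[lab] = float(np.sum(freqs[lo : hi + 1] * weights) / weights.sum())
    found = [v for v in per_channel.values() if v is not None]
    return PafEstimate(
        method="K",
        value=float(np.mean(found)) if found else None,
        per_channel=per_channel,
        n_channels_used=len(found),
    )
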