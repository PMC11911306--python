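"""Parametric model of the resting-EEG log2-amplitude spectrum.

The spectrum is modelled as an aperiodic (1/f-like) background plus five
Gaussian band peaks (theta, alpha, beta1, beta2, gamma):

    log2 A(f) = A0 * (0.1 * f)**m + sum_i A_i * exp(-0.5 * ((f - mu_i)/sigma_i)**2) + k

with m < 0, 0 <= A_i <= 10, band-specific bounds on the peak centres mu_i
and maximum widths sigma_i.  The aperiodic term is normalised so that it
equals A0 at f = 10 Hz (where 0.1*f = 1); this convention is shared by the
synthetic generator and the fitter so round trips are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Band order used throughout the package.
BAND_NAMES = ("theta", "alpha", "beta1", "beta2", "gamma")

#: Allowed peak-centre range per band, Hz.
MU_BOUNDS = ((1.0, 7.0), (7.0, 13.0), (13.0, 21.0), (21.0, 29.0), (29.0, 47.0))

#: Maximum Gaussian width per band, Hz.
SIGMA_MAX = (15.0, 10.0, 30.0, 30.0, 30.0)

#: Minimum Gaussian width, Hz (widths must be strictly positive).
SIGMA_MIN = 0.1

#: Amplitude bounds for each band peak, log2-amplitude units.
AMP_BOUNDS = (0.0, 10.0)

ALPHA = BAND_NAMES.index("alpha")


@dataclass
class BandPeak:
    """One Gaussian band peak: height (log2-amplitude), centre and width (Hz)."""

    amplitude: float
    mu: float
    sigma: float


@dataclass
class SpectralModelParams:
    """Full parameter set of the spectral model, plus fit quality if fitted."""

    a0: float
    m: float
    k: float
    bands: list[BandPeak] = field(default_factory=list)
    adj_r2: float | None = None
    sse: float | None = None

    def __post_init__(self) -> None:
        if len(self.bands) != len(BAND_NAMES):
            raise ValueError(f"expected {len(BAND_NAMES)} band peaks, got {len(self.bands)}")

    @property
    def alpha(self) -> BandPeak:
        return self.bands[ALPHA]

    def to_vector(self) -> np.ndarray:
        """Pack as [a0, m, k, A1, mu1, s1, ..., A5, mu5, s5]."""
        head = [self.a0, self.m, self.k]
        for b in self.bands:
            head.extend([b.amplitude, b.mu, b.sigma])
        return np.asarray(head, dtype=float)

    @classmethod
    def from_vector(cls, vec: np.ndarray, **extra) -> "SpectralModelParams":
        vec = np.asarray(vec, dtype=float)
        bands = [BandPeak(*vec[3 + 3 * i : 6 + 3 * i]) for i in range(len(BAND_NAMES))]
        return cls(a0=vec[0], m=vec[1], k=vec[2], bands=bands, **extra)

    def as_dict(self) -> dict:
        d = {"a0": self.a0, "m": self.m, "k": self.k}
        for name, b in zip(BAND_NAMES, self.bands):
            d[f"{name}_amplitude"] = b.amplitude
            d[f"{name}_mu"] = b.mu
            d[f"{name}_sigma"] = b.sigma
        if self.adj_r2 is not None:
            d["adj_r2"] = self.adj_r2
        if self.sse is not None:
            d["sse"] = self.sse
        return d


def aperiodic(freqs: np.ndarray, a0: float, m: float, k: float) -> np.ndarray:
    """Aperiodic background A0*(0.1 f)^m + k on the log2-amplitude scale."""
    f = np.asarray(freqs, dtype=float)
    return a0 * np.power(0.1 * f, m) + k


def evaluate_spectrum(
    params: SpectralModelParams,
    freqs: np.ndarray,
    band_gains: np.ndarray | None = None,
) -> np.ndarray:
    """Model log2-amplitude at ``freqs``.

    ``band_gains`` optionally scales each band's Gaussian height (used by the
    synthetic generator for channel-specific alpha gain).
    """
    f = np.asarray(freqs, dtype=float)
    out = aperiodic(f, params.a0, params.m, params.k)
    gains = np.ones(len(BAND_NAMES)) if band_gains is None else np.asarray(band_gains, float)
    for g, b in zip(gains, params.bands):
        out = out + g * b.amplitude * np.exp(-0.5 * ((f - b.mu) / b.sigma) ** 2)
    return out


def model_from_vector(vec: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Vectorised model evaluation from a packed parameter vector."""
    f = np.asarray(freqs, dtype=float)
    out = vec[0] * np.power(0.1 * f, vec[1]) + vec[2]
    for i in range(len(BAND_NAMES)):
        a, mu, s = vec[3 + 3 * i : 6 + 3 * i]
        out = out + a * np.exp(-0.5 * ((f - mu) / s) ** 2)
    return out


def model_jacobian(vec: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the model w.r.t. the packed parameter vector."""
    f = np.asarray(freqs, dtype=float)
    n = f.size
    jac = np.empty((n, 3 + 3 * len(BAND_NAMES)))
    base = np.power(0.1 * f, vec[1])
    jac[:, 0] = base
    # d/dm of a0*(0.1 f)^m = a0*(0.1 f)^m * ln(0.1 f)
    jac[:, 1] = vec[0] * base * np.log(0.1 * f)
    jac[:, 2] = 1.0
    for i in range(len(BAND_NAMES)):
        a, mu, s = vec[3 + 3 * i : 6 + 3 * i]
        z = (f - mu) / s
        g = np.exp(-0.5 * z**2)
        jac[:, 3 + 3 * i] = g
        jac[:, 4 + 3 * i] = a * g * z / s
        jac[:, 5 + 3 * i] = a * g * z**2 / s
    return jac
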