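"""Synthetic resting-EEG cohorts with known ground truth.

Each synthetic participant carries a full set of generating spectral
parameters (aperiodic background + five band peaks).  The alpha-peak centre
follows an age trend, by default the fitted line PAF = -0.025 x age + 10.8
plus Gaussian scatter, so the cohort plants a known PAF-age slope that the
downstream pipeline should recover.  Demographics (NART reading errors /
NART-IQ, QMCI, GDS) are linear-Gaussian in age with configurable
coefficients.

Per-channel spectra share the participant's parameters except for a
channel-specific alpha gain with a posterior-dominant gradient (occipital
maximum).  Time series are produced by inverse-FFT spectral shaping with
random phases, plus a slow drift and Poisson-placed transient artifact
pulses whose intervals are returned as a ledger for the cleaning stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .io import RawEEG
from .model import ALPHA, BAND_NAMES, MU_BOUNDS, BandPeak, SpectralModelParams, evaluate_spectrum
from .spectra import FrequencyGrid

NART_INTERCEPT = 126.41
NART_SLOPE = -0.9775

#: 10-20 montage with alpha gains increasing front to back (occipital maximum).
#: The gradient is modest (0.70 -> 1.00): posterior dominance in real resting
#: alpha is strong in power but the peak is still detectable frontally.
DEFAULT_MONTAGE: dict[str, float] = {
    "Fp1": 0.70, "Fp2": 0.70,
    "F7": 0.78, "F3": 0.78, "Fz": 0.78, "F4": 0.78, "F8": 0.78,
    "T7": 0.85, "C3": 0.85, "Cz": 0.85, "C4": 0.85, "T8": 0.85,
    "P7": 0.93, "P3": 0.93, "Pz": 0.93, "P4": 0.93, "P8": 0.93,
    "O1": 1.00, "O2": 1.00,
}

#: Default uniform sampling ranges for the generating parameters.
DEFAULT_BAND_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "theta": {"amplitude": (0.0, 0.5), "mu": (3.5, 6.5), "sigma": (1.0, 3.0)},
    "alpha": {"amplitude": (1.0, 3.0), "mu": (7.2, 11.8), "sigma": (0.8, 1.5)},
    "beta1": {"amplitude": (0.0, 0.5), "mu": (14.0, 20.0), "sigma": (1.5, 4.0)},
    "beta2": {"amplitude": (0.0, 0.5), "mu": (22.0, 28.0), "sigma": (1.5, 4.0)},
    "gamma": {"amplitude": (0.0, 0.5), "mu": (30.0, 44.0), "sigma": (2.0, 5.0)},
}

# Centred near A0 = 1, m = -0.6, k = 0: on the log2-amplitude scale this
# plants roughly a 60x power drop from 1 Hz to 10 Hz and keeps the alpha
# Gaussian visible as a local maximum on every channel -- the regime in
# which all five PAF estimators are defined.
DEFAULT_APERIODIC_RANGES: dict[str, tuple[float, float]] = {
    "a0": (0.8, 1.2),
    "m": (-0.7, -0.5),
    "k": (-0.5, 0.5),
}


@dataclass
class LinearNoiseModel:
    """y = intercept + slope * age + Normal(0, sd)."""

    intercept: float
    slope: float
    sd: float


# Defaults plant corr(NART-IQ, age) ~ +0.5 and a weak negative corr(QMCI, age),
# with marginal means/SDs near those reported for healthy cohorts.
DEFAULT_NART_MODEL = LinearNoiseModel(intercept=20.4, slope=-0.179, sd=5.0)
DEFAULT_QMCI_MODEL = LinearNoiseModel(intercept=80.6, slope=-0.074, sd=7.3)


def nart_to_iq(errors):
    """Convert NART error count(s) to NART-IQ: 126.41 - 0.9775 * errors."""
    arr = np.asarray(errors, dtype=float)
    if np.any(arr < 0):
        raise ValueError("NART error count must be non-negative")
    out = NART_INTERCEPT + NART_SLOPE * arr
    return float(out) if np.isscalar(errors) or arr.ndim == 0 else out


@dataclass
class CohortSpec:
    """Generating conditions for a synthetic cohort."""

    n_participants: int = 60
    age_design: str = "stratified_by_decade"  # or "uniform"
    age_range: tuple[int, int] = (20, 78)
    seed: int = 0
    paf_slope: float = -0.025  # Hz per year
    paf_intercept: float = 10.8  # Hz
    paf_residual_sd: float = 0.9  # Hz
    paf_clip: tuple[float, float] = (7.2, 11.8)
    band_param_distributions: dict = field(
        default_factory=lambda: {b: dict(v) for b, v in DEFAULT_BAND_RANGES.items()}
    )
    aperiodic_distribution: dict = field(
        default_factory=lambda: dict(DEFAULT_APERIODIC_RANGES)
    )
    montage: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MONTAGE))
    artifact_rate: float = 2.0  # events per minute
    drift_amplitude: float = 20.0  # uV (RMS of the slow drift)
    recording_seconds: float = 240.0
    nart_model: LinearNoiseModel = field(default_factory=lambda: DEFAULT_NART_MODEL)
    qmci_model: LinearNoiseModel = field(default_factory=lambda: DEFAULT_QMCI_MODEL)

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be at least 2")
        if self.age_design not in ("stratified_by_decade", "uniform"):
            raise ValueError(f"unknown age_design: {self.age_design!r}")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        if not self.montage:
            raise ValueError("montage must name at least one channel")
        for name, (lo, hi) in zip(BAND_NAMES, MU_BOUNDS):
            rng = self.band_param_distributions.get(name)
            if rng is None:
                raise ValueError(f"band_param_distributions missing band {name!r}")
            mlo, mhi = rng["mu"]
            if mlo < lo or mhi > hi:
                raise ValueError(
                    f"band_param_distributions[{name!r}]['mu'] = ({mlo}, {mhi}) "
                    f"not nested in the model bound ({lo}, {hi})"
                )
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be non-negative")
        if self.recording_seconds < 10:
            raise ValueError("recording_seconds must be at least 10")


@dataclass
class SyntheticParticipant:
    participant_id: str
    age: float
    true_params: SpectralModelParams
    channel_gains: dict[str, float]
    nart_errors: int
    nart_iq: float
    qmci: float
    gds: int

    def __post_init__(self) -> None:
        alpha = self.true_params.alpha
        lo, hi = MU_BOUNDS[ALPHA]
        if not lo <= alpha.mu <= hi:
            raise ValueError(f"alpha centre {alpha.mu} outside [{lo}, {hi}] Hz")
        if not 0 <= self.qmci <= 100:
            raise ValueError("QMCI must lie in [0, 100]")
        if not 0 <= self.gds <= 15:
            raise ValueError("GDS must lie in [0, 15]")
        if self.nart_errors < 0:
            raise ValueError("NART error count must be non-negative")


def _draw_ages(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.age_range
    if spec.age_design == "uniform":
        return rng.integers(lo, hi + 1, size=spec.n_participants).astype(float)
    decades = []
    d = (lo // 10) * 10
    while d <= hi:
        decades.append((max(lo, d), min(hi, d + 9)))
        d += 10
    n_bins = len(decades)
    base, extra = divmod(spec.n_participants, n_bins)
    ages = []
    for i, (blo, bhi) in enumerate(decades):
        n = base + (1 if i < extra else 0)
        ages.extend(rng.integers(blo, bhi + 1, size=n).tolist())
    return np.asarray(ages, dtype=float)


def generate_cohort(spec: CohortSpec) -> list[SyntheticParticipant]:
    """Draw a cohort of synthetic participants from ``spec`` (deterministic per seed)."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    ages = _draw_ages(spec, rng)
    cohort: list[SyntheticParticipant] = []
    ap = spec.aperiodic_distribution
    for i, age in enumerate(ages):
        mu_alpha = spec.paf_intercept + spec.paf_slope * age
        if spec.paf_residual_sd > 0:
            mu_alpha += rng.normal(0.0, spec.paf_residual_sd)
        mu_alpha = float(np.clip(mu_alpha, *spec.paf_clip))
        bands = []
        for name in BAND_NAMES:
            ranges = spec.band_param_distributions[name]
            amp = rng.uniform(*ranges["amplitude"])
            mu = mu_alpha if name == "alpha" else rng.uniform(*ranges["mu"])
            sigma = rng.uniform(*ranges["sigma"])
            bands.append(BandPeak(amplitude=amp, mu=mu, sigma=sigma))
        params = SpectralModelParams(
            a0=rng.uniform(*ap["a0"]), m=rng.uniform(*ap["m"]), k=rng.uniform(*ap["k"]),
            bands=bands,
        )
        nm, qm = spec.nart_model, spec.qmci_model
        nart_errors = int(round(np.clip(
            nm.intercept + nm.slope * age + rng.normal(0.0, nm.sd), 0, 50)))
        qmci = float(np.clip(round(
            qm.intercept + qm.slope * age + rng.normal(0.0, qm.sd)), 0, 100))
        gds = int(np.clip(rng.poisson(2.0), 0, 15))
        cohort.append(
            SyntheticParticipant(
                participant_id=f"sub-{i + 1:03d}",
                age=float(age),
                true_params=params,
                channel_gains=dict(spec.montage),
                nart_errors=nart_errors,
                nart_iq=nart_to_iq(nart_errors),
                qmci=qmci,
                gds=gds,
            )
        )
    return cohort


def _band_gains_for_channel(participant: SyntheticParticipant, channel: str) -> np.ndarray:
    if channel not in participant.channel_gains:
        raise KeyError(f"channel {channel!r} not in montage {list(participant.channel_gains)}")
    gains = np.ones(len(BAND_NAMES))
    gains[ALPHA] = participant.channel_gains[channel]
    return gains


def synthesize_spectrum(
    participant: SyntheticParticipant,
    channel: str,
    grid: FrequencyGrid | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Ground-truth log2-amplitude spectrum for one channel (plus optional noise)."""
    grid = grid or FrequencyGrid()
    values = evaluate_spectrum(
        participant.true_params, grid.values, _band_gains_for_channel(participant, channel)
    )
    if noise_sd > 0:
        values = values + np.random.default_rng(seed).normal(0.0, noise_sd, size=values.shape)
    return values


@dataclass
class ArtifactEvent:
    channel: str
    start: int  # sample index
    end: int  # half-open
    amplitude: float  # uV, signed


@dataclass
class SynthesizedEEG:
    raw: RawEEG
    artifacts: list[ArtifactEvent]


def synthesize_timeseries(
    participant: SyntheticParticipant,
    duration_s: float = 120.0,
    fs: float = 500.0,
    drift_amplitude: float = 20.0,
    artifact_rate: float = 2.0,
    seed: int = 0,
    target_rms_uv: float = 20.0,
    spectral_floor_hz: float = 1.0,
) -> SynthesizedEEG:
    """Time-domain EEG whose spectrum follows the participant's ground truth.

    Per channel: inverse-FFT shaping of white phases to the target amplitude
    spectrum (model values, held constant below ``spectral_floor_hz`` where
    the separate drift term supplies the power), rescaled to
    ``target_rms_uv``; plus an independent low-pass random-walk drift and
    Poisson-placed transient pulses of 150-500 uV.  Returns the EEG and a
    ledger of every planted artifact interval.
    """
    if duration_s < 10:
        raise ValueError("duration_s must be at least 10")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    labels = list(participant.channel_gains)
    data = np.empty((len(labels), n))
    f_eval = np.maximum(freqs, spectral_floor_hz)
    for c, label in enumerate(labels):
        log2_amp = evaluate_spectrum(
            participant.true_params, f_eval, _band_gains_for_channel(participant, label)
        )
        amp = np.exp2(log2_amp)
        amp[0] = 0.0  # no DC; drift is added separately
        phases = np.exp(2j * np.pi * rng.random(freqs.size))
        x = np.fft.irfft(amp * phases, n=n)
        x *= target_rms_uv / max(x.std(), 1e-30)
        if drift_amplitude > 0:
            walk = np.cumsum(rng.normal(size=n))
            sos = sp_signal.butter(2, 0.1, btype="lowpass", fs=fs, output="sos")
            drift = sp_signal.sosfiltfilt(sos, walk - walk.mean())
            x += drift * (drift_amplitude / max(drift.std(), 1e-30))
        data[c] = x

    events: list[ArtifactEvent] = []
    n_events = rng.poisson(artifact_rate * duration_s / 60.0) if artifact_rate > 0 else 0
    for _ in range(n_events):
        c = int(rng.integers(len(labels)))
        width = int(rng.uniform(0.1, 0.3) * fs)
        start = int(rng.integers(0, max(n - width, 1)))
        amplitude = float(rng.uniform(150.0, 500.0) * rng.choice([-1.0, 1.0]))
        pulse = amplitude * np.hanning(width)
        data[c, start : start + width] += pulse
        events.append(ArtifactEvent(channel=labels[c], start=start, end=start + width,
                                    amplitude=amplitude))
    return SynthesizedEEG(raw=RawEEG(data=data, fs=fs, labels=labels), artifacts=events)


def cohort_to_frame(cohort: list[SyntheticParticipant]):
    """Cohort demographics as a pandas DataFrame (one row per participant)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in cohort],
            "age": [p.age for p in cohort],
            "nart_errors": [p.nart_errors for p in cohort],
            "nart_iq": [p.nart_iq for p in cohort],
            "qmci": [p.qmci for p in cohort],
            "gds": [p.gds for p in cohort],
        }
    )


def write_cohort(cohort: list[SyntheticParticipant], csv_path, sidecar_path=None):
    """Write demographics CSV plus a JSON sidecar of ground-truth parameters."""
    from .io import write_json

    frame = cohort_to_frame(cohort)
    frame.to_csv(csv_path, index=False)
    if sidecar_path is not None:
        truth = {
            p.participant_id: {
                "spectral_params": p.true_params.as_dict(),
                "channel_gains": p.channel_gains,
            }
            for p in cohort
        }
        write_json(truth, sidecar_path)
    return frame
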