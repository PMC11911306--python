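"""Cleaning of DC-coupled resting EEG.

DC recordings drift slowly, so artifact detection is relative to a
time-varying baseline: each channel is demeaned, a 3rd-order Savitzky-Golay
baseline spanning 1025 samples (about +/- 2 s at 500 Hz) is subtracted, and
samples deviating from it by more than +/-120 uV are flagged.  The longest
contiguous stretch that is clean on every retained channel is kept; if it is
shorter than the target duration, channels are dropped greedily (the channel
whose removal lengthens the clean segment the most goes first).  The kept
segment is finally re-referenced to the common average.

Pipeline order is fixed: demean -> baseline -> flag -> channel exclusion ->
segment crop -> common-average reference.  Flagging is non-destructive;
sample values are only ever altered by demeaning and re-referencing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .io import RawEEG

DEFAULT_WINDOW = 1025
DEFAULT_ORDER = 3
DEFAULT_THRESHOLD_UV = 120.0


@dataclass
class CleanResult:
    """Outcome of cleaning: cropped re-referenced segment plus provenance."""

    segment: np.ndarray  # retained channels x samples, common-average referenced
    interval: tuple[int, int]  # [start, end) in samples of the original recording
    artifact_mask: np.ndarray  # all channels x samples, True = flagged
    dropped_channels: list[str]
    labels: list[str]  # retained channel labels, in recording order
    fs: float
    reached_target: bool = True

    @property
    def duration(self) -> float:
        return (self.interval[1] - self.interval[0]) / self.fs


def _edge_polyfit(x: np.ndarray, half: int, order: int) -> np.ndarray:
    """Left-edge baseline values by least squares on truncated windows.

    For t < half the centred window is truncated to [0, t+half]; an
    order-``order`` polynomial is fitted to that stretch and evaluated at t.
    Prefix sums over a scaled abscissa make this O(half * order^3).
    """
    n_pre = 2 * half  # samples ever touched by a truncated window
    u = np.arange(n_pre) / (2.0 * half)  # scaled abscissa for conditioning
    powers = np.vander(u, 2 * order + 1, increasing=True)  # u^0 .. u^2*order
    s_mom = np.cumsum(powers, axis=0)  # prefix sums of u^j
    s_dat = np.cumsum(powers[:, : order + 1] * x[:n_pre, None], axis=0)
    t = np.arange(half)
    end = t + half  # inclusive window end
    gram = np.empty((half, order + 1, order + 1))
    for j in range(order + 1):
        for k in range(order + 1):
            gram[:, j, k] = s_mom[end, j + k]
    rhs = s_dat[end]
    coef = np.linalg.solve(gram, rhs[..., None])[..., 0]
    ut = np.vander(u[t], order + 1, increasing=True)
    return np.einsum("ij,ij->i", coef, ut)


def savgol_baseline(
    x: np.ndarray, window: int = DEFAULT_WINDOW, order: int = DEFAULT_ORDER
) -> np.ndarray:
    """Savitzky-Golay baseline with truncated-window least squares at the edges.

    Interior samples get the standard centred filter; within half a window of
    either boundary the polynomial is refitted on the truncated window only,
    so no samples are fabricated by padding or extrapolation.
    """
    x = np.asarray(x, dtype=float).ravel()
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if x.size < window:
        raise ValueError(f"signal length {x.size} shorter than window {window}")
    half = window // 2
    base = sp_signal.savgol_filter(x, window, order, mode="interp")
    base[:half] = _edge_polyfit(x, half, order)
    base[-half:] = _edge_polyfit(x[::-1], half, order)[::-1]
    return base


def flag_artifacts(
    raw: RawEEG,
    threshold: float = DEFAULT_THRESHOLD_UV,
    window: int = DEFAULT_WINDOW,
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Per-channel boolean mask: sample deviates from its SG baseline by > threshold.

    Each channel is demeaned before the baseline is computed, so the
    criterion is insensitive to the arbitrary DC offset of the recording.
    """
    mask = np.empty(raw.data.shape, dtype=bool)
    for c in range(raw.n_channels):
        xd = raw.data[c] - raw.data[c].mean()
        mask[c] = np.abs(xd - savgol_baseline(xd, window, order)) > threshold
    return mask


def largest_clean_segment(
    artifact_mask: np.ndarray, retained: np.ndarray | list[int] | None = None
) -> tuple[int, int]:
    """Longest half-open run [start, end) clean on all retained channels.

    Ties are broken in favour of the earliest start; returns (0, 0) when no
    sample is clean anywhere.
    """
    mask = np.atleast_2d(np.asarray(artifact_mask, dtype=bool))
    if mask.size == 0:
        raise ValueError("empty artifact mask")
    if retained is not None:
        mask = mask[np.asarray(retained, dtype=int)]
    dirty = mask.any(axis=0)
    padded = np.concatenate(([True], dirty, [True])).astype(int)
    starts = np.flatnonzero(np.diff(padded) == -1)
    ends = np.flatnonzero(np.diff(padded) == 1)
    if starts.size == 0:
        return (0, 0)
    best = int(np.argmax(ends - starts))  # argmax takes the first maximum
    return (int(starts[best]), int(ends[best]))


@dataclass
class ChannelExclusion:
    dropped: list[int]  # channel indices, in drop order
    interval: tuple[int, int]
    reached_target: bool


def exclude_channels_for_target(
    artifact_mask: np.ndarray,
    fs: float,
    target_seconds: float = 100.0,
    max_drop: int = 16,
) -> ChannelExclusion:
    """Greedy channel exclusion until the clean segment reaches the target.

    While the best common clean segment is shorter than ``target_seconds``,
    drop the channel whose removal lengthens it the most; stop at the
    target, after ``max_drop`` drops, or when no single drop helps.
    """
    if target_seconds <= 0:
        raise ValueError("target_seconds must be positive")
    mask = np.atleast_2d(np.asarray(artifact_mask, dtype=bool))
    n_channels = mask.shape[0]
    target = int(round(target_seconds * fs))
    retained = list(range(n_channels))
    dropped: list[int] = []
    interval = largest_clean_segment(mask, retained)

    def length(iv):
        return iv[1] - iv[0]

    while length(interval) < target and len(dropped) < max_drop and len(retained) > 1:
        best_gain, best_channel, best_interval = 0, None, interval
        for ch in retained:
            trial = [c for c in retained if c != ch]
            iv = largest_clean_segment(mask, trial)
            if length(iv) - length(interval) > best_gain:
                best_gain, best_channel, best_interval = length(iv) - length(interval), ch, iv
        if best_channel is None:
            break
        retained.remove(best_channel)
        dropped.append(best_channel)
        interval = best_interval

    reached = length(interval) >= target
    if not reached:
        warnings.warn(
            f"target of {target_seconds:g} s unreachable; best clean segment is "
            f"{length(interval) / fs:g} s after dropping {len(dropped)} channel(s)",
            stacklevel=2,
        )
    return ChannelExclusion(dropped=dropped, interval=interval, reached_target=reached)


def common_average_reference(segment: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous cross-channel mean from every channel."""
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    if segment.shape[0] < 2:
        raise ValueError("common average reference requires at least two channels")
    return segment - segment.mean(axis=0, keepdims=True)


def clean_raw(
    raw: RawEEG,
    threshold: float = DEFAULT_THRESHOLD_UV,
    window: int = DEFAULT_WINDOW,
    order: int = DEFAULT_ORDER,
    target_seconds: float = 100.0,
    max_drop: int = 16,
) -> CleanResult:
    """Full cleaning pass: demean, flag, exclude channels, crop, re-reference.

    Re-referencing happens after cropping and exclusion so that dropped
    channels and flagged stretches cannot contaminate the common average.
    """
    mask = flag_artifacts(raw, threshold=threshold, window=window, order=order)
    excl = exclude_channels_for_target(mask, raw.fs, target_seconds, max_drop)
    retained = [c for c in range(raw.n_channels) if c not in excl.dropped]
    start, end = excl.interval
    if end <= start:
        raise ValueError("no artifact-free samples on any channel subset")
    demeaned = raw.data[retained] - raw.data[retained].mean(axis=1, keepdims=True)
    segment = common_average_reference(demeaned[:, start:end])
    return CleanResult(
        segment=segment,
        interval=(start, end),
        artifact_mask=mask,
        dropped_channels=[raw.labels[c] for c in excl.dropped],
        labels=[raw.labels[c] for c in retained],
        fs=raw.fs,
        reached_target=excl.reached_target,
    )
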