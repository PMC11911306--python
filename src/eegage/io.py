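"""Readers and writers for raw EEG and derived tables.

Raw EEG enters either as EDF (read through mne) or as delimited text with a
one-line header carrying the sampling rate and channel labels; all
amplitudes are held in microvolts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class RawEEG:
    """Multichannel EEG: channels x samples matrix in microvolts."""

    data: np.ndarray
    fs: float
    labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def read_eeg(path: str | Path) -> RawEEG:
    """Read EDF (via mne) or delimited text (see :func:`write_eeg_text`)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return RawEEG(data=raw.get_data() * 1e6, fs=float(raw.info["sfreq"]), labels=list(raw.ch_names))
    return read_eeg_text(path)


def write_eeg_text(raw: RawEEG, path: str | Path) -> Path:
    """Write EEG as tab-delimited text: one header line, then samples as rows."""
    path = Path(path)
    header = f"# fs={raw.fs:g} channels={','.join(raw.labels)} orientation=samples-by-channels"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, raw.data.T, fmt="%.10g", delimiter="\t")
    return path


def read_eeg_text(path: str | Path) -> RawEEG:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '#' header line with fs and channel labels")
        fields = dict(
            tok.split("=", 1) for tok in header.lstrip("#").split() if "=" in tok
        )
        try:
            fs = float(fields["fs"])
            labels = fields["channels"].split(",")
        except KeyError as exc:
            raise ValueError(f"{path}: header missing field {exc}") from exc
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if data.shape[1] != len(labels):
        raise ValueError(
            f"{path}: header names {len(labels)} channels but rows have {data.shape[1]} columns"
        )
    return RawEEG(data=data.T, fs=fs, labels=labels)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "as_dict"):
            return o.as_dict()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=_default) + "\n")
    return path
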