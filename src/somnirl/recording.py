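"""Multichannel EEG containers and plain-text I/O.

A :class:`Recording` is a channels x samples matrix in microvolts together with
its sampling rate, 10-20 channel labels and (for simulated or scored data) a
sleep-state label and an optional per-sample ground-truth microstate sequence.

Recordings are stored on disk as a tab-separated matrix (samples x channels,
header row of channel labels) plus a JSON sidecar carrying the sampling rate
and metadata; a ground-truth microstate sequence, when present, goes to a
companion ``*.labels.tsv``.  EDF files can be read through :mod:`mne` when it
is installed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

#: The 19 scalp electrodes of the international 10-20 system, in the
#: conventional anterior-to-posterior order.
MONTAGE_10_20 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
]

#: The four experimental conditions: eyes-open wake, eyes-closed NREM onset,
#: REM sleep with auditory stimuli, REM sleep without stimuli.
STATE_NAMES = ["EO", "EC", "REM_stim", "REM_nostim"]


@dataclass
class Recording:
    """Channels x samples EEG matrix with metadata.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per row of ``data``.
    state_label : str, optional
        Sleep-state / condition label for the whole recording.
    true_label_sequence : ndarray of int, optional
        Per-sample ground-truth microstate index (simulated data only).
    seed : int, optional
        Seed the recording was generated from, for provenance.
    rec_id : str, optional
        Identifier used in feature tables.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    state_label: str | None = None
    true_label_sequence: np.ndarray | None = None
    seed: int | None = None
    rec_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels were given"
            )
        if self.data.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.true_label_sequence is not None:
            self.true_label_sequence = np.asarray(self.true_label_sequence, dtype=int)
            if self.true_label_sequence.shape != (self.data.shape[1],):
                raise ValueError("true_label_sequence length must equal n_samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "Recording":
        """Copy of this recording with the signal matrix replaced."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class EpochSet:
    """Stack of equal-length epochs cut from one recording.

    ``epochs`` has shape (n_epochs, n_channels, epoch_length_samples); epochs
    are contiguous and non-overlapping unless an overlap was configured at
    construction.  ``labels`` carries the source recording's state label, one
    entry per epoch.
    """

    epochs: np.ndarray
    fs: float
    epoch_length_s: float
    source_id: str | None = None
    labels: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epochs x channels x samples)")
        expected = int(round(self.epoch_length_s * self.fs))
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} samples does not match "
                f"epoch_length_s*fs = {expected}"
            )
        if not self.labels:
            self.labels = [None] * self.epochs.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def save_recording(rec: Recording, path_base: str | Path) -> Path:
    """Write a recording as ``<base>.tsv`` + ``<base>.json`` (+ labels file).

    Returns the path of the TSV file.
    """
    base = Path(path_base)
    base.parent.mkdir(parents=True, exist_ok=True)
    tsv = base.with_suffix(".tsv")
    header = "\t".join(rec.channel_labels)
    np.savetxt(tsv, rec.data.T, delimiter="\t", header=header, comments="")
    meta = {
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "state_label": rec.state_label,
        "seed": rec.seed,
        "rec_id": rec.rec_id,
        "has_true_labels": rec.true_label_sequence is not None,
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    if rec.true_label_sequence is not None:
        np.savetxt(base.parent / (base.stem + ".labels.tsv"),
                   rec.true_label_sequence, fmt="%d")
    return tsv


def load_recording(path_base: str | Path) -> Recording:
    """Read a recording written by :func:`save_recording`."""
    base = Path(path_base)
    meta = json.loads(base.with_suffix(".json").read_text())
    data = np.loadtxt(base.with_suffix(".tsv"), delimiter="\t", skiprows=1).T
    if data.ndim == 1:
        data = data[None, :]
    labels = None
    if meta.get("has_true_labels"):
        labels = np.loadtxt(base.parent / (base.stem + ".labels.tsv"), dtype=int)
    return Recording(
        data=data,
        fs=float(meta["fs"]),
        channel_labels=list(meta["channel_labels"]),
        state_label=meta.get("state_label"),
        true_label_sequence=labels,
        seed=meta.get("seed"),
        rec_id=meta.get("rec_id"),
    )


def read_edf(path: str | Path, state_label: str | None = None) -> Recording:
    """Read an EDF file into a :class:`Recording` (requires ``mne``)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading EDF requires the optional 'mne' dependency "
            "(pip install somnirl[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        state_label=state_label,
        rec_id=Path(path).stem,
    )
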