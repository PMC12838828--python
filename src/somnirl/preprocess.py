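"""Deterministic signal conditioning: filtering, re-referencing, epoching.

All operations are linear, zero-phase and shape-preserving.  Filtering uses a
forward-backward (zero-phase) Butterworth design of order 4 per pass so that
microstate timing is not shifted; edge effects are handled by the odd
reflect-padding built into :func:`scipy.signal.sosfiltfilt`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import EpochSet, Recording

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class BandDefinition:
    """A named EEG frequency band with corner frequencies in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 <= self.low_hz < self.high_hz):
            raise ValueError(
                f"invalid band corners {self.low_hz}-{self.high_hz} Hz"
            )


#: Conventional band corners.  The gamma lower edge is not universal; 30 Hz is
#: used here, with the upper edge at the 70 Hz analysis-filter corner.
DEFAULT_BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 0.5, 4.0),
    "theta": BandDefinition("theta", 4.0, 7.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 70.0),
}


def _check_band(low_hz: float, high_hz: float, fs: float) -> None:
    nyq = fs / 2.0
    if not (0 < low_hz < high_hz):
        raise ValueError(f"need 0 < low ({low_hz}) < high ({high_hz})")
    if high_hz >= nyq:
        raise ValueError(
            f"upper cutoff {high_hz} Hz is at or above Nyquist ({nyq} Hz)"
        )


def bandpass(rec: Recording, low_hz: float, high_hz: float,
             order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass filter.

    The default 0.5-70 Hz analysis band removes slow drifts and
    high-frequency noise; the DC component is rejected entirely.
    """
    _check_band(low_hz, high_hz, rec.fs)
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=rec.fs, output="sos")
    # reflect-pad generously: the slow low-frequency corner rings for
    # ~ fs/low_hz samples, far longer than sosfiltfilt's default pad; even
    # reflection avoids the derivative kink of odd reflection, which leaks
    # low-frequency transients into the passband
    padlen = min(rec.n_samples - 1, int(np.ceil(3 * rec.fs / low_hz)))
    return rec.with_data(signal.sosfiltfilt(sos, rec.data, axis=1,
                                            padtype="even", padlen=padlen))


def notch(rec: Recording, freq_hz: float = 50.0,
          quality: float = 30.0) -> Recording:
    """Zero-phase narrowband notch (power-line) filter."""
    if not (0 < freq_hz < rec.fs / 2):
        raise ValueError(
            f"notch frequency {freq_hz} Hz must lie in (0, {rec.fs / 2}) Hz"
        )
    b, a = signal.iirnotch(freq_hz, quality, fs=rec.fs)
    return rec.with_data(signal.filtfilt(b, a, rec.data, axis=1))


def rereference(rec: Recording, scheme: str = "common_average") -> Recording:
    """Subtract a reference signal from every channel.

    ``common_average`` subtracts the instantaneous mean over all channels;
    ``linked_mastoids`` subtracts the mean of the A1 and A2 channels (the
    standard mastoid reference).
    """
    if scheme == "common_average":
        ref = rec.data.mean(axis=0, keepdims=True)
    elif scheme == "linked_mastoids":
        missing = [ch for ch in ("A1", "A2") if ch not in rec.channel_labels]
        if missing:
            raise ValueError(
                f"linked-mastoid reference needs channels {missing}; "
                f"available: {rec.channel_labels}"
            )
        idx = [rec.channel_labels.index(ch) for ch in ("A1", "A2")]
        ref = rec.data[idx].mean(axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown re-reference scheme {scheme!r}")
    return rec.with_data(rec.data - ref)


def epoch(rec: Recording, length_s: float = 2.0,
          overlap_s: float = 0.0) -> EpochSet:
    """Cut a recording into equal-length epochs.

    Non-overlapping by default; trailing samples that do not fill a whole
    epoch are dropped.  With overlap the hop is ``length_s - overlap_s``.
    """
    L = int(round(length_s * rec.fs))
    if L < 2:
        raise ValueError("epoch length must span at least 2 samples")
    if not overlap_s < length_s:
        raise ValueError("overlap must be shorter than the epoch length")
    hop = int(round((length_s - overlap_s) * rec.fs))
    T = rec.n_samples
    if T < L:
        raise ValueError(
            f"recording of {T} samples is shorter than one epoch ({L})"
        )
    n = (T - L) // hop + 1
    starts = np.arange(n) * hop
    epochs = np.stack([rec.data[:, s:s + L] for s in starts])
    return EpochSet(
        epochs=epochs,
        fs=rec.fs,
        epoch_length_s=length_s,
        source_id=rec.rec_id,
        labels=[rec.state_label] * n,
    )


def extract_band(rec: Recording, band: BandDefinition | str,
                 order: int = 4) -> Recording:
    """Band-pass a recording to one of the named EEG bands."""
    if isinstance(band, str):
        band = DEFAULT_BANDS[band]
    return bandpass(rec, band.low_hz, band.high_hz, order=order)
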