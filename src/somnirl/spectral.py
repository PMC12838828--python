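"""Welch power spectral density and band power.

The spectral estimate is the average of modified periodograms
``|sum_n x(n) w(n) e^{-j 2 pi f n}|^2 / (M U)`` over L windowed segments,
where ``M`` is the segment length and ``U = (1/M) sum w(n)^2`` normalizes the
window power.  Densities are one-sided with the usual factor-2 correction off
DC and Nyquist, in uV^2/Hz.  :func:`scipy.signal.welch` implements exactly
this estimator and is used as the backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .preprocess import BandDefinition


@dataclass(frozen=True)
class SpectralConfig:
    """Welch estimator configuration.

    The default window is a Hamming taper, with non-overlapping segments of
    one 2 s epoch each (``segment_length`` in samples), so that every epoch
    contributes exactly one periodogram to the average.
    """

    segment_length: int = 500
    window: str = "hamming"
    overlap: int = 0

    def __post_init__(self) -> None:
        if self.segment_length < 8:
            raise ValueError("segment_length must be >= 8 samples")
        if not 0 <= self.overlap < self.segment_length:
            raise ValueError("overlap must lie in [0, segment_length)")

    @property
    def normalization(self) -> float:
        """Window power normalization U = (1/M) sum w(n)^2."""
        w = signal.get_window(self.window, self.segment_length)
        return float(np.sum(w**2) / self.segment_length)

    def n_segments(self, n_samples: int) -> int:
        hop = self.segment_length - self.overlap
        return (n_samples - self.segment_length) // hop + 1


@dataclass(frozen=True)
class PSDResult:
    """One-sided PSD: frequencies (Hz) and per-channel power (uV^2/Hz)."""

    freqs: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs)
    config: SpectralConfig = field(default_factory=SpectralConfig)


def welch_psd(epoch: np.ndarray, fs: float,
              config: SpectralConfig | None = None) -> PSDResult:
    """Welch PSD of a channels x samples array (or a single channel)."""
    x = np.atleast_2d(np.asarray(epoch, dtype=float))
    config = config or SpectralConfig()
    if x.shape[1] < config.segment_length:
        raise ValueError(
            f"signal of {x.shape[1]} samples is shorter than one Welch "
            f"segment ({config.segment_length})"
        )
    freqs, power = signal.welch(
        x, fs=fs,
        window=signal.get_window(config.window, config.segment_length),
        nperseg=config.segment_length,
        noverlap=config.overlap,
        detrend=False,
        scaling="density",
        axis=-1,
    )
    return PSDResult(freqs=freqs, power=power, config=config)


def band_power(psd: PSDResult, band: BandDefinition) -> np.ndarray:
    """Per-channel trapezoidal integral of the PSD over one band (uV^2)."""
    f = psd.freqs
    if band.low_hz < f[0] or band.high_hz > f[-1]:
        raise ValueError(
            f"band {band.low_hz}-{band.high_hz} Hz outside the PSD grid "
            f"[{f[0]}, {f[-1]}] Hz"
        )
    idx = np.flatnonzero((f >= band.low_hz) & (f <= band.high_hz))
    if idx.size < 2:
        raise ValueError(
            f"band {band.name} contains fewer than two frequency bins"
        )
    return np.trapezoid(psd.power[:, idx], f[idx], axis=1)


def average_psd(psds: list[PSDResult]) -> PSDResult:
    """Element-wise mean PSD across recordings/epochs (grand average)."""
    if not psds:
        raise ValueError("need at least one PSD")
    f0 = psds[0].freqs
    for p in psds[1:]:
        if p.freqs.shape != f0.shape or not np.allclose(p.freqs, f0):
            raise ValueError("PSDs are on different frequency grids")
    power = np.mean([p.power for p in psds], axis=0)
    return PSDResult(freqs=f0, power=power, config=psds[0].config)
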