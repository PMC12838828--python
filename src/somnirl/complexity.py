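"""Lempel-Ziv complexity of analytic-signal amplitudes, and feature assembly.

Per channel, a band-filtered epoch is turned into its analytic signal (real
part the signal itself, imaginary part its Hilbert transform), the
instantaneous amplitude (modulus) is binarized against the median amplitude
of the window, and the binary string is scored with the LZ76 complexity: the
number of components in the exhaustive-history parsing of Lempel and Ziv
(1976).  Counts are normalized by ``n / log2(n)`` so strings of different
lengths are comparable (a random binary string then scores ~1).

Ties at the median map to 0, deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .microstates import MicrostateFeatures

#: Feature-set identifiers: each microstate temporal parameter, alone or
#: concatenated with the per-channel LZC vector.
MS_PARAMS = ("duration", "occurrence", "coverage", "mean_gfp")
FEATURE_SETS = tuple(MS_PARAMS) + tuple(p + "+lzc" for p in MS_PARAMS)


def analytic_signal(x: np.ndarray) -> np.ndarray:
    """Complex analytic signal; real part equals the input exactly."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 4:
        raise ValueError("need at least 4 samples")
    z = hilbert(x, axis=-1)
    # enforce the defining identity exactly (hilbert's real part already is x
    # up to float rounding)
    return x + 1j * z.imag


def binarize_median(amplitude: np.ndarray) -> str:
    """1 where the amplitude exceeds the window median, else 0."""
    a = np.asarray(amplitude, dtype=float)
    if a.size < 1:
        raise ValueError("empty amplitude series")
    bits = (a > np.median(a)).astype(int)
    return "".join("1" if b else "0" for b in bits)


def lzc(bits: str) -> int:
    """LZ76 complexity: components of the exhaustive-history parsing.

    Linear-time scan (Kaspar & Schuster, 1987): a new component ends as soon
    as the current phrase stops being reproducible from the prior history;
    a final reproducible phrase still counts as one component.
    """
    n = len(bits)
    if n < 1:
        raise ValueError("empty sequence")
    c = 1       # the first symbol is always a component
    l = 1       # start of the current component
    i = 0       # candidate match position in the history
    k = 1       # current phrase length
    kmax = 1    # longest reproducible phrase found so far
    while l + k <= n:
        if bits[i + k - 1] == bits[l + k - 1]:
            k += 1
        else:
            kmax = max(kmax, k)
            i += 1
            if i == l:  # no history position reproduces the phrase
                c += 1
                l += kmax
                i, k, kmax = 0, 1, 1
            else:
                k = 1
    if l < n:  # trailing (possibly reproducible) phrase counts once
        c += 1
    return c


def lzc_normalized(bits: str) -> float:
    """LZ76 count scaled by log2(n)/n (random strings score ~1)."""
    n = len(bits)
    if n < 2:
        raise ValueError("need at least 2 symbols to normalize")
    return lzc(bits) * np.log2(n) / n


def epoch_lzc(epoch: np.ndarray) -> np.ndarray:
    """Normalized LZC per channel of a (band-filtered) channels x samples epoch.

    The pipeline applies this to band-filtered data (delta band by default in
    the feature extraction); this function itself does no filtering.
    """
    x = np.atleast_2d(np.asarray(epoch, dtype=float))
    amp = np.abs(analytic_signal(x))
    return np.array([lzc_normalized(binarize_median(a)) for a in amp])


@dataclass(frozen=True)
class FeatureVector:
    """One epoch's feature vector with its schema.

    ``values`` concatenates, in order: the chosen microstate parameter (one
    entry per microstate class) and, for ``*+lzc`` sets, the per-channel
    normalized LZC vector.  ``names`` documents every column.
    """

    feature_set: str
    values: np.ndarray
    names: tuple[str, ...]
    epoch_id: str | None = None
    label: str | None = None


def build_features(ms: MicrostateFeatures, lzc_values: np.ndarray | None,
                   feature_set: str = "mean_gfp+lzc",
                   epoch_id: str | None = None,
                   label: str | None = None,
                   lzc_epoch_id: str | None = None) -> FeatureVector:
    """Assemble one epoch's feature vector for a declared feature set."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}; "
                         f"choose from {FEATURE_SETS}")
    if lzc_epoch_id is not None and lzc_epoch_id != epoch_id:
        raise ValueError(
            f"microstate features come from epoch {epoch_id!r} but LZC from "
            f"{lzc_epoch_id!r}")
    base = feature_set.removesuffix("+lzc")
    param = {
        "duration": ms.duration_ms,
        "occurrence": ms.occurrence_per_s,
        "coverage": ms.coverage,
        "mean_gfp": ms.mean_gfp,
    }[base]
    values = np.asarray(param, dtype=float)
    names = tuple(f"{base}_ms{k}" for k in range(len(values)))
    if feature_set.endswith("+lzc"):
        if lzc_values is None:
            raise ValueError(f"feature set {feature_set!r} needs LZC values")
        lz = np.asarray(lzc_values, dtype=float)
        values = np.concatenate([values, lz])
        names = names + tuple(f"lzc_ch{c}" for c in range(len(lz)))
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite feature values")
    return FeatureVector(feature_set=feature_set, values=values, names=names,
                         epoch_id=epoch_id, label=label)
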