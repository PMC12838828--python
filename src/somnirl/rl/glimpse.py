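"""Multi-scale glimpse ("retina") extraction from a 1-D observation sequence.

A glimpse at normalized location ``l`` in [-1, 1] is a stack of
``n_scales`` windows centered at the same point, of lengths
``base_length * scale_factor**k``, each average-pooled back down to
``base_length`` samples.  The innermost scale is therefore at full
resolution and the outer scales see progressively wider context at coarser
resolution — resolution is highest at the center of gaze and falls off
peripherally.  Regions outside the sequence are zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GlimpseConfig:
    """Glimpse sensor geometry."""

    n_scales: int = 3
    base_length: int = 16
    scale_factor: int = 2

    def __post_init__(self) -> None:
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if self.base_length < 4:
            raise ValueError("base_length must be >= 4")
        if self.scale_factor < 2:
            raise ValueError("scale_factor must be >= 2")

    @property
    def widest(self) -> int:
        return self.base_length * self.scale_factor ** (self.n_scales - 1)


def glimpse_batch(x: np.ndarray, loc: np.ndarray,
                  cfg: GlimpseConfig) -> np.ndarray:
    """Glimpse stacks for a batch: (B, N) x (B,) -> (B, n_scales, base_length)."""
    x = np.asarray(x, dtype=float)
    B, N = x.shape
    if N < cfg.base_length:
        raise ValueError(
            f"sequence of {N} samples shorter than base_length "
            f"({cfg.base_length})")
    loc = np.clip(np.asarray(loc, dtype=float).reshape(B), -1.0, 1.0)
    center = (loc + 1.0) / 2.0 * (N - 1)
    out = np.zeros((B, cfg.n_scales, cfg.base_length))
    for s in range(cfg.n_scales):
        w = cfg.base_length * cfg.scale_factor**s
        start = np.floor(center - w / 2.0 + 0.5).astype(int)
        idx = start[:, None] + np.arange(w)[None, :]
        valid = (idx >= 0) & (idx < N)
        vals = np.take_along_axis(x, np.clip(idx, 0, N - 1), axis=1) * valid
        out[:, s, :] = vals.reshape(B, cfg.base_length, -1).mean(axis=2)
    return out


def glimpse(x: np.ndarray, l: float, cfg: GlimpseConfig) -> np.ndarray:
    """Single-sequence glimpse: (N,) -> (n_scales, base_length)."""
    if not -1.0 <= l <= 1.0:
        raise ValueError("location must lie in [-1, 1]")
    return glimpse_batch(np.asarray(x, dtype=float)[None, :],
                         np.array([l]), cfg)[0]
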