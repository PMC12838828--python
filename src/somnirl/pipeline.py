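"""End-to-end feature extraction: recordings -> classifier dataset.

For each recording: band-pass (0.5-70 Hz) and optional notch filtering,
average re-referencing, GFP and GFP-peak candidate maps; microstate
prototypes are fit on the peak maps *pooled across recordings* (one shared
prototype set, so temporal parameters are comparable between recordings and
states), then backfitted per recording.  The recording is cut into
non-overlapping windows and each window yields

* the GFP amplitude sequence (the agent's observation),
* microstate temporal parameters within the window,
* per-channel normalized LZC of the band-filtered window (delta band by
  default),
* the recording's state label.

These become rows of a classification dataset whose columns are the GFP
sequence followed by the static features of the chosen feature set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import preprocess
from .complexity import build_features, epoch_lzc
from .microstates import (MicrostateModel, backfit, fit_microstates, gfp,
                          gfp_peaks, select_n_states, temporal_parameters)
from .recording import Recording


@dataclass(frozen=True)
class PipelineConfig:
    """Feature-extraction configuration.

    ``window_s`` is the analysis window (2 s epochs by default; 256-sample
    windows can be requested via ``window_samples``).  ``n_microstates``
    pins K; ``None`` selects K in 4..10 by maximal GEV.
    """

    band: tuple[float, float] = (0.5, 70.0)
    notch_hz: float | None = 50.0
    reref: str = "common_average"
    window_s: float | None = 2.0
    window_samples: int | None = None
    lzc_band: str = "delta"
    n_microstates: int | None = 4
    n_init: int = 10
    max_iter: int = 500
    min_duration_ms: float = 20.0
    peak_separation_ms: float = 10.0
    max_peak_maps: int = 4000
    feature_set: str = "mean_gfp+lzc"

    def window_len(self, fs: float) -> int:
        if self.window_samples is not None:
            return int(self.window_samples)
        return int(round((self.window_s or 2.0) * fs))


def preprocess_recording(rec: Recording, cfg: PipelineConfig) -> Recording:
    out = preprocess.bandpass(rec, *cfg.band)
    if cfg.notch_hz is not None and cfg.notch_hz < rec.fs / 2:
        out = preprocess.notch(out, cfg.notch_hz)
    if cfg.reref is not None:
        out = preprocess.rereference(out, cfg.reref)
    return out


def fit_shared_microstates(recordings: list[Recording], cfg: PipelineConfig,
                           seed: int = 0) -> MicrostateModel:
    """Fit one prototype set on GFP-peak maps pooled over recordings."""
    rng = np.random.default_rng(seed)
    maps = []
    gfps = []
    for rec in recordings:
        series = gfp(rec.data, rec.fs)
        peaks = gfp_peaks(series, cfg.peak_separation_ms)
        maps.append(rec.data[:, peaks].T)
        gfps.append(series.values[peaks])
    maps = np.concatenate(maps, axis=0)
    gfps = np.concatenate(gfps)
    if len(maps) > cfg.max_peak_maps:
        keep = rng.choice(len(maps), size=cfg.max_peak_maps, replace=False)
        maps, gfps = maps[keep], gfps[keep]
    if cfg.n_microstates is not None:
        return fit_microstates(maps, cfg.n_microstates, n_init=cfg.n_init,
                               max_iter=cfg.max_iter, seed=seed,
                               gfp_at_maps=gfps)
    return select_n_states(maps, n_init=cfg.n_init, max_iter=cfg.max_iter,
                           seed=seed, gfp_at_maps=gfps)


@dataclass(frozen=True)
class WindowFeatures:
    """Per-window outputs of the extraction stage."""

    gfp_sequence: np.ndarray
    static: np.ndarray
    static_names: tuple[str, ...]
    label: str | None
    rec_id: str | None
    window_index: int


def extract_window_features(rec: Recording, model: MicrostateModel,
                            cfg: PipelineConfig) -> list[WindowFeatures]:
    """Slice one preprocessed recording into windows of features."""
    L = cfg.window_len(rec.fs)
    series = gfp(rec.data, rec.fs)
    labels = backfit(model, rec.data, rec.fs, cfg.min_duration_ms)
    band = preprocess.DEFAULT_BANDS[cfg.lzc_band]
    banded = preprocess.extract_band(rec, band)
    out = []
    n_windows = rec.n_samples // L
    from .microstates import GFPSeries, LabelSequence
    for w in range(n_windows):
        sl = slice(w * L, (w + 1) * L)
        ms = temporal_parameters(
            LabelSequence(labels.labels[sl], rec.fs, model.n_states,
                          cfg.min_duration_ms),
            GFPSeries(series.values[sl], rec.fs))
        lz = epoch_lzc(banded.data[:, sl])
        epoch_id = f"{rec.rec_id}:{w}"
        fv = build_features(ms, lz, cfg.feature_set, epoch_id=epoch_id,
                            label=rec.state_label)
        out.append(WindowFeatures(
            gfp_sequence=series.values[sl], static=fv.values,
            static_names=fv.names, label=rec.state_label,
            rec_id=rec.rec_id, window_index=w))
    return out


@dataclass(frozen=True)
class ClassificationDataset:
    """Rows = windows; columns = GFP sequence then static features."""

    X: np.ndarray
    y: np.ndarray
    class_names: tuple[str, ...]
    n_static: int
    seq_len: int
    static_names: tuple[str, ...] = ()
    rec_ids: tuple[str, ...] = ()
    model: MicrostateModel | None = None
    config: PipelineConfig = field(default_factory=PipelineConfig)


def build_dataset(recordings: list[Recording],
                  cfg: PipelineConfig | None = None,
                  seed: int = 0) -> ClassificationDataset:
    """Full extraction over a list of labeled recordings."""
    cfg = cfg or PipelineConfig()
    pre = [preprocess_recording(r, cfg) for r in recordings]
    model = fit_shared_microstates(pre, cfg, seed=seed)
    windows: list[WindowFeatures] = []
    for rec in pre:
        windows.extend(extract_window_features(rec, model, cfg))
    labels = sorted({w.label for w in windows if w.label is not None})
    if not labels:
        raise ValueError("recordings carry no state labels")
    X = np.stack([np.concatenate([w.gfp_sequence, w.static])
                  for w in windows])
    y = np.array([w.label for w in windows])
    return ClassificationDataset(
        X=X, y=y, class_names=tuple(labels),
        n_static=len(windows[0].static),
        seq_len=len(windows[0].gfp_sequence),
        static_names=windows[0].static_names,
        rec_ids=tuple(w.rec_id or "" for w in windows),
        model=model, config=cfg)


def features_table(windows: list[WindowFeatures]):
    """Window features as a pandas DataFrame (one row per window)."""
    import pandas as pd
    rows = []
    for w in windows:
        row = {"rec_id": w.rec_id, "window": w.window_index, "label": w.label}
        row.update(dict(zip(w.static_names, w.static)))
        rows.append(row)
    return pd.DataFrame(rows)
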