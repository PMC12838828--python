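"""Experiment harnesses: channel-subset and window-length grids.

Both retrain the classifier from scratch per grid cell on features
re-extracted under that cell's condition, and evaluate on a held-out split,
mirroring the montage-reduction and window-length analyses of sleep-state
classification studies.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .pipeline import ClassificationDataset, PipelineConfig, build_dataset
from .recording import Recording
from .rl.evaluation import EvalReport, evaluate
from .rl.training import GlimpseAgentClassifier

#: Default montage subsets by size, frontally/centrally weighted for the
#: smaller montages (the regions most informative for sleep states).
DEFAULT_CHANNEL_SUBSETS: dict[int, tuple[str, ...]] = {
    19: ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
         "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2"),
    13: ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
         "C4", "T4", "Pz"),
    12: ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
         "C4", "T4"),
    10: ("Fp1", "Fp2", "F3", "Fz", "F4", "C3", "Cz", "C4", "T3", "T4"),
    7: ("Fp1", "Fp2", "Fz", "C3", "Cz", "C4", "Pz"),
    2: ("C3", "C4"),
}

#: Default window lengths in seconds for the window-length grid.
DEFAULT_WINDOW_LENGTHS_S = (1.0, 5.0, 10.0, 20.0, 30.0, 40.0)


def _train_eval(ds: ClassificationDataset, clf_params: dict,
                test_fraction: float, seed: int) -> EvalReport:
    rng = np.random.default_rng(seed)
    n = len(ds.y)
    order = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    test, tr = order[:n_test], order[n_test:]
    params = dict(clf_params)
    params.setdefault("random_state", seed)
    clf = GlimpseAgentClassifier(n_static_features=ds.n_static, **params)
    clf.fit(ds.X[tr], ds.y[tr])
    return evaluate(clf, ds.X[test], ds.y[test])


def restrict_channels(rec: Recording, channels: tuple[str, ...]) -> Recording:
    unknown = [c for c in channels if c not in rec.channel_labels]
    if unknown:
        raise ValueError(f"unknown channel labels {unknown}; "
                         f"available: {rec.channel_labels}")
    idx = [rec.channel_labels.index(c) for c in channels]
    return Recording(
        data=rec.data[idx], fs=rec.fs, channel_labels=list(channels),
        state_label=rec.state_label,
        true_label_sequence=rec.true_label_sequence,
        seed=rec.seed, rec_id=rec.rec_id)


def channel_subset_experiment(recordings: list[Recording],
                              subsets: dict[int, tuple[str, ...]] | None = None,
                              pipeline_cfg: PipelineConfig | None = None,
                              clf_params: dict | None = None,
                              test_fraction: float = 0.25,
                              seed: int = 0) -> dict[int, EvalReport]:
    """Retrain + evaluate per channel subset; keyed by subset size."""
    subsets = subsets or DEFAULT_CHANNEL_SUBSETS
    results: dict[int, EvalReport] = {}
    for size, channels in subsets.items():
        subset_recs = [restrict_channels(r, tuple(channels))
                       for r in recordings]
        ds = build_dataset(subset_recs, pipeline_cfg, seed=seed)
        report = _train_eval(ds, clf_params or {}, test_fraction, seed)
        report.metadata.update(subset_size=size, channels=tuple(channels))
        results[size] = report
    return results


def window_length_experiment(recordings: list[Recording],
                             lengths_s: tuple[float, ...] = DEFAULT_WINDOW_LENGTHS_S,
                             pipeline_cfg: PipelineConfig | None = None,
                             clf_params: dict | None = None,
                             test_fraction: float = 0.25,
                             seed: int = 0) -> dict[float, EvalReport]:
    """Re-extract features at each window length, retrain and evaluate."""
    base = pipeline_cfg or PipelineConfig()
    shortest = min(r.duration_s for r in recordings)
    results: dict[float, EvalReport] = {}
    for length in lengths_s:
        if length > shortest:
            raise ValueError(
                f"window of {length} s exceeds the shortest recording "
                f"({shortest:.1f} s)")
        cfg = replace(base, window_s=float(length), window_samples=None)
        ds = build_dataset(recordings, cfg, seed=seed)
        report = _train_eval(ds, clf_params or {}, test_fraction, seed)
        report.metadata.update(window_s=float(length))
        results[float(length)] = report
    return results
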