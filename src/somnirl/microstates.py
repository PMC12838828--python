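"""EEG microstate analysis.

The scalp potential field is modeled as a sequence of K quasi-stable
prototype topographies.  The analysis follows the standard four stages:

1. global field power (GFP) — the spatial standard deviation across
   electrodes at each sample, ``GFP_t = sqrt(sum_i (x_it - xbar_t)^2 / N)``;
2. candidate extraction — topographies at local GFP maxima, where the
   signal-to-noise of the field is highest;
3. clustering — a *modified* (polarity-invariant) k-means: samples are
   assigned by maximal squared spatial correlation ignoring sign, and each
   prototype is updated as the dominant spatial eigenvector of its assigned
   maps.  Model selection over K uses the global explained variance (GEV),
   the GFP^2-weighted mean squared correlation between each map and its
   prototype;
4. backfitting and temporal parameters — every sample is labeled with its
   best prototype, short segments are absorbed by their better-correlated
   neighbor, and per-state duration / occurrence / coverage / mean GFP and
   the segment-level transition matrix are computed.

All correlations are spatial Pearson correlations, i.e. cosines of
average-referenced, unit-normalized maps; the polarity of a map is ignored
throughout, which is the defining convention of microstate analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# GFP

@dataclass(frozen=True)
class GFPSeries:
    """Per-sample global field power (uV) at sampling rate ``fs``."""

    values: np.ndarray
    fs: float


def gfp(epoch: np.ndarray, fs: float = 1.0) -> GFPSeries:
    """Global field power of a channels x samples array.

    GFP is the instantaneous standard deviation of the potential across the
    N electrodes (population convention, divisor N).
    """
    x = np.asarray(epoch, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("GFP needs a 2-D array with at least 2 channels")
    centered = x - x.mean(axis=0, keepdims=True)
    return GFPSeries(np.sqrt(np.mean(centered**2, axis=0)), fs)


def gfp_peaks(series: GFPSeries, min_separation_ms: float = 0.0) -> np.ndarray:
    """Indices of strict local GFP maxima, thinned to a minimal separation.

    Peaks closer than ``min_separation_ms`` are greedily thinned keeping the
    larger peak (descending-height pass).
    """
    v = series.values
    if v.size < 3:
        raise ValueError("need at least 3 samples to find interior maxima")
    interior = np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])) + 1
    if min_separation_ms <= 0 or interior.size == 0:
        return interior
    min_sep = int(np.ceil(min_separation_ms / 1000.0 * series.fs))
    order = interior[np.argsort(v[interior])[::-1]]
    blocked = np.zeros(v.size, dtype=bool)
    kept: list[int] = []
    for idx in order:
        if not blocked[idx]:
            kept.append(int(idx))
            blocked[max(0, idx - min_sep + 1):idx + min_sep] = True
    return np.array(sorted(kept), dtype=int)


# --------------------------------------------------------------------------
# helpers

def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Average-reference and unit-normalize each row; zero rows stay zero."""
    m = np.asarray(maps, dtype=float)
    m = m - m.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return m / norms


def _spatial_corr(maps: np.ndarray, prototypes: np.ndarray) -> np.ndarray:
    """(P x K) spatial correlations between normalized maps and prototypes."""
    return _normalize_maps(maps) @ _normalize_maps(prototypes).T


# --------------------------------------------------------------------------
# modified k-means

class ModifiedKMeans(BaseEstimator):
    """Polarity-invariant k-means over topographic maps.

    Scikit-learn style estimator: ``fit(X)`` on a (n_maps x n_channels)
    array of candidate topographies (typically GFP-peak maps).  Assignment
    maximizes the *squared* spatial correlation, so a map and its negative
    are equivalent; the prototype of a cluster is the dominant eigenvector
    of the summed outer products of its maps (equivalently the leading right
    singular vector of the stacked maps).

    Parameters
    ----------
    n_states : int
        Number of prototypes K.
    n_init : int
        Random restarts; the fit with maximal GEV is kept.
    max_iter : int
        Iteration cap per restart.
    tol : float
        Convergence threshold on the relative GEV change (the loop also
        stops as soon as assignments stabilize).
    random_state : int or None
        Seed for restart initialization.

    Attributes
    ----------
    prototypes_ : ndarray (n_states x n_channels)
        Zero-mean, unit-norm prototype maps.
    gev_ : float
        Global explained variance of the kept restart.
    labels_ : ndarray (n_maps,)
        Cluster index of each training map.
    gev_history_ : list of float
        GEV per iteration of the kept restart.
    n_iter_ : int
        Iterations run by the kept restart.
    """

    def __init__(self, n_states: int = 4, n_init: int = 10,
                 max_iter: int = 500, tol: float = 1e-6,
                 random_state: int | None = None):
        self.n_states = n_states
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None, sample_weight: np.ndarray | None = None):
        """Cluster candidate maps; ``sample_weight`` defaults to GFP^2 = 1."""
        maps = _normalize_maps(X)
        P, C = maps.shape
        K = self.n_states
        if not 2 <= K <= P:
            raise ValueError(f"need 2 <= n_states ({K}) <= n_maps ({P})")
        w = (np.ones(P) if sample_weight is None
             else np.asarray(sample_weight, dtype=float))
        if w.shape != (P,) or np.any(w < 0):
            raise ValueError("sample_weight must be non-negative, length n_maps")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_init):
            protos, labels, history = self._fit_once(maps, w, rng)
            gev_val = history[-1]
            if best is None or gev_val > best[0]:
                best = (gev_val, protos, labels, history)
        self.gev_, self.prototypes_, self.labels_, self.gev_history_ = (
            best[0], best[1], best[2], list(best[3]))
        self.n_iter_ = len(self.gev_history_)
        return self

    def _fit_once(self, maps, w, rng):
        P, C = maps.shape
        K = self.n_states
        protos = maps[rng.choice(P, size=K, replace=False)].copy()
        labels = np.full(P, -1)
        history: list[float] = []
        total_w = w.sum()
        for _ in range(self.max_iter):
            corr = maps @ protos.T
            new_labels = np.argmax(corr**2, axis=1)
            # empty clusters are re-seeded from the currently worst-fit map,
            # never stealing the last member of another cluster
            fit_quality = corr[np.arange(P), new_labels] ** 2
            for k in range(K):
                if not np.any(new_labels == k):
                    counts = np.bincount(new_labels, minlength=K)
                    donors = counts[new_labels] > 1
                    order = np.argsort(fit_quality)
                    worst = int(next(i for i in order if donors[i]))
                    logger.info("re-seeding empty microstate cluster %d", k)
                    protos[k] = maps[worst]
                    new_labels[worst] = k
                    fit_quality[worst] = 1.0
            for k in range(K):
                members = np.flatnonzero(new_labels == k)
                sub = maps[members] * np.sqrt(w[members])[:, None]
                # dominant spatial eigenvector (sign-invariant mean map)
                _, _, vt = np.linalg.svd(sub, full_matrices=False)
                proto = vt[0]
                proto = proto - proto.mean()
                n = np.linalg.norm(proto)
                protos[k] = proto / n if n > 0 else proto
            corr = maps @ _normalize_maps(protos).T
            assigned = corr[np.arange(P), new_labels] ** 2
            gev_val = float(np.sum(w * assigned) / total_w) if total_w > 0 else 0.0
            stalled = bool(history) and (abs(gev_val - history[-1])
                                         <= self.tol * max(history[-1], 1e-12))
            converged = np.array_equal(new_labels, labels) or stalled
            labels = new_labels
            history.append(gev_val)
            if converged:
                break
        return _normalize_maps(protos), labels, history


@dataclass
class MicrostateModel:
    """Fitted prototype set with its global explained variance."""

    prototypes: np.ndarray
    gev: float
    n_init: int
    max_iter: int
    seed: int | None
    gev_history: list[float] = field(default_factory=list)
    gev_table: dict[int, float] = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return self.prototypes.shape[0]


def fit_microstates(maps: np.ndarray, n_states: int, n_init: int = 10,
                    max_iter: int = 500, seed: int | None = None,
                    gfp_at_maps: np.ndarray | None = None) -> MicrostateModel:
    """Fit K microstate prototypes to candidate maps (functional wrapper).

    ``gfp_at_maps`` supplies GFP^2 sample weights for the GEV objective;
    unweighted by default (normalized peak maps).
    """
    est = ModifiedKMeans(n_states=n_states, n_init=n_init,
                         max_iter=max_iter, random_state=seed)
    weight = None if gfp_at_maps is None else np.asarray(gfp_at_maps) ** 2
    est.fit(maps, sample_weight=weight)
    return MicrostateModel(
        prototypes=est.prototypes_, gev=est.gev_, n_init=n_init,
        max_iter=max_iter, seed=seed, gev_history=est.gev_history_)


def gev(model: MicrostateModel, maps: np.ndarray,
        gfp_at_maps: np.ndarray) -> float:
    """Global explained variance of ``maps`` under a fitted model.

    GFP^2-weighted mean of the squared spatial correlation between each map
    and its best (polarity-ignored) prototype.
    """
    g = np.asarray(gfp_at_maps, dtype=float)
    total = np.sum(g**2)
    if total <= 0:
        raise ValueError("total GFP is zero; GEV undefined")
    corr = _spatial_corr(maps, model.prototypes)
    best = np.max(corr**2, axis=1)
    return float(np.sum(g**2 * best) / total)


def select_n_states(maps: np.ndarray, k_range: range | list[int] | None = None,
                    n_init: int = 10, max_iter: int = 500,
                    seed: int | None = None,
                    gfp_at_maps: np.ndarray | None = None) -> MicrostateModel:
    """Fit every K in ``k_range`` (default 4..10), keep the maximal-GEV model.

    The full GEV-versus-K table is retained on the returned model.  Note
    that GEV typically increases with K, so the max-GEV rule tends to pick
    the top of the range; pin K by passing a single-element range.
    """
    ks = list(k_range) if k_range is not None else list(range(4, 11))
    P = np.asarray(maps).shape[0]
    if any(k < 2 or k > min(10, P) for k in ks):
        raise ValueError(f"k_range must lie within [2, {min(10, P)}]")
    table: dict[int, float] = {}
    best: MicrostateModel | None = None
    for k in ks:
        model = fit_microstates(maps, k, n_init=n_init, max_iter=max_iter,
                                seed=seed, gfp_at_maps=gfp_at_maps)
        table[k] = model.gev
        if best is None or model.gev > best.gev:
            best = model
    assert best is not None
    best.gev_table = table
    return best


# --------------------------------------------------------------------------
# backfitting and temporal parameters

@dataclass(frozen=True)
class LabelSequence:
    """Per-sample microstate labels at sampling rate ``fs``."""

    labels: np.ndarray
    fs: float
    n_states: int
    min_duration_ms: float = 0.0


def _segments(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Runs of equal labels as (state, start, length)."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((int(labels[start]), start, i - start))
            start = i
    return out


def backfit(model: MicrostateModel, epoch: np.ndarray, fs: float,
            min_duration_ms: float = 20.0) -> LabelSequence:
    """Assign every sample to its best prototype; absorb short segments.

    Assignment is by maximal squared spatial correlation (ties break to the
    lowest prototype index).  Segments shorter than ``min_duration_ms`` are
    relabeled to whichever neighboring state correlates better with their
    samples, scanning left to right and re-examining merged segments until
    none remain (deterministic).
    """
    x = np.asarray(epoch, dtype=float)
    if x.shape[0] != model.prototypes.shape[1]:
        raise ValueError("channel count does not match the fitted model")
    corr = _spatial_corr(x.T, model.prototypes) ** 2
    labels = np.argmax(corr, axis=1)
    min_len = int(np.ceil(min_duration_ms / 1000.0 * fs))
    if min_len > 1:
        segs = [[s, a, n] for s, a, n in _segments(labels)]
        i = 0
        while len(segs) > 1 and i < len(segs):
            state, start, length = segs[i]
            if length >= min_len:
                i += 1
                continue
            left = segs[i - 1][0] if i > 0 else None
            right = segs[i + 1][0] if i < len(segs) - 1 else None
            sl = slice(start, start + length)
            if left is None:
                target = right
            elif right is None:
                target = left
            else:
                target = (left if corr[sl, left].mean() >= corr[sl, right].mean()
                          else right)
            segs[i][0] = target
            # merge with equal-label neighbors, then re-examine the result
            if i + 1 < len(segs) and segs[i + 1][0] == target:
                segs[i][2] += segs[i + 1][2]
                del segs[i + 1]
            if i > 0 and segs[i - 1][0] == target:
                segs[i - 1][2] += segs[i][2]
                del segs[i]
                i -= 1
        for state, start, length in segs:
            labels[start:start + length] = state
    return LabelSequence(labels=labels, fs=fs, n_states=model.n_states,
                         min_duration_ms=min_duration_ms)


@dataclass(frozen=True)
class MicrostateFeatures:
    """Per-state temporal parameters and the segment transition matrix.

    ``duration_ms[k]`` is the mean contiguous segment length of state k,
    ``occurrence_per_s[k]`` its segment count per second of data,
    ``coverage[k]`` its fraction of samples, ``mean_gfp[k]`` the mean GFP
    over its samples.  States that never occur get zeros (and are listed in
    ``absent_states``).  ``transition[i, j]`` is the probability that a
    segment of state i is followed by one of state j (self-transitions are
    structurally zero); rows of states with no observed successor are zero.
    """

    duration_ms: np.ndarray
    occurrence_per_s: np.ndarray
    coverage: np.ndarray
    mean_gfp: np.ndarray
    transition: np.ndarray
    absent_states: tuple[int, ...] = ()

    @property
    def n_states(self) -> int:
        return len(self.coverage)


def transition_matrix(labels: LabelSequence | np.ndarray,
                      n_states: int | None = None) -> np.ndarray:
    """Segment-level transition probabilities P(next=j | current=i)."""
    if isinstance(labels, LabelSequence):
        arr, K = labels.labels, labels.n_states
    else:
        arr = np.asarray(labels, dtype=int)
        K = n_states if n_states is not None else int(arr.max()) + 1
    segs = _segments(arr)
    if len(segs) < 2:
        raise ValueError("need at least 2 segments for a transition matrix")
    counts = np.zeros((K, K))
    for (a, _, _), (b, _, _) in zip(segs[:-1], segs[1:]):
        counts[a, b] += 1
    rows = counts.sum(axis=1, keepdims=True)
    T = np.divide(counts, rows, out=np.zeros_like(counts), where=rows > 0)
    return T


def temporal_parameters(labels: LabelSequence,
                        gfp_series: GFPSeries) -> MicrostateFeatures:
    """Duration, occurrence, coverage and mean GFP per microstate."""
    arr = labels.labels
    if len(arr) != len(gfp_series.values):
        raise ValueError("label sequence and GFP series differ in length")
    K = labels.n_states
    fs = labels.fs
    total_s = len(arr) / fs
    segs = _segments(arr)
    duration = np.zeros(K)
    occurrence = np.zeros(K)
    coverage = np.zeros(K)
    mean_g = np.zeros(K)
    absent = []
    for k in range(K):
        lens = [s[2] for s in segs if s[0] == k]
        mask = arr == k
        if not lens:
            absent.append(k)
            logger.info("microstate %d absent from the label sequence", k)
            continue
        duration[k] = np.mean(lens) / fs * 1000.0
        occurrence[k] = len(lens) / total_s
        coverage[k] = mask.mean()
        mean_g[k] = gfp_series.values[mask].mean()
    try:
        T = transition_matrix(labels)
    except ValueError:
        T = np.zeros((K, K))
    return MicrostateFeatures(
        duration_ms=duration, occurrence_per_s=occurrence, coverage=coverage,
        mean_gfp=mean_g, transition=T, absent_states=tuple(absent))
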