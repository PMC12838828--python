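"""Seeded generator of labeled multichannel EEG with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: scalp potentials are a sequence of quasi-stable topographic
microstates (dwell times ~60-120 ms) whose source signals are band-shaped
noise with state-dependent band gains, plus white sensor noise.  Every
recording carries its true per-sample microstate sequence so segmentation,
temporal parameters and complexity measures can be validated against ground
truth.

The four default conditions mirror a sleep/auditory-stimulation protocol:

``EO``
    eyes-open wake - dominant alpha (strongest over a posterior-weighted
    montage in real data; spatial structure here is statistical only).
``EC``
    eyes-closed NREM onset - dominant delta, reduced alpha, low complexity.
``REM_stim``
    REM sleep during auditory stimulation - elevated delta and alpha and the
    highest broadband irregularity (complexity).
``REM_nostim``
    REM sleep without stimulation - mixed low-amplitude theta/delta,
    intermediate complexity.

``complexity_knob`` is the fraction of broadband (unfiltered) white noise
mixed into each microstate's source signal; it gives monotone control over
the Lempel-Ziv complexity of the resulting signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

from .preprocess import BAND_NAMES, DEFAULT_BANDS
from .recording import MONTAGE_10_20, STATE_NAMES, Recording

_DWELL_FLOOR_MS = 20.0


@dataclass(frozen=True)
class TopographySet:
    """K prototype scalp maps (K x C), zero-mean and unit-norm per map."""

    maps: np.ndarray
    channel_labels: list[str]
    seed: int

    @property
    def n_states(self) -> int:
        return self.maps.shape[0]


@dataclass(frozen=True)
class StateSpec:
    """Generative description of one sleep state.

    Parameters
    ----------
    state_name : str
        One of EO / EC / REM_stim / REM_nostim (free-form allowed).
    band_gains : dict
        Per-band (delta/theta/alpha/beta/gamma) amplitude multipliers, >= 0.
    ms_duration_ms : (mean, jitter)
        Mean and s.d. of the truncated-normal microstate dwell time;
        mean must lie in [20, 500] ms.
    ms_transition : ndarray (K x K), optional
        Row-stochastic segment-to-segment transition matrix; ``None`` means
        uniform over the other states (no self-transitions).
    noise_sd : float
        White sensor-noise scale (same units as the unit-variance sources).
    complexity_knob : float in [0, 1]
        Fraction of broadband noise mixed into the sources.
    """

    state_name: str
    band_gains: dict[str, float]
    ms_duration_ms: tuple[float, float] = (90.0, 20.0)
    ms_transition: np.ndarray | None = None
    noise_sd: float = 0.3
    complexity_knob: float = 0.3

    def __post_init__(self) -> None:
        for name, g in self.band_gains.items():
            if name not in BAND_NAMES:
                raise ValueError(f"unknown band {name!r}")
            if g < 0:
                raise ValueError("band gains must be non-negative")
        mean, _jitter = self.ms_duration_ms
        if not (_DWELL_FLOOR_MS <= mean <= 500.0):
            raise ValueError("dwell mean must lie in [20, 500] ms")
        if not 0.0 <= self.complexity_knob <= 1.0:
            raise ValueError("complexity_knob must lie in [0, 1]")
        if self.ms_transition is not None:
            P = np.asarray(self.ms_transition, dtype=float)
            if P.ndim != 2 or P.shape[0] != P.shape[1]:
                raise ValueError("ms_transition must be square")
            if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError("ms_transition rows must sum to 1")
            object.__setattr__(self, "ms_transition", P)


def default_state_specs() -> dict[str, StateSpec]:
    """The four study conditions with their generative parameters.

    Band gains follow the qualitative spectral contrasts of the conditions
    (alpha maximal in EO; delta dominant in EC; delta and alpha both elevated
    under REM stimulation; low-amplitude mixed activity in unstimulated REM),
    and the complexity knob is ordered EC < REM_nostim < EO < REM_stim to
    match the observed ordering of signal irregularity.
    """
    return {
        "EO": StateSpec(
            "EO",
            {"delta": 1.0, "theta": 0.5, "alpha": 2.5, "beta": 0.8, "gamma": 0.3},
            complexity_knob=0.45,
        ),
        "EC": StateSpec(
            "EC",
            {"delta": 2.5, "theta": 1.0, "alpha": 1.0, "beta": 0.5, "gamma": 0.2},
            complexity_knob=0.15,
        ),
        "REM_stim": StateSpec(
            "REM_stim",
            {"delta": 3.0, "theta": 1.5, "alpha": 1.8, "beta": 0.8, "gamma": 0.5},
            complexity_knob=0.70,
        ),
        "REM_nostim": StateSpec(
            "REM_nostim",
            {"delta": 1.5, "theta": 1.5, "alpha": 0.8, "beta": 0.6, "gamma": 0.3},
            complexity_knob=0.30,
        ),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Master configuration for :func:`make_dataset`."""

    n_states: int = 4
    fs: float = 250.0
    duration_s: float = 60.0
    channel_labels: list[str] = field(default_factory=lambda: list(MONTAGE_10_20))
    corr_cap: float = 0.5
    state_specs: dict[str, StateSpec] = field(default_factory=default_state_specs)


def make_topographies(n_states: int, channel_labels: list[str] | None = None,
                      corr_cap: float = 0.5, seed: int = 0,
                      max_tries: int = 2000) -> TopographySet:
    """Sample prototype topographies with bounded pairwise correlation.

    Maps are drawn i.i.d. Gaussian, average-referenced (zero mean across
    channels) and unit-normalized; a candidate is rejected when its absolute
    spatial correlation with any accepted map exceeds ``corr_cap``.
    """
    if channel_labels is None:
        channel_labels = list(MONTAGE_10_20)
    if not 2 <= n_states <= 10:
        raise ValueError("n_states must lie in [2, 10]")
    if len(channel_labels) < 4:
        raise ValueError("need at least 4 channels")
    rng = np.random.default_rng(seed)
    C = len(channel_labels)
    maps: list[np.ndarray] = []
    tries = 0
    while len(maps) < n_states:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not sample {n_states} maps with pairwise |corr| <= "
                f"{corr_cap} in {max_tries} draws; raise corr_cap"
            )
        tries += 1
        m = rng.standard_normal(C)
        m -= m.mean()
        m /= np.linalg.norm(m)
        if all(abs(m @ other) <= corr_cap for other in maps):
            maps.append(m)
    return TopographySet(np.stack(maps), list(channel_labels), seed)


def simulate_label_sequence(spec: StateSpec, n_samples: int, fs: float,
                            seed: int = 0, n_states: int | None = None) -> np.ndarray:
    """Piecewise-constant microstate index sequence.

    Segment dwell times are truncated-normal (mean, jitter) with a 20 ms /
    1-sample floor; successor states follow ``spec.ms_transition`` (uniform
    over the other states when unset).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    if spec.ms_transition is not None:
        P = spec.ms_transition
        K = P.shape[0]
    else:
        if n_states is None:
            raise ValueError("n_states required when spec.ms_transition is None")
        K = n_states
        P = (np.ones((K, K)) - np.eye(K)) / max(K - 1, 1)
    mean_ms, jitter_ms = spec.ms_duration_ms
    floor = max(1, int(round(_DWELL_FLOOR_MS / 1000.0 * fs)))
    labels = np.empty(n_samples, dtype=int)
    state = int(rng.integers(K))
    pos = 0
    while pos < n_samples:
        dur_ms = mean_ms if jitter_ms == 0 else rng.normal(mean_ms, jitter_ms)
        length = max(floor, int(round(dur_ms / 1000.0 * fs)))
        labels[pos:pos + length] = state
        pos += length
        state = int(rng.choice(K, p=P[state]))
    return labels


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                low: float, high: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [low, high] Hz."""
    x = rng.standard_normal(n)
    high = min(high, 0.99 * fs / 2)
    sos = _signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    y = _signal.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def simulate_recording(topo: TopographySet, spec: StateSpec, duration_s: float,
                       fs: float = 250.0, seed: int = 0) -> Recording:
    """Simulate one labeled recording.

    Each microstate k owns a source signal: a gain-weighted sum of
    band-limited noise mixed with a ``complexity_knob`` fraction of broadband
    noise.  The scalp data is ``sum_k map_k (x) source_k(t) * [label==k]``
    plus white sensor noise, so with zero noise each sample's topography is
    exactly (proportional to) the active prototype.
    """
    n = int(round(duration_s * fs))
    if n < 2 * fs:
        raise ValueError("duration must be at least 2 s")
    rng = np.random.default_rng(seed)
    K, C = topo.maps.shape
    labels = simulate_label_sequence(
        spec, n, fs, seed=int(rng.integers(2**31)), n_states=K)
    knob = spec.complexity_knob
    data = np.zeros((C, n))
    for k in range(K):
        shaped = np.zeros(n)
        for name in BAND_NAMES:
            gain = spec.band_gains.get(name, 0.0)
            if gain > 0:
                band = DEFAULT_BANDS[name]
                shaped += gain * _band_noise(
                    rng, n, fs, band.low_hz, band.high_hz)
        broadband = rng.standard_normal(n)
        source = (1.0 - knob) * shaped + knob * broadband
        data += np.outer(topo.maps[k], source * (labels == k))
    if spec.noise_sd > 0:
        data += spec.noise_sd * rng.standard_normal(data.shape)
    return Recording(
        data=data,
        fs=fs,
        channel_labels=list(topo.channel_labels),
        state_label=spec.state_name,
        true_label_sequence=labels,
        seed=seed,
    )


def make_dataset(n_recordings_per_state: int,
                 config: GeneratorConfig | None = None,
                 seed: int = 0) -> list[Recording]:
    """Balanced labeled dataset over the configured states.

    One topography set is shared by all recordings (microstates are a
    property of the head, not the state); per-recording seeds are derived
    reproducibly from the master seed.
    """
    if n_recordings_per_state < 1:
        raise ValueError("n_recordings_per_state must be >= 1")
    cfg = config or GeneratorConfig()
    master = np.random.SeedSequence(seed)
    topo_seed, rec_seed = master.spawn(2)
    topo = make_topographies(
        cfg.n_states, cfg.channel_labels, cfg.corr_cap,
        seed=int(topo_seed.generate_state(1)[0] % (2**31)))
    recordings: list[Recording] = []
    children = rec_seed.spawn(len(cfg.state_specs) * n_recordings_per_state)
    i = 0
    for name, spec in cfg.state_specs.items():
        for j in range(n_recordings_per_state):
            s = int(children[i].generate_state(1)[0] % (2**31))
            rec = simulate_recording(topo, spec, cfg.duration_s, cfg.fs, seed=s)
            recordings.append(replace(rec, rec_id=f"{name}_{j:02d}"))
            i += 1
    return recordings
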