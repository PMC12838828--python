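# Methods

This note documents the models and procedures implemented in `somnirl`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data tests do and do not demonstrate.

## Problem setting

The package analyses multichannel scalp EEG recorded under four conditions —
eyes-open wake (EO), eyes-closed NREM onset (EC), REM sleep with auditory
stimulation (REM_stim), and REM sleep without stimulation (REM_nostim) — and
classifies those states from two families of brain-dynamics features:
microstate temporal parameters and Lempel–Ziv complexity (LZC).  The
classifier is an attention-glimpse agent: a CNN+GRU network that inspects
the global-field-power (GFP) sequence through localized multi-resolution
glimpses and is trained with policy gradients.

## Preprocessing

Signals are band-passed 0.5–70 Hz with a zero-phase (forward–backward)
Butterworth filter of order 4 per pass, notch-filtered at 50 Hz (quality 30)
and re-referenced (common average by default; linked mastoids A1/A2 when
those channels exist).  Zero-phase filtering is used so that microstate
segment boundaries are not shifted in time.  Edge effects are controlled by
even-symmetric reflect padding of about three time constants of the slow
corner (`3·fs/low_hz` samples, capped at the signal length); odd reflection
was measured to leak low-frequency edge transients of ~10% amplitude into
short segments, even reflection keeps stopband leakage below 1%.  Filter
order, notch frequency and quality are configuration entries; the defaults
are stated assumptions, not measurements.

Continuous data are cut into non-overlapping 2 s epochs (configurable length
and overlap; trailing samples that do not fill an epoch are dropped).

## Spectral analysis

Welch power spectral density: modified periodograms
`|Σ_n x(n) w(n) e^{-j2πfn}|² / (M·U)` with a Hamming taper `w`, segment
length `M` of one epoch (so each epoch contributes exactly one
periodogram), no overlap, averaged over `L` segments; one-sided density with
the factor-2 correction off DC and Nyquist, in µV²/Hz.  Band powers are
trapezoidal integrals over delta 0.5–4, theta 4–7, alpha 8–12, beta 13–30
and gamma 30–70 Hz.  The gamma lower edge is a design choice (30 Hz); the
upper edge coincides with the analysis filter corner.

## Microstate analysis

GFP is the per-sample spatial standard deviation across the N electrodes
(population divisor N).  Candidate topographies are taken at strict local
GFP maxima, greedily thinned to a minimal separation (default 10 ms in the
pipeline) keeping the larger peak.

Clustering is the *modified* (polarity-invariant) k-means of microstate
analysis: maps are average-referenced and unit-normalized; assignment
maximizes the squared spatial correlation, so a map and its negation are
equivalent; each prototype is updated as the dominant spatial eigenvector of
its assigned maps (leading right singular vector).  Restarts (default 10)
are scored by global explained variance — the GFP²-weighted mean squared
correlation between each map and its prototype — and the best restart is
kept; iteration stops when assignments stabilize or the relative GEV change
falls below 1e-6 (cap 500).  Empty clusters are re-seeded from the
worst-fit map, never stealing the last member of another cluster.  Model
selection fits K = 4..10 and keeps the maximal-GEV model; because GEV
increases with K almost always, pipelines that need a fixed feature
dimension pin K (default 4, the canonical microstate count).

Backfitting assigns every sample to its best prototype (ties to the lowest
index, deterministically); segments shorter than a minimal duration
(default 20 ms) are absorbed into whichever neighboring state correlates
better with their samples, scanning left to right and re-examining merged
segments until none remain.  Temporal parameters per state: mean segment
duration (ms), occurrence (segments/s), coverage (sample fraction), mean
GFP while active, plus the segment-level transition matrix (self-transitions
structurally zero).  A state that never occurs contributes zeros and is
flagged; a transition row with no observed successor stays all-zero rather
than being invented.

Prototypes may be fit per recording or pooled; the classification pipeline
pools GFP-peak maps across recordings (subsampled to 4000) so that state
identities, and hence feature columns, are comparable between recordings.

## Lempel–Ziv complexity

Per channel: analytic signal (real part the band-filtered signal, imaginary
part its Hilbert transform), instantaneous amplitude = modulus, binarized
against the window median (ties map to 0, deterministically), scored with
the LZ76 exhaustive-history complexity (Kaspar–Schuster linear scan) and
normalized by `log2(n)/n` so lengths are comparable — a random string scores
≈ 1.  The pipeline extracts LZC from the delta band by default, the band
with the strongest state contrasts.  Feature sets pair one microstate
parameter (duration, occurrence, coverage or mean GFP; one value per state)
with, optionally, the per-channel LZC vector ("mean_gfp+lzc" is the
default, K + C columns).

## Statistics

Kolmogorov–Smirnov one-sample normality test with parameters estimated from
the sample (conservative; labeled as such).  Mann–Whitney U with midrank
ties: full enumeration of all C(n, n1) group assignments when
n1+n2 ≤ 20 (two-sided by distance of U from its null mean), otherwise the
normal approximation with tie and continuity corrections.  Effect size
η² = z²/n, clipped to [0, 1].  Significance masks threshold at α (default
0.05) or α/m with Bonferroni correction.

## The attention-glimpse agent

The environment presents one observation sequence per episode (a GFP
amplitude trace, optionally with a static feature vector of microstate
parameters and LZC from the same window).  A glimpse at normalized location
l ∈ [−1, 1] stacks `n_scales` windows (default 3) of lengths
`base_length·scale_factor^k` (default 16·2^k), each average-pooled to
`base_length` — full resolution at the gaze center, coarser peripherally;
out-of-range regions are zero-padded.

Each step the glimpse stack passes through two 1-D convolutions (8 and 16
channels, kernels 5 and 3, ReLU, global average pooling), is concatenated
with the location and static features, embedded (64 units, ReLU, dropout
0.2), and drives a GRU core (hidden size 128).  Three linear heads read the
hidden state: a location head (tanh-squashed mean of an isotropic Gaussian
with fixed σ = 0.1, clipped to [−1, 1]; a categorical head over a fixed
location grid is available and makes small problems exactly enumerable), a
softmax action head over the sleep states, and a scalar value baseline.
Architecture variants: `cnn_gru_rl` (default), `cnn_rl` (memoryless
feed-forward core, tanh), `gru_rl` (flattened glimpse, no convolutions).
None of these sizes is canonical; all are configuration-exposed.

Episodes run T = 6 glimpse steps.  The initial location is sampled from the
location head applied to the zero initial hidden state, so the first gaze is
itself learned.  The per-step reward is 1 for a correct classification and 0
otherwise; the episode return is `R = Σ_t γ^{t-1} r_t` with γ = 0.9, and the
final prediction is the last step's action.

Training maximizes expected return with REINFORCE and a learned baseline:
the estimator is `(1/M) Σ_i Σ_t ∇log π(u_t|s_1:t)·(G_t − b(s_t))`, where
u_t is the joint (location, action) whose log-probabilities add, G_t is the
discounted reward-to-go, and b is the value head regressed to G_t by squared
error on a *detached* hidden state — the baseline loss cannot perturb the
policy pathway, which keeps the estimator exactly unbiased (verified against
finite differences on an enumerable toy to ~1e-9 relative error).  The
gradient of the location log-density is evaluated at the pre-clip sample.
The last location of an episode influences nothing and is excluded from the
loss.  The per-step weighting omits the additional γ^{t-1} factor of the
strictly discounted objective, the common convention.  ε-greedy exploration
applies to the class action only (not locations), annealed 1.0 → 0.1 over
1000 episodes; gradients use the policy's own log-probability for the taken
action, the usual (slightly biased under exploration) practice.  Optimizer:
Adam at 1e-3, batch 128 episodes, up to 500 epochs with early stopping
(patience 20) on validation reward; 75% of the data trains, the rest
validates; one master seed fans out to the split, the initialization and
all sampling.  The classifier standardizes sequences by their global
standard deviation and static features per column (fitted attributes).

Evaluation is deterministic: mean locations, greedy actions.  Metrics are
one-vs-rest per class: ACC = (TP+TN)/total, PPV = TP/(TP+FP),
NPV = TN/(TN+FN); undefined ratios are reported as missing, never as 0.

The whole agent is NumPy (float64) with hand-written backpropagation
(im2col convolutions, GRU backprop-through-time, Adam), which keeps the
gradient estimator exactly checkable and trains the default sizes on one
CPU in seconds.

## Synthetic EEG generator

Recordings are sums over K = 4 prototype topographies (zero-mean, unit-norm
random maps with pairwise |correlation| ≤ 0.5, shared across a dataset) of
gated source signals, plus white sensor noise (default s.d. 0.3).  The
microstate label sequence is piecewise constant with truncated-normal dwell
times (mean 90 ms, jitter 20 ms, floor 20 ms — inside the 60–120 ms range
typical of microstates) and uniform off-diagonal transitions.  Each state's
source is a gain-weighted sum of unit-variance band-limited noise
(delta/theta/alpha/beta/gamma), mixed with a `complexity_knob` fraction of
broadband white noise.  The four default state specifications encode the
qualitative contrasts of the conditions: alpha maximal in EO, delta dominant
in EC, delta and alpha both elevated in REM_stim, low-amplitude mixed
theta/delta in REM_nostim, with complexity ordered
EC (0.15) < REM_nostim (0.30) < EO (0.45) < REM_stim (0.70).

The generator gives exact ground truth: with zero sensor noise every
sample's topography is proportional to the active prototype, so
segmentation can be validated sample-by-sample.  What it does **not**
emulate: volume-conduction physics (maps are statistical, not dipolar),
artifacts (blinks, muscle, electrode drift), non-stationarity across a
night, spindles/K-complexes, and inter-subject variability.  Passing tests
on this generator therefore demonstrate correctness of the algorithms under
their own model assumptions, not clinical performance on real
polysomnography.

The knob-to-LZC monotonicity is measured on the broadband signal: after
narrow band-pass filtering (e.g. delta), both the structured and the
broadband source components reduce to in-band Gaussian noise and the knob is
nearly unidentifiable, so the broadband measurement is the honest readout of
what the knob controls.

## Problem sizes used in the checks

The automated checks run at desk scale on one CPU: the oracle comparisons
use 1000 random strings (LZ76) and exhaustive enumeration of a
2-location/2-class/1-step toy (policy gradient); learnability uses 256
training sequences; the end-to-end run uses 5 recordings per state of 60 s
at 250 Hz; statistical calibration uses 2000 null replicates.  Cohort-scale accuracies from overnight
recordings are out of scope — the study data behind them are private.

## Known limitations

* The max-GEV rule over K = 4..10 nearly always selects the top of the
  range on real-like data; pinning K is the practical choice for fixed
  feature dimensions, and the GEV-vs-K table is always retained.
* ε-greedy REINFORCE is slightly off-policy during exploration; the
  estimator is exactly unbiased only at ε = 0 (where it is verified).
* The Mann–Whitney exact path enumerates C(n, n1) assignments and is capped
  at n1+n2 ≤ 20 by default.
* EDF files can be read (via `mne`, optional extra) but are written only as
  delimited text + JSON sidecar.
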