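# somnirl

EEG sleep-state analysis with microstates, Lempel–Ziv complexity, and an
attention-glimpse CNN+GRU agent trained by policy-gradient reinforcement
learning.

## The problem

Sleep unfolds as a sequence of brain states — eyes-open wake (EO),
eyes-closed NREM onset (EC), and REM sleep with or without auditory
stimulation — each with a distinct spectral and dynamical signature.
`somnirl` is for researchers who want to classify these states from
multichannel scalp EEG using *dynamical* features rather than raw spectra:

* **Microstates** — the scalp potential field dwells in quasi-stable
  topographies for ~60–120 ms before switching.  With GFP the global field
  power (the spatial s.d. across the N electrodes,
  `GFP_t = √(Σ_i (x_it − x̄_t)²/N)`), candidate maps at GFP peaks are
  clustered by polarity-invariant ("modified") k-means; the number of
  classes K is selected by the global explained variance (GEV), the
  GFP²-weighted mean squared spatial correlation between each map and its
  prototype.  Backfitting labels every sample, yielding per-state duration,
  occurrence, coverage, mean GFP and the transition matrix.
* **Lempel–Ziv complexity (LZC)** — per channel, the instantaneous
  amplitude of the analytic (Hilbert) signal is binarized at the window
  median and scored with the LZ76 exhaustive-history complexity,
  normalized by `log₂(n)/n`.
* **The classifier** — a recurrent attention agent.  At each step t the
  agent observes the GFP sequence x through a multi-scale glimpse
  `MuS_t = F(x, l_{t−1})` centered at a location it chose itself, updates a
  CNN+GRU hidden state `h_t = f(h_{t−1}, MuS_t)`, and samples a location
  `l_t` and a class action `a_t` from distributions parameterized by
  `h_t`.  The reward is `r_t = 1` for a correct classification; training
  maximizes `E[Σ_t γ^{t−1} r_t]` by REINFORCE with a learned value
  baseline, `∇J ≈ (1/M) Σ_i Σ_t ∇log π(u_t|s_1:t)·(G_t − b(s_t))`, with
  Adam, ε-greedy exploration annealed 1.0 → 0.1, γ = 0.9.

A seeded synthetic-EEG generator produces 19-channel 10–20-montage
recordings with known microstate ground truth, state-dependent band power
and controllable signal complexity, so every stage is testable without
private sleep recordings.  A statistics module (KS normality, exact
Mann–Whitney U with η² effect sizes, Bonferroni masks) supports feature
selection between states.

## Worked example

```python
import numpy as np
from somnirl import (GeneratorConfig, PipelineConfig, GlimpseAgentClassifier,
                     make_dataset, build_dataset, evaluate)

# 1. simulate a labeled dataset: 4 sleep states x 3 recordings x 30 s
recordings = make_dataset(3, GeneratorConfig(duration_s=30.0), seed=42)

# 2. preprocess, fit microstates, extract per-window features
dataset = build_dataset(recordings, PipelineConfig(), seed=42)
print(f"windows: {dataset.X.shape[0]}, GFP sequence length: {dataset.seq_len}, "
      f"static features: {dataset.n_static}")
print(f"microstate model: K={dataset.model.n_states}, GEV={dataset.model.gev:.3f}")

# 3. train the attention-glimpse agent, evaluate on a held-out quarter
rng = np.random.default_rng(42)
order = rng.permutation(len(dataset.y))
test, train_idx = order[:len(order) // 4], order[len(order) // 4:]
clf = GlimpseAgentClassifier(n_static_features=dataset.n_static,
                             epochs=100, random_state=42)
clf.fit(dataset.X[train_idx], dataset.y[train_idx])
report = evaluate(clf, dataset.X[test], dataset.y[test])
print(f"held-out accuracy: {report.overall_accuracy:.3f}")
```

prints

```
windows: 180, GFP sequence length: 500, static features: 23
microstate model: K=4, GEV=0.823
held-out accuracy: 0.511
```

Each 2 s window contributes its GFP sequence (500 samples at 250 Hz) plus
23 static features (mean GFP for each of the K = 4 microstates and LZC for
each of the 19 channels — the "mean GFP + LZC" feature set).  The fitted
microstate model explains 82% of the GFP²-weighted topographic variance at
the pinned K = 4 (the generator's true microstate count).
On this deliberately small dataset (90 s per state) the agent reaches 51%
held-out accuracy against a 25% chance level; larger simulated cohorts
reach higher (see the reproduction script below).

The same workflow is available from the shell:

```bash
somnirl simulate --n 5 --duration 60 --seed 42 --out data/
somnirl microstate --in data/ --k 4 --out model.json
somnirl features --in data/ --set mean_gfp+lzc --out features.tsv
somnirl stats --features features.tsv --correction bonferroni --out stats.tsv
somnirl train --in data/ --arch cnn_gru_rl --checkpoint policy.json
somnirl evaluate --in data/ --checkpoint policy.json
somnirl experiment channels --in data/ --out grid.json
```

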