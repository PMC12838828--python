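"""The attention-glimpse agent: encoder, recurrent core, and heads.

The agent observes a 1-D sequence (a GFP amplitude trace) through localized
multi-scale glimpses.  Each step a convolutional encoder embeds the glimpse
stack (optionally together with a static feature vector, e.g. microstate
parameters + LZC of the same segment), a gated recurrent core integrates it
into the hidden state, and three heads read the hidden state out:

* a location head parameterizing the distribution of the next glimpse
  location (isotropic Gaussian with fixed sigma around a tanh-squashed mean,
  or a categorical distribution over a fixed grid of locations — the latter
  makes small problems exactly enumerable);
* an action head giving a softmax distribution over sleep-state classes;
* a value (baseline) head predicting the expected return of the current
  state, read from a *detached* hidden state so its regression loss never
  perturbs the policy gradient.

Three architectures are supported: ``cnn_gru_rl`` (convolutional encoder +
GRU core), ``cnn_rl`` (convolutional encoder + memoryless feed-forward
core), and ``gru_rl`` (flattened glimpse + GRU core).

Everything is batched over episodes; ``rollout`` runs the forward pass and
records caches, and ``backward`` turns per-step advantages into parameter
gradients by backpropagation through time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .glimpse import GlimpseConfig, glimpse_batch

ARCHITECTURES = ("cnn_gru_rl", "cnn_rl", "gru_rl")


@dataclass(frozen=True)
class PolicyConfig:
    """Architecture and dimensioning of the agent."""

    n_classes: int = 4
    architecture: str = "cnn_gru_rl"
    glimpse: GlimpseConfig = field(default_factory=GlimpseConfig)
    hidden_size: int = 128
    conv_channels: tuple[int, int] = (8, 16)
    conv_kernels: tuple[int, int] = (5, 3)
    feature_dim: int = 64
    n_static: int = 0
    sigma_loc: float = 0.1
    location_mode: str = "gaussian"      # "gaussian" | "grid"
    loc_grid: tuple[float, ...] = (-0.5, 0.5)
    dropout: float = 0.2

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.location_mode not in ("gaussian", "grid"):
            raise ValueError(f"unknown location mode {self.location_mode!r}")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


class AgentPolicy:
    """Parameter container plus forward/backward machinery."""

    def __init__(self, config: PolicyConfig, seed: int | None = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        g = config.glimpse
        p: nn.Params = {}
        if config.architecture in ("cnn_gru_rl", "cnn_rl"):
            c1, c2 = config.conv_channels
            k1, k2 = config.conv_kernels
            if g.base_length - k1 - k2 + 2 < 1:
                raise ValueError("glimpse base_length too short for the convs")
            nn.init_conv1d(p, "conv1", g.n_scales, c1, k1, rng)
            nn.init_conv1d(p, "conv2", c1, c2, k2, rng)
            enc_dim = c2
        else:
            enc_dim = g.n_scales * g.base_length
        nn.init_linear(p, "embed", enc_dim + 1 + config.n_static,
                       config.feature_dim, rng)
        H = config.hidden_size
        if config.architecture in ("cnn_gru_rl", "gru_rl"):
            nn.init_gru(p, "gru", config.feature_dim, H, rng)
        else:
            nn.init_linear(p, "core", config.feature_dim, H, rng)
        d_loc = 1 if config.location_mode == "gaussian" else len(config.loc_grid)
        nn.init_linear(p, "loc", H, d_loc, rng)
        nn.init_linear(p, "act", H, config.n_classes, rng)
        nn.init_linear(p, "baseline", H, 1, rng)
        self.params = p

    # -- forward pieces ----------------------------------------------------

    def _encode(self, g: np.ndarray, loc: np.ndarray, static: np.ndarray | None,
                rng: np.random.Generator, train: bool):
        cfg = self.config
        caches: dict = {}
        if cfg.architecture in ("cnn_gru_rl", "cnn_rl"):
            y, caches["conv1"] = nn.conv1d_forward(self.params, "conv1", g)
            y, caches["relu1"] = nn.relu_forward(y)
            y, caches["conv2"] = nn.conv1d_forward(self.params, "conv2", y)
            y, caches["relu2"] = nn.relu_forward(y)
            caches["pool_len"] = y.shape[2]
            enc = y.mean(axis=2)
        else:
            caches["flat_shape"] = g.shape
            enc = g.reshape(g.shape[0], -1)
        parts = [enc, loc.reshape(-1, 1)]
        if cfg.n_static:
            parts.append(static)
        z = np.concatenate(parts, axis=1)
        caches["enc_dim"] = enc.shape[1]
        y, caches["embed"] = nn.linear_forward(self.params, "embed", z)
        y, caches["relu_e"] = nn.relu_forward(y)
        y, caches["drop"] = nn.dropout_forward(y, cfg.dropout, rng, train)
        return y, caches

    def _encode_backward(self, grads: nn.Grads, caches, dfeat: np.ndarray):
        cfg = self.config
        dy = nn.dropout_backward(caches["drop"], dfeat)
        dy = nn.relu_backward(caches["relu_e"], dy)
        dz = nn.linear_backward(self.params, grads, caches["embed"], dy)
        denc = dz[:, :caches["enc_dim"]]
        # gradients w.r.t. the sampled location and static inputs are
        # discarded: glimpse extraction is non-differentiable by design
        if cfg.architecture in ("cnn_gru_rl", "cnn_rl"):
            L = caches["pool_len"]
            dy = np.repeat(denc[:, :, None] / L, L, axis=2)
            dy = nn.relu_backward(caches["relu2"], dy)
            dy = nn.conv1d_backward(self.params, grads, caches["conv2"], dy)
            dy = nn.relu_backward(caches["relu1"], dy)
            nn.conv1d_backward(self.params, grads, caches["conv1"], dy)

    def _core(self, h: np.ndarray, feat: np.ndarray):
        if self.config.architecture in ("cnn_gru_rl", "gru_rl"):
            h_new, cache = nn.gru_forward(self.params, "gru", feat, h)
            return h_new, ("gru", cache)
        y, lin = nn.linear_forward(self.params, "core", feat)
        h_new, tc = nn.tanh_forward(y)
        return h_new, ("ff", (lin, tc))

    def _core_backward(self, grads: nn.Grads, cache, dh_new: np.ndarray):
        kind, c = cache
        if kind == "gru":
            return nn.gru_backward(self.params, grads, c, dh_new)
        lin, tc = c
        dy = nn.tanh_backward(tc, dh_new)
        dfeat = nn.linear_backward(self.params, grads, lin, dy)
        return dfeat, np.zeros_like(dh_new)  # memoryless core: no path to h_prev

    # -- heads -------------------------------------------------------------

    def location_distribution(self, h: np.ndarray):
        """Head output: (mode, mean-or-probs, cache)."""
        out, lin = nn.linear_forward(self.params, "loc", h)
        if self.config.location_mode == "gaussian":
            mu, tc = nn.tanh_forward(out)
            return "gaussian", mu[:, 0], (lin, tc, mu)
        probs = nn.softmax(out)
        return "grid", probs, (lin, probs)

    def sample_location_batch(self, h: np.ndarray, rng: np.random.Generator,
                              stochastic: bool, forced: np.ndarray | None = None):
        mode, param, cache = self.location_distribution(h)
        B = h.shape[0]
        if mode == "gaussian":
            mu = param
            if forced is not None:
                u = np.asarray(forced, dtype=float)
            elif stochastic:
                u = mu + self.config.sigma_loc * rng.standard_normal(B)
            else:
                u = mu.copy()
            l = np.clip(u, -1.0, 1.0)
            return l, {"mode": mode, "cache": cache, "u": u, "mu": mu}
        probs = param
        grid = np.asarray(self.config.loc_grid)
        if forced is not None:
            idx = np.asarray(forced, dtype=int)
        elif stochastic:
            cum = probs.cumsum(axis=1)
            r = rng.random((B, 1))
            idx = (r > cum).sum(axis=1)
        else:
            idx = probs.argmax(axis=1)
        return grid[idx], {"mode": mode, "cache": cache, "idx": idx,
                           "probs": probs}

    def location_backward(self, grads: nn.Grads, info, coeff: np.ndarray):
        """Gradient of  -sum_b coeff_b * log pi_l(l_b)  w.r.t. params -> dh."""
        if info["mode"] == "gaussian":
            lin, tc, mu = info["cache"]
            # d(-log N(u; mu, s^2))/dmu = -(u - mu)/s^2
            dmu = -(info["u"] - info["mu"]) / self.config.sigma_loc**2 * coeff
            dout = nn.tanh_backward(tc, dmu[:, None])
            return nn.linear_backward(self.params, grads, lin, dout)
        lin, probs = info["cache"]
        onehot = np.zeros_like(probs)
        onehot[np.arange(len(info["idx"])), info["idx"]] = 1.0
        dlogits = (probs - onehot) * coeff[:, None]
        return nn.linear_backward(self.params, grads, lin, dlogits)

    def action_distribution(self, h: np.ndarray):
        logits, lin = nn.linear_forward(self.params, "act", h)
        return nn.softmax(logits), lin

    def act_batch(self, h: np.ndarray, epsilon: float,
                  rng: np.random.Generator, greedy: bool = False,
                  forced: np.ndarray | None = None):
        probs, lin = self.action_distribution(h)
        B, K = probs.shape
        if forced is not None:
            a = np.asarray(forced, dtype=int)
        elif greedy:
            a = probs.argmax(axis=1)
        else:
            cum = probs.cumsum(axis=1)
            a = (rng.random((B, 1)) > cum).sum(axis=1)
            if epsilon > 0:
                explore = rng.random(B) < epsilon
                a = np.where(explore, rng.integers(K, size=B), a)
        return a, probs, lin

    def action_backward(self, grads: nn.Grads, lin, probs: np.ndarray,
                        actions: np.ndarray, coeff: np.ndarray):
        onehot = np.zeros_like(probs)
        onehot[np.arange(len(actions)), actions] = 1.0
        dlogits = (probs - onehot) * coeff[:, None]
        return nn.linear_backward(self.params, grads, lin, dlogits)

    def baseline_value(self, h: np.ndarray):
        v, lin = nn.linear_forward(self.params, "baseline", h)
        return v[:, 0], lin

    # -- rollout and backward ---------------------------------------------

    def rollout(self, X: np.ndarray, static: np.ndarray | None,
                y: np.ndarray | None, T: int, epsilon: float,
                rng: np.random.Generator, train: bool,
                forced_locs: list | None = None,
                forced_acts: list | None = None) -> dict:
        """Run T glimpse steps for a batch of sequences.

        Returns a trajectory record with per-step hidden states, sampled
        locations/actions, rewards, and the caches needed by ``backward``.
        """
        X = np.asarray(X, dtype=float)
        B = X.shape[0]
        H = self.config.hidden_size
        h = np.zeros((B, H))
        traj: dict = {"h": [h], "enc": [], "core": [], "loc": [], "locs": [],
                      "act": [], "probs": [], "actions": [], "rewards": [],
                      "T": T, "B": B}
        fl = forced_locs or [None] * (T + 1)
        fa = forced_acts or [None] * T
        l, loc_info = self.sample_location_batch(h, rng, stochastic=train,
                                                 forced=fl[0])
        traj["loc"].append(loc_info)
        traj["locs"].append(l)
        for t in range(1, T + 1):
            g = glimpse_batch(X, l, self.config.glimpse)
            feat, enc_cache = self._encode(g, l, static, rng, train)
            h, core_cache = self._core(h, feat)
            traj["h"].append(h)
            traj["enc"].append(enc_cache)
            traj["core"].append(core_cache)
            l, loc_info = self.sample_location_batch(
                h, rng, stochastic=train, forced=fl[t])
            traj["loc"].append(loc_info)
            traj["locs"].append(l)
            a, probs, act_lin = self.act_batch(
                h, epsilon, rng, greedy=not train, forced=fa[t - 1])
            traj["act"].append(act_lin)
            traj["probs"].append(probs)
            traj["actions"].append(a)
            if y is not None:
                traj["rewards"].append((a == np.asarray(y)).astype(float))
        return traj

    def returns(self, traj: dict, gamma: float) -> np.ndarray:
        """Discounted reward-to-go G_t (B, T); G_1 is the episode return R."""
        R = np.stack(traj["rewards"], axis=1)  # (B, T)
        G = np.zeros_like(R)
        acc = np.zeros(R.shape[0])
        for t in range(R.shape[1] - 1, -1, -1):
            acc = R[:, t] + gamma * acc
            G[:, t] = acc
        return G

    def backward(self, traj: dict, gamma: float,
                 weights: np.ndarray | None = None) -> tuple[nn.Grads, dict]:
        """Policy-gradient + baseline-regression gradients for one batch.

        The estimator is
        ``-sum_t w_b [ log pi_a(a_t) + log pi_l(l_{t-1}) ] * (G - b)``
        with reward-to-go ``G`` and the learned value baseline ``b`` (both
        treated as constants), plus a squared-error loss attaching the
        baseline head to the *detached* hidden states.  ``weights`` are
        per-episode weights (default 1/B, the Monte-Carlo average).
        """
        B, T = traj["B"], traj["T"]
        w = (np.full(B, 1.0 / B) if weights is None
             else np.asarray(weights, dtype=float))
        G = self.returns(traj, gamma)
        grads = nn.zero_grads(self.params)
        # baseline values on detached hidden states
        v = np.zeros((B, T + 1))
        base_caches = []
        for t in range(T + 1):
            v[:, t], lin = self.baseline_value(traj["h"][t])
            base_caches.append(lin)
        # baseline regression: v_t -> G_{max(t,1)}
        targets = np.concatenate([G[:, :1], G], axis=1)  # (B, T+1)
        baseline_loss = 0.0
        for t in range(T + 1):
            err = (v[:, t] - targets[:, t]) * w
            baseline_loss += 0.5 * float(np.sum(err * (v[:, t] - targets[:, t])))
            bg: nn.Grads = {k: np.zeros_like(p) for k, p in self.params.items()
                            if k.startswith("baseline")}
            nn.linear_backward(self.params, bg, base_caches[t], err[:, None])
            for k in bg:
                grads[k] += bg[k]
        # BPTT over the policy pathway
        dh_next = np.zeros_like(traj["h"][-1])
        for t in range(T, 0, -1):
            adv_a = (G[:, t - 1] - v[:, t]) * w
            dh = self.action_backward(grads, traj["act"][t - 1],
                                      traj["probs"][t - 1],
                                      traj["actions"][t - 1], adv_a)
            if t < T:
                adv_l = (G[:, t] - v[:, t]) * w
                dh += self.location_backward(grads, traj["loc"][t], adv_l)
            dh += dh_next
            dfeat, dh_prev = self._core_backward(grads, traj["core"][t - 1], dh)
            self._encode_backward(grads, traj["enc"][t - 1], dfeat)
            dh_next = dh_prev
        # initial location head (reads h_0 = 0)
        adv_l0 = (G[:, 0] - v[:, 0]) * w
        self.location_backward(grads, traj["loc"][0], adv_l0)
        diag = {
            "mean_return": float(G[:, 0].mean()),
            "baseline_loss": baseline_loss,
            "mean_reward": float(np.mean(np.stack(traj["rewards"]))),
        }
        return grads, diag

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file JSON checkpoint: manifest + parameters."""
        cfg = asdict(self.config)
        cfg["glimpse"] = asdict(self.config.glimpse)
        blob = {
            "manifest": {"format": "somnirl-policy", "version": 1,
                         "config": cfg, "seed": self.seed},
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "AgentPolicy":
        blob = json.loads(Path(path).read_text())
        cfg_d = dict(blob["manifest"]["config"])
        cfg_d["glimpse"] = GlimpseConfig(**cfg_d["glimpse"])
        for key in ("conv_channels", "conv_kernels", "loc_grid"):
            cfg_d[key] = tuple(cfg_d[key])
        policy = cls(PolicyConfig(**cfg_d), seed=blob["manifest"]["seed"])
        policy.params = {k: np.array(v) for k, v in blob["params"].items()}
        return policy


# --------------------------------------------------------------------------
# single-sample functional wrappers

def core_step(policy: AgentPolicy, h_prev: np.ndarray,
              g: np.ndarray) -> np.ndarray:
    """One deterministic core update for a single glimpse stack."""
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=float))
    if h_prev.shape[1] != policy.config.hidden_size:
        raise ValueError(
            f"hidden state has {h_prev.shape[1]} units, policy expects "
            f"{policy.config.hidden_size}")
    g = np.asarray(g, dtype=float)[None, ...]
    rng = np.random.default_rng(0)
    feat, _ = policy._encode(g, np.zeros(1),
                             np.zeros((1, policy.config.n_static))
                             if policy.config.n_static else None,
                             rng, train=False)
    h, _ = policy._core(h_prev, feat)
    return h[0]


def sample_location(policy: AgentPolicy, h: np.ndarray,
                    stochastic: bool = True,
                    seed: int | None = None) -> float:
    """Sample (or return the mean of) the next glimpse location in [-1, 1]."""
    rng = np.random.default_rng(seed)
    l, _ = policy.sample_location_batch(
        np.atleast_2d(np.asarray(h, dtype=float)), rng, stochastic=stochastic)
    return float(l[0])


def act(policy: AgentPolicy, h: np.ndarray, epsilon: float = 0.0,
        seed: int | None = None, greedy: bool = False):
    """Sample a class action; returns (class index, probability vector)."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    a, probs, _ = policy.act_batch(
        np.atleast_2d(np.asarray(h, dtype=float)), epsilon, rng, greedy=greedy)
    return int(a[0]), probs[0]
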