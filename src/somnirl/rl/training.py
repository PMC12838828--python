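"""REINFORCE-with-baseline training of the glimpse agent.

The gradient estimator is the Monte-Carlo policy gradient

    (1/M) sum_i sum_t  grad log pi(u_t^i | s_1:t^i)  (G_t^i - b(s_t^i))

over a batch of M episodes, where u_t is the pair (location, action) whose
log-probabilities add, G_t is the discounted reward-to-go and b is a learned
value baseline regressed to the observed returns on detached hidden states.
Optimization uses Adam.  Exploration is epsilon-greedy on the class action
only, with epsilon annealed linearly over a fixed number of episodes.

The public surface is the scikit-learn style
:class:`GlimpseAgentClassifier`; :func:`train` and
:func:`reinforce_update` are thin functional wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .glimpse import GlimpseConfig
from .policy import ARCHITECTURES, AgentPolicy, PolicyConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    Defaults: learning rate 1e-3 with Adam, discount 0.9, 500 epochs, batch
    size 128, epsilon annealed 1.0 -> 0.1 over 1000 episodes, dropout 0.2,
    75% train split, early stopping with patience 20 on validation reward.
    """

    learning_rate: float = 1e-3
    gamma: float = 0.9
    epochs: int = 500
    batch_size: int = 128
    epsilon_start: float = 1.0
    epsilon_end: float = 0.1
    epsilon_decay_episodes: int = 1000
    dropout: float = 0.2
    monte_carlo_episodes: int | None = None  # None -> batch_size
    n_glimpses: int = 6
    train_fraction: float = 0.75
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ValueError("discount gamma must lie in (0, 1]")
        for eps in (self.epsilon_start, self.epsilon_end):
            if not 0 <= eps <= 1:
                raise ValueError("epsilon must lie in [0, 1]")
        if min(self.epochs, self.batch_size, self.n_glimpses,
               self.epsilon_decay_episodes, self.patience) < 1:
            raise ValueError("all counts must be positive")

    def epsilon_at(self, episodes_seen: int) -> float:
        frac = min(episodes_seen / self.epsilon_decay_episodes, 1.0)
        return self.epsilon_start + frac * (self.epsilon_end - self.epsilon_start)


def reinforce_update(policy: AgentPolicy, traj: dict, cfg: TrainConfig,
                     optimizer: nn.Adam | None = None,
                     weights: np.ndarray | None = None) -> dict:
    """One gradient-ascent step from a batch trajectory record.

    Mutates ``policy.params`` in place; returns diagnostics.  ``weights``
    overrides the default uniform 1/M episode weighting (used by
    enumeration oracles).
    """
    if traj["B"] < 1:
        raise ValueError("empty episode batch")
    grads, diag = policy.backward(traj, cfg.gamma, weights=weights)
    opt = optimizer or nn.Adam(policy.params, lr=cfg.learning_rate)
    opt.step(policy.params, grads)
    diag["grad_norm"] = float(np.sqrt(sum(np.sum(g**2)
                                          for g in grads.values())))
    return diag


class GlimpseAgentClassifier(BaseEstimator, ClassifierMixin):
    """Sequence classifier built on the attention-glimpse RL agent.

    ``X`` rows are observation sequences, optionally with ``n_static_features``
    trailing columns of static per-example features (the multimodal state:
    GFP sequence + microstate parameters + LZC).  ``fit`` holds out a
    validation fraction, anneals exploration, and restores the parameters of
    the best validation epoch (early stopping).

    Parameters mirror :class:`TrainConfig` and :class:`PolicyConfig`;
    ``architecture`` is one of ``cnn_gru_rl`` (default), ``cnn_rl``,
    ``gru_rl``.

    Attributes
    ----------
    classes_ : ndarray
        Class labels in encoding order.
    policy_ : AgentPolicy
        Trained policy (best validation epoch).
    history_ : list of dict
        Per-epoch reward / accuracy / epsilon log.
    """

    def __init__(self, architecture: str = "cnn_gru_rl",
                 n_glimpses: int = 6, base_length: int = 16,
                 n_scales: int = 3, scale_factor: int = 2,
                 hidden_size: int = 128, feature_dim: int = 64,
                 conv_channels: tuple[int, int] = (8, 16),
                 sigma_loc: float = 0.1, location_mode: str = "gaussian",
                 n_static_features: int = 0,
                 learning_rate: float = 1e-3, gamma: float = 0.9,
                 epochs: int = 500, batch_size: int = 128,
                 epsilon_start: float = 1.0, epsilon_end: float = 0.1,
                 epsilon_decay_episodes: int = 1000, dropout: float = 0.2,
                 train_fraction: float = 0.75, patience: int = 20,
                 random_state: int | None = 0):
        self.architecture = architecture
        self.n_glimpses = n_glimpses
        self.base_length = base_length
        self.n_scales = n_scales
        self.scale_factor = scale_factor
        self.hidden_size = hidden_size
        self.feature_dim = feature_dim
        self.conv_channels = conv_channels
        self.sigma_loc = sigma_loc
        self.location_mode = location_mode
        self.n_static_features = n_static_features
        self.learning_rate = learning_rate
        self.gamma = gamma
        self.epochs = epochs
        self.batch_size = batch_size
        self.epsilon_start = epsilon_start
        self.epsilon_end = epsilon_end
        self.epsilon_decay_episodes = epsilon_decay_episodes
        self.dropout = dropout
        self.train_fraction = train_fraction
        self.patience = patience
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _split_X(self, X: np.ndarray):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, seq_len [+ static])")
        s = self.n_static_features
        if s:
            return X[:, :-s], X[:, -s:]
        return X, None

    def _standardize(self, seq, static, fit: bool):
        if fit:
            self.seq_scale_ = float(seq.std()) or 1.0
            if static is not None:
                self.static_mean_ = static.mean(axis=0)
                self.static_std_ = static.std(axis=0)
                self.static_std_[self.static_std_ == 0] = 1.0
        seq = seq / self.seq_scale_
        if static is not None:
            static = (static - self.static_mean_) / self.static_std_
        return seq, static

    def fit(self, X, y):
        seq, static = self._split_X(X)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class")
        self.n_features_in_ = X.shape[1]
        cfg = TrainConfig(
            learning_rate=self.learning_rate, gamma=self.gamma,
            epochs=self.epochs, batch_size=self.batch_size,
            epsilon_start=self.epsilon_start, epsilon_end=self.epsilon_end,
            epsilon_decay_episodes=self.epsilon_decay_episodes,
            dropout=self.dropout, n_glimpses=self.n_glimpses,
            train_fraction=self.train_fraction, patience=self.patience,
            seed=self.random_state if self.random_state is not None else 0)
        pcfg = PolicyConfig(
            n_classes=len(self.classes_), architecture=self.architecture,
            glimpse=GlimpseConfig(self.n_scales, self.base_length,
                                  self.scale_factor),
            hidden_size=self.hidden_size,
            conv_channels=tuple(self.conv_channels),
            feature_dim=self.feature_dim,
            n_static=self.n_static_features, sigma_loc=self.sigma_loc,
            location_mode=self.location_mode, dropout=self.dropout)
        seq, static = self._standardize(seq, static, fit=True)
        self.policy_, self.history_ = _train_loop(seq, static, y_enc, pcfg, cfg)
        return self

    def _deterministic_rollout(self, X):
        seq, static = self._split_X(X)
        seq, static = self._standardize(seq, static, fit=False)
        rng = np.random.default_rng(0)
        traj = self.policy_.rollout(seq, static, None, self.n_glimpses,
                                    0.0, rng, train=False)
        return traj

    def predict(self, X):
        traj = self._deterministic_rollout(X)
        return self.classes_[traj["actions"][-1]]

    def predict_proba(self, X):
        traj = self._deterministic_rollout(X)
        return traj["probs"][-1]


def _iter_minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _train_loop(seq, static, y, pcfg: PolicyConfig, cfg: TrainConfig):
    master = np.random.SeedSequence(cfg.seed)
    s_split, s_init, s_rollout = (int(c.generate_state(1)[0] % (2**31))
                                  for c in master.spawn(3))
    n = len(y)
    rng_split = np.random.default_rng(s_split)
    order = rng_split.permutation(n)
    n_train = max(2, int(round(cfg.train_fraction * n)))
    tr, va = order[:n_train], order[n_train:]
    if va.size == 0:  # degenerate split: validate on a tail of the train set
        va = tr[-max(1, n // 10):]
    policy = AgentPolicy(pcfg, seed=s_init)
    optimizer = nn.Adam(policy.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(s_rollout)
    st = (lambda idx: None if static is None else static[idx])
    episodes_seen = 0
    best = (-np.inf, None, 0)
    history: list[dict] = []
    for epoch in range(cfg.epochs):
        train_rewards = []
        for idx in _iter_minibatches(len(tr), cfg.batch_size, rng):
            batch = tr[idx]
            eps = cfg.epsilon_at(episodes_seen)
            traj = policy.rollout(seq[batch], st(batch), y[batch],
                                  cfg.n_glimpses, eps, rng, train=True)
            diag = reinforce_update(policy, traj, cfg, optimizer=optimizer)
            episodes_seen += len(batch)
            train_rewards.append(diag["mean_reward"])
        vtraj = policy.rollout(seq[va], st(va), y[va], cfg.n_glimpses,
                               0.0, rng, train=False)
        val_G = policy.returns(vtraj, cfg.gamma)
        val_reward = float(val_G[:, 0].mean())
        val_acc = float((vtraj["actions"][-1] == y[va]).mean())
        history.append({
            "epoch": epoch, "epsilon": cfg.epsilon_at(episodes_seen),
            "train_reward": float(np.mean(train_rewards)),
            "val_reward": val_reward, "val_accuracy": val_acc,
        })
        if val_reward > best[0]:
            best = (val_reward,
                    {k: v.copy() for k, v in policy.params.items()}, epoch)
        elif epoch - best[2] >= cfg.patience:
            logger.info("early stopping at epoch %d (best %d)",
                        epoch, best[2])
            break
    if best[1] is not None:
        policy.params = best[1]
    return policy, history


def train(sequences, labels, cfg: TrainConfig | None = None,
          architecture: str = "cnn_gru_rl",
          static: np.ndarray | None = None):
    """Functional wrapper: returns (fitted classifier, training history)."""
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")
    cfg = cfg or TrainConfig()
    X = np.asarray(sequences, dtype=float)
    n_static = 0
    if static is not None:
        static = np.asarray(static, dtype=float)
        n_static = static.shape[1]
        X = np.concatenate([X, static], axis=1)
    clf = GlimpseAgentClassifier(
        architecture=architecture, n_glimpses=cfg.n_glimpses,
        n_static_features=n_static, learning_rate=cfg.learning_rate,
        gamma=cfg.gamma, epochs=cfg.epochs, batch_size=cfg.batch_size,
        epsilon_start=cfg.epsilon_start, epsilon_end=cfg.epsilon_end,
        epsilon_decay_episodes=cfg.epsilon_decay_episodes,
        dropout=cfg.dropout, train_fraction=cfg.train_fraction,
        patience=cfg.patience, random_state=cfg.seed)
    clf.fit(X, np.asarray(labels))
    return clf, clf.history_
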