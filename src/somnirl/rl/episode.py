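"""Single-episode record and runner."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .policy import AgentPolicy


@dataclass(frozen=True)
class Episode:
    """One agent-environment interaction of T glimpse steps.

    ``rewards[t]`` is 1 when step t+1 classified the sequence correctly and
    0 otherwise; ``ret`` is the discounted return sum_t gamma^(t-1) r_t.
    The final prediction is the last step's action.
    """

    observations: np.ndarray
    locations: np.ndarray       # l_0 .. l_T
    actions: np.ndarray         # a_1 .. a_T
    rewards: np.ndarray         # r_1 .. r_T, in {0, 1}
    ret: float
    gamma: float
    true_label: int | None = None

    def __post_init__(self) -> None:
        expected = float(np.sum(self.gamma ** np.arange(len(self.rewards))
                                * self.rewards))
        if abs(expected - self.ret) > 1e-9:
            raise ValueError("return does not match the discounted reward sum")

    @property
    def prediction(self) -> int:
        return int(self.actions[-1])


def run_episode(policy: AgentPolicy, x: np.ndarray, true_label: int,
                n_glimpses: int = 6, gamma: float = 0.9,
                epsilon: float = 0.0, seed: int | None = None,
                static: np.ndarray | None = None,
                train: bool = True) -> Episode:
    """Run one episode on a single observation sequence."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("observation sequence must be 1-D")
    if x.size < policy.config.glimpse.base_length:
        raise ValueError("sequence too short for a glimpse")
    rng = np.random.default_rng(seed)
    st = None if static is None else np.atleast_2d(np.asarray(static, float))
    traj = policy.rollout(x[None, :], st, np.array([true_label]),
                          n_glimpses, epsilon, rng, train=train)
    rewards = np.array([r[0] for r in traj["rewards"]])
    ret = float(np.sum(gamma ** np.arange(len(rewards)) * rewards))
    return Episode(
        observations=x,
        locations=np.array([l[0] for l in traj["locs"]]),
        actions=np.array([a[0] for a in traj["actions"]]),
        rewards=rewards,
        ret=ret,
        gamma=gamma,
        true_label=int(true_label),
    )
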