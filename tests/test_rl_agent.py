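"""Glimpse sensor, policy heads, episodes, and the REINFORCE update."""

import numpy as np
import pytest

from somnirl.rl.glimpse import GlimpseConfig, glimpse, glimpse_batch
from somnirl.rl.nn import Adam
from somnirl.rl.policy import (AgentPolicy, PolicyConfig, act, core_step,
                               sample_location)
from somnirl.rl.episode import Episode, run_episode
from somnirl.rl.training import TrainConfig, reinforce_update


def tiny_policy(architecture="cnn_gru_rl", location_mode="gaussian",
                n_classes=2, seed=0, dropout=0.0):
    return AgentPolicy(PolicyConfig(
        n_classes=n_classes, architecture=architecture,
        glimpse=GlimpseConfig(n_scales=2, base_length=8, scale_factor=2),
        hidden_size=10, conv_channels=(3, 3), conv_kernels=(3, 3),
        feature_dim=6, location_mode=location_mode, dropout=dropout),
        seed=seed)


class TestGlimpse:
    def test_single_scale_full_width_is_identity(self, rng):
        x = rng.standard_normal(16)
        cfg = GlimpseConfig(n_scales=1, base_length=16)
        assert np.array_equal(glimpse(x, 0.0, cfg)[0], x)

    def test_right_edge_is_half_zero_padded(self, rng):
        x = rng.standard_normal(64)
        cfg = GlimpseConfig(n_scales=1, base_length=16)
        g = glimpse(x, 1.0, cfg)[0]
        assert np.all(g[9:] == 0)  # beyond the last sample
        assert np.any(g[:8] != 0)

    def test_coarse_scale_averages_ramp_exactly(self):
        x = np.arange(64, dtype=float)
        cfg = GlimpseConfig(n_scales=2, base_length=8, scale_factor=2)
        g = glimpse(x, 0.0, cfg)
        # scale 1 window of 16 samples -> pairs averaged: centers k+0.5
        start = int(np.floor(63 / 2 - 8 + 0.5))
        expected = x[start:start + 16].reshape(8, 2).mean(axis=1)
        assert np.allclose(g[1], expected)

    def test_batch_matches_single(self, rng):
        x = rng.standard_normal((3, 64))
        cfg = GlimpseConfig(n_scales=3, base_length=8)
        locs = np.array([-0.7, 0.0, 0.9])
        batch = glimpse_batch(x, locs, cfg)
        for i in range(3):
            assert np.allclose(batch[i], glimpse(x[i], locs[i], cfg))

    def test_out_of_range_location_rejected(self, rng):
        with pytest.raises(ValueError):
            glimpse(rng.standard_normal(32), 1.5, GlimpseConfig())


class TestCoreStep:
    @pytest.mark.parametrize("arch", ["cnn_gru_rl", "cnn_rl", "gru_rl"])
    def test_deterministic(self, arch, rng):
        policy = tiny_policy(arch)
        h = rng.standard_normal(10) * 0.1
        g = rng.standard_normal((2, 8))
        assert np.array_equal(core_step(policy, h, g),
                              core_step(policy, h, g))

    def test_hidden_state_bounded(self, rng):
        policy = tiny_policy()
        h = np.zeros(10)
        for _ in range(20):
            h = core_step(policy, h, 10.0 * rng.standard_normal((2, 8)))
            assert np.all(np.abs(h) < 1.0)

    def test_zero_inputs_give_reproducible_bias_response(self):
        policy = tiny_policy()
        a = core_step(policy, np.zeros(10), np.zeros((2, 8)))
        b = core_step(policy, np.zeros(10), np.zeros((2, 8)))
        assert np.array_equal(a, b)

    def test_shape_mismatch_rejected(self):
        policy = tiny_policy()
        with pytest.raises(ValueError, match="hidden"):
            core_step(policy, np.zeros(7), np.zeros((2, 8)))


class TestSampleLocation:
    def test_deterministic_mode_repeats(self, rng):
        policy = tiny_policy()
        h = rng.standard_normal(10) * 0.3
        vals = {sample_location(policy, h, stochastic=False, seed=i)
                for i in range(5)}
        assert len(vals) == 1

    def test_stochastic_mean_matches_head_output(self, rng):
        policy = tiny_policy()
        h = rng.standard_normal(10) * 0.1
        mean = sample_location(policy, h, stochastic=False)
        draws = np.array([
            policy.sample_location_batch(h[None, :],
                                         np.random.default_rng(s),
                                         stochastic=True)[0][0]
            for s in range(10_000)])
        se = policy.config.sigma_loc / np.sqrt(10_000)
        assert abs(draws.mean() - mean) < 3 * se

    def test_outputs_clipped(self, rng):
        policy = tiny_policy()
        h = 5.0 * rng.standard_normal(10)
        for s in range(100):
            assert -1.0 <= sample_location(policy, h, seed=s) <= 1.0


class TestAct:
    def test_forced_exploration_is_uniform(self, rng):
        policy = tiny_policy(n_classes=4)
        h = rng.standard_normal(10) * 0.2
        draws = np.array([act(policy, h, epsilon=1.0, seed=s)[0]
                          for s in range(10_000)])
        freqs = np.bincount(draws, minlength=4) / 10_000
        se = np.sqrt(0.25 * 0.75 / 10_000)
        assert np.all(np.abs(freqs - 0.25) < 3 * se)

    def test_eval_mode_takes_dominant_class(self, rng):
        policy = tiny_policy(n_classes=3)
        h = rng.standard_normal(10) * 0.2
        _, probs = act(policy, h, epsilon=0.0, greedy=True)
        dominant = int(np.argmax(probs))
        for s in range(20):
            a, _ = act(policy, h, epsilon=0.0, seed=s, greedy=True)
            assert a == dominant

    def test_probabilities_normalized(self, rng):
        policy = tiny_policy(n_classes=4)
        _, probs = act(policy, rng.standard_normal(10), greedy=True)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_invalid_epsilon_rejected(self):
        with pytest.raises(ValueError):
            act(tiny_policy(), np.zeros(10), epsilon=1.5)


class TestEpisode:
    def test_return_identity_enforced(self):
        with pytest.raises(ValueError, match="return"):
            Episode(observations=np.zeros(8), locations=np.zeros(2),
                    actions=np.array([1]), rewards=np.array([1.0]),
                    ret=0.5, gamma=0.9)

    def test_all_correct_discounted_return(self):
        policy = tiny_policy()
        x = np.random.default_rng(0).standard_normal(64)
        traj = policy.rollout(x[None, :], None, np.array([1]), 3, 0.0,
                              np.random.default_rng(0), train=True,
                              forced_acts=[np.array([1])] * 3)
        G = policy.returns(traj, 0.9)
        assert G[0, 0] == pytest.approx(1 + 0.9 + 0.81)

    def test_all_wrong_zero_return(self):
        policy = tiny_policy()
        x = np.random.default_rng(0).standard_normal(64)
        traj = policy.rollout(x[None, :], None, np.array([1]), 3, 0.0,
                              np.random.default_rng(0), train=True,
                              forced_acts=[np.array([0])] * 3)
        assert policy.returns(traj, 0.9)[0, 0] == 0.0

    def test_undiscounted_counts_correct_steps(self):
        policy = tiny_policy()
        x = np.random.default_rng(0).standard_normal(64)
        traj = policy.rollout(x[None, :], None, np.array([1]), 4, 0.0,
                              np.random.default_rng(0), train=True,
                              forced_acts=[np.array([1]), np.array([0]),
                                           np.array([1]), np.array([0])])
        assert policy.returns(traj, 1.0)[0, 0] == 2.0

    def test_run_episode_record_consistent(self):
        policy = tiny_policy()
        x = np.random.default_rng(1).standard_normal(64)
        ep = run_episode(policy, x, true_label=1, n_glimpses=4, gamma=0.9,
                         seed=3)
        assert len(ep.actions) == 4
        assert len(ep.locations) == 5          # l_0 .. l_4
        assert set(np.unique(ep.rewards)) <= {0.0, 1.0}
        assert np.all(np.abs(ep.locations) <= 1.0)
        assert ep.prediction == ep.actions[-1]


class TestReinforceUpdate:
    def test_zero_advantage_moves_only_baseline(self):
        """With the baseline exactly matching the return, the policy
        gradient vanishes (only the value head may still move)."""
        policy = tiny_policy()
        x = np.random.default_rng(0).standard_normal(64)
        traj = policy.rollout(x[None, :], None, np.array([1]), 1, 0.0,
                              np.random.default_rng(0), train=True,
                              forced_acts=[np.array([1])])
        # force v(h) = 1.0 = G for every state
        policy.params["baseline.W"][:] = 0.0
        policy.params["baseline.b"][:] = 1.0
        grads, _ = policy.backward(traj, 0.9)
        for name, g in grads.items():
            if not name.startswith("baseline"):
                assert np.allclose(g, 0.0, atol=1e-12), name

    def test_update_deterministic_under_fixed_seed(self):
        def one_update(seed):
            policy = tiny_policy(seed=5)
            rng = np.random.default_rng(seed)
            x = np.random.default_rng(2).standard_normal((4, 64))
            y = np.array([0, 1, 0, 1])
            traj = policy.rollout(x, None, y, 3, 0.5, rng, train=True)
            reinforce_update(policy, traj, TrainConfig(seed=0),
                             optimizer=Adam(policy.params, lr=1e-3))
            return policy.params

        a, b = one_update(11), one_update(11)
        for k in a:
            assert np.array_equal(a[k], b[k])

    def test_empty_batch_rejected(self):
        policy = tiny_policy()
        with pytest.raises(ValueError, match="empty"):
            reinforce_update(policy, {"B": 0, "T": 1}, TrainConfig())


class TestPolicyPersistence:
    def test_save_load_roundtrip(self, tmp_path, rng):
        policy = tiny_policy()
        path = tmp_path / "policy.json"
        policy.save(path)
        back = AgentPolicy.load(path)
        assert back.config == policy.config
        x = rng.standard_normal((2, 64))
        t1 = policy.rollout(x, None, None, 3, 0.0,
                            np.random.default_rng(0), train=False)
        t2 = back.rollout(x, None, None, 3, 0.0,
                          np.random.default_rng(0), train=False)
        assert np.array_equal(t1["actions"][-1], t2["actions"][-1])
        assert np.allclose(t1["probs"][-1], t2["probs"][-1])
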