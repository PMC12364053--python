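"""Learning machinery: network gradients, replay/target mechanics, TD
targets, GAE, PPO losses, and convergence on exactly solvable problems."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from replanrl.agents import (
    BanditEnv,
    ChainMDP,
    DQNAgent,
    DQNConfig,
    MLP,
    PPOAgent,
    PPOConfig,
    ReplayBuffer,
    dqn_loss,
    gae,
    ppo_losses,
    td_target,
    train,
)
from replanrl.agents.ppo import discounted_returns


# -- neural network -----------------------------------------------------


def test_mlp_backward_matches_finite_differences():
    rng = np.random.default_rng(0)
    net = MLP([4, 5, 3], rng)
    X = rng.normal(size=(6, 4))
    target = rng.normal(size=(6, 3))

    def loss():
        return 0.5 * np.sum((net(X) - target) ** 2)

    out, cache = net.forward(X)
    grads = net.backward(cache, out - target)
    params = net.parameters()
    eps = 1e-6
    for p, g in zip(params, grads):
        it = np.nditer(p, flags=["multi_index"])
        for _ in itertools.islice(it, 5):  # spot-check a few entries
            idx = it.multi_index
            orig = p[idx]
            p[idx] = orig + eps
            up = loss()
            p[idx] = orig - eps
            down = loss()
            p[idx] = orig
            assert g[idx] == pytest.approx((up - down) / (2 * eps), rel=1e-4, abs=1e-6)


def test_mlp_clone_is_independent():
    rng = np.random.default_rng(1)
    net = MLP([3, 4, 2], rng)
    other = net.clone()
    net.W[0][0, 0] += 1.0
    assert other.W[0][0, 0] != net.W[0][0, 0]


# -- DQN ----------------------------------------------------------------


def test_q_values_have_action_space_size_and_are_deterministic():
    agent = DQNAgent(obs_dim=1500, n_actions=22, config=DQNConfig(seed=3))
    obs = np.random.default_rng(0).uniform(0, 1, 1500)
    q1 = agent.q_values(obs)
    q2 = agent.q_values(obs)
    assert q1.shape == (22,)
    assert np.array_equal(q1, q2)
    assert np.all(np.isfinite(q1))


def test_fully_exploratory_policy_ignores_values():
    cfg = DQNConfig(epsilon_start=1.0, epsilon_end=1.0, seed=0)
    agent = DQNAgent(obs_dim=4, n_actions=5, config=cfg)
    obs = np.zeros(4)
    actions = {agent.act(obs) for _ in range(300)}
    assert actions == set(range(5))  # every action reachable under eps = 1


@pytest.mark.parametrize(
    "r,qmax,done,gamma,expected",
    [
        (1.0, 5.0, False, 0.0, 1.0),  # myopic limit
        (1.0, 5.0, True, 0.9, 1.0),  # terminal bootstrap
        (1.0, 5.0, False, 0.9, 5.5),
    ],
)
def test_td_target_bellman_backup(r, qmax, done, gamma, expected):
    out = td_target(np.array([r]), np.array([qmax]), np.array([done]), gamma)
    assert out[0] == pytest.approx(expected)


def test_td_targets_match_hand_bellman_backup_on_chain():
    """Two-step chain: targets equal the value-iteration backup."""
    gamma = 0.9
    # exact Q from the ChainMDP dynamics by backward induction
    q1 = {0: 2.0, 1: 0.0}
    q2 = {0: 0.3, 1: 0.6}
    q0 = {a: r + gamma * max(q.values())
          for a, (r, q) in {0: (0.0, q1), 1: (0.5, q2)}.items()}
    assert q0[0] == pytest.approx(0.0 + gamma * 2.0)
    assert q0[1] == pytest.approx(0.5 + gamma * 0.6)
    # a td_target computed with the exact next-state values reproduces q0
    y = td_target(
        np.array([0.0, 0.5]),
        np.array([max(q1.values()), max(q2.values())]),
        np.array([False, False]),
        gamma,
    )
    assert np.allclose(y, [q0[0], q0[1]])


def test_dqn_loss_zero_iff_predictions_equal_targets():
    rng = np.random.default_rng(0)
    net = MLP([3, 8, 2], rng)
    target_net = net.clone()
    s = np.eye(3)
    a = np.array([0, 1, 0])
    # rewards chosen so the TD target equals the current prediction (gamma=0)
    r = net(s)[np.arange(3), a]
    done = np.array([True, True, True])
    assert dqn_loss(s, a, r, s, done, net, target_net, 0.9) == pytest.approx(0.0)
    assert dqn_loss(s, a, r + 1.0, s, done, net, target_net, 0.9) == pytest.approx(1.0)


def test_replay_buffer_capacity_and_seeded_sampling():
    buf = ReplayBuffer(5, np.random.default_rng(0))
    for i in range(12):
        buf.push(np.array([i]), 0, float(i), np.array([i]), False)
    assert len(buf) == 5
    s, a, r, s2, d = buf.sample(4)
    buf2 = ReplayBuffer(5, np.random.default_rng(0))
    for i in range(12):
        buf2.push(np.array([i]), 0, float(i), np.array([i]), False)
    s_again = buf2.sample(4)[0]
    assert np.array_equal(s, s_again)


def test_target_network_syncs_only_at_interval():
    cfg = DQNConfig(
        hidden_sizes=(8,), batch_size=4, replay_capacity=100,
        target_sync_interval=10, seed=0,
    )
    agent = DQNAgent(obs_dim=1, n_actions=2, config=cfg)
    env = BanditEnv()
    frozen = agent.target_net.get_params()
    for step in range(1, 10):
        env.reset()
        agent.observe(env.step(0))
        if step < 10:
            for p, q in zip(agent.target_net.get_params(), frozen):
                assert np.array_equal(p, q)
    env.reset()
    agent.observe(env.step(0))  # step 10: sync
    for p, q in zip(agent.target_net.get_params(), agent.net.get_params()):
        assert np.array_equal(p, q)


# -- GAE / PPO ----------------------------------------------------------


def gae_double_sum(rewards, values, dones, gamma, lam):
    """Direct evaluation of the exponentially weighted TD-residual sum."""
    T = len(rewards)
    adv = np.zeros(T)
    for t in range(T):
        acc = 0.0
        weight = 1.0
        for l in range(t, T):
            nonterminal = 0.0 if dones[l] else 1.0
            next_v = values[l + 1] * nonterminal
            delta = rewards[l] + gamma * next_v - values[l]
            acc += weight * delta
            adv[t] = acc
            if dones[l]:
                break
            weight *= gamma * lam
        adv[t] = acc
    return adv


def test_gae_one_step_limit_at_lambda_zero():
    r = np.array([1.0, 2.0, 3.0])
    v = np.array([0.5, 1.5, 2.5, 3.5])
    d = np.array([False, False, False])
    adv = gae(r, v, d, gamma=0.9, lam=0.0)
    expected = r + 0.9 * v[1:] - v[:-1]
    assert np.allclose(adv, expected)


def test_gae_monte_carlo_limit_is_return_to_go():
    r = np.array([1.0, 2.0, 3.0, 4.0])
    v = np.zeros(5)
    d = np.array([False, False, False, True])
    adv = gae(r, v, d, gamma=1.0, lam=1.0)
    assert np.allclose(adv, [10.0, 9.0, 7.0, 4.0])


def test_gae_matches_double_sum_on_fixed_episode():
    r = np.array([1.0, -0.5, 2.0, 0.3])
    v = np.array([0.2, 0.8, -0.1, 0.5, 1.0])
    d = np.array([False, False, False, False])
    assert np.allclose(
        gae(r, v, d, 0.95, 0.7), gae_double_sum(r, v, d, 0.95, 0.7)
    )


@given(
    data=st.data(),
    gamma=st.floats(0.0, 0.99),
    lam=st.floats(0.0, 1.0),
)
@settings(max_examples=80, deadline=None)
def test_gae_matches_double_sum_on_random_episodes(data, gamma, lam):
    T = data.draw(st.integers(1, 8))
    floats = st.floats(-5, 5, allow_nan=False)
    r = np.array(data.draw(st.lists(floats, min_size=T, max_size=T)))
    v = np.array(data.draw(st.lists(floats, min_size=T + 1, max_size=T + 1)))
    d = np.array(data.draw(st.lists(st.booleans(), min_size=T, max_size=T)))
    assert np.allclose(
        gae(r, v, d, gamma, lam), gae_double_sum(r, v, d, gamma, lam),
        atol=1e-10,
    )


def test_discounted_returns_restart_at_episode_boundaries():
    r = np.array([1.0, 1.0, 1.0, 1.0])
    d = np.array([False, True, False, False])
    out = discounted_returns(r, d, gamma=0.5, bootstrap=8.0)
    # tail: R3 = 1 + 0.5 * 8 = 5, R2 = 1 + 0.5 * 5 = 3.5;
    # head restarts after the terminal at t=1: R1 = 1, R0 = 1.5
    assert np.allclose(out, [1.5, 1.0, 3.5, 5.0])


def test_ppo_actor_term_is_mean_advantage_at_old_params():
    rng = np.random.default_rng(0)
    logits = rng.normal(size=(16, 22))
    actions = rng.integers(0, 22, 16)
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    old_logp = np.log(p[np.arange(16), actions])
    adv = rng.normal(size=16)
    out = ppo_losses(
        logits, actions, old_logp, adv, np.zeros(16), np.zeros(16),
        clip_epsilon=0.2, value_coef=0.5, entropy_coef=0.01,
    )
    assert out["actor"] == pytest.approx(adv.mean())


def test_ppo_clip_freezes_favorable_out_of_range_ratios():
    logits = np.zeros((1, 2))
    actions = np.array([0])
    adv = np.array([2.0])
    # old log-prob much lower than current -> ratio well above 1 + eps
    old_logp = np.array([np.log(0.5) - 1.0])
    out = ppo_losses(
        logits, actions, old_logp, adv, np.zeros(1), np.zeros(1),
        clip_epsilon=0.2, value_coef=0.0, entropy_coef=0.0,
    )
    assert out["actor"] == pytest.approx(1.2 * 2.0)  # clipped at (1 + eps) * A


def test_uniform_policy_entropy_is_log_action_count():
    out = ppo_losses(
        np.zeros((4, 22)), np.array([0, 5, 11, 21]),
        np.full(4, -np.log(22.0)), np.zeros(4), np.zeros(4), np.zeros(4),
        clip_epsilon=0.2, value_coef=0.5, entropy_coef=0.01,
    )
    assert out["entropy"] == pytest.approx(np.log(22.0))


# -- training loops on exactly solvable environments --------------------


def test_zero_episodes_returns_empty_log_and_untouched_params():
    agent = DQNAgent(obs_dim=1, n_actions=2, config=DQNConfig(hidden_sizes=(4,)))
    before = agent.net.get_params()
    log = train(agent, BanditEnv(), 0)
    assert log.episodes == []
    for p, q in zip(agent.net.get_params(), before):
        assert np.array_equal(p, q)


def test_fixed_seed_reproduces_training_log():
    logs = []
    for _ in range(2):
        agent = DQNAgent(
            obs_dim=3, n_actions=2,
            config=DQNConfig(hidden_sizes=(16,), batch_size=8,
                             replay_capacity=500, seed=9),
        )
        logs.append(train(agent, ChainMDP(), 40).to_dataframe())
    assert logs[0].equals(logs[1])


def test_dqn_solves_the_two_armed_bandit():
    cfg = DQNConfig(
        hidden_sizes=(16,), learning_rate=5e-3, batch_size=16,
        replay_capacity=500, target_sync_interval=20,
        epsilon_decay_steps=150, gamma=0.0, seed=1,
    )
    agent = DQNAgent(obs_dim=1, n_actions=2, config=cfg)
    train(agent, BanditEnv(rewards=(0.0, 1.0)), 250)
    assert agent.act(np.ones(1), explore=False) == 1


def test_ppo_solves_the_two_armed_bandit():
    cfg = PPOConfig(
        hidden_sizes=(16,), learning_rate=0.02, rollout_length=16,
        epochs_per_update=4, minibatch_size=8, gamma=0.0, seed=1,
    )
    agent = PPOAgent(obs_dim=1, n_actions=2, config=cfg)
    train(agent, BanditEnv(rewards=(0.0, 1.0)), 250)
    assert agent.act(np.ones(1), explore=False) == 1
    assert agent.action_probabilities(np.ones(1))[1] > 0.8


def chain_optimal_return():
    """Exhaustive search over all action sequences of the chain MDP."""
    best = -np.inf
    for a0 in range(2):
        for a1 in range(2):
            env = ChainMDP()
            env.reset()
            tr0 = env.step(a0)
            tr1 = env.step(a1)
            best = max(best, tr0.reward + tr1.reward)
    return best


def run_greedy_chain(agent):
    env = ChainMDP()
    obs = env.reset()
    total = 0.0
    done = False
    while not done:
        tr = env.step(agent.act(obs, explore=False))
        total += tr.reward
        obs = tr.next_state
        done = tr.done
    return total


def test_dqn_greedy_policy_attains_chain_optimum():
    """The delayed-reward path beats the myopic one; DQN must find it."""
    cfg = DQNConfig(
        hidden_sizes=(32,), learning_rate=5e-3, batch_size=16,
        replay_capacity=1000, target_sync_interval=25,
        epsilon_decay_steps=400, gamma=0.99, seed=2,
    )
    agent = DQNAgent(obs_dim=3, n_actions=2, config=cfg)
    train(agent, ChainMDP(), 400)
    optimum = chain_optimal_return()
    assert optimum == pytest.approx(2.0)  # sanity of the oracle itself
    assert run_greedy_chain(agent) == pytest.approx(optimum)
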