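"""Deep Q-learning over the priority-tuning environment.

The Q-network maps a flattened DVH state to one action value per priority
adjustment.  Training uses the standard machinery: an experience replay
buffer sampled uniformly, a target network with delayed parameters synced
every ``target_sync_interval`` environment steps, epsilon-greedy
exploration with a linear schedule, and the squared TD error

    L(theta) = E[(y - Q(s, a; theta))^2],
    y = r + gamma * max_a' Q(s', a'; theta^-)      (y = r at terminal s').
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import MLP, Adam, flatten_obs

__all__ = ["DQNConfig", "ReplayBuffer", "DQNAgent", "td_target", "dqn_loss"]


@dataclass(frozen=True)
class DQNConfig:
    hidden_sizes: tuple[int, ...] = (256, 128)
    learning_rate: float = 1e-3
    batch_size: int = 64
    replay_capacity: int = 10_000
    target_sync_interval: int = 100
    epsilon_start: float = 1.0
    epsilon_end: float = 0.05
    epsilon_decay_steps: int = 1000
    gamma: float = 0.99
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must be in [0, 1)")
        for eps in (self.epsilon_start, self.epsilon_end):
            if not 0.0 <= eps <= 1.0:
                raise ValueError("epsilon must be in [0, 1]")
        if self.replay_capacity < self.batch_size:
            raise ValueError("replay capacity must be >= batch size")

    @classmethod
    def from_dict(cls, d: dict) -> "DQNConfig":
        d = dict(d)
        if "hidden_sizes" in d:
            d["hidden_sizes"] = tuple(d["hidden_sizes"])
        return cls(**d)


class ReplayBuffer:
    """Fixed-capacity ring buffer with seeded uniform sampling."""

    def __init__(self, capacity: int, rng: np.random.Generator):
        self.capacity = capacity
        self.rng = rng
        self._data: list[tuple] = []
        self._pos = 0

    def __len__(self) -> int:
        return len(self._data)

    def push(self, s, a, r, s2, done) -> None:
        item = (s, int(a), float(r), s2, bool(done))
        if len(self._data) < self.capacity:
            self._data.append(item)
        else:
            self._data[self._pos] = item
        self._pos = (self._pos + 1) % self.capacity

    def sample(self, batch_size: int):
        idx = self.rng.integers(0, len(self._data), size=batch_size)
        s, a, r, s2, done = zip(*(self._data[i] for i in idx))
        return (
            np.stack(s),
            np.asarray(a),
            np.asarray(r, dtype=float),
            np.stack(s2),
            np.asarray(done, dtype=bool),
        )


def td_target(
    r: np.ndarray, next_q_max: np.ndarray, done: np.ndarray, gamma: float
) -> np.ndarray:
    """Bellman backup target: r + gamma * max_a' Q_target(s', a'), r at terminal."""
    r = np.asarray(r, dtype=float)
    return r + gamma * np.asarray(next_q_max, dtype=float) * (~np.asarray(done, bool))


def dqn_loss(
    states: np.ndarray,
    actions: np.ndarray,
    rewards: np.ndarray,
    next_states: np.ndarray,
    dones: np.ndarray,
    net: MLP,
    target_net: MLP,
    gamma: float,
) -> float:
    """Mean squared TD error of a batch (zero iff predictions equal targets)."""
    q = net(states)
    q_sa = q[np.arange(len(actions)), actions]
    y = td_target(rewards, target_net(next_states).max(axis=1), dones, gamma)
    return float(np.mean((q_sa - y) ** 2))


class DQNAgent:
    """Epsilon-greedy DQN with replay buffer and target network."""

    name = "dqn"

    def __init__(self, obs_dim: int, n_actions: int, config: DQNConfig | None = None):
        self.config = config or DQNConfig()
        self.n_actions = n_actions
        self.obs_dim = obs_dim
        self.rng = np.random.default_rng(self.config.seed)
        sizes = [obs_dim, *self.config.hidden_sizes, n_actions]
        self.net = MLP(sizes, self.rng)
        self.target_net = self.net.clone()
        self.opt = Adam(self.net.parameters(), lr=self.config.learning_rate)
        self.buffer = ReplayBuffer(self.config.replay_capacity, self.rng)
        self.step_count = 0
        self.losses: list[float] = []

    # -- policy ------------------------------------------------------------
    @property
    def epsilon(self) -> float:
        c = self.config
        frac = min(self.step_count / max(c.epsilon_decay_steps, 1), 1.0)
        return c.epsilon_start + frac * (c.epsilon_end - c.epsilon_start)

    def q_values(self, obs) -> np.ndarray:
        return self.net(flatten_obs(obs)[None, :])[0]

    def act(self, obs, explore: bool = True) -> int:
        if explore and self.rng.random() < self.epsilon:
            return int(self.rng.integers(self.n_actions))
        return int(np.argmax(self.q_values(obs)))

    # -- learning ----------------------------------------------------------
    def observe(self, transition) -> None:
        self.buffer.push(
            flatten_obs(transition.state),
            transition.action,
            transition.reward,
            flatten_obs(transition.next_state),
            transition.done,
        )
        self.step_count += 1
        if len(self.buffer) >= self.config.batch_size:
            self.losses.append(self._update())
        if self.step_count % self.config.target_sync_interval == 0:
            self.target_net.set_params(self.net.get_params())

    def end_episode(self) -> None:  # DQN updates per step; nothing to flush
        pass

    def _update(self) -> float:
        c = self.config
        s, a, r, s2, done = self.buffer.sample(c.batch_size)
        y = td_target(r, self.target_net(s2).max(axis=1), done, c.gamma)
        q, cache = self.net.forward(s)
        q_sa = q[np.arange(len(a)), a]
        err = q_sa - y
        grad_out = np.zeros_like(q)
        grad_out[np.arange(len(a)), a] = 2.0 * err / len(a)
        grads = self.net.backward(cache, grad_out)
        self.opt.step(self.net.parameters(), grads)
        return float(np.mean(err**2))

    # -- persistence ---------------------------------------------------------
    def state_dict(self) -> dict:
        return {
            "params": self.net.get_params(),
            "target_params": self.target_net.get_params(),
            "step_count": self.step_count,
        }

    def load_state_dict(self, d: dict) -> None:
        self.net.set_params(d["params"])
        self.target_net.set_params(d["target_params"])
        self.step_count = int(d.get("step_count", 0))
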