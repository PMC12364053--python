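"""Proximal policy optimization with generalized advantage estimation.

An actor network outputs action logits, a critic estimates the state
value.  Advantages are the exponentially weighted sums of TD residuals

    A_t = sum_l (gamma*lambda)^l * delta_{t+l},
    delta_t = r_t + gamma * V(s_{t+1}) - V(s_t),

truncated at episode ends.  The actor maximizes the clipped surrogate

    L_actor = E[min(rho_t * A_t, clip(rho_t, 1-eps, 1+eps) * A_t)],

with rho_t the probability ratio between current and collection-time
policies; the critic minimizes the squared error to the discounted
return; and the combined objective is

    L = -L_actor + c1 * L_critic - c2 * entropy,

so that c2 > 0 rewards exploratory (high-entropy) policies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import MLP, Adam, flatten_obs, softmax

__all__ = ["PPOConfig", "PPOAgent", "gae", "discounted_returns", "ppo_losses"]


@dataclass(frozen=True)
class PPOConfig:
    hidden_sizes: tuple[int, ...] = (256, 128)
    learning_rate: float = 3e-4
    rollout_length: int = 60
    epochs_per_update: int = 4
    minibatch_size: int = 32
    clip_epsilon: float = 0.2
    gae_lambda: float = 0.95
    gamma: float = 0.99
    value_coef: float = 0.5
    entropy_coef: float = 0.01
    normalize_advantages: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must be in [0, 1)")
        if not 0.0 <= self.gae_lambda <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
        if self.clip_epsilon <= 0:
            raise ValueError("clip epsilon must be > 0")
        if self.value_coef < 0 or self.entropy_coef < 0:
            raise ValueError("loss coefficients must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "PPOConfig":
        d = dict(d)
        if "hidden_sizes" in d:
            d["hidden_sizes"] = tuple(d["hidden_sizes"])
        return cls(**d)


def gae(
    rewards: np.ndarray,
    values: np.ndarray,
    dones: np.ndarray,
    gamma: float,
    lam: float,
) -> np.ndarray:
    """Generalized advantage estimates for a rollout of T steps.

    ``values`` has length T+1: V(s_0..s_T), the last entry being the
    bootstrap value of the state after the final step (ignored when that
    step terminated an episode).  Episode boundaries (``dones``) truncate
    both the TD residual and the exponential accumulation.
    """
    rewards = np.asarray(rewards, dtype=float)
    values = np.asarray(values, dtype=float)
    dones = np.asarray(dones, dtype=bool)
    T = rewards.size
    if values.size != T + 1:
        raise ValueError("values must have length len(rewards) + 1")
    adv = np.zeros(T)
    running = 0.0
    for t in range(T - 1, -1, -1):
        nonterminal = 0.0 if dones[t] else 1.0
        delta = rewards[t] + gamma * values[t + 1] * nonterminal - values[t]
        running = delta + gamma * lam * nonterminal * running
        adv[t] = running
    return adv


def discounted_returns(
    rewards: np.ndarray, dones: np.ndarray, gamma: float, bootstrap: float = 0.0
) -> np.ndarray:
    """Discounted rewards-to-go R_t, restarting at episode boundaries.

    A rollout truncated mid-episode is closed with the critic's
    ``bootstrap`` value.
    """
    rewards = np.asarray(rewards, dtype=float)
    dones = np.asarray(dones, dtype=bool)
    out = np.zeros_like(rewards)
    running = bootstrap
    for t in range(rewards.size - 1, -1, -1):
        if dones[t]:
            running = 0.0
        running = rewards[t] + gamma * running
        out[t] = running
    return out


def ppo_losses(
    logits: np.ndarray,
    actions: np.ndarray,
    old_logp: np.ndarray,
    advantages: np.ndarray,
    values: np.ndarray,
    returns: np.ndarray,
    clip_epsilon: float,
    value_coef: float,
    entropy_coef: float,
) -> dict[str, float]:
    """Evaluate the PPO loss components on a batch (no gradients).

    Returns actor (to be maximized), critic, entropy, and the combined
    loss  -actor + c1*critic - c2*entropy.
    """
    p = softmax(logits)
    logp = np.log(np.clip(p, 1e-12, None))
    idx = np.arange(len(actions))
    logp_a = logp[idx, actions]
    ratio = np.exp(logp_a - old_logp)
    if not np.all(np.isfinite(ratio)):
        raise FloatingPointError("non-finite probability ratio in PPO update")
    surr1 = ratio * advantages
    surr2 = np.clip(ratio, 1 - clip_epsilon, 1 + clip_epsilon) * advantages
    actor = float(np.mean(np.minimum(surr1, surr2)))
    critic = float(np.mean((values - returns) ** 2))
    entropy = float(np.mean(-(p * logp).sum(axis=1)))
    combined = -actor + value_coef * critic - entropy_coef * entropy
    return {
        "actor": actor,
        "critic": critic,
        "entropy": entropy,
        "combined": combined,
    }


class PPOAgent:
    """Clipped-surrogate actor-critic over discrete priority adjustments."""

    name = "ppo"

    def __init__(self, obs_dim: int, n_actions: int, config: PPOConfig | None = None):
        self.config = config or PPOConfig()
        self.obs_dim = obs_dim
        self.n_actions = n_actions
        self.rng = np.random.default_rng(self.config.seed)
        hidden = list(self.config.hidden_sizes)
        self.policy = MLP([obs_dim, *hidden, n_actions], self.rng)
        self.value = MLP([obs_dim, *hidden, 1], self.rng)
        self.policy_opt = Adam(self.policy.parameters(), lr=self.config.learning_rate)
        self.value_opt = Adam(self.value.parameters(), lr=self.config.learning_rate)
        self._rollout: list[tuple] = []
        self.loss_log: list[dict] = []

    # -- policy ------------------------------------------------------------
    def action_probabilities(self, obs) -> np.ndarray:
        logits = self.policy(flatten_obs(obs)[None, :])[0]
        return softmax(logits)

    def act(self, obs, explore: bool = True) -> int:
        p = self.action_probabilities(obs)
        if explore:
            return int(self.rng.choice(self.n_actions, p=p))
        return int(np.argmax(p))

    # -- learning ----------------------------------------------------------
    def observe(self, transition) -> None:
        s = flatten_obs(transition.state)
        logits = self.policy(s[None, :])[0]
        p = softmax(logits)
        logp_a = float(np.log(max(p[transition.action], 1e-12)))
        v = float(self.value(s[None, :])[0, 0])
        s_next = flatten_obs(transition.next_state)
        self._rollout.append(
            (s, transition.action, transition.reward, transition.done, logp_a, v, s_next)
        )
        if len(self._rollout) >= self.config.rollout_length:
            self._update()

    def end_episode(self) -> None:  # updates are rollout-driven
        pass

    def _update(self) -> None:
        c = self.config
        s, a, r, done, old_logp, v, s_next = map(np.asarray, zip(*self._rollout))
        self._rollout = []
        s = np.stack(s)
        if done[-1]:
            last_value = 0.0
        else:
            last_value = float(self.value(s_next[-1][None, :])[0, 0])
        values_ext = np.append(v.astype(float), last_value)
        adv = gae(r, values_ext, done, c.gamma, c.gae_lambda)
        returns = discounted_returns(r, done, c.gamma, bootstrap=last_value)
        if c.normalize_advantages and adv.size > 1:
            adv = (adv - adv.mean()) / (adv.std() + 1e-8)

        a = a.astype(int)
        old_logp = old_logp.astype(float)
        n = len(a)
        for _ in range(c.epochs_per_update):
            order = self.rng.permutation(n)
            for start in range(0, n, c.minibatch_size):
                mb = order[start : start + c.minibatch_size]
                self._minibatch_step(s[mb], a[mb], old_logp[mb], adv[mb], returns[mb])

    def _minibatch_step(self, s, a, old_logp, adv, returns) -> None:
        c = self.config
        B = len(a)
        idx = np.arange(B)

        logits, pol_cache = self.policy.forward(s)
        p = softmax(logits)
        logp = np.log(np.clip(p, 1e-12, None))
        logp_a = logp[idx, a]
        ratio = np.exp(logp_a - old_logp)
        if not np.all(np.isfinite(ratio)):
            raise FloatingPointError("non-finite probability ratio in PPO update")

        surr1 = ratio * adv
        surr2 = np.clip(ratio, 1 - c.clip_epsilon, 1 + c.clip_epsilon) * adv
        inside = (ratio > 1 - c.clip_epsilon) & (ratio < 1 + c.clip_epsilon)
        # gradient flows through the ratio only where the unclipped branch is
        # active (or the clip is inactive, where both branches coincide)
        g_ratio = np.where(surr1 <= surr2, adv, np.where(inside, adv, 0.0))
        dlogp_a = g_ratio * ratio  # d(actor)/d logp_a, per sample

        onehot = np.zeros_like(p)
        onehot[idx, a] = 1.0
        H = -(p * logp).sum(axis=1, keepdims=True)
        # combined loss: -actor - c2 * entropy (critic handled separately)
        dlogits = (-dlogp_a[:, None] * (onehot - p)) / B
        dlogits += c.entropy_coef * p * (logp + H) / B
        pol_grads = self.policy.backward(pol_cache, dlogits)
        self.policy_opt.step(self.policy.parameters(), pol_grads)

        v_out, val_cache = self.value.forward(s)
        dv = c.value_coef * 2.0 * (v_out[:, 0] - returns)[:, None] / B
        val_grads = self.value.backward(val_cache, dv)
        self.value_opt.step(self.value.parameters(), val_grads)

        self.loss_log.append(
            ppo_losses(
                logits, a, old_logp, adv, v_out[:, 0], returns,
                c.clip_epsilon, c.value_coef, c.entropy_coef,
            )
        )

    # -- persistence ---------------------------------------------------------
    def state_dict(self) -> dict:
        return {
            "policy_params": self.policy.get_params(),
            "value_params": self.value.get_params(),
        }

    def load_state_dict(self, d: dict) -> None:
        self.policy.set_params(d["policy_params"])
        self.value.set_params(d["value_params"])
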