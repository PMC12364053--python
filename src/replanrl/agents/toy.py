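"""Tiny deterministic sanity environments for the learning algorithms.

These mimic the planning environment's reset/step contract (Transition
records, one-hot observations) at tabular size, so that agent behaviour
can be checked against exact solutions: a two-armed bandit whose optimal
arm is known, and a three-state deterministic chain whose optimal return
is computable by exhaustive search over action sequences.
"""

from __future__ import annotations

import numpy as np

from ..environment import EpisodeDoneError, Transition

__all__ = ["BanditEnv", "ChainMDP"]


class BanditEnv:
    """Single-step, two-action environment with fixed rewards per arm."""

    def __init__(self, rewards: tuple[float, ...] = (0.0, 1.0)):
        self.rewards = tuple(rewards)
        self.n_actions = len(self.rewards)
        self.obs_dim = 1
        self._done = True

    def _obs(self) -> np.ndarray:
        return np.ones(1)

    def reset(self, seed=None) -> np.ndarray:
        self._done = False
        return self._obs()

    def step(self, a: int) -> Transition:
        if self._done:
            raise EpisodeDoneError("bandit episode already finished")
        self._done = True
        return Transition(
            state=self._obs(), action=int(a), reward=self.rewards[a],
            next_state=self._obs(), done=True, info={},
        )


class ChainMDP:
    """Deterministic 3-state, 2-action, 2-step MDP.

    From the start state, action 0 leads to a state whose best follow-up
    pays a large delayed reward; action 1 pays an immediate reward but
    caps the total.  The optimal policy therefore requires bootstrapped
    credit assignment, not greedy reward chasing.

    Transitions: s0 --a0/r=0--> s1,  s0 --a1/r=0.5--> s2;
    from s1: a0 terminates with r=2.0, a1 with r=0.0;
    from s2: a0 terminates with r=0.3, a1 with r=0.6.
    """

    n_states = 3
    n_actions = 2
    obs_dim = 3

    #: (next_state or None, reward) indexed by [state][action]
    dynamics = {
        0: {0: (1, 0.0), 1: (2, 0.5)},
        1: {0: (None, 2.0), 1: (None, 0.0)},
        2: {0: (None, 0.3), 1: (None, 0.6)},
    }

    def __init__(self):
        self._state: int | None = None

    def _obs(self, s: int) -> np.ndarray:
        v = np.zeros(self.n_states)
        v[s] = 1.0
        return v

    def reset(self, seed=None) -> np.ndarray:
        self._state = 0
        return self._obs(0)

    def step(self, a: int) -> Transition:
        if self._state is None:
            raise EpisodeDoneError("chain episode already finished")
        nxt, r = self.dynamics[self._state][int(a)]
        obs = self._obs(self._state)
        done = nxt is None
        next_obs = self._obs(nxt) if nxt is not None else np.zeros(self.n_states)
        tr = Transition(
            state=obs, action=int(a), reward=r,
            next_state=next_obs, done=done, info={},
        )
        self._state = nxt
        return tr
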