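"""Episodic training loop shared by both agents.

Patient-specific training cycles episodes round-robin over the anatomies
provided (typically original, progression, regression); population
training passes a pool of environments built from different phantoms
instead.  All stochasticity lives in the agent (action sampling, replay
sampling, initialization), so a fixed agent seed reproduces the score log
bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TrainingLog", "train", "rollout_episode"]


@dataclass
class TrainingLog:
    episodes: list[dict] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.episodes)

    @property
    def best_score(self) -> float:
        return max((e["best_score"] for e in self.episodes), default=float("nan"))

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def rollout_episode(env, select_action, max_steps: int | None = None):
    """Run one episode under a policy callable; return the transitions."""
    transitions = []
    state = env.reset()
    done = False
    steps = 0
    while not done and (max_steps is None or steps < max_steps):
        a = select_action(state)
        tr = env.step(a)
        transitions.append(tr)
        state = tr.next_state
        done = tr.done
        steps += 1
    return transitions


def train(agent, envs, episodes: int) -> TrainingLog:
    """Train an agent for ``episodes`` episodes, cycling over ``envs``.

    Logs, per episode, the anatomy index, final and best-so-far plan score
    (when the environment exposes them), the episode's total reward and
    step count.  ``episodes=0`` returns an empty log with the agent's
    parameters untouched.
    """
    if not isinstance(envs, (list, tuple)):
        envs = [envs]
    log = TrainingLog()
    for ep in range(episodes):
        env = envs[ep % len(envs)]
        state = env.reset()
        done = False
        total_reward = 0.0
        steps = 0
        while not done:
            a = agent.act(state, explore=True)
            tr = env.step(a)
            agent.observe(tr)
            total_reward += tr.reward
            state = tr.next_state
            done = tr.done
            steps += 1
        agent.end_episode()
        final = getattr(env, "score", total_reward)
        best = getattr(env, "best_score", final)
        log.episodes.append(
            {
                "episode": ep,
                "anatomy": ep % len(envs),
                "steps": steps,
                "total_reward": total_reward,
                "final_score": final,
                "best_score": best,
            }
        )
    return log
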