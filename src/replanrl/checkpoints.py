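"""Single-file agent checkpoints (.npz with a JSON metadata entry)."""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .agents import DQNAgent, DQNConfig, PPOAgent, PPOConfig

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(agent, path) -> None:
    meta = {
        "agent": agent.name,
        "obs_dim": agent.obs_dim,
        "n_actions": agent.n_actions,
        "config": dataclasses.asdict(agent.config),
    }
    arrays = {}
    for key, params in agent.state_dict().items():
        if isinstance(params, list):
            for i, arr in enumerate(params):
                arrays[f"{key}.{i}"] = arr
        else:
            arrays[key] = np.asarray(params)
    np.savez(path, _meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path):
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["_meta"]))
        arrays = {k: data[k] for k in data.files if k != "_meta"}
    state: dict = {}
    for key, arr in arrays.items():
        if "." in key:
            base, idx = key.rsplit(".", 1)
            state.setdefault(base, {})[int(idx)] = arr
        else:
            state[key] = arr
    for key, val in state.items():
        if isinstance(val, dict):
            state[key] = [val[i] for i in sorted(val)]
    cfg = meta["config"]
    if meta["agent"] == "dqn":
        agent = DQNAgent(meta["obs_dim"], meta["n_actions"], DQNConfig.from_dict(cfg))
    elif meta["agent"] == "ppo":
        agent = PPOAgent(meta["obs_dim"], meta["n_actions"], PPOConfig.from_dict(cfg))
    else:
        raise ValueError(f"unknown agent kind {meta['agent']!r}")
    if meta["agent"] == "dqn" and "step_count" in state:
        state["step_count"] = int(np.asarray(state["step_count"]))
    agent.load_state_dict(state)
    return agent
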