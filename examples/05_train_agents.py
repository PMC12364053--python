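"""Train DQN and PPO agents on the priority-tuning task (short demo).

Uses the small phantom preset and a handful of episodes; the full
protocol is 100 episodes cycling over the original, progression, and
regression anatomies (see 06_full_experiment.py).
"""

import dataclasses

import replanrl as rl
from replanrl.agents import train

spec = rl.ExperimentSpec.small(episodes=10)
geom = rl.generate_phantom(spec.phantom, seed=0)
dinf = rl.compute_dose_influence(geom, spec.beams)
env = rl.PlanningEnv(geom, dinf, config=spec.env)
env.reset()
print(f"initial plan score: {env.initial_score:.2f}")

for name, cls, cfg in (("DQN", rl.DQNAgent, spec.dqn),
                       ("PPO", rl.PPOAgent, spec.ppo)):
    agent = cls(env.obs_dim, env.n_actions, dataclasses.replace(cfg, seed=0))
    log = train(agent, env, spec.episodes)
    df = log.to_dataframe()
    print(f"{name}: best plan score over {len(df)} episodes = "
          f"{log.best_score:.2f}; per-episode best = "
          f"{[round(v, 1) for v in df.best_score.tolist()]}")
# 'best' is the best intermediate plan within an episode -- the quantity a
# clinic would keep.  Scores above the initial value mean the agent found
# priority settings that recover clinical-goal points.
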