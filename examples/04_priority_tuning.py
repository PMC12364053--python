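"""Tune priorities by hand through the MDP environment.

Each step applies one of 22 clipped priority adjustments, re-optimizes
the plan (warm-started), and returns the score change as reward.  Here a
hand-picked sequence raises the weights of OAR groups that start out
over their dose limits.
"""

import replanrl as rl

geom = rl.generate_phantom(rl.PhantomConfig.default(), seed=7)
dinf = rl.compute_dose_influence(geom, rl.BeamConfig())
env = rl.PlanningEnv(geom, dinf)

state = env.reset()
print(f"initial plan score: {env.score:.2f} / 150")
table = env.config.action_table
raise_parotids = next(i for i, s in enumerate(table)
                      if s.targets == ("PARL", "PARR") and s.delta > 0)
raise_smg = next(i for i, s in enumerate(table)
                 if s.targets == ("SMGL", "SMGR") and s.delta > 0)
raise_lar = next(i for i, s in enumerate(table)
                 if s.targets == ("LAR", "PHY") and s.delta > 0)

for a in (raise_parotids, raise_smg, raise_lar, raise_parotids):
    tr = env.step(a)
    print(f"  action '{tr.info['action_label']:18s}' reward {tr.reward:+6.2f} "
          f"-> score {tr.info['score']:7.2f}")
print(f"best plan so far: {env.best_score:.2f} at step {env.best_step}")
# Positive rewards mean the re-optimized plan recovered OAR goal points
# without giving up more elsewhere; the sum of rewards always equals the
# total score change.
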