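"""A complete patient-specific experiment at reduced scale.

Builds one synthetic patient (original + progression + regression +
held-out replan anatomy), trains both agents on the three training
anatomies, evaluates them greedily on the replan anatomy, and prints the
comparison table.
"""

import dataclasses

import replanrl as rl

spec = dataclasses.replace(rl.ExperimentSpec.small(episodes=15), seeds=(0, 1))
reports = rl.run_experiment(spec)

for rep in reports:
    print(f"seed {rep.seed}: initial {rep.initial_score:.2f}  " +
          "  ".join(f"{n} best {r.best_score:.2f} (step {r.best_step})"
                    for n, r in rep.agents.items()))

print()
print(rl.compare_agents(reports).to_string(index=False))
# The dosimetric goal table for each seed is in reports[i].goal_table
# (metric value and awarded points per plan, recomputable from the saved
# dose distributions).
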