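# replanrl

A self-contained, desk-scale simulator of **reinforcement-learning-driven
replanning for intensity-modulated proton therapy (IMPT)**.

When a head-and-neck cancer patient's anatomy changes during a proton
therapy course — tumors grow or shrink, tissue along the beam path moves —
the Bragg peaks shift, and the treatment plan must be re-optimized.  In
practice a planner does this by iteratively adjusting the *priority
weights* of a multi-objective optimization until the plan meets its
clinical goals, a slow trial-and-error loop.  `replanrl` casts that loop
as a Markov decision process and trains deep RL agents (DQN and PPO) to
do the tuning, entirely on synthetic anatomies, so every component can be
verified against an exact oracle.

The package provides, as importable modules with an `examples/` gallery
and a thin CLI (`replanrl`):

- **phantom** — synthetic voxelized anatomies (3 target volumes + 12
  organs at risk), morphological tumor progression/regression, and a
  held-out "replan" anatomy;
- **dose** — sparse pencil-beam dose-influence matrices `D` with
  Bragg-like depth-dose profiles (`d = D x`);
- **optimizer** — the weighted inverse-planning objective

  `L(x) = Σ_m ω_CTVm ‖D_CTVm x − d_Rx,m‖² + Σ_k ω_OARk ‖D_OARk x‖²,  x ≥ 0`

  solved by (accelerated) projected gradient descent;
- **dosimetry** — DVHs, the dosimetric metrics `V_d`, `D_v`, `D0%`,
  `Dmean`, and a 150-point plan-quality score over 16 clinical goals;
- **environment** — the tuning MDP: DVH-matrix state (15×100), 22
  clipped priority-adjustment actions (`ω ← clip(ω + Δ_a, 0, 1)`),
  plan re-optimization as the transition, score change as the reward,
  15-step episodes;
- **agents** — DQN (replay buffer, target network, ε-greedy) and PPO
  (clipped surrogate, generalized advantage estimation), in pure numpy;
- **pipeline** — patient-specific experiments: train on the original +
  augmented anatomies, evaluate on the held-out replan anatomy.

## Worked example

Build a phantom, optimize a plan under the default priorities
(ω = 0.8 for targets, 0.2 for OARs), and score it:

```python
import replanrl as rl

geom = rl.generate_phantom(rl.PhantomConfig.default(), seed=7)
dinf = rl.compute_dose_influence(geom, rl.BeamConfig())
x, report = rl.optimize_plan(dinf, rl.default_priorities(geom), geom.prescriptions)
dose = rl.compute_dose(dinf, x)
score = rl.score_plan(dose, geom, rl.default_goals(geom.prescriptions))
print(score.total)            # 94.13
```

The per-goal table (`examples/03_plan_scoring.py`) shows where those
points come from — e.g. both parotids start above their 26 GyRBE mean-dose
goal and score only partially:

```
PARL Dmean          29.62    3.32 / 7.5
PARR Dmean          31.79    0.81 / 7.5
total plan score: 94.13 / 150
```

Tuning priorities through the environment recovers those points; each
step re-optimizes the plan and returns the score change as reward
(`examples/04_priority_tuning.py`):

```
initial plan score: 94.13 / 150
  action 'PARL/PARR +0.1' reward  +8.78 -> score  102.91
  action 'SMGL/SMGR +0.1' reward  +0.06 -> score  102.97
  action 'LAR/PHY +0.1  ' reward  +0.65 -> score  103.62
  action 'PARL/PARR +0.1' reward  +1.30 -> score  104.92
```

Trained agents learn the same thing from scratch
(`examples/05_train_agents.py`, small phantom, 10 episodes):

```
initial plan score: 90.00
DQN: best plan score over 10 episodes = 105.00
PPO: best plan score over 10 episodes = 105.00
```

A full patient-specific experiment — train on original/progression/
regression anatomies, evaluate greedily on the held-out replan anatomy —
is `examples/06_full_experiment.py` or, from the shell:

```bash
replanrl phantom build --small --seed 0 --outdir out/phantom
replanrl train --agent dqn --mode patient --small --episodes 30 --seed 0 --outdir out
replanrl evaluate --checkpoint out/dqn_patient_seed0.npz --small --outdir out/eval
replanrl report --indir out
```

## Scope

This is a methods simulator, not a treatment planning system: the dose
model is a parametric pencil beam on a schematic phantom, and scores say
nothing quantitative about clinical plans.  See `docs/methods.md` for the
model details, default calibrations, numerical choices, and known
limitations (in particular why coverage objectives act as a score ceiling
under the symmetric quadratic objective).
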