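# Methods

`replanrl` is a desk-scale simulator of priority-driven replanning in
intensity-modulated proton therapy (IMPT).  It reproduces, end to end and
without any patient data, the computational structure of an adaptive
planning workflow: a voxelized anatomy, a linear dose model, weighted
inverse plan optimization, dose-volume-histogram (DVH) plan scoring, and
reinforcement-learning agents that tune the optimization priorities.
This note records the model, its assumptions, the defaults and why they
were chosen, and what the synthetic setting does and does not show.

## Dose model

Dose is linear in the beamlet intensities: `d = D x` with `x >= 0`.  The
dose-influence matrix `D` is built from a simplified pencil-beam model:
each beamlet deposits a parametric Bragg-like depth-dose along its ray
(entrance plateau `0.35` of the peak, broad proximal Gaussian of width
14 mm, sharp distal Gaussian falloff of width 3 mm) times a lateral
Gaussian.  By default each beam's peak is placed at the isocenter depth
(the centroid of all target voxels), which is what a target-centred spot
arrangement does.  Any smooth nonnegative linear operator supports the
method; the Bragg shape keeps the proton-therapy depth-selectivity
visible in the DVHs.

The default lateral sigma is 12 mm with 5 mm spot spacing — deliberately
coarse compared with clinical proton spots (3–8 mm).  At the default grid
resolution (64x64 voxels of 2 mm, a single axial slice) and beamlet count
(3 beams x 15 spots), this width is what makes organ-at-risk (OAR)
sparing genuinely compete with target coverage: with narrow kernels the
optimizer spares every OAR almost for free at any reasonable priority
setting and the tuning problem degenerates (every action has zero
reward).  The kernel width is therefore a task-difficulty parameter, not
a beam-physics claim.

## Phantom

The default phantom has three **disjoint** clinical target volumes
(CTV1/CTV2/CTV3, prescriptions 70 / 59.85 / 53.90 GyRBE) and twelve OARs
drawn from the standard head-and-neck roster (brainstem, spinal cord,
mandible, larynx, pharynx, paired parotids, cochleas, submandibular
glands, esophagus).  The CTVs are modelled as independent targets (a
primary volume plus two nodal volumes) rather than nested contours:
nested masks with per-structure uniform prescriptions put contradictory
targets on shared voxels and systematically depress the primary target
dose, an artefact of the uniform-prescription objective rather than of
the tuning method.  Several OARs (parotids, submandibular glands,
larynx, pharynx, spinal cord) abut the targets or sit in the beam
paths; the rest are peripheral.  OARs never overlap targets, so a dose
that is exactly the prescription on each target and zero elsewhere
meets every clinical goal — this is the scoring-ceiling reference used
in the tests.

Anatomical change is simulated morphologically: *progression* dilates
every CTV by a physical margin (default 2 mm), *regression* erodes by
3 mm; the structuring element is a discrete ball with per-axis radius
`round(margin / spacing)`, and axes of extent one (single-slice grids)
get radius zero.  The held-out *replan* anatomy — the stand-in for the
anatomy captured at replanning time — is deliberately distinct from both
training augmentations: anisotropic CTV dilation (3 mm / 1 mm / 0 mm per
axis) plus a rigid 2-voxel shift of the left parotid.

## Inverse plan optimization

The planning loss is the weighted least-squares objective

```
L(x) = sum_m w_CTVm ||D_CTVm x - d_Rx,m||^2 + sum_k w_OARk ||D_OARk x||^2,
x >= 0,
```

with uniform prescription vectors (every voxel of a target carries the
target's scalar prescription) and weights `w` in `[0, 1]` acting as the
treatment planning priorities.  Voxels belonging to several structures
contribute to every term they belong to.

The solver is projected gradient descent with step `1/L`, where `L` is
twice the largest eigenvalue of the weighted normal operator, estimated
by a deterministic 50-step power iteration.  Three step rules are
provided; the default, `accelerated`, adds FISTA-style momentum with
adaptive restart and a monotone safeguard (if the momentum candidate
would increase the objective, the momentum is reset and a plain —
halved, if necessary — projected-gradient step is taken).  The objective
trace is non-increasing under every rule.  Momentum matters: random beam
geometries routinely produce normal-matrix condition numbers beyond
1e8, where the plain iteration needs hundreds of thousands of steps for
four digits of objective accuracy and the accelerated rule needs a few
thousand.  Defaults: 1000 iterations maximum, relative objective
decrease below 1e-5 as the stopping rule, warm starting on (inside an
episode each re-optimization starts from the previous optimum; across
episodes the fluence restarts from zero).

Degenerate inputs: all-zero weights return the starting fluence with
objective zero; non-finite objectives or gradients raise a numerical
error naming the iteration; a beamlet whose ray misses the grid keeps an
all-zero column (with a warning) so beamlet indexing is stable across
anatomies.

## Plan scoring

Plan quality is the sum of 16 piecewise-linear objective scores, 150
points total: the four target objectives (coverage `V_Rx >= 98%` for each
CTV and the CTV1 hot-spot `D0% <= 110% Rx`) carry 15 points each, the
twelve OAR objectives 7.5 points each.  Metric conventions: `V_d` is the
percent of a structure's volume at or above dose `d`; `D_v` the dose at
rank `ceil(v / voxel_volume)` of the descending-sorted voxel doses (so
`D0.03cc` with 0.008 cc voxels is the 4th-hottest voxel); `D0%` the
maximum; `Dmean` the voxelwise mean.  Each score is maximal when the
goal is met, zero at a configurable zero-score level — goal x 1.25 for
upper limits, goal minus 5 percentage points for coverage — and linear
in between.  Both levels and the per-goal point allocation are
configurable; the defaults preserve the 150-point total and the
dominance of target objectives.

A structural property of this simulator worth stating plainly: under the
symmetric quadratic objective with the prescription as the target, the
optimized target dose distribution centres *at* the prescription, so
roughly half the voxels sit marginally below it and `V_Rx` hovers near
50% regardless of the priorities.  The coverage objectives therefore act
as a fixed ceiling (45 of 150 points are out of reach of the optimizer)
rather than a gradient, and the attainable score band on the default
phantom is roughly 90–105.  Clinical systems escape this knife-edge by
plan normalization or one-sided underdose penalties, both of which are
outside this model.  The learning signal here lives in the hot-spot and
OAR components, which is also where the interesting trade-offs are.

## The tuning MDP

State: the normalized cumulative DVH matrix of all 15 structures at 100
dose bins (axis 0 to 1.2x the highest prescription), flattened to 1500
dimensions for the networks.  Actions: 22 discrete priority adjustments
— a signed increment of 0.1 to one of 11 targets (the three CTVs
individually and eight OAR groups that respect bilateral symmetry:
brainstem, spinal cord, mandible, larynx+pharynx, parotids, cochleas,
submandibular glands, esophagus), clipped to `[0, 1]`.  With a 15-step
horizon, increments of 0.1 can traverse the full weight range of any
single target.  Weights are snapped to 12 decimals after each update so
decimal increments compose exactly and bounds are hit precisely; an
action clipped into a no-op skips re-optimization and has reward exactly
zero.  Transition: re-optimize the plan under the new priorities
(warm-started).  Reward: the change in total plan score, so episode
rewards telescope exactly to final minus initial score.  Episodes start
from the default priorities w0 (0.8 for CTVs, 0.2 for OARs — calibrated
so that several OAR objectives start in their linear scoring bands and
both action directions matter) and end after 15 steps or on reaching
150.  The environment is deterministic given the anatomy and action
sequence; the best intermediate plan (score, fluence, priorities) is
tracked so evaluation can report the best plan rather than the last.

## Agents

Both agents operate on the flattened DVH state with two-hidden-layer
ReLU networks (256/128 units by default; 64/32 in the small experiment
preset), implemented directly in numpy with hand-written backprop and
Adam — at these sizes a deep-learning framework buys nothing and costs a
heavyweight dependency.

**DQN**: epsilon-greedy exploration with a linear schedule (1.0 to 0.05
over 1000 steps), uniform replay (capacity 10 000, batch 64), a target
network synced every 100 environment steps, squared TD error against
`y = r + gamma * max_a' Q_target(s', a')` (y = r at terminal states).

**PPO**: actor-critic with generalized advantage estimation
(`A_t = sum_l (gamma*lambda)^l delta_{t+l}` truncated at episode ends,
lambda = 0.95), clipped surrogate objective (clip 0.2), critic regressed
on discounted returns (bootstrapped when a rollout truncates an
episode), combined loss `-actor + 0.5 * critic - 0.01 * entropy`,
rollouts of 60 steps, 4 epochs of minibatch 32 per update, advantages
normalized per rollout.  Gradients flow through the probability ratio
only where the unclipped branch of the surrogate is active.

All hyperparameters are conventional defaults, configurable, and not a
reproduction of any published setting.  All randomness (initialization,
exploration, replay sampling, minibatch shuffling) comes from a single
seeded generator per agent, so training logs are bitwise reproducible
per seed.

Patient-specific training cycles episodes round-robin over the original,
progression, and regression anatomies; population mode cycles over a
pool of phantoms with jittered layouts instead.  Evaluation runs the
greedy policy on the held-out replan anatomy, may extend the horizon
beyond 15, and reports the best intermediate plan.

## Problem sizes and numerical choices

The shipped experiment presets are sized for a single CPU: the default
phantom is a 64x64x1 grid (45 beamlets), the small preset 48x48x1 (33
beamlets) with structure radii scaled by 48/64 to keep the layout's
adjacency relations.  The end-to-end improvement check trains each agent
for 30 episodes on the small phantom with three seeds and compares the
median best plan score against the default-priority plan; the default
100-episode protocol is the same loop with a larger budget.  Environment
resets are cached per instance (the w0 plan is solved once), and
per-structure submatrices of `D` are cached per anatomy.

Ties and degenerate cases: `D0%` with `v = 0` returns the maximum dose;
hot-volume ranks are clamped to `[1, n]`; empty structures produce
all-zero, flagged DVH rows and raise on metric evaluation; goal tables
whose zero-score level lies on the wrong side of the goal are rejected
at construction.

## What the synthetic setting shows — and does not

Passing tests demonstrate that the machinery is correct (optimizer
against brute-force nonnegative-quadratic enumeration, DVH metrics
against sort-and-count, GAE/TD/PPO losses against closed forms, exact
reward telescoping, deterministic replay) and that the full loop learns:
both agents reliably recover the reachable score headroom on the
synthetic task.  The phantom does not emulate tissue heterogeneity,
range uncertainty, setup error, realistic organ shapes, or the
deformation patterns of real anatomical change, and the dose model is
not a transport calculation — so scores, margins, and learned policies
here say nothing quantitative about clinical plan quality.  The
simulator's claim is architectural: the priority-tuning MDP, its reward
shaping, and the agents are implemented faithfully and verifiably at a
scale where every component can be checked against an oracle.
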