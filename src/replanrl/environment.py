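"""The priority-tuning Markov decision process.

State: the normalized cumulative DVH matrix of all rostered structures
(default 15 structures x 100 dose bins).  Actions: a discrete table of 22
clinically constrained priority adjustments -- a signed increment applied
to one CTV weight or to one OAR group's weights, clipped to [0, 1].
Transition: the plan is re-optimized under the new priorities (warm-started
from the previous fluence).  Reward: the change in the 150-point plan
quality score.  Episodes run for at most ``horizon`` steps (default 15) or
terminate early when the maximum score is reached.

The environment is deterministic given (anatomy, action sequence):
replaying a sequence of actions reproduces every reward bitwise.  The
reset/step contract mirrors the de-facto episodic RL environment API,
returning a :class:`Transition` record per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dose import DoseInfluence
from .dosimetry import ClinicalGoal, DVHState, PlanScore, compute_dvh, default_goals, score_plan
from .optimizer import OptimizerSettings, PlanProblem, compute_dose, default_priorities
from .phantom import PhantomGeometry

__all__ = [
    "ActionSpec",
    "EnvConfig",
    "Transition",
    "EpisodeDoneError",
    "default_action_table",
    "apply_action",
    "PlanningEnv",
]


class EpisodeDoneError(RuntimeError):
    """step() called on a finished episode."""


@dataclass(frozen=True)
class ActionSpec:
    """One priority adjustment: add ``delta`` to every target's weight."""

    targets: tuple[str, ...]
    delta: float

    @property
    def label(self) -> str:
        sign = "+" if self.delta >= 0 else "-"
        return f"{'/'.join(self.targets)} {sign}{abs(self.delta):g}"


#: Tuning targets of the default action table: the three CTVs individually
#: plus eight OAR groups respecting bilateral-organ symmetry.
DEFAULT_ACTION_TARGETS: tuple[tuple[str, ...], ...] = (
    ("CTV1",), ("CTV2",), ("CTV3",),
    ("BRS",), ("SC",), ("MAN",),
    ("LAR", "PHY"),
    ("PARL", "PARR"),
    ("COCHL", "COCHR"),
    ("SMGL", "SMGR"),
    ("ESO",),
)


def default_action_table(delta: float = 0.1) -> tuple[ActionSpec, ...]:
    """22 actions: +/- ``delta`` for each of the 11 tuning targets.

    With a 15-step horizon and weights bounded in [0, 1], increments of 0.1
    let an agent traverse the whole range of any single priority within an
    episode.
    """
    table = []
    for targets in DEFAULT_ACTION_TARGETS:
        table.append(ActionSpec(targets, +delta))
        table.append(ActionSpec(targets, -delta))
    return tuple(table)


def apply_action(
    weights: dict[str, float], a: int, table: tuple[ActionSpec, ...]
) -> dict[str, float]:
    """Clipped priority update: w <- clip(w + delta_a, 0, 1) on the targets."""
    if not 0 <= a < len(table):
        raise IndexError(f"action index {a} out of range [0, {len(table)})")
    new = dict(weights)
    for name in table[a].targets:
        # round to 12 decimals so decimal increments compose exactly and
        # clipped bounds are hit precisely after repeated adjustments
        new[name] = float(np.clip(round(new[name] + table[a].delta, 12), 0.0, 1.0))
    return new


@dataclass(frozen=True)
class EnvConfig:
    action_table: tuple[ActionSpec, ...] = field(default_factory=default_action_table)
    horizon: int = 15
    terminal_score: float = 150.0
    gamma: float = 0.99  # exposed to agents; the env itself does not discount
    initial_ctv_weight: float = 0.8
    initial_oar_weight: float = 0.2
    n_bins: int = 100
    dose_max: float | None = None
    optimizer: OptimizerSettings = field(default_factory=OptimizerSettings)

    def __post_init__(self):
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must be in [0, 1)")


@dataclass
class Transition:
    """One environment step; ``reward`` is exactly score(next) - score(cur)."""

    state: DVHState
    action: int
    reward: float
    next_state: DVHState
    done: bool
    info: dict


class PlanningEnv:
    """Reset/step environment wrapping one anatomy's plan optimization."""

    def __init__(
        self,
        geom: PhantomGeometry,
        dinf: DoseInfluence,
        goals: list[ClinicalGoal] | None = None,
        config: EnvConfig | None = None,
    ):
        self.geom = geom
        self.dinf = dinf
        self.config = config or EnvConfig()
        self.goals = goals if goals is not None else default_goals(geom.prescriptions)
        self.problem = PlanProblem(dinf, geom.prescriptions)
        names = set(geom.masks)
        for spec in self.config.action_table:
            unknown = set(spec.targets) - names
            if unknown:
                raise ValueError(f"action targets {sorted(unknown)} not in roster")
        self._reset_cache: tuple | None = None
        self._state: DVHState | None = None
        self._done = True

    # -- observation / action space -------------------------------------
    @property
    def n_actions(self) -> int:
        return len(self.config.action_table)

    @property
    def observation_shape(self) -> tuple[int, int]:
        return (len(self.geom.masks), self.config.n_bins)

    @property
    def obs_dim(self) -> int:
        m, n = self.observation_shape
        return m * n

    # -- episode bookkeeping ---------------------------------------------
    @property
    def score(self) -> float:
        return self._score.total

    @property
    def best_score(self) -> float:
        return self._best_score

    def _evaluate(self, x: np.ndarray) -> tuple[DVHState, PlanScore]:
        dose = compute_dose(self.dinf, x)
        dvh = compute_dvh(
            dose, self.geom, n_bins=self.config.n_bins, dose_max=self.config.dose_max
        )
        return dvh, score_plan(dose, self.geom, self.goals)

    def reset(self, seed: int | None = None) -> DVHState:
        """Start an episode: optimize once under the default priorities w0.

        The w0 solution is cached per environment instance, so repeated
        resets are bitwise identical and cost one optimization in total.
        """
        del seed  # the environment is deterministic; accepted for API parity
        w0 = default_priorities(
            self.geom,
            ctv_weight=self.config.initial_ctv_weight,
            oar_weight=self.config.initial_oar_weight,
        ).as_dict()
        if self._reset_cache is None:
            x, report = self.problem.solve(w0, settings=self.config.optimizer)
            dvh, score = self._evaluate(x)
            self._reset_cache = (x, report, dvh, score)
        x, report, dvh, score = self._reset_cache
        self.priorities = dict(w0)
        self._x = x.copy()
        self._state = dvh
        self._score = score
        self.initial_score = score.total
        self._steps = 0
        self._done = False
        self._best_score = score.total
        self._best_x = x.copy()
        self._best_priorities = dict(w0)
        self._best_step = 0
        self.trace: list[dict] = []
        return dvh

    def step(self, a: int) -> Transition:
        if self._done or self._state is None:
            raise EpisodeDoneError("step() called before reset() or after done")
        before = dict(self.priorities)
        after = apply_action(before, a, self.config.action_table)
        if after == before:
            # clipped into a no-op: the plan is unchanged by definition
            x, report = self._x, None
            dvh, score = self._state, self._score
        else:
            x0 = self._x if self.config.optimizer.warm_start else None
            x, report = self.problem.solve(
                after, settings=self.config.optimizer, x0=x0
            )
            dvh, score = self._evaluate(x)
        reward = score.total - self._score.total
        self._steps += 1
        done = (self._steps >= self.config.horizon) or (
            score.total >= self.config.terminal_score
        )
        if score.total > self._best_score:
            self._best_score = score.total
            self._best_x = x.copy()
            self._best_priorities = dict(after)
            self._best_step = self._steps
        info = {
            "step": self._steps,
            "priorities_before": before,
            "priorities_after": after,
            "plan_score": score,
            "score": score.total,
            "best_score": self._best_score,
            "best_step": self._best_step,
            "optimizer_report": report,
            "action_label": self.config.action_table[a].label,
        }
        tr = Transition(
            state=self._state, action=a, reward=reward,
            next_state=dvh, done=done, info=info,
        )
        self.trace.append(
            {
                "step": self._steps,
                "action": a,
                "action_label": info["action_label"],
                "reward": reward,
                "score": score.total,
                "best_score": self._best_score,
            }
        )
        self.priorities = after
        self._x = x
        self._state = dvh
        self._score = score
        self._done = done
        return tr

    @property
    def best_fluence(self) -> np.ndarray:
        return self._best_x.copy()

    @property
    def best_priorities(self) -> dict[str, float]:
        return dict(self._best_priorities)

    @property
    def best_step(self) -> int:
        return self._best_step
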