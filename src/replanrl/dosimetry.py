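"""Dose-volume histograms, dosimetric metrics, and the 150-point plan score.

Plan quality is quantified by a score of at most 150 points summed over
16 clinical objectives on 15 structures (3 CTVs, 12 OARs):

======================  =============================  ==========
structure               planning objective             max points
======================  =============================  ==========
CTV1                    V_Rx >= 98% of volume          15
CTV1                    D0% <= 110% of Rx              15
CTV2                    V_Rx >= 98%                    15
CTV3                    V_Rx >= 98%                    15
BRS, SC                 D0.03cc <= 30 GyRBE            7.5 each
MAN                     V70 <= 10% of volume           7.5
LAR / PHY / ESO         Dmean <= 45 / 50 / 40 GyRBE    7.5 each
PARL, PARR              Dmean <= 26 GyRBE              7.5 each
COCHL, COCHR            Dmean <= 35 GyRBE              7.5 each
SMGL, SMGR              Dmean <= 35 GyRBE              7.5 each
======================  =============================  ==========

Each objective is scored by a monotone piecewise-linear curve: full points
when the goal is met or bettered, zero at a configurable zero-score level
(default: goal x 1.25 for upper limits, goal - 5 percentage points for
coverage), linear in between.  The per-step change of the total score is
the reinforcement-learning reward, so these curves shape the entire
learning signal.

Metric definitions: V_d is the percent of a structure's volume receiving
at least dose d; D_v the minimum dose of the hottest v (cc or % of
volume), evaluated at rank ceil(v / voxel_volume) of the descending-sorted
voxel doses; D0% is the structure maximum; Dmean the voxelwise mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml

from .optimizer import DoseDistribution
from .phantom import PhantomGeometry

__all__ = [
    "DVHState",
    "ClinicalGoal",
    "PlanScore",
    "GoalConfigError",
    "compute_dvh",
    "metric_value",
    "score_goal",
    "score_plan",
    "default_goals",
    "goals_from_dicts",
    "load_goals",
]


class GoalConfigError(ValueError):
    """Raised for inconsistently configured clinical goals."""


@dataclass(frozen=True)
class DVHState:
    """Normalized cumulative DVH matrix: the RL state.

    ``matrix[s, b]`` is the fraction of structure ``structure_order[s]``'s
    volume receiving at least ``dose_axis[b]`` GyRBE.  Rows of empty
    structures are all zero and listed in ``empty_structures``.
    """

    matrix: np.ndarray
    dose_axis: np.ndarray
    structure_order: tuple[str, ...]
    empty_structures: frozenset[str] = frozenset()

    def flatten(self) -> np.ndarray:
        return self.matrix.ravel().copy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def row(self, name: str) -> np.ndarray:
        return self.matrix[self.structure_order.index(name)]


def compute_dvh(
    dose: DoseDistribution | np.ndarray,
    geom: PhantomGeometry,
    n_bins: int = 100,
    dose_max: float | None = None,
) -> DVHState:
    """Cumulative DVH on a uniform dose axis from 0 to ``dose_max``.

    ``dose_max`` defaults to 1.2 x the highest prescription, so the state
    matrix covers the clinically relevant range including modest hot spots.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = dose.values if isinstance(dose, DoseDistribution) else np.asarray(dose)
    if dose_max is None:
        dose_max = 1.2 * max(geom.prescriptions.values())
    if dose_max <= 0:
        raise ValueError("dose_max must be > 0")
    axis = np.linspace(0.0, dose_max, n_bins)

    order = tuple(geom.masks)
    matrix = np.zeros((len(order), n_bins))
    empty = set()
    for i, name in enumerate(order):
        idx = geom.structure_indices(name)
        if idx.size == 0:
            empty.add(name)
            continue
        d = np.sort(values[idx])
        # fraction of voxels with dose >= axis[b], as an exact count ratio
        matrix[i] = (d.size - np.searchsorted(d, axis, side="left")) / d.size
    return DVHState(
        matrix=matrix,
        dose_axis=axis,
        structure_order=order,
        empty_structures=frozenset(empty),
    )


@dataclass(frozen=True)
class ClinicalGoal:
    """One dosimetric planning objective and its scoring curve.

    ``metric`` is one of ``"V"`` (volume at threshold dose, in %),
    ``"D_cc"`` (dose to the hottest ``param`` cc), ``"D_pct"`` (dose to the
    hottest ``param`` % of volume; 0 means the maximum dose), ``"Dmean"``.
    ``limit`` is the goal level in the metric's units; ``direction`` says
    whether the clinically favorable side is ``at_least`` (coverage) or
    ``at_most`` (dose/volume limits).  ``zero_level`` is where the awarded
    points reach zero; between it and ``limit`` the score is linear.
    """

    structure: str
    metric: str
    limit: float
    direction: str
    max_points: float
    param: float | None = None
    zero_level: float | None = None

    def __post_init__(self):
        if self.metric not in ("V", "D_cc", "D_pct", "Dmean"):
            raise GoalConfigError(f"unknown metric {self.metric!r}")
        if self.direction not in ("at_least", "at_most"):
            raise GoalConfigError(f"unknown direction {self.direction!r}")
        if self.max_points <= 0:
            raise GoalConfigError("max_points must be > 0")
        if self.metric == "V" and self.param is None:
            raise GoalConfigError("V metric needs a threshold dose param")
        z = self.resolved_zero_level()
        if self.direction == "at_most" and z <= self.limit:
            raise GoalConfigError(
                f"{self.label}: zero-score level {z} must exceed the goal {self.limit}"
            )
        if self.direction == "at_least" and z >= self.limit:
            raise GoalConfigError(
                f"{self.label}: zero-score level {z} must be below the goal {self.limit}"
            )

    def resolved_zero_level(
        self, beta: float = 0.25, delta: float = 5.0
    ) -> float:
        """Default zero-score level: goal x (1+beta) for limits, goal - delta
        (percentage points) for coverage."""
        if self.zero_level is not None:
            return self.zero_level
        if self.direction == "at_most":
            return self.limit * (1.0 + beta)
        return self.limit - delta

    @property
    def label(self) -> str:
        if self.metric == "V":
            return f"{self.structure} V{self.param:g}"
        if self.metric == "D_cc":
            return f"{self.structure} D{self.param:g}cc"
        if self.metric == "D_pct":
            return f"{self.structure} D{self.param:g}%"
        return f"{self.structure} Dmean"


@dataclass(frozen=True)
class PlanScore:
    """Per-goal points and their total on the 0-150 scale."""

    per_goal: dict[str, float]
    per_goal_value: dict[str, float]
    total: float

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "per_goal": dict(self.per_goal),
            "per_goal_value": dict(self.per_goal_value),
        }


def metric_value(
    dose: DoseDistribution | np.ndarray, geom: PhantomGeometry, goal: ClinicalGoal
) -> float:
    """Evaluate a goal's dosimetric metric on a dose distribution."""
    values = dose.values if isinstance(dose, DoseDistribution) else np.asarray(dose)
    idx = geom.structure_indices(goal.structure)
    if idx.size == 0:
        raise ValueError(f"structure {goal.structure!r} is empty")
    d = values[idx]
    if goal.metric == "V":
        return 100.0 * np.count_nonzero(d >= goal.param) / d.size
    if goal.metric == "Dmean":
        return float(d.mean())
    if goal.metric == "D_cc":
        rank = math.ceil(goal.param / geom.voxel_volume)
    else:  # D_pct; param = 0 denotes the maximum dose
        rank = math.ceil(goal.param / 100.0 * d.size) if goal.param else 1
    rank = min(max(rank, 1), d.size)
    return float(np.sort(d)[::-1][rank - 1])


def score_goal(value: float, goal: ClinicalGoal) -> float:
    """Piecewise-linear points for a metric value.

    Full points when the goal is met or bettered, zero at/beyond the
    zero-score level, linear in between; monotone in the clinically
    favorable direction.
    """
    zero = goal.resolved_zero_level()
    if goal.direction == "at_most":
        if value <= goal.limit:
            return goal.max_points
        if value >= zero:
            return 0.0
        return goal.max_points * (zero - value) / (zero - goal.limit)
    if value >= goal.limit:
        return goal.max_points
    if value <= zero:
        return 0.0
    return goal.max_points * (value - zero) / (goal.limit - zero)


def score_plan(
    dose: DoseDistribution | np.ndarray,
    geom: PhantomGeometry,
    goals: list[ClinicalGoal],
) -> PlanScore:
    """Total plan quality: the sum of per-goal scores (max 150 by default)."""
    per_goal = {}
    per_value = {}
    for goal in goals:
        v = metric_value(dose, geom, goal)
        per_goal[goal.label] = score_goal(v, goal)
        per_value[goal.label] = v
    return PlanScore(
        per_goal=per_goal, per_goal_value=per_value, total=sum(per_goal.values())
    )


def default_goals(
    prescriptions: dict[str, float],
    ctv_points: float = 15.0,
    oar_points: float = 7.5,
) -> list[ClinicalGoal]:
    """The default 16-objective goal table (4 x 15 + 12 x 7.5 = 150 points).

    CTV coverage goals use each target's own prescription as the V-metric
    threshold; the CTV1 hot-spot goal caps the maximum dose at 110% of its
    prescription.  OAR limits follow typical head-and-neck tolerances.
    """
    ctvs = sorted(prescriptions)
    goals = []
    for name in ctvs:
        rx = prescriptions[name]
        goals.append(
            ClinicalGoal(name, "V", limit=98.0, direction="at_least",
                         max_points=ctv_points, param=rx)
        )
    rx1 = prescriptions[ctvs[0]]
    goals.append(
        ClinicalGoal(ctvs[0], "D_pct", limit=1.10 * rx1, direction="at_most",
                     max_points=ctv_points, param=0.0)
    )
    oar_defs = [
        ("BRS", "D_cc", 30.0, 0.03),
        ("SC", "D_cc", 30.0, 0.03),
        ("MAN", "V", 10.0, 70.0),
        ("LAR", "Dmean", 45.0, None),
        ("PHY", "Dmean", 50.0, None),
        ("PARL", "Dmean", 26.0, None),
        ("PARR", "Dmean", 26.0, None),
        ("COCHL", "Dmean", 35.0, None),
        ("COCHR", "Dmean", 35.0, None),
        ("SMGL", "Dmean", 35.0, None),
        ("SMGR", "Dmean", 35.0, None),
        ("ESO", "Dmean", 40.0, None),
    ]
    for name, metric, limit, param in oar_defs:
        goals.append(
            ClinicalGoal(name, metric, limit=limit, direction="at_most",
                         max_points=oar_points, param=param)
        )
    return goals


def plot_dvh(dvhs, labels=None, structures=None, ax=None):
    """Overlay cumulative DVH curves for one or more plans.

    ``dvhs`` is a single :class:`DVHState` or a list of them (e.g. initial
    vs. agent plans, drawn with different line styles); ``structures``
    restricts the curves shown.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if not isinstance(dvhs, (list, tuple)):
        dvhs = [dvhs]
    if labels is None:
        labels = [f"plan {i}" for i in range(len(dvhs))]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    styles = ["-", "--", ":", "-."]
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for k, (dvh, label) in enumerate(zip(dvhs, labels)):
        names = structures or dvh.structure_order
        for i, name in enumerate(names):
            ax.plot(
                dvh.dose_axis, 100 * dvh.row(name),
                linestyle=styles[k % len(styles)],
                color=colors[i % len(colors)],
                label=f"{name} ({label})" if len(dvhs) > 1 else name,
                linewidth=1.2,
            )
    ax.set_xlabel("dose (GyRBE)")
    ax.set_ylabel("volume (%)")
    ax.set_ylim(0, 102)
    ax.legend(fontsize=7, ncol=2)
    return ax


def goals_from_dicts(entries: list[dict]) -> list[ClinicalGoal]:
    return [ClinicalGoal(**e) for e in entries]


def load_goals(path) -> list[ClinicalGoal]:
    with open(path) as fh:
        return goals_from_dicts(yaml.safe_load(fh))
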