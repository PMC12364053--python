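"""Weighted inverse plan optimization by projected gradient descent.

The fluence-map optimization problem is the weighted least-squares loss

    L(x) = sum_m w_CTVm ||D_CTVm x - d_Rx,m||^2  +  sum_k w_OARk ||D_OARk x||^2
    s.t.  x_j >= 0,

where x is the vector of beamlet intensities, D_S the rows of the
dose-influence matrix belonging to structure S, d_Rx,m the (uniform)
prescription vector of the m-th target, and the weights w in [0, 1] are the
treatment planning priorities that the tuning agent adjusts.  Voxels shared
by several structures contribute to every term they belong to.

The solver iterates x <- max(x - eta * grad L, 0).  The default step is the
inverse Lipschitz constant of the gradient (2 * lambda_max of the weighted
normal operator, estimated by power iteration), with an Armijo-style
halving safeguard; a pure backtracking rule is available.  Warm starting
from the previous optimum is the intended mode inside a tuning episode,
where consecutive problems differ only by one priority increment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .dose import DoseInfluence

__all__ = [
    "PriorityVector",
    "OptimizerSettings",
    "ConvergenceReport",
    "NumericalError",
    "PlanProblem",
    "DoseDistribution",
    "objective",
    "optimize_plan",
    "compute_dose",
    "default_priorities",
]


class NumericalError(RuntimeError):
    """Non-finite objective or gradient during optimization."""


@dataclass(frozen=True)
class PriorityVector:
    """Per-structure priority weights w in [0, 1] (the tunable TPPs)."""

    weights: dict[str, float]

    def __post_init__(self):
        for name, w in self.weights.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"weight for {name!r} out of [0, 1]: {w}")

    def __getitem__(self, name: str) -> float:
        return self.weights[name]

    def as_dict(self) -> dict[str, float]:
        return dict(self.weights)


def default_priorities(
    geom, ctv_weight: float = 0.8, oar_weight: float = 0.2
) -> PriorityVector:
    """The default initial priority set w0: CTVs high, OARs low.

    Chosen so that both increase and decrease actions are non-trivial from
    the first tuning step.
    """
    w = {n: ctv_weight for n in geom.ctv_names}
    w.update({n: oar_weight for n in geom.oar_names})
    return PriorityVector(w)


@dataclass(frozen=True)
class OptimizerSettings:
    """Projected-gradient solver settings.

    ``accelerated`` (default) is FISTA-style momentum with adaptive restart
    and a monotone safeguard: whenever the momentum candidate would raise
    the objective, the momentum is reset and a plain (halved if necessary)
    projected-gradient step is taken instead, so the objective trace is
    non-increasing under every rule.  ``fixed_lipschitz`` is the plain
    iteration x <- max(x - grad/L, 0); ``backtracking`` additionally adapts
    the step length between iterations.
    """

    max_iterations: int = 1000
    relative_tolerance: float = 1e-5
    step_rule: str = "accelerated"
    warm_start: bool = True

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.relative_tolerance <= 0:
            raise ValueError("relative_tolerance must be > 0")
        if self.step_rule not in ("accelerated", "fixed_lipschitz", "backtracking"):
            raise ValueError(f"unknown step rule {self.step_rule!r}")


@dataclass
class ConvergenceReport:
    iterations: int
    initial_objective: float
    final_objective: float
    converged: bool
    step_rule: str
    #: objective value after every accepted iterate (starts at the initial)
    trace: list = dataclasses.field(default_factory=list)

    def save_trace_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("iteration,objective\n")
            for i, f in enumerate(self.trace):
                fh.write(f"{i},{f!r}\n")

    def as_dict(self) -> dict:
        return {
            "iterations": self.iterations,
            "initial_objective": self.initial_objective,
            "final_objective": self.final_objective,
            "converged": self.converged,
            "step_rule": self.step_rule,
        }


@dataclass
class DoseDistribution:
    """Voxel doses (GyRBE) on the flattened grid."""

    values: np.ndarray
    grid_shape: tuple[int, ...]

    def structure_dose(self, dinf_or_indices, name: str | None = None) -> np.ndarray:
        if name is not None:
            idx = dinf_or_indices.structure_rows[name]
        else:
            idx = dinf_or_indices
        return self.values[idx]


def compute_dose(dinf: DoseInfluence, x: np.ndarray) -> DoseDistribution:
    """Evaluate d = D x (exact sparse matrix-vector product)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (dinf.n_beamlets,):
        raise ValueError(
            f"fluence length {x.shape} does not match {dinf.n_beamlets} beamlets"
        )
    return DoseDistribution(values=dinf.matrix @ x, grid_shape=dinf.grid_shape)


class PlanProblem:
    """A fluence optimization problem bound to one anatomy.

    Caches the per-structure submatrices of D and the uniform prescription
    vectors so that an episode's repeated re-optimizations only pay for
    matrix-vector products.
    """

    def __init__(self, dinf: DoseInfluence, prescriptions: dict[str, float]):
        self.dinf = dinf
        self.prescriptions = dict(prescriptions)
        self.structures = list(dinf.structure_rows)
        self._mats = {name: dinf.view(name) for name in self.structures}
        self.n_beamlets = dinf.n_beamlets

    def _weights(self, w) -> dict[str, float]:
        wd = w.as_dict() if isinstance(w, PriorityVector) else dict(w)
        missing = set(self.structures) - set(wd)
        if missing:
            raise ValueError(f"missing priority weights for {sorted(missing)}")
        return wd

    def objective(self, x: np.ndarray, w) -> float:
        wd = self._weights(w)
        total = 0.0
        for name in self.structures:
            wt = wd[name]
            if wt == 0.0:
                continue
            r = self._mats[name] @ x
            if name in self.prescriptions:
                r = r - self.prescriptions[name]
            total += wt * float(r @ r)
        return total

    def gradient(self, x: np.ndarray, w) -> np.ndarray:
        wd = self._weights(w)
        g = np.zeros(self.n_beamlets)
        for name in self.structures:
            wt = wd[name]
            if wt == 0.0:
                continue
            D = self._mats[name]
            r = D @ x
            if name in self.prescriptions:
                r = r - self.prescriptions[name]
            g += 2.0 * wt * (D.T @ r)
        return g

    def lipschitz(self, w, n_iter: int = 50) -> float:
        """2 * lambda_max of sum_S w_S D_S^T D_S via power iteration.

        Deterministic (fixed all-ones start vector).
        """
        wd = self._weights(w)
        active = [n for n in self.structures if wd[n] > 0]
        if not active:
            return 0.0
        v = np.ones(self.n_beamlets)
        v /= np.linalg.norm(v)
        lam = 0.0
        for _ in range(n_iter):
            av = np.zeros_like(v)
            for name in active:
                D = self._mats[name]
                av += wd[name] * (D.T @ (D @ v))
            norm = np.linalg.norm(av)
            if norm == 0.0:
                return 0.0
            lam = norm
            v = av / norm
        return 2.0 * lam

    def solve(
        self,
        w,
        settings: OptimizerSettings | None = None,
        x0: np.ndarray | None = None,
    ) -> tuple[np.ndarray, ConvergenceReport]:
        settings = settings or OptimizerSettings()
        x = (
            np.zeros(self.n_beamlets)
            if x0 is None
            else np.asarray(x0, dtype=float).copy()
        )
        if x.min() < 0:
            raise ValueError("initial fluence must be nonnegative")

        f = self.objective(x, w)
        f0 = f
        if not np.isfinite(f):
            raise NumericalError("non-finite objective at iteration 0")

        L = self.lipschitz(w)
        if L == 0.0:  # all weights zero: any x is optimal, objective 0
            return x, ConvergenceReport(0, f0, f, True, settings.step_rule, [f0])
        eta = 1.0 / L

        converged = False
        iterations = 0
        trace = [f0]
        tiny = np.finfo(float).tiny
        accelerated = settings.step_rule == "accelerated"
        y = x.copy()  # momentum extrapolation point
        t_mom = 1.0
        for k in range(settings.max_iterations):
            f_new = None
            if accelerated:
                g = self.gradient(y, w)
                if not np.all(np.isfinite(g)):
                    raise NumericalError(f"non-finite gradient at iteration {k}")
                x_cand = np.maximum(y - eta * g, 0.0)
                f_cand = self.objective(x_cand, w)
                if np.isfinite(f_cand) and f_cand <= f:
                    x_old = x
                    x, f_new = x_cand, f_cand
                    t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
                    y = x + ((t_mom - 1.0) / t_next) * (x - x_old)
                    t_mom = t_next
            if f_new is None:
                # plain projected-gradient step (momentum restarted); halve
                # the step until monotone descent -- with eta = 1/L the
                # first trial is accepted for a convex quadratic
                g = self.gradient(x, w)
                if not np.all(np.isfinite(g)):
                    raise NumericalError(f"non-finite gradient at iteration {k}")
                step = eta
                for _ in range(60):
                    x_new = np.maximum(x - step * g, 0.0)
                    f_new = self.objective(x_new, w)
                    if not np.isfinite(f_new):
                        raise NumericalError(
                            f"non-finite objective at iteration {k}"
                        )
                    if f_new <= f:
                        break
                    step *= 0.5
                x = x_new
                y = x.copy()
                t_mom = 1.0
                if settings.step_rule == "backtracking":
                    eta = step * 1.2  # allow the accepted step to grow again
            iterations = k + 1
            decrease = f - f_new
            f = f_new
            trace.append(f)
            if decrease <= settings.relative_tolerance * max(f, tiny):
                converged = True
                break

        return x, ConvergenceReport(
            iterations, f0, f, converged, settings.step_rule, trace
        )


def objective(
    x: np.ndarray, dinf: DoseInfluence, w, prescriptions: dict[str, float]
) -> float:
    """The planning loss L(x) for given priorities and prescriptions."""
    return PlanProblem(dinf, prescriptions).objective(np.asarray(x, float), w)


def optimize_plan(
    dinf: DoseInfluence,
    w,
    prescriptions: dict[str, float],
    settings: OptimizerSettings | None = None,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, ConvergenceReport]:
    """Solve the nonnegatively-constrained plan optimization from scratch.

    Convenience wrapper over :class:`PlanProblem`; environments that
    re-solve many closely related problems should hold a ``PlanProblem``
    and call :meth:`PlanProblem.solve` with a warm start instead.
    """
    return PlanProblem(dinf, prescriptions).solve(w, settings=settings, x0=x0)
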