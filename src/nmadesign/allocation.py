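"""Constrained integer allocation of a fixed total sample size over three arms.

The objective is the variance of the contrast of interest — Z-vs-B
(non-inferiority) or Z-vs-A (superiority) — including the borrowing term
from the existing network.  No closed form exists for the constrained
minimizer, so the solver runs differential evolution over the continuous
two-dimensional slice of the simplex (``n_A``, ``n_B`` free, ``n_Z``
implied) and then enumerates integers in a small box around the rounded
continuous solution, keeping the best feasible triple.  A brute-force
enumeration over all feasible integer triples serves as the validation
oracle at moderate totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import differential_evolution

from . import design
from .data import DataValidationError

DEFAULT_SEED = 20221122
_REFINE_RADIUS = 3
_BRUTE_FORCE_CAP = 2000


@dataclass(frozen=True)
class AllocationProblem:
    """A fixed-total allocation problem with per-arm floors."""

    total_n: int
    p_A: float
    p_B: float
    p_Z: float
    sigma2_exg: float = math.inf
    min_per_arm: int = 10
    objective: str = "var_BZ"  # or "var_AZ"
    seed: int = DEFAULT_SEED
    # optional context for reporting analytic power at the solution
    alpha: float = 0.05
    margin: float | None = None
    effect: float | None = None

    def __post_init__(self) -> None:
        if self.total_n < 3 * self.min_per_arm:
            raise DataValidationError(
                f"total_n={self.total_n} infeasible with min_per_arm={self.min_per_arm}"
            )
        if self.objective not in ("var_BZ", "var_AZ"):
            raise DataValidationError(f"unknown objective {self.objective!r}")


@dataclass(frozen=True)
class AllocationResult:
    n_A: int
    n_B: int
    n_Z: int
    objective_value: float
    power: float | None
    method: str

    @property
    def allocation(self) -> tuple:
        return (self.n_A, self.n_B, self.n_Z)


def objective(problem: AllocationProblem, n_A: float, n_B: float, n_Z: float) -> float:
    """Contrast variance at a (possibly real-valued) allocation."""
    if min(n_A, n_B, n_Z) <= 0:
        raise DataValidationError("arm sizes must be positive")
    inputs = design.DesignInputs(
        n_A, n_B, n_Z, problem.p_A, problem.p_B, problem.p_Z, problem.sigma2_exg
    )
    comparison = "BZ" if problem.objective == "var_BZ" else "AZ"
    return design.var_with_network(inputs, comparison)


def _objective_grid(problem: AllocationProblem, n_a, n_b):
    """Vectorized objective over integer arrays (n_Z implied by the total)."""
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    n_z = problem.total_n - n_a - n_b
    q_a = problem.p_A * (1.0 - problem.p_A)
    q_b = problem.p_B * (1.0 - problem.p_B)
    q_z = problem.p_Z * (1.0 - problem.p_Z)
    v_a = 1.0 / (n_a * q_a)
    v_b = 1.0 / (n_b * q_b)
    v_z = 1.0 / (n_z * q_z)
    direct = v_b if problem.objective == "var_BZ" else v_a
    borrow = direct
    if math.isinf(problem.sigma2_exg):
        return direct + v_z
    return direct + v_z - borrow**2 / (problem.sigma2_exg + v_a + v_b)


def _power_at(problem: AllocationProblem, value: float):
    if problem.effect is None:
        return None
    request = design.PowerRequest(
        effect=problem.effect,
        variance=value,
        alpha=problem.alpha,
        margin=problem.margin or 0.0,
    )
    if problem.objective == "var_BZ":
        return design.power_noninferiority(request)
    return design.power_superiority(request)


def _feasible(problem: AllocationProblem, n_a: int, n_b: int) -> bool:
    n_z = problem.total_n - n_a - n_b
    return min(n_a, n_b, n_z) >= problem.min_per_arm


def _best_of(problem: AllocationProblem, candidates) -> tuple:
    """Exact argmin over integer (n_A, n_B) candidates; ties to smallest n_A then n_B."""
    best = None
    for n_a, n_b in sorted(set(candidates)):
        if not _feasible(problem, n_a, n_b):
            continue
        value = float(_objective_grid(problem, n_a, n_b))
        # candidates arrive sorted, so strict improvement keeps the
        # tie-break at smallest n_A, then smallest n_B
        if best is None or value < best[0]:
            best = (value, n_a, n_b)
    if best is None:
        raise DataValidationError("no feasible integer allocation among candidates")
    return best


def optimize_allocation(problem: AllocationProblem) -> AllocationResult:
    """Global continuous search plus exhaustive local integer refinement.

    Deterministic for a given ``problem.seed``.  The refined solution is
    additionally compared against the even split and the floor-control
    splits, so it can never be worse than those reference allocations.
    """
    lo = float(problem.min_per_arm)
    hi = float(problem.total_n - 2 * problem.min_per_arm)
    penalty_base = 1e6

    def fun(x):
        n_a, n_b = x
        n_z = problem.total_n - n_a - n_b
        if n_z < problem.min_per_arm:
            return penalty_base + (problem.min_per_arm - n_z)
        return float(_objective_grid(problem, n_a, n_b))

    result = differential_evolution(
        fun,
        bounds=[(lo, hi), (lo, hi)],
        seed=problem.seed,
        tol=1e-12,
        maxiter=300,
        popsize=25,
        polish=True,
    )
    center_a = int(round(result.x[0]))
    center_b = int(round(result.x[1]))

    candidates = [
        (center_a + da, center_b + db)
        for da in range(-_REFINE_RADIUS, _REFINE_RADIUS + 1)
        for db in range(-_REFINE_RADIUS, _REFINE_RADIUS + 1)
    ]
    # reference allocations the solution must not lose to
    third = problem.total_n // 3
    rem = problem.total_n - 3 * third
    candidates.append((third, third + (rem > 0)))
    floor = problem.min_per_arm
    half = (problem.total_n - floor) // 2
    candidates.append((floor, half))
    candidates.append((floor, problem.total_n - floor - half))
    candidates = [
        (min(max(a, floor), problem.total_n - 2 * floor),
         min(max(b, floor), problem.total_n - 2 * floor))
        for a, b in candidates
    ]

    value, n_a, n_b = _best_of(problem, candidates)
    n_z = problem.total_n - n_a - n_b
    return AllocationResult(
        n_A=n_a,
        n_B=n_b,
        n_Z=n_z,
        objective_value=value,
        power=_power_at(problem, value),
        method="global+refine",
    )


def brute_force_allocation(problem: AllocationProblem, cap: int = _BRUTE_FORCE_CAP) -> AllocationResult:
    """Exhaustive scan of every feasible integer triple (validation oracle).

    O(total_n^2) objective evaluations, vectorized per control-arm slice;
    refuses totals above ``cap``.
    """
    if problem.total_n > cap:
        raise DataValidationError(
            f"total_n={problem.total_n} exceeds brute-force cap {cap}; "
            "use optimize_allocation"
        )
    floor = problem.min_per_arm
    best = None
    for n_a in range(floor, problem.total_n - 2 * floor + 1):
        n_b = np.arange(floor, problem.total_n - n_a - floor + 1)
        values = _objective_grid(problem, np.full_like(n_b, n_a), n_b)
        i = int(np.argmin(values))  # argmin takes the first (smallest n_b) on ties
        if best is None or values[i] < best[0]:
            best = (float(values[i]), n_a, int(n_b[i]))
    value, n_a, n_b = best
    return AllocationResult(
        n_A=n_a,
        n_B=n_b,
        n_Z=problem.total_n - n_a - n_b,
        objective_value=value,
        power=_power_at(problem, value),
        method="brute_force",
    )


def even_allocation(problem: AllocationProblem) -> AllocationResult:
    """Equal split (remainder to the later arms), as the comparison baseline."""
    third = problem.total_n // 3
    rem = problem.total_n - 3 * third
    n_a = third
    n_b = third + (1 if rem >= 1 else 0)
    n_z = third + (1 if rem == 2 else 0)
    value = objective(problem, n_a, n_b, n_z)
    return AllocationResult(
        n_A=n_a, n_B=n_b, n_Z=n_z, objective_value=value,
        power=_power_at(problem, value), method="even",
    )
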