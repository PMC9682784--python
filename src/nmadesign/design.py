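"""Closed-form variance, power and sample-size calculations for the new trial.

All quantities live on the log-odds-ratio scale.  The variance of the
Z-vs-B estimate from the new trial alone is the sum of the two arms'
reciprocal information,

    Var(mu_BZ_hat) = 1/(n_B p_B (1-p_B)) + 1/(n_Z p_Z (1-p_Z)).

When treatments A and B already sit in an evidence network whose A-vs-B
estimate has variance ``sigma2_exg``, the indirect path Z-A-B contributes
information and the variance drops by a borrowing term:

    Var(mu_BZ_hat) = v_B + v_Z - v_B^2 / (sigma2_exg + v_A + v_B),

with ``v_i = 1/(n_i p_i (1-p_i))``.  ``sigma2_exg = inf`` encodes "no
network" and recovers the stand-alone formula, so the two situations share
one code path.  For a superiority comparison against the control A the same
derivation with the roles of A and B exchanged gives
``v_A + v_Z - v_A^2 / (sigma2_exg + v_A + v_B)``.

Power uses the normal approximation throughout: one-sided critical value
for non-inferiority, two-sided for superiority.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import expit, logit
from scipy.stats import norm

from .data import DataValidationError, TrialSpec


@dataclass(frozen=True)
class DesignInputs:
    """Arm sizes, anticipated event probabilities and network precision."""

    n_A: float
    n_B: float
    n_Z: float
    p_A: float
    p_B: float
    p_Z: float
    sigma2_exg: float = math.inf  # Var of the A-vs-B network estimate; inf = no network

    def __post_init__(self) -> None:
        for name in ("n_A", "n_B", "n_Z"):
            if getattr(self, name) <= 0:
                raise DataValidationError(f"{name} must be positive")
        for name in ("p_A", "p_B", "p_Z"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise DataValidationError(f"{name}={p} must lie strictly inside (0, 1)")
        if self.sigma2_exg < 0:
            raise DataValidationError("sigma2_exg must be non-negative")


@dataclass(frozen=True)
class PowerRequest:
    """Effect size, margin (non-inferiority only), alpha, and the estimate variance."""

    effect: float
    variance: float
    alpha: float = 0.05
    margin: float = 0.0

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise DataValidationError("variance must be > 0")


def shift_probability(p: float, lor: float) -> float:
    """Event probability after shifting the log odds of ``p`` by ``lor``.

    ``shift_probability(p, lor) = p e^lor / (p e^lor + 1 - p)``; used to
    derive one arm's anticipated probability from another's plus a network
    log odds ratio.
    """
    if not 0.0 < p < 1.0:
        raise DataValidationError(f"p={p} must lie strictly inside (0, 1)")
    return float(expit(logit(p) + lor))


def _arm_info_inverse(n: float, p: float) -> float:
    if not 0.0 < p < 1.0:
        raise DataValidationError(f"event probability {p} must lie strictly inside (0, 1)")
    if n <= 0:
        raise DataValidationError(f"arm size {n} must be positive")
    return 1.0 / (n * p * (1.0 - p))


def var_without_network(n_B: float, n_Z: float, p_B: float, p_Z: float) -> float:
    """Variance of the Z-vs-B log odds ratio from the new trial alone."""
    return _arm_info_inverse(n_B, p_B) + _arm_info_inverse(n_Z, p_Z)


def var_with_network(inputs: DesignInputs, comparison: str = "BZ") -> float:
    """Variance of the contrast of interest when the trial joins the network.

    ``comparison="BZ"`` targets the reference comparison (non-inferiority),
    ``"AZ"`` the control comparison (superiority).  An infinite
    ``sigma2_exg`` gives the stand-alone value exactly.
    """
    v_a = _arm_info_inverse(inputs.n_A, inputs.p_A)
    v_b = _arm_info_inverse(inputs.n_B, inputs.p_B)
    v_z = _arm_info_inverse(inputs.n_Z, inputs.p_Z)
    if comparison == "BZ":
        direct, borrow = v_b, v_b
    elif comparison == "AZ":
        direct, borrow = v_a, v_a
    else:
        raise DataValidationError(f"comparison must be 'BZ' or 'AZ', got {comparison!r}")
    if math.isinf(inputs.sigma2_exg):
        return direct + v_z
    return direct + v_z - borrow**2 / (inputs.sigma2_exg + v_a + v_b)


def power_noninferiority(request: PowerRequest) -> float:
    """Power of the one-sided non-inferiority test H0: effect >= margin."""
    z_alpha = norm.ppf(1.0 - request.alpha)
    se = math.sqrt(request.variance)
    return float(norm.cdf(-(request.effect - request.margin) / se - z_alpha))


def power_superiority(request: PowerRequest) -> float:
    """Power of the two-sided superiority test H0: effect = 0."""
    z_half = norm.ppf(1.0 - request.alpha / 2.0)
    se = math.sqrt(request.variance)
    scaled = request.effect / se
    return float(norm.cdf(scaled - z_half) + norm.cdf(-scaled - z_half))


def analytic_power(spec: TrialSpec, variance: float) -> float:
    """Analytic power of the spec's test at the given contrast variance."""
    request = PowerRequest(
        effect=spec.effect,
        variance=variance,
        alpha=spec.alpha,
        margin=spec.margin or 0.0,
    )
    if spec.test == "noninferiority":
        return power_noninferiority(request)
    return power_superiority(request)


def _power_at_total(spec: TrialSpec, sigma2_exg: float, total: int, rule: str):
    """(power, allocation) for a given total under an allocation rule."""
    if rule == "even":
        m = total // 3
        inputs = DesignInputs(m, m, m, spec.p_A, spec.p_B, spec.p_Z, sigma2_exg)
        comparison = "BZ" if spec.test == "noninferiority" else "AZ"
        return analytic_power(spec, var_with_network(inputs, comparison)), (m, m, m)
    from .allocation import AllocationProblem, optimize_allocation

    problem = AllocationProblem(
        total_n=total,
        p_A=spec.p_A,
        p_B=spec.p_B,
        p_Z=spec.p_Z,
        sigma2_exg=sigma2_exg,
        min_per_arm=spec.min_per_arm,
        objective="var_BZ" if spec.test == "noninferiority" else "var_AZ",
        alpha=spec.alpha,
        margin=spec.margin,
        effect=spec.effect,
    )
    result = optimize_allocation(problem)
    return analytic_power(spec, result.objective_value), (result.n_A, result.n_B, result.n_Z)


def required_total_n(
    spec: TrialSpec, sigma2_exg: float = math.inf, allocation_rule: str = "even"
):
    """Smallest total sample size reaching the spec's target power.

    Power is monotone in the total, so the search is a doubling phase
    followed by bisection.  The even rule returns equal arms (total a
    multiple of 3); the optimal rule nests the allocation optimizer at each
    probed total.  Returns ``(total_n, (n_A, n_B, n_Z))``.
    """
    if spec.target_power is None:
        raise DataValidationError("required_total_n needs a TrialSpec with target_power")
    if allocation_rule not in ("even", "optimal"):
        raise DataValidationError(f"unknown allocation rule {allocation_rule!r}")
    if spec.target_power <= spec.alpha:
        raise DataValidationError(
            f"target power {spec.target_power} must exceed alpha {spec.alpha}"
        )

    if allocation_rule == "even":
        lo = hi = None
        m = spec.min_per_arm
        while True:
            power, _ = _power_at_total(spec, sigma2_exg, 3 * m, "even")
            if power >= spec.target_power:
                hi = m
                break
            lo = m
            if m > 10_000_000:
                raise DataValidationError(
                    "target power unachievable: power plateaus below target "
                    f"(reached {power:.4f} at {3 * m} subjects)"
                )
            m *= 2
        lo = lo or spec.min_per_arm
        while hi - lo > 1:
            mid = (lo + hi) // 2
            power, _ = _power_at_total(spec, sigma2_exg, 3 * mid, "even")
            if power >= spec.target_power:
                hi = mid
            else:
                lo = mid
        # lo may itself already satisfy the target when the floor does
        power, alloc = _power_at_total(spec, sigma2_exg, 3 * lo, "even")
        if power >= spec.target_power:
            return 3 * lo, alloc
        _, alloc = _power_at_total(spec, sigma2_exg, 3 * hi, "even")
        return 3 * hi, alloc

    floor = 3 * spec.min_per_arm
    total = floor
    lo = None
    while True:
        power, _ = _power_at_total(spec, sigma2_exg, total, "optimal")
        if power >= spec.target_power:
            hi = total
            break
        lo = total
        if total > 30_000_000:
            raise DataValidationError(
                "target power unachievable under the allocation constraints "
                f"(reached {power:.4f} at {total} subjects)"
            )
        total *= 2
    lo = lo or floor
    while hi - lo > 1:
        mid = (lo + hi) // 2
        power, _ = _power_at_total(spec, sigma2_exg, mid, "optimal")
        if power >= spec.target_power:
            hi = mid
        else:
            lo = mid
    power, alloc = _power_at_total(spec, sigma2_exg, lo, "optimal")
    if power >= spec.target_power:
        return lo, alloc
    _, alloc = _power_at_total(spec, sigma2_exg, hi, "optimal")
    return hi, alloc
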