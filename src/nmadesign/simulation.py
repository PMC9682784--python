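"""Monte-Carlo operating characteristics of the proposed trial designs.

Each replicate (1) draws binomial event counts for the three arms, (2) fits
the saturated three-arm logistic model — whose maximum-likelihood contrast
estimates are the empirical log odds ratios, with Wald standard errors read
off the information matrix — (3) optionally adds the trial to the existing
network and re-reads the contrast from the updated fixed-effects fit, and
(4) applies the one-sided confidence-interval decision rule.  Rejection
rates over many replicates estimate power (truth at the alternative) or
type-I error (truth at the null boundary).

Decision rules, on the log-odds-ratio scale of an adverse outcome:

* non-inferiority of Z vs B: reject when ``estimate + z_{1-alpha} * se < M``;
* superiority of Z vs the control A: reject when
  ``estimate + z_{1-alpha/2} * se < 0`` (the two-sided-level critical value,
  matching the two-sided power formula; only the benefit direction counts).

Replicates use independent RNG substreams spawned from the study seed, so
identical configurations reproduce bit-identical reports.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from . import nma
from .data import ArmRecord, DataValidationError, Network, Study, TrialSpec


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation study: a fixed design replicated under known truth."""

    trial: TrialSpec
    allocation: tuple  # (n_A, n_B, n_Z)
    true_p_A: float
    true_p_B: float
    true_p_Z: float
    reps: int = 10_000
    seed: int = 0
    with_network: bool = False
    network: Network | None = None

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise DataValidationError("reps must be >= 1")
        if len(self.allocation) != 3 or min(self.allocation) < 1:
            raise DataValidationError("allocation must be three positive arm sizes")
        if min(self.allocation) < self.trial.min_per_arm:
            raise DataValidationError(
                f"allocation {self.allocation} violates min_per_arm={self.trial.min_per_arm}"
            )
        if self.with_network and self.network is None:
            raise DataValidationError("with_network=True requires a network")
        for name in ("true_p_A", "true_p_B", "true_p_Z"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise DataValidationError(f"{name}={p} must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class SimulationReport:
    rejection_rate: float
    mc_se: float
    reps_completed: int
    n_degenerate: int
    seed: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    def table_row(self, config: SimulationConfig) -> dict:
        """One row in the schema of the operating-characteristic tables."""
        return {
            "total_n": int(sum(config.allocation)),
            "p_A": config.true_p_A,
            "p_B": config.true_p_B,
            "p_Z": config.true_p_Z,
            "allocation": "({}, {}, {})".format(*config.allocation),
            "with_network": "Yes" if config.with_network else "No",
            "test": config.trial.test,
            "rate": self.rejection_rate,
            "mc_se": self.mc_se,
            "reps": self.reps_completed,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# single-replicate pieces


def _pair_stats(r1: int, n1: int, r2: int, n2: int):
    """(lor of arm2 over arm1, se, corrected?) with the 0.5 rule on the 2x2."""
    cells = (r1, n1 - r1, r2, n2 - r2)
    if min(cells) == 0:
        a, b, c, d = (x + 0.5 for x in cells)
        return math.log(c / d) - math.log(a / b), math.sqrt(1 / a + 1 / b + 1 / c + 1 / d), True
    a, b, c, d = cells
    return math.log(c / d) - math.log(a / b), math.sqrt(1 / a + 1 / b + 1 / c + 1 / d), False


def simulate_replicate(config: SimulationConfig, rng: np.random.Generator):
    """Draw one trial and return the stand-alone (estimate, se) of the
    contrast of interest (Z-vs-B for non-inferiority, Z-vs-A for superiority).

    The estimate is the saturated logistic model's MLE of the log odds
    ratio; its standard error comes from the observed information matrix,
    i.e. ``sqrt(sum 1/cell)`` over the contrast's two-by-two table.
    """
    n_a, n_b, n_z = config.allocation
    r_a = int(rng.binomial(n_a, config.true_p_A))
    r_b = int(rng.binomial(n_b, config.true_p_B))
    r_z = int(rng.binomial(n_z, config.true_p_Z))
    if config.trial.test == "noninferiority":
        lor, se, _ = _pair_stats(r_b, n_b, r_z, n_z)
    else:
        lor, se, _ = _pair_stats(r_a, n_a, r_z, n_z)
    return lor, se


def test_decision(estimate: float, se: float, test: str, margin: float = 0.0,
                  alpha: float = 0.05) -> bool:
    """Apply the one-sided upper-confidence-limit decision rule."""
    if not se > 0:
        raise DataValidationError("se must be > 0")
    if test == "noninferiority":
        z = norm.ppf(1.0 - alpha)
        return estimate + z * se < margin
    if test == "superiority":
        z = norm.ppf(1.0 - alpha / 2.0)
        return estimate + z * se < 0.0
    raise DataValidationError(f"unknown test type {test!r}")


def refit_with_network(network: Network, trial_study: Study,
                       treat_ref: str, treat_alt: str):
    """Add the replicate trial to the network, refit, and return the updated
    (estimate, se) of ``treat_alt`` over ``treat_ref``."""
    augmented = nma.augment_network(network, trial_study)
    fit = nma.fit_fixed_effects_nma(augmented)
    return fit.estimate(treat_ref, treat_alt), math.sqrt(
        nma.contrast_variance(fit, treat_ref, treat_alt)
    )


def _network_summary(config: SimulationConfig):
    """(mu_AB_exg, sigma2_AB_exg) of the existing network for the trial's A-B pair."""
    fit = nma.fit_fixed_effects_nma(config.network)
    a, b = config.trial.treat_A, config.trial.treat_B
    return fit.estimate(a, b), nma.contrast_variance(fit, a, b)


def _arm_logit(r: int, n: int):
    """(logit p-hat, var) with the per-arm 0.5 correction; flags degeneracy."""
    if r == 0 or r == n:
        rr, nn = r + 0.5, n + 1.0
        return math.log(rr / (nn - rr)), 1.0 / rr + 1.0 / (nn - rr), True
    return math.log(r / (n - r)), 1.0 / r + 1.0 / (n - r), False


def _borrowed_estimate(counts, allocation, mu_ab: float, sigma2: float, test: str):
    """Contrast estimate and se after combining the trial with the network.

    The existing network enters only through its A-vs-B summary
    ``(mu_ab, sigma2)``; combining it with the trial's independent arm-logit
    estimates is algebraically identical to augmenting the network and
    refitting the full GLS model (verified against that route in the test
    suite).
    """
    (r_a, r_b, r_z), (n_a, n_b, n_z) = counts, allocation
    t_a, v_a, d_a = _arm_logit(r_a, n_a)
    t_b, v_b, d_b = _arm_logit(r_b, n_b)
    t_z, v_z, d_z = _arm_logit(r_z, n_z)
    degenerate = d_a or d_b or d_z
    if test == "noninferiority":
        # theta_B from its own arm plus the indirect route A + network LOR
        w_direct = 1.0 / v_b
        w_indirect = 1.0 / (v_a + sigma2)
        theta_b = (w_direct * t_b + w_indirect * (t_a + mu_ab)) / (w_direct + w_indirect)
        est = t_z - theta_b
        var = v_z + 1.0 / (w_direct + w_indirect)
    else:
        w_direct = 1.0 / v_a
        w_indirect = 1.0 / (v_b + sigma2)
        theta_a = (w_direct * t_a + w_indirect * (t_b - mu_ab)) / (w_direct + w_indirect)
        est = t_z - theta_a
        var = v_z + 1.0 / (w_direct + w_indirect)
    return est, math.sqrt(var), degenerate


def run_study(config: SimulationConfig) -> SimulationReport:
    """Replicate the trial ``config.reps`` times and report the rejection rate.

    Each replicate draws from an independent substream of the study seed.
    Degenerate replicates (a zero or full cell) are analyzed from
    continuity-corrected counts and counted in ``n_degenerate``.
    """
    trial = config.trial
    n_a, n_b, n_z = config.allocation
    margin = trial.margin or 0.0
    if config.with_network:
        mu_ab, sigma2 = _network_summary(config)

    streams = np.random.SeedSequence(config.seed).spawn(config.reps)
    rejections = 0
    n_degenerate = 0
    for child in streams:
        rng = np.random.Generator(np.random.PCG64(child))
        r_a = int(rng.binomial(n_a, config.true_p_A))
        r_b = int(rng.binomial(n_b, config.true_p_B))
        r_z = int(rng.binomial(n_z, config.true_p_Z))
        if config.with_network:
            est, se, degen = _borrowed_estimate(
                (r_a, r_b, r_z), (n_a, n_b, n_z), mu_ab, sigma2, trial.test
            )
        elif trial.test == "noninferiority":
            est, se, degen = _pair_stats(r_b, n_b, r_z, n_z)
        else:
            est, se, degen = _pair_stats(r_a, n_a, r_z, n_z)
        n_degenerate += degen
        rejections += test_decision(est, se, trial.test, margin, trial.alpha)

    rate = rejections / config.reps
    return SimulationReport(
        rejection_rate=rate,
        mc_se=math.sqrt(rate * (1.0 - rate) / config.reps),
        reps_completed=config.reps,
        n_degenerate=n_degenerate,
        seed=config.seed,
    )


def trial_study_from_counts(study_id: str, trial: TrialSpec, counts, allocation) -> Study:
    """Package one replicate's counts as an arm-level study for augmentation."""
    labels = (trial.treat_A, trial.treat_B, trial.treat_Z)
    return Study(
        study_id=study_id,
        arms=tuple(
            ArmRecord(study_id, label, int(r), int(n))
            for label, r, n in zip(labels, counts, allocation)
        ),
    )
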