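"""Fixed-effects contrast-based network meta-analysis by generalized least squares.

Model
-----
Each study *j* contributes its observed within-study log odds ratios
``y_j`` (one per non-baseline arm), with within-study covariance ``S_j``.
Under consistency every contrast is a linear combination of the *basic
parameters* ``mu_b`` — the effects of each treatment relative to the network
baseline — so ``E[y] = X mu_b`` with a design matrix of +1/0/-1 entries.
Stacking studies gives a block-diagonal covariance ``S`` and the GLS / ML
estimate

    mu_b_hat = (X' S^-1 X)^-1 X' S^-1 y,   Var(mu_b_hat) = (X' S^-1 X)^-1.

Multi-arm studies are handled through the off-diagonal entries of ``S_j``:
two contrasts sharing the study's baseline arm covary by that arm's
variance contribution, which also equals
``(sigma2_AB + sigma2_AZ - sigma2_BZ) / 2``.

The linear algebra accumulates per-study Cholesky solves; the full ``S`` is
never formed or inverted explicitly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .data import (
    ContrastRecord,
    DataValidationError,
    Network,
    Study,
    assemble_network,
)


class EstimationError(RuntimeError):
    """Raised when the NMA model cannot be estimated from the given network."""


# ---------------------------------------------------------------------------
# per-study rows: the single source of truth for row ordering


def _study_baseline(study: Study, network_baseline: str) -> str:
    """Deterministic anchor arm for expanding a study into contrasts.

    The network baseline if the study includes it, else the lexicographically
    first treatment.  The choice does not affect the fit, only the
    parametrization of the study's rows.
    """
    labels = study.treatments
    return network_baseline if network_baseline in labels else min(labels)


def _arm_stats(arm) -> tuple[float, float]:
    """(logit p-hat, variance of logit p-hat) with a per-arm 0.5 correction
    when the arm has a zero cell, so that a shared arm contributes the same
    term to every contrast of its study."""
    r, n = float(arm.events), float(arm.total)
    if r == 0 or r == n:
        warnings.warn(
            f"study {arm.study_id!r} arm {arm.treatment!r}: zero cell, "
            "adding 0.5 to both cells",
            stacklevel=3,
        )
        r += 0.5
        n += 1.0
    return math.log(r / (n - r)), 1.0 / r + 1.0 / (n - r)


def _study_rows(study: Study, network_baseline: str):
    """Return (pairs, y, S_j) for one study.

    ``pairs`` is a list of (ref, alt) label tuples, ``y`` the observed log
    odds ratios (alt over ref) and ``S_j`` their covariance.  Arm-level
    studies anchor every contrast at the study baseline; contrast-level
    studies are used as given.
    """
    if study.is_arm_level:
        base = _study_baseline(study, network_baseline)
        by_label = {a.treatment: a for a in study.arms}
        if len(by_label) != len(study.arms):
            raise DataValidationError(
                f"study {study.study_id!r}: duplicate treatment labels"
            )
        t_base, v_base = _arm_stats(by_label[base])
        others = [t for t in sorted(by_label) if t != base]
        y = np.empty(len(others))
        s = np.full((len(others), len(others)), v_base)
        for i, label in enumerate(others):
            t_alt, v_alt = _arm_stats(by_label[label])
            y[i] = t_alt - t_base
            s[i, i] = v_base + v_alt
        return [(base, t) for t in others], y, s

    contrasts = list(study.contrasts)
    n_arms = len(study.treatments)
    if len(contrasts) == n_arms - 1:
        pairs = [(c.treat_ref, c.treat_alt) for c in contrasts]
        y = np.array([c.lor for c in contrasts])
        if len(contrasts) == 1:
            s = np.array([[contrasts[0].se ** 2]])
        elif study.covariance is not None:
            s = np.asarray(study.covariance, dtype=float)
        else:
            raise DataValidationError(
                f"study {study.study_id!r}: multi-arm contrast-level study needs "
                "an explicit covariance or the full set of pairwise contrasts"
            )
    elif n_arms == 3 and len(contrasts) == 3:
        # all three pairwise contrasts given: keep the two anchored at the
        # study baseline and reconstruct the shared-arm covariance from the
        # identity off-diag = (s2_ab + s2_ac - s2_bc) / 2
        base = _study_baseline(study, network_baseline)
        var = {}
        for c in contrasts:
            var[frozenset((c.treat_ref, c.treat_alt))] = c.se ** 2
        anchored = []
        for c in contrasts:
            if c.treat_ref == base:
                anchored.append(c)
            elif c.treat_alt == base:
                anchored.append(c.reversed())
        if len(anchored) != 2:
            raise DataValidationError(
                f"study {study.study_id!r}: cannot anchor contrasts at {base!r}"
            )
        anchored.sort(key=lambda c: c.treat_alt)
        b, z = anchored[0].treat_alt, anchored[1].treat_alt
        off = (
            var[frozenset((base, b))] + var[frozenset((base, z))] - var[frozenset((b, z))]
        ) / 2.0
        pairs = [(base, b), (base, z)]
        y = np.array([anchored[0].lor, anchored[1].lor])
        s = np.array(
            [[anchored[0].se ** 2, off], [off, anchored[1].se ** 2]]
        )
    else:
        raise DataValidationError(
            f"study {study.study_id!r}: expected {n_arms - 1} contrasts "
            f"(or all {n_arms * (n_arms - 1) // 2} pairwise), got {len(contrasts)}"
        )

    _check_positive_definite(s, study.study_id)
    return pairs, y, s


def _check_positive_definite(s: np.ndarray, study_id: str) -> None:
    if s.shape[0] != s.shape[1] or not np.allclose(s, s.T):
        raise DataValidationError(f"study {study_id!r}: covariance block not symmetric")
    try:
        np.linalg.cholesky(s)
    except np.linalg.LinAlgError as exc:
        raise DataValidationError(
            f"study {study_id!r}: covariance block not positive definite"
        ) from exc


# ---------------------------------------------------------------------------
# public builders


@dataclass(frozen=True)
class DesignMatrix:
    """Stacked contrast design: one row per study-specific comparison."""

    matrix: np.ndarray  # (sum_j (n_j - 1)) x (T - 1), entries in {-1, 0, 1}
    rows: tuple  # (study_id, ref, alt) per row
    columns: tuple  # basic-parameter labels (non-baseline treatments, sorted)


@dataclass(frozen=True)
class CovarianceBlocks:
    """Per-study covariance blocks of the stacked contrast vector."""

    blocks: tuple  # one (n_j - 1) x (n_j - 1) array per study
    study_ids: tuple

    def dense(self) -> np.ndarray:
        """Assembled block-diagonal matrix (for inspection / small oracles)."""
        sizes = [b.shape[0] for b in self.blocks]
        out = np.zeros((sum(sizes), sum(sizes)))
        pos = 0
        for b in self.blocks:
            k = b.shape[0]
            out[pos : pos + k, pos : pos + k] = b
            pos += k
        return out


def _column_index(network: Network) -> dict:
    return {t: i for i, t in enumerate(network.treatments[1:])}


def _contrast_row(index: dict, baseline: str, ref: str, alt: str, width: int) -> np.ndarray:
    row = np.zeros(width)
    for label, sign in ((alt, 1.0), (ref, -1.0)):
        if label == baseline:
            continue
        if label not in index:
            raise EstimationError(f"treatment {label!r} absent from parameter index")
        row[index[label]] = sign
    return row


def build_design_matrix(network: Network) -> DesignMatrix:
    """Design matrix mapping basic parameters to every study-specific contrast."""
    index = _column_index(network)
    width = len(index)
    rows, entries = [], []
    for study in network.studies:
        pairs, _, _ = _study_rows(study, network.baseline)
        for ref, alt in pairs:
            entries.append(_contrast_row(index, network.baseline, ref, alt, width))
            rows.append((study.study_id, ref, alt))
    return DesignMatrix(
        matrix=np.array(entries), rows=tuple(rows), columns=tuple(network.treatments[1:])
    )


def build_covariance(network: Network) -> CovarianceBlocks:
    """Within-study covariance blocks, ordered as the design-matrix rows."""
    blocks, ids = [], []
    for study in network.studies:
        _, _, s = _study_rows(study, network.baseline)
        blocks.append(s)
        ids.append(study.study_id)
    return CovarianceBlocks(blocks=tuple(blocks), study_ids=tuple(ids))


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class NMAFit:
    """GLS estimate of the basic parameters and its covariance."""

    mu_b_hat: np.ndarray  # length T-1
    cov_mu_b: np.ndarray  # (T-1) x (T-1)
    baseline: str
    treatment_index: dict  # label -> column (baseline absent)

    def _contrast_vector(self, treat_ref: str, treat_alt: str) -> np.ndarray:
        c = np.zeros(len(self.mu_b_hat))
        for label, sign in ((treat_alt, 1.0), (treat_ref, -1.0)):
            if label == self.baseline:
                continue
            if label not in self.treatment_index:
                raise EstimationError(f"unknown treatment {label!r}")
            c[self.treatment_index[label]] += sign
        return c

    def estimate(self, treat_ref: str, treat_alt: str) -> float:
        """Estimated log odds ratio of ``treat_alt`` over ``treat_ref``."""
        return float(self._contrast_vector(treat_ref, treat_alt) @ self.mu_b_hat)


def _check_connected(network: Network) -> None:
    import networkx as nx

    graph = network.comparison_graph()
    components = list(nx.connected_components(graph))
    if len(components) > 1:
        pretty = "; ".join(sorted(",".join(sorted(c)) for c in components))
        raise EstimationError(
            f"comparison graph disconnected (components [{pretty}]); "
            "basic parameters are not estimable"
        )


def fit_fixed_effects_nma(network: Network) -> NMAFit:
    """Fit the fixed-effects NMA by GLS.

    The normal equations are accumulated study by study through Cholesky
    solves of the small per-study blocks; the stacked covariance is never
    inverted.  Connectivity is checked up front since it guarantees full
    column rank of the design.
    """
    _check_connected(network)
    index = _column_index(network)
    k = len(index)
    info = np.zeros((k, k))
    rhs = np.zeros(k)
    for study in network.studies:
        pairs, y, s = _study_rows(study, network.baseline)
        x = np.array(
            [_contrast_row(index, network.baseline, ref, alt, k) for ref, alt in pairs]
        )
        factor = cho_factor(s, lower=True)
        sinv_x = cho_solve(factor, x)
        info += x.T @ sinv_x
        rhs += sinv_x.T @ y
    try:
        factor = cho_factor(info, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by connectivity
        raise EstimationError("information matrix is rank deficient") from exc
    mu = cho_solve(factor, rhs)
    cov = cho_solve(factor, np.eye(k))
    cov = (cov + cov.T) / 2.0  # symmetrize roundoff
    return NMAFit(mu_b_hat=mu, cov_mu_b=cov, baseline=network.baseline, treatment_index=index)


def contrast_variance(fit: NMAFit, treat_x: str, treat_y: str) -> float:
    """Variance of the estimated log odds ratio of ``treat_y`` over ``treat_x``."""
    c = fit._contrast_vector(treat_x, treat_y)
    return float(c @ fit.cov_mu_b @ c)


# ---------------------------------------------------------------------------
# augmentation with a new trial


def augment_network(network: Network, new_trial: Study) -> Network:
    """Append a new trial containing exactly one treatment absent from the network.

    The returned network's design matrix gains one basic-parameter column and
    the new trial's rows; refitting it yields the updated (borrowing)
    estimates.
    """
    known = set(network.treatments)
    novel = [t for t in new_trial.treatments if t not in known]
    if len(novel) != 1:
        raise DataValidationError(
            f"new trial must introduce exactly one novel treatment, found {novel or 'none'}"
        )
    existing = [t for t in new_trial.treatments if t in known]
    if len(existing) < 2:
        raise DataValidationError(
            "new trial must share at least two treatments with the network"
        )
    if any(s.study_id == new_trial.study_id for s in network.studies):
        raise DataValidationError(f"duplicate study id {new_trial.study_id!r}")
    return Network(studies=network.studies + (new_trial,), baseline=network.baseline)
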