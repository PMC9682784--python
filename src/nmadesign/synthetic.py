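"""Synthetic evidence networks with known ground truth.

The generator draws arm-level binomial data under the logistic model: the
baseline treatment has event probability ``baseline_p`` and every other
treatment's probability is the baseline log-odds shifted by its entry in
``true_mu_b``.  Topology schemes control which treatments each study
compares; the comparison graph is always connected so the resulting network
is estimable.

``brd_like_blueprint`` emulates the shape of the motivating
bovine-respiratory-disease antibiotics network — 98 mostly two-arm trials
over 13 treatments, eight three-arm trials, a heavily connected negative
control, a control event probability of 0.681, and a control-vs-reference
log odds ratio of 2.007.  It is a statistical stand-in with the same
structure, not a reconstruction of the deposited dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .data import ArmRecord, DataValidationError, Network, assemble_network

_TOPOLOGIES = ("star", "chain", "random-connected")

# negative control plus 12 antibiotic classes, mirroring the motivating network
BRD_TREATMENTS = (
    "NC", "CEFTP", "CEFTS", "DANO", "ENFO", "FLOR", "GAMI",
    "OXY", "TILD", "TILM", "TMS", "TULA", "TYLO",
)


@dataclass(frozen=True)
class NetworkBlueprint:
    """Recipe for one synthetic arm-level network."""

    n_treatments: int
    n_studies: int
    true_mu_b: tuple  # length T-1, log odds ratios of each treatment vs baseline
    baseline_p: float
    arm_size_range: tuple = (100, 400)
    three_arm_fraction: float = 0.0
    connectivity: str = "star"
    seed: int = 0
    treatments: tuple | None = None  # optional labels; generated if omitted

    def __post_init__(self) -> None:
        if self.n_treatments < 2:
            raise DataValidationError("need at least two treatments")
        if self.n_studies < 1:
            raise DataValidationError("need at least one study")
        if len(self.true_mu_b) != self.n_treatments - 1:
            raise DataValidationError(
                f"true_mu_b must have length T-1={self.n_treatments - 1}"
            )
        if not 0.0 < self.baseline_p < 1.0:
            raise DataValidationError("baseline_p must lie strictly inside (0, 1)")
        if self.connectivity not in _TOPOLOGIES:
            raise DataValidationError(f"connectivity must be one of {_TOPOLOGIES}")
        if not 0.0 <= self.three_arm_fraction <= 1.0:
            raise DataValidationError("three_arm_fraction must lie in [0, 1]")
        if self.treatments is not None and len(self.treatments) != self.n_treatments:
            raise DataValidationError("treatments must match n_treatments")

    @property
    def labels(self) -> tuple:
        if self.treatments is not None:
            return tuple(self.treatments)
        width = len(str(self.n_treatments - 1))
        return ("NC",) + tuple(f"T{i:0{width}d}" for i in range(1, self.n_treatments))

    @property
    def true_probabilities(self) -> dict:
        base = float(logit(self.baseline_p))
        labels = self.labels
        probs = {labels[0]: self.baseline_p}
        for label, mu in zip(labels[1:], self.true_mu_b):
            probs[label] = float(expit(base + mu))
        return probs

    def true_contrast(self, treat_ref: str, treat_alt: str) -> float:
        """True log odds ratio of ``treat_alt`` over ``treat_ref``."""
        mu = {self.labels[0]: 0.0}
        mu.update(dict(zip(self.labels[1:], self.true_mu_b)))
        return mu[treat_alt] - mu[treat_ref]


def _study_treatment_sets(bp: NetworkBlueprint, rng: np.random.Generator) -> list:
    """Pick each study's treatment subset under the topology scheme.

    Every non-baseline treatment is seeded into the first studies so the
    graph is connected by construction for star and chain; random-connected
    retries until connected.
    """
    labels = list(bp.labels)
    baseline, others = labels[0], labels[1:]
    n3 = int(round(bp.three_arm_fraction * bp.n_studies))
    sizes = [3] * n3 + [2] * (bp.n_studies - n3)
    rng.shuffle(sizes)

    def star() -> list:
        sets = []
        for j, size in enumerate(sizes):
            forced = others[j % len(others)] if j < len(others) else None
            pool = [t for t in others if t != forced]
            extra = list(rng.choice(pool, size=size - 1 - bool(forced), replace=False))
            members = [baseline] + ([forced] if forced else []) + extra
            sets.append(tuple(members))
        return sets

    def chain() -> list:
        sets = []
        for j, size in enumerate(sizes):
            start = j % (len(labels) - 1) if j < len(labels) - 1 else int(
                rng.integers(0, len(labels) - 1)
            )
            members = labels[start : start + size]
            if len(members) < size:  # wrap at the end of the chain
                members = labels[-size:]
            sets.append(tuple(members))
        return sets

    def random_connected() -> list:
        sets = []
        for j, size in enumerate(sizes):
            if j < len(others):
                forced = others[j]
                pool = [t for t in labels if t != forced]
                members = [forced] + list(rng.choice(pool, size=size - 1, replace=False))
            else:
                members = list(rng.choice(labels, size=size, replace=False))
            sets.append(tuple(members))
        return sets

    builder = {"star": star, "chain": chain, "random-connected": random_connected}[
        bp.connectivity
    ]
    for _ in range(50):
        sets = builder()
        edges = {frozenset(p) for s in sets for p in zip(s, s[1:])}
        seen = set().union(*sets)
        if len(seen) == bp.n_treatments and _connected(labels, sets):
            return sets
    raise DataValidationError(
        "could not generate a connected topology; increase n_studies"
    )


def _connected(labels, sets) -> bool:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(labels)
    for s in sets:
        g.add_edges_from((s[i], s[k]) for i in range(len(s)) for k in range(i + 1, len(s)))
    return nx.is_connected(g)


def generate_network(blueprint: NetworkBlueprint) -> Network:
    """Draw one arm-level network; deterministic per blueprint seed."""
    rng = np.random.default_rng(blueprint.seed)
    probs = blueprint.true_probabilities
    lo, hi = blueprint.arm_size_range
    records = []
    for j, members in enumerate(_study_treatment_sets(blueprint, rng), start=1):
        sid = f"S{j:03d}"
        for label in members:
            n = int(rng.integers(lo, hi + 1))
            r = int(rng.binomial(n, probs[label]))
            records.append(ArmRecord(sid, label, r, n))
    return assemble_network(records, baseline=blueprint.labels[0])


def brd_like_blueprint(seed: int = 681) -> NetworkBlueprint:
    """Blueprint emulating the motivating 98-trial, 13-treatment network.

    The negative control NC is the baseline with event probability 0.681;
    the NC-vs-ENFO log odds ratio is fixed at 2.007 (ENFO entry -2.007, the
    event being adverse) and CEFTS at the log odds ratio implied by its
    anticipated event probability 0.4303.  The remaining effects are fixed
    plausible values in the same range.
    """
    labels = BRD_TREATMENTS
    ceft_s = float(logit(0.4303) - logit(0.681))
    mu = {
        "CEFTP": -1.35, "CEFTS": ceft_s, "DANO": -1.10, "ENFO": -2.007,
        "FLOR": -1.60, "GAMI": -1.25, "OXY": -0.70, "TILD": -1.85,
        "TILM": -1.45, "TMS": -0.45, "TULA": -2.20, "TYLO": -0.90,
    }
    return NetworkBlueprint(
        n_treatments=13,
        n_studies=98,
        true_mu_b=tuple(mu[t] for t in labels[1:]),
        baseline_p=0.681,
        arm_size_range=(100, 400),
        three_arm_fraction=8 / 98,
        connectivity="star",
        seed=seed,
        treatments=labels,
    )
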