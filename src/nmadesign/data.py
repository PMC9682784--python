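"""Domain types and CSV I/O for network meta-analysis data.

A network is a collection of randomized trials ("studies"), each comparing a
subset of treatments on a binary outcome.  Data arrive either *arm-level*
(events / total per treatment arm) or *contrast-level* (an observed log odds
ratio and its standard error per within-study comparison).  Both CSV dialects
are plain comma-separated files with a required header.

Sign convention, fixed package-wide: the log odds ratio of ``alt`` over
``ref`` is ``lor = logit(p_alt) - logit(p_ref)``.  The outcome throughout is
an adverse event, so a *negative* lor favors ``alt``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd


class DataValidationError(ValueError):
    """Raised when input records violate a structural invariant."""


# ---------------------------------------------------------------------------
# records


@dataclass(frozen=True)
class ArmRecord:
    """One treatment arm of one study: ``events`` successes out of ``total``."""

    study_id: str
    treatment: str
    events: int
    total: int

    def __post_init__(self) -> None:
        if self.total < 1:
            raise DataValidationError(
                f"study {self.study_id!r} arm {self.treatment!r}: total must be >= 1"
            )
        if not (0 <= self.events <= self.total):
            raise DataValidationError(
                f"study {self.study_id!r} arm {self.treatment!r}: "
                f"events={self.events} outside [0, total={self.total}]"
            )

    @property
    def proportion(self) -> float:
        return self.events / self.total


@dataclass(frozen=True)
class ContrastRecord:
    """An observed within-study log odds ratio of ``treat_alt`` over ``treat_ref``."""

    study_id: str
    treat_ref: str
    treat_alt: str
    lor: float
    se: float

    def __post_init__(self) -> None:
        if self.treat_ref == self.treat_alt:
            raise DataValidationError(
                f"study {self.study_id!r}: contrast compares {self.treat_ref!r} with itself"
            )
        if not self.se > 0:
            raise DataValidationError(
                f"study {self.study_id!r} contrast {self.treat_ref}-{self.treat_alt}: "
                f"se must be > 0, got {self.se}"
            )

    def reversed(self) -> "ContrastRecord":
        """The same comparison with the roles of the two treatments swapped."""
        return ContrastRecord(self.study_id, self.treat_alt, self.treat_ref, -self.lor, self.se)


@dataclass(frozen=True)
class Study:
    """All the data of one trial: its arms, or its ``n_arms - 1`` contrasts.

    For a multi-arm contrast-level study an explicit covariance matrix of the
    contrasts (ordered as given) may be supplied; otherwise it is
    reconstructed where possible (see :mod:`nmadesign.nma`).
    """

    study_id: str
    arms: tuple = ()
    contrasts: tuple = ()
    covariance: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        if bool(self.arms) == bool(self.contrasts):
            raise DataValidationError(
                f"study {self.study_id!r}: provide either arms or contrasts (exactly one)"
            )
        if len(self.treatments) < 2:
            raise DataValidationError(
                f"study {self.study_id!r}: needs >= 2 distinct treatments"
            )

    @property
    def treatments(self) -> tuple:
        if self.arms:
            return tuple(dict.fromkeys(a.treatment for a in self.arms))
        labels: dict = {}
        for c in self.contrasts:
            labels.setdefault(c.treat_ref)
            labels.setdefault(c.treat_alt)
        return tuple(labels)

    @property
    def is_arm_level(self) -> bool:
        return bool(self.arms)


@dataclass(frozen=True)
class Network:
    """A connected evidence network of studies with a designated baseline."""

    studies: tuple
    baseline: str
    treatments: tuple = field(init=False)

    def __post_init__(self) -> None:
        labels = set()
        for s in self.studies:
            labels.update(s.treatments)
        if self.baseline not in labels:
            raise DataValidationError(
                f"baseline {self.baseline!r} does not appear in any study"
            )
        ordered = (self.baseline,) + tuple(sorted(labels - {self.baseline}))
        object.__setattr__(self, "treatments", ordered)

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def n_treatments(self) -> int:
        return len(self.treatments)

    def comparison_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.treatments)
        for s in self.studies:
            t = list(s.treatments)
            for i in range(len(t)):
                for j in range(i + 1, len(t)):
                    g.add_edge(t[i], t[j])
        return g


@dataclass(frozen=True)
class TrialSpec:
    """Design request for a new three-arm trial.

    ``treat_A`` is the control (negative control), ``treat_B`` the reference,
    both present in the existing network; ``treat_Z`` is the new treatment,
    absent from it.  Exactly one of ``total_n`` / ``target_power`` must be
    given.
    """

    treat_A: str
    treat_B: str
    treat_Z: str
    p_A: float
    p_B: float
    p_Z: float
    test: str = "noninferiority"  # or "superiority"
    margin: float | None = None
    alpha: float = 0.05
    total_n: int | None = None
    target_power: float | None = None
    min_per_arm: int = 10

    def __post_init__(self) -> None:
        for name in ("p_A", "p_B", "p_Z"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise DataValidationError(f"{name}={p} must lie strictly inside (0, 1)")
        if self.test not in ("noninferiority", "superiority"):
            raise DataValidationError(f"unknown test type {self.test!r}")
        if self.test == "noninferiority" and self.margin is None:
            raise DataValidationError("non-inferiority design requires a margin")
        if not 0.0 < self.alpha < 1.0:
            raise DataValidationError(f"alpha={self.alpha} must lie in (0, 1)")
        if (self.total_n is None) == (self.target_power is None):
            raise DataValidationError(
                "specify exactly one restriction: total_n or target_power"
            )
        if self.total_n is not None and self.total_n < 3 * self.min_per_arm:
            raise DataValidationError(
                f"total_n={self.total_n} < 3*min_per_arm={3 * self.min_per_arm}"
            )
        if self.target_power is not None and not 0.0 < self.target_power < 1.0:
            raise DataValidationError("target_power must lie in (0, 1)")

    @property
    def effect(self) -> float:
        """True log odds ratio of the comparison of interest.

        Z-over-B for non-inferiority, Z-over-A (vs negative control) for
        superiority.
        """
        ref = self.p_B if self.test == "noninferiority" else self.p_A
        return _logit(self.p_Z) - _logit(ref)


# ---------------------------------------------------------------------------
# helpers


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


Records = Union[Sequence[ArmRecord], Sequence[ContrastRecord]]


# ---------------------------------------------------------------------------
# CSV I/O

ARM_COLUMNS = ("study", "treatment", "events", "total")
CONTRAST_COLUMNS = ("study", "treat1", "treat2", "lor", "se")


def read_arm_csv(path) -> list:
    """Read arm-level records from a CSV with columns study,treatment,events,total.

    Extra columns are ignored.  Malformed rows raise
    :class:`DataValidationError` naming the offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in ARM_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing column(s) {missing}")
    records = []
    for idx, row in df.iterrows():
        try:
            events, total = row["events"], row["total"]
            if float(events) != int(events) or float(total) != int(total):
                raise DataValidationError("non-integer count")
            records.append(
                ArmRecord(str(row["study"]), str(row["treatment"]), int(events), int(total))
            )
        except (ValueError, TypeError, DataValidationError) as exc:
            raise DataValidationError(f"{path} row {idx + 2}: {exc}") from exc
    return records


def write_arm_csv(path, records: Iterable[ArmRecord]) -> None:
    pd.DataFrame(
        [(r.study_id, r.treatment, r.events, r.total) for r in records],
        columns=list(ARM_COLUMNS),
    ).to_csv(path, index=False)


def read_contrast_csv(path) -> list:
    """Read contrast-level records; ``lor`` is treat2-over-treat1."""
    df = pd.read_csv(path)
    missing = [c for c in CONTRAST_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing column(s) {missing}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                ContrastRecord(
                    str(row["study"]),
                    str(row["treat1"]),
                    str(row["treat2"]),
                    float(row["lor"]),
                    float(row["se"]),
                )
            )
        except (ValueError, TypeError, DataValidationError) as exc:
            raise DataValidationError(f"{path} row {idx + 2}: {exc}") from exc
    return records


def write_contrast_csv(path, records: Iterable[ContrastRecord]) -> None:
    pd.DataFrame(
        [(r.study_id, r.treat_ref, r.treat_alt, r.lor, r.se) for r in records],
        columns=list(CONTRAST_COLUMNS),
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# transformations


def arms_to_contrasts(study_arms: Sequence[ArmRecord], study_baseline: str) -> list:
    """Expand one study's arms into contrasts against ``study_baseline``.

    Each non-baseline arm contributes one contrast with
    ``lor = logit(p_alt) - logit(p_base)`` and
    ``se^2 = 1/(n*p*(1-p))`` summed over the two arms (equivalently
    ``1/r + 1/(n-r)`` per arm).  When any cell of a contrast's two-by-two
    table is zero, 0.5 is added to all four cells of that contrast
    (Haldane–Anscombe) and a warning is emitted.
    """
    arms = list(study_arms)
    if len(arms) < 2:
        raise DataValidationError(
            f"study {arms[0].study_id!r}: cannot form contrasts from a single arm"
        )
    by_label = {a.treatment: a for a in arms}
    if len(by_label) != len(arms):
        raise DataValidationError(
            f"study {arms[0].study_id!r}: duplicate treatment labels within study"
        )
    if study_baseline not in by_label:
        raise DataValidationError(
            f"study {arms[0].study_id!r}: baseline {study_baseline!r} not among its arms"
        )
    base = by_label[study_baseline]
    out = []
    for label in sorted(by_label):
        if label == study_baseline:
            continue
        alt = by_label[label]
        cells = [base.events, base.total - base.events, alt.events, alt.total - alt.events]
        if min(cells) == 0:
            warnings.warn(
                f"study {base.study_id!r} contrast {study_baseline}-{label}: "
                "zero cell, adding 0.5 to all four cells",
                stacklevel=2,
            )
            r0, nr0, r1, nr1 = (c + 0.5 for c in cells)
        else:
            r0, nr0, r1, nr1 = cells
        lor = math.log(r1 / nr1) - math.log(r0 / nr0)
        se = math.sqrt(1.0 / r0 + 1.0 / nr0 + 1.0 / r1 + 1.0 / nr1)
        out.append(ContrastRecord(base.study_id, study_baseline, label, lor, se))
    return out


def assemble_network(records: Records, baseline: str) -> Network:
    """Group validated records by study and build a connected :class:`Network`.

    Raises if the comparison graph is disconnected (listing components) or if
    the baseline is absent.
    """
    if not records:
        raise DataValidationError("no records supplied")
    grouped: dict = {}
    for r in records:
        grouped.setdefault(r.study_id, []).append(r)
    studies = []
    for sid, recs in grouped.items():
        if isinstance(recs[0], ArmRecord):
            studies.append(Study(study_id=sid, arms=tuple(recs)))
        else:
            studies.append(Study(study_id=sid, contrasts=tuple(recs)))
    network = Network(studies=tuple(studies), baseline=baseline)
    graph = network.comparison_graph()
    components = list(nx.connected_components(graph))
    if len(components) > 1:
        pretty = "; ".join(sorted(",".join(sorted(c)) for c in components))
        raise DataValidationError(f"comparison graph is disconnected: components [{pretty}]")
    return network


def pooled_event_probability(network: Network, treatment: str) -> float:
    """Event probability pooled over all arms of ``treatment``: sum r / sum n."""
    events = totals = 0
    seen = False
    for s in network.studies:
        if not s.is_arm_level:
            continue
        for a in s.arms:
            if a.treatment == treatment:
                events += a.events
                totals += a.total
                seen = True
    if not seen:
        raise DataValidationError(f"treatment {treatment!r} has no arm-level data")
    return events / totals
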