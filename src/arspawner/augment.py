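"""Acceptance-constrained augmentation driver.

A generated candidate X* of class k is kept only if it is simultaneously

* far enough from where it came from — its DTW distance ``d1`` to its first
  parent and ``d2`` to the class representative must both exceed the lower
  bound ``r1 * d_mean_k`` (a candidate near existing examples adds no new
  knowledge), and
* not so far that it drifts into territory plausibly occupied by another
  class — ``d1`` and ``d2`` must both stay below the threshold

      T = r1 * d_mean_k + d_std_k * (r2 + d_std_k / d_mean_k).

All four comparisons are strict.  ``r1`` and ``r2`` in (0, 1] trade off how
aggressive the filter is; ablation modes allow switching off the lower
bound, the upper bound, or all conditions involving ``d1`` or ``d2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dba import ClassRepresentative, ClassStatistics, class_statistics, dba
from .dtw import dtw
from .errors import DegenerateClassError
from .spawner import SpawnerCandidate, spawn
from .timeseries import Dataset, TimeSeries

__all__ = [
    "AugmentationConfig",
    "AcceptanceReport",
    "ABLATION_MODES",
    "acceptance_threshold",
    "evaluate_candidate",
    "augment",
]

#: which of the four comparisons each ablation mode keeps active
ABLATION_MODES: dict[str, frozenset[str]] = {
    "both": frozenset({"d1-lower", "d2-lower", "d1-upper", "d2-upper"}),
    "lower-only": frozenset({"d1-lower", "d2-lower"}),
    "upper-only": frozenset({"d1-upper", "d2-upper"}),
    "no-d1": frozenset({"d2-lower", "d2-upper"}),
    "no-d2": frozenset({"d1-lower", "d1-upper"}),
}


@dataclass(frozen=True)
class AugmentationConfig:
    """Knobs of the augmentation driver.

    ``r1``/``r2`` scale the lower/upper acceptance bounds; ``window`` (when
    set) is a global Sakoe-Chiba band applied to every DTW call, including
    class statistics and the d1/d2 evaluations — by default those are
    unbanded.  ``symmetric_d1`` replaces d1 by the minimum distance over
    both parents instead of the first parent alone.
    """

    r1: float = 0.5
    r2: float = 0.5
    seed: int | None = None
    window: int | None = None
    candidates_per_pair: int = 1
    mode: str = "both"
    symmetric_d1: bool = False
    dba_max_iter: int = 10
    dba_tol: float = 1e-5

    def __post_init__(self) -> None:
        if not (self.r1 > 0 and self.r2 > 0):
            raise ValueError("r1 and r2 must be positive")
        if self.mode not in ABLATION_MODES:
            raise ValueError(
                f"unknown ablation mode {self.mode!r}; choose from {sorted(ABLATION_MODES)}"
            )
        if self.candidates_per_pair < 1:
            raise ValueError("candidates_per_pair must be >= 1")


@dataclass(frozen=True)
class AcceptanceReport:
    """Verdict and every compared quantity for one candidate."""

    candidate_id: str
    label: str
    parents: tuple[str, str]
    d1: float
    d2: float
    lower_bound: float
    upper_bound: float
    accepted: bool
    failed_conditions: tuple[str, ...] = field(default=())


def acceptance_threshold(stats: ClassStatistics, r1: float, r2: float) -> float:
    """Upper acceptance bound T = r1*mean + std*(r2 + std/mean)."""
    if stats.mean_distance <= 0:
        raise DegenerateClassError(
            f"class {stats.label!r}: mean within-class distance is zero; "
            "threshold undefined"
        )
    m, s = stats.mean_distance, stats.std_distance
    return r1 * m + s * (r2 + s / m)


def evaluate_candidate(
    candidate: SpawnerCandidate,
    parent1: TimeSeries,
    rep: ClassRepresentative,
    stats: ClassStatistics,
    r1: float,
    r2: float,
    window: int | None = None,
    mode: str = "both",
    parent2: TimeSeries | None = None,
    symmetric_d1: bool = False,
) -> AcceptanceReport:
    """Apply the acceptance constraints to one candidate.

    ``d1`` is the DTW distance to the first parent (or, with
    ``symmetric_d1`` and ``parent2`` given, the smaller of the two parent
    distances); ``d2`` is the distance to the class representative.
    """
    if not (candidate.label == parent1.label == rep.label == stats.label):
        raise ValueError(
            "class mismatch among candidate/parent/representative/statistics: "
            f"{candidate.label!r}, {parent1.label!r}, {rep.label!r}, {stats.label!r}"
        )
    active = ABLATION_MODES[mode]
    d1 = dtw(parent1.values, candidate.values, window).distance
    if symmetric_d1 and parent2 is not None:
        d1 = min(d1, dtw(parent2.values, candidate.values, window).distance)
    d2 = dtw(rep.values, candidate.values, window).distance
    lower = r1 * stats.mean_distance
    upper = acceptance_threshold(stats, r1, r2)
    checks = {
        "d1-lower": d1 > lower,
        "d2-lower": d2 > lower,
        "d1-upper": d1 < upper,
        "d2-upper": d2 < upper,
    }
    failed = tuple(name for name in sorted(active) if not checks[name])
    return AcceptanceReport(
        candidate_id=candidate.candidate_id,
        label=candidate.label,
        parents=candidate.parents,
        d1=float(d1),
        d2=float(d2),
        lower_bound=float(lower),
        upper_bound=float(upper),
        accepted=not failed,
        failed_conditions=failed,
    )


def augment(
    train: Dataset, config: AugmentationConfig | None = None
) -> tuple[Dataset, list[AcceptanceReport]]:
    """Generate and filter candidates for every unordered within-class pair.

    Returns a new dataset consisting of the untouched input series followed
    by the accepted candidates, plus one report per generated candidate.
    Classes with fewer than two members, or whose members are all identical
    (zero mean pairwise distance), are skipped with a warning.
    """
    if config is None:
        config = AugmentationConfig()
    rng = np.random.default_rng(config.seed)
    by_class = train.by_class()

    usable: dict[str, list[TimeSeries]] = {}
    for label in sorted(by_class):
        members = by_class[label]
        if len(members) < 2:
            warnings.warn(f"class {label!r} has < 2 members; skipped")
            continue
        usable[label] = members

    accepted_series: list[TimeSeries] = []
    reports: list[AcceptanceReport] = []
    for label, members in usable.items():
        sub = Dataset(members, name=label)
        stats = class_statistics(sub, config.window)[label]
        if stats.mean_distance <= 0:
            warnings.warn(
                f"class {label!r}: all members identical (zero mean distance); skipped"
            )
            continue
        rep = dba(
            members,
            max_iter=config.dba_max_iter,
            tol=config.dba_tol,
            window=config.window,
        )
        n = len(members)
        for a in range(n):
            for b in range(a + 1, n):
                p1, p2 = members[a], members[b]
                for k in range(config.candidates_per_pair):
                    cid = f"aug:{p1.series_id}+{p2.series_id}:{k}"
                    cand = spawn(p1, p2, rng, candidate_id=cid)
                    report = evaluate_candidate(
                        cand,
                        p1,
                        rep,
                        stats,
                        config.r1,
                        config.r2,
                        window=config.window,
                        mode=config.mode,
                        parent2=p2,
                        symmetric_d1=config.symmetric_d1,
                    )
                    reports.append(report)
                    if report.accepted:
                        accepted_series.append(
                            TimeSeries(
                                values=cand.values,
                                label=cand.label,
                                subject=f"{p1.subject}+{p2.subject}",
                                series_id=cid,
                            )
                        )
    augmented = Dataset(
        list(train.series) + accepted_series, name=f"{train.name}-augmented"
    )
    return augmented, reports


def reports_to_frame(reports: list[AcceptanceReport]):
    """Tabulate acceptance reports (one row per candidate) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "candidate_id": [r.candidate_id for r in reports],
            "label": [r.label for r in reports],
            "parent1": [r.parents[0] for r in reports],
            "parent2": [r.parents[1] for r in reports],
            "d1": [r.d1 for r in reports],
            "d2": [r.d2 for r in reports],
            "lower_bound": [r.lower_bound for r in reports],
            "upper_bound": [r.upper_bound for r in reports],
            "accepted": [r.accepted for r in reports],
            "failed_conditions": [";".join(r.failed_conditions) for r in reports],
        }
    )
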