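"""Per-class DTW distance statistics and barycenter-averaged representatives.

The acceptance constraints of the augmenter need, for every class k of the
training split:

* the mean ``d_mean_k`` and standard deviation ``d_std_k`` of the DTW
  distances over all unordered distinct within-class pairs, and
* a representative sequence obtained by DTW barycenter averaging (DBA):
  the minimiser of the summed squared DTW distance to the class members,
  refined with an expectation-maximisation-style loop — align every member
  to the current barycenter, then replace each barycenter element by the
  mean of all member elements mapped onto it.

The barycenter is initialised at the class medoid (the member with the
smallest summed DTW distance to the others), which keeps the procedure
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dtw import dtw, pairwise_dtw
from .errors import DegenerateClassError
from .timeseries import Dataset, TimeSeries

__all__ = [
    "ClassStatistics",
    "ClassRepresentative",
    "class_statistics",
    "dba",
    "dba_objective",
]


@dataclass(frozen=True)
class ClassStatistics:
    label: str
    mean_distance: float
    std_distance: float
    n_pairs: int


@dataclass(frozen=True)
class ClassRepresentative:
    label: str
    values: np.ndarray
    objective_trace: tuple[float, ...]


def class_statistics(
    train: Dataset, window: int | None = None
) -> dict[str, ClassStatistics]:
    """Mean/std of within-class pairwise DTW distances, per class.

    Uses the population convention (divide by the number of pairs).
    Classes with fewer than two members raise
    :class:`~arspawner.errors.DegenerateClassError`.
    """
    out: dict[str, ClassStatistics] = {}
    for label, members in sorted(train.by_class().items()):
        n = len(members)
        if n < 2:
            raise DegenerateClassError(
                f"class {label!r} has {n} training series; need >= 2 for statistics"
            )
        dm = pairwise_dtw(members, window)
        iu = np.triu_indices(n, k=1)
        dists = dm[iu]
        out[label] = ClassStatistics(
            label=label,
            mean_distance=float(np.mean(dists)),
            std_distance=float(np.std(dists)),  # population std over pairs
            n_pairs=len(dists),
        )
    return out


def _values(s) -> np.ndarray:
    v = np.asarray(getattr(s, "values", s), dtype=np.float64)
    return v[:, None] if v.ndim == 1 else v


def dba_objective(
    rep_values: np.ndarray,
    series,
    window: int | None = None,
    squared: bool = True,
) -> float:
    """Sum over members of the (squared, by default) DTW distance to ``rep``.

    The engine's DTW distance is already an accumulated sum of squared
    element differences; ``squared=True`` squares that accumulated cost once
    more (the literal objective), ``squared=False`` treats the accumulated
    cost itself as the squared dissimilarity.
    """
    rep_values = _values(rep_values)
    total = 0.0
    for s in series:
        d = dtw(rep_values, _values(s), window).distance
        total += d * d if squared else d
    return float(total)


def dba(
    series,
    init: str = "medoid",
    max_iter: int = 10,
    tol: float = 1e-5,
    window: int | None = None,
    squared: bool = True,
    label: str | None = None,
) -> ClassRepresentative:
    """DTW barycenter average of a collection of series.

    Parameters
    ----------
    series
        Non-empty list of :class:`TimeSeries` or arrays sharing M.
    init
        ``"medoid"`` (default) or ``"first"``.
    max_iter, tol
        Refinement stops after ``max_iter`` updates or when the relative
        objective decrease falls below ``tol``.
    squared
        Objective convention, see :func:`dba_objective`.

    The returned ``objective_trace`` holds the objective at the initial
    barycenter and after each accepted refinement; the final ``values``
    correspond to the last trace entry.
    """
    arrays = [_values(s) for s in series]
    if not arrays:
        raise ValueError("dba requires at least one series")
    if label is None:
        labels = {getattr(s, "label", "") for s in series}
        label = labels.pop() if len(labels) == 1 else ""
    if len(arrays) == 1:
        return ClassRepresentative(label, arrays[0].copy(), (0.0,))

    if init == "medoid":
        dm = pairwise_dtw(arrays, window)
        B = arrays[int(np.argmin(dm.sum(axis=0)))].copy()
    elif init == "first":
        B = arrays[0].copy()
    else:
        raise ValueError(f"unknown init strategy {init!r}")

    def align_all(bary: np.ndarray):
        """One expectation pass: paths of every member against ``bary``."""
        obj = 0.0
        paths = []
        for arr in arrays:
            res = dtw(bary, arr, window)
            obj += res.distance**2 if squared else res.distance
            paths.append(res.path.pairs)
        return paths, float(obj)

    paths, obj = align_all(B)
    trace = [obj]
    for _ in range(max_iter):
        # maximisation: each barycenter element becomes the mean of all
        # member elements its index is aligned with
        sums = np.zeros_like(B)
        counts = np.zeros(B.shape[0])
        for arr, pairs in zip(arrays, paths):
            np.add.at(sums, pairs[:, 0] - 1, arr[pairs[:, 1] - 1])
            np.add.at(counts, pairs[:, 0] - 1, 1.0)
        newB = sums / counts[:, None]
        new_paths, new_obj = align_all(newB)
        if new_obj > trace[-1]:
            break  # refinement stalled; keep the better barycenter
        B, paths = newB, new_paths
        trace.append(new_obj)
        if trace[-2] - trace[-1] <= tol * max(trace[-2], 1e-300):
            break
    return ClassRepresentative(label, B, tuple(trace))
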