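"""Banded dynamic time warping with explicit warping paths.

The local cost between two M-dimensional elements is the squared Euclidean
norm, and the returned distance is the accumulated cost at the end cell
``D(L1, L2)`` — no final square root is taken, matching the recurrence

    D(i, j) = ||x1_i - x2_j||^2 + min(D(i-1, j), D(i, j-1), D(i-1, j-1)).

A warping path is the sequence of aligned index pairs; it starts at (1, 1),
ends at (L1, L2), is monotone, and moves only in steps of (1,0), (0,1) or
(1,1).  An optional Sakoe-Chiba window ``w`` restricts alignment to cells
with ``|i - j| <= w``.  When the window is narrower than ``|L1 - L2|`` the
end cell is unreachable; by default the band is widened to ``|L1 - L2|``
with a warning (``on_infeasible="error"`` raises instead).

Ties in the recurrence minimum are broken deterministically: diagonal
first, then the vertical (i-1, j) step, then the horizontal (i, j-1) step,
so the returned path is a pure function of the inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

from .errors import DimensionMismatchError, InfeasibleBandError

__all__ = [
    "WarpingPath",
    "DtwResult",
    "dtw",
    "dtw_bruteforce",
    "pairwise_dtw",
    "local_cost_matrix",
    "resolve_window",
]


@dataclass(frozen=True)
class WarpingPath:
    """Monotone, continuous, boundary-anchored alignment path.

    ``pairs`` is an integer array of shape ``(P, 2)`` with 1-based indices.
    """

    pairs: np.ndarray

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=np.int64)
        pairs.flags.writeable = False
        object.__setattr__(self, "pairs", pairs)

    def __len__(self) -> int:
        return self.pairs.shape[0]

    @property
    def end(self) -> tuple[int, int]:
        return int(self.pairs[-1, 0]), int(self.pairs[-1, 1])

    def validate(self, L1: int, L2: int) -> None:
        """Raise ``ValueError`` unless the path is admissible on an L1 x L2 grid."""
        p = self.pairs
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] == 0:
            raise ValueError("path must be a non-empty (P, 2) array")
        if tuple(p[0]) != (1, 1):
            raise ValueError(f"path must start at (1, 1), starts at {tuple(p[0])}")
        if tuple(p[-1]) != (L1, L2):
            raise ValueError(
                f"path must end at ({L1}, {L2}), ends at {tuple(p[-1])}"
            )
        steps = np.diff(p, axis=0)
        ok = (
            ((steps[:, 0] == 1) & (steps[:, 1] == 0))
            | ((steps[:, 0] == 0) & (steps[:, 1] == 1))
            | ((steps[:, 0] == 1) & (steps[:, 1] == 1))
        )
        if not np.all(ok):
            bad = int(np.argmin(ok))
            raise ValueError(f"illegal step {tuple(steps[bad])} at position {bad}")
        P = p.shape[0]
        if not (max(L1, L2) <= P < L1 + L2):
            raise ValueError(f"path length {P} outside [max(L1,L2), L1+L2) for {L1}x{L2}")


@dataclass(frozen=True)
class DtwResult:
    distance: float
    path: WarpingPath


def _as_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError(f"expected a non-empty L x M matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in input series")
    return X


def local_cost_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean costs, shape ``(L1, L2)``."""
    A, B = _as_matrix(A), _as_matrix(B)
    if A.shape[1] != B.shape[1]:
        raise DimensionMismatchError(
            f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}"
        )
    return cdist(A, B, metric="sqeuclidean")


def resolve_window(
    window: int | None, L1: int, L2: int, on_infeasible: str = "widen"
) -> int:
    """Turn a user window into a feasible band half-width (-1 = unbanded)."""
    if window is None:
        return -1
    window = int(window)
    if window < 0:
        raise ValueError(f"window must be non-negative, got {window}")
    gap = abs(L1 - L2)
    if window < gap:
        if on_infeasible == "error":
            raise InfeasibleBandError(
                f"window {window} < |L1 - L2| = {gap}: end cell unreachable"
            )
        warnings.warn(
            f"widening warping window from {window} to {gap} "
            f"(band infeasible for lengths {L1}, {L2})",
            stacklevel=3,
        )
        return gap
    return window


@njit(cache=True)
def _accumulate(cost: np.ndarray, w: int) -> np.ndarray:  # pragma: no cover
    L1, L2 = cost.shape
    D = np.full((L1, L2), np.inf)
    for i in range(L1):
        if w < 0:
            jlo, jhi = 0, L2
        else:
            jlo = max(0, i - w)
            jhi = min(L2, i + w + 1)
        for j in range(jlo, jhi):
            if i == 0 and j == 0:
                D[0, 0] = cost[0, 0]
                continue
            best = np.inf
            if i > 0 and j > 0 and D[i - 1, j - 1] < best:
                best = D[i - 1, j - 1]
            if i > 0 and D[i - 1, j] < best:
                best = D[i - 1, j]
            if j > 0 and D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = cost[i, j] + best
    return D


def _backtrack(D: np.ndarray) -> np.ndarray:
    """Recover one optimal path from the accumulated matrix (0-based in, 1-based out)."""
    i, j = D.shape[0] - 1, D.shape[1] - 1
    rev = [(i, j)]
    while i > 0 or j > 0:
        # preference order: diagonal, vertical, horizontal
        cands = []
        if i > 0 and j > 0:
            cands.append((D[i - 1, j - 1], 0, i - 1, j - 1))
        if i > 0:
            cands.append((D[i - 1, j], 1, i - 1, j))
        if j > 0:
            cands.append((D[i, j - 1], 2, i, j - 1))
        _, _, i, j = min(cands)
        rev.append((i, j))
    pairs = np.asarray(rev[::-1], dtype=np.int64) + 1
    return pairs


def dtw(
    A: np.ndarray,
    B: np.ndarray,
    window: int | None = None,
    on_infeasible: str = "widen",
) -> DtwResult:
    """Minimal accumulated squared-distance alignment of two sequences.

    Parameters
    ----------
    A, B
        Sequences of shape ``(L1, M)`` and ``(L2, M)`` (1-D inputs are
        treated as ``M = 1``).
    window
        Sakoe-Chiba band half-width; ``None`` disables banding.
    on_infeasible
        ``"widen"`` (default) enlarges an infeasible band to ``|L1 - L2|``
        with a warning; ``"error"`` raises :class:`InfeasibleBandError`.
    """
    cost = local_cost_matrix(A, B)
    L1, L2 = cost.shape
    w = resolve_window(window, L1, L2, on_infeasible)
    D = _accumulate(cost, w)
    path = WarpingPath(_backtrack(D))
    return DtwResult(distance=float(D[-1, -1]), path=path)


def dtw_bruteforce(A: np.ndarray, B: np.ndarray, max_cells: int = 100) -> float:
    """Minimal accumulated cost by exhaustive path enumeration.

    Independent oracle for :func:`dtw`: walks every admissible monotone
    boundary-anchored path on the grid (with cost-bound pruning) instead of
    using the recurrence.  Guarded to small instances.
    """
    cost = local_cost_matrix(A, B)
    L1, L2 = cost.shape
    if L1 * L2 > max_cells:
        raise ValueError(f"instance {L1}x{L2} exceeds brute-force guard of {max_cells} cells")
    best = [np.inf]

    def rec(i: int, j: int, acc: float) -> None:
        acc += cost[i, j]
        if acc >= best[0]:
            return
        if i == L1 - 1 and j == L2 - 1:
            best[0] = acc
            return
        if i + 1 < L1 and j + 1 < L2:
            rec(i + 1, j + 1, acc)
        if i + 1 < L1:
            rec(i + 1, j, acc)
        if j + 1 < L2:
            rec(i, j + 1, acc)

    rec(0, 0, 0.0)
    return float(best[0])


def pairwise_dtw(series, window: int | None = None) -> np.ndarray:
    """Symmetric matrix of DTW distances between all pairs of series.

    ``series`` may be :class:`~arspawner.timeseries.TimeSeries` objects or
    plain arrays.
    """
    arrays = [_as_matrix(getattr(s, "values", s)) for s in series]
    n = len(arrays)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            try:
                out[a, b] = out[b, a] = dtw(arrays[a], arrays[b], window).distance
            except Exception as exc:
                raise type(exc)(f"pair ({a}, {b}): {exc}") from exc
    return out
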