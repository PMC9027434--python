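"""Suboptimal-warping generation of new series from same-class parent pairs.

Given two parents X1 (length L1) and X2 (length L2), a split fraction
``r ~ U(0, 1)`` fixes the pair ``(R1, R2) = (ceil(r*L1), ceil(r*L2))`` that
the warping path is forced to pass through.  The two sides of the split are
aligned independently with narrow Sakoe-Chiba bands

    xi1 = ceil(0.1 * max(R1, R2)),
    xi2 = ceil(0.1 * max(L1 - R1, L2 - R2)),

and the two optimal sub-paths are concatenated into one path that is
suboptimal on the full grid.  Both parents are then expanded along this
path and merged element-wise with Gaussian noise::

    x* ~ N(mu, sigma^2),  mu = 0.5 (x1* + x2*),  sigma = 0.05 |x1* - x2*|

Identical aligned elements therefore reproduce exactly (sigma = 0), and a
fixed random generator makes every candidate bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dtw import WarpingPath, dtw
from .errors import SplitError
from .timeseries import TimeSeries

__all__ = [
    "SpawnerCandidate",
    "split_point",
    "suboptimal_path",
    "align_to_path",
    "merge_aligned",
    "spawn",
]

_MAX_SPLIT_TRIES = 128


@dataclass(frozen=True)
class SpawnerCandidate:
    """A generated series with full provenance."""

    values: np.ndarray
    parents: tuple[str, str]
    label: str
    split_fraction: float
    split: tuple[int, int]
    path: WarpingPath
    candidate_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape[0] != len(self.path):
            raise ValueError("candidate length must equal path length")
        values.flags.writeable = False
        object.__setattr__(self, "values", values)


def split_point(
    L1: int, L2: int, rng: np.random.Generator
) -> tuple[float, int, int]:
    """Draw a split fraction r and the forced path element (R1, R2).

    ``R = ceil(r * L)`` for each side.  Draws leaving an empty segment on
    either side (``R = 0`` or ``R = L``) are resampled so that both
    sub-alignments have non-empty inputs; after a bounded number of tries a
    :class:`SplitError` is raised.
    """
    if L1 < 2 or L2 < 2:
        raise SplitError(f"cannot split series of lengths {L1}, {L2} (need >= 2)")
    for _ in range(_MAX_SPLIT_TRIES):
        r = float(rng.uniform(0.0, 1.0))
        R1 = math.ceil(r * L1)
        R2 = math.ceil(r * L2)
        if 1 <= R1 < L1 and 1 <= R2 < L2:
            return r, R1, R2
    raise SplitError(
        f"no admissible split after {_MAX_SPLIT_TRIES} draws for lengths {L1}, {L2}"
    )


def suboptimal_path(
    X1: np.ndarray, X2: np.ndarray, R1: int, R2: int
) -> WarpingPath:
    """Best warping path forced through (R1, R2), built from two banded halves.

    Each half is aligned optimally within its own narrow band; the
    concatenation is admissible on the full grid (the junction step from
    (R1, R2) to (R1+1, R2+1) is the diagonal) but generally suboptimal.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=np.float64))
    X2 = np.atleast_2d(np.asarray(X2, dtype=np.float64))
    L1, L2 = X1.shape[0], X2.shape[0]
    if not (1 <= R1 < L1 and 1 <= R2 < L2):
        raise ValueError(f"split ({R1}, {R2}) invalid for lengths ({L1}, {L2})")
    xi1 = math.ceil(0.1 * max(R1, R2))
    xi2 = math.ceil(0.1 * max(L1 - R1, L2 - R2))
    left = dtw(X1[:R1], X2[:R2], window=xi1).path.pairs
    right = dtw(X1[R1:], X2[R2:], window=xi2).path.pairs
    pairs = np.vstack([left, right + np.array([R1, R2])])
    path = WarpingPath(pairs)
    path.validate(L1, L2)
    return path


def align_to_path(
    X1: np.ndarray, X2: np.ndarray, path: WarpingPath
) -> tuple[np.ndarray, np.ndarray]:
    """Expand both parents along the path: output p holds (X1[i_p], X2[j_p])."""
    X1 = np.atleast_2d(np.asarray(X1, dtype=np.float64))
    X2 = np.atleast_2d(np.asarray(X2, dtype=np.float64))
    i = path.pairs[:, 0] - 1
    j = path.pairs[:, 1] - 1
    if i[-1] >= X1.shape[0] or j[-1] >= X2.shape[0]:
        raise IndexError("path indices exceed series lengths")
    return X1[i], X2[j]


def merge_aligned(
    X1s: np.ndarray, X2s: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Merge two aligned sequences with element-wise Gaussian draws.

    Each element (per time step and per dimension) is drawn independently
    from N(mu, sigma^2) with mu the midpoint and sigma = 0.05 times the gap,
    so coinciding elements pass through unchanged.
    """
    X1s = np.asarray(X1s, dtype=np.float64)
    X2s = np.asarray(X2s, dtype=np.float64)
    if X1s.shape != X2s.shape:
        raise ValueError(f"aligned shapes differ: {X1s.shape} vs {X2s.shape}")
    mu = 0.5 * (X1s + X2s)
    sigma = 0.05 * np.abs(X1s - X2s)
    return rng.normal(mu, sigma)


def spawn(
    X1: TimeSeries,
    X2: TimeSeries,
    rng: np.random.Generator,
    candidate_id: str = "",
) -> SpawnerCandidate:
    """Generate one candidate from a same-class parent pair."""
    if X1.label != X2.label:
        raise ValueError(
            f"parents must share a label: {X1.label!r} vs {X2.label!r}"
        )
    r, R1, R2 = split_point(X1.length, X2.length, rng)
    path = suboptimal_path(X1.values, X2.values, R1, R2)
    a1, a2 = align_to_path(X1.values, X2.values, path)
    merged = merge_aligned(a1, a2, rng)
    return SpawnerCandidate(
        values=merged,
        parents=(X1.series_id, X2.series_id),
        label=X1.label,
        split_fraction=r,
        split=(R1, R2),
        path=path,
        candidate_id=candidate_id,
    )
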