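"""Synthetic skeleton sequences and labelled feature series.

The generators emulate the statistical structure of small motion-capture
action benchmarks: a handful of classes (default 8), several performers,
variable sequence lengths (default 13-76 frames), smooth class-specific
motion, per-subject idiosyncrasy, nonlinear time warping between
repetitions, and additive sensor noise.  They make every stage of the
pipeline testable without any external download.

Each class owns a motion template: per joint (or per feature dimension) a
sum of low-frequency sinusoids with class-specific amplitudes and phases.
A repetition samples the template at a randomly warped phase grid (a
monotone piecewise-linear reparameterisation of [0, 1]), adds a constant
subject offset, and i.i.d. Gaussian noise.  A ``separation`` factor scales
the class-specific part of the template; at 0 all classes collapse onto a
shared base motion and classification accuracy drops to chance.
"""

from __future__ import annotations

import numpy as np

from .layouts import base_pose_array, get_layout
from .timeseries import Dataset, SkeletonSequence, TimeSeries

__all__ = ["generate_skeletons", "generate_feature_series", "monotone_warp"]


def monotone_warp(L: int, jitter: float, rng: np.random.Generator) -> np.ndarray:
    """L phase values: a random monotone piecewise-linear map of [0, 1].

    ``jitter`` = 0 yields the identity grid; larger values make segment
    speeds more uneven (Dirichlet-distributed segment weights).
    """
    t = np.linspace(0.0, 1.0, L)
    if jitter <= 0:
        return t
    n_seg = 4
    alpha = max(1.0 / jitter, 1e-3)
    weights = rng.dirichlet(np.full(n_seg, alpha))
    knots_x = np.linspace(0.0, 1.0, n_seg + 1)
    knots_y = np.concatenate([[0.0], np.cumsum(weights)])
    return np.interp(t, knots_x, knots_y)


def _sinusoid_bank(
    rng: np.random.Generator, shape: tuple[int, ...], n_harmonics: int = 2
):
    """Random amplitudes/frequencies/phases for a sum-of-sinusoids template."""
    amps = rng.uniform(0.5, 1.5, size=(n_harmonics, *shape))
    freqs = rng.integers(1, 4, size=(n_harmonics, *shape)).astype(float)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_harmonics, *shape))
    return amps, freqs, phases


def _eval_bank(bank, phase: np.ndarray) -> np.ndarray:
    """Evaluate a sinusoid bank on a phase grid -> (L, *shape)."""
    amps, freqs, phases = bank
    ph = phase[(slice(None), None) + (None,) * (amps.ndim - 1)]
    terms = amps[None] * np.sin(2.0 * np.pi * freqs[None] * ph + phases[None])
    return terms.sum(axis=1)


def generate_skeletons(
    n_classes: int = 8,
    n_subjects: int = 10,
    reps_per_subject: int = 3,
    layout: str = "kinect20",
    length_range: tuple[int, int] = (13, 76),
    motion_amp: float = 0.25,
    separation: float = 1.0,
    subject_scale: float = 0.03,
    jitter: float = 0.3,
    noise: float = 0.01,
    seed: int | None = None,
) -> list[SkeletonSequence]:
    """Draw a labelled collection of synthetic skeleton sequences.

    Joint trajectories are the layout's base standing pose plus a shared
    base motion and a class-specific deviation (both sums of sinusoids,
    metres), scaled by ``motion_amp``; the deviation is additionally scaled
    by ``separation``.  Subjects get a constant per-joint pose offset of
    scale ``subject_scale``; every repetition draws its own length,
    monotone time warp and i.i.d. positional noise.
    """
    if n_classes < 2 or n_subjects < 2:
        raise ValueError("need at least 2 classes and 2 subjects")
    lo, hi = length_range
    if not (2 <= lo <= hi):
        raise ValueError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    lay = get_layout(layout)
    pose = base_pose_array(layout)
    J = pose.shape[0]

    base_bank = _sinusoid_bank(rng, (J, 3))
    class_banks = [_sinusoid_bank(rng, (J, 3)) for _ in range(n_classes)]
    subject_offsets = rng.normal(0.0, subject_scale, size=(n_subjects, J, 3))

    out: list[SkeletonSequence] = []
    for c in range(n_classes):
        for s in range(n_subjects):
            for rep in range(reps_per_subject):
                L = int(rng.integers(lo, hi + 1))
                phase = monotone_warp(L, jitter, rng)
                motion = motion_amp * (
                    _eval_bank(base_bank, phase)
                    + separation * _eval_bank(class_banks[c], phase)
                )
                frames = (
                    pose[None]
                    + motion
                    + subject_offsets[s][None]
                    + rng.normal(0.0, noise, size=(L, J, 3))
                )
                out.append(
                    SkeletonSequence(
                        frames=frames,
                        layout=lay,
                        label=f"a{c + 1:02d}",
                        subject=f"s{s + 1:02d}",
                        series_id=f"a{c + 1:02d}-s{s + 1:02d}-r{rep + 1:02d}",
                    )
                )
    return out


def generate_feature_series(
    n_classes: int = 8,
    n_per_class: int = 20,
    n_dims: int = 3,
    length_range: tuple[int, int] = (13, 76),
    separation: float = 1.0,
    noise: float = 0.1,
    jitter: float = 0.3,
    n_subjects: int = 10,
    subject_scale: float = 0.1,
    seed: int | None = None,
    name: str = "synthetic",
) -> Dataset:
    """Draw a balanced dataset of labelled multivariate feature series.

    Per class, the template is a shared base curve plus a class-specific
    deviation scaled by ``separation`` (amplitudes of order 1); repetitions
    vary in length, time warp, a per-subject constant offset, and additive
    Gaussian noise.  Subjects are assigned round-robin within each class.
    """
    if n_dims < 1 or n_classes < 1 or n_per_class < 1:
        raise ValueError("n_classes, n_per_class and n_dims must be positive")
    lo, hi = length_range
    if not (2 <= lo <= hi):
        raise ValueError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    base_bank = _sinusoid_bank(rng, (n_dims,))
    class_banks = [_sinusoid_bank(rng, (n_dims,)) for _ in range(n_classes)]
    subject_offsets = rng.normal(0.0, subject_scale, size=(n_subjects, n_dims))

    series: list[TimeSeries] = []
    for c in range(n_classes):
        for k in range(n_per_class):
            s = k % n_subjects
            L = int(rng.integers(lo, hi + 1))
            phase = monotone_warp(L, jitter, rng)
            values = (
                _eval_bank(base_bank, phase)
                + separation * _eval_bank(class_banks[c], phase)
                + subject_offsets[s][None]
                + rng.normal(0.0, noise, size=(L, n_dims))
            )
            series.append(
                TimeSeries(
                    values=values,
                    label=f"c{c + 1:02d}",
                    subject=f"s{s + 1:02d}",
                    series_id=f"c{c + 1:02d}-{k + 1:03d}",
                )
            )
    return Dataset(series, name=name)
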