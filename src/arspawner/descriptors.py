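"""Per-frame skeletal feature descriptors.

Two descriptors turn a skeleton frame into a fixed-length feature vector:

**Distance Descriptor (DD).**  For a subset of N joints, each joint ranks
the other N-1 joints by ascending Euclidean distance (ranks 1..N-1).  The
two ranks of each unordered pair are summed — mutual nearest neighbours
score 2, mutually farthest joints score 2(N-1) — and divided by 2(N-1),
giving N(N-1)/2 values in (0, 1].  Ranks depend only on distance order, so
DD is invariant under rigid motion and uniform scaling.

**Bone Pair Descriptor (BPD).**  For each selected non-central bone
``b_i`` (origin joint P_i), a Darboux frame is erected from the central
bone direction ``u`` and the displacement ``d_i = P_i - P_c``:

    u = unit(b_c),  v_i = unit(d_i) x u,  w_i = u x v_i

and the relative orientation of the bone is read off as
``alpha = acos(v_i . unit(b_i))``, ``phi = acos(u . unit(d_i))`` and
``theta = atan2(w_i . unit(b_i), u . unit(b_i))``.  Angles are normalised
to [0, 1] by pi (alpha, phi) or 2*pi (theta).  Theta is excluded by
default, giving 2 features per non-central bone.

For the default 20-joint configuration (10 DD joints, 12 non-central
bones) the concatenated per-frame vector has 45 + 24 = 69 features.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import DegenerateGeometryError
from .layouts import BPD_BONES, DD_JOINTS
from .timeseries import SkeletonLayout, SkeletonSequence, TimeSeries

__all__ = [
    "distance_descriptor",
    "darboux_angles",
    "bone_pair_descriptor",
    "sequence_features",
    "dd_feature_count",
    "bpd_feature_count",
]

_EPS = 1e-12


def dd_feature_count(n_joints: int) -> int:
    return n_joints * (n_joints - 1) // 2


def bpd_feature_count(n_bones: int, include_theta: bool = False) -> int:
    return n_bones * (3 if include_theta else 2)


def _frame_positions(
    frame, layout: SkeletonLayout | None, joints
) -> np.ndarray:
    """Select named joint positions from a frame (array or mapping)."""
    if isinstance(frame, dict):
        try:
            pos = np.asarray([frame[j] for j in joints], dtype=np.float64)
        except KeyError as exc:
            raise KeyError(f"joint {exc.args[0]!r} missing from frame") from None
    else:
        if layout is None:
            raise ValueError("a layout is required when the frame is an array")
        frame = np.asarray(frame, dtype=np.float64)
        pos = frame[[layout.index(j) for j in joints]]
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite joint positions")
    return pos


def distance_descriptor(
    frame,
    joints,
    layout: SkeletonLayout | None = None,
) -> np.ndarray:
    """Rank-of-distance features for one frame.

    ``frame`` is either a mapping joint-name -> 3-D position or a
    ``(J, 3)`` array accompanied by its ``layout``.  ``joints`` is the
    ordered subset of N >= 3 joint names; ties in distance are broken by
    subset order (stable sort), keeping the output deterministic.
    Returns ``N(N-1)/2`` values in (0, 1], pairs in lexicographic order.
    """
    joints = list(joints)
    n = len(joints)
    if n < 3:
        raise ValueError(f"distance descriptor needs >= 3 joints, got {n}")
    if len(set(joints)) != n:
        raise ValueError("duplicate joints in subset")
    pos = _frame_positions(frame, layout, joints)
    dist = squareform(pdist(pos))
    ranks = np.zeros((n, n), dtype=np.int64)
    others_all = np.arange(n)
    for i in range(n):
        others = others_all[others_all != i]
        order = others[np.argsort(dist[i, others], kind="stable")]
        ranks[i, order] = np.arange(1, n)
    iu, ju = np.triu_indices(n, k=1)
    reduced = ranks[iu, ju] + ranks[ju, iu]
    return reduced / (2.0 * (n - 1))


def darboux_angles(
    central_origin,
    central_end,
    bone_origin,
    bone_end,
) -> tuple[float, float, float]:
    """Darboux-frame angles (alpha, phi, theta) of one bone vs the central bone.

    All inputs are 3-D points.  Raises
    :class:`~arspawner.errors.DegenerateGeometryError` when the central
    bone, the target bone, or the displacement from the central origin to
    the bone origin vanishes, or when that displacement is parallel to the
    central bone (the frame's second axis is then undefined).
    """
    pc = np.asarray(central_origin, dtype=np.float64)
    bc = np.asarray(central_end, dtype=np.float64) - pc
    pi_ = np.asarray(bone_origin, dtype=np.float64)
    bi = np.asarray(bone_end, dtype=np.float64) - pi_
    di = pi_ - pc
    for name, vec in (("central bone", bc), ("bone", bi), ("displacement", di)):
        if np.linalg.norm(vec) < _EPS:
            raise DegenerateGeometryError(f"{name} vector has zero length")
    u = bc / np.linalg.norm(bc)
    di_hat = di / np.linalg.norm(di)
    bi_hat = bi / np.linalg.norm(bi)
    v = np.cross(di_hat, u)
    vnorm = np.linalg.norm(v)
    if vnorm < _EPS:
        raise DegenerateGeometryError(
            "displacement to bone origin is parallel to the central bone; "
            "Darboux frame undefined"
        )
    v /= vnorm
    w = np.cross(u, v)
    alpha = float(np.arccos(np.clip(np.dot(v, bi_hat), -1.0, 1.0)))
    phi = float(np.arccos(np.clip(np.dot(u, di_hat), -1.0, 1.0)))
    theta = float(np.arctan2(np.dot(w, bi_hat), np.dot(u, bi_hat))) % (2.0 * np.pi)
    return alpha, phi, theta


def bone_pair_descriptor(
    frame,
    bones: dict | None = None,
    layout: SkeletonLayout | None = None,
    include_theta: bool = False,
) -> np.ndarray:
    """Normalised Darboux angles of every selected bone against the central one.

    ``bones`` is ``{"central": (origin, end), "bones": ((origin, end), ...)}``;
    when omitted it defaults to the built-in subset for ``layout``.  Output
    order follows the bone list: per bone alpha/pi, phi/pi (and theta/2pi
    when requested), all in [0, 1].
    """
    if bones is None:
        if layout is None:
            raise ValueError("either bones or a layout with defaults is required")
        bones = BPD_BONES[layout.name]
    c_origin, c_end = bones["central"]
    joints_needed = {c_origin, c_end}
    for o, e in bones["bones"]:
        joints_needed.update((o, e))
    joints = sorted(joints_needed)
    pos = _frame_positions(frame, layout, joints)
    lookup = {j: pos[k] for k, j in enumerate(joints)}
    feats: list[float] = []
    for origin, end in bones["bones"]:
        try:
            alpha, phi, theta = darboux_angles(
                lookup[c_origin], lookup[c_end], lookup[origin], lookup[end]
            )
        except DegenerateGeometryError as exc:
            raise DegenerateGeometryError(f"bone {origin}-{end}: {exc}") from exc
        feats.append(alpha / np.pi)
        feats.append(phi / np.pi)
        if include_theta:
            feats.append(theta / (2.0 * np.pi))
    return np.asarray(feats, dtype=np.float64)


def sequence_features(
    seq: SkeletonSequence,
    joints=None,
    bones: dict | None = None,
    include_theta: bool = False,
) -> TimeSeries:
    """Concatenated per-frame DD and BPD features of a skeleton sequence.

    Defaults to the built-in joint and bone subsets of the sequence's
    layout; for the 20-joint layout this yields a 69-dimensional series
    (45 DD + 24 BPD).  Frame-level geometry errors are re-raised with the
    frame index.
    """
    layout = seq.layout
    if joints is None:
        try:
            joints = DD_JOINTS[layout.name]
        except KeyError:
            raise KeyError(
                f"no built-in joint subset for layout {layout.name!r}; pass one"
            ) from None
    rows = []
    for t in range(len(seq)):
        try:
            dd = distance_descriptor(seq.frames[t], joints, layout)
            bpd = bone_pair_descriptor(
                seq.frames[t], bones, layout, include_theta=include_theta
            )
        except Exception as exc:
            raise type(exc)(f"frame {t}: {exc}") from exc
        rows.append(np.concatenate([dd, bpd]))
    return TimeSeries(
        values=np.vstack(rows),
        label=seq.label,
        subject=seq.subject,
        series_id=seq.series_id or "features",
    )
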