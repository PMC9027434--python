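"""Built-in skeleton layouts and the descriptor joint/bone subsets.

Three layouts are shipped: the 20-joint Kinect v1 skeleton (``kinect20``,
used by the MSRA-style benchmarks) and two 15-joint variants (``florence15``
with wrist/ankle end effectors, ``kard15`` with hand/foot end effectors).
For each layout a default joint subset for the Distance Descriptor and a
default bone subset for the Bone Pair Descriptor are provided; the central
bone is always Spine-Head.

``BASE_POSE`` gives a plausible upright standing pose (metres, y up) for
every layout, used by the synthetic-data generator and as a non-degenerate
test frame.
"""

from __future__ import annotations

import numpy as np

from .timeseries import SkeletonLayout

__all__ = [
    "LAYOUTS",
    "DD_JOINTS",
    "BPD_BONES",
    "BASE_POSE",
    "get_layout",
    "base_pose_array",
]

KINECT20 = SkeletonLayout(
    "kinect20",
    (
        "Head", "Shoulder Center", "Spine", "Hip Center",
        "Shoulder L.", "Elbow L.", "Wrist L.", "Hand L.",
        "Shoulder R.", "Elbow R.", "Wrist R.", "Hand R.",
        "Hip L.", "Knee L.", "Ankle L.", "Foot L.",
        "Hip R.", "Knee R.", "Ankle R.", "Foot R.",
    ),
)

FLORENCE15 = SkeletonLayout(
    "florence15",
    (
        "Head", "Neck", "Spine",
        "Shoulder L.", "Elbow L.", "Wrist L.",
        "Shoulder R.", "Elbow R.", "Wrist R.",
        "Hip L.", "Knee L.", "Ankle L.",
        "Hip R.", "Knee R.", "Ankle R.",
    ),
)

KARD15 = SkeletonLayout(
    "kard15",
    (
        "Head", "Neck", "Spine",
        "Shoulder L.", "Elbow L.", "Hand L.",
        "Shoulder R.", "Elbow R.", "Hand R.",
        "Hip L.", "Knee L.", "Foot L.",
        "Hip R.", "Knee R.", "Foot R.",
    ),
)

LAYOUTS: dict[str, SkeletonLayout] = {
    l.name: l for l in (KINECT20, FLORENCE15, KARD15)
}

#: default 10-joint subsets for the Distance Descriptor
DD_JOINTS: dict[str, tuple[str, ...]] = {
    "kinect20": (
        "Hand L.", "Hand R.", "Shoulder L.", "Shoulder R.", "Head",
        "Spine", "Hip L.", "Hip R.", "Ankle L.", "Ankle R.",
    ),
    "florence15": (
        "Wrist L.", "Wrist R.", "Shoulder L.", "Shoulder R.", "Head",
        "Spine", "Hip L.", "Hip R.", "Ankle L.", "Ankle R.",
    ),
    "kard15": (
        "Hand L.", "Hand R.", "Shoulder L.", "Shoulder R.", "Head",
        "Spine", "Hip L.", "Hip R.", "Foot L.", "Foot R.",
    ),
}

#: default bone subsets for the Bone Pair Descriptor; the first entry is the
#: central bone, the rest are the non-central bones (origin joint first)
BPD_BONES: dict[str, dict] = {
    "kinect20": {
        "central": ("Spine", "Head"),
        "bones": (
            ("Elbow R.", "Wrist R."),
            ("Wrist R.", "Hand R."),
            ("Shoulder R.", "Elbow R."),
            ("Elbow L.", "Wrist L."),
            ("Wrist L.", "Hand L."),
            ("Shoulder L.", "Elbow L."),
            ("Hip R.", "Knee R."),
            ("Knee R.", "Ankle R."),
            ("Ankle R.", "Foot R."),
            ("Hip L.", "Knee L."),
            ("Knee L.", "Ankle L."),
            ("Ankle L.", "Foot L."),
        ),
    },
    "florence15": {
        "central": ("Spine", "Head"),
        "bones": (
            ("Elbow R.", "Wrist R."),
            ("Shoulder R.", "Elbow R."),
            ("Elbow L.", "Wrist L."),
            ("Shoulder L.", "Elbow L."),
            ("Hip R.", "Knee R."),
            ("Knee R.", "Ankle R."),
            ("Hip L.", "Knee L."),
            ("Knee L.", "Ankle L."),
        ),
    },
    "kard15": {
        "central": ("Spine", "Head"),
        "bones": (
            ("Elbow R.", "Hand R."),
            ("Shoulder R.", "Elbow R."),
            ("Elbow L.", "Hand L."),
            ("Shoulder L.", "Elbow L."),
            ("Hip R.", "Knee R."),
            ("Knee R.", "Foot R."),
            ("Hip L.", "Knee L."),
            ("Knee L.", "Foot L."),
        ),
    },
}

# upright standing pose, metres, y up, x to the subject's left
_COMMON_POSE = {
    "Head": (0.00, 1.70, 0.00),
    "Neck": (0.00, 1.50, 0.00),
    "Shoulder Center": (0.00, 1.50, 0.00),
    "Spine": (0.00, 1.20, 0.00),
    "Hip Center": (0.00, 1.00, 0.00),
    "Shoulder L.": (0.20, 1.45, 0.00),
    "Elbow L.": (0.28, 1.18, 0.02),
    "Wrist L.": (0.32, 0.95, 0.05),
    "Hand L.": (0.34, 0.86, 0.07),
    "Shoulder R.": (-0.20, 1.45, 0.00),
    "Elbow R.": (-0.28, 1.18, 0.02),
    "Wrist R.": (-0.32, 0.95, 0.05),
    "Hand R.": (-0.34, 0.86, 0.07),
    "Hip L.": (0.11, 0.98, 0.00),
    "Knee L.": (0.12, 0.52, 0.01),
    "Ankle L.": (0.13, 0.08, 0.00),
    "Foot L.": (0.14, 0.03, 0.12),
    "Hip R.": (-0.11, 0.98, 0.00),
    "Knee R.": (-0.12, 0.52, 0.01),
    "Ankle R.": (-0.13, 0.08, 0.00),
    "Foot R.": (-0.14, 0.03, 0.12),
}

# kard15 bones run Knee->Foot directly, so its feet sit at the ankle height
_KARD_OVERRIDES = {
    "Foot L.": (0.13, 0.06, 0.06),
    "Foot R.": (-0.13, 0.06, 0.06),
}

BASE_POSE: dict[str, dict[str, tuple[float, float, float]]] = {
    "kinect20": {j: _COMMON_POSE[j] for j in KINECT20.joints},
    "florence15": {j: _COMMON_POSE[j] for j in FLORENCE15.joints},
    "kard15": {
        j: _KARD_OVERRIDES.get(j, _COMMON_POSE[j]) for j in KARD15.joints
    },
}


def get_layout(name: str) -> SkeletonLayout:
    try:
        return LAYOUTS[name]
    except KeyError:
        raise KeyError(
            f"unknown layout {name!r}; available: {sorted(LAYOUTS)}"
        ) from None


def base_pose_array(layout_name: str) -> np.ndarray:
    """Base pose as a ``(J, 3)`` array in layout joint order."""
    layout = get_layout(layout_name)
    pose = BASE_POSE[layout_name]
    return np.asarray([pose[j] for j in layout.joints], dtype=np.float64)
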