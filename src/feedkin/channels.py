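"""Canonical joint-motion channel set and sign conventions.

The pipeline reports eleven joint-motion directions of the right upper limb,
neck and hip. Some motion-capture biomechanical models record the opposite
direction for a few channels (palmar flexion instead of dorsiflexion, radial
instead of ulnar deviation, left instead of right neck rotation); a per-channel
sign of +1/-1 maps model output onto the reported convention. The mapping is
its own inverse (an involution), which the tests rely on.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

#: Canonical channel names, in reporting order.
JOINT_CHANNELS: tuple[str, ...] = (
    "shoulder_flexion",
    "shoulder_abduction",
    "shoulder_internal_rotation",
    "elbow_flexion",
    "forearm_pronation",
    "wrist_dorsiflexion",
    "wrist_ulnar_deviation",
    "neck_flexion",
    "neck_right_lateral_flexion",
    "neck_right_rotation",
    "hip_flexion",
)

#: Sign applied to model-convention angles to obtain the reported direction.
#: The model records palmar flexion, radial deviation and left neck rotation,
#: so those three channels are negated.
MODEL_SIGN: dict[str, int] = {name: 1 for name in JOINT_CHANNELS}
MODEL_SIGN["wrist_dorsiflexion"] = -1
MODEL_SIGN["wrist_ulnar_deviation"] = -1
MODEL_SIGN["neck_right_rotation"] = -1

#: Phases of one eating cycle, in temporal order: reaching, table (picking or
#: scooping at the bowl), transporting, and mouth.
PHASES: tuple[str, ...] = ("Re", "Ta", "Tr", "Mo")

SEXES: tuple[str, ...] = ("male", "female")
CONDITIONS: tuple[str, ...] = ("chopsticks", "spoon")

EXCLUSION_REASONS: tuple[str, ...] = (
    "excessive_elevation",
    "looked_away",
    "extraneous_head_movement",
    "separated_food",
    "multiple_scoops",
    "none",
)


def angle_column(channel: str) -> str:
    """CSV column name for a joint channel."""
    return f"{channel}_deg"


def apply_sign_convention(
    angles: Mapping[str, np.ndarray],
    signs: Mapping[str, int] = MODEL_SIGN,
) -> dict[str, np.ndarray]:
    """Map model-convention angle series onto the reported convention.

    Applying the map twice restores the input (involution).
    """
    out: dict[str, np.ndarray] = {}
    for name, series in angles.items():
        sign = signs.get(name, 1)
        out[name] = np.asarray(series, dtype=float) * sign
    return out


def check_channels(names: Iterable[str]) -> None:
    """Raise if *names* is not exactly the canonical channel set."""
    from .errors import SchemaError

    missing = [c for c in JOINT_CHANNELS if c not in set(names)]
    if missing:
        raise SchemaError(f"missing joint channels: {', '.join(missing)}")
    extra = [c for c in names if c not in JOINT_CHANNELS]
    if extra:
        raise SchemaError(f"unknown joint channels: {', '.join(extra)}")
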