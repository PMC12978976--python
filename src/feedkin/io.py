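"""File formats: motion CSV, event-annotation JSON, tidy results tables.

The motion format is a flat CSV — one row per 120 Hz sample — with canonical
column names (``time_s``, eleven ``*_deg`` angle columns, and
``hand/mouth/bowl_{x,y,z}_m``) and a metadata block in ``#``-prefixed header
comments. Angles are stored in the reported sign convention; pass
``model_convention=True`` to :func:`read_motion_csv` when a file was exported
in the raw model convention (palmar flexion / radial deviation / left neck
rotation) and needs the sign map applied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import (
    EXCLUSION_REASONS,
    JOINT_CHANNELS,
    MODEL_SIGN,
    PHASES,
    angle_column,
    apply_sign_convention,
)
from .errors import SchemaError, ValidationError
from .recording import MotionRecording

log = logging.getLogger(__name__)

_POS_COLUMNS = [
    f"{landmark}_{axis}_m" for landmark in ("hand", "mouth", "bowl") for axis in "xyz"
]
MOTION_COLUMNS = ["time_s", *[angle_column(c) for c in JOINT_CHANNELS], *_POS_COLUMNS]

_META_KEYS = ("participant_id", "sex", "condition", "sample_rate")


def read_motion_csv(path: str | Path, model_convention: bool = False) -> MotionRecording:
    """Read and validate a motion CSV.

    The sample rate is inferred from the time column and checked against the
    declared ``# sample_rate=`` header when present.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    df = pd.read_csv(path, skiprows=skip)

    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s): {', '.join(missing)}")
    if len(df) < 2:
        raise ValidationError(f"{path.name}: fewer than 2 data rows")

    time = df["time_s"].to_numpy(dtype=float)
    inferred_rate = 1.0 / float(np.median(np.diff(time)))
    declared = float(meta.get("sample_rate", inferred_rate))
    if abs(inferred_rate - declared) > 0.5:
        raise ValidationError(
            f"{path.name}: inferred sample rate {inferred_rate:.2f} Hz "
            f"disagrees with declared {declared:.2f} Hz"
        )

    angles = {c: df[angle_column(c)].to_numpy(dtype=float) for c in JOINT_CHANNELS}
    if model_convention:
        angles = apply_sign_convention(angles, MODEL_SIGN)

    def pos(landmark: str) -> np.ndarray:
        return df[[f"{landmark}_{a}_m" for a in "xyz"]].to_numpy(dtype=float)

    rec = MotionRecording(
        participant_id=meta.get("participant_id", path.stem),
        sex=meta.get("sex", "male"),
        condition=meta.get("condition", "chopsticks"),
        sample_rate=declared,
        time=time,
        angles=angles,
        hand_pos=pos("hand"),
        mouth_pos=pos("mouth"),
        bowl_pos=pos("bowl"),
    )
    return rec.validate()


def write_motion_csv(rec: MotionRecording, path: str | Path) -> Path:
    """Write a recording as a motion CSV with a metadata header block."""
    if rec.n_samples < 2:
        raise ValidationError("refusing to write a recording with fewer than 2 samples")
    path = Path(path)
    data = {"time_s": rec.time}
    for c in JOINT_CHANNELS:
        data[angle_column(c)] = rec.angles[c]
    for landmark in ("hand", "mouth", "bowl"):
        pos = getattr(rec, f"{landmark}_pos")
        for k, axis in enumerate("xyz"):
            data[f"{landmark}_{axis}_m"] = pos[:, k]
    df = pd.DataFrame(data, columns=MOTION_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# participant_id={rec.participant_id}\n")
        fh.write(f"# sex={rec.sex}\n")
        fh.write(f"# condition={rec.condition}\n")
        fh.write(f"# sample_rate={rec.sample_rate:g}\n")
        df.to_csv(fh, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# Event annotations
# ---------------------------------------------------------------------------

@dataclass
class CycleAnnotation:
    """One candidate eating cycle: bounds, success flag, optional boundaries.

    Indices are 0-based; windows are half-open ``[start, end)``. Manual phase
    boundaries, when present, map each phase name to its window and override
    automatic event detection.
    """

    start_index: int
    end_index: int
    success: bool = True
    exclusion_reason: str = "none"
    phase_boundaries: dict[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValidationError(f"unknown exclusion_reason {self.exclusion_reason!r}")
        if self.end_index <= self.start_index:
            raise ValidationError("cycle end_index must exceed start_index")
        if self.phase_boundaries is not None:
            bad = [p for p in self.phase_boundaries if p not in PHASES]
            if bad:
                raise ValidationError(f"unknown phase name(s): {bad}")


@dataclass
class EventAnnotations:
    """Per-trial list of candidate cycles with success/exclusion flags."""

    cycles: list[CycleAnnotation] = field(default_factory=list)

    def validate(self, n_samples: int | None = None) -> "EventAnnotations":
        prev_end = -1
        for cyc in sorted(self.cycles, key=lambda c: c.start_index):
            if cyc.start_index < prev_end:
                raise ValidationError(
                    f"cycles overlap at index {cyc.start_index} (< previous end {prev_end})"
                )
            prev_end = cyc.end_index
            if n_samples is not None and cyc.end_index > n_samples:
                raise ValidationError(
                    f"cycle end {cyc.end_index} beyond recording length {n_samples}"
                )
        self.cycles.sort(key=lambda c: c.start_index)
        return self


def read_events(path: str | Path) -> EventAnnotations:
    """Read event annotations from JSON."""
    with open(path) as fh:
        payload = json.load(fh)
    cycles = []
    for item in payload.get("cycles", []):
        pb = item.get("phase_boundaries")
        if pb is not None:
            pb = {phase: (int(lo), int(hi)) for phase, (lo, hi) in pb.items()}
        cycles.append(
            CycleAnnotation(
                start_index=int(item["start_index"]),
                end_index=int(item["end_index"]),
                success=bool(item.get("success", True)),
                exclusion_reason=item.get("exclusion_reason", "none"),
                phase_boundaries=pb,
            )
        )
    return EventAnnotations(cycles=cycles).validate()


def write_events(ev: EventAnnotations, path: str | Path) -> Path:
    """Write event annotations as JSON (round-trips with :func:`read_events`)."""
    ev.validate()
    payload = {
        "cycles": [
            {
                "start_index": c.start_index,
                "end_index": c.end_index,
                "success": c.success,
                "exclusion_reason": c.exclusion_reason,
                **(
                    {"phase_boundaries": {p: list(w) for p, w in c.phase_boundaries.items()}}
                    if c.phase_boundaries is not None
                    else {}
                ),
            }
            for c in ev.cycles
        ]
    }
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path
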