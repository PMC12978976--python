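"""Eating-cycle detection and four-phase segmentation.

One eating cycle runs from just after the utensil leaves the mouth to just
before it next leaves the mouth, and splits into four contiguous phases:

* ``Re`` (reaching) — hand travels from the mouth toward the food;
* ``Ta`` (table) — picking up or scooping at the bowl;
* ``Tr`` (transporting) — carrying the food to the mouth;
* ``Mo`` (mouth) — utensil in the mouth.

Boundaries are detected from hand-landmark proximity: the hand-mouth distance
crossing ``d_mouth`` outward marks a mouth exit (cycle boundary) and inward a
mouth entry (Tr/Mo); the hand-bowl distance crossing ``d_bowl`` inward marks
bowl entry (Re/Ta) and ``d_bowl + hysteresis`` outward marks bowl exit
(Ta/Tr). Each crossing must be sustained for ``min_dwell`` seconds, and
distances are computed on zero-phase low-pass-filtered positions. Manual
phase boundaries from annotations override detection. Windows are half-open
``[start, end)`` with 0-based indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .channels import PHASES
from .errors import ParticipantExclusionError, SegmentationError, ValidationError
from .filtering import lowpass
from .io import CycleAnnotation, EventAnnotations
from .recording import MotionRecording

log = logging.getLogger(__name__)

#: Speed below this fraction of the within-reach peak, sustained, flags a pause.
PAUSE_SPEED_FRACTION = 0.05
PAUSE_MIN_DURATION_S = 0.3


@dataclass(frozen=True)
class EventThresholds:
    """Proximity radii and debounce settings for event detection.

    The original study confirmed events on synchronized video; these distance
    thresholds are the automated stand-in and are exposed in the config.
    """

    d_mouth: float = 0.10        # hand-mouth proximity radius, m
    d_bowl: float = 0.08         # hand-bowl proximity radius, m
    hysteresis: float = 0.02     # extra radius a bowl exit must clear, m
    min_dwell: float = 0.05      # crossing must persist this long, s
    smoothing_cutoff: float = 6.0  # position low-pass cutoff, Hz

    def __post_init__(self) -> None:
        for name in ("d_mouth", "d_bowl", "hysteresis", "min_dwell", "smoothing_cutoff"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"EventThresholds.{name} must be positive")
        if self.hysteresis >= min(self.d_mouth, self.d_bowl):
            raise ValidationError("hysteresis must be smaller than both radii")


@dataclass
class CycleSegmentation:
    """One segmented eating cycle: bounds, ordered phase windows, flags."""

    cycle_bounds: tuple[int, int]
    phases: dict[str, tuple[int, int]]
    sample_rate: float
    success: bool = True
    exclusion_reason: str = "none"
    pause_detected_in_reach: bool = False

    def validate(self) -> "CycleSegmentation":
        lo, hi = self.cycle_bounds
        cursor = lo
        for phase in PHASES:
            if phase not in self.phases:
                raise ValidationError(f"missing phase {phase}")
            a, b = self.phases[phase]
            if a != cursor:
                raise ValidationError(f"phase {phase} starts at {a}, expected {cursor}")
            if b - a < 2:
                raise ValidationError(f"phase {phase} has {b - a} samples; need >= 2")
            cursor = b
        if cursor != hi:
            raise ValidationError(f"phases end at {cursor}, cycle ends at {hi}")
        return self


def _distances(rec: MotionRecording, cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """Filtered hand-mouth and hand-bowl distance series."""
    hand = lowpass(rec.hand_pos, cutoff, rec.sample_rate)
    d_mouth = np.linalg.norm(hand - rec.mouth_pos, axis=1)
    d_bowl = np.linalg.norm(hand - rec.bowl_pos, axis=1)
    return d_mouth, d_bowl


def _sustained_crossings(below: np.ndarray, dwell: int, start: int = 0,
                         direction: str = "up") -> list[int]:
    """Indices where *below* flips (down->up for "up") and stays flipped.

    ``below`` is a boolean series (inside the radius). A crossing at ``i``
    requires the new state to persist for ``dwell`` samples.
    """
    flips = []
    n = len(below)
    want = ~below if direction == "up" else below
    for i in range(max(start, 1), n):
        if want[i] and not want[i - 1]:
            hi = min(n, i + dwell)
            if want[i:hi].all():
                flips.append(i)
    return flips


def _first_sustained(below: np.ndarray, dwell: int, start: int, stop: int,
                     direction: str) -> int | None:
    want = ~below if direction == "up" else below
    n = len(below)
    i = max(start, 1)
    while i < stop:
        if want[i] and not want[i - 1]:
            hi = min(n, i + dwell)
            if want[i:hi].all():
                return i
        i += 1
    return None


def detect_cycles(rec: MotionRecording, thr: EventThresholds = EventThresholds()
                  ) -> list[tuple[int, int]]:
    """Detect complete eating cycles as windows between mouth-exit events.

    Returns half-open windows ``[exit_k, exit_{k+1})``; the trailing partial
    cycle after the last exit is discarded. An empty list (with a logged
    warning) means no mouth-exit event was found.
    """
    if rec.duration_s < 1.0:
        raise ValidationError(f"recording of {rec.duration_s:.2f} s is shorter than 1 s")
    d_mouth, _ = _distances(rec, thr.smoothing_cutoff)
    dwell = max(1, int(round(thr.min_dwell * rec.sample_rate)))
    inside = d_mouth < thr.d_mouth
    exits = _sustained_crossings(inside, dwell, direction="up")
    if not exits:
        log.warning("no mouth-exit events found; returning 0 cycles")
        return []
    return [(exits[k], exits[k + 1]) for k in range(len(exits) - 1)]


def _detect_pause_in_reach(rec: MotionRecording, window: tuple[int, int],
                           cutoff: float) -> bool:
    lo, hi = window
    if hi - lo < 3:
        return False
    hand = lowpass(rec.hand_pos, cutoff, rec.sample_rate)[lo:hi]
    vel = np.gradient(hand, 1.0 / rec.sample_rate, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    peak = speed.max()
    if peak <= 0:
        return False
    slow = speed < PAUSE_SPEED_FRACTION * peak
    need = int(round(PAUSE_MIN_DURATION_S * rec.sample_rate))
    run = 0
    for flag in slow:
        run = run + 1 if flag else 0
        if run >= need:
            return True
    return False


def segment_phases(rec: MotionRecording, cycle: tuple[int, int],
                   thr: EventThresholds = EventThresholds(),
                   annotation: CycleAnnotation | None = None) -> CycleSegmentation:
    """Split one cycle window into the four feeding phases.

    Manual phase boundaries in *annotation* are returned verbatim. Otherwise
    the Re/Ta boundary is the first sustained bowl entry, Ta/Tr the first
    sustained bowl exit after it, and Tr/Mo the first sustained mouth entry.
    """
    start, end = cycle
    if annotation is not None and annotation.phase_boundaries is not None:
        seg = CycleSegmentation(
            cycle_bounds=cycle,
            phases={p: tuple(annotation.phase_boundaries[p]) for p in PHASES},
            sample_rate=rec.sample_rate,
            success=annotation.success,
            exclusion_reason=annotation.exclusion_reason,
        )
        seg.pause_detected_in_reach = _detect_pause_in_reach(
            rec, seg.phases["Re"], thr.smoothing_cutoff)
        return seg.validate()

    d_mouth, d_bowl = _distances(rec, thr.smoothing_cutoff)
    dwell = max(1, int(round(thr.min_dwell * rec.sample_rate)))

    in_bowl = d_bowl < thr.d_bowl
    bowl_entry = _first_sustained(in_bowl, dwell, start + 1, end, "down")
    if bowl_entry is None:
        raise SegmentationError("bowl-entry")
    out_bowl_h = d_bowl < thr.d_bowl + thr.hysteresis
    bowl_exit = _first_sustained(out_bowl_h, dwell, bowl_entry + 1, end, "up")
    if bowl_exit is None:
        raise SegmentationError("bowl-exit")
    in_mouth = d_mouth < thr.d_mouth
    mouth_entry = _first_sustained(in_mouth, dwell, bowl_exit + 1, end, "down")
    if mouth_entry is None:
        raise SegmentationError("mouth-entry")

    seg = CycleSegmentation(
        cycle_bounds=cycle,
        phases={
            "Re": (start, bowl_entry),
            "Ta": (bowl_entry, bowl_exit),
            "Tr": (bowl_exit, mouth_entry),
            "Mo": (mouth_entry, end),
        },
        sample_rate=rec.sample_rate,
    )
    if annotation is not None:
        seg.success = annotation.success
        seg.exclusion_reason = annotation.exclusion_reason
    seg.pause_detected_in_reach = _detect_pause_in_reach(
        rec, seg.phases["Re"], thr.smoothing_cutoff)
    return seg.validate()


def apply_annotations(segs: list[CycleSegmentation],
                      annotations: EventAnnotations) -> list[CycleSegmentation]:
    """Copy success/exclusion flags onto segmentations by cycle order."""
    out = []
    for k, seg in enumerate(segs):
        if k < len(annotations.cycles):
            ann = annotations.cycles[k]
            out.append(replace(seg, success=ann.success,
                               exclusion_reason=ann.exclusion_reason))
        else:
            out.append(seg)
    return out


def select_success_cycle(segs: list[CycleSegmentation],
                         require_two: bool = False) -> CycleSegmentation:
    """Pick the analysis cycle: the first successful one.

    With ``require_two=True`` (the study's protocol of three sequential eats
    yielding two candidate cycles) exactly two candidates are expected.
    Raises :class:`ParticipantExclusionError` when every cycle failed —
    mirroring participant exclusion in the source protocol.
    """
    if require_two and len(segs) != 2:
        raise ValidationError(f"expected exactly 2 candidate cycles, got {len(segs)}")
    for seg in segs:
        if seg.success:
            return seg
    raise ParticipantExclusionError(
        "no successful eating cycle; participant excluded for this condition"
    )
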