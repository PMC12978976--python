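"""In-memory container for one motion trial.

A :class:`MotionRecording` holds uniformly sampled joint-angle channels
(degrees) and 3-D landmark positions (meters) for the hand origin — the
midpoint between the wrist styloid processes — plus mouth and bowl reference
points, together with participant metadata. All downstream stages
(segmentation, metrics) consume this container.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .channels import CONDITIONS, JOINT_CHANNELS, SEXES, check_channels
from .errors import SamplingError, ValidationError

log = logging.getLogger(__name__)

#: Maximum tolerated deviation of the time step from 1/sample_rate, seconds.
TIME_TOLERANCE_S = 1e-6
#: NaN gaps at most this long (seconds) are linearly interpolated; longer
#: gaps reject the recording. Inertial exports occasionally drop frames.
MAX_NAN_GAP_S = 0.1


def _interpolate_short_gaps(series: np.ndarray, max_gap: int, label: str) -> np.ndarray:
    """Linearly fill NaN runs of length <= max_gap; raise on longer runs."""
    x = np.asarray(series, dtype=float).copy()
    isnan = ~np.isfinite(x)
    if not isnan.any():
        return x
    # locate runs of non-finite samples
    idx = np.flatnonzero(isnan)
    runs: list[tuple[int, int]] = []
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            runs.append((start, prev))
            start = i
        prev = i
    runs.append((start, prev))
    for lo, hi in runs:
        length = hi - lo + 1
        if length > max_gap or lo == 0 or hi == len(x) - 1:
            raise ValidationError(
                f"{label}: non-finite run of {length} samples at index {lo} "
                f"exceeds the {max_gap}-sample interpolation limit"
            )
    good = np.flatnonzero(~isnan)
    x[isnan] = np.interp(np.flatnonzero(isnan), good, x[good])
    log.warning("%s: interpolated %d non-finite samples in short gaps", label, int(isnan.sum()))
    return x


@dataclass
class MotionRecording:
    """One trial: angles, landmark positions and metadata at a fixed rate."""

    participant_id: str
    sex: str
    condition: str
    sample_rate: float
    time: np.ndarray
    angles: dict[str, np.ndarray]
    hand_pos: np.ndarray   # (n, 3) meters
    mouth_pos: np.ndarray  # (n, 3) meters, may be constant
    bowl_pos: np.ndarray   # (n, 3) meters, may be constant
    validated: bool = field(default=False, repr=False)

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def duration_s(self) -> float:
        return float(self.time[-1] - self.time[0])

    def validate(self) -> "MotionRecording":
        """Check invariants; interpolate short NaN gaps in place.

        Raises :class:`SamplingError` for a non-uniform time base and
        :class:`ValidationError` for structural problems.
        """
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        self.time = np.asarray(self.time, dtype=float)
        n = len(self.time)
        if n < 2:
            raise ValidationError(f"recording has {n} samples; need at least 2")
        check_channels(self.angles.keys())

        dt = np.diff(self.time)
        expected = 1.0 / self.sample_rate
        dev = np.abs(dt - expected)
        if dev.max() > TIME_TOLERANCE_S:
            raise SamplingError(
                f"non-uniform time base: max deviation {dev.max():.3g} s from "
                f"the expected step of {expected:.6g} s"
            )

        max_gap = max(1, int(round(MAX_NAN_GAP_S * self.sample_rate)))
        for name in JOINT_CHANNELS:
            series = np.asarray(self.angles[name], dtype=float)
            if len(series) != n:
                raise ValidationError(f"channel {name}: length {len(series)} != {n}")
            self.angles[name] = _interpolate_short_gaps(series, max_gap, name)
        for label in ("hand_pos", "mouth_pos", "bowl_pos"):
            pos = np.asarray(getattr(self, label), dtype=float)
            if pos.shape != (n, 3):
                raise ValidationError(f"{label}: shape {pos.shape} != ({n}, 3)")
            cols = [
                _interpolate_short_gaps(pos[:, k], max_gap, f"{label}[{k}]")
                for k in range(3)
            ]
            setattr(self, label, np.column_stack(cols))
        self.validated = True
        return self
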