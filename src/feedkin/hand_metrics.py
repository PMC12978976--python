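"""Transporting-phase hand spatiotemporal parameters.

From the hand-origin trajectory inside a window (by default the transporting
phase) this module computes:

* actual distance traveled — path integral of the filtered hand position;
* relative distance traveled — actual / straight-line distance (>= 1; 1.0 is
  a maximally efficient straight transport);
* mean and maximum velocity (scalar tangential speed), and the timing of
  maximum velocity as a percentage of the window;
* the number of movement units — a smoothness count: one unit per local
  minimum -> next retained speed maximum whose excursion exceeds an amplitude
  limit (default 20 mm/s), with retained maxima at least a minimum interval
  apart (default 150 ms; the larger of two close peaks wins).

"Velocity" here means speed; mean velocity is path length over duration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegeneratePathError, ValidationError
from .filtering import lowpass
from .recording import MotionRecording
from .segmentation import CycleSegmentation

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MovementUnitParams:
    """Thresholds of the movement-unit smoothness count."""

    amplitude_limit: float = 0.020     # m/s: min speed excursion of a unit
    min_peak_interval: float = 0.150   # s: min spacing between retained maxima

    def __post_init__(self) -> None:
        if self.amplitude_limit <= 0 or self.min_peak_interval <= 0:
            raise ValidationError("movement-unit thresholds must be positive")


@dataclass
class SpeedProfile:
    """Tangential hand speed over one window, with its path length."""

    time: np.ndarray
    speed: np.ndarray
    path_length_m: float

    @property
    def duration_s(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass(frozen=True)
class TransportMetrics:
    actual_distance_m: float
    relative_distance: float
    mean_velocity_mps: float
    max_velocity_mps: float
    timing_max_velocity_pct: float
    n_movement_units: int


def _filtered_hand(rec: MotionRecording, cutoff: float) -> np.ndarray:
    return lowpass(rec.hand_pos, cutoff, rec.sample_rate)


def compute_speed(rec: MotionRecording, window: tuple[int, int],
                  cutoff: float = 6.0) -> SpeedProfile:
    """Speed profile of the hand origin inside ``[start, end)``.

    The full-trial position is low-pass filtered, the window sliced out, and
    speed taken as the Euclidean norm of the central-difference derivative
    (one-sided at the window edges).
    """
    lo, hi = window
    if hi - lo < 3:
        raise ValidationError(f"window [{lo}, {hi}) has fewer than 3 samples")
    hand = _filtered_hand(rec, cutoff)[lo:hi]
    vel = np.gradient(hand, 1.0 / rec.sample_rate, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    path = float(np.linalg.norm(np.diff(hand, axis=0), axis=1).sum())
    return SpeedProfile(time=rec.time[lo:hi].copy(), speed=speed, path_length_m=path)


def path_metrics(rec: MotionRecording, window: tuple[int, int],
                 cutoff: float = 6.0) -> tuple[float, float]:
    """(actual_distance_m, relative_distance) for the hand inside a window."""
    lo, hi = window
    if hi - lo < 2:
        raise ValidationError(f"window [{lo}, {hi}) has fewer than 2 samples")
    hand = _filtered_hand(rec, cutoff)[lo:hi]
    actual = float(np.linalg.norm(np.diff(hand, axis=0), axis=1).sum())
    straight = float(np.linalg.norm(hand[-1] - hand[0]))
    if straight < 1e-3:
        raise DegeneratePathError(
            f"window start and end coincide within 1 mm ({straight * 1e3:.3f} mm)"
        )
    return actual, actual / straight


def velocity_metrics(sp: SpeedProfile) -> tuple[float, float, float]:
    """(mean_velocity_mps, max_velocity_mps, timing_max_velocity_pct).

    Mean velocity is path length over duration. Timing is the time of the
    (first-occurring) speed maximum as a percentage of the window.
    """
    if len(sp.speed) == 0:
        raise ValidationError("empty speed profile")
    mean_v = sp.path_length_m / sp.duration_s if sp.duration_s > 0 else 0.0
    k = int(np.argmax(sp.speed))  # first occurrence on ties
    max_v = float(sp.speed[k])
    timing = 100.0 * (sp.time[k] - sp.time[0]) / (sp.time[-1] - sp.time[0])
    return mean_v, max_v, float(timing)


# ---------------------------------------------------------------------------
# Movement units
# ---------------------------------------------------------------------------

def _local_extrema(speed: np.ndarray) -> tuple[list[int], list[int]]:
    """Indices of local maxima and minima; plateaus collapse to midpoints."""
    # compress runs of equal consecutive values
    keep = np.empty(len(speed), dtype=bool)
    keep[0] = True
    keep[1:] = np.diff(speed) != 0
    reduced_idx = np.flatnonzero(keep)
    reduced = speed[reduced_idx]
    # plateau representative = midpoint of the run
    run_ends = np.append(reduced_idx[1:], len(speed))
    rep = (reduced_idx + run_ends - 1) // 2

    maxima, minima = [], []
    for j in range(1, len(reduced) - 1):
        if reduced[j] > reduced[j - 1] and reduced[j] > reduced[j + 1]:
            maxima.append(int(rep[j]))
        elif reduced[j] < reduced[j - 1] and reduced[j] < reduced[j + 1]:
            minima.append(int(rep[j]))
    return maxima, minima


def count_movement_units(sp: SpeedProfile, p: MovementUnitParams = MovementUnitParams()
                         ) -> int:
    """Count movement units in a speed profile.

    1. Find local maxima/minima (plateaus collapse to their midpoint).
    2. Walk maxima in time order; a maximum closer than ``min_peak_interval``
       to the previously retained one is merged with it, the larger winning.
    3. For each retained maximum, take the lowest speed since the previous
       retained maximum (or the window start) as its trough; count one unit
       when maximum - trough exceeds ``amplitude_limit``. The initial rise
       from the window-start speed therefore counts as the first unit when it
       is large enough.
    """
    speed = np.asarray(sp.speed, dtype=float)
    if len(speed) < 3:
        raise ValidationError("speed profile needs at least 3 samples")
    if np.allclose(speed, 0.0):
        log.warning("all-zero speed profile; 0 movement units")
        return 0
    dt = float(np.median(np.diff(sp.time)))
    maxima, _ = _local_extrema(speed)
    if not maxima:
        return 0

    # peaks exactly at the interval are kept: the 1 ns guard keeps the
    # comparison stable when gap * dt lands on the threshold
    retained: list[int] = []
    for m in maxima:
        if retained and (m - retained[-1]) * dt < p.min_peak_interval - 1e-9:
            if speed[m] > speed[retained[-1]]:
                retained[-1] = m
        else:
            retained.append(m)

    count = 0
    prev = 0
    for m in retained:
        trough = speed[prev:m + 1].min()
        if speed[m] - trough > p.amplitude_limit:
            count += 1
        prev = m
    return count


def transport_metrics(rec: MotionRecording, seg: CycleSegmentation,
                      params: MovementUnitParams = MovementUnitParams(),
                      cutoff: float = 6.0,
                      window: tuple[int, int] | None = None) -> TransportMetrics:
    """All hand spatiotemporal parameters for one window (default: Tr phase)."""
    if window is None:
        window = seg.phases["Tr"]
    sp = compute_speed(rec, window, cutoff)
    actual, relative = path_metrics(rec, window, cutoff)
    mean_v, max_v, timing = velocity_metrics(sp)
    n_units = count_movement_units(sp, params)
    return TransportMetrics(
        actual_distance_m=actual,
        relative_distance=relative,
        mean_velocity_mps=mean_v,
        max_velocity_mps=max_v,
        timing_max_velocity_pct=timing,
        n_movement_units=n_units,
    )
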