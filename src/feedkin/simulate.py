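"""Synthetic feeding-trial generator with known ground truth.

Emulates the study protocol — a seated participant eats three times in
sequence, producing two complete eating cycles — as a phase-structured hand
trajectory built from minimum-jerk primitives plus keyframed joint-angle
channels:

* mouth dwell -> reach (mouth to bowl, optional mid-reach pause) -> table
  dwell -> curved transport back to the mouth (commanded detour ratio and
  submovement count) -> mouth dwell, three times;
* phase boundaries are the same proximity-threshold crossings the
  segmentation stage detects, so ground truth and detection share one
  definition; commanded phase durations are honored by solving segment times
  against the analytically known crossing fractions of the minimum-jerk law;
* submovements are speed dips superimposed on the transport arc-length time
  law; the commanded count is clamped to what the drawn transport duration
  can hold at a countable peak spacing, and the effective count is recorded.

Defaults reproduce the study's scale: phase-duration and joint-angle medians
per sex and condition, reach-pause prevalence (84% chopsticks / 65% spoon),
transport detour ratios and movement-unit counts (see ``_table_defaults``).
Angle channels are generated independently of the hand path (no forward
kinematics), phase-locked through shared keyframe times.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from . import _table_defaults as tables
from .channels import JOINT_CHANNELS, PHASES
from .errors import ValidationError
from .recording import MotionRecording
from .segmentation import EventThresholds

log = logging.getLogger(__name__)

#: Generator-internal minimum spacing between transport speed peaks so every
#: commanded submovement is countable under the default 150 ms interval rule.
MIN_PEAK_SPACING_S = 0.20


# ---------------------------------------------------------------------------
# Minimum-jerk primitives
# ---------------------------------------------------------------------------

def minjerk_s(tau):
    """Normalized minimum-jerk position 10t^3 - 15t^4 + 6t^5."""
    tau = np.asarray(tau, dtype=float)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def minjerk_sdot(tau):
    """Normalized minimum-jerk velocity; peak 1.875 at tau = 0.5."""
    tau = np.asarray(tau, dtype=float)
    return 30 * tau**2 - 60 * tau**3 + 30 * tau**4


def inv_minjerk_s(s: float) -> float:
    """tau such that minjerk_s(tau) == s, for s in [0, 1]."""
    if s <= 0:
        return 0.0
    if s >= 1:
        return 1.0
    return float(brentq(lambda t: float(minjerk_s(t)) - s, 0.0, 1.0, xtol=1e-12))


def min_jerk_segment(start, end, T: float, rate: float) -> np.ndarray:
    """Sampled straight minimum-jerk move from *start* to *end*.

    Returns an ``(n, 3)`` position series covering [0, T] inclusive at the
    given rate; velocity and acceleration vanish at both endpoints.
    """
    if T <= 0:
        raise ValidationError("min_jerk_segment: duration must be positive")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    n = int(round(T * rate)) + 1
    tau = np.linspace(0.0, 1.0, n)
    return start[None, :] + (end - start)[None, :] * minjerk_s(tau)[:, None]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study-condition parameters of the trial generator.

    Durations and angle levels default to the reported group medians per sex
    and condition; geometry places the bowl at forward-reach distance from a
    seated posture. Noise terms are artifact choices (the source data's
    within-participant variability is not reported).
    """

    seed: int = 0
    sample_rate: float = 120.0
    mouth: tuple[float, float, float] = (0.0, 0.0, 0.30)
    bowl: tuple[float, float, float] = (0.26, 0.0, 0.0)
    thresholds: EventThresholds = field(default_factory=EventThresholds)

    phase_durations: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 tables.PHASE_DURATION_MEDIANS_S.items()})
    duration_sigma: float = 0.12          # lognormal sigma of per-cycle draws
    pause_probability: dict = field(
        default_factory=lambda: dict(tables.PAUSE_PROBABILITY))
    pause_min_s: float = 0.3
    reach_motion_time_s: float = 1.2      # ballistic reach time when pausing
    detour_ratio: dict = field(default_factory=lambda: dict(tables.DETOUR_RATIO))
    n_submovements: dict = field(
        default_factory=lambda: dict(tables.MOVEMENT_UNIT_MEDIANS))
    submovement_amplitude_mps: float = 0.06
    angle_medians: dict = field(default_factory=lambda: tables.ANGLE_MEDIANS_DEG)
    angle_trial_sd_deg: float = 2.0       # per-trial keyframe jitter
    angle_noise_sd_deg: float = 0.5       # additive sample noise
    pos_noise_sd_m: float = 0.002         # additive hand-position noise
    initial_dwell_s: float = 0.5
    n_eats: int = 3

    # anchor radii as fractions of the proximity thresholds
    mouth_anchor_frac: float = 0.9        # hand rest point: 0.9 * d_mouth
    bowl_anchor_frac: float = 0.5         # picking point: 0.5 * d_bowl

    def noise_free(self) -> "SimConfig":
        return replace(self, angle_noise_sd_deg=0.0, pos_noise_sd_m=0.0,
                       angle_trial_sd_deg=0.0)


@dataclass
class CycleTruth:
    """Ground truth for one complete eating cycle."""

    cycle_bounds: tuple[int, int]
    phases: dict[str, tuple[int, int]]
    pause_in_reach: bool
    commanded_durations_s: dict[str, float]
    transport: dict[str, float]
    angle_extrema: dict[str, dict[str, tuple[float, float]]]


@dataclass
class GroundTruth:
    """Everything the generator knows about an emitted trial."""

    condition: str
    sex: str
    cycles: list[CycleTruth]
    detour_ratio: float
    n_submovements_commanded: int
    n_submovements_effective: int


# ---------------------------------------------------------------------------
# Transport path and time law
# ---------------------------------------------------------------------------

class _TransportPath:
    """Curved bowl-to-mouth path: straight chord plus a perpendicular
    sine bump of height *h*, arc-length parameterized on a dense grid."""

    N_GRID = 1500

    def __init__(self, a: np.ndarray, b: np.ndarray, h: float, normal: np.ndarray):
        self.a, self.b, self.h = a, b, h
        u = np.linspace(0.0, 1.0, self.N_GRID + 1)
        pts = a[None, :] + (b - a)[None, :] * u[:, None] \
            + normal[None, :] * (h * np.sin(np.pi * u))[:, None]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self.u = u
        self.pts = pts
        self.arc = np.concatenate([[0.0], np.cumsum(seg)])
        self.length = float(self.arc[-1])

    def pos_at_arc(self, s) -> np.ndarray:
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        out = np.empty((len(s), 3))
        for k in range(3):
            out[:, k] = np.interp(s, self.arc, self.pts[:, k])
        return out

    def first_arc_above(self, point: np.ndarray, radius: float) -> float:
        """Arc length where distance to *point* first exceeds *radius*."""
        d = np.linalg.norm(self.pts - point[None, :], axis=1)
        idx = np.flatnonzero(d >= radius)
        idx = idx[idx > 0]
        if len(idx) == 0:
            raise ValidationError("path never leaves the radius")
        i = int(idx[0])
        f = (radius - d[i - 1]) / (d[i] - d[i - 1])
        return float(self.arc[i - 1] + f * (self.arc[i] - self.arc[i - 1]))

    def first_arc_below(self, point: np.ndarray, radius: float) -> float:
        """Arc length where distance to *point* first drops below *radius*."""
        d = np.linalg.norm(self.pts - point[None, :], axis=1)
        idx = np.flatnonzero(d <= radius)
        idx = idx[idx > 0]
        if len(idx) == 0:
            raise ValidationError("path never enters the radius")
        i = int(idx[0])
        f = (d[i - 1] - radius) / (d[i - 1] - d[i])
        return float(self.arc[i - 1] + f * (self.arc[i] - self.arc[i - 1]))


def _perpendicular(e: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 1.0, 0.0])
    n = np.cross(e, ref)
    if np.linalg.norm(n) < 1e-9:
        n = np.cross(e, np.array([1.0, 0.0, 0.0]))
    return n / np.linalg.norm(n)


def _calibrate_bump(a, b, normal, mouth, bowl, r_bowl_exit, r_mouth,
                    ratio: float) -> _TransportPath:
    """Find the bump height whose *measured-window* detour ratio (path length
    over straight distance between the bowl-exit and mouth-entry crossings)
    equals the commanded ratio."""

    def window_ratio(h: float) -> float:
        path = _TransportPath(a, b, h, normal)
        s1 = path.first_arc_above(bowl, r_bowl_exit)
        s2 = path.first_arc_below(mouth, r_mouth)
        q1 = path.pos_at_arc([s1])[0]
        q2 = path.pos_at_arc([s2])[0]
        return (s2 - s1) / float(np.linalg.norm(q2 - q1))

    if ratio <= 1.0 + 1e-9:
        return _TransportPath(a, b, 0.0, normal)
    chord = float(np.linalg.norm(b - a))
    hi = 0.8 * chord
    if window_ratio(hi) < ratio:
        raise ValidationError(f"detour ratio {ratio} not reachable")
    h = brentq(lambda x: window_ratio(x) - ratio, 0.0, hi, xtol=1e-6)
    return _TransportPath(a, b, float(h), normal)


@dataclass
class _TransportLaw:
    """Arc-length time law of one transport: normalized cumulative arc S(gamma)
    on a dense grid, crossing times gamma1/gamma2, total duration, truth."""

    path: _TransportPath
    gamma: np.ndarray
    S: np.ndarray          # normalized cumulative arc fraction
    g: np.ndarray          # normalized speed dS/dgamma
    gamma1: float
    gamma2: float
    T_full: float
    n_units: int

    def sample(self, t: np.ndarray) -> np.ndarray:
        gam = np.clip(t / self.T_full, 0.0, 1.0)
        s = np.interp(gam, self.gamma, self.S) * self.path.length
        return self.path.pos_at_arc(s)

    def truth_metrics(self) -> dict[str, float]:
        L = self.path.length
        lo = np.searchsorted(self.gamma, self.gamma1)
        hi = np.searchsorted(self.gamma, self.gamma2)
        v = L * self.g / self.T_full
        win = slice(lo, hi + 1)
        k = lo + int(np.argmax(v[win]))
        s1 = float(np.interp(self.gamma1, self.gamma, self.S)) * L
        s2 = float(np.interp(self.gamma2, self.gamma, self.S)) * L
        q1 = self.path.pos_at_arc([s1])[0]
        q2 = self.path.pos_at_arc([s2])[0]
        straight = float(np.linalg.norm(q2 - q1))
        dur = (self.gamma2 - self.gamma1) * self.T_full
        return {
            "actual_distance_m": s2 - s1,
            "relative_distance": (s2 - s1) / straight,
            "mean_velocity_mps": (s2 - s1) / dur,
            "max_velocity_mps": float(v[k]),
            "timing_max_velocity_pct":
                100.0 * (self.gamma[k] - self.gamma1) / (self.gamma2 - self.gamma1),
            "n_movement_units": float(self.n_units),
        }


def _build_transport_law(path: _TransportPath, s_bx: float, s_mx: float,
                         duration_tr: float, k_cmd: int,
                         amplitude: float) -> _TransportLaw:
    """Compose the base minimum-jerk arc law with submovement speed dips and
    scale total time so the bowl-exit -> mouth-entry interval equals the
    commanded transporting-phase duration."""
    L = path.length
    f1, f2 = s_bx / L, s_mx / L
    g1_0 = inv_minjerk_s(f1)
    g2_0 = inv_minjerk_s(f2)
    T0 = duration_tr / (g2_0 - g1_0)

    lo = g1_0 + 0.06 * (g2_0 - g1_0)
    hi = g2_0 - 0.12 * (g2_0 - g1_0)
    span_s = (hi - lo) * T0
    k_eff = max(1, min(int(k_cmd), int(span_s / MIN_PEAK_SPACING_S)))

    gamma = np.linspace(0.0, 1.0, 2001)
    base = minjerk_sdot(gamma)
    mod = np.zeros_like(gamma)
    if k_eff > 1:
        slot = (hi - lo) / k_eff
        # dips wide and deep enough to survive the 6 Hz measurement filter
        w = 0.33 * slot
        for j in range(1, k_eff):
            c = lo + j * slot
            v_est = L * float(minjerk_sdot(c)) / T0
            depth = float(np.clip(amplitude / max(v_est, 1e-9), 0.5, 0.85))
            mask = np.abs(gamma - c) < w
            mod[mask] += depth * np.cos(np.pi * (gamma[mask] - c) / (2 * w)) ** 2
    g = base * (1.0 - np.clip(mod, 0.0, 0.95))
    S = cumulative_trapezoid(g, gamma, initial=0.0)
    g = g / S[-1]
    S = S / S[-1]

    gamma1 = float(np.interp(f1, S, gamma))
    gamma2 = float(np.interp(f2, S, gamma))
    T_full = duration_tr / (gamma2 - gamma1)
    return _TransportLaw(path=path, gamma=gamma, S=S, g=g,
                         gamma1=gamma1, gamma2=gamma2, T_full=T_full,
                         n_units=k_eff)


# ---------------------------------------------------------------------------
# Trial assembly
# ---------------------------------------------------------------------------

def _lognormal_around(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * math.exp(sigma * rng.standard_normal())) if sigma > 0 else median


def synth_trial(cfg: SimConfig, condition: str = "chopsticks", sex: str = "male",
                participant_id: str = "P00",
                participant_effects: dict | None = None,
                rng: np.random.Generator | None = None
                ) -> tuple[MotionRecording, GroundTruth]:
    """Generate one trial (three sequential eats -> two complete cycles).

    ``participant_effects`` may carry ``duration_factor`` (multiplicative,
    shared across conditions) and ``angle_offsets`` (per-channel additive
    degrees) so paired conditions share participant-level structure.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    eff = participant_effects or {}
    dur_factor = float(eff.get("duration_factor", 1.0))
    angle_offsets = eff.get("angle_offsets", {})
    angle_shift = eff.get("condition_angle_shift", {}) if condition == "chopsticks" else {}

    mouth = np.asarray(cfg.mouth, dtype=float)
    bowl = np.asarray(cfg.bowl, dtype=float)
    sep = float(np.linalg.norm(bowl - mouth))
    if sep < 1e-6:
        raise ValidationError("degenerate geometry: mouth and bowl coincide")
    e = (bowl - mouth) / sep
    thr = cfg.thresholds
    r_m_in = cfg.mouth_anchor_frac * thr.d_mouth
    r_b_in = cfg.bowl_anchor_frac * thr.d_bowl
    p_m = mouth + r_m_in * e       # hand rest point near the mouth
    p_b = bowl - r_b_in * e        # hand picking point at the bowl
    L_re = sep - r_m_in - r_b_in
    half = L_re / 2.0
    if half <= (thr.d_mouth - r_m_in) or half <= (L_re - (thr.d_bowl - r_b_in)) - half:
        raise ValidationError("geometry too tight for the proximity thresholds")

    # analytic crossing fractions of the straight two-half reach
    tau_exit = inv_minjerk_s((thr.d_mouth - r_m_in) / half)
    tau_bowl = inv_minjerk_s((L_re - (thr.d_bowl - r_b_in) - half) / half)

    # transport path with the commanded window detour ratio
    ratio = float(cfg.detour_ratio[(sex, condition)])
    normal = _perpendicular(e)
    path = _calibrate_bump(p_b, p_m, normal, mouth, bowl,
                           thr.d_bowl + thr.hysteresis, thr.d_mouth, ratio)
    s_bx = path.first_arc_above(bowl, thr.d_bowl + thr.hysteresis)
    s_mx = path.first_arc_below(mouth, thr.d_mouth)

    medians = cfg.phase_durations[(sex, condition)]
    k_cmd = int(cfg.n_submovements[(sex, condition)])

    # per-eat commanded durations, pause decisions and transport laws.
    # The reach is two minimum-jerk halves (pause slot between). The first
    # half keeps a bounded duration so the mouth-exit crossing — which ends
    # the previous cycle — stays prompt even for slow paced reaches; the
    # second half absorbs the remaining reaching-phase budget.
    eats = []
    half_cap = cfg.reach_motion_time_s / 2.0
    for _ in range(cfg.n_eats):
        cmd = {p: dur_factor * _lognormal_around(rng, medians[p], cfg.duration_sigma)
               for p in PHASES}
        pause = bool(rng.random() < cfg.pause_probability[condition])
        T_h1 = half_cap
        if pause:
            P = cmd["Re"] - (1 - tau_exit) * T_h1 - tau_bowl * half_cap
            T_h2 = half_cap
            if P < cfg.pause_min_s:
                pause, P = False, 0.0
        if not pause:
            P = 0.0
            T_h2 = (cmd["Re"] - (1 - tau_exit) * T_h1) / tau_bowl
            if T_h2 < half_cap:  # very short reaching phase: symmetric halves
                c_re = (1.0 - tau_exit + tau_bowl) / 2.0
                T_h1 = T_h2 = max(0.2, cmd["Re"] / c_re / 2.0)
        law = _build_transport_law(path, s_bx, s_mx, cmd["Tr"], k_cmd,
                                   cfg.submovement_amplitude_mps)
        eats.append({"cmd": cmd, "pause": pause, "P": P,
                     "T_h1": T_h1, "T_h2": T_h2, "law": law})

    # dwell times that honor the commanded Ta and Mo phase durations
    for j, eat in enumerate(eats):
        law = eat["law"]
        eat["T_ta"] = max(0.1, eat["cmd"]["Ta"] - (1 - tau_bowl) * eat["T_h2"]
                          - law.gamma1 * law.T_full)
        if j + 1 < len(eats):
            lead_next = tau_exit * eats[j + 1]["T_h1"]
        else:
            lead_next = 0.0
        eat["T_mo"] = max(0.05, eat["cmd"]["Mo"] - (1 - law.gamma2) * law.T_full
                          - lead_next)

    # segment chain: (kind, duration, payload)
    segments: list[tuple[str, float, dict]] = [
        ("dwell", cfg.initial_dwell_s, {"pos": p_m})]
    mid = p_m + (p_b - p_m) * 0.5
    events = {"exit": [], "bowl_entry": [], "bowl_exit": [], "mouth_entry": []}

    def elapsed() -> float:
        return sum(d for _, d, _ in segments)

    for eat in eats:
        T_h1, T_h2, P, law = eat["T_h1"], eat["T_h2"], eat["P"], eat["law"]
        t_reach = elapsed()
        events["exit"].append(t_reach + tau_exit * T_h1)
        segments.append(("move", T_h1, {"a": p_m, "b": mid}))
        if P > 0:
            segments.append(("dwell", P, {"pos": mid}))
        events["bowl_entry"].append(t_reach + T_h1 + P + tau_bowl * T_h2)
        segments.append(("move", T_h2, {"a": mid, "b": p_b}))
        segments.append(("dwell", eat["T_ta"], {"pos": p_b}))
        t_tr = elapsed()
        events["bowl_exit"].append(t_tr + law.gamma1 * law.T_full)
        events["mouth_entry"].append(t_tr + law.gamma2 * law.T_full)
        segments.append(("transport", law.T_full, {"law": law}))
        segments.append(("dwell", eat["T_mo"], {"pos": p_m}))

    # sample the hand trajectory
    fs = cfg.sample_rate
    bounds = np.concatenate([[0.0], np.cumsum([d for _, d, _ in segments])])
    total = float(bounds[-1])
    n = int(math.floor(total * fs))
    t = np.arange(n) / fs
    hand = np.empty((n, 3))
    seg_of = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, len(segments) - 1)
    for si, (kind, dur, pay) in enumerate(segments):
        idx = np.flatnonzero(seg_of == si)
        if len(idx) == 0:
            continue
        local = t[idx] - bounds[si]
        if kind == "dwell":
            hand[idx] = pay["pos"][None, :]
        elif kind == "move":
            tau = np.clip(local / dur, 0.0, 1.0)
            hand[idx] = pay["a"][None, :] \
                + (pay["b"] - pay["a"])[None, :] * minjerk_s(tau)[:, None]
        else:
            hand[idx] = pay["law"].sample(local)

    # joint-angle keyframes, phase-locked to the segment chain
    node_t: list[float] = [0.0, cfg.initial_dwell_s / 2]
    node_kind: list[tuple[str, str]] = [("Mo", "mid"), ("Mo", "mid")]
    cursor = cfg.initial_dwell_s
    for eat in eats:
        span_re = eat["T_h1"] + eat["P"] + eat["T_h2"]
        node_t += [cursor + 0.25 * span_re, cursor + 0.75 * span_re]
        node_kind += [("Re", "min"), ("Re", "max")]
        cursor += span_re
        node_t.append(cursor + eat["T_ta"] / 2)
        node_kind.append(("Ta", "mid"))
        cursor += eat["T_ta"]
        node_t += [cursor + 0.25 * eat["law"].T_full, cursor + 0.75 * eat["law"].T_full]
        node_kind += [("Tr", "min"), ("Tr", "max")]
        cursor += eat["law"].T_full
        node_t.append(cursor + eat["T_mo"] / 2)
        node_kind.append(("Mo", "mid"))
        cursor += eat["T_mo"]
    node_t.append(total)
    node_kind.append(("Mo", "mid"))
    node_t = np.asarray(node_t)
    keep = np.concatenate([[True], np.diff(node_t) > 1e-9])
    node_t = node_t[keep]
    node_kind = [nk for nk, k in zip(node_kind, keep) if k]

    cond_idx = 0 if condition == "chopsticks" else 1
    angles: dict[str, np.ndarray] = {}
    for ch in JOINT_CHANNELS:
        med = cfg.angle_medians[sex][ch]
        offset = float(angle_offsets.get(ch, 0.0)) + float(angle_shift.get(ch, 0.0))
        vals = []
        for phase, which in node_kind:
            mx = med[phase][cond_idx]
            mn = med[phase][2 + cond_idx]
            base = {"max": mx, "min": mn, "mid": 0.5 * (mx + mn)}[which]
            jitter = cfg.angle_trial_sd_deg * rng.standard_normal() \
                if cfg.angle_trial_sd_deg > 0 else 0.0
            vals.append(base + offset + jitter)
        angles[ch] = PchipInterpolator(node_t, np.asarray(vals))(t)

    # ground truth before noise
    def cross_idx(t_cross: float) -> int:
        return int(math.ceil(t_cross * fs - 1e-9))

    from .filtering import lowpass

    hand_smooth = lowpass(hand, thr.smoothing_cutoff, fs)

    def window_transport_truth(lo: int, hi: int, n_units: int) -> dict[str, float]:
        """Transport metrics of the clean sampled trajectory over [lo, hi).

        Speed-based quantities use the same zero-phase low-pass as the
        measurement stage so truth and noise-free measurement agree; the
        path metrics come from the raw clean trajectory.
        """
        w = hand[lo:hi]
        dist = float(np.linalg.norm(np.diff(w, axis=0), axis=1).sum())
        straight = float(np.linalg.norm(w[-1] - w[0]))
        speed = np.linalg.norm(np.gradient(hand_smooth[lo:hi], 1.0 / fs, axis=0), axis=1)
        k = int(np.argmax(speed))
        dur = (hi - lo) / fs
        return {
            "actual_distance_m": dist,
            "relative_distance": dist / straight,
            "mean_velocity_mps": dist / dur,
            "max_velocity_mps": float(speed[k]),
            "timing_max_velocity_pct": 100.0 * k / (hi - lo - 1),
            "n_movement_units": float(n_units),
        }

    # effective count over the complete cycles (per-cycle truth also records it)
    n_eff = min(eat["law"].n_units for eat in eats[:max(1, cfg.n_eats - 1)])
    cycles: list[CycleTruth] = []
    for j in range(cfg.n_eats - 1):
        c0 = cross_idx(events["exit"][j])
        c1 = cross_idx(events["exit"][j + 1])
        phases = {
            "Re": (c0, cross_idx(events["bowl_entry"][j])),
            "Ta": (cross_idx(events["bowl_entry"][j]), cross_idx(events["bowl_exit"][j])),
            "Tr": (cross_idx(events["bowl_exit"][j]), cross_idx(events["mouth_entry"][j])),
            "Mo": (cross_idx(events["mouth_entry"][j]), c1),
        }
        extrema = {
            p: {ch: (float(angles[ch][lo:hi].min()), float(angles[ch][lo:hi].max()))
                for ch in JOINT_CHANNELS}
            for p, (lo, hi) in phases.items()
        }
        cycles.append(CycleTruth(
            cycle_bounds=(c0, c1),
            phases=phases,
            pause_in_reach=eats[j]["pause"],
            commanded_durations_s=dict(eats[j]["cmd"]),
            transport=window_transport_truth(*phases["Tr"], eats[j]["law"].n_units),
            angle_extrema=extrema,
        ))

    if cfg.pos_noise_sd_m > 0:
        hand = hand + rng.normal(0.0, cfg.pos_noise_sd_m, hand.shape)
    if cfg.angle_noise_sd_deg > 0:
        for ch in JOINT_CHANNELS:
            angles[ch] = angles[ch] + rng.normal(0.0, cfg.angle_noise_sd_deg, n)

    rec = MotionRecording(
        participant_id=participant_id,
        sex=sex,
        condition=condition,
        sample_rate=fs,
        time=t,
        angles=angles,
        hand_pos=hand,
        mouth_pos=np.tile(mouth, (n, 1)),
        bowl_pos=np.tile(bowl, (n, 1)),
    ).validate()
    truth = GroundTruth(
        condition=condition, sex=sex, cycles=cycles,
        detour_ratio=ratio,
        n_submovements_commanded=k_cmd,
        n_submovements_effective=n_eff,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Paired-cohort layout: strata sizes and participant-level variability."""

    n_male: int = 22
    n_female: int = 21
    duration_factor_sigma: float = 0.15
    angle_between_sd_deg: float = 5.0
    condition_angle_shift: dict = field(default_factory=dict)  # chopsticks +=

    def __post_init__(self) -> None:
        if self.n_male < 1 or self.n_female < 1:
            raise ValidationError("each stratum needs at least one participant")


def synth_cohort(spec: CohortSpec, cfg: SimConfig, out_dir=None):
    """Generate a paired cohort: one trial per condition per participant.

    Returns a list of ``(recording, truth)`` tuples plus a truth table; when
    *out_dir* is given, also writes motion CSVs, per-trial events JSON (all
    cycles flagged successful) and ``truth.csv``.
    """
    import pandas as pd

    from .io import CycleAnnotation, EventAnnotations, write_events, write_motion_csv

    rng = np.random.default_rng(cfg.seed)
    dataset = []
    rows = []
    for sex, count in (("male", spec.n_male), ("female", spec.n_female)):
        for i in range(count):
            pid = f"{sex[0].upper()}{i + 1:02d}"
            effects = {
                "duration_factor": math.exp(
                    spec.duration_factor_sigma * rng.standard_normal()),
                "angle_offsets": {
                    ch: spec.angle_between_sd_deg * rng.standard_normal()
                    for ch in JOINT_CHANNELS},
                "condition_angle_shift": dict(spec.condition_angle_shift),
            }
            for condition in ("chopsticks", "spoon"):
                rec, truth = synth_trial(cfg, condition, sex, pid, effects, rng)
                dataset.append((rec, truth))
                for c, cyc in enumerate(truth.cycles):
                    rows.append({
                        "participant_id": pid, "sex": sex, "condition": condition,
                        "cycle": c, **{f"true_{k}": v for k, v in cyc.transport.items()},
                        **{f"true_dur_{p}": cyc.commanded_durations_s[p] for p in PHASES},
                        "pause_in_reach": cyc.pause_in_reach,
                    })
                if out_dir is not None:
                    from pathlib import Path

                    out = Path(out_dir)
                    out.mkdir(parents=True, exist_ok=True)
                    write_motion_csv(rec, out / f"{pid}_{condition}.csv")
                    ev = EventAnnotations(cycles=[
                        CycleAnnotation(start_index=cyc.cycle_bounds[0],
                                        end_index=cyc.cycle_bounds[1])
                        for cyc in truth.cycles])
                    write_events(ev, out / f"{pid}_{condition}_events.json")
    truth_table = pd.DataFrame(rows)
    if out_dir is not None:
        from pathlib import Path

        truth_table.to_csv(Path(out_dir) / "truth.csv", index=False)
    return dataset, truth_table


def synth_paired_metric(n_pairs: int, shift: float = 0.0, between_sd: float = 5.0,
                        noise_sd: float = 2.0, base: float = 30.0,
                        rng: np.random.Generator | None = None):
    """Metric-level paired sample: participant random effect + measurement
    noise, with an additive condition shift on condition a (chopsticks).

    Used for null calibration and shift-recovery studies of the statistical
    stage without simulating full motion trials.
    """
    from .stats import PairedSample

    if rng is None:
        rng = np.random.default_rng()
    b = base + between_sd * rng.standard_normal(n_pairs)
    a_vals = b + shift + noise_sd * rng.standard_normal(n_pairs)
    b_vals = b + noise_sd * rng.standard_normal(n_pairs)
    return PairedSample(values_a=a_vals, values_b=b_vals)
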