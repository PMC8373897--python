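"""Synthetic multimodal sessions with known ground truth.

Emulates the study design this package analyzes: 58 producers each
communicating 20 action verbs, with the noise condition (clear, 4-talker
babble, 8-talker babble) drawn at random per round, random participant and
item effects, condition shifts on speech intensity, submovement rate,
holdtime, and mouth kinematics, and per-participant slope heterogeneity
(some participants respond positively, some negatively).

Two layers:

- ``generate_latent_table`` draws the per-round latent feature values from
  the configured mixed-effects structure (fast; used for parameter-recovery
  simulation).
- ``generate_dataset`` additionally renders body/face tracks, acoustic
  contours, and annotation tiers whose *extracted* features match the latent
  values, giving every extractor a round-trip oracle.

Gesture trajectories are built from minimum-jerk velocity pulses
(bell-shaped, closed-form peak ``1.875 L/T``). Submovements beyond the first
traverse a small diamond around the gesture apex with 90-degree turns, so
merged pulses keep a supra-threshold saddle and are counted by peak
prominence, while requested holds are rendered as explicit plateaus whose
duration is shrunk by the closed-form sub-threshold tail time of the
adjacent pulses, making the extracted holdtime equal the target.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gesture import DEFAULT_HOLD_THRESHOLD, DEFAULT_MIN_HOLD
from .types import (
    GESTURE,
    GESTURE_ONLY,
    MULTIMODAL,
    SPEECH,
    SPEECH_ONLY,
    AcousticContour,
    BodyTrack,
    FaceTrack,
    TimedEvent,
)

# ---------------------------------------------------------------------------
# body geometry (meters, y up)

REST_POSE: dict[str, tuple[float, float, float]] = {
    "spine_base": (0.0, 1.00, 0.0),
    "spine_shoulder": (0.0, 1.45, 0.0),
    "shoulder_l": (-0.20, 1.44, 0.0),
    "shoulder_r": (0.20, 1.44, 0.0),
    "face_mid": (0.0, 1.62, 0.02),
    "head_top": (0.0, 1.80, 0.0),
    "hand_l": (-0.20, 0.95, 0.10),
    "hand_r": (0.20, 0.95, 0.10),
}

_TORSO_MID = (1.00 + 1.45) / 2  # 1.225
_TORSO_UQ = 1.00 + 0.75 * 0.45  # 1.3375
_SHOULDER = 1.44
_FACE_MID = 1.62
_HEAD_TOP = 1.80

#: apex target height per vertical-amplitude band (band centers)
BIN_APEX_Y = {
    0: 1.10,
    1: (_TORSO_MID + _TORSO_UQ) / 2,
    2: (_TORSO_UQ + _SHOULDER) / 2,
    3: (_SHOULDER + _FACE_MID) / 2,
    4: (_FACE_MID + _HEAD_TOP) / 2,
    5: _HEAD_TOP + 0.08,
}

FACE_POSE: dict[str, tuple[float, float, float]] = {
    "nose_bridge": (0.0, 1.645, 0.080),
    "mouth_upper_inner": (0.0, 1.615, 0.080),
    "mouth_corner_l": (-0.004, 1.611, 0.080),
    "mouth_corner_r": (0.004, 1.611, 0.080),
    "mouth_lower_inner": (0.0, 1.615, 0.080),  # moves down with the aperture
    "lower_lip_center": (0.0, 1.613, 0.080),
}


class InfeasibleGestureError(ValueError):
    """Requested gesture parameters cannot be rendered as a trajectory."""


# ---------------------------------------------------------------------------
# minimum-jerk machinery


def _minjerk_s(tau: np.ndarray) -> np.ndarray:
    """Normalized min-jerk displacement 0..1."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _tail_tau(level_ratio: float) -> float:
    """Fraction of pulse duration with speed below ``level_ratio * peak``.

    The min-jerk speed shape is ``16 tau^2 (1-tau)^2`` of the peak; solving
    for the crossing gives a closed form used both for hold bookkeeping and
    for pulse blending.
    """
    lr = float(np.clip(level_ratio, 0.0, 1.0))
    c = math.sqrt(lr) / 4.0
    disc = max(0.0, 1.0 - 4.0 * c)
    return (1.0 - math.sqrt(disc)) / 2.0


@dataclass
class Leg:
    """One straight minimum-jerk movement segment."""

    t0: float
    duration: float
    length: float
    direction: np.ndarray  # unit 3-vector

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    @property
    def peak_speed(self) -> float:
        return 1.875 * self.length / self.duration

    def displacement(self, t: np.ndarray) -> np.ndarray:
        tau = (t - self.t0) / self.duration
        return np.outer(_minjerk_s(tau) * self.length, self.direction)


@dataclass
class GestureScript:
    """A planned gesture: legs + annotation span + ground truth."""

    start_pos: np.ndarray
    legs: list[Leg]
    span: tuple[float, float]  # annotated gesture span (s, relative)
    truth: dict
    retraction: Leg | None = None

    @property
    def t_end(self) -> float:
        end = max(l.t_end for l in self.legs)
        if self.retraction is not None:
            end = max(end, self.retraction.t_end)
        return end

    def positions(self, t: np.ndarray) -> np.ndarray:
        pos = np.tile(self.start_pos, (t.size, 1))
        for leg in self.legs:
            pos += leg.displacement(t)
        if self.retraction is not None:
            pos += self.retraction.displacement(t)
        return pos


def plan_gesture(
    n_submovements: int,
    hold_total: float,
    peak_vel: float,
    max_dist: float,
    amplitude_bin: int,
    sample_rate: float,
    start_pos: np.ndarray | None = None,
    hold_threshold: float = DEFAULT_HOLD_THRESHOLD,
    min_hold: float = DEFAULT_MIN_HOLD,
    max_duration_s: float | None = None,
) -> GestureScript:
    """Plan a gesture whose extracted features equal the requested ones."""
    if n_submovements < 1:
        raise InfeasibleGestureError("need at least one submovement")
    if hold_total < 0:
        raise InfeasibleGestureError("hold_total must be non-negative")
    if peak_vel <= 2 * hold_threshold:
        raise InfeasibleGestureError(
            f"peak velocity {peak_vel} must exceed twice the hold threshold"
        )
    if amplitude_bin not in BIN_APEX_Y:
        raise InfeasibleGestureError("amplitude_bin must be in 0..5")
    start = np.asarray(start_pos if start_pos is not None else REST_POSE["hand_r"], dtype=float)
    dt = 1.0 / sample_rate

    rise = BIN_APEX_Y[amplitude_bin] - start[1]
    dist = max(max_dist, abs(rise) + 0.02, 0.2)
    dz = math.sqrt(max(dist**2 - rise**2, 1e-6))
    u_hat = np.array([0.0, rise, dz]) / dist  # apex direction
    x_hat = np.array([1.0, 0.0, 0.0])

    legs: list[Leg] = []
    main = Leg(0.0, 1.875 * dist / peak_vel, dist, u_hat)
    legs.append(main)

    # diamond wander around the apex: all turns are 90 degrees so blended
    # junction speed never collapses toward zero
    v_w = min(max(0.7 * peak_vel, 0.38), 0.95 * peak_vel, 0.85)
    r = 0.08
    apex = u_hat * dist
    verts = [
        apex,
        apex - r * u_hat + r * x_hat,
        apex - 2 * r * u_hat,
        apex - r * u_hat - r * x_hat,
    ]
    wander: list[Leg] = []
    cur = 0
    for _ in range(n_submovements - 1):
        nxt = (cur + 1) % 4
        delta = verts[nxt] - verts[cur]
        length = float(np.linalg.norm(delta))
        wander.append(Leg(0.0, 1.875 * length / v_w, length, delta / length))
        cur = nxt

    # hold allocation over the n-1 junctions plus an end slot
    n_junc = len(wander)
    peaks = [peak_vel] + [v_w] * n_junc
    junc_tails = []
    for k in range(n_junc):
        t_prev = _tail_tau(hold_threshold / peaks[k]) * (legs + wander)[k].duration
        t_next = _tail_tau(hold_threshold / peaks[k + 1]) * wander[k].duration
        junc_tails.append(t_prev + t_next)
    end_tail = _tail_tau(hold_threshold / peaks[-1]) * ((wander[-1] if wander else main).duration)

    # a hold is only placed where the sub-threshold run survives the
    # extractor's 3-frame smoothing: plateau of at least min_hold + margin
    allocs = [0.0] * n_junc
    end_alloc = 0.0
    remaining = hold_total
    cap = 0.9
    for j in range(n_junc):
        if remaining <= 0:
            break
        need = junc_tails[j] + min_hold + 2.5 * dt
        take = min(remaining, max(cap, need))
        if take + 1e-12 >= need:
            allocs[j] = take
            remaining -= take
    if remaining > 1e-9:
        need = end_tail + min_hold + 2.5 * dt
        if remaining + 1e-12 >= need:
            end_alloc = remaining
            remaining = 0.0
    rendered_hold = sum(allocs) + end_alloc

    # schedule: blend (overlap) hold-free junctions, insert plateaus otherwise.
    # The blended saddle is aimed at a target between the stillness threshold
    # and the adjacent peaks, deep enough that each peak keeps its prominence:
    # at the handoff both legs run at `level`, and their vector sum scales
    # with the angle between the leg directions.
    seq = [main]
    for k, leg in enumerate(wander):
        prev = seq[-1]
        if allocs[k] > 0:
            # +0.75 frames compensates the smoothing loss at the run edges
            plateau = allocs[k] - junc_tails[k] + 0.75 * dt
            leg = replace(leg, t0=prev.t_end + plateau)
        else:
            vmin = min(prev.peak_speed, leg.peak_speed)
            factor = float(np.linalg.norm(prev.direction + leg.direction))
            saddle = min(max(1.25 * hold_threshold, 0.45 * vmin), 0.8 * vmin)
            lvl = min(saddle / max(factor, 0.5), 0.8 * vmin)
            shift = (
                _tail_tau(lvl / prev.peak_speed) * prev.duration
                + _tail_tau(lvl / leg.peak_speed) * leg.duration
            )
            leg = replace(leg, t0=prev.t_end - shift)
        seq.append(leg)

    last = seq[-1]
    # annotated span: from first supra-threshold frame to last, plus end hold
    on = _tail_tau(hold_threshold / main.peak_speed) * main.duration - 1.5 * dt
    t_last_cross = last.t_end - _tail_tau(hold_threshold / last.peak_speed) * last.duration
    off = t_last_cross + end_alloc + 1.5 * dt
    duration = off - max(on, 0.0)
    if max_duration_s is not None and (duration > max_duration_s or hold_total >= max_duration_s):
        raise InfeasibleGestureError(
            f"gesture of {duration:.2f}s (hold {hold_total:.2f}s) exceeds {max_duration_s}s"
        )

    end_pos = start + apex if not wander else start + verts[cur]
    retract_delta = np.asarray(REST_POSE["hand_r"], dtype=float) - end_pos
    retract_len = float(np.linalg.norm(retract_delta))
    retraction = None
    if retract_len > 1e-6:
        retraction = Leg(off + 2.5 * dt, max(0.5, 1.875 * retract_len / 0.8),
                         retract_len, retract_delta / retract_len)

    span = (max(on, 0.0), off)
    script = GestureScript(start, seq, span, {}, retraction)
    # the extractor measures distance from the hand position at the annotated
    # onset; evaluate the continuous trajectory densely for the exact value
    t_dense = np.arange(span[0], span[1], 1e-3)
    p_dense = script.positions(t_dense)
    ref = script.positions(np.array([span[0] + 0.5 * dt]))[0]
    dist_truth = float(np.max(np.linalg.norm(p_dense - ref, axis=1)))
    script.truth = {
        "submovements": int(n_submovements),
        "holdtime_s": float(rendered_hold),
        "peak_velocity_m_s": float(peak_vel),
        "max_distance_m": dist_truth,
        "vertical_amplitude": int(amplitude_bin),
    }
    return script


def generate_gesture_track(
    n_submovements: int,
    hold_total: float,
    peak_vel: float,
    max_dist: float,
    amplitude_bin: int,
    sample_rate: float = 30.0,
    rng: np.random.Generator | None = None,
    noise_m: float = 0.0,
    hold_threshold: float = DEFAULT_HOLD_THRESHOLD,
    min_hold: float = DEFAULT_MIN_HOLD,
    max_duration_s: float | None = None,
) -> tuple[BodyTrack, tuple[float, float], dict]:
    """A standalone body-track segment containing one planned gesture.

    Returns ``(track, span_s, truth)`` where ``truth`` holds the feature
    values the gesture-kinematics extractor should recover.
    """
    script = plan_gesture(
        n_submovements, hold_total, peak_vel, max_dist, amplitude_bin,
        sample_rate, None, hold_threshold, min_hold, max_duration_s,
    )
    pad = 0.4
    t = np.arange(0.0, script.t_end + pad, 1.0 / sample_rate)
    points = {
        name: np.tile(np.asarray(p, dtype=float), (t.size, 1))
        for name, p in REST_POSE.items()
    }
    points["hand_r"] = script.positions(t)
    if noise_m > 0 and rng is not None:
        for name in points:
            points[name] = points[name] + rng.normal(0.0, noise_m, points[name].shape)
    return BodyTrack(t, points), script.span, script.truth


# ---------------------------------------------------------------------------
# lip track


def plan_lip_motion(
    opening_max_mm: float,
    movement_rate_mm_s: float,
    span_s: tuple[float, float],
    utterances_s: list[tuple[float, float]],
    peak_velocity_mm_s: float | None = None,
    sample_rate: float = 30.0,
) -> dict:
    """Aperture schedule whose extracted features match the targets.

    The lower lip performs full open-close cycles (aperture
    ``a sin^2(pi t/cycle)``) inside utterances, so the mouth is closed at
    every cycle boundary and the path length is exactly ``sum 2a``. Cycle
    amplitudes are solved so the total path equals ``movement_rate *
    span_duration`` (span = attempt span, the extractor's denominator); the
    first cycle of the first utterance uses the full opening, making the
    aperture maximum the configured one, and its duration is solved so the
    *extracted* (discretized, smoothed) peak lip velocity equals the target.
    Remaining cycles run at 80% of that peak, with idle closed-mouth time
    filling the rest of the utterance; when an utterance is too short for
    its path share the cycles are compressed and the realized (higher) peak
    is recorded as the truth instead.
    """
    if opening_max_mm < 0:
        raise ValueError("opening_max must be non-negative")
    span_dur = span_s[1] - span_s[0]
    if span_dur <= 0:
        raise ValueError("span duration must be positive")
    A = opening_max_mm / 1000.0
    target_path = movement_rate_mm_s / 1000.0 * span_dur
    utt_durs = [off - on for on, off in utterances_s]
    utt_time = sum(utt_durs)

    if A <= 0 or utt_time <= 0 or not utterances_s:
        return {
            "schedule": [],
            "truth": {
                "max_mouth_opening_mm": 8.0,
                "mean_lip_movement_mm_s": 0.0,
                "peak_lip_velocity_mm_s": 0.0,
            },
        }

    c_min = 8.0 / sample_rate  # below ~8 frames/cycle the response model fails

    def att(cyc: float) -> float:
        # known discrete-time response of the extractor at the sample rate:
        # central-difference gradient times the 3-frame moving average
        cyc = max(cyc, c_min)
        w = 2 * math.pi / (cyc * sample_rate)
        return (math.sin(w) / w) * (1 + 2 * math.cos(w)) / 3

    def cyc_for_peak(amp: float, v: float) -> float:
        # largest extracted peak any cycle of this amplitude can show
        cap = att(c_min) * math.pi * amp / c_min
        v = min(v, 0.98 * cap)
        c = math.pi * amp / v
        for _ in range(40):
            c_new = max(c_min, att(c) * math.pi * amp / v)
            if abs(c_new - c) < 1e-5:
                break
            c = c_new
        return c

    v_t = (peak_velocity_mm_s or 0.0) / 1000.0
    if v_t <= 0:
        v_t = math.pi * A / min(max(utt_durs), 1.0)  # one leisurely cycle

    schedule: list[tuple[float, float, float]] = []  # (t_on, amp, cyc)
    path_total = 0.0
    peak_truth = 0.0
    for j, ((on, off), dur) in enumerate(zip(utterances_s, utt_durs)):
        share = target_path * dur / utt_time
        cycles: list[tuple[float, float]] = []  # (amp, cyc)
        if j == 0:
            cycles.append((A, cyc_for_peak(A, v_t)))
            rest = max(0.0, share - 2 * A)
        else:
            rest = share
        if rest > 1e-6:
            a_r = min(A, rest / 2)
            n_rest = max(1, math.ceil(rest / (2 * a_r)))
            a_r = rest / (2 * n_rest)
            cyc_r = cyc_for_peak(a_r, 0.8 * v_t)
            cycles.extend([(a_r, cyc_r)] * n_rest)
        # drop rest cycles (shrinking the path, which is recorded) rather
        # than compressing cycles below the resolvable duration
        while len(cycles) > 1 and sum(c for _, c in cycles) > dur:
            cycles.pop()
        if cycles and cycles[0][1] > dur:
            cycles[0] = (cycles[0][0], dur)
        # short lead-in keeps the first flank away from the span edge, where
        # one-sided differencing would otherwise overestimate the velocity
        total_c = sum(c for _, c in cycles)
        t_cursor = on + min(2.0 / sample_rate, max(0.0, dur - total_c))
        for a, c in cycles:
            schedule.append((t_cursor, a, c))
            t_cursor += c
            path_total += 2 * a
            peak_truth = max(peak_truth, att(c) * math.pi * a / c)
    # the extractor's denominator is the time covered by frame-to-frame
    # steps inside the span, which is one frame short of the span itself
    covered = max(span_dur - 1.0 / sample_rate, 1e-6)
    return {
        "schedule": schedule,
        "truth": {
            "max_mouth_opening_mm": max(opening_max_mm, 8.0),
            "mean_lip_movement_mm_s": path_total / covered * 1000.0,
            "peak_lip_velocity_mm_s": peak_truth * 1000.0,
        },
    }


def _lip_aperture(t: np.ndarray, plan: dict) -> np.ndarray:
    """Aperture (vertical lower-lip displacement) at times t."""
    aperture = np.zeros(t.size)
    for t_on, amp, cyc in plan["schedule"]:
        mask = (t >= t_on) & (t < t_on + cyc)
        phase = (t[mask] - t_on) / cyc
        aperture[mask] += amp * np.sin(math.pi * phase) ** 2
    return aperture


def generate_lip_track(
    opening_max_mm: float,
    movement_rate_mm_s: float,
    duration_s: float,
    sample_rate: float = 30.0,
    rng: np.random.Generator | None = None,
    peak_velocity_mm_s: float | None = None,
    noise_m: float = 0.0,
) -> tuple[FaceTrack, dict]:
    """A standalone face-track segment: one utterance filling the duration."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    utterances = [(0.0, duration_s)]
    plan = plan_lip_motion(
        opening_max_mm, movement_rate_mm_s, (0.0, duration_s), utterances,
        peak_velocity_mm_s, sample_rate,
    )
    t = np.arange(0.0, duration_s, 1.0 / sample_rate)
    aperture = _lip_aperture(t, plan)
    points = {
        name: np.tile(np.asarray(p, dtype=float), (t.size, 1))
        for name, p in FACE_POSE.items()
    }
    for name in ("mouth_lower_inner", "lower_lip_center"):
        points[name] = points[name].copy()
        points[name][:, 1] -= aperture
    if noise_m > 0 and rng is not None:
        for name in points:
            points[name] = points[name] + rng.normal(0.0, noise_m, points[name].shape)
    return FaceTrack(t, points), plan["truth"]


# ---------------------------------------------------------------------------
# acoustic contour

CONTOUR_FLOOR_DB = 45.0


def generate_acoustic_contour(
    base_db: float,
    shift_db: float,
    f0_hz: float,
    utterance_intervals_s: list[tuple[float, float]],
    duration_s: float,
    rng: np.random.Generator | None = None,
    noise_sd_db: float = 0.0,
    step_s: float = 0.01,
    relative_levels_db: list[float] | None = None,
) -> AcousticContour:
    """Intensity/F0 contour whose per-utterance maximum is ``base+shift``.

    ``relative_levels_db`` offsets individual utterances (<= 0 keeps the
    first utterance the attempt maximum). F0 is defined only inside
    utterances, declining from its onset maximum.
    """
    ivs = sorted(utterance_intervals_s)
    for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
        if b0 < a1:
            raise ValueError("utterance intervals must not overlap")
    for on, off in ivs:
        if not (0 <= on < off <= duration_s + 1e-9):
            raise ValueError(f"interval [{on}, {off}) outside track duration")
    t = np.arange(0.0, duration_s, step_s)
    inten = np.full(t.size, CONTOUR_FLOOR_DB)
    f0 = np.full(t.size, np.nan)
    levels = relative_levels_db or [0.0] * len(ivs)
    for (on, off), rel in zip(ivs, levels):
        target = base_db + shift_db + rel
        if rng is not None and noise_sd_db > 0:
            target += rng.normal(0.0, noise_sd_db)
        mask = (t >= on) & (t < off)
        local = (t[mask] - on) / max(off - on, 1e-9)
        inten[mask] = target - 6.0 * (1.0 - np.sin(math.pi * local))
        # ensure the exact maximum is on the grid
        if mask.any():
            mid = np.flatnonzero(mask)[np.argmin(np.abs(local - 0.5))]
            inten[mid] = target
        f0[mask] = (f0_hz + rel / 2.0) - 12.0 * local
        if mask.any():
            f0[np.flatnonzero(mask)[0]] = f0_hz + rel / 2.0
    return AcousticContour(t, inten, f0, step_s)


# ---------------------------------------------------------------------------
# study configuration

CONDITIONS = ("clear", "babble4", "babble8")

#: Observed modality proportions per condition (counts from the study's
#: modality-usage table), used as default multinomial probabilities over
#: (speech_only, gesture_only, multimodal).
OBSERVED_MODALITY_COUNTS = {
    "clear": (78, 236, 140),
    "babble4": (71, 252, 88),
    "babble8": (94, 244, 99),
}


def _props(counts: tuple[int, int, int]) -> tuple[float, float, float]:
    tot = sum(counts)
    return tuple(c / tot for c in counts)


SPEECH_FEATURES = ("max_intensity_db", "max_f0_hz", "max_mouth_opening_mm",
                   "mean_lip_movement_mm_s", "peak_lip_velocity_mm_s")
GESTURE_FEATURES = ("peak_velocity_m_s", "max_distance_m", "vertical_amplitude",
                    "holdtime_s", "submovements")
ALL_FEATURES = SPEECH_FEATURES + GESTURE_FEATURES


def _default_participant_sd() -> dict[str, float]:
    return {
        "max_intensity_db": 2.0, "max_f0_hz": 30.0,
        "max_mouth_opening_mm": 3.0, "mean_lip_movement_mm_s": 10.0,
        "peak_lip_velocity_mm_s": 30.0, "peak_velocity_m_s": 0.15,
        "max_distance_m": 0.08, "vertical_amplitude": 1.0,
        "holdtime_s": 0.35, "submovements": 0.25,
    }


def _default_item_sd() -> dict[str, float]:
    return {
        "max_intensity_db": 0.2, "max_f0_hz": 2.0,
        "max_mouth_opening_mm": 0.4, "mean_lip_movement_mm_s": 1.0,
        "peak_lip_velocity_mm_s": 3.0, "peak_velocity_m_s": 0.03,
        "max_distance_m": 0.02, "vertical_amplitude": 0.3,
        "holdtime_s": 0.10, "submovements": 0.08,
    }


def _default_slope_sd() -> dict[str, float]:
    return {
        "holdtime_s": 0.25, "max_mouth_opening_mm": 0.8,
        "mean_lip_movement_mm_s": 2.0,
    }


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic study.

    Effect tuples are ordered (clear, babble4, babble8), additive on each
    feature's model scale (dB for intensity, log rate for submovements, log
    seconds for holdtime, mm for mouth opening). Defaults reflect the study
    design: 58 producers x 20 items, condition drawn uniformly per round,
    modality drawn from the observed per-condition proportions, intensity
    and submovement shifts at the published point estimates.
    """

    n_participants: int = 58
    n_items: int = 20
    conditions: tuple[str, str, str] = CONDITIONS
    sample_rate_hz: float = 30.0
    contour_step_s: float = 0.01

    intensity_base_db: float = 75.0
    intensity_effect_db: tuple[float, float, float] = (0.0, 0.12, 0.29)
    intensity_effect_scope: str = "all"  # "all" | "speech_only"
    intensity_resid_sd: float = 0.6
    f0_base_hz: float = 220.0
    f0_effect_hz: tuple[float, float, float] = (0.0, 0.0, 0.0)
    f0_resid_sd: float = 10.0
    submovement_log_base: float = math.log(4.0)
    submovement_log_rate_effect: tuple[float, float, float] = (0.0, 0.0889, 0.1328)
    holdtime_log_base: float = math.log(0.8)
    holdtime_effect: tuple[float, float, float] = (1.0, 1.05, 1.10)  # multiplicative
    holdtime_shape: float = 3.0
    mouth_opening_base_mm: float = 22.0
    mouth_opening_effect_mm: tuple[float, float, float] = (0.0, 0.4, 0.7)
    mouth_opening_resid_sd: float = 2.0
    lip_movement_base: float = 60.0
    lip_movement_effect: tuple[float, float, float] = (0.0, 1.0, 2.0)
    lip_movement_resid_sd: float = 8.0
    lip_velocity_base: float = 150.0
    lip_velocity_effect: tuple[float, float, float] = (0.0, 0.0, 0.0)
    lip_velocity_resid_sd: float = 25.0
    peak_velocity_base: float = 0.9
    peak_velocity_effect: tuple[float, float, float] = (0.0, 0.0, 0.0)
    peak_velocity_resid_sd: float = 0.2
    max_distance_base: float = 0.45
    max_distance_effect: tuple[float, float, float] = (0.0, 0.008, 0.015)
    max_distance_resid_sd: float = 0.10
    va_effect: tuple[float, float, float] = (0.0, -0.07, -0.12)
    va_thresholds: tuple[float, ...] = (-2.2, -0.8, 0.6, 2.0, 3.2)

    participant_sd: dict[str, float] = field(default_factory=_default_participant_sd)
    item_sd: dict[str, float] = field(default_factory=_default_item_sd)
    participant_slope_sd: dict[str, float] = field(default_factory=_default_slope_sd)
    modality_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {c: _props(OBSERVED_MODALITY_COUNTS[c]) for c in CONDITIONS}
    )
    extra_attempt_prob: float = 0.2
    second_utterance_prob: float = 0.3
    track_noise_m: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.conditions)) != 3:
            raise ValueError("conditions must be 3 distinct labels")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        for d in (self.participant_sd, self.item_sd, self.participant_slope_sd):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"negative SD for {k}")
        for c, probs in self.modality_probs.items():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"modality_probs for {c} must sum to 1")
        if self.intensity_effect_scope not in ("all", "speech_only"):
            raise ValueError("intensity_effect_scope must be 'all' or 'speech_only'")

    def effects_on_model_scale(self) -> dict[str, tuple[float, float, float]]:
        """Per-feature condition effects on the scale the model fits."""
        return {
            "max_intensity_db": self.intensity_effect_db,
            "max_f0_hz": self.f0_effect_hz,
            "submovements": self.submovement_log_rate_effect,
            "holdtime_s": tuple(math.log(f) for f in self.holdtime_effect),
            "max_mouth_opening_mm": self.mouth_opening_effect_mm,
            "mean_lip_movement_mm_s": self.lip_movement_effect,
            "peak_lip_velocity_mm_s": self.lip_velocity_effect,
            "peak_velocity_m_s": self.peak_velocity_effect,
            "max_distance_m": self.max_distance_effect,
            "vertical_amplitude": self.va_effect,
        }


# ---------------------------------------------------------------------------
# latent table


def generate_latent_table(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """One row per round with latent (pre-rendering) feature values.

    Deterministic given the config seed. Speech features are absent (NaN)
    in gesture-only rounds, gesture features absent in speech-only rounds.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    cfg = config
    participants = [f"p{i + 1:02d}" for i in range(cfg.n_participants)]
    items = [f"word{i + 1:02d}" for i in range(cfg.n_items)]
    n = cfg.n_participants * cfg.n_items

    p_idx = np.repeat(np.arange(cfg.n_participants), cfg.n_items)
    i_idx = np.tile(np.arange(cfg.n_items), cfg.n_participants)
    cond_idx = rng.integers(0, 3, size=n)
    conds = np.array(cfg.conditions)[cond_idx]

    modality = np.empty(n, dtype=object)
    u = rng.random(n)
    for ci, c in enumerate(cfg.conditions):
        probs = np.cumsum(cfg.modality_probs[c])
        rows = cond_idx == ci
        modality[rows] = np.array([SPEECH_ONLY, GESTURE_ONLY, MULTIMODAL])[
            np.searchsorted(probs, u[rows], side="right").clip(0, 2)
        ]

    df = pd.DataFrame(
        {
            "participant": np.array(participants)[p_idx],
            "item": np.array(items)[i_idx],
            "condition": conds,
            "modality": modality,
        }
    )
    effects = cfg.effects_on_model_scale()
    bases = {
        "max_intensity_db": cfg.intensity_base_db,
        "max_f0_hz": cfg.f0_base_hz,
        "submovements": cfg.submovement_log_base,
        "holdtime_s": cfg.holdtime_log_base,
        "max_mouth_opening_mm": cfg.mouth_opening_base_mm,
        "mean_lip_movement_mm_s": cfg.lip_movement_base,
        "peak_lip_velocity_mm_s": cfg.lip_velocity_base,
        "peak_velocity_m_s": cfg.peak_velocity_base,
        "max_distance_m": cfg.max_distance_base,
        "vertical_amplitude": 0.0,
    }
    resid = {
        "max_intensity_db": cfg.intensity_resid_sd,
        "max_f0_hz": cfg.f0_resid_sd,
        "max_mouth_opening_mm": cfg.mouth_opening_resid_sd,
        "mean_lip_movement_mm_s": cfg.lip_movement_resid_sd,
        "peak_lip_velocity_mm_s": cfg.lip_velocity_resid_sd,
        "peak_velocity_m_s": cfg.peak_velocity_resid_sd,
        "max_distance_m": cfg.max_distance_resid_sd,
    }
    has_speech = np.isin(modality, [SPEECH_ONLY, MULTIMODAL])
    has_gesture = np.isin(modality, [GESTURE_ONLY, MULTIMODAL])

    for feat in ALL_FEATURES:
        b_p = rng.normal(0.0, cfg.participant_sd.get(feat, 0.0), cfg.n_participants)
        b_i = rng.normal(0.0, cfg.item_sd.get(feat, 0.0), cfg.n_items)
        slope_sd = cfg.participant_slope_sd.get(feat, 0.0)
        s_p = rng.normal(0.0, slope_sd, (cfg.n_participants, 2))
        eff = np.asarray(effects[feat])[cond_idx]
        if feat == "max_intensity_db" and cfg.intensity_effect_scope == "speech_only":
            eff = np.where(modality == SPEECH_ONLY, eff, 0.0)
        slope = np.where(cond_idx >= 1, s_p[p_idx, np.maximum(cond_idx - 1, 0)], 0.0)
        eta = bases[feat] + eff + slope + b_p[p_idx] + b_i[i_idx]

        if feat == "submovements":
            y = np.maximum(1, rng.poisson(np.exp(eta))).astype(float)
        elif feat == "holdtime_s":
            k = cfg.holdtime_shape
            y = rng.gamma(k, np.exp(eta) / k)
        elif feat == "vertical_amplitude":
            latent = eta + rng.logistic(0.0, 1.0, n)
            y = np.searchsorted(np.asarray(cfg.va_thresholds), latent).astype(float)
        else:
            y = eta + rng.normal(0.0, resid[feat], n)

        # renderability clamps (part of the generated truth)
        if feat == "max_f0_hz":
            y = np.clip(y, 100.0, 480.0)
        elif feat == "max_mouth_opening_mm":
            y = np.clip(y, 10.0, None)
        elif feat == "mean_lip_movement_mm_s":
            y = np.clip(y, 30.0, None)
        elif feat == "peak_velocity_m_s":
            y = np.clip(y, 0.45, None)
        elif feat == "max_distance_m":
            y = np.clip(y, 0.22, 1.2)
        df[feat] = y

    df["peak_lip_velocity_mm_s"] = np.maximum(
        df["peak_lip_velocity_mm_s"], 1.15 * (math.pi / 2) * df["mean_lip_movement_mm_s"]
    )
    for feat in SPEECH_FEATURES:
        df.loc[~has_speech, feat] = np.nan
    for feat in GESTURE_FEATURES:
        df.loc[~has_gesture, feat] = np.nan
    return df


# ---------------------------------------------------------------------------
# full sessions


@dataclass
class SyntheticSession:
    """Rendered tracks + annotation tiers for one participant."""

    participant_id: str
    round_meta: pd.DataFrame  # participant, item, condition, round_onset_ms
    tiers: dict[str, list[TimedEvent]]
    body_track: BodyTrack
    face_track: FaceTrack
    contour: AcousticContour


def _render_session(
    cfg: GeneratorConfig, pid: str, rows: pd.DataFrame, rng: np.random.Generator
) -> tuple[SyntheticSession, pd.DataFrame]:
    fs = cfg.sample_rate_hz
    dt = 1.0 / fs
    speech_events: list[TimedEvent] = []
    gesture_events: list[TimedEvent] = []
    meta_rows = []
    scripts: list[GestureScript] = []
    script_t0: list[float] = []
    lip_plans: list[tuple[dict, list[tuple[float, float]]]] = []
    utt_specs: list[tuple[list[tuple[float, float]], list[float], float, float]] = []
    rendered = rows.copy()

    cursor = 0.5
    for ridx, row in rows.iterrows():
        round_on = cursor
        modality = row["modality"]
        has_g = modality in (GESTURE_ONLY, MULTIMODAL)
        has_s = modality in (SPEECH_ONLY, MULTIMODAL)
        t_first = round_on + 0.3

        g_span = None
        if has_g:
            script = plan_gesture(
                int(row["submovements"]), float(row["holdtime_s"]),
                float(row["peak_velocity_m_s"]), float(row["max_distance_m"]),
                int(row["vertical_amplitude"]), fs,
            )
            scripts.append(script)
            script_t0.append(t_first)
            g_span = (t_first + script.span[0], t_first + script.span[1])
            gesture_events.append(
                TimedEvent(g_span[0] * 1000, g_span[1] * 1000, "gesture", GESTURE)
            )
            rendered.loc[ridx, "holdtime_s"] = script.truth["holdtime_s"]
            rendered.loc[ridx, "max_distance_m"] = script.truth["max_distance_m"]

        utts: list[tuple[float, float]] = []
        if has_s:
            if has_g:
                on = g_span[0] + 0.15
                dur = min(1.2, max(0.4, (g_span[1] - g_span[0]) * 0.6))
            else:
                on = t_first
                dur = float(rng.uniform(0.6, 1.4))
            utts.append((on, on + dur))
            if rng.random() < cfg.second_utterance_prob:
                on2 = on + dur + 0.12  # gap below the 200 ms rule: same attempt
                utts.append((on2, on2 + 0.5))
            for u_on, u_off in utts:
                speech_events.append(
                    TimedEvent(u_on * 1000, u_off * 1000, str(row["item"]), SPEECH)
                )

        ev_end = max(
            [e for e in ([g_span[1]] if g_span else []) + [u[1] for u in utts]]
        )
        span_on = min(([g_span[0]] if g_span else []) + [u[0] for u in utts])

        if has_s:
            rel = [0.0] + [-1.5] * (len(utts) - 1)
            utt_specs.append(
                (list(utts), rel, float(row["max_intensity_db"]), float(row["max_f0_hz"]))
            )
            plan = plan_lip_motion(
                float(row["max_mouth_opening_mm"]),
                float(row["mean_lip_movement_mm_s"]),
                (span_on, ev_end),
                utts,
                float(row["peak_lip_velocity_mm_s"]),
                fs,
            )
            lip_plans.append(plan)
            rendered.loc[ridx, "peak_lip_velocity_mm_s"] = plan["truth"][
                "peak_lip_velocity_mm_s"
            ]
            rendered.loc[ridx, "mean_lip_movement_mm_s"] = plan["truth"][
                "mean_lip_movement_mm_s"
            ]

        # occasional second attempt, separated by > 200 ms: exercised by the
        # first-attempt filter, never part of the ground-truth features
        if rng.random() < cfg.extra_attempt_prob:
            on2 = ev_end + 0.45
            if rng.random() < 0.5 or not has_s:
                mean_db = rows["max_intensity_db"].dropna().mean()
                if not np.isfinite(mean_db):
                    mean_db = 70.0
                speech_events.append(
                    TimedEvent(on2 * 1000, (on2 + 0.5) * 1000, str(row["item"]), SPEECH)
                )
                utt_specs.append(
                    ([(on2, on2 + 0.5)], [0.0], float(mean_db) - 2.0, 220.0)
                )
                ev_end = on2 + 0.5
            else:
                script2 = plan_gesture(1, 0.0, 0.6, 0.3, 1, fs)
                scripts.append(script2)
                script_t0.append(on2 - script2.span[0])
                g2 = (on2, on2 - script2.span[0] + script2.span[1])
                gesture_events.append(
                    TimedEvent(g2[0] * 1000, g2[1] * 1000, "gesture", GESTURE)
                )
                ev_end = g2[1]

        meta_rows.append(
            {
                "participant": pid, "item": row["item"], "condition": row["condition"],
                "round_onset_ms": round_on * 1000,
            }
        )
        cursor = ev_end + 0.6

    duration = cursor + 0.5
    t = np.arange(0.0, duration, dt)

    body_points = {
        name: np.tile(np.asarray(p, dtype=float), (t.size, 1))
        for name, p in REST_POSE.items()
    }
    hand = body_points["hand_r"]
    for t0, script in zip(script_t0, scripts):
        mask = (t >= t0) & (t <= t0 + script.t_end)
        hand[mask] = script.positions(t[mask] - t0)
    if cfg.track_noise_m > 0:
        for name in body_points:
            body_points[name] = body_points[name] + rng.normal(
                0.0, cfg.track_noise_m, body_points[name].shape
            )
    body = BodyTrack(t, body_points)

    face_points = {
        name: np.tile(np.asarray(p, dtype=float), (t.size, 1))
        for name, p in FACE_POSE.items()
    }
    aperture = np.zeros(t.size)
    for plan in lip_plans:
        aperture += _lip_aperture(t, plan)
    for name in ("mouth_lower_inner", "lower_lip_center"):
        face_points[name] = face_points[name].copy()
        face_points[name][:, 1] -= aperture
    if cfg.track_noise_m > 0:
        noise_face = cfg.track_noise_m / 25.0  # face tracking is finer-grained
        for name in face_points:
            face_points[name] = face_points[name] + rng.normal(
                0.0, noise_face, face_points[name].shape
            )
    face = FaceTrack(t, face_points)

    tc = np.arange(0.0, duration, cfg.contour_step_s)
    inten = np.full(tc.size, CONTOUR_FLOOR_DB)
    f0 = np.full(tc.size, np.nan)
    for utts, rels, max_db, max_f0 in utt_specs:
        sub = generate_acoustic_contour(
            max_db, 0.0, max_f0, [(u[0], u[1]) for u in utts],
            duration, None, 0.0, cfg.contour_step_s, rels,
        )
        mask = sub.intensity_db > CONTOUR_FLOOR_DB
        inten[mask] = sub.intensity_db[mask]
        f0[~np.isnan(sub.f0_hz)] = sub.f0_hz[~np.isnan(sub.f0_hz)]
    contour = AcousticContour(tc, inten, f0, cfg.contour_step_s)

    meta = pd.DataFrame(meta_rows)
    session = SyntheticSession(
        pid, meta, {"speech": speech_events, "gesture": gesture_events},
        body, face, contour,
    )
    return session, rendered


def generate_dataset(
    config: GeneratorConfig, render_tracks: bool = True
) -> tuple[list[SyntheticSession], pd.DataFrame]:
    """Synthetic sessions plus the ground-truth feature table.

    The truth table holds the values the extraction pipeline should recover
    (rendering adjustments, e.g. the holdtime floor, are already applied).
    Deterministic given ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed).spawn(3)
    rng_latent = np.random.default_rng(ss[0])
    rng_render = np.random.default_rng(ss[1])
    latent = generate_latent_table(config, rng_latent)
    sessions: list[SyntheticSession] = []
    if not render_tracks:
        return sessions, latent
    rendered_parts = []
    for pid, rows in latent.groupby("participant", sort=True):
        session, rendered = _render_session(config, pid, rows, rng_render)
        sessions.append(session)
        rendered_parts.append(rendered)
    truth = pd.concat(rendered_parts).sort_index()
    return sessions, truth


def write_session(session: SyntheticSession, out_dir, use_eaf: bool = True) -> dict:
    """Write one session in the pipeline's input formats; returns the paths."""
    from pathlib import Path

    from . import eaf as _eaf
    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pid = session.participant_id
    paths = {
        "rounds": out / f"{pid}_rounds.csv",
        "body": out / f"{pid}_body.csv",
        "face": out / f"{pid}_face.csv",
        "contour": out / f"{pid}_contour.csv",
    }
    _io.write_round_csv(paths["rounds"], session.round_meta)
    _io.write_track_csv(paths["body"], session.body_track)
    _io.write_track_csv(paths["face"], session.face_track)
    _io.write_contour_csv(paths["contour"], session.contour)
    if use_eaf:
        paths["tiers"] = out / f"{pid}.eaf"
        _eaf.write_eaf(paths["tiers"], session.tiers)
    else:
        paths["tiers"] = out / f"{pid}_tiers.csv"
        _io.write_tier_csv(paths["tiers"], session.tiers)
    return paths
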