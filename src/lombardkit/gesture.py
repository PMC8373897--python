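"""Gesture kinematic features from body keypoint tracks.

Five features per gesture, aggregated to the communicative attempt:
peak velocity, maximum distance from the starting position, ordinal
vertical amplitude (0-5 bands relative to torso/shoulders/face/head),
holdtime (time spent below a stillness threshold), and the number of
submovements (distinct velocity peaks / supra-threshold segments).

All positions are meters, times seconds. The vertical axis defaults to
y (index 1). Smoothing is a centered 3-frame moving average, sized for
~30 Hz tracker jitter; every threshold is an explicit argument.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .types import BodyTrack, CommunicativeAttempt, GestureFeatures

#: hold/movement stillness threshold (m/s); tracker noise at 30 Hz sits well below
DEFAULT_HOLD_THRESHOLD = 0.15
#: minimum duration (s) for a sub-threshold run to count as a hold
DEFAULT_MIN_HOLD = 0.1
#: minimum velocity-peak prominence (m/s) for counting merged submovements
DEFAULT_PROMINENCE = 0.05

UP_AXIS = 1


@dataclass(frozen=True)
class JointMap:
    """Names of the joints the feature definitions refer to (Kinect-style preset)."""

    hands: tuple[str, ...] = ("hand_l", "hand_r")
    shoulders: tuple[str, str] = ("shoulder_l", "shoulder_r")
    spine_base: str = "spine_base"
    spine_shoulder: str = "spine_shoulder"
    face_mid: str = "face_mid"
    head_top: str = "head_top"


DEFAULT_JOINTS = JointMap()


def moving_average(x: np.ndarray, width: int = 3) -> np.ndarray:
    """Centered moving average; shrinks the window at the edges."""
    if width <= 1 or x.size < 2:
        return x.astype(float, copy=True)
    kernel = np.ones(width)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


def fill_small_gaps(pos: np.ndarray, max_gap: int = 3) -> np.ndarray:
    """Linearly interpolate NaN runs of up to ``max_gap`` frames per coordinate.

    Longer runs are left as NaN; downstream computations split on them.
    """
    pos = np.array(pos, dtype=float)
    n = pos.shape[0]
    for c in range(pos.shape[1]):
        col = pos[:, c]
        isnan = np.isnan(col)
        if not isnan.any() or isnan.all():
            continue
        idx = np.arange(n)
        starts, lengths = _runs(isnan)
        fillable = np.zeros(n, dtype=bool)
        for s, ln in zip(starts, lengths):
            interior = s > 0 and s + ln < n
            if ln <= max_gap and interior:
                fillable[s : s + ln] = True
        col[fillable] = np.interp(idx[fillable], idx[~isnan], col[~isnan])
        pos[:, c] = col
    return pos


def _runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start indices and lengths of runs of True in a boolean mask."""
    if mask.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return starts, ends - starts


def velocity_profile(
    track: BodyTrack,
    hand: str,
    span_s: tuple[float, float],
    smooth_width: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed frame-wise speed (m/s) of one hand within ``span_s``.

    Returns ``(times, speed)``. Raises ``KeyError`` for an unknown hand label
    and ``ValueError`` for spans with fewer than two frames.
    """
    if hand not in track.points:
        raise KeyError(f"unknown hand label {hand!r}; track has {track.names}")
    mask = track.frame_mask(span_s)
    if mask.sum() < 2:
        raise ValueError("velocity profile needs at least two frames in span")
    t = track.times[mask]
    pos = fill_small_gaps(track[hand][mask])
    vel = np.gradient(pos, t, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    speed = np.where(np.isnan(speed), np.nan, speed)
    smoothed = moving_average(np.nan_to_num(speed, nan=0.0), smooth_width)
    smoothed[np.isnan(speed)] = np.nan
    return t, smoothed


def peak_velocity(profiles: list[np.ndarray], threshold: float = DEFAULT_HOLD_THRESHOLD) -> float:
    """Maximum speed over the hands involved in the gesture.

    A hand counts as involved if its speed ever exceeds the movement
    threshold; if no hand does, the plain maximum over all hands is used.
    """
    if not profiles:
        raise ValueError("need at least one hand profile")
    maxima = [float(np.nanmax(p)) for p in profiles]
    moving = [m for m in maxima if m > threshold]
    return max(moving) if moving else max(maxima)


def max_distance(
    track: BodyTrack,
    hand: str,
    span_s: tuple[float, float],
    reference: str = "onset",
    joints: JointMap = DEFAULT_JOINTS,
) -> float:
    """Maximum Euclidean excursion (m) of the hand within the gesture span.

    ``reference="onset"`` measures from the hand's position at gesture onset;
    ``reference="body"`` measures the per-frame distance from the torso center.
    """
    if hand not in track.points:
        raise KeyError(f"unknown hand label {hand!r}; track has {track.names}")
    mask = track.frame_mask(span_s)
    if not mask.any():
        raise ValueError("max_distance needs at least one frame in span")
    pos = fill_small_gaps(track[hand][mask])
    if reference == "onset":
        ref = pos[0]
    elif reference == "body":
        ref = 0.5 * (track[joints.spine_base][mask] + track[joints.spine_shoulder][mask])
    else:
        raise ValueError(f"unknown reference {reference!r}")
    d = np.linalg.norm(pos - ref, axis=1)
    return float(np.nanmax(d))


def vertical_amplitude(
    track: BodyTrack,
    span_s: tuple[float, float],
    joints: JointMap = DEFAULT_JOINTS,
    up_axis: int = UP_AXIS,
) -> int:
    """Highest 0-5 height band reached by either hand during the gesture.

    Bands (per frame, from that frame's landmark heights):
    0 below torso middle; 1 torso middle to upper quarter; 2 within the upper
    quarter; 3 above the shoulders; 4 above the middle of the face; 5 above
    the head.
    """
    mask = track.frame_mask(span_s)
    if not mask.any():
        raise ValueError("vertical_amplitude needs at least one frame in span")
    for name in (joints.spine_base, joints.spine_shoulder, joints.face_mid, joints.head_top, *joints.shoulders):
        if name not in track.points:
            raise KeyError(f"missing reference landmark {name!r}")
    base = track[joints.spine_base][mask][:, up_axis]
    top = track[joints.spine_shoulder][mask][:, up_axis]
    torso_mid = 0.5 * (base + top)
    torso_uq = base + 0.75 * (top - base)
    shoulder = 0.5 * (
        track[joints.shoulders[0]][mask][:, up_axis]
        + track[joints.shoulders[1]][mask][:, up_axis]
    )
    face_mid = track[joints.face_mid][mask][:, up_axis]
    head_top = track[joints.head_top][mask][:, up_axis]

    best = 0
    for hand in joints.hands:
        if hand not in track.points:
            continue
        h = track[hand][mask][:, up_axis]
        band = np.zeros(h.shape, dtype=int)
        band[h >= torso_mid] = 1
        band[h >= torso_uq] = 2
        band[h >= shoulder] = 3
        band[h >= face_mid] = 4
        band[h >= head_top] = 5
        valid = ~np.isnan(h)
        if valid.any():
            best = max(best, int(band[valid].max()))
    return best


def holdtime(
    profiles: list[np.ndarray],
    dt: float,
    threshold: float = DEFAULT_HOLD_THRESHOLD,
    min_hold: float = DEFAULT_MIN_HOLD,
) -> float:
    """Total stillness time (s): sub-threshold runs of at least ``min_hold``.

    All involved hands must be simultaneously still, so the combined speed is
    the maximum over hands. A run of k frames counts as k*dt seconds.
    """
    if not profiles:
        raise ValueError("need at least one hand profile")
    combined = np.nanmax(np.vstack(profiles), axis=0)
    below = combined < threshold
    starts, lengths = _runs(below)
    total = 0.0
    for ln in lengths:
        dur = ln * dt
        if dur >= min_hold:
            total += dur
    return float(total)


def submovements(
    profile: np.ndarray,
    threshold: float = DEFAULT_HOLD_THRESHOLD,
    prominence: float = DEFAULT_PROMINENCE,
) -> int:
    """Count distinct movements: supra-threshold segments, splitting merged
    segments at interior velocity peaks that meet the prominence criterion."""
    above = np.nan_to_num(profile, nan=0.0) > threshold
    starts, lengths = _runs(above)
    count = 0
    for s, ln in zip(starts, lengths):
        seg = profile[s : s + ln]
        peaks, _ = find_peaks(seg, prominence=prominence)
        count += max(1, len(peaks))
    return count


@dataclass
class GestureThresholds:
    """Tunable segmentation constants, surfaced in every report."""

    hold_threshold: float = DEFAULT_HOLD_THRESHOLD
    min_hold: float = DEFAULT_MIN_HOLD
    prominence: float = DEFAULT_PROMINENCE
    smooth_width: int = 3
    distance_reference: str = "onset"


def gesture_unit_features(
    track: BodyTrack,
    span_s: tuple[float, float],
    hands: tuple[str, ...] | None = None,
    joints: JointMap = DEFAULT_JOINTS,
    thresholds: GestureThresholds | None = None,
) -> dict:
    """All five features for one annotated gesture unit."""
    th = thresholds or GestureThresholds()
    hands = hands or joints.hands
    profs = []
    times = None
    for hand in hands:
        t, p = velocity_profile(track, hand, span_s, th.smooth_width)
        profs.append(p)
        times = t
    dt = float(np.median(np.diff(times))) if times.size > 1 else 0.0
    pv = peak_velocity(profs, th.hold_threshold)
    moving = [h for h, p in zip(hands, profs) if np.nanmax(p) > th.hold_threshold]
    dist_hands = moving or list(hands)
    dist = max(
        max_distance(track, h, span_s, th.distance_reference, joints) for h in dist_hands
    )
    amp = vertical_amplitude(track, span_s, joints)
    ht = holdtime(profs, dt, th.hold_threshold, th.min_hold)
    dominant = max(zip(profs, hands), key=lambda pr: np.nanmax(pr[0]))[1]
    dom_prof = profs[list(hands).index(dominant)]
    sm = submovements(dom_prof, th.hold_threshold, th.prominence)
    return {
        "peak_velocity": pv,
        "max_distance": dist,
        "vertical_amplitude": amp,
        "holdtime": ht,
        "submovements": max(1, sm),
        "duration_s": span_s[1] - span_s[0],
    }


def aggregate_attempt(attempt_id: str, per_gesture: list[dict]) -> GestureFeatures:
    """Aggregate per-gesture features to the attempt.

    Extremal features take the maximum across gestures; additive ones
    (holdtime, submovements) are summed, preserving the reading of
    submovements as the amount of segmented visual information per attempt.
    """
    if not per_gesture:
        raise ValueError("gesture features are undefined for attempts without gesture")
    return GestureFeatures(
        attempt_id=attempt_id,
        peak_velocity=max(g["peak_velocity"] for g in per_gesture),
        max_distance=max(g["max_distance"] for g in per_gesture),
        vertical_amplitude=max(g["vertical_amplitude"] for g in per_gesture),
        holdtime=sum(g["holdtime"] for g in per_gesture),
        submovements=sum(g["submovements"] for g in per_gesture),
    )


def attempt_gesture_features(
    track: BodyTrack,
    attempt: CommunicativeAttempt,
    hands: tuple[str, ...] | None = None,
    joints: JointMap = DEFAULT_JOINTS,
    thresholds: GestureThresholds | None = None,
) -> GestureFeatures:
    """Features for every gesture unit in the attempt, aggregated."""
    spans = [(on / 1000.0, off / 1000.0) for on, off in attempt.gesture_intervals_ms]
    if not spans:
        raise ValueError("gesture features are undefined for attempts without gesture")
    per_gesture = [
        gesture_unit_features(track, span, hands, joints, thresholds) for span in spans
    ]
    return aggregate_attempt(attempt.attempt_id, per_gesture)
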