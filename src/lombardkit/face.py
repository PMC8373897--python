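"""Visual-speech features from facial landmark tracks.

Three features per speech-bearing attempt: maximum mouth opening (largest
pairwise distance among inner-mouth landmarks), mean lip movement (path
length of the lower-lip center per second), and peak lip velocity.

Tracks are assumed head-stabilized: global head motion inflates every
feature, so an optional nose-bridge reference subtraction is provided
(off by default; the upstream tracker normally compensates).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .types import CommunicativeAttempt, FaceFeatures, FaceTrack
from .gesture import fill_small_gaps, moving_average


@dataclass(frozen=True)
class LandmarkMap:
    """User-supplied landmark-name map; the inner-mouth set is tracker-specific."""

    inner_mouth: tuple[str, ...] = (
        "mouth_upper_inner",
        "mouth_lower_inner",
        "mouth_corner_l",
        "mouth_corner_r",
    )
    lower_lip_center: str = "lower_lip_center"
    nose_bridge: str = "nose_bridge"


DEFAULT_LANDMARKS = LandmarkMap()


def _positions(
    track: FaceTrack,
    name: str,
    mask: np.ndarray,
    stabilize: bool,
    landmarks: LandmarkMap,
) -> np.ndarray:
    pos = fill_small_gaps(track[name][mask])
    if stabilize:
        ref = fill_small_gaps(track[landmarks.nose_bridge][mask])
        pos = pos - ref
    return pos


def max_mouth_opening(
    track: FaceTrack,
    span_s: tuple[float, float],
    landmarks: LandmarkMap = DEFAULT_LANDMARKS,
    stabilize: bool = False,
) -> float:
    """Max over frames of the max pairwise distance among inner-mouth points (m)."""
    mask = track.frame_mask(span_s)
    if not mask.any():
        raise ValueError("max_mouth_opening needs at least one frame in span")
    names = [n for n in landmarks.inner_mouth if n in track.points]
    if len(names) < 2:
        raise ValueError("need at least two inner-mouth landmarks")
    pts = {n: _positions(track, n, mask, stabilize, landmarks) for n in names}
    best = np.nan
    for a, b in combinations(names, 2):
        d = np.linalg.norm(pts[a] - pts[b], axis=1)
        m = np.nanmax(d) if np.any(~np.isnan(d)) else np.nan
        best = np.nanmax([best, m])
    if np.isnan(best):
        raise ValueError("all inner-mouth landmarks missing across the span")
    return float(best)


def _lower_lip_path(
    track: FaceTrack,
    span_s: tuple[float, float],
    landmarks: LandmarkMap,
    stabilize: bool,
) -> tuple[np.ndarray, np.ndarray]:
    mask = track.frame_mask(span_s)
    if mask.sum() < 2:
        raise ValueError("lip movement features need at least two frames in span")
    t = track.times[mask]
    pos = _positions(track, landmarks.lower_lip_center, mask, stabilize, landmarks)
    return t, pos


def mean_lip_movement(
    track: FaceTrack,
    span_s: tuple[float, float],
    landmarks: LandmarkMap = DEFAULT_LANDMARKS,
    stabilize: bool = False,
) -> float:
    """Lower-lip path length divided by span duration (m/s).

    NaN gaps longer than the interpolation limit split the path; segment
    lengths are summed and divided by the total covered time.
    """
    t, pos = _lower_lip_path(track, span_s, landmarks, stabilize)
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    dts = np.diff(t)
    valid = ~np.isnan(steps)
    covered = dts[valid].sum()
    if covered <= 0:
        raise ValueError("no valid lower-lip frames in span")
    return float(steps[valid].sum() / covered)


def peak_lip_velocity(
    track: FaceTrack,
    span_s: tuple[float, float],
    landmarks: LandmarkMap = DEFAULT_LANDMARKS,
    stabilize: bool = False,
    smooth_width: int = 3,
) -> float:
    """Max of the smoothed frame-to-frame lower-lip speed (m/s)."""
    t, pos = _lower_lip_path(track, span_s, landmarks, stabilize)
    vel = np.gradient(pos, t, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    smoothed = moving_average(np.nan_to_num(speed, nan=0.0), smooth_width)
    smoothed[np.isnan(speed)] = np.nan
    return float(np.nanmax(smoothed))


def attempt_face_features(
    track: FaceTrack,
    attempt: CommunicativeAttempt,
    landmarks: LandmarkMap = DEFAULT_LANDMARKS,
    stabilize: bool = False,
) -> FaceFeatures:
    """All three visual-speech features over the attempt span (speech attempts only)."""
    span = (attempt.onset_ms / 1000.0, attempt.offset_ms / 1000.0)
    return FaceFeatures(
        attempt_id=attempt.attempt_id,
        max_mouth_opening=max_mouth_opening(track, span, landmarks, stabilize),
        mean_lip_movement=mean_lip_movement(track, span, landmarks, stabilize),
        peak_lip_velocity=peak_lip_velocity(track, span, landmarks, stabilize),
    )
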