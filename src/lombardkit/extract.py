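"""Build the per-attempt feature table from tiers, tracks and contours.

One row per analyzed (first) attempt: participant, item, condition,
modality, and the nine features. Speech features are computed only for
attempts containing speech, gesture features only for attempts containing
gesture; the rest stay absent (NaN), mirroring how the features are
defined.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acoustics import attempt_acoustics_for
from .face import DEFAULT_LANDMARKS, LandmarkMap, attempt_face_features
from .gesture import DEFAULT_JOINTS, GestureThresholds, JointMap, attempt_gesture_features
from .types import AcousticContour, BodyTrack, CommunicativeAttempt, FaceTrack

log = logging.getLogger("lombardkit.extract")

FEATURE_COLUMNS = [
    "max_intensity_db", "max_f0_hz",
    "max_mouth_opening_mm", "mean_lip_movement_mm_s", "peak_lip_velocity_mm_s",
    "peak_velocity_m_s", "max_distance_m", "vertical_amplitude",
    "holdtime_s", "submovements",
]


@dataclass
class ExtractionConfig:
    joints: JointMap = field(default_factory=JointMap)
    landmarks: LandmarkMap = field(default_factory=LandmarkMap)
    thresholds: GestureThresholds = field(default_factory=GestureThresholds)
    stabilize_face: bool = False


def attempt_features(
    attempt: CommunicativeAttempt,
    body: BodyTrack | None,
    face: FaceTrack | None,
    contour: AcousticContour | None,
    config: ExtractionConfig | None = None,
) -> dict:
    """Feature dict for one attempt; missing inputs leave features absent."""
    cfg = config or ExtractionConfig()
    row: dict = {
        "attempt_id": attempt.attempt_id,
        "participant": attempt.participant_id,
        "item": attempt.item,
        "condition": attempt.condition,
        "modality": attempt.modality,
        "flags": ";".join(attempt.flags),
    }
    for col in FEATURE_COLUMNS:
        row[col] = np.nan
    has_speech = bool(attempt.speech_intervals_ms)
    has_gesture = bool(attempt.gesture_intervals_ms)
    if has_speech and contour is not None:
        ac = attempt_acoustics_for(contour, attempt)
        row["max_intensity_db"] = ac.max_intensity_db
        row["max_f0_hz"] = ac.max_f0_hz if ac.max_f0_hz is not None else np.nan
    if has_speech and face is not None:
        ff = attempt_face_features(face, attempt, cfg.landmarks, cfg.stabilize_face)
        row["max_mouth_opening_mm"] = ff.max_mouth_opening * 1000.0
        row["mean_lip_movement_mm_s"] = ff.mean_lip_movement * 1000.0
        row["peak_lip_velocity_mm_s"] = ff.peak_lip_velocity * 1000.0
    if has_gesture and body is not None:
        gf = attempt_gesture_features(
            body, attempt, cfg.joints.hands, cfg.joints, cfg.thresholds
        )
        row["peak_velocity_m_s"] = gf.peak_velocity
        row["max_distance_m"] = gf.max_distance
        row["vertical_amplitude"] = float(gf.vertical_amplitude)
        row["holdtime_s"] = gf.holdtime
        row["submovements"] = float(gf.submovements)
    return row


def feature_table(
    attempts: list[CommunicativeAttempt],
    body: BodyTrack | None,
    face: FaceTrack | None,
    contour: AcousticContour | None,
    config: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """Feature table for one participant's analyzed attempts."""
    rows = []
    for a in attempts:
        try:
            rows.append(attempt_features(a, body, face, contour, config))
        except Exception as exc:  # noqa: BLE001 - log and drop the attempt
            log.warning("attempt %s dropped during extraction: %s", a.attempt_id, exc)
    return pd.DataFrame(rows)
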