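"""Core data containers shared across the package.

Time conventions: annotation tiers use milliseconds with half-open
[onset, offset) intervals; signal tracks and contours use seconds.
Positions are in meters unless a name says otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

SPEECH = "speech_utterance"
GESTURE = "gesture"
EVENT_KINDS = (SPEECH, GESTURE)

SPEECH_ONLY = "speech_only"
GESTURE_ONLY = "gesture_only"
MULTIMODAL = "multimodal"
MODALITIES = (SPEECH_ONLY, GESTURE_ONLY, MULTIMODAL)


@dataclass(frozen=True)
class TimedEvent:
    """One annotated behavior: a speech utterance or a gesture unit."""

    onset_ms: float
    offset_ms: float
    label: str
    kind: str

    def __post_init__(self) -> None:
        if not (self.offset_ms > self.onset_ms >= 0):
            raise ValueError(
                f"event needs offset > onset >= 0, got [{self.onset_ms}, {self.offset_ms})"
            )
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")

    def overlaps(self, other: "TimedEvent") -> bool:
        """Strict temporal overlap (> 0 ms shared time; abutment is not overlap)."""
        return self.onset_ms < other.offset_ms and other.onset_ms < self.offset_ms


@dataclass
class CommunicativeAttempt:
    """A segmented communicative attempt: the unit of all downstream analysis.

    An attempt groups speech utterances and gestures separated from any other
    communicative behavior by at least the segmentation gap (200 ms default).
    """

    attempt_id: str
    participant_id: str
    item: str
    condition: str
    modality: str
    events: list[TimedEvent]
    attempt_index: int
    span: tuple[float, float]
    flags: list[str] = field(default_factory=list)

    @property
    def onset_ms(self) -> float:
        return self.span[0]

    @property
    def offset_ms(self) -> float:
        return self.span[1]

    def events_of_kind(self, kind: str) -> list[TimedEvent]:
        return [e for e in self.events if e.kind == kind]

    @property
    def speech_intervals_ms(self) -> list[tuple[float, float]]:
        return [(e.onset_ms, e.offset_ms) for e in self.events_of_kind(SPEECH)]

    @property
    def gesture_intervals_ms(self) -> list[tuple[float, float]]:
        return [(e.onset_ms, e.offset_ms) for e in self.events_of_kind(GESTURE)]


@dataclass
class Round:
    """One experimental round: a participant communicating one item in one condition."""

    participant_id: str
    item: str
    condition: str
    onset_ms: float
    attempts: list[CommunicativeAttempt] = field(default_factory=list)
    success: Optional[bool] = None


class _PointTrack:
    """Time-indexed 3-D positions for a fixed set of named points."""

    def __init__(self, times: np.ndarray, points: dict[str, np.ndarray]):
        times = np.asarray(times, dtype=float)
        if times.ndim != 1 or times.size == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        self.times = times
        self.points: dict[str, np.ndarray] = {}
        for name, pos in points.items():
            pos = np.asarray(pos, dtype=float)
            if pos.shape != (times.size, 3):
                raise ValueError(
                    f"point {name!r} has shape {pos.shape}, expected {(times.size, 3)}"
                )
            self.points[name] = pos

    @property
    def names(self) -> list[str]:
        return list(self.points)

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])

    def frame_mask(self, span_s: tuple[float, float]) -> np.ndarray:
        """Boolean mask of frames whose timestamps fall in [onset, offset)."""
        on, off = span_s
        return (self.times >= on) & (self.times < off)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]


class BodyTrack(_PointTrack):
    """Whole-body keypoint track (hands, shoulders, torso, head landmarks)."""


class FaceTrack(_PointTrack):
    """Facial landmark track (inner-mouth ring, lower-lip center, nose bridge)."""


@dataclass
class AcousticContour:
    """Frame-wise intensity (dB) and F0 (Hz, NaN where unvoiced) contour."""

    times: np.ndarray
    intensity_db: np.ndarray
    f0_hz: np.ndarray
    frame_step_s: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity_db = np.asarray(self.intensity_db, dtype=float)
        self.f0_hz = np.asarray(self.f0_hz, dtype=float)
        n = self.times.size
        if self.intensity_db.shape != (n,) or self.f0_hz.shape != (n,):
            raise ValueError("contour arrays must share one length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("contour times must be strictly increasing")
        if not np.all(np.isfinite(self.intensity_db)):
            raise ValueError("intensity must be finite (clamp the silence floor)")

    def frame_mask(self, span_s: tuple[float, float]) -> np.ndarray:
        on, off = span_s
        return (self.times >= on) & (self.times < off)


@dataclass
class AttemptAcoustics:
    """Per-attempt speech acoustics, maxima over utterance intervals only."""

    attempt_id: str
    max_intensity_db: float
    max_f0_hz: Optional[float]


@dataclass
class FaceFeatures:
    """Per-attempt visual-speech features (meters / meters-per-second)."""

    attempt_id: str
    max_mouth_opening: float
    mean_lip_movement: float
    peak_lip_velocity: float


@dataclass
class GestureFeatures:
    """Per-attempt gesture kinematics, aggregated over the attempt's gestures."""

    attempt_id: str
    peak_velocity: float
    max_distance: float
    vertical_amplitude: int
    holdtime: float
    submovements: int

    def __post_init__(self) -> None:
        if not (0 <= int(self.vertical_amplitude) <= 5):
            raise ValueError("vertical_amplitude must be an ordinal in 0..5")
        if self.submovements < 1:
            raise ValueError("an annotated gesture has at least one submovement")
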