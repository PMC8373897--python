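"""Speech acoustics: intensity and F0 contours, reduced to per-attempt maxima.

Intensity is windowed RMS energy in dB re. digital full scale (the analysis
runs on within-subject contrasts, so the absolute reference cancels; SPL
calibration is out of scope). F0 comes from normalized autocorrelation peak
picking with a voicing threshold, searched in a configurable range.

Per-attempt maxima are taken over the union of annotated utterance
intervals only, never over the whole attempt span, so non-speech sound
between utterances cannot leak into the features.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import AcousticContour, AttemptAcoustics, CommunicativeAttempt

DB_FLOOR = -100.0


@dataclass(frozen=True)
class AcousticSettings:
    """Analysis settings, PRAAT-like defaults; all configurable."""

    frame_len_s: float = 0.040
    step_s: float = 0.010
    f0_min_hz: float = 75.0
    f0_max_hz: float = 500.0
    voicing_threshold: float = 0.45


DEFAULT_ACOUSTICS = AcousticSettings()


def _frame_starts(n: int, rate: float, frame_len_s: float, step_s: float) -> np.ndarray:
    frame = int(round(frame_len_s * rate))
    step = int(round(step_s * rate))
    if frame <= 0 or step <= 0:
        raise ValueError("frame_len and step must be positive")
    if n < frame:
        return np.array([0]) if n > 0 else np.array([], dtype=int)
    return np.arange(0, n - frame + 1, step)


def intensity_contour(
    audio: np.ndarray,
    rate: float,
    frame_len_s: float = DEFAULT_ACOUSTICS.frame_len_s,
    step_s: float = DEFAULT_ACOUSTICS.step_s,
) -> AcousticContour:
    """Windowed (Hanning) RMS energy in dB re. full scale, floor-clamped."""
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1 or audio.size == 0:
        raise ValueError("audio must be a non-empty mono array")
    if rate <= 0:
        raise ValueError("rate must be positive")
    if frame_len_s < step_s:
        raise ValueError("need frame_len >= step")
    frame = min(int(round(frame_len_s * rate)), audio.size)
    starts = _frame_starts(audio.size, rate, frame / rate, step_s)
    window = np.hanning(frame) if frame > 1 else np.ones(1)
    wsum = window.sum()
    times = (starts + frame / 2) / rate
    db = np.empty(starts.size)
    for i, s in enumerate(starts):
        seg = audio[s : s + frame]
        rms = np.sqrt(np.sum(window * seg * seg) / wsum)
        db[i] = 20.0 * np.log10(rms) if rms > 0 else DB_FLOOR
    db = np.maximum(db, DB_FLOOR)
    return AcousticContour(times, db, np.full(times.size, np.nan), step_s)


def f0_contour(
    audio: np.ndarray,
    rate: float,
    f0_min_hz: float = DEFAULT_ACOUSTICS.f0_min_hz,
    f0_max_hz: float = DEFAULT_ACOUSTICS.f0_max_hz,
    step_s: float = DEFAULT_ACOUSTICS.step_s,
    voicing_threshold: float = DEFAULT_ACOUSTICS.voicing_threshold,
) -> AcousticContour:
    """Autocorrelation pitch contour; unvoiced frames are NaN.

    A frame is voiced when the normalized autocorrelation peak within the
    candidate lag range reaches the voicing threshold. The peak lag gets
    parabolic interpolation for sub-sample precision.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1 or audio.size == 0:
        raise ValueError("audio must be a non-empty mono array")
    if not (0 < f0_min_hz < f0_max_hz):
        raise ValueError("need 0 < f0_min < f0_max")
    if rate < 4 * f0_max_hz:
        raise ValueError("sample rate must be at least 4x f0_max")
    # window long enough for ~3 periods of the lowest candidate
    frame_len_s = 3.0 / f0_min_hz
    frame = min(int(round(frame_len_s * rate)), audio.size)
    starts = _frame_starts(audio.size, rate, frame / rate, step_s)
    window = np.hanning(frame) if frame > 1 else np.ones(1)
    lag_min = max(2, int(np.floor(rate / f0_max_hz)))
    lag_max = min(frame - 2, int(np.ceil(rate / f0_min_hz)))
    times = (starts + frame / 2) / rate
    f0 = np.full(starts.size, np.nan)
    nfft = int(2 ** np.ceil(np.log2(2 * frame)))
    for i, s in enumerate(starts):
        seg = audio[s : s + frame]
        seg = (seg - seg.mean()) * window
        power = np.abs(np.fft.rfft(seg, nfft)) ** 2
        ac = np.fft.irfft(power)[: frame]
        if ac[0] <= 0 or lag_max <= lag_min:
            continue
        r = ac / ac[0]
        band = r[lag_min : lag_max + 1]
        k = int(np.argmax(band)) + lag_min
        if r[k] < voicing_threshold:
            continue
        # parabolic interpolation around the peak lag
        if 1 <= k < frame - 1:
            y0, y1, y2 = r[k - 1], r[k], r[k + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        cand = rate / (k + delta)
        if f0_min_hz <= cand <= f0_max_hz:
            f0[i] = cand
    return AcousticContour(times, np.full(times.size, DB_FLOOR), f0, step_s)


def analyze_audio(
    audio: np.ndarray, rate: float, settings: AcousticSettings = DEFAULT_ACOUSTICS
) -> AcousticContour:
    """Intensity and F0 on one shared frame grid."""
    inten = intensity_contour(audio, rate, settings.frame_len_s, settings.step_s)
    pitch = f0_contour(
        audio, rate, settings.f0_min_hz, settings.f0_max_hz, settings.step_s,
        settings.voicing_threshold,
    )
    f0 = np.interp(inten.times, pitch.times, pitch.f0_hz, left=np.nan, right=np.nan)
    # interpolation across voiced/unvoiced boundaries must stay unvoiced
    voiced = ~np.isnan(pitch.f0_hz)
    nearest = np.interp(inten.times, pitch.times, voiced.astype(float), left=0, right=0)
    f0[nearest < 0.999] = np.nan
    return AcousticContour(inten.times, inten.intensity_db, f0, settings.step_s)


def attempt_acoustics(
    contour: AcousticContour,
    utterance_intervals_s: list[tuple[float, float]],
    attempt_id: str = "",
) -> AttemptAcoustics:
    """Maxima over the union of utterance intervals; frames outside are ignored."""
    if not utterance_intervals_s:
        raise ValueError("speech features are only defined for attempts with speech")
    mask = np.zeros(contour.times.size, dtype=bool)
    for on, off in utterance_intervals_s:
        if off <= on:
            raise ValueError(f"bad utterance interval [{on}, {off})")
        mask |= contour.frame_mask((on, off))
    if not mask.any():
        raise ValueError("no contour frames inside the utterance intervals")
    max_db = float(np.max(contour.intensity_db[mask]))
    f0_vals = contour.f0_hz[mask]
    voiced = f0_vals[~np.isnan(f0_vals)]
    max_f0 = float(voiced.max()) if voiced.size else None
    return AttemptAcoustics(attempt_id, max_db, max_f0)


def attempt_acoustics_for(
    contour: AcousticContour, attempt: CommunicativeAttempt
) -> AttemptAcoustics:
    intervals = [(on / 1000.0, off / 1000.0) for on, off in attempt.speech_intervals_ms]
    return attempt_acoustics(contour, intervals, attempt.attempt_id)
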