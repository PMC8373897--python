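"""Readers and writers for the package's plain-text interchange formats.

Formats:
- tier CSV: columns ``tier,onset_ms,offset_ms,label`` (tier names map to
  event kinds via a configurable tier map);
- round metadata CSV: ``participant,item,condition,round_onset_ms``;
- track CSV: ``time_s`` plus ``<point>_x,<point>_y,<point>_z`` per landmark
  (JSON variant mirrors the same structure);
- contour CSV: ``time_s,intensity_db,f0_hz`` with empty f0 = unvoiced;
- WAV via scipy (mono, normalized to full scale for integer encodings).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .types import AcousticContour, BodyTrack, FaceTrack, TimedEvent, SPEECH, GESTURE

#: default mapping from annotation tier name to event kind
DEFAULT_TIER_MAP = {"speech": SPEECH, "gesture": GESTURE}

TIER_COLUMNS = ["tier", "onset_ms", "offset_ms", "label"]
ROUND_COLUMNS = ["participant", "item", "condition", "round_onset_ms"]


def write_tier_csv(path: str | Path, events: dict[str, list[TimedEvent]]) -> None:
    """Write events grouped by tier name."""
    rows = []
    for tier, evs in events.items():
        for e in evs:
            rows.append({"tier": tier, "onset_ms": e.onset_ms, "offset_ms": e.offset_ms, "label": e.label})
    pd.DataFrame(rows, columns=TIER_COLUMNS).to_csv(path, index=False)


def read_tier_csv(
    path: str | Path, tier_map: dict[str, str] | None = None
) -> list[TimedEvent]:
    """Read a tier CSV into typed, time-ordered events."""
    tier_map = tier_map or DEFAULT_TIER_MAP
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ValueError(f"malformed tier CSV {path}: {exc}") from exc
    missing = [c for c in TIER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tier CSV {path} lacks columns {missing}")
    events = []
    for i, row in df.iterrows():
        tier = str(row["tier"])
        if tier not in tier_map:
            continue
        try:
            events.append(
                TimedEvent(
                    float(row["onset_ms"]), float(row["offset_ms"]),
                    str(row["label"]), tier_map[tier],
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"tier CSV {path}, tier {tier!r}, row {i + 2}: {exc}") from exc
    events.sort(key=lambda e: (e.onset_ms, e.offset_ms))
    return events


def write_round_csv(path: str | Path, rounds: pd.DataFrame) -> None:
    rounds.loc[:, ROUND_COLUMNS].to_csv(path, index=False)


def read_round_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ROUND_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"round CSV {path} lacks columns {missing}")
    return df[ROUND_COLUMNS].astype(
        {"participant": str, "item": str, "condition": str, "round_onset_ms": float}
    )


def _track_frame(track) -> pd.DataFrame:
    data = {"time_s": track.times}
    for name, pos in track.points.items():
        for j, ax in enumerate("xyz"):
            data[f"{name}_{ax}"] = pos[:, j]
    return pd.DataFrame(data)


def write_track_csv(path: str | Path, track) -> None:
    _track_frame(track).to_csv(path, index=False)


def write_track_json(path: str | Path, track) -> None:
    payload = {
        "time_s": track.times.tolist(),
        "points": {name: pos.tolist() for name, pos in track.points.items()},
    }
    Path(path).write_text(json.dumps(payload))


def _parse_track_frame(df: pd.DataFrame, cls):
    if "time_s" not in df.columns:
        raise ValueError("track table lacks time_s column")
    names = sorted({c[:-2] for c in df.columns if c.endswith(("_x", "_y", "_z"))})
    points = {}
    for name in names:
        cols = [f"{name}_{ax}" for ax in "xyz"]
        if not all(c in df.columns for c in cols):
            raise ValueError(f"track point {name!r} is missing a coordinate column")
        points[name] = df[cols].to_numpy(dtype=float)
    return cls(df["time_s"].to_numpy(dtype=float), points)


def read_body_track(path: str | Path) -> BodyTrack:
    return _read_track(path, BodyTrack)


def read_face_track(path: str | Path) -> FaceTrack:
    return _read_track(path, FaceTrack)


def _read_track(path: str | Path, cls):
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        points = {n: np.asarray(p, dtype=float) for n, p in payload["points"].items()}
        return cls(np.asarray(payload["time_s"], dtype=float), points)
    return _parse_track_frame(pd.read_csv(path), cls)


def write_contour_csv(path: str | Path, contour: AcousticContour) -> None:
    df = pd.DataFrame(
        {
            "time_s": contour.times,
            "intensity_db": contour.intensity_db,
            "f0_hz": contour.f0_hz,
        }
    )
    df.to_csv(path, index=False, na_rep="")


def read_contour_csv(path: str | Path) -> AcousticContour:
    df = pd.read_csv(path)
    for col in ("time_s", "intensity_db", "f0_hz"):
        if col not in df.columns:
            raise ValueError(f"contour CSV {path} lacks column {col}")
    t = df["time_s"].to_numpy(dtype=float)
    step = float(np.median(np.diff(t))) if t.size > 1 else 0.01
    return AcousticContour(
        t,
        df["intensity_db"].to_numpy(dtype=float),
        df["f0_hz"].to_numpy(dtype=float),
        step,
    )


def read_wav(path: str | Path) -> tuple[float, np.ndarray]:
    """Mono audio normalized to [-1, 1] full scale."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return float(rate), data


def write_wav(path: str | Path, rate: float, audio: np.ndarray) -> None:
    wavfile.write(path, int(rate), np.asarray(audio, dtype=np.float32))
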