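"""Segmenting communicative attempts from annotation tiers.

A communicative attempt is a spoken utterance, a gesture, or a multimodal
(speech + gesture) unit separated by at least 200 ms from any other
communicative behavior. Consecutive behaviors belong to the same attempt
iff their gap is below the threshold or they overlap. Intervals are
half-open [onset, offset) in milliseconds, so abutment is unambiguous.

Only the first attempt per round enters the analysis; later attempts
reflect an evolving communicative strategy rather than the initial
response to the noise condition.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import eaf as _eaf
from . import io as _io
from .types import (
    GESTURE,
    GESTURE_ONLY,
    MODALITIES,
    MULTIMODAL,
    SPEECH,
    SPEECH_ONLY,
    CommunicativeAttempt,
    Round,
    TimedEvent,
)

log = logging.getLogger("lombardkit.annotations")

DEFAULT_GAP_MS = 200.0


def parse_tiers(
    source: str | Path, tier_map: dict[str, str] | None = None
) -> list[TimedEvent]:
    """Read events from an EAF or tier-CSV file, typed and time-ordered.

    Overlapping identical events (same tier, same interval) trigger a
    validation warning but are kept.
    """
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(source)
    if source.suffix.lower() == ".eaf":
        tiers = _eaf.read_eaf(source, tier_map)
        events = [e for evs in tiers.values() for e in evs]
        events.sort(key=lambda e: (e.onset_ms, e.offset_ms))
    else:
        events = _io.read_tier_csv(source, tier_map)
    seen = set()
    for e in events:
        key = (e.kind, e.onset_ms, e.offset_ms, e.label)
        if key in seen:
            log.warning("duplicate event %s", key)
        seen.add(key)
    return events


def segment_attempts(
    events: list[TimedEvent], gap_ms: float = DEFAULT_GAP_MS
) -> list[CommunicativeAttempt]:
    """Group time-ordered events into attempts using the separation rule.

    Two consecutive behaviors share an attempt iff their gap is < ``gap_ms``
    or they overlap. Attempt metadata (participant, item, condition) is left
    empty for the caller to fill; modality is classified immediately.
    """
    ordered = sorted(events, key=lambda e: (e.onset_ms, e.offset_ms))
    clusters: list[list[TimedEvent]] = []
    cur: list[TimedEvent] = []
    cur_end = -np.inf
    for e in ordered:
        if cur and e.onset_ms - cur_end < gap_ms:
            cur.append(e)
            cur_end = max(cur_end, e.offset_ms)
        else:
            if cur:
                clusters.append(cur)
            cur = [e]
            cur_end = e.offset_ms
    if cur:
        clusters.append(cur)
    attempts = []
    for idx, members in enumerate(clusters, start=1):
        span = (min(e.onset_ms for e in members), max(e.offset_ms for e in members))
        attempt = CommunicativeAttempt(
            attempt_id="", participant_id="", item="", condition="",
            modality="", events=members, attempt_index=idx, span=span,
        )
        attempt.modality = classify_modality(attempt)
        attempts.append(attempt)
    return attempts


def classify_modality(attempt: CommunicativeAttempt) -> str:
    """Speech-only, gesture-only, or multimodal (strict temporal overlap).

    An attempt containing both kinds with zero overlap (abutting within the
    gap threshold) is a boundary case the annotation scheme does not define:
    it is labeled by the kind with the larger total duration and flagged
    ``mixed_no_overlap`` so downstream reports can surface it.
    """
    if not attempt.events:
        raise ValueError("attempt has no events")
    speech = attempt.events_of_kind(SPEECH)
    gestures = attempt.events_of_kind(GESTURE)
    if speech and gestures:
        if any(s.overlaps(g) for s in speech for g in gestures):
            return MULTIMODAL
        if "mixed_no_overlap" not in attempt.flags:
            attempt.flags.append("mixed_no_overlap")
        sdur = sum(s.offset_ms - s.onset_ms for s in speech)
        gdur = sum(g.offset_ms - g.onset_ms for g in gestures)
        return SPEECH_ONLY if sdur >= gdur else GESTURE_ONLY
    return SPEECH_ONLY if speech else GESTURE_ONLY


def build_rounds(
    events: list[TimedEvent],
    round_meta: pd.DataFrame,
    gap_ms: float = DEFAULT_GAP_MS,
) -> list[Round]:
    """Bucket events into rounds by onset time, then segment each round.

    ``round_meta`` columns: participant, item, condition, round_onset_ms
    (one session = one participant; rounds partition the timeline from each
    round onset to the next).
    """
    meta = round_meta.sort_values("round_onset_ms").reset_index(drop=True)
    onsets = meta["round_onset_ms"].to_numpy(dtype=float)
    bounds = np.append(onsets, np.inf)
    rounds = []
    for i, row in meta.iterrows():
        lo, hi = bounds[i], bounds[i + 1]
        members = [e for e in events if lo <= e.onset_ms < hi]
        r = Round(
            participant_id=str(row["participant"]), item=str(row["item"]),
            condition=str(row["condition"]), onset_ms=float(row["round_onset_ms"]),
        )
        for a in segment_attempts(members, gap_ms):
            a.participant_id = r.participant_id
            a.item = r.item
            a.condition = r.condition
            a.attempt_id = f"{r.participant_id}:{r.item}:{a.attempt_index}"
            r.attempts.append(a)
        rounds.append(r)
    return rounds


def first_attempts(rounds: list[Round]) -> list[CommunicativeAttempt]:
    """The earliest attempt of each round; onset ties break on earlier offset,
    then on segmentation order. Empty rounds are dropped with a log entry."""
    selected = []
    for r in rounds:
        if not r.attempts:
            log.info(
                "round %s/%s (%s) has no attempts; dropped",
                r.participant_id, r.item, r.condition,
            )
            continue
        best = min(
            enumerate(r.attempts),
            key=lambda pair: (pair[1].onset_ms, pair[1].offset_ms, pair[0]),
        )[1]
        selected.append(best)
    return selected


def modality_table(
    attempts: list[CommunicativeAttempt],
    conditions: list[str] | None = None,
) -> pd.DataFrame:
    """Counts and row percentages (one decimal) per condition x modality.

    Returns a DataFrame indexed by condition with count columns, percentage
    columns (``<modality>_pct``), and a ``total`` column.
    """
    if conditions is None:
        conditions = sorted({a.condition for a in attempts})
    counts = pd.DataFrame(0, index=list(conditions), columns=list(MODALITIES), dtype=int)
    for a in attempts:
        if a.condition in counts.index and a.modality in counts.columns:
            counts.loc[a.condition, a.modality] += 1
    out = counts.copy()
    out["total"] = counts.sum(axis=1)
    for m in MODALITIES:
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * counts[m] / out["total"].replace(0, np.nan)
        out[f"{m}_pct"] = pct.round(1).fillna(0.0)
    return out
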