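"""Segment communicative attempts from annotation tiers.

Speech utterances and gestures separated by less than 200 ms (or
overlapping) form one communicative attempt; only the first attempt per
round enters the analysis. This script builds a tiny tier set by hand and
shows how the segmentation and modality classification behave.
"""
from lombardkit.annotations import first_attempts, segment_attempts, build_rounds
from lombardkit.types import GESTURE, SPEECH, TimedEvent

import pandas as pd

events = [
    TimedEvent(0, 900, "hammer", SPEECH),        # utterance
    TimedEvent(700, 2100, "gesture", GESTURE),   # overlaps -> multimodal
    TimedEvent(2600, 3400, "hammer", SPEECH),    # 500 ms later -> attempt 2
    TimedEvent(3550, 4200, "gesture", GESTURE),  # 150 ms gap -> same attempt
]

attempts = segment_attempts(events)
for a in attempts:
    print(f"attempt {a.attempt_index}: span={a.span}, modality={a.modality}, "
          f"{len(a.events)} events, flags={a.flags}")

meta = pd.DataFrame([{"participant": "p01", "item": "hammer",
                      "condition": "babble8", "round_onset_ms": 0.0}])
rounds = build_rounds(events, meta)
first = first_attempts(rounds)
print(f"\nfirst attempt retained: {first[0].attempt_id} ({first[0].modality})")
# Attempt 1 is multimodal (speech and gesture overlap); attempt 2 contains
# abutting speech+gesture within 200 ms and is flagged as a boundary case.
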