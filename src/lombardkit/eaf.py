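"""Minimal ELAN EAF (XML) reading and writing.

Covers the subset the pipeline needs: time-aligned annotations on named
tiers. Tier names map to event kinds through the same tier map the CSV
reader uses. Written files round-trip losslessly through :func:`read_eaf`
at millisecond resolution.
"""
from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

from .io import DEFAULT_TIER_MAP
from .types import TimedEvent


def write_eaf(path: str | Path, tiers: dict[str, list[TimedEvent]], author: str = "lombardkit") -> None:
    root = ET.Element(
        "ANNOTATION_DOCUMENT",
        {"AUTHOR": author, "DATE": "1970-01-01T00:00:00+00:00", "FORMAT": "3.0", "VERSION": "3.0"},
    )
    ET.SubElement(root, "HEADER", {"MEDIA_FILE": "", "TIME_UNITS": "milliseconds"})
    time_order = ET.SubElement(root, "TIME_ORDER")
    slots: dict[int, str] = {}

    def slot(ms: float) -> str:
        key = int(round(ms))
        if key not in slots:
            slots[key] = f"ts{len(slots) + 1}"
            ET.SubElement(
                time_order, "TIME_SLOT", {"TIME_SLOT_ID": slots[key], "TIME_VALUE": str(key)}
            )
        return slots[key]

    ann_id = 0
    for tier_name, events in tiers.items():
        tier = ET.SubElement(
            root, "TIER", {"TIER_ID": tier_name, "LINGUISTIC_TYPE_REF": "default-lt"}
        )
        for e in sorted(events, key=lambda ev: (ev.onset_ms, ev.offset_ms)):
            ann_id += 1
            ann = ET.SubElement(tier, "ANNOTATION")
            al = ET.SubElement(
                ann,
                "ALIGNABLE_ANNOTATION",
                {
                    "ANNOTATION_ID": f"a{ann_id}",
                    "TIME_SLOT_REF1": slot(e.onset_ms),
                    "TIME_SLOT_REF2": slot(e.offset_ms),
                },
            )
            ET.SubElement(al, "ANNOTATION_VALUE").text = e.label
    ET.SubElement(
        root, "LINGUISTIC_TYPE",
        {"LINGUISTIC_TYPE_ID": "default-lt", "TIME_ALIGNABLE": "true"},
    )
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def read_eaf(
    path: str | Path, tier_map: dict[str, str] | None = None
) -> dict[str, list[TimedEvent]]:
    """Parse time-aligned tiers; returns only tiers present in the tier map."""
    tier_map = tier_map or DEFAULT_TIER_MAP
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed EAF {path}: {exc}") from exc
    times: dict[str, float] = {}
    for ts in root.iter("TIME_SLOT"):
        val = ts.get("TIME_VALUE")
        if val is not None:
            times[ts.get("TIME_SLOT_ID")] = float(val)
    out: dict[str, list[TimedEvent]] = {}
    for tier in root.iter("TIER"):
        name = tier.get("TIER_ID")
        if name not in tier_map:
            continue
        events = []
        for ann in tier.iter("ALIGNABLE_ANNOTATION"):
            ref1, ref2 = ann.get("TIME_SLOT_REF1"), ann.get("TIME_SLOT_REF2")
            if ref1 not in times or ref2 not in times:
                raise ValueError(
                    f"malformed EAF {path}: tier {name!r} annotation "
                    f"{ann.get('ANNOTATION_ID')} references an unvalued time slot"
                )
            label_el = ann.find("ANNOTATION_VALUE")
            label = label_el.text if label_el is not None and label_el.text else ""
            events.append(TimedEvent(times[ref1], times[ref2], label, tier_map[name]))
        events.sort(key=lambda e: (e.onset_ms, e.offset_ms))
        out[name] = events
    return out
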