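"""The "ear flicker" facial movement index.

An ear flicker is an *ears forward* (EAD101) and an *ear rotator* (EAD104)
occurring within one second of each other; the pair is counted as a single
composite movement so that the two constituents are never double-counted.
Proximity is measured onset-to-onset, because onsets are the coders' most
reliable timestamps.

Pairing is greedy over the onset-sorted stream: each unconsumed ear event is
paired with the earliest subsequent opposite-code ear event whose onset lies
within the window; both constituents are consumed. Either order (101 then
104, or 104 then 101) qualifies. The greedy rule is deterministic and
guarantees that no residual EAD101 onset lies within the window of any
residual EAD104 onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .events_io import AnnotationEvent
from .vocabulary import EAR_FORWARD, EAR_ROTATOR, FLICKER

EAR_CODES = (EAR_FORWARD, EAR_ROTATOR)


@dataclass(frozen=True)
class EarFlickerEvent:
    """A composite ear-flicker occurrence.

    ``onset`` is the earlier constituent's onset and ``offset`` the later
    constituent's offset; ``constituents`` holds the consumed EAD101/EAD104
    events in onset order.
    """

    video_id: str
    onset: float
    offset: float
    constituents: tuple[AnnotationEvent, AnnotationEvent]


def build_ear_flicker(
    events: Sequence[AnnotationEvent], window: float = 1.0
) -> tuple[list[EarFlickerEvent], list[AnnotationEvent]]:
    """Pair EAD101/EAD104 events of one video into ear flickers.

    Returns ``(flickers, residual)`` where ``residual`` contains every
    unconsumed event (non-ear codes pass through untouched). Each original
    event appears exactly once in ``residual`` plus the flicker
    constituents.
    """
    videos = {e.video_id for e in events}
    if len(videos) > 1:
        raise ValueError("build_ear_flicker expects events from a single video")
    order = sorted(
        (i for i, e in enumerate(events) if e.code in EAR_CODES),
        key=lambda i: (events[i].onset, i),
    )
    consumed: set[int] = set()
    flickers: list[EarFlickerEvent] = []
    for pos, i in enumerate(order):
        if i in consumed:
            continue
        a = events[i]
        for j in order[pos + 1:]:
            if j in consumed:
                continue
            b = events[j]
            if b.onset - a.onset > window:
                break
            if b.code != a.code:
                consumed.update((i, j))
                flickers.append(
                    EarFlickerEvent(a.video_id, a.onset, b.offset, (a, b))
                )
                break
    residual = [e for k, e in enumerate(events) if k not in consumed]
    return flickers, residual


def apply_fmi(
    events: Sequence[AnnotationEvent], window: float = 1.0
) -> list[AnnotationEvent]:
    """Replace paired EAD101/EAD104 occurrences by ``FMI_EAR_FLICKER`` events.

    Works across videos; the output is onset-sorted per video and contains
    the residual events plus one composite event per flicker.
    """
    by_video: dict[str, list[AnnotationEvent]] = {}
    for e in events:
        by_video.setdefault(e.video_id, []).append(e)
    out: list[AnnotationEvent] = []
    for vid in sorted(by_video):
        flickers, residual = build_ear_flicker(by_video[vid], window)
        out.extend(residual)
        out.extend(
            AnnotationEvent(f.video_id, FLICKER, f.onset, f.offset)
            for f in flickers
        )
    out.sort(key=lambda e: (e.video_id, e.onset, e.offset, e.code))
    return out
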