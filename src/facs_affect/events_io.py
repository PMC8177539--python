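"""Readers, writers and validation for annotation event tables, clip
metadata and R-R interval recordings.

Annotation events are rows of ``video_id,code,onset,offset`` (seconds, dot
decimal) as exported from ELAN; clip metadata rows are
``video_id,horse_id,group,condition,clip_start,clip_length``. R-R interval
recordings are accepted either in the sectioned Polar HRM text dialect or as
a two-column ``beat_time_s,rr_ms`` CSV.

Times are session-relative seconds; an event occupies the closed-open
interval ``[onset, offset)``. Zero-duration events (``offset == onset``) are
permitted — they count toward frequencies and contribute nothing to
durations.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .vocabulary import DEFAULT_VOCABULARY, UNSCORABLE

GROUPS = ("PRI", "UNI")
CONDITIONS = ("baseline", "transportation", "isolation")
INTERVENTIONS = ("transportation", "isolation")

EVENT_HEADER = ["video_id", "code", "onset", "offset"]
CLIP_HEADER = ["video_id", "horse_id", "group", "condition", "clip_start", "clip_length"]


class EventFileError(ValueError):
    """Malformed annotation, clip or R-R input."""


@dataclass(frozen=True)
class AnnotationEvent:
    """One coded facial action occurrence."""

    video_id: str
    code: str
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"negative onset {self.onset} for {self.code}")
        if self.offset < self.onset:
            raise ValueError(
                f"offset {self.offset} precedes onset {self.onset} for {self.code}"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class ClipRecord:
    """A scored clip (30 s by default) with horse, group and condition labels."""

    video_id: str
    horse_id: str
    group: str
    condition: str
    clip_start: float = 0.0
    clip_length: float = 30.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r} (expected one of {GROUPS})")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r} (expected one of {CONDITIONS})"
            )
        if self.clip_length <= 0:
            raise ValueError(f"clip_length must be positive, got {self.clip_length}")


@dataclass
class RRSeries:
    """Ordered R-R intervals (ms) for one recording session.

    ``beat_times`` places each beat at the *end* of its interval, at
    ``t0 + cumsum(rr)/1000`` seconds.
    """

    session_id: str
    horse_id: str = ""
    condition: str = ""
    t0: float = 0.0
    rr: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if self.rr.ndim != 1:
            raise ValueError("rr must be a 1-D sequence of intervals")
        if len(self.rr) and np.any(self.rr <= 0):
            raise EventFileError(f"{self.session_id}: non-positive R-R interval")

    def __len__(self) -> int:
        return len(self.rr)

    @property
    def beat_times(self) -> np.ndarray:
        return self.t0 + np.cumsum(self.rr) / 1000.0


def _sort_key(e: AnnotationEvent):
    return (e.video_id, e.onset, e.offset, e.code)


def read_events(
    path,
    vocabulary: frozenset[str] | set[str] | None = DEFAULT_VOCABULARY,
    lax: bool = False,
) -> list[AnnotationEvent]:
    """Read an annotation event table, sorted by (video_id, onset).

    Unknown codes raise :class:`EventFileError` unless ``lax`` is true, in
    which case they are kept with a warning. Errors name the offending line.
    """
    events: list[AnnotationEvent] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != EVENT_HEADER:
            raise EventFileError(
                f"{path}: expected header {','.join(EVENT_HEADER)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            if len(row) != 4:
                raise EventFileError(
                    f"{path}:{lineno}: expected 4 fields, got {len(row)}"
                )
            vid, code, onset_s, offset_s = (f.strip() for f in row)
            try:
                onset, offset = float(onset_s), float(offset_s)
            except ValueError:
                raise EventFileError(
                    f"{path}:{lineno}: non-numeric onset/offset"
                ) from None
            if vocabulary is not None and code not in vocabulary:
                if lax:
                    warnings.warn(f"{path}:{lineno}: unknown code {code!r} kept")
                else:
                    raise EventFileError(
                        f"{path}:{lineno}: unknown EquiFACS code {code!r}"
                    )
            try:
                events.append(AnnotationEvent(vid, code, onset, offset))
            except ValueError as exc:
                raise EventFileError(f"{path}:{lineno}: {exc}") from None
    return sorted(events, key=_sort_key)


def write_events(events: Iterable[AnnotationEvent], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_HEADER)
        for e in events:
            writer.writerow([e.video_id, e.code, repr(e.onset), repr(e.offset)])


def read_clips(path) -> list[ClipRecord]:
    """Read clip metadata; ``clip_start``/``clip_length`` default to 0/30."""
    clips: list[ClipRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = set(CLIP_HEADER[:4])
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise EventFileError(
                f"{path}: expected at least columns {','.join(CLIP_HEADER[:4])}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                clips.append(
                    ClipRecord(
                        video_id=row["video_id"].strip(),
                        horse_id=row["horse_id"].strip(),
                        group=row["group"].strip(),
                        condition=row["condition"].strip(),
                        clip_start=float(row.get("clip_start") or 0.0),
                        clip_length=float(row.get("clip_length") or 30.0),
                    )
                )
            except (ValueError, AttributeError) as exc:
                raise EventFileError(f"{path}:{lineno}: {exc}") from None
    seen: set[str] = set()
    for c in clips:
        if c.video_id in seen:
            raise EventFileError(f"{path}: duplicate video_id {c.video_id!r}")
        seen.add(c.video_id)
    return clips


def write_clips(clips: Iterable[ClipRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CLIP_HEADER)
        for c in clips:
            writer.writerow(
                [c.video_id, c.horse_id, c.group, c.condition, c.clip_start, c.clip_length]
            )


def validate_dataset(
    events: Sequence[AnnotationEvent], clips: Sequence[ClipRecord]
) -> None:
    """Check that every event's video_id resolves to exactly one clip."""
    known = {c.video_id for c in clips}
    orphans = sorted({e.video_id for e in events} - known)
    if orphans:
        raise EventFileError(
            f"events reference unknown video_id(s): {', '.join(orphans[:5])}"
        )


# ---------------------------------------------------------------------------
# R-R interval files
# ---------------------------------------------------------------------------

_SECTION_RE = re.compile(r"^\[(?P<name>[^\]]+)\]\s*$")
_TIME_RE = re.compile(r"^(\d+):(\d\d):(\d\d(?:\.\d+)?)$")


def read_hrm(path, session_id: str | None = None, horse_id: str = "",
             condition: str = "") -> RRSeries:
    """Read a Polar HRM file or a two-column ``beat_time_s,rr_ms`` CSV.

    HRM dialect: INI-style sections; R-R values as integer milliseconds, one
    per line (first tab-separated field), under ``[HRData]``; ``t0`` from the
    ``StartTime`` key of ``[Params]`` (seconds since midnight) when present,
    else 0.
    """
    path = Path(path)
    sid = session_id or path.stem
    text = path.read_text()
    if text.lstrip().startswith("["):
        return _parse_hrm(text, sid, horse_id, condition, path)
    return _parse_rr_csv(text, sid, horse_id, condition, path)


def _parse_hrm(text, sid, horse_id, condition, path) -> RRSeries:
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    for line in text.splitlines():
        m = _SECTION_RE.match(line.strip())
        if m:
            current = sections.setdefault(m.group("name").lower(), [])
        elif current is not None and line.strip():
            current.append(line.strip())
    if "hrdata" not in sections:
        raise EventFileError(f"{path}: missing [HRData] section")
    t0 = 0.0
    for line in sections.get("params", []):
        key, _, value = line.partition("=")
        if key.strip().lower() == "starttime":
            m = _TIME_RE.match(value.strip())
            if m:
                h, mi, s = m.groups()
                t0 = int(h) * 3600 + int(mi) * 60 + float(s)
    rr = []
    for line in sections["hrdata"]:
        first = line.split("\t")[0].split()[0]
        rr.append(float(first))
    if not rr:
        raise EventFileError(f"{path}: empty [HRData] section")
    return RRSeries(sid, horse_id, condition, t0, np.asarray(rr))


def _parse_rr_csv(text, sid, horse_id, condition, path) -> RRSeries:
    reader = csv.reader(text.splitlines())
    rows = [r for r in reader if r and any(f.strip() for f in r)]
    if rows and not _is_number(rows[0][0]):
        rows = rows[1:]  # optional header
    if not rows:
        raise EventFileError(f"{path}: no R-R rows")
    times, rr = [], []
    for row in rows:
        if len(row) < 2:
            raise EventFileError(f"{path}: expected beat_time_s,rr_ms rows")
        times.append(float(row[0]))
        rr.append(float(row[1]))
    t0 = times[0] - rr[0] / 1000.0
    return RRSeries(sid, horse_id, condition, t0, np.asarray(rr))


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_hrm(series: RRSeries, path) -> None:
    """Write an :class:`RRSeries` in the minimal Polar HRM dialect."""
    t0 = max(series.t0, 0.0)
    h, rem = divmod(t0, 3600)
    mi, s = divmod(rem, 60)
    lines = [
        "[Params]",
        "Version=106",
        "Interval=238",
        f"StartTime={int(h)}:{int(mi):02d}:{s:04.1f}",
        "",
        "[HRData]",
    ]
    lines += [str(int(round(v))) for v in series.rr]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Visibility handling
# ---------------------------------------------------------------------------

def drop_unscorable(events: Sequence[AnnotationEvent]) -> list[AnnotationEvent]:
    """Remove VC74 spans and any event fully covered by one.

    An event is dropped when its interval lies entirely inside a VC74
    interval of the same video. Partial overlaps are kept untrimmed — a
    conservative choice that preserves observed durations.
    """
    spans: dict[str, list[tuple[float, float]]] = {}
    for e in events:
        if e.code == UNSCORABLE:
            spans.setdefault(e.video_id, []).append((e.onset, e.offset))
    kept = []
    for e in events:
        if e.code == UNSCORABLE:
            continue
        covered = any(
            on <= e.onset and e.offset <= off
            for on, off in spans.get(e.video_id, ())
        )
        if not covered:
            kept.append(e)
    return kept
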