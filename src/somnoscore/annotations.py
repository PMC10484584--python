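"""Shared data model for sleep recordings: hypnograms, scored events, annotation sets.

Conventions used throughout the package:

* All times are seconds from recording start.
* Event intervals are half-open ``[onset, onset + duration)``.
* Hypnogram epochs are 30 s; epoch ``i`` covers ``[30*i, 30*(i+1))``.

Annotations are serialized to a small versioned JSON schema (v1)::

    {"schema_version": 1, "rec_duration_s": float, "epoch_len_s": 30,
     "stages": ["W", ...],
     "events": [{"type": str, "onset_s": float, "duration_s": float,
                 "depth_pct": float | null}]}
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

EPOCH_LEN = 30.0

STAGES = ("W", "N1", "N2", "N3", "R")
SLEEP_STAGES = ("N1", "N2", "N3", "R")

EVENT_TYPES = (
    "arousal_cortical",
    "arousal_autonomic",
    "apnea_obstructive",
    "apnea_central",
    "apnea_mixed",
    "hypopnea",
    "desaturation",
)
APNEA_TYPES = ("apnea_obstructive", "apnea_central", "apnea_mixed")
RESPIRATORY_TYPES = APNEA_TYPES + ("hypopnea",)
AROUSAL_TYPES = ("arousal_cortical", "arousal_autonomic")


class AnnotationError(ValueError):
    """Raised when an annotation document violates the schema or an invariant."""


@dataclass(frozen=True)
class ScoredEvent:
    """A scored event on the recording timeline.

    ``depth`` is the desaturation depth in percent and is only meaningful for
    ``etype == "desaturation"``.
    """

    etype: str
    onset: float
    duration: float
    depth: float | None = None

    def __post_init__(self) -> None:
        if self.etype not in EVENT_TYPES:
            raise AnnotationError(f"unknown event type: {self.etype!r}")
        if not (math.isfinite(self.onset) and math.isfinite(self.duration)):
            raise AnnotationError("event onset/duration must be finite")
        if self.onset < 0:
            raise AnnotationError(f"event onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise AnnotationError(f"event duration must be > 0, got {self.duration}")
        if self.depth is not None:
            if not math.isfinite(self.depth) or self.depth < 0:
                raise AnnotationError(f"desaturation depth must be >= 0, got {self.depth}")

    @property
    def end(self) -> float:
        return self.onset + self.duration

    def overlaps(self, start: float, stop: float) -> bool:
        """Half-open interval intersection with ``[start, stop)``."""
        return self.onset < stop and start < self.end

    def shifted(self, dt: float) -> "ScoredEvent":
        return replace(self, onset=self.onset + dt)


@dataclass(frozen=True)
class Hypnogram:
    """A sequence of 30-s sleep stage epochs."""

    stages: tuple[str, ...]

    def __init__(self, stages: Iterable[str]):
        stages = tuple(stages)
        for s in stages:
            if s not in STAGES:
                raise AnnotationError(f"unknown sleep stage: {s!r}")
        object.__setattr__(self, "stages", stages)

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> float:
        return EPOCH_LEN * len(self.stages)

    def stage_at(self, t: float) -> str:
        """Stage covering time ``t`` (half-open epochs)."""
        if not 0 <= t < self.duration:
            raise AnnotationError(f"time {t} outside hypnogram [0, {self.duration})")
        return self.stages[int(t // EPOCH_LEN)]

    def is_sleep(self, idx: int) -> bool:
        return self.stages[idx] != "W"

    def total_sleep_time(self, rec_duration: float | None = None) -> float:
        """Total sleep time in seconds.

        When ``rec_duration`` is given and the last epoch is partial, that
        epoch contributes its full 30 s if it is at least 15 s long, otherwise
        only its actual (pro-rata) length.
        """
        n = len(self.stages)
        if n == 0:
            return 0.0
        tst = EPOCH_LEN * sum(1 for s in self.stages[:-1] if s != "W")
        last_len = EPOCH_LEN
        if rec_duration is not None:
            partial = rec_duration - EPOCH_LEN * (n - 1)
            if partial < EPOCH_LEN:
                last_len = EPOCH_LEN if partial >= 15.0 else max(partial, 0.0)
        if self.stages[-1] != "W":
            tst += last_len
        return tst

    def wake_runs(self) -> list[tuple[float, float]]:
        """Maximal runs of wake epochs as half-open second intervals."""
        runs: list[tuple[float, float]] = []
        start = None
        for i, s in enumerate(self.stages):
            if s == "W" and start is None:
                start = i * EPOCH_LEN
            elif s != "W" and start is not None:
                runs.append((start, i * EPOCH_LEN))
                start = None
        if start is not None:
            runs.append((start, self.duration))
        return runs


def stage_at(h: Hypnogram, t: float) -> str:
    return h.stage_at(t)


def total_sleep_time(h: Hypnogram, rec_duration: float | None = None) -> float:
    return h.total_sleep_time(rec_duration)


@dataclass
class AnnotationSet:
    """Hypnogram plus scored events for one recording."""

    hypnogram: Hypnogram
    events: list[ScoredEvent]
    rec_duration: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.rec_duration) or self.rec_duration <= 0:
            raise AnnotationError(f"rec_duration must be positive, got {self.rec_duration}")
        n_expected = math.ceil(self.rec_duration / EPOCH_LEN)
        if len(self.hypnogram) != n_expected:
            raise AnnotationError(
                f"hypnogram has {len(self.hypnogram)} epochs, expected "
                f"ceil({self.rec_duration}/30) = {n_expected}"
            )
        for ev in self.events:
            if ev.end > self.rec_duration + 1e-9:
                raise AnnotationError(
                    f"event {ev.etype} [{ev.onset}, {ev.end}) outside recording "
                    f"of duration {self.rec_duration}"
                )
        self.events = sorted(self.events, key=lambda e: (e.onset, e.etype))

    def events_of(self, *etypes: str) -> list[ScoredEvent]:
        return [e for e in self.events if e.etype in etypes]

    @property
    def tst(self) -> float:
        return self.hypnogram.total_sleep_time(self.rec_duration)


@dataclass
class SubjectRecord:
    """One subject: reference (PSG-style) and estimated (HSAT-style) annotations."""

    subject_id: str
    database: str
    psg_ref: AnnotationSet
    hsat_est: AnnotationSet
    waveforms: dict = field(default_factory=dict)
    ihr_ref: object | None = None  # ground-truth 2 Hz IHR trace when synthetic


# ---------------------------------------------------------------------------
# JSON serialization (schema v1)

def annotations_to_dict(a: AnnotationSet) -> dict:
    return {
        "schema_version": 1,
        "rec_duration_s": float(a.rec_duration),
        "epoch_len_s": 30,
        "stages": list(a.hypnogram.stages),
        "events": [
            {
                "type": e.etype,
                "onset_s": float(e.onset),
                "duration_s": float(e.duration),
                "depth_pct": None if e.depth is None else float(e.depth),
            }
            for e in a.events
        ],
    }


def annotations_from_dict(doc: dict) -> AnnotationSet:
    for key in ("rec_duration_s", "stages", "events"):
        if key not in doc:
            raise AnnotationError(f"annotation document missing field {key!r}")
    if doc.get("epoch_len_s", 30) != 30:
        raise AnnotationError("only 30-s epochs are supported (epoch_len_s)")
    events = []
    for i, ev in enumerate(doc["events"]):
        for key in ("type", "onset_s", "duration_s"):
            if key not in ev:
                raise AnnotationError(f"events[{i}] missing field {key!r}")
        events.append(
            ScoredEvent(
                etype=ev["type"],
                onset=float(ev["onset_s"]),
                duration=float(ev["duration_s"]),
                depth=None if ev.get("depth_pct") is None else float(ev["depth_pct"]),
            )
        )
    return AnnotationSet(
        hypnogram=Hypnogram(doc["stages"]),
        events=events,
        rec_duration=float(doc["rec_duration_s"]),
    )


def write_annotations(a: AnnotationSet, path: str | Path) -> None:
    """Write an annotation set as canonical schema-v1 JSON (stable field order)."""
    doc = annotations_to_dict(a)
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read and validate a schema-v1 annotation JSON file."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"malformed annotation JSON in {path}: {exc}") from exc
    return annotations_from_dict(doc)
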