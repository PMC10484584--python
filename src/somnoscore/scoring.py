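"""Respiratory-event scoring rules and per-subject index computation.

Implements the HSAT scoring chain:

* wake filtering — apneas/hypopneas count only if they overlap a sleep epoch;
  arousals count if they start during sleep or within the first/last 15 s of a
  maximal wake period (the tolerance captures arousals leading to awakenings);
* hypopnea confirmation — by an associated >=3% desaturation, or (for the
  arousal-augmented index) by an associated arousal; apneas need no
  confirmation;
* the three AHI surrogates: REI (all desaturation-confirmed events per hour of
  recording time), AHI_est (sleep-filtered events per hour of estimated
  sleep), and the arousal-augmented AHI_est; plus the PSG reference AHI,
  arousal indices, and obstructive/central apnea indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import (
    APNEA_TYPES,
    EPOCH_LEN,
    RESPIRATORY_TYPES,
    AnnotationSet,
    Hypnogram,
    ScoredEvent,
    SubjectRecord,
)
from .stats import severity_class


@dataclass
class ScoringConfig:
    """Association windows (seconds after event end) for confirming hypopneas."""

    desat_window: float = 45.0  # circulatory delay to the oximeter
    arousal_window: float = 5.0
    min_desat_depth: float = 3.0  # percent


def filter_respiratory_events(events: list[ScoredEvent], h: Hypnogram) -> list[ScoredEvent]:
    """Keep apneas/hypopneas whose interval intersects at least one sleep epoch."""
    kept = []
    for ev in events:
        if ev.etype not in RESPIRATORY_TYPES:
            continue
        first = int(ev.onset // EPOCH_LEN)
        last = int(np.nextafter(ev.end, ev.onset) // EPOCH_LEN)
        last = min(last, len(h) - 1)
        if any(h.stages[i] != "W" for i in range(first, last + 1)):
            kept.append(ev)
    return kept


def filter_arousals(arousals: list[ScoredEvent], h: Hypnogram) -> list[ScoredEvent]:
    """Keep arousals starting in sleep or within 15 s of a wake-period edge."""
    wake = h.wake_runs()
    kept = []
    for ev in arousals:
        t = ev.onset
        run = next((r for r in wake if r[0] <= t < r[1]), None)
        if run is None:
            if t < h.duration:
                kept.append(ev)
            continue
        if t < run[0] + 15.0 or t >= run[1] - 15.0:
            kept.append(ev)
    return kept


def confirm_hypopneas(hypopneas: list[ScoredEvent], desats: list[ScoredEvent],
                      arousals: list[ScoredEvent], mode: str = "desat_only",
                      cfg: ScoringConfig | None = None) -> list[ScoredEvent]:
    """Return the hypopneas confirmed by a desaturation (or arousal).

    A desaturation of depth >= 3% confirms a hypopnea when its onset falls in
    ``[hypopnea onset, hypopnea end + desat_window]``; pairing is one-to-one
    greedy by proximity so a single desaturation cannot confirm two events.
    In ``desat_or_arousal`` mode an arousal with onset in
    ``[hypopnea onset, hypopnea end + arousal_window]`` also confirms.
    """
    if mode not in ("desat_only", "desat_or_arousal"):
        raise ValueError(f"unknown confirmation mode: {mode!r}")
    cfg = cfg or ScoringConfig()
    confirmed: set[int] = set()

    usable = sorted((d for d in desats
                     if d.depth is not None and d.depth >= cfg.min_desat_depth),
                    key=lambda d: d.onset)
    used = [False] * len(usable)
    for i, hyp in enumerate(sorted(hypopneas, key=lambda e: e.onset)):
        best, best_dist = None, None
        for k, d in enumerate(usable):
            if used[k] or not hyp.onset <= d.onset <= hyp.end + cfg.desat_window:
                continue
            dist = abs(d.onset - hyp.end)
            if best_dist is None or dist < best_dist:
                best, best_dist = k, dist
        if best is not None:
            used[best] = True
            confirmed.add(i)
    if mode == "desat_or_arousal":
        for i, hyp in enumerate(sorted(hypopneas, key=lambda e: e.onset)):
            if i in confirmed:
                continue
            if any(hyp.onset <= a.onset <= hyp.end + cfg.arousal_window
                   for a in arousals):
                confirmed.add(i)
    ordered = sorted(hypopneas, key=lambda e: e.onset)
    return [ordered[i] for i in sorted(confirmed)]


@dataclass
class IndexReport:
    """All per-subject indices (events per hour) and severity classes."""

    subject_id: str
    ahi_psg: float
    rei: float
    ahi_est: float
    ahi_est_autar: float
    ari: float
    autari: float
    oai: float
    cai: float
    tst_ref_h: float
    tst_est_h: float
    rec_time_h: float
    severity: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.severity:
            self.severity = {
                "ahi_psg": severity_class(self.ahi_psg),
                "rei": severity_class(self.rei),
                "ahi_est": severity_class(self.ahi_est),
                "ahi_est_autar": severity_class(self.ahi_est_autar),
            }


def _scored_events(ann: AnnotationSet, arousal_type: str, mode: str,
                   cfg: ScoringConfig, sleep_filter: bool) -> list[ScoredEvent]:
    """Apneas plus confirmed hypopneas, optionally wake-filtered first."""
    resp = ann.events_of(*RESPIRATORY_TYPES)
    desats = ann.events_of("desaturation")
    arousals = filter_arousals(ann.events_of(arousal_type), ann.hypnogram)
    if sleep_filter:
        resp = filter_respiratory_events(resp, ann.hypnogram)
    apneas = [e for e in resp if e.etype in APNEA_TYPES]
    hyps = [e for e in resp if e.etype == "hypopnea"]
    return apneas + confirm_hypopneas(hyps, desats, arousals, mode, cfg)


def compute_indices(rec: SubjectRecord, cfg: ScoringConfig | None = None) -> IndexReport:
    """Compute every per-subject index from reference and estimated annotations."""
    cfg = cfg or ScoringConfig()
    ref, est = rec.psg_ref, rec.hsat_est

    tst_ref_h = ref.tst / 3600.0
    tst_est_h = est.tst / 3600.0
    rec_time_h = est.rec_duration / 3600.0

    def _index(count: int, hours: float) -> float:
        if hours == 0:
            if count:
                raise ZeroDivisionError("index undefined: events present but zero sleep time")
            return 0.0
        return count / hours

    for ann, tst in ((ref, tst_ref_h), (est, tst_est_h)):
        if tst == 0 and ann.events_of(*RESPIRATORY_TYPES):
            raise ZeroDivisionError(
                "index undefined: respiratory events present but zero sleep time")

    # PSG reference AHI: sleep-filtered, hypopneas confirmed by desaturation
    # or cortical arousal, per hour of reference sleep.
    n_ref = len(_scored_events(ref, "arousal_cortical", "desat_or_arousal", cfg, True))
    ahi_psg = _index(n_ref, tst_ref_h)

    # REI: desaturation-confirmed events per hour of recording time, no sleep
    # filtering (the estimated hypnogram is deliberately unused here).
    n_rei = len(_scored_events(est, "arousal_autonomic", "desat_only", cfg, False))
    rei = n_rei / rec_time_h

    n_est = len(_scored_events(est, "arousal_autonomic", "desat_only", cfg, True))
    ahi_est = _index(n_est, tst_est_h)

    n_autar = len(_scored_events(est, "arousal_autonomic", "desat_or_arousal", cfg, True))
    ahi_est_autar = _index(n_autar, tst_est_h)

    ari_events = filter_arousals(ref.events_of("arousal_cortical"), ref.hypnogram)
    autari_events = filter_arousals(est.events_of("arousal_autonomic"), est.hypnogram)
    apneas_ref = filter_respiratory_events(ref.events_of(*APNEA_TYPES), ref.hypnogram)

    return IndexReport(
        subject_id=rec.subject_id,
        ahi_psg=ahi_psg,
        rei=rei,
        ahi_est=ahi_est,
        ahi_est_autar=ahi_est_autar,
        ari=_index(len(ari_events), tst_ref_h),
        autari=_index(len(autari_events), tst_est_h),
        oai=_index(sum(e.etype == "apnea_obstructive" for e in apneas_ref), tst_ref_h),
        cai=_index(sum(e.etype == "apnea_central" for e in apneas_ref), tst_ref_h),
        tst_ref_h=tst_ref_h,
        tst_est_h=tst_est_h,
        rec_time_h=rec_time_h,
    )
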