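"""Discrete arousal events from probability traces, event matching, threshold
calibration and cross-validation fold bookkeeping.

An autonomic arousal event is a maximal run of 2 Hz probability samples
strictly above the detection threshold lasting at least 2 s (4 samples, each
covering 0.5 s). The detection threshold is calibrated per cross-validation
model by maximizing event-level F1 on the training folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .annotations import ScoredEvent


@dataclass
class ProbabilitySeries:
    """2 Hz arousal probability trace."""

    values: np.ndarray
    start: float = 0.0
    rate: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def times(self) -> np.ndarray:
        return self.start + np.arange(self.values.size) / self.rate


def probability_to_events(p: ProbabilitySeries, threshold: float,
                          min_duration: float = 2.0) -> list[ScoredEvent]:
    """Maximal runs of samples strictly above ``threshold`` lasting >= 2 s.

    Each sample covers ``1/rate`` seconds, so a run of ``k`` samples becomes an
    event of duration ``k/rate`` starting at the first sample's time.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    above = p.values > threshold
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    min_samples = int(round(min_duration * p.rate))
    events = []
    for i0, i1 in zip(starts, stops):
        if i1 - i0 >= min_samples:
            events.append(ScoredEvent("arousal_autonomic",
                                      p.start + i0 / p.rate, (i1 - i0) / p.rate))
    return events


@dataclass
class EventMatch:
    pairs: list[tuple[ScoredEvent, ScoredEvent]]
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2.0 * p * r / (p + r) if p + r else 0.0


def match_events(pred: list[ScoredEvent], ref: list[ScoredEvent],
                 criterion: str = "overlap", onset_tol: float = 5.0) -> EventMatch:
    """Greedy one-to-one matching in onset order.

    ``criterion="overlap"`` pairs events whose half-open intervals intersect;
    ``criterion="onset"`` pairs events whose onsets differ by at most
    ``onset_tol`` seconds.
    """
    if any(pred[i].onset > pred[i + 1].onset for i in range(len(pred) - 1)) or \
       any(ref[i].onset > ref[i + 1].onset for i in range(len(ref) - 1)):
        warnings.warn("event lists were not sorted by onset; sorting internally")
        pred = sorted(pred, key=lambda e: e.onset)
        ref = sorted(ref, key=lambda e: e.onset)
    pairs = []
    used = np.zeros(len(ref), dtype=bool)
    j = 0
    for ev in pred:
        for k in range(j, len(ref)):
            if used[k]:
                continue
            r = ref[k]
            if criterion == "overlap":
                hit = ev.onset < r.end and r.onset < ev.end
                if r.end <= ev.onset:
                    continue
                if r.onset >= ev.end:
                    break
            elif criterion == "onset":
                hit = abs(ev.onset - r.onset) <= onset_tol
                if r.onset > ev.onset + onset_tol:
                    break
            else:
                raise ValueError(f"unknown matching criterion: {criterion!r}")
            if hit:
                pairs.append((ev, r))
                used[k] = True
                break
    tp = len(pairs)
    return EventMatch(pairs=pairs, tp=tp, fp=len(pred) - tp, fn=len(ref) - tp)


def calibrate_threshold(prob_and_ref: list[tuple[ProbabilitySeries, list[ScoredEvent]]],
                        grid_step: float = 0.01, criterion: str = "overlap") -> float:
    """Grid-search the detection threshold maximizing pooled event F1.

    Counts are pooled over all training subjects; ties are broken toward the
    larger threshold.
    """
    if not prob_and_ref or all(len(ref) == 0 for _, ref in prob_and_ref):
        raise ValueError("threshold calibration requires reference arousals")
    grid = np.round(np.arange(grid_step, 1.0, grid_step), 10)
    best_thr, best_f1 = grid[0], -1.0
    for thr in grid:
        tp = fp = fn = 0
        for series, ref in prob_and_ref:
            m = match_events(probability_to_events(series, thr), ref,
                             criterion=criterion)
            tp += m.tp
            fp += m.fp
            fn += m.fn
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        if f1 >= best_f1:
            best_f1, best_thr = f1, thr
    return float(best_thr)


@dataclass
class FoldAssignment:
    """Per-subject fold index for stratified 4-fold cross-validation."""

    folds: dict[str, int]
    seed: int
    n_folds: int = 4

    def subjects_in(self, fold: int) -> list[str]:
        return [s for s, f in self.folds.items() if f == fold]

    def training_subjects(self, fold: int) -> list[str]:
        return [s for s, f in self.folds.items() if f != fold]


def make_folds(subjects: list[tuple[str, str]], seed: int,
               n_folds: int = 4) -> FoldAssignment:
    """Stratified-by-database fold assignment, reproducible from the seed.

    ``subjects`` is a list of (subject_id, database) pairs. Within each
    database, subjects are shuffled pseudo-randomly and dealt round-robin, so
    every fold holds the same number of subjects per database up to +/-1.
    """
    rng = np.random.default_rng(seed)
    by_db: dict[str, list[str]] = {}
    for sid, db in subjects:
        by_db.setdefault(db, []).append(sid)
    folds: dict[str, int] = {}
    for db in sorted(by_db):
        ids = sorted(by_db[db])
        if len(ids) < n_folds:
            warnings.warn(f"database {db!r} has fewer than {n_folds} subjects; "
                          "stratification is best-effort")
        rng.shuffle(ids)
        for i, sid in enumerate(ids):
            folds[sid] = i % n_folds
    return FoldAssignment(folds=folds, seed=seed, n_folds=n_folds)
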