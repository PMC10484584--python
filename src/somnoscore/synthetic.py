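"""Physiologically structured synthetic sleep cohorts.

Emulates, per subject, everything the downstream pipeline consumes:

* a Markov-chain hypnogram (30-s epochs, starting awake);
* respiratory events (apneas by subtype, hypopneas) placed during sleep at a
  Poisson rate per sleep-hour, with probabilistic >=3% desaturations and
  event-terminating cortical arousals;
* autonomic arousals coupled to cortical ones, plus spurious autonomic
  arousals (emulating e.g. periodic limb movement responses);
* a 2 Hz instantaneous heart rate (IHR) trace with a gamma-shaped surge at
  every autonomic arousal;
* a 100 Hz PPG pulse train driven by the IHR, a 10 Hz respiratory flow
  signal whose amplitude envelope drops during events, and a 1 Hz SpO2
  trace with desaturation dips;
* an HSAT-style estimated annotation set with a confusion-matrix-corrupted
  hypnogram (a stand-in for cardio-respiratory sleep staging error).

The per-subject event rate is drawn from a severity mixture so a cohort spans
all four sleep-disordered-breathing severity classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .annotations import (
    EPOCH_LEN,
    STAGES,
    AnnotationSet,
    Hypnogram,
    ScoredEvent,
    SubjectRecord,
)
from .waveio import Waveform

# Stage transition matrix (rows/cols in STAGES order W,N1,N2,N3,R), one step
# per 30-s epoch. Produces ~75-85% sleep efficiency with consolidated NREM and
# intermittent REM, adequate for overnight polygraphy emulation.
DEFAULT_TRANSITIONS = np.array(
    [
        [0.90, 0.08, 0.02, 0.00, 0.00],
        [0.10, 0.50, 0.38, 0.01, 0.01],
        [0.03, 0.04, 0.85, 0.05, 0.03],
        [0.01, 0.01, 0.10, 0.87, 0.01],
        [0.03, 0.03, 0.05, 0.00, 0.89],
    ]
)

# Per-epoch stage confusion of the estimated (cardio-respiratory) hypnogram:
# rows = true stage, cols = estimated stage. Wake/sleep confusion dominates,
# mirroring the weakness of cardio-respiratory staging around transitions.
DEFAULT_CORRUPTION = np.array(
    [
        [0.80, 0.12, 0.06, 0.01, 0.01],
        [0.15, 0.55, 0.25, 0.02, 0.03],
        [0.04, 0.08, 0.80, 0.05, 0.03],
        [0.01, 0.02, 0.12, 0.84, 0.01],
        [0.04, 0.04, 0.06, 0.01, 0.85],
    ]
)

# Severity mixture for per-subject respiratory event rates (events per sleep
# hour): weights follow the none/mild/moderate/severe prevalences of a typical
# sleep-clinic referral population.
SEVERITY_MIXTURE = ((0.5, 5.0), (5.0, 15.0), (15.0, 30.0), (30.0, 60.0))
SEVERITY_WEIGHTS = (0.12, 0.19, 0.26, 0.43)


@dataclass
class CohortConfig:
    """Generation parameters; defaults define the standard study conditions."""

    n_subjects: int = 20
    rec_duration: float = 8 * 3600.0
    seed: int = 0
    transitions: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITIONS.copy())
    event_rate: float | None = None  # events/sleep-hour; None -> severity mixture
    p_apnea: float = 0.5  # respiratory events that are apneas (vs hypopneas)
    apnea_subtype_p: tuple[float, float, float] = (0.7, 0.2, 0.1)  # obstructive/central/mixed
    p_desat: float = 0.6  # hypopnea followed by a >=3% desaturation
    p_arousal: float = 0.7  # event terminates in a cortical arousal
    p_autonomic_given_cortical: float = 0.8
    p_autonomic_spurious: float = 0.1  # per respiratory event, autonomic w/o cortical
    spontaneous_arousal_rate: float = 15.0  # cortical arousals per sleep-hour
    hr_baseline: float = 62.0  # bpm
    hr_surge: float = 18.0  # bpm peak of the post-arousal tachycardia
    hrv_sd: float = 2.5  # bpm, slow heart-rate variability
    corruption: np.ndarray = field(default_factory=lambda: DEFAULT_CORRUPTION.copy())
    with_waveforms: bool = True

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.corruption = np.asarray(self.corruption, dtype=float)
        for name, m in (("transitions", self.transitions), ("corruption", self.corruption)):
            if m.shape != (5, 5) or np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0):
                raise ValueError(f"{name} must be a 5x5 row-stochastic matrix")
        for p in (self.p_apnea, self.p_desat, self.p_arousal,
                  self.p_autonomic_given_cortical, self.p_autonomic_spurious):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.spontaneous_arousal_rate < 0 or (self.event_rate or 0) < 0:
            raise ValueError("rates must be >= 0")


# ---------------------------------------------------------------------------
# hypnograms

def gen_hypnogram(cfg: CohortConfig, rng: np.random.Generator) -> Hypnogram:
    """Markov-chain hypnogram; first epoch is wake."""
    n = int(np.ceil(cfg.rec_duration / EPOCH_LEN))
    if cfg.transitions[0, 0] >= 1.0 - 1e-12:
        warnings.warn("wake is absorbing: generated hypnogram will contain no sleep")
    idx = np.empty(n, dtype=int)
    idx[0] = 0  # W
    cum = np.cumsum(cfg.transitions, axis=1)
    u = rng.random(n)
    for i in range(1, n):
        idx[i] = np.searchsorted(cum[idx[i - 1]], u[i])
    return Hypnogram(STAGES[i] for i in idx)


def corrupt_hypnogram(h: Hypnogram, corruption: np.ndarray,
                      rng: np.random.Generator) -> Hypnogram:
    """Independent per-epoch relabeling by a stage confusion matrix."""
    corruption = np.asarray(corruption, dtype=float)
    if corruption.shape != (5, 5) or not np.allclose(corruption.sum(axis=1), 1.0):
        raise ValueError("corruption must be a 5x5 row-stochastic matrix")
    cum = np.cumsum(corruption, axis=1)
    stage_idx = {s: i for i, s in enumerate(STAGES)}
    u = rng.random(len(h))
    out = [STAGES[np.searchsorted(cum[stage_idx[s]], ui)] for s, ui in zip(h.stages, u)]
    return Hypnogram(out)


# ---------------------------------------------------------------------------
# events

def _sleep_seconds(h: Hypnogram, rec_duration: float) -> np.ndarray:
    """Start times (1-s grid) of seconds falling in sleep epochs."""
    secs = np.arange(int(rec_duration))
    stages = np.array([h.stages[min(int(s // EPOCH_LEN), len(h) - 1)] for s in secs])
    return secs[stages != "W"]


def gen_events(h: Hypnogram, cfg: CohortConfig, rng: np.random.Generator,
               event_rate: float | None = None) -> list[ScoredEvent]:
    """Respiratory events with desaturation/arousal consequences, plus arousals."""
    rec_duration = cfg.rec_duration
    rate = cfg.event_rate if event_rate is None else event_rate
    if rate is None:
        rate = 0.0
    sleep_secs = _sleep_seconds(h, rec_duration)
    sleep_h = sleep_secs.size / 3600.0
    events: list[ScoredEvent] = []
    if sleep_h == 0:
        return events

    subtype_cum = np.cumsum(cfg.apnea_subtype_p)

    def _add_arousals(t0: float, spurious_roll: float) -> None:
        """Cortical/autonomic arousal pair (or spurious autonomic) at time t0."""
        dur = rng.uniform(3.0, 10.0)
        if t0 + dur > rec_duration:
            return
        cortical = rng.random() < cfg.p_arousal
        if cortical:
            events.append(ScoredEvent("arousal_cortical", t0, dur))
            if rng.random() < cfg.p_autonomic_given_cortical:
                events.append(ScoredEvent("arousal_autonomic", t0, dur))
        elif spurious_roll < cfg.p_autonomic_spurious:
            events.append(ScoredEvent("arousal_autonomic", t0, dur))

    n_resp = rng.poisson(rate * sleep_h)
    onsets = rng.choice(sleep_secs, size=n_resp) + rng.random(n_resp)
    for onset in np.sort(onsets):
        dur = rng.uniform(10.0, 60.0)
        end = min(onset + dur, rec_duration)
        dur = end - onset
        if dur < 10.0:
            continue
        if rng.random() < cfg.p_apnea:
            etype = ("apnea_obstructive", "apnea_central",
                     "apnea_mixed")[int(np.searchsorted(subtype_cum, rng.random()))]
            events.append(ScoredEvent(etype, onset, dur))
        else:
            events.append(ScoredEvent("hypopnea", onset, dur))
            if rng.random() < cfg.p_desat:
                lag = rng.uniform(10.0, 30.0)
                d_dur = rng.uniform(10.0, 20.0)
                depth = rng.uniform(3.0, 8.0)
                if end + lag + d_dur <= rec_duration:
                    events.append(ScoredEvent("desaturation", end + lag, d_dur, depth))
        _add_arousals(end, rng.random())

    n_spont = rng.poisson(cfg.spontaneous_arousal_rate * sleep_h)
    spont = rng.choice(sleep_secs, size=n_spont) + rng.random(n_spont)
    for t0 in np.sort(spont):
        dur = rng.uniform(3.0, 10.0)
        if t0 + dur > rec_duration:
            continue
        events.append(ScoredEvent("arousal_cortical", t0, dur))
        if rng.random() < cfg.p_autonomic_given_cortical:
            events.append(ScoredEvent("arousal_autonomic", t0, dur))
    return sorted(events, key=lambda e: (e.onset, e.etype))


# ---------------------------------------------------------------------------
# signals

def _surge_kernel(decay: float = 8.0, rise: float = 1.0, rate: float = 2.0) -> np.ndarray:
    """Gamma-like surge: ~2 s to peak, ~8 s decay; normalized to peak 1."""
    t = np.arange(0, decay * 5, 1.0 / rate)
    k = (1.0 - np.exp(-t / rise)) * np.exp(-t / decay)
    return k / k.max()


def gen_ihr(events: list[ScoredEvent], cfg: CohortConfig, rng: np.random.Generator,
            rec_duration: float | None = None) -> Waveform:
    """2 Hz instantaneous heart rate: baseline + slow HRV + arousal surges."""
    rec_duration = cfg.rec_duration if rec_duration is None else rec_duration
    n = int(round(rec_duration * 2))
    ihr = np.full(n, cfg.hr_baseline)
    if cfg.hrv_sd > 0:
        # smooth (~0.05 Hz bandwidth) variability
        noise = rng.standard_normal(n)
        noise = gaussian_filter1d(noise, sigma=8.0)
        sd = noise.std()
        if sd > 0:
            ihr += cfg.hrv_sd * noise / sd
    kernel = _surge_kernel()
    for ev in events:
        if ev.etype != "arousal_autonomic":
            continue
        i0 = int(round(ev.onset * 2))
        amp = cfg.hr_surge * rng.uniform(0.85, 1.15)
        seg = kernel[: max(0, n - i0)]
        ihr[i0: i0 + seg.size] += amp * seg
    return Waveform(label="IHR", rate=2.0, samples=np.maximum(ihr, 35.0))


_PULSE_T = np.arange(0, 0.75, 0.01)
_PULSE = (np.exp(-(((_PULSE_T - 0.15) / 0.05) ** 2))
          + 0.35 * np.exp(-(((_PULSE_T - 0.40) / 0.08) ** 2)))


def gen_ppg(ihr: Waveform, rng: np.random.Generator) -> Waveform:
    """100 Hz PPG pulse train whose beat intervals follow the IHR trace."""
    if np.any(ihr.samples <= 30):
        raise ValueError("IHR must exceed 30 bpm everywhere")
    n100 = int(round(ihr.duration * 100))
    t100 = np.arange(n100) / 100.0
    f = np.interp(t100, ihr.times, ihr.samples) / 60.0  # beats per second
    phase = np.cumsum(f) / 100.0
    beat_idx = np.flatnonzero(np.diff(np.floor(phase)) > 0) + 1
    ppg = np.zeros(n100)
    amps = 1.0 + 0.05 * rng.standard_normal(beat_idx.size)
    for i, a in zip(beat_idx, amps):
        seg = _PULSE[: max(0, n100 - i)]
        ppg[i: i + seg.size] += a * seg
    ppg += 0.01 * rng.standard_normal(n100)
    return Waveform(label="PPG", rate=100.0, samples=ppg)


def gen_flow(h: Hypnogram, events: list[ScoredEvent], cfg: CohortConfig,
             rng: np.random.Generator, rec_duration: float | None = None) -> Waveform:
    """10 Hz respiratory flow with amplitude drops during apneas/hypopneas."""
    rec_duration = cfg.rec_duration if rec_duration is None else rec_duration
    n = int(round(rec_duration * 10))
    t = np.arange(n) / 10.0
    f0 = rng.uniform(12.0, 18.0) / 60.0  # breaths per second
    wander = 1.0 + 0.05 * np.sin(2 * np.pi * t / 300.0 + rng.uniform(0, 2 * np.pi))
    phase = np.cumsum(f0 * wander) / 10.0
    env = np.ones(n)
    for ev in events:
        level = None
        if ev.etype == "hypopnea":
            level = 0.4
        elif ev.etype.startswith("apnea"):
            level = 0.05
        if level is not None:
            i0, i1 = int(ev.onset * 10), int(ev.end * 10)
            env[i0:i1] = np.minimum(env[i0:i1], level)
    env = uniform_filter1d(env, size=20, mode="nearest")  # <=2 s transitions
    flow = env * np.sin(2 * np.pi * phase) + 0.02 * rng.standard_normal(n)
    return Waveform(label="Flow", rate=10.0, samples=flow)


def gen_spo2(events: list[ScoredEvent], rng: np.random.Generator,
             rec_duration: float) -> Waveform:
    """1 Hz oxygen saturation with dips at the annotated desaturations."""
    n = int(round(rec_duration))
    spo2 = np.full(n, 96.0) + 0.2 * rng.standard_normal(n)
    t = np.arange(n, dtype=float)
    for ev in events:
        if ev.etype != "desaturation":
            continue
        mid, half = ev.onset + ev.duration / 2.0, ev.duration / 2.0
        dip = (ev.depth or 3.0) * np.exp(-(((t - mid) / max(half, 1.0)) ** 2))
        spo2 -= dip
    return Waveform(label="SpO2", rate=1.0, samples=np.clip(spo2, 50.0, 100.0))


# ---------------------------------------------------------------------------
# cohorts

def draw_event_rate(rng: np.random.Generator) -> float:
    """Per-subject respiratory event rate from the severity mixture."""
    k = rng.choice(len(SEVERITY_WEIGHTS), p=SEVERITY_WEIGHTS)
    lo, hi = SEVERITY_MIXTURE[k]
    return float(rng.uniform(lo, hi))


def gen_subject(cfg: CohortConfig, rng: np.random.Generator, subject_id: str,
                database: str) -> SubjectRecord:
    h_ref = gen_hypnogram(cfg, rng)
    rate = cfg.event_rate if cfg.event_rate is not None else draw_event_rate(rng)
    events = gen_events(h_ref, cfg, rng, event_rate=rate)
    ihr = gen_ihr(events, cfg, rng)
    waveforms: dict[str, Waveform] = {}
    if cfg.with_waveforms:
        waveforms["ppg"] = gen_ppg(ihr, rng)
        waveforms["flow"] = gen_flow(h_ref, events, cfg, rng)
        waveforms["spo2"] = gen_spo2(events, rng, cfg.rec_duration)
    ref_events = [e for e in events if e.etype != "arousal_autonomic"]
    est_events = [e for e in events if e.etype != "arousal_cortical"]
    psg_ref = AnnotationSet(h_ref, ref_events, cfg.rec_duration)
    hsat_est = AnnotationSet(corrupt_hypnogram(h_ref, cfg.corruption, rng),
                             est_events, cfg.rec_duration)
    return SubjectRecord(subject_id=subject_id, database=database,
                         psg_ref=psg_ref, hsat_est=hsat_est,
                         waveforms=waveforms, ihr_ref=ihr)


def gen_cohort(cfg: CohortConfig) -> list[SubjectRecord]:
    """Reproducible cohort: alternating database tags, independent streams."""
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    records = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        db = "cohortA" if i % 2 == 0 else "cohortB"
        records.append(gen_subject(cfg, rng, subject_id=f"S{i:03d}", database=db))
    return records
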