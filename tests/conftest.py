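import numpy as np
import pytest

from somnoscore.annotations import AnnotationSet, Hypnogram, ScoredEvent
from somnoscore.synthetic import CohortConfig, gen_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Eight 10-minute subjects without waveforms, for scoring/fold tests."""
    cfg = CohortConfig(n_subjects=8, rec_duration=600.0, seed=11,
                       with_waveforms=False)
    return gen_cohort(cfg)


@pytest.fixture(scope="session")
def small_wave_cohort():
    """Eight 10-minute subjects with waveforms, for pipeline tests."""
    cfg = CohortConfig(n_subjects=8, rec_duration=600.0, seed=21)
    return gen_cohort(cfg)


def random_annotation_set(rng: np.random.Generator,
                          duration: float = 1800.0) -> AnnotationSet:
    """A small random but valid annotation set (not via the generator)."""
    n_epochs = int(np.ceil(duration / 30.0))
    stages = rng.choice(["W", "N1", "N2", "N3", "R"], size=n_epochs,
                        p=[0.25, 0.15, 0.35, 0.15, 0.10])
    events = []
    for _ in range(rng.integers(0, 15)):
        etype = rng.choice(["apnea_obstructive", "apnea_central", "apnea_mixed",
                            "hypopnea", "arousal_cortical", "arousal_autonomic",
                            "desaturation"])
        onset = rng.uniform(0, duration - 65)
        dur = rng.uniform(5, 60)
        depth = rng.uniform(1, 9) if etype == "desaturation" else None
        events.append(ScoredEvent(etype, onset, dur, depth))
    return AnnotationSet(Hypnogram(stages), events, duration)
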