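"""End-to-end experiment orchestration.

``run_crossval`` performs the full four-fold cross-validation: for each fold,
the network is trained (cardiac phase, then end-to-end with the cardiac
module frozen) on the other three folds, the detection threshold is
calibrated on the training folds, and every subject is scored exactly once by
the model from the iteration in which it sat in the validation fold. The run
manifest records fold assignment, thresholds, seeds and cardiac parameter
hashes so the no-leakage contract is auditable.

``run_evaluation`` turns per-subject index reports into the full statistics
battery: severity confusion tables, binary metrics at the 5/15/30 cuts,
four-class metrics, index agreement (ICC, Bland-Altman), and the arousal
index ROC/PR analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .annotations import AnnotationSet, SubjectRecord
from .events import (FoldAssignment, ProbabilitySeries, calibrate_threshold,
                     make_folds, probability_to_events)
from .net.model import ArousalNet, ModelConfig, preprocess_flow, preprocess_ppg
from .net.train import TrainConfig, predict_ihr, train_cardiac, train_end2end
from .scoring import IndexReport, ScoringConfig, compute_indices, filter_arousals
from .stats import (AgreementReport, ConfusionMatrix4, bland_altman,
                    binary_metrics, fourclass_metrics, icc_absolute,
                    roc_pr_curves, SEVERITY_CUTS)


def prepare_cohort(cohort: list[SubjectRecord]) -> list[SubjectRecord]:
    """Apply the standard signal conditioning to every record's waveforms."""
    out = []
    for rec in cohort:
        wf = dict(rec.waveforms)
        if "ppg" in wf:
            wf["ppg"] = preprocess_ppg(wf["ppg"])
        if "flow" in wf:
            wf["flow"] = preprocess_flow(wf["flow"])
        out.append(replace(rec, waveforms=wf))
    return out


def detect_arousals(model: ArousalNet, rec: SubjectRecord,
                    threshold: float) -> tuple[list, ProbabilitySeries]:
    """Run the detector on one record and return autonomic arousal events."""
    series, _ihr = model.predict(rec.waveforms["ppg"], rec.waveforms["flow"])
    return probability_to_events(series, threshold), series


def rescore_with_detections(rec: SubjectRecord, detected: list) -> SubjectRecord:
    """Replace the estimated annotations' autonomic arousals by detections."""
    est = rec.hsat_est
    events = [e for e in est.events if e.etype != "arousal_autonomic"] + list(detected)
    new_est = AnnotationSet(est.hypnogram, events, est.rec_duration)
    return replace(rec, hsat_est=new_est)


@dataclass
class RunManifest:
    fold_seed: int
    folds: FoldAssignment
    thresholds: dict[int, float] = field(default_factory=dict)
    train_seeds: dict[int, int] = field(default_factory=dict)
    cardiac_hashes: dict[int, str] = field(default_factory=dict)
    scored_by_fold: dict[str, int] = field(default_factory=dict)


def train_fold_model(train_recs: list[SubjectRecord], model_cfg: ModelConfig,
                     cardiac_tc: TrainConfig, e2e_tc: TrainConfig) -> ArousalNet:
    model = ArousalNet(model_cfg)
    train_cardiac(model, train_recs, cardiac_tc)
    train_end2end(model, train_recs, e2e_tc)
    return model


def run_crossval(cohort: list[SubjectRecord], model_cfg: ModelConfig,
                 cardiac_tc: TrainConfig, e2e_tc: TrainConfig,
                 fold_seed: int = 0, n_folds: int = 4,
                 scoring_cfg: ScoringConfig | None = None,
                 ) -> tuple[RunManifest, dict[str, IndexReport],
                            dict[str, ProbabilitySeries]]:
    """Cross-validated detection and scoring of a prepared cohort."""
    folds = make_folds([(r.subject_id, r.database) for r in cohort], seed=fold_seed,
                       n_folds=n_folds)
    manifest = RunManifest(fold_seed=fold_seed, folds=folds)
    by_id = {r.subject_id: r for r in cohort}
    reports: dict[str, IndexReport] = {}
    probs: dict[str, ProbabilitySeries] = {}
    for fold in range(n_folds):
        train_ids = set(folds.training_subjects(fold))
        train_recs = [by_id[s] for s in sorted(train_ids)]
        val_recs = [by_id[s] for s in sorted(folds.subjects_in(fold))]
        seed = cardiac_tc.seed + fold
        c_tc = replace(cardiac_tc, seed=seed)
        e_tc = replace(e2e_tc, seed=seed)
        model = train_fold_model(train_recs, replace(model_cfg, seed=seed),
                                 c_tc, e_tc)
        manifest.train_seeds[fold] = seed
        manifest.cardiac_hashes[fold] = model.cardiac_hash()

        calib = []
        for rec in train_recs:
            series, _ = model.predict(rec.waveforms["ppg"], rec.waveforms["flow"])
            ref = filter_arousals(rec.psg_ref.events_of("arousal_cortical"),
                                  rec.psg_ref.hypnogram)
            calib.append((series, ref))
        threshold = calibrate_threshold(calib)
        manifest.thresholds[fold] = threshold

        for rec in val_recs:
            detected, series = detect_arousals(model, rec, threshold)
            scored = rescore_with_detections(rec, detected)
            reports[rec.subject_id] = compute_indices(scored, scoring_cfg)
            probs[rec.subject_id] = series
            manifest.scored_by_fold[rec.subject_id] = fold
    return manifest, reports, probs


@dataclass
class EvaluationReport:
    confusions: dict[str, ConfusionMatrix4]
    binary: dict[str, dict[float, object]]
    fourclass: dict[str, object]
    agreement: dict[str, AgreementReport]
    arousal_agreement: AgreementReport | None = None
    arousal_roc: object = None
    arousal_pr: object = None


SURROGATES = ("rei", "ahi_est", "ahi_est_autar")


def run_evaluation(reports: list[IndexReport], ari_cut: float = 20.0) -> EvaluationReport:
    """Full statistics battery over per-subject index reports."""
    if len(reports) < 2:
        raise ValueError("evaluation requires at least two subjects")
    truth = np.array([r.ahi_psg for r in reports])
    confusions, binary, fourclass, agreement = {}, {}, {}, {}
    for name in SURROGATES:
        est = np.array([getattr(r, name) for r in reports])
        cm = ConfusionMatrix4.from_indices(est, truth)
        confusions[name] = cm
        per_cut = {}
        for cut in SEVERITY_CUTS:
            try:
                per_cut[cut] = binary_metrics(cm, cut)
            except ValueError:
                per_cut[cut] = None  # degenerate class split; flagged, not fatal
        binary[name] = per_cut
        try:
            fourclass[name] = fourclass_metrics(cm)
        except ValueError:
            fourclass[name] = None  # single-class cohort: kappa undefined
        ba = bland_altman(truth, est)
        try:
            agr = icc_absolute(truth, est)
            ba = replace(ba, icc=agr.icc, icc_ci=agr.icc_ci)
        except ValueError:
            pass  # zero variance in both raters: ICC stays flagged as nan
        agreement[name] = ba

    out = EvaluationReport(confusions=confusions, binary=binary,
                           fourclass=fourclass, agreement=agreement)
    ari = np.array([r.ari for r in reports])
    autari = np.array([r.autari for r in reports])
    agr = icc_absolute(ari, autari)
    ba = bland_altman(ari, autari)
    out.arousal_agreement = replace(ba, icc=agr.icc, icc_ci=agr.icc_ci)
    labels = ari >= ari_cut
    if labels.any() and not labels.all():
        out.arousal_roc, out.arousal_pr = roc_pr_curves(autari, labels)
    return out


def evaluate_counts(confusions: dict[str, ConfusionMatrix4]) -> EvaluationReport:
    """Tables-only evaluation path for externally supplied confusion counts."""
    binary = {name: {cut: binary_metrics(cm, cut) for cut in SEVERITY_CUTS}
              for name, cm in confusions.items()}
    fourclass = {name: fourclass_metrics(cm) for name, cm in confusions.items()}
    return EvaluationReport(confusions=confusions, binary=binary,
                            fourclass=fourclass, agreement={})
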