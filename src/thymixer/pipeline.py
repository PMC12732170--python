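"""Model/Results surface tying the whole pipeline together.

:class:`ThymomaMixerCV` is built from a cohort (in memory or on disk) and a
task; ``fit()`` runs patient-level stratified k-fold cross-validation —
preprocessing, training the CNN+mixer classifier per fold, predicting the
held-out patches and aggregating them to patient decisions — and returns a
:class:`CVResults` carrying per-fold and averaged metrics, the patch
predictions, the patient decisions and a ``summary()`` table.

Typical use::

    cohort = phantom.generate_cohort(n_healthy=12, n_benign=6, n_malignant=6,
                                     slices_per_scan=(9, 15),
                                     lesion_contrast=0.5, seed=7)
    model = ThymomaMixerCV(cohort, model_config=ModelConfig(backbone="small"),
                           train_config=TrainConfig(epochs=10,
                                                    learning_rate=1e-3))
    res = model.fit(k=3, seed=7)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregate import THYMOMA, patient_decision, scan_decision, stage2_decision
from .crossval import (STAGE1, STAGE2, FoldPlan, FoldResult, TrainConfig,
                       cohort_to_patches, make_folds, run_fold,
                       select_task_patches)
from .metrics import ConfusionCounts, MetricReport, compute_metrics, confusion, \
    fold_average
from .mixer import MixerNet, ModelConfig
from .phantom import HEALTHY, MALIGNANT, PhantomCohort, load_cohort
from .preprocess import FusedPatch, PreprocessConfig

__all__ = ["ThymomaMixerCV", "CVResults"]


@dataclass
class CVResults:
    """Cross-validated evaluation of the patch classifier plus aggregation."""

    task: str
    classes: tuple[str, str]
    fold_plan: FoldPlan
    fold_reports: list[MetricReport]          # patch-level, per fold
    patient_reports: list[MetricReport]       # patient-level, per fold
    patient_confusions: list[ConfusionCounts]
    predictions: pd.DataFrame                 # all held-out patch predictions
    patient_decisions: pd.DataFrame           # patient_id, fold, true, decision
    loss_histories: list[list[float]]
    models: list[MixerNet] = field(default_factory=list)

    @property
    def average_report(self) -> MetricReport:
        """Unweighted mean of the per-fold patch-level reports."""
        return fold_average(self.fold_reports)

    @property
    def average_patient_report(self) -> MetricReport:
        return fold_average(self.patient_reports)

    def summary(self) -> str:
        lines = [
            f"Patient-level {self.fold_plan.k}-fold cross-validation — task: {self.task}",
            f"classes: {self.classes[0]} / {self.classes[1]}",
            "",
            "Patch level (per fold, %):",
            f"{'fold':>4} {'acc':>7} {'macroP':>7} {'macroR':>7} {'macroF1':>7} {'n':>6}",
        ]
        for i, r in enumerate(self.fold_reports):
            rr = r.rounded()
            lines.append(f"{i + 1:>4} {rr.accuracy:>7.2f} {rr.macro_precision:>7.2f} "
                         f"{rr.macro_recall:>7.2f} {rr.macro_f1:>7.2f} {r.n:>6}")
        avg = self.average_report.rounded()
        lines.append(f"{'avg':>4} {avg.accuracy:>7.2f} {avg.macro_precision:>7.2f} "
                     f"{avg.macro_recall:>7.2f} {avg.macro_f1:>7.2f} "
                     f"{sum(r.n for r in self.fold_reports):>6}")
        lines += ["", "Patient level (per fold):",
                  f"{'fold':>4} {'acc%':>7} {'TP':>4} {'FP':>4} {'FN':>4} {'TN':>4}"]
        for i, (r, c) in enumerate(zip(self.patient_reports, self.patient_confusions)):
            lines.append(f"{i + 1:>4} {r.rounded().accuracy:>7.2f} {c.tp:>4} "
                         f"{c.fp:>4} {c.fn:>4} {c.tn:>4}")
        pavg = self.average_patient_report.rounded()
        lines.append(f"{'avg':>4} {pavg.accuracy:>7.2f}")
        return "\n".join(lines)


class ThymomaMixerCV:
    """Cross-validated CNN + MLP-Mixer thymoma classifier.

    Parameters
    ----------
    cohort:
        A :class:`~thymixer.phantom.PhantomCohort` (or anything iterable of
        patients with ``patient_id``, ``label`` and ``volume``).
    task:
        ``"thymoma_vs_healthy"`` (stage 1, all patients, any-positive
        aggregation) or ``"benign_vs_malignant"`` (stage 2, thymoma patients
        only, majority-vote aggregation).
    """

    def __init__(self, cohort: PhantomCohort, task: str = STAGE1,
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None,
                 preprocess_config: PreprocessConfig | None = None):
        self.cohort = cohort
        self.task = task
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig(task=task)
        self.preprocess_config = preprocess_config or PreprocessConfig()

    @classmethod
    def from_directory(cls, directory: str | Path, **kwargs) -> "ThymomaMixerCV":
        return cls(load_cohort(directory), **kwargs)

    # positive class conventions used for per-fold confusion counts
    _POSITIVE = {STAGE1: HEALTHY, STAGE2: MALIGNANT}

    def fit(self, k: int = 5, seed: int = 0, verbose: bool = False,
            store_models: bool = False) -> CVResults:
        all_patches = cohort_to_patches(self.cohort, self.preprocess_config)
        patches = select_task_patches(all_patches, self.task)
        patient_labels = {}
        for p in patches:
            patient_labels[p.patient_id] = p.label
        # stratify by the full 3-way label so folds mirror the cohort
        strat_labels = {pid: self.cohort.labels.get(pid, patient_labels[pid])
                        for pid in patient_labels}
        plan = make_folds(strat_labels, k=k, seed=seed)
        classes = tuple(sorted(set(patient_labels.values())))
        positive = self._POSITIVE[self.task]

        fold_reports, patient_reports, patient_confusions = [], [], []
        preds_frames, decision_rows, losses, models = [], [], [], []
        for fold in range(k):
            train = [p for p in patches if plan.assignments[p.patient_id] != fold]
            test = [p for p in patches if plan.assignments[p.patient_id] == fold]
            res = run_fold(train, test, self.model_config, self.train_config,
                           fold=fold, verbose=verbose)
            df = res.predictions.assign(fold=fold)
            preds_frames.append(df)
            losses.append(res.loss_history)
            if store_models:
                models.append(res.model)

            c = confusion(df["true"], df["pred"], positive_class=positive)
            fold_reports.append(compute_metrics(c))

            p_true, p_pred = self._aggregate(df, patient_labels, res.classes)
            for pid in sorted(p_true):
                decision_rows.append((pid, fold, p_true[pid], p_pred[pid]))
            pc = confusion([p_true[p] for p in sorted(p_true)],
                           [p_pred[p] for p in sorted(p_true)],
                           positive_class=positive)
            patient_confusions.append(pc)
            patient_reports.append(compute_metrics(pc))

        return CVResults(
            task=self.task, classes=classes, fold_plan=plan,
            fold_reports=fold_reports, patient_reports=patient_reports,
            patient_confusions=patient_confusions,
            predictions=pd.concat(preds_frames, ignore_index=True),
            patient_decisions=pd.DataFrame(
                decision_rows, columns=["patient_id", "fold", "true", "decision"]),
            loss_histories=losses, models=models)

    def _aggregate(self, df: pd.DataFrame, patient_labels: dict[str, str],
                   classes: tuple[str, str]):
        """Patch predictions -> one decision per held-out patient."""
        p_true, p_pred = {}, {}
        for pid, g in df.groupby("patient_id"):
            p_true[pid] = patient_labels[pid]
            if self.task == STAGE1:
                per_scan = [scan_decision(list(sg["pred"]), scan_id=sid)
                            for sid, sg in g.groupby("scan_id")]
                p_pred[pid] = patient_decision(per_scan)
            else:
                p_pred[pid] = stage2_decision(labels=list(g["pred"]))
        return p_true, p_pred
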