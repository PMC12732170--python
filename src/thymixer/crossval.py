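"""Patient-level stratified k-fold cross-validation and the training loop.

Fold assignment is by *patient identity*, never by slice or patch: every
patient's patches appear in the test set of exactly one fold, and a hard
:class:`~thymixer.errors.LeakageError` is raised if a patient ever shows up
on both sides of a split.  Stratification uses the full three-way label
(healthy/benign/malignant) even for the stage-1 task, so each fold mirrors
the cohort's composition.

The default training configuration matches the reference protocol: Adam,
batch size 64, learning rate 1e-4, 100 epochs, categorical cross-entropy,
no early stopping and no class weighting.  Experiments on phantoms override
epochs/learning-rate downward through the same config object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import nn
from .errors import EmptyTaskError, LeakageError, ParameterError, StratificationError
from .mixer import MixerNet, ModelConfig
from .phantom import BENIGN, HEALTHY, MALIGNANT, PhantomCohort
from .preprocess import FusedPatch, PreprocessConfig, preprocess_scan

STAGE1 = "thymoma_vs_healthy"
STAGE2 = "benign_vs_malignant"

__all__ = ["FoldPlan", "TrainConfig", "FoldResult", "make_folds",
           "cohort_to_patches", "select_task_patches", "run_fold",
           "STAGE1", "STAGE2"]


@dataclass
class FoldPlan:
    """A patient-level partition: ``assignments[pid]`` is the fold whose
    *test* set contains that patient."""

    k: int
    assignments: dict[str, int]

    def test_patients(self, fold: int) -> set[str]:
        return {p for p, f in self.assignments.items() if f == fold}

    def train_patients(self, fold: int) -> set[str]:
        return {p for p, f in self.assignments.items() if f != fold}


@dataclass
class TrainConfig:
    batch_size: int = 64
    learning_rate: float = 1e-4
    epochs: int = 100
    optimizer: str = "adam"
    seed: int = 0
    task: str = STAGE1

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ParameterError("epochs and batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ParameterError("only the adam optimizer is supported")
        if self.task not in (STAGE1, STAGE2):
            raise ParameterError(f"task must be {STAGE1!r} or {STAGE2!r}")


@dataclass
class FoldResult:
    fold: int
    classes: tuple[str, str]
    predictions: pd.DataFrame  # patient_id, scan_id, patch_idx, true, pred, p_*
    loss_history: list[float]
    model: MixerNet


def make_folds(labels: dict[str, str], k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified patient-level folds, deterministic given the seed."""
    pids = sorted(labels)
    ys = [labels[p] for p in pids]
    counts = pd.Series(ys).value_counts()
    if k > counts.min():
        raise StratificationError(
            f"k={k} exceeds the size of the smallest class "
            f"({counts.idxmin()}: {counts.min()} patients)")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(pids, ys)):
        for i in test_idx:
            assignments[pids[i]] = fold
    return FoldPlan(k=k, assignments=assignments)


def cohort_to_patches(cohort: PhantomCohort,
                      cfg: PreprocessConfig | None = None) -> list[FusedPatch]:
    """Preprocess every scan of a cohort into labeled fused patches."""
    patches: list[FusedPatch] = []
    for p in cohort:
        patches.extend(preprocess_scan(p.volume, cfg, label=p.label))
    return patches


def select_task_patches(patches: list[FusedPatch], task: str
                        ) -> list[FusedPatch]:
    """Relabel (stage 1) or restrict (stage 2) patches for a task.

    Stage 1 keeps every patch, collapsing benign and malignant to
    ``"thymoma"``.  Stage 2 keeps only thymoma patients' patches with their
    benign/malignant labels.  Returns copies; the inputs are not mutated.
    """
    if task == STAGE1:
        out = [replace(p, label=HEALTHY if p.label == HEALTHY else "thymoma")
               for p in patches]
    elif task == STAGE2:
        out = [replace(p) for p in patches if p.label in (BENIGN, MALIGNANT)]
    else:
        raise EmptyTaskError(f"unknown task {task!r}")
    if not out:
        raise EmptyTaskError(f"task {task!r} selected zero patches")
    return out


def run_fold(train_patches: list[FusedPatch], test_patches: list[FusedPatch],
             model_cfg: ModelConfig | None = None,
             train_cfg: TrainConfig | None = None,
             fold: int = 0, verbose: bool = False) -> FoldResult:
    """Train on one fold's training patches and predict its test patches.

    The patient disjointness of the two sides is *verified*, not assumed.
    Class order is the sorted pair of labels present in the training set;
    predictions carry per-class probabilities and hard labels.
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    train_pids = {p.patient_id for p in train_patches}
    test_pids = {p.patient_id for p in test_patches}
    overlap = train_pids & test_pids
    if overlap:
        raise LeakageError(
            f"patients present in both train and test sets of fold {fold}: "
            f"{sorted(overlap)}")
    classes = tuple(sorted({p.label for p in train_patches}))
    if len(classes) != 2:
        raise EmptyTaskError(f"fold {fold} training set has classes {classes}; "
                             f"need exactly 2")
    cls_idx = {c: i for i, c in enumerate(classes)}
    x_train = np.stack([p.pixels for p in train_patches]).astype(np.float32)
    y_train = np.array([cls_idx[p.label] for p in train_patches])
    x_test = np.stack([p.pixels for p in test_patches]).astype(np.float32)

    model = MixerNet(model_cfg, seed=train_cfg.seed)
    opt = nn.Adam(model.trainable_layers, lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed + 1)
    losses: list[float] = []
    for epoch in range(train_cfg.epochs):
        perm = rng.permutation(len(x_train))
        epoch_loss, n_batches = 0.0, 0
        for i in range(0, len(perm), train_cfg.batch_size):
            idx = perm[i:i + train_cfg.batch_size]
            logits = model.forward(x_train[idx])
            loss, dlogits = nn.softmax_cross_entropy(logits, y_train[idx])
            opt.zero_grads()
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / max(n_batches, 1))
        if verbose:
            print(f"fold={fold} epoch={epoch + 1}/{train_cfg.epochs} "
                  f"loss={losses[-1]:.4f}")

    probs = model.predict_proba(x_test, batch_size=train_cfg.batch_size)
    pred = [classes[i] for i in probs.argmax(axis=1)]
    predictions = pd.DataFrame({
        "patient_id": [p.patient_id for p in test_patches],
        "scan_id": [p.scan_id for p in test_patches],
        "patch_idx": list(range(len(test_patches))),
        "true": [p.label for p in test_patches],
        "pred": pred,
        f"p_{classes[0]}": probs[:, 0],
        f"p_{classes[1]}": probs[:, 1],
    })
    return FoldResult(fold=fold, classes=classes, predictions=predictions,
                      loss_history=losses, model=model)
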