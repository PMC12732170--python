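"""Patch-to-scan and scan-to-patient decision aggregation.

Stage 1 (thymoma vs healthy) uses the *any-positive* rule: every patch of a
scan is classified independently, the hard labels are collected, and the
scan is called thymoma if at least one patch is; otherwise healthy.  The
same rule lifts scan decisions to the patient level.  Decisions operate on
hard labels, matching the stated algorithm; no probability thresholding is
involved at this stage.

Stage 2 (benign vs malignant) has no published aggregation rule, so the
default here is a majority vote over patch hard labels with ties resolved
to malignant (the conservative clinical call); a mean-probability argmax
variant is available via ``rule="mean_prob"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoPatchesError
from .phantom import BENIGN, HEALTHY, MALIGNANT

THYMOMA = "thymoma"

__all__ = ["ScanDecision", "scan_decision", "patient_decision",
           "stage2_decision", "THYMOMA"]


@dataclass
class ScanDecision:
    scan_id: str
    patch_labels: list[str]
    final_label: str
    n_positive_patches: int


def scan_decision(patch_labels: list[str], scan_id: str = "",
                  positive: str = THYMOMA, negative: str = HEALTHY
                  ) -> ScanDecision:
    """Any-positive rule: one positive patch makes the whole scan positive."""
    labels = list(patch_labels)
    if not labels:
        raise NoPatchesError(f"scan {scan_id or '<unnamed>'} has no patches")
    n_pos = sum(1 for l in labels if l == positive)
    return ScanDecision(scan_id=scan_id, patch_labels=labels,
                        final_label=positive if n_pos >= 1 else negative,
                        n_positive_patches=n_pos)


def patient_decision(scan_decisions: list[ScanDecision],
                     positive: str = THYMOMA, negative: str = HEALTHY) -> str:
    """Any-positive rule across all of a patient's scans."""
    if not scan_decisions:
        raise NoPatchesError("patient has no scan decisions")
    return positive if any(d.final_label == positive for d in scan_decisions) \
        else negative


def stage2_decision(labels: list[str] | None = None,
                    probs: np.ndarray | None = None,
                    rule: str = "majority",
                    classes: tuple[str, str] = (BENIGN, MALIGNANT)) -> str:
    """Benign/malignant call for one patient from patch outputs.

    ``rule="majority"`` votes over hard ``labels`` (ties -> malignant);
    ``rule="mean_prob"`` takes the argmax of the mean probability pair in
    ``probs`` (rows ordered as ``classes``; exact ties -> malignant).
    """
    benign, malignant = classes
    if rule == "majority":
        if not labels:
            raise NoPatchesError("majority vote needs at least one patch label")
        n_mal = sum(1 for l in labels if l == malignant)
        n_ben = sum(1 for l in labels if l == benign)
        return malignant if n_mal >= n_ben else benign
    if rule == "mean_prob":
        if probs is None or len(probs) == 0:
            raise NoPatchesError("mean_prob needs at least one probability pair")
        mean = np.asarray(probs, dtype=float).mean(axis=0)
        return malignant if mean[1] >= mean[0] else benign
    raise ValueError(f"unknown stage-2 rule {rule!r}")
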