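"""Segmentation quality metrics for mask pairs.

Five standard measures over a segmented mask A and ground truth B:

    VOE       = (1 - |A n B| / |A u B|) * 100      (volumetric overlap error, %)
    precision = TP / (TP + FP)
    accuracy  = (TP + TN) / (TP + FP + FN + TN)
    DSC       = 2 TP / (2 TP + FP + FN)            (Dice similarity)
    RVD       = (|A| - |B|) / |B| * 100            (relative volume difference, %)

RVD is signed: negative means under-segmentation.  VOE and DSC are tied
by DSC = 2(1 - V)/(2 - V) with V = VOE/100.  An RVD of zero does not
imply a good segmentation — any equal-volume mask achieves it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class OverlapReport:
    """Confusion counts and derived overlap measures for one mask pair."""

    tp: int
    fp: int
    fn: int
    tn: int
    voe: float  # percent, 0 = perfect
    precision: float
    accuracy: float
    dsc: float
    rvd: float | None  # signed percent; None when the truth is empty

    @property
    def rvd_abs(self) -> float | None:
        return None if self.rvd is None else abs(self.rvd)

    def as_dict(self) -> dict:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "TN": self.tn,
            "VOE_percent": self.voe,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "DSC": self.dsc,
            "RVD_percent": self.rvd,
            "RVD_abs_percent": self.rvd_abs,
        }


def confusion_counts(segmented: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) pixel counts for binary masks of equal shape."""
    a = np.asarray(segmented, dtype=bool)
    b = np.asarray(truth, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    tp = int((a & b).sum())
    fp = int((a & ~b).sum())
    fn = int((~a & b).sum())
    tn = int((~a & ~b).sum())
    return tp, fp, fn, tn


def compute_report(segmented: np.ndarray, truth: np.ndarray) -> OverlapReport:
    """Full overlap report for one mask pair.

    Conventions: both masks empty -> VOE 0, DSC 1 (a vacuous perfect
    match); empty truth -> RVD is None (undefined).
    """
    tp, fp, fn, tn = confusion_counts(segmented, truth)
    union = tp + fp + fn
    inter = tp
    n_a = tp + fp
    n_b = tp + fn
    voe = 0.0 if union == 0 else (1.0 - inter / union) * 100.0
    dsc = 1.0 if (2 * tp + fp + fn) == 0 else 2.0 * tp / (2 * tp + fp + fn)
    precision = 1.0 if n_a == 0 else tp / n_a
    total = tp + fp + fn + tn
    accuracy = (tp + tn) / total if total else 1.0
    rvd = None if n_b == 0 else (n_a - n_b) / n_b * 100.0
    return OverlapReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        voe=voe, precision=precision, accuracy=accuracy, dsc=dsc, rvd=rvd,
    )
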