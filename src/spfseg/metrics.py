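"""Segmentation overlap metrics (Dice similarity coefficient).

DSC(S1, S2) = 2 N(S1 and S2) / (N(S1) + N(S2)), the standard voxel-overlap
measure: 1 for identical masks, 0 for disjoint ones. Multi-label maps are
scored per label; when the label identities of prediction and truth are not
in canonical correspondence (phantom solver output vs generator labels),
the best label permutation is searched exhaustively.
"""

from __future__ import annotations

import csv
import itertools
import json
import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = ["DiceReport", "dice", "multi_label_dice", "robustness_summary", "write_report"]

logger = logging.getLogger(__name__)


@dataclass
class DiceReport:
    per_label: Dict[int, float]
    mean: float
    label_mapping: Dict[int, int] | None = None  # pred label -> truth label


def dice(s1: np.ndarray, s2: np.ndarray) -> float:
    """Dice coefficient of two boolean masks; empty-vs-empty counts as 1."""
    s1 = np.asarray(s1).astype(bool)
    s2 = np.asarray(s2).astype(bool)
    if s1.shape != s2.shape:
        raise ValueError(f"mask shapes disagree: {s1.shape} vs {s2.shape}")
    denom = int(s1.sum()) + int(s2.sum())
    if denom == 0:
        logger.info("both masks empty; Dice defined as 1.0")
        return 1.0
    return 2.0 * int((s1 & s2).sum()) / denom


def multi_label_dice(
    labels1: np.ndarray,
    labels2: np.ndarray,
    label_matching: str = "fixed",
) -> DiceReport:
    """Per-label Dice between two label maps.

    ``labels1`` is the prediction, ``labels2`` the reference. With
    ``label_matching="fixed"`` labels are compared by value; with
    ``"best-permutation"`` every bijection between the prediction's and the
    reference's label sets is tried and the one maximizing the mean Dice is
    reported (per-label values are keyed by reference label).
    """
    labels1 = np.asarray(labels1)
    labels2 = np.asarray(labels2)
    if labels1.shape != labels2.shape:
        raise ValueError("label map shapes disagree")
    if label_matching not in ("fixed", "best-permutation"):
        raise ValueError(f"unknown label_matching {label_matching!r}")

    ref_labels = sorted(int(v) for v in np.unique(labels2))
    pred_labels = sorted(int(v) for v in np.unique(labels1))

    if label_matching == "fixed":
        per = {lab: dice(labels1 == lab, labels2 == lab) for lab in ref_labels}
        return DiceReport(per_label=per, mean=float(np.mean(list(per.values()))))

    # pad the shorter label set so every reference label gets an assignment
    k = max(len(ref_labels), len(pred_labels))
    pad_pred = pred_labels + [None] * (k - len(pred_labels))
    best = None
    for perm in itertools.permutations(pad_pred, k):
        per = {}
        for ref_lab, pred_lab in zip(ref_labels, perm):
            pred_mask = (labels1 == pred_lab) if pred_lab is not None else np.zeros_like(labels1, bool)
            per[ref_lab] = dice(pred_mask, labels2 == ref_lab)
        mean = float(np.mean(list(per.values())))
        if best is None or mean > best[0]:
            mapping = {p: r for r, p in zip(ref_labels, perm) if p is not None}
            best = (mean, per, mapping)
    mean, per, mapping = best
    return DiceReport(per_label=per, mean=mean, label_mapping=mapping)


def robustness_summary(masks: Sequence[np.ndarray]) -> Tuple[float, float]:
    """(min, mean) pairwise Dice over all unordered pairs of masks.

    Quantifies initialization robustness: masks obtained from different
    initial contours should be nearly identical for a robust model.
    """
    if len(masks) < 2:
        raise ValueError("need at least 2 masks")
    pair_values: List[float] = [
        dice(a, b) for a, b in itertools.combinations(masks, 2)
    ]
    return float(min(pair_values)), float(np.mean(pair_values))


def write_report(report: DiceReport, json_path=None, csv_path=None) -> None:
    """Serialize a DiceReport as JSON and/or CSV (one row per label)."""
    payload = {
        "per_label": {str(k): v for k, v in report.per_label.items()},
        "mean": report.mean,
    }
    if report.label_mapping is not None:
        payload["label_mapping"] = {str(k): v for k, v in report.label_mapping.items()}
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["label", "dice"])
            for lab in sorted(report.per_label):
                writer.writerow([lab, f"{report.per_label[lab]:.6f}"])
            writer.writerow(["mean", f"{report.mean:.6f}"])
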