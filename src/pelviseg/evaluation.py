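"""Dice similarity coefficient and per-case summaries.

By default the evaluation pools compact bone (1) and filled interior (2)
into a single "bone" foreground, matching the marrow-inclusive bone
definition used for the ground truth.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import AlignmentError, ParameterError
from .volumes import BinaryMask, LabelVolume

DEFAULT_POSITIVE_LABELS = (1, 2)


@dataclass
class DiceResult:
    """Dice overlap between a predicted and a reference segmentation."""

    case_id: str
    dice: float
    n_truth: int
    n_pred: int
    n_intersection: int

    def __post_init__(self):
        if not (0.0 <= self.dice <= 1.0):
            raise ParameterError(f"dice must lie in [0, 1], got {self.dice}")
        if self.n_intersection > min(self.n_truth, self.n_pred):
            raise ParameterError("intersection larger than one of the sets")

    def row(self) -> dict:
        return {"case_id": self.case_id, "dice": f"{self.dice:.6f}",
                "n_truth": self.n_truth, "n_pred": self.n_pred,
                "n_intersection": self.n_intersection}


def _binarize(vol: BinaryMask | LabelVolume | np.ndarray,
              positive_labels: Sequence[int]) -> np.ndarray:
    if isinstance(vol, BinaryMask):
        return vol.data
    if isinstance(vol, LabelVolume):
        return np.isin(vol.data, np.asarray(positive_labels))
    arr = np.asarray(vol)
    if arr.dtype == bool:
        return arr
    return np.isin(arr, np.asarray(positive_labels))


def dice_coefficient(pred, truth,
                     positive_labels: Sequence[int] = DEFAULT_POSITIVE_LABELS,
                     case_id: str = "") -> DiceResult:
    """Dice = 2|A∩B| / (|A|+|B|) between prediction and reference.

    Accepts binary masks or label volumes; label volumes are binarized by
    ``positive_labels`` (default ``{1, 2}``: all bone).  When both sets are
    empty, Dice is defined as 1.0 (perfect agreement on absence) with a
    warning.  Symmetric in its two arguments.
    """
    a = _binarize(pred, positive_labels)
    b = _binarize(truth, positive_labels)
    if a.shape != b.shape:
        raise AlignmentError(f"shape mismatch: {a.shape} vs {b.shape}")
    n_a, n_b = int(a.sum()), int(b.sum())
    n_i = int((a & b).sum())
    if n_a + n_b == 0:
        warnings.warn("both segmentations empty; Dice defined as 1.0", stacklevel=2)
        dice = 1.0
    else:
        dice = 2.0 * n_i / (n_a + n_b)
    return DiceResult(case_id=case_id, dice=dice, n_truth=n_b, n_pred=n_a,
                      n_intersection=n_i)


def summarize(results: Iterable[DiceResult], bins: int = 10) -> dict:
    """Mean/min/max and a histogram over [0, 1] of per-case Dice values."""
    values = np.array([r.dice for r in results], dtype=float)
    if values.size == 0:
        raise ParameterError("cannot summarize an empty result list")
    counts, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    return {
        "n": int(values.size),
        "mean": float(values.mean()),
        "min": float(values.min()),
        "max": float(values.max()),
        "histogram_counts": counts.tolist(),
        "histogram_edges": edges.tolist(),
    }


def write_csv(results: Iterable[DiceResult], path: str | Path) -> None:
    rows = [r.row() for r in results]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["case_id", "dice", "n_truth",
                                                "n_pred", "n_intersection"])
        writer.writeheader()
        writer.writerows(rows)


def read_csv(path: str | Path) -> list[DiceResult]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(DiceResult(case_id=row["case_id"], dice=float(row["dice"]),
                                  n_truth=int(row["n_truth"]),
                                  n_pred=int(row["n_pred"]),
                                  n_intersection=int(row["n_intersection"])))
    return out
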