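"""Overlap metrics between an automatic mask and a ground-truth mask.

With ``A`` the ground-truth region and ``B`` the predicted region:

    JSC = |A and B| / |A or B|          (Jaccard)
    DSC = 2 |A and B| / (|A| + |B|)     (Dice)
    FPR = |B - A| / |A or B|            (over-segmentation)
    FNR = |A - B| / |A or B|            (under-segmentation)

All four are set-difference areas normalised by the union, so the identity
``JSC = 1 - FPR - FNR`` holds exactly, and ``DSC = 2 JSC / (1 + JSC)``.

``paper_orientation=True`` swaps the FPR/FNR numerators to the printed
orientation of the source equations (FPR numerator = truth-only pixels);
the default follows the conventional reading in which FPR counts pixels
the algorithm added and FNR pixels it missed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, Sequence

import numpy as np

from .io_formats import BinaryMask

__all__ = [
    "UndefinedMetricError",
    "MetricsReport",
    "SummaryRow",
    "compute_metrics",
    "summarize",
]

METRIC_NAMES = ("jsc", "dsc", "fpr", "fnr")


class UndefinedMetricError(ValueError):
    """Raised when both masks are empty and the ratios are undefined."""


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    jsc: float
    dsc: float
    fpr: float
    fnr: float
    n_truth: int
    n_pred: int
    n_intersection: int
    n_union: int

    def to_dict(self) -> Dict[str, float]:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class SummaryRow:
    """Per-metric mean and sample standard deviation over a batch of cases."""

    mean: Dict[str, float]
    sd: Dict[str, float]
    n: int

    def to_dict(self) -> Dict[str, object]:
        return {"n": self.n, "mean": dict(self.mean), "sd": dict(self.sd)}

    def to_text(self) -> str:
        cells = [
            f"{name.upper()} {self.mean[name]:.2f} ± {self.sd[name]:.2f}"
            for name in METRIC_NAMES
        ]
        return f"n={self.n}  " + "  ".join(cells)


def compute_metrics(
    truth: BinaryMask, pred: BinaryMask, paper_orientation: bool = False
) -> MetricsReport:
    """Compare a predicted mask against ground truth (see module docstring)."""
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {pred.shape}")
    a = truth.pixels
    b = pred.pixels
    n_truth = int(np.count_nonzero(a))
    n_pred = int(np.count_nonzero(b))
    n_inter = int(np.count_nonzero(a & b))
    n_union = n_truth + n_pred - n_inter
    if n_union == 0:
        raise UndefinedMetricError("both masks are empty; overlap metrics undefined")
    jsc = n_inter / n_union
    dsc = 2.0 * n_inter / (n_truth + n_pred)
    pred_only = (n_pred - n_inter) / n_union
    truth_only = (n_truth - n_inter) / n_union
    if paper_orientation:
        fpr, fnr = truth_only, pred_only
    else:
        fpr, fnr = pred_only, truth_only
    return MetricsReport(jsc, dsc, fpr, fnr, n_truth, n_pred, n_inter, n_union)


def summarize(reports: Sequence[MetricsReport]) -> SummaryRow:
    """Mean and sample SD (n-1 denominator; 0 for a single case) per metric."""
    if len(reports) == 0:
        raise ValueError("need at least one report to summarise")
    mean: Dict[str, float] = {}
    sd: Dict[str, float] = {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(r, name) for r in reports], dtype=np.float64)
        mean[name] = float(vals.mean())
        sd[name] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        if not math.isfinite(sd[name]):
            sd[name] = 0.0
    return SummaryRow(mean=mean, sd=sd, n=len(reports))
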