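"""Agreement and detection metrics against reader segmentations.

The gold standard (GS) is a majority vote over reader masks (a voxel is
lesion if at least 3 of 4 readers marked it).  Voxel-level agreement is the
Dice similarity coefficient; lesion-level detection counts a GS lesion as
found if it overlaps — at least partially, one voxel suffices — any
predicted component, and a predicted component as correct if it overlaps
any GS lesion, giving sensitivity = detected/GS and PPV = correct/predicted.
Quantitative agreement between paired measurements (ADC metrics, volumes)
uses the intraclass correlation coefficient ICC(2,1): two-way random
effects, absolute agreement, single measures, computed from the ANOVA mean
squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import BinaryMask, LabeledComponents, mask_union

__all__ = [
    "DetectionMetrics",
    "majority_vote",
    "dice",
    "match_lesions",
    "icc",
    "pairwise_dice",
    "compare_dsc_distributions",
    "truncate3",
]


def truncate3(value: float) -> float:
    """Truncate toward zero at 3 decimals (reporting convention: 4/6 -> 0.666)."""
    return math.trunc(value * 1000) / 1000.0


@dataclass
class DetectionMetrics:
    """Lesion-level detection counts plus voxel-level Dice.

    ``sensitivity``/``ppv`` are None (undefined), never silently 0, when
    their denominator is zero.
    """

    dsc: float
    sensitivity: float | None
    ppv: float | None
    n_gs: int
    n_pred: int
    n_gs_detected: int
    n_pred_correct: int
    match_pairs: list[tuple[int, int]]  # (pred_id, gs_id) overlapping pairs

    def matched_pred_ids(self) -> list[int]:
        return sorted({p for p, _ in self.match_pairs})

    def matched_gs_ids(self) -> list[int]:
        return sorted({g for _, g in self.match_pairs})


def majority_vote(masks: Sequence[BinaryMask], quorum: int = 3) -> BinaryMask:
    """Voxel true iff marked by at least ``quorum`` readers (default 3 of 4)."""
    if quorum < 1:
        raise ValueError("quorum must be >= 1")
    if quorum > len(masks):
        raise ValueError(f"quorum {quorum} exceeds number of masks ({len(masks)})")
    mask_union(list(masks))  # grid-compatibility check
    votes = np.zeros(masks[0].shape, dtype=np.int16)
    for m in masks:
        votes += m.data
    return masks[0].with_data(votes >= quorum)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|); NaN when both empty."""
    if not a.grid_compatible(b):
        raise ValueError("masks are not grid-compatible")
    denom = a.voxel_count + b.voxel_count
    if denom == 0:
        return float("nan")
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / denom


def match_lesions(pred: LabeledComponents, gs: LabeledComponents) -> DetectionMetrics:
    """Lesion-level matching by any-voxel overlap.

    Each GS lesion and each predicted component is counted once no matter
    how many partners it overlaps, so a single blob covering two GS lesions
    detects both while contributing one correct prediction.
    """
    if not pred.grid_compatible(gs):
        raise ValueError("label volumes are not grid-compatible")
    overlap = (pred.labels > 0) & (gs.labels > 0)
    pairs = sorted(
        set(
            zip(
                pred.labels[overlap].ravel().tolist(),
                gs.labels[overlap].ravel().tolist(),
            )
        )
    )
    n_gs = gs.n_components
    n_pred = pred.n_components
    detected = len({g for _, g in pairs})
    correct = len({p for p, _ in pairs})
    return DetectionMetrics(
        dsc=dice(pred.binary(), gs.binary()),
        sensitivity=detected / n_gs if n_gs else None,
        ppv=correct / n_pred if n_pred else None,
        n_gs=n_gs,
        n_pred=n_pred,
        n_gs_detected=detected,
        n_pred_correct=correct,
        match_pairs=[(int(p), int(g)) for p, g in pairs],
    )


def icc(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Computed directly from the two-way ANOVA mean squares of the n-by-2
    (subject by rater) table; the p-value is from the F test of the subject
    effect (F = MSR/MSE on (n-1, (n-1)(k-1)) degrees of freedom).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (x, y)")
    n, k = arr.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 pairs")
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    ss_total = ((arr - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0:
        return float("nan"), float("nan")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    value = (msr - mse) / denom if denom != 0 else float("nan")
    if mse == 0:
        p = 0.0 if msr > 0 else float("nan")
    else:
        f = msr / mse
        p = float(stats.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return float(value), p


def pairwise_dice(masks: Sequence[BinaryMask]) -> np.ndarray:
    """Symmetric matrix of pairwise Dice coefficients between reader masks."""
    m = len(masks)
    out = np.full((m, m), np.nan)
    for i in range(m):
        out[i, i] = dice(masks[i], masks[i])
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = dice(masks[i], masks[j])
    return out


def compare_dsc_distributions(dsc_a: Sequence[float], dsc_b: Sequence[float]):
    """Paired Wilcoxon signed-rank comparison of two DSC distributions.

    Delegated to scipy's standard routine; returns (statistic, p_value).
    """
    res = stats.wilcoxon(np.asarray(dsc_a, float), np.asarray(dsc_b, float))
    return float(res.statistic), float(res.pvalue)
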