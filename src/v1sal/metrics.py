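"""Eye-fixation / salient-object evaluation scores: ROC, AUC, CC, NSS.

A saliency map is treated as a pixel classifier against a ground truth in
which fixated (or object) pixels form the positive set and all remaining
pixels the negative set.  Thresholds sweep the unique saliency values and a
pixel is called positive when its saliency is >= the threshold; AUC is the
trapezoidal area under the resulting TPR-vs-FPR curve (1 = perfect,
0.5 = chance) and is invariant to any strictly increasing transform of the
map.  CC is the Pearson correlation with a continuous ground-truth map, and
NSS the mean z-scored saliency over fixated pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["EvalResult", "roc_curve", "auc", "cc", "nss", "evaluate"]


@dataclass
class EvalResult:
    roc_points: np.ndarray  # (n, 2) columns (FPR, TPR)
    auc: float
    cc: float
    nss: float
    n_pos: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "cc": self.cc, "nss": self.nss, "n_pos": self.n_pos
        }


def _as_binary(gt: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Binarize a continuous ground truth at > threshold."""
    gt = np.asarray(gt, dtype=np.float64)
    return gt > threshold


def roc_curve(sm: np.ndarray, gt: np.ndarray, gt_threshold: float = 0.0) -> np.ndarray:
    """ROC points (FPR, TPR) from sweeping thresholds over unique values.

    The sweep includes +inf (nothing called positive) so the curve always
    contains (0, 0) and (1, 1).  Ties share a threshold and are counted as
    positive calls together.
    """
    sm = np.asarray(sm, dtype=np.float64).ravel()
    pos = _as_binary(gt, gt_threshold).ravel()
    if sm.shape != pos.shape:
        raise ValueError("saliency map and ground truth sizes differ")
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ground truth must contain both positive and negative pixels")

    # descending unique thresholds; cumulative counts give TPR/FPR per cut
    order = np.argsort(-sm, kind="stable")
    sorted_vals = sm[order]
    sorted_pos = pos[order]
    tp = np.cumsum(sorted_pos)
    fp = np.cumsum(~sorted_pos)
    # last index of each distinct value = counts with ">= value" convention
    last = np.nonzero(np.diff(sorted_vals, append=-np.inf))[0]
    tpr = np.concatenate([[0.0], tp[last] / n_pos])
    fpr = np.concatenate([[0.0], fp[last] / n_neg])
    return np.column_stack([fpr, tpr])


def auc(roc_points: np.ndarray) -> float:
    """Trapezoidal area under the ROC curve; in [0, 1]."""
    pts = np.asarray(roc_points, dtype=np.float64)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def cc(sm: np.ndarray, gt_map: np.ndarray) -> float:
    """Pearson linear correlation between the two maps over all pixels."""
    sm = np.asarray(sm, dtype=np.float64).ravel()
    gt = np.asarray(gt_map, dtype=np.float64).ravel()
    if sm.shape != gt.shape:
        raise ValueError("saliency map and ground truth sizes differ")
    if sm.std() == 0 or gt.std() == 0:
        raise ValueError("correlation undefined: one of the maps is constant")
    return float(stats.pearsonr(sm, gt).statistic)


def nss(sm: np.ndarray, fixations: np.ndarray, gt_threshold: float = 0.0) -> float:
    """Mean z-scored saliency at fixated pixels (affine-invariant)."""
    sm = np.asarray(sm, dtype=np.float64)
    fix = _as_binary(fixations, gt_threshold)
    if sm.shape != fix.shape:
        raise ValueError("saliency map and fixation map sizes differ")
    if fix.sum() == 0:
        raise ValueError("no fixated pixels")
    sigma = sm.std()
    if sigma == 0:
        raise ValueError("NSS undefined: constant saliency map")
    z = (sm - sm.mean()) / sigma
    return float(z[fix].mean())


def evaluate(sm: np.ndarray, gt: np.ndarray, gt_threshold: float = 0.0) -> EvalResult:
    """All four scores for one (saliency map, ground truth) pair.

    A continuous ground truth is used directly for CC and binarized at
    > ``gt_threshold`` for ROC/AUC/NSS.
    """
    pts = roc_curve(sm, gt, gt_threshold)
    gt_arr = np.asarray(gt, dtype=np.float64)
    return EvalResult(
        roc_points=pts,
        auc=auc(pts),
        cc=cc(sm, gt_arr),
        nss=nss(sm, gt_arr, gt_threshold),
        n_pos=int(_as_binary(gt_arr, gt_threshold).sum()),
    )
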