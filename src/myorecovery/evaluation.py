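"""Quantitative evaluation: segmentation matching, classification and stats.

Object-level segmentation metrics follow the convention that an
undetected ground-truth cell scores IoU 0 (mean IoU averages over the
ground-truth cells), and F1 counts a prediction as a true positive only
when it overlaps a ground-truth cell with IoU at or above a threshold
(0.7 in the reference protocol), matched one-to-one.  Classification is
summarized by a confusion matrix (rows = true class) with per-class
precision/recall/F1, and day-level proportion agreement by the KL
divergence of the true from the inferred proportions.  Group comparisons
use the two-sided Mann-Whitney U test and Cliff's delta with a normal
95% confidence interval; delta interpretation bands at 0.330 (medium) and
0.474 (large) are conventional thresholds, reported not recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .classifier import KL_EPS, proportion_loss

#: conventional Cliff's delta interpretation bands (medium, large)
CLIFFS_DELTA_BANDS = (0.330, 0.474)


# ---------------------------------------------------------------------------
# segmentation metrics

def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two pixel sets (boolean masks)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = (a | b).sum()
    if union == 0:
        raise ValueError("IoU of two empty pixel sets is undefined")
    return float((a & b).sum() / union)


def _contingency(gt: np.ndarray, pred: np.ndarray):
    """Pairwise pixel-overlap counts between gt and pred labels."""
    gt = np.asarray(gt).ravel()
    pred = np.asarray(pred).ravel()
    gt_ids = np.unique(gt[gt > 0])
    pred_ids = np.unique(pred[pred > 0])
    gt_areas = {g: int((gt == g).sum()) for g in gt_ids}
    pred_areas = {p: int((pred == p).sum()) for p in pred_ids}
    overlap: dict[tuple[int, int], int] = {}
    both = (gt > 0) & (pred > 0)
    pairs, counts = np.unique(
        np.stack([gt[both], pred[both]]), axis=1, return_counts=True
    )
    for (g, p), c in zip(pairs.T, counts):
        overlap[(int(g), int(p))] = int(c)
    return gt_ids, pred_ids, gt_areas, pred_areas, overlap


def mean_iou(gt_mask: np.ndarray, pred_mask: np.ndarray) -> float:
    """Mean per-ground-truth-cell IoU; undetected cells score 0.

    For each ground-truth cell, the prediction with the largest pixel
    overlap is taken (no uniqueness constraint; overlap ties broken by
    the higher IoU) and the IoU with it recorded, 0 if nothing overlaps;
    the average runs over the ground-truth cells.
    """
    gt_ids, _, gt_areas, pred_areas, overlap = _contingency(gt_mask, pred_mask)
    if len(gt_ids) == 0:
        raise ValueError("no ground-truth cells: mean IoU undefined")
    ious = []
    for g in gt_ids:
        best = 0.0
        best_key = (0, 0.0)
        for (gg, p), c in overlap.items():
            if gg != g:
                continue
            val = c / (gt_areas[int(g)] + pred_areas[p] - c)
            if (c, val) > best_key:
                best_key = (c, val)
                best = val
        ious.append(best)
    return float(np.mean(ious))


@dataclass(frozen=True)
class MatchResult:
    """One-to-one matching of ground-truth and predicted cells at IoU >= tau."""

    pairs: tuple[tuple[int, int, float], ...]  # (gt_id, pred_id, IoU)
    unmatched_gt: tuple[int, ...]
    unmatched_pred: tuple[int, ...]
    threshold: float

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.unmatched_pred)

    @property
    def fn(self) -> int:
        return len(self.unmatched_gt)


def f1_at_threshold(
    gt_mask: np.ndarray, pred_mask: np.ndarray, tau: float = 0.7
) -> tuple[float, float, float, MatchResult]:
    """Object-level precision/recall/F1 at IoU threshold ``tau``.

    Candidate (gt, pred) pairs with IoU >= tau are matched greedily in
    descending IoU, one-to-one (ties broken by lowest ids for
    determinism).  TP = matched pairs, FP = unmatched predictions,
    FN = unmatched ground truths; 0/0 ratios are 0.
    """
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must be in (0, 1]")
    gt_ids, pred_ids, gt_areas, pred_areas, overlap = _contingency(gt_mask, pred_mask)
    cands = []
    for (g, p), c in overlap.items():
        val = c / (gt_areas[g] + pred_areas[p] - c)
        if val >= tau:
            cands.append((val, g, p))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_g: set[int] = set()
    used_p: set[int] = set()
    pairs = []
    for val, g, p in cands:
        if g in used_g or p in used_p:
            continue
        used_g.add(g)
        used_p.add(p)
        pairs.append((g, p, val))
    match = MatchResult(
        tuple(pairs),
        tuple(int(g) for g in gt_ids if g not in used_g),
        tuple(int(p) for p in pred_ids if p not in used_p),
        tau,
    )
    tp, fp, fn = match.tp, match.fp, match.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1, match


# ---------------------------------------------------------------------------
# classification metrics

def confusion_and_prf(
    true_classes, pred_classes, K: int | None = None, sentinel: int | None = None
):
    """Confusion matrix (rows = true class) and per-class precision/recall/F1.

    Pairs where the true class equals ``sentinel`` (unannotated cells)
    are excluded.  Returns ``(matrix, metrics)`` where metrics is a
    pandas DataFrame with one row per class; 0/0 ratios are 0.
    """
    import pandas as pd

    t = np.asarray(true_classes)
    p = np.asarray(pred_classes)
    if t.shape != p.shape:
        raise ValueError("true and predicted class lists differ in length")
    if sentinel is not None:
        keep = t != sentinel
        t, p = t[keep], p[keep]
    if K is None:
        K = int(max(t.max(initial=-1), p.max(initial=-1))) + 1
    matrix = np.zeros((K, K), dtype=np.int64)
    np.add.at(matrix, (t, p), 1)

    diag = np.diag(matrix).astype(float)
    col = matrix.sum(axis=0).astype(float)
    row = matrix.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / np.where(col > 0, col, 1), 0.0)
        recall = np.where(row > 0, diag / np.where(row > 0, row, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    metrics = pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1, "support": row.astype(int)}
    )
    return matrix, metrics


def kl_eval(true_props, pred_props, eps: float = KL_EPS):
    """Per-item KL divergence D_KL(true || pred) and its mean.

    Used for cross-validated day-level proportion agreement: a smaller
    value means the inferred proportions are closer to the truth.
    """
    true_props = list(true_props)
    pred_props = list(pred_props)
    if len(true_props) != len(pred_props):
        raise ValueError("paired proportion lists differ in length")
    vals = [proportion_loss(t, p, eps) for t, p in zip(true_props, pred_props)]
    mean = float(np.mean(vals)) if vals else float("nan")
    return vals, mean


# ---------------------------------------------------------------------------
# nonparametric statistics

def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (midranks, tie and continuity corrected).

    Returns ``(U, p)`` where U is the statistic of the first sample and p
    the two-sided p-value from the normal approximation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class EffectSize:
    """Cliff's delta with a 95% normal-approximation confidence interval."""

    delta: float
    ci_low: float
    ci_high: float
    n: int
    m: int

    @property
    def magnitude(self) -> str:
        d = abs(self.delta)
        if d >= CLIFFS_DELTA_BANDS[1]:
            return "large"
        if d >= CLIFFS_DELTA_BANDS[0]:
            return "medium"
        return "small-or-negligible"


def cliffs_delta(x, y, confidence: float = 0.95) -> EffectSize:
    """Cliff's delta effect size of x over y.

    delta = (#{x_i > y_j} - #{x_i < y_j}) / (n m), in [-1, 1]; the CI uses
    the consistent two-sample U-statistic variance estimate
    s1^2/n + s2^2/m from the row/column dominance means, with normal
    quantiles.  Antisymmetric: cliffs_delta(x, y) = -cliffs_delta(y, x).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be nonempty")
    sign = np.sign(x[:, None] - y[None, :])
    delta = float(sign.mean())
    d_rows = sign.mean(axis=1)
    d_cols = sign.mean(axis=0)
    s1 = d_rows.var(ddof=1) if n > 1 else 0.0
    s2 = d_cols.var(ddof=1) if m > 1 else 0.0
    se = float(np.sqrt(s1 / n + s2 / m))
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    lo = max(-1.0, min(delta, delta - z * se))
    hi = min(1.0, max(delta, delta + z * se))
    return EffectSize(delta, lo, hi, n, m)
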