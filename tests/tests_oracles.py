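"""Brute-force oracles for the object-matching metrics, shared by tests."""

import itertools

import numpy as np


def random_label_mask(rng, shape=(20, 20), max_objects=5):
    mask = np.zeros(shape, dtype=int)
    for label in range(1, rng.integers(0, max_objects + 1) + 1):
        h = rng.integers(2, 7)
        w = rng.integers(2, 7)
        y = rng.integers(0, shape[0] - h)
        x = rng.integers(0, shape[1] - w)
        mask[y : y + h, x : x + w] = label  # later rectangles may overwrite
    return mask


def oracle_mean_iou(gt, pred):
    """Per-ground-truth best-overlap IoU (ties by IoU), averaged."""
    gts = np.unique(gt[gt > 0])
    preds = np.unique(pred[pred > 0])
    vals = []
    for g in gts:
        region = gt == g
        best_overlap, best_iou = 0, 0.0
        for p in preds:
            pregion = pred == p
            ov = int((region & pregion).sum())
            if ov == 0:
                continue
            val = ov / int((region | pregion).sum())
            if (ov, val) > (best_overlap, best_iou):
                best_overlap, best_iou = ov, val
        vals.append(best_iou)
    return float(np.mean(vals)) if vals else 0.0


def oracle_max_matching(gt, pred, tau):
    """Maximum-cardinality one-to-one matching at IoU >= tau, by search
    over all one-to-one assignments."""
    gts = list(np.unique(gt[gt > 0]))
    preds = list(np.unique(pred[pred > 0]))
    iou_ok = set()
    for g in gts:
        for p in preds:
            inter = int(((gt == g) & (pred == p)).sum())
            if inter == 0:
                continue
            union = int(((gt == g) | (pred == p)).sum())
            if inter / union >= tau:
                iou_ok.add((g, p))
    for k in range(min(len(gts), len(preds)), 0, -1):
        for gsub in itertools.combinations(gts, k):
            for psub in itertools.permutations(preds, k):
                if all((g, p) in iou_ok for g, p in zip(gsub, psub)):
                    return k
    return 0
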