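"""Independent brute-force oracles shared by the metric and acceptance tests.

Everything here is deliberately naive — O(n^2) loops, explicit pair counting,
manual percentiles — and shares no code with the package implementation.
"""

import numpy as np
from scipy.spatial.distance import cdist


def brute_dice(pred, truth):
    inter = sum(int(p and t) for p, t in zip(pred.ravel(), truth.ravel()))
    denom = int(pred.sum()) + int(truth.sum())
    return 1.0 if denom == 0 else 2.0 * inter / denom


def brute_iou(pred, truth):
    inter = sum(int(p and t) for p, t in zip(pred.ravel(), truth.ravel()))
    union = sum(int(p or t) for p, t in zip(pred.ravel(), truth.ravel()))
    return 1.0 if union == 0 else inter / union


def brute_boundary(mask):
    """8-connectivity boundary; outside the image counts as background."""
    pts = []
    H, W = mask.shape
    for i in range(H):
        for j in range(W):
            if not mask[i, j]:
                continue
            nb = [bool(mask[a, b]) if 0 <= a < H and 0 <= b < W else False
                  for a in range(i - 1, i + 2) for b in range(j - 1, j + 2)]
            if not all(nb):
                pts.append((i, j))
    return np.array(pts, dtype=float)


def brute_hd95(pred, truth):
    bp, bt = brute_boundary(pred), brute_boundary(truth)
    d = cdist(bp, bt)
    pooled = np.sort(np.concatenate([d.min(axis=1), d.min(axis=0)]))
    q = 0.95 * (len(pooled) - 1)  # manual linear-interpolation percentile
    lo = int(np.floor(q))
    frac = q - lo
    if lo + 1 >= len(pooled):
        return float(pooled[lo])
    return float(pooled[lo] * (1 - frac) + pooled[lo + 1] * frac)


def brute_auroc(scores, labels):
    pos = scores[labels]
    neg = scores[~labels]
    gt = sum((p > n) for p in pos for n in neg)
    eq = sum((p == n) for p in pos for n in neg)
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


def brute_f1_threshold(scores, labels):
    """Exhaustive sweep over all observed score values; ties -> larger tau."""
    best_f1, best_tau = -1.0, None
    for tau in np.unique(scores):
        pred = scores >= tau
        tp = int((pred & labels).sum())
        fp = int((pred & ~labels).sum())
        fn = int((~pred & labels).sum())
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best_f1 or (f1 == best_f1 and tau > best_tau):
            best_f1, best_tau = f1, tau
    return best_tau
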