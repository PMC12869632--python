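"""Evaluation harness: liver-masked metrics, size strata, grouped CV, ablations.

All metrics are scoped to the liver mask. Dice and IoU on the both-empty
case are defined as 1.0 and flagged so abnormal-cohort summaries can exclude
them; HD95 pools the bidirectional boundary surface distances (8-connected
boundaries, Euclidean, in px) before taking the 95th percentile, with an
undefined flag (NaN) when either mask is empty; per-slice AUROC uses
midrank tie handling over in-liver pixels, and cohort tables report the
mean/SD/95% t-CI of per-slice values. Size stratification bins slices by
the quartiles of their tumor pixel areas; cross-validation is grouped by
subject with greedy subject-count balancing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from sklearn.metrics import roc_auc_score

from .core import EvalRecord, SlicePairRecord
from .anomaly import PostprocessParams, base_map, binarize, f1_optimal_threshold, postprocess
from .reconstruct import reconstruct_slice

__all__ = [
    "EvalRecord", "SizeStratumReport", "dice", "iou", "hd95", "pixel_auroc",
    "evaluate_slice", "stratify_by_size", "grouped_kfold", "fold_ci",
    "evaluate_cohort", "run_ablations", "metric_stats",
]


def _scope(pred, truth, scope):
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes must match")
    if scope is not None:
        scope = np.asarray(scope).astype(bool)
        if scope.shape != pred.shape:
            raise ValueError("scope shape must match")
        pred, truth = pred & scope, truth & scope
    return pred, truth


def dice(pred, truth, scope=None) -> float:
    """2|P∩T| / (|P|+|T|) within the scope mask; both-empty defined as 1.0."""
    pred, truth = _scope(pred, truth, scope)
    denom = int(pred.sum()) + int(truth.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((pred & truth).sum()) / denom


def iou(pred, truth, scope=None) -> float:
    """|P∩T| / |P∪T| within the scope mask; both-empty defined as 1.0."""
    pred, truth = _scope(pred, truth, scope)
    union = int((pred | truth).sum())
    if union == 0:
        return 1.0
    return int((pred & truth).sum()) / union


def _boundary(mask):
    """8-connectivity boundary: mask pixels with a background neighbour."""
    er = ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool))
    return np.argwhere(mask & ~er)


def hd95(pred, truth) -> float:
    """95th percentile of pooled bidirectional boundary distances, in px.

    Returns NaN (the undefined flag) when either mask is empty; callers
    exclude NaNs from means and report the excluded count.
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes must match")
    if pred.sum() == 0 or truth.sum() == 0:
        return float("nan")
    bp, bt = _boundary(pred), _boundary(truth)
    d_pt = cKDTree(bt).query(bp)[0]
    d_tp = cKDTree(bp).query(bt)[0]
    return float(np.percentile(np.concatenate([d_pt, d_tp]), 95))


def pixel_auroc(score_map, truth, scope) -> float:
    """Rank-based AUROC over in-scope pixels (midrank ties); NaN if single-class."""
    scope = np.asarray(scope).astype(bool)
    y = np.asarray(truth).astype(bool)[scope]
    s = np.asarray(score_map, dtype=np.float64)[scope]
    if y.all() or not y.any():
        return float("nan")
    return float(roc_auc_score(y, s))


def evaluate_slice(binary_map, score_map, sl_truth, liver_mask,
                   subject_id="", slice_index=0) -> EvalRecord:
    return EvalRecord(
        subject_id=subject_id, slice_index=slice_index,
        dice=dice(binary_map, sl_truth, liver_mask),
        iou=iou(binary_map, sl_truth, liver_mask),
        hd95=hd95(np.asarray(binary_map).astype(bool) & np.asarray(liver_mask).astype(bool),
                  np.asarray(sl_truth).astype(bool) & np.asarray(liver_mask).astype(bool)),
        auroc=pixel_auroc(score_map, sl_truth, liver_mask),
        tumor_area=int((np.asarray(sl_truth).astype(bool)
                        & np.asarray(liver_mask).astype(bool)).sum()))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

_METRICS = ("dice", "iou", "hd95", "auroc")


@dataclass
class SizeStratumReport:
    label: str
    n: int
    area_range: tuple[float, float]
    stats: pd.DataFrame  # rows: metric; columns: mean, sd, ci_lo, ci_hi, n_defined
    degenerate: bool = False


def metric_stats(records: list[EvalRecord]) -> pd.DataFrame:
    rows = {}
    for m in _METRICS:
        v = np.array([getattr(r, m) for r in records], dtype=np.float64)
        v = v[~np.isnan(v)]
        n = len(v)
        mean = float(v.mean()) if n else float("nan")
        sd = float(v.std(ddof=1)) if n > 1 else 0.0
        if n > 1 and sd > 0:
            half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        else:
            half = 0.0
        rows[m] = {"mean": mean, "sd": sd, "ci_lo": mean - half,
                   "ci_hi": mean + half, "n_defined": n}
    return pd.DataFrame(rows).T


def stratify_by_size(records: list[EvalRecord]) -> list[SizeStratumReport]:
    """Quartile-bin records by tumor area; report per-bin metric summaries."""
    if len(records) < 4:
        raise ValueError("need at least 4 records to form quartile bins")
    areas = np.array([r.tumor_area for r in records], dtype=np.float64)
    edges = np.quantile(areas, [0.25, 0.5, 0.75])
    degenerate = len(np.unique(edges)) < 3
    bins = np.digitize(areas, edges, right=True)  # 0..3
    labels = ["0-25%", "25-50%", "50-75%", "75-100%"]
    out = []
    for b in range(4):
        sub = [r for r, k in zip(records, bins) if k == b]
        sub_areas = areas[bins == b]
        rng = (float(sub_areas.min()), float(sub_areas.max())) if len(sub) else (float("nan"),) * 2
        out.append(SizeStratumReport(label=labels[b], n=len(sub), area_range=rng,
                                     stats=metric_stats(sub) if sub else metric_stats([]),
                                     degenerate=degenerate))
    assert sum(s.n for s in out) == len(records)
    return out


def grouped_kfold(records, K: int = 5, seed: int = 0) -> dict[str, int]:
    """Assign each subject to one of K folds, greedily balanced.

    Subjects are shuffled (seeded), ordered by slice count (descending,
    stable) and assigned to the fold with the fewest subjects, ties broken
    by fewest slices then fold index. Every slice of a subject shares its
    fold; fold subject counts differ by at most one.
    """
    counts: dict[str, int] = {}
    for r in records:
        counts[r.subject_id] = counts.get(r.subject_id, 0) + 1
    subjects = list(counts)
    if K > len(subjects):
        raise ValueError(f"K={K} exceeds the {len(subjects)} distinct subjects")
    rng = np.random.default_rng(seed)
    subjects = [subjects[i] for i in rng.permutation(len(subjects))]
    subjects.sort(key=lambda s: -counts[s])  # stable: keeps shuffled order within ties
    fold_subjects = [0] * K
    fold_slices = [0] * K
    assignment = {}
    for s in subjects:
        k = min(range(K), key=lambda f: (fold_subjects[f], fold_slices[f], f))
        assignment[s] = k
        fold_subjects[k] += 1
        fold_slices[k] += counts[s]
    return assignment


def fold_ci(values) -> tuple[float, float]:
    """Mean and 95% t-CI half-width of per-fold means."""
    v = np.asarray(values, dtype=np.float64)
    if len(v) < 2:
        raise ValueError("need at least 2 folds")
    half = stats.t.ppf(0.975, len(v) - 1) * v.std(ddof=1) / np.sqrt(len(v))
    return float(v.mean()), float(half)


# ---------------------------------------------------------------------------
# cohort-level evaluation and ablations
# ---------------------------------------------------------------------------

def _anomaly_scores(pairs, model, params):
    """Cleaned (pre-threshold) score maps for a list of pairs.

    ``model=None`` is the inpainting-only configuration: the anomaly signal
    is |original - inpainted| with no learned reconstruction.
    """
    maps = []
    for p in pairs:
        recon = p.inpainted if model is None else reconstruct_slice(model, p)
        raw = base_map(p.original, recon, p.liver_mask)
        clean, _ = postprocess(raw, p.liver_mask, params)
        maps.append(clean)
    return maps


def evaluate_cohort(pairs: list[SlicePairRecord], model, params: PostprocessParams,
                    K: int = 5, seed: int = 0):
    """Grouped-CV evaluation with one F1-optimal threshold per fold.

    Returns (records, fold_table, thresholds). Every pair must carry a
    tumor mask (the abnormal evaluation cohort).
    """
    for p in pairs:
        if p.tumor_mask is None:
            raise ValueError("evaluation pairs must carry tumor masks")
    assignment = grouped_kfold(pairs, K=K, seed=seed)
    maps = _anomaly_scores(pairs, model, params)
    records = []
    thresholds = {}
    for k in range(K):
        idx = [i for i, p in enumerate(pairs) if assignment[p.subject_id] == k]
        if not idx:
            continue
        pooled_s = np.concatenate([maps[i][pairs[i].liver_mask.astype(bool)] for i in idx])
        pooled_y = np.concatenate([pairs[i].tumor_mask[pairs[i].liver_mask.astype(bool)]
                                   for i in idx])
        tau = f1_optimal_threshold(pooled_s, pooled_y)
        thresholds[k] = tau
        for i in idx:
            p = pairs[i]
            binary = binarize(maps[i], p.liver_mask, tau, params)
            rec = evaluate_slice(binary, maps[i], p.tumor_mask, p.liver_mask,
                                 subject_id=p.subject_id, slice_index=p.slice_index)
            rec.fold_id = k
            records.append(rec)
    fold_rows = []
    for k in sorted(thresholds):
        sub = [r for r in records if r.fold_id == k]
        st = metric_stats(sub)
        fold_rows.append({"fold": k, "n_slices": len(sub), "threshold": thresholds[k],
                          **{m: st.loc[m, "mean"] for m in _METRICS}})
    return records, pd.DataFrame(fold_rows), thresholds


ABLATION_CONFIGS = ("full", "no_postprocess", "inpaint_only")


def run_ablations(pairs: list[SlicePairRecord], model, params: PostprocessParams,
                  K: int = 5, seed: int = 0) -> pd.DataFrame:
    """Evaluate the three ablation configurations on identical splits.

    (1) full model; (2) full minus post-processing (all params zeroed);
    (3) healthy-prior only: |original - inpainted| with no reconstruction.
    Thresholds are refit per configuration under the shared fold assignment.
    """
    rows = []
    for name in ABLATION_CONFIGS:
        p = params.zeroed() if name == "no_postprocess" else params
        m = None if name == "inpaint_only" else model
        records, _, _ = evaluate_cohort(pairs, m, p, K=K, seed=seed)
        st = metric_stats(records)
        row = {"configuration": name, "n_slices": len(records)}
        for metric in _METRICS:
            row[f"{metric}_mean"] = st.loc[metric, "mean"]
            row[f"{metric}_sd"] = st.loc[metric, "sd"]
            row[f"{metric}_ci_lo"] = st.loc[metric, "ci_lo"]
            row[f"{metric}_ci_hi"] = st.loc[metric, "ci_hi"]
        rows.append(row)
    return pd.DataFrame(rows)
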