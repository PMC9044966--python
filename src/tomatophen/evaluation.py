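"""Instance-segmentation evaluation and verification statistics.

Detection metrics: IoU-based greedy matching of scored predictions to
ground-truth masks (a match requires IoU strictly greater than the
threshold, 0.5 by default), precision / recall / F1 from the matched
counts, a precision-recall curve swept over the unique prediction scores,
and average precision (AP) as the area under that curve with the standard
all-point precision-envelope interpolation. A bookkeeping operation allows
re-scoring qualitatively-correct cases (e.g. partial segmentations that
still count the right number of locules) as true positives with a full
audit trail.

Verification statistics compare image-recognition measurements against
manual ones: the relative root-mean-square error

    RMSE = sqrt( (1/n) * sum_i ((R_i - M_i) / M_i)^2 )

with R the recognized and M the manual values, squared Pearson correlation,
a median-centred variance-equality test (Brown-Forsythe form of Levene's
test) and an unequal-variance two-sample location test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InputError, UndefinedMetricError

__all__ = [
    "Detection",
    "MatchResult",
    "PRCurve",
    "VerificationReport",
    "mask_iou",
    "match_instances",
    "precision_recall_f1",
    "pr_curve_and_ap",
    "apply_practical_corrections",
    "relative_rmse",
    "verification_report",
]


@dataclass
class Detection:
    """A scored predicted mask (score defaults to 1.0 for oracle inputs)."""

    mask: np.ndarray
    score: float = 1.0


def _as_mask(obj) -> np.ndarray:
    mask = getattr(obj, "mask", obj)
    return np.asarray(mask, dtype=bool)


def _score_of(obj) -> float:
    return float(getattr(obj, "score", 1.0))


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks (both-empty is undefined)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise InputError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise UndefinedMetricError("IoU undefined when both masks are empty")
    inter = np.logical_and(a, b).sum()
    return float(inter / union)


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]]  # (prediction id, ground-truth id, IoU)
    iou_threshold: float
    unmatched_pred_ids: list[int] = field(default_factory=list)
    unmatched_gt_ids: list[int] = field(default_factory=list)


def match_instances(
    predictions: Sequence,
    ground_truths: Sequence,
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one matching in descending score order.

    Each prediction (highest score first, prediction index as the
    deterministic tie-break) claims the unmatched ground truth of highest
    IoU provided that IoU is strictly greater than ``iou_threshold``.
    Matched pairs are TP, leftover predictions FP, leftover ground truths
    FN. This is the standard detection-evaluation convention; a brute-force
    optimal assignment is used as an independent cross-check in the test
    suite, not as the API.
    """
    pred_masks = [_as_mask(p) for p in predictions]
    gt_masks = [_as_mask(g) for g in ground_truths]
    order = sorted(range(len(pred_masks)), key=lambda i: (-_score_of(predictions[i]), i))
    matched_gt: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for i in order:
        best_iou, best_j = 0.0, None
        for j, gm in enumerate(gt_masks):
            if j in matched_gt:
                continue
            try:
                iou = mask_iou(pred_masks[i], gm)
            except UndefinedMetricError:
                continue
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j is not None and best_iou > iou_threshold:
            matched_gt.add(best_j)
            pairs.append((i, best_j, best_iou))
    pairs.sort(key=lambda t: t[0])
    matched_pred = {p for p, _, _ in pairs}
    unmatched_pred = [i for i in range(len(pred_masks)) if i not in matched_pred]
    unmatched_gt = [j for j in range(len(gt_masks)) if j not in matched_gt]
    return MatchResult(
        tp=len(pairs),
        fp=len(unmatched_pred),
        fn=len(unmatched_gt),
        pairs=pairs,
        iou_threshold=iou_threshold,
        unmatched_pred_ids=unmatched_pred,
        unmatched_gt_ids=unmatched_gt,
    )


def precision_recall_f1(
    m: MatchResult,
) -> tuple[float | None, float | None, float | None]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R).

    A quantity whose denominator is zero is reported as None (undefined),
    never coerced to 0.
    """
    p = m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else None
    r = m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else None
    if p is None or r is None or (p + r) == 0:
        f1 = None
    else:
        f1 = 2 * p * r / (p + r)
    return p, r, f1


@dataclass
class PRCurve:
    score_thresholds: list[float]  # descending
    precision: list[float]
    recall: list[float]
    f1: list[float | None]
    ap: float
    interpolation: str = "envelope"


def pr_curve_and_ap(
    predictions: Sequence,
    ground_truths: Sequence,
    iou_threshold: float = 0.5,
    *,
    interpolation: str = "envelope",
) -> PRCurve:
    """Precision-recall curve over the unique prediction scores, plus AP.

    At each threshold the predictions scoring at least that value are kept
    and re-matched. AP integrates precision over recall; with the default
    ``"envelope"`` interpolation the precision at each recall level is the
    running maximum toward higher recall (all-point interpolation, the
    instance-segmentation standard); ``"trapezoid"`` integrates the raw
    curve instead, for sensitivity checks.
    """
    if len(ground_truths) == 0:
        raise UndefinedMetricError("AP undefined without ground truths")
    if interpolation not in ("envelope", "trapezoid"):
        raise InputError(f"unknown interpolation {interpolation!r}")
    scores = sorted({_score_of(p) for p in predictions}, reverse=True)
    precisions: list[float] = []
    recalls: list[float] = []
    f1s: list[float | None] = []
    for thr in scores:
        kept = [p for p in predictions if _score_of(p) >= thr]
        m = match_instances(kept, ground_truths, iou_threshold)
        p, r, f1 = precision_recall_f1(m)
        precisions.append(p if p is not None else 0.0)
        recalls.append(r if r is not None else 0.0)
        f1s.append(f1)
    if interpolation == "envelope":
        ap = 0.0
        prev_recall = 0.0
        for k in range(len(scores)):
            envelope = max(precisions[k:], default=0.0)
            ap += (recalls[k] - prev_recall) * envelope
            prev_recall = recalls[k]
    else:
        rr = [0.0] + recalls
        pp = [precisions[0] if precisions else 0.0] + precisions
        ap = float(np.trapezoid(pp, rr))
    return PRCurve(
        score_thresholds=list(scores),
        precision=precisions,
        recall=recalls,
        f1=f1s,
        ap=float(ap),
        interpolation=interpolation,
    )


def apply_practical_corrections(
    m: MatchResult,
    rules: Sequence[dict],
) -> tuple[MatchResult, list[dict]]:
    """Re-classify enumerated FP/FN cases as TP, with an audit log.

    Each rule is ``{"kind": "fn", "id": <gt id>, "reason": ...}`` or
    ``{"kind": "fp", "id": <prediction id>, "reason": ...}``; the id must
    currently be unmatched. Corrections only ever move cases into TP, so
    recall never decreases. Returns the corrected result and the audit log.
    """
    tp, fp, fn = m.tp, m.fp, m.fn
    pairs = list(m.pairs)
    un_pred = list(m.unmatched_pred_ids)
    un_gt = list(m.unmatched_gt_ids)
    audit: list[dict] = []
    for rule in rules:
        kind = rule.get("kind")
        rid = rule.get("id")
        if kind == "fn":
            if rid not in un_gt:
                raise InputError(f"rule references unknown FN ground-truth id {rid}")
            un_gt.remove(rid)
            fn -= 1
            tp += 1
            pairs.append((-1, rid, float("nan")))
        elif kind == "fp":
            if rid not in un_pred:
                raise InputError(f"rule references unknown FP prediction id {rid}")
            un_pred.remove(rid)
            fp -= 1
            tp += 1
            pairs.append((rid, -1, float("nan")))
        else:
            raise InputError(f"rule kind must be 'fn' or 'fp', got {kind!r}")
        audit.append({"kind": kind, "id": rid,
                      "reason": rule.get("reason", ""), "reclassified_as": "tp"})
    corrected = MatchResult(
        tp=tp, fp=fp, fn=fn, pairs=pairs, iou_threshold=m.iou_threshold,
        unmatched_pred_ids=un_pred, unmatched_gt_ids=un_gt,
    )
    return corrected, audit


def relative_rmse(recognized: Sequence[float], manual: Sequence[float]) -> float:
    """Relative root-mean-square error of recognized vs manual measurements."""
    r = np.asarray(recognized, dtype=float)
    m = np.asarray(manual, dtype=float)
    if r.shape != m.shape or r.ndim != 1:
        raise InputError("recognized and manual must be equal-length 1-D sequences")
    if r.size == 0:
        raise InputError("need at least one measurement")
    if np.any(m == 0):
        raise UndefinedMetricError("relative RMSE undefined when a manual value is 0")
    return float(np.sqrt(np.mean(((r - m) / m) ** 2)))


@dataclass
class VerificationReport:
    rmse_rel: float
    pearson_r2: float | None
    variance_test_p: float
    mean_difference_p: float
    n: int
    notes: list[str] = field(default_factory=list)


def verification_report(
    recognized: Sequence[float], manual: Sequence[float]
) -> VerificationReport:
    """Accuracy report for paired recognized/manual measurements.

    Relative RMSE, squared Pearson correlation (None and flagged if either
    input is constant), a Brown-Forsythe (median-centred Levene) variance
    equality p-value, and a Welch two-sample location p-value.
    """
    r = np.asarray(recognized, dtype=float)
    m = np.asarray(manual, dtype=float)
    if r.shape != m.shape or r.ndim != 1:
        raise InputError("recognized and manual must be equal-length 1-D sequences")
    if r.size < 3:
        raise InputError("need at least 3 paired measurements")
    notes: list[str] = []
    rmse = relative_rmse(r, m)
    if np.ptp(r) == 0 or np.ptp(m) == 0:
        r2 = None
        notes.append("correlation undefined for constant input")
    else:
        r2 = float(stats.pearsonr(r, m).statistic ** 2)
    lev = stats.levene(r, m, center="median")
    var_p = float(lev.pvalue) if np.isfinite(lev.pvalue) else 1.0
    tt = stats.ttest_ind(r, m, equal_var=False)
    mean_p = float(tt.pvalue) if np.isfinite(tt.pvalue) else 1.0
    return VerificationReport(
        rmse_rel=rmse,
        pearson_r2=r2,
        variance_test_p=var_p,
        mean_difference_p=mean_p,
        n=int(r.size),
        notes=notes,
    )
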