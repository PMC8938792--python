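"""Segmentation metrics, ROC/Youden analysis, the symptom-responder
rule and the cohort statistical battery.

Overlap metrics follow the usual definitions: per-class Dice
``2|P∩R|/(|P|+|R|)`` and IoU ``|P∩R|/|P∪R|`` (so IoU = Dice/(2−Dice)),
pixel accuracy as the confusion-matrix trace over the total.  ROC
curves are built by an explicit threshold sweep; the trapezoid AUC
equals the rank statistic P(s⁺ > s⁻) + ½P(tie) exactly, and the Youden
cut-point maximises sensitivity + specificity − 1, ties broken toward
higher specificity, reported as the midpoint between adjacent observed
scores (so integer scores yield half-integer cut-points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SegMetrics",
    "RocResult",
    "confusion_matrix",
    "seg_metrics",
    "region_agreement",
    "roc",
    "responder",
    "stat_battery",
]


def confusion_matrix(pred: np.ndarray, ref: np.ndarray,
                     n_classes: int | None = None) -> np.ndarray:
    """K×K integer counts: rows = reference class, cols = predicted."""
    pred = np.asarray(pred).ravel()
    ref = np.asarray(ref).ravel()
    if pred.shape != ref.shape:
        raise ValueError("prediction and reference sizes differ")
    k = n_classes or int(max(pred.max(initial=0), ref.max(initial=0))) + 1
    return np.bincount(ref * k + pred, minlength=k * k).reshape(k, k)


@dataclass(frozen=True)
class SegMetrics:
    pixel_accuracy: float
    per_class_dice: dict[int, float]
    mean_dice: float
    per_class_iou: dict[int, float]
    miou: float


def seg_metrics(pred: np.ndarray, ref: np.ndarray,
                n_classes: int | None = None) -> SegMetrics:
    """Pixel accuracy, per-class Dice/IoU and their means.

    Classes absent from both grids are excluded from the means; a class
    present in only one of them scores 0 and is included.
    """
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {ref.shape}")
    cm = confusion_matrix(pred, ref, n_classes)
    total = cm.sum()
    pa = float(np.trace(cm) / total)
    ref_sizes = cm.sum(axis=1)
    pred_sizes = cm.sum(axis=0)
    inter = np.diag(cm)
    dice, iou = {}, {}
    for c in range(cm.shape[0]):
        denom = ref_sizes[c] + pred_sizes[c]
        if denom == 0:
            continue  # absent from both
        dice[c] = float(2.0 * inter[c] / denom)
        iou[c] = float(inter[c] / (denom - inter[c]))
    return SegMetrics(
        pixel_accuracy=pa,
        per_class_dice=dice,
        mean_dice=float(np.mean(list(dice.values()))) if dice else float("nan"),
        per_class_iou=iou,
        miou=float(np.mean(list(iou.values()))) if iou else float("nan"),
    )


def region_agreement(pred_reports: dict[str, list], ref_reports: dict[str, list],
                     tolerance: float = 0.1) -> pd.DataFrame:
    """Fraction of subjects whose per-region opacification ratio agrees
    within ``tolerance``; rows are region groups, columns Left/Right."""
    if set(pred_reports) != set(ref_reports):
        raise ValueError("subject ids of prediction and reference differ")
    agree: dict[str, list[float]] = {}
    for sid in pred_reports:
        pred = {r.region_id: r for r in pred_reports[sid]}
        ref = {r.region_id: r for r in ref_reports[sid]}
        if set(pred) != set(ref):
            raise ValueError(f"region sets differ for subject {sid}")
        for rid in pred:
            agree.setdefault(rid, []).append(
                float(abs(pred[rid].ratio - ref[rid].ratio) <= tolerance))
    groups = sorted({rid[:-2] for rid in agree})
    table = {
        side: [float(np.mean(agree[f"{g}-{side[0]}"])) for g in groups]
        for side in ("Left", "Right")
    }
    return pd.DataFrame(table, index=groups)


@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    youden_cutpoint: float
    sensitivity: float
    specificity: float


def roc(scores, labels) -> RocResult:
    """ROC by explicit threshold sweep over the unique scores.

    A sample is called positive when its score is >= the threshold.
    Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1D arrays")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    uniq = np.unique(scores)[::-1]
    thresholds = np.concatenate(([np.inf], uniq))
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        called = scores >= t
        tpr[i] = (called & (labels == 1)).sum() / n_pos
        fpr[i] = (called & (labels == 0)).sum() / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    # ties toward higher specificity = lower fpr = earlier index
    best = int(np.argmax(j))
    t = thresholds[best]
    if np.isinf(t):
        cut = float(uniq[0] + 1.0)
    else:
        below = uniq[uniq < t]
        cut = float((t + below.max()) / 2.0) if len(below) else float(t)
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc,
                     youden_cutpoint=cut, sensitivity=float(tpr[best]),
                     specificity=float(1.0 - fpr[best]))


def responder(snot_pre: float, snot_post: float,
              reduction: float = 0.25) -> bool:
    """True when the symptom score dropped by at least ``reduction``
    (fractional) after surgery."""
    if snot_pre <= 0:
        raise ValueError("pre-operative score must be positive")
    return (snot_pre - snot_post) / snot_pre >= reduction


def stat_battery(cohort_table: pd.DataFrame, formula_specs: list[dict],
                 alpha: float = 0.05) -> pd.DataFrame:
    """Run the study's statistical battery on a cohort table.

    Each spec is a dict with ``kind`` one of:

    * ``{"kind": "ttest", "value": col, "group": col, "equal_var": bool}``
      — two-sample t-test (Welch by default);
    * ``{"kind": "anova", "value": col, "group": col}`` — one-way ANOVA;
    * ``{"kind": "ols", "formula": str}`` — ordinary least squares via
      the formula interface, one row per coefficient.

    Returns a tidy frame with estimate, statistic, p-value and a
    significance flag at ``alpha``.
    """
    import statsmodels.formula.api as smf

    rows = []
    for spec in formula_specs:
        kind = spec["kind"]
        if kind in ("ttest", "anova"):
            groups = [g.dropna().to_numpy()
                      for _, g in cohort_table.groupby(spec["group"])[spec["value"]]]
            if len(groups) < 2 or any(len(g) < 2 for g in groups):
                raise ValueError(f"degenerate groups for {spec}")
            if kind == "ttest":
                if len(groups) != 2:
                    raise ValueError("t-test needs exactly two groups")
                res = sps.ttest_ind(groups[0], groups[1],
                                    equal_var=spec.get("equal_var", False))
                est = float(np.mean(groups[0]) - np.mean(groups[1]))
                rows.append({"test": "ttest", "term": spec["value"],
                             "estimate": est, "statistic": float(res.statistic),
                             "p_value": float(res.pvalue)})
            else:
                res = sps.f_oneway(*groups)
                rows.append({"test": "anova", "term": spec["value"],
                             "estimate": float("nan"),
                             "statistic": float(res.statistic),
                             "p_value": float(res.pvalue)})
        elif kind == "ols":
            fit = smf.ols(spec["formula"], data=cohort_table).fit()
            for term in fit.params.index:
                rows.append({"test": f"ols[{spec['formula']}]", "term": term,
                             "estimate": float(fit.params[term]),
                             "statistic": float(fit.tvalues[term]),
                             "p_value": float(fit.pvalues[term]),
                             "conf_low": float(fit.conf_int().loc[term, 0]),
                             "conf_high": float(fit.conf_int().loc[term, 1])})
        else:
            raise ValueError(f"unknown test kind {kind!r}")
    out = pd.DataFrame(rows)
    out["significant"] = out["p_value"] < alpha
    return out
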