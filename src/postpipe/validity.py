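"""Content validity indices and cut-off validation of the score.

* I-CVI: proportion of panel experts rating an item 3 or 4 on the 4-point
  Likert scale (Lynn convention); S-CVI/Ave: mean of item I-CVIs.
* Cut-off validation: the score thresholded at a candidate cut-off is a
  binary classifier; against one rater's labels its ROC has a single interior
  operating point and the trapezoidal AUC reduces to
  (sensitivity + specificity) / 2.
* Binormal ROC: smooth curve assuming normal score distributions within each
  label class, ROC(t) = Phi(a + b * Phi^-1(t)) with
  a = (mean_pos - mean_neg) / sd_pos and b = sd_neg / sd_pos.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .cohort_model import ExpertRating, RaterLabel
from .score import Pathway, ScoreBreakdown

#: Likert level from which a rating counts as endorsement.
CVI_AGREEMENT_MIN = 3


@dataclass(frozen=True)
class CVIReport:
    i_cvi_relevance: dict[str, float]
    i_cvi_clarity: dict[str, float]
    mean_relevance: dict[str, float]
    mean_clarity: dict[str, float]
    s_cvi_ave_relevance: float
    s_cvi_ave_clarity: float
    s_cvi_ave_overall: float
    n_raters: int


@dataclass(frozen=True)
class CutoffValidation:
    rater_id: str
    cutoff: int
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    auc: float


@dataclass(frozen=True)
class BinormalROC:
    a: float
    b: float
    auc_smooth: float

    def curve(self, grid: Sequence[float] | None = None) -> np.ndarray:
        """ROC coordinates on a false-positive-rate grid; returns (n, 2)
        array of (fpr, tpr)."""
        if grid is None:
            grid = np.linspace(0.001, 0.999, 199)
        t = np.asarray(grid, dtype=float)
        tpr = norm.cdf(self.a + self.b * norm.ppf(t))
        return np.column_stack([t, tpr])


def item_cvi(ratings: Sequence[int]) -> float:
    """Proportion of ratings >= 3; ratings must be Likert values in 1..4."""
    if len(ratings) == 0:
        raise ValueError("item_cvi requires at least one rating")
    if any(r not in (1, 2, 3, 4) for r in ratings):
        raise ValueError("Likert ratings must be integers in 1..4")
    return sum(1 for r in ratings if r >= CVI_AGREEMENT_MIN) / len(ratings)


def scale_cvi_ave(i_cvis: Sequence[float]) -> float:
    """Arithmetic mean of item-level CVIs."""
    if len(i_cvis) == 0:
        raise ValueError("scale_cvi_ave requires at least one item CVI")
    return float(np.mean(i_cvis))


def compute_cvi(ratings: Iterable[ExpertRating]) -> CVIReport:
    """Aggregate a long-format expert panel into per-item and scale CVIs."""
    by_item: dict[str, list[ExpertRating]] = {}
    raters = set()
    for r in ratings:
        by_item.setdefault(r.item_id, []).append(r)
        raters.add(r.rater_id)
    if not by_item:
        raise ValueError("empty expert panel")
    items = sorted(by_item, key=ExpertRating.ITEMS.index)
    i_rel = {it: item_cvi([r.relevance for r in by_item[it]]) for it in items}
    i_cla = {it: item_cvi([r.clarity for r in by_item[it]]) for it in items}
    mean_rel = {it: float(np.mean([r.relevance for r in by_item[it]])) for it in items}
    mean_cla = {it: float(np.mean([r.clarity for r in by_item[it]])) for it in items}
    s_rel = scale_cvi_ave(list(i_rel.values()))
    s_cla = scale_cvi_ave(list(i_cla.values()))
    return CVIReport(
        i_cvi_relevance=i_rel,
        i_cvi_clarity=i_cla,
        mean_relevance=mean_rel,
        mean_clarity=mean_cla,
        s_cvi_ave_relevance=s_rel,
        s_cvi_ave_clarity=s_cla,
        s_cvi_ave_overall=(s_rel + s_cla) / 2,
        n_raters=len(raters),
    )


def predict_at_cutoff(breakdown: ScoreBreakdown, cutoff: int) -> bool:
    """Binary diagnosis at a candidate cut-off.

    The naive pathway (B) is diagnostic whenever criteria A and D hold; the
    pre-existing pathway compares the total against the cut-off (ties count
    as positive, matching the ">= threshold" rule).
    """
    if not (breakdown.criterion_A and breakdown.criterion_D):
        return False
    if breakdown.pathway is Pathway.NEW_ONSET_B:
        return True
    if breakdown.pathway is Pathway.NOT_APPLICABLE:
        return False
    return breakdown.total >= cutoff


def single_threshold_auc(sensitivity: float, specificity: float) -> float:
    """Trapezoidal area under the three-point ROC
    {(0,0), (1-specificity, sensitivity), (1,1)}; equals (sens + spec) / 2."""
    fpr = np.array([0.0, 1.0 - specificity, 1.0])
    tpr = np.array([0.0, sensitivity, 1.0])
    return float(np.trapezoid(tpr, fpr))


def confusion_at_cutoff(
    scores: Mapping[str, ScoreBreakdown],
    labels: Iterable[RaterLabel],
    cutoff: int,
) -> CutoffValidation:
    """Validate the thresholded score against one rater's labels."""
    labels = list(labels)
    rater_ids = {lab.rater_id for lab in labels}
    if len(rater_ids) != 1:
        raise ValueError(f"expected labels from exactly one rater, got {sorted(rater_ids)}")
    tp = fp = tn = fn = 0
    for lab in labels:
        if lab.patient_id not in scores:
            raise ValueError(f"label references unknown patient {lab.patient_id!r}")
        pred = predict_at_cutoff(scores[lab.patient_id], cutoff)
        if lab.label and pred:
            tp += 1
        elif lab.label:
            fn += 1
        elif pred:
            fp += 1
        else:
            tn += 1
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return CutoffValidation(
        rater_id=rater_ids.pop(),
        cutoff=cutoff,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        auc=(sens + spec) / 2,
    )


def rater_operating_point(
    labels: Iterable[RaterLabel], reference: Mapping[str, bool]
) -> tuple[float, float]:
    """Class-conditional accuracy of one rater against a reference diagnosis.

    Returns ``(sensitivity, specificity)`` of the rater's labels, i.e.
    P(label+ | reference+) and P(label- | reference-). With labels generated
    by class-conditional flips of the reference, the expected operating point
    is (1 - fn_rate, 1 - fp_rate) independent of prevalence.
    """
    tp = fn = tn = fp = 0
    for lab in labels:
        if lab.patient_id not in reference:
            raise ValueError(f"label references unknown patient {lab.patient_id!r}")
        ref = reference[lab.patient_id]
        if ref and lab.label:
            tp += 1
        elif ref:
            fn += 1
        elif lab.label:
            fp += 1
        else:
            tn += 1
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec


def fit_binormal(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> BinormalROC:
    """Fit the two-parameter binormal ROC from label-positive and
    label-negative score samples (label-positive spread as reference)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(np.unique(pos)) < 2 or len(np.unique(neg)) < 2:
        raise ValueError("each label group needs >= 2 distinct score values")
    sd_pos = pos.std(ddof=1)
    sd_neg = neg.std(ddof=1)
    if sd_pos == 0:
        raise ValueError("degenerate fit: zero variance in label-positive scores")
    a = (pos.mean() - neg.mean()) / sd_pos
    b = sd_neg / sd_pos
    auc = float(norm.cdf(a / np.sqrt(1.0 + b * b)))
    return BinormalROC(a=float(a), b=float(b), auc_smooth=auc)


def validate_cutoffs(
    scores: Mapping[str, ScoreBreakdown],
    labels: Iterable[RaterLabel],
    cutoffs: Sequence[int] = (8, 9, 10),
) -> list[CutoffValidation]:
    """Per-rater, per-cutoff validation (raters never pooled)."""
    by_rater: dict[str, list[RaterLabel]] = {}
    for lab in labels:
        by_rater.setdefault(lab.rater_id, []).append(lab)
    out = []
    for rater_id in sorted(by_rater):
        for cutoff in cutoffs:
            out.append(confusion_at_cutoff(scores, by_rater[rater_id], cutoff))
    return out
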