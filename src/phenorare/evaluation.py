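"""Metrics for imbalanced case detection at a fixed operating point.

The classifiers are compared at a common specificity (default 90%): the
decision threshold is tuned on control scores so that at most 10% of
controls score above it, and sensitivity is read off at that threshold.
Ranking metrics (recall@k% / precision@k%) describe the top of the patient
list a clinician would review; AUROC and AUPRC summarise the global ranking.
Under a label-independent ranker AUPRC and precision@k both concentrate at
the case prevalence, which in a 30 / 7,231 cohort is 0.41%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import average_precision_score, roc_auc_score

RATE_METRICS = (
    "sensitivity_at_spec", "recall_at_1pct", "recall_at_10pct",
    "precision_at_1pct", "precision_at_10pct", "auroc", "auprc",
)


@dataclass(frozen=True)
class RankedList:
    """Patients ordered by descending score; ties broken by patient id."""

    patient_ids: tuple[str, ...]
    scores: tuple[float, ...]

    @classmethod
    def from_scores(cls, scores: Mapping[str, float]) -> "RankedList":
        order = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(
            patient_ids=tuple(pid for pid, _ in order),
            scores=tuple(s for _, s in order),
        )

    def __len__(self) -> int:
        return len(self.patient_ids)


@dataclass(frozen=True)
class EvaluationReport:
    per_repetition: tuple[dict, ...]
    aggregate: dict
    config: dict = field(default_factory=dict)


def threshold_at_specificity(
    control_scores: Sequence[float], target: float = 0.90
) -> float:
    """Smallest observed control score t with P(control > t) <= 1 - target.

    Positives are defined by strict inequality (score > t), so the achieved
    specificity is at least the target by construction.
    """
    scores = np.asarray(control_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("need at least one control score")
    if not (0.0 < target < 1.0):
        raise ValueError("target specificity must be in (0, 1)")
    # epsilon guards (1 - target) * n landing just under an integer
    allowed_fp = (1.0 - target) * scores.size + 1e-9
    for t in np.unique(scores):  # ascending order statistics
        if (scores > t).sum() <= allowed_fp:
            return float(t)
    return float(scores.max())  # pragma: no cover - the max always qualifies


def sensitivity_at_threshold(case_scores: Sequence[float], threshold: float) -> float:
    scores = np.asarray(case_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("need at least one case score")
    return float((scores > threshold).mean())


def specificity_at_threshold(control_scores: Sequence[float], threshold: float) -> float:
    scores = np.asarray(control_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("need at least one control score")
    return float((scores <= threshold).mean())


def recall_precision_at_k(
    ranked: RankedList, labels: Mapping[str, int], k_percent: float
) -> tuple[float, float]:
    """Recall and precision within the top k% of the ranked list.

    The slice size is ``m = max(1, round(k/100 * n))``.
    """
    if not (0.0 < k_percent <= 100.0):
        raise ValueError("k_percent must be in (0, 100]")
    missing = [pid for pid in ranked.patient_ids if pid not in labels]
    if missing:
        raise ValueError(f"labels missing for ranked patients: {missing[:5]}")
    n = len(ranked)
    m = max(1, round(k_percent / 100.0 * n))
    top = ranked.patient_ids[:m]
    hits = sum(labels[pid] for pid in top)
    total_cases = sum(labels[pid] for pid in ranked.patient_ids)
    recall = hits / total_cases if total_cases else 0.0
    return float(recall), float(hits / m)


def auroc_auprc(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, float]:
    """AUROC (Mann-Whitney form, ties count 1/2) and AUPRC (average precision)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for AUROC/AUPRC")
    s = np.asarray(scores, dtype=float)
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


def evaluate_scores(
    scores: Mapping[str, float],
    labels: Mapping[str, int],
    *,
    specificity: float = 0.90,
    k_percents: Sequence[float] = (1.0, 10.0),
) -> dict:
    """All per-repetition metrics from one test set's scores and labels."""
    ranked = RankedList.from_scores(scores)
    case_scores = [s for pid, s in scores.items() if labels[pid] == 1]
    control_scores = [s for pid, s in scores.items() if labels[pid] == 0]
    t = threshold_at_specificity(control_scores, target=specificity)
    metrics = {
        "threshold": t,
        "sensitivity_at_spec": sensitivity_at_threshold(case_scores, t),
        "specificity_achieved": specificity_at_threshold(control_scores, t),
    }
    for k in k_percents:
        r, p = recall_precision_at_k(ranked, labels, k)
        key = f"{k:g}pct"
        metrics[f"recall_at_{key}"] = r
        metrics[f"precision_at_{key}"] = p
    ordered_ids = list(scores)
    auroc, auprc = auroc_auprc(
        [scores[pid] for pid in ordered_ids], [labels[pid] for pid in ordered_ids]
    )
    metrics["auroc"] = auroc
    metrics["auprc"] = auprc
    return metrics


def aggregate(per_repetition: Sequence[dict], *, truncate_rates: bool = True) -> dict:
    """Mean and 95% t-interval per metric across repetitions.

    The CI is ``mean +/- t(0.975, R-1) * sd / sqrt(R)``; for rate metrics the
    interval is truncated to [0, 1].  With a single repetition only the mean
    is reported.
    """
    if not per_repetition:
        raise ValueError("no repetitions to aggregate")
    keys = [k for k in per_repetition[0] if isinstance(per_repetition[0][k], (int, float))]
    out = {}
    r = len(per_repetition)
    for key in keys:
        vals = np.array([rep[key] for rep in per_repetition], dtype=float)
        mean = float(vals.mean())
        entry = {"mean": mean}
        if r >= 2:
            half = float(sps.t.ppf(0.975, r - 1) * vals.std(ddof=1) / np.sqrt(r))
            lo, hi = mean - half, mean + half
            if truncate_rates and key in RATE_METRICS:
                lo, hi = max(0.0, lo), min(1.0, hi)
            entry["ci95"] = [lo, hi]
        out[key] = entry
    return out
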