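"""Evaluation metrics: Dice overlap, score-agreement summaries, bootstrap CIs.

Segmentation quality is measured by the Dice similarity coefficient
DSC = 2|A ∩ B| / (|A| + |B|); Lund-Mackay score agreement by accuracy
and support-weighted precision/recall/F1 over the three sub-score
classes, with per-region 3x3 confusion tables.  Confidence intervals use
a seeded percentile bootstrap over subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ShapeMismatchError
from .regions import Region, SinusType
from .scoring import LMSReport

__all__ = [
    "dice",
    "dice_table",
    "ScoreConfusion",
    "MetricSummary",
    "score_metrics",
    "bootstrap_ci",
    "evaluate_lms",
]

N_SCORE_CLASSES = 3


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient between two binary masks.

    Convention for degenerate inputs: both masks empty -> 1.0 (perfect
    agreement on an aplastic region); exactly one empty -> 0.0.
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na = int(a.sum())
    nb = int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (na + nb)


def bootstrap_ci(
    per_subject_values,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean of per-subject values."""
    values = np.asarray(per_subject_values, dtype=float)
    if values.size < 2:
        raise ValueError("bootstrap CI requires at least 2 subjects")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def dice_table(
    per_subject_dice: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Summarize per-subject, per-region Dice into mean + 95% CI rows.

    ``per_subject_dice`` has columns ``subject``, ``region`` (sinus type
    name) and ``dsc``.  Output mirrors a mean-DSC-with-CI results table:
    one row per region plus a pooled ``mean_excluding_omc`` row.
    """
    rows = []
    for region, grp in per_subject_dice.groupby("region", sort=False):
        vals = grp["dsc"].to_numpy()
        lo, hi = bootstrap_ci(vals, n_boot=n_boot, seed=seed)
        rows.append(
            {"region": region, "mean_dsc": float(vals.mean()), "ci_low": lo, "ci_high": hi}
        )
    non_omc = per_subject_dice[per_subject_dice["region"] != SinusType.OMC.value]
    if len(non_omc):
        by_subj = non_omc.groupby("subject")["dsc"].mean().to_numpy()
        if by_subj.size >= 2:
            lo, hi = bootstrap_ci(by_subj, n_boot=n_boot, seed=seed)
        else:
            lo = hi = float(by_subj.mean())
        rows.append(
            {
                "region": "mean_excluding_omc",
                "mean_dsc": float(by_subj.mean()),
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ScoreConfusion:
    """3x3 contingency table of (true sub-score, predicted sub-score)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_SCORE_CLASSES, N_SCORE_CLASSES):
            raise ValueError(f"expected a 3x3 table, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_pairs(cls, true_scores, predicted_scores) -> "ScoreConfusion":
        t = np.asarray(true_scores, dtype=int)
        p = np.asarray(predicted_scores, dtype=int)
        if t.shape != p.shape:
            raise ShapeMismatchError("true/predicted score arrays differ in length")
        counts = np.zeros((N_SCORE_CLASSES, N_SCORE_CLASSES), dtype=np.int64)
        np.add.at(counts, (t, p), 1)
        return cls(counts)


@dataclass
class MetricSummary:
    accuracy: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
        }


def score_metrics(confusion: ScoreConfusion) -> MetricSummary:
    """Accuracy and support-weighted precision/recall/F1 from a table.

    Weights are true-class supports; classes with zero support are
    excluded from the weighting, and a class that is never predicted
    contributes precision 0.  For single-label multiclass input the
    weighted recall equals the accuracy algebraically.
    """
    c = confusion.counts
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion table")
    support = c.sum(axis=1).astype(float)
    predicted = c.sum(axis=0).astype(float)
    diag = np.diag(c).astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(predicted > 0, diag / predicted, 0.0)
        recall = np.where(support > 0, diag / support, 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / pr, 0.0)

    w = support / support.sum()
    return MetricSummary(
        accuracy=float(diag.sum() / total),
        weighted_precision=float((w * precision).sum()),
        weighted_recall=float((w * recall).sum()),
        weighted_f1=float((w * f1).sum()),
    )


def evaluate_lms(
    reference: dict[str, LMSReport],
    predicted: dict[str, LMSReport],
) -> tuple[dict[str, ScoreConfusion], pd.DataFrame]:
    """Compare predicted against reference sub-scores, pooled per sinus type.

    ``reference`` and ``predicted`` map case identifiers to reports on the
    same cases.  Left/right instances of each sinus are pooled, giving one
    3x3 confusion table and one accuracy/precision/recall/F1 row per sinus
    type (the conventional one-column-per-sinus layout); the per-side
    detail remains available through the returned confusion counts'
    construction order.
    """
    missing = sorted(set(reference) ^ set(predicted))
    if missing:
        raise ValueError(f"unpaired cases: {missing}")
    if not reference:
        raise ValueError("no cases to evaluate")

    confusions: dict[str, ScoreConfusion] = {}
    rows = []
    for sinus in SinusType:
        t, p = [], []
        for case in sorted(reference):
            for region in Region:
                if region.sinus != sinus:
                    continue
                t.append(reference[case].sub_score(region))
                p.append(predicted[case].sub_score(region))
        conf = ScoreConfusion.from_pairs(t, p)
        confusions[sinus.value] = conf
        summary = score_metrics(conf)
        rows.append({"region": sinus.value, **summary.as_dict()})
    return confusions, pd.DataFrame(rows)
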