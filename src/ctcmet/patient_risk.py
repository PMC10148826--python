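"""Patient-level CTC count classifiers and their evaluation.

Cell subgroup labels are aggregated to per-patient total / C1 / C2 counts.
Count cutoffs are chosen by the Youden index on the ROC curve, patients
are classified by a strict count rule (high total or C2 count, low C1
count are unfavorable), and classifiers are evaluated with
sensitivity/specificity/accuracy, the confusion matrix, tie-aware
Mann-Whitney AUC, and uni-/multivariate logistic association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._logit import fit_logit

__all__ = [
    "PerformanceMetrics",
    "RocCurve",
    "aggregate_patient_counts",
    "roc_auc",
    "optimal_count_cutoff",
    "classify_patients",
    "performance_metrics",
    "implied_confusion",
    "logistic_association",
]


def aggregate_patient_counts(
    patient_ids: pd.Series,
    subgroup_labels: Sequence[str],
    roster: Sequence | None = None,
) -> pd.DataFrame:
    """Per-patient total, C1 and C2 CTC counts.

    Parameters
    ----------
    patient_ids : Series
        Patient id per cell (indexed by cell id).
    subgroup_labels : sequence of "C1"/"C2"
        Subgroup call per cell, aligned with ``patient_ids``.
    roster : optional sequence of patient ids
        Patients to report even when no cell maps to them; those get zero
        counts and ``ctc_negative=True`` (they are excluded from
        count-classifier evaluation, mirroring clinical practice where the
        classifier applies only to CTC-positive patients).
    """
    labels = np.asarray(subgroup_labels)
    if labels.shape[0] != len(patient_ids):
        raise ValueError("one subgroup label per cell required")
    bad = set(np.unique(labels)) - {"C1", "C2"}
    if bad:
        raise ValueError(f"labels must be C1/C2, got extras {sorted(bad)}")

    df = pd.DataFrame({"patient_id": patient_ids.to_numpy(), "label": labels})
    counts = (
        df.pivot_table(index="patient_id", columns="label", aggfunc="size", fill_value=0)
        .reindex(columns=["C1", "C2"], fill_value=0)
        .rename(columns={"C1": "c1_count", "C2": "c2_count"})
    )
    counts["total_ctc_count"] = counts["c1_count"] + counts["c2_count"]
    counts["ctc_negative"] = False
    if roster is not None:
        counts = counts.reindex(pd.Index(roster, name="patient_id"))
        absent = counts["total_ctc_count"].isna()
        counts.loc[absent, ["c1_count", "c2_count", "total_ctc_count"]] = 0
        counts.loc[absent, "ctc_negative"] = True
        counts = counts.astype(
            {"c1_count": int, "c2_count": int, "total_ctc_count": int}
        )
    return counts[["total_ctc_count", "c1_count", "c2_count", "ctc_negative"]]


@dataclass(frozen=True)
class RocCurve:
    """ROC points (one per distinct threshold) and the tie-aware AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float
    direction: str


def _oriented(values, direction: str) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if direction == "greater":
        return v
    if direction == "less":
        return -v
    raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")


def roc_auc(values, outcomes, direction: str = "greater") -> RocCurve:
    """ROC analysis of a per-patient statistic against a binary outcome.

    AUC is the Mann-Whitney probability that a positive patient scores
    higher than a negative one, with ties credited 0.5. ``direction`` is
    "greater" when high values indicate the positive class (total and C2
    counts) and "less" for the reversed C1-count classifier.
    """
    y = np.asarray(outcomes).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("outcomes must be binary 0/1")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    v = _oriented(values, direction)

    ranks = stats.rankdata(v)  # midranks handle ties at 0.5 credit
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    thresholds = np.unique(v)[::-1]
    sens = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = v >= t
        sens[i] = (pred & (y == 1)).sum() / n_pos
        fpr[i] = (pred & (y == 0)).sum() / n_neg
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        one_minus_specificity=fpr,
        auc=float(auc),
        direction=direction,
    )


def optimal_count_cutoff(counts, outcomes, direction: str = "greater") -> int:
    """Integer count cutoff maximizing the Youden index.

    Candidates are the observed count values. A patient is called positive
    iff count > cutoff under direction "greater" (total / C2 counts) or
    count < cutoff under "less" (C1 count). Ties in J go to the smallest
    cutoff.
    """
    c = np.asarray(counts)
    y = np.asarray(outcomes).astype(int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    candidates = np.unique(c)
    if candidates.size < 2:
        raise ValueError("constant counts admit no cutoff")
    best_j, best_cut = -np.inf, None
    for cut in candidates:  # ascending, so ties keep the smallest cutoff
        pred = classify_patients(c, int(cut), direction)
        tp = int((pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        j = tp / n_pos + tn / n_neg - 1.0
        if j > best_j:
            best_j, best_cut = j, int(cut)
    return best_cut


def classify_patients(counts, cutoff: int, direction: str = "greater") -> np.ndarray:
    """Strict count rule: positive iff count > cutoff ("greater") or < cutoff ("less").

    A count exactly at the cutoff is negative (favorable) — e.g. a C2 CTC
    count of 1 at the published cutoff of 1 does not predict metastasis.
    """
    if cutoff < 0 or int(cutoff) != cutoff:
        raise ValueError(f"cutoff must be a non-negative integer, got {cutoff}")
    c = np.asarray(counts)
    if direction == "greater":
        return c > cutoff
    if direction == "less":
        return c < cutoff
    raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")


@dataclass(frozen=True)
class PerformanceMetrics:
    """Confusion counts and rates of a binary patient classifier."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float | None = None
    cutoff: int | None = None
    direction: str | None = None

    @property
    def confusion(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.tn, self.fn)

    def as_percent(self) -> dict[str, float]:
        """Rates as percentages rounded to 1 decimal (reporting convention)."""
        return {
            "sensitivity": round(100 * self.sensitivity, 1),
            "specificity": round(100 * self.specificity, 1),
            "accuracy": round(100 * self.accuracy, 1),
        }


def performance_metrics(
    predictions,
    outcomes,
    auc: float | None = None,
    cutoff: int | None = None,
    direction: str | None = None,
) -> PerformanceMetrics:
    """Confusion matrix, sensitivity, specificity and accuracy."""
    pred = np.asarray(predictions).astype(bool)
    y = np.asarray(outcomes).astype(int)
    if pred.shape != y.shape or pred.size == 0:
        raise ValueError("predictions and outcomes must be equal-length, non-empty")
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    tn = int((~pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / pred.size
    return PerformanceMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec, accuracy=acc,
        auc=auc, cutoff=cutoff, direction=direction,
    )


def implied_confusion(
    sensitivity_pct: float,
    specificity_pct: float,
    group_sizes: tuple[int, int],
) -> tuple[int, int, int, int]:
    """Integer confusion matrix implied by reported sensitivity/specificity.

    Reported rates are percentages rounded to one decimal; the cohort
    splits into two groups of known sizes, but published legends do not
    always make clear which group is the positive class. Both assignments
    of ``group_sizes`` to (positives, negatives) are tried and the one
    whose integer counts reproduce BOTH printed rates at 1-decimal
    rounding is returned as (TP, FP, TN, FN).

    Raises
    ------
    ValueError
        If neither assignment is integer-consistent with the printed rates.
    """
    for n_pos, n_neg in (group_sizes, group_sizes[::-1]):
        tp = round(sensitivity_pct / 100.0 * n_pos)
        tn = round(specificity_pct / 100.0 * n_neg)
        if (
            round(100.0 * tp / n_pos, 1) == round(sensitivity_pct, 1)
            and round(100.0 * tn / n_neg, 1) == round(specificity_pct, 1)
        ):
            return int(tp), int(n_neg - tn), int(tn), int(n_pos - tp)
    raise ValueError(
        f"no integer confusion matrix with groups {group_sizes} reproduces "
        f"sensitivity {sensitivity_pct}% and specificity {specificity_pct}%"
    )


def logistic_association(
    patient_table: pd.DataFrame,
    predictors: Sequence[str],
    outcome: str = "outcome",
) -> pd.DataFrame:
    """Uni- and multivariate logistic association of predictors with outcome.

    Returns one row per predictor and model ("univariate"/"multivariate")
    with the odds ratio (per unit), Wald 95% CI and p-value. Separation
    triggers a flagged ridge fallback.
    """
    if len(patient_table) < 10:
        raise ValueError("need >= 10 patients for association analysis")
    y = patient_table[outcome].to_numpy(dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    for p in predictors:
        if patient_table[p].nunique() < 2:
            raise ValueError(f"constant predictor {p!r}")

    rows = []

    def _append(model: str, names: Sequence[str], X: np.ndarray) -> None:
        fit = fit_logit(y, X, add_const=True)
        if fit.flagged:
            warnings.warn(
                f"{model} fit used penalized fallback (separation)", stacklevel=3
            )
        z = stats.norm.ppf(0.975)
        for i, name in enumerate(names, start=1):
            b, se = fit.params[i], fit.bse[i]
            rows.append(
                {
                    "predictor": name,
                    "model": model,
                    "odds_ratio": float(np.exp(b)),
                    "ci_low": float(np.exp(b - z * se)),
                    "ci_high": float(np.exp(b + z * se)),
                    "p": float(fit.p_values[i]),
                    "penalized": fit.flagged,
                }
            )

    for p in predictors:
        _append("univariate", [p], patient_table[[p]].to_numpy(dtype=float))
    _append(
        "multivariate", list(predictors), patient_table[list(predictors)].to_numpy(dtype=float)
    )
    return pd.DataFrame(rows)
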