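"""ROC evaluation, AUC comparison tests, and clinical confusion statistics.

Classifier performance is measured by leave-one-out cross-validation
(LOOCV): each record is scored by a model trained on the remaining N-1
records, and the held-out decision scores are pooled into one ROC curve.
The area under the curve, Az, is the probability that a random malignant
lesion scores above a random benign one (ties counted 1/2).  Two correlated
ROC curves from the same records are compared with DeLong's
structural-components test and with a paired bootstrap t-test on Az.
Clinical count tables (correct/incorrect diagnoses per histological
category) yield sensitivity, specificity, accuracy and Wilson 95% CIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .selection import (
    DEFAULT_COST,
    LabeledFeatureTable,
    decision_scores,
    train_linear_svm,
)

__all__ = [
    "RocResult",
    "ConfusionCounts",
    "loocv_scores",
    "auc",
    "roc_result",
    "delong_test",
    "paired_bootstrap_az",
    "operating_point",
    "univariate_az",
    "confusion_stats",
    "group_accuracy",
]


class UndefinedMetricError(ValueError):
    """A metric's denominator is empty (single class, zero counts)."""


def _check_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels, dtype=np.int64)
    if not ((y == 0) | (y == 1)).all():
        raise ValueError("labels must be 0/1")
    if y.min() == y.max():
        raise UndefinedMetricError("both classes must be present")
    return y


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Az: P(score_malignant > score_benign) + 1/2 P(tie).

    Computed exactly with midranks; identical to the trapezoidal ROC area.
    """
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=np.float64)
    ranks = stats.rankdata(s)
    n1 = int(y.sum())
    n0 = len(y) - n1
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


@dataclass(frozen=True)
class RocResult:
    """Pooled decision scores with the ROC operating points and Az."""

    scores: np.ndarray
    labels: np.ndarray
    points: pd.DataFrame  # columns threshold, sensitivity, specificity, accuracy
    az: float


def _thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct scores, plus -inf/+inf sentinels."""
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2 if len(distinct) > 1 else np.array([])
    return np.concatenate([[-np.inf], mids, [np.inf]])


def roc_result(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """Build the full ROC table (score >= threshold classified malignant)."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=np.float64)
    n1 = int(y.sum())
    n0 = len(y) - n1
    rows = []
    for t in _thresholds(s):
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        rows.append((t, tp / n1, tn / n0, (tp + tn) / len(y)))
    points = pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity", "accuracy"])
    return RocResult(scores=s, labels=y, points=points, az=auc(s, y))


def loocv_scores(
    table: LabeledFeatureTable,
    feature_subset=None,
    cost: float = DEFAULT_COST,
) -> np.ndarray:
    """Held-out decision score for every record under leave-one-out CV.

    Standardization is refit inside each fold (no leakage of the held-out
    record into the column scaling).
    """
    if table.n < 3:
        raise ValueError("LOOCV needs at least 3 records")
    sub = table.subset(feature_subset) if feature_subset is not None else table
    scores = np.empty(sub.n)
    idx = np.arange(sub.n)
    for i in range(sub.n):
        train = sub.select_rows(idx[idx != i])
        if train.labels.min() == train.labels.max():
            raise UndefinedMetricError(
                f"fold {i}: training portion lost one class entirely"
            )
        model = train_linear_svm(train, cost=cost)
        scores[i] = decision_scores(model, sub.features.iloc[[i]])[0]
    return scores


def _structural_components(scores: np.ndarray, y: np.ndarray):
    """DeLong V10 (per malignant record) and V01 (per benign record)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    # psi(x, y) = 1 if x > y, 1/2 if tie, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(np.float64)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)  # V10 per positive, V01 per negative


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float, float]:
    """DeLong's test for two correlated ROC curves on paired records.

    Returns ``(az_a, az_b, z, p)`` with a two-sided normal p-value for the
    difference az_a - az_b.
    """
    y = _check_labels(labels)
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("scores_a, scores_b and labels must be the same length")
    az_a, az_b = auc(a, y), auc(b, y)
    v10_a, v01_a = _structural_components(a, y)
    v10_b, v01_b = _structural_components(b, y)
    v10 = np.vstack([v10_a, v10_b])
    v01 = np.vstack([v01_a, v01_b])
    m, n = v10.shape[1], v01.shape[1]
    s10 = np.cov(v10, ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01, ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = az_a - az_b
    if var <= 0:
        if diff == 0:
            return az_a, az_b, 0.0, 1.0
        raise FloatingPointError(
            "zero variance of the Az difference with unequal Az values"
        )
    z = diff / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return az_a, az_b, float(z), float(p)


def paired_bootstrap_az(
    scores_a,
    scores_b,
    labels,
    B: int = 1000,
    seed: int = 0,
    max_redraws: int = 100,
) -> float:
    """Paired bootstrap t-test of the Az difference.

    Records are resampled with replacement B times; each replicate
    contributes az_a - az_b.  The replicate spread estimates the sampling
    standard deviation of the Az difference, so the test statistic is
    t = mean(diffs) / sd(diffs) (a studentized bootstrap pivot, NOT scaled
    by sqrt(B): replicates are not independent samples), referred to a
    t distribution with B - 1 degrees of freedom, two-sided.  Replicates
    that lose one class entirely are redrawn (up to ``max_redraws`` each).
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    y = _check_labels(labels)
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    rng = np.random.default_rng(seed)
    n = len(y)
    diffs = np.empty(B)
    for t in range(B):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            yi = y[idx]
            if 0 < yi.sum() < n:
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap replicate")
        diffs[t] = auc(a[idx], yi) - auc(b[idx], yi)
    sd = diffs.std(ddof=1)
    if np.isclose(sd, 0.0):
        return 1.0 if np.isclose(diffs.mean(), 0.0) else 0.0
    t = diffs.mean() / sd
    return float(2 * stats.t.sf(abs(t), df=B - 1))


def operating_point(
    roc: RocResult,
    mode: str = "max-accuracy",
    threshold: float | None = None,
    sensitivity_target: float | None = None,
) -> dict:
    """Select one operating point of a ROC curve.

    ``max-accuracy`` maximizes (TP+TN)/N over thresholds, breaking ties by
    higher specificity then higher threshold; ``fixed-threshold`` classifies
    score >= t as malignant; ``sensitivity-target`` returns the most specific
    point whose sensitivity meets the target (nearest achievable, flagged,
    when the target is unattainable).
    """
    pts = roc.points
    if mode == "max-accuracy":
        best = pts.sort_values(
            ["accuracy", "specificity", "threshold"], ascending=False
        ).iloc[0]
    elif mode == "fixed-threshold":
        if threshold is None:
            raise ValueError("fixed-threshold mode needs a threshold")
        pred = roc.scores >= threshold
        y = roc.labels
        tp = int((pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        n1 = int(y.sum())
        return {
            "threshold": float(threshold),
            "sensitivity": tp / n1,
            "specificity": tn / (len(y) - n1),
            "accuracy": (tp + tn) / len(y),
            "attained": True,
        }
    elif mode == "sensitivity-target":
        if sensitivity_target is None:
            raise ValueError("sensitivity-target mode needs a target")
        ok = pts[pts["sensitivity"] >= sensitivity_target]
        if len(ok):
            best = ok.sort_values(["specificity", "sensitivity"], ascending=False).iloc[0]
        else:
            best = pts.sort_values("sensitivity", ascending=False).iloc[0]
            return {**best[["threshold", "sensitivity", "specificity", "accuracy"]].to_dict(),
                    "attained": False}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = best[["threshold", "sensitivity", "specificity", "accuracy"]].to_dict()
    out["attained"] = True
    return out


def univariate_az(table: LabeledFeatureTable) -> pd.Series:
    """Orientation-free single-feature Az, max(A, 1-A) per column, in [0.5, 1]."""
    y = _check_labels(table.labels)
    out = {}
    for name in table.columns:
        a = auc(table.features[name].to_numpy(), y)
        out[name] = max(a, 1.0 - a)
    return pd.Series(out, name="az")


@dataclass(frozen=True)
class ConfusionCounts:
    """Correct/incorrect diagnosis counts per histological category.

    ``table`` columns: category, class ('benign'|'malignant'), group
    (e.g. 'melanocytic'|'non_melanocytic'), n_correct, n_incorrect.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"category", "class", "n_correct", "n_incorrect"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"counts table missing columns: {sorted(missing)}")
        counts = self.table[["n_correct", "n_incorrect"]].to_numpy()
        if (counts < 0).any() or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        bad = set(self.table["class"]) - {"benign", "malignant"}
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")

    @classmethod
    def from_csv(cls, path, rater: str | None = None) -> "ConfusionCounts":
        df = pd.read_csv(path)
        if rater is not None:
            df = df[df["rater"] == rater].reset_index(drop=True)
            if not len(df):
                raise ValueError(f"no rows for rater {rater!r}")
        return cls(df)


def _wilson(k: int, n: int) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def confusion_stats(counts: ConfusionCounts) -> dict:
    """Sensitivity, specificity and accuracy (with Wilson 95% CIs) of a rater."""
    t = counts.table
    mal = t[t["class"] == "malignant"]
    ben = t[t["class"] == "benign"]
    tp, fn = int(mal["n_correct"].sum()), int(mal["n_incorrect"].sum())
    tn, fp = int(ben["n_correct"].sum()), int(ben["n_incorrect"].sum())
    n_mal, n_ben = tp + fn, tn + fp
    if n_mal == 0 or n_ben == 0:
        raise UndefinedMetricError("both classes need nonzero totals")
    n = n_mal + n_ben
    return {
        "sensitivity": tp / n_mal,
        "sensitivity_ci": _wilson(tp, n_mal),
        "specificity": tn / n_ben,
        "specificity_ci": _wilson(tn, n_ben),
        "accuracy": (tp + tn) / n,
        "accuracy_ci": _wilson(tp + tn, n),
        "n_malignant": n_mal,
        "n_benign": n_ben,
        "n_total": n,
    }


def group_accuracy(counts: ConfusionCounts, grouping: dict[str, str] | None = None) -> dict[str, float]:
    """Diagnostic accuracy per lesion group (e.g. melanocytic vs not).

    ``grouping`` maps category name -> group name; when omitted, the counts
    table's own ``group`` column is used.  Every category must be mapped.
    """
    t = counts.table.copy()
    if grouping is not None:
        unmapped = set(t["category"]) - set(grouping)
        if unmapped:
            raise ValueError(f"unmapped categories: {sorted(unmapped)}")
        t["group"] = t["category"].map(grouping)
    elif "group" not in t.columns or t["group"].isna().any():
        raise ValueError("no grouping supplied and counts table lacks a full 'group' column")
    out = {}
    for name, sub in t.groupby("group"):
        correct = int(sub["n_correct"].sum())
        total = correct + int(sub["n_incorrect"].sum())
        out[str(name)] = correct / total
    return out
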