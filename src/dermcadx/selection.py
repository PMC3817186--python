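"""Feature standardization, linear SVM training, and SVM-RFE feature ranking.

The ranking engine is recursive feature elimination (RFE) with a linear
soft-margin SVM: at each step a classifier is refit on the surviving
columns, the column with the smallest squared weight w_j^2 is discarded, and
the final ranking is the reverse of the elimination order.  Features are
z-scored inside every fit so that squared weights are comparable across
features with different natural scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC

__all__ = [
    "LabeledFeatureTable",
    "LinearModel",
    "RankingResult",
    "standardize",
    "train_linear_svm",
    "decision_scores",
    "rfe_rank",
]

DEFAULT_COST = 1.0


@dataclass(frozen=True)
class LabeledFeatureTable:
    """N feature vectors with binary labels (1 = malignant, 0 = benign)."""

    features: pd.DataFrame  # N x p, named columns
    labels: np.ndarray      # N ints in {0, 1}
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = self.features
        y = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", y)
        if len(X) != len(y):
            raise ValueError(f"{len(X)} rows but {len(y)} labels")
        if X.columns.duplicated().any():
            dup = X.columns[X.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature columns: {dup}")
        if not np.isfinite(X.to_numpy(dtype=np.float64)).all():
            raise ValueError("feature table contains non-finite entries")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be 0 (benign) or 1 (malignant)")
        if not self.ids:
            object.__setattr__(self, "ids", tuple(str(i) for i in range(len(y))))

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.features.columns)

    def subset(self, names) -> "LabeledFeatureTable":
        return LabeledFeatureTable(self.features[list(names)], self.labels, self.ids)

    def select_rows(self, index) -> "LabeledFeatureTable":
        idx = np.asarray(index)
        return LabeledFeatureTable(
            self.features.iloc[idx].reset_index(drop=True),
            self.labels[idx],
            tuple(np.asarray(self.ids, dtype=object)[idx]),
        )

    @classmethod
    def from_csv(cls, path) -> "LabeledFeatureTable":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError("feature CSV must have a 'label' column")
        ids = tuple(df["id"].astype(str)) if "id" in df.columns else ()
        X = df.drop(columns=[c for c in ("id", "label") if c in df.columns])
        return cls(X, df["label"].to_numpy(), ids)

    def to_csv(self, path) -> None:
        out = self.features.copy()
        out.insert(0, "label", self.labels)
        out.insert(0, "id", list(self.ids))
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class Scaling:
    """Per-column center/spread captured at fit time (population std)."""

    center: np.ndarray
    spread: np.ndarray
    constant: np.ndarray  # bool flags for zero-spread columns

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (X - self.center) / self.spread


@dataclass(frozen=True)
class LinearModel:
    """A trained linear maximum-margin classifier.

    The decision score of a record x is ``w . z(x) + b`` where z applies the
    stored standardization; positive scores vote malignant.
    """

    weights: np.ndarray
    bias: float
    scaling: Scaling
    columns: tuple[str, ...]
    cost: float


@dataclass(frozen=True)
class RankingResult:
    """RFE output: elimination order (first = least informative) and ranks."""

    elimination_order: tuple[str, ...]
    rank: dict[str, int] = field(default_factory=dict)

    def top(self, n: int) -> tuple[str, ...]:
        """The n most informative features, best first."""
        return tuple(reversed(self.elimination_order[-n:])) if n else ()


def standardize(X: np.ndarray) -> tuple[np.ndarray, Scaling]:
    """Center each column to mean 0 and scale to unit population std.

    Constant columns are left at spread 1 (their centered values are all 0)
    and flagged.
    """
    X = np.asarray(X, dtype=np.float64)
    center = X.mean(axis=0)
    spread = X.std(axis=0)
    constant = spread == 0
    spread = np.where(constant, 1.0, spread)
    scaling = Scaling(center=center, spread=spread, constant=constant)
    return scaling.apply(X), scaling


def train_linear_svm(table: LabeledFeatureTable, cost: float = DEFAULT_COST) -> LinearModel:
    """Fit an L2-regularized linear SVM (squared hinge loss, primal solver).

    Standardization is applied internally and stored on the model; the
    primal coordinate-descent solver with a tight tolerance makes refits
    deterministic.
    """
    if cost <= 0:
        raise ValueError("cost must be positive")
    classes = np.unique(table.labels)
    if len(classes) < 2:
        raise ValueError("training requires both benign and malignant records")
    X = table.features.to_numpy(dtype=np.float64)
    Z, scaling = standardize(X)
    clf = LinearSVC(
        C=cost,
        loss="squared_hinge",
        penalty="l2",
        dual=False,
        tol=1e-10,
        max_iter=100_000,
        fit_intercept=True,
    )
    clf.fit(Z, table.labels)
    return LinearModel(
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        scaling=scaling,
        columns=table.columns,
        cost=float(cost),
    )


def decision_scores(model: LinearModel, table: LabeledFeatureTable | pd.DataFrame) -> np.ndarray:
    """Signed distances (unnormalized) from the separating hyperplane."""
    X = table.features if isinstance(table, LabeledFeatureTable) else table
    if tuple(X.columns) != model.columns:
        raise ValueError(
            f"column mismatch: model trained on {model.columns}, got {tuple(X.columns)}"
        )
    Z = model.scaling.apply(X.to_numpy(dtype=np.float64))
    return Z @ model.weights + model.bias


def rfe_rank(table: LabeledFeatureTable, cost: float = DEFAULT_COST) -> RankingResult:
    """Recursive feature elimination with the squared-weight criterion.

    One feature is removed per iteration: the one whose squared SVM weight is
    smallest (ties broken by removing the lexicographically last name), until
    no features remain.  Rank 1 is the last survivor.
    """
    remaining = list(table.columns)
    eliminated: list[str] = []
    while remaining:
        if len(remaining) == 1:
            eliminated.append(remaining.pop())
            break
        model = train_linear_svm(table.subset(remaining), cost=cost)
        w2 = model.weights**2
        min_w2 = w2.min()
        tied = [name for name, v in zip(remaining, w2) if v == min_w2]
        drop = max(tied)  # lexicographically last
        remaining.remove(drop)
        eliminated.append(drop)
    order = tuple(eliminated)
    rank = {name: len(order) - i for i, name in enumerate(order)}
    return RankingResult(elimination_order=order, rank=rank)
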