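"""End-to-end orchestration: extraction runs, RFE + LOOCV sweeps, comparisons.

``evaluate_table`` reproduces the evaluation protocol of the classifier
study: rank features by SVM-RFE, then for each top-n feature set estimate
the LOOCV Az, select the best subset (optionally capped — the default cap of
16 follows the rule of keeping the model size below one tenth of the number
of malignant cases), and report its ROC operating points.
``compare_feature_sets`` runs that protocol for the 73-feature conventional
set and the full 91-feature set and compares the two ROC curves with
DeLong's test and a paired bootstrap t-test.
"""

from __future__ import annotations

import numpy as np

from .evaluation import (
    auc,
    delong_test,
    loocv_scores,
    operating_point,
    paired_bootstrap_az,
    roc_result,
    univariate_az,
)
from .features import ALL_FEATURES, CONVENTIONAL_FEATURES
from .selection import DEFAULT_COST, LabeledFeatureTable, rfe_rank

__all__ = ["FEATURE_SETS", "evaluate_table", "compare_feature_sets"]

FEATURE_SETS = {
    "conventional-73": CONVENTIONAL_FEATURES,
    "all-91": ALL_FEATURES,
}

MAX_FEATURES_DEFAULT = 16


def _resolve_feature_set(table: LabeledFeatureTable, feature_set) -> tuple[str, ...]:
    if isinstance(feature_set, str):
        if feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {feature_set!r}")
        names = [f for f in FEATURE_SETS[feature_set] if f in table.columns]
        if not names:
            raise ValueError(f"table has no columns of feature set {feature_set!r}")
        return tuple(names)
    return tuple(feature_set)


def evaluate_table(
    table: LabeledFeatureTable,
    feature_set="all-91",
    cost: float = DEFAULT_COST,
    max_features: int | None = MAX_FEATURES_DEFAULT,
    seed: int = 0,
    include_univariate: bool = False,
) -> dict:
    """RFE ranking + top-n LOOCV Az sweep + best operating point.

    Returns a JSON-serializable report; deterministic for a fixed
    (table, cost, seed).
    """
    names = _resolve_feature_set(table, feature_set)
    sub = table.subset(names)
    ranking = rfe_rank(sub, cost=cost)
    cap = len(names) if max_features is None else min(max_features, len(names))
    sweep = []
    best = None
    for n in range(1, cap + 1):
        top = ranking.top(n)
        scores = loocv_scores(sub, feature_subset=top, cost=cost)
        az = auc(scores, sub.labels)
        sweep.append({"top_n": n, "az": az})
        if best is None or az > best["az"]:
            best = {"top_n": n, "az": az, "features": top, "scores": scores}
    roc = roc_result(best["scores"], sub.labels)
    op = operating_point(roc, mode="max-accuracy")
    report = {
        "feature_set": feature_set if isinstance(feature_set, str) else list(feature_set),
        "cost": cost,
        "max_features": cap,
        "n_records": table.n,
        "ranking": list(ranking.elimination_order[::-1]),  # rank 1 first
        "sweep": sweep,
        "best": {
            "top_n": best["top_n"],
            "az": best["az"],
            "features": list(best["features"]),
            "operating_point": op,
        },
        "loocv_scores": [float(s) for s in best["scores"]],
    }
    if include_univariate:
        report["univariate_az"] = univariate_az(sub).to_dict()
    return report


def compare_feature_sets(
    table: LabeledFeatureTable,
    baseline="conventional-73",
    proposed="all-91",
    cost: float = DEFAULT_COST,
    max_features: int | None = MAX_FEATURES_DEFAULT,
    bootstrap_b: int = 1000,
    seed: int = 0,
) -> dict:
    """Baseline-vs-proposed comparison on one feature table.

    Both feature sets are ranked, swept and operated independently; their
    best LOOCV score vectors (on identical records) feed DeLong's test and
    the paired bootstrap Az t-test.
    """
    rep_base = evaluate_table(table, baseline, cost=cost, max_features=max_features, seed=seed)
    rep_prop = evaluate_table(table, proposed, cost=cost, max_features=max_features, seed=seed)
    s_base = np.array(rep_base["loocv_scores"])
    s_prop = np.array(rep_prop["loocv_scores"])
    az_p, az_b, z, p_delong = delong_test(s_prop, s_base, table.labels)
    p_boot = paired_bootstrap_az(s_prop, s_base, table.labels, B=bootstrap_b, seed=seed)
    return {
        "baseline": rep_base,
        "proposed": rep_prop,
        "comparison": {
            "az_baseline": az_b,
            "az_proposed": az_p,
            "az_difference": az_p - az_b,
            "delong_z": z,
            "delong_p": p_delong,
            "bootstrap_p": p_boot,
            "bootstrap_B": bootstrap_b,
        },
    }
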