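"""Random-forest disease-status classification from microbiome profiles.

A forest of decision trees is fitted on the samples x features abundance
matrix; each sample's score is its out-of-bag (OOB) vote fraction for the
case class, which gives an honest estimate without a separate test split.
Discrimination is summarised by the ROC AUC (equal to the normalised
Mann-Whitney U statistic) with a DeLong 95% confidence interval, and feature
importance by mean decrease in impurity with an enrichment direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.tree import DecisionTreeClassifier


@dataclass
class OOBScores:
    """Out-of-bag case-vote fractions and impurity importances."""

    scores: pd.Series        # sample -> P(case) from OOB trees
    importances: pd.Series   # feature -> mean decrease in impurity
    case: str


@dataclass
class ClassifierReport:
    auc: float
    ci_low: float
    ci_high: float
    scores: pd.Series
    roc_points: pd.DataFrame  # fpr, tpr, threshold
    top_features: pd.DataFrame | None = None


def fit_and_score(
    matrix,
    labels: pd.Series,
    n_trees: int = 1000,
    rng_seed: int = 0,
    case: str | None = None,
) -> OOBScores:
    """Fit a random forest and return per-sample out-of-bag case scores.

    Trees are grown on class-stratified bootstraps (each class resampled to
    its own size), which keeps every tree's class balance equal to the
    cohort's. Plain bootstraps let per-tree class imbalance leak into the
    out-of-bag votes and bias the null OOB AUC well below 0.5 on small
    cohorts; stratification removes that. A sample's score is the fraction
    of case votes among the trees whose bootstrap did not contain it (hard
    majority votes per tree, as in R's randomForest). Deterministic under a
    fixed seed.
    """
    data = getattr(matrix, "data", matrix)
    y = labels.reindex(data.index)
    classes = sorted(y.dropna().unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    counts = y.value_counts()
    if counts.min() < 5:
        raise ValueError("need at least 5 samples per class")
    case = case if case is not None else classes[0]

    x = data.to_numpy(dtype=float)
    y_arr = y.to_numpy()
    n = len(y_arr)
    rng = np.random.default_rng(rng_seed)
    class_idx = [np.flatnonzero(y_arr == c) for c in classes]
    case_votes = np.zeros(n)
    oob_counts = np.zeros(n)
    importances = np.zeros(data.shape[1])
    all_idx = np.arange(n)
    for _ in range(n_trees):
        boot = np.concatenate([rng.choice(ci, size=ci.size, replace=True)
                               for ci in class_idx])
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(0, 2**31 - 1))
        )
        tree.fit(x[boot], y_arr[boot])
        importances += tree.feature_importances_
        oob = np.setdiff1d(all_idx, boot, assume_unique=False)
        if oob.size:
            case_votes[oob] += tree.predict(x[oob]) == case
            oob_counts[oob] += 1
    # samples never out of bag (vanishingly rare with many trees) score 0.5
    scores = np.where(oob_counts > 0,
                      case_votes / np.maximum(oob_counts, 1), 0.5)
    return OOBScores(
        scores=pd.Series(scores, index=data.index, name="oob_score"),
        importances=pd.Series(importances / n_trees, index=data.columns,
                              name="importance"),
        case=case,
    )


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (ties get the average rank), 1-based."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j < len(x) and sx[j] == sx[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
        i = j
    return ranks


def delong_auc_variance(scores_case: np.ndarray, scores_control: np.ndarray
                        ) -> tuple[float, float]:
    """AUC and its DeLong variance for one classifier.

    The AUC equals the Mann-Whitney U statistic divided by n_case*n_control,
    with half credit for ties; the variance follows DeLong's structural
    components (matching pROC's default CI).
    """
    m, n = len(scores_case), len(scores_control)
    allv = np.concatenate([scores_case, scores_control])
    r_all = _midrank(allv)
    r_case = _midrank(scores_case)
    r_control = _midrank(scores_control)
    auc = (r_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (r_all[:m] - r_case) / n            # per-case structural components
    v01 = 1.0 - (r_all[m:] - r_control) / m   # per-control components
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_auc(scores: pd.Series | np.ndarray, labels: pd.Series | np.ndarray,
            case: str | None = None, ci_level: float = 0.95) -> ClassifierReport:
    """ROC curve and AUC with a DeLong confidence interval.

    AUC by the trapezoidal rule over all score thresholds (identical to the
    normalised Mann-Whitney U with half credit for ties); the CI is
    AUC +/- z * sqrt(DeLong variance), clipped to [0, 1].
    """
    s = pd.Series(scores)
    y = pd.Series(np.asarray(labels), index=s.index) if not isinstance(labels, pd.Series) \
        else labels.reindex(s.index)
    classes = sorted(y.dropna().unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    case = case if case is not None else classes[0]
    pos = s[y == case].to_numpy(dtype=float)
    neg = s[y != case].to_numpy(dtype=float)
    auc, var = delong_auc_variance(pos, neg)
    z = norm.ppf(0.5 + ci_level / 2)
    half = z * np.sqrt(var)
    ci_low, ci_high = max(0.0, auc - half), min(1.0, auc + half)

    thresholds = np.concatenate(([np.inf], np.unique(s.to_numpy())[::-1]))
    fpr = [(neg >= t).mean() for t in thresholds]
    tpr = [(pos >= t).mean() for t in thresholds]
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return ClassifierReport(auc, ci_low, ci_high, s, roc)


def classify_report(
    matrix,
    labels: pd.Series,
    n_trees: int = 1000,
    rng_seed: int = 0,
    case: str | None = None,
    n_top: int = 30,
) -> ClassifierReport:
    """Fit, score out-of-bag and assemble the full report with top features."""
    data = getattr(matrix, "data", matrix)
    oob = fit_and_score(matrix, labels, n_trees=n_trees, rng_seed=rng_seed, case=case)
    report = roc_auc(oob.scores, labels, case=oob.case)
    y = labels.reindex(data.index)
    mean_case = data.loc[y == oob.case].mean()
    mean_ctrl = data.loc[y != oob.case].mean()
    top = oob.importances.sort_values(ascending=False).head(n_top)
    report.top_features = pd.DataFrame(
        {
            "importance": top,
            "direction": np.where(
                mean_case.loc[top.index] >= mean_ctrl.loc[top.index],
                f"{oob.case}-enriched",
                "control-enriched",
            ),
        }
    )
    return report
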