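"""Diagnostic-performance evaluation: ROC/AUC, Youden cut-offs, bootstrap
AUC comparison, SMOTE class balancing, repeated SVM evaluation and Dunnett
many-to-one subgroup comparison.

Orientation
-----------
Every index carries a polarity: for iLoss and WR *high* values indicate
disease; for iUp/iLoss, eHMR and dHMR *low* values do.  All ROC utilities
take a ``positive_high`` flag and orient scores internally, so AUCs are
always reported on the "higher score = more diseased" scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.model_selection import train_test_split
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "RocResult",
    "ClassifierEvaluation",
    "roc_auc",
    "youden_cutoff",
    "bootstrap_auc_test",
    "smote",
    "diagnostic_odds_ratio",
    "repeated_svm_evaluation",
    "dunnett_comparison",
]


def _check_binary(scores: np.ndarray, labels: np.ndarray) -> None:
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("need exactly two classes present")


def _orient(scores: np.ndarray, positive_high: bool) -> np.ndarray:
    return scores if positive_high else -scores


@dataclass
class RocResult:
    """ROC summary for one index (one row of a cut-off table)."""

    auc: float
    ci95: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    sens_ci95: tuple[float, float]
    spec_ci95: tuple[float, float]
    positive_high: bool
    n_pos: int
    n_neg: int


def youden_cutoff(
    scores, labels, positive_high: bool = True
) -> tuple[float, float, float]:
    """Cut-off from the observed score set maximising Youden's J.

    The decision rule is ``score >= cutoff`` (or ``<=`` when low values
    indicate disease).  Ties in J are broken toward the least extreme
    threshold (the candidate closest to the median score), deterministically.

    Returns ``(cutoff, sensitivity, specificity)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_binary(scores, labels)
    cand = np.unique(scores)
    pos = labels == 1
    neg = ~pos
    best_j = -np.inf
    ties: list[float] = []
    for theta in cand:
        pred = scores >= theta if positive_high else scores <= theta
        sens = np.mean(pred[pos])
        spec = np.mean(~pred[neg])
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, ties = j, [float(theta)]
        elif abs(j - best_j) <= 1e-12:
            ties.append(float(theta))
    med = float(np.median(scores))
    cutoff = min(ties, key=lambda t: (abs(t - med), t))
    pred = scores >= cutoff if positive_high else scores <= cutoff
    return cutoff, float(np.mean(pred[pos])), float(np.mean(~pred[neg]))


def roc_auc(
    scores,
    labels,
    positive_high: bool = True,
    n_boot: int = 2000,
    seed: int = 0,
    compute_ci: bool = True,
) -> RocResult:
    """AUC (Mann-Whitney probability, half credit for ties) with stratified
    bootstrap 95% CI, plus the Youden cut-off and its operating point with
    Wilson score CIs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_binary(scores, labels)
    s = _orient(scores, positive_high)
    auc = float(roc_auc_score(labels, s))
    pos_idx = np.nonzero(labels == 1)[0]
    neg_idx = np.nonzero(labels == 0)[0]

    if compute_ci and n_boot > 0:
        rng = np.random.default_rng(seed)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            pi = rng.choice(pos_idx, pos_idx.size, replace=True)
            ni = rng.choice(neg_idx, neg_idx.size, replace=True)
            idx = np.concatenate([pi, ni])
            aucs[b] = roc_auc_score(labels[idx], s[idx])
        lo, hi = np.percentile(aucs, [2.5, 97.5])
        ci = (float(lo), float(hi))
    else:
        ci = (float("nan"), float("nan"))

    cutoff, sens, spec = youden_cutoff(scores, labels, positive_high)
    n_pos, n_neg = pos_idx.size, neg_idx.size
    sens_ci = proportion_confint(round(sens * n_pos), n_pos, method="wilson")
    spec_ci = proportion_confint(round(spec * n_neg), n_neg, method="wilson")
    return RocResult(
        auc=auc,
        ci95=ci,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        sens_ci95=(float(sens_ci[0]), float(sens_ci[1])),
        spec_ci95=(float(spec_ci[0]), float(spec_ci[1])),
        positive_high=positive_high,
        n_pos=int(n_pos),
        n_neg=int(n_neg),
    )


def bootstrap_auc_test(
    scores_a,
    scores_b,
    labels,
    positive_high_a: bool = True,
    positive_high_b: bool = True,
    n_boot: int = 2000,
    seed: int = 0,
) -> float:
    """Two-sided bootstrap test for a difference between two paired AUCs.

    Subjects are resampled with stratification; the observed AUC difference
    is referred to the bootstrap standard deviation of the difference
    (normal-theory two-sided p, as in the pROC bootstrap method).
    """
    a = _orient(np.asarray(scores_a, dtype=float), positive_high_a)
    b = _orient(np.asarray(scores_b, dtype=float), positive_high_b)
    labels = np.asarray(labels).astype(int)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    _check_binary(a, labels)
    d_obs = roc_auc_score(labels, a) - roc_auc_score(labels, b)
    rng = np.random.default_rng(seed)
    pos_idx = np.nonzero(labels == 1)[0]
    neg_idx = np.nonzero(labels == 0)[0]
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        idx = np.concatenate(
            [
                rng.choice(pos_idx, pos_idx.size, replace=True),
                rng.choice(neg_idx, neg_idx.size, replace=True),
            ]
        )
        diffs[i] = roc_auc_score(labels[idx], a[idx]) - roc_auc_score(
            labels[idx], b[idx]
        )
    sd = float(np.std(diffs, ddof=1))
    if sd == 0.0:
        return 1.0
    z = d_obs / sd
    return float(2.0 * stats.norm.sf(abs(z)))


def smote(
    features, labels, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling: balance classes by interpolating
    between minority points and their k nearest minority neighbours.

    Each synthetic sample lies at a uniform random fraction along the segment
    from a randomly chosen minority point to one of its ``k`` nearest minority
    neighbours.  The majority class is untouched; originals are returned
    first, synthetic rows appended.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be 2-D with one row per label")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_new = int(n_maj - n_min)
    X_min = X[y == minority]
    if k >= n_min:
        warnings.warn(
            f"k={k} >= minority size {n_min}; reducing k to {n_min - 1}",
            stacklevel=2,
        )
        k = int(n_min - 1)
    if k < 1:
        raise ValueError("minority class must have at least 2 members")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    _, neigh = nn.kneighbors(X_min)  # col 0 is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)
    frac = rng.uniform(size=n_new)[:, None]
    a = X_min[base]
    b = X_min[neigh[base, pick]]
    X_new = a + frac * (b - a)
    return (
        np.vstack([X, X_new]),
        np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)]),
    )


def diagnostic_odds_ratio(tp: int, fp: int, fn: int, tn: int) -> float:
    """DOR = (TP*TN)/(FP*FN), with 0.5 added to every cell if any is zero."""
    cells = np.array([tp, fp, fn, tn], dtype=float)
    if np.any(cells == 0):
        cells = cells + 0.5
    tp, fp, fn, tn = cells
    return float((tp * tn) / (fp * fn))


@dataclass
class ClassifierEvaluation:
    """Aggregate of repeated split-train-test SVM runs."""

    kernel: str
    n_runs: int
    mean_auc: float
    mean_dor: float
    runs: pd.DataFrame = field(repr=False)


def repeated_svm_evaluation(
    features,
    labels,
    kernel: str = "linear",
    n_runs: int = 200,
    train_frac: float = 0.7,
    C: float = 1.0,
    seed: int = 0,
) -> ClassifierEvaluation:
    """Evaluate an SVM over repeated stratified 70/30 splits.

    Per run: stratified split, feature standardisation fitted on the training
    portion only, SVM fit (``C`` fixed, RBF bandwidth by the inverse
    feature-variance heuristic), test AUC from decision values, confusion
    counts at the default decision boundary, and the diagnostic odds ratio
    (zero cells corrected by adding 0.5 everywhere).  Aggregates are
    arithmetic means over runs.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31 - 1)
    records = []
    for i in range(n_runs):
        rs = int(child_seeds[i])
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=train_frac, stratify=y, random_state=rs
        )
        scaler = StandardScaler().fit(X_tr)
        clf = SVC(kernel=kernel, C=C, gamma="scale")
        clf.fit(scaler.transform(X_tr), y_tr)
        dec = clf.decision_function(scaler.transform(X_te))
        auc = roc_auc_score(y_te, dec)
        pred = (dec > 0).astype(int)
        tn, fp, fn, tp = confusion_matrix(y_te, pred, labels=[0, 1]).ravel()
        records.append(
            {
                "seed": rs,
                "auc": auc,
                "dor": diagnostic_odds_ratio(tp, fp, fn, tn),
                "tp": int(tp),
                "fp": int(fp),
                "fn": int(fn),
                "tn": int(tn),
            }
        )
    runs = pd.DataFrame(records)
    return ClassifierEvaluation(
        kernel=kernel,
        n_runs=n_runs,
        mean_auc=float(runs["auc"].mean()),
        mean_dor=float(runs["dor"].mean()),
        runs=runs,
    )


def dunnett_comparison(
    groups, reference_index: int = 0, seed: int | None = None
) -> np.ndarray:
    """Dunnett many-to-one comparison of group means against a reference.

    Returns family-wise adjusted two-sided p-values for each non-reference
    group, in input order.  Uses the pooled-variance many-to-one t statistics
    referred to the equicorrelated multivariate-t distribution.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least two observations")
    pooled = np.concatenate(groups)
    if np.allclose(pooled.var(), 0.0):
        raise ValueError("zero pooled variance")
    control = groups[reference_index]
    treatments = [g for i, g in enumerate(groups) if i != reference_index]
    rng = np.random.default_rng(seed) if seed is not None else None
    res = stats.dunnett(*treatments, control=control, random_state=rng)
    return np.asarray(res.pvalue, dtype=float)
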