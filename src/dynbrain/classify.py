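"""F-score feature ranking and leave-one-out SVM discrimination.

The per-feature F-score contrasts positive (MHE) and negative (noHE)
class means against pooled within-class sample variances:

    F(i) = [ (xbar_i^+ - xbar_i)^2 + (xbar_i^- - xbar_i)^2 ]
           / [ (1/(n+ - 1)) sum_k (x_ki^+ - xbar_i^+)^2
             + (1/(n- - 1)) sum_k (x_ki^- - xbar_i^-)^2 ]

Classification is leave-one-out cross-validated: for every held-out
subject, features are ranked by F-score *on the training fold only*, the
top k are z-scored with training-fold statistics and fed to an SVM (RBF
kernel by default, C = 1, kernel width 1/k).  Aggregated confusion counts
give accuracy / sensitivity / specificity; the decision scores give the
ROC curve and AUC; significance of the accuracy comes from rerunning the
whole procedure (including per-fold selection) under label permutations
with the add-one p estimator ``p = (1 + #{perm >= observed})/(n_perm + 1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

logger = logging.getLogger("dynbrain")

POSITIVE = 1  # MHE coded as the positive class


@dataclass(frozen=True)
class SvmConfig:
    kernel: str = "rbf"
    C: float = 1.0


@dataclass
class CvResult:
    """Leave-one-out outputs: per-fold predictions, summary rates (%), ROC."""

    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray                  # decision-function values per fold
    selected: list[tuple[int, ...]]     # 0-based selected feature indices per fold
    consensus_features: tuple[int, ...] # top-k by selection frequency
    accuracy: float
    sensitivity: float
    specificity: float
    roc_points: np.ndarray              # (n_thresholds, 2): FPR, TPR
    auc: float
    permutation_p: float | None = None
    perm_accuracies: np.ndarray | None = None


def f_score(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature F-score with (n - 1)-denominator sample variances.

    Equal class means give F = 0 even when both within-class variances are
    zero; unequal means over zero variance give F = inf (ranked first).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    pos, neg = X[y == POSITIVE], X[y != POSITIVE]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 samples per class")
    xbar = X.mean(axis=0)
    num = (pos.mean(axis=0) - xbar) ** 2 + (neg.mean(axis=0) - xbar) ** 2
    den = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    out = np.empty(X.shape[1])
    zero_den = den == 0
    if np.any(zero_den & (num > 0)):
        logger.warning("feature(s) %s have zero within-class variance and unequal means",
                       np.flatnonzero(zero_den & (num > 0)).tolist())
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(zero_den, np.where(num > 0, np.inf, 0.0), num / np.where(zero_den, 1.0, den))
    return out


def _rank_features(X: np.ndarray, y: np.ndarray, k: int) -> tuple[int, ...]:
    scores = f_score(X, y)
    # stable sort: ties broken by lower feature index
    order = np.argsort(-scores, kind="stable")
    return tuple(int(i) for i in order[:k])


def roc_auc(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points from a threshold sweep over the scores and trapezoid AUC.

    The trapezoid AUC equals the Mann-Whitney pair-counting statistic
    ``U / (n+ n-)`` (ties counted half).
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for ROC analysis")
    fpr, tpr, _ = roc_curve(y, scores, pos_label=POSITIVE)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def loocv_classify(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    svm: SvmConfig = SvmConfig(),
) -> CvResult:
    """Leave-one-out SVM with per-fold F-score feature selection.

    ``y`` codes MHE as 1 (positive) and noHE as 0.  Feature selection and
    z-scoring are fitted strictly inside each training fold; the kernel
    width is ``1 / k`` (scikit-learn's ``gamma='auto'`` convention on the
    selected feature count).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n, p = X.shape
    if not 1 <= k <= p:
        raise ValueError(f"k must be in 1..{p}")
    if min((y == POSITIVE).sum(), (y != POSITIVE).sum()) < 3:
        raise ValueError("need at least 3 subjects per class")
    preds = np.empty(n, dtype=int)
    scores = np.empty(n)
    selected: list[tuple[int, ...]] = []
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        feats = _rank_features(X[train], y[train], k)
        Xtr = X[np.ix_(train, feats)]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        clf = SVC(kernel=svm.kernel, C=svm.C, gamma="auto")
        clf.fit((Xtr - mu) / sd, y[train])
        xte = (X[i, list(feats)] - mu) / sd
        preds[i] = int(clf.predict(xte[None, :])[0])
        scores[i] = float(clf.decision_function(xte[None, :])[0])
        selected.append(feats)
    tp = int(((preds == POSITIVE) & (y == POSITIVE)).sum())
    tn = int(((preds != POSITIVE) & (y != POSITIVE)).sum())
    fp = int(((preds == POSITIVE) & (y != POSITIVE)).sum())
    fn = int(((preds != POSITIVE) & (y == POSITIVE)).sum())
    counts = np.bincount(np.concatenate([np.array(f) for f in selected]), minlength=p)
    consensus = tuple(int(i) for i in np.argsort(-counts, kind="stable")[:k])
    roc_points, auc = roc_auc(scores, y)
    return CvResult(
        y_true=y,
        y_pred=preds,
        scores=scores,
        selected=selected,
        consensus_features=consensus,
        accuracy=100.0 * (tp + tn) / n,
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        roc_points=roc_points,
        auc=auc,
    )


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    n_perm: int = 1000,
    seed: int = 0,
    svm: SvmConfig = SvmConfig(),
) -> tuple[float, np.ndarray]:
    """Permutation significance of the LOOCV accuracy (add-one estimator).

    Labels are shuffled ``n_perm`` times (seeded) and the *full* procedure —
    per-fold feature selection included — is rerun each time.  Returns
    ``(p, permuted accuracies)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    observed = loocv_classify(X, y, k, svm=svm).accuracy
    rng = np.random.default_rng(seed)
    perm_acc = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(y)
        perm_acc[b] = loocv_classify(X, y_perm, k, svm=svm).accuracy
    p = (1.0 + float((perm_acc >= observed).sum())) / (n_perm + 1.0)
    return p, perm_acc


def select_k(
    X: np.ndarray,
    y: np.ndarray,
    k_grid: tuple[int, ...] | list[int],
    svm: SvmConfig = SvmConfig(),
) -> int:
    """Pick k by the mean LOOCV accuracy over a grid (lowest k wins ties)."""
    best_k, best_acc = None, -1.0
    for k in k_grid:
        acc = loocv_classify(X, y, k, svm=svm).accuracy
        if acc > best_acc:
            best_k, best_acc = k, acc
    return int(best_k)
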