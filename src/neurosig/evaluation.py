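"""Classification metrics, model comparison, and learning curves.

Multiclass AUC follows the pairwise-conditional construction of Hand & Till:
for classes i < j,

    A(i, j) = [A(i | j) + A(j | i)] / 2

where ``A(i | j)`` is the rank-based (Mann-Whitney, midrank ties) probability
that a class-i sample receives a higher class-i probability than a class-j
sample, computed from class i's own probability column.  The overall measure
averages ``A(i, j)`` over all class pairs:  M = 2 / (c (c - 1)) * sum_{i<j}.
For two classes this reduces exactly to the usual ROC AUC.

Classifier comparison uses McNemar's test on the discordant correct/incorrect
pairs, with an exact two-sided binomial p-value (discordant counts on a
40-subject holdout are small enough that the chi-square approximation is
unreliable); a continuity-corrected chi-square variant is also available.

The learning curve follows the protocol of repeated subsampling at six
training sizes: at each size, subjects are drawn without replacement for
fitting and the remaining subjects' maps form the evaluation set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .classifiers import fit_lasso_pcr, fit_lda, predict
from .data_model import CLASS_LABELS, CLASS_TO_INDEX, BetaMapSet, LabelError

N_CLASSES = len(CLASS_LABELS)

#: Marker for metrics whose denominator is empty (e.g. a class with no truth
#: maps): explicit, instead of a silent NaN.
UNDEFINED = "undefined"

#: Training sizes of the learning-curve protocol.
DEFAULT_SIZES = (5, 14, 28, 41, 55, 69)
DEFAULT_REPEATS = 20


def _as_indices(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        try:
            arr = np.array([CLASS_TO_INDEX[str(v)] for v in arr])
        except KeyError as e:
            raise LabelError(f"unknown class label {e.args[0]!r}") from e
    arr = arr.astype(int)
    if arr.size and (arr.min() < 0 or arr.max() >= N_CLASSES):
        raise LabelError("integer labels must be in {0, 1, 2}")
    return arr


def confusion(true_labels, predicted_labels) -> np.ndarray:
    """3x3 confusion counts; rows = true class, columns = predicted class,
    ordered (neutral, negative, decrease)."""
    yt = _as_indices(true_labels)
    yp = _as_indices(predicted_labels)
    if yt.shape != yp.shape:
        raise ValueError("true and predicted label vectors differ in length")
    return _sk_confusion(yt, yp, labels=list(range(N_CLASSES)))


def auc_hand_till(probabilities: np.ndarray, true_labels) -> float:
    """Hand-Till multiclass AUC M from per-class probability columns.

    Pairs involving an absent class are skipped with a warning; if no pair
    can be formed an error is raised.
    """
    y = _as_indices(true_labels)
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 2 or p.shape[0] != len(y):
        raise ValueError("probabilities must be (n_samples, n_classes)")
    pair_aucs = []
    for i in range(N_CLASSES):
        for j in range(i + 1, N_CLASSES):
            ni = int((y == i).sum())
            nj = int((y == j).sum())
            if ni == 0 or nj == 0:
                warnings.warn(
                    f"class pair ({CLASS_LABELS[i]}, {CLASS_LABELS[j]}) "
                    "skipped: a class is absent",
                    stacklevel=2,
                )
                continue
            a_ij = _conditional_auc(p[:, i], y, i, j)
            a_ji = _conditional_auc(p[:, j], y, j, i)
            pair_aucs.append(0.5 * (a_ij + a_ji))
    if not pair_aucs:
        raise ValueError("no class pair present; AUC undefined")
    return float(np.mean(pair_aucs))


def _conditional_auc(col: np.ndarray, y: np.ndarray, pos: int, neg: int) -> float:
    """A(pos | neg): P(score of a pos sample > score of a neg sample) with
    midrank tie handling, using the pos class's probability column."""
    sel = (y == pos) | (y == neg)
    scores = col[sel]
    is_pos = y[sel] == pos
    n_pos = int(is_pos.sum())
    n_neg = int((~is_pos).sum())
    ranks = rankdata(scores)  # midranks
    s_pos = ranks[is_pos].sum()
    return (s_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


@dataclass
class MetricsReport:
    """Holdout-style metrics: overall accuracy and Hand-Till AUC plus
    per-class sensitivity / specificity / one-vs-rest AUC."""

    confusion: np.ndarray
    accuracy: float
    auc_multiclass: float | str
    sensitivity: dict[str, float | str] = field(default_factory=dict)
    specificity: dict[str, float | str] = field(default_factory=dict)
    auc_ovr: dict[str, float | str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": c,
                "sensitivity": self.sensitivity[c],
                "specificity": self.specificity[c],
                "auc_ovr": self.auc_ovr.get(c, UNDEFINED),
            }
            for c in CLASS_LABELS
        ]
        rows.append(
            {
                "class": "overall",
                "sensitivity": self.accuracy,
                "specificity": "",
                "auc_ovr": self.auc_multiclass,
            }
        )
        return pd.DataFrame(rows)


def metrics(
    conf: np.ndarray,
    probabilities: np.ndarray | None = None,
    true_labels=None,
) -> MetricsReport:
    """Compute the metrics table from a confusion matrix and, if provided,
    per-map probabilities (needed for the AUC entries).

    Degenerate denominators (a class with zero truth maps) yield the
    explicit ``"undefined"`` marker plus a warning, never a NaN.
    """
    conf = np.asarray(conf)
    if conf.shape != (N_CLASSES, N_CLASSES):
        raise ValueError("confusion matrix must be 3x3")
    total = conf.sum()
    accuracy = float(np.trace(conf) / total) if total else 0.0
    sens: dict[str, float | str] = {}
    spec: dict[str, float | str] = {}
    for k, c in enumerate(CLASS_LABELS):
        row = conf[k].sum()
        if row == 0:
            warnings.warn(f"class {c!r} has no truth maps; sensitivity undefined",
                          stacklevel=2)
            sens[c] = UNDEFINED
        else:
            sens[c] = float(conf[k, k] / row)
        negatives = total - row
        if negatives == 0:
            spec[c] = UNDEFINED
        else:
            tn = total - row - conf[:, k].sum() + conf[k, k]
            spec[c] = float(tn / negatives)

    auc_m: float | str = UNDEFINED
    auc_ovr: dict[str, float | str] = {c: UNDEFINED for c in CLASS_LABELS}
    if probabilities is not None and true_labels is not None:
        y = _as_indices(true_labels)
        p = np.asarray(probabilities, dtype=float)
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")
        auc_m = auc_hand_till(p, y)
        for k, c in enumerate(CLASS_LABELS):
            if 0 < (y == k).sum() < len(y):
                auc_ovr[c] = float(roc_auc_score((y == k).astype(int), p[:, k]))
            else:
                warnings.warn(f"one-vs-rest AUC undefined for class {c!r}",
                              stacklevel=2)
    return MetricsReport(
        confusion=conf,
        accuracy=accuracy,
        auc_multiclass=auc_m,
        sensitivity=sens,
        specificity=spec,
        auc_ovr=auc_ovr,
    )


def evaluate(model, data: BetaMapSet) -> MetricsReport:
    """Predict on ``data`` and assemble the full metrics report."""
    pred = predict(model, data)
    conf = confusion(data.labels(), pred.labels)
    return metrics(conf, pred.probabilities, data.labels())


def mcnemar(
    correct_a, correct_b, exact: bool = True
) -> tuple[float, float]:
    """McNemar's test on paired correctness indicators.

    Returns ``(statistic, p)``.  With ``exact=True`` the statistic is the
    smaller discordant count and p is the exact two-sided binomial tail
    probability; otherwise the continuity-corrected chi-square is used.
    Zero discordant pairs give p = 1 by convention (with a warning).
    """
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("correctness vectors must have equal length")
    n01 = int((~a & b).sum())  # A wrong, B right
    n10 = int((a & ~b).sum())  # A right, B wrong
    if n01 + n10 == 0:
        warnings.warn("no discordant pairs; p = 1 by convention", stacklevel=2)
        return 0.0, 1.0
    table = [[int((a & b).sum()), n10], [n01, int((~a & ~b).sum())]]
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class LearningCurveResult:
    """Per (size, repeat, family) accuracy and Hand-Till AUC."""

    records: pd.DataFrame  # columns: size, repeat, family, accuracy, auc

    def summary(self) -> pd.DataFrame:
        return (
            self.records.groupby(["family", "size"], as_index=False)[
                ["accuracy", "auc"]
            ]
            .mean()
            .sort_values(["family", "size"], ignore_index=True)
        )


def learning_curve(
    train: BetaMapSet,
    sizes=DEFAULT_SIZES,
    repeats: int = DEFAULT_REPEATS,
    families: tuple[str, ...] = ("pcr", "lda"),
    seed: int = 0,
    variance_threshold: float = 0.90,
    n_folds: int = 5,
    n_lambda: int = 40,
) -> LearningCurveResult:
    """Repeated-subsampling learning curve over training sizes.

    For each size and repeat, that many subjects are drawn without
    replacement for fitting; all remaining subjects' maps form the
    evaluation set.  Fixed seed gives identical draws and results.
    """
    subjects = np.array(train.subjects)
    sizes = [int(s) for s in sizes]
    if min(sizes) < 2:
        raise ValueError("training sizes must be >= 2")
    if max(sizes) >= len(subjects):
        raise ValueError(
            f"largest size {max(sizes)} must be < n_subjects {len(subjects)}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        for rep in range(repeats):
            chosen = rng.choice(len(subjects), size=size, replace=False)
            fit_set = train.select_subjects(subjects[chosen])
            eval_set = train.select_subjects(
                np.delete(subjects, chosen)
            )
            for family in families:
                if family == "pcr":
                    model = fit_lasso_pcr(
                        fit_set,
                        variance_threshold=variance_threshold,
                        n_folds=min(n_folds, size),
                        seed=int(rng.integers(2**31 - 1)),
                        n_lambda=n_lambda,
                    )
                elif family == "lda":
                    model = fit_lda(fit_set)
                else:
                    raise ValueError(f"unknown family {family!r}")
                pred = predict(model, eval_set)
                conf = confusion(eval_set.labels(), pred.labels)
                rows.append(
                    {
                        "size": size,
                        "repeat": rep,
                        "family": family,
                        "accuracy": float(np.trace(conf) / conf.sum()),
                        "auc": auc_hand_till(
                            pred.probabilities, eval_set.labels()
                        ),
                    }
                )
    return LearningCurveResult(records=pd.DataFrame(rows))
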