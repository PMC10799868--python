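"""Signature classifiers: LASSO principal-components regression and
two-component linear discriminant analysis.

Both models reduce the voxel dimension with loadings learned on training
data only, then classify the three task conditions with multinomial logistic
regression on the reduced scores:

* **LASSO-PCR** — PCA of the centered training maps (maps as rows, no voxel
  scaling); the smallest number of components reaching a cumulative
  explained-variance threshold (default 0.90) is retained.  Component scores
  feed an L1-penalized multinomial logistic regression; the penalty
  ``lambda`` is chosen to minimize multinomial deviance in grouped,
  class-stratified cross-validation (a subject's three maps never split
  across folds), then the model is refitted on all training data at the
  selected ``lambda``.
* **LDA** — two linear discriminant directions (three classes admit at most
  two), solved by SVD-based whitening so the within-class scatter need not be
  invertible in the voxels >> maps regime, followed by an *unpenalized*
  multinomial logistic regression on the two discriminant scores.

At test time, training loadings are projected onto new data; no model field
is ever updated by prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression

from .data_model import CLASS_LABELS, BetaMapSet, DimensionError

N_CLASSES = len(CLASS_LABELS)

#: glmnet-style path: n_lambda log-spaced values from lambda_max down by 1e-4.
DEFAULT_N_LAMBDA = 100
DEFAULT_LAMBDA_MIN_RATIO = 1e-4


class StratificationError(ValueError):
    """A cross-validation fold is missing one of the three classes."""


class NotFittedError(RuntimeError):
    pass


@dataclass
class Prediction:
    """Per-map class probabilities and argmax labels."""

    probabilities: np.ndarray  # (n_maps, 3), rows sum to 1
    labels: np.ndarray         # (n_maps,) integer class indices

    @property
    def label_names(self) -> list[str]:
        return [CLASS_LABELS[i] for i in self.labels]


@dataclass
class PcrModel:
    """Fitted LASSO-PCR: PCA loadings + penalized multinomial coefficients."""

    train_mean: np.ndarray        # (n_voxels,)
    V_pca: np.ndarray             # (n_voxels, m), orthonormal columns
    m: int
    variance_threshold: float
    explained_variance: np.ndarray  # full EVR spectrum of the training PCA
    B_coef: np.ndarray            # (m, 3) coefficients on the score scale
    intercepts: np.ndarray        # (3,)
    lambda_: float
    lambda_path: np.ndarray = field(default_factory=lambda: np.empty(0))
    cv_deviance: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_nonzero(self) -> int:
        return int((np.abs(self.B_coef) > 0).any(axis=1).sum())


@dataclass
class LdaModel:
    """Fitted LDA: 2 discriminant loadings + unpenalized multinomial fit."""

    train_mean: np.ndarray     # (n_voxels,)
    V_lda: np.ndarray          # (n_voxels, 2)
    class_means: np.ndarray    # (3, n_voxels) per-class training means
    priors: np.ndarray         # (3,)
    B_coef: np.ndarray         # (2, 3)
    intercepts: np.ndarray     # (3,)


def fit_pca(
    train: BetaMapSet | np.ndarray, variance_threshold: float = 0.90
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Centered PCA of training maps (rows = maps).

    Returns ``(train_mean, V_full, explained_variance_ratio, m)`` where
    ``V_full`` holds all principal axes as columns and ``m`` is the smallest
    component count whose cumulative explained-variance ratio reaches
    ``variance_threshold`` (at threshold 1.0, the rank of the centered data).
    """
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError(
            f"variance_threshold must be in (0, 1], got {variance_threshold}"
        )
    x = train.values_matrix() if isinstance(train, BetaMapSet) else np.asarray(train)
    if x.shape[0] < 2:
        raise ValueError("PCA requires at least 2 maps")
    mean = x.mean(axis=0)
    xc = x - mean
    _, svals, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int((svals > svals[0] * 1e-10).sum()) if svals.size else 0
    total = (svals**2).sum()
    evr = svals**2 / total if total > 0 else np.zeros_like(svals)
    cum = np.cumsum(evr)
    m = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    m = max(1, min(m, rank))
    return mean, vt.T, evr, m


def _lambda_max(x: np.ndarray, y: np.ndarray) -> float:
    """Smallest L1 penalty zeroing all multinomial slopes (glmnet rule):
    max_{j,k} |x_j' (1[y=k] - pbar_k)| / n on standardized predictors."""
    n = x.shape[0]
    indicators = np.stack([(y == k).astype(float) for k in range(N_CLASSES)], axis=1)
    resid = indicators - indicators.mean(axis=0)
    return float(np.abs(x.T @ resid).max() / n)


def _lasso_multinomial(
    x: np.ndarray,
    y: np.ndarray,
    lambda_: float,
    warm: LogisticRegression | None = None,
    max_iter: int = 3000,
    tol: float = 1e-5,
    quiet: bool = False,
) -> LogisticRegression:
    """L1 multinomial logistic fit at penalty ``lambda_`` (glmnet scale:
    mean NLL + lambda * ||B||_1).

    ``quiet`` suppresses convergence warnings — used along the CV penalty
    path, where the near-unpenalized tail need not be iterated to full
    precision for deviance-based selection.
    """
    n = x.shape[0]
    c = 1.0 / max(n * lambda_, 1e-12)
    if warm is not None:
        warm.set_params(C=c)
        clf = warm
    else:
        clf = LogisticRegression(
            l1_ratio=1.0,  # pure L1 penalty
            C=c,
            solver="saga",
            max_iter=max_iter,
            tol=tol,
            warm_start=True,
            random_state=0,
        )
    with warnings.catch_warnings():
        if quiet:
            warnings.simplefilter("ignore", ConvergenceWarning)
        return clf.fit(x, y)


def _deviance(probs: np.ndarray, y: np.ndarray) -> float:
    """Total multinomial deviance: -2 sum log p(true class)."""
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
    return float(-2.0 * np.log(p).sum())


def make_subject_folds(
    subject_ids: np.ndarray,
    labels: np.ndarray,
    n_folds: int,
    seed: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Subject-grouped CV folds: subjects are shuffled and split into
    ``n_folds`` nearly equal groups; a subject's maps stay together.  Raises
    :class:`StratificationError` if any fold's training side misses a class.
    """
    subjects = list(dict.fromkeys(subject_ids))
    if n_folds < 2 or n_folds > len(subjects):
        raise ValueError(
            f"n_folds={n_folds} invalid for {len(subjects)} subjects"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    assignments = np.empty(len(subjects), dtype=int)
    for fold, pos in enumerate(np.array_split(order, n_folds)):
        assignments[pos] = fold
    subj_fold = {s: assignments[i] for i, s in enumerate(subjects)}
    map_fold = np.array([subj_fold[s] for s in subject_ids])
    folds = []
    for f in range(n_folds):
        val = np.nonzero(map_fold == f)[0]
        tr = np.nonzero(map_fold != f)[0]
        if len(set(labels[tr])) < N_CLASSES:
            raise StratificationError(
                f"fold {f}: training side is missing a class"
            )
        folds.append((tr, val))
    return folds


def fit_lasso_pcr(
    train: BetaMapSet,
    variance_threshold: float = 0.90,
    n_folds: int = 10,
    seed: int = 0,
    lambda_: float | None = None,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
) -> PcrModel:
    """Fit the LASSO-PCR model.

    If ``lambda_`` is given the cross-validation search is skipped and the
    model is fitted directly at that penalty (used for bootstrap refits at
    the full-data penalty).  Scores are internally standardized for the
    penalized fit (glmnet convention); returned coefficients are on the raw
    score scale so that voxel weights are ``V_pca @ B_coef``.
    """
    x_full = train.values_matrix()
    y = train.labels()
    if len(set(y)) < N_CLASSES:
        raise StratificationError("training data must contain all 3 classes")
    mean, v_full, evr, m = fit_pca(x_full, variance_threshold)
    v = v_full[:, :m]
    scores = (x_full - mean) @ v

    score_mean = scores.mean(axis=0)
    score_sd = scores.std(axis=0, ddof=0)
    score_sd = np.where(score_sd <= 1e-12, 1.0, score_sd)
    z = (scores - score_mean) / score_sd

    lambda_path = np.empty(0)
    cv_dev = np.empty(0)
    if lambda_ is None:
        lmax = _lambda_max(z, y)
        lambda_path = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)
        folds = make_subject_folds(train.subject_ids(), y, n_folds, seed)
        dev_total = np.zeros(n_lambda)
        for tr_idx, val_idx in folds:
            z_tr = z[tr_idx]
            mu_tr = z_tr.mean(axis=0)
            sd_tr = z_tr.std(axis=0, ddof=0)
            sd_tr = np.where(sd_tr <= 1e-12, 1.0, sd_tr)
            zz_tr = (z_tr - mu_tr) / sd_tr
            zz_val = (z[val_idx] - mu_tr) / sd_tr
            clf: LogisticRegression | None = None
            for i, lam in enumerate(lambda_path):
                clf = _lasso_multinomial(zz_tr, y[tr_idx], lam, warm=clf,
                                         max_iter=800, tol=1e-4, quiet=True)
                dev_total[i] += _deviance(clf.predict_proba(zz_val), y[val_idx])
        cv_dev = dev_total / len(y)
        lambda_ = float(lambda_path[int(np.argmin(cv_dev))])

    clf = _lasso_multinomial(z, y, lambda_, max_iter=5000)
    # back to raw score scale: beta_raw = beta_std / sd
    b_std = clf.coef_  # (3, m)
    b_raw = (b_std / score_sd).T  # (m, 3)
    if np.all(b_std == 0.0):
        # null model: the intercept MLE is exactly the log class frequencies
        freqs = np.bincount(y, minlength=N_CLASSES) / len(y)
        logf = np.log(np.clip(freqs, 1e-12, None))
        intercepts = logf - logf.mean()
    else:
        intercepts = clf.intercept_ - b_std @ (score_mean / score_sd)
    return PcrModel(
        train_mean=mean,
        V_pca=v,
        m=m,
        variance_threshold=variance_threshold,
        explained_variance=evr,
        B_coef=b_raw,
        intercepts=np.asarray(intercepts),
        lambda_=float(lambda_),
        lambda_path=lambda_path,
        cv_deviance=cv_dev,
    )


def fit_lda(train: BetaMapSet) -> LdaModel:
    """Fit two-component LDA plus an unpenalized multinomial logistic
    regression on the two discriminant scores."""
    x = train.values_matrix()
    y = train.labels()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < N_CLASSES:
        raise StratificationError("training data must contain all 3 classes")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 maps for LDA")
    lda = LinearDiscriminantAnalysis(solver="svd", n_components=2)
    lda.fit(x, y)
    v = np.asarray(lda.scalings_)[:, :2]
    mean = np.asarray(lda.xbar_)
    scores = (x - mean) @ v
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    clf.fit(scores, y)
    return LdaModel(
        train_mean=mean,
        V_lda=v,
        class_means=np.asarray(lda.means_),
        priors=np.asarray(lda.priors_),
        B_coef=clf.coef_.T,  # (2, 3)
        intercepts=clf.intercept_.copy(),
    )


def _loadings(model: PcrModel | LdaModel) -> np.ndarray:
    return model.V_pca if isinstance(model, PcrModel) else model.V_lda


def project(model: PcrModel | LdaModel, data: BetaMapSet | np.ndarray) -> np.ndarray:
    """Project data onto the model's training loadings:
    ``scores = (values - train_mean) @ V``.  Never refits."""
    x = data.values_matrix() if isinstance(data, BetaMapSet) else np.atleast_2d(data)
    v = _loadings(model)
    if x.shape[1] != v.shape[0]:
        raise DimensionError(
            f"data has {x.shape[1]} voxels, model expects {v.shape[0]}"
        )
    return (x - model.train_mean) @ v


def predict(model: PcrModel | LdaModel, data: BetaMapSet | np.ndarray) -> Prediction:
    """Softmax class probabilities and argmax labels (ties break to the
    lowest class index)."""
    if model.B_coef is None:  # pragma: no cover - defensive
        raise NotFittedError("model has no fitted coefficients")
    scores = project(model, data)
    logits = scores @ model.B_coef + model.intercepts
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    probs = expl / expl.sum(axis=1, keepdims=True)
    return Prediction(probabilities=probs, labels=np.argmax(probs, axis=1))


def voxel_weights(model: PcrModel | LdaModel) -> np.ndarray:
    """Per-class voxel contribution weights ``W_k = V @ beta_k``, shape
    (n_voxels, 3).  For LASSO-PCR, components zeroed by the penalty
    contribute nothing, so using the full loading matrix is identical to
    restricting to the nonzero-coefficient columns."""
    return _loadings(model) @ model.B_coef
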