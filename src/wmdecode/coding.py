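"""Coding dimensions: regularized linear-discriminant decoding of task and cue
identity from delay activity, with leave-one-out cross-validation, embedding
dimensionality sweeps, single-trial persistence, and outcome prediction.

The coding dimension between conditions a and b is

    w = (Sigma + gamma I)^{-1} (mu_a - mu_b)

where Sigma is the covariance of the trials x cells activity matrix pooled
over all training trials and gamma is a small ridge term stabilizing the
inversion.  A trial is classified by the nearest projected training-class
mean, i.e. by thresholding the projection at the midpoint of the projected
class means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .activity import TrialAlignedTensor


class InsufficientDataError(ValueError):
    pass


class CodingDimensionClassifier(ClassifierMixin, BaseEstimator):
    """Regularized-LDA coding dimension as a scikit-learn binary classifier.

    Parameters
    ----------
    gamma : float, default 1e-4
        Ridge regularizer added to the diagonal of the covariance.
    positive_class : object, optional
        The class mapped to positive projections.  By default the
        lexicographically larger label is positive, which puts the WM task and
        cue B on the positive side under the package's label conventions.

    Attributes
    ----------
    weights_ : (n_features,) ndarray
        The coding dimension (unnormalized discriminant vector).
    class_means_projected_ : dict
        Projection of each training-class mean onto ``weights_``.
    threshold_ : float
        Midpoint of the projected class means; the decision boundary.
    covariance_rank_ : int
        Rank of the training covariance before regularization.
    """

    def __init__(self, gamma: float = 1e-4, positive_class=None):
        self.gamma = gamma
        self.positive_class = positive_class

    def fit(self, X, y):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be trials x cells matching y")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"need exactly two classes, got {list(classes)}")
        for c in classes:
            if (y == c).sum() < 2:
                raise ValueError(f"class {c!r} has fewer than 2 trials")
        pos = self.positive_class if self.positive_class is not None else classes[-1]
        if pos not in classes:
            raise ValueError("positive_class not present in y")
        neg = classes[classes != pos][0]
        self.classes_ = np.array([neg, pos])
        mu_pos = X[y == pos].mean(axis=0)
        mu_neg = X[y == neg].mean(axis=0)
        cov = np.cov(X, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        self.covariance_rank_ = int(np.linalg.matrix_rank(cov))
        w = linalg.solve(
            cov + self.gamma * np.eye(X.shape[1]), mu_pos - mu_neg,
            assume_a="pos",
        )
        self.weights_ = w
        self.coef_ = w[None, :]
        proj_pos, proj_neg = float(mu_pos @ w), float(mu_neg @ w)
        self.class_means_projected_ = {pos: proj_pos, neg: proj_neg}
        self.threshold_ = 0.5 * (proj_pos + proj_neg)
        self.n_features_in_ = X.shape[1]
        return self

    def project(self, X) -> np.ndarray:
        """Raw projection of trials onto the coding dimension."""
        check_is_fitted(self, "weights_")
        return np.asarray(X, dtype=float) @ self.weights_

    def decision_function(self, X) -> np.ndarray:
        return self.project(X) - self.threshold_

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def fit_cd(X, y, gamma: float = 1e-4) -> CodingDimensionClassifier:
    """Fit a coding dimension; thin wrapper over CodingDimensionClassifier."""
    return CodingDimensionClassifier(gamma=gamma).fit(X, y)


@dataclass
class DecodingResult:
    scores: np.ndarray              # z-scored held-out projections
    predicted: np.ndarray
    truth: np.ndarray
    correct: np.ndarray
    accuracy: float
    train_accuracy: float
    mode: str = "loo_test"
    skipped: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    extra_scores: dict = field(default_factory=dict)


def loo_decode(
    X: np.ndarray,
    y: np.ndarray,
    gamma: float = 1e-4,
    extra: dict[str, np.ndarray] | None = None,
    positive_class=None,
) -> DecodingResult:
    """Leave-one-out decoding with per-trial held-out projections.

    Each trial is predicted from the coding dimension fit on the remaining
    trials; projections are z-scored with the training fold's projection
    statistics so no information leaks from the held-out trial.  ``extra``
    maps names to additional trials x cells feature matrices (e.g. early- and
    late-delay averages) projected through the same per-fold models.

    The per-fold covariance and class means are obtained by rank-one downdates
    of the full-sample statistics, so the whole sweep costs one covariance
    plus one small solve per trial; ``loo_decode_naive`` refits from scratch
    and is retained as the reference implementation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    full = CodingDimensionClassifier(gamma=gamma, positive_class=positive_class)
    full.fit(X, y)
    neg, pos = full.classes_
    scores = np.full(n, np.nan)
    pred = np.empty(n, dtype=y.dtype)
    skipped = np.zeros(n, dtype=bool)
    extra = extra or {}
    extra_scores = {k: np.full(n, np.nan) for k in extra}

    mu = X.mean(axis=0)
    Xc = X - mu
    S = Xc.T @ Xc                      # full scatter matrix
    sums = {c: X[y == c].sum(axis=0) for c in (neg, pos)}
    counts = {c: int((y == c).sum()) for c in (neg, pos)}
    I = np.eye(p)
    for i in range(n):
        ci = y[i]
        if counts[ci] - 1 < 2:
            # the downdated training set would leave a class with <2 trials
            skipped[i] = True
            pred[i] = full.predict(X[i : i + 1])[0]
            continue
        d = X[i] - mu
        S_tr = S - (n / (n - 1.0)) * np.outer(d, d)
        cov_tr = S_tr / (n - 2.0)
        m = {c: sums[c].copy() for c in (neg, pos)}
        cnt = dict(counts)
        m[ci] = m[ci] - X[i]
        cnt[ci] -= 1
        mu_pos, mu_neg = m[pos] / cnt[pos], m[neg] / cnt[neg]
        w = linalg.solve(cov_tr + gamma * I, mu_pos - mu_neg, assume_a="pos")
        thr = 0.5 * (mu_pos @ w + mu_neg @ w)
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        tr_proj = X[mask] @ w
        pm, psd = tr_proj.mean(), tr_proj.std()
        psd = psd if psd > 0 else 1.0
        scores[i] = (X[i] @ w - pm) / psd
        pred[i] = pos if X[i] @ w > thr else neg
        for k, Xe in extra.items():
            extra_scores[k][i] = (Xe[i] @ w - pm) / psd
    ok = ~skipped
    correct = pred == y
    return DecodingResult(
        scores=scores,
        predicted=pred,
        truth=y,
        correct=correct,
        accuracy=float(correct[ok].mean()) if ok.any() else np.nan,
        train_accuracy=float((full.predict(X) == y).mean()),
        skipped=skipped,
        extra_scores=extra_scores,
    )


def loo_decode_naive(
    X: np.ndarray,
    y: np.ndarray,
    gamma: float = 1e-4,
    positive_class=None,
) -> DecodingResult:
    """Reference leave-one-out decoder that refits every fold from scratch."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    scores = np.full(n, np.nan)
    pred = np.empty(n, dtype=y.dtype)
    skipped = np.zeros(n, dtype=bool)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        ytr = y[mask]
        vals, cnts = np.unique(ytr, return_counts=True)
        if len(vals) < 2 or cnts.min() < 2:
            skipped[i] = True
            clf = CodingDimensionClassifier(gamma=gamma, positive_class=positive_class)
            pred[i] = clf.fit(X, y).predict(X[i : i + 1])[0]
            continue
        clf = CodingDimensionClassifier(gamma=gamma, positive_class=positive_class)
        clf.fit(X[mask], ytr)
        tr_proj = clf.project(X[mask])
        m, sd = tr_proj.mean(), tr_proj.std()
        sd = sd if sd > 0 else 1.0
        scores[i] = (clf.project(X[i : i + 1])[0] - m) / sd
        pred[i] = clf.predict(X[i : i + 1])[0]
    ok = ~skipped
    correct = pred == y
    full = CodingDimensionClassifier(gamma=gamma, positive_class=positive_class)
    full.fit(X, y)
    return DecodingResult(
        scores=scores, predicted=pred, truth=y, correct=correct,
        accuracy=float(correct[ok].mean()) if ok.any() else np.nan,
        train_accuracy=float((full.predict(X) == y).mean()),
        skipped=skipped,
    )


def delay_feature(
    tensor: TrialAlignedTensor, k: int = 5, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell mean over k randomly sampled delay frames per trial.

    Equalizes the information available across delay durations (at 4.68 Hz,
    k=5 frames span 1,068 ms of data).  Trials with fewer than k delay frames
    are excluded (mask False).  Sampling is without replacement, so the
    feature is an unbiased estimate of the full-delay mean.
    """
    rng = rng if rng is not None else np.random.default_rng()
    n_units = tensor.windows[0].shape[0] if len(tensor) else 0
    out = np.full((len(tensor), n_units), np.nan)
    ok = np.zeros(len(tensor), dtype=bool)
    for i, w in enumerate(tensor.windows):
        if w.shape[1] >= k:
            sel = rng.choice(w.shape[1], size=k, replace=False)
            out[i] = w[:, sel].mean(axis=1)
            ok[i] = True
    return out, ok


def sweep_cells(
    X: np.ndarray,
    y: np.ndarray,
    ns: list[int],
    repeats: int = 50,
    gamma: float = 1e-4,
    rng: np.random.Generator | None = None,
) -> dict:
    """Decoding accuracy and variance fraction versus number of sampled cells."""
    rng = rng if rng is not None else np.random.default_rng()
    total_var = np.var(X, axis=0, ddof=1).sum()
    acc = np.zeros((len(ns), repeats))
    varfrac = np.zeros((len(ns), repeats))
    n_cells = X.shape[1]
    for j, n in enumerate(ns):
        if n > n_cells:
            raise ValueError("cannot sample more cells than available")
        for r in range(repeats):
            cols = rng.choice(n_cells, size=n, replace=False) if n < n_cells \
                else np.arange(n_cells)
            acc[j, r] = loo_decode(X[:, cols], y, gamma=gamma).accuracy
            varfrac[j, r] = np.var(X[:, cols], axis=0, ddof=1).sum() / total_var
    return dict(
        ns=np.array(ns), accuracy=acc.mean(axis=1), accuracy_sd=acc.std(axis=1),
        variance_fraction=varfrac.mean(axis=1),
    )


def sweep_pcs(
    frames: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    ks: list[int],
    mode: str = "top",
    gamma: float = 1e-4,
) -> dict:
    """Decoding accuracy versus number of PCs kept or excluded.

    PCs are computed from single-trial frames concatenated in time
    (``frames``: n_frames x cells, excluded trials already removed).  With
    ``mode='top'`` decoding is restricted to PCs 1..k; with ``mode='exclude'``
    PCs 1..k are projected out and decoding uses the remainder.  k = 0 in
    either mode is identical to full decoding.
    """
    if mode not in ("top", "exclude"):
        raise ValueError("mode must be 'top' or 'exclude'")
    pca = PCA()
    pca.fit(frames)
    V = pca.components_
    evr = pca.explained_variance_ratio_
    rank = V.shape[0]
    Xc = X - frames.mean(axis=0)
    accs, varfracs = [], []
    for k in ks:
        if k == 0:
            Xk = Xc
            vf = 1.0
        elif mode == "top":
            Xk = Xc @ V[: min(k, rank)].T
            vf = float(evr[: min(k, rank)].sum())
        else:
            if k >= rank:
                warnings.warn("excluding every PC leaves no signal; chance expected")
                Xk = Xc - Xc @ V.T @ V
                vf = 0.0
            else:
                Vk = V[:k]
                Xk = Xc - Xc @ Vk.T @ Vk
                vf = float(evr[k:].sum())
        accs.append(loo_decode(Xk, y, gamma=gamma).accuracy)
        varfracs.append(vf)
    return dict(ks=np.array(ks), accuracy=np.array(accs),
                variance_fraction=np.array(varfracs))


def stimulus_period_cd(
    X_wm: np.ndarray,
    y_wm: np.ndarray,
    X_other: np.ndarray,
    y_other: np.ndarray,
    gamma: float = 1e-4,
) -> dict:
    """Stimulus-period cue code: fit on WM-task stimulus-evoked responses,
    apply unchanged to the other task's responses of the same orientations."""
    wm = loo_decode(X_wm, y_wm, gamma=gamma)
    clf = fit_cd(X_wm, y_wm, gamma=gamma)
    missing = set(np.unique(y_other)) - set(clf.classes_)
    if missing:
        raise ValueError(f"orientation classes {missing} absent from training task")
    cross_acc = float((clf.predict(X_other) == y_other).mean())
    return dict(within_task=wm, cross_task_accuracy=cross_acc, model=clf)


@dataclass
class PersistenceResult:
    early_z: np.ndarray
    late_z: np.ndarray
    slope: float
    r_squared: float
    n_trials: int
    sign_convention_applied: bool


def persistence_stats(
    early_scores: np.ndarray,
    late_scores: np.ndarray,
    delays_ms: np.ndarray,
    min_delay_ms: float = 2000.0,
    invert: np.ndarray | None = None,
    min_trials: int = 10,
) -> PersistenceResult:
    """Single-trial persistence of coding-dimension activity.

    ``early_scores``/``late_scores`` are held-out projections of the first
    (< 1.6 s) and second (>= 1.6 s) delay halves.  Only trials with delays of
    at least ``min_delay_ms`` enter.  ``invert`` flips the sign of the listed
    trials (Discrimination-task or cue-A projections) so both classes pool.
    Scores are z-scored across included trials; the least-squares slope of
    late on early indexes persistence and R^2 indexes robustness.
    """
    sel = (np.asarray(delays_ms) >= min_delay_ms)
    sel &= np.isfinite(early_scores) & np.isfinite(late_scores)
    e = np.asarray(early_scores, dtype=float).copy()
    l = np.asarray(late_scores, dtype=float).copy()
    applied = False
    if invert is not None:
        e[invert] *= -1.0
        l[invert] *= -1.0
        applied = True
    e, l = e[sel], l[sel]
    if len(e) < min_trials:
        raise InsufficientDataError(f"only {len(e)} qualifying trials")
    ez = (e - e.mean()) / e.std()
    lz = (l - l.mean()) / l.std()
    fit = stats.linregress(ez, lz)
    return PersistenceResult(ez, lz, float(fit.slope), float(fit.rvalue**2),
                             len(e), applied)


def decode_with_outcome_control(
    X: np.ndarray,
    y: np.ndarray,
    correct_mask: np.ndarray,
    gamma: float = 1e-4,
) -> np.ndarray:
    """Per-trial classification correctness where models are trained on
    correct trials only: correct trials are decoded leave-one-out among
    themselves; incorrect trials are scored by the model trained on all
    correct trials (they never enter any training set)."""
    correct_mask = np.asarray(correct_mask, dtype=bool)
    out = np.zeros(len(y), dtype=bool)
    res = loo_decode(X[correct_mask], y[correct_mask], gamma=gamma)
    out[correct_mask] = res.correct
    if (~correct_mask).any():
        clf = fit_cd(X[correct_mask], y[correct_mask], gamma=gamma)
        out[~correct_mask] = clf.predict(X[~correct_mask]) == y[~correct_mask]
    return out


def outcome_split_accuracy(
    classified_correct: np.ndarray, outcomes: np.ndarray
) -> dict:
    """Decoding accuracy among delays preceding correct rejections versus
    false alarms, with a two-sided Fisher exact test on the
    correct/incorrect x CR/FA table."""
    cr = outcomes == "CR"
    fa = outcomes == "FA"
    if fa.sum() == 0 or cr.sum() == 0:
        return dict(acc_pre_cr=np.nan, acc_pre_fa=np.nan, fisher_p=np.nan,
                    testable=False)
    a = int(classified_correct[cr].sum())
    b = int(cr.sum()) - a
    c = int(classified_correct[fa].sum())
    d = int(fa.sum()) - c
    p = float(stats.fisher_exact([[a, b], [c, d]])[1])
    return dict(
        acc_pre_cr=a / cr.sum(), acc_pre_fa=c / fa.sum(), fisher_p=p,
        testable=True,
    )


def conditional_cue_accuracy(
    task_correct: np.ndarray, cue_correct: np.ndarray
) -> dict:
    """Cue-decoding accuracy split by task-decoding correctness, plus the
    Pearson correlation between the two per-trial correctness indicators."""
    task_correct = np.asarray(task_correct, dtype=bool)
    cue_correct = np.asarray(cue_correct, dtype=bool)
    if task_correct.all() or (~task_correct).all():
        split = (np.nan, np.nan)
        testable = False
    else:
        split = (
            float(cue_correct[task_correct].mean()),
            float(cue_correct[~task_correct].mean()),
        )
        testable = True
    if task_correct.std() > 0 and cue_correct.std() > 0:
        r = float(stats.pearsonr(task_correct, cue_correct)[0])
    else:
        r = np.nan
    return dict(
        cue_acc_task_correct=split[0], cue_acc_task_incorrect=split[1],
        pearson_r=r, testable=testable,
    )
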