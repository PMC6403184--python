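"""Shrinkage linear discriminant analysis with CAT-score variable selection.

This is the prediction engine of the package, implemented from the estimator
family behind the R ``sda`` package rather than calling it:

* **Shrunk moments** — class means, pooled per-feature variances shrunk toward
  their median, and the pooled correlation matrix shrunk toward the identity,
  with the analytic (Schafer-Strimmer) mean-squared-error-minimizing
  intensities estimated from the data and clipped to [0, 1].
* **CAT scores** — correlation-adjusted t-scores tau = (P*)^(-1/2) t, where t
  is the vector of two-sample t-scores using the shrunk variances and P* the
  shrunk correlation matrix; decorrelation shares the discriminative mass of
  correlated features.
* **Cross-validated selection** — features whose mean |tau| across stratified
  CV folds exceeds a threshold (default 4) are included.
* **Discriminant** — Gaussian linear discriminant on the selected features
  with covariance rebuilt from the shrunk moments; an empty selection falls
  back to the training-majority class so that permutation reruns stay
  well defined.

All estimation here is small-n / moderate-p (tens of subjects, 48 regions),
and every routine operates on plain numpy arrays for speed: the permutation
test re-runs the entire selection + fit pipeline thousands of times.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

VAR_FLOOR = 1e-12


def stratified_folds(y, folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified k-fold test-index sets (lightweight splitter).

    Indices of each class are shuffled and dealt round-robin across folds, so
    every fold's class proportions match the sample's as closely as integer
    counts allow. Used in the permutation inner loop where the splitter runs
    tens of thousands of times.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    assign = np.empty(y.size, dtype=int)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        assign[idx] = np.arange(idx.size) % folds
    return [np.flatnonzero(assign == f) for f in range(folds)]


@dataclass
class Moments:
    """Shrunk first and second moments of a two-class sample."""

    means: np.ndarray              # 2 x p class means (class order: labels[0], labels[1])
    n_per_class: tuple[int, int]
    variances: np.ndarray          # p pooled variances, shrunk toward their median
    correlation: np.ndarray        # p x p pooled correlation, shrunk toward identity
    lambda_corr: float
    lambda_var: float
    classes: tuple
    raw_correlation: np.ndarray | None = None


@dataclass
class SLDAModel:
    moments: Moments
    selected: np.ndarray           # indices into the original feature axis
    cat: np.ndarray                # CAT scores on the full feature set
    priors: np.ndarray             # class frequencies
    feature_names: list[str] | None = None
    _coef: np.ndarray | None = field(default=None, repr=False)
    _const: np.ndarray | None = field(default=None, repr=False)

    def to_json(self) -> str:
        m = self.moments
        return json.dumps({
            "means": m.means.tolist(), "variances": m.variances.tolist(),
            "correlation": m.correlation.tolist(),
            "lambda_corr": m.lambda_corr, "lambda_var": m.lambda_var,
            "classes": list(m.classes), "n_per_class": list(m.n_per_class),
            "selected": self.selected.tolist(), "cat": self.cat.tolist(),
            "priors": self.priors.tolist(), "feature_names": self.feature_names,
        })


@dataclass
class SelectionResult:
    """Cross-validated CAT-score selection summary."""

    mean_abs_cat: np.ndarray       # per-feature mean |tau| across folds x repeats
    included: np.ndarray           # indices with mean |tau| > threshold
    inclusion_frequency: np.ndarray  # fraction of folds where |tau| > threshold
    threshold: float


def _class_split(y) -> tuple[np.ndarray, tuple, np.ndarray, np.ndarray]:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    m0 = y == classes[0]
    return y, tuple(classes), m0, ~m0


def shrink_moments(X: np.ndarray, y, lambda_corr: float | None = None,
                   lambda_var: float | None = None) -> Moments:
    """Class means plus analytically shrunk pooled variances and correlations.

    Pooled (class-centered) residuals feed the Schafer-Strimmer estimators:
    correlation entries are shrunk toward zero off-diagonals with intensity
    lambda_corr = sum Var(r_ij) / sum r_ij^2, variances toward their median
    with the analogous intensity; both are clipped to [0, 1]. A constant
    feature has its variance floored with a warning. Passing ``lambda_corr``
    or ``lambda_var`` overrides the data-driven intensity (0 recovers the
    classical pooled estimates, ``lambda_corr=1`` the diagonal model).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 4:
        raise ValueError("need at least 4 samples")
    y, classes, m0, m1 = _class_split(y)
    n0, n1 = int(m0.sum()), int(m1.sum())
    means = np.vstack([X[m0].mean(axis=0), X[m1].mean(axis=0)])
    xc = X.copy()
    xc[m0] -= means[0]
    xc[m1] -= means[1]
    df = n - 2
    v = (xc ** 2).sum(axis=0) / df
    n_const = int((v <= VAR_FLOOR).sum())
    if n_const:
        logger.warning("shrink_moments: %d constant feature(s), variance floored", n_const)
    v = np.maximum(v, VAR_FLOOR)

    # variance shrinkage toward the median (Opgen-Rhein & Strimmer target)
    v_med = float(np.median(v))
    if lambda_var is not None:
        lam_v = float(lambda_var)
    else:
        c = xc ** 2
        var_v = (n / ((n - 1.0) ** 3)) * ((c - c.mean(axis=0)) ** 2).sum(axis=0)
        denom_v = ((v - v_med) ** 2).sum()
        lam_v = 1.0 if denom_v <= 0 else float(np.clip(var_v.sum() / denom_v, 0.0, 1.0))
    v_star = lam_v * v_med + (1.0 - lam_v) * v

    # correlation shrinkage toward identity
    if p == 1:
        r_star = np.ones((1, 1))
        lam_c = 0.0
        r = r_star
    else:
        # standardize residuals so that w^T w / n is exactly the pooled
        # correlation matrix: unit diagonal and PSD by construction
        ss = np.maximum((xc ** 2).sum(axis=0), VAR_FLOOR)
        w = xc * np.sqrt(n / ss)
        r = (w.T @ w) / n
        np.fill_diagonal(r, 1.0)
        if lambda_corr is not None:
            lam_c = float(lambda_corr)
        else:
            # Var(r_ij) from the spread of per-sample products w_ki w_kj;
            # sum_k (w_ki w_kj - r_ij)^2 = (w^2)^T (w^2) - n r^2 (BLAS form)
            w_sq = w ** 2
            var_r = (n / ((n - 1.0) ** 3)) * (w_sq.T @ w_sq - n * r ** 2)
            off = ~np.eye(p, dtype=bool)
            denom_c = (r[off] ** 2).sum()
            lam_c = 1.0 if denom_c <= 0 else float(
                np.clip(var_r[off].sum() / denom_c, 0.0, 1.0))
        r_star = (1.0 - lam_c) * r
        np.fill_diagonal(r_star, 1.0)
    return Moments(means, (n0, n1), v_star, r_star, lam_c, lam_v, classes,
                   raw_correlation=r)


def t_scores(moments: Moments) -> np.ndarray:
    """Two-sample t-scores with shrunk pooled variances: class0 minus class1."""
    n0, n1 = moments.n_per_class
    se = np.sqrt(moments.variances * (1.0 / n0 + 1.0 / n1))
    return (moments.means[0] - moments.means[1]) / se


def _inv_sqrt_psd(m: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(m)
    if evals.min() <= 0:
        raise ValueError("correlation matrix is not positive definite")
    return (evecs * (evals ** -0.5)) @ evecs.T


def cat_scores(moments: Moments) -> np.ndarray:
    """Correlation-adjusted t-scores tau = (P*)^(-1/2) t.

    The inverse square root is taken by symmetric eigendecomposition of the
    shrunk correlation matrix; with P* = I this reduces to the plain t-score.
    """
    t = t_scores(moments)
    if moments.correlation.shape[0] == 1:
        return t
    if moments.lambda_corr >= 1.0:
        return t
    return _inv_sqrt_psd(moments.correlation) @ t


def crossval_select(X: np.ndarray, y, folds: int = 5, repeats: int = 1,
                    threshold: float = 4.0, seed: int = 0) -> SelectionResult:
    """Select features by mean |CAT score| across stratified CV folds.

    For each fold's training split the shrunk moments and CAT scores are
    recomputed; features whose |tau| averaged over all folds x repeats exceeds
    ``threshold`` are included. The threshold applies to |tau| so that
    negative-effect features are admissible.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    _, counts = np.unique(y, return_counts=True)
    folds = min(folds, int(counts.min()))
    if folds < 2:
        raise ValueError("stratified folding infeasible: a class has < 2 members")
    acc = np.zeros(p)
    freq = np.zeros(p)
    k = 0
    all_idx = np.arange(n)
    for rep in range(repeats):
        for te in stratified_folds(y, folds, seed + rep):
            tr = np.setdiff1d(all_idx, te, assume_unique=True)
            tau = np.abs(cat_scores(shrink_moments(X[tr], y[tr])))
            acc += tau
            freq += tau > threshold
            k += 1
    mean_abs = acc / k
    return SelectionResult(mean_abs, np.flatnonzero(mean_abs > threshold),
                           freq / k, threshold)


def fit_slda(X: np.ndarray, y, selected=None, lambda_corr: float | None = None,
             lambda_var: float | None = None) -> SLDAModel:
    """Fit the shrinkage discriminant on (optionally pre-selected) features.

    ``selected`` holds indices into X's feature axis; None means all features.
    An empty selection is allowed: prediction then falls back to the
    training-majority class (logged). The ``lambda_*`` overrides force the
    shrinkage intensities (see :func:`shrink_moments`).
    """
    X = np.asarray(X, dtype=float)
    y, classes, m0, m1 = _class_split(y)
    moments = shrink_moments(X, y, lambda_corr, lambda_var)
    cat = cat_scores(moments)
    priors = np.array([m0.mean(), m1.mean()])
    if selected is None:
        selected = np.arange(X.shape[1])
    selected = np.asarray(selected, dtype=int)
    model = SLDAModel(moments, selected, cat, priors)
    if selected.size == 0:
        logger.info("fit_slda: empty selection, majority-class fallback")
        return model
    s = selected
    sd = np.sqrt(moments.variances[s])
    p_sub = moments.correlation[np.ix_(s, s)]
    evals, evecs = np.linalg.eigh(p_sub)
    if evals.min() <= 0:
        raise ValueError("shrunk correlation restricted to selection is not PD")
    pinv = (evecs / evals) @ evecs.T
    sigma_inv = pinv / np.outer(sd, sd)
    mu = moments.means[:, s]
    coef = mu @ sigma_inv                                   # 2 x k
    const = -0.5 * np.einsum("ij,ij->i", coef, mu) + np.log(priors)
    model._coef, model._const = coef, const
    return model


def predict_slda(model: SLDAModel, X: np.ndarray):
    """Predict classes and posterior probabilities for new samples."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    classes = model.moments.classes
    if model.selected.size == 0:
        k = int(np.argmax(model.priors))
        post = np.tile(model.priors, (X.shape[0], 1))
        return np.array([classes[k]] * X.shape[0]), post
    if X.shape[1] == model.moments.means.shape[1]:
        Xs = X[:, model.selected]
    elif X.shape[1] == model.selected.size:
        Xs = X
    else:
        raise ValueError("feature dimension mismatch at predict time")
    d = Xs @ model._coef.T + model._const                    # n x 2 discriminants
    d -= d.max(axis=1, keepdims=True)
    post = np.exp(d)
    post /= post.sum(axis=1, keepdims=True)
    idx = np.argmax(d, axis=1)
    return np.asarray(classes)[idx], post


def partial_correlations(X_selected: np.ndarray, score, names=None) -> list[dict]:
    """Partial correlation of each selected feature with a continuous outcome.

    For feature j, both the feature and the outcome are residualized on the
    remaining selected features (ordinary least squares with intercept); the
    Pearson correlation of the residuals is reported with a p-value from a
    t-distribution on n - 2 - (k-1) degrees of freedom, k the number of
    selected features. A single selected feature reduces to the plain Pearson
    correlation.
    """
    X = np.atleast_2d(np.asarray(X_selected, dtype=float))
    score = np.asarray(score, dtype=float)
    n, k = X.shape
    if n != score.size:
        raise ValueError("feature rows and outcome length differ")
    out = []
    for j in range(k):
        others = np.delete(X, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise ValueError("collinear control variables; cannot residualize")
        beta_x, *_ = np.linalg.lstsq(design, X[:, j], rcond=None)
        beta_y, *_ = np.linalg.lstsq(design, score, rcond=None)
        rx = X[:, j] - design @ beta_x
        ry = score - design @ beta_y
        if rx.std() == 0 or ry.std() == 0:
            raise ValueError("zero residual variance")
        r = float(np.corrcoef(rx, ry)[0, 1])
        df = n - 2 - (k - 1)
        if df <= 0:
            raise ValueError("not enough samples for the requested controls")
        tstat = r * np.sqrt(df / max(1.0 - r ** 2, 1e-300))
        p = float(2.0 * stats.t.sf(abs(tstat), df))
        out.append({"feature": names[j] if names is not None else j,
                    "partial_r": r, "p": p, "df": df})
    return out
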