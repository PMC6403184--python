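"""Band-power features, the three LDA classifiers, and feedback position.

Each 4-s epoch (motor imagery or baseline) is subdivided into overlapping 1-s
bins shifted by 62.5 ms (49 bins for a 4-s epoch); every bin yields a feature
vector of log mean band power per spatially filtered component. Three linear
discriminant classifiers are trained on these bin features:

* BaseL — baseline vs left motor imagery,
* BaseR — baseline vs right motor imagery,
* LR    — left vs right motor imagery.

Each classifier is the arithmetic mean of the weight vectors and biases of
seven stratified cross-validation fold fits ("mean classifier"); classified
1-s segments then drive the feedback ball and are tallied into the
performance statistics of :mod:`minf.performance`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .eeg_pipeline import EpochSet

logger = logging.getLogger(__name__)

EPS_POWER = 1e-20


@dataclass
class BinFeatures:
    """Per-epoch bin features: epochs x bins x components log mean band power."""

    features: np.ndarray
    bin_times: np.ndarray          # bin start offsets, seconds from epoch start
    labels: list[str]
    bin_len: float = 1.0
    bin_shift: float = 0.0625

    @property
    def n_bins(self) -> int:
        return self.features.shape[1]

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to (epochs*bins) x components with repeated epoch labels."""
        n_ep, n_bins, n_comp = self.features.shape
        X = self.features.reshape(n_ep * n_bins, n_comp)
        y = np.repeat(self.labels, n_bins)
        return X, y


@dataclass
class LinearClassifier:
    """w^T x + b > 0 decides the second class; ties go to the first class."""

    weights: np.ndarray
    bias: float
    classes: tuple[str, str]
    kind: str = "LR"

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        if X.shape[1] != self.weights.shape[0]:
            raise ValueError("feature dimension does not match classifier")
        return X @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_values(X)
        return np.where(d > 0, self.classes[1], self.classes[0])

    def to_json(self) -> str:
        return json.dumps(
            {"weights": self.weights.tolist(), "bias": float(self.bias),
             "classes": list(self.classes), "kind": self.kind}
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearClassifier":
        d = json.loads(text)
        return cls(np.array(d["weights"]), d["bias"], tuple(d["classes"]), d["kind"])


def n_bins_for(epoch_len: float, bin_len: float = 1.0, shift: float = 0.0625) -> int:
    """Number of overlapping bins: floor((L - bin_len)/shift) + 1."""
    if epoch_len < bin_len:
        raise ValueError("epoch shorter than one bin")
    return int(np.floor((epoch_len - bin_len) / shift + 1e-9)) + 1


def extract_bins(ep: EpochSet, bin_len: float = 1.0, shift: float = 0.0625) -> BinFeatures:
    """Log mean band power per overlapping bin and component.

    Assumes the epochs are already spatially and band-pass filtered, so mean
    squared amplitude within a bin is band power. Bin windows are half-open;
    zero-power bins are floored at log(1e-20).
    """
    n_ep, n_comp, n_s = ep.data.shape
    epoch_len = n_s / ep.fs
    nb = n_bins_for(epoch_len, bin_len, shift)
    bin_samples = int(round(bin_len * ep.fs))
    starts = np.round(np.arange(nb) * shift * ep.fs).astype(int)
    feats = np.empty((n_ep, nb, n_comp))
    sq = ep.data ** 2
    for b, s0 in enumerate(starts):
        feats[:, b, :] = sq[:, :, s0 : s0 + bin_samples].mean(axis=2)
    n_floored = int((feats <= 0).sum())
    if n_floored:
        logger.warning("extract_bins: %d zero-power bins floored", n_floored)
    feats = np.log(np.maximum(feats, EPS_POWER))
    return BinFeatures(feats, starts / ep.fs, list(ep.labels), bin_len, shift)


def train_lda(X: np.ndarray, y, classes: tuple[str, str], kind: str = "LR") -> LinearClassifier:
    """Fisher LDA with pooled covariance and equal priors.

    The returned boundary is the equal-posterior surface; a singular pooled
    covariance falls back to a ridge-regularized (shrinkage) solver.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.isnan(X).any():
        raise ValueError("features contain NaN")
    present = set(np.unique(y))
    if not set(classes) <= present:
        raise ValueError("both classes must be present in the training labels")
    yi = (y == classes[1]).astype(int)
    lda = LinearDiscriminantAnalysis(solver="lsqr", priors=[0.5, 0.5])
    try:
        lda.fit(X, yi)
    except np.linalg.LinAlgError:
        logger.warning("train_lda: singular pooled covariance, adding shrinkage ridge")
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-6, priors=[0.5, 0.5])
        lda.fit(X, yi)
    return LinearClassifier(lda.coef_.ravel().copy(), float(lda.intercept_[0]), classes, kind)


def train_mean_classifier(X: np.ndarray, y, classes: tuple[str, str], folds: int = 7,
                          kind: str = "LR", seed: int = 0) -> LinearClassifier:
    """Mean classifier: average of per-fold LDA weights and biases.

    One LDA is fit on each stratified fold's training split; the mean of the
    fold weight vectors and biases is returned. Per-fold validation accuracies
    are logged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    for c in classes:
        if (y == c).sum() < folds:
            raise ValueError(f"class {c!r} has fewer samples than folds={folds}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    ws, bs, accs = [], [], []
    for tr, va in skf.split(X, y):
        clf = train_lda(X[tr], y[tr], classes, kind)
        ws.append(clf.weights)
        bs.append(clf.bias)
        accs.append(float((clf.predict(X[va]) == y[va]).mean()))
    logger.info("train_mean_classifier[%s]: fold accuracies %s", kind,
                np.round(accs, 3).tolist())
    return LinearClassifier(np.mean(ws, axis=0), float(np.mean(bs)), classes, kind)


def classify_segments(feat: BinFeatures, clf: LinearClassifier):
    """One decision and decision-value magnitude per bin.

    Returns (decisions, values): arrays of shape epochs x bins. A decision
    value of exactly 0 is a tie, broken to the first class.
    """
    n_ep, nb, n_comp = feat.features.shape
    X = feat.features.reshape(n_ep * nb, n_comp)
    vals = clf.decision_values(X).reshape(n_ep, nb)
    decisions = np.where(vals > 0, clf.classes[1], clf.classes[0])
    return decisions, vals


def ball_position(lr_value: float, base_value: float, scale: float = 1.0) -> tuple[float, float]:
    """Feedback ball coordinates in [-1, 1]^2.

    The LR decision value drives the horizontal axis, the Base(L|R) value the
    vertical axis; both are clipped after scaling.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if not (np.isfinite(lr_value) and np.isfinite(base_value)):
        raise ValueError("classifier outputs must be finite")
    return (float(np.clip(lr_value / scale, -1, 1)),
            float(np.clip(base_value / scale, -1, 1)))


def train_session_classifiers(mi_bins: BinFeatures, base_bins: BinFeatures,
                              folds: int = 7, seed: int = 0,
                              side_scope: str = "matching") -> dict[str, LinearClassifier]:
    """Train BaseL, BaseR and LR mean classifiers from calibration features.

    ``side_scope`` controls which baseline epochs enter the Base classifiers:
    "matching" uses the baselines of same-side trials only, "pooled" all of
    them. ``base_bins.labels`` must carry the originating trial's side as
    "baseline/left" or "baseline/right" (or plain "baseline" for pooled use).
    """
    X_mi, y_mi = mi_bins.stacked()
    X_b, y_b = base_bins.stacked()
    out: dict[str, LinearClassifier] = {}
    for side, kind in (("left", "BaseL"), ("right", "BaseR")):
        if side_scope == "matching" and any("/" in l for l in y_b):
            sel_b = np.array([l == f"baseline/{side}" for l in y_b])
        else:
            sel_b = np.ones(len(y_b), bool)
        sel_m = y_mi == side
        X = np.vstack([X_b[sel_b], X_mi[sel_m]])
        y = np.array(["baseline"] * int(sel_b.sum()) + [side] * int(sel_m.sum()))
        out[kind] = train_mean_classifier(X, y, ("baseline", side), folds, kind, seed)
    sel = np.isin(y_mi, ("left", "right"))
    out["LR"] = train_mean_classifier(X_mi[sel], y_mi[sel], ("left", "right"),
                                      folds, "LR", seed)
    return out
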