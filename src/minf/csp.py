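"""Common spatial patterns for the left- vs right-hand motor imagery contrast.

CSP finds spatial filters w maximizing the variance ratio between two signal
classes by solving the generalized eigenproblem

    Sigma_left w = lambda (Sigma_left + Sigma_right) w,

with per-epoch covariances normalized by their trace before class averaging.
Eigenvalues lie in [0, 1]: a component with lambda near 1 captures variance
expressed almost exclusively during left-hand trials, near 0 during right-hand
trials, and 0.5 components are uninformative. One filter per side is selected
among the three most segregating candidates, optionally by a
neurophysiological-plausibility criterion on the spatial patterns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .eeg_pipeline import EpochSet, Recording


@dataclass
class CSPModel:
    """Spatial filters (rows of W), patterns (columns of A) and eigenvalues."""

    filters: np.ndarray      # components x channels
    patterns: np.ndarray     # channels x components
    eigenvalues: np.ndarray  # variance ratio for the first class, in [0,1], descending
    class_order: tuple[str, str] = ("left", "right")
    channel_labels: list[str] | None = None

    @property
    def n_components(self) -> int:
        return self.filters.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "filters": self.filters.tolist(),
                "patterns": self.patterns.tolist(),
                "eigenvalues": self.eigenvalues.tolist(),
                "class_order": list(self.class_order),
                "channel_labels": self.channel_labels,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CSPModel":
        d = json.loads(text)
        return cls(
            np.array(d["filters"]), np.array(d["patterns"]), np.array(d["eigenvalues"]),
            tuple(d["class_order"]), d["channel_labels"],
        )


def _mean_normalized_cov(ep: EpochSet) -> np.ndarray:
    covs = []
    for x in ep.data:
        c = x @ x.T
        tr = np.trace(c)
        if tr <= 0:
            continue
        covs.append(c / tr)
    if not covs:
        raise ValueError("no usable epochs for covariance estimation")
    return np.mean(covs, axis=0)


def fit_csp(left: EpochSet, right: EpochSet, channel_labels=None) -> CSPModel:
    """Fit CSP on band-pass-filtered left/right epoch sets.

    Returns all components, eigenvalues sorted descending (left-dominant
    first). Raises if the pooled covariance is effectively rank deficient;
    callers may then reduce the channel set.
    """
    if left.n_epochs == 0 or right.n_epochs == 0:
        raise ValueError("both classes need at least one epoch")
    if left.data.shape[1] != right.data.shape[1]:
        raise ValueError("left and right epochs must share channels")
    cov_l = _mean_normalized_cov(left)
    cov_r = _mean_normalized_cov(right)
    pooled = cov_l + cov_r
    evs = np.linalg.eigvalsh(pooled)
    if evs[0] <= 1e-10 * evs[-1]:
        raise ValueError(
            "pooled covariance is rank deficient; reduce the channel set before CSP"
        )
    # small diagonal load for numerical stability on short sessions
    pooled = pooled + 1e-9 * np.trace(pooled) * np.eye(pooled.shape[0])
    evals, evecs = linalg.eigh(cov_l, pooled)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, 1.0)
    W = evecs[:, order].T                     # components x channels
    A = np.linalg.inv(W)                      # channels x components (mixing)
    # sign convention: largest-magnitude pattern weight positive
    for k in range(W.shape[0]):
        j = np.argmax(np.abs(A[:, k]))
        if A[j, k] < 0:
            A[:, k] *= -1
            W[k, :] *= -1
    return CSPModel(W, A, evals, ("left", "right"), channel_labels)


def select_filters(model: CSPModel, plausibility=None, motor_channels=None):
    """Pick one filter per side from the three most segregating components.

    Candidates for the left side are the three largest-eigenvalue components,
    for the right side the three smallest. The selected candidate maximizes
    ``plausibility(pattern)`` if given; otherwise, if ``motor_channels`` (a
    list of channel indices) is configured, the one with the largest absolute
    pattern weight on those channels; with neither, the most extreme
    eigenvalue wins.

    Returns (filter_left, filter_right) as 1-D weight vectors.
    """
    k = model.n_components
    n_cand = min(3, k)
    if k < 3:
        warnings.warn("fewer than 3 components per side; using all available as candidates")
    left_cand = list(range(n_cand))
    right_cand = list(range(k - n_cand, k))

    def pick(cands, extreme_first: bool) -> int:
        if plausibility is not None:
            return max(cands, key=lambda i: plausibility(model.patterns[:, i]))
        if motor_channels is not None:
            return max(cands, key=lambda i: np.abs(model.patterns[motor_channels, i]).max())
        return cands[0] if extreme_first else cands[-1]

    i_left = pick(left_cand, True)
    i_right = pick(right_cand, False)
    return model.filters[i_left], model.filters[i_right]


def apply_csp(x, filters) -> np.ndarray | EpochSet:
    """Project a Recording, EpochSet or raw array onto spatial filters.

    Virtual channel i is w_i^T . signal; output keeps the input's structure
    (EpochSet in, EpochSet out).
    """
    W = np.atleast_2d(np.asarray(filters, dtype=float))
    if isinstance(x, EpochSet):
        if x.data.shape[1] != W.shape[1]:
            raise ValueError("filter length does not match channel count")
        data = np.einsum("kc,ncs->nks", W, x.data)
        return EpochSet(data, list(x.labels), x.window, x.fs)
    if isinstance(x, Recording):
        sig = x.signal
    else:
        sig = np.asarray(x, dtype=float)
    if sig.shape[0] != W.shape[1]:
        raise ValueError("filter length does not match channel count")
    return W @ sig
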