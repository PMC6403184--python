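"""Repeated cross-validation, permutation significance, and correlation reports.

The evaluation protocol mirrors small-sample neuroimaging prediction studies:
prediction accuracy is the fraction of correct held-out predictions over ten
repeats of stratified fivefold cross-validation, with CAT-score variable
selection re-run inside every training split (no label leakage). Statistical
significance comes from a Monte Carlo permutation test that shuffles the
group labels across subjects and re-runs the *entire* pipeline — selection
included — for each permutation; the p-value is the plain proportion of
permutations whose accuracy is greater than or equal to the observed one
(no +1 correction, so the smallest reportable p is 0, flagged as
"< 1/n_perm"). The exact binomial tail is provided for comparison only: it is
known to overstate significance for cross-validated accuracies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .slda import (
    cat_scores,
    crossval_select,
    fit_slda,
    predict_slda,
    shrink_moments,
    stratified_folds,
)

logger = logging.getLogger(__name__)


@dataclass
class CVResult:
    accuracy: float                   # percent, over all repeats x subjects
    fold_accuracy: np.ndarray         # repeats x folds, percent
    selections: list[list[int]]       # per outer fold: selected feature indices
    folds: int
    repeats: int
    seed: int


@dataclass
class PermutationResult:
    observed: float                   # percent
    null: np.ndarray                  # percent, one per permutation
    n_perm: int
    p_value: float
    seed: int

    @property
    def p_display(self) -> str:
        return f"< {1.0 / self.n_perm:g}" if self.p_value == 0 else f"{self.p_value:g}"


def _as_xy(table, candidate_columns, outcome):
    """Pull a numeric feature matrix and binary label vector from a table."""
    if isinstance(table, pd.DataFrame):
        missing = [c for c in candidate_columns if c not in table.columns]
        if missing:
            raise KeyError(f"unknown columns: {missing}")
        sub = table[list(candidate_columns)]
        if sub.isna().any().any():
            n_bad = int(sub.isna().any(axis=1).sum())
            logger.warning("excluding %d subject(s) with missing cells listwise", n_bad)
            keep = ~sub.isna().any(axis=1)
            sub = sub[keep]
            y = np.asarray(table[outcome] if isinstance(outcome, str) else outcome)[keep]
        else:
            y = np.asarray(table[outcome] if isinstance(outcome, str) else outcome)
        X = sub.to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
        y = np.asarray(outcome)
    return X, y


def _cv_accuracy(X: np.ndarray, y: np.ndarray, folds: int, repeats: int, seed: int,
                 select: bool, threshold: float, collect=False):
    """Core numpy path shared by repeated_cv and permutation_test.

    Variable selection inside each training split thresholds the CAT scores
    computed on that split (|tau| > threshold), mirroring the per-fold
    ranking-then-fit idiom of shrinkage-discriminant cross-validation; no
    held-out information enters the selection.
    """
    classes, counts = np.unique(y, return_counts=True)
    eff_folds = min(folds, int(counts.min()))
    if eff_folds < folds:
        warnings.warn(f"reducing folds from {folds} to {eff_folds} (small class)")
    correct = 0
    total = 0
    fold_acc = np.zeros((repeats, eff_folds))
    selections: list[list[int]] = []
    all_idx = np.arange(X.shape[0])
    for rep in range(repeats):
        fold_tests = stratified_folds(y, eff_folds, (seed + 7919 * rep) % (2 ** 31))
        for f, te in enumerate(fold_tests):
            tr = np.setdiff1d(all_idx, te, assume_unique=True)
            if select:
                tau = np.abs(cat_scores(shrink_moments(X[tr], y[tr])))
                sel = np.flatnonzero(tau > threshold)
                if sel.size == 0:
                    # no variable clears the threshold: fall back to the
                    # unselected ("All") shrinkage discriminant, keeping the
                    # CV statistic continuous under label permutations
                    sel = np.arange(X.shape[1])
            else:
                sel = np.arange(X.shape[1])
            model = fit_slda(X[tr], y[tr], sel)
            pred, _ = predict_slda(model, X[te])
            ok = int((pred == y[te]).sum())
            correct += ok
            total += te.size
            fold_acc[rep, f] = 100.0 * ok / te.size
            if collect:
                selections.append(list(map(int, sel)))
    return 100.0 * correct / total, fold_acc, selections


def repeated_cv(table, candidate_columns, outcome="label", folds: int = 5,
                repeats: int = 10, seed: int = 0, select: bool = True,
                threshold: float = 4.0) -> CVResult:
    """Repeated stratified k-fold CV of the selection + SLDA pipeline.

    ``select=False`` bypasses CAT selection and uses every candidate column
    (the fixed-subset analyses). Fresh folds are drawn for every repeat.
    ``repeats=1, folds=n`` degenerates to leave-one-out.
    """
    X, y = _as_xy(table, candidate_columns, outcome)
    acc, fold_acc, selections = _cv_accuracy(
        X, y, folds, repeats, seed, select, threshold, collect=True)
    return CVResult(acc, fold_acc, selections, fold_acc.shape[1], repeats, seed)


def permutation_test(table, candidate_columns, outcome="label", folds: int = 5,
                     repeats: int = 10, n_perm: int = 10_000, seed: int = 0,
                     select: bool = True, threshold: float = 4.0) -> PermutationResult:
    """Monte Carlo permutation test of the repeated-CV accuracy.

    Each permutation shuffles the outcome across all subjects and re-runs the
    entire repeated-CV pipeline, selection included. p is the proportion of
    null accuracies >= the observed accuracy.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100: the permutation p-value will be unstable")
    X, y = _as_xy(table, candidate_columns, outcome)
    observed, _, _ = _cv_accuracy(X, y, folds, repeats, seed, select, threshold)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        if np.unique(yp).size < 2:   # cannot happen for 2-class input, kept for safety
            null[b] = 50.0
            continue
        null[b], _, _ = _cv_accuracy(X, yp, folds, repeats,
                                     int(rng.integers(2 ** 31)), select, threshold)
    p = float((null >= observed).mean())
    return PermutationResult(observed, null, n_perm, p, seed)


def binomial_test(k: int, n: int, p0: float = 0.5, one_sided: bool = True) -> float:
    """Exact binomial tail probability P(X >= k), X ~ Binomial(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if one_sided:
        return float(stats.binom.sf(k - 1, n, p0))
    return float(stats.binomtest(k, n, p0).pvalue)


def pearson_cor(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with the usual two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need n >= 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def run_analysis_suite(table: pd.DataFrame, analyses: list[dict], seed: int = 0,
                       n_perm: int = 1000, folds: int = 5, repeats: int = 10) -> pd.DataFrame:
    """Run a battery of selection + SLDA + permutation analyses on one cohort.

    Each analysis dict names: ``analysis`` (id), ``outcome`` (label column),
    ``candidates`` (feature columns), and ``select`` (True to run CAT
    selection; False uses all listed variables, reported as "All"). Returns
    one report row per analysis with the selected variables, repeated-CV
    accuracy (percent), and the permutation p-value.
    """
    rows = []
    for i, spec in enumerate(analyses):
        candidates = list(spec["candidates"])
        outcome = spec["outcome"]
        select = bool(spec.get("select", True))
        a_seed = (seed + 1009 * i) % (2 ** 31)
        cv = repeated_cv(table, candidates, outcome, folds=folds, repeats=repeats,
                         seed=a_seed, select=select)
        pt = permutation_test(table, candidates, outcome, folds=folds,
                              repeats=repeats, n_perm=n_perm, seed=a_seed,
                              select=select)
        if select:
            X, y = _as_xy(table, candidates, outcome)
            sel = crossval_select(X, y, folds=folds, repeats=repeats, seed=a_seed)
            selected = [candidates[j] for j in sel.included]
            sel_str = "; ".join(selected) if selected else "(none)"
        else:
            sel_str = "All"
        rows.append({
            "analysis": spec.get("analysis", i + 1),
            "outcome": outcome,
            "n_candidates": len(candidates),
            "variables_selected": sel_str,
            "accuracy_pct": cv.accuracy,
            "p_value": pt.p_value,
        })
        logger.info("analysis %s: acc=%.1f%% p=%s", rows[-1]["analysis"],
                    cv.accuracy, pt.p_display)
    return pd.DataFrame(rows)
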