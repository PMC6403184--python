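"""End-to-end scoring of a simulated neurofeedback session.

Reproduces the two-block protocol: a calibration block without feedback is
band-pass filtered, epoched and artifact-rejected, CSP filters are fitted on
the left-vs-right contrast and one filter per side selected; the calibration
data are then re-filtered with the causal Butterworth band-pass (the real-time
path), binned into 1-s log band-power segments and used to train the BaseL,
BaseR and LR mean classifiers. A second (feedback) block is pushed through the
same spatial and temporal filters, its segments classified, and the tallies
converted into the three performance percentages and their maximum.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import csp, eeg_pipeline as ep, neurofeedback as nf
from .performance import (
    PerformanceResult,
    classifier_performance,
    max_performance,
    tally_segments,
)
from .synthetic_data import EEGSimConfig, generate_eeg_session

MI_WINDOW = (0.5, 4.5)
BASE_WINDOW = (-7.0, -3.0)


def _epochs_for_block(rec: ep.Recording, filters: np.ndarray) -> dict[str, ep.EpochSet]:
    """Causal 8-30 Hz filter, CSP projection, MI + side-tagged baseline epochs."""
    filtered = ep.butter_bandpass(rec, 8.0, 30.0)
    virt = csp.apply_csp(filtered, filters)
    virt_rec = ep.Recording(virt, rec.fs, ["csp_left", "csp_right"], list(rec.events))
    out = {"mi": ep.epoch(virt_rec, MI_WINDOW)}
    for side in ("left", "right"):
        side_rec = replace(virt_rec, events=[e for e in virt_rec.events if e[1] == side])
        out[f"base_{side}"] = ep.epoch(side_rec, BASE_WINDOW, label=f"baseline/{side}")
    return out


def fit_session(calibration: ep.Recording, folds: int = 7, seed: int = 0,
                reject: bool = True):
    """Fit CSP filters and the three mean classifiers from a calibration block."""
    filt = ep.fir_bandpass(calibration, 8.0, 30.0)
    mi = ep.epoch(filt, MI_WINDOW)
    if reject and mi.n_epochs >= 5:
        mi = ep.reject_threshold(mi)
        mi = ep.reject_jointprob(mi)
    model = csp.fit_csp(mi.by_class("left"), mi.by_class("right"),
                        calibration.channel_labels)
    w_left, w_right = csp.select_filters(model)
    filters = np.vstack([w_left, w_right])

    blocks = _epochs_for_block(calibration, filters)
    mi_bins = nf.extract_bins(blocks["mi"])
    base = blocks["base_left"]
    base_all = ep.EpochSet(
        np.concatenate([blocks["base_left"].data, blocks["base_right"].data]),
        blocks["base_left"].labels + blocks["base_right"].labels,
        BASE_WINDOW, base.fs)
    base_bins = nf.extract_bins(base_all)
    classifiers = nf.train_session_classifiers(mi_bins, base_bins, folds=folds, seed=seed)
    return model, filters, classifiers


def score_block(rec: ep.Recording, filters: np.ndarray,
                classifiers: dict[str, nf.LinearClassifier],
                side_scope: str = "matching") -> PerformanceResult:
    """Classify every 1-s segment of a feedback block and compute Eq. 1-3 scores.

    Each classifier judges the segments of its own contrast: the Base
    classifiers see baseline and same-side MI segments (Eqs. 1-2), the LR
    classifier the MI segments of both sides (Eq. 3), so the MI tallies of the
    Base equations and of the LR equation come from different decisions.
    """
    blocks = _epochs_for_block(rec, filters)
    decisions: dict[str, np.ndarray] = {}
    truths: dict[str, np.ndarray] = {}
    base_mi: dict[str, np.ndarray] = {}
    for side, kind in (("left", "BaseL"), ("right", "BaseR")):
        feats = nf.extract_bins(blocks[f"base_{side}"])
        if feats.features.shape[0]:
            dec, _ = nf.classify_segments(feats, classifiers[kind])
            decisions[f"base_{side}"] = dec
            truths[f"base_{side}"] = np.full(dec.shape, "baseline")
        mi_feats = nf.extract_bins(blocks["mi"].by_class(side))
        dec_b, _ = nf.classify_segments(mi_feats, classifiers[kind])
        dec_lr, _ = nf.classify_segments(mi_feats, classifiers["LR"])
        base_mi[side] = dec_b            # baseline-vs-MI decisions on MI segments
        decisions[f"mi_{side}"] = dec_lr  # left-vs-right decisions on MI segments
        truths[f"mi_{side}"] = np.full(dec_lr.shape, side)

    # Eq. 3 (and the shared baseline tallies) from the LR decisions
    counts_lr = tally_segments(decisions, truths, side_scope=side_scope)
    # Eqs. 1-2 re-tally the MI segments with the Base classifiers' decisions
    dec_base = dict(decisions)
    truth_base = dict(truths)
    for side in ("left", "right"):
        dec_base[f"mi_{side}"] = base_mi[side]
    counts_base = tally_segments(dec_base, truth_base, side_scope=side_scope)

    base_result = classifier_performance(counts_base)
    lr_result = classifier_performance(counts_lr)
    return max_performance(base_result.baseL, base_result.baseR, lr_result.lr)


def simulate_session_performance(erd_depth: float = 0.5, snr: float = 2.0,
                                 n_channels: int = 16, n_trials: int = 20,
                                 seed: int = 0) -> PerformanceResult:
    """Generate calibration + feedback blocks and score the feedback block."""
    ss = np.random.SeedSequence(seed)
    s_train, s_test = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2))
    cfg = EEGSimConfig(n_channels=n_channels, n_trials_per_class=n_trials,
                       erd_depth=erd_depth, snr=snr, seed=s_train)
    rec_train = generate_eeg_session(cfg)
    rec_test = generate_eeg_session(replace(cfg, seed=s_test))
    _, filters, classifiers = fit_session(rec_train, seed=seed)
    return score_block(rec_test, filters, classifiers)
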