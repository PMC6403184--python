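"""EEG preprocessing: filtering, bad-channel detection, epoching, artifact rejection.

Two preprocessing paths are supported, mirroring the online (feedback) and
offline (re-analysis) pipelines of a calibrated motor-imagery neurofeedback
session:

* online path: 8-30 Hz band-pass (Hamming FIR for calibration, causal 4th-order
  Butterworth for the feedback block) and epoching only;
* offline path: 1 Hz high-pass / 40 Hz low-pass Hamming FIR on the continuous
  data, variance-based bad-channel removal, then amplitude-threshold and
  joint-probability rejection of artifactual epochs.

Independent-component cleaning and bad-channel interpolation are deliberately
out of scope (they require human inspection and electrode geometry); flagged
channels are dropped instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

CLASSES = ("left", "right")


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts.

    signal is channels x samples; events is a list of (sample_index, klass)
    with klass in {"left", "right"} marking motor-imagery onsets.
    """

    signal: np.ndarray
    fs: float
    channel_labels: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if not np.isfinite(self.signal).all():
            raise ValueError("signal contains NaN or Inf")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("channel_labels length must match channel count")
        n = self.signal.shape[1]
        for samp, klass in self.events:
            if not 0 <= samp < n:
                raise ValueError(f"event sample {samp} outside recording")
            if klass not in CLASSES:
                raise ValueError(f"unknown event class {klass!r}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def drop_channels(self, indices) -> "Recording":
        keep = [i for i in range(self.n_channels) if i not in set(indices)]
        return replace(
            self,
            signal=self.signal[keep],
            channel_labels=[self.channel_labels[i] for i in keep],
            events=list(self.events),
        )


@dataclass
class EpochSet:
    """Fixed-length epochs: trials x channels x samples with per-trial labels."""

    data: np.ndarray
    labels: list[str]
    window: tuple[float, float]
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must match trial count")
        start, end = self.window
        expected = (end - start) * self.fs
        if self.data.shape[0] and abs(self.data.shape[2] - expected) > 1:
            raise ValueError("window length inconsistent with samples per trial")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        labels = [l for l, keep in zip(self.labels, mask) if keep]
        return EpochSet(self.data[mask], labels, self.window, self.fs)

    def by_class(self, klass: str) -> "EpochSet":
        return self.select(np.array([l == klass for l in self.labels]))


def _fir_taps(fs: float, lo: float | None, hi: float | None) -> np.ndarray:
    """Hamming-window FIR taps; transition width 25% of the nearest edge."""
    edges = [e for e in (lo, hi) if e is not None]
    trans = max(min(edges) * 0.25, 1.0)
    numtaps = int(np.ceil(3.3 * fs / trans)) | 1  # odd length, Hamming rule of thumb
    if lo is not None and hi is not None:
        return signal.firwin(numtaps, [lo, hi], pass_zero=False, window="hamming", fs=fs)
    if lo is not None:
        return signal.firwin(numtaps, lo, pass_zero=False, window="hamming", fs=fs)
    return signal.firwin(numtaps, hi, pass_zero=True, window="hamming", fs=fs)


def _check_band(fs: float, lo: float, hi: float) -> None:
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"invalid band edges ({lo}, {hi}) for fs={fs}")


def fir_bandpass(rec: Recording, lo: float, hi: float) -> Recording:
    """Zero-phase Hamming-window FIR band-pass; removes DC by construction."""
    _check_band(rec.fs, lo, hi)
    taps = _fir_taps(rec.fs, lo, hi)
    out = signal.filtfilt(taps, [1.0], rec.signal - rec.signal.mean(axis=1, keepdims=True), axis=1)
    return replace(rec, signal=out, events=list(rec.events))


def fir_highlow(rec: Recording, lo: float = 1.0, hi: float = 40.0) -> Recording:
    """Offline-path filtering: separate Hamming FIR high-pass and low-pass."""
    _check_band(rec.fs, lo, hi)
    x = rec.signal - rec.signal.mean(axis=1, keepdims=True)
    x = signal.filtfilt(_fir_taps(rec.fs, lo, None), [1.0], x, axis=1)
    x = signal.filtfilt(_fir_taps(rec.fs, None, hi), [1.0], x, axis=1)
    return replace(rec, signal=x, events=list(rec.events))


def butter_bandpass(rec: Recording, lo: float, hi: float, order: int = 4,
                    zero_phase: bool = False) -> Recording:
    """4th-order Butterworth band-pass.

    Causal (forward-only) by default, matching the real-time feedback path;
    ``zero_phase=True`` applies it forward-backward for offline use. The
    maximally flat Butterworth design keeps passband attenuation well inside
    0.5 dB away from the band edges.
    """
    _check_band(rec.fs, lo, hi)
    sos = signal.butter(order, [lo, hi], btype="bandpass", output="sos", fs=rec.fs)
    filt = signal.sosfiltfilt if zero_phase else signal.sosfilt
    out = filt(sos, rec.signal, axis=1)
    return replace(rec, signal=np.asarray(out), events=list(rec.events))


def detect_bad_channels(rec: Recording) -> list[int]:
    """Channels whose temporal variance exceeds mean + 3 SD across channels.

    Returns flagged channel indices; the caller decides removal (the manual
    confirmation step of the original pipeline is a hook — default accepts all
    flags via :func:`Recording.drop_channels`).
    """
    if rec.n_channels < 3:
        raise ValueError("need at least 3 channels to estimate the variance distribution")
    v = rec.signal.var(axis=1)
    thresh = v.mean() + 3.0 * v.std()
    if v.std() == 0:
        return []
    return [int(i) for i in np.flatnonzero(v > thresh)]


def epoch(rec: Recording, window: tuple[float, float], classes=CLASSES,
          label: str | None = None) -> EpochSet:
    """Cut epochs around motor-imagery onsets.

    ``window`` is (start_s, end_s) relative to MI onset, half-open
    [start, end). Events whose window would fall outside the recording are
    skipped with a warning. ``label`` overrides the per-event class label
    (used to mark baseline epochs cut at negative offsets).
    """
    start, end = window
    if end <= start:
        raise ValueError("epoch window must have positive length")
    n = int(round((end - start) * rec.fs))
    data, labels = [], []
    skipped = 0
    for samp, klass in rec.events:
        if klass not in classes:
            continue
        i0 = samp + int(round(start * rec.fs))
        i1 = i0 + n
        if i0 < 0 or i1 > rec.n_samples:
            skipped += 1
            continue
        data.append(rec.signal[:, i0:i1])
        labels.append(label if label is not None else klass)
    if skipped:
        warnings.warn(f"skipped {skipped} event(s) too close to the recording edge")
    arr = np.array(data) if data else np.empty((0, rec.n_channels, n))
    logger.info("epoch: %d epochs cut, %d skipped", len(labels), skipped)
    return EpochSet(arr, labels, window, rec.fs)


def fixed_length_epochs(rec: Recording, length_s: float = 1.0) -> EpochSet:
    """Non-overlapping fixed-length segmentation of the continuous data."""
    n = int(round(length_s * rec.fs))
    k = rec.n_samples // n
    data = rec.signal[:, : k * n].reshape(rec.n_channels, k, n).transpose(1, 0, 2)
    return EpochSet(data, ["baseline"] * k, (0.0, length_s), rec.fs)


def reject_threshold(ep: EpochSet, limit_uv: float = 500.0) -> EpochSet:
    """Drop epochs containing any sample with |value| > limit (microvolts)."""
    if limit_uv <= 0:
        raise ValueError("amplitude limit must be positive")
    if ep.n_epochs == 0:
        return ep
    keep = np.abs(ep.data).max(axis=(1, 2)) <= limit_uv
    logger.info("reject_threshold: %d -> %d epochs", ep.n_epochs, int(keep.sum()))
    return ep.select(keep)


def _jointprob_logp(data: np.ndarray, n_bins: int = 100) -> np.ndarray:
    """Per-epoch, per-channel joint log-probability under a histogram density.

    The value distribution of each channel is estimated over all epochs with a
    fixed 100-bin histogram (Laplace smoothing); an epoch's log-probability on
    a channel is the sum of log-densities of its samples.
    """
    n_ep, n_ch, n_s = data.shape
    logp = np.empty((n_ep, n_ch))
    for c in range(n_ch):
        x = data[:, c, :]
        lo, hi = x.min(), x.max()
        if hi <= lo:
            logp[:, c] = 0.0
            continue
        edges = np.linspace(lo, hi, n_bins + 1)
        counts, _ = np.histogram(x, bins=edges)
        dens = (counts + 1.0) / (counts.sum() + n_bins)  # Laplace smoothing
        idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
        logp[:, c] = np.log(dens)[idx].sum(axis=1)
    return logp


def reject_jointprob(ep: EpochSet, local_sd: float = 6.0, global_sd: float = 2.0) -> EpochSet:
    """Joint-probability rejection of improbable epochs (single pass).

    An epoch is rejected if any single channel's joint log-probability deviates
    from the across-epoch mean by more than ``local_sd`` standard deviations,
    or if the all-channel aggregate deviates by more than ``global_sd``.
    """
    if ep.n_epochs < 5:
        raise ValueError("joint-probability rejection needs at least 5 epochs")
    logp = _jointprob_logp(ep.data)
    mu, sd = logp.mean(axis=0), logp.std(axis=0)
    sd[sd == 0] = np.inf
    local_dev = np.abs(logp - mu) / sd
    g = logp.sum(axis=1)
    gsd = g.std() or np.inf
    global_dev = np.abs(g - g.mean()) / gsd
    with np.errstate(invalid="ignore"):
        bad = (local_dev > local_sd).any(axis=1) | (global_dev > global_sd)
    logger.info("reject_jointprob: %d -> %d epochs", ep.n_epochs, int((~bad).sum()))
    return ep.select(~bad)


def offline_preprocess(rec: Recording, lo: float = 1.0, hi: float = 40.0,
                       accept_flags=None) -> Recording:
    """Offline cleaning path: 1-40 Hz FIR filtering plus bad-channel removal.

    ``accept_flags`` is a hook receiving the flagged channel index list and
    returning the subset to actually drop; by default every flag is accepted.
    Epoch-level rejection is applied downstream, on the cut epochs.
    """
    filtered = fir_highlow(rec, lo, hi)
    flags = detect_bad_channels(filtered)
    if accept_flags is not None:
        flags = list(accept_flags(flags))
    if flags:
        logger.info("offline_preprocess: dropping channels %s", flags)
        filtered = filtered.drop_channels(flags)
    return filtered
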