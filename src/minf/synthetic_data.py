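"""Synthetic EEG sessions and FA cohorts with the structure the analysis assumes.

Two generators make every downstream stage testable without any recorded data:

* :func:`generate_eeg_session` builds a continuous multichannel recording of a
  two-class motor-imagery block: two amplitude-modulated mu-band sources with
  fixed lateralized ("C3/C4-like") mixing columns, whose amplitude drops by a
  configurable fraction (event-related desynchronization) during contralateral
  imagery windows, on top of spectrally 1/f channel noise.

* :func:`generate_fa_cohort` builds a subjects x (48 regions + covariates)
  feature table: region FA values around realistic white-matter means, a
  latent aptitude score whose median split defines low/high performers,
  informative regions shifted between groups by a configured Cohen's d, an
  imposed age-fornix FA correlation, and demographic/cognitive covariates.

* :func:`generate_fa_volume_fixture` builds small pre-aligned FA + label
  volumes for the region-extraction stage.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eeg_pipeline import Recording
from .performance import median_split
from .regions import FORNIX, region_names

_TWO_SQRT_2_OVER_PI = 2.0 * np.sqrt(2.0 / np.pi)  # group mean gap of a split N(0,1)


@dataclass
class EEGSimConfig:
    """Conditions of one simulated motor-imagery block.

    Defaults emulate the acquisition this package models: 500 Hz sampling,
    20 trials per hand in quasi-random order, a rest baseline followed by a
    3-s cue and a 5-s imagery period (so the baseline starts 8 s before MI
    onset), an 11 Hz mu rhythm, and 0-4 s inter-trial jitter.
    """

    n_channels: int = 96
    fs: float = 500.0
    n_trials_per_class: int = 20
    trial_layout: tuple[float, float, float, float] = (-8.0, -3.0, 0.0, 5.0)
    mu_freq: float = 11.0
    erd_depth: float = 0.5
    snr: float = 2.0
    inter_trial_jitter: tuple[float, float] = (0.0, 4.0)
    seed: int = 0
    amplitude_uv: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth < 1.0:
            raise ValueError("erd_depth must be in [0, 1)")
        if self.fs <= 2 * 30.0:
            raise ValueError("sampling rate must exceed twice the 30 Hz band edge")
        b0, cue, onset, dur = self.trial_layout
        if not (b0 < cue <= onset and dur > 0):
            raise ValueError("trial windows must be ordered and non-overlapping")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        j0, j1 = self.inter_trial_jitter
        if j0 < 0 or j1 < j0:
            raise ValueError("invalid inter-trial jitter range")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


def _smooth_envelope(n: int, fs: float, rng: np.random.Generator,
                     depth: float = 0.25, cutoff_hz: float = 1.0) -> np.ndarray:
    """Slowly varying positive amplitude envelope around 1."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[f > cutoff_hz] = 0.0
    slow = np.fft.irfft(spec, n)
    sd = slow.std()
    if sd > 0:
        slow = slow / sd
    return np.clip(1.0 + depth * slow, 0.1, None)


def _one_over_f_noise(shape: tuple[int, int], fs: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Channel-independent noise with ~1/f power spectral density."""
    n_ch, n = shape
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** -0.5
    noise = np.fft.irfft(spec * scale, n, axis=1)
    return noise / noise.std(axis=1, keepdims=True)


def _mixing_columns(n_channels: int) -> np.ndarray:
    """Fixed C3/C4-like spatial mixing: Gaussian bumps over the channel axis."""
    idx = np.arange(n_channels)
    width = max(n_channels / 8.0, 1.0)
    a_left = np.exp(-0.5 * ((idx - n_channels / 4.0) / width) ** 2)
    a_right = np.exp(-0.5 * ((idx - 3.0 * n_channels / 4.0) / width) ** 2)
    return np.column_stack([a_left, a_right])  # channels x 2


def generate_eeg_session(cfg: EEGSimConfig, return_sources: bool = False):
    """Simulate one continuous motor-imagery block.

    The left-hemisphere ("C3-like") source is attenuated by (1 - erd_depth)
    during right-hand imagery windows and vice versa. ``snr`` is the linear
    ratio of source amplitude (at the best-coupled channel) to noise amplitude.
    Returns a :class:`Recording`; with ``return_sources=True`` also a dict with
    the pre-mixing source signals, their ERD gain masks, the mixing matrix and
    the trial onset samples.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    b0, _cue, onset_off, mi_dur = cfg.trial_layout
    pre = -b0          # seconds of trial before MI onset
    classes = np.array(["left"] * cfg.n_trials_per_class + ["right"] * cfg.n_trials_per_class)
    rng.shuffle(classes)
    jit = rng.uniform(*cfg.inter_trial_jitter, size=classes.size)

    pad = 1.5          # edge padding so baseline windows and filters stay in bounds
    onsets_s = np.empty(classes.size)
    cursor = pad + pre
    for k in range(classes.size):
        onsets_s[k] = cursor
        cursor += pre + mi_dur + jit[k]
    n = int(round((cursor + pad) * fs))
    t = np.arange(n) / fs

    # two mu-band sources with slow amplitude modulation
    sources = np.empty((2, n))
    gains = np.ones((2, n))
    for s in range(2):
        env = _smooth_envelope(n, fs, rng)
        phase = rng.uniform(0, 2 * np.pi)
        sources[s] = env * np.sin(2 * np.pi * cfg.mu_freq * t + phase)
    for k, klass in enumerate(classes):
        i0 = int(round(onsets_s[k] * fs))
        i1 = int(round((onsets_s[k] + mi_dur) * fs))
        s = 0 if klass == "right" else 1   # contralateral hemisphere
        gains[s, i0:i1] = 1.0 - cfg.erd_depth
    modulated = sources * gains

    mixing = _mixing_columns(cfg.n_channels)
    clean = mixing @ modulated
    source_rms = np.sqrt(np.mean(sources ** 2))
    noise = _one_over_f_noise((cfg.n_channels, n), fs, rng) * (source_rms / cfg.snr)
    signal = cfg.amplitude_uv * (clean + noise)

    events = [(int(round(o * fs)), str(c)) for o, c in zip(onsets_s, classes)]
    labels = [f"ch{i:03d}" for i in range(cfg.n_channels)]
    rec = Recording(signal, fs, labels, events)
    if return_sources:
        return rec, {"sources": sources, "gains": gains, "modulated": modulated,
                     "mixing": mixing, "onsets_s": onsets_s, "classes": classes}
    return rec


@dataclass
class CohortSimConfig:
    """Conditions of one simulated FA cohort.

    ``informative_regions`` maps region names to signed Cohen's d values: the
    standardized FA difference (high minus low performers) realized for that
    region. The fornix-age coupling is imposed exactly on the sampled values.
    """

    n_subjects: int = 21
    region_names: tuple[str, ...] = field(default_factory=region_names)
    informative_regions: dict[str, float] = field(default_factory=dict)
    age_range: tuple[float, float] = (48.0, 77.0)
    age_fa_corr_target: float = -0.49
    age_corr_region: str = FORNIX
    noise_sd: float = 0.04
    include_covariates: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        names = set(self.region_names)
        unknown = set(self.informative_regions) - names
        if unknown:
            raise ValueError(f"informative regions not in region_names: {sorted(unknown)}")
        if self.age_corr_region not in names:
            raise ValueError(f"age-correlated region {self.age_corr_region!r} unknown")
        if not abs(self.age_fa_corr_target) < 1:
            raise ValueError("|age_fa_corr_target| must be < 1")
        for name, d in self.informative_regions.items():
            if not np.isfinite(d):
                raise ValueError(f"effect size for {name!r} must be finite")
        if self.n_subjects < 4:
            raise ValueError("need at least 4 subjects")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _empirical_orthogonal_mix(a: np.ndarray, z: np.ndarray, r: float) -> np.ndarray:
    """Mix z with a so that the *sample* correlation of the result with a is r."""
    a_std = (a - a.mean()) / a.std()
    resid = z - a_std * (z @ a_std) / (a_std @ a_std)
    resid = (resid - resid.mean()) / resid.std()
    return r * a_std + np.sqrt(1.0 - r ** 2) * resid


def _default_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Demographics and CERAD-style cognitive scores of a healthy older cohort."""
    return pd.DataFrame({
        "education": rng.integers(9, 19, size=n),                       # years
        "gender": rng.choice([0, 1], size=n),                            # 1 = female
        "handedness": rng.choice([1, -1, 0], size=n, p=[0.76, 0.14, 0.10]),
        "vf_a": np.round(np.clip(rng.normal(24, 6, n), 5, None)),        # animal fluency
        "vf_s": np.round(np.clip(rng.normal(16, 5, n), 3, None)),        # S-word fluency
        "tmt_a": np.round(np.clip(rng.normal(42, 12, n), 15, None)),     # seconds
        "tmt_b": np.round(np.clip(rng.normal(95, 35, n), 30, None)),     # seconds
    })


def generate_fa_cohort(cfg: CohortSimConfig) -> pd.DataFrame:
    """Simulate a cohort feature table.

    Columns: the 48 region FA means, covariates (age, education, gender,
    handedness, vf_a, vf_s, tmt_a, tmt_b) when enabled, the latent continuous
    ``performance_score``, and the ``label`` ('low'/'high') from its median
    split. All FA values are clipped to (0, 1).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    names = list(cfg.region_names)
    p = len(names)

    base = np.clip(rng.normal(0.5, 0.07, size=p), 0.30, 0.72)
    z = rng.standard_normal((n, p))
    age = rng.uniform(*cfg.age_range, size=n)

    j_age = names.index(cfg.age_corr_region)
    z[:, j_age] = _empirical_orthogonal_mix(age, z[:, j_age], cfg.age_fa_corr_target)

    score = rng.standard_normal(n)
    label = median_split(score)
    g = (label == "high").astype(float) - 0.5
    for name, d in cfg.informative_regions.items():
        z[:, names.index(name)] += d * g     # between-group gap d, within-group SD 1

    fa = np.clip(base + cfg.noise_sd * z, 1e-3, 1.0 - 1e-3)
    table = pd.DataFrame(fa, columns=names)
    table["age"] = np.round(age, 1)
    if cfg.include_covariates:
        cov = _default_covariates(n, rng)
        for c in cov.columns:
            table[c] = cov[c].to_numpy()
    table["performance_score"] = score
    table["label"] = label
    return table


def realized_effect_size(table: pd.DataFrame, region: str) -> float:
    """Two-sample Cohen's d (pooled SD) of a region's FA between label groups."""
    hi = table.loc[table["label"] == "high", region].to_numpy()
    lo = table.loc[table["label"] == "low", region].to_numpy()
    n1, n2 = hi.size, lo.size
    sp = np.sqrt(((n1 - 1) * hi.var(ddof=1) + (n2 - 1) * lo.var(ddof=1)) / (n1 + n2 - 2))
    return float((hi.mean() - lo.mean()) / sp)


def generate_fa_volume_fixture(shape: tuple[int, int, int], regions: dict,
                               seed: int = 0, fa_values: dict | None = None):
    """Small pre-aligned FA and label volumes for the extraction stage.

    ``regions`` maps positive integer labels to voxel masks (boolean arrays of
    ``shape``) or tuples of slices; overlapping regions are rejected.
    ``fa_values`` optionally fixes a region's FA to a scalar or a flat array
    (in mask order); unfixed region voxels draw from U(0.2, 0.9) so that some
    fall below the 0.25 floor, and background voxels from U(0, 0.2).
    """
    shape = tuple(shape)
    if len(shape) != 3 or any(s < 1 for s in shape) or np.prod(shape) > 32 ** 3:
        raise ValueError("shape must be 3-D and at most 32^3 voxels")
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int16)
    fa = rng.uniform(0.0, 0.2, size=shape)
    for lab, spec in regions.items():
        lab = int(lab)
        if lab <= 0:
            raise ValueError("region labels must be positive integers")
        mask = np.zeros(shape, dtype=bool)
        if isinstance(spec, tuple):
            mask[spec] = True
        else:
            mask = np.asarray(spec, dtype=bool)
            if mask.shape != shape:
                raise ValueError("mask shape mismatch")
        if (labels[mask] != 0).any():
            raise ValueError("overlapping label definitions")
        labels[mask] = lab
        if fa_values is not None and lab in fa_values:
            vals = np.asarray(fa_values[lab], dtype=float)
            fa[mask] = vals if vals.ndim == 0 else vals.reshape(-1)
        else:
            fa[mask] = rng.uniform(0.2, 0.9, size=int(mask.sum()))
    if not ((fa >= 0) & (fa <= 1)).all():
        raise ValueError("FA values must lie in [0, 1]")
    return fa, labels


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    """Write a cohort table to CSV with region names verbatim in the header."""
    table.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_volume_nifti(volume: np.ndarray, path) -> None:
    """Write a volume as NIfTI-1 with an identity affine (fixtures are aligned)."""
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(volume), np.eye(4)), str(path))
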