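"""Mean fractional anisotropy per atlas region from pre-aligned volumes.

Volumes are assumed already co-registered (template warping is an external
step); for each integer-labelled atlas region the mean FA is taken over the
voxels of that region whose FA strictly exceeds a floor (default 0.25), which
suppresses partial-volume voxels at white-matter boundaries. Regions with no
qualifying voxel are flagged missing (NaN) rather than silently dropped.
"""

from __future__ import annotations

import logging

import nibabel as nib
import numpy as np
import pandas as pd

from .regions import region_names

logger = logging.getLogger(__name__)


def load_volume(path) -> np.ndarray:
    """Load a NIfTI volume as a float array (nibabel)."""
    return np.asarray(nib.load(str(path)).get_fdata())


def region_mean_fa(fa: np.ndarray, labels: np.ndarray, fa_floor: float = 0.25,
                   names=None) -> dict[str, float]:
    """Mean FA over voxels with label == r and FA > fa_floor, per region.

    ``names`` maps the ordered positive labels 1..48 to region names (defaults
    to the packaged ICBM Mori list). Missing regions (no voxel above the
    floor, or label absent) get NaN.
    """
    fa = np.asarray(fa, dtype=float)
    labels = np.asarray(labels)
    if fa.shape != labels.shape:
        raise ValueError("FA and label volumes must share a grid")
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.allclose(labels, np.round(labels)):
            raise ValueError("label volume must be integer-coded")
        labels = np.round(labels).astype(int)
    if names is None:
        names = region_names()
    out: dict[str, float] = {}
    qualifying = fa > fa_floor  # strict: voxels at exactly the floor are excluded
    for r, name in enumerate(names, start=1):
        mask = (labels == r) & qualifying
        if not mask.any():
            logger.warning("region_mean_fa: region %r flagged missing", name)
            out[name] = float("nan")
        else:
            out[name] = float(fa[mask].mean())
    return out


def region_mean_fa_files(fa_path, label_path, fa_floor: float = 0.25, names=None):
    """File-path convenience wrapper around :func:`region_mean_fa`."""
    return region_mean_fa(load_volume(fa_path), load_volume(label_path), fa_floor, names)


def build_feature_table(region_maps: list[dict[str, float]],
                        covariates: pd.DataFrame | None = None,
                        subject_ids=None) -> pd.DataFrame:
    """Assemble the subjects x (48 regions [+ covariates]) feature table.

    All subjects must share the same region set. If both ``age`` and
    ``education`` covariates are present, the centered-product interaction
    column ``age_x_education`` is added; it is all-zero (non-informative,
    logged) when either variable is constant. Missing region means stay NaN
    and are excluded listwise by downstream modelling, with a logged count.
    """
    if not region_maps:
        raise ValueError("no subjects")
    cols = list(region_maps[0])
    for m in region_maps[1:]:
        if list(m) != cols:
            raise ValueError("inconsistent region sets across subjects")
    table = pd.DataFrame(region_maps, index=subject_ids)
    n_missing = int(table.isna().sum().sum())
    if n_missing:
        logger.warning("build_feature_table: %d missing region cells flagged", n_missing)
    if covariates is not None:
        covariates = covariates.reset_index(drop=True).set_axis(table.index)
        table = pd.concat([table, covariates], axis=1)
        if {"age", "education"} <= set(table.columns):
            age_c = table["age"] - table["age"].mean()
            edu_c = table["education"] - table["education"].mean()
            inter = age_c * edu_c
            if (inter == 0).all():
                logger.warning("age_x_education interaction is all-zero (non-informative)")
            table["age_x_education"] = inter
    return table
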