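"""Voxel-wise kurtosis and skewness maps for distribution-shape diagnosis.

Normative atlases built from mean +/- SD assume per-voxel Gaussian
distributions. Grey-matter proportion data in older cohorts are bounded on
[0, 1] and frequently skewed and leptokurtic, so before trusting a
parametric atlas one maps the third and fourth standardised central moments
at every voxel across the cohort.

Conventions: both moments use population (divide-by-n) normalisation,

    kurtosis = (1/n) * sum_i ((x_i - mu) / sigma)^4
    skewness = (1/n) * sum_i ((x_i - mu) / sigma)^3

with sigma the divide-by-n standard deviation, so that Gaussian data give
kurtosis 3 and skewness 0 exactly in the large-n limit. No small-sample
bias correction is applied. Voxels with zero sample variance have no
defined moments; they are returned as NaN with a companion validity mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .volume_io import CohortStack, VolumeGrid

__all__ = ["MomentMaps", "kurtosis", "skewness", "moment_maps", "UndefinedMomentError"]


class UndefinedMomentError(ValueError):
    """Raised for a scalar sample with zero variance."""


def _standardised_moment(values: np.ndarray, order: int, axis: int = 0) -> np.ndarray:
    """Population standardised central moment along ``axis``.

    Zero-variance slices yield NaN (with the numpy warning suppressed);
    scalar callers convert that to an exception.
    """
    x = np.asarray(values, dtype=float)
    n = x.shape[axis]
    if n < 2:
        raise ValueError("need at least 2 observations")
    mu = x.mean(axis=axis, keepdims=True)
    dev = x - mu
    var = np.mean(dev**2, axis=axis)
    # scale-aware zero-variance cutoff: constant samples accumulate O(eps)
    # round-off in the mean, so compare against the data's magnitude
    scale = np.maximum(np.abs(mu).max(axis=axis), 1.0)
    tiny = (100 * np.finfo(float).eps * scale) ** 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.mean(dev**order, axis=axis) / var ** (order / 2.0)
    return np.where(var > tiny, out, np.nan)


def kurtosis(values: np.ndarray) -> float:
    """Fourth standardised moment of a 1D sample (Gaussian reference: 3).

    The analytic lower bound is 1, attained by symmetric two-point data.
    """
    out = float(_standardised_moment(np.ravel(values), 4))
    if np.isnan(out):
        raise UndefinedMomentError("kurtosis undefined: sample variance is zero")
    return out


def skewness(values: np.ndarray) -> float:
    """Third standardised moment of a 1D sample (Gaussian reference: 0)."""
    out = float(_standardised_moment(np.ravel(values), 3))
    if np.isnan(out):
        raise UndefinedMomentError("skewness undefined: sample variance is zero")
    return out


@dataclass
class MomentMaps:
    """Per-voxel kurtosis and skewness across a cohort.

    ``valid`` is False where the cohort sample had zero variance; there the
    maps hold NaN.
    """

    grid: VolumeGrid
    mask: np.ndarray
    kurtosis: np.ndarray  # (n_mask,)
    skewness: np.ndarray  # (n_mask,)
    valid: np.ndarray  # bool, (n_mask,)
    n_subjects: int
    metadata: dict = field(default_factory=dict)

    def summary(self) -> dict:
        """Cohort-level median and IQR of each map over valid voxels."""
        out: dict[str, float] = {"n_subjects": self.n_subjects,
                                 "n_valid_voxels": int(self.valid.sum()),
                                 "n_undefined_voxels": int((~self.valid).sum())}
        for name, arr in (("kurtosis", self.kurtosis), ("skewness", self.skewness)):
            vals = arr[self.valid]
            if vals.size:
                q25, q50, q75 = np.percentile(vals, [25, 50, 75])
                out[f"{name}_median"] = float(q50)
                out[f"{name}_iqr"] = float(q75 - q25)
            else:
                out[f"{name}_median"] = float("nan")
                out[f"{name}_iqr"] = float("nan")
        return out


def moment_maps(cohort: CohortStack) -> MomentMaps:
    """Compute kurtosis and skewness independently at every in-mask voxel.

    Requires at least 4 subjects (fourth moments need headroom); a warning
    is emitted below 20 where the estimators are still very noisy.
    """
    n = cohort.n_subjects
    if n < 4:
        raise ValueError("moment maps need at least 4 subjects")
    if n < 20:
        warnings.warn(
            f"moment maps from only {n} subjects are noisy; interpret with care",
            stacklevel=2,
        )
    kurt = _standardised_moment(cohort.data, 4, axis=0)
    skew = _standardised_moment(cohort.data, 3, axis=0)
    valid = ~np.isnan(kurt)
    return MomentMaps(
        grid=cohort.grid,
        mask=cohort.mask,
        kurtosis=kurt,
        skewness=skew,
        valid=valid,
        n_subjects=n,
        metadata={"normalisation": "population (divide-by-n)"},
    )
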