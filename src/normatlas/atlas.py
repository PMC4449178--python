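"""Percentile-rank atlases: parametric (mean +/- SD) vs nonparametric (order-based).

A percentile-rank atlas stores, at every in-mask voxel, the cohort values of
an ordered set of percentile ranks (default 2.5, 25, 50, 75, 97.5). Two
estimators are provided:

* **parametric** — Gaussian approximation from the per-voxel mean and
  population SD, with fixed multipliers

      2.5th: mu - 2*sigma    25th: mu - 0.7*sigma    50th: mu
      75th:  mu + 0.7*sigma  97.5th: mu + 2*sigma

  The +/-2 multiplier (rather than the strict 1.96) is the conventional
  generalisable choice for normal limits. Parametric values are *not*
  clamped to [0, 1]: a negative lower limit on a proportion image is
  precisely the failure mode this package exists to expose.

* **nonparametric** — order statistics. With x_1 <= ... <= x_n the sorted
  per-voxel sample and p = t/100 for the t-th percentile, let np = j + g
  (j integer part, g fractional part); the percentile value is
  (x_j + x_{j+1})/2 when g = 0 and x_{j+1} when g > 0. Values therefore
  always lie within the observed sample range — the "true limits" of the
  cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
from scipy import stats

from .volume_io import CohortStack, VolumeGrid

__all__ = [
    "DEFAULT_RANKS",
    "PARAMETRIC_MULTIPLIERS",
    "PercentileAtlas",
    "parametric_percentiles",
    "nonparametric_percentile",
    "build_atlas",
]

DEFAULT_RANKS: tuple[float, ...] = (2.5, 25.0, 50.0, 75.0, 97.5)

#: fixed Gaussian-style multipliers for the five canonical ranks
PARAMETRIC_MULTIPLIERS: dict[float, float] = {
    2.5: -2.0,
    25.0: -0.7,
    50.0: 0.0,
    75.0: 0.7,
    97.5: 2.0,
}

#: absolute tolerance on the fractional part of n*p/100 when deciding g = 0
G_ZERO_ATOL = 1e-9

#: cohort size below which nonparametric extreme ranks are warned unstable
STABILITY_WARN_N = 70


@dataclass
class PercentileAtlas:
    """Per-voxel percentile-rank values for one estimation method."""

    grid: VolumeGrid
    mask: np.ndarray
    ranks: list[float]
    values: np.ndarray  # (n_ranks, n_mask)
    method: str  # "parametric" | "nonparametric"
    n_subjects: int
    extension: bool = False  # True when non-canonical parametric ranks used
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.values = np.asarray(self.values, dtype=float)
        self.ranks = [float(r) for r in self.ranks]
        if self.method not in ("parametric", "nonparametric"):
            raise ValueError(f"unknown atlas method {self.method!r}")
        if any(not (0.0 < r < 100.0) for r in self.ranks):
            raise ValueError("ranks must lie strictly inside (0, 100)")
        if any(b <= a for a, b in zip(self.ranks, self.ranks[1:])):
            raise ValueError("ranks must be strictly increasing")
        if self.values.shape != (len(self.ranks), int(self.mask.sum())):
            raise ValueError("values must be (n_ranks, n_mask_voxels)")

    def rank_values(self, rank: float) -> np.ndarray:
        """Per-voxel atlas values for one percentile rank."""
        try:
            idx = self.ranks.index(float(rank))
        except ValueError:
            raise KeyError(f"rank {rank} not in atlas ranks {self.ranks}") from None
        return self.values[idx]

    @property
    def lower_limit(self) -> np.ndarray:
        """Values of the lowest stored rank (the abnormality threshold)."""
        return self.values[0]


def parametric_percentiles(
    mean: float, sd: float, ranks: Sequence[float] = DEFAULT_RANKS
) -> dict[float, float]:
    """Gaussian-approximation percentile values from a mean and SD.

    The five canonical ranks use the fixed multipliers (-2, -0.7, 0, 0.7, 2);
    other ranks fall back to exact Normal quantile multipliers and mark the
    result as an extension of the canonical scheme.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    out: dict[float, float] = {}
    for r in ranks:
        r = float(r)
        mult = PARAMETRIC_MULTIPLIERS.get(r)
        if mult is None:
            mult = float(stats.norm.ppf(r / 100.0))
        out[r] = mean + mult * sd
    return out


def _np_indices(n: int, p: float) -> tuple[int, bool]:
    """Order-statistic index arithmetic for the t-th percentile.

    Returns ``(j, g_zero)`` where j is the integer part of n*p/100 and
    g_zero marks a (tolerance-checked) integral product.
    """
    if not 0.0 < p < 100.0:
        raise ValueError(f"percentile must be in (0, 100), got {p}")
    np_prod = n * p / 100.0
    nearest = round(np_prod)
    if abs(np_prod - nearest) <= G_ZERO_ATOL:
        return int(nearest), True
    return int(np.floor(np_prod)), False


def nonparametric_percentile(sorted_values: np.ndarray, p: float) -> float:
    """Order-based percentile of an ascending 1D sample.

    Implements the rank rule described in the module docstring, with the
    sample-range edge conventions: indices below x_1 clamp to x_1 and the
    g = 0, j = n case returns x_n.
    """
    x = np.asarray(sorted_values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 sorted values")
    j, g_zero = _np_indices(n, p)
    if g_zero:
        if j <= 0:
            return float(x[0])
        if j >= n:
            return float(x[n - 1])
        return float(0.5 * (x[j - 1] + x[j]))  # (x_j + x_{j+1})/2, 1-based
    # g > 0: y = x_{j+1}; j+1 <= n because n*p/100 < n
    return float(x[min(j, n - 1)])


def _nonparametric_rank_rows(sorted_data: np.ndarray, p: float) -> np.ndarray:
    """Vectorised order-statistic percentile over columns of a sorted matrix."""
    n = sorted_data.shape[0]
    j, g_zero = _np_indices(n, p)
    if g_zero:
        if j <= 0:
            return sorted_data[0].copy()
        if j >= n:
            return sorted_data[n - 1].copy()
        return 0.5 * (sorted_data[j - 1] + sorted_data[j])
    return sorted_data[min(j, n - 1)].copy()


def build_atlas(
    cohort: CohortStack,
    method: str,
    ranks: Sequence[float] = DEFAULT_RANKS,
    stability_warn_n: int = STABILITY_WARN_N,
) -> PercentileAtlas:
    """Build a percentile-rank atlas from a cohort with the chosen estimator.

    Each in-mask voxel is treated independently. Below ``stability_warn_n``
    subjects the extreme nonparametric ranks rest on very few order
    statistics and a warning is emitted.
    """
    if method not in ("parametric", "nonparametric"):
        raise ValueError(f"unknown atlas method {method!r}")
    if cohort.n_voxels == 0:
        raise ValueError("empty mask: no voxels to build an atlas over")
    ranks = [float(r) for r in ranks]
    n = cohort.n_subjects
    if n < stability_warn_n:
        warnings.warn(
            f"atlas built from {n} subjects; percentile values may still "
            f"oscillate below ~{stability_warn_n} subjects",
            stacklevel=2,
        )
    extension = False
    if method == "parametric":
        mu = cohort.data.mean(axis=0)
        sigma = cohort.data.std(axis=0)  # population (divide-by-n) SD
        rows = []
        for r in ranks:
            mult = PARAMETRIC_MULTIPLIERS.get(r)
            if mult is None:
                mult = float(stats.norm.ppf(r / 100.0))
                extension = True
            rows.append(mu + mult * sigma)
        values = np.stack(rows)
    else:
        sorted_data = np.sort(cohort.data, axis=0)
        values = np.stack([_nonparametric_rank_rows(sorted_data, r) for r in ranks])
    return PercentileAtlas(
        grid=cohort.grid,
        mask=cohort.mask,
        ranks=ranks,
        values=values,
        method=method,
        n_subjects=n,
        extension=extension,
        metadata={"sd_normalisation": "population (divide-by-n)"} if method == "parametric" else {},
    )
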