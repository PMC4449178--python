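"""Single-subject classification against a percentile-rank atlas.

Each in-mask voxel of a subject volume is assigned the atlas rank whose
value is nearest to the subject's value (ties break toward the lower rank),
and is called *abnormal* when the subject value falls strictly below the
atlas's lowest stored rank (the 2.5th-percentile normal limit by default).

Because a parametric atlas can place that lower limit below zero while
tissue proportions cannot go negative, the parametric and nonparametric
atlases disagree systematically at the lower limit; the discordance
machinery here tabulates those disagreements per subject and per brain
region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import PercentileAtlas
from .volume_io import LabelVolume, MaskedVolume, VolumeGrid

__all__ = [
    "RankClassification",
    "DiscordanceCategory",
    "DiscordanceReport",
    "assign_rank",
    "classify_subject",
    "discordance",
    "summarize_discordance",
]


class DiscordanceCategory(IntEnum):
    """Per-voxel agreement category between two classifications.

    The two discordant categories are named neutrally by which atlas calls
    the voxel abnormal; no atlas is treated as ground truth.
    """

    CONCORDANT_NORMAL = 0
    CONCORDANT_ABNORMAL = 1
    NORMAL_P_ABNORMAL_NP = 2
    ABNORMAL_P_NORMAL_NP = 3


@dataclass
class RankClassification:
    """Per-voxel nearest-rank assignment and abnormality calls for one subject."""

    grid: VolumeGrid
    mask: np.ndarray
    assigned_rank: np.ndarray  # int codes 1..R ascending, (n_mask,)
    abnormal: np.ndarray  # bool, (n_mask,)
    atlas_method: str
    subject_id: str
    ranks: list[float] = field(default_factory=list)

    @property
    def n_abnormal(self) -> int:
        return int(self.abnormal.sum())


def assign_rank(value: float, rank_values: np.ndarray) -> int:
    """Nearest-rank code (1-based, ascending) for one value.

    Ties on absolute distance break toward the lower rank.
    """
    rv = np.asarray(rank_values, dtype=float)
    if np.any(np.diff(rv) < 0):
        raise ValueError("rank values must be non-decreasing")
    return int(np.argmin(np.abs(rv - value))) + 1


def _assign_ranks_vec(values: np.ndarray, rank_values: np.ndarray) -> np.ndarray:
    """Vectorised nearest-rank assignment, (n_ranks, n_vox) atlas values."""
    dist = np.abs(rank_values - values[None, :])
    # argmin picks the first (= lower) rank on ties
    return np.argmin(dist, axis=0).astype(np.int16) + 1


def classify_subject(
    subject: MaskedVolume, atlas: PercentileAtlas, subject_id: str = ""
) -> RankClassification:
    """Classify a subject volume voxel-by-voxel against an atlas.

    Abnormal means strictly below the atlas's lowest-rank value; equality
    is normal.
    """
    subject.grid.require_match(atlas.grid, context="subject vs atlas")
    if subject.mask.shape != atlas.mask.shape or not np.array_equal(subject.mask, atlas.mask):
        raise ValueError("subject mask does not match atlas mask")
    assigned = _assign_ranks_vec(subject.values, atlas.values)
    abnormal = subject.values < atlas.lower_limit
    return RankClassification(
        grid=subject.grid,
        mask=subject.mask,
        assigned_rank=assigned,
        abnormal=abnormal,
        atlas_method=atlas.method,
        subject_id=subject_id,
        ranks=list(atlas.ranks),
    )


def discordance(
    class_p: RankClassification, class_np: RankClassification
) -> np.ndarray:
    """Per-voxel discordance categories between parametric and nonparametric calls.

    Returns an int array over in-mask voxels using :class:`DiscordanceCategory`
    codes; the four categories partition the mask.
    """
    if class_p.atlas_method != "parametric" or class_np.atlas_method != "nonparametric":
        raise ValueError("expected (parametric, nonparametric) classification pair")
    if class_p.mask.shape != class_np.mask.shape or not np.array_equal(
        class_p.mask, class_np.mask
    ):
        raise ValueError("classifications are on different masks")
    if class_p.subject_id != class_np.subject_id:
        raise ValueError(
            f"classifications are for different subjects: "
            f"{class_p.subject_id!r} vs {class_np.subject_id!r}"
        )
    a_p = class_p.abnormal
    a_np = class_np.abnormal
    cat = np.full(a_p.shape, DiscordanceCategory.CONCORDANT_NORMAL, dtype=np.int8)
    cat[a_p & a_np] = DiscordanceCategory.CONCORDANT_ABNORMAL
    cat[~a_p & a_np] = DiscordanceCategory.NORMAL_P_ABNORMAL_NP
    cat[a_p & ~a_np] = DiscordanceCategory.ABNORMAL_P_NORMAL_NP
    return cat


@dataclass
class DiscordanceReport:
    """Per-subject discordance percentages and pooled regional proportions.

    ``per_subject`` columns:
      pct_normalP_abnormalNP — of the voxels the nonparametric atlas calls
        abnormal, the percentage the parametric atlas calls normal;
      pct_abnormalP_normalNP — of the voxels the parametric atlas calls
        abnormal, the percentage the nonparametric atlas calls normal.
    Subjects with a zero denominator are reported as NaN and excluded from
    the cohort median/IQR (their count is recorded).
    """

    per_subject: pd.DataFrame
    summary: pd.DataFrame  # rows: the two percentages; cols: median, iqr, n
    per_region: pd.DataFrame  # rows: discordance category; cols: region names
    pooling: str = "pooled"  # regional proportions pooled over subjects
    n_excluded: dict[str, int] = field(default_factory=dict)


def summarize_discordance(
    category_maps: Sequence[np.ndarray],
    subject_ids: Sequence[str],
    labels: LabelVolume | None = None,
    mask: np.ndarray | None = None,
    per_subject_regions: bool = False,
) -> DiscordanceReport:
    """Tabulate discordance per subject and (optionally) per region.

    ``category_maps`` are per-subject in-mask category arrays from
    :func:`discordance`. Regional proportions are pooled over subjects by
    default: for each discordant category, the fraction of its voxels
    (summed over all subjects) falling inside each label. With
    ``per_subject_regions`` the per-subject proportions are averaged
    instead. In-mask voxels with label 0 are reported under "unlabelled".
    """
    if len(category_maps) == 0:
        raise ValueError("need at least one subject")
    if len(subject_ids) != len(category_maps):
        raise ValueError("subject_ids must match category_maps")

    rows = []
    for sid, cat in zip(subject_ids, category_maps):
        cat = np.asarray(cat)
        n_np_abn = int(np.sum((cat == DiscordanceCategory.CONCORDANT_ABNORMAL)
                              | (cat == DiscordanceCategory.NORMAL_P_ABNORMAL_NP)))
        n_p_abn = int(np.sum((cat == DiscordanceCategory.CONCORDANT_ABNORMAL)
                             | (cat == DiscordanceCategory.ABNORMAL_P_NORMAL_NP)))
        n_n_ab = int(np.sum(cat == DiscordanceCategory.NORMAL_P_ABNORMAL_NP))
        n_ab_n = int(np.sum(cat == DiscordanceCategory.ABNORMAL_P_NORMAL_NP))
        rows.append({
            "subject_id": sid,
            "n_np_abnormal": n_np_abn,
            "n_p_abnormal": n_p_abn,
            "pct_normalP_abnormalNP": 100.0 * n_n_ab / n_np_abn if n_np_abn else np.nan,
            "pct_abnormalP_normalNP": 100.0 * n_ab_n / n_p_abn if n_p_abn else np.nan,
        })
    per_subject = pd.DataFrame(rows).set_index("subject_id")

    n_excluded = {}
    summary_rows = []
    for col in ("pct_normalP_abnormalNP", "pct_abnormalP_normalNP"):
        vals = per_subject[col].dropna()
        n_excluded[col] = int(per_subject[col].isna().sum())
        if len(vals):
            q25, q50, q75 = np.percentile(vals, [25, 50, 75])
        else:
            q25 = q50 = q75 = np.nan
        summary_rows.append({"measure": col, "median": q50, "iqr": q75 - q25,
                             "n_subjects": len(vals)})
    summary = pd.DataFrame(summary_rows).set_index("measure")

    if labels is not None:
        if mask is None:
            raise ValueError("mask required to locate in-mask voxels in label space")
        label_flat = labels.labels[np.asarray(mask, dtype=bool)]
        legend = {0: "unlabelled", **labels.legend}
        region_ids = sorted(set(int(v) for v in np.unique(label_flat)))
        cat_names = {
            DiscordanceCategory.NORMAL_P_ABNORMAL_NP: "normalP_abnormalNP",
            DiscordanceCategory.ABNORMAL_P_NORMAL_NP: "abnormalP_normalNP",
        }
        region_rows = {}
        for code, name in cat_names.items():
            if per_subject_regions:
                per_subj_props = []
                for cat in category_maps:
                    in_cat = np.asarray(cat) == code
                    tot = int(in_cat.sum())
                    if tot:
                        per_subj_props.append(
                            [np.sum(in_cat & (label_flat == r)) / tot for r in region_ids]
                        )
                props = (np.mean(per_subj_props, axis=0) if per_subj_props
                         else np.full(len(region_ids), np.nan))
            else:
                counts = np.zeros(len(region_ids))
                for cat in category_maps:
                    in_cat = np.asarray(cat) == code
                    for k, r in enumerate(region_ids):
                        counts[k] += np.sum(in_cat & (label_flat == r))
                total = counts.sum()
                props = counts / total if total else np.full(len(region_ids), np.nan)
            region_rows[name] = props
        per_region = pd.DataFrame(
            region_rows, index=[legend.get(r, f"region_{r}") for r in region_ids]
        ).T
    else:
        per_region = pd.DataFrame()

    return DiscordanceReport(
        per_subject=per_subject,
        summary=summary,
        per_region=per_region,
        pooling="per_subject_mean" if per_subject_regions else "pooled",
        n_excluded=n_excluded,
    )
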