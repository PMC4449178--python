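"""Seeded synthetic grey-matter-proportion cohorts.

Generates NIfTI-compatible fixtures with the statistical structure the
atlas method is designed for: values bounded in [0, 1], per-voxel
distributions that differ by region and are deliberately non-Gaussian
(Beta families with region-specific shape pairs — a strongly left-skewed,
leptokurtic "hippocampus-like" region among them), plus disease-like
subjects whose values are reduced in chosen regions.

Voxels are spatially independent by default: the classification method
operates voxel-by-voxel without smoothing, so spatial autocorrelation is
deliberately not emulated. An optional Gaussian smoothing kernel exists
for experiments but is off by default.

The region layout is a brain-ish ellipsoid mask split into four lobe-like
quadrant labels (frontal / temporal / parietal / occipital) with a small
spherical hippocampus-like sublabel embedded in the temporal region.
Everything is driven by one seed; the same spec and seed always produce
byte-identical volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume_io import (
    CohortStack,
    LabelVolume,
    MaskedVolume,
    VolumeGrid,
    write_volume,
)

__all__ = [
    "RegionSpec",
    "CohortSpec",
    "SyntheticCohort",
    "AtrophiedSubjects",
    "beta_moments",
    "make_geometry",
    "generate_normal_cohort",
    "generate_atrophied_subjects",
    "write_cohort",
]

LOBE_LEGEND = {1: "frontal", 2: "temporal", 3: "parietal", 4: "occipital",
               5: "hippocampus"}


@dataclass(frozen=True)
class RegionSpec:
    """Beta(a, b) voxel distribution for one labelled region."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError(f"beta parameters must be positive, got ({self.a}, {self.b})")


#: default per-region shapes: symmetric frontal, mildly left-skewed
#: temporal/parietal, right-skewed occipital, and a strongly left-skewed
#: leptokurtic hippocampus-like region
DEFAULT_REGIONS: dict[int, RegionSpec] = {
    1: RegionSpec(2.0, 2.0),
    2: RegionSpec(4.0, 2.0),
    3: RegionSpec(3.0, 2.0),
    4: RegionSpec(2.0, 3.0),
    5: RegionSpec(5.0, 1.5),
}


@dataclass
class CohortSpec:
    """Everything needed to generate a synthetic cohort reproducibly."""

    shape: tuple[int, int, int] = (32, 32, 32)
    regions: dict[int, RegionSpec] = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    legend: dict[int, str] = field(default_factory=lambda: dict(LOBE_LEGEND))
    n_normal: int = 98
    n_atrophied: int = 10
    atrophy_labels: tuple[int, ...] = (2, 5)  # temporal + hippocampus-like
    severity_range: tuple[float, float] = (0.2, 0.5)
    smoothing_sigma: float = 0.0  # voxels; 0 disables (the default)
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "regions" in d:
            d["regions"] = {int(k): RegionSpec(**v) if isinstance(v, dict)
                            else RegionSpec(*v) for k, v in d["regions"].items()}
        if "legend" in d:
            d["legend"] = {int(k): str(v) for k, v in d["legend"].items()}
        for key in ("shape", "atrophy_labels", "severity_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def beta_moments(a: float, b: float) -> dict[str, float]:
    """Analytic mean, SD, skewness and kurtosis of Beta(a, b)."""
    s = a + b
    mean = a / s
    var = a * b / (s**2 * (s + 1))
    skew = 2 * (b - a) * np.sqrt(s + 1) / ((s + 2) * np.sqrt(a * b))
    excess = (6 * ((a - b) ** 2 * (s + 1) - a * b * (s + 2))
              / (a * b * (s + 2) * (s + 3)))
    return {"mean": mean, "sd": float(np.sqrt(var)), "skewness": float(skew),
            "kurtosis": float(3.0 + excess)}


def make_geometry(spec: CohortSpec) -> tuple[VolumeGrid, np.ndarray, LabelVolume]:
    """Ellipsoid mask + lobe-quadrant labels + hippocampus sphere."""
    shape = tuple(int(s) for s in spec.shape)
    grid = VolumeGrid(shape, np.diag([2.0, 2.0, 2.0, 1.0]))  # 2 mm iso
    idx = np.indices(shape, dtype=float)
    center = (np.asarray(shape, dtype=float) - 1) / 2.0
    semi = np.asarray(shape, dtype=float) * 0.42
    r2 = sum(((idx[k] - center[k]) / semi[k]) ** 2 for k in range(3))
    mask = r2 <= 1.0

    labels = np.zeros(shape, dtype=np.int32)
    ant = idx[1] >= center[1]  # anterior/posterior along axis 1
    sup = idx[2] >= center[2]  # superior/inferior along axis 2
    labels[mask & ant & sup] = 1    # frontal
    labels[mask & ant & ~sup] = 2   # temporal
    labels[mask & ~ant & sup] = 3   # parietal
    labels[mask & ~ant & ~sup] = 4  # occipital

    # hippocampus-like sphere inside the temporal quadrant
    hip_c = center + np.asarray(shape) * np.array([0.0, 0.12, -0.18])
    hip_r = max(2.0, min(shape) * 0.09)
    hip = sum((idx[k] - hip_c[k]) ** 2 for k in range(3)) <= hip_r**2
    labels[mask & hip & (labels == 2)] = 5

    legend = {k: v for k, v in spec.legend.items() if k in np.unique(labels)}
    return grid, mask, LabelVolume(grid, labels, legend)


@dataclass
class SyntheticCohort:
    """A generated normal cohort with its geometry and ground-truth manifest."""

    cohort: CohortStack
    mask_volume: MaskedVolume
    labels: LabelVolume
    manifest: dict

    @property
    def grid(self) -> VolumeGrid:
        return self.cohort.grid


@dataclass
class AtrophiedSubjects:
    """Disease-like subjects plus the ground-truth effect map.

    ``effect_mask`` flags the in-mask voxels whose values were reduced;
    ``severities`` records the per-subject multiplicative reduction.
    """

    cohort: CohortStack
    effect_mask: np.ndarray  # bool, (n_mask,)
    severities: np.ndarray  # (n_subjects,)
    manifest: dict


def _draw_subject(
    rng: np.random.Generator,
    region_flat: np.ndarray,
    regions: dict[int, RegionSpec],
    smoothing_sigma: float,
    mask: np.ndarray,
) -> np.ndarray:
    vals = np.zeros(region_flat.shape, dtype=float)
    for label, rs in regions.items():
        sel = region_flat == label
        if sel.any():
            vals[sel] = rng.beta(rs.a, rs.b, size=int(sel.sum()))
    if smoothing_sigma > 0:
        dense = np.zeros(mask.shape)
        dense[mask] = vals
        dense = ndimage.gaussian_filter(dense, smoothing_sigma)
        vals = np.clip(dense[mask], 0.0, 1.0)
    return vals


def generate_normal_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate the normal (atlas-building) cohort.

    Each subject's in-mask voxels are independent draws from the Beta
    distribution of their region. The manifest records the true region
    parameters and the analytic moments they imply, so downstream moment
    maps can be checked against ground truth.
    """
    if spec.n_normal < 2:
        raise ValueError("need at least 2 normal subjects")
    grid, mask, labels = make_geometry(spec)
    region_flat = labels.labels[mask]
    missing = set(int(v) for v in np.unique(region_flat)) - set(spec.regions)
    if missing:
        raise ValueError(f"no distribution given for labels {sorted(missing)}")
    rng = np.random.default_rng(spec.seed)
    data = np.empty((spec.n_normal, int(mask.sum())))
    for i in range(spec.n_normal):
        data[i] = _draw_subject(rng, region_flat, spec.regions, spec.smoothing_sigma, mask)
    ids = [f"normal_{i:03d}" for i in range(spec.n_normal)]
    manifest = {
        "kind": "synthetic-normal-cohort",
        "seed": spec.seed,
        "n_subjects": spec.n_normal,
        "shape": list(spec.shape),
        "smoothing_sigma": spec.smoothing_sigma,
        "regions": {
            str(k): {"name": spec.legend.get(k, f"region_{k}"),
                     "beta": [rs.a, rs.b], **beta_moments(rs.a, rs.b)}
            for k, rs in spec.regions.items()
        },
    }
    cohort = CohortStack(grid, mask, data, ids)
    mask_vol = MaskedVolume(grid, mask, np.ones(int(mask.sum())))
    return SyntheticCohort(cohort, mask_vol, labels, manifest)


def generate_atrophied_subjects(spec: CohortSpec) -> AtrophiedSubjects:
    """Generate disease-like subjects with region-concentrated reductions.

    Each subject is a fresh normal draw whose values inside the affected
    labels are multiplied by (1 - severity), severity drawn uniformly from
    ``spec.severity_range``; values stay in [0, 1] by construction. Uses a
    seed stream offset from the normal cohort so the two sets are
    independent but jointly reproducible.
    """
    lo, hi = spec.severity_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("severity range must satisfy 0 <= lo <= hi <= 1")
    grid, mask, labels = make_geometry(spec)
    region_flat = labels.labels[mask]
    effect = np.isin(region_flat, np.asarray(spec.atrophy_labels))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    n = spec.n_atrophied
    if n < 2:
        raise ValueError("need at least 2 atrophied subjects")
    data = np.empty((n, int(mask.sum())))
    severities = rng.uniform(lo, hi, size=n)
    for i in range(n):
        vals = _draw_subject(rng, region_flat, spec.regions, spec.smoothing_sigma, mask)
        vals[effect] *= 1.0 - severities[i]
        data[i] = np.clip(vals, 0.0, 1.0)
    ids = [f"atrophy_{i:03d}" for i in range(n)]
    manifest = {
        "kind": "synthetic-atrophied-subjects",
        "seed": spec.seed,
        "n_subjects": n,
        "atrophy_labels": [int(l) for l in spec.atrophy_labels],
        "affected_names": [spec.legend.get(l, f"region_{l}") for l in spec.atrophy_labels],
        "severity_range": [lo, hi],
        "severities": [float(s) for s in severities],
    }
    cohort = CohortStack(grid, mask, data, ids)
    return AtrophiedSubjects(cohort, effect, severities, manifest)


def write_cohort(
    synth: SyntheticCohort,
    outdir: Path | str,
    atrophied: AtrophiedSubjects | None = None,
) -> dict:
    """Write a generated cohort to disk as NIfTI files + JSON manifest.

    Returns the manifest (also written as ``manifest.json``) augmented with
    the relative file names.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = synth.grid
    write_volume(synth.mask_volume.mask.astype(np.uint8), outdir / "mask.nii.gz",
                 grid=grid, dtype=np.uint8)
    write_volume(synth.labels.labels, outdir / "labels.nii.gz", grid=grid,
                 dtype=np.int16)
    files = []
    for i, sid in enumerate(synth.cohort.subject_ids):
        p = outdir / f"{sid}.nii.gz"
        write_volume(synth.cohort.subject(i), p)
        files.append(p.name)
    manifest = dict(synth.manifest)
    manifest["mask"] = "mask.nii.gz"
    manifest["labels"] = "labels.nii.gz"
    manifest["legend"] = {str(k): v for k, v in synth.labels.legend.items()}
    manifest["subjects"] = files
    if atrophied is not None:
        afiles = []
        for i, sid in enumerate(atrophied.cohort.subject_ids):
            p = outdir / f"{sid}.nii.gz"
            write_volume(atrophied.cohort.subject(i), p)
            afiles.append(p.name)
        manifest["atrophied"] = dict(atrophied.manifest)
        manifest["atrophied"]["subjects"] = afiles
        effect_dense = np.zeros(grid.shape, dtype=np.uint8)
        effect_dense[synth.mask_volume.mask] = atrophied.effect_mask.astype(np.uint8)
        write_volume(effect_dense, outdir / "effect_mask.nii.gz", grid=grid,
                     dtype=np.uint8)
        manifest["atrophied"]["effect_mask"] = "effect_mask.nii.gz"
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
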