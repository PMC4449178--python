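"""NIfTI volume I/O and cohort stacking.

All volumes entering an analysis are assumed to live on one shared
"standard space" grid: spatial normalisation happens upstream, and this
module refuses grid mismatches rather than resampling. Grey-matter
proportion images carry voxel values in [0, 1]; values outside that range
(or NaN inside the analysis mask) are rejected by default because the
bounded support of tissue proportions is central to everything downstream.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "MaskedVolume",
    "CohortStack",
    "LabelVolume",
    "GridMismatchError",
    "AtlasFormatError",
    "read_volume",
    "read_mask",
    "read_labels",
    "stack_cohort",
    "write_volume",
    "write_atlas",
    "read_atlas",
]

#: elementwise tolerance when comparing affines of "identical" grids
AFFINE_ATOL = 1e-5


class GridMismatchError(ValueError):
    """Two volumes do not share the same voxel grid (shape + affine)."""


class AtlasFormatError(ValueError):
    """An on-disk atlas bundle is missing or inconsistent."""


@dataclass(frozen=True)
class VolumeGrid:
    """Voxel grid geometry: array shape plus voxel-to-world affine.

    Voxel indices are 0-based C-order internally; the affine maps voxel
    indices to world (scanner) millimetres as in the NIfTI-1 convention.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray  # (4, 4)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be a positive triple, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    def matches(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=AFFINE_ATOL, rtol=0.0
        )

    def require_match(self, other: "VolumeGrid", context: str = "") -> None:
        if not self.matches(other):
            where = f" ({context})" if context else ""
            raise GridMismatchError(
                f"grid mismatch{where}: {self.shape} vs {other.shape}; "
                "inputs must already share one standard space"
            )


@dataclass
class MaskedVolume:
    """A scalar 3D volume restricted to an analysis mask.

    ``values`` holds the in-mask voxels in C-order flat index order; the
    full 3D array can be reconstructed with :meth:`to_dense`.
    """

    grid: VolumeGrid
    mask: np.ndarray  # bool, grid.shape
    values: np.ndarray  # float, (n_mask,)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise GridMismatchError("mask shape does not match grid shape")
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != int(self.mask.sum()):
            raise ValueError(
                f"got {self.values.size} values for {int(self.mask.sum())} mask voxels"
            )

    @property
    def n_voxels(self) -> int:
        return self.values.size

    def to_dense(self, fill: float = 0.0) -> np.ndarray:
        out = np.full(self.grid.shape, fill, dtype=float)
        out[self.mask] = self.values
        return out

    def validate_proportions(self, clamp: bool = False) -> "MaskedVolume":
        """Check (or clamp) grey-matter-proportion bounds [0, 1], no NaN."""
        if np.isnan(self.values).any():
            raise ValueError("NaN inside the analysis mask")
        out_of_range = (self.values < 0.0) | (self.values > 1.0)
        if out_of_range.any():
            if not clamp:
                bad = int(out_of_range.sum())
                raise ValueError(
                    f"{bad} in-mask voxels outside [0, 1]; tissue proportions are "
                    "bounded — pass clamp=True to clip instead"
                )
            self.values = np.clip(self.values, 0.0, 1.0)
        return self


@dataclass
class CohortStack:
    """Subjects x in-mask-voxels matrix sharing one grid and mask."""

    grid: VolumeGrid
    mask: np.ndarray
    data: np.ndarray  # (n_subjects, n_mask)
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("cohort data must be 2D (subjects x voxels)")
        if self.data.shape[0] < 2:
            raise ValueError("a cohort needs at least 2 subjects")
        if self.data.shape[1] != int(self.mask.sum()):
            raise ValueError("data columns do not match mask voxel count")
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("subject_ids length does not match data rows")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def subject(self, i: int) -> MaskedVolume:
        return MaskedVolume(self.grid, self.mask, self.data[i])


@dataclass
class LabelVolume:
    """Integer region labels (e.g. lobes) on the shared grid; 0 = background."""

    grid: VolumeGrid
    labels: np.ndarray  # int, grid.shape
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if self.labels.shape != self.grid.shape:
            raise GridMismatchError("label shape does not match grid shape")
        if (self.labels < 0).any():
            raise ValueError("labels must be non-negative (0 = background)")
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from legend")

    def region_names(self) -> dict[int, str]:
        return dict(self.legend)


def _grid_from_img(img: nib.spatialimages.SpatialImage) -> VolumeGrid:
    return VolumeGrid(tuple(int(s) for s in img.shape[:3]), np.asarray(img.affine))


def _load_3d(path: os.PathLike | str) -> tuple[np.ndarray, VolumeGrid]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise OSError(f"cannot read NIfTI volume {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D scalar volume, got {data.ndim}D")
    return data, _grid_from_img(img)


def read_mask(path: os.PathLike | str) -> MaskedVolume:
    """Read a binary analysis mask; nonzero voxels are in-mask."""
    data, grid = _load_3d(path)
    mask = np.asarray(data) != 0
    return MaskedVolume(grid, mask, np.ones(int(mask.sum())))


def read_labels(
    path: os.PathLike | str, legend: Mapping[int, str] | None = None
) -> LabelVolume:
    """Read an integer region-label volume; legend defaults to label numbers."""
    data, grid = _load_3d(path)
    labels = np.rint(np.asarray(data)).astype(np.int32)
    if legend is None:
        legend = {int(v): f"region_{int(v)}" for v in np.unique(labels) if v != 0}
    return LabelVolume(grid, labels, dict(legend))


def read_volume(
    path: os.PathLike | str,
    mask: MaskedVolume | None = None,
    validate_proportions: bool = False,
    clamp: bool = False,
) -> MaskedVolume:
    """Read a 3D scalar NIfTI volume, optionally restricted to a mask.

    Without a mask every voxel is in-mask. With a mask, the grids must
    match exactly (no resampling is attempted).
    """
    data, grid = _load_3d(path)
    if mask is None:
        vol_mask = np.ones(grid.shape, dtype=bool)
    else:
        grid.require_match(mask.grid, context=str(path))
        vol_mask = mask.mask
    vol = MaskedVolume(grid, vol_mask, np.asarray(data, dtype=float)[vol_mask])
    if validate_proportions:
        vol.validate_proportions(clamp=clamp)
    return vol


def write_volume(
    dense_or_masked: MaskedVolume | np.ndarray,
    path: os.PathLike | str,
    grid: VolumeGrid | None = None,
    dtype: np.dtype | type = np.float32,
) -> None:
    """Write a volume as NIfTI-1; MaskedVolume is densified with 0 fill."""
    if isinstance(dense_or_masked, MaskedVolume):
        arr = dense_or_masked.to_dense()
        grid = dense_or_masked.grid
    else:
        arr = np.asarray(dense_or_masked)
        if grid is None:
            raise ValueError("grid required when writing a bare array")
    img = nib.Nifti1Image(arr.astype(dtype), grid.affine)
    nib.save(img, str(path))


def stack_cohort(
    paths: Sequence[os.PathLike | str],
    mask: MaskedVolume,
    subject_ids: Sequence[str] | None = None,
    validate_proportions: bool = True,
    clamp: bool = False,
) -> CohortStack:
    """Stack co-registered subject volumes into a subjects x voxels matrix.

    Row order follows ``paths``; any grid mismatch aborts naming the
    offending file.
    """
    paths = list(paths)
    if len(paths) < 2:
        raise ValueError("a cohort needs at least 2 volumes")
    if subject_ids is None:
        subject_ids = [Path(p).name.removesuffix(".gz").removesuffix(".nii") for p in paths]
    subject_ids = list(subject_ids)
    if len(subject_ids) != len(paths):
        raise ValueError("subject_ids length does not match paths")
    n_vox = int(mask.mask.sum())
    data = np.empty((len(paths), n_vox), dtype=float)
    for i, p in enumerate(paths):
        vol = read_volume(p, mask=mask, validate_proportions=validate_proportions, clamp=clamp)
        data[i] = vol.values
    return CohortStack(mask.grid, mask.mask, data, subject_ids)


# --- atlas bundle serialisation -------------------------------------------
#
# An atlas bundle is a 4D NIfTI whose 4th axis indexes percentile ranks in
# ascending order, plus a JSON sidecar that is the authority for the rank
# labels, estimation method, and provenance. Values are stored float32.

def write_atlas(atlas, path: os.PathLike | str) -> None:
    """Write a PercentileAtlas as ``<path>.nii.gz`` + ``<path>.json``."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".json" else path
    n_ranks = len(atlas.ranks)
    dense = np.zeros(atlas.grid.shape + (n_ranks,), dtype=np.float32)
    for k in range(n_ranks):
        dense[..., k][atlas.mask] = atlas.values[k].astype(np.float32)
    img = nib.Nifti1Image(dense, atlas.grid.affine)
    nib.save(img, str(base.with_suffix(".nii.gz")))
    mask_img = nib.Nifti1Image(atlas.mask.astype(np.uint8), atlas.grid.affine)
    mask_path = base.parent / (base.name + "_mask.nii.gz")
    nib.save(mask_img, str(mask_path))
    sidecar = {
        "format": "normatlas-percentile-atlas",
        "version": 1,
        "ranks": [float(r) for r in atlas.ranks],
        "method": atlas.method,
        "n_subjects": int(atlas.n_subjects),
        "dtype": "float32",
        "mask_file": mask_path.name,
        "extension": bool(getattr(atlas, "extension", False)),
        "metadata": dict(getattr(atlas, "metadata", {})),
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_atlas(path: os.PathLike | str):
    """Read an atlas bundle written by :func:`write_atlas`."""
    from .atlas import PercentileAtlas  # local import avoids a cycle

    path = Path(path)
    base = path.with_suffix("") if path.suffix in {".json", ".gz"} else path
    if base.suffix == ".nii":
        base = base.with_suffix("")
    nii = base.with_suffix(".nii.gz")
    sidecar_path = base.with_suffix(".json")
    if not sidecar_path.exists():
        raise AtlasFormatError(f"atlas sidecar {sidecar_path} not found")
    if not nii.exists():
        raise AtlasFormatError(f"atlas volume {nii} not found")
    meta = json.loads(sidecar_path.read_text())
    if meta.get("format") != "normatlas-percentile-atlas":
        raise AtlasFormatError(f"{sidecar_path}: not an atlas sidecar")
    img = nib.load(str(nii))
    dense = np.asanyarray(img.dataobj)
    if dense.ndim != 4 or dense.shape[3] != len(meta["ranks"]):
        raise AtlasFormatError("atlas 4th axis does not match sidecar ranks")
    grid = _grid_from_img(img)
    mask_path = base.parent / meta.get("mask_file", base.name + "_mask.nii.gz")
    if not mask_path.exists():
        raise AtlasFormatError(f"atlas mask {mask_path} not found")
    mask_img = nib.load(str(mask_path))
    _grid_from_img(mask_img).require_match(grid, context=str(mask_path))
    mask = np.asanyarray(mask_img.dataobj) != 0
    values = np.stack([dense[..., k][mask] for k in range(dense.shape[3])])
    return PercentileAtlas(
        grid=grid,
        mask=mask,
        ranks=list(map(float, meta["ranks"])),
        values=values.astype(float),
        method=meta["method"],
        n_subjects=int(meta["n_subjects"]),
        extension=bool(meta.get("extension", False)),
        metadata=dict(meta.get("metadata", {})),
    )
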