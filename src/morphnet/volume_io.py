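"""Reading volumes and atlas parcellations, atlas refinement, voxel extraction.

Volumes are expected to be VBM-style outputs (segmented, normalized,
modulated gray-matter maps) already resampled to a common grid; no
resampling or reorientation is performed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

#: regions at or below this voxel count get a small-sample warning
SMALL_REGION_VOXELS = 120


class GridMismatchError(ValueError):
    """Two images that must share a voxel grid do not."""


@dataclass
class VolumeImage:
    """A 3-D gray-matter volume map on a fixed voxel grid."""

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {self.values.ndim}-D")
        n_bad = int(np.size(self.values) - np.isfinite(self.values).sum())
        if n_bad:
            raise ValueError(f"volume contains {n_bad} non-finite voxel(s)")
        if (self.values < 0).any():
            raise ValueError("gray-matter values must be non-negative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.values.astype(np.float64), self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))


@dataclass
class AtlasParcellation:
    """Integer-labelled parcellation (0 = background) on a voxel grid."""

    labels: np.ndarray
    region_ids: list[int]
    region_names: dict[int, str]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3-D atlas, got {self.labels.ndim}-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.asarray(self.labels, dtype=float)
            if not np.allclose(lab, np.round(lab)):
                raise ValueError("atlas labels must be integers")
            self.labels = np.round(lab).astype(np.int32)
        self.region_ids = sorted(int(r) for r in self.region_ids)
        present = set(np.unique(self.labels[self.labels != 0]).tolist())
        unknown = present - set(self.region_ids)
        if unknown:
            raise ValueError(f"atlas contains unknown label(s): {sorted(unknown)}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def region_voxel_counts(self) -> dict[int, int]:
        return {r: int((self.labels == r).sum()) for r in self.region_ids}

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), self.affine), str(path))


@dataclass
class RegionalSample:
    """The gray-matter intensities of all voxels inside one region."""

    region_id: int
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 2:
            raise ValueError(
                f"region {self.region_id} has {self.values.size} voxel(s); need >= 2"
            )
        if not np.isfinite(self.values).all():
            raise ValueError(f"region {self.region_id} contains non-finite values")

    @property
    def n_voxels(self) -> int:
        return int(self.values.size)


def _voxel_size_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(s) for s in np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))


def load_gm_volume(path: str | Path) -> VolumeImage:
    """Load a 3-D gray-matter volume from a NIfTI file.

    Fails loudly on non-3-D images or non-finite voxels rather than
    attempting any repair or reorientation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume, got {data.ndim}-D: {path}")
    data = np.asarray(data, dtype=float)
    n_bad = int(data.size - np.isfinite(data).sum())
    if n_bad:
        raise ValueError(f"{path}: volume contains {n_bad} non-finite voxel(s)")
    return VolumeImage(values=data, voxel_size=_voxel_size_from_affine(img.affine), affine=img.affine)


def read_region_table(path: str | Path) -> dict[int, str]:
    """Read a tab-separated region table with columns id, name[, hemisphere]."""
    table: dict[int, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0].lower() in ("id", "region_id"):
            continue
        table[int(parts[0])] = parts[1] if len(parts) > 1 else str(parts[0])
    if not table:
        raise ValueError(f"empty region table: {path}")
    return table


def load_atlas(
    path: str | Path,
    region_table: Mapping[int, str] | str | Path,
    reference: VolumeImage | None = None,
) -> AtlasParcellation:
    """Load an integer-labelled atlas and validate it against a region table.

    Parameters
    ----------
    path
        NIfTI label image; 0 is background.
    region_table
        Mapping of integer label -> region name, or path to a TSV file.
    reference
        Optional companion volume that must share the atlas grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such atlas file: {path}")
    if not isinstance(region_table, Mapping):
        region_table = read_region_table(region_table)
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj)
    if labels.ndim != 3:
        raise ValueError(f"expected 3-D atlas, got {labels.ndim}-D: {path}")
    if reference is not None and tuple(labels.shape) != tuple(reference.shape):
        raise GridMismatchError(
            f"atlas grid {tuple(labels.shape)} does not match volume grid {tuple(reference.shape)}"
        )
    present = np.unique(labels[labels != 0]).astype(int)
    unknown = sorted(set(present.tolist()) - set(int(k) for k in region_table))
    if unknown:
        raise ValueError(f"atlas contains label(s) not in region table: {unknown}")
    region_ids = sorted(int(k) for k in region_table)
    missing = sorted(set(region_ids) - set(present.tolist()))
    if missing:
        warnings.warn(f"region table ids with no voxels in atlas: {missing}", stacklevel=2)
        region_ids = sorted(present.tolist())
    return AtlasParcellation(
        labels=np.asarray(labels),
        region_ids=region_ids,
        region_names={int(k): str(v) for k, v in region_table.items()},
        voxel_size=_voxel_size_from_affine(img.affine),
        affine=img.affine,
    )


def refine_atlas(
    atlas: AtlasParcellation,
    gm_volume: VolumeImage,
    gm_threshold: float = 0.0,
    neighborhood_mm: float = 2.0,
) -> tuple[AtlasParcellation, dict[int, int]]:
    """Drop labelled voxels with no gray matter in their cubic neighborhood.

    A labelled voxel is retained iff at least one voxel with
    ``gm_volume > gm_threshold`` lies within the closed cubic (Chebyshev)
    neighborhood of radius ``neighborhood_mm``, itself included.  The
    radius is converted to voxel offsets per axis as
    ``floor(neighborhood_mm / voxel_size)``.

    Returns the refined parcellation and per-region removed-voxel counts.
    Raises if any region would be emptied.
    """
    if tuple(atlas.shape) != tuple(gm_volume.shape):
        raise GridMismatchError(
            f"atlas grid {tuple(atlas.shape)} does not match volume grid {tuple(gm_volume.shape)}"
        )
    radii = [int(np.floor(neighborhood_mm / vs)) for vs in atlas.voxel_size]
    gm_mask = gm_volume.values > gm_threshold
    if any(r > 0 for r in radii):
        structure = np.ones(tuple(2 * r + 1 for r in radii), dtype=bool)
        reach = ndimage.binary_dilation(gm_mask, structure=structure)
    else:
        reach = gm_mask
    new_labels = np.where(reach, atlas.labels, 0)
    removed: dict[int, int] = {}
    for r in atlas.region_ids:
        before = int((atlas.labels == r).sum())
        after = int((new_labels == r).sum())
        removed[r] = before - after
        if before > 0 and after == 0:
            name = atlas.region_names.get(r, str(r))
            raise ValueError(f"refinement emptied region {r} ({name})")
    refined = AtlasParcellation(
        labels=new_labels,
        region_ids=atlas.region_ids,
        region_names=atlas.region_names,
        voxel_size=atlas.voxel_size,
        affine=atlas.affine,
    )
    return refined, removed


def extract_region_samples(
    volume: VolumeImage,
    atlas: AtlasParcellation,
    include_zero_voxels: bool = True,
) -> list[RegionalSample]:
    """Collect the voxel intensities of every region, in region_ids order.

    Emits a warning for regions at or below the small-sample guidance of
    120 voxels (KDE quality degrades for small samples).  Voxels valued
    exactly 0 inside a retained region are included unless
    ``include_zero_voxels`` is False.
    """
    if tuple(atlas.shape) != tuple(volume.shape):
        raise GridMismatchError(
            f"atlas grid {tuple(atlas.shape)} does not match volume grid {tuple(volume.shape)}"
        )
    samples: list[RegionalSample] = []
    for r in atlas.region_ids:
        vals = volume.values[atlas.labels == r]
        if not include_zero_voxels:
            vals = vals[vals != 0]
        if vals.size <= SMALL_REGION_VOXELS:
            warnings.warn(
                f"region {r} has {vals.size} voxels (<= {SMALL_REGION_VOXELS}); "
                "density estimates may be unstable for small samples",
                stacklevel=2,
            )
        samples.append(
            RegionalSample(region_id=r, values=vals, name=atlas.region_names.get(r, str(r)))
        )
    return samples
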