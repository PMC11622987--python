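"""Atlas-labelled volume I/O and region condensation.

A preprocessed scan registered to an integer-labelled parcellation (for the
full pipeline, the 116-region AAL template) is the unit of input.  Each
atlas region's voxel data is pulled out as an ``np_i x nrt`` value matrix
(``nrt = 1`` for structural MRI) and condensed into a fixed-size square
array — three channels for fMRI, one for MRI — by flattening, zero-padding
to the next admissible side length, and reshaping.  The side is the smallest
multiple of 10 whose square (times the channel count) covers the value
count, e.g. 1,000 voxels x 140 time points -> 220 x 220 x 3 and 1,500 voxels
-> 40 x 40 x 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "LabeledVolume",
    "AtlasMap",
    "RegionArray",
    "extract_region",
    "side_length",
    "make_region_array",
    "unmake_region_array",
    "load_volume",
    "load_atlas",
    "save_volume",
    "save_atlas",
]


@dataclass
class LabeledVolume:
    """A preprocessed 3-D (MRI) or 4-D (fMRI, trailing time axis) scan."""

    grid: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    modality: str = "MRI"

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.modality not in ("MRI", "fMRI"):
            raise ValueError(f"modality must be 'MRI' or 'fMRI', got {self.modality!r}")
        expected_ndim = 4 if self.modality == "fMRI" else 3
        if self.grid.ndim != expected_ndim:
            raise ValueError(
                f"{self.modality} volume must be {expected_ndim}-D, got {self.grid.ndim}-D"
            )
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("volume contains non-finite values")
        if self.modality == "fMRI" and self.grid.shape[-1] < 2:
            raise ValueError("fMRI time axis must have length >= 2")

    @property
    def spatial_shape(self) -> tuple:
        return self.grid.shape[:3]

    @property
    def nrt(self) -> int:
        """Number of time points (1 for structural MRI)."""
        return self.grid.shape[-1] if self.modality == "fMRI" else 1


@dataclass
class AtlasMap:
    """Integer label volume (0 = background) plus a label -> name table."""

    labels: np.ndarray
    names: dict
    k: int = 0

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if self.k == 0:
            self.k = int(self.labels.max())
        present = np.unique(self.labels)
        if present.min() < 0 or present.max() > self.k:
            raise ValueError(f"labels must lie in [0, {self.k}]")

    def region_name(self, region_id: int) -> str:
        return self.names.get(region_id, f"region_{region_id}")

    def voxel_count(self, region_id: int) -> int:
        return int(np.count_nonzero(self.labels == region_id))


@dataclass
class RegionArray:
    """Square condensed array for one region, with padding provenance."""

    data: np.ndarray          # side x side x channels
    region_id: int
    side: int
    pad_count: int
    modality: str = "MRI"
    n_values: int = 0         # source value count before padding


def extract_region(volume: LabeledVolume, atlas: AtlasMap, region_id: int) -> np.ndarray:
    """Pull one region's values as an ``np_i x nrt`` matrix.

    Rows are voxels in z-major raster order (index order of the label grid),
    columns are time points (a single column for MRI).
    """
    if not (1 <= region_id <= atlas.k):
        raise ValueError(f"region_id must be in [1, {atlas.k}], got {region_id}")
    if volume.spatial_shape != atlas.labels.shape:
        raise ValueError(
            f"volume spatial shape {volume.spatial_shape} does not match "
            f"atlas shape {atlas.labels.shape}"
        )
    mask = atlas.labels == region_id
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"region {region_id} ({atlas.region_name(region_id)}) is empty")
    # boolean fancy indexing follows C order == z-major raster scan
    if volume.modality == "fMRI":
        return volume.grid[mask]          # n x nrt
    return volume.grid[mask][:, None]     # n x 1


def side_length(total_values: int, channels: int, granularity: int = 10) -> int:
    """Smallest multiple of `granularity` s with s^2 * channels >= total_values."""
    if total_values < 1:
        raise ValueError("total_values must be positive")
    if channels not in (1, 3):
        raise ValueError("channels must be 1 or 3")
    s = math.sqrt(total_values / channels)
    side = max(granularity, int(math.ceil(s / granularity)) * granularity)
    return side


def make_region_array(
    values: np.ndarray,
    channels: int,
    region_id: int = 0,
    modality: str = "MRI",
    granularity: int = 10,
    min_side: int | None = None,
) -> RegionArray:
    """Flatten row-major, zero-pad to side^2*channels, reshape to side x side x channels.

    ``min_side`` forces a larger (dataset-uniform) side than the per-region
    sizing rule requires, so that every region of a cohort shares one raster
    layout; extra cells are zero padding like any other.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot condense an empty value matrix")
    if not np.all(np.isfinite(values)):
        raise ValueError("values contain non-finite entries")
    flat = values.ravel(order="C")
    side = side_length(flat.size, channels, granularity=granularity)
    if min_side is not None:
        side = max(side, min_side)
    total = side * side * channels
    pad = total - flat.size
    data = np.concatenate([flat, np.zeros(pad)]).reshape(side, side, channels)
    return RegionArray(
        data=data,
        region_id=region_id,
        side=side,
        pad_count=pad,
        modality=modality,
        n_values=flat.size,
    )


def unmake_region_array(arr: RegionArray, n_rows: int | None = None) -> np.ndarray:
    """Invert :func:`make_region_array` up to padding (round-trip check)."""
    flat = arr.data.ravel(order="C")[: arr.n_values]
    if n_rows is not None:
        return flat.reshape(n_rows, -1)
    return flat


# ---- file I/O ----------------------------------------------------------

def load_volume(path: str | Path, modality: str = "MRI") -> LabeledVolume:
    img = nib.load(str(path))
    grid = np.asarray(img.get_fdata(), dtype=np.float64)
    zooms = img.header.get_zooms()[:3]
    return LabeledVolume(grid=grid, voxel_size=tuple(float(z) for z in zooms),
                         affine=np.asarray(img.affine), modality=modality)


def save_volume(vol: LabeledVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(vol.grid, vol.affine), str(path))


def load_atlas(label_path: str | Path, names_path: str | Path | None = None) -> AtlasMap:
    """Load an integer label NIfTI and an optional TSV (columns: label, name)."""
    img = nib.load(str(label_path))
    labels = np.asarray(img.get_fdata()).round().astype(np.int64)
    names: dict = {}
    if names_path is not None:
        tab = pd.read_csv(names_path, sep="\t")
        names = dict(zip(tab["label"].astype(int), tab["name"].astype(str)))
    return AtlasMap(labels=labels, names=names)


def save_atlas(atlas: AtlasMap, label_path: str | Path, names_path: str | Path | None = None) -> None:
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), np.eye(4)), str(label_path))
    if names_path is not None:
        pd.DataFrame(
            {"label": sorted(atlas.names), "name": [atlas.names[i] for i in sorted(atlas.names)]}
        ).to_csv(names_path, sep="\t", index=False)
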