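"""Synthetic atlas-labelled MRI/fMRI generator.

Produces small, fully in-memory datasets with the class-conditional
structure the pipeline is designed to detect:

* a contiguous Voronoi parcellation of a cubic grid into k regions;
* fMRI: every voxel's series is its region's latent series plus white
  noise; for each class-designated coupled region pair the two latents
  share a common component so their correlation is exactly rho (shared-
  latent construction: l_i = sqrt(rho) * z_common + sqrt(1-rho) * z_i);
* MRI: region intensities are a base level plus a class-specific shift in
  designated "atrophic" regions, plus noise.

Defaults (24^3 grid, 12 regions, 3 classes, 140 time points, rho = 0.8,
noise sd 0.5) keep the full pipeline runnable in minutes on one CPU while
emulating the class-dependent functional coupling / regional atrophy the
method assumes.  No hemodynamics, scanner artefacts or drift are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .atlas_io import AtlasMap, LabeledVolume, save_atlas, save_volume
from .regional_association import RegionPair

__all__ = ["SyntheticSpec", "make_atlas", "simulate_fmri", "simulate_mri",
           "simulate_dataset", "write_dataset"]


def _default_coupled_pairs():
    # distinct coupled pair sets per class
    return {
        0: [RegionPair(1, 2), RegionPair(3, 4)],
        1: [RegionPair(5, 6), RegionPair(7, 8)],
        2: [RegionPair(9, 10), RegionPair(11, 12)],
    }


def _default_atrophy():
    # class -> {region: mean intensity shift}
    return {0: {}, 1: {2: -1.0}, 2: {2: -2.0, 5: -1.0}}


@dataclass
class SyntheticSpec:
    grid_size: int = 24
    k: int = 12
    classes: int = 3
    nrt: int = 140
    coupled_pairs: dict = field(default_factory=_default_coupled_pairs)
    rho: float = 0.8
    atrophy: dict = field(default_factory=_default_atrophy)
    base_intensity: float = 10.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("need at least 2 regions")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [0, 1]")
        for pairs in self.coupled_pairs.values():
            for p in pairs:
                if p.j > self.k:
                    raise ValueError(f"coupled pair {p} outside [1, {self.k}]")


def make_atlas(spec: SyntheticSpec) -> AtlasMap:
    """Voronoi parcellation around seeded centroids; every region nonempty."""
    n = spec.grid_size
    if spec.k > n ** 3 // 8:
        raise ValueError(f"k={spec.k} infeasible for a {n}^3 grid")
    rng = np.random.default_rng(spec.seed)
    centroids = rng.uniform(0, n, size=(spec.k, 3))
    zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    coords = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3).astype(float)
    d2 = ((coords[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=-1)
    labels = (d2.argmin(axis=1) + 1).reshape(n, n, n).astype(np.int64)
    # Voronoi cells of interior seeds are nonempty by construction; verify anyway
    present = set(np.unique(labels))
    missing = set(range(1, spec.k + 1)) - present
    for m in sorted(missing):  # pragma: no cover - vanishingly unlikely
        flat = labels.ravel()
        counts = np.bincount(flat, minlength=spec.k + 1)
        donor = counts.argmax()
        flat[np.flatnonzero(flat == donor)[0]] = m
    names = {i: f"synthetic_region_{i}" for i in range(1, spec.k + 1)}
    return AtlasMap(labels=labels, names=names, k=spec.k)


def _region_latents(spec: SyntheticSpec, class_id: int, rng) -> np.ndarray:
    """k x nrt latent series with exact-rho coupling for the class's pairs."""
    lat = rng.standard_normal((spec.k, spec.nrt))
    for pair in spec.coupled_pairs.get(class_id, []):
        common = rng.standard_normal(spec.nrt)
        a, b = np.sqrt(spec.rho), np.sqrt(1.0 - spec.rho)
        lat[pair.i - 1] = a * common + b * rng.standard_normal(spec.nrt)
        lat[pair.j - 1] = a * common + b * rng.standard_normal(spec.nrt)
    return lat


def simulate_fmri(spec: SyntheticSpec, class_id: int, atlas: AtlasMap | None = None,
                  seed: int | None = None) -> LabeledVolume:
    """One 4-D scan: voxel series = region latent + N(0, noise_sd^2) noise."""
    if not (0 <= class_id < spec.classes):
        raise ValueError(f"class_id must be in [0, {spec.classes})")
    if atlas is None:
        atlas = make_atlas(spec)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    lat = _region_latents(spec, class_id, rng)
    n = spec.grid_size
    grid = np.zeros((n, n, n, spec.nrt))
    for region in range(1, spec.k + 1):
        mask = atlas.labels == region
        nv = int(mask.sum())
        grid[mask] = lat[region - 1] + spec.noise_sd * rng.standard_normal((nv, spec.nrt))
    return LabeledVolume(grid=grid, modality="fMRI")


def simulate_mri(spec: SyntheticSpec, class_id: int, atlas: AtlasMap | None = None,
                 seed: int | None = None) -> LabeledVolume:
    """One 3-D scan: region intensity = base + class-specific shift + noise."""
    if not (0 <= class_id < spec.classes):
        raise ValueError(f"class_id must be in [0, {spec.classes})")
    if atlas is None:
        atlas = make_atlas(spec)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    shifts = spec.atrophy.get(class_id, {})
    n = spec.grid_size
    grid = np.zeros((n, n, n))
    for region in range(1, spec.k + 1):
        mask = atlas.labels == region
        level = spec.base_intensity + shifts.get(region, 0.0)
        grid[mask] = level + spec.noise_sd * rng.standard_normal(int(mask.sum()))
    return LabeledVolume(grid=grid, modality="MRI")


def simulate_dataset(spec: SyntheticSpec, n_per_class: int, modality: str = "fMRI",
                     seed: int | None = None):
    """(atlas, volumes, labels) for a balanced multi-class cohort."""
    atlas = make_atlas(spec)
    base = spec.seed if seed is None else seed
    volumes, labels = [], []
    sim = simulate_fmri if modality == "fMRI" else simulate_mri
    for c in range(spec.classes):
        for s in range(n_per_class):
            volumes.append(sim(spec, c, atlas=atlas, seed=base + 1000 * c + s + 1))
            labels.append(c)
    return atlas, volumes, np.array(labels)


def write_dataset(spec: SyntheticSpec, n_per_class: int, out_dir: str | Path,
                  modality: str = "fMRI", seed: int | None = None) -> Path:
    """Write NIfTI volumes + atlas NIfTI + label TSVs under ``out_dir``."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas, volumes, labels = simulate_dataset(spec, n_per_class, modality, seed)
    save_atlas(atlas, out / "atlas.nii.gz", out / "atlas_labels.tsv")
    rows = []
    for idx, (vol, lab) in enumerate(zip(volumes, labels)):
        name = f"subject_{idx:03d}.nii.gz"
        save_volume(vol, out / name)
        rows.append({"subject": name, "label": int(lab), "modality": modality})
    pd.DataFrame(rows).to_csv(out / "subjects.tsv", sep="\t", index=False)
    return out
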