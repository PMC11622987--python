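"""End-to-end orchestration: volumes -> region features -> pair scores ->
classifier -> metrics and saliency.

Stage order follows the block design: an optional heterogeneous feature
stage transforms the data, regions are extracted and condensed through the
backbone encoders, all-pair regional association scores are assembled into
a pair-score image, and the transformer head classifies it.  The repeated
random-split protocol evaluates the whole chain.
"""

from __future__ import annotations

import numpy as np

from . import transforms
from .atlas_io import AtlasMap, LabeledVolume, extract_region, make_region_array
from .backbones import Backbone, BackboneSpec, DEFAULT_FAMILIES
from .classifier import ViTConfig, gradient_rollout, train_two_phase
from .evaluation import SplitPlan, confusion_from_labels, make_splits
from .regional_association import enumerate_pairs, proxy_label

__all__ = [
    "region_value_matrices",
    "condense_subjects",
    "compute_proxies",
    "run_repeated_splits",
]


def region_value_matrices(volume: LabeledVolume, atlas: AtlasMap,
                          stage: str = "NT") -> list:
    """Per-region value matrices after the selected feature stage.

    ``NT`` extracts raw voxel values.  ``WT`` extracts from the level-1
    wavelet approximation (atlas downsampled to match).  Vector-valued
    stages (``GLCM``, ``RROI``, ``ST``, custom) are applied per region to
    the region's bounding-box block (temporal mean for fMRI) and the
    resulting descriptor becomes the region's value column.
    """
    fn = transforms.get_transform(stage)  # raises with available stages listed
    if stage == "NT":
        return [extract_region(volume, atlas, r) for r in range(1, atlas.k + 1)]

    if stage == "WT":
        def approx(grid3d):
            pad = [(0, s % 2) for s in grid3d.shape]
            g = np.pad(grid3d, pad)
            return transforms.dwt3d(g, levels=1).approximation

        small_labels = atlas.labels[::2, ::2, ::2]
        small_atlas = AtlasMap(labels=small_labels, names=atlas.names, k=atlas.k)
        if volume.modality == "fMRI":
            frames = [approx(volume.grid[..., t]) for t in range(volume.grid.shape[-1])]
            grid = np.stack(frames, axis=-1)
            shp = small_labels.shape
            vol2 = LabeledVolume(grid=grid[: shp[0], : shp[1], : shp[2]], modality="fMRI")
        else:
            grid = approx(volume.grid)
            shp = small_labels.shape
            vol2 = LabeledVolume(grid=grid[: shp[0], : shp[1], : shp[2]], modality="MRI")
        out = []
        for r in range(1, atlas.k + 1):
            if small_atlas.voxel_count(r) == 0:
                out.append(np.zeros((1, vol2.nrt if vol2.modality == "fMRI" else 1)))
            else:
                out.append(extract_region(vol2, small_atlas, r))
        return out

    # per-region vector stages
    grid3d = volume.grid.mean(axis=-1) if volume.modality == "fMRI" else volume.grid
    mats = []
    for r in range(1, atlas.k + 1):
        mask = atlas.labels == r
        if not mask.any():
            raise ValueError(f"region {r} is empty")
        zs, ys, xs = np.nonzero(mask)
        block = grid3d[zs.min():zs.max() + 1, ys.min():ys.max() + 1, xs.min():xs.max() + 1]
        vec = np.asarray(fn(block), dtype=np.float64).ravel()
        mats.append(vec[:, None])
    return mats


def condense_subjects(volumes, atlas: AtlasMap, families=DEFAULT_FAMILIES,
                      stage: str = "NT", seed: int = 0, widths=None,
                      uniform_side: bool = True):
    """Condensed features: list per family of (n_subjects, k, 256) arrays.

    With ``uniform_side`` (default) every region array of the cohort is
    padded to the maximum side the sizing rule assigns, so all regions share
    one raster layout and the backbone projections are comparable across
    regions.  Also returns the per-subject regional mean time series (or
    mean intensities) used for similarity proxies.
    """
    from .atlas_io import side_length

    backbones = [Backbone(BackboneSpec(family=f, seed=seed, widths=widths))
                 for f in families]
    n = len(volumes)
    feats = [np.zeros((n, atlas.k, 256)) for _ in families]

    min_side = None
    if uniform_side:
        # region sizes depend only on the atlas and the stage, not the subject
        mats0 = region_value_matrices(volumes[0], atlas, stage=stage)
        channels0 = 3 if volumes[0].modality == "fMRI" else 1
        min_side = max(side_length(m.size, channels0) for m in mats0)

    mean_series = []
    for s, vol in enumerate(volumes):
        mats = region_value_matrices(vol, atlas, stage=stage)
        mean_series.append(np.stack([m.mean(axis=0) if m.ndim == 2 else m
                                     for m in mats]))
        channels = 3 if vol.modality == "fMRI" else 1
        for r, mat in enumerate(mats):
            arr = make_region_array(mat, channels=channels, region_id=r + 1,
                                    modality=vol.modality, min_side=min_side)
            for b, bb in enumerate(backbones):
                feats[b][s, r] = bb.condense(arr)
    return feats, mean_series


def compute_proxies(mean_series, modality: str, k: int,
                    features: np.ndarray | None = None) -> np.ndarray:
    """(n_subjects, n_pairs) proxy targets in enumerate_pairs order."""
    pairs = enumerate_pairs(k)
    n = len(mean_series)
    out = np.zeros((n, len(pairs)))
    for s in range(n):
        for pi, pair in enumerate(pairs):
            if modality == "fMRI":
                out[s, pi] = proxy_label(mean_series[s][pair.i - 1],
                                         mean_series[s][pair.j - 1], "fMRI")
            else:
                out[s, pi] = proxy_label(features[s, pair.i - 1],
                                         features[s, pair.j - 1], "MRI")
    return out


def run_repeated_splits(features, proxies, labels, vit_config: ViTConfig,
                        plan: SplitPlan, seed: int = 0, **train_kw) -> dict:
    """Train/evaluate over the repeated random-split protocol.

    Returns per-repeat test accuracies, mean accuracy, and the last trained
    model for inspection.
    """
    labels = np.asarray(labels)
    splits = make_splits(labels, plan, seed=seed)
    accs, model, images = [], None, None
    for rep, (train, val, test) in enumerate(splits):
        ds = {
            "features": [f[train] for f in features],
            "proxy_targets": proxies[train],
            "labels": labels[train],
        }
        model, ra_nets, _, logs = train_two_phase(ds, vit_config,
                                                  seed=seed + rep, **train_kw)
        # score the test subjects through the trained RA nets
        from .regional_association import assemble_channels, score_all_pairs

        k = features[0].shape[1]
        pairs = enumerate_pairs(k)
        chans = [score_all_pairs(nets, feat[test], pairs)
                 for nets, feat in zip(ra_nets, features)]
        images = np.stack([assemble_channels([c[i] for c in chans], k)
                           for i in range(len(test))])
        preds = model.predict(images)
        accs.append(float((preds == labels[test]).mean()))
    return {"accuracies": accs, "mean_accuracy": float(np.mean(accs)),
            "model": model, "last_test_images": images,
            "last_test_labels": labels[test], "last_ra_nets": ra_nets}
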