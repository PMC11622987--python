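"""Multi-trait condensed feature extraction backbones.

Three configurable convolutional encoder families (Alex-style, VGG-style,
ResNet-style), each ending in a single 256-unit dense block, map a condensed
region array (side x side x channels) to a 256-vector.  The number of
stride-2 downsampling steps adapts to the input side (largest count of
halvings that keeps the spatial side >= 4), so arbitrarily sized region
arrays condense to the same feature length.

Weights are He-normal, drawn once from a seeded generator and then fixed:
the encoders act as deterministic random-projection feature extractors
(training happens downstream, in the regional association networks and the
classifier head).  Two consequences of that frozen regime shape the
defaults:

* the dense block sits on the *flattened* final feature map (as in the
  named families), not on a global average — global pooling is a spatial
  low-pass, and in the condensed raster layout time is the fastest axis, so
  spatial averaging averages over time and erases inter-regional coupling
  information that the downstream association networks need;
* downsampling defaults to stride-2 decimation (subsampling) for the same
  reason; classic max or average pooling are available via ``pool``.

Stage widths are deliberately scaled-down renditions of the named families
and fully config-driven.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas_io import RegionArray

__all__ = ["BackboneSpec", "Backbone", "adapt_pooling", "condense", "DEFAULT_FAMILIES"]

DEFAULT_FAMILIES = ("alex", "vgg", "resnet")

_DEFAULT_WIDTHS = {
    "alex": (8, 16, 32),
    "vgg": (8, 16, 32),
    "resnet": (8, 16, 32),
}


@dataclass
class BackboneSpec:
    family: str = "alex"
    widths: tuple = None
    output_dim: int = 256
    seed: int = 0
    min_side: int = 4
    pool: str = "decimate"   # {"decimate", "max", "avg"}

    def __post_init__(self):
        if self.family not in DEFAULT_FAMILIES:
            raise ValueError(f"family must be one of {DEFAULT_FAMILIES}")
        if self.widths is None:
            self.widths = _DEFAULT_WIDTHS[self.family]
        if self.output_dim != 256:
            raise ValueError("output_dim is fixed at 256")
        if self.pool not in ("decimate", "max", "avg"):
            raise ValueError("pool must be 'decimate', 'max' or 'avg'")


def adapt_pooling(input_side: int, spec: BackboneSpec | None = None) -> int:
    """Largest number of stride-2 halvings leaving the spatial side >= min_side."""
    min_side = spec.min_side if spec is not None else 4
    count, side = 0, input_side
    while side // 2 >= min_side:
        side //= 2
        count += 1
    return count


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int = 1) -> np.ndarray:
    """Same-padded 2-D convolution; x: H x W x Cin, w: k x k x Cin x Cout.

    ``stride=2`` evaluates only at even positions (identical to computing the
    full map and decimating, but 4x cheaper).
    """
    k = w.shape[0]
    pad = k // 2
    H, W, Cin = x.shape
    xp = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
    Ho = (H + stride - 1) // stride
    Wo = (W + stride - 1) // stride
    cols = np.empty((Ho, Wo, k * k * Cin))
    idx = 0
    for di in range(k):
        for dj in range(k):
            cols[..., idx * Cin:(idx + 1) * Cin] = \
                xp[di:di + H:stride, dj:dj + W:stride, :]
            idx += 1
    out = cols.reshape(Ho * Wo, -1) @ w.reshape(-1, w.shape[-1]) + b
    return out.reshape(Ho, Wo, -1)


def _downsample(x: np.ndarray, mode: str) -> np.ndarray:
    if mode == "decimate":
        return x[::2, ::2]
    H, W, C = x.shape
    H2, W2 = H // 2, W // 2
    x = x[: 2 * H2, : 2 * W2]
    blocks = x.reshape(H2, 2, W2, 2, C)
    return blocks.max(axis=(1, 3)) if mode == "max" else blocks.mean(axis=(1, 3))


class Backbone:
    """One seeded encoder instance; weights fixed after construction."""

    def __init__(self, spec: BackboneSpec):
        self.spec = spec
        self._convs: dict = {}    # keyed by input channel count
        self._dense: dict = {}    # keyed by flattened feature dimension

    def _conv_stack(self, in_channels: int) -> list:
        rng = np.random.default_rng((self.spec.seed, 7919, in_channels,
                                     DEFAULT_FAMILIES.index(self.spec.family)))
        layers = []
        cin = in_channels
        for si, cout in enumerate(self.spec.widths):
            k = 5 if (self.spec.family == "alex" and si == 0) else 3
            n_convs = 2 if self.spec.family in ("vgg", "resnet") else 1
            stage, c = [], cin
            for _ in range(n_convs):
                w = rng.standard_normal((k, k, c, cout)) * np.sqrt(2.0 / (k * k * c))
                stage.append((w, np.zeros(cout)))
                c = cout
                k = 3
            proj = None
            if self.spec.family == "resnet" and cin != cout:
                proj = rng.standard_normal((1, 1, cin, cout)) * np.sqrt(2.0 / cin)
            layers.append({"convs": stage, "proj": proj})
            cin = cout
        return layers

    def _dense_block(self, flat_dim: int) -> tuple:
        rng = np.random.default_rng((self.spec.seed, 104729, flat_dim,
                                     DEFAULT_FAMILIES.index(self.spec.family)))
        w = rng.standard_normal((flat_dim, self.spec.output_dim)) * np.sqrt(2.0 / flat_dim)
        return w, np.zeros(self.spec.output_dim)

    def condense(self, region_array: RegionArray | np.ndarray) -> np.ndarray:
        x = region_array.data if isinstance(region_array, RegionArray) else np.asarray(region_array)
        if x.ndim == 2:
            x = x[..., None]
        side = x.shape[0]
        if side < 2 * self.spec.min_side:
            raise ValueError(
                f"input side {side} too small for the pooling schedule "
                f"(needs >= {2 * self.spec.min_side}); reduce min_side or widths"
            )
        cin = x.shape[-1]
        if cin not in self._convs:
            self._convs[cin] = self._conv_stack(cin)

        n_down = adapt_pooling(side, self.spec)
        done = 0
        for stage in self._convs[cin]:
            # fuse the stage's trailing decimation into a strided conv
            want_down = done < n_down and x.shape[0] // 2 >= self.spec.min_side
            fuse = want_down and self.spec.pool == "decimate"
            h = x
            for ci, (w, b) in enumerate(stage["convs"]):
                s = 2 if (fuse and ci == len(stage["convs"]) - 1) else 1
                h = np.maximum(_conv2d(h, w, b, stride=s), 0.0)
            if self.spec.family == "resnet":
                xs = x[::2, ::2] if fuse else x
                shortcut = xs if stage["proj"] is None else _conv2d(
                    x, stage["proj"], np.zeros(stage["proj"].shape[-1]),
                    stride=2 if fuse else 1)
                h = np.maximum(h + shortcut, 0.0)
            x = h
            if fuse:
                done += 1
            elif want_down:
                x = _downsample(x, self.spec.pool)
                done += 1
        while done < n_down and x.shape[0] // 2 >= self.spec.min_side:
            x = _downsample(x, self.spec.pool)
            done += 1

        flat = x.ravel()
        if flat.size not in self._dense:
            self._dense[flat.size] = self._dense_block(flat.size)
        wd, bd = self._dense[flat.size]
        return np.maximum(flat @ wd + bd, 0.0)


_CACHE: dict = {}


def condense(region_array: RegionArray | np.ndarray, spec: BackboneSpec) -> np.ndarray:
    """Condense one region array to a 256-vector with a cached seeded encoder."""
    key = (spec.family, tuple(spec.widths), spec.seed, spec.pool)
    if key not in _CACHE:
        _CACHE[key] = Backbone(spec)
    return _CACHE[key].condense(region_array)
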