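"""Heterogeneous feature transforms applied ahead of region condensation.

Implements the texture and multi-resolution stages of the pipeline:

* 3-D gray-level co-occurrence matrices over the 13 antipodally-unique
  directions of the 26-neighbourhood, distances 1-3, with the classical
  11 Haralick descriptors (429 features per block).
* RROI block tiling of 2-D slices (block sizes 15 and 21) with per-block
  central moments and co-occurrence statistics.
* A separable orthonormal 3-D discrete wavelet transform (tensor-product
  basis: one approximation + seven orientation detail groups per level,
  each downsampled by 2 per axis) with perfect reconstruction.
* A windowed-scattering cascade (Gaussian low pass + Morlet band passes,
  modulus between layers, order <= 2).
* A plugin registry so external stages (shearlets, curvelets, anything
  satisfying the array -> array contract) slot into the pipeline under a
  config name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = [
    "GLCMConfig",
    "TextureVector",
    "SubbandSet",
    "unique_directions_3d",
    "quantize",
    "cooccurrence_3d",
    "HARALICK_FEATURES",
    "haralick",
    "glcm_block_features",
    "rroi_blocks",
    "rroi_block_features",
    "dwt3d",
    "idwt3d",
    "scattering",
    "register_transform",
    "get_transform",
    "available_stages",
    "BUILTIN_STAGES",
]


# ----------------------------------------------------------------------
# GLCM
# ----------------------------------------------------------------------

@dataclass
class GLCMConfig:
    levels: int = 16
    distances: tuple = (1, 2, 3)
    directions: tuple = None  # default: the 13 unique 3-D directions
    symmetric: bool = True
    normalize: bool = True

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.directions is None:
            self.directions = tuple(unique_directions_3d())
        for d in self.directions:
            if all(c == 0 for c in d):
                raise ValueError("zero offset is not a direction")
        for a in self.directions:
            for b in self.directions:
                if tuple(-c for c in a) == tuple(b):
                    raise ValueError(f"directions contain antipodal pair {a}/{b}")


@dataclass
class TextureVector:
    values: np.ndarray
    schema: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != len(self.schema):
            raise ValueError("schema length must match value length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("texture vector contains non-finite values")

    def __len__(self):
        return len(self.values)


def unique_directions_3d() -> list:
    """The 13 directions of the 26-neighbourhood after antipodal identification.

    Canonical representative: the first nonzero component is positive;
    ordering is lexicographic over (dz, dy, dx).
    """
    dirs = []
    for d in product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        first = next(c for c in d if c != 0)
        if first > 0:
            dirs.append(d)
    return sorted(dirs)


def quantize(volume: np.ndarray, levels: int) -> np.ndarray:
    """Uniform gray-level binning to integer levels [0, levels)."""
    v = np.asarray(volume, dtype=np.float64)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros(v.shape, dtype=np.int64)
    q = np.floor((v - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def cooccurrence_3d(volume: np.ndarray, offset, config: GLCMConfig) -> np.ndarray:
    """Count co-occurring gray-level pairs at a voxel offset.

    ``volume`` must already be quantized to integers in [0, levels).
    """
    vol = np.asarray(volume)
    if not np.issubdtype(vol.dtype, np.integer):
        raise ValueError("volume must be an integer (quantized) array")
    off = tuple(int(o) for o in offset)
    if all(o == 0 for o in off):
        raise ValueError("offset must be nonzero")
    if vol.min() < 0 or vol.max() >= config.levels:
        raise ValueError(f"gray levels must lie in [0, {config.levels})")

    # source/destination slabs for (p, p + offset) pairs inside bounds
    src, dst = [], []
    for size, o in zip(vol.shape, off):
        if abs(o) >= size:
            raise ValueError(f"offset {off} out of range for shape {vol.shape}")
        if o >= 0:
            src.append(slice(0, size - o))
            dst.append(slice(o, size))
        else:
            src.append(slice(-o, size))
            dst.append(slice(0, size + o))
    a = vol[tuple(src)].ravel()
    b = vol[tuple(dst)].ravel()
    if a.size == 0:
        raise ValueError("all voxel pairs fall outside the volume")

    L = config.levels
    mat = np.bincount(a * L + b, minlength=L * L).reshape(L, L).astype(np.float64)
    if config.symmetric:
        mat = mat + mat.T
    if config.normalize:
        mat = mat / mat.sum()
    return mat


#: The classical 11-descriptor set, in fixed schema order.
HARALICK_FEATURES = (
    "angular_second_moment",
    "contrast",
    "correlation",
    "variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
)

_EPS = 1e-12


def haralick(matrix: np.ndarray, feature_set=HARALICK_FEATURES) -> np.ndarray:
    """Scalar texture descriptors of a normalized co-occurrence matrix."""
    p = np.asarray(matrix, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("co-occurrence matrix must be square")
    if p.min() < 0 or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("matrix must be normalized (entries >= 0 summing to 1)")

    L = p.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (np.arange(L) * px).sum()
    mu_y = (np.arange(L) * py).sum()
    sd_x = np.sqrt(((np.arange(L) - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((np.arange(L) - mu_y) ** 2 * py).sum())

    # p_{x+y}(s), s = 0..2L-2  and  p_{x-y}(d), d = 0..L-1
    psum = np.zeros(2 * L - 1)
    np.add.at(psum, (i + j).ravel(), p.ravel())
    pdiff = np.zeros(L)
    np.add.at(pdiff, np.abs(i - j).ravel(), p.ravel())

    mu = p.sum() * mu_x  # overall mean index for "variance" (Haralick f4 uses mu)

    feats = {}
    feats["angular_second_moment"] = float((p ** 2).sum())
    feats["contrast"] = float((p * (i - j) ** 2).sum())
    if sd_x * sd_y > _EPS:
        feats["correlation"] = float(((i * j * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        feats["correlation"] = 0.0
    feats["variance"] = float((p * (i - mu) ** 2).sum())
    feats["inverse_difference_moment"] = float((p / (1.0 + (i - j) ** 2)).sum())
    s = np.arange(2 * L - 1)
    sum_avg = float((s * psum).sum())
    feats["sum_average"] = sum_avg
    feats["sum_variance"] = float(((s - sum_avg) ** 2 * psum).sum())
    feats["sum_entropy"] = float(-(psum * np.log2(psum + _EPS)).sum())
    feats["entropy"] = float(-(p * np.log2(p + _EPS)).sum())
    d = np.arange(L)
    diff_avg = float((d * pdiff).sum())
    feats["difference_variance"] = float(((d - diff_avg) ** 2 * pdiff).sum())
    feats["difference_entropy"] = float(-(pdiff * np.log2(pdiff + _EPS)).sum())

    unknown = set(feature_set) - set(feats)
    if unknown:
        raise ValueError(f"unknown Haralick features: {sorted(unknown)}")
    return np.array([feats[name] for name in feature_set])


def glcm_block_features(block: np.ndarray, config: GLCMConfig | None = None,
                        feature_set=HARALICK_FEATURES) -> TextureVector:
    """All Haralick descriptors of a 3-D block: feature x direction x distance.

    Default configuration (11 features, 13 directions, distances 1-3) yields
    the 429-length descriptor.
    """
    if config is None:
        config = GLCMConfig()
    block = np.asarray(block)
    if block.size <= 1 or max(block.shape) <= min(config.distances):
        raise ValueError("block too small for the smallest co-occurrence distance")
    q = block if np.issubdtype(block.dtype, np.integer) else quantize(block, config.levels)

    values, schema = [], []
    for dist in config.distances:
        for direction in config.directions:
            off = tuple(dist * c for c in direction)
            mat = cooccurrence_3d(q, off, config)
            if not config.normalize:
                mat = mat / mat.sum()
            feats = haralick(mat, feature_set)
            values.extend(feats)
            schema.extend(f"{name}_d{dist}_o{direction}" for name in feature_set)
    return TextureVector(values=np.array(values), schema=schema)


# ----------------------------------------------------------------------
# RROI block textures
# ----------------------------------------------------------------------

RROI_BLOCK_FEATURES = (
    "mean", "central_moment_2", "central_moment_3", "central_moment_4",
    "contrast", "entropy", "inverse_difference_moment", "homogeneity",
)


def rroi_blocks(slice_image: np.ndarray, B_l: int) -> list:
    """Non-overlapping B_l x B_l tiling from the origin, row-major.

    Trailing partial tiles are dropped.  Default block sizes in the pipeline
    are 15 and 21.
    """
    img = np.asarray(slice_image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("slice image must be 2-D")
    K, N = img.shape
    if K < B_l or N < B_l:
        raise ValueError(f"image {img.shape} smaller than block size {B_l}")
    blocks = []
    for r in range(K // B_l):
        for c in range(N // B_l):
            blocks.append(img[r * B_l:(r + 1) * B_l, c * B_l:(c + 1) * B_l])
    return blocks


def rroi_block_features(block: np.ndarray, levels: int = 16) -> TextureVector:
    """Per-block stats: central moments plus 2-D co-occurrence descriptors."""
    b = np.asarray(block, dtype=np.float64)
    m = b.mean()
    cm2 = ((b - m) ** 2).mean()
    cm3 = ((b - m) ** 3).mean()
    cm4 = ((b - m) ** 4).mean()

    q = quantize(b, levels)
    # average the two axis-aligned 2-D offsets, symmetric + normalized
    L = levels
    mat = np.zeros((L, L))
    for off in ((0, 1), (1, 0)):
        a = q[: q.shape[0] - off[0], : q.shape[1] - off[1]].ravel()
        c = q[off[0]:, off[1]:].ravel()
        sub = np.bincount(a * L + c, minlength=L * L).reshape(L, L).astype(np.float64)
        mat += sub + sub.T
    mat /= mat.sum()

    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    contrast = float((mat * (i - j) ** 2).sum())
    entropy = float(-(mat * np.log2(mat + _EPS)).sum())
    idm = float((mat / (1.0 + (i - j) ** 2)).sum())
    homogeneity = float((mat / (1.0 + np.abs(i - j))).sum())

    return TextureVector(
        values=np.array([m, cm2, cm3, cm4, contrast, entropy, idm, homogeneity]),
        schema=list(RROI_BLOCK_FEATURES),
    )


# ----------------------------------------------------------------------
# Separable orthonormal 3-D DWT
# ----------------------------------------------------------------------

# standard orthonormal compact-support analysis filters (scaling coefficients)
_WAVELET_FILTERS = {
    "haar": np.array([1.0, 1.0]) / np.sqrt(2.0),
    "db2": np.array([
        0.48296291314469025, 0.836516303737469,
        0.22414386804185735, -0.12940952255092145,
    ]),
}

#: detail-group labels; L/H = low/high pass along (axis0, axis1, axis2)
DETAIL_ORIENTATIONS = ("LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


@dataclass
class SubbandSet:
    approximation: np.ndarray            # final-level LLL
    details: list                        # per level: dict orientation -> array
    levels: int
    wavelet: str = "db2"


def _qmf(h: np.ndarray) -> np.ndarray:
    g = h[::-1].copy()
    g[1::2] *= -1
    return g


def _analysis_axis(x: np.ndarray, filt: np.ndarray, axis: int) -> np.ndarray:
    """Periodized filter + downsample-by-2 along one axis."""
    n = x.shape[axis]
    idx = (np.arange(0, n, 2)[:, None] + np.arange(len(filt))[None, :]) % n
    moved = np.moveaxis(x, axis, -1)
    out = np.tensordot(moved[..., idx], filt, axes=([-1], [0]))
    return np.moveaxis(out, -1, axis)


def _synthesis_axis(lo: np.ndarray, hi: np.ndarray, h: np.ndarray, g: np.ndarray,
                    axis: int) -> np.ndarray:
    """Transpose of the analysis operator (exact inverse for orthonormal filters)."""
    n2 = lo.shape[axis]
    n = 2 * n2
    lo_m = np.moveaxis(lo, axis, -1)
    hi_m = np.moveaxis(hi, axis, -1)
    out = np.zeros(lo_m.shape[:-1] + (n,))
    for k, (hk, gk) in enumerate(zip(h, g)):
        pos = (2 * np.arange(n2) + k) % n
        np.add.at(out, (..., pos), hk * lo_m + gk * hi_m)
    return np.moveaxis(out, -1, axis)


def dwt3d(volume: np.ndarray, levels: int = 1, wavelet: str = "db2") -> SubbandSet:
    """Separable tensor-product 3-D DWT.

    Each level splits the running approximation into 8 subbands (1
    approximation + 7 orientation detail groups), each downsampled by 2 in
    every axis.  Periodized orthonormal filters give perfect reconstruction
    and energy conservation.
    """
    x = np.asarray(volume, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("input must be 3-D")
    if wavelet not in _WAVELET_FILTERS:
        raise ValueError(f"unknown wavelet {wavelet!r}; available: {sorted(_WAVELET_FILTERS)}")
    for s in x.shape:
        if s % (2 ** levels) != 0:
            raise ValueError(f"shape {x.shape} not divisible by 2^{levels}")
    h = _WAVELET_FILTERS[wavelet]
    g = _qmf(h)

    details = []
    approx = x
    for _ in range(levels):
        bands = {"": approx}
        for axis in range(3):
            new = {}
            for tag, arr in bands.items():
                new[tag + "L"] = _analysis_axis(arr, h, axis)
                new[tag + "H"] = _analysis_axis(arr, g, axis)
            bands = new
        approx = bands.pop("LLL")
        details.append({k: bands[k] for k in DETAIL_ORIENTATIONS})
    return SubbandSet(approximation=approx, details=details, levels=levels, wavelet=wavelet)


def idwt3d(subbands: SubbandSet) -> np.ndarray:
    """Inverse of :func:`dwt3d`."""
    h = _WAVELET_FILTERS[subbands.wavelet]
    g = _qmf(h)
    approx = subbands.approximation
    for level_details in reversed(subbands.details):
        bands = dict(level_details)
        bands["LLL"] = approx
        for axis in (2, 1, 0):
            # merge band pairs that differ only in position `axis`
            new = {}
            seen = set()
            for key in bands:
                stem = key[:axis] + key[axis + 1:]
                if stem in seen:
                    continue
                seen.add(stem)
                lo = bands[key[:axis] + "L" + key[axis + 1:]]
                hi = bands[key[:axis] + "H" + key[axis + 1:]]
                new[stem] = _synthesis_axis(lo, hi, h, g, axis)
            bands = new
        approx = bands[""]
    return approx


# ----------------------------------------------------------------------
# Scattering transform
# ----------------------------------------------------------------------

def _morlet_bank(shape: tuple, J: int, L: int):
    """Fourier-domain Gaussian low pass phi_J and Morlet band passes psi_{j,l}."""
    ndim = len(shape)
    grids = np.meshgrid(*[np.fft.fftfreq(n) * 2 * np.pi for n in shape], indexing="ij")
    omega = np.stack(grids)  # ndim x shape

    if ndim == 2:
        thetas = [np.array([np.cos(np.pi * l / L), np.sin(np.pi * l / L)]) for l in range(L)]
    else:
        base = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (0, 1, 1), (1, 0, 1), (1, 1, 1)]
        thetas = [np.array(base[l % len(base)], dtype=float) for l in range(L)]
        thetas = [t / np.linalg.norm(t) for t in thetas]

    sigma0, xi0 = 0.8, 3 * np.pi / 4
    psis = {}
    for j in range(J):
        scale = 2.0 ** j
        for l, th in enumerate(thetas):
            center = (xi0 / scale) * th
            diff = omega - center.reshape((ndim,) + (1,) * ndim)
            sq = (diff ** 2).sum(axis=0)
            env = np.exp(-sq * (scale * sigma0) ** 2 / 2)
            # subtract DC so that band passes kill constants
            dc = np.exp(-((omega ** 2).sum(axis=0) + (center ** 2).sum())
                        * (scale * sigma0) ** 2 / 2)
            psis[(j, l)] = env - dc
    sq = (omega ** 2).sum(axis=0)
    phi = np.exp(-sq * (2.0 ** J * sigma0) ** 2 / 2)
    return phi, psis


def scattering(array: np.ndarray, J: int = 3, L: int = 4, order: int = 2) -> np.ndarray:
    """Windowed scattering coefficients (global average per path).

    Path structure: the order-0 low-pass mean; order-1 means of
    ``|f * psi_{j1,l1}| * phi``; order-2 means of
    ``||f * psi_{j1,l1}| * psi_{j2,l2}| * phi`` for j2 > j1.  All
    coefficients of order >= 1 are nonnegative by construction.
    """
    f = np.asarray(array, dtype=np.float64)
    if f.ndim not in (2, 3):
        raise ValueError("scattering input must be 2-D or 3-D")
    if min(f.shape) < 2 ** J:
        raise ValueError(f"every side must be >= 2^J = {2 ** J}")
    if order not in (0, 1, 2):
        raise ValueError("order must be <= 2")

    phi, psis = _morlet_bank(f.shape, J, L)
    F = np.fft.fftn(f)

    def lowpass_mean(spec):
        return float(np.real(np.fft.ifftn(spec * phi)).mean())

    coeffs = [lowpass_mean(F)]
    if order >= 1:
        first = {}
        for (j1, l1), psi in sorted(psis.items()):
            u = np.abs(np.fft.ifftn(F * psi))
            first[(j1, l1)] = u
            coeffs.append(float(np.real(np.fft.ifftn(np.fft.fftn(u) * phi)).mean()))
        if order == 2:
            for (j1, l1), u in sorted(first.items()):
                U = np.fft.fftn(u)
                for (j2, l2), psi2 in sorted(psis.items()):
                    if j2 <= j1:
                        continue
                    v = np.abs(np.fft.ifftn(U * psi2))
                    coeffs.append(float(np.real(np.fft.ifftn(np.fft.fftn(v) * phi)).mean()))
    return np.array(coeffs)


# ----------------------------------------------------------------------
# Transform plugin registry
# ----------------------------------------------------------------------

def _stage_nt(arr):
    return np.asarray(arr, dtype=np.float64)


def _stage_wt(arr):
    sb = dwt3d(arr, levels=1)
    out = np.concatenate([sb.approximation.ravel()]
                         + [sb.details[0][o].ravel() for o in DETAIL_ORIENTATIONS])
    return out.reshape(sb.approximation.shape[0], sb.approximation.shape[1], -1)


def _stage_glcm(arr):
    return glcm_block_features(arr).values


def _stage_rroi(arr):
    arr = np.asarray(arr)
    mid = arr[..., arr.shape[-1] // 2] if arr.ndim == 3 else arr
    feats = [rroi_block_features(b).values for b in rroi_blocks(mid, 15)]
    return np.concatenate(feats)


def _stage_st(arr):
    return scattering(arr)


BUILTIN_STAGES = ("NT", "WT", "RROI", "GLCM", "CT", "HT", "ST")

_REGISTRY: dict = {
    "NT": _stage_nt,
    "WT": _stage_wt,
    "RROI": _stage_rroi,
    "GLCM": _stage_glcm,
    "ST": _stage_st,
}


def register_transform(name: str, fn, overwrite: bool = False) -> None:
    """Register a custom stage (e.g. shearlets 'HT' or curvelets 'CT')."""
    if name in _REGISTRY and not overwrite:
        raise ValueError(f"stage {name!r} already registered")
    if not callable(fn):
        raise TypeError("fn must be callable")
    _REGISTRY[name] = fn


def get_transform(name: str):
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown feature stage {name!r}; available: {sorted(_REGISTRY)} "
            f"(register 'CT'/'HT' or custom stages with register_transform)"
        )
    return _REGISTRY[name]


def available_stages() -> list:
    return sorted(_REGISTRY)
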