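"""Vision-transformer head over the region-pair score image.

The assembled k x k x C pair-score matrix is treated as an image: zero-padded
to a patchable side, split into patches, linearly embedded with positional
embeddings and a class token, and passed through multi-head self-attention
blocks.  Training follows the two-phase schedule: phase 1 freezes the NGA
min/max statistics on a class-balanced mini-batch and fits the regional
association nets to their similarity proxies (Adam, lr 1e-4, batch 5,
15 epochs); phase 2 fits the transformer with cross-entropy (Adam, lr 1e-5,
batch 5, 50 epochs).

Explainability: class-specific gradient attention rollout.  Per block the
post-softmax attention is fused with its gradient w.r.t. the class logit
(elementwise product, negatives clamped, head-averaged), residual-adjusted
(identity added, rows renormalized), and the per-block maps are multiplied;
the class-token row, reshaped to the patch grid and upsampled to the k x k
pair grid, is the saliency map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._autodiff import Adam, Tensor
from .regional_association import RANet, RegionPair, assemble_channels, enumerate_pairs, train_ra_net

__all__ = [
    "ViTConfig",
    "RolloutMap",
    "patchify",
    "ViT",
    "train_two_phase",
    "gradient_rollout",
    "top_pairs",
]


@dataclass
class ViTConfig:
    patch_size: int = 10
    embed_dim: int = 64
    heads: int = 4
    depth: int = 4
    mlp_dim: int = 128
    classes: int = 2
    pad_to: int | None = None  # None: next multiple of patch_size
    seed: int = 0

    def __post_init__(self):
        if self.classes < 2:
            raise ValueError("need at least 2 classes")
        if self.embed_dim % self.heads != 0:
            raise ValueError("embed_dim must be divisible by heads")
        if self.pad_to is not None and self.pad_to % self.patch_size != 0:
            raise ValueError("pad_to must be divisible by patch_size")

    def padded_side(self, side: int) -> int:
        if self.pad_to is not None:
            if self.pad_to < side:
                raise ValueError(f"pad_to {self.pad_to} smaller than input side {side}")
            return self.pad_to
        return int(np.ceil(side / self.patch_size)) * self.patch_size


@dataclass
class RolloutMap:
    """Per-class saliency over the pair grid; nonnegative, max-normalized."""

    grid: np.ndarray          # k x k saliency
    patch_grid: np.ndarray    # raw patch-level saliency
    target_class: int


def patchify(image: np.ndarray, config: ViTConfig) -> np.ndarray:
    """Zero-pad to a patchable side and split into row-major flattened patches."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[..., None]
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    side = config.padded_side(max(img.shape[0], img.shape[1]))
    padded = np.zeros((side, side, img.shape[2]))
    padded[: img.shape[0], : img.shape[1]] = img
    g = side // config.patch_size
    p = config.patch_size
    patches = (padded.reshape(g, p, g, p, -1)
                     .transpose(0, 2, 1, 3, 4)
                     .reshape(g * g, p * p * img.shape[2]))
    return patches


class ViT:
    """Small vanilla vision transformer (pre-norm blocks, ReLU MLP)."""

    def __init__(self, config: ViTConfig, patch_dim: int, n_patches: int | None = None):
        self.config = config
        rng = np.random.default_rng(config.seed)
        D, H = config.embed_dim, config.heads
        self.dh = D // H

        def he(shape, fan_in):
            return Tensor(rng.standard_normal(shape) * np.sqrt(2.0 / fan_in),
                          requires_grad=True)

        self.w_embed = he((patch_dim, D), patch_dim)
        self.b_embed = Tensor(np.zeros(D), requires_grad=True)
        self.cls_token = Tensor(rng.standard_normal((1, D)) * 0.02, requires_grad=True)
        self.pos: Tensor | None = None  # sized to the token count (lazy if unknown)
        self._rng = rng
        if n_patches is not None:
            self.pos = Tensor(rng.standard_normal((n_patches + 1, D)) * 0.02,
                              requires_grad=True)
        self.blocks = []
        for _ in range(config.depth):
            blk = {
                "ln1_g": Tensor(np.ones(D), requires_grad=True),
                "ln1_b": Tensor(np.zeros(D), requires_grad=True),
                "wq": he((D, D), D), "wk": he((D, D), D), "wv": he((D, D), D),
                "wo": he((D, D), D),
                "ln2_g": Tensor(np.ones(D), requires_grad=True),
                "ln2_b": Tensor(np.zeros(D), requires_grad=True),
                "w1": he((D, config.mlp_dim), D),
                "b1": Tensor(np.zeros(config.mlp_dim), requires_grad=True),
                "w2": he((config.mlp_dim, D), config.mlp_dim),
                "b2": Tensor(np.zeros(D), requires_grad=True),
            }
            self.blocks.append(blk)
        self.ln_f_g = Tensor(np.ones(D), requires_grad=True)
        self.ln_f_b = Tensor(np.zeros(D), requires_grad=True)
        self.w_head = he((D, config.classes), D)
        self.b_head = Tensor(np.zeros(config.classes), requires_grad=True)
        self.attentions: list = []  # post-softmax attention tensors, last forward

    @property
    def parameters(self):
        ps = [self.w_embed, self.b_embed, self.cls_token,
              self.ln_f_g, self.ln_f_b, self.w_head, self.b_head]
        if self.pos is not None:
            ps.append(self.pos)
        for blk in self.blocks:
            ps.extend(blk.values())
        return ps

    @staticmethod
    def _layernorm(x: Tensor, g: Tensor, b: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) * (x - mu)).mean(axis=-1, keepdims=True)
        return (x - mu) * (var + 1e-6) ** -0.5 * g + b

    def forward(self, patch_batch: np.ndarray) -> Tensor:
        """patch_batch: B x n_patches x patch_dim -> logits B x classes."""
        B, n_patches, _ = patch_batch.shape
        T = n_patches + 1
        if self.pos is None:
            self.pos = Tensor(self._rng.standard_normal((T, self.config.embed_dim)) * 0.02,
                              requires_grad=True)
        if self.pos.data.shape[0] != T:
            raise ValueError("token count changed between calls")

        x = Tensor(patch_batch) @ self.w_embed + self.b_embed       # B x n x D
        cls = Tensor(np.ones((B, 1, 1))) * self.cls_token           # broadcast to B x 1 x D
        from ._autodiff import concatenate
        x = concatenate([cls, x], axis=1) + self.pos                # B x T x D

        H, dh = self.config.heads, self.dh
        D = self.config.embed_dim
        self.attentions = []
        for blk in self.blocks:
            h = self._layernorm(x, blk["ln1_g"], blk["ln1_b"])
            q = (h @ blk["wq"]).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            k = (h @ blk["wk"]).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            v = (h @ blk["wv"]).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            scores = q @ k.transpose(0, 1, 3, 2) * (dh ** -0.5)
            attn = scores.softmax(axis=-1)                          # B x H x T x T
            self.attentions.append(attn)
            ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
            x = x + ctx @ blk["wo"]
            h2 = self._layernorm(x, blk["ln2_g"], blk["ln2_b"])
            x = x + (h2 @ blk["w1"] + blk["b1"]).relu() @ blk["w2"] + blk["b2"]
        x = self._layernorm(x, self.ln_f_g, self.ln_f_b)
        cls_out = x[:, 0, :]                                        # B x D
        return cls_out @ self.w_head + self.b_head

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Class labels for a stack of pair images (n x k x k x C)."""
        return np.argmax(self.predict_scores(images), axis=1)

    def predict_scores(self, images: np.ndarray) -> np.ndarray:
        """Softmax class probabilities."""
        patches = np.stack([patchify(im, self.config) for im in images])
        logits = self.forward(patches).data
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


def _cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    probs = logits.softmax(axis=-1)
    onehot = np.zeros(probs.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    return -((probs + 1e-12).log() * Tensor(onehot)).sum() * (1.0 / len(labels))


def train_two_phase(dataset: dict, config: ViTConfig,
                    ra_lr: float = 1e-4, ra_epochs: int = 15,
                    vit_lr: float = 1e-5, vit_epochs: int = 50,
                    batch_size: int = 5, stats_fraction: float = 0.2,
                    seed: int = 0, shared_net: bool = True,
                    verbose: bool = False):
    """Two-phase training.

    ``dataset`` keys:
      * ``features``: list (one per backbone channel) of (n, k, 256) arrays,
        OR ``images``: precomputed (n, k, k, C) pair images (skips phase 1).
      * ``proxy_targets``: (n, n_pairs) similarity targets (with features).
      * ``labels``: (n,) integer class labels.

    Returns (model, ra_nets, images, logs).
    """
    labels = np.asarray(dataset["labels"])
    n = len(labels)
    if n < batch_size:
        raise ValueError(f"need at least batch_size={batch_size} samples, got {n}")
    logs = {"phase1_epochs": 0, "phase2_epochs": 0, "ra_loss": [], "vit_loss": []}

    ra_nets = None
    if "images" in dataset:
        images = np.asarray(dataset["images"], dtype=np.float64)
    else:
        features = [np.asarray(f, dtype=np.float64) for f in dataset["features"]]
        proxies = np.asarray(dataset["proxy_targets"], dtype=np.float64)
        k = features[0].shape[1]
        pairs = enumerate_pairs(k)
        if proxies.shape[1] != len(pairs):
            raise ValueError("proxy_targets second axis must be k(k-1)/2")

        # phase 1: NGA stats on a class-balanced mini-batch + RA proxy regression
        from .regional_association import score_all_pairs

        stats_idx = _class_balanced_subset(labels, stats_fraction, seed)
        ra_nets, channel_scores = [], []
        for ch, feat in enumerate(features):
            if shared_net:
                x1 = np.concatenate([feat[:, p.i - 1, :] for p in pairs])
                x2 = np.concatenate([feat[:, p.j - 1, :] for p in pairs])
                t = proxies.T.ravel()
                # order stats subset first so train_ra_net freezes NGA on it
                pair_stats = np.concatenate(
                    [np.arange(len(pairs)) * n + si for si in stats_idx])
                rest = np.setdiff1d(np.arange(len(t)), pair_stats)
                order = np.concatenate([pair_stats, rest])
                net = RANet(in_dim=feat.shape[-1], seed=seed + ch)
                loss = train_ra_net(net, x1[order], x2[order], t[order],
                                    lr=ra_lr, epochs=ra_epochs, batch_size=batch_size,
                                    stats_fraction=len(pair_stats) / len(t),
                                    seed=seed + 100 + ch)
                logs["ra_loss"].append(loss)
                nets = net
            else:
                # one association net per region pair, as printed
                nets, losses = [], []
                rest = np.setdiff1d(np.arange(n), stats_idx)
                order = np.concatenate([stats_idx, rest])
                for pi, p in enumerate(pairs):
                    pnet = RANet(in_dim=feat.shape[-1],
                                 seed=seed + ch * 100003 + pi)
                    losses.append(train_ra_net(
                        pnet, feat[order, p.i - 1, :], feat[order, p.j - 1, :],
                        proxies[order, pi], lr=ra_lr, epochs=ra_epochs,
                        batch_size=batch_size,
                        stats_fraction=len(stats_idx) / n,
                        seed=seed + 100 + ch))
                    nets.append(pnet)
                logs["ra_loss"].append([float(np.mean(col)) for col in zip(*losses)])
            ra_nets.append(nets)
            channel_scores.append(score_all_pairs(nets, feat, pairs))
        logs["phase1_epochs"] = ra_epochs
        images = np.stack(
            [assemble_channels([cs[i] for cs in channel_scores], k) for i in range(n)])

    # phase 2: transformer with cross-entropy
    patches = np.stack([patchify(im, config) for im in images])
    model = ViT(config, patch_dim=patches.shape[-1], n_patches=patches.shape[1])
    opt = Adam(model.parameters, lr=vit_lr)
    rng = np.random.default_rng(seed + 1)
    for epoch in range(vit_epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            logits = model.forward(patches[idx])
            loss = _cross_entropy(logits, labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
        logs["vit_loss"].append(total / n)
        if verbose:
            print(f"epoch {epoch + 1}/{vit_epochs} loss {total / n:.4f}")
    logs["phase2_epochs"] = vit_epochs
    return model, ra_nets, images, logs


def _class_balanced_subset(labels: np.ndarray, fraction: float, seed: int) -> np.ndarray:
    """Indices of a class-balanced mini-batch covering ~fraction of the data."""
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    per_class = max(1, int(round(fraction * len(labels) / len(classes))))
    picks = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        picks.append(rng.choice(idx, size=min(per_class, len(idx)), replace=False))
    return np.sort(np.concatenate(picks))


def gradient_rollout(model: ViT, image: np.ndarray, target_class: int) -> RolloutMap:
    """Class-specific gradient attention rollout for one pair image."""
    if not (0 <= target_class < model.config.classes):
        raise ValueError(f"class index {target_class} out of range")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[..., None]
    k_side = img.shape[0]
    patches = patchify(img, model.config)[None]
    logits = model.forward(patches)

    grad_seed = np.zeros(logits.data.shape)
    grad_seed[0, target_class] = 1.0
    logits.backward(grad_seed)

    T = patches.shape[1] + 1
    rollout = np.eye(T)
    for attn in model.attentions:
        a = attn.data[0]                      # H x T x T
        g = attn.grad[0] if attn.grad is not None else np.zeros_like(a)
        fused = np.maximum(a * g, 0.0).mean(axis=0)   # clamp negatives, head-average
        fused = fused + np.eye(T)                     # residual adjustment
        fused = fused / fused.sum(axis=1, keepdims=True)
        rollout = fused @ rollout
    saliency = rollout[0, 1:]                 # class-token row over patch tokens
    g = int(np.sqrt(len(saliency)))
    patch_grid = saliency.reshape(g, g)

    side = model.config.padded_side(k_side)
    up = ndimage.zoom(patch_grid, side / g, order=1)[:k_side, :k_side]
    up = np.maximum(up, 0.0)
    if up.max() > 0:
        up = up / up.max()
    return RolloutMap(grid=up, patch_grid=patch_grid, target_class=target_class)


def top_pairs(rollout: RolloutMap, n: int, names: dict | None = None) -> list:
    """Ranked (RegionPair, name_i, name_j, saliency); ties broken by (i, j)."""
    grid = rollout.grid
    k = grid.shape[0]
    cells = [(i + 1, j + 1, float((grid[i, j] + grid[j, i]) / 2.0))
             for i in range(k) for j in range(i + 1, k)]
    if n > len(cells):
        import warnings
        warnings.warn(f"requested {n} pairs but only {len(cells)} available; clamping")
        n = len(cells)
    cells.sort(key=lambda c: (-c[2], c[0], c[1]))
    out = []
    for i, j, s in cells[:max(n, 0)]:
        name_i = names.get(i, f"region_{i}") if names else f"region_{i}"
        name_j = names.get(j, f"region_{j}") if names else f"region_{j}"
        out.append((RegionPair(i, j), name_i, name_j, s))
    return out
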