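"""Regional association networks with normalized group activations.

For every unordered pair of atlas regions, a small Siamese network scores
the correspondence of the two regions' condensed 256-vectors in [0, 1].
The fusion is elementwise-symmetric — the net sees [|x1 - x2|, x1 * x2] —
so score(x1, x2) == score(x2, x1) holds architecturally.  Two hidden dense
blocks carry NGA layers; a terminal sigmoid bounds the score.

Supervision: the networks regress a connectivity/similarity proxy target —
for fMRI, (Pearson r of the two regions' mean time series + 1)/2; for MRI,
(cosine similarity of the condensed vectors + 1)/2 — during the
pre-training phase (Adam, lr 1e-4, batch 5, 15 epochs), then are frozen.
Scores for all k(k-1)/2 pairs are assembled into a symmetric k x k matrix
per backbone (diagonal fixed at 1) and stacked as channels for the
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._autodiff import Adam, Tensor, concatenate
from .nga import ActivationSet, NGALayer

__all__ = [
    "RegionPair",
    "enumerate_pairs",
    "RANet",
    "ra_score",
    "proxy_label",
    "assemble_channels",
    "train_ra_net",
    "top_edges",
    "save_score_matrix",
]


@dataclass(frozen=True)
class RegionPair:
    i: int
    j: int

    def __post_init__(self):
        if self.i >= self.j:
            raise ValueError(f"require i < j, got ({self.i}, {self.j})")
        if self.i < 1:
            raise ValueError("region ids start at 1")


def enumerate_pairs(k: int) -> list:
    """All unordered region pairs in lexicographic order; k(k-1)/2 of them.

    For the 116-region AAL atlas this is the full set of G = 6,670 pairs.
    """
    if k < 2:
        raise ValueError("need at least 2 regions")
    return [RegionPair(i, j) for i in range(1, k + 1) for j in range(i + 1, k + 1)]


class RANet:
    """Siamese pair-scoring net: [|x1-x2|, x1*x2] -> 128+NGA -> 32+NGA -> sigmoid."""

    def __init__(self, in_dim: int = 256, hidden=(128, 32),
                 acts: ActivationSet | None = None, seed: int = 0,
                 nga_init: str = "identity"):
        rng = np.random.default_rng(seed)
        self.in_dim = in_dim
        dims = [2 * in_dim, *hidden]
        self.weights, self.biases, self.nga_layers = [], [], []
        for a, b in zip(dims[:-1], dims[1:]):
            self.weights.append(Tensor(rng.standard_normal((a, b)) * np.sqrt(2.0 / a),
                                       requires_grad=True))
            self.biases.append(Tensor(np.zeros(b), requires_grad=True))
            self.nga_layers.append(NGALayer(b, acts=acts, init=nga_init))
        self.w_out = Tensor(rng.standard_normal((dims[-1], 1)) * np.sqrt(2.0 / dims[-1]),
                            requires_grad=True)
        self.b_out = Tensor(np.zeros(1), requires_grad=True)

    @property
    def parameters(self):
        ps = [*self.weights, *self.biases, self.w_out, self.b_out]
        for layer in self.nga_layers:
            ps.extend(layer.parameters)
        return ps

    def _fuse(self, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
        return np.concatenate([np.abs(x1 - x2), x1 * x2], axis=-1)

    def forward(self, fused) -> Tensor:
        h = fused if isinstance(fused, Tensor) else Tensor(np.atleast_2d(fused))
        for w, b, nga in zip(self.weights, self.biases, self.nga_layers):
            h = nga(h @ w + b)
        return (h @ self.w_out + self.b_out).sigmoid()

    def estimate_stats(self, fused_batch: np.ndarray) -> None:
        """Freeze NGA min/max from a mini-batch of fused pair features."""
        h = np.atleast_2d(fused_batch)
        for w, b, nga in zip(self.weights, self.biases, self.nga_layers):
            pre = h @ w.data + b.data
            nga.estimate(pre)
            h = nga(Tensor(pre)).data

    def score(self, x1: np.ndarray, x2: np.ndarray) -> float:
        return float(ra_score(x1, x2, self))

    def project(self):
        for layer in self.nga_layers:
            layer.project()


def ra_score(x1: np.ndarray, x2: np.ndarray, net: RANet) -> np.ndarray:
    """Symmetric association score in [0,1] for a pair of condensed vectors."""
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    if x1.shape[-1] != net.in_dim or x2.shape[-1] != net.in_dim:
        raise ValueError(f"expected {net.in_dim}-vectors, got {x1.shape} and {x2.shape}")
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
        raise ValueError("non-finite inputs")
    out = net.forward(net._fuse(np.atleast_2d(x1), np.atleast_2d(x2)))
    return out.data.squeeze()


def proxy_label(data_i: np.ndarray, data_j: np.ndarray, modality: str) -> float:
    """Training target for a pair: similarity mapped to [0, 1].

    fMRI: (Pearson r of the regions' mean time series + 1)/2.
    MRI: (cosine similarity of the condensed vectors + 1)/2.
    """
    a = np.asarray(data_i, dtype=np.float64)
    b = np.asarray(data_j, dtype=np.float64)
    if modality == "fMRI":
        sa = a.mean(axis=0) if a.ndim == 2 else a
        sb = b.mean(axis=0) if b.ndim == 2 else b
        if sa.std() == 0 or sb.std() == 0:
            raise ValueError("zero-variance time series has no defined correlation")
        r = float(np.corrcoef(sa, sb)[0, 1])
    elif modality == "MRI":
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            raise ValueError("zero vector has no defined cosine similarity")
        r = float(a @ b / (na * nb))
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return (r + 1.0) / 2.0


def train_ra_net(net: RANet, x1: np.ndarray, x2: np.ndarray, targets: np.ndarray,
                 lr: float = 1e-4, epochs: int = 15, batch_size: int = 5,
                 stats_fraction: float = 0.2, seed: int = 0) -> list:
    """Regress proxy targets with MSE; NGA stats frozen from a leading mini-batch.

    Returns the per-epoch mean losses.
    """
    x1 = np.atleast_2d(x1)
    x2 = np.atleast_2d(x2)
    targets = np.asarray(targets, dtype=np.float64).ravel()
    n = len(targets)
    fused = net._fuse(x1, x2)

    n_stats = max(2, int(round(stats_fraction * n)))
    net.estimate_stats(fused[:n_stats])

    opt = Adam(net.parameters, lr=lr)
    rng = np.random.default_rng(seed)
    losses = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            pred = net.forward(Tensor(fused[idx]))
            diff = pred.reshape(len(idx)) - Tensor(targets[idx])
            loss = (diff * diff).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            net.project()
            epoch_loss += float(loss.data) * len(idx)
        losses.append(epoch_loss / n)
    return losses


def score_all_pairs(nets, feat: np.ndarray, pairs) -> np.ndarray:
    """(n_subjects, n_pairs) scores from a shared net or a per-pair net list.

    ``feat``: (n_subjects, k, 256); ``nets``: one RANet (shared across pairs)
    or a list with one RANet per pair.
    """
    from ._autodiff import Tensor

    n = feat.shape[0]
    if isinstance(nets, RANet):
        x1 = np.concatenate([feat[:, p.i - 1, :] for p in pairs])
        x2 = np.concatenate([feat[:, p.j - 1, :] for p in pairs])
        out = nets.forward(Tensor(nets._fuse(x1, x2))).data
        return out.reshape(len(pairs), n).T
    if len(nets) != len(pairs):
        raise ValueError(f"need {len(pairs)} nets, got {len(nets)}")
    scores = np.zeros((n, len(pairs)))
    for pi, (net, p) in enumerate(zip(nets, pairs)):
        fused = net._fuse(feat[:, p.i - 1, :], feat[:, p.j - 1, :])
        scores[:, pi] = net.forward(Tensor(fused)).data.ravel()
    return scores


def assemble_channels(score_lists, k: int, diagonal: float = 1.0) -> np.ndarray:
    """Fill symmetric k x k score matrices (one channel per backbone).

    Scores are in enumerate_pairs(k) order; output is k x k x channels.
    """
    if isinstance(score_lists, np.ndarray) and score_lists.ndim == 1:
        score_lists = [score_lists]
    pairs = enumerate_pairs(k)
    channels = []
    for scores in score_lists:
        scores = np.asarray(scores, dtype=np.float64).ravel()
        if len(scores) != len(pairs):
            raise ValueError(f"expected {len(pairs)} scores for k={k}, got {len(scores)}")
        mat = np.full((k, k), 0.0)
        np.fill_diagonal(mat, diagonal)
        for pair, s in zip(pairs, scores):
            mat[pair.i - 1, pair.j - 1] = s
            mat[pair.j - 1, pair.i - 1] = s
        channels.append(mat)
    return np.stack(channels, axis=-1)


def top_edges(score_matrix: np.ndarray, n: int = 100, names: dict | None = None) -> pd.DataFrame:
    """Strongest n region-pair edges; deterministic (score desc, then (i,j))."""
    mat = np.asarray(score_matrix)
    if mat.ndim == 3:
        mat = mat.mean(axis=-1)
    k = mat.shape[0]
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            rows.append((i + 1, j + 1, float(mat[i, j])))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    rows = rows[:n]
    df = pd.DataFrame(rows, columns=["region_i", "region_j", "strength"])
    if names:
        df.insert(2, "name_i", [names.get(i, f"region_{i}") for i in df["region_i"]])
        df.insert(3, "name_j", [names.get(j, f"region_{j}") for j in df["region_j"]])
    return df


def save_score_matrix(score_matrix: np.ndarray, path) -> None:
    """Long-format TSV: region_i, region_j, channel, score."""
    mat = np.asarray(score_matrix)
    if mat.ndim == 2:
        mat = mat[..., None]
    k, _, c = mat.shape
    rows = [(i + 1, j + 1, ch, mat[i, j, ch])
            for ch in range(c) for i in range(k) for j in range(i + 1, k)]
    pd.DataFrame(rows, columns=["region_i", "region_j", "channel", "score"]).to_csv(
        path, sep="\t", index=False)
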