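"""Normalized group activations (NGA).

Instead of a single activation function per unit, an NGA layer applies a
small set of activations A = {A_1..A_m} (default ReLU, ELU, ELiSH) to each
pre-activation, min-max normalizes every activation using statistics frozen
from a class-balanced mini-batch,

    g_j^k(c) = (A_j(c) - min_v A_j(c_vk)) / (max_v A_j(c_vk) - min_v A_j(c_vk) + eps),

and emits the learnable combination

    y^k = sum_j eta_j^k (kappa_j g_j^k + gamma_j),

with the weights eta constrained to [0, 1] by projection after every
optimizer step.  On the estimation batch every g lies in [0, 1); values
outside the batch range are clipped to [0, 1] at inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import Tensor

__all__ = [
    "ActivationSet",
    "NGAStats",
    "NGAParams",
    "estimate_stats",
    "normalize",
    "nga_forward",
    "project_params",
    "NGALayer",
    "DEFAULT_EPSILON",
]

DEFAULT_EPSILON = 1e-6


def _exp(x):
    return x.exp() if isinstance(x, Tensor) else np.exp(x)


def _sigmoid(x):
    if isinstance(x, Tensor):
        return x.sigmoid()
    return 1.0 / (1.0 + np.exp(-x))


def _relu_fn(x):
    if isinstance(x, Tensor):
        return x.relu()
    return np.maximum(x, 0.0)


def _softplus_mask(x):
    """Smooth 0/1 gate for x >= 0 used to express piecewise activations.

    Piecewise activations are written as  mask * pos_branch + (1-mask) *
    neg_branch with a hard indicator; the indicator is treated as constant
    under differentiation (exact almost everywhere).
    """
    data = x.data if isinstance(x, Tensor) else np.asarray(x)
    return (data >= 0).astype(np.float64)


def _elu_fn(x):
    mask = _softplus_mask(x)
    return x * mask + (_exp(x) - 1.0) * (1.0 - mask)


def _elish_fn(x):
    # standard ELiSH: x*sigmoid(x) for x >= 0, (e^x - 1)*sigmoid(x) for x < 0
    mask = _softplus_mask(x)
    s = _sigmoid(x)
    return x * s * mask + (_exp(x) - 1.0) * s * (1.0 - mask)


def _elish_printed_fn(x):
    # the variant printed in the source description: (e^x - 1)/(1 + e^x) everywhere
    return (_exp(x) - 1.0) / (1.0 + _exp(x))


_KNOWN_ACTIVATIONS = {
    "relu": _relu_fn,
    "elu": _elu_fn,
    "elish": _elish_fn,
    "elish_printed": _elish_printed_fn,
}


@dataclass
class ActivationSet:
    """Ordered set of scalar activation functions."""

    names: tuple = ("relu", "elu", "elish")

    def __post_init__(self):
        if len(self.names) < 1:
            raise ValueError("need at least one activation")
        unknown = [n for n in self.names if n not in _KNOWN_ACTIVATIONS]
        if unknown:
            raise ValueError(f"unknown activations {unknown}; known: {sorted(_KNOWN_ACTIVATIONS)}")

    @property
    def m(self) -> int:
        return len(self.names)

    def apply(self, j: int, x):
        """Apply the j-th activation; works on numpy arrays and Tensors."""
        return _KNOWN_ACTIVATIONS[self.names[j]](x)


@dataclass
class NGAStats:
    """Frozen per-unit, per-activation min/max over the estimation mini-batch."""

    mins: np.ndarray   # m x units
    maxs: np.ndarray   # m x units
    epsilon: float = DEFAULT_EPSILON
    batch_size: int = 0

    def __post_init__(self):
        self.mins = np.asarray(self.mins, dtype=np.float64)
        self.maxs = np.asarray(self.maxs, dtype=np.float64)
        if self.mins.shape != self.maxs.shape:
            raise ValueError("min/max shapes differ")
        if np.any(self.maxs < self.mins):
            raise ValueError("max < min")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class NGAParams:
    """Learnable eta (per unit, per activation, in [0,1]) and kappa/gamma (per activation)."""

    eta: np.ndarray     # m x units
    kappa: np.ndarray   # m
    gamma: np.ndarray   # m

    def __post_init__(self):
        self.eta = np.asarray(self.eta, dtype=np.float64)
        self.kappa = np.asarray(self.kappa, dtype=np.float64)
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        for a in (self.eta, self.kappa, self.gamma):
            if not np.all(np.isfinite(a)):
                raise ValueError("parameters must be finite")


def estimate_stats(preactivations: np.ndarray, acts: ActivationSet,
                   epsilon: float = DEFAULT_EPSILON) -> NGAStats:
    """Min/max of every activation of every unit over a mini-batch (p x units)."""
    c = np.asarray(preactivations, dtype=np.float64)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[0] < 2:
        raise ValueError("mini-batch must contain at least 2 samples")
    if not np.all(np.isfinite(c)):
        raise ValueError("non-finite pre-activations")
    mins = np.empty((acts.m, c.shape[1]))
    maxs = np.empty((acts.m, c.shape[1]))
    for j in range(acts.m):
        a = acts.apply(j, c)
        mins[j] = a.min(axis=0)
        maxs[j] = a.max(axis=0)
    return NGAStats(mins=mins, maxs=maxs, epsilon=epsilon, batch_size=c.shape[0])


def normalize(c, unit: int, activation: int, stats: NGAStats,
              acts: ActivationSet, clip: bool = True):
    """Min-max normalized activation g_j^k(c); clipped to [0,1] by default."""
    j, k = activation, unit
    if j >= stats.mins.shape[0] or k >= stats.mins.shape[1]:
        raise ValueError(f"no stats for unit {k}, activation {j}")
    a = acts.apply(j, c)
    g = (a - stats.mins[j, k]) / (stats.maxs[j, k] - stats.mins[j, k] + stats.epsilon)
    if clip:
        g = g.clip(0.0, 1.0) if isinstance(g, Tensor) else np.clip(g, 0.0, 1.0)
    return g


def nga_forward(c, unit: int, params: NGAParams, stats: NGAStats,
                acts: ActivationSet):
    """y^k = sum_j eta_j^k (kappa_j g_j^k + gamma_j) for a scalar/array input."""
    m = acts.m
    if params.eta.shape[0] != m or stats.mins.shape[0] != m:
        raise ValueError("params/stats inconsistent with the activation set")
    y = None
    for j in range(m):
        g = normalize(c, unit, j, stats, acts)
        term = params.eta[j, unit] * (params.kappa[j] * g + params.gamma[j])
        y = term if y is None else y + term
    return y


def project_params(params: NGAParams) -> NGAParams:
    """Clip eta elementwise to [0,1]; kappa and gamma untouched.  Idempotent."""
    return NGAParams(eta=np.clip(params.eta, 0.0, 1.0),
                     kappa=params.kappa.copy(), gamma=params.gamma.copy())


class NGALayer:
    """Trainable NGA layer over a dense pre-activation (batch x units).

    ``init="identity"`` (default) sets eta=1/m, kappa=1, gamma=0 so the layer
    starts as the mean of the normalized activations; ``init="paper"`` uses
    the printed initial state eta=1/m, kappa=0, gamma=1 (constant output 1
    until kappa/gamma move).
    """

    def __init__(self, units: int, acts: ActivationSet | None = None,
                 epsilon: float = DEFAULT_EPSILON, init: str = "identity"):
        self.acts = acts or ActivationSet()
        self.units = units
        self.epsilon = epsilon
        m = self.acts.m
        if init == "identity":
            kappa, gamma = np.ones(m), np.zeros(m)
        elif init == "paper":
            kappa, gamma = np.zeros(m), np.ones(m)
        else:
            raise ValueError("init must be 'identity' or 'paper'")
        self.eta = Tensor(np.full((m, units), 1.0 / m), requires_grad=True)
        self.kappa = Tensor(kappa, requires_grad=True)
        self.gamma = Tensor(gamma, requires_grad=True)
        self.stats: NGAStats | None = None

    @property
    def parameters(self):
        return [self.eta, self.kappa, self.gamma]

    def estimate(self, preactivations: np.ndarray) -> NGAStats:
        self.stats = estimate_stats(preactivations, self.acts, self.epsilon)
        return self.stats

    def __call__(self, x: Tensor) -> Tensor:
        if self.stats is None:
            # bootstrap: estimate on the incoming batch (frozen thereafter);
            # a single sample gets neutral unit-interval stats instead
            data = np.atleast_2d(x.data if isinstance(x, Tensor) else x)
            if data.shape[0] >= 2:
                self.estimate(data)
            else:
                self.stats = NGAStats(mins=np.zeros((self.acts.m, self.units)),
                                      maxs=np.ones((self.acts.m, self.units)),
                                      epsilon=self.epsilon, batch_size=1)
        if not isinstance(x, Tensor):
            x = Tensor(x)
        st = self.stats
        y = None
        for j in range(self.acts.m):
            a = self.acts.apply(j, x)
            g = (a - st.mins[j]) * (1.0 / (st.maxs[j] - st.mins[j] + st.epsilon))
            g = g.clip(0.0, 1.0)
            term = self.eta[j] * (self.kappa[j] * g + self.gamma[j])
            y = term if y is None else y + term
        return y

    def project(self) -> None:
        """Enforce eta in [0,1] (call after every optimizer step)."""
        np.clip(self.eta.data, 0.0, 1.0, out=self.eta.data)

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "activations": list(self.acts.names),
            "units": self.units,
            "epsilon": self.epsilon,
            "eta": self.eta.data.tolist(),
            "kappa": self.kappa.data.tolist(),
            "gamma": self.gamma.data.tolist(),
            "stats": None if self.stats is None else {
                "mins": self.stats.mins.tolist(),
                "maxs": self.stats.maxs.tolist(),
                "epsilon": self.stats.epsilon,
                "batch_size": self.stats.batch_size,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NGALayer":
        layer = cls(units=d["units"], acts=ActivationSet(tuple(d["activations"])),
                    epsilon=d["epsilon"])
        layer.eta.data = np.asarray(d["eta"], dtype=np.float64)
        layer.kappa.data = np.asarray(d["kappa"], dtype=np.float64)
        layer.gamma.data = np.asarray(d["gamma"], dtype=np.float64)
        if d["stats"] is not None:
            s = d["stats"]
            layer.stats = NGAStats(mins=np.asarray(s["mins"]), maxs=np.asarray(s["maxs"]),
                                   epsilon=s["epsilon"], batch_size=s["batch_size"])
        return layer

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "NGALayer":
        return cls.from_dict(json.loads(Path(path).read_text()))
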