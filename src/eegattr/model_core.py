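"""Compact convolutional classifiers for multichannel EEG, written on numpy.

The module provides the model abstraction the attribution engine works on:
every network is a finite ordered list of :class:`LayerSpec` entries, each
layer exposes a forward mapping and a backward (adjoint) mapping, and the
local derivative at each elementwise nonlinearity can be replaced by a
rule-specific factor during backpropagation (see :mod:`eegattr.attribution`).

Two stock architectures are provided — ``relu-compact`` and ``elu-compact`` —
a temporal convolution followed by a spatial (cross-channel) convolution,
batch normalization, the nonlinearity, mean pooling over time and a dense
output layer.  They are deliberately small: the point is to exercise every
gradient-rule branch (ReLU vs ELU, batchnorm, pooling) on a network that
trains in seconds, not to reproduce any published architecture layer for
layer.

Batch normalization can be *frozen*: the batch mean and variance are fixed
from one forward pass of a reference batch, after which the layer is a plain
affine map.  Attribution of a single sample is then independent of whatever
other samples share its batch.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InputError

# ---------------------------------------------------------------------------
# Layer specifications
# ---------------------------------------------------------------------------

CONV_TIME = "conv-over-time"
CONV_CHANNELS = "conv-over-channels"
POINTWISE_LINEAR = "pointwise-linear"
BATCHNORM = "batchnorm"
NONLINEARITY = "nonlinearity"
POOLING = "pooling"
FLATTEN = "flatten"
DENSE = "dense"

LAYER_KINDS = (
    CONV_TIME,
    CONV_CHANNELS,
    POINTWISE_LINEAR,
    BATCHNORM,
    NONLINEARITY,
    POOLING,
    FLATTEN,
    DENSE,
)

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class LayerSpec:
    """Declarative description of one network layer.

    Parameters that do not apply to ``kind`` are left ``None``; derived
    dimensions (input feature counts, dense input width) are inferred when
    the model is built.
    """

    kind: str
    nonlinearity: str | None = None  # "relu" | "elu", for nonlinearity layers
    out_features: int | None = None  # conv feature maps
    kernel_length: int | None = None  # temporal conv kernel (odd)
    pool_size: int | None = None
    pool_kind: str = "mean"  # "mean" | "max"
    units: int | None = None  # dense output width; None => num_classes

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ConfigurationError(f"unknown layer kind {self.kind!r}")
        if self.kind == NONLINEARITY and self.nonlinearity not in ("relu", "elu"):
            raise ConfigurationError(
                f"nonlinearity must be 'relu' or 'elu', got {self.nonlinearity!r}"
            )
        if self.kind == CONV_TIME:
            if not self.kernel_length or self.kernel_length < 1 or self.kernel_length % 2 == 0:
                raise ConfigurationError("conv-over-time requires an odd kernel_length >= 1")
            if not self.out_features:
                raise ConfigurationError("conv-over-time requires out_features")
        if self.kind in (CONV_CHANNELS, POINTWISE_LINEAR) and not self.out_features:
            raise ConfigurationError(f"{self.kind} requires out_features")
        if self.kind == POOLING:
            if self.pool_size is None or self.pool_size < 0:
                raise ConfigurationError("pooling requires pool_size >= 1, or 0 for global pooling")
            if self.pool_kind not in ("mean", "max"):
                raise ConfigurationError("pool_kind must be 'mean' or 'max'")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "LayerSpec":
        return cls(**d)


def stock_architecture(name: str) -> list[LayerSpec]:
    """Return one of the stock architectures: ``relu-compact`` / ``elu-compact``."""
    if name not in ("relu-compact", "elu-compact"):
        raise ConfigurationError(f"unknown stock architecture {name!r}")
    nl = "relu" if name.startswith("relu") else "elu"
    return [
        LayerSpec(kind=CONV_TIME, out_features=12, kernel_length=33),
        LayerSpec(kind=CONV_CHANNELS, out_features=12),
        LayerSpec(kind=BATCHNORM),
        LayerSpec(kind=NONLINEARITY, nonlinearity=nl),
        LayerSpec(kind=POOLING, pool_size=0, pool_kind="mean"),  # global over time
        LayerSpec(kind=FLATTEN),
        LayerSpec(kind=DENSE),
    ]


# ---------------------------------------------------------------------------
# Gradient rules (used by the attribution engine)
# ---------------------------------------------------------------------------


@dataclass
class GradientRule:
    """How the local factor at each elementwise nonlinearity is computed.

    ``plain``     — the true derivative f'(z).
    ``deconv``    — negative backward signals are zeroed (deconvnet rule).
    ``guided``    — backward signal zeroed where it or the pre-activation z
                    is negative.
    ``lrp_eps``   — g = f(z) / (z + eps * sign(z)), sign(0) = +1.
    ``deeplift_rescale`` — g = (f(z) - f(zbar)) / (z - zbar) against the
                    pre-activations ``zbar`` of a baseline forward pass,
                    falling back to f'(z) where |z - zbar| < eps.
    """

    name: str
    epsilon: float = 1e-9

    def __post_init__(self) -> None:
        valid = ("plain", "deconv", "guided", "lrp_eps", "deeplift_rescale")
        if self.name not in valid:
            raise ConfigurationError(f"unknown gradient rule {self.name!r}")
        if self.epsilon <= 0:
            raise ConfigurationError("rule epsilon must be > 0")


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class _Layer:
    """One network layer: forward, adjoint backward, optional parameters."""

    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray, accumulate: bool = True) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, shape: tuple) -> tuple:
        raise NotImplementedError


class _TemporalConv(_Layer):
    """Same-padded 1-D convolution along the time axis, shared over channels."""

    def __init__(self, in_feat: int, out_feat: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        scale = np.sqrt(2.0 / (in_feat * kernel))
        self.params = {
            "W": rng.normal(0.0, scale, size=(out_feat, in_feat, kernel)),
            "b": np.zeros(out_feat),
        }

    def _windows(self, x: np.ndarray) -> np.ndarray:
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (p, p)))
        return np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=3)

    def forward(self, x, train=False):
        win = self._windows(x)
        self._cache = win
        W, b = self.params["W"], self.params["b"]
        return np.einsum("bfntk,ofk->bont", win, W) + b[None, :, None, None]

    def backward(self, g, accumulate=True):
        W = self.params["W"]
        if accumulate:
            self.grads["W"] = np.einsum("bont,bfntk->ofk", g, self._cache)
            self.grads["b"] = g.sum(axis=(0, 2, 3))
        gwin = self._windows(g)
        return np.einsum("bontk,ofk->bfnt", gwin, W[:, :, ::-1])

    def out_shape(self, shape):
        _, n, t = shape
        return (self.params["W"].shape[0], n, t)


class _ChannelConv(_Layer):
    """Full-height spatial filter collapsing the channel axis."""

    def __init__(self, in_feat: int, out_feat: int, n_channels: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (in_feat * n_channels))
        self.params = {
            "W": rng.normal(0.0, scale, size=(out_feat, in_feat, n_channels)),
            "b": np.zeros(out_feat),
        }

    def forward(self, x, train=False):
        self._cache = x
        W, b = self.params["W"], self.params["b"]
        y = np.einsum("bfnt,ofn->bot", x, W) + b[None, :, None]
        return y[:, :, None, :]

    def backward(self, g, accumulate=True):
        g2 = g[:, :, 0, :]
        if accumulate:
            self.grads["W"] = np.einsum("bot,bfnt->ofn", g2, self._cache)
            self.grads["b"] = g2.sum(axis=(0, 2))
        return np.einsum("bot,ofn->bfnt", g2, self.params["W"])

    def out_shape(self, shape):
        _, _, t = shape
        return (self.params["W"].shape[0], 1, t)


class _PointwiseLinear(_Layer):
    """1x1 mixing of feature maps."""

    def __init__(self, in_feat: int, out_feat: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / in_feat)
        self.params = {
            "W": rng.normal(0.0, scale, size=(out_feat, in_feat)),
            "b": np.zeros(out_feat),
        }

    def forward(self, x, train=False):
        self._cache = x
        return np.einsum("bfnt,of->bont", x, self.params["W"]) + self.params["b"][None, :, None, None]

    def backward(self, g, accumulate=True):
        if accumulate:
            self.grads["W"] = np.einsum("bont,bfnt->of", g, self._cache)
            self.grads["b"] = g.sum(axis=(0, 2, 3))
        return np.einsum("bont,of->bfnt", g, self.params["W"])

    def out_shape(self, shape):
        _, n, t = shape
        return (self.params["W"].shape[0], n, t)


class _BatchNorm(_Layer):
    """Per-feature normalization over (batch, channel, time).

    In training mode the batch statistics are used and running averages are
    updated.  In evaluation mode the running (or explicitly frozen)
    statistics are constants, so the layer is a fixed affine map and its
    adjoint is simply gamma / sqrt(var + eps).
    """

    def __init__(self, n_feat: int):
        super().__init__()
        self.params = {"gamma": np.ones(n_feat), "beta": np.zeros(n_feat)}
        self.running_mean = np.zeros(n_feat)
        self.running_var = np.ones(n_feat)
        self.frozen = False
        self.frozen_mean: np.ndarray | None = None
        self.frozen_var: np.ndarray | None = None

    def _stats(self, train: bool) -> tuple[np.ndarray, np.ndarray]:
        if self.frozen:
            return self.frozen_mean, self.frozen_var
        if train:
            raise RuntimeError("train-mode stats are computed in forward")
        return self.running_mean, self.running_var

    def forward(self, x, train=False):
        g, b = self.params["gamma"], self.params["beta"]
        if train and not self.frozen:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - _BN_MOMENTUM) * self.running_mean + _BN_MOMENTUM * mu
            self.running_var = (1 - _BN_MOMENTUM) * self.running_var + _BN_MOMENTUM * var
            self._train_mode = True
        else:
            mu, var = self._stats(train=False)
            self._train_mode = False
        s = np.sqrt(var + _BN_EPS)
        xhat = (x - mu[None, :, None, None]) / s[None, :, None, None]
        self._cache = (xhat, s)
        return g[None, :, None, None] * xhat + b[None, :, None, None]

    def backward(self, g, accumulate=True):
        xhat, s = self._cache
        gamma = self.params["gamma"]
        if accumulate:
            self.grads["gamma"] = (g * xhat).sum(axis=(0, 2, 3))
            self.grads["beta"] = g.sum(axis=(0, 2, 3))
        coef = (gamma / s)[None, :, None, None]
        if not self._train_mode:
            return g * coef
        m = g.shape[0] * g.shape[2] * g.shape[3]
        sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
        sum_gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return coef * (g - sum_g / m - xhat * sum_gx / m)

    def freeze(self, mean: np.ndarray, var: np.ndarray) -> None:
        self.frozen = True
        self.frozen_mean = np.asarray(mean, dtype=float).copy()
        self.frozen_var = np.asarray(var, dtype=float).copy()

    def out_shape(self, shape):
        return shape


class _Nonlinearity(_Layer):
    """Elementwise relu/elu; backward factor replaceable by a GradientRule."""

    def __init__(self, name: str):
        super().__init__()
        self.name = name
        self.rule: GradientRule | None = None  # set by the attribution engine
        self.baseline_z: np.ndarray | None = None

    def f(self, z):
        if self.name == "relu":
            return np.maximum(z, 0.0)
        return np.where(z > 0, z, np.expm1(z))

    def fprime(self, z):
        if self.name == "relu":
            return (z > 0).astype(z.dtype)
        return np.where(z > 0, 1.0, np.exp(z))

    def forward(self, x, train=False):
        self._z = x
        return self.f(x)

    def backward(self, g, accumulate=True):
        z = self._z
        rule = self.rule
        if rule is None or rule.name == "plain":
            return g * self.fprime(z)
        if rule.name == "deconv":
            return g * (g > 0)
        if rule.name == "guided":
            return g * ((g > 0) & (z > 0))
        if rule.name == "lrp_eps":
            denom = z + rule.epsilon * np.where(z >= 0, 1.0, -1.0)
            return g * self.f(z) / denom
        if rule.name == "deeplift_rescale":
            zb = self.baseline_z
            if zb is None:
                raise ConfigurationError("deeplift_rescale rule requires baseline pre-activations")
            dz = z - zb
            degenerate = np.abs(dz) < rule.epsilon
            safe = np.where(degenerate, 1.0, dz)
            factor = np.where(degenerate, self.fprime(z), (self.f(z) - self.f(zb)) / safe)
            return g * factor
        raise ConfigurationError(f"unknown gradient rule {rule.name!r}")

    def out_shape(self, shape):
        return shape


class _Pool(_Layer):
    """Pooling along time with stride == window; trailing remainder dropped.

    ``size == 0`` pools globally over the whole time axis.
    """

    def __init__(self, size: int, kind: str):
        super().__init__()
        self.size = size
        self.kind = kind

    def _window(self, t: int) -> int:
        return t if self.size == 0 else self.size

    def forward(self, x, train=False):
        size = self._window(x.shape[3])
        self._fwd_size = size
        t_out = x.shape[3] // size
        xv = x[:, :, :, : t_out * size].reshape(
            x.shape[0], x.shape[1], x.shape[2], t_out, size
        )
        self._in_t = x.shape[3]
        if self.kind == "mean":
            return xv.mean(axis=4)
        self._argmax = xv.argmax(axis=4)  # first index on ties
        return xv.max(axis=4)

    def backward(self, g, accumulate=True):
        b, f, n, t_out = g.shape
        size = self._fwd_size
        out = np.zeros((b, f, n, self._in_t))
        blk = out[:, :, :, : t_out * size].reshape(b, f, n, t_out, size)
        if self.kind == "mean":
            blk[:] = g[..., None] / size
        else:
            np.put_along_axis(blk, self._argmax[..., None], g[..., None], axis=4)
        return out

    def out_shape(self, shape):
        f, n, t = shape
        return (f, n, t // self._window(t))


class _Flatten(_Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g, accumulate=True):
        return g.reshape(self._shape)

    def out_shape(self, shape):
        return (int(np.prod(shape)),)


class _Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params = {"W": rng.normal(0.0, scale, size=(n_out, n_in)), "b": np.zeros(n_out)}

    def forward(self, x, train=False):
        self._cache = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, g, accumulate=True):
        if accumulate:
            self.grads["W"] = g.T @ self._cache
            self.grads["b"] = g.sum(axis=0)
        return g @ self.params["W"]

    def out_shape(self, shape):
        return (self.params["W"].shape[0],)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass
class ClassScores:
    """Pre-softmax activations and softmax probabilities for one sample."""

    activations: np.ndarray
    probabilities: np.ndarray

    @classmethod
    def from_activations(cls, a: np.ndarray) -> "ClassScores":
        return cls(activations=a, probabilities=softmax(a))


def softmax(a: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(a - a.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


class Model:
    """An ordered stack of layers mapping a channels x time sample to class scores."""

    def __init__(self, arch: Sequence[LayerSpec], num_classes: int, input_shape: tuple[int, int], seed: int, tag: str = "model"):
        self.arch = list(arch)
        self.num_classes = int(num_classes)
        self.input_shape = tuple(int(v) for v in input_shape)
        self.seed = int(seed)
        self.tag = tag
        self.layers = self._build(np.random.default_rng(seed))

    def _build(self, rng: np.random.Generator) -> list[_Layer]:
        n, t = self.input_shape
        shape: tuple = (1, n, t)  # (features, channels, time)
        flat = False
        layers: list[_Layer] = []
        for i, spec in enumerate(self.arch):
            if spec.kind in (CONV_TIME, CONV_CHANNELS, POINTWISE_LINEAR, BATCHNORM, POOLING):
                if flat:
                    raise ConfigurationError(f"layer {i}: {spec.kind} cannot follow flatten")
            if spec.kind == DENSE and not flat:
                raise ConfigurationError(f"layer {i}: dense requires a preceding flatten")
            if spec.kind == CONV_TIME:
                layer = _TemporalConv(shape[0], spec.out_features, spec.kernel_length, rng)
            elif spec.kind == CONV_CHANNELS:
                layer = _ChannelConv(shape[0], spec.out_features, shape[1], rng)
            elif spec.kind == POINTWISE_LINEAR:
                layer = _PointwiseLinear(shape[0], spec.out_features, rng)
            elif spec.kind == BATCHNORM:
                layer = _BatchNorm(shape[0])
            elif spec.kind == NONLINEARITY:
                layer = _Nonlinearity(spec.nonlinearity)
            elif spec.kind == POOLING:
                layer = _Pool(spec.pool_size, spec.pool_kind)
            elif spec.kind == FLATTEN:
                layer = _Flatten()
                flat = True
            elif spec.kind == DENSE:
                units = spec.units if spec.units is not None else self.num_classes
                layer = _Dense(shape[0], units, rng)
            else:  # pragma: no cover - guarded by LayerSpec
                raise ConfigurationError(f"unknown layer kind {spec.kind!r}")
            shape = layer.out_shape(shape)
            layers.append(layer)
        if not self.arch or self.arch[-1].kind != DENSE:
            raise ConfigurationError("the final layer must be dense (one score per class)")
        if shape[0] != self.num_classes:
            raise ConfigurationError(
                f"output width {shape[0]} does not match num_classes {self.num_classes}"
            )
        return layers

    # -- forward ------------------------------------------------------------

    def _check_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1:] != self.input_shape:
            raise InputError(
                f"batch shape {x.shape} does not match model input {self.input_shape}"
            )
        if not np.all(np.isfinite(x)):
            raise InputError("batch contains non-finite values")
        return x

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Pre-softmax activations, shape (batch, num_classes)."""
        a = self._check_batch(x)[:, None, :, :]
        for layer in self.layers:
            a = layer.forward(a, train=train)
        return a

    def backward(self, g_out: np.ndarray, accumulate: bool = True) -> np.ndarray:
        """Adjoint pass from output-space gradient to input-space gradient."""
        g = g_out
        for layer in reversed(self.layers):
            g = layer.backward(g, accumulate=accumulate)
        return g[:, 0, :, :]

    def input_gradient(
        self,
        x: np.ndarray,
        target_class: int | np.ndarray,
        rule: GradientRule,
        baseline: np.ndarray | None = None,
    ) -> np.ndarray:
        """(Modified) gradient of S_c w.r.t. the input, shape (batch, N, T).

        For the deeplift_rescale rule a second forward pass on ``baseline``
        records the baseline pre-activations at every nonlinearity.
        """
        x = self._check_batch(x)
        nls = [l for l in self.layers if isinstance(l, _Nonlinearity)]
        if rule.name == "deeplift_rescale":
            if baseline is None:
                raise ConfigurationError("deeplift_rescale requires a baseline")
            self.forward(np.asarray(baseline, dtype=float))
            for l in nls:
                l.baseline_z = l._z
        act = self.forward(x)
        for l in nls:
            l.rule = rule
        try:
            seed = np.zeros_like(act)
            if np.isscalar(target_class) or np.asarray(target_class).ndim == 0:
                seed[:, int(target_class)] = 1.0
            else:
                seed[np.arange(act.shape[0]), np.asarray(target_class, dtype=int)] = 1.0
            grad = self.backward(seed, accumulate=False)
        finally:
            for l in nls:
                l.rule = None
                l.baseline_z = None
        return grad

    # -- parameters ----------------------------------------------------------

    def parameters(self) -> list[tuple[_Layer, str, np.ndarray]]:
        return [(l, k, v) for l in self.layers for k, v in l.params.items()]

    def get_state(self) -> list[np.ndarray]:
        return [v.copy() for _, _, v in self.parameters()]

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        for (layer, key, _), val in zip(self.parameters(), state):
            layer.params[key] = val.copy()

    @property
    def has_frozen_stats(self) -> bool:
        return any(isinstance(l, _BatchNorm) and l.frozen for l in self.layers)


def build_model(
    arch: Sequence[LayerSpec] | str,
    num_classes: int,
    input_shape: tuple[int, int],
    seed: int,
    tag: str | None = None,
) -> Model:
    """Build a model with seeded random initialization.

    ``arch`` may be a stock-architecture name ("relu-compact"/"elu-compact")
    or an explicit list of LayerSpecs.
    """
    if isinstance(arch, str):
        tag = tag or arch
        arch = stock_architecture(arch)
    return Model(arch, num_classes, input_shape, seed, tag=tag or "model")


def forward_scores(model: Model, batch: Sequence) -> list[ClassScores]:
    """Class scores (activations + softmax probabilities) for a batch of samples."""
    values = np.stack([np.asarray(getattr(s, "values", s), dtype=float) for s in batch])
    act = model.forward(values)
    return [ClassScores.from_activations(a) for a in act]


def freeze_batch_stats(model: Model, reference_batch: Sequence) -> Model:
    """Return a copy of ``model`` whose batchnorm layers are fixed affine maps.

    The mean/variance constants are captured from a single forward pass of
    ``reference_batch``; attribution of one sample is then independent of the
    other samples in its batch.
    """
    if len(reference_batch) == 0:
        raise InputError("reference batch must not be empty")
    frozen = copy.deepcopy(model)
    values = np.stack([np.asarray(getattr(s, "values", s), dtype=float) for s in reference_batch])
    a = frozen._check_batch(values)[:, None, :, :]
    for layer in frozen.layers:
        if isinstance(layer, _BatchNorm):
            layer.freeze(a.mean(axis=(0, 2, 3)), a.var(axis=(0, 2, 3)))
        a = layer.forward(a, train=False)
    return frozen


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Adam demo-trainer settings (defaults: lr 1e-3, betas 0.9/0.999, batch 50)."""

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 50
    max_epochs: int = 50
    class_weights: dict[int, float] | None = None
    seed: int = 0
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.max_epochs > 50:
            raise ConfigurationError("max_epochs must be <= 50")
        if self.class_weights is not None and any(w <= 0 for w in self.class_weights.values()):
            raise ConfigurationError("class weights must be strictly positive")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ConfigurationError("val_fraction must be in [0, 1)")


@dataclass
class TrainHistory:
    epoch_loss: list[float] = field(default_factory=list)
    epoch_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _weighted_ce(act: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, np.ndarray]:
    p = softmax(act)
    b = act.shape[0]
    wy = w[y]
    loss = float(-(wy * np.log(np.maximum(p[np.arange(b), y], 1e-300))).mean())
    grad = p.copy()
    grad[np.arange(b), y] -= 1.0
    grad *= wy[:, None] / b
    return loss, grad


def train(model: Model, samples: Sequence, labels: Sequence[int], config: TrainConfig) -> tuple[Model, TrainHistory]:
    """Train a copy of ``model`` with Adam + weighted cross-entropy.

    A held-out validation split (``val_fraction``) selects the best epoch by
    lowest validation loss; the returned model carries that epoch's
    parameters.  Fully reproducible from ``config.seed``.
    """
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ConfigurationError("training requires at least two classes in the dataset")
    x = np.stack([np.asarray(getattr(s, "values", s), dtype=float) for s in samples])
    if x.shape[1:] != model.input_shape:
        raise InputError(f"sample shape {x.shape[1:]} does not match model input {model.input_shape}")

    w = np.ones(int(classes.max()) + 1)
    if config.class_weights:
        for c, cw in config.class_weights.items():
            w[int(c)] = float(cw)

    net = copy.deepcopy(model)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(y))
    n_val = int(round(config.val_fraction * len(y)))
    val_idx, tr_idx = order[:n_val], order[n_val:]

    params = net.parameters()
    m = [np.zeros_like(v) for _, _, v in params]
    v2 = [np.zeros_like(v) for _, _, v in params]
    t_step = 0
    hist = TrainHistory()
    best_state, best_val = net.get_state(), np.inf

    for epoch in range(config.max_epochs):
        perm = rng.permutation(tr_idx)
        losses = []
        for start in range(0, len(perm), config.batch_size):
            idx = perm[start : start + config.batch_size]
            act = net.forward(x[idx], train=True)
            loss, g = _weighted_ce(act, y[idx], w)
            losses.append(loss)
            net.backward(g, accumulate=True)
            t_step += 1
            for j, (layer, key, _) in enumerate(net.parameters()):
                grad = layer.grads.get(key)
                if grad is None:
                    continue
                m[j] = config.beta1 * m[j] + (1 - config.beta1) * grad
                v2[j] = config.beta2 * v2[j] + (1 - config.beta2) * grad**2
                mhat = m[j] / (1 - config.beta1**t_step)
                vhat = v2[j] / (1 - config.beta2**t_step)
                layer.params[key] = layer.params[key] - config.learning_rate * mhat / (np.sqrt(vhat) + 1e-8)

        act_tr = net.forward(x[tr_idx])
        loss_tr, _ = _weighted_ce(act_tr, y[tr_idx], w)
        hist.epoch_loss.append(loss_tr)
        hist.epoch_accuracy.append(float((act_tr.argmax(axis=1) == y[tr_idx]).mean()))
        if len(val_idx):
            act_val = net.forward(x[val_idx])
            loss_val, _ = _weighted_ce(act_val, y[val_idx], w)
            hist.val_loss.append(loss_val)
            hist.val_accuracy.append(float((act_val.argmax(axis=1) == y[val_idx]).mean()))
        else:
            loss_val = loss_tr
            hist.val_loss.append(loss_val)
            hist.val_accuracy.append(hist.epoch_accuracy[-1])
        if loss_val < best_val:
            best_val = loss_val
            best_state = net.get_state()
            hist.best_epoch = epoch

    net.set_state(best_state)
    return net, hist


def train_with_restarts(
    arch: Sequence[LayerSpec] | str,
    num_classes: int,
    input_shape: tuple[int, int],
    samples: Sequence,
    labels: Sequence[int],
    config: TrainConfig,
    n_restarts: int = 3,
    tag: str | None = None,
) -> tuple[Model, TrainHistory]:
    """Train from several seeded initializations and keep the best restart.

    Stochastic initialization occasionally lands in a poor basin; restarting
    with consecutive seeds and selecting by validation loss makes the demo
    trainer robust without touching the optimizer settings.
    """
    import dataclasses as _dc

    best: tuple[Model, TrainHistory, float] | None = None
    for r in range(n_restarts):
        seed_r = config.seed + r
        model = build_model(arch, num_classes, input_shape, seed=seed_r, tag=tag)
        trained, hist = train(model, samples, labels, _dc.replace(config, seed=seed_r))
        val = hist.val_loss[hist.best_epoch] if hist.best_epoch >= 0 else np.inf
        if best is None or val < best[2]:
            best = (trained, hist, val)
    return best[0], best[1]


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: Model, path) -> None:
    """Serialize parameters plus a JSON header describing the architecture."""
    header = {
        "arch": [s.to_dict() for s in model.arch],
        "num_classes": model.num_classes,
        "input_shape": list(model.input_shape),
        "seed": model.seed,
        "tag": model.tag,
        "frozen": model.has_frozen_stats,
    }
    arrays = {}
    for i, layer in enumerate(model.layers):
        for k, val in layer.params.items():
            arrays[f"p{i}__{k}"] = val
        if isinstance(layer, _BatchNorm):
            arrays[f"s{i}__running_mean"] = layer.running_mean
            arrays[f"s{i}__running_var"] = layer.running_var
            if layer.frozen:
                arrays[f"s{i}__frozen_mean"] = layer.frozen_mean
                arrays[f"s{i}__frozen_var"] = layer.frozen_var
    with open(path, "wb") as fh:
        np.savez(fh, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> Model:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        model = Model(
            [LayerSpec.from_dict(d) for d in header["arch"]],
            header["num_classes"],
            tuple(header["input_shape"]),
            header["seed"],
            tag=header["tag"],
        )
        for i, layer in enumerate(model.layers):
            for k in list(layer.params):
                layer.params[k] = data[f"p{i}__{k}"].copy()
            if isinstance(layer, _BatchNorm):
                layer.running_mean = data[f"s{i}__running_mean"].copy()
                layer.running_var = data[f"s{i}__running_var"].copy()
                if f"s{i}__frozen_mean" in data:
                    layer.freeze(data[f"s{i}__frozen_mean"], data[f"s{i}__frozen_var"])
    return model
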