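"""Contribution maps for EEG classifiers: seven backpropagation-based methods.

Each method assigns a score R_c(i, j) to every sampling point X(i, j) of a
channels x time EEG sample, quantifying its contribution to the model's
pre-softmax score S_c for a target class c.  All seven methods share one
engine: a backward pass in which the local derivative f'(z) at each
elementwise nonlinearity may be replaced by a rule-specific factor g
(:class:`eegattr.model_core.GradientRule`):

===================  =======================================================
method               scores
===================  =======================================================
saliency             dS_c/dx (signed; absolute value behind a flag)
deconvolution        modified gradient, negative backward signals zeroed
guided_backprop      modified gradient, zeroed where backward signal or
                     pre-activation is negative
gradient_x_input     x * dS_c/dx
integrated_gradient  (x - xbar) * mean of dS_c/dx along the straight path
                     from xbar to x (midpoint rule, m steps)
lrp_eps              x * modified gradient with g = f(z)/(z + eps*sign(z))
deeplift_rescale     (x - xbar) * modified gradient with
                     g = (f(z) - f(zbar))/(z - zbar)
===================  =======================================================

On a purely linear model the last four collapse to w_ji * x_i while the
first three return the input-independent w_ji — the analytic basis for the
two performance groups seen in the faithfulness tests.

Averaging a contribution map over time yields the channel contribution map
(one score per electrode).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InputError, NumericalError
from .model_core import GradientRule, Model

METHODS = (
    "saliency",
    "deconvolution",
    "guided_backprop",
    "gradient_x_input",
    "integrated_gradient",
    "lrp_eps",
    "deeplift_rescale",
)

#: methods whose maps scale with the input (faithful on linear models)
GROUP_INPUT_SCALED = ("gradient_x_input", "integrated_gradient", "lrp_eps", "deeplift_rescale")
#: methods whose maps are input-independent on linear models
GROUP_GRADIENT_ONLY = ("saliency", "deconvolution", "guided_backprop")


@dataclass
class EEGSample:
    """One EEG sample: an N x T matrix of amplitudes (microvolts) + metadata."""

    values: np.ndarray
    channel_names: list[str]
    sampling_rate: float
    label: int | None = None
    subject: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise InputError(f"sample values must be a 2-D N x T matrix, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise InputError("sample contains non-finite values")
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != self.values.shape[0]:
            raise InputError(
                f"{len(self.channel_names)} channel names for {self.values.shape[0]} rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise InputError("channel names must be unique")
        if self.sampling_rate <= 0:
            raise InputError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "EEGSample":
        return EEGSample(
            self.values.copy(), list(self.channel_names), self.sampling_rate,
            label=self.label, subject=self.subject,
        )


@dataclass
class ContributionMap:
    """Per-point scores for one sample / target class / method."""

    scores: np.ndarray
    target_class: int
    method: str
    model_tag: str = "model"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise InputError("contribution map scores must be 2-D")
        if not np.all(np.isfinite(self.scores)):
            raise NumericalError("contribution map contains non-finite scores")

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape


@dataclass
class ChannelContributionMap:
    """Per-channel mean scores (temporal average of a contribution map)."""

    scores: np.ndarray
    target_class: int
    method: str
    model_tag: str = "model"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise InputError("channel contribution map scores must be 1-D")


@dataclass
class AttributionConfig:
    """Method selection and engine settings.

    ``baseline`` defaults to the all-zero sample; ``ig_steps`` is the number
    of path points for integrated gradients; ``lrp_epsilon`` stabilizes the
    LRP rule and doubles as the DeepLIFT degeneracy cutoff.
    """

    method: str = "gradient_x_input"
    baseline: np.ndarray | None = None
    ig_steps: int = 100
    lrp_epsilon: float = 1e-9
    saliency_absolute: bool = False
    batch_stat_mode: str = "frozen-from-batch"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown attribution method {self.method!r}")
        if self.ig_steps < 1:
            raise ConfigurationError("ig_steps must be >= 1")
        if self.lrp_epsilon <= 0:
            raise ConfigurationError("lrp_epsilon must be > 0")
        if self.batch_stat_mode not in ("running", "frozen-from-batch"):
            raise ConfigurationError(f"unknown batch_stat_mode {self.batch_stat_mode!r}")


def _as_values(sample) -> np.ndarray:
    return np.asarray(getattr(sample, "values", sample), dtype=float)


def modified_gradient(
    model: Model,
    sample,
    target_class: int,
    rule: str | GradientRule,
    baseline: np.ndarray | None = None,
    epsilon: float = 1e-9,
) -> np.ndarray:
    """Backpropagated dS_c/dx with the nonlinearity factor replaced per ``rule``.

    ``rule`` is one of plain / deconv / guided / lrp_eps / deeplift_rescale
    (or a :class:`GradientRule`).  The deeplift_rescale rule runs a second
    forward pass on ``baseline`` (default all-zero) to obtain the baseline
    pre-activations.
    """
    if isinstance(rule, str):
        rule = GradientRule(rule, epsilon=epsilon)
    x = _as_values(sample)
    if x.ndim != 2:
        raise InputError("modified_gradient expects a single N x T sample")
    if rule.name == "deeplift_rescale" and baseline is None:
        baseline = np.zeros_like(x)
    grad = model.input_gradient(x, target_class, rule, baseline=baseline)[0]
    if not np.all(np.isfinite(grad)):
        raise NumericalError("modified gradient produced non-finite values")
    return grad


def compute_contribution(
    model: Model,
    sample,
    target_class: int,
    config: AttributionConfig | None = None,
) -> ContributionMap:
    """Contribution map R_c for one sample, one target class, one method."""
    config = config or AttributionConfig()
    x = _as_values(sample)
    if x.shape != model.input_shape:
        raise InputError(f"sample shape {x.shape} does not match model input {model.input_shape}")
    baseline = config.baseline
    if baseline is None:
        baseline = np.zeros_like(x)
    else:
        baseline = np.asarray(baseline, dtype=float)
        if baseline.shape != x.shape:
            raise InputError(f"baseline shape {baseline.shape} does not match sample {x.shape}")

    method = config.method
    if method == "saliency":
        g = modified_gradient(model, x, target_class, "plain")
        scores = np.abs(g) if config.saliency_absolute else g
    elif method == "deconvolution":
        scores = modified_gradient(model, x, target_class, "deconv")
    elif method == "guided_backprop":
        scores = modified_gradient(model, x, target_class, "guided")
    elif method == "gradient_x_input":
        scores = x * modified_gradient(model, x, target_class, "plain")
    elif method == "integrated_gradient":
        # midpoint quadrature of the path integral: O(1/m^2) completeness
        # error; evaluated in chunks to bound peak memory at large step counts
        m = config.ig_steps
        alphas = (np.arange(m) + 0.5) / m
        total = np.zeros_like(x)
        for start in range(0, m, 128):
            a = alphas[start : start + 128]
            path = baseline[None] + a[:, None, None] * (x - baseline)[None]
            total += model.input_gradient(path, target_class, GradientRule("plain")).sum(axis=0)
        scores = (x - baseline) * total / m
    elif method == "lrp_eps":
        scores = x * modified_gradient(model, x, target_class, "lrp_eps", epsilon=config.lrp_epsilon)
    elif method == "deeplift_rescale":
        scores = (x - baseline) * modified_gradient(
            model, x, target_class, "deeplift_rescale", baseline=baseline, epsilon=config.lrp_epsilon
        )
    else:  # pragma: no cover - guarded by AttributionConfig
        raise ConfigurationError(f"unknown attribution method {method!r}")
    return ContributionMap(scores=scores, target_class=int(target_class), method=method, model_tag=model.tag)


def channel_contribution(cmap: ContributionMap) -> ChannelContributionMap:
    """Temporal mean of a contribution map: one score per channel."""
    return ChannelContributionMap(
        scores=cmap.scores.mean(axis=1),
        target_class=cmap.target_class,
        method=cmap.method,
        model_tag=cmap.model_tag,
        meta=dict(cmap.meta),
    )


def attribute_batch(
    model: Model,
    samples: Sequence,
    methods: Sequence[str],
    config: AttributionConfig | None = None,
) -> dict[str, list[ContributionMap]]:
    """Contribution maps for each sample's *predicted* class, per method."""
    from .model_core import forward_scores

    base = config or AttributionConfig()
    preds = [int(np.argmax(s.activations)) for s in forward_scores(model, samples)]
    out: dict[str, list[ContributionMap]] = {}
    for method in methods:
        cfg = AttributionConfig(
            method=method, baseline=base.baseline, ig_steps=base.ig_steps,
            lrp_epsilon=base.lrp_epsilon, saliency_absolute=base.saliency_absolute,
            batch_stat_mode=base.batch_stat_mode,
        )
        out[method] = [
            compute_contribution(model, s, c, cfg) for s, c in zip(samples, preds)
        ]
    return out
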