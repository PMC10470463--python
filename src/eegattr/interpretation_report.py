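"""Map post-processing, overlay rendering and the sample-wise trust report.

Raw backpropagation-based contribution maps are too noisy to read directly.
The fixed processing pipeline is normalize -> threshold -> smooth:

1. **normalize** — global z-score of the map;
2. **threshold** — entries below the cutoff (default 2 for sample maps,
   1 for channel maps) are zeroed, keeping only strong positive evidence;
3. **smooth**    — centred moving average along time (default window 5),
   shrinking to the valid overlap at the boundaries.

The sample-wise evaluation report bundles, for one sample: the model and
processing settings; the sensitivity-test correlations of the *original*
map per patch fraction plus the channel-level correlation; the deletion
outcome of the *processed* map (new probability after removing the
highlighted points, the deleted portion, and the top-3 channels by deleted
portion); the channel-deletion outcome (new probability after removing the
supra-threshold channels); and the prediction metadata.  It renders as a
four-line text block and serializes to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from typing import Sequence

import numpy as np

from .attribution import ChannelContributionMap, ContributionMap, EEGSample
from .errors import ConfigurationError, InputError, PipelineOrderError
from .evaluation import (
    DEFAULT_PATCH_FRACTIONS,
    PerturbationSpec,
    patch_length,
    sensitivity_test,
    sensitivity_test_channels,
)
from .model_core import Model, softmax

_DEGENERATE_STD = 1e-12


@dataclass
class VisualizationConfig:
    """Thresholds and smoothing for map post-processing.

    Thresholds are cutoffs on the z-scored map (standard-score units);
    ``signed_threshold`` keeps |v| >= threshold instead of v >= threshold.
    """

    sample_threshold: float = 2.0
    channel_threshold: float = 1.0
    smoothing_window: int = 5
    normalization: str = "zscore"
    signed_threshold: bool = False

    def __post_init__(self) -> None:
        if self.sample_threshold < 0 or self.channel_threshold < 0:
            raise ConfigurationError("thresholds must be >= 0")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ConfigurationError("smoothing_window must be odd and >= 1")
        if self.normalization != "zscore":
            raise ConfigurationError("only zscore normalization is supported")


def _stage(cmap) -> str:
    return cmap.meta.get("stage", "raw")


def normalize_map(cmap: ContributionMap) -> ContributionMap:
    """Global z-score of all entries; constant maps come back all-zero, flagged."""
    if _stage(cmap) in ("thresholded", "processed"):
        raise PipelineOrderError("normalize must precede thresholding/smoothing")
    mu = cmap.scores.mean()
    sd = cmap.scores.std()
    degenerate = sd < _DEGENERATE_STD
    scores = np.zeros_like(cmap.scores) if degenerate else (cmap.scores - mu) / sd
    meta = dict(cmap.meta, stage="normalized", degenerate=bool(degenerate), normalization="zscore")
    return ContributionMap(scores, cmap.target_class, cmap.method, cmap.model_tag, meta)


def threshold_map(cmap: ContributionMap, threshold: float, signed: bool = False) -> ContributionMap:
    """Zero entries below ``threshold`` on a *normalized* map.

    Default keeps only positive evidence (v >= threshold); ``signed`` keeps
    |v| >= threshold.
    """
    if _stage(cmap) != "normalized":
        raise PipelineOrderError("threshold_map requires a normalized map (normalize first)")
    keep = np.abs(cmap.scores) >= threshold if signed else cmap.scores >= threshold
    scores = np.where(keep, cmap.scores, 0.0)
    meta = dict(cmap.meta, stage="thresholded", threshold=float(threshold), signed=bool(signed))
    return ContributionMap(scores, cmap.target_class, cmap.method, cmap.model_tag, meta)


def smooth_map(cmap: ContributionMap, window: int) -> ContributionMap:
    """Centred moving average along time, per channel; boundary windows shrink."""
    if window < 1 or window % 2 == 0:
        raise ConfigurationError("smoothing window must be odd and >= 1")
    kernel = np.ones(window)
    sums = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, cmap.scores)
    counts = np.convolve(np.ones(cmap.scores.shape[1]), kernel, mode="same")
    scores = sums / counts[None, :]
    meta = dict(cmap.meta, stage="processed", smoothing_window=int(window))
    return ContributionMap(scores, cmap.target_class, cmap.method, cmap.model_tag, meta)


def process_map(cmap: ContributionMap, config: VisualizationConfig, threshold: float | None = None) -> ContributionMap:
    """The fixed pipeline: normalize -> threshold -> smooth."""
    thr = config.sample_threshold if threshold is None else threshold
    out = normalize_map(cmap)
    if out.meta.get("degenerate"):
        return out
    out = threshold_map(out, thr, signed=config.signed_threshold)
    return smooth_map(out, config.smoothing_window)


def _normalize_channel_map(chmap: ChannelContributionMap) -> tuple[np.ndarray, bool]:
    sd = chmap.scores.std()
    if sd < _DEGENERATE_STD:
        return np.zeros_like(chmap.scores), True
    return (chmap.scores - chmap.scores.mean()) / sd, False


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Fig-style sample-wise trust report (four-line text block + JSON)."""

    model_tag: str
    method: str
    smoothing_window: int
    sample_threshold: float
    channel_threshold: float
    predicted_class: int
    label: int | None
    class_probabilities: list[float]
    sensitivity_pcc: dict[str, float]  # patch fraction (as str) -> r
    channel_sensitivity_pcc: float
    deletion_probability: float | None
    deleted_portion: float
    deleted_portion_exact: str  # exact rational "k/NT"
    top_channels: list[dict]  # [{channel, name, portion}], up to 3
    channel_deletion_probability: float | None
    deleted_channels: list[str]
    degenerate: bool = False
    assumptions: dict = field(default_factory=lambda: {
        "normalization": "global zscore",
        "pipeline_order": "normalize->threshold->smooth",
        "threshold_mode": "positive scores only",
    })

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        return cls(**json.loads(text))

    def render_text(self) -> str:
        """The four-line report block shown under the overlay figure."""
        line1 = (
            f"model: {self.model_tag} | method: {self.method} | "
            f"window: {self.smoothing_window} | thresholds: "
            f"{self.sample_threshold:g}/{self.channel_threshold:g}"
        )
        pccs = ", ".join(f"{k}: {v:.2f}" for k, v in self.sensitivity_pcc.items())
        line2 = f"sensitivity r [{pccs}] | channel r: {self.channel_sensitivity_pcc:.2f}"
        if self.degenerate or self.deletion_probability is None:
            line3 = "sample deletion: skipped (degenerate map)"
            line4 = "channel deletion: skipped (degenerate map)"
        else:
            tops = ", ".join(
                f"{t['name']} ({t['portion']:.3f})" for t in self.top_channels
            )
            line3 = (
                f"prob after deletion: {self.deletion_probability:.2f} | "
                f"portion deleted: {self.deleted_portion:.2f} | top channels: {tops}"
            )
            line4 = (
                f"prob after channel deletion: {self.channel_deletion_probability:.2f} | "
                f"channels: {', '.join(self.deleted_channels) or 'none'}"
            )
        return "\n".join([line1, line2, line3, line4])


def generate_report(
    model: Model,
    sample: EEGSample,
    cmap: ContributionMap,
    chmap: ChannelContributionMap,
    vis_config: VisualizationConfig | None = None,
    patch_fractions: Sequence[float] = DEFAULT_PATCH_FRACTIONS,
    num_perturbations: int = 100,
    seed: int = 0,
    fill_value: float = 0.0,
) -> EvaluationReport:
    """Sample-wise evaluation: sensitivity on the original map, deletion on
    the processed map.

    The sample-level deletion zeroes exactly the points surviving
    threshold+smooth; the channel-level deletion zeroes the channels whose
    normalized channel scores survive the channel threshold.
    """
    vis = vis_config or VisualizationConfig()
    if cmap.shape != sample.values.shape:
        raise InputError("contribution map does not match sample")
    act = model.forward(sample.values)[0]
    probs = softmax(act)
    pred = int(np.argmax(act))

    sens: dict[str, float] = {}
    for frac in patch_fractions:
        spec = PerturbationSpec(
            patch_length=patch_length(frac, sample.n_times),
            num_perturbations=num_perturbations,
            seed=seed,
            fill_value=fill_value,
        )
        sens[f"{frac:g}"] = sensitivity_test(model, sample, cmap, spec).pcc
    ch_pcc = sensitivity_test_channels(model, sample, chmap, fill_value=fill_value).pcc

    processed = process_map(cmap, vis)
    n_ch, n_t = sample.values.shape
    total = n_ch * n_t
    common = dict(
        model_tag=model.tag, method=cmap.method, smoothing_window=vis.smoothing_window,
        sample_threshold=vis.sample_threshold, channel_threshold=vis.channel_threshold,
        predicted_class=pred, label=sample.label,
        class_probabilities=[float(p) for p in probs],
        sensitivity_pcc=sens, channel_sensitivity_pcc=float(ch_pcc),
    )
    if processed.meta.get("degenerate"):
        return EvaluationReport(
            **common, deletion_probability=None, deleted_portion=0.0,
            deleted_portion_exact="0/1", top_channels=[],
            channel_deletion_probability=None, deleted_channels=[], degenerate=True,
        )

    delete_mask = processed.scores != 0.0
    deleted = sample.values.copy()
    deleted[delete_mask] = fill_value
    del_prob = float(softmax(model.forward(deleted)[0])[pred])
    portion = Fraction(int(delete_mask.sum()), total)
    per_channel = delete_mask.sum(axis=1)
    top_idx = sorted(range(n_ch), key=lambda i: (-per_channel[i], i))[:3]
    top_channels = [
        {
            "channel": int(i),
            "name": sample.channel_names[i],
            "portion": float(Fraction(int(per_channel[i]), total)),
        }
        for i in top_idx
        if per_channel[i] > 0
    ]

    ch_norm, ch_degenerate = _normalize_channel_map(chmap)
    if ch_degenerate:
        kept = np.zeros(n_ch, dtype=bool)
    else:
        kept = (
            np.abs(ch_norm) >= vis.channel_threshold
            if vis.signed_threshold
            else ch_norm >= vis.channel_threshold
        )
    ch_deleted = sample.values.copy()
    ch_deleted[kept, :] = fill_value
    ch_prob = float(softmax(model.forward(ch_deleted)[0])[pred])

    return EvaluationReport(
        **common,
        deletion_probability=del_prob,
        deleted_portion=float(portion),
        deleted_portion_exact=f"{portion.numerator}/{portion.denominator}",
        top_channels=top_channels,
        channel_deletion_probability=ch_prob,
        deleted_channels=[sample.channel_names[i] for i in np.flatnonzero(kept)],
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render_overlay(
    sample: EEGSample,
    processed_map: ContributionMap,
    out_path,
    report: EvaluationReport | None = None,
    cmap_name: str = "Reds",
) -> None:
    """Stacked-trace figure with contribution intensity overlaid as color.

    One line per channel, offset vertically; segments are colored by the
    processed map scores.  If a report is given its four-line text block is
    placed below the traces.  Output is deterministic for fixed inputs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    if processed_map.shape != sample.values.shape:
        raise InputError("processed map does not match sample")
    n_ch, n_t = sample.values.shape
    t = np.arange(n_t) / sample.sampling_rate
    spread = 3.0 * np.abs(sample.values).std()
    scores = processed_map.scores
    smax = scores.max()
    norm_scores = scores / smax if smax > 0 else np.zeros_like(scores)

    fig, ax = plt.subplots(figsize=(10, 0.6 * n_ch + (2 if report else 0.5)))
    colormap = plt.get_cmap(cmap_name)
    for i in range(n_ch):
        y = sample.values[i] + (n_ch - 1 - i) * spread
        pts = np.column_stack([t, y]).reshape(-1, 1, 2)
        segs = np.concatenate([pts[:-1], pts[1:]], axis=1)
        cvals = np.maximum(norm_scores[i][:-1], norm_scores[i][1:])
        colors = colormap(0.15 + 0.85 * cvals)
        colors[cvals <= 0] = (0.3, 0.3, 0.3, 0.9)
        ax.add_collection(LineCollection(segs, colors=colors, linewidths=0.8))
    ax.set_xlim(t[0], t[-1])
    ax.set_ylim(-spread, n_ch * spread)
    ax.set_yticks([(n_ch - 1 - i) * spread for i in range(n_ch)])
    ax.set_yticklabels(sample.channel_names)
    ax.set_xlabel("time (s)")
    if report is not None:
        fig.text(0.02, 0.01, report.render_text(), fontsize=7, family="monospace", va="bottom")
        fig.subplots_adjust(bottom=0.35)
    fig.savefig(out_path, dpi=110, metadata={"Software": "eegattr"})
    plt.close(fig)
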