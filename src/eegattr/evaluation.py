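"""Faithfulness tests for contribution maps: patch sensitivity and deletion.

Two quantitative checks of whether a contribution map actually tracks the
model's behaviour:

* **Sensitivity test** — the sample is perturbed many times by zeroing one
  randomly placed patch of fixed length n within one randomly chosen
  channel; the Pearson correlation r between the drop in the pre-softmax
  class score and the summed contribution inside the patch measures local
  accuracy of the map.  Patch lengths are fractions 0.1-0.5 of the sample
  length (n = floor(fraction * T)).  The channel contribution map is scored
  with a single correlation obtained by zeroing each channel once.

* **Deletion test** — sampling points are ranked by their contribution
  scores in descending order and cumulatively set to zero at fractions
  1%, 2%, ..., 100% of the sample size; a sharp drop of the predicted-class
  probability, i.e. a small area under the probability-vs-fraction curve,
  indicates a faithful map.  The channel variant removes whole channels in
  descending channel-score order.

A seeded uniform random contribution map serves as the chance baseline for
both tests.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .attribution import (
    AttributionConfig,
    ChannelContributionMap,
    ContributionMap,
    EEGSample,
    attribute_batch,
    channel_contribution,
)
from .errors import ConfigurationError, InputError
from .model_core import Model, softmax

DEFAULT_PATCH_FRACTIONS = (0.1, 0.2, 0.3, 0.4, 0.5)


# ---------------------------------------------------------------------------
# Worked-example arithmetic (patch sizing and evaluation-set bookkeeping)
# ---------------------------------------------------------------------------


def patch_length(fraction: float, n_times: int) -> int:
    """Patch length in sampling points for a fraction of the sample length.

    n = floor(fraction * T); e.g. fractions 0.1-0.5 of a 254-point sample
    give n = 25-127.
    """
    if not 0 < fraction <= 1:
        raise InputError("patch fraction must be in (0, 1]")
    return int(math.floor(fraction * n_times))


def patch_percent_of_sample(patch_len: int, n_channels: int, n_times: int) -> float:
    """A patch of ``patch_len`` points as a percentage of all N*T points."""
    if patch_len < 1 or patch_len > n_times:
        raise InputError("patch length must be in [1, T]")
    return 100.0 * patch_len / (n_channels * n_times)


def session_trial_count(tasks_per_session: Sequence[int], items_per_task: int) -> int:
    """Total trials across sessions: sum(tasks) * items per task."""
    return int(sum(tasks_per_session)) * int(items_per_task)


def evaluation_sample_count(n_subjects: int, n_classes: int, samples_per_class: int) -> int:
    """Evaluation-set size: subjects x classes x samples per class."""
    return int(n_subjects) * int(n_classes) * int(samples_per_class)


# ---------------------------------------------------------------------------
# Sensitivity test
# ---------------------------------------------------------------------------


@dataclass
class PerturbationSpec:
    """Patch perturbation settings: length n, count, fill amplitude, seed."""

    patch_length: int
    num_perturbations: int = 100
    fill_value: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_length < 1:
            raise InputError("patch_length must be >= 1")
        if self.num_perturbations < 2:
            raise InputError("num_perturbations must be >= 2 (correlation undefined otherwise)")


@dataclass
class SensitivityResult:
    """Pearson r between score drops and summed patch contributions."""

    patch_fraction: float
    pcc: float
    undefined: bool
    records: pd.DataFrame  # columns: channel, start, delta_score, patch_contribution
    low_power: bool = False


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """(r, undefined) — undefined when either vector has zero variance."""
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan"), True
    return float(np.corrcoef(a, b)[0, 1]), False


def perturb_patch(sample: EEGSample, channel: int, start: int, spec: PerturbationSpec) -> EEGSample:
    """Copy of ``sample`` with values[channel, start:start+n) set to fill_value."""
    n = spec.patch_length
    if not 0 <= channel < sample.n_channels:
        raise InputError(f"channel {channel} out of range")
    if start < 0 or start + n > sample.n_times:
        raise InputError(f"patch [{start}, {start + n}) out of range for T={sample.n_times}")
    out = sample.copy()
    out.values[channel, start : start + n] = spec.fill_value
    return out


def sensitivity_test(
    model: Model, sample: EEGSample, cmap: ContributionMap, spec: PerturbationSpec
) -> SensitivityResult:
    """Patch-sensitivity test of a sample contribution map.

    Draws (channel, start) uniformly ``num_perturbations`` times with the
    spec seed; each delta is S_c(x) - S_c(x_perturbed) on the pre-softmax
    activation of the map's target class, compared against the summed map
    scores inside the patch.
    """
    if cmap.shape != sample.values.shape:
        raise InputError("contribution map shape does not match sample")
    n = spec.patch_length
    if n > sample.n_times:
        raise InputError("patch longer than sample")
    rng = np.random.default_rng(spec.seed)
    channels = rng.integers(0, sample.n_channels, size=spec.num_perturbations)
    starts = rng.integers(0, sample.n_times - n + 1, size=spec.num_perturbations)

    c = cmap.target_class
    base_score = float(model.forward(sample.values)[0, c])
    batch = np.repeat(sample.values[None], spec.num_perturbations, axis=0)
    contribs = np.empty(spec.num_perturbations)
    for k, (ch, st) in enumerate(zip(channels, starts)):
        batch[k, ch, st : st + n] = spec.fill_value
        contribs[k] = cmap.scores[ch, st : st + n].sum()
    deltas = base_score - model.forward(batch)[:, c]
    pcc, undefined = _pearson(deltas, contribs)
    records = pd.DataFrame(
        {"channel": channels, "start": starts, "delta_score": deltas, "patch_contribution": contribs}
    )
    return SensitivityResult(
        patch_fraction=n / sample.n_times, pcc=pcc, undefined=undefined, records=records
    )


def sensitivity_test_channels(
    model: Model, sample: EEGSample, chmap: ChannelContributionMap, fill_value: float = 0.0
) -> SensitivityResult:
    """Single-correlation sensitivity test of a channel contribution map.

    Each channel is zeroed once; the per-channel score drops are correlated
    with the channel map.  With fewer than 3 channels the result is flagged
    low-power.
    """
    n_ch = sample.n_channels
    if chmap.scores.shape != (n_ch,):
        raise InputError("channel map length does not match sample")
    c = chmap.target_class
    base_score = float(model.forward(sample.values)[0, c])
    batch = np.repeat(sample.values[None], n_ch, axis=0)
    for i in range(n_ch):
        batch[i, i, :] = fill_value
    deltas = base_score - model.forward(batch)[:, c]
    pcc, undefined = _pearson(deltas, chmap.scores)
    records = pd.DataFrame(
        {
            "channel": np.arange(n_ch),
            "start": np.zeros(n_ch, dtype=int),
            "delta_score": deltas,
            "patch_contribution": chmap.scores * sample.n_times,
        }
    )
    return SensitivityResult(
        patch_fraction=1.0 / n_ch, pcc=pcc, undefined=undefined,
        records=records, low_power=n_ch < 3,
    )


# ---------------------------------------------------------------------------
# Deletion test
# ---------------------------------------------------------------------------


@dataclass
class DeletionCurve:
    """Predicted-class probability as a function of the deleted fraction."""

    fractions: np.ndarray
    probabilities: np.ndarray
    auc: float
    mode: str = "sample"
    meta: dict = field(default_factory=dict)


def _ranked_flat_indices(scores: np.ndarray) -> np.ndarray:
    """Flat indices sorted by score descending; ties by (channel, time) asc."""
    flat = scores.reshape(-1)
    return np.argsort(-flat, kind="stable")


def deletion_curve(
    model: Model,
    sample: EEGSample,
    cmap: ContributionMap | ChannelContributionMap,
    fractions: Sequence[float] | None = None,
    mode: str = "sample",
    fill_value: float = 0.0,
) -> DeletionCurve:
    """Cumulative-deletion probability curve and its trapezoidal AUC.

    sample mode: points ranked by map score descending are cumulatively set
    to ``fill_value``, the predicted-class softmax probability recorded at
    each fraction of N*T (point count = ceil(fraction * N * T)).
    channel mode: whole channels cumulatively zeroed in descending
    channel-score order over fractions k/N.
    """
    if mode not in ("sample", "channel"):
        raise ConfigurationError(f"unknown deletion mode {mode!r}")
    n_ch, n_t = sample.values.shape
    c = cmap.target_class
    if mode == "sample":
        if not isinstance(cmap, ContributionMap) or cmap.shape != sample.values.shape:
            raise InputError("sample-mode deletion requires a matching contribution map")
        if fractions is None:
            fractions = np.arange(1, 101) / 100.0
        fractions = np.asarray(fractions, dtype=float)
        if fractions.size == 0:
            raise InputError("fraction grid must not be empty")
        if np.any(np.diff(fractions) <= 0):
            raise InputError("fractions must be strictly increasing")
        order = _ranked_flat_indices(cmap.scores)
        total = n_ch * n_t
        batch = np.repeat(sample.values[None], fractions.size, axis=0)
        flat = batch.reshape(fractions.size, -1)
        for k, frac in enumerate(fractions):
            m = min(total, math.ceil(frac * total))
            flat[k, order[:m]] = fill_value
    else:
        scores = cmap.scores if isinstance(cmap, ChannelContributionMap) else np.asarray(cmap.scores).mean(axis=1)
        if scores.shape != (n_ch,):
            raise InputError("channel-mode deletion requires a matching channel map")
        if fractions is None:
            fractions = np.arange(1, n_ch + 1) / n_ch
        fractions = np.asarray(fractions, dtype=float)
        if fractions.size == 0:
            raise InputError("fraction grid must not be empty")
        order = np.argsort(-scores, kind="stable")
        batch = np.repeat(sample.values[None], fractions.size, axis=0)
        for k, frac in enumerate(fractions):
            m = min(n_ch, math.ceil(frac * n_ch))
            batch[k, order[:m], :] = fill_value
    probs = softmax(model.forward(batch))[:, c]
    auc = float(np.trapezoid(probs, fractions))
    return DeletionCurve(
        fractions=fractions, probabilities=probs, auc=auc, mode=mode,
        meta={"fill_value": fill_value, "target_class": int(c)},
    )


def channel_deletion_single(
    model: Model, sample: EEGSample, chmap: ChannelContributionMap, fill_value: float = 0.0
) -> np.ndarray:
    """Predicted-class probability after removing each channel individually."""
    n_ch = sample.n_channels
    batch = np.repeat(sample.values[None], n_ch, axis=0)
    for i in range(n_ch):
        batch[i, i, :] = fill_value
    return softmax(model.forward(batch))[:, chmap.target_class]


def random_contribution_map(shape: tuple[int, int], seed: int, target_class: int = 0) -> ContributionMap:
    """Seeded i.i.d. uniform(-1, 1) map — the chance baseline for both tests."""
    rng = np.random.default_rng(seed)
    return ContributionMap(
        scores=rng.uniform(-1.0, 1.0, size=shape),
        target_class=target_class,
        method="random",
    )


# ---------------------------------------------------------------------------
# Batch benchmarking
# ---------------------------------------------------------------------------


def benchmark(
    model: Model,
    samples: Sequence[EEGSample],
    methods: Sequence[str],
    tests: Sequence[str] = ("sensitivity", "deletion"),
    seed: int = 0,
    patch_fractions: Sequence[float] = DEFAULT_PATCH_FRACTIONS,
    num_perturbations: int = 100,
    attribution_config: AttributionConfig | None = None,
) -> pd.DataFrame:
    """Run the faithfulness tests over samples x methods; long-format table.

    Each sample is classified first and its predicted class is the
    attribution target.  ``methods`` may include "random" for the baseline
    map.  Detail rows carry (sample, method, test, fraction, statistic);
    summary rows (sample == "summary") give median and quartiles per
    (method, test, fraction) cell.  Per-sample perturbation seeds derive
    from the sample content, so summary statistics are invariant to sample
    order.
    """
    for t in tests:
        if t not in ("sensitivity", "deletion"):
            raise ConfigurationError(f"unknown test {t!r}")
    real_methods = [m for m in methods if m != "random"]
    from .attribution import METHODS as _M

    for m in real_methods:
        if m not in _M:
            raise ConfigurationError(f"unknown attribution method {m!r}")
    maps = attribute_batch(model, samples, real_methods, attribution_config)

    def sample_seed(s: EEGSample) -> int:
        return (seed * 1000003 + zlib.crc32(s.values.tobytes())) % (2**31)

    if "random" in methods:
        preds = [maps[real_methods[0]][i].target_class for i in range(len(samples))] if real_methods else [
            int(np.argmax(model.forward(s.values)[0])) for s in samples
        ]
        maps["random"] = [
            ContributionMap(
                scores=random_contribution_map(s.values.shape, seed=sample_seed(s)).scores,
                target_class=preds[i],
                method="random",
            )
            for i, s in enumerate(samples)
        ]
    rows = []
    for method in methods:
        for i, sample in enumerate(samples):
            cmap = maps[method][i]
            if "sensitivity" in tests:
                for frac in patch_fractions:
                    spec = PerturbationSpec(
                        patch_length=patch_length(frac, sample.n_times),
                        num_perturbations=num_perturbations,
                        seed=sample_seed(sample),
                    )
                    res = sensitivity_test(model, sample, cmap, spec)
                    rows.append((i, method, "sensitivity", frac, res.pcc))
            if "deletion" in tests:
                curve = deletion_curve(model, sample, cmap, mode="sample")
                rows.append((i, method, "deletion", 1.0, curve.auc))
    table = pd.DataFrame(rows, columns=["sample", "method", "test", "fraction", "statistic"])
    summaries = (
        table.groupby(["method", "test", "fraction"])["statistic"]
        .quantile([0.25, 0.5, 0.75])
        .unstack()
        .reset_index()
        .rename(columns={0.25: "q1", 0.5: "median", 0.75: "q3"})
    )
    summaries.insert(0, "sample", "summary")
    return pd.concat([table, summaries], ignore_index=True)
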