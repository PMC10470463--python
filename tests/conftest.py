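"""Shared fixtures: tiny fixed-weight models and one trained synthetic setup."""

import dataclasses

import numpy as np
import pytest

import eegattr as ea
from eegattr.model_core import (
    CONV_CHANNELS,
    CONV_TIME,
    DENSE,
    FLATTEN,
    NONLINEARITY,
    POOLING,
    LayerSpec,
    Model,
)


def make_linear_model(W: np.ndarray, b: np.ndarray, input_shape: tuple[int, int]) -> Model:
    """Purely linear classifier: activations = W @ x.flatten() + b."""
    W = np.asarray(W, dtype=float)
    b = np.asarray(b, dtype=float)
    arch = [LayerSpec(kind=FLATTEN), LayerSpec(kind=DENSE, units=W.shape[0])]
    model = Model(arch, num_classes=W.shape[0], input_shape=input_shape, seed=0, tag="linear")
    model.layers[1].params["W"] = W.copy()
    model.layers[1].params["b"] = b.copy()
    return model


def make_relu_scalar_net(w: np.ndarray, b: float) -> Model:
    """y = ReLU(w . x + b) via a trailing identity dense output layer."""
    w = np.asarray(w, dtype=float)
    arch = [
        LayerSpec(kind=FLATTEN),
        LayerSpec(kind=DENSE, units=1),
        LayerSpec(kind=NONLINEARITY, nonlinearity="relu"),
        LayerSpec(kind=DENSE, units=1),
    ]
    model = Model(arch, num_classes=1, input_shape=(1, w.size), seed=0, tag="relu-scalar")
    model.layers[1].params["W"] = w.reshape(1, -1).copy()
    model.layers[1].params["b"] = np.array([float(b)])
    model.layers[3].params["W"] = np.array([[1.0]])
    model.layers[3].params["b"] = np.array([0.0])
    return model


def small_conv_arch(nonlinearity: str = "relu", with_batchnorm: bool = True) -> list[LayerSpec]:
    """A miniature stock-style architecture for fast attribution tests."""
    from eegattr.model_core import BATCHNORM

    arch = [
        LayerSpec(kind=CONV_TIME, out_features=4, kernel_length=7),
        LayerSpec(kind=CONV_CHANNELS, out_features=4),
    ]
    if with_batchnorm:
        arch.append(LayerSpec(kind=BATCHNORM))
    arch += [
        LayerSpec(kind=NONLINEARITY, nonlinearity=nonlinearity),
        LayerSpec(kind=POOLING, pool_size=4, pool_kind="mean"),
        LayerSpec(kind=FLATTEN),
        LayerSpec(kind=DENSE),
    ]
    return arch


def make_sample(values: np.ndarray, fs: float = 128.0, label=None) -> ea.EEGSample:
    values = np.asarray(values, dtype=float)
    return ea.EEGSample(
        values=values,
        channel_names=[f"CH{i}" for i in range(values.shape[0])],
        sampling_rate=fs,
        label=label,
    )


def small_spec(seed: int = 0, **kw) -> ea.SyntheticSpec:
    """A fast 4x64 generator spec for unit tests."""
    defaults = dict(
        n_channels=4, n_timepoints=64, feature_channels=(1, 2),
        feature_duration_s=(0.15, 0.4), seed=seed,
    )
    defaults.update(kw)
    return ea.SyntheticSpec(**defaults)


@pytest.fixture(scope="session")
def trained_setup():
    """Compact ReLU CNN trained on 200 default-spec synthetic samples.

    Returns (frozen model, fresh evaluation dataset, training dataset).
    Evaluation samples come from an independent generator seed; batchnorm
    statistics are frozen from the evaluation batch.
    """
    spec = ea.SyntheticSpec(seed=42)
    train_ds = ea.generate_dataset(spec, 200)
    model = ea.build_model("relu-compact", 2, (spec.n_channels, spec.n_timepoints), seed=7)
    trained, history = ea.train(model, train_ds.samples, train_ds.labels, ea.TrainConfig(seed=7))
    eval_ds = ea.generate_dataset(dataclasses.replace(spec, seed=10042), 50)
    frozen = ea.freeze_batch_stats(trained, eval_ds.samples)
    return {"model": frozen, "eval": eval_ds, "train": train_ds, "history": history}
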