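"""Per-scale 1D convolutional feature extractor.

The backbone is a small four-conv-layer network applied to one block-averaged
view of the gait window:

    Conv 9x1/32 (valid) -> MaxPool 2/2 -> Conv 5x1/64 (valid)
    -> Conv 5x1/128 (stride 2, same) -> MaxPool 2/2 -> Conv 3x1/128 (valid)

with ReLU after every convolution and dropout after the conv stack.  On a
200-step window this yields per-layer lengths 192, 96, 92, 46, 23, 21 and
parameter counts 1760 / 10,304 / 41,088 / 49,280.  Convolution follows the
cross-correlation convention standard in deep learning (no kernel flip);
"same" padding follows the TensorFlow rule (extra padding goes on the
right).  Forward and backward passes are implemented directly on NumPy
arrays; each per-scale branch has its own weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass(frozen=True)
class LayerSpec:
    kind: str                  # "conv" | "maxpool"
    kernel_size: int
    n_kernels: int = 0         # conv only
    stride: int = 1
    padding: str = "valid"     # "valid" | "same"

    def __post_init__(self) -> None:
        if self.kind not in ("conv", "maxpool"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kernel_size <= 0 or self.stride <= 0:
            raise ValueError("kernel size and stride must be positive")
        if self.padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {self.padding!r}")


@dataclass(frozen=True)
class BackboneConfig:
    """Ordered layer plan plus activation/regularization knobs.

    ReLU follows every conv layer; ``dropout_rate`` applies once after the
    conv stack (training only); ``l2_reg`` is the L2 penalty coefficient on
    conv kernels.
    """

    layers: Tuple[LayerSpec, ...]
    in_channels: int = 6
    dropout_rate: float = 0.5
    l2_reg: float = 1e-4

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


def default_config(dropout_rate: float = 0.5, l2_reg: float = 1e-4) -> BackboneConfig:
    """The standard single-scale plan (see module docstring)."""
    return BackboneConfig(
        layers=(
            LayerSpec("conv", 9, 32, 1, "valid"),      # Conv1_1
            LayerSpec("maxpool", 2, 0, 2),             # MaxPool1
            LayerSpec("conv", 5, 64, 1, "valid"),      # Conv2_1
            LayerSpec("conv", 5, 128, 2, "same"),      # Conv2_2
            LayerSpec("maxpool", 2, 0, 2),             # MaxPool2
            LayerSpec("conv", 3, 128, 1, "valid"),     # Conv3_1
        ),
        dropout_rate=dropout_rate,
        l2_reg=l2_reg,
    )


def count_parameters(config: BackboneConfig) -> List[int]:
    """Per-layer parameter counts: k*Cin*Cout + Cout per conv, 0 per pool."""
    counts, c_in = [], config.in_channels
    for spec in config.layers:
        if spec.kind == "conv":
            counts.append(spec.kernel_size * c_in * spec.n_kernels + spec.n_kernels)
            c_in = spec.n_kernels
        else:
            counts.append(0)
    return counts


def output_lengths(config: BackboneConfig, input_length: int) -> List[int]:
    """Temporal length after each layer; raises naming the failing layer."""
    lengths, L = [], input_length
    for i, spec in enumerate(config.layers):
        if spec.kind == "conv":
            if spec.padding == "same":
                L = math.ceil(L / spec.stride)
            else:
                L = (L - spec.kernel_size) // spec.stride + 1
        else:
            L = L // spec.stride
        if L < 1:
            raise ValueError(
                f"layer {i} ({spec.kind}, k={spec.kernel_size}) reduces "
                f"input of length {input_length} to an empty output"
            )
        lengths.append(L)
    return lengths


def init_params(
    config: BackboneConfig, rng: np.random.Generator
) -> Dict[str, np.ndarray]:
    """Kaiming-normal conv kernels (fan-in of k*Cin), zero biases."""
    params: Dict[str, np.ndarray] = {}
    c_in = config.in_channels
    for i, spec in enumerate(config.layers):
        if spec.kind != "conv":
            continue
        fan_in = spec.kernel_size * c_in
        params[f"conv{i}_W"] = rng.normal(
            0.0, math.sqrt(2.0 / fan_in), size=(spec.kernel_size, c_in, spec.n_kernels)
        )
        params[f"conv{i}_b"] = np.zeros(spec.n_kernels)
        c_in = spec.n_kernels
    return params


# ----------------------------------------------------------------------
# layer primitives (batched): x is (B, L, C)
# ----------------------------------------------------------------------

def _same_padding(L: int, k: int, stride: int) -> Tuple[int, int]:
    out = math.ceil(L / stride)
    total = max((out - 1) * stride + k - L, 0)
    return total // 2, total - total // 2


def conv1d_forward(
    x: np.ndarray,
    W: np.ndarray,
    b: np.ndarray,
    stride: int = 1,
    padding: str = "valid",
) -> Tuple[np.ndarray, tuple]:
    """Cross-correlation along time: out[t] = sum_m x[t*stride + m] W[m] + b."""
    k = W.shape[0]
    pad_l = pad_r = 0
    if padding == "same":
        pad_l, pad_r = _same_padding(x.shape[1], k, stride)
        x = np.pad(x, ((0, 0), (pad_l, pad_r), (0, 0)))
    if x.shape[1] < k:
        raise ValueError(
            f"input length {x.shape[1]} shorter than kernel size {k}")
    win = sliding_window_view(x, k, axis=1)[:, ::stride]  # (B, Lout, C, k)
    out = np.einsum("blck,kco->blo", win, W, optimize=True) + b
    return out, (x, win, W, stride, pad_l, pad_r)


def conv1d_backward(
    dout: np.ndarray, cache: tuple
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dW, db) of a conv1d_forward call."""
    x_pad, win, W, stride, pad_l, pad_r = cache
    k = W.shape[0]
    dW = np.einsum("blck,blo->kco", win, dout, optimize=True)
    db = dout.sum(axis=(0, 1))
    dx_pad = np.zeros_like(x_pad)
    L_out = dout.shape[1]
    pos = stride * np.arange(L_out)
    for m in range(k):
        # indices pos+m are distinct for fixed m, so fancy-index += is safe
        dx_pad[:, pos + m] += dout @ W[m].T
    if pad_l or pad_r:
        dx_pad = dx_pad[:, pad_l: dx_pad.shape[1] - pad_r]
    return dx_pad, dW, db


def maxpool_forward(x: np.ndarray, width: int = 2, stride: int = 2
                    ) -> Tuple[np.ndarray, tuple]:
    """Non-overlapping temporal max pooling (width == stride); odd tail dropped."""
    if width != stride:
        raise NotImplementedError("only width == stride pooling supported")
    L = x.shape[1] // width * width
    xr = x[:, :L].reshape(x.shape[0], L // width, width, x.shape[2])
    arg = xr.argmax(axis=2)
    out = np.take_along_axis(xr, arg[:, :, None, :], axis=2)[:, :, 0, :]
    return out, (x.shape, arg, width)


def maxpool_backward(dout: np.ndarray, cache: tuple) -> np.ndarray:
    shape, arg, width = cache
    B, L, C = shape
    dx = np.zeros((B, L // width, width, C), dtype=dout.dtype)
    np.put_along_axis(dx, arg[:, :, None, :], dout[:, :, None, :], axis=2)
    dx = dx.reshape(B, (L // width) * width, C)
    if dx.shape[1] < L:
        dx = np.pad(dx, ((0, 0), (0, L - dx.shape[1]), (0, 0)))
    return dx


@dataclass
class ScaleFeatureMap:
    """Output of one backbone branch: ``(locations, channels)`` values."""

    values: np.ndarray

    @property
    def locations(self) -> int:
        return self.values.shape[0]

    @property
    def channels(self) -> int:
        return self.values.shape[1]


def forward_batch(
    signals: np.ndarray,
    config: BackboneConfig,
    params: Dict[str, np.ndarray],
    train: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, list]:
    """Run the conv stack on ``(B, L, Cin)``; returns feature maps + caches.

    During training, inverted dropout at ``config.dropout_rate`` is applied
    to the final feature map.
    """
    x = np.asarray(signals, dtype=np.float64)
    caches: list = []
    for i, spec in enumerate(config.layers):
        if spec.kind == "conv":
            try:
                z, cache = conv1d_forward(
                    x, params[f"conv{i}_W"], params[f"conv{i}_b"],
                    spec.stride, spec.padding)
            except ValueError as exc:
                raise ValueError(f"layer {i} (conv): {exc}") from exc
            x = np.maximum(z, 0.0)
            caches.append(("conv", cache, z > 0))
        else:
            if x.shape[1] < spec.kernel_size:
                raise ValueError(
                    f"layer {i} (maxpool): input length {x.shape[1]} "
                    f"shorter than pool width {spec.kernel_size}")
            x, cache = maxpool_forward(x, spec.kernel_size, spec.stride)
            caches.append(("pool", cache, None))
    if train and config.dropout_rate > 0:
        if rng is None:
            raise ValueError("rng required for dropout in training mode")
        keep = 1.0 - config.dropout_rate
        mask = (rng.random(x.shape) < keep) / keep
        x = x * mask
        caches.append(("dropout", mask, None))
    return x, caches


def backward_batch(
    dfmap: np.ndarray, caches: list, config: BackboneConfig,
    params: Dict[str, np.ndarray],
) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
    """Backprop through the conv stack; adds the L2 kernel-penalty gradient."""
    grads: Dict[str, np.ndarray] = {}
    dx = dfmap
    conv_indices = [i for i, s in enumerate(config.layers) if s.kind == "conv"]
    layer_iter = list(enumerate(config.layers))
    cache_iter = list(caches)
    if cache_iter and cache_iter[-1][0] == "dropout":
        dx = dx * cache_iter[-1][1]
        cache_iter = cache_iter[:-1]
    for (i, spec), (kind, cache, relu_mask) in zip(
            reversed(layer_iter), reversed(cache_iter)):
        if kind == "conv":
            dz = dx * relu_mask
            dx, dW, db = conv1d_backward(dz, cache)
            grads[f"conv{i}_W"] = dW + 2.0 * config.l2_reg * params[f"conv{i}_W"]
            grads[f"conv{i}_b"] = db
        else:
            dx = maxpool_backward(dx, cache)
    return dx, grads


def forward(
    signal: np.ndarray,
    config: BackboneConfig,
    params: Dict[str, np.ndarray],
) -> ScaleFeatureMap:
    """Inference-mode forward of a single ``(L, Cin)`` signal."""
    fmap, _ = forward_batch(signal[None], config, params, train=False)
    return ScaleFeatureMap(fmap[0])


def l2_penalty(config: BackboneConfig, params: Dict[str, np.ndarray]) -> float:
    """L2 kernel penalty added to the training loss."""
    return config.l2_reg * sum(
        float(np.sum(params[k] ** 2)) for k in params if k.endswith("_W"))
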