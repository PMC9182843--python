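"""Normalization and fixed-length windowing of 6-channel inertial streams.

A sample is a fixed-length window of tri-axial accelerometer and gyroscope
readings, columns ordered ``Ax, Ay, Az, Gx, Gy, Gz``.  Per-time-step L2
normalization of each sensor triple removes the overall magnitude of the
3-vector, which cancels orientation/placement changes of the phone while
keeping the directional gait pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

CHANNEL_NAMES = ("Ax", "Ay", "Az", "Gx", "Gy", "Gz")
N_CHANNELS = 6

#: index ranges of the two sensor triples
ACC_SLICE = slice(0, 3)
GYRO_SLICE = slice(3, 6)

#: a triple whose Euclidean norm falls below this is left untouched
_NORM_EPS = 1e-12


@dataclass
class InertialWindow:
    """One fixed-length 6-channel gait segment, the unit of classification.

    Parameters
    ----------
    values
        ``(length, 6)`` float array, columns ``Ax, Ay, Az, Gx, Gy, Gz``.
    label
        Optional integer subject label.
    """

    values: np.ndarray
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != N_CHANNELS:
            raise ValueError(
                f"window values must be (length, {N_CHANNELS}), "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("window contains non-finite values")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "InertialWindow":
        return InertialWindow(self.values.copy(), self.label)


def _normalize_triples(values: np.ndarray) -> np.ndarray:
    out = values.copy()
    for sl in (ACC_SLICE, GYRO_SLICE):
        triple = values[:, sl]
        norms = np.linalg.norm(triple, axis=1)
        ok = norms > _NORM_EPS
        out[ok, sl] = triple[ok] / norms[ok, None]
    return out


def l2_normalize(window: InertialWindow) -> InertialWindow:
    """Normalize each sensor triple to unit Euclidean norm per time step.

    The accelerometer triple (Ax,Ay,Az) and the gyroscope triple (Gx,Gy,Gz)
    are scaled independently at every time step.  Steps where a triple's norm
    is below 1e-12 are left unchanged (effectively zero).  An all-zero window
    triggers a warning and is returned unchanged.
    """
    if not np.any(window.values):
        warnings.warn("l2_normalize: all-zero window, returned unchanged")
        return window.copy()
    return InertialWindow(_normalize_triples(window.values), window.label)


def l2_normalize_array(signals: np.ndarray) -> np.ndarray:
    """Vectorised triple normalization for a stack of windows ``(n, L, 6)``."""
    signals = np.asarray(signals, dtype=np.float64)
    out = signals.copy()
    for sl in (ACC_SLICE, GYRO_SLICE):
        norms = np.linalg.norm(signals[..., sl], axis=-1)
        ok = norms > _NORM_EPS
        out[..., sl][ok] = signals[..., sl][ok] / norms[ok, None]
    return out


def window_stream(
    stream: np.ndarray,
    length: int,
    stride: int,
    label: Optional[int] = None,
) -> List[InertialWindow]:
    """Cut a ``(T, 6)`` stream into contiguous fixed-length windows.

    Returns ``floor((T - length)/stride) + 1`` windows; no padding is
    applied.  A stream shorter than ``length`` yields an empty list with a
    warning.
    """
    if length <= 0 or stride <= 0:
        raise ValueError("length and stride must be positive")
    stream = np.asarray(stream, dtype=np.float64)
    if stream.ndim != 2 or stream.shape[1] != N_CHANNELS:
        raise ValueError(f"stream must be (T, {N_CHANNELS})")
    T = stream.shape[0]
    if T < length:
        warnings.warn(
            f"window_stream: stream of length {T} shorter than window "
            f"length {length}; returning no windows"
        )
        return []
    n = (T - length) // stride + 1
    return [
        InertialWindow(stream[i * stride : i * stride + length].copy(), label)
        for i in range(n)
    ]
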