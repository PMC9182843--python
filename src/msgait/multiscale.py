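"""Multi-scale signal reconstruction by non-overlapping block averaging.

At scale factor tau, the coarse signal's t-th sample is the mean of input
samples (t-1)*tau+1 .. t*tau (1-based), per channel; the trailing remainder
(N mod tau samples) is discarded.  tau=1 is the identity.  The coarse views
expose gait sub-dynamics at increasing temporal granularity and feed one CNN
branch each.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Union

import numpy as np

from .preprocess import InertialWindow

DEFAULT_SCALES = (2, 3, 4, 5)


def downsample(window: Union[InertialWindow, np.ndarray], tau: int) -> np.ndarray:
    """Block-average a window at scale ``tau``; returns ``(N//tau, C)``."""
    x = window.values if isinstance(window, InertialWindow) else np.asarray(window)
    if tau < 1:
        raise ValueError("tau must be a positive integer")
    n = x.shape[0]
    if tau > n:
        raise ValueError(f"tau={tau} exceeds window length {n}")
    blocks = n // tau
    return x[: blocks * tau].reshape(blocks, tau, *x.shape[1:]).mean(axis=1)


def downsample_batch(signals: np.ndarray, tau: int) -> np.ndarray:
    """Block-average a stack of windows ``(B, N, C)`` at scale ``tau``."""
    signals = np.asarray(signals)
    n = signals.shape[1]
    if tau < 1 or tau > n:
        raise ValueError(f"invalid tau={tau} for length {n}")
    blocks = n // tau
    return signals[:, : blocks * tau].reshape(
        signals.shape[0], blocks, tau, signals.shape[2]).mean(axis=2)


@dataclass
class MultiScaleBundle:
    """Mapping scale tau -> block-averaged signal of length N//tau."""

    scales: tuple
    signals: Dict[int, np.ndarray]

    def __getitem__(self, tau: int) -> np.ndarray:
        return self.signals[tau]


def build_bundle(
    window: Union[InertialWindow, np.ndarray],
    scales: Sequence[int] = DEFAULT_SCALES,
) -> MultiScaleBundle:
    """Downsample a window at every requested scale (duplicates rejected)."""
    scales = [int(t) for t in scales]
    if len(set(scales)) != len(scales):
        raise ValueError(f"duplicate scales in {scales}")
    scales = sorted(scales)
    return MultiScaleBundle(
        tuple(scales), {tau: downsample(window, tau) for tau in scales}
    )
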