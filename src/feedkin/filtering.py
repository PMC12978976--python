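"""Zero-phase low-pass filtering for kinematic series.

A 2nd-order Butterworth applied forward and backward (zero phase lag) with a
6 Hz cutoff is the conventional choice for upper-limb position data; the
cutoff is configurable everywhere it is used. Windows too short to filter are
returned unchanged.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt


def lowpass(x: np.ndarray, cutoff_hz: float, sample_rate: float, order: int = 2,
            axis: int = 0) -> np.ndarray:
    """Zero-phase Butterworth low-pass along *axis*.

    ``cutoff_hz <= 0`` disables filtering. The effective filter order is
    doubled by the forward-backward pass.
    """
    x = np.asarray(x, dtype=float)
    if cutoff_hz <= 0:
        return x
    nyq = sample_rate / 2.0
    if cutoff_hz >= nyq:
        return x
    n = x.shape[axis]
    padlen = 3 * (order + 1)
    if n <= padlen:
        return x
    b, a = butter(order, cutoff_hz / nyq)
    return filtfilt(b, a, x, axis=axis)
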