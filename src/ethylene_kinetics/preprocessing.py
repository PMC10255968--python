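"""Data cleaning for raw sensor traces.

Two steps, applied before any feature extraction: a Hampel-style rolling
median test that replaces gross errors/outliers (vibration hits, transient
electrical interference), and a centred moving-average (mean) filter that
suppresses measurement noise and periodic disturbances.  Both preserve the
time grid, the gas markers and the trace length; edge windows shrink rather
than pad, so no values are fabricated at the boundaries that feed the
time-parameter extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_model import SensorTrace

# consistency factor making the median absolute deviation estimate the
# standard deviation under Gaussian noise
_MAD_SCALE = 1.4826


class InputError(ValueError):
    """Raised for invalid preprocessing inputs."""


@dataclass(frozen=True)
class FilterConfig:
    """Cleaning parameters: mean-filter window (odd sample count), rolling
    window of the outlier test and its threshold in multiples of the robust
    (MAD-based) scale."""

    window_length: int = 5
    outlier_window: int = 7
    outlier_threshold: float = 3.0

    def __post_init__(self) -> None:
        for w in (self.window_length, self.outlier_window):
            if w < 1 or w % 2 == 0:
                raise InputError("filter windows must be odd and >= 1")
        if self.outlier_threshold <= 0:
            raise InputError("outlier_threshold must be positive")


def remove_gross_errors(trace: SensorTrace,
                        config: FilterConfig = FilterConfig()) -> SensorTrace:
    """Replace samples deviating from a rolling median by more than
    ``threshold`` robust scales with that median (Hampel filter).

    Grid, markers and length are unchanged.
    """
    if trace.values.size == 0:
        raise InputError("empty trace")
    s = pd.Series(trace.values)
    w = config.outlier_window
    med = s.rolling(w, center=True, min_periods=1).median()
    mad = (s - med).abs().rolling(w, center=True, min_periods=1).median()
    scale = _MAD_SCALE * mad.to_numpy()
    dev = np.abs(trace.values - med.to_numpy())
    bad = dev > config.outlier_threshold * scale
    cleaned = np.where(bad, med.to_numpy(), trace.values)
    return trace.copy_with(cleaned, outliers_replaced=int(bad.sum()),
                           outlier_threshold=config.outlier_threshold)


def mean_filter(trace: SensorTrace, window_length: int = 5) -> SensorTrace:
    """Centred moving average with truncated (shrinking) edge windows.

    ``window_length`` must be odd and no longer than the trace; a window of
    1 is the identity.  Constant traces are unchanged and markers are kept.
    """
    if window_length < 1 or window_length % 2 == 0:
        raise InputError("window_length must be odd and >= 1")
    if window_length > trace.values.size:
        raise InputError("window_length exceeds trace length")
    if window_length == 1:
        return trace.copy_with(trace.values.copy(), mean_filter_window=1)
    half = window_length // 2
    csum = np.concatenate(([0.0], np.cumsum(trace.values)))
    n = trace.values.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    out = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return trace.copy_with(out, mean_filter_window=window_length)


def preprocess(trace: SensorTrace,
               config: FilterConfig = FilterConfig()) -> SensorTrace:
    """Standard cleaning chain: outlier replacement, then mean filtering."""
    return mean_filter(remove_gross_errors(trace, config), config.window_length)
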