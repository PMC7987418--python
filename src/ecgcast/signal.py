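"""Evenly sampled scalar signal container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class InvalidInputError(ValueError):
    """Raised when an input violates an operation's preconditions."""


class ConfigurationError(ValueError):
    """Raised when a configuration is inconsistent with the input."""


@dataclass
class Signal:
    """A single-channel evenly sampled time series.

    Parameters
    ----------
    samples : array-like of float
        Amplitude values (mV for ECG data).
    fs : float, optional
        Sampling rate in samples/second. Metadata only; the decomposition
        and forecasting operate in units of samples.
    name : str
        Free-text label (e.g. a record name).
    """

    samples: np.ndarray
    fs: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        # empty container allowed (e.g. a zero-length read window); a
        # single sample is neither empty nor analyzable
        if self.samples.size == 1:
            raise InvalidInputError("signal must contain at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidInputError("signal contains non-finite samples")
        if self.fs is not None and not self.fs > 0:
            raise InvalidInputError("fs must be positive when given")

    def __len__(self) -> int:
        return self.samples.size
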