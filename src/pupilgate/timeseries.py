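"""Uniformly sampled multichannel time series.

The container used for both EEG-like voltage signals (microvolts) and pupil
diameter traces (millimetres).  Invalid samples (e.g. blinks) are NaN.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

__all__ = ["Signal"]


@dataclass
class Signal:
    """A uniformly sampled signal with one or more channels.

    Parameters
    ----------
    values : ndarray, shape (n_channels, n_samples)
        Sample values; NaN marks invalid samples.
    rate_hz : float
        Sampling rate in Hz, strictly positive.
    t0_ms : float
        Time of the first sample on the recording clock, in milliseconds.
    channels : tuple of str
        Channel names, one per row of ``values``.
    """

    values: np.ndarray
    rate_hz: float
    t0_ms: float = 0.0
    channels: tuple[str, ...] = field(default=("ch0",))

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.rate_hz <= 0:
            raise DataError(f"rate_hz must be positive, got {self.rate_hz}")
        if len(self.channels) != self.values.shape[0]:
            raise DataError(
                f"{len(self.channels)} channel names for {self.values.shape[0]} rows"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.rate_hz

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times on the recording clock (ms)."""
        return self.t0_ms + np.arange(self.n_samples) * self.dt_ms

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms

    def channel(self, name: str) -> np.ndarray:
        try:
            i = self.channels.index(name)
        except ValueError:
            raise DataError(f"no channel named {name!r}; have {self.channels}") from None
        return self.values[i]

    def copy(self) -> "Signal":
        return Signal(self.values.copy(), self.rate_hz, self.t0_ms, tuple(self.channels))
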