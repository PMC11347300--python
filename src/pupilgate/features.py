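"""Amplitude/latency feature extraction from averaged epochs.

Features are defined on three fixed post-stimulus windows named after the
ERP components they bracket: P3a (200-350 ms), P3b (400-490 ms) and LPP
(530-750 ms).  Within a window:

* **amplitude** is the peak-to-peak value, ``max - min`` of the averaged
  epoch over the window's samples (always >= 0);
* **latency** is the time, in ms after stimulus onset, of the window's
  maximum sample (ties broken by the earliest sample).

The same definitions apply to EEG channels (ERP) and to the pupil-size-change
trace (ErPR).  A cohort feature table has one row per (subject, condition):
with four EEG channels and three windows the ERP amplitude table has 12
feature columns; the single-channel ErPR table has 3.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

if TYPE_CHECKING:  # pragma: no cover
    from .preprocess import Epoch

__all__ = [
    "FeatureWindow",
    "DEFAULT_WINDOWS",
    "amplitude",
    "latency",
    "build_feature_table",
]


@dataclass(frozen=True)
class FeatureWindow:
    """A named post-stimulus analysis window, in ms after stimulus onset."""

    name: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ConfigError(f"window {self.name}: start must be < end ({self.start} >= {self.end})")
        if self.start < 0:
            raise ConfigError(f"window {self.name}: start must be >= 0 ms post-onset")


DEFAULT_WINDOWS: tuple[FeatureWindow, ...] = (
    FeatureWindow("P3a", 200.0, 350.0),
    FeatureWindow("P3b", 400.0, 490.0),
    FeatureWindow("LPP", 530.0, 750.0),
)


def window_by_name(name: str) -> FeatureWindow:
    for w in DEFAULT_WINDOWS:
        if w.name == name:
            return w
    raise ConfigError(f"unknown window name {name!r}; expected one of "
                      f"{[w.name for w in DEFAULT_WINDOWS]}")


def _window_slice(times_ms: np.ndarray, window: FeatureWindow) -> np.ndarray:
    mask = (times_ms >= window.start) & (times_ms <= window.end)
    if times_ms[mask].size < 2:
        raise DataError(
            f"window {window.name} [{window.start}, {window.end}] ms contains "
            f"{int(mask.sum())} samples of the epoch span "
            f"[{times_ms[0]:.1f}, {times_ms[-1]:.1f}] ms; need >= 2"
        )
    return mask


def amplitude(values: np.ndarray, times_ms: np.ndarray, window: FeatureWindow) -> float:
    """Peak-to-peak amplitude (max - min) of ``values`` within ``window``."""
    m = _window_slice(np.asarray(times_ms, float), window)
    v = np.asarray(values, float)[m]
    return float(v.max() - v.min())


def latency(values: np.ndarray, times_ms: np.ndarray, window: FeatureWindow) -> float:
    """Time (ms post-onset) of the maximum sample within ``window``; earliest on ties."""
    t = np.asarray(times_ms, float)
    m = _window_slice(t, window)
    v = np.asarray(values, float)[m]
    return float(t[m][int(np.argmax(v))])


def build_feature_table(
    subject_averages: Mapping[str, Mapping[str, "Epoch"]],
    windows: Iterable[FeatureWindow] = DEFAULT_WINDOWS,
    channels: Iterable[str] | None = None,
    include_latency: bool = False,
) -> pd.DataFrame:
    """Build the cohort feature table from per-subject averaged epochs.

    Parameters
    ----------
    subject_averages : mapping
        ``subject_id -> {condition -> Epoch}`` where condition is
        ``"target"``/``"nontarget"`` and each Epoch holds the averaged,
        baseline-corrected waveform for all channels.
    windows : iterable of FeatureWindow
        Analysis windows (default: P3a, P3b, LPP).
    channels : iterable of str, optional
        Channels to extract, in feature-column order; defaults to each
        epoch's own channel list.
    include_latency : bool
        If True, latency columns are appended after each amplitude column.

    Returns
    -------
    DataFrame
        One row per (subject, condition).  Feature columns are ordered
        channel-major, window-minor: ``<channel>_<window>_amp`` (and
        ``..._lat`` when requested).
    """
    windows = tuple(windows)
    missing = [
        s for s, conds in subject_averages.items()
        if not {"target", "nontarget"} <= set(conds)
    ]
    if missing:
        raise DataError(f"subjects missing a condition average: {missing}")
    rows = []
    for subject, conds in subject_averages.items():
        for condition in ("target", "nontarget"):
            ep = conds[condition]
            chans = tuple(channels) if channels is not None else tuple(ep.channels)
            row: dict[str, object] = {"subject": subject, "condition": condition}
            for ch in chans:
                v = ep.channel(ch)
                for w in windows:
                    row[f"{ch}_{w.name}_amp"] = amplitude(v, ep.times_ms, w)
                    if include_latency:
                        row[f"{ch}_{w.name}_lat"] = latency(v, ep.times_ms, w)
            rows.append(row)
    return pd.DataFrame(rows)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the numeric feature columns of a feature table."""
    return [c for c in table.columns if c not in ("subject", "condition")]
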