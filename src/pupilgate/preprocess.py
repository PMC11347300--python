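"""Raw recordings -> baseline-corrected averaged epochs (ERP and ErPR).

The two modalities share one epoching/baseline/averaging code path and
differ only in the series fed in:

* **ERP**: EEG is resampled to ``target_rate`` (anti-aliased), band-pass
  filtered with a zero-phase fourth-order Butterworth (0.1-50 Hz by
  default), then segmented around each stimulus onset.
* **ErPR**: blink gaps in the pupil diameter trace are linearly
  interpolated, the trace is differenced frame-to-frame into the pupil size
  change (PSC) series, then segmented the same way.

Epochs span -200...+800 ms around onset (1000 ms, so the 530-750 ms LPP
window fits) and are baseline-corrected by subtracting the per-channel mean
over [-200, 0) ms.  Filtering is applied forward-backward so peak latencies
are not shifted.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, resample_poly, sosfiltfilt

from .errors import ConfigError, DataError
from .synth import SubjectRecording
from .timeseries import Signal

__all__ = [
    "PreprocessConfig",
    "Epoch",
    "EpochSet",
    "resample",
    "bandpass",
    "compute_psc",
    "interpolate_blinks",
    "extract_epochs",
    "baseline_correct",
    "average_epochs",
    "preprocess_subject",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters (times in ms, rates in Hz).

    ``epoch_reject_threshold`` (signal units, optional) drops EEG epochs
    whose absolute amplitude exceeds the threshold — an automated stand-in
    for manual artifact screening; off by default.
    """

    target_rate: float = 200.0
    band_low: float = 0.1
    band_high: float = 50.0
    filter_order: int = 4
    epoch_start: float = -200.0
    epoch_end: float = 800.0
    baseline_start: float = -200.0
    baseline_end: float = 0.0
    blink_interpolation: str = "linear"  # or "none"
    max_blink_gap_ms: float = 1000.0
    epoch_reject_threshold: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ConfigError(f"band_low must satisfy 0 < band_low < band_high, got {self.band_low}")
        if self.band_high >= self.target_rate / 2:
            raise ConfigError(
                f"band_high {self.band_high} Hz must be below Nyquist "
                f"({self.target_rate / 2} Hz at target_rate {self.target_rate})"
            )
        if self.epoch_start >= self.epoch_end:
            raise ConfigError("epoch_start must be < epoch_end")
        # an empty (start == end) window disables baseline correction
        if not (self.epoch_start <= self.baseline_start <= self.baseline_end <= 0):
            raise ConfigError(
                "baseline window must lie within [epoch_start, 0] ms, got "
                f"[{self.baseline_start}, {self.baseline_end})"
            )
        if self.blink_interpolation not in ("linear", "none"):
            raise ConfigError(f"blink_interpolation must be 'linear' or 'none', got {self.blink_interpolation!r}")

    @property
    def epoch_n_samples(self) -> int:
        return int(round((self.epoch_end - self.epoch_start) / 1000.0 * self.target_rate))


@dataclass
class Epoch:
    """An event-locked segment: (n_channels, n_samples) values on a relative time axis."""

    values: np.ndarray
    times_ms: np.ndarray  # relative to stimulus onset
    label: str
    channels: tuple[str, ...]
    event_index: int = -1
    trial: int = -1
    n_averaged: int = 1

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.values[self.channels.index(name)]
        except ValueError:
            raise DataError(f"no channel named {name!r}; have {self.channels}") from None


@dataclass
class EpochSet:
    """All epochs of one subject and modality, plus exclusion bookkeeping."""

    subject_id: str
    modality: str  # "ERP" or "ErPR"
    epochs: list[Epoch]
    channels: tuple[str, ...]
    rate_hz: float
    n_excluded: int = 0
    averaged: dict[str, Epoch] = field(default_factory=dict)

    def average(self) -> dict[str, Epoch]:
        self.averaged = average_epochs(self.epochs)
        return self.averaged


def resample(values: np.ndarray, from_rate: float, to_rate: float) -> np.ndarray:
    """Anti-aliased rate conversion along the last axis.

    Output length is ``round(n * to_rate / from_rate)``.  Upsampling is not
    supported (the pipeline only ever downsamples).
    """
    if from_rate <= 0 or to_rate <= 0:
        raise ConfigError(f"rates must be positive, got {from_rate} -> {to_rate}")
    if to_rate > from_rate:
        raise ConfigError(f"upsampling unsupported ({from_rate} -> {to_rate} Hz)")
    values = np.asarray(values, float)
    if to_rate == from_rate:
        return values.copy()
    from fractions import Fraction

    frac = Fraction(to_rate / from_rate).limit_denominator(10_000)
    out = resample_poly(values, frac.numerator, frac.denominator, axis=-1, padtype="line")
    n_target = int(round(values.shape[-1] * to_rate / from_rate))
    if out.shape[-1] > n_target:
        out = out[..., :n_target]
    elif out.shape[-1] < n_target:
        pad = [(0, 0)] * out.ndim
        pad[-1] = (0, n_target - out.shape[-1])
        out = np.pad(out, pad, mode="edge")
    return out


def bandpass(values: np.ndarray, rate_hz: float, config: PreprocessConfig) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, no latency shift)."""
    if config.band_high >= rate_hz / 2:
        raise ConfigError(
            f"band_high {config.band_high} Hz >= Nyquist ({rate_hz / 2} Hz)"
        )
    values = np.asarray(values, float)
    if values.shape[-1] <= 3 * config.filter_order:
        raise DataError(
            f"series length {values.shape[-1]} too short for order-{config.filter_order} filtering"
        )
    sos = butter(config.filter_order, [config.band_low, config.band_high],
                 btype="bandpass", fs=rate_hz, output="sos")
    return sosfiltfilt(sos, values, axis=-1)


def interpolate_blinks(signal: Signal, max_gap_ms: float = 1000.0) -> Signal:
    """Linearly interpolate NaN (blink) gaps no longer than ``max_gap_ms``.

    Longer gaps and leading/trailing NaN runs are left invalid; epochs that
    still touch them are excluded later.
    """
    out = signal.copy()
    max_gap = int(round(max_gap_ms * signal.rate_hz / 1000.0))
    for row in out.values:
        bad = np.isnan(row)
        if not bad.any():
            continue
        if bad.all():
            raise DataError("pupil series is entirely invalid (all samples NaN)")
        idx = np.flatnonzero(np.diff(np.concatenate(([False], bad, [False])).astype(int)))
        for start, stop in zip(idx[::2], idx[1::2]):
            if start == 0 or stop == row.size or (stop - start) > max_gap:
                continue
            row[start:stop] = np.interp(
                np.arange(start, stop), [start - 1, stop], [row[start - 1], row[stop]]
            )
    return out


def compute_psc(signal: Signal) -> Signal:
    """Pupil size change: frame-to-frame first difference of the diameter trace.

    ``PSC[i] = diameter[i] - diameter[i-1]``; the PSC sample inherits the
    timestamp of sample ``i``, so the output starts one sample period later
    and is one sample shorter.
    """
    if np.sum(~np.isnan(signal.values[0])) < 2:
        raise DataError("need at least 2 valid samples to difference")
    return Signal(
        np.diff(signal.values, axis=-1),
        signal.rate_hz,
        signal.t0_ms + signal.dt_ms,
        signal.channels,
    )


def _onset_index(signal: Signal, onset_ms: float) -> int:
    # nearest sample; exact midpoints resolve to the earlier sample
    x = (onset_ms - signal.t0_ms) / signal.dt_ms
    return int(np.ceil(x - 0.5))


def extract_epochs(
    signal: Signal,
    events: pd.DataFrame,
    config: PreprocessConfig,
    subject_id: str = "",
    modality: str = "ERP",
) -> EpochSet:
    """Segment ``signal`` around each event onset into an :class:`EpochSet`.

    One epoch per event row; overlapping epochs are permitted.  Epochs whose
    window exceeds the recording, or which contain invalid (NaN) samples,
    are excluded and counted in ``n_excluded``.
    """
    rate = signal.rate_hz
    offset = int(round(config.epoch_start * rate / 1000.0))
    n_samp = int(round((config.epoch_end - config.epoch_start) / 1000.0 * rate))
    times = (offset + np.arange(n_samp)) * (1000.0 / rate)
    epochs: list[Epoch] = []
    excluded = 0
    for i, row in enumerate(events.itertuples(index=False)):
        idx = _onset_index(signal, float(row.onset_ms))
        lo, hi = idx + offset, idx + offset + n_samp
        if lo < 0 or hi > signal.n_samples:
            excluded += 1
            continue
        vals = signal.values[:, lo:hi]
        if np.isnan(vals).any():
            excluded += 1
            continue
        epochs.append(
            Epoch(
                values=vals.copy(),
                times_ms=times.copy(),
                label=str(row.label),
                channels=tuple(signal.channels),
                event_index=i,
                trial=int(getattr(row, "trial", -1)),
            )
        )
    if excluded:
        log.info("%s/%s: excluded %d of %d epochs", subject_id, modality, excluded, len(events))
    return EpochSet(
        subject_id=subject_id,
        modality=modality,
        epochs=epochs,
        channels=tuple(signal.channels),
        rate_hz=rate,
        n_excluded=excluded,
    )


def baseline_correct(epoch: Epoch, baseline: tuple[float, float] = (-200.0, 0.0)) -> Epoch:
    """Subtract the per-channel mean over ``[baseline_start, baseline_end)`` ms.

    Idempotent: applying twice equals applying once.
    """
    mask = (epoch.times_ms >= baseline[0]) & (epoch.times_ms < baseline[1])
    if not mask.any():
        raise DataError(f"baseline window {baseline} ms contains no samples")
    mean = epoch.values[:, mask].mean(axis=1, keepdims=True)
    return replace(epoch, values=epoch.values - mean)


def average_epochs(epochs: Sequence[Epoch], labels: tuple[str, ...] = ("target", "nontarget")) -> dict[str, Epoch]:
    """Pointwise mean epoch per label; the result records how many went in."""
    out: dict[str, Epoch] = {}
    for label in labels:
        group = [e for e in epochs if e.label == label]
        if not group:
            raise DataError(f"no usable epochs for label {label!r}")
        stack = np.stack([e.values for e in group])
        out[label] = Epoch(
            values=stack.mean(axis=0),
            times_ms=group[0].times_ms.copy(),
            label=label,
            channels=group[0].channels,
            n_averaged=len(group),
        )
    return out


def preprocess_subject(
    recording: SubjectRecording,
    config: PreprocessConfig | None = None,
    average: bool = True,
) -> dict[str, EpochSet]:
    """Run both modality pipelines on one subject.

    ERP: resample -> band-pass -> epoch -> baseline (-> average).
    ErPR: blink interpolation -> PSC -> epoch -> baseline (-> average).

    Returns ``{"ERP": EpochSet, "ErPR": EpochSet}``; with ``average=True``
    each set also carries its per-condition averaged epoch.
    """
    config = PreprocessConfig() if config is None else config

    eeg = recording.eeg
    vals = resample(eeg.values, eeg.rate_hz, config.target_rate)
    vals = bandpass(vals, config.target_rate, config)
    eeg200 = Signal(vals, config.target_rate, eeg.t0_ms, eeg.channels)
    erp = extract_epochs(eeg200, recording.events, config, recording.subject_id, "ERP")
    do_baseline = config.baseline_start < config.baseline_end
    if do_baseline:
        erp.epochs = [baseline_correct(e, (config.baseline_start, config.baseline_end))
                      for e in erp.epochs]
    if config.epoch_reject_threshold is not None:
        kept = [e for e in erp.epochs if np.abs(e.values).max() <= config.epoch_reject_threshold]
        erp.n_excluded += len(erp.epochs) - len(kept)
        erp.epochs = kept

    pupil = recording.pupil
    if config.blink_interpolation == "linear":
        pupil = interpolate_blinks(pupil, config.max_blink_gap_ms)
    psc = compute_psc(pupil)
    erpr = extract_epochs(psc, recording.events, config, recording.subject_id, "ErPR")
    if do_baseline:
        erpr.epochs = [baseline_correct(e, (config.baseline_start, config.baseline_end))
                       for e in erpr.epochs]

    if average:
        erp.average()
        erpr.average()
    return {"ERP": erp, "ErPR": erpr}
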