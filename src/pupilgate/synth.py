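"""Synthetic cohort simulator with recoverable ground truth.

Generates per-subject EEG-like and pupil-diameter recordings, event-locked to
an RSVP :class:`~pupilgate.paradigm.Schedule`.  Each stimulus adds one
Gaussian-in-time positive deflection per component window (P3a, P3b, LPP),
larger for targets than nontargets, on top of 1/f^beta Gaussian noise (EEG)
and of a slow, blink-contaminated diameter trace (pupil).  The amplitude and
latency actually used for every event are stored as ground truth so the
downstream pipeline's estimates can be checked against a known answer.

The pupil response is the same event-locked bumps (scaled to mm) convolved
with a first-order low-pass kernel: pupil size follows cognitive drive
sluggishly, and frame-to-frame differencing of such a slow trace recovers
bump-like deflections that correlate with, but are not identical to, the EEG
components.

Per-event amplitudes share a single multiplicative draw across modalities and
channels, and per-subject offsets shift both condition means, which is what
makes ERP and ErPR features correlated across a cohort.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .errors import ConfigError, DataError
from .features import DEFAULT_WINDOWS, window_by_name
from .paradigm import ParadigmConfig, Schedule, build_schedule, events_to_table
from .timeseries import Signal

__all__ = [
    "ComponentTemplate",
    "NoiseModel",
    "SubjectRecording",
    "default_templates",
    "DEFAULT_CHANNEL_GAINS",
    "simulate_subject",
    "simulate_cohort",
    "cohort_seeds",
    "inject_blinks",
]

EEG_CHANNELS = ("Fz", "Cz", "Pz", "Oz")

#: Relative component strength per electrode: P3-family components are
#: largest centro-parietally and weakest occipitally.
DEFAULT_CHANNEL_GAINS: dict[str, float] = {"Fz": 0.95, "Cz": 1.05, "Pz": 1.10, "Oz": 0.60}


@dataclass(frozen=True)
class ComponentTemplate:
    """Ground-truth description of one event-locked component.

    ``center_latency`` (ms post-onset) must lie inside the window named by
    ``window_name``; ``width`` is the Gaussian sigma in ms.  Amplitudes are in
    signal units (microvolts for EEG; the pupil drive is scaled separately).
    ``subject_sd`` is the between-subject standard deviation of the amplitude
    offset shared by both conditions.
    """

    window_name: str
    center_latency: float
    width: float
    target_amplitude: float
    nontarget_amplitude: float
    subject_sd: float = 0.0

    def __post_init__(self) -> None:
        w = window_by_name(self.window_name)
        if not (w.start <= self.center_latency <= w.end):
            raise ConfigError(
                f"center_latency {self.center_latency} ms outside window "
                f"{self.window_name} [{w.start}, {w.end}] ms"
            )
        if not self.width > 0:
            raise ConfigError(f"width must be > 0 ms, got {self.width}")
        if self.subject_sd < 0:
            raise ConfigError(f"subject_sd must be >= 0, got {self.subject_sd}")


def default_templates() -> tuple[ComponentTemplate, ...]:
    """Default three-component template set (amplitudes in microvolts).

    Target amplitudes are double the nontarget ones, mirroring the direction
    of the familiar-vs-stranger face effect; the resulting cohort-level
    effect sizes are large (Cohen's d of order 2).
    """
    return (
        ComponentTemplate("P3a", 275.0, 30.0, 8.0, 4.0, subject_sd=1.0),
        ComponentTemplate("P3b", 445.0, 20.0, 7.0, 3.5, subject_sd=1.0),
        ComponentTemplate("LPP", 640.0, 45.0, 6.0, 3.0, subject_sd=0.8),
    )


@dataclass(frozen=True)
class NoiseModel:
    """Noise/artifact parameters for the simulator.

    ``eeg_noise_sd`` is the standard deviation (microvolts) of the 1/f^beta
    background per channel; ``spectral_exponent`` is beta.  The pupil trace
    gets a slow drift (sd in mm), white measurement noise, and Poisson-placed
    blinks marked invalid (NaN), never zero.
    """

    eeg_noise_sd: float = 10.0
    spectral_exponent: float = 1.0
    pupil_drift_sd: float = 0.10
    pupil_noise_sd: float = 0.005
    blink_rate: float = 15.0  # blinks per minute
    blink_duration: float = 200.0  # ms

    def __post_init__(self) -> None:
        for name in (
            "eeg_noise_sd",
            "spectral_exponent",
            "pupil_drift_sd",
            "pupil_noise_sd",
            "blink_rate",
            "blink_duration",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")


ZERO_NOISE = NoiseModel(0.0, 1.0, 0.0, 0.0, 0.0, 200.0)


@dataclass
class SubjectRecording:
    """One subject's simulated session: signals, events and ground truth.

    ``ground_truth`` has one row per (event, component) with the amplitude
    (microvolts, before per-channel gain), pupil drive amplitude (mm) and
    latency (ms post-onset) actually rendered for that event.
    """

    subject_id: str
    eeg: Signal
    pupil: Signal
    events: pd.DataFrame
    ground_truth: pd.DataFrame
    config: ParadigmConfig = field(repr=False)


def _powerlaw_noise(n: int, exponent: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, scaled to ``sd``."""
    if sd == 0 or n < 2:
        return np.zeros(n)
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n)
    x *= sd / x.std()
    return x


def _add_bump(out: np.ndarray, rate_hz: float, t0_ms: float,
              center_ms: float, sigma_ms: float, amp: float) -> None:
    """Add ``amp * exp(-(t-center)^2 / 2 sigma^2)`` in place (support +-5 sigma)."""
    dt = 1000.0 / rate_hz
    lo = max(0, int(np.floor((center_ms - 5 * sigma_ms - t0_ms) / dt)))
    hi = min(out.size, int(np.ceil((center_ms + 5 * sigma_ms - t0_ms) / dt)) + 1)
    if hi <= lo:
        return
    t = t0_ms + np.arange(lo, hi) * dt
    out[lo:hi] += amp * np.exp(-0.5 * ((t - center_ms) / sigma_ms) ** 2)


def _check_resolvable(rate_hz: float, templates: tuple[ComponentTemplate, ...], what: str) -> None:
    for tpl in templates:
        if rate_hz * tpl.width / 1000.0 < 2.0:
            raise ConfigError(
                f"{what} sampling rate {rate_hz} Hz cannot resolve the "
                f"{tpl.window_name} template width {tpl.width} ms "
                "(need >= 2 samples per sigma)"
            )


def inject_blinks(pupil: Signal, blink_rate: float, blink_duration: float, seed: int) -> Signal:
    """Mark Poisson-placed blink gaps as invalid (NaN) in a pupil trace.

    ``blink_rate`` is in blinks/minute, ``blink_duration`` in ms.  A zero rate
    returns the series unchanged.
    """
    if blink_duration >= pupil.duration_ms:
        raise DataError(
            f"blink_duration {blink_duration} ms >= series duration {pupil.duration_ms} ms"
        )
    out = pupil.copy()
    if blink_rate == 0:
        return out
    rng = np.random.default_rng(seed)
    minutes = pupil.duration_ms / 60_000.0
    n_blinks = rng.poisson(blink_rate * minutes)
    gap = max(1, int(round(blink_duration * pupil.rate_hz / 1000.0)))
    if n_blinks:
        starts = rng.integers(0, max(1, pupil.n_samples - gap), size=n_blinks)
        for s in starts:
            out.values[:, s : s + gap] = np.nan
    return out


def simulate_subject(
    schedule: Schedule,
    templates: tuple[ComponentTemplate, ...] | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    *,
    subject_id: str = "S00",
    eeg_rate: float = 2048.0,
    pupil_rate: float = 200.0,
    channel_gains: dict[str, float] | None = None,
    pupil_gain: float = 0.02,
    pupil_tau_ms: float = 500.0,
    pupil_baseline_mm: float = 4.0,
    amplitude_cv: float = 0.10,
    latency_jitter_sd: float = 10.0,
) -> SubjectRecording:
    """Render one subject's EEG and pupil recording for ``schedule``.

    Per component, the event amplitude is
    ``(condition_mean + subject_offset) * (1 + amplitude_cv * z)`` with the
    multiplicative draw shared between EEG and pupil; the event latency is
    the template center plus Gaussian jitter, clipped to the component's
    window.  ``pupil_gain`` (mm per microvolt) converts the shared amplitude
    into the pupil drive, which is convolved with a normalized first-order
    low-pass kernel of time constant ``pupil_tau_ms``.

    Everything is drawn from ``numpy.random.default_rng(seed)``: the same
    (schedule, parameters, seed) reproduces the recording bit for bit.
    """
    templates = default_templates() if templates is None else tuple(templates)
    noise = NoiseModel() if noise is None else noise
    gains = DEFAULT_CHANNEL_GAINS if channel_gains is None else channel_gains
    _check_resolvable(eeg_rate, templates, "EEG")
    _check_resolvable(pupil_rate, templates, "pupil")

    rng = np.random.default_rng(seed)
    cfg = schedule.config
    n_eeg = int(round(cfg.total_duration * eeg_rate / 1000.0))
    n_pup = int(round(cfg.total_duration * pupil_rate / 1000.0))

    subject_offset = {t.window_name: rng.normal(0.0, t.subject_sd) for t in templates}

    gt_rows = []
    for i, ev in enumerate(schedule.events):
        for tpl in templates:
            mean = tpl.target_amplitude if ev.label == "target" else tpl.nontarget_amplitude
            amp = max(0.0, (mean + subject_offset[tpl.window_name])
                      * (1.0 + amplitude_cv * rng.standard_normal()))
            w = window_by_name(tpl.window_name)
            lat = float(np.clip(tpl.center_latency + latency_jitter_sd * rng.standard_normal(),
                                w.start, w.end))
            gt_rows.append(
                {
                    "event_index": i,
                    "trial": ev.trial,
                    "label": ev.label,
                    "component": tpl.window_name,
                    "amplitude": amp,
                    "pupil_amplitude": amp * pupil_gain,
                    "latency_ms": lat,
                }
            )
    ground_truth = pd.DataFrame(gt_rows)

    width = {t.window_name: t.width for t in templates}
    eeg = np.zeros((len(EEG_CHANNELS), n_eeg))
    drive = np.zeros(n_pup)
    for row in gt_rows:
        ev = schedule.events[row["event_index"]]
        center = ev.onset + row["latency_ms"]
        sigma = width[row["component"]]
        for c, ch in enumerate(EEG_CHANNELS):
            _add_bump(eeg[c], eeg_rate, 0.0, center, sigma, row["amplitude"] * gains[ch])
        _add_bump(drive, pupil_rate, 0.0, center, sigma, row["pupil_amplitude"])

    for c in range(len(EEG_CHANNELS)):
        eeg[c] += _powerlaw_noise(n_eeg, noise.spectral_exponent, noise.eeg_noise_sd, rng)

    # Sluggish pupil: drive convolved with a unit-area exponential kernel.
    dt_pup = 1000.0 / pupil_rate
    kt = np.arange(0, 5 * pupil_tau_ms, dt_pup)
    kernel = np.exp(-kt / pupil_tau_ms)
    kernel /= kernel.sum()
    response = fftconvolve(drive, kernel)[:n_pup]
    diameter = (
        pupil_baseline_mm
        + response
        + _powerlaw_noise(n_pup, 2.0, noise.pupil_drift_sd, rng)
        + noise.pupil_noise_sd * rng.standard_normal(n_pup)
    )

    pupil = Signal(diameter, pupil_rate, 0.0, ("pupil",))
    blink_seed = int(rng.integers(0, 2**31 - 1))
    pupil = inject_blinks(pupil, noise.blink_rate, noise.blink_duration, blink_seed)

    return SubjectRecording(
        subject_id=subject_id,
        eeg=Signal(eeg, eeg_rate, 0.0, EEG_CHANNELS),
        pupil=pupil,
        events=events_to_table(schedule),
        ground_truth=ground_truth,
        config=cfg,
    )


def cohort_seeds(master_seed: int, n_subjects: int) -> list[tuple[int, int]]:
    """Deterministic (schedule_seed, signal_seed) pairs for each subject."""
    ss = np.random.SeedSequence(master_seed)
    return [tuple(int(s % 2**31) for s in child.generate_state(2)) for child in ss.spawn(n_subjects)]


def simulate_cohort(
    n_subjects: int = 30,
    schedule_config: ParadigmConfig | None = None,
    templates: tuple[ComponentTemplate, ...] | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    **subject_kwargs,
) -> list[SubjectRecording]:
    """Simulate ``n_subjects`` recordings with per-subject derived seeds.

    Each subject gets their own randomized stimulus schedule (target
    positions differ between subjects) and their own signal seed, both
    derived deterministically from ``seed`` via :func:`cohort_seeds`.
    """
    if n_subjects < 1:
        raise ConfigError(f"n_subjects must be >= 1, got {n_subjects}")
    cfg = ParadigmConfig() if schedule_config is None else schedule_config
    out = []
    for i, (sched_seed, sig_seed) in enumerate(cohort_seeds(seed, n_subjects)):
        schedule = build_schedule(cfg, seed=sched_seed)
        out.append(
            simulate_subject(
                schedule, templates, noise, seed=sig_seed,
                subject_id=f"S{i:02d}", **subject_kwargs,
            )
        )
    return out
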