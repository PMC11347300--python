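"""Simulator: determinism, noiseless identity, linearity, blinks, seed derivation."""
import numpy as np
import pandas as pd
import pytest

import pupilgate as pg
from pupilgate.errors import ConfigError, DataError
from pupilgate.features import window_by_name
from pupilgate.synth import (
    DEFAULT_CHANNEL_GAINS,
    ZERO_NOISE,
    ComponentTemplate,
    cohort_seeds,
    default_templates,
)
from pupilgate.timeseries import Signal


def sparse_config(**kw):
    base = dict(n_blocks=1, trials_per_block=2, stimuli_per_trial=5,
                stimulus_duration=100.0, blank_duration=900.0,
                inter_trial_interval=1000.0, preparation_period=3000.0,
                relaxation_period=3000.0)
    base.update(kw)
    return pg.ParadigmConfig(**base)


def test_same_seed_bit_identical():
    s = pg.build_schedule(sparse_config(), seed=1)
    a = pg.simulate_subject(s, seed=7)
    b = pg.simulate_subject(s, seed=7)
    assert np.array_equal(a.eeg.values, b.eeg.values)
    assert np.array_equal(a.pupil.values, b.pupil.values, equal_nan=True)
    pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)


def test_different_seed_differs():
    s = pg.build_schedule(sparse_config(), seed=1)
    a = pg.simulate_subject(s, seed=7)
    b = pg.simulate_subject(s, seed=8)
    assert not np.array_equal(a.eeg.values, b.eeg.values)


def test_noiseless_single_component_average_equals_template():
    """With zero noise and one component, the averaged raw epoch is the bump."""
    cfg = sparse_config(stimuli_per_trial=2, targets_per_trial=1)
    schedule = pg.build_schedule(cfg, seed=2)
    tpl = ComponentTemplate("P3b", 445.0, 20.0, 5.0, 5.0, subject_sd=0.0)
    rec = pg.simulate_subject(schedule, templates=(tpl,), noise=ZERO_NOISE, seed=0,
                              amplitude_cv=0.0, latency_jitter_sd=0.0)
    config = pg.PreprocessConfig()
    eeg = Signal(pg.resample(rec.eeg.values, rec.eeg.rate_hz, 200.0), 200.0,
                 0.0, rec.eeg.channels)
    epochs = pg.extract_epochs(eeg, rec.events, config).epochs
    avg = pg.average_epochs(epochs)
    for label in ("target", "nontarget"):
        got = avg[label].channel("Cz")
        t = avg[label].times_ms
        expected = 5.0 * DEFAULT_CHANNEL_GAINS["Cz"] * np.exp(-0.5 * ((t - 445.0) / 20.0) ** 2)
        assert np.allclose(got, expected, atol=0.02 * expected.max())


def test_linearity_doubling_amplitude_doubles_peak_to_peak(sparse_noiseless):
    cfg = sparse_config()
    schedule = pg.build_schedule(cfg, seed=4)
    def p2p(amp):
        tpl = ComponentTemplate("P3a", 275.0, 30.0, amp, amp, subject_sd=0.0)
        rec = pg.simulate_subject(schedule, templates=(tpl,), noise=ZERO_NOISE, seed=0,
                                  amplitude_cv=0.0, latency_jitter_sd=0.0)
        sets = pg.preprocess_subject(rec)
        ep = sets["ERP"].averaged["target"]
        return pg.amplitude(ep.channel("Pz"), ep.times_ms, window_by_name("P3a"))
    assert p2p(6.0) == pytest.approx(2.0 * p2p(3.0), rel=1e-6)


def test_ground_truth_aligned_to_events():
    s = pg.build_schedule(sparse_config(), seed=1)
    rec = pg.simulate_subject(s, seed=3)
    gt = rec.ground_truth
    assert len(gt) == len(s.events) * 3  # three components per event
    assert set(gt.component) == {"P3a", "P3b", "LPP"}
    # latencies stay inside their named windows
    for name in ("P3a", "P3b", "LPP"):
        w = window_by_name(name)
        lat = gt[gt.component == name].latency_ms
        assert lat.between(w.start, w.end).all()
    # target events carry larger mean true amplitudes
    m = gt.groupby(["component", "label"]).amplitude.mean().unstack()
    assert (m["target"] > m["nontarget"]).all()


def test_recording_lengths_cover_total_duration():
    cfg = sparse_config()
    rec = pg.simulate_subject(pg.build_schedule(cfg, seed=0), seed=0)
    assert rec.eeg.n_samples == round(cfg.total_duration * 2048 / 1000)
    assert rec.pupil.n_samples == round(cfg.total_duration * 200 / 1000)


def test_unresolvable_template_width_rejected():
    s = pg.build_schedule(sparse_config(), seed=0)
    with pytest.raises(ConfigError, match="resolve"):
        pg.simulate_subject(s, seed=0, pupil_rate=20.0)


def test_template_center_must_lie_in_named_window():
    with pytest.raises(ConfigError, match="center_latency"):
        ComponentTemplate("P3a", 500.0, 30.0, 1.0, 1.0)


class TestCohort:
    def test_cohort_size_and_distinct_seeds(self):
        seeds = cohort_seeds(42, 30)
        assert len(seeds) == 30
        assert len({s for pair in seeds for s in pair}) == 60  # all distinct
        assert all(0 <= s < 2**31 for pair in seeds for s in pair)

    def test_single_subject_cohort_matches_direct_simulation(self):
        cfg = sparse_config()
        (cohort,) = pg.simulate_cohort(1, cfg, seed=5)
        sched_seed, sig_seed = cohort_seeds(5, 1)[0]
        direct = pg.simulate_subject(pg.build_schedule(cfg, seed=sched_seed),
                                     seed=sig_seed, subject_id="S00")
        assert np.array_equal(cohort.eeg.values, direct.eeg.values)
        pd.testing.assert_frame_equal(cohort.ground_truth, direct.ground_truth)

    def test_same_master_seed_identical_ground_truths(self):
        cfg = sparse_config()
        a = pg.simulate_cohort(3, cfg, seed=9)
        b = pg.simulate_cohort(3, cfg, seed=9)
        for ra, rb in zip(a, b):
            pd.testing.assert_frame_equal(ra.ground_truth, rb.ground_truth)


class TestBlinks:
    def make_series(self, seconds=60.0, rate=200.0):
        n = int(seconds * rate)
        return Signal(np.full(n, 4.0), rate, 0.0, ("pupil",))

    def test_zero_rate_unchanged(self):
        s = self.make_series()
        out = pg.inject_blinks(s, 0.0, 200.0, seed=1)
        assert np.array_equal(out.values, s.values)

    def test_expected_blink_mass_matches_rate(self):
        # Monte-Carlo over seeds: NaN mass ~= blinks/min * minutes * gap samples
        s = self.make_series(seconds=60.0)
        gap = int(round(200.0 * s.rate_hz / 1000.0))
        counts = [
            np.isnan(pg.inject_blinks(s, 6.0, 200.0, seed=k).values).sum() / gap
            for k in range(200)
        ]
        assert np.mean(counts) == pytest.approx(6.0, rel=0.15)

    def test_blink_longer_than_series_rejected(self):
        s = Signal(np.full(10, 4.0), 200.0, 0.0, ("pupil",))
        with pytest.raises(DataError, match="blink_duration"):
            pg.inject_blinks(s, 10.0, 1000.0, seed=0)

    def test_all_invalid_series_rejected_downstream(self):
        s = Signal(np.full(100, np.nan), 200.0, 0.0, ("pupil",))
        with pytest.raises(DataError):
            pg.compute_psc(s)


def test_amplitude_recovery_degrades_with_noise():
    """Pipeline-estimated window amplitudes track ground truth tightly at zero
    noise and progressively less so as EEG noise grows."""
    cfg = pg.ParadigmConfig(n_blocks=2, trials_per_block=3, stimuli_per_trial=5,
                            stimulus_duration=100.0, blank_duration=900.0,
                            preparation_period=5000.0, relaxation_period=5000.0)
    correlations = {}
    for sd in (0.0, 30.0):
        noise = pg.NoiseModel(eeg_noise_sd=sd, pupil_drift_sd=0.0, pupil_noise_sd=0.0,
                              blink_rate=0.0)
        est, truth = [], []
        for i, (sched_seed, sig_seed) in enumerate(cohort_seeds(21, 8)):
            schedule = pg.build_schedule(cfg, seed=sched_seed)
            rec = pg.simulate_subject(schedule, noise=noise, seed=sig_seed)
            sets = pg.preprocess_subject(rec)
            ep = sets["ERP"].averaged["target"]
            gt = rec.ground_truth
            for name in ("P3a", "P3b", "LPP"):
                w = window_by_name(name)
                est.append(pg.amplitude(ep.channel("Pz"), ep.times_ms, w))
                truth.append(gt[(gt.component == name) & (gt.label == "target")].amplitude.mean())
        correlations[sd] = np.corrcoef(est, truth)[0, 1]
    assert correlations[0.0] > 0.95
    assert correlations[0.0] > correlations[30.0]
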