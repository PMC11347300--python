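"""Resampling, filtering, PSC differencing, epoching, baseline, averaging."""
import numpy as np
import pandas as pd
import pytest

import pupilgate as pg
from pupilgate.errors import ConfigError, DataError
from pupilgate.preprocess import interpolate_blinks
from pupilgate.timeseries import Signal


class TestResample:
    def test_constant_series_stays_constant(self):
        out = pg.resample(np.full(2048, 3.5), 2048.0, 200.0)
        assert out.shape == (200,)
        assert np.allclose(out, 3.5, rtol=1e-2)

    def test_one_second_at_2048_gives_200_samples(self):
        out = pg.resample(np.random.default_rng(0).standard_normal(2048), 2048.0, 200.0)
        assert out.shape == (200,)

    def test_sinusoid_amplitude_preserved(self):
        t = np.arange(10 * 2048) / 2048.0
        x = np.sin(2 * np.pi * 5.0 * t)
        out = pg.resample(x, 2048.0, 200.0)
        mid = out[200:-200]  # away from edge transients
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.01)

    def test_upsampling_unsupported(self):
        with pytest.raises(ConfigError, match="upsampling"):
            pg.resample(np.zeros(100), 200.0, 2048.0)

    def test_length_formula_on_awkward_ratio(self):
        n = 1003
        out = pg.resample(np.zeros(n), 250.0, 200.0)
        assert out.shape[-1] == round(n * 200.0 / 250.0)


class TestBandpass:
    config = pg.PreprocessConfig()

    def sinusoid(self, f, rate=200.0, seconds=120.0):
        t = np.arange(int(seconds * rate)) / rate
        return np.sin(2 * np.pi * f * t), t

    def test_dc_removed(self):
        out = pg.bandpass(np.full(4000, 7.0), 200.0, self.config)
        assert np.abs(out[500:-500]).max() < 0.2

    def test_passband_gain_near_unity(self):
        x, _ = self.sinusoid(10.0)
        out = pg.bandpass(x, 200.0, self.config)
        # keep clear of the slow transient of the 0.1 Hz high-pass corner
        assert np.abs(out[6000:-6000]).max() == pytest.approx(1.0, rel=0.02)

    def test_stopband_attenuated(self):
        x, _ = self.sinusoid(80.0)
        out = pg.bandpass(x, 200.0, self.config)
        assert np.abs(out[6000:-6000]).max() < 0.1

    def test_zero_phase_keeps_peak_position(self):
        t = np.arange(2000) / 200.0
        x = np.exp(-0.5 * ((t - 5.0) / 0.05) ** 2)
        out = pg.bandpass(x, 200.0, self.config)
        assert abs(int(np.argmax(out)) - int(np.argmax(x))) <= 1

    def test_band_violating_nyquist_rejected(self):
        with pytest.raises(ConfigError, match="Nyquist"):
            pg.bandpass(np.zeros(4000), 80.0, self.config)

    def test_too_short_series_rejected(self):
        with pytest.raises(DataError, match="too short"):
            pg.bandpass(np.zeros(10), 200.0, self.config)


class TestPSC:
    def test_constant_diameter_gives_zero_psc(self):
        s = Signal(np.full(100, 4.2), 200.0, 0.0, ("pupil",))
        psc = pg.compute_psc(s)
        assert psc.n_samples == 99
        assert np.allclose(psc.values, 0.0)

    def test_linear_ramp_gives_constant_slope(self):
        s = Signal(0.01 * np.arange(50), 200.0, 0.0, ("pupil",))
        assert np.allclose(pg.compute_psc(s).values, 0.01)

    def test_matches_brute_force_differencing(self, rng):
        x = rng.standard_normal(500)
        s = Signal(x, 200.0, 100.0, ("pupil",))
        psc = pg.compute_psc(s)
        oracle = np.array([x[i] - x[i - 1] for i in range(1, 500)])
        assert np.array_equal(psc.values[0], oracle)
        # PSC[i] carries the timestamp of sample i
        assert psc.t0_ms == pytest.approx(100.0 + s.dt_ms)

    def test_too_few_valid_samples_rejected(self):
        s = Signal(np.array([1.0, np.nan, np.nan]), 200.0, 0.0, ("pupil",))
        with pytest.raises(DataError, match="valid samples"):
            pg.compute_psc(s)


class TestBlinkInterpolation:
    def test_short_gap_linearly_bridged(self):
        x = np.arange(20.0)
        x[5:8] = np.nan
        s = Signal(x, 200.0, 0.0, ("pupil",))
        out = interpolate_blinks(s, max_gap_ms=1000.0)
        assert np.allclose(out.values[0], np.arange(20.0))

    def test_long_gap_left_invalid(self):
        x = np.ones(1000)
        x[100:500] = np.nan  # 2 s gap at 200 Hz
        out = interpolate_blinks(Signal(x, 200.0, 0.0, ("p",)), max_gap_ms=1000.0)
        assert np.isnan(out.values[0, 300])


class TestEpoching:
    config = pg.PreprocessConfig()

    def flat_signal(self, n=4000, rate=200.0):
        return Signal(np.zeros(n), rate, 0.0, ("Cz",))

    def events(self, onsets):
        return pd.DataFrame({"onset_ms": onsets, "block": 0, "trial": 0,
                             "position": 0, "label": "target", "stimulus_id": "x"})

    def test_default_epoch_has_200_samples(self):
        es = pg.extract_epochs(self.flat_signal(), self.events([5000.0]), self.config)
        (ep,) = es.epochs
        assert ep.values.shape == (1, 200)
        assert ep.times_ms[0] == -200.0 and ep.times_ms[-1] == 795.0

    def test_onset_sample_lands_40_samples_into_the_epoch(self):
        rate = 200.0
        sig = Signal(np.arange(4000, dtype=float), rate, 0.0, ("Cz",))
        es = pg.extract_epochs(sig, self.events([1000.0]), self.config)
        (ep,) = es.epochs
        onset_value = 1000.0 / 1000.0 * rate  # sample index 200 holds value 200
        assert ep.values[0, 40] == onset_value  # 40 samples after epoch start = onset

    def test_zero_epoch_start_begins_exactly_at_onset(self):
        cfg = pg.PreprocessConfig(epoch_start=0.0, epoch_end=800.0,
                                  baseline_start=0.0, baseline_end=0.0)
        sig = Signal(np.arange(4000, dtype=float), 200.0, 0.0, ("Cz",))
        es = pg.extract_epochs(sig, self.events([1000.0]), cfg)
        assert es.epochs[0].values[0, 0] == 200  # sample at exactly 1000 ms
        assert es.epochs[0].times_ms[0] == 0.0

    def test_midpoint_onset_resolves_to_earlier_sample(self):
        sig = Signal(np.arange(4000, dtype=float), 200.0, 0.0, ("Cz",))
        es = pg.extract_epochs(sig, self.events([1002.5]), self.config)  # halfway between samples
        (ep,) = es.epochs
        assert ep.values[0, 40] == 200  # not 201

    def test_full_schedule_epoch_counts(self, protocol_config):
        schedule = pg.build_schedule(protocol_config)
        n = int(protocol_config.total_duration / 1000 * 200)
        sig = Signal(np.zeros(n), 200.0, 0.0, ("Cz",))
        es = pg.extract_epochs(sig, pg.events_to_table(schedule), self.config)
        labels = [e.label for e in es.epochs]
        assert labels.count("target") == 50
        assert labels.count("nontarget") == 450
        assert es.n_excluded == 0

    def test_event_beyond_recording_flagged_and_excluded(self):
        es = pg.extract_epochs(self.flat_signal(n=400), self.events([1000.0, 1900.0]),
                               self.config)
        assert len(es.epochs) == 1 and es.n_excluded == 1


class TestBaseline:
    def make_epoch(self, values):
        times = (np.arange(200) - 40) * 5.0
        return pg.Epoch(values=np.atleast_2d(values), times_ms=times, label="target",
                        channels=("Cz",))

    def test_constant_epoch_becomes_zero(self):
        ep = pg.baseline_correct(self.make_epoch(np.full(200, 3.3)))
        assert np.allclose(ep.values, 0.0)

    def test_idempotent(self, rng):
        ep = self.make_epoch(rng.standard_normal(200))
        once = pg.baseline_correct(ep)
        twice = pg.baseline_correct(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    def test_baseline_mean_zero_after_correction(self, rng):
        ep = pg.baseline_correct(self.make_epoch(rng.standard_normal(200) + 5))
        mask = (ep.times_ms >= -200) & (ep.times_ms < 0)
        assert abs(ep.values[:, mask].mean()) < 1e-12

    def test_empty_baseline_window_rejected(self, rng):
        ep = self.make_epoch(rng.standard_normal(200))
        with pytest.raises(DataError, match="baseline"):
            pg.baseline_correct(ep, (-1000.0, -900.0))


class TestAveraging:
    def make(self, values, label="target"):
        return pg.Epoch(values=np.atleast_2d(np.asarray(values, float)),
                        times_ms=np.arange(np.size(values)) * 5.0,
                        label=label, channels=("Cz",))

    def test_identical_epochs_average_to_themselves(self):
        eps = [self.make(np.sin(np.arange(10))) for _ in range(5)]
        eps += [self.make(np.zeros(10), "nontarget")]
        avg = pg.average_epochs(eps)
        assert np.allclose(avg["target"].values, eps[0].values)
        assert avg["target"].n_averaged == 5

    def test_symmetric_pair_averages_to_zero(self):
        x = np.arange(10.0)
        eps = [self.make(x), self.make(-x), self.make(np.ones(10), "nontarget")]
        assert np.allclose(pg.average_epochs(eps)["target"].values, 0.0)

    def test_missing_label_error_names_label(self):
        with pytest.raises(DataError, match="nontarget"):
            pg.average_epochs([self.make(np.zeros(4))])

    def test_averaging_reduces_noise_variance(self, rng):
        eps = [self.make(rng.standard_normal(100), "nontarget") for _ in range(450)]
        eps += [self.make(np.zeros(100))]
        avg = pg.average_epochs(eps)["nontarget"]
        single_var = np.mean([e.values.var() for e in eps if e.label == "nontarget"])
        assert avg.values.var() < single_var / 100


class TestSubjectPipeline:
    def test_deterministic(self, sparse_noiseless):
        rec, sets = sparse_noiseless
        again = pg.preprocess_subject(rec)
        for m in ("ERP", "ErPR"):
            for label in ("target", "nontarget"):
                assert np.array_equal(sets[m].averaged[label].values,
                                      again[m].averaged[label].values)

    def test_noiseless_average_equals_component_sum(self, sparse_noiseless):
        """ERP pipeline output reproduces the sum of rendered templates."""
        rec, sets = sparse_noiseless
        gt = rec.ground_truth
        ep = sets["ERP"].averaged["target"]
        t = ep.times_ms
        from pupilgate.synth import DEFAULT_CHANNEL_GAINS, default_templates
        expected = np.zeros_like(t)
        for tpl in default_templates():
            amp = gt[(gt.component == tpl.window_name) & (gt.label == "target")].amplitude.mean()
            expected += amp * DEFAULT_CHANNEL_GAINS["Pz"] * np.exp(
                -0.5 * ((t - tpl.center_latency) / tpl.width) ** 2)
        got = ep.channel("Pz")
        mask = t >= 0
        assert np.allclose(got[mask], expected[mask], atol=0.03 * expected.max())

    def test_epoch_rejection_threshold_drops_large_epochs(self, sparse_noiseless):
        rec, _ = sparse_noiseless
        strict = pg.PreprocessConfig(epoch_reject_threshold=1e-6)
        sets_strict = pg.preprocess_subject(rec, strict, average=False)
        assert len(sets_strict["ERP"].epochs) == 0
        assert sets_strict["ERP"].n_excluded == len(rec.events)
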