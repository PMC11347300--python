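import numpy as np
import pytest

import pupilgate as pg
from pupilgate.io import RunConfig
from pupilgate.pipeline import analyze_cohort
from pupilgate.synth import ZERO_NOISE


@pytest.fixture(scope="session")
def protocol_config() -> pg.ParadigmConfig:
    return pg.ParadigmConfig()


@pytest.fixture(scope="session")
def full_cohort():
    """Feature tables for a full-size cohort (30 subjects, default protocol)."""
    return analyze_cohort(RunConfig(seed=11))


@pytest.fixture(scope="session")
def sparse_noiseless():
    """A noiseless subject on a sparse schedule (1 s between onsets, so epochs
    never overlap), with event-level variability switched off: the averaged
    epoch must reproduce the component templates exactly."""
    cfg = pg.ParadigmConfig(
        n_blocks=1, trials_per_block=5, stimuli_per_trial=10,
        stimulus_duration=100.0, blank_duration=900.0,
        inter_trial_interval=2000.0, preparation_period=5000.0, relaxation_period=5000.0,
    )
    schedule = pg.build_schedule(cfg, seed=3)
    rec = pg.simulate_subject(schedule, noise=ZERO_NOISE, seed=3,
                              amplitude_cv=0.0, latency_jitter_sd=0.0)
    sets = pg.preprocess_subject(rec)
    return rec, sets


@pytest.fixture(scope="session")
def small_schedule():
    cfg = pg.ParadigmConfig(n_blocks=2, trials_per_block=2, preparation_period=3000.0,
                            relaxation_period=3000.0)
    return pg.build_schedule(cfg, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_feature_table(n_subjects: int, n_features: int, separation: float,
                         seed: int = 0, prefix: str = "f"):
    """A synthetic (subject, condition) feature table with a given
    target-vs-nontarget mean separation (in noise-sd units)."""
    import pandas as pd

    r = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        for cond, mu in (("target", separation), ("nontarget", 0.0)):
            row = {"subject": f"S{i:02d}", "condition": cond}
            for j in range(n_features):
                row[f"{prefix}{j}_X_amp"] = mu + r.standard_normal()
            rows.append(row)
    return pd.DataFrame(rows)
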