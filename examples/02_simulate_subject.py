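"""Simulate one subject's EEG and pupil recording with known ground truth.

Every stimulus evokes three positive deflections (P3a, P3b, LPP windows),
larger for the familiar face, on 1/f EEG noise; the pupil trace is the same
drive fed through a sluggish low-pass response plus drift and blinks.
"""
import numpy as np

import pupilgate as pg

schedule = pg.build_schedule(pg.ParadigmConfig(), seed=2)
recording = pg.simulate_subject(schedule, seed=2, subject_id="demo")

print(f"EEG  : {recording.eeg.values.shape[0]} channels x "
      f"{recording.eeg.n_samples} samples at {recording.eeg.rate_hz:.0f} Hz")
print(f"pupil: {recording.pupil.n_samples} samples at "
      f"{recording.pupil.rate_hz:.0f} Hz, "
      f"{int(np.isnan(recording.pupil.values).sum())} blink samples marked invalid")

truth = recording.ground_truth.groupby(["component", "label"]).amplitude.mean().unstack()
print("\nmean true component amplitude (uV):")
print(truth.round(2).to_string())
# The target column should be about twice the nontarget column: that
# amplitude gap is what the whole authentication pipeline tries to recover.
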