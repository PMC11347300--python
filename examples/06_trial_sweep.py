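"""How authentication accuracy depends on the number of RSVP trials.

Re-averages each subject's epochs from only the first n trials (keeping the
1 target : 9 nontarget ratio), rebuilds the features and re-runs the
classifier.  Fewer trials means noisier averaged epochs and lower accuracy —
the price of a shorter enrolment task.  The EEG modality is used here
because its 1/f background noise makes the trade-off visible; the simulated
pupil trace is clean enough to stay near ceiling at every n.
"""
import pupilgate as pg
from pupilgate.autheval import trial_sweep

cohort = pg.simulate_cohort(10, pg.ParadigmConfig(), seed=6)
sweep = trial_sweep(cohort, n_trials_list=[5, 10, 20, 30, 40, 50],
                    classifier_name="LSVM", seed=6, modality="ERP")

print("n_trials  accuracy_%   FAR    FRR")
for s in sweep:
    r = s.report
    print(f"{s.n_trials:8d}  {r.accuracy:9.1f}  {r.far:5.2f}  {r.frr:5.2f}")
# Each extra trial adds one target epoch and nine nontarget epochs to the
# averages; the curve shows how much task time the accuracy target costs.
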