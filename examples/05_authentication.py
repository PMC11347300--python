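"""Classifier-based authentication on the default 30-subject cohort.

Evaluates five classifiers with stratified 5-fold cross-validation on the
12 ERP amplitude features and separately on the 3 ErPR features, reporting
fold-mean accuracy, AUC, the false acceptance rate (impostor accepted) and
the false rejection rate (genuine user rejected).  Takes a minute or two.
"""
import pandas as pd

import pupilgate as pg
from pupilgate.io import RunConfig
from pupilgate.pipeline import amplitude_columns, analyze_cohort

result = analyze_cohort(RunConfig(seed=5))

rows = []
for modality, table in (("ERP", result.erp_features), ("ErPR", result.erpr_features)):
    amp = amplitude_columns(table)
    for name in ("LSVM", "QDA", "NB", "LR", "RBF-SVM"):
        rep = pg.crossval_evaluate(amp, amp["condition"].to_numpy(), name, seed=5)
        rows.append({"modality": modality, "classifier": name,
                     "accuracy_%": round(rep.accuracy, 1), "AUC": round(rep.auc, 2),
                     "FAR": round(rep.far, 2), "FRR": round(rep.frr, 2)})
print(pd.DataFrame(rows).to_string(index=False))

amp = amplitude_columns(result.erpr_features)
p = pg.permutation_test(amp[[c for c in amp.columns if c.endswith("_amp")]],
                        amp["condition"].to_numpy(), "QDA",
                        n_permutations=199, seed=5)
print(f"\nErPR/QDA label-permutation p-value (199 reps): {p:.4f}")
# Accuracy near 100% with FAR/FRR near 0 means the familiar-face response is
# separable from the stranger-face response; the permutation p confirms the
# separation is not a small-sample artifact.
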