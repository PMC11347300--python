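"""Statistical layer: paired comparisons, family-wise control, agreement.

Covers the within-subject analysis of the cohort feature tables:

* paired t-tests (target vs nontarget) with Cohen's d on the paired
  differences, ``d = mean(diff) / sd(diff)``;
* Bonferroni threshold adjustment, ``alpha / n_tests``;
* Pearson correlation between ERP and ErPR features;
* Bland-Altman agreement (mean difference, +-1.96 SD limits, proportion of
  pairs within the limits, and a qualitative category);
* a label-permutation test of classifier accuracy.

ERP features are in microvolts and ErPR features in mm/frame, so the two
modalities are z-scored before Bland-Altman differencing — otherwise the
"difference" would be dominated by the unit mismatch.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError

__all__ = [
    "PairedTestResult",
    "AgreementReport",
    "paired_t",
    "effect_size_label",
    "bonferroni_alpha",
    "pearson",
    "bland_altman",
    "permutation_test",
    "shapiro_gate",
    "paired_feature_tests",
]


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    cohens_d: float
    n_pairs: int
    zero_variance: bool = False

    def significant(self, alpha: float) -> bool:
        return self.p < alpha


@dataclass(frozen=True)
class AgreementReport:
    mean_diff: float
    sd_diff: float
    upper_limit: float
    lower_limit: float
    proportion_within: float
    n: int
    category: str


def paired_t(x, y) -> PairedTestResult:
    """Two-sided paired-samples t-test of x vs y (pairs aligned by subject).

    Cohen's d is ``mean(diff)/sd(diff)`` (sample sd, ddof=1); df is
    ``n_pairs - 1``.  Identical inputs return t=0, d=0 with the
    ``zero_variance`` flag set; a nonzero constant shift with zero spread is
    an error (the statistic is undefined).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError(f"paired inputs must be equal-length 1-D, got {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise DataError(f"need >= 3 pairs, got {n}")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return PairedTestResult(0.0, n - 1, 1.0, 0.0, n, zero_variance=True)
        raise DataError("zero variance of nonzero paired differences: t undefined")
    res = sps.ttest_rel(x, y)
    return PairedTestResult(
        t=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
        cohens_d=float(diff.mean() / sd),
        n_pairs=n,
    )


def effect_size_label(d: float) -> str:
    """Qualitative Cohen's d bands: small >= 0.20, medium >= 0.50, large >= 0.80."""
    a = abs(d)
    if a >= 0.80:
        return "large"
    if a >= 0.50:
        return "medium"
    if a >= 0.20:
        return "small"
    return "negligible"


def bonferroni_alpha(family_alpha: float, n_tests: int) -> float:
    """Per-test significance threshold: ``family_alpha / n_tests``."""
    if n_tests < 1:
        raise DataError(f"n_tests must be >= 1, got {n_tests}")
    return family_alpha / n_tests


def pearson(x, y) -> tuple[float, float]:
    """Pearson r with two-sided p; zero-variance input is an error."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise DataError(f"need equal lengths >= 3, got {x.size} and {y.size}")
    if x.std() == 0 or y.std() == 0:
        raise DataError("zero variance input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def bland_altman(
    x,
    y,
    good_cutoff: float = 1.0,
    fairly_good_cutoff: float = 0.95,
) -> AgreementReport:
    """Bland-Altman limits of agreement between two paired measurements.

    Computes the mean difference d-bar, its sd, the 95% limits
    ``d-bar +- 1.96 sd`` and the fraction of pairs falling within them.  The
    category is "good" when every pair lies within the limits (proportion >=
    ``good_cutoff``), "fairly good" at >= ``fairly_good_cutoff``, else
    "poor"; the cutoffs are explicit because the qualitative labels have no
    universal thresholds.

    Callers comparing different units (e.g. ERP microvolts vs ErPR mm)
    should z-score each input first.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise DataError(f"need equal lengths >= 3, got {x.size} and {y.size}")
    diff = x - y
    d_bar = float(diff.mean())
    sd = float(diff.std(ddof=1))
    upper = d_bar + 1.96 * sd
    lower = d_bar - 1.96 * sd
    within = float(np.mean((diff >= lower) & (diff <= upper)))
    if within >= good_cutoff:
        category = "good"
    elif within >= fairly_good_cutoff:
        category = "fairly good"
    else:
        category = "poor"
    return AgreementReport(d_bar, sd, upper, lower, within, int(x.size), category)


def shapiro_gate(x) -> tuple[float, float]:
    """Shapiro-Wilk normality diagnostic (W, p); reported, never enforced."""
    w, p = sps.shapiro(np.asarray(x, float))
    return float(w), float(p)


def permutation_test(
    features: pd.DataFrame | np.ndarray,
    labels,
    classifier_name: str,
    n_permutations: int = 10_000,
    seed: int = 0,
    k: int = 5,
) -> float:
    """Label-permutation p-value for cross-validated classifier accuracy.

    The observed fold-mean accuracy is compared against the accuracies
    obtained after permuting the labels (the full CV protocol is re-run per
    permutation).  ``p = (1 + #{perm >= observed}) / (1 + n_permutations)``.
    """
    from .autheval import crossval_evaluate  # deferred: avoids an import cycle

    if n_permutations < 100:
        raise DataError(f"n_permutations must be >= 100, got {n_permutations}")
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise DataError("labels are single-class: permutation test undefined")
    X = features.to_numpy() if isinstance(features, pd.DataFrame) else np.asarray(features, float)
    observed = crossval_evaluate(X, y, classifier_name, k=k, seed=seed).accuracy
    rng = np.random.default_rng(seed)
    count = 0
    for i in range(n_permutations):
        perm = rng.permutation(y)
        acc = crossval_evaluate(X, perm, classifier_name, k=k, seed=seed).accuracy
        if acc >= observed:
            count += 1
    return (1 + count) / (1 + n_permutations)


def paired_feature_tests(table: pd.DataFrame, family_alpha: float = 0.05,
                         n_family: int | None = None) -> pd.DataFrame:
    """Target-vs-nontarget paired t-test for every feature column.

    ``table`` is a feature table with ``subject``/``condition`` columns.  The
    Bonferroni threshold divides ``family_alpha`` by ``n_family`` (defaults
    to the number of feature columns).  Returns one row per feature with t,
    df, p, Cohen's d, its qualitative size and the significance flag.
    """
    cols = [c for c in table.columns if c not in ("subject", "condition")]
    tgt = table[table.condition == "target"].sort_values("subject")
    non = table[table.condition == "nontarget"].sort_values("subject")
    if not (tgt.subject.values == non.subject.values).all():
        raise DataError("target and nontarget rows are not aligned by subject")
    n_family = len(cols) if n_family is None else n_family
    threshold = bonferroni_alpha(family_alpha, n_family)
    rows = []
    for c in cols:
        r = paired_t(tgt[c].to_numpy(), non[c].to_numpy())
        rows.append(
            {
                "feature": c,
                "t": r.t,
                "df": r.df,
                "p": r.p,
                "cohens_d": r.cohens_d,
                "effect_size": effect_size_label(r.cohens_d),
                "bonferroni_threshold": threshold,
                "significant": r.significant(threshold),
            }
        )
    return pd.DataFrame(rows)
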