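"""End-to-end orchestration: simulate -> preprocess -> features -> stats -> evaluate.

`analyze_cohort` is the in-memory workhorse: it streams subjects one at a
time (simulate, preprocess, average, extract features, discard the raw
signals) so a full-size cohort never holds thirty 2048-Hz recordings at
once.  `run_pipeline` wraps it with artifact files (feature tables, stats
report, classification report, manifest) and supports resuming from existing
feature tables.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .autheval import crossval_evaluate
from .errors import StageError
from .features import build_feature_table, feature_columns
from .io import RunConfig, config_hash, save_config
from .paradigm import build_schedule
from .preprocess import preprocess_subject
from .stats import bland_altman, paired_feature_tests, pearson
from .synth import SubjectRecording, cohort_seeds, simulate_subject

__all__ = ["CohortResult", "analyze_cohort", "run_pipeline",
           "amplitude_columns", "cross_modality_correlations", "cross_modality_agreement"]

log = logging.getLogger(__name__)


@dataclass
class CohortResult:
    """Feature tables and bookkeeping for one simulated cohort."""

    config: RunConfig
    erp_features: pd.DataFrame  # amplitude + latency columns
    erpr_features: pd.DataFrame
    n_excluded: dict[str, dict[str, int]]
    recordings: list[SubjectRecording] | None = None


def analyze_cohort(config: RunConfig | None = None, keep_recordings: bool = False) -> CohortResult:
    """Simulate and fully preprocess a cohort, returning its feature tables.

    Tables carry both amplitude and latency columns; classification uses the
    amplitude subset (see :func:`amplitude_columns`).
    """
    config = RunConfig() if config is None else config
    erp_avgs: dict[str, dict] = {}
    erpr_avgs: dict[str, dict] = {}
    excluded: dict[str, dict[str, int]] = {}
    recordings: list[SubjectRecording] = []
    for i, (sched_seed, sig_seed) in enumerate(cohort_seeds(config.seed, config.n_subjects)):
        schedule = build_schedule(config.paradigm, seed=sched_seed)
        rec = simulate_subject(
            schedule, config.templates, config.noise, seed=sig_seed, subject_id=f"S{i:02d}"
        )
        sets = preprocess_subject(rec, config.preprocess)
        erp_avgs[rec.subject_id] = sets["ERP"].averaged
        erpr_avgs[rec.subject_id] = sets["ErPR"].averaged
        excluded[rec.subject_id] = {m: sets[m].n_excluded for m in sets}
        if keep_recordings:
            recordings.append(rec)
    erp = build_feature_table(erp_avgs, config.windows, include_latency=True)
    erpr = build_feature_table(erpr_avgs, config.windows, include_latency=True)
    return CohortResult(config, erp, erpr, excluded, recordings or None)


def amplitude_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Restrict a feature table to its amplitude columns (classifier input)."""
    keep = ["subject", "condition"] + [c for c in feature_columns(table) if c.endswith("_amp")]
    return table[keep]


def cross_modality_correlations(
    erp: pd.DataFrame, erpr: pd.DataFrame, measure: str = "amp"
) -> pd.DataFrame:
    """Pearson r between ERP and ErPR features, per (channel, window).

    Rows of the two tables are aligned on (subject, condition); the ErPR
    counterpart of every EEG channel is the single pupil trace.
    """
    erp = erp.sort_values(["subject", "condition"]).reset_index(drop=True)
    erpr = erpr.sort_values(["subject", "condition"]).reset_index(drop=True)
    rows = []
    for col in feature_columns(erp):
        ch, window, meas = col.split("_")
        if meas != measure:
            continue
        r, p = pearson(erp[col], erpr[f"pupil_{window}_{meas}"])
        rows.append({"channel": ch, "window": window, "measure": meas, "r": r, "p": p,
                     "n": len(erp)})
    return pd.DataFrame(rows)


def cross_modality_agreement(
    erp: pd.DataFrame, erpr: pd.DataFrame, channel: str, measure: str = "amp"
):
    """Bland-Altman agreement between z-scored ERP and ErPR features.

    Pools the three windows for one EEG channel against the pupil trace, so
    a 60-row cohort table yields n = 180 pairs.  Each (channel, window)
    feature is z-scored before differencing because the modalities are on
    different scales.
    """
    erp = erp.sort_values(["subject", "condition"]).reset_index(drop=True)
    erpr = erpr.sort_values(["subject", "condition"]).reset_index(drop=True)
    def z(v):
        v = np.asarray(v, float)
        return (v - v.mean()) / v.std(ddof=1)
    xs, ys = [], []
    for col in feature_columns(erp):
        ch, window, meas = col.split("_")
        if ch != channel or meas != measure:
            continue
        xs.append(z(erp[col]))
        ys.append(z(erpr[f"pupil_{window}_{meas}"]))
    return bland_altman(np.concatenate(xs), np.concatenate(ys))


def _stats_report(result: CohortResult) -> dict:
    n_family = len(feature_columns(result.erp_features)) + len(
        feature_columns(result.erpr_features)
    )
    report = {"bonferroni_family_size": n_family}
    for modality, table in (("ERP", result.erp_features), ("ErPR", result.erpr_features)):
        report[modality] = paired_feature_tests(table, n_family=n_family).to_dict("records")
    report["correlations"] = {
        meas: cross_modality_correlations(result.erp_features, result.erpr_features, meas)
        .to_dict("records")
        for meas in ("amp", "lat")
    }
    report["agreement"] = {
        meas: {
            ch: dataclasses.asdict(
                cross_modality_agreement(result.erp_features, result.erpr_features, ch, meas)
            )
            for ch in ("Fz", "Cz", "Pz", "Oz")
        }
        for meas in ("amp", "lat")
    }
    return report


def _classification_report(result: CohortResult, k: int = 5) -> dict:
    out: dict = {}
    for modality, table in (("ERP", result.erp_features), ("ErPR", result.erpr_features)):
        amp = amplitude_columns(table)
        out[modality] = [
            crossval_evaluate(amp, amp["condition"].to_numpy(), name,
                              k=k, seed=result.config.seed).to_dict()
            for name in result.config.classifiers
        ]
    return out


def run_pipeline(config: RunConfig | None = None, out_dir: str | Path = "pupilgate_run",
                 resume: bool = False) -> Path:
    """Run the full pipeline and write artifacts into ``out_dir``.

    Stages: simulate+preprocess+features (skipped when ``resume`` is true and
    the feature tables already exist), statistics, classification, manifest.
    A failing stage aborts with the stage name and the underlying cause.
    """
    config = RunConfig() if config is None else config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")

    erp_path, erpr_path = out / "features_erp.tsv", out / "features_erpr.tsv"
    try:
        if resume and erp_path.exists() and erpr_path.exists():
            log.info("resuming from existing feature tables in %s", out)
            erp = pd.read_csv(erp_path, sep="\t", float_precision="round_trip")
            erpr = pd.read_csv(erpr_path, sep="\t", float_precision="round_trip")
            result = CohortResult(config, erp, erpr, {})
        else:
            result = analyze_cohort(config)
            result.erp_features.to_csv(erp_path, sep="\t", index=False, float_format="%.17g")
            result.erpr_features.to_csv(erpr_path, sep="\t", index=False, float_format="%.17g")
    except Exception as err:  # noqa: BLE001
        raise StageError("simulate/preprocess/features", err) from err

    try:
        stats_report = _stats_report(result)
        (out / "stats.json").write_text(json.dumps(stats_report, indent=2, default=float))
    except Exception as err:  # noqa: BLE001
        raise StageError("stats", err) from err

    try:
        clf_report = _classification_report(result)
        (out / "classification.json").write_text(json.dumps(clf_report, indent=2, default=float))
    except Exception as err:  # noqa: BLE001
        raise StageError("evaluate", err) from err

    manifest = {
        "pupilgate_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config_hash": config_hash(config),
        "n_subjects": config.n_subjects,
        "n_feature_rows": len(result.erp_features),
        "n_erp_amplitude_features": sum(c.endswith("_amp") for c in feature_columns(result.erp_features)),
        "n_erpr_amplitude_features": sum(c.endswith("_amp") for c in feature_columns(result.erpr_features)),
        "excluded_epochs": result.n_excluded,
        "artifacts": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
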