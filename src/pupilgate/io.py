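"""Plain-text readers/writers and configuration handling.

Formats:

* recording: tab-separated, header comment lines ``# rate_hz=``, ``# t0_ms=``
  and ``# channels=`` followed by ``sample_index`` + one column per channel;
  NaN marks invalid samples.
* event table: tab-separated with one header row (onset in integer ms,
  0-based indices).
* run configuration: YAML mapping of the dataclass fields; resolved configs
  are written back beside outputs together with a content hash.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError
from .features import FeatureWindow, DEFAULT_WINDOWS
from .paradigm import ParadigmConfig
from .preprocess import PreprocessConfig
from .synth import ComponentTemplate, NoiseModel, default_templates
from .timeseries import Signal

__all__ = [
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
]


def write_recording(signal: Signal, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# rate_hz={signal.rate_hz!r}\n")
        fh.write(f"# t0_ms={signal.t0_ms!r}\n")
        fh.write("# channels=" + ",".join(signal.channels) + "\n")
        fh.write("sample_index\t" + "\t".join(signal.channels) + "\n")
        for i in range(signal.n_samples):
            row = "\t".join(f"{v:.17g}" for v in signal.values[:, i])
            fh.write(f"{i}\t{row}\n")


def read_recording(path: str | Path) -> Signal:
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    n_cols = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line[1:].partition("=")
                    meta[key.strip()] = val.strip()
                continue
            if line.startswith("sample_index"):
                continue
            parts = line.split("\t")
            if n_cols is None:
                n_cols = len(parts)
            elif len(parts) != n_cols:
                raise DataError(f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {n_cols})")
            try:
                rows.append([float(p) for p in parts[1:]])
            except ValueError as err:
                raise DataError(f"{path}:{lineno}: {err}") from None
    if "rate_hz" not in meta:
        raise DataError(f"{path}: missing '# rate_hz=' header")
    rate = float(meta["rate_hz"])
    t0 = float(meta.get("t0_ms", 0.0))
    channels = tuple(meta.get("channels", "ch0").split(","))
    values = np.asarray(rows, float).T if rows else np.empty((len(channels), 0))
    return Signal(values, rate, t0, channels)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    out = events.copy()
    out["onset_ms"] = out["onset_ms"].round().astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"onset_ms", "block", "trial", "position", "label", "stimulus_id"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: event table missing columns {sorted(missing)}")
    return df


# --- configuration -----------------------------------------------------------

@dataclass
class RunConfig:
    """Everything an end-to-end run needs, round-trippable through YAML."""

    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    templates: tuple[ComponentTemplate, ...] = field(default_factory=default_templates)
    noise: NoiseModel = field(default_factory=NoiseModel)
    windows: tuple[FeatureWindow, ...] = DEFAULT_WINDOWS
    n_subjects: int = 30
    classifiers: tuple[str, ...] = ("LSVM", "QDA", "NB", "LR", "RBF-SVM")
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "paradigm": dataclasses.asdict(self.paradigm),
            "preprocess": dataclasses.asdict(self.preprocess),
            "templates": [dataclasses.asdict(t) for t in self.templates],
            "noise": dataclasses.asdict(self.noise),
            "windows": [dataclasses.asdict(w) for w in self.windows],
            "n_subjects": self.n_subjects,
            "classifiers": list(self.classifiers),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw: dict = {}
        if "paradigm" in d:
            kw["paradigm"] = ParadigmConfig(**d["paradigm"])
        if "preprocess" in d:
            kw["preprocess"] = PreprocessConfig(**d["preprocess"])
        if "templates" in d:
            kw["templates"] = tuple(ComponentTemplate(**t) for t in d["templates"])
        if "noise" in d:
            kw["noise"] = NoiseModel(**d["noise"])
        if "windows" in d:
            kw["windows"] = tuple(FeatureWindow(**w) for w in d["windows"])
        for key in ("n_subjects", "seed"):
            if key in d:
                kw[key] = int(d[key])
        if "classifiers" in d:
            kw["classifiers"] = tuple(d["classifiers"])
        return cls(**kw)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    with Path(path).open() as fh:
        d = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(d)


def save_config(config: RunConfig, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
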