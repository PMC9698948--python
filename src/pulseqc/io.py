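"""Readers, writers and pipeline configuration.

Waveforms travel as two-column CSV (sample_index, pressure) with a JSON
sidecar carrying metadata and, for synthetic records, the ground truth.
Feature tables and comparisons are TSV; configuration and results are JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import SimulationConfig, WaveformRecord

__all__ = [
    "PipelineConfig",
    "write_record",
    "read_waveform_csv",
    "write_cohort",
    "read_cohort",
    "write_features",
    "read_features",
]


def write_record(record: WaveformRecord, directory, config_hash=None) -> Path:
    """Write one record as CSV plus a JSON sidecar; returns the CSV path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{record.subject_id}_{record.regime}"
    csv_path = directory / f"{stem}.csv"
    frame = pd.DataFrame(
        {"sample_index": np.arange(record.samples.size), "pressure": record.samples}
    )
    frame.to_csv(csv_path, index=False)
    sidecar = {
        "subject_id": record.subject_id,
        "regime": record.regime,
        "sampling_rate_hz": record.sampling_rate,
        "truth_onsets": None if record.truth_onsets is None else record.truth_onsets.tolist(),
        "truth_beat_labels": None
        if record.truth_beat_labels is None
        else record.truth_beat_labels.tolist(),
    }
    if config_hash is not None:
        sidecar["config_hash"] = config_hash
    (directory / f"{stem}.json").write_text(json.dumps(sidecar))
    return csv_path


def read_waveform_csv(path, sampling_rate=None) -> WaveformRecord:
    """Read a single-channel pressure CSV, with or without a header row.

    Accepts one- or two-column files (the last column is the pressure).  A
    JSON sidecar next to the file, if present, supplies the sampling rate,
    identifiers and any ground truth; otherwise ``sampling_rate`` is
    required.
    """
    path = Path(path)
    samples = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            try:
                samples.append(float(fields[-1]))
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise ValueError(f"{path}: non-numeric value at line {lineno}") from None
    if not samples:
        raise ValueError(f"{path}: empty input file")

    sidecar_path = path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    rate = meta.get("sampling_rate_hz", sampling_rate)
    if rate is None:
        raise ValueError(f"{path}: sampling rate required (no sidecar found)")
    return WaveformRecord(
        subject_id=meta.get("subject_id", path.stem),
        regime=meta.get("regime", "unknown"),
        sampling_rate=float(rate),
        samples=np.asarray(samples),
        truth_onsets=meta.get("truth_onsets"),
        truth_beat_labels=meta.get("truth_beat_labels"),
    )


def write_cohort(records, directory, config_hash=None) -> Path:
    """Write every record plus a manifest TSV; returns the manifest path."""
    directory = Path(directory)
    rows = []
    for record in records:
        csv_path = write_record(record, directory, config_hash=config_hash)
        rows.append({"path": csv_path.name, "subject": record.subject_id, "regime": record.regime})
    manifest = directory / "manifest.tsv"
    _write_table(pd.DataFrame(rows), manifest, config_hash)
    return manifest


def read_cohort(manifest_path, sampling_rate=None) -> list:
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, sep="\t", comment="#")
    return [
        read_waveform_csv(manifest_path.parent / rel, sampling_rate=sampling_rate)
        for rel in table["path"]
    ]


def _write_table(table: pd.DataFrame, path, config_hash=None, index=False) -> Path:
    """TSV writer; a leading ``# config_hash=...`` comment ties the file to its run."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        table.to_csv(fh, sep="\t", index=index)
    return path


def write_features(features: pd.DataFrame, path, config_hash=None) -> Path:
    return _write_table(features, path, config_hash)


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to rerun the whole pipeline deterministically."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    window: object = "record"  # "record" or sliding-window size in beats
    normalization: str = "sum"
    min_hr: float = 30.0
    max_hr: float = 240.0
    protocols: tuple = ("threefold", "loso", "holdout")
    methods: object = "all"
    split: float = 0.8
    loso_unit: str = "recording"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        object.__setattr__(self, "protocols", tuple(self.protocols))
        if not isinstance(self.methods, str):
            object.__setattr__(self, "methods", tuple(self.methods))

    def to_dict(self):
        return {
            "simulation": self.simulation.to_dict(),
            "window": self.window,
            "normalization": self.normalization,
            "min_hr": self.min_hr,
            "max_hr": self.max_hr,
            "protocols": list(self.protocols),
            "methods": self.methods if isinstance(self.methods, str) else list(self.methods),
            "split": self.split,
            "loso_unit": self.loso_unit,
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if "simulation" in d:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def from_json(cls, path):
        return cls.from_dict(json.loads(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
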