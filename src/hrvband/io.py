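"""Plain-text readers and writers for IBI, ECG and cohort files, plus pipeline configuration.

Formats follow the field's text conventions:

* IBI: one interval in milliseconds per line (the RR-interval text format).
* ECG: two tab-separated columns ``time_s  mv`` preceded by a ``# fs_hz=``
  header line.
* Cohort: tab-separated table with a header row matching the Subject
  schema.
* Config: a YAML mapping mirroring :class:`PipelineConfig`.

Every writer has a matching reader and write→read round-trips are exact
for canonical files.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ECGRecord, IBISeries
from .stats import REQUIRED_COHORT_COLUMNS

__all__ = [
    "PipelineConfig",
    "read_ibi", "write_ibi", "read_ecg", "write_ecg",
    "read_cohort", "write_cohort",
]


@dataclass
class PipelineConfig:
    """End-to-end analysis parameters; defaults are the standard protocol values."""

    band_low_hz: float = 0.12
    band_high_hz: float = 0.40
    fir_taps: int = 241
    resample_hz: float = 10.0
    epoch_s: float = 30.0
    artifact_threshold_ms: float = 300.0
    responder_fraction: float = 0.30
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.band_low_hz < self.band_high_hz < self.resample_hz / 2):
            raise ValueError(
                "band must satisfy 0 < low < high < resample_hz/2, got "
                f"({self.band_low_hz}, {self.band_high_hz}) at {self.resample_hz} Hz"
            )
        if self.fir_taps % 2 == 0 or self.fir_taps < 3:
            raise ValueError("fir_taps must be an odd integer >= 3")
        if not (0 < self.responder_fraction < 1):
            raise ValueError("responder_fraction must be in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


# -- IBI ----------------------------------------------------------------------

def write_ibi(ibi: IBISeries, path) -> None:
    """Write one interval (ms) per line."""
    Path(path).write_text("".join(f"{_fmt(v)}\n" for v in ibi.intervals_ms))


def read_ibi(path) -> IBISeries:
    """Read a one-interval-per-line file into an :class:`IBISeries`."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                v = float(line)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric interval {line!r}") from None
            if v <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive interval {v}")
            intervals.append(v)
    if not intervals:
        raise ValueError(f"{path}: no intervals found")
    return IBISeries.from_intervals(np.array(intervals))


# -- ECG ----------------------------------------------------------------------

def write_ecg(ecg: ECGRecord, path) -> None:
    """Write two columns (time_s, mv) with a ``# fs_hz=`` header."""
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={_fmt(ecg.fs_hz)}\n")
        for t, v in zip(ecg.times_s, ecg.samples):
            fh.write(f"{t:.6f}\t{v:.6f}\n")


def read_ecg(path) -> ECGRecord:
    fs_hz = None
    times, values = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "fs_hz=" in line:
                    fs_hz = float(line.split("fs_hz=")[1])
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'time_s\\tmv', got {line!r}")
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric field in {line!r}") from None
    if fs_hz is None:
        raise ValueError(f"{path}: missing '# fs_hz=' header")
    if not values:
        raise ValueError(f"{path}: no samples found")
    return ECGRecord(fs_hz=fs_hz, samples=np.array(values), start_time_s=times[0])


# -- cohort -------------------------------------------------------------------

_BOOL_COLS = ["unemployed", "unmarried", "smoker", "responder"]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cohort file missing required column(s) {missing}")
    for col in ["age", "bdi_baseline", "bdi_month1", "hrv_baseline", "hrv_month1"]:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            raise ValueError(f"{path}: non-numeric values in column {col!r}") from None
        if df[col].isna().any():
            bad = df.index[df[col].isna()].tolist()
            raise ValueError(f"{path}: missing values in column {col!r} at rows {bad}")
    if (df["bdi_baseline"] <= 0).any():
        raise ValueError(f"{path}: bdi_baseline must be positive")
    for col in _BOOL_COLS:
        if col in df.columns:
            df[col] = df[col].map(
                {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
            ).astype(bool)
    if "responder" not in df.columns:
        df["responder"] = (
            (df["bdi_baseline"] - df["bdi_month1"]) / df["bdi_baseline"] >= 0.30
        )
    return df
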