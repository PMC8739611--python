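"""Readers and writers for ECG signals, feature tables and trait tables.

The on-disk ECG dialect is deliberately plain: a text file with one amplitude
column (an optional leading time column is ignored), values in millivolts,
and the sampling rate either in a ``# fs=<Hz>`` header comment, in a YAML
sidecar (``<file>.yaml`` with an ``fs`` key), or supplied by the caller.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, LoadError, StructuralError
from .features import ALL_FEATURES, TRAITS, validate_feature_names

logger = logging.getLogger("cardiotrait")

SCORE_MIN, SCORE_MAX = 1.0, 5.0


@dataclass(frozen=True)
class EcgRecord:
    """A single-lead ECG signal.

    Parameters
    ----------
    samples : ndarray
        Amplitude series, typically millivolts.
    fs : float
        Sampling frequency in Hz (the study dialect is Lead I at 2000 Hz).
    subject_id : str
        Opaque identifier.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise LoadError(f"sampling frequency must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size < 2:
            raise LoadError("ECG record needs a 1-D series of at least 2 samples")
        if np.isnan(samples).any():
            row = int(np.flatnonzero(np.isnan(samples))[0])
            raise LoadError(f"NaN sample at index {row}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def __len__(self) -> int:
        return self.samples.size


def _fs_from_header(path: Path) -> float | None:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                if key.strip().lower() == "fs":
                    try:
                        return float(value.strip())
                    except ValueError as exc:
                        raise LoadError(f"unparseable fs header in {path}: {line!r}") from exc
    return None


def _fs_from_sidecar(path: Path) -> float | None:
    for sidecar in (path.with_suffix(path.suffix + ".yaml"), path.with_suffix(".yaml")):
        if sidecar.exists():
            meta = yaml.safe_load(sidecar.read_text()) or {}
            if "fs" in meta:
                return float(meta["fs"])
    return None


def read_ecg(path: str | Path, fs_override: float | None = None) -> EcgRecord:
    """Load a single-channel ECG text file.

    The sampling rate is resolved in order of precedence: ``fs_override``,
    ``# fs=<Hz>`` header comment, YAML sidecar. A two-column file is read as
    (time, value) and the time column is discarded.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")

    rows: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) not in (1, 2):
                raise LoadError(f"{path}: row {lineno} has {len(parts)} columns, expected 1 or 2")
            try:
                value = float(parts[-1])
            except ValueError as exc:
                raise LoadError(f"{path}: non-numeric value at row {lineno}: {parts[-1]!r}") from exc
            if math.isnan(value):
                raise LoadError(f"{path}: NaN value at row {lineno}")
            rows.append(value)
    if not rows:
        raise LoadError(f"{path}: no data rows")

    fs = fs_override if fs_override is not None else _fs_from_header(path)
    if fs is None:
        fs = _fs_from_sidecar(path)
    if fs is None:
        raise ConfigurationError(
            f"{path}: sampling frequency unknown; add a '# fs=<Hz>' header, "
            "a YAML sidecar with an 'fs' key, or pass fs_override"
        )
    record = EcgRecord(np.asarray(rows, dtype=float), fs=float(fs), subject_id=path.stem)
    logger.info("loaded %s: %d samples at %g Hz (%.1f s)",
                path.name, len(record), record.fs, record.duration_s)
    return record


def write_ecg(record: EcgRecord, path: str | Path) -> None:
    """Write a record in the package's text dialect (fs in a header comment)."""
    path = Path(path)
    header = f"# fs={record.fs:g}\n"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, record.samples, fmt="%.10g")


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(rows, path: str | Path) -> None:
    """Write per-subject feature vectors as CSV.

    ``rows`` is an iterable of ``(subject_id, mapping)`` where every mapping
    holds exactly the 62 canonical features. Values round-trip at 10
    significant digits.
    """
    records = []
    for subject_id, vector in rows:
        values = dict(vector)
        validate_feature_names(values.keys())
        records.append({"subject_id": subject_id, **{f: values[f] for f in ALL_FEATURES}})
    df = pd.DataFrame(records, columns=["subject_id", *ALL_FEATURES])
    df.to_csv(path, index=False, float_format="%.10g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV back into a DataFrame indexed by subject_id."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise StructuralError(f"{path}: missing subject_id column")
    validate_feature_names(c for c in df.columns if c != "subject_id")
    return df.set_index("subject_id")


# ---------------------------------------------------------------------------
# trait tables


def write_trait_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write per-subject trait scores (subjects in the index) as CSV."""
    df.to_csv(path, index_label="subject_id", float_format="%.10g")


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a trait-score CSV; scores must lie in [1, 5]."""
    df = pd.read_csv(path, dtype={"subject_id": str}).set_index("subject_id")
    traits = [c for c in df.columns if c in TRAITS]
    if not traits:
        raise StructuralError(f"{path}: no recognised trait columns among {list(df.columns)}")
    scores = df[traits]
    bad = (scores.lt(SCORE_MIN) | scores.gt(SCORE_MAX)) & scores.notna()
    if bad.any().any():
        where = [(i, c) for c in traits for i in df.index[bad[c]]]
        raise LoadError(f"{path}: trait scores outside [1, 5] at {where[:5]}")
    return df
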