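"""Reading and writing recordings, cohort manifests, matrices and reports.

On-disk conventions
-------------------
* Time series: plain CSV/TSV, one row per time sample, one column per
  channel, optional header row of channel labels.  The delimiter (comma,
  tab or whitespace) is auto-detected from the first line.
* Cohort manifest: CSV with columns ``subject_id,group,signal_kind,path``
  (or a YAML list of mappings with the same keys).
* Matrices: TSV with a header row and a leading label column; values are
  printed with 12 significant digits so a read/write round trip is the
  identity at that precision.
* Performance reports: JSON.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "ManifestEntry",
    "CohortManifest",
    "read_recording",
    "write_recording",
    "read_manifest",
    "write_manifest",
    "load_cohort",
    "combine_total",
    "write_matrix",
    "read_matrix",
    "write_report",
    "read_report",
    "GROUP_PATIENT",
    "GROUP_CONTROL",
    "GROUP_UNKNOWN",
]

# Group encoding follows the clinical tables: +1 = schizophrenia, -1 = healthy.
GROUP_PATIENT = 1
GROUP_CONTROL = -1
GROUP_UNKNOWN = 0

SIGNAL_KINDS = ("oxy", "deoxy", "total")

_GROUP_TOKENS = {
    "1": GROUP_PATIENT,
    "+1": GROUP_PATIENT,
    "patient": GROUP_PATIENT,
    "schizophrenia": GROUP_PATIENT,
    "-1": GROUP_CONTROL,
    "control": GROUP_CONTROL,
    "healthy": GROUP_CONTROL,
    "0": GROUP_UNKNOWN,
    "unknown": GROUP_UNKNOWN,
}


@dataclass
class Recording:
    """One subject's multichannel hemodynamic recording.

    ``data`` is stored channels x samples (C x N); concentration changes are
    in arbitrary units.  ``group`` uses +1 for patients, -1 for controls and
    0 when unknown.
    """

    subject_id: str
    data: np.ndarray
    sampling_rate_hz: float
    channel_labels: list[str] = field(default_factory=list)
    group: int = GROUP_UNKNOWN
    signal_kind: str = "oxy"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be a 2-D channels x samples array")
        if self.data.shape[1] < 2:
            raise ValueError("recording must contain at least 2 samples per channel")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i + 1:02d}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValueError(f"signal_kind must be one of {SIGNAL_KINDS}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass(frozen=True)
class ManifestEntry:
    subject_id: str
    group: int
    signal_kind: str
    path: str


@dataclass
class CohortManifest:
    """Ordered list of cohort members with per-group counts."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("manifest contains no subjects")
        ids = [e.subject_id for e in self.entries]
        dupes = {s for s in ids if ids.count(s) > 1}
        if dupes:
            raise ValueError(f"duplicate subject_id in manifest: {sorted(dupes)}")

    @property
    def n_patients(self) -> int:
        return sum(1 for e in self.entries if e.group == GROUP_PATIENT)

    @property
    def n_controls(self) -> int:
        return sum(1 for e in self.entries if e.group == GROUP_CONTROL)

    @property
    def counts(self) -> tuple[int, int]:
        return (self.n_patients, self.n_controls)

    def __len__(self) -> int:
        return len(self.entries)


def _detect_delimiter(line: str) -> str | None:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # whitespace split


def _split(line: str, delim: str | None) -> list[str]:
    if delim is None:
        return line.split()
    return [tok.strip() for tok in line.split(delim)]


def parse_group(token: str | int) -> int:
    key = str(token).strip().lower()
    if key not in _GROUP_TOKENS:
        raise ValueError(
            f"unknown group token {token!r}; expected one of "
            f"{sorted(set(_GROUP_TOKENS))}"
        )
    return _GROUP_TOKENS[key]


def read_recording(
    path: str | os.PathLike,
    sampling_rate_hz: float,
    *,
    subject_id: str | None = None,
    group: int = GROUP_UNKNOWN,
    signal_kind: str = "oxy",
    channel_labels: Sequence[str] | None = None,
) -> Recording:
    """Read a samples x channels delimited text file into a Recording.

    The data matrix is transposed so the Recording holds channels x samples.
    A non-numeric first row is treated as a header of channel labels.
    Ragged rows and non-numeric cells raise ``ValueError`` with the offending
    row (1-based, counting data rows) and column.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln for ln in (raw.rstrip("\n\r") for raw in fh) if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty recording file")

    delim = _detect_delimiter(lines[0])
    first = _split(lines[0], delim)
    header: list[str] | None = None
    try:
        [float(tok) for tok in first]
        data_lines = lines
    except ValueError:
        header = first
        data_lines = lines[1:]
        if not data_lines:
            raise ValueError(f"{path}: header but no data rows")

    n_cols = len(_split(data_lines[0], delim))
    rows = np.empty((len(data_lines), n_cols), dtype=float)
    for i, line in enumerate(data_lines):
        toks = _split(line, delim)
        if len(toks) != n_cols:
            raise ValueError(
                f"{path}: ragged row {i + 1}: expected {n_cols} columns, "
                f"got {len(toks)}"
            )
        for j, tok in enumerate(toks):
            try:
                rows[i, j] = float(tok)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {tok!r} at row {i + 1}, "
                    f"column {j + 1}"
                ) from None

    labels = list(channel_labels) if channel_labels is not None else header
    return Recording(
        subject_id=subject_id if subject_id is not None else path.stem,
        data=rows.T,
        sampling_rate_hz=sampling_rate_hz,
        channel_labels=labels or [],
        group=group,
        signal_kind=signal_kind,
    )


def write_recording(rec: Recording, path: str | os.PathLike) -> None:
    """Write a Recording as CSV, samples x channels with a label header."""
    df = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
    df.to_csv(path, index=False, float_format="%.12g")


def read_manifest(path: str | os.PathLike) -> CohortManifest:
    """Read a cohort manifest (CSV or YAML, judged by extension)."""
    path = Path(path)
    entries: list[ManifestEntry] = []
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not raw:
            raise ValueError(f"{path}: manifest contains no subjects")
        for row in raw:
            entries.append(
                ManifestEntry(
                    subject_id=str(row["subject_id"]),
                    group=parse_group(row["group"]),
                    signal_kind=str(row["signal_kind"]),
                    path=str(row["path"]),
                )
            )
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                entries.append(
                    ManifestEntry(
                        subject_id=row["subject_id"].strip(),
                        group=parse_group(row["group"]),
                        signal_kind=row["signal_kind"].strip(),
                        path=row["path"].strip(),
                    )
                )
    return CohortManifest(entries)


def write_manifest(manifest: CohortManifest, path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "group", "signal_kind", "path"])
        for e in manifest.entries:
            writer.writerow([e.subject_id, e.group, e.signal_kind, e.path])


def load_cohort(
    manifest: CohortManifest,
    sampling_rate_hz: float,
    *,
    base_dir: str | os.PathLike | None = None,
) -> list[Recording]:
    """Load every recording listed in a manifest.

    Relative paths are resolved against ``base_dir`` (default: the current
    working directory).
    """
    recs = []
    for e in manifest.entries:
        p = Path(e.path)
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        recs.append(
            read_recording(
                p,
                sampling_rate_hz,
                subject_id=e.subject_id,
                group=e.group,
                signal_kind=e.signal_kind,
            )
        )
    return recs


def combine_total(oxy: Recording, deoxy: Recording) -> Recording:
    """Total-Hb recording: per-sample sum of oxy and deoxy concentration changes.

    Both inputs must share subject, geometry and sampling rate.
    """
    if oxy.signal_kind != "oxy" or deoxy.signal_kind != "deoxy":
        raise ValueError("combine_total expects one oxy and one deoxy recording")
    if oxy.subject_id != deoxy.subject_id:
        raise ValueError("recordings belong to different subjects")
    if oxy.data.shape != deoxy.data.shape or oxy.sampling_rate_hz != deoxy.sampling_rate_hz:
        raise ValueError("oxy and deoxy recordings must share shape and sampling rate")
    return Recording(
        subject_id=oxy.subject_id,
        data=oxy.data + deoxy.data,
        sampling_rate_hz=oxy.sampling_rate_hz,
        channel_labels=list(oxy.channel_labels),
        group=oxy.group,
        signal_kind="total",
    )


def write_matrix(
    matrix: np.ndarray,
    path: str | os.PathLike,
    labels: Sequence[str] | None = None,
) -> None:
    """Write a square matrix as labelled TSV (12 significant digits)."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"matrix must be square, got shape {matrix.shape}")
    if labels is None:
        labels = [f"ch{i + 1:02d}" for i in range(matrix.shape[0])]
    df = pd.DataFrame(matrix, index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_matrix(path: str | os.PathLike) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_report(report, path: str | os.PathLike) -> None:
    """Serialise a classifier PerformanceReport to JSON."""
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | os.PathLike):
    from .classifier import PerformanceReport

    with open(path) as fh:
        return PerformanceReport.from_dict(json.load(fh))
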