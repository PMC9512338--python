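"""Plain-text cohort format: one long/tidy CSV per cohort.

Layout (comma-delimited, header row, ``#`` metadata comments first):

    # intramargin cohort v1
    # technique: SS-IMRT
    # axes: si_mm ap_mm lr_mm; positive = superior, anterior, left
    technique,patient_id,fraction_id,time_s,si_mm,ap_mm,lr_mm
    SS-IMRT,P01,F01,0.000000,0.000000,0.000000,0.000000
    ...

Numbers are serialized at fixed 1e-6 precision (mm and s); writing is
canonical (rows sorted by patient, fraction, time) so write-read-write is
byte-stable.  Reading validates the trace invariants and rejects violations
rather than silently fixing them.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AXIS_COLUMNS, CohortDataset, ValidationError

_COLUMNS = ["technique", "patient_id", "fraction_id", "time_s", *AXIS_COLUMNS]
_MAGIC = "# intramargin cohort v1"


def write_cohort(dataset: CohortDataset, path: str | Path) -> Path:
    """Write a cohort to ``path`` in the canonical dialect; returns the path."""
    dataset.validate()
    frame = dataset.to_frame()
    if len(frame):
        frame = frame.sort_values(
            ["patient_id", "fraction_id", "time_s"], kind="mergesort"
        )
    buf = io.StringIO()
    buf.write(f"{_MAGIC}\n")
    buf.write(f"# technique: {dataset.technique}\n")
    buf.write("# axes: si_mm ap_mm lr_mm; positive = superior, anterior, left\n")
    frame.to_csv(buf, index=False, float_format="%.6f", columns=_COLUMNS)
    Path(path).write_text(buf.getvalue())
    return Path(path)


def _read_technique_comment(path: Path) -> str | None:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# technique:"):
                return line.split(":", 1)[1].strip()
    return None


def read_cohort(path: str | Path) -> CohortDataset:
    """Read and validate a cohort file written in the documented dialect.

    Row order in the file is irrelevant (samples are re-sorted by time within
    each fraction), but invariant violations — missing columns, malformed
    numbers, duplicate times, a nonzero first sample — raise
    :class:`ValidationError` naming the offending row.
    """
    path = Path(path)
    raw = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    missing = [c for c in _COLUMNS if c not in raw.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    for col in ("time_s", *AXIS_COLUMNS):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path}: malformed numeric value {raw[col].iloc[idx]!r} in column "
                f"{col!r}, data row {idx + 1}"
            )
        if converted.isna().any():
            idx = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise ValidationError(f"{path}: empty cell in column {col!r}, data row {idx + 1}")
        raw[col] = converted
    if len(raw) == 0:
        technique = _read_technique_comment(path) or ""
        return CohortDataset(technique=technique, patients=[])

    for (pid, fid), grp in raw.groupby(["patient_id", "fraction_id"], sort=False):
        t = grp["time_s"].to_numpy()
        order = np.argsort(t, kind="mergesort")
        t = t[order]
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"{path}: duplicate/non-increasing times in fraction {pid}/{fid}"
            )
        if t[0] != 0.0:
            raise ValidationError(
                f"{path}: fraction {pid}/{fid} does not start at time 0 (first time {t[0]})"
            )
        first = grp.iloc[order[0]][list(AXIS_COLUMNS)].to_numpy(dtype=float)
        if np.any(first != 0.0):
            raise ValidationError(
                f"{path}: fraction {pid}/{fid} has nonzero displacement "
                f"{first.tolist()} at time 0"
            )
    try:
        return CohortDataset.from_frame(raw)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
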