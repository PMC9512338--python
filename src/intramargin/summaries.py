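"""Descriptive statistics of intra-fraction motion.

Per-fraction maximum absolute displacement from the zeroed start position,
per-patient mean +/- SD of those maxima, time-resolved mean absolute
displacement curves, and the between-technique rank-sum comparison.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    AXIS_COLUMNS,
    CohortDataset,
    FractionSummary,
    MotionTrace,
    PatientSummary,
    ValidationError,
)


def max_abs_displacement(trace: MotionTrace) -> np.ndarray:
    """Per-axis maximum of |displacement| over all samples of one fraction."""
    if trace.n_samples == 0:
        raise ValidationError("empty trace")
    return np.abs(trace.displacement_mm).max(axis=0)


def summarize_fraction(trace: MotionTrace) -> FractionSummary:
    trace.validate()
    d = trace.displacement_mm
    abs_d = np.abs(d)
    idx = abs_d.argmax(axis=0)
    n = trace.n_samples
    return FractionSummary(
        patient_id=trace.patient_id,
        fraction_id=trace.fraction_id,
        duration_s=trace.duration_s,
        max_abs_mm=abs_d.max(axis=0),
        signed_at_max_mm=d[idx, np.arange(3)],
        mean_mm=d.mean(axis=0),
        sd_mm=d.std(axis=0, ddof=1) if n > 1 else np.zeros(3),
    )


def summarize_patient(
    fractions: Sequence[MotionTrace | FractionSummary],
) -> PatientSummary:
    """Mean and sample SD (n-1) of the per-fraction maximum absolute
    displacements of one patient; SD is 0 for a single fraction."""
    if len(fractions) == 0:
        raise ValidationError("summarize_patient requires at least one fraction")
    summaries = [
        fr if isinstance(fr, FractionSummary) else summarize_fraction(fr)
        for fr in fractions
    ]
    pid = summaries[0].patient_id
    if any(s.patient_id != pid for s in summaries):
        raise ValidationError("fractions belong to different patients")
    maxima = np.vstack([s.max_abs_mm for s in summaries])
    n = len(summaries)
    return PatientSummary(
        patient_id=pid,
        n_fractions=n,
        mean_of_max_mm=maxima.mean(axis=0),
        sd_of_max_mm=maxima.std(axis=0, ddof=1) if n > 1 else np.zeros(3),
    )


def fraction_table(dataset: CohortDataset) -> pd.DataFrame:
    rows = []
    for tr in dataset.iter_traces():
        s = summarize_fraction(tr)
        rows.append(
            {
                "patient_id": s.patient_id,
                "fraction_id": s.fraction_id,
                "duration_s": s.duration_s,
                **{f"max_abs_{c}": v for c, v in zip(AXIS_COLUMNS, s.max_abs_mm)},
                **{f"mean_{c}": v for c, v in zip(AXIS_COLUMNS, s.mean_mm)},
                **{f"sd_{c}": v for c, v in zip(AXIS_COLUMNS, s.sd_mm)},
            }
        )
    return pd.DataFrame(rows)


def patient_table(dataset: CohortDataset) -> pd.DataFrame:
    rows = []
    for pat in dataset.patients:
        s = summarize_patient(pat.traces)
        rows.append(
            {
                "patient_id": s.patient_id,
                "n_fractions": s.n_fractions,
                **{f"mean_max_{c}": v for c, v in zip(AXIS_COLUMNS, s.mean_of_max_mm)},
                **{f"sd_max_{c}": v for c, v in zip(AXIS_COLUMNS, s.sd_of_max_mm)},
            }
        )
    return pd.DataFrame(rows)


def mean_abs_curve(dataset: CohortDataset, bin_s: float = 1.0) -> pd.DataFrame:
    """Mean |displacement| per axis in time bins of width ``bin_s``.

    Each bin averages over every sample (from every fraction still running)
    whose time falls in [k*bin_s, (k+1)*bin_s); fractions shorter than a bin's
    start contribute nothing to it.  Returns a frame with the bin start time,
    per-axis means and the number of contributing samples.
    """
    if not bin_s > 0:
        raise ValidationError("bin_s must be > 0")
    if dataset.n_fractions == 0:
        raise ValidationError("empty dataset")
    times = np.concatenate([tr.times_s for tr in dataset.iter_traces()])
    disp = np.concatenate([np.abs(tr.displacement_mm) for tr in dataset.iter_traces()])
    bins = np.floor(times / bin_s).astype(int)
    frame = pd.DataFrame(disp, columns=list(AXIS_COLUMNS))
    frame["bin"] = bins
    agg = frame.groupby("bin").agg(
        **{c: (c, "mean") for c in AXIS_COLUMNS}, n_samples=("si_mm", "size")
    )
    agg = agg.reset_index()
    agg.insert(0, "time_s", agg.pop("bin") * bin_s)
    return agg


def wilcoxon_compare(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) between two groups.

    Exact enumeration for combined n <= 20 without ties; otherwise the normal
    approximation with tie correction.  Degenerate input (all values identical
    across both groups) returns p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; p set to 1")
        return float(a.size * b.size / 2.0), 1.0
    n = a.size + b.size
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def max_abs_by_technique(
    datasets: Sequence[CohortDataset], axis: int
) -> dict[str, np.ndarray]:
    """Per-fraction maximum absolute displacements pooled by technique label,
    for one axis — the unit of comparison used by the rank-sum test."""
    out: dict[str, list[float]] = {}
    for ds in datasets:
        vals = out.setdefault(ds.technique, [])
        for tr in ds.iter_traces():
            vals.append(float(max_abs_displacement(tr)[axis]))
    return {k: np.asarray(v) for k, v in out.items()}
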