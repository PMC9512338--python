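"""Core containers for intra-fraction motion analysis.

Displacements are in millimetres, signed, relative to the zeroed position at
scan start.  Axis order is superior-inferior (SI), anterior-posterior (AP),
left-right (LR) everywhere; positive = superior / anterior / left.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

AXES = ("SI", "AP", "LR")
AXIS_COLUMNS = ("si_mm", "ap_mm", "lr_mm")
AXIS_INDEX = {name: i for i, name in enumerate(AXES)}


class ValidationError(ValueError):
    """Raised when a trace, cohort or config violates a structural invariant."""


def axis_index(axis: str | int) -> int:
    if isinstance(axis, (int, np.integer)):
        if not 0 <= int(axis) < 3:
            raise ValidationError(f"axis index out of range: {axis}")
        return int(axis)
    try:
        return AXIS_INDEX[str(axis).upper()]
    except KeyError:
        raise ValidationError(
            f"unknown axis {axis!r}; expected one of {AXES}"
        ) from None


@dataclass
class MotionTrace:
    """One fraction's time-sampled 3-axis displacement from the zeroed start.

    ``times_s`` is strictly increasing and starts at 0; the displacement at
    t = 0 is the zeroing reference and is identically the zero vector.
    """

    patient_id: str
    fraction_id: str
    times_s: np.ndarray
    displacement_mm: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)

    @property
    def n_samples(self) -> int:
        return int(self.times_s.shape[0])

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1])

    def validate(self) -> "MotionTrace":
        t, d = self.times_s, self.displacement_mm
        if t.ndim != 1 or t.size == 0:
            raise ValidationError(
                f"trace {self.patient_id}/{self.fraction_id}: empty or non-1d times"
            )
        if d.shape != (t.size, 3):
            raise ValidationError(
                f"trace {self.patient_id}/{self.fraction_id}: displacement shape "
                f"{d.shape} does not match {t.size} samples x 3 axes"
            )
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(d)):
            raise ValidationError(
                f"trace {self.patient_id}/{self.fraction_id}: non-finite values"
            )
        if t[0] != 0.0:
            raise ValidationError(
                f"trace {self.patient_id}/{self.fraction_id}: first time sample is "
                f"{t[0]}, must be 0"
            )
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError(
                f"trace {self.patient_id}/{self.fraction_id}: times not strictly increasing"
            )
        if np.any(d[0] != 0.0):
            raise ValidationError(
                f"trace {self.patient_id}/{self.fraction_id}: displacement at t=0 is "
                f"{d[0].tolist()}, must be the zero vector"
            )
        return self

    def with_displacement(self, displacement_mm: np.ndarray) -> "MotionTrace":
        return replace(self, displacement_mm=np.asarray(displacement_mm, dtype=float))


@dataclass
class PatientRecord:
    patient_id: str
    traces: list[MotionTrace] = field(default_factory=list)


@dataclass
class CohortDataset:
    """Technique-labelled nesting of patients -> fractions -> traces."""

    technique: str
    patients: list[PatientRecord] = field(default_factory=list)

    def validate(self) -> "CohortDataset":
        seen_pat: set[str] = set()
        for pat in self.patients:
            if pat.patient_id in seen_pat:
                raise ValidationError(f"duplicate patient_id {pat.patient_id!r}")
            seen_pat.add(pat.patient_id)
            seen_fr: set[str] = set()
            for tr in pat.traces:
                if tr.patient_id != pat.patient_id:
                    raise ValidationError(
                        f"trace patient_id {tr.patient_id!r} does not match record "
                        f"{pat.patient_id!r}"
                    )
                if tr.fraction_id in seen_fr:
                    raise ValidationError(
                        f"duplicate fraction_id {tr.fraction_id!r} for patient "
                        f"{pat.patient_id!r}"
                    )
                seen_fr.add(tr.fraction_id)
                tr.validate()
        return self

    def iter_traces(self) -> Iterator[MotionTrace]:
        for pat in self.patients:
            yield from pat.traces

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_fractions(self) -> int:
        return sum(len(p.traces) for p in self.patients)

    @property
    def n_samples(self) -> int:
        return sum(tr.n_samples for tr in self.iter_traces())

    def fractions_per_patient(self) -> list[int]:
        return [len(p.traces) for p in self.patients]

    def to_frame(self, drop_reference: bool = False) -> pd.DataFrame:
        """Long/tidy view: one row per sample.

        ``drop_reference=True`` drops the t = 0 sample of every fraction; that
        sample is the zeroing reference (identically 0) and carries no
        information about the motion process.
        """
        rows = []
        for tr in self.iter_traces():
            sel = slice(1, None) if drop_reference else slice(None)
            t = tr.times_s[sel]
            d = tr.displacement_mm[sel]
            df = pd.DataFrame(
                {
                    "technique": self.technique,
                    "patient_id": tr.patient_id,
                    "fraction_id": tr.fraction_id,
                    "time_s": t,
                    "si_mm": d[:, 0],
                    "ap_mm": d[:, 1],
                    "lr_mm": d[:, 2],
                }
            )
            rows.append(df)
        if not rows:
            return pd.DataFrame(
                columns=["technique", "patient_id", "fraction_id", "time_s", *AXIS_COLUMNS]
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, technique: str | None = None) -> "CohortDataset":
        if technique is None:
            uniq = frame["technique"].unique()
            if len(uniq) > 1:
                raise ValidationError(f"multiple technique labels in frame: {list(uniq)}")
            technique = str(uniq[0]) if len(uniq) else ""
        patients: list[PatientRecord] = []
        for pid, pgrp in frame.groupby("patient_id", sort=False):
            rec = PatientRecord(patient_id=str(pid))
            for fid, fgrp in pgrp.groupby("fraction_id", sort=False):
                fgrp = fgrp.sort_values("time_s")
                rec.traces.append(
                    MotionTrace(
                        patient_id=str(pid),
                        fraction_id=str(fid),
                        times_s=fgrp["time_s"].to_numpy(),
                        displacement_mm=fgrp[list(AXIS_COLUMNS)].to_numpy(),
                    )
                )
            patients.append(rec)
        return cls(technique=technique, patients=patients).validate()


@dataclass
class FractionSummary:
    patient_id: str
    fraction_id: str
    duration_s: float
    max_abs_mm: np.ndarray        # per-axis max |displacement|
    signed_at_max_mm: np.ndarray  # signed value at the sample achieving it
    mean_mm: np.ndarray
    sd_mm: np.ndarray             # sample SD (n-1), 0 for a single sample


@dataclass
class PatientSummary:
    patient_id: str
    n_fractions: int
    mean_of_max_mm: np.ndarray
    sd_of_max_mm: np.ndarray      # sample SD over fractions, 0 when n_fractions == 1


@dataclass
class VarianceComponents:
    """Nested variance components for one axis, in mm.

    ``sigma_pt`` is the inter-patient SD (systematic), ``sigma_fr`` the
    inter-fraction SD within patient, ``sigma_intra`` the intra-fraction SD.
    CIs are (lo, hi) tuples at ``ci_level``.
    """

    axis: str
    sigma_pt_mm: float
    sigma_fr_mm: float
    sigma_intra_mm: float
    overall_mean_mm: float
    ci_level: float
    ci_pt: tuple[float, float]
    ci_fr: tuple[float, float]
    ci_intra: tuple[float, float]
    ci_mean: tuple[float, float]
    estimator: str                # "moment" | "reml"
    n_patients: int
    fractions_per_patient: tuple[int, ...]
    samples_per_fraction: tuple[int, ...]

    def validate(self) -> "VarianceComponents":
        for name in ("sigma_pt_mm", "sigma_fr_mm", "sigma_intra_mm"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} negative")
        for name, est in (
            ("ci_pt", self.sigma_pt_mm),
            ("ci_fr", self.sigma_fr_mm),
            ("ci_intra", self.sigma_intra_mm),
            ("ci_mean", self.overall_mean_mm),
        ):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ValidationError(f"{name}: lo > hi")
            if not (lo - 1e-9 <= est <= hi + 1e-9):
                raise ValidationError(f"{name} does not contain its point estimate")
        return self


@dataclass
class EffectiveErrors:
    """Effective systematic / random errors for a course of N fractions."""

    axis: str
    sigma_sys_eff_mm: float   # Sigma_eff = sqrt(Sigma_pt^2 + sigma_fr^2 / N)
    sigma_rand_eff_mm: float  # sigma_eff = sqrt((1 - 1/N) sigma_fr^2 + sigma_intra^2)
    n_fractions: int
    source: str


@dataclass
class MarginResult:
    """Internal margin: IM = c_sys * Sigma_eff + c_rand * sigma_eff (default 2.5, 0.7)."""

    axis: str
    im_mm: float
    coefficients: tuple[float, float]
    lineage: dict

    def validate(self) -> "MarginResult":
        if self.im_mm < 0:
            raise ValidationError("negative margin")
        return self
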