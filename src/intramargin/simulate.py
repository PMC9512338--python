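"""Synthetic cohorts of intra-fraction prostate-motion traces.

The generator is the sampling twin of the nested random-effects model the
estimators assume: per axis

    y(p, f, t) = m + a_p + b_pf + e_pf(t),   t > 0,

with a_p ~ N(0, sigma_pt^2) (patient offsets), b_pf ~ N(0, sigma_fr^2)
(fraction offsets) and e_pf a stationary intra-fraction process with SD
sigma_intra (white noise by default, AR(1) when a correlation time is set).
The t = 0 sample is the zeroing reference and is identically 0, mirroring the
clinical convention that the position at scan start defines zero; the offsets
and noise apply from the first post-reference sample onward, so the t > 0
samples are exactly stationary and the configured components are recoverable.

Optional non-model features emulate real traces: a linear baseline drift and
rare transient "rectal gas" excursions, modelled as half-sine pulses on the
AP axis with Poisson counts per fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import CohortDataset, MotionTrace, PatientRecord, ValidationError


def _as_vec3(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape == ():
        arr = np.full(3, float(arr))
    if arr.shape != (3,):
        raise ValidationError(f"{name}: expected a scalar or 3-vector (SI, AP, LR)")
    return arr


@dataclass
class SimulationConfig:
    """Generative parameters for one technique's cohort.

    Defaults reproduce an SS-IMRT-like cohort: 5 patients x 37 fractions,
    492 s fractions sampled at 4 Hz, with the per-axis variance components
    and overall means reported for ultrasound-monitored step-and-shoot
    delivery.  Drift and gas events default to off so that the generator
    matches the estimation model exactly; enable them to stress-test the
    exchangeability assumption.
    """

    n_patients: int = 5
    fractions_per_patient: list[int] = field(default_factory=lambda: [37] * 5)
    duration_s: float = 492.0
    sample_rate_hz: float = 4.0
    overall_mean_mm: np.ndarray = field(default_factory=lambda: np.array([0.05, -0.10, 0.03]))
    sigma_pt_mm: np.ndarray = field(default_factory=lambda: np.array([0.00, 0.10, 0.00]))
    sigma_fr_mm: np.ndarray = field(default_factory=lambda: np.array([0.41, 0.80, 0.31]))
    sigma_intra_mm: np.ndarray = field(default_factory=lambda: np.array([0.34, 0.69, 0.23]))
    drift_rate_mm_per_min: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gas_event_rate_per_fraction: float = 0.0
    gas_event_amplitude_mm: float = 9.7
    gas_event_duration_s: float = 10.0
    ar_time_s: float = 0.0     # AR(1) correlation time of the intra-fraction noise; 0 = white
    seed: int = 0
    technique: str = "SS-IMRT"

    def __post_init__(self) -> None:
        for name in ("overall_mean_mm", "sigma_pt_mm", "sigma_fr_mm",
                     "sigma_intra_mm", "drift_rate_mm_per_min"):
            setattr(self, name, _as_vec3(getattr(self, name), name))
        self.fractions_per_patient = [int(f) for f in np.atleast_1d(self.fractions_per_patient)]

    def validate(self) -> "SimulationConfig":
        if self.n_patients < 1:
            raise ValidationError("n_patients: must be >= 1")
        if len(self.fractions_per_patient) != self.n_patients:
            raise ValidationError(
                "fractions_per_patient: length "
                f"{len(self.fractions_per_patient)} != n_patients {self.n_patients}"
            )
        if any(f < 1 for f in self.fractions_per_patient):
            raise ValidationError("fractions_per_patient: all counts must be >= 1")
        if not self.duration_s > 0:
            raise ValidationError("duration_s: must be > 0")
        if not self.sample_rate_hz > 0:
            raise ValidationError("sample_rate_hz: must be > 0")
        for name in ("sigma_pt_mm", "sigma_fr_mm", "sigma_intra_mm"):
            if np.any(getattr(self, name) < 0):
                raise ValidationError(f"{name}: SDs must be >= 0")
        if self.gas_event_rate_per_fraction < 0:
            raise ValidationError("gas_event_rate_per_fraction: must be >= 0")
        if not self.gas_event_amplitude_mm > 0:
            raise ValidationError("gas_event_amplitude_mm: must be > 0")
        if not self.gas_event_duration_s > 0:
            raise ValidationError("gas_event_duration_s: must be > 0")
        if self.ar_time_s < 0:
            raise ValidationError("ar_time_s: must be >= 0")
        return self

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimulationConfig":
        kwargs = dict(mapping)
        n = int(kwargs.get("n_patients", 5))
        fr = kwargs.get("fractions_per_patient", 37)
        if np.ndim(fr) == 0:
            kwargs["fractions_per_patient"] = [int(fr)] * n
        kwargs["n_patients"] = n
        return cls(**kwargs).validate()


def half_sine_pulse(times_s: np.ndarray, onset_s: float, amplitude_mm: float,
                    duration_s: float) -> np.ndarray:
    """Smooth unipolar pulse: amplitude * sin(pi (t - onset) / duration) inside
    [onset, onset + duration], zero outside."""
    phase = (np.asarray(times_s, dtype=float) - onset_s) / duration_s
    pulse = np.where((phase >= 0.0) & (phase <= 1.0),
                     np.sin(np.pi * np.clip(phase, 0.0, 1.0)), 0.0)
    return amplitude_mm * pulse


def inject_gas_event(trace: MotionTrace, onset_s: float, amplitude_mm: float,
                     duration_s: float, axis: int | str = "AP") -> MotionTrace:
    """Return a copy of ``trace`` with a half-sine excursion added on one axis.

    The pulse peaks at |amplitude_mm| (signed by the sign of ``amplitude_mm``)
    at onset + duration/2; samples outside [onset, onset + duration] are
    unchanged.
    """
    from .datatypes import axis_index

    if not duration_s > 0:
        raise ValidationError("duration_s: must be > 0")
    if not 0.0 <= onset_s < trace.duration_s:
        raise ValidationError(
            f"onset_s {onset_s} outside trace time range [0, {trace.duration_s})"
        )
    ax = axis_index(axis)
    d = trace.displacement_mm.copy()
    d[:, ax] += half_sine_pulse(trace.times_s, onset_s, amplitude_mm, duration_s)
    return trace.with_displacement(d)


def _intra_noise(rng: np.random.Generator, n: int, sigma: np.ndarray,
                 phi: float) -> np.ndarray:
    """Stationary intra-fraction noise for the n post-reference samples (n x 3)."""
    z = rng.standard_normal((n, 3))
    if phi == 0.0 or n <= 1:
        return z * sigma
    from scipy.signal import lfilter

    w = z.copy()
    w[1:] *= np.sqrt(1.0 - phi * phi)  # innovations scaled for stationary unit SD
    x = lfilter([1.0], [1.0, -phi], w, axis=0)
    return x * sigma


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Sample a full cohort from the nested model; bit-identical for equal seeds."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.sample_rate_hz
    n_post = int(np.floor(config.duration_s * config.sample_rate_hz))
    times = np.arange(n_post + 1) * dt
    phi = float(np.exp(-dt / config.ar_time_s)) if config.ar_time_s > 0 else 0.0
    drift_per_s = config.drift_rate_mm_per_min / 60.0

    patients: list[PatientRecord] = []
    for p in range(config.n_patients):
        pid = f"P{p + 1:02d}"
        a_p = rng.standard_normal(3) * config.sigma_pt_mm
        rec = PatientRecord(patient_id=pid)
        for f in range(config.fractions_per_patient[p]):
            fid = f"F{f + 1:02d}"
            b_pf = rng.standard_normal(3) * config.sigma_fr_mm
            disp = np.zeros((n_post + 1, 3))
            disp[1:] = (
                config.overall_mean_mm + a_p + b_pf
                + _intra_noise(rng, n_post, config.sigma_intra_mm, phi)
                + times[1:, None] * drift_per_s
            )
            trace = MotionTrace(patient_id=pid, fraction_id=fid,
                                times_s=times.copy(), displacement_mm=disp)
            if config.gas_event_rate_per_fraction > 0:
                n_events = rng.poisson(config.gas_event_rate_per_fraction)
                for _ in range(n_events):
                    dur = min(config.gas_event_duration_s, config.duration_s)
                    onset = rng.uniform(0.0, max(config.duration_s - dur, dt))
                    # peak ~ Exponential with mean amplitude/2: typical events are a
                    # few mm, rare ones reach the configured amplitude scale
                    peak = rng.exponential(config.gas_event_amplitude_mm / 2.0)
                    trace = inject_gas_event(trace, onset, peak, dur, axis="AP")
            rec.traces.append(trace)
        patients.append(rec)
    return CohortDataset(technique=config.technique, patients=patients).validate()
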