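import numpy as np
import pandas as pd
import pytest

from intramargin import CohortDataset, MotionTrace, PatientRecord, SimulationConfig, simulate_cohort


def make_trace(patient_id, fraction_id, values_by_axis, dt=0.25, validate=True):
    """Trace with given per-axis values for t > 0 and the zero reference at t = 0.

    ``values_by_axis``: dict axis index -> sequence (all same length).
    """
    n = len(next(iter(values_by_axis.values())))
    disp = np.zeros((n + 1, 3))
    for ax, vals in values_by_axis.items():
        disp[1:, ax] = vals
    tr = MotionTrace(
        patient_id=patient_id,
        fraction_id=fraction_id,
        times_s=np.arange(n + 1) * dt,
        displacement_mm=disp,
    )
    return tr.validate() if validate else tr


def make_long_frame(layout):
    """Long frame from {patient: {fraction: [values]}} for direct estimator input."""
    rows = []
    for pid, fractions in layout.items():
        for fid, values in fractions.items():
            for v in values:
                rows.append(
                    {"patient_id": pid, "fraction_id": fid, "value_mm": float(v)}
                )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate simulated cohort with known generative components."""
    cfg = SimulationConfig(
        n_patients=6,
        fractions_per_patient=[8] * 6,
        duration_s=60.0,
        sigma_pt_mm=0.3,
        sigma_fr_mm=0.6,
        sigma_intra_mm=0.4,
        overall_mean_mm=0.1,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def tiny_unbalanced_frame():
    """2 patients, unequal fractions/samples — small enough for dense oracles."""
    rng = np.random.default_rng(314)
    layout = {
        "p1": {"f1": rng.normal(0.2, 1.0, 3), "f2": rng.normal(0.2, 1.0, 4)},
        "p2": {"f1": rng.normal(-0.4, 1.0, 2), "f2": rng.normal(-0.4, 1.0, 5), "f3": rng.normal(-0.4, 1.0, 3)},
    }
    return make_long_frame(layout)


def dense_restricted_loglik(frame, sigma_pt, sigma_fr, sigma_intra, mean=None,
                            value_col="value_mm"):
    """Brute-force restricted log-likelihood via the explicit dense covariance.

    Independent of the sufficient-statistics path: builds
    V = sigma_pt^2 B_patient + sigma_fr^2 B_fraction + sigma_intra^2 I and uses
    generalized least squares and slogdet directly.
    """
    y = frame[value_col].to_numpy(dtype=float)
    pats = frame["patient_id"].to_numpy()
    frs = (frame["patient_id"].astype(str) + "/" + frame["fraction_id"].astype(str)).to_numpy()
    n = y.size
    V = (
        sigma_pt**2 * (pats[:, None] == pats[None, :])
        + sigma_fr**2 * (frs[:, None] == frs[None, :])
        + sigma_intra**2 * np.eye(n)
    )
    Vi = np.linalg.inv(V)
    one = np.ones(n)
    weight = one @ Vi @ one
    beta = (one @ Vi @ y) / weight if mean is None else mean
    r = y - beta
    _, logdet = np.linalg.slogdet(V)
    return -0.5 * ((n - 1) * np.log(2 * np.pi) + logdet + np.log(weight) + r @ Vi @ r)


def zero_cohort(n_patients=2, fractions=2, n_samples=4, technique="TEST"):
    patients = []
    for p in range(n_patients):
        pid = f"P{p}"
        rec = PatientRecord(patient_id=pid)
        for f in range(fractions):
            rec.traces.append(
                MotionTrace(
                    patient_id=pid,
                    fraction_id=f"F{f}",
                    times_s=np.arange(n_samples) * 0.25,
                    displacement_mm=np.zeros((n_samples, 3)),
                )
            )
        patients.append(rec)
    return CohortDataset(technique=technique, patients=patients).validate()
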