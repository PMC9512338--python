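import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intramargin import (
    RemlVarianceEstimator,
    SimulationConfig,
    ValidationError,
    moment_components,
    reml_fit,
    reml_loglik,
    simulate_cohort,
)
from intramargin.variance import MomentVarianceEstimator, build_stats, _restricted_loglik
from conftest import dense_restricted_loglik, make_long_frame


# ---- moment estimator ---------------------------------------------------


def test_moment_hand_arithmetic_oracle():
    # 2 patients x 1 fraction x 2 samples, values {0,2} and {4,6}:
    # patient means {1,5} -> Sigma = SD({1,5}) = 2*sqrt(2); within SDs sqrt(2)
    frame = make_long_frame({"p1": {"f1": [0.0, 2.0]}, "p2": {"f1": [4.0, 6.0]}})
    comp = moment_components(frame)
    assert comp.sigma_pt_mm == pytest.approx(2 * np.sqrt(2))
    assert comp.sigma_intra_mm == pytest.approx(np.sqrt(2))
    assert comp.sigma_fr_mm == 0.0
    assert comp.overall_mean_mm == pytest.approx(3.0)


def test_moment_constant_patient_offsets():
    frame = make_long_frame(
        {
            "p1": {"f1": [1.0] * 3, "f2": [1.0] * 3},
            "p2": {"f1": [-1.0] * 3, "f2": [-1.0] * 3},
            "p3": {"f1": [0.0] * 3, "f2": [0.0] * 3},
        }
    )
    comp = moment_components(frame)
    assert comp.sigma_fr_mm == 0.0
    assert comp.sigma_intra_mm == 0.0
    assert comp.sigma_pt_mm == pytest.approx(np.std([1.0, -1.0, 0.0], ddof=1))


def test_moment_single_patient_rejected():
    frame = make_long_frame({"p1": {"f1": [0.0, 1.0], "f2": [2.0, 1.0]}})
    with pytest.raises(ValidationError, match="2 patients"):
        MomentVarianceEstimator().fit(frame)


# ---- restricted log-likelihood ------------------------------------------


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    sigma_pt=st.floats(0.0, 2.0),
    sigma_fr=st.floats(0.05, 2.0),
    sigma_intra=st.floats(0.05, 2.0),
    seed=st.integers(0, 1000),
)
def test_loglik_matches_dense_oracle(sigma_pt, sigma_fr, sigma_intra, seed):
    """Sufficient-statistics path == dense-covariance GLS on small cohorts."""
    rng = np.random.default_rng(seed)
    layout = {
        "p1": {"f1": rng.normal(0, 1, 3), "f2": rng.normal(0, 1, 4)},
        "p2": {"f1": rng.normal(0, 1, 2), "f2": rng.normal(0, 1, 5), "f3": rng.normal(0, 1, 3)},
        "p3": {"f1": rng.normal(0, 1, 6)},
    }
    frame = make_long_frame(layout)
    fast = reml_loglik((sigma_pt, sigma_fr, sigma_intra, None), frame)
    slow = dense_restricted_loglik(frame, sigma_pt, sigma_fr, sigma_intra)
    assert fast == pytest.approx(slow, abs=1e-8)


def test_loglik_with_fixed_mean_matches_dense(tiny_unbalanced_frame):
    for mean in (-0.5, 0.0, 0.7):
        fast = reml_loglik((0.3, 0.6, 0.4, mean), tiny_unbalanced_frame)
        slow = dense_restricted_loglik(tiny_unbalanced_frame, 0.3, 0.6, 0.4, mean=mean)
        assert fast == pytest.approx(slow, abs=1e-8)


def test_loglik_translation_invariance(tiny_unbalanced_frame):
    shifted = tiny_unbalanced_frame.copy()
    shifted["value_mm"] += 5.0
    fit_a = RemlVarianceEstimator(compute_ci=False).fit(tiny_unbalanced_frame)
    fit_b = RemlVarianceEstimator(compute_ci=False).fit(shifted)
    assert fit_b.mean_ == pytest.approx(fit_a.mean_ + 5.0, abs=1e-6)
    assert fit_b.loglik_ == pytest.approx(fit_a.loglik_, abs=1e-6)
    assert fit_b.sigma_intra_ == pytest.approx(fit_a.sigma_intra_, abs=1e-6)


def test_loglik_collapses_to_iid_reml():
    # with Sigma_pt = sigma_fr = 0 the model is iid N(m, sigma^2) and the
    # restricted likelihood has the (n-1)-denominator form
    rng = np.random.default_rng(5)
    y = rng.normal(0.3, 0.8, 12)
    frame = make_long_frame({"p1": {"f1": y[:6]}, "p2": {"f1": y[6:]}})
    sigma = 0.7
    n = y.size
    ss = np.sum((y - y.mean()) ** 2)
    expected = -0.5 * (
        (n - 1) * np.log(2 * np.pi)
        + n * np.log(sigma**2)
        + np.log(n / sigma**2)
        + ss / sigma**2
    )
    assert reml_loglik((0.0, 0.0, sigma, None), frame) == pytest.approx(expected, abs=1e-10)


def test_loglik_degenerate_dataset_rejected():
    frame = make_long_frame({"p1": {"f1": [1.0]}})
    with pytest.raises(ValidationError):
        reml_loglik((0.1, 0.1, 0.5, None), frame)


# ---- REML fit -----------------------------------------------------------


def _balanced_frame(seed=7, a=6, b=5, n=8, sp=0.8, sf=0.6, se=0.5, mean=0.2):
    rng = np.random.default_rng(seed)
    layout = {}
    for p in range(a):
        ap = rng.normal(0, sp)
        layout[f"p{p}"] = {
            f"f{f}": mean + ap + rng.normal(0, sf) + rng.normal(0, se, n)
            for f in range(b)
        }
    return layout, (a, b, n)


def _anova_estimates(frame, a, b, n):
    y = frame["value_mm"].to_numpy().reshape(a, b, n)
    ybar_pf = y.mean(axis=2)
    ybar_p = y.mean(axis=(1, 2))
    grand = y.mean()
    mse = ((y - ybar_pf[:, :, None]) ** 2).sum() / (a * b * (n - 1))
    msf = n * ((ybar_pf - ybar_p[:, None]) ** 2).sum() / (a * (b - 1))
    msp = b * n * ((ybar_p - grand) ** 2).sum() / (a - 1)
    return np.sqrt([(msp - msf) / (b * n), (msf - mse) / n, mse])


@pytest.mark.parametrize("seed", [7, 19])
def test_reml_equals_balanced_anova(seed):
    """On balanced designs with interior optima REML reproduces the
    expected-mean-squares (nested ANOVA) closed form."""
    layout, (a, b, n) = _balanced_frame(seed=seed)
    frame = make_long_frame(layout)
    sp, sf, se = _anova_estimates(frame, a, b, n)
    est = RemlVarianceEstimator(compute_ci=False).fit(frame)
    assert est.sigma_pt_ == pytest.approx(sp, abs=1e-6)
    assert est.sigma_fr_ == pytest.approx(sf, abs=1e-6)
    assert est.sigma_intra_ == pytest.approx(se, abs=1e-6)


def test_reml_scale_equivariance():
    layout, _ = _balanced_frame(seed=11, a=4, b=4, n=5)
    frame = make_long_frame(layout)
    k = 3.0
    scaled = frame.copy()
    scaled["value_mm"] *= k
    fa = RemlVarianceEstimator().fit(frame)
    fb = RemlVarianceEstimator().fit(scaled)
    for attr in ("sigma_pt_", "sigma_fr_", "sigma_intra_", "mean_"):
        assert getattr(fb, attr) == pytest.approx(k * getattr(fa, attr), rel=1e-4, abs=1e-7)
    for attr in ("ci_pt_", "ci_fr_", "ci_intra_", "ci_mean_"):
        np.testing.assert_allclose(
            getattr(fb, attr), np.multiply(k, getattr(fa, attr)), rtol=1e-3, atol=1e-6
        )


def test_reml_boundary_sigma_pt_zero():
    """Data with no patient effect: fit lands on the 0 boundary, CI low = 0."""
    cfg = SimulationConfig(
        n_patients=8, fractions_per_patient=[10] * 8, duration_s=30.0,
        sigma_pt_mm=0.0, sigma_fr_mm=0.5, sigma_intra_mm=0.4,
        overall_mean_mm=0.0, seed=77,
    )
    comp = reml_fit(simulate_cohort(cfg), axis="AP")
    assert comp.sigma_pt_mm < 0.12
    assert comp.ci_pt[0] == 0.0
    assert comp.ci_fr[0] <= comp.sigma_fr_mm <= comp.ci_fr[1]


def test_reml_point_estimates_recover_truth(small_cohort):
    comp = reml_fit(small_cohort, axis="AP", compute_ci=False)
    # generative truth: 0.3 / 0.6 / 0.4; patient/fraction terms have few df
    assert comp.sigma_pt_mm == pytest.approx(0.3, abs=0.25)
    assert comp.sigma_fr_mm == pytest.approx(0.6, abs=0.15)
    assert comp.sigma_intra_mm == pytest.approx(0.4, abs=0.01)


def test_reml_fit_deterministic(small_cohort):
    a = RemlVarianceEstimator(axis="SI").fit(small_cohort)
    b = RemlVarianceEstimator(axis="SI").fit(small_cohort)
    assert a.sigma_pt_ == b.sigma_pt_ and a.ci_fr_ == b.ci_fr_


def test_reml_requires_two_patients():
    frame = make_long_frame({"p1": {"f1": [0.0, 1.0], "f2": [1.0, 2.0]}})
    with pytest.raises(ValidationError, match="2 patients"):
        RemlVarianceEstimator().fit(frame)


def test_estimators_follow_sklearn_protocol(small_cohort):
    est = RemlVarianceEstimator(axis="AP", ci_level=0.9)
    params = est.get_params()
    assert params["ci_level"] == 0.9
    clone = RemlVarianceEstimator(**params)
    assert clone.get_params() == params
    est.set_params(ci_level=0.95)
    assert est.ci_level == 0.95


def test_thinning_changes_sample_counts(small_cohort):
    full = build_stats(small_cohort, axis="AP", thin=1)
    thinned = build_stats(small_cohort, axis="AP", thin=4)
    assert thinned.n_total < full.n_total
    comp = reml_fit(small_cohort, axis="AP", compute_ci=False, thin=4)
    assert comp.sigma_intra_mm == pytest.approx(0.4, abs=0.03)


def test_reml_matches_lme4_reference():
    """Independent cross-check against the standard mixed-model fitter."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available for the cross-check")
    layout, _ = _balanced_frame(seed=23, a=5, b=6, n=12, sp=0.4, sf=0.7, se=0.5)
    frame = make_long_frame(layout)
    import tempfile, os

    with tempfile.TemporaryDirectory() as tmp:
        csv = os.path.join(tmp, "d.csv")
        frame.to_csv(csv, index=False)
        script = os.path.join(tmp, "fit.R")
        with open(script, "w") as fh:
            fh.write(
                """
suppressMessages(library(lme4))
d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
m <- lmer(value_mm ~ 1 + (1|patient_id) + (1|patient_id:fraction_id), data=d, REML=TRUE)
vc <- as.data.frame(VarCorr(m))
cat(vc$sdcor[vc$grp=="patient_id"],
    vc$sdcor[vc$grp=="patient_id:fraction_id"],
    vc$sdcor[vc$grp=="Residual"],
    fixef(m)[1], sep="\\n")
"""
            )
        out = subprocess.run(
            ["Rscript", script, csv], capture_output=True, text=True, check=True
        )
    r_sp, r_sf, r_se, r_mean = (float(x) for x in out.stdout.strip().split())
    est = RemlVarianceEstimator(compute_ci=False).fit(frame)
    assert est.sigma_pt_ == pytest.approx(r_sp, abs=2e-4)
    assert est.sigma_fr_ == pytest.approx(r_sf, abs=2e-4)
    assert est.sigma_intra_ == pytest.approx(r_se, abs=2e-4)
    assert est.mean_ == pytest.approx(r_mean, abs=2e-4)
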