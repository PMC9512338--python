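"""Variance components of intra-fraction motion.

Model (per axis, displacement in mm):

    y_pft = m + a_p + b_pf + e_pft,
    a_p ~ N(0, sigma_pt^2),  b_pf ~ N(0, sigma_fr^2),  e_pft ~ N(0, sigma_intra^2),

with fractions nested in patients (fraction labels only meaningful within a
patient) and all components independent.  Two estimators are provided:

* :class:`MomentVarianceEstimator` — the classic moment definitions used with
  the van Herk recipe: the systematic SD is the SD of per-patient mean
  displacements, the random SDs are pooled SDs of fraction means and the RMS
  of within-fraction SDs.
* :class:`RemlVarianceEstimator` — restricted maximum likelihood for the
  nested model, computed from per-fraction sufficient statistics (fraction
  means and within-fraction sums of squares) so one likelihood evaluation is
  O(number of fractions), with profile-likelihood confidence intervals
  (chi-square(1) cutoff, truncated at the 0 boundary).

Both follow the scikit-learn estimator protocol: ``fit(X)`` accepts either a
:class:`~intramargin.datatypes.CohortDataset` or a long DataFrame with
``patient_id``, ``fraction_id`` and a value column, and exposes fitted
attributes with trailing underscores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.stats import chi2, t as t_dist
from sklearn.base import BaseEstimator

from .datatypes import (
    AXIS_COLUMNS,
    AXES,
    CohortDataset,
    ValidationError,
    VarianceComponents,
    axis_index,
)

_LOG2PI = np.log(2.0 * np.pi)
_XCLIP = 60.0  # clip for log-variance coordinates (exp stays finite)


# --------------------------------------------------------------------------
# sufficient statistics


@dataclass
class NestedStats:
    """Per-fraction sufficient statistics, grouped by patient (contiguous)."""

    n: np.ndarray        # samples per fraction
    ybar: np.ndarray     # fraction means
    ss: np.ndarray       # within-fraction sums of squares
    starts: np.ndarray   # reduceat start index of each patient's block
    f_per_patient: np.ndarray
    n_total: int
    n_patients: int

    @property
    def n_fractions(self) -> int:
        return self.n.size


def _stats_from_arrays(n, ybar, ss, f_per_patient) -> NestedStats:
    n = np.asarray(n, dtype=float)
    f_per_patient = np.asarray(f_per_patient, dtype=int)
    starts = np.concatenate([[0], np.cumsum(f_per_patient)[:-1]])
    return NestedStats(
        n=n,
        ybar=np.asarray(ybar, dtype=float),
        ss=np.asarray(ss, dtype=float),
        starts=starts,
        f_per_patient=f_per_patient,
        n_total=int(round(n.sum())),
        n_patients=f_per_patient.size,
    )


def build_stats(
    data: CohortDataset | pd.DataFrame,
    axis: str | int = "AP",
    drop_reference: bool = True,
    thin: int = 1,
) -> NestedStats:
    """Reduce a cohort (or long frame) to per-fraction sufficient statistics.

    ``drop_reference`` excludes each fraction's t = 0 sample, which is the
    zeroing reference (identically 0) rather than an observation.  ``thin``
    keeps every ``thin``-th remaining sample, for autocorrelation sensitivity
    checks.
    """
    if thin < 1:
        raise ValidationError("thin must be >= 1")
    ax = axis_index(axis)
    ns, ybars, sss, fpp = [], [], [], []
    if isinstance(data, CohortDataset):
        for pat in data.patients:
            count = 0
            for tr in pat.traces:
                y = tr.displacement_mm[1:, ax] if drop_reference else tr.displacement_mm[:, ax]
                y = y[::thin]
                if y.size == 0:
                    continue
                m = y.mean()
                ns.append(y.size)
                ybars.append(m)
                sss.append(float(np.sum((y - m) ** 2)))
                count += 1
            if count:
                fpp.append(count)
    else:
        frame = data
        col = AXIS_COLUMNS[ax] if AXIS_COLUMNS[ax] in frame.columns else "value_mm"
        if col not in frame.columns:
            raise ValidationError(
                f"frame lacks both {AXIS_COLUMNS[ax]!r} and 'value_mm' columns"
            )
        if drop_reference and "time_s" in frame.columns:
            frame = frame[frame["time_s"] > 0.0]
        for _, pgrp in frame.groupby("patient_id", sort=False):
            count = 0
            for _, fgrp in pgrp.groupby("fraction_id", sort=False):
                y = fgrp[col].to_numpy(dtype=float)[::thin]
                if y.size == 0:
                    continue
                m = y.mean()
                ns.append(y.size)
                ybars.append(m)
                sss.append(float(np.sum((y - m) ** 2)))
                count += 1
            if count:
                fpp.append(count)
    if not ns:
        raise ValidationError("no samples to estimate from")
    return _stats_from_arrays(ns, ybars, sss, fpp)


# --------------------------------------------------------------------------
# restricted log-likelihood (sufficient-statistics path)


def _restricted_loglik(
    stats: NestedStats,
    var_pt: float,
    var_fr: float,
    var_intra: float,
    mean: float | None = None,
) -> tuple[float, float]:
    """Restricted log-likelihood and the GLS mean.

    Convention: ll = -1/2 [ (N-1) log 2pi + log|V| + log(1'V^-1 1) + r'V^-1 r ]
    with r the residual around the GLS mean (or around ``mean`` if given; the
    log(1'V^-1 1) term is kept either way).
    """
    if var_intra <= 0:
        raise ValidationError("sigma_intra must be > 0")
    if var_pt < 0 or var_fr < 0:
        raise ValidationError("variances must be >= 0")
    if stats.n_total < 2:
        raise ValidationError("degenerate dataset: fewer than 2 samples")
    n = stats.n
    d = var_fr + var_intra / n            # variance of a fraction mean, sans patient effect
    inv_d = 1.0 / d
    s1 = np.add.reduceat(inv_d, stats.starts)
    denom = 1.0 + var_pt * s1
    weight = (s1 / denom).sum()           # 1' V^-1 1
    sy = np.add.reduceat(stats.ybar * inv_d, stats.starts)
    gls_mean = float((sy / denom).sum() / weight)
    beta = gls_mean if mean is None else float(mean)
    yc = stats.ybar - beta
    syc = np.add.reduceat(yc * inv_d, stats.starts)
    sycc = np.add.reduceat(yc * yc * inv_d, stats.starts)
    quad = sycc.sum() - (var_pt * syc * syc / denom).sum() + stats.ss.sum() / var_intra
    logdet = (
        float(((n - 1.0) * np.log(var_intra)).sum())
        + float(np.log(n).sum())
        + float(np.log(d).sum())
        + float(np.log(denom).sum())
    )
    ll = -0.5 * ((stats.n_total - 1.0) * _LOG2PI + logdet + np.log(weight) + quad)
    return float(ll), gls_mean


def reml_loglik(
    theta: tuple[float, float, float, float | None],
    data: CohortDataset | pd.DataFrame,
    axis: str | int = "AP",
    drop_reference: bool = True,
) -> float:
    """Restricted log-likelihood at theta = (sigma_pt, sigma_fr, sigma_intra, mean).

    SDs in mm; ``mean=None`` profiles the mean out by generalized least
    squares.  Cost is linear in the number of samples (one pass to build the
    sufficient statistics) and independent of it thereafter.
    """
    sigma_pt, sigma_fr, sigma_intra, mean = theta
    stats = build_stats(data, axis=axis, drop_reference=drop_reference)
    ll, _ = _restricted_loglik(
        stats, sigma_pt**2, sigma_fr**2, sigma_intra**2, mean=mean
    )
    return ll


# --------------------------------------------------------------------------
# moment estimator


def _moment_point_estimates(stats: NestedStats) -> dict:
    n, ybar, ss = stats.n, stats.ybar, stats.ss
    nw = np.add.reduceat(n, stats.starts)
    patient_mean = np.add.reduceat(n * ybar, stats.starts) / nw
    grand_mean = float((n * ybar).sum() / n.sum())
    var_pt = float(np.var(patient_mean, ddof=1)) if stats.n_patients > 1 else np.nan

    # pooled within-patient variance of fraction means
    ss_fr = 0.0
    df_fr = 0
    for i, (start, f) in enumerate(zip(stats.starts, stats.f_per_patient)):
        if f >= 2:
            block = ybar[start : start + f]
            ss_fr += float(np.sum((block - block.mean()) ** 2))
            df_fr += f - 1
    var_fr = ss_fr / df_fr if df_fr > 0 else 0.0

    # RMS of within-fraction SDs (unweighted over fractions with >= 2 samples)
    mask = n >= 2
    var_intra = float(np.mean(ss[mask] / (n[mask] - 1.0))) if mask.any() else 0.0
    df_intra = int((n[mask] - 1.0).sum()) if mask.any() else 0
    return {
        "patient_mean": patient_mean,
        "grand_mean": grand_mean,
        "var_pt": var_pt,
        "var_fr": var_fr,
        "df_fr": df_fr,
        "var_intra": var_intra,
        "df_intra": df_intra,
    }


def _chi2_sd_ci(variance: float, df: int, level: float) -> tuple[float, float]:
    if df <= 0 or variance <= 0:
        return (0.0, np.inf) if variance == 0 and df <= 0 else (0.0, 0.0)
    alpha = 1.0 - level
    lo = df * variance / chi2.ppf(1.0 - alpha / 2.0, df)
    hi = df * variance / chi2.ppf(alpha / 2.0, df)
    return (float(np.sqrt(lo)), float(np.sqrt(hi)))


class MomentVarianceEstimator(BaseEstimator):
    """Classic moment variance components (van Herk-style definitions).

    Systematic SD = sample SD of per-patient mean displacements (all samples
    pooled within patient); inter-fraction SD = pooled within-patient SD of
    fraction means; intra-fraction SD = RMS of within-fraction SDs.  CIs are
    chi-square (variances) / t (mean, over patient means) approximations.

    Parameters
    ----------
    axis : "SI" | "AP" | "LR" or 0..2
    ci_level : confidence level for the intervals.
    drop_reference, thin : sample selection, see :func:`build_stats`.
    """

    def __init__(self, axis="AP", ci_level=0.95, drop_reference=True, thin=1):
        self.axis = axis
        self.ci_level = ci_level
        self.drop_reference = drop_reference
        self.thin = thin

    def fit(self, X, y=None):
        stats = build_stats(
            X, axis=self.axis, drop_reference=self.drop_reference, thin=self.thin
        )
        if stats.n_patients < 2:
            raise ValidationError(
                "moment estimator needs >= 2 patients (systematic SD undefined)"
            )
        est = _moment_point_estimates(stats)
        p = stats.n_patients
        sd_pm = float(np.std(est["patient_mean"], ddof=1))
        half = (
            t_dist.ppf(0.5 + self.ci_level / 2.0, p - 1) * sd_pm / np.sqrt(p)
            if sd_pm > 0
            else 0.0
        )
        self.sigma_pt_ = float(np.sqrt(est["var_pt"]))
        self.sigma_fr_ = float(np.sqrt(est["var_fr"]))
        self.sigma_intra_ = float(np.sqrt(est["var_intra"]))
        self.mean_ = est["grand_mean"]
        self.ci_pt_ = _chi2_sd_ci(est["var_pt"], p - 1, self.ci_level)
        self.ci_fr_ = _chi2_sd_ci(est["var_fr"], est["df_fr"], self.ci_level)
        self.ci_intra_ = _chi2_sd_ci(est["var_intra"], est["df_intra"], self.ci_level)
        self.ci_mean_ = (self.mean_ - half, self.mean_ + half)
        self.stats_ = stats
        return self

    def components_(self) -> VarianceComponents:
        ax = axis_index(self.axis)
        return VarianceComponents(
            axis=AXES[ax],
            sigma_pt_mm=self.sigma_pt_,
            sigma_fr_mm=self.sigma_fr_,
            sigma_intra_mm=self.sigma_intra_,
            overall_mean_mm=self.mean_,
            ci_level=self.ci_level,
            ci_pt=self.ci_pt_,
            ci_fr=self.ci_fr_,
            ci_intra=self.ci_intra_,
            ci_mean=self.ci_mean_,
            estimator="moment",
            n_patients=self.stats_.n_patients,
            fractions_per_patient=tuple(int(f) for f in self.stats_.f_per_patient),
            samples_per_fraction=tuple(int(n) for n in self.stats_.n),
        ).validate()


# --------------------------------------------------------------------------
# REML estimator


def _nm_minimize(fun, x0, xatol=1e-9, fatol=1e-10, maxiter=5000):
    res = minimize(
        fun,
        np.asarray(x0, dtype=float),
        method="Nelder-Mead",
        options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter, "maxfev": maxiter},
    )
    return res


def _optimize_variances(
    stats: NestedStats,
    free: tuple[int, ...],
    fixed: np.ndarray,
    x0_logvar: np.ndarray,
    mean: float | None = None,
    xatol: float = 1e-9,
):
    """Maximize the restricted log-likelihood over ``free`` log-variance
    coordinates with the others pinned at ``fixed``; returns (ll, variances)."""

    def nll(x):
        v = fixed.copy()
        v[list(free)] = np.exp(np.clip(x, -_XCLIP, _XCLIP))
        ll, _ = _restricted_loglik(stats, v[0], v[1], v[2], mean=mean)
        return -ll

    res = _nm_minimize(nll, x0_logvar, xatol=xatol)
    v = fixed.copy()
    v[list(free)] = np.exp(np.clip(res.x, -_XCLIP, _XCLIP))
    return -res.fun, v


class RemlVarianceEstimator(BaseEstimator):
    """REML fit of the nested random-effects model for one axis.

    Optimization is derivative-free simplex on log variances, multi-started
    from the moment estimates plus fixed perturbations, with explicit boundary
    refits at sigma_pt = 0 and/or sigma_fr = 0 so boundary estimates are exact
    zeros.  Confidence intervals are profile-likelihood (chi-square(1) cutoff
    at ``ci_level``), truncated at 0; the mean CI profiles the variances at
    each fixed mean.  Deterministic given the data.

    Fitted attributes: ``sigma_pt_``, ``sigma_fr_``, ``sigma_intra_``,
    ``mean_`` (GLS), ``loglik_``, ``ci_pt_``, ``ci_fr_``, ``ci_intra_``,
    ``ci_mean_``, ``stats_``.
    """

    def __init__(
        self,
        axis="AP",
        ci_level=0.95,
        compute_ci=True,
        drop_reference=True,
        thin=1,
        boundary_tol=1e-7,
    ):
        self.axis = axis
        self.ci_level = ci_level
        self.compute_ci = compute_ci
        self.drop_reference = drop_reference
        self.thin = thin
        self.boundary_tol = boundary_tol

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y=None):
        stats = build_stats(
            X, axis=self.axis, drop_reference=self.drop_reference, thin=self.thin
        )
        self.stats_ = stats
        if stats.n_patients < 2:
            raise ValidationError("REML fit needs >= 2 patients")
        if not np.any(stats.f_per_patient >= 2):
            raise ValidationError("REML fit needs >= 2 fractions for some patient")
        total_var = self._total_variance(stats)
        if total_var == 0.0:
            self._set_degenerate(stats)
            return self
        if not np.any(stats.n >= 2):
            raise ValidationError("REML fit needs >= 2 samples per fraction")

        ll, v = self._maximize(stats)
        self.var_ = v
        self.loglik_ = ll
        _, self.mean_ = self._ll(stats, v)
        self.sigma_pt_ = float(np.sqrt(v[0]))
        self.sigma_fr_ = float(np.sqrt(v[1]))
        self.sigma_intra_ = float(np.sqrt(v[2]))
        if self.compute_ci:
            self.ci_pt_ = self._profile_ci_sd(0)
            self.ci_fr_ = self._profile_ci_sd(1)
            self.ci_intra_ = self._profile_ci_sd(2)
            self.ci_mean_ = self._profile_ci_mean()
        else:
            self.ci_pt_ = (self.sigma_pt_, self.sigma_pt_)
            self.ci_fr_ = (self.sigma_fr_, self.sigma_fr_)
            self.ci_intra_ = (self.sigma_intra_, self.sigma_intra_)
            self.ci_mean_ = (self.mean_, self.mean_)
        return self

    @staticmethod
    def _total_variance(stats: NestedStats) -> float:
        grand = (stats.n * stats.ybar).sum() / stats.n.sum()
        return float(
            (stats.ss.sum() + (stats.n * (stats.ybar - grand) ** 2).sum()) / stats.n.sum()
        )

    def _set_degenerate(self, stats: NestedStats) -> None:
        mean = float(stats.ybar[0])
        self.var_ = np.zeros(3)
        self.loglik_ = np.inf
        self.sigma_pt_ = self.sigma_fr_ = self.sigma_intra_ = 0.0
        self.mean_ = mean
        self.ci_pt_ = self.ci_fr_ = self.ci_intra_ = (0.0, 0.0)
        self.ci_mean_ = (mean, mean)

    @staticmethod
    def _ll(stats, v, mean=None):
        return _restricted_loglik(stats, v[0], v[1], v[2], mean=mean)

    def _starts(self, stats: NestedStats) -> list[np.ndarray]:
        est = _moment_point_estimates(stats)
        scale = max(self._total_variance(stats), 1e-12)
        floor = 1e-6 * scale
        base = np.log(
            np.maximum(
                [np.nan_to_num(est["var_pt"]), est["var_fr"], est["var_intra"]], floor
            )
        )
        return [
            base,
            base + np.array([-3.0, 0.0, 0.0]),
            base + np.array([1.0, 1.0, 1.0]),
            base + np.array([-1.0, -1.0, -1.0]),
        ]

    def _maximize(self, stats: NestedStats):
        best_ll, best_v = -np.inf, None
        for x0 in self._starts(stats):
            ll, v = _optimize_variances(stats, (0, 1, 2), np.zeros(3), x0)
            if ll > best_ll:
                best_ll, best_v = ll, v
        # boundary refits: prefer exact zeros for patient and/or fraction
        # variance whenever they cost at most boundary_tol in log-likelihood
        x0 = np.log(np.maximum(best_v, 1e-300))
        candidates = [
            _optimize_variances(stats, (1, 2), np.array([0.0, 0.0, 0.0]), x0[[1, 2]]),
            _optimize_variances(stats, (0, 2), np.array([0.0, 0.0, 0.0]), x0[[0, 2]]),
            _optimize_variances(stats, (2,), np.array([0.0, 0.0, 0.0]), x0[[2]]),
        ]
        for ll, v in candidates:
            better = ll > best_ll
            simpler = (
                ll >= best_ll - self.boundary_tol
                and np.count_nonzero(v == 0.0) > np.count_nonzero(best_v == 0.0)
            )
            if better or simpler:
                best_v = v
        best_ll, _ = self._ll(stats, best_v)
        return best_ll, best_v

    # -- profile-likelihood CIs -------------------------------------------

    def _profile_ll_factory(self, k: int):
        """prof(sd_k) -> profiled restricted log-likelihood, warm-started."""
        stats = self.stats_
        others = tuple(i for i in range(3) if i != k)
        state = {"x0": np.log(np.maximum(self.var_[list(others)], 1e-300))}

        def prof(sd_k: float) -> float:
            fixed = np.zeros(3)
            fixed[k] = sd_k * sd_k
            ll, v = _optimize_variances(
                stats, others, fixed, state["x0"], xatol=1e-8
            )
            state["x0"] = np.log(np.maximum(v[list(others)], 1e-300))
            return ll

        return prof

    def _profile_ci_sd(self, k: int) -> tuple[float, float]:
        cutoff = chi2.ppf(self.ci_level, 1) / 2.0
        target = self.loglik_ - cutoff
        sd_hat = float(np.sqrt(self.var_[k]))
        scale = max(sd_hat, np.sqrt(self._total_variance(self.stats_)) * 1e-2, 1e-6)
        prof = self._profile_ll_factory(k)

        # lower bound: geometric continuation downward from the optimum, so
        # the warm-started nuisance optimization tracks the profile path
        if sd_hat == 0.0:
            lo = 0.0
        else:
            prev = sd_hat
            probe = sd_hat / 2.0
            lo = None
            for _ in range(80):
                if probe < 1e-10 * max(scale, 1.0):
                    break
                if prof(probe) < target:
                    lo = brentq(lambda s: prof(s) - target, probe, prev, xtol=1e-9)
                    break
                prev = probe
                probe /= 2.0
            if lo is None:
                # profile stayed above the cutoff all the way down
                if k == 2:
                    lo = 0.0
                else:
                    lo = 0.0 if prof(0.0) >= target else brentq(
                        lambda s: prof(s) - target, 0.0, prev, xtol=1e-9
                    )

        # upper bound
        hi = sd_hat if sd_hat > 0 else 0.0
        step = 0.25 * scale
        probe = hi + step
        for _ in range(200):
            if prof(probe) < target:
                break
            hi = probe
            probe = probe + step
            step *= 1.6
        else:
            raise ValidationError("profile CI upper bound did not bracket")
        hi = brentq(lambda s: prof(s) - target, hi, probe, xtol=1e-9)
        return (float(lo), float(hi))

    def _profile_ci_mean(self) -> tuple[float, float]:
        cutoff = chi2.ppf(self.ci_level, 1) / 2.0
        target = self.loglik_ - cutoff
        stats = self.stats_
        state = {"x0": np.log(np.maximum(self.var_, 1e-300))}

        def prof(m: float) -> float:
            ll, v = _optimize_variances(
                stats, (0, 1, 2), np.zeros(3), state["x0"], mean=m, xatol=1e-8
            )
            state["x0"] = np.log(np.maximum(v, 1e-300))
            return ll

        # Wald width from the GLS information as the initial bracket scale
        n = stats.n
        d = self.var_[1] + self.var_[2] / n
        s1 = np.add.reduceat(1.0 / d, stats.starts)
        weight = (s1 / (1.0 + self.var_[0] * s1)).sum()
        se = 1.0 / np.sqrt(weight)
        out = []
        for sign in (-1.0, 1.0):
            step = 1.5 * se
            inner, probe = self.mean_, self.mean_ + sign * step
            for _ in range(200):
                if prof(probe) < target:
                    break
                inner = probe
                probe = probe + sign * step
                step *= 1.6
            else:
                raise ValidationError("mean profile CI did not bracket")
            out.append(
                brentq(lambda m: prof(m) - target, *sorted((inner, probe)), xtol=1e-10)
            )
        return (float(min(out)), float(max(out)))

    def components_(self) -> VarianceComponents:
        ax = axis_index(self.axis)
        return VarianceComponents(
            axis=AXES[ax],
            sigma_pt_mm=self.sigma_pt_,
            sigma_fr_mm=self.sigma_fr_,
            sigma_intra_mm=self.sigma_intra_,
            overall_mean_mm=self.mean_,
            ci_level=self.ci_level,
            ci_pt=self.ci_pt_,
            ci_fr=self.ci_fr_,
            ci_intra=self.ci_intra_,
            ci_mean=self.ci_mean_,
            estimator="reml",
            n_patients=self.stats_.n_patients,
            fractions_per_patient=tuple(int(f) for f in self.stats_.f_per_patient),
            samples_per_fraction=tuple(int(n) for n in self.stats_.n),
        ).validate()


# --------------------------------------------------------------------------
# thin functional wrappers


def moment_components(
    data, axis="AP", ci_level=0.95, drop_reference=True, thin=1
) -> VarianceComponents:
    est = MomentVarianceEstimator(
        axis=axis, ci_level=ci_level, drop_reference=drop_reference, thin=thin
    ).fit(data)
    return est.components_()


def reml_fit(
    data, axis="AP", ci_level=0.95, compute_ci=True, drop_reference=True, thin=1
) -> VarianceComponents:
    est = RemlVarianceEstimator(
        axis=axis,
        ci_level=ci_level,
        compute_ci=compute_ci,
        drop_reference=drop_reference,
        thin=thin,
    ).fit(data)
    return est.components_()
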