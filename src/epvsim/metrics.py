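"""Evaluation statistics for resampled Cox prediction models.

Two families:

* coefficient accuracy/precision across Monte-Carlo replicates — signed
  percent relative bias, model-to-empirical variance ratio, 95% coverage,
  significance proportion, RMSE;
* predictive performance of a fitted model — Harrell's c-index, the
  rank-based D-statistic of prognostic separation, the explained-variation
  measures R2_rs (from D) and R2_oxs (from the partial-likelihood gain per
  event), and the calibration slope on external data.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .cohort import Cohort
from .cox import CoxFit, FitConfig, fit_cox, prognostic_index

KAPPA = math.sqrt(8.0 / math.pi)  # sd ratio linking Blom scores to the D scale
SIGMA2 = math.pi**2 / 6.0  # variance of the standard log-hazard frailty scale
_Z975 = 1.959964


# ---------------------------------------------------------------- coefficients


def pct_relative_bias(estimates: np.ndarray, true_beta: float) -> float:
    """Signed percent relative bias 100 * (mean(estimates) - beta) / beta."""
    if true_beta == 0:
        raise ValueError("percent relative bias is undefined for true beta = 0")
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size < 1:
        raise ValueError("need at least one estimate")
    return float(100.0 * (estimates.mean() - true_beta) / true_beta)


def variance_ratio(estimates: np.ndarray, std_errors: np.ndarray) -> float:
    """Mean model-based variance over the empirical variance of the estimates.

    The empirical variance is the across-replicate sample variance of the
    estimates (ddof=1).  A ratio far from 1 indicates the model-based
    standard errors misstate the true sampling variability.
    """
    estimates = np.asarray(estimates, dtype=float)
    std_errors = np.asarray(std_errors, dtype=float)
    if estimates.size < 2:
        raise ValueError("need at least two estimates")
    emp = estimates.var(ddof=1)
    if emp == 0:
        raise ValueError("degenerate input: zero empirical variance")
    return float(np.mean(std_errors**2) / emp)


def coverage95(estimates: np.ndarray, std_errors: np.ndarray, true_beta: float) -> float:
    """Fraction of replicates whose 95% Wald interval contains the truth."""
    estimates = np.asarray(estimates, dtype=float)
    std_errors = np.asarray(std_errors, dtype=float)
    if estimates.size < 1:
        raise ValueError("need at least one estimate")
    return float(np.mean(np.abs(estimates - true_beta) <= _Z975 * std_errors))


def significance_proportion(pvalues: np.ndarray, alpha: float = 0.05) -> float:
    """Fraction of replicates significant at ``alpha`` (two-sided Wald)."""
    pvalues = np.asarray(pvalues, dtype=float)
    return float(np.mean(pvalues < alpha))


def rmse(values: np.ndarray, true_value: float) -> float:
    """Root mean square error around the true value."""
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("need at least one value")
    return float(np.sqrt(np.mean((values - true_value) ** 2)))


def performance_bias_and_rmse(
    per_replicate: np.ndarray, true_value: float
) -> tuple[float, float]:
    """(percent relative bias, RMSE) of a performance measure across replicates."""
    return pct_relative_bias(per_replicate, true_value), rmse(per_replicate, true_value)


# ---------------------------------------------------------------- discrimination


def c_index(pi: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's concordance index of a prognostic index against survival.

    Usable pairs are those orderable under censoring: the member with the
    shorter time had the event (pairs of events tied on time are not
    usable; an event tied on time with a censored subject is).  Higher PI
    with the shorter time counts as concordant; ties in PI count half.
    """
    pi = np.asarray(pi, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    pi, time, event = pi[order], time[order], event[order]
    n = len(time)
    concordant = 0.0
    usable = 0
    for i in np.flatnonzero(event == 1):
        later = (time > time[i]) | ((time == time[i]) & (event == 0))
        later[i] = False
        k = int(later.sum())
        if k == 0:
            continue
        usable += k
        concordant += np.sum(pi[i] > pi[later]) + 0.5 * np.sum(pi[i] == pi[later])
    if usable == 0:
        raise ValueError("no usable pairs: c-index undefined")
    return float(concordant / usable)


def d_statistic(
    pi: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    fit_config: FitConfig = FitConfig(),
) -> float:
    """Prognostic-separation D: log hazard ratio across the PI distribution.

    The PI is replaced by Blom normal scores z_(i) = Phi^{-1}((i - 3/8) /
    (n + 1/4)) (averaged within PI ties), scaled by 1/kappa with
    kappa = sqrt(8/pi), and a univariate Cox model of survival on the scaled
    scores is fitted; D is its coefficient.  Under a normally distributed
    PI, D estimates the log hazard ratio between the upper and lower halves
    of the prognostic distribution.  Constant PI gives D = 0 by convention.
    """
    pi = np.asarray(pi, dtype=float)
    n = len(pi)
    if n < 3:
        raise ValueError("D-statistic needs n >= 3")
    if np.ptp(pi) == 0:
        return 0.0
    order = np.argsort(pi, kind="stable")
    z_sorted = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    z = np.empty(n)
    z[order] = z_sorted
    # average scores within tied PI values so ties get identical scores
    pi_sorted = pi[order]
    i = 0
    while i < n:
        j = i
        while j < n and pi_sorted[j] == pi_sorted[i]:
            j += 1
        if j - i > 1:
            z[order[i:j]] = z_sorted[i:j].mean()
        i = j
    scaled = z / KAPPA
    cohort = Cohort(scaled[:, None], time, np.asarray(event, dtype=int), ["z"])
    fit = fit_cox(cohort, ["z"], fit_config)
    if not fit.converged:
        raise ValueError("D-statistic Cox fit did not converge")
    return float(fit.coefficients[0])


def r2_rs(d: float) -> float:
    """Explained variation derived from the D-statistic."""
    q = d**2 / KAPPA**2
    return float(q / (SIGMA2 + q))


def r2_oxs(loglik: float, loglik_null: float, k_events: int) -> float:
    """Explained randomness 1 - exp(-2 (l_beta - l_0) / k)."""
    if k_events < 1:
        raise ValueError("k_events must be >= 1")
    gain = loglik - loglik_null
    if gain < -1e-8:
        raise ValueError("loglik below null loglik: invalid fit")
    return float(1.0 - math.exp(-2.0 * max(gain, 0.0) / k_events))


# ---------------------------------------------------------------- calibration


def calibration_slope(
    fit: CoxFit, validation: Cohort, fit_config: FitConfig = FitConfig()
) -> float:
    """Coefficient of a univariate Cox refit of validation survival on the PI.

    1 means the development model's predictions transport as-is; < 1 means
    the predictions are too extreme (the overfitting signature).
    """
    if validation.n_events < 1:
        raise ValueError("validation cohort has no events")
    pi = prognostic_index(fit, validation)
    if np.ptp(pi) == 0:
        raise ValueError("constant prognostic index: calibration slope undefined")
    cohort = Cohort(pi[:, None], validation.time, validation.event, ["pi"])
    refit = fit_cox(cohort, ["pi"], fit_config)
    if not refit.converged:
        raise ValueError("calibration-slope refit did not converge")
    return float(refit.coefficients[0])


def apparent_performance(fit: CoxFit, cohort: Cohort) -> dict[str, float]:
    """c-index, D, R2_rs and R2_oxs of a fit evaluated on a cohort."""
    pi = prognostic_index(fit, cohort)
    if np.ptp(pi) == 0:
        d = 0.0
        c = 0.5
    else:
        d = d_statistic(pi, cohort.time, cohort.event)
        c = c_index(pi, cohort.time, cohort.event)
    return {
        "c_index": c,
        "d_stat": d,
        "r2_rs": r2_rs(d),
        "r2_oxs": r2_oxs(fit.loglik, fit.loglik_null, fit.n_events),
    }


def external_performance(
    fit: CoxFit, validation: Cohort, fit_config: FitConfig = FitConfig()
) -> dict[str, float]:
    """Discrimination, separation and calibration of a fit on new data.

    R2_oxs needs the partial-likelihood gain of the *fixed* coefficients on
    the validation data, so both log-likelihoods are evaluated there via an
    offset-style univariate fit on the PI restricted to slope 1 — here
    computed directly from the validation partial likelihood at the fitted
    and null coefficient vectors.
    """
    pi = prognostic_index(fit, validation)
    out: dict[str, float] = {}
    out["c_index"] = c_index(pi, validation.time, validation.event)
    d = d_statistic(pi, validation.time, validation.event, fit_config)
    out["d_stat"] = d
    out["r2_rs"] = r2_rs(d)
    from .cox import _PartialLikelihood  # local import to avoid cycle at module load

    pl = _PartialLikelihood(
        validation.matrix(fit.names), validation.time, validation.event, fit_config.ties
    )
    ll = pl.loglik(fit.coefficients)
    ll0 = pl.loglik(np.zeros(len(fit.names)))
    out["r2_oxs"] = r2_oxs(ll, ll0, validation.n_events) if ll >= ll0 else 0.0
    try:
        out["calib_slope"] = calibration_slope(fit, validation, fit_config)
    except ValueError:
        out["calib_slope"] = float("nan")
    return out
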