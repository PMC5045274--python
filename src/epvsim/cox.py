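"""Cox proportional-hazards fitting with explicit nonconvergence detection.

Newton-Raphson maximisation of the Breslow-ties partial likelihood, from
beta = 0, with step-halving.  Monotone likelihood (the survival analogue
of separation, typically triggered by a low-prevalence binary predictor
whose events all share one level) is declared when a coefficient path
exits a configurable bound; a fit is "converged" only when the step
criterion is met inside the iteration budget, every coefficient stays
inside the bound, and the observed information is invertible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort

_Z975 = 1.959964  # Phi^{-1}(0.975)


@dataclass(frozen=True)
class FitConfig:
    """Convergence rule for the partial-likelihood maximiser.

    ``tol`` bounds the max absolute Newton step at convergence;
    ``coef_bound`` is the absolute coefficient beyond which monotone
    likelihood is declared; ``ties`` is "breslow" (default) or "efron".
    """

    max_iter: int = 50
    tol: float = 1e-9
    coef_bound: float = 15.0
    ridge_eps: float = 0.0
    ties: str = "breslow"

    def __post_init__(self) -> None:
        if self.tol <= 0 or self.coef_bound <= 0:
            raise ValueError("tol and coef_bound must be positive")
        if self.ties not in ("breslow", "efron"):
            raise ValueError("ties must be 'breslow' or 'efron'")


@dataclass
class CoxFit:
    """Result of one partial-likelihood maximisation."""

    names: list[str]
    coefficients: np.ndarray
    std_errors: np.ndarray
    loglik: float
    loglik_null: float
    converged: bool
    monotone_flag: bool
    n_iter: int
    n_events: int

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.std_errors[self.names.index(name)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variable": self.names, "coef": self.coefficients, "se": self.std_errors}
        )


_BLOCK = 65536  # suffix-sum block size: keeps the n x p x p workspace bounded


def _suffix_sums(w: np.ndarray, x: np.ndarray, need_s2: bool):
    """Reverse cumulative sums of w, w*x and w*x x^T (blocked for memory)."""
    n, p = x.shape
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.empty((n, p))
    s2 = np.empty((n, p, p)) if need_s2 else None
    carry1 = np.zeros(p)
    carry2 = np.zeros((p, p))
    start = n
    while start > 0:
        stop = start
        start = max(0, start - _BLOCK)
        xb = x[start:stop]
        wb = w[start:stop]
        wx = wb[:, None] * xb
        s1[start:stop] = np.cumsum(wx[::-1], axis=0)[::-1] + carry1
        carry1 = s1[start]
        if need_s2:
            wxx = wx[:, :, None] * xb[:, None, :]
            s2[start:stop] = np.cumsum(wxx[::-1], axis=0)[::-1] + carry2
            carry2 = s2[start]
    return s0, s1, s2


class _PartialLikelihood:
    """Breslow/Efron partial likelihood on a cohort, pre-sorted by time."""

    def __init__(self, x: np.ndarray, time: np.ndarray, event: np.ndarray, ties: str):
        order = np.argsort(time, kind="stable")
        self.x = np.ascontiguousarray(x[order])
        self.time = time[order]
        self.event = event[order].astype(bool)
        self.ties = ties
        # first index of each tied-time block: risk set = everyone from there on
        self.first_idx = np.searchsorted(self.time, self.time, side="left")
        self.ev_idx = np.flatnonzero(self.event)
        self.ev_first = self.first_idx[self.ev_idx]
        if ties == "efron":
            # within-block event order for the Efron correction
            block = self.ev_first
            self.ev_rank = np.zeros(len(self.ev_idx))
            self.ev_count = np.zeros(len(self.ev_idx))
            i = 0
            while i < len(block):
                j = i
                while j < len(block) and block[j] == block[i]:
                    j += 1
                d = j - i
                self.ev_rank[i:j] = np.arange(d)
                self.ev_count[i:j] = d
                i = j

    def loglik(self, beta: np.ndarray) -> float:
        eta = self.x @ beta
        m = eta.max()
        w = np.exp(eta - m)
        s0 = np.cumsum(w[::-1])[::-1]
        denom = s0[self.ev_first]
        if self.ties == "efron":
            dsum = self._tie_sums(w)
            denom = denom - (self.ev_rank / self.ev_count) * dsum
        return float(np.sum(eta[self.ev_idx] - m - np.log(denom)))

    def _tie_sums(self, w: np.ndarray) -> np.ndarray:
        """Sum of w over the event's tied-event block, per event."""
        out = np.empty(len(self.ev_idx))
        ev_w = w[self.ev_idx]
        i = 0
        block = self.ev_first
        while i < len(block):
            j = i
            while j < len(block) and block[j] == block[i]:
                j += 1
            out[i:j] = ev_w[i:j].sum()
            i = j
        return out

    def score_info(self, beta: np.ndarray):
        """Log-likelihood, score vector and observed information at beta.

        Breslow path avoids materialising suffix sums of w*x*x^T: since
        sum_e S2(t_e)/S0(t_e) = sum_j w_j x_j x_j^T A_j with
        A_j = sum_{e: first_e <= j} 1/S0(t_e), the information reduces to
        one weighted Gram matrix minus the event-wise outer products of the
        risk-set means.
        """
        eta = self.x @ beta
        m = eta.max()
        w = np.exp(eta - m)
        if self.ties == "breslow":
            n = len(w)
            s0 = np.cumsum(w[::-1])[::-1]
            wx = w[:, None] * self.x
            s1 = np.cumsum(wx[::-1], axis=0)[::-1]
            d0 = s0[self.ev_first]
            xbar = s1[self.ev_first] / d0[:, None]
            incr = np.zeros(n)
            np.add.at(incr, self.ev_first, 1.0 / d0)
            a = np.cumsum(incr)
            gram = (self.x * (w * a)[:, None]).T @ self.x
            ll = float(np.sum(eta[self.ev_idx] - m - np.log(d0)))
            score = self.x[self.ev_idx].sum(axis=0) - xbar.sum(axis=0)
            info = gram - np.einsum("ij,ik->jk", xbar, xbar)
            return ll, score, info
        s0, s1, s2 = _suffix_sums(w, self.x, need_s2=True)
        d0 = s0[self.ev_first]
        d1 = s1[self.ev_first]
        d2 = s2[self.ev_first]
        if self.ties == "efron":
            f = (self.ev_rank / self.ev_count)[:, None]
            ev_w = w[self.ev_idx]
            ev_wx = ev_w[:, None] * self.x[self.ev_idx]
            ev_wxx = ev_wx[:, :, None] * self.x[self.ev_idx][:, None, :]
            t0 = self._tie_block_totals(ev_w)
            t1 = self._tie_block_totals(ev_wx)
            t2 = self._tie_block_totals(ev_wxx)
            d0 = d0 - f[:, 0] * t0
            d1 = d1 - f * t1
            d2 = d2 - f[:, :, None] * t2
        xbar = d1 / d0[:, None]
        ll = float(np.sum(eta[self.ev_idx] - m - np.log(d0)))
        score = self.x[self.ev_idx].sum(axis=0) - xbar.sum(axis=0)
        info = (d2 / d0[:, None, None]).sum(axis=0) - np.einsum("ij,ik->jk", xbar, xbar)
        return ll, score, info

    def _tie_block_totals(self, ev_arr: np.ndarray) -> np.ndarray:
        """Per-event total of ``ev_arr`` over its tied-event block."""
        out = np.empty_like(ev_arr)
        i = 0
        block = self.ev_first
        while i < len(block):
            j = i
            while j < len(block) and block[j] == block[i]:
                j += 1
            out[i:j] = ev_arr[i:j].sum(axis=0)
            i = j
        return out


def fit_cox(
    cohort: Cohort,
    variables: Sequence[str],
    config: FitConfig = FitConfig(),
) -> CoxFit:
    """Fit a Cox model for the named covariates by Newton-Raphson.

    Starts from beta = 0 for reproducibility.  Step-halving is applied
    whenever a Newton step would decrease the partial likelihood.  The fit
    is flagged nonconvergent (``converged=False``) when the step criterion
    is not met within ``max_iter`` iterations, the information matrix is
    singular, or a coefficient exits ``coef_bound`` — the last case also
    sets ``monotone_flag``, the deterministic stand-in for the "error
    message" a packaged maximiser would raise under monotone likelihood.
    """
    variables = list(variables)
    x = cohort.matrix(variables)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite covariate values")
    n_events = cohort.n_events
    if n_events < 1:
        raise ValueError("cohort has no events")
    pl = _PartialLikelihood(x, cohort.time, cohort.event, config.ties)
    p = x.shape[1]
    beta = np.zeros(p)
    ll_null = pl.loglik(beta)
    ll = ll_null
    converged = False
    monotone = False
    n_iter = 0
    info = None
    for n_iter in range(1, config.max_iter + 1):
        ll, score, info = pl.score_info(beta)
        if config.ridge_eps > 0:
            info = info + config.ridge_eps * np.eye(p)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break  # singular information: nonconvergent
        if not np.all(np.isfinite(step)):
            break
        # step-halving: never accept a likelihood decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            if pl.loglik(cand) >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break  # cannot improve: treat as nonconvergent
        beta = beta + scale * step
        if np.any(np.abs(beta) >= config.coef_bound):
            monotone = True
            break
        if np.max(np.abs(scale * step)) < config.tol:
            converged = True
            break
    if converged:
        ll, _, info = pl.score_info(beta)
        if config.ridge_eps > 0:
            info = info + config.ridge_eps * np.eye(p)
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.diag(cov))
            if not np.all(np.isfinite(se)):
                converged = False
        except np.linalg.LinAlgError:
            converged = False
        ll = float(ll)
    if not converged:
        se = np.full(p, np.nan)
        ll = pl.loglik(beta)
    return CoxFit(
        names=variables,
        coefficients=beta,
        std_errors=se,
        loglik=float(ll),
        loglik_null=float(ll_null),
        converged=converged,
        monotone_flag=monotone,
        n_iter=n_iter,
        n_events=n_events,
    )


def wald_pvalues(fit: CoxFit) -> np.ndarray:
    """Two-sided normal-approximation p-values for each coefficient."""
    if not fit.converged:
        raise ValueError("Wald inference requires a converged fit")
    z = fit.coefficients / fit.std_errors
    return 2.0 * stats.norm.sf(np.abs(z))


def confint95(fit: CoxFit) -> np.ndarray:
    """95% Wald confidence intervals, one (lower, upper) row per coefficient."""
    if not fit.converged:
        raise ValueError("confidence intervals require a converged fit")
    half = _Z975 * fit.std_errors
    return np.column_stack([fit.coefficients - half, fit.coefficients + half])


def prognostic_index(fit: CoxFit, cohort: Cohort, center: bool = False) -> np.ndarray:
    """Linear predictor sum_j beta_j x_ij of a fitted model on a cohort."""
    if not fit.converged:
        raise ValueError("prognostic index requires a converged fit")
    pi = cohort.matrix(fit.names) @ fit.coefficients
    if center:
        pi = pi - pi.mean()
    return pi
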