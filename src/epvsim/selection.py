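"""Backward elimination with noise variables under EPV-controlled resampling.

The five-predictor base model is augmented with independent standard-normal
noise variables; backward elimination drops the least significant variable
(largest Wald p-value above the threshold) one at a time until all retained
variables pass.  Thresholds: 0.05, or 0.157 — the single-degree-of-freedom
p-value cutoff exactly equivalent to one-step AIC comparisons
(delta-AIC < 0 iff p > 0.1573 for a 1-df term).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .cox import CoxFit, FitConfig, fit_cox, wald_pvalues
from .resampling import epv_sample, model_variables, replicate_counts
from . import metrics as M

CRITERION_ALPHA = {"pvalue_0.05": 0.05, "aic": 0.157}


def add_noise(cohort: Cohort, n_noise: int, rng: np.random.Generator) -> Cohort:
    """Append ``n_noise`` independent N(0,1) columns named noise1..noiseN."""
    if n_noise < 0:
        raise ValueError("n_noise must be >= 0")
    if n_noise == 0:
        return cohort
    z = rng.standard_normal((cohort.n, n_noise))
    return cohort.with_columns(z, [f"noise{i + 1}" for i in range(n_noise)])


def backward_eliminate(
    cohort: Cohort,
    variables: Sequence[str],
    criterion: str,
    fit_config: FitConfig = FitConfig(),
) -> tuple[list[str], CoxFit | None, bool]:
    """Backward elimination; returns (retained variables, final fit, converged).

    One variable is dropped per step: the one with the largest Wald p-value
    exceeding the criterion's threshold, ties broken toward the later list
    position.  Elimination stops when every retained variable passes, or no
    variables remain.  A nonconvergent fit at any step marks the whole
    replicate nonconvergent (converged=False, no retained set).
    """
    if criterion not in CRITERION_ALPHA:
        raise ValueError(f"criterion must be one of {sorted(CRITERION_ALPHA)}")
    alpha = CRITERION_ALPHA[criterion]
    current = list(variables)
    fit: CoxFit | None = None
    while current:
        fit = fit_cox(cohort, current, fit_config)
        if not fit.converged:
            return [], None, False
        pvals = wald_pvalues(fit)
        worst_j = -1
        worst_p = alpha
        for j, p in enumerate(pvals):
            if p >= worst_p:  # >= breaks ties toward later position
                worst_p = p
                worst_j = j
        if worst_j < 0 or worst_p <= alpha:
            break
        current.pop(worst_j)
        fit = None
    return current, fit if current else None, True


@dataclass(frozen=True)
class SelectionSpec:
    """One cell of the variable-selection experiment."""

    epv: float
    criterion: str = "pvalue_0.05"
    base_model_size: int = 5
    n_noise: int = 10
    n_replicates: int = 1000
    event_rate: float = 0.045
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_noise < 0:
            raise ValueError("n_noise must be >= 0")
        if self.criterion not in CRITERION_ALPHA:
            raise ValueError(f"criterion must be one of {sorted(CRITERION_ALPHA)}")


@dataclass
class SelectionResult:
    """Retention frequencies and external performance of selected models."""

    spec: SelectionSpec
    variables: list[str]
    n_converged: int
    per_variable_frequency: dict[str, float]
    all_main_frequency: float
    records: pd.DataFrame
    external_aggregates: pd.DataFrame | None = None


def run_selection_study(
    dev: Cohort,
    val: Cohort | None,
    spec: SelectionSpec,
    fit_config: FitConfig = FitConfig(),
    compute_external: bool = False,
) -> SelectionResult:
    """Resample, add noise, eliminate, and tabulate retention frequencies.

    The EPV denominator counts all candidate parameters (base predictors
    plus noise variables), so event counts grow with the candidate set.
    Fresh noise columns are drawn per replicate.  External metrics of each
    selected model are evaluated on ``val`` when requested.
    """
    base = model_variables(spec.base_model_size)
    noise_names = [f"noise{i + 1}" for i in range(spec.n_noise)]
    candidates = base + noise_names
    n_params = len(candidates)
    n_events, n_nonevents = replicate_counts(spec.epv, n_params, spec.event_rate)
    streams = np.random.SeedSequence(spec.seed).spawn(max(spec.n_replicates, 1))
    rows: list[dict] = []
    for r in range(spec.n_replicates):
        rng = np.random.default_rng(streams[r])
        sample = epv_sample(dev, n_events, n_nonevents, rng)
        sample = add_noise(sample, spec.n_noise, rng)
        retained, fit, converged = backward_eliminate(sample, candidates, spec.criterion, fit_config)
        row: dict = {"replicate_id": r, "converged": converged}
        for v in candidates:
            row[f"kept_{v}"] = (v in retained) if converged else None
        row["all_main"] = all(v in retained for v in base) if converged else None
        if compute_external and converged and fit is not None and val is not None:
            try:
                for key, value in M.external_performance(fit, val, fit_config).items():
                    row[f"ext_{key}"] = value
            except ValueError:
                pass
        rows.append(row)
    records = pd.DataFrame(rows)
    conv = records[records["converged"]] if len(records) else records
    n_converged = len(conv)
    if n_converged:
        freq = {v: float(conv[f"kept_{v}"].mean()) for v in candidates}
        all_main = float(conv["all_main"].mean())
    else:
        freq = {v: float("nan") for v in candidates}
        all_main = float("nan")
    ext_agg = None
    if compute_external and n_converged:
        ext_cols = [c for c in records.columns if c.startswith("ext_")]
        if ext_cols:
            ext_agg = conv[ext_cols].agg(["mean", "std"]).T.reset_index(names="measure")
    return SelectionResult(
        spec=spec,
        variables=candidates,
        n_converged=n_converged,
        per_variable_frequency=freq,
        all_main_frequency=all_main,
        records=records,
        external_aggregates=ext_agg,
    )


def selection_frequency_table(results: Sequence[SelectionResult]) -> pd.DataFrame:
    """Percent retained per variable (plus 'all') across EPV values."""
    if not results:
        return pd.DataFrame()
    variables = results[0].variables
    data: dict[str, list[float]] = {}
    for res in sorted(results, key=lambda r: r.spec.epv):
        col = f"EPV={res.spec.epv:g}"
        data[col] = [100.0 * res.per_variable_frequency[v] for v in variables]
        data[col].append(100.0 * res.all_main_frequency)
    return pd.DataFrame(data, index=variables + ["all"]).rename_axis("Variable")
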