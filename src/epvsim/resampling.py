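"""EPV-controlled resampling of a development cohort.

Replicate samples are drawn with replacement, separately from the event
and non-event strata, so every replicate has exactly the event count
implied by the requested events-per-variable (EPV) and exactly the 4.5%
(configurable) event fraction.  Nonconvergent fits are recorded and
excluded from aggregates, never redrawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .cox import FitConfig, fit_cox, wald_pvalues
from . import metrics as M

#: Nested prespecified models, ordered by standardized effect size in the
#: full-data fit: continuous/strong predictors first, then binary predictors
#: of decreasing prevalence.
MODEL_VARIABLES: dict[int, list[str]] = {
    3: ["BMI", "Age", "Sex"],
    5: ["BMI", "Age", "Sex", "SBP", "RATIO"],
    7: ["BMI", "Age", "Sex", "SBP", "RATIO", "HYPER", "TYPE2"],
    10: ["BMI", "Age", "Sex", "SBP", "RATIO", "HYPER", "TYPE2", "SMK", "FHCVD", "BRA"],
    12: [
        "BMI", "Age", "Sex", "SBP", "RATIO", "HYPER", "TYPE2",
        "SMK", "FHCVD", "BRA", "BAF", "RENAL",
    ],
}


def model_variables(model_size: int) -> list[str]:
    """Variable list for one of the nested 3/5/7/10/12-predictor models."""
    try:
        return list(MODEL_VARIABLES[model_size])
    except KeyError:
        raise ValueError(f"model_size must be one of {sorted(MODEL_VARIABLES)}") from None


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def replicate_counts(epv: float, n_params: int, event_rate: float = 0.045) -> tuple[int, int]:
    """(n_events, n_nonevents) fixing both EPV and the marginal event fraction.

    n_events = round(epv * n_params); the non-event count makes the sample's
    event fraction equal the development rate, rounded to the nearest
    integer (half away from zero).
    """
    if epv <= 0 or n_params <= 0 or not 0 < event_rate < 1:
        raise ValueError("epv, n_params and event_rate must be positive (rate in (0,1))")
    n_events = _round_half_up(epv * n_params)
    if n_events == 0:
        raise ValueError("infeasible scenario: zero events")
    n_nonevents = _round_half_up(n_events * (1.0 - event_rate) / event_rate)
    return n_events, n_nonevents


def true_model_epv(n_events: int, n_params: int) -> int:
    """Events per variable of a full-data model: floor(events / parameters)."""
    if n_events <= 0 or n_params <= 0:
        raise ValueError("counts must be positive")
    return n_events // n_params


def epv_sample(
    dev: Cohort, n_events: int, n_nonevents: int, rng: np.random.Generator
) -> Cohort:
    """With-replacement stratified draw with exact event/non-event counts."""
    ev_idx = np.flatnonzero(dev.event == 1)
    ne_idx = np.flatnonzero(dev.event == 0)
    if len(ev_idx) == 0 or len(ne_idx) == 0:
        raise ValueError("development cohort must contain both events and non-events")
    take = np.concatenate(
        [
            ev_idx[rng.integers(0, len(ev_idx), n_events)],
            ne_idx[rng.integers(0, len(ne_idx), n_nonevents)],
        ]
    )
    return dev.subset(take)


@dataclass(frozen=True)
class ScenarioSpec:
    """One (model size x EPV) cell of the resampling grid."""

    model_size: int
    epv: float
    n_replicates: int = 1000
    event_rate: float = 0.045
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epv <= 0:
            raise ValueError("epv must be positive")
        if self.n_replicates < 0:
            raise ValueError("n_replicates must be >= 0")


@dataclass
class ScenarioResult:
    """Per-replicate records plus aggregates for one scenario cell."""

    spec: ScenarioSpec
    variables: list[str]
    n_events: int
    n_nonevents: int
    records: pd.DataFrame
    n_converged: int
    coef_aggregates: pd.DataFrame
    performance_aggregates: pd.DataFrame | None = None

    def write(self, records_path, aggregates_path) -> None:
        self.records.to_csv(records_path, index=False)
        self.coef_aggregates.to_csv(aggregates_path, index=False)


def _aggregate_coefficients(
    records: pd.DataFrame, variables: Sequence[str], true_coefs: Mapping[str, float]
) -> pd.DataFrame:
    conv = records[records["converged"]]
    rows = []
    for v in variables:
        beta = true_coefs[v]
        est = conv[f"coef_{v}"].to_numpy()
        se = conv[f"se_{v}"].to_numpy()
        pv = conv[f"p_{v}"].to_numpy()
        row = {"variable": v, "true_coef": beta, "n_converged": len(conv)}
        if len(conv) >= 1:
            row["pct_bias"] = M.pct_relative_bias(est, beta)
            row["coverage95"] = M.coverage95(est, se, beta)
            row["sig_prop"] = M.significance_proportion(pv)
            row["n_significant"] = int((pv < 0.05).sum())
            row["rmse"] = M.rmse(est, beta)
            row["var_ratio"] = M.variance_ratio(est, se) if len(conv) >= 2 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


_PERF_KEYS = ("c_index", "d_stat", "r2_rs", "r2_oxs")


def run_scenario(
    dev: Cohort,
    spec: ScenarioSpec,
    fit_config: FitConfig = FitConfig(),
    true_coefs: Mapping[str, float] | None = None,
    validation: Cohort | None = None,
    compute_performance: bool = False,
    true_performance: Mapping[str, float] | None = None,
) -> ScenarioResult:
    """Run one scenario: sample, fit, record, aggregate.

    Each replicate gets its own spawned RNG substream from ``spec.seed``,
    so results are independent of execution order.  ``true_coefs`` defaults
    to nothing — pass the generator's coefficient map to obtain bias,
    coverage and variance-ratio aggregates.  With ``compute_performance``
    the apparent (and, given ``validation``, external) c-index, D-statistic
    and R2 measures are recorded per converged replicate.
    """
    variables = model_variables(spec.model_size)
    n_events, n_nonevents = replicate_counts(spec.epv, len(variables), spec.event_rate)
    streams = np.random.SeedSequence(spec.seed).spawn(max(spec.n_replicates, 1))
    rows: list[dict] = []
    for r in range(spec.n_replicates):
        rng = np.random.default_rng(streams[r])
        sample = epv_sample(dev, n_events, n_nonevents, rng)
        fit = fit_cox(sample, variables, fit_config)
        row: dict = {
            "replicate_id": r,
            "converged": fit.converged,
            "monotone": fit.monotone_flag,
            "n_iter": fit.n_iter,
        }
        if fit.converged:
            pvals = wald_pvalues(fit)
            for j, v in enumerate(variables):
                row[f"coef_{v}"] = fit.coefficients[j]
                row[f"se_{v}"] = fit.std_errors[j]
                row[f"p_{v}"] = pvals[j]
            if compute_performance:
                for key, val in M.apparent_performance(fit, sample).items():
                    row[f"app_{key}"] = val
                if validation is not None:
                    for key, val in M.external_performance(fit, validation, fit_config).items():
                        row[f"ext_{key}"] = val
        rows.append(row)
    columns = ["replicate_id", "converged", "monotone", "n_iter"]
    for v in variables:
        columns += [f"coef_{v}", f"se_{v}", f"p_{v}"]
    if compute_performance:
        columns += [f"app_{k}" for k in _PERF_KEYS]
        if validation is not None:
            columns += [f"ext_{k}" for k in _PERF_KEYS] + ["ext_calib_slope"]
    records = pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)
    n_converged = int(records["converged"].sum()) if len(records) else 0
    if true_coefs is not None and len(records):
        coef_agg = _aggregate_coefficients(records, variables, true_coefs)
    else:
        coef_agg = pd.DataFrame(
            columns=["variable", "true_coef", "n_converged", "pct_bias", "coverage95",
                     "sig_prop", "n_significant", "rmse", "var_ratio"]
        )
    perf_agg = None
    if compute_performance and n_converged > 0:
        perf_rows = []
        conv = records[records["converged"]]
        for prefix in ("app", "ext"):
            for key in _PERF_KEYS + (("calib_slope",) if prefix == "ext" else ()):
                col = f"{prefix}_{key}"
                if col not in conv.columns or conv[col].isna().all():
                    continue
                vals = conv[col].dropna().to_numpy()
                row = {"measure": col, "mean": vals.mean(), "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan}
                if true_performance and key in true_performance and true_performance[key] != 0:
                    bias, rm = M.performance_bias_and_rmse(vals, true_performance[key])
                    row["pct_bias"] = bias
                    row["rmse"] = rm
                perf_rows.append(row)
        perf_agg = pd.DataFrame(perf_rows)
    return ScenarioResult(
        spec=spec,
        variables=variables,
        n_events=n_events,
        n_nonevents=n_nonevents,
        records=records,
        n_converged=n_converged,
        coef_aggregates=coef_agg,
        performance_aggregates=perf_agg,
    )


def significance_table(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Count (percent) of converged replicates significant at 0.05, per variable.

    Rows: 'Converged' then each variable; columns: EPV values — the layout
    of the published per-model significance tables.
    """
    if not results:
        return pd.DataFrame()
    variables = results[0].variables
    data: dict[str, list[str]] = {}
    for res in sorted(results, key=lambda r: r.spec.epv):
        col = f"EPV={res.spec.epv:g}"
        cells = [str(res.n_converged)]
        agg = res.coef_aggregates.set_index("variable") if len(res.coef_aggregates) else None
        has_counts = (
            agg is not None and "n_significant" in agg.columns and res.n_converged > 0
        )
        for v in variables:
            if has_counts and v in agg.index and pd.notna(agg.loc[v, "n_significant"]):
                n_sig = int(agg.loc[v, "n_significant"])
                pct = 100.0 * n_sig / res.n_converged
                cells.append(f"{n_sig} ({pct:.1f})")
            else:
                cells.append("")
        data[col] = cells
    return pd.DataFrame(data, index=["Converged"] + variables).rename_axis("Variable")
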