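"""Config-driven orchestration of the full resampling study.

``run_study`` generates (or loads) development and validation cohorts,
runs every (model size x EPV) scenario and optional selection study, and
writes delimited reports: a convergence table, per-model significance
tables, bias / variance-ratio / coverage tables, performance tables,
selection-frequency tables, and a manifest recording every setting.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    Cohort,
    GeneratorConfig,
    PredictorSpec,
    calibrated_config,
    default_thin_spec,
    generate_development_and_validation,
    true_coef_map,
)
from .cox import FitConfig, fit_cox
from .resampling import (
    ScenarioResult,
    ScenarioSpec,
    run_scenario,
    significance_table,
)
from .selection import SelectionSpec, run_selection_study, selection_frequency_table
from . import metrics as M


@dataclass
class StudyConfig:
    """Everything needed to reproduce a study run."""

    generator: GeneratorConfig
    model_sizes: list[int] = field(default_factory=lambda: [3, 5, 7, 10, 12])
    epv_grid: list[float] = field(default_factory=lambda: [2, 5, 10, 15, 20, 25, 50])
    n_replicates: int = 1000
    fit: FitConfig = field(default_factory=FitConfig)
    selection: list[SelectionSpec] = field(default_factory=list)
    n_dev: int = 200_000
    n_val: int = 50_000
    seed: int = 0
    compute_performance: bool = False
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.model_sizes or not self.epv_grid:
            raise ValueError("scenario grid must be nonempty")


def _spec_to_dict(s: PredictorSpec) -> dict:
    d = {"name": s.name, "kind": s.kind, "true_coef": s.true_coef}
    if s.kind == "continuous":
        d.update(mean=s.mean, sd=s.sd)
    else:
        d.update(prevalence=s.prevalence)
    return d


def generator_config_to_dict(g: GeneratorConfig) -> dict:
    return {
        "predictors": [_spec_to_dict(s) for s in g.predictors],
        "target_event_rate": g.target_event_rate,
        "baseline_log_hazard": g.baseline_log_hazard,
        "censor_horizon": g.censor_horizon,
        "correlation": None if g.correlation is None else np.asarray(g.correlation).tolist(),
        "seed": g.seed,
    }


def generator_config_from_dict(d: Mapping) -> GeneratorConfig:
    preds = [PredictorSpec(**p) for p in d["predictors"]]
    corr = d.get("correlation")
    return GeneratorConfig(
        predictors=preds,
        target_event_rate=d.get("target_event_rate", 0.045),
        baseline_log_hazard=d.get("baseline_log_hazard"),
        censor_horizon=d.get("censor_horizon", 10.0),
        correlation=None if corr is None else np.asarray(corr, dtype=float),
        seed=d.get("seed", 0),
    )


def study_config_to_yaml(config: StudyConfig, path) -> None:
    d = {
        "generator": generator_config_to_dict(config.generator),
        "model_sizes": list(config.model_sizes),
        "epv_grid": list(config.epv_grid),
        "n_replicates": config.n_replicates,
        "fit": dataclasses.asdict(config.fit),
        "selection": [dataclasses.asdict(s) for s in config.selection],
        "n_dev": config.n_dev,
        "n_val": config.n_val,
        "seed": config.seed,
        "compute_performance": config.compute_performance,
        "output_dir": config.output_dir,
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def study_config_from_yaml(path) -> StudyConfig:
    d = yaml.safe_load(Path(path).read_text())
    return StudyConfig(
        generator=generator_config_from_dict(d["generator"]),
        model_sizes=d.get("model_sizes", [3, 5, 7, 10, 12]),
        epv_grid=d.get("epv_grid", [2, 5, 10, 15, 20, 25, 50]),
        n_replicates=d.get("n_replicates", 1000),
        fit=FitConfig(**d.get("fit", {})),
        selection=[SelectionSpec(**s) for s in d.get("selection", [])],
        n_dev=d.get("n_dev", 200_000),
        n_val=d.get("n_val", 50_000),
        seed=d.get("seed", 0),
        compute_performance=d.get("compute_performance", False),
        output_dir=d.get("output_dir", "results"),
    )


def default_study_config(**overrides) -> StudyConfig:
    """The study grid with the published predictor set and event rate."""
    gen = GeneratorConfig(predictors=default_thin_spec())
    return StudyConfig(generator=gen, **overrides)


def true_performance_reference(
    config: GeneratorConfig,
    n_reference: int = 500_000,
    rng: np.random.Generator | None = None,
    variables: Sequence[str] | None = None,
) -> dict[str, float]:
    """Performance of the generating model on a very large fresh cohort.

    Stands in for the full-data 'true' performance values: the generating
    coefficients' prognostic index is evaluated on an independent cohort of
    ``n_reference`` individuals.
    """
    from .cohort import generate_cohort

    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    ref = generate_cohort(config, n_reference, rng)
    names = list(variables) if variables is not None else config.names
    coefs = np.array([true_coef_map(config.predictors)[v] for v in names])
    pi = ref.matrix(names) @ coefs
    d = M.d_statistic(pi, ref.time, ref.event)
    out = {
        "c_index": M.c_index(pi, ref.time, ref.event),
        "d_stat": d,
        "r2_rs": M.r2_rs(d),
    }
    return out


def _derive_seed(global_seed: int, *parts: int) -> int:
    """Deterministic per-cell seed below 2^31."""
    ss = np.random.SeedSequence([global_seed, *parts])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full grid and write all report tables.

    Returns a dict with the cohorts, per-cell results and output paths.
    """
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    gen = config.generator
    if gen.baseline_log_hazard is None:
        gen = calibrated_config(gen, rng=np.random.default_rng(_derive_seed(config.seed, 0)))
    rng = np.random.default_rng(_derive_seed(config.seed, 1))
    dev, val = generate_development_and_validation(gen, config.n_dev, config.n_val, rng)
    truths = true_coef_map(gen.predictors)

    results: dict[int, list[ScenarioResult]] = {}
    convergence_rows = []
    coef_tables = []
    perf_tables = []
    for size in config.model_sizes:
        per_model: list[ScenarioResult] = []
        for epv in config.epv_grid:
            spec = ScenarioSpec(
                model_size=size,
                epv=epv,
                n_replicates=config.n_replicates,
                event_rate=gen.target_event_rate,
                seed=_derive_seed(config.seed, 2, size, int(round(epv * 1000))),
            )
            res = run_scenario(
                dev,
                spec,
                fit_config=config.fit,
                true_coefs=truths,
                validation=val if config.compute_performance else None,
                compute_performance=config.compute_performance,
            )
            per_model.append(res)
            convergence_rows.append(
                {"model_size": size, "epv": epv, "n_converged": res.n_converged,
                 "n_replicates": spec.n_replicates}
            )
            agg = res.coef_aggregates.copy()
            agg.insert(0, "epv", epv)
            agg.insert(0, "model_size", size)
            coef_tables.append(agg)
            if res.performance_aggregates is not None:
                pa = res.performance_aggregates.copy()
                pa.insert(0, "epv", epv)
                pa.insert(0, "model_size", size)
                perf_tables.append(pa)
        results[size] = per_model
        significance_table(per_model).to_csv(out / f"significance_model{size}.csv")

    pd.DataFrame(convergence_rows).to_csv(out / "convergence.csv", index=False)
    if coef_tables:
        pd.concat(coef_tables, ignore_index=True).to_csv(out / "coefficient_metrics.csv", index=False)
    if perf_tables:
        pd.concat(perf_tables, ignore_index=True).to_csv(out / "performance_metrics.csv", index=False)

    selection_results = []
    if config.selection:
        by_criterion: dict[str, list] = {}
        for sel in config.selection:
            sel_res = run_selection_study(dev, val, sel, config.fit, compute_external=False)
            selection_results.append(sel_res)
            by_criterion.setdefault(sel.criterion, []).append(sel_res)
        for criterion, group in by_criterion.items():
            selection_frequency_table(group).to_csv(
                out / f"selection_frequency_{criterion.replace('.', '')}.csv"
            )

    manifest = {
        "seed": config.seed,
        "n_dev": config.n_dev,
        "n_val": config.n_val,
        "n_replicates": config.n_replicates,
        "model_sizes": list(config.model_sizes),
        "epv_grid": [float(e) for e in config.epv_grid],
        "baseline_log_hazard": gen.baseline_log_hazard,
        "dev_event_rate": dev.event_rate,
        "val_event_rate": val.event_rate,
        "fit": dataclasses.asdict(config.fit),
        "selection": [dataclasses.asdict(s) for s in config.selection],
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "dev": dev,
        "val": val,
        "generator": gen,
        "results": results,
        "selection": selection_results,
        "output_dir": out,
        "manifest": manifest,
    }


def run_on_user_cohort(
    path: str | Path,
    config: StudyConfig,
    true_coefs: Mapping[str, float] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Apply the resampling pipeline to a user-supplied delimited cohort.

    The file needs columns time, event, then covariates.  'True'
    coefficients either come from the caller or from a full-data fit of
    the largest requested model (full-data-fit truth mode).
    """
    dev = Cohort.read_csv(path)
    if dev.n_events < 1:
        raise ValueError("user cohort has no events")
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    sizes = [s for s in config.model_sizes]
    if true_coefs is None:
        from .resampling import model_variables

        full_fit = fit_cox(dev, model_variables(max(sizes)), config.fit)
        if not full_fit.converged:
            raise ValueError("full-data truth fit did not converge; supply true coefficients")
        true_coefs = dict(zip(full_fit.names, full_fit.coefficients))
    event_rate = dev.event_rate
    convergence_rows = []
    coef_tables = []
    results: dict[int, list[ScenarioResult]] = {}
    for size in sizes:
        per_model = []
        for epv in config.epv_grid:
            spec = ScenarioSpec(
                model_size=size,
                epv=epv,
                n_replicates=config.n_replicates,
                event_rate=event_rate,
                seed=_derive_seed(config.seed, 3, size, int(round(epv * 1000))),
            )
            res = run_scenario(dev, spec, fit_config=config.fit, true_coefs=true_coefs)
            per_model.append(res)
            convergence_rows.append(
                {"model_size": size, "epv": epv, "n_converged": res.n_converged,
                 "n_replicates": spec.n_replicates}
            )
            agg = res.coef_aggregates.copy()
            agg.insert(0, "epv", epv)
            agg.insert(0, "model_size", size)
            coef_tables.append(agg)
        results[size] = per_model
        significance_table(per_model).to_csv(out / f"significance_model{size}.csv")
    pd.DataFrame(convergence_rows).to_csv(out / "convergence.csv", index=False)
    if coef_tables:
        pd.concat(coef_tables, ignore_index=True).to_csv(out / "coefficient_metrics.csv", index=False)
    return {"dev": dev, "results": results, "output_dir": out}
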