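"""Synthetic survival cohorts calibrated to published summary statistics.

The generator emulates a large UK general-practice cardiovascular cohort
from printed quantities only: covariate means/SDs and prevalences, the
fitted Cox log hazard ratios, and the 4.5% marginal event rate.  Event
times are exponential given the linear predictor (proportional hazards
hold exactly); censoring is administrative-uniform on (0, horizon).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PredictorSpec:
    """Marginal distribution and true log hazard ratio for one covariate.

    Continuous predictors are Normal(mean, sd^2) in natural units; binary
    predictors are Bernoulli(prevalence).  ``true_coef`` is the generating
    log hazard ratio per unit of the covariate.
    """

    name: str
    kind: str  # "continuous" | "binary"
    true_coef: float
    mean: float | None = None
    sd: float | None = None
    prevalence: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "continuous":
            if self.mean is None or self.sd is None:
                raise ValueError(f"{self.name}: continuous spec needs mean and sd")
            if self.prevalence is not None:
                raise ValueError(f"{self.name}: continuous spec must not set prevalence")
            if not self.sd > 0:
                raise ValueError(f"{self.name}: sd must be > 0")
        elif self.kind == "binary":
            if self.prevalence is None:
                raise ValueError(f"{self.name}: binary spec needs prevalence")
            if self.mean is not None or self.sd is not None:
                raise ValueError(f"{self.name}: binary spec must not set mean/sd")
            if not 0.0 < self.prevalence < 1.0:
                raise ValueError(f"{self.name}: prevalence must be in (0,1)")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")


def default_thin_spec() -> list[PredictorSpec]:
    """The 12 cardiovascular-risk predictors with their published summaries.

    Order follows the fitted 12-covariate model (strongest standardized
    effects first): BMI, Age, Sex, RATIO, SBP, HYPER, TYPE2, SMK, FHCVD,
    BRA, BAF, RENAL.  Smoking is dichotomised (light/moderate/heavy
    combined, prevalence 0.07+0.11+0.10 = 0.28).  Renal disease prints as
    prevalence 0.00 after rounding; 0.004 is used as a strictly positive
    stand-in below the rounding boundary.
    """
    c, b = "continuous", "binary"
    return [
        PredictorSpec("BMI", c, 0.0233, mean=26.25, sd=4.41),
        PredictorSpec("Age", c, 0.0725, mean=48.66, sd=14.09),
        PredictorSpec("Sex", b, 0.4667, prevalence=0.51),
        PredictorSpec("RATIO", c, 0.0410, mean=4.04, sd=1.31),
        PredictorSpec("SBP", c, 0.0069, mean=131.84, sd=20.34),
        PredictorSpec("HYPER", b, 0.2278, prevalence=0.05),
        PredictorSpec("TYPE2", b, 0.5174, prevalence=0.02),
        PredictorSpec("SMK", b, 0.3964, prevalence=0.28),
        PredictorSpec("FHCVD", b, 0.8959, prevalence=0.04),
        PredictorSpec("BRA", b, 0.2991, prevalence=0.01),
        PredictorSpec("BAF", b, 0.5293, prevalence=0.01),
        PredictorSpec("RENAL", b, 0.4919, prevalence=0.004),
    ]


def true_coef_map(specs: Sequence[PredictorSpec]) -> dict[str, float]:
    """Name -> generating log hazard ratio."""
    return {s.name: s.true_coef for s in specs}


@dataclass
class GeneratorConfig:
    """Full description of the synthetic cohort generating law."""

    predictors: list[PredictorSpec]
    target_event_rate: float = 0.045
    baseline_log_hazard: float | None = None
    censor_horizon: float = 10.0
    correlation: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_event_rate < 0.5:
            raise ValueError("target_event_rate must be in (0, 0.5)")
        if self.censor_horizon <= 0:
            raise ValueError("censor_horizon must be positive")
        if self.correlation is not None:
            r = np.asarray(self.correlation, dtype=float)
            p = len(self.predictors)
            if r.shape != (p, p):
                raise ValueError("correlation dimension must match predictors")
            if not np.allclose(np.diag(r), 1.0):
                raise ValueError("correlation must have unit diagonal")
            if not np.allclose(r, r.T):
                raise ValueError("correlation must be symmetric")
            object.__setattr__(self, "correlation", r)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.predictors]

    @property
    def coefs(self) -> np.ndarray:
        return np.array([s.true_coef for s in self.predictors])


@dataclass
class Cohort:
    """Individuals with covariates (natural units), follow-up time and event flag."""

    covariates: np.ndarray  # n x p
    time: np.ndarray  # n, > 0
    event: np.ndarray  # n, {0,1}
    names: list[str]

    def __post_init__(self) -> None:
        self.covariates = np.asarray(self.covariates, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.time)
        if self.covariates.shape[0] != n or len(self.event) != n:
            raise ValueError("covariates, time and event must align")
        if self.covariates.shape[1] != len(self.names):
            raise ValueError("names must match covariate columns")
        if not np.all(np.isfinite(self.covariates)):
            raise ValueError("covariates contain non-finite values")
        if np.any(self.time <= 0):
            raise ValueError("all follow-up times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event must be 0/1")

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def event_rate(self) -> float:
        return float(self.event.mean())

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.names.index(name)
        except ValueError:
            raise KeyError(f"cohort has no covariate {name!r}") from None
        return self.covariates[:, j]

    def matrix(self, names: Sequence[str]) -> np.ndarray:
        idx = []
        for name in names:
            if name not in self.names:
                raise KeyError(f"cohort has no covariate {name!r}")
            idx.append(self.names.index(name))
        return self.covariates[:, idx]

    def subset(self, indices: np.ndarray) -> "Cohort":
        return Cohort(
            self.covariates[indices], self.time[indices], self.event[indices], list(self.names)
        )

    def with_columns(self, values: np.ndarray, names: Sequence[str]) -> "Cohort":
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[0] != self.n:
            values = values.T
        return Cohort(
            np.column_stack([self.covariates, values]),
            self.time,
            self.event,
            list(self.names) + list(names),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.covariates, columns=self.names)
        df.insert(0, "event", self.event)
        df.insert(0, "time", self.time)
        df.insert(0, "id", np.arange(self.n))
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Cohort":
        for col in ("time", "event"):
            if col not in df.columns:
                raise ValueError(f"cohort file is missing required column {col!r}")
        covar_cols = [c for c in df.columns if c not in ("id", "time", "event")]
        if df[["time", "event"] + covar_cols].isna().any().any():
            bad = df.columns[df.isna().any()].tolist()
            raise ValueError(f"cohort file has missing values in columns {bad}")
        return cls(
            df[covar_cols].to_numpy(float),
            df["time"].to_numpy(float),
            df["event"].to_numpy(int),
            covar_cols,
        )

    @classmethod
    def read_csv(cls, path) -> "Cohort":
        return cls.from_frame(pd.read_csv(path))


def sample_covariates(
    specs: Sequence[PredictorSpec],
    n: int,
    correlation: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw an n x p covariate matrix with the specified marginals.

    Independent columns by default.  With a correlation matrix, draws are
    latent jointly normal and transformed per column (affine for
    continuous, thresholded at the prevalence quantile for binary), which
    preserves every marginal exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    p = len(specs)
    if correlation is None:
        z = rng.standard_normal((n, p))
    else:
        r = np.asarray(correlation, dtype=float)
        try:
            chol = np.linalg.cholesky(r)
        except np.linalg.LinAlgError:
            raise ValueError("correlation matrix is not positive definite") from None
        z = rng.standard_normal((n, p)) @ chol.T
    x = np.empty((n, p))
    for j, s in enumerate(specs):
        if s.kind == "continuous":
            x[:, j] = s.mean + s.sd * z[:, j]
        else:
            x[:, j] = (z[:, j] < stats.norm.ppf(s.prevalence)).astype(float)
    return x


def generate_cohort(config: GeneratorConfig, n: int, rng: np.random.Generator) -> Cohort:
    """Generate a cohort of size n from the configured law.

    Requires ``baseline_log_hazard`` to be set (see :func:`calibrate_baseline`).
    """
    if config.baseline_log_hazard is None:
        raise ValueError("baseline_log_hazard is not set; calibrate or supply it")
    x = sample_covariates(config.predictors, n, config.correlation, rng)
    eta = config.baseline_log_hazard + x @ config.coefs
    t_event = rng.exponential(1.0, n) / np.exp(eta)
    t_cens = rng.uniform(0.0, config.censor_horizon, n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    # guard against an exact-zero exponential draw (measure zero but float-possible)
    time = np.maximum(time, np.finfo(float).tiny)
    return Cohort(x, time, event, config.names)


def calibrate_baseline(
    config: GeneratorConfig,
    n_pilot: int = 200_000,
    tolerance: float = 0.002,
    rng: np.random.Generator | None = None,
    max_expand: int = 60,
) -> float:
    """Find the baseline log hazard giving the target marginal event rate.

    Bisection on a fixed pilot draw: each pilot individual has a threshold
    b* above which it becomes an event, so the simulated rate is a monotone
    step function of the baseline and the search is deterministic given the
    seed.  Errors if the target cannot be bracketed within the expansion
    budget or if the pilot is too small for the requested tolerance.
    """
    target = config.target_event_rate
    if not 0.0 < target < 0.5:
        raise ValueError("target event rate must be in (0, 0.5)")
    mc_se = math.sqrt(target * (1 - target) / n_pilot)
    if mc_se >= tolerance / 2:
        raise ValueError(
            f"n_pilot={n_pilot} gives Monte-Carlo SE {mc_se:.2g} >= tolerance/2; enlarge the pilot"
        )
    rng = np.random.default_rng(config.seed) if rng is None else rng
    x = sample_covariates(config.predictors, n_pilot, config.correlation, rng)
    eta = x @ config.coefs
    e = rng.exponential(1.0, n_pilot)
    c = rng.uniform(0.0, config.censor_horizon, n_pilot)
    thresholds = np.sort(np.log(e) - np.log(c) - eta)

    def rate(b: float) -> float:
        return np.searchsorted(thresholds, b, side="right") / n_pilot

    lo, hi = -5.0, 0.0
    for _ in range(max_expand):
        if rate(lo) < target:
            break
        lo -= 5.0
    else:
        raise ValueError("failed to bracket target event rate from below")
    for _ in range(max_expand):
        if rate(hi) > target:
            break
        hi += 5.0
    else:
        raise ValueError("failed to bracket target event rate from above")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        r = rate(mid)
        if abs(r - target) <= tolerance / 2:
            return mid
        if r < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrated_config(
    config: GeneratorConfig,
    n_pilot: int = 200_000,
    tolerance: float = 0.002,
    rng: np.random.Generator | None = None,
) -> GeneratorConfig:
    """Copy of ``config`` with the baseline log hazard calibrated."""
    b = calibrate_baseline(config, n_pilot=n_pilot, tolerance=tolerance, rng=rng)
    return dataclasses.replace(config, baseline_log_hazard=b)


def generate_development_and_validation(
    config: GeneratorConfig,
    n_dev: int,
    n_val: int,
    rng: np.random.Generator,
    validation_shift: Mapping[str, float] | None = None,
) -> tuple[Cohort, Cohort]:
    """Two independent cohorts from the same law, on disjoint random streams.

    ``validation_shift`` optionally perturbs validation-set means (continuous)
    or prevalences (binary) by the given per-variable deltas, to emulate a
    population shift between development and external-validation settings.
    Default is no shift: both cohorts share the generating law.
    """
    rng_dev, rng_val = rng.spawn(2)
    dev = generate_cohort(config, n_dev, rng_dev)
    val_config = config
    if validation_shift:
        shifted = []
        for s in config.predictors:
            if s.name in validation_shift:
                d = validation_shift[s.name]
                if s.kind == "continuous":
                    shifted.append(dataclasses.replace(s, mean=s.mean + d))
                else:
                    shifted.append(dataclasses.replace(s, prevalence=s.prevalence + d))
            else:
                shifted.append(s)
        val_config = dataclasses.replace(config, predictors=shifted)
    val = generate_cohort(val_config, n_val, rng_val)
    return dev, val
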