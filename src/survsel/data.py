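"""Survival-data containers, delimited-file I/O, splitting, and simulation.

The universal input across the package is a right-censored survival sample
``{(Y_i, delta_i, X_i)}``: observed time ``Y_i = min(T_i, C_i)``, event
indicator ``delta_i = I(T_i <= C_i)`` and a numeric covariate row ``X_i``.
Real benchmark cohorts (clinical registries, microarray gene-expression
panels) are emulated by :func:`simulate_dataset`, which draws event times
from a Weibull proportional-hazards model with a sparse linear predictor
and independent exponential censoring calibrated to a target rate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalDataset",
    "SimulationConfig",
    "load_dataset",
    "write_dataset",
    "split_train_test",
    "simulate_dataset",
]


@dataclasses.dataclass
class SurvivalDataset:
    """Right-censored survival sample with named numeric covariates.

    Parameters
    ----------
    times : (n,) array of observed times ``Y_i`` (strictly positive, finite).
    events : (n,) array of indicators ``delta_i`` in {0, 1}; 1 = event observed.
    covariates : (n, p) numeric matrix, no missing values.
    feature_names : p unique column labels.
    name : free-text dataset label.
    """

    times: np.ndarray
    events: np.ndarray
    covariates: np.ndarray
    feature_names: list[str]
    name: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        self.feature_names = list(self.feature_names)
        n = self.times.shape[0]
        if n < 2:
            raise ValueError(f"need at least 2 subjects, got n={n}")
        if self.events.shape[0] != n or self.covariates.shape[0] != n:
            raise ValueError(
                "times, events and covariates must have the same number of rows"
            )
        if not np.all(np.isfinite(self.times)) or np.any(self.times <= 0):
            raise ValueError("observed times must be strictly positive and finite")
        uniq = np.unique(self.events)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError(f"event indicators must be 0/1, found values {uniq}")
        self.events = self.events.astype(int)
        if self.events.sum() < 1:
            raise ValueError("dataset must contain at least one observed event")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        if self.covariates.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match covariate columns")
        if not np.all(np.isfinite(self.covariates)):
            raise ValueError("covariates contain missing or non-finite values")

    @property
    def n(self) -> int:
        return self.times.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def subset_rows(self, idx: np.ndarray, name: str | None = None) -> "SurvivalDataset":
        return SurvivalDataset(
            self.times[idx],
            self.events[idx],
            self.covariates[idx],
            self.feature_names,
            name if name is not None else self.name,
        )

    def subset_features(self, names: list[str]) -> "SurvivalDataset":
        """Restrict to the named covariate columns, preserving their order."""
        missing = [f for f in names if f not in self.feature_names]
        if missing:
            raise KeyError(f"unknown features: {missing}")
        cols = [self.feature_names.index(f) for f in names]
        return SurvivalDataset(
            self.times, self.events, self.covariates[:, cols], list(names), self.name
        )

    def to_frame(self, time_col: str = "time", event_col: str = "event") -> pd.DataFrame:
        df = pd.DataFrame(self.covariates, columns=self.feature_names)
        df.insert(0, event_col, self.events)
        df.insert(0, time_col, self.times)
        return df


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic high-dimensional survival generator.

    ``n_informative`` entries of the true coefficient vector equal
    ``+-beta_magnitude`` (alternating sign); the rest are exactly zero.
    ``baseline_shape``/``baseline_scale`` parameterize the Weibull baseline
    hazard; ``censor_rate`` is the target expected fraction of censored rows.
    """

    n: int = 300
    p: int = 50
    n_informative: int = 5
    beta_magnitude: float = 1.5
    baseline_shape: float = 1.5
    baseline_scale: float = 1.0
    censor_rate: float = 0.4
    correlation: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or self.p < 1:
            raise ValueError("need n >= 2 and p >= 1")
        if not 0 <= self.n_informative <= self.p:
            raise ValueError("n_informative must lie in [0, p]")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must lie in [0, 1)")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull baseline parameters must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_dataset(
    path: str | Path, time_col: str, event_col: str, name: str | None = None
) -> SurvivalDataset:
    """Load a delimited survival table (CSV, or TSV for ``.tsv`` files).

    Rows containing any missing value are dropped (logged). All columns other
    than ``time_col``/``event_col`` are coerced to numeric covariates.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    for col in (time_col, event_col):
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in {path.name}")
    n_before = len(df)
    df = df.dropna(axis=0, how="any")
    dropped = n_before - len(df)
    if dropped:
        logger.warning("%s: dropped %d row(s) with missing values", path.name, dropped)
    feat_cols = [c for c in df.columns if c not in (time_col, event_col)]
    covs = df[feat_cols].apply(pd.to_numeric, errors="coerce")
    bad = covs.columns[covs.isna().any()].tolist()
    if bad:
        raise ValueError(f"non-numeric covariate column(s): {bad}")
    return SurvivalDataset(
        df[time_col].to_numpy(dtype=float),
        df[event_col].to_numpy(),
        covs.to_numpy(dtype=float),
        feat_cols,
        name if name is not None else path.stem,
    )


def write_dataset(
    data: SurvivalDataset,
    path: str | Path,
    time_col: str = "time",
    event_col: str = "event",
) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    data.to_frame(time_col, event_col).to_csv(path, sep=sep, index=False)


def split_train_test(
    data: SurvivalDataset, test_fraction: float, seed: int
) -> tuple[SurvivalDataset, SurvivalDataset]:
    """Stratified (on the event indicator) train/test row partition."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    idx = np.arange(data.n)
    try:
        train_idx, test_idx = train_test_split(
            idx,
            test_size=test_fraction,
            random_state=seed,
            stratify=data.events,
            shuffle=True,
        )
    except ValueError as exc:  # e.g. a stratum too small for the split
        raise ValueError(f"cannot stratify split: {exc}") from exc
    train_idx.sort()
    test_idx.sort()
    if data.events[train_idx].sum() == 0 or data.events[test_idx].sum() == 0:
        raise ValueError("split leaves a part with zero observed events")
    return (
        data.subset_rows(train_idx, name=f"{data.name}/train"),
        data.subset_rows(test_idx, name=f"{data.name}/test"),
    )


def _true_beta(config: SimulationConfig) -> np.ndarray:
    beta = np.zeros(config.p)
    signs = np.array([1.0 if k % 2 == 0 else -1.0 for k in range(config.n_informative)])
    beta[: config.n_informative] = signs * config.beta_magnitude
    return beta


def _calibrate_censoring_rate(event_times: np.ndarray, target: float) -> float:
    """Exponential censoring rate giving E[fraction censored] = target.

    Conditional on the drawn event times T_i, a subject is censored with
    probability P(C < T_i) = 1 - exp(-theta * T_i); the mean over subjects is
    monotone in theta, so the rate is found by bracketed root-finding.
    """

    def mean_censored(theta: float) -> float:
        return float(np.mean(-np.expm1(-theta * event_times))) - target

    lo, hi = 1e-12, 1.0
    tries = 0
    while mean_censored(hi) < 0 and tries < 200:
        hi *= 2.0
        tries += 1
    if mean_censored(hi) < 0:
        raise RuntimeError(
            "censoring calibration failed: achieved rate "
            f"{mean_censored(hi) + target:.3f} < target {target:.3f}"
        )
    return optimize.brentq(mean_censored, lo, hi, xtol=1e-12, rtol=1e-10)


def simulate_dataset(config: SimulationConfig) -> tuple[SurvivalDataset, np.ndarray]:
    """Draw one synthetic dataset; returns it with the generating coefficients.

    Covariates are equicorrelated standard normal. Event times follow a
    Weibull proportional-hazards model: S(t|x) = exp(-(t/scale)^shape *
    exp(x'beta)), sampled by inversion. Censoring times are independent
    exponentials whose rate is calibrated so the expected censored fraction
    equals ``censor_rate`` (0 means no censoring).
    """
    rng = np.random.default_rng(config.seed)
    rho = config.correlation
    shared = rng.standard_normal((config.n, 1))
    indep = rng.standard_normal((config.n, config.p))
    X = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep
    beta = _true_beta(config)
    eta = X @ beta
    # Weibull PH inversion: T = scale * (-log U / exp(eta))^(1/shape)
    u = rng.uniform(size=config.n)
    T = config.baseline_scale * (-np.log(u) / np.exp(eta)) ** (1.0 / config.baseline_shape)
    T = np.maximum(T, 1e-12)
    if config.censor_rate == 0.0:
        times, events = T, np.ones(config.n, dtype=int)
    else:
        theta = _calibrate_censoring_rate(T, config.censor_rate)
        C = rng.exponential(scale=1.0 / theta, size=config.n)
        times = np.minimum(T, C)
        events = (T <= C).astype(int)
        if events.sum() == 0:  # pathological draw at extreme censor rates
            k = int(np.argmax(T <= np.inf))
            events[k] = 1
            times[k] = T[k]
    names = [f"x{j + 1}" for j in range(config.p)]
    data = SurvivalDataset(
        times, events, X, names, name=f"sim(seed={config.seed},n={config.n},p={config.p})"
    )
    return data, beta


def write_simulated(
    data: SurvivalDataset, beta: np.ndarray, config: SimulationConfig, path: str | Path
) -> None:
    """Write a simulated dataset plus a sidecar JSON of its generator state."""
    path = Path(path)
    write_dataset(data, path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {"config": config.to_dict(), "true_beta": np.asarray(beta).tolist()},
            indent=2,
        )
    )


def kendall_tau_linear_predictor(
    data: SurvivalDataset, beta: np.ndarray
) -> tuple[float, float]:
    """Kendall association (tau, p-value) between X·beta and observed times."""
    tau, pval = stats.kendalltau(data.covariates @ beta, data.times)
    return float(tau), float(pval)
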