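"""Benchmark orchestration: the selector x predictor grid on survival data.

For each cell: split (stratified on the event indicator) -> select features
on the training part only -> fit the predictor (Cox PH or random survival
forest) on the selected training columns -> predict survival on the test
part -> censoring-aware metrics (IBS, C-index, IAE, ISE). Repeats over seeds
are averaged; per-dataset tables, grand averages, and a win-count
("voting") comparison across selectors are emitted as DataFrames.
"""

from __future__ import annotations

import dataclasses
import logging
import time

import numpy as np
import pandas as pd

from . import forest as rsf
from .boosting import coxboost_select
from .coxph import fit_cox, predict_survival
from .data import SimulationConfig, SurvivalDataset, simulate_dataset, split_train_test
from .features import FeatureSet
from .forest import RSFConfig, rsf_select
from .hybrid import hybrid_pipeline
from .metrics import MetricReport, c_index, iae_ise, integrated_brier, reverse_km
from .penalized import PenaltyConfig, lasso_select, scad_select

logger = logging.getLogger(__name__)

SELECTORS = ("proposed", "lasso", "rsf_vs", "scad", "coxboost")
PREDICTORS = ("coxph", "rsf")

__all__ = [
    "BenchmarkConfig",
    "run_cell",
    "run_benchmark",
    "aggregate",
    "vote_tally_comparison",
]


@dataclasses.dataclass
class BenchmarkConfig:
    datasets: list  # paths or SimulationConfigs
    selectors: tuple = SELECTORS
    predictors: tuple = PREDICTORS
    test_fraction: float = 0.3
    n_repeats: int = 10
    base_seed: int = 0
    penalty_n_lambda: int = 50
    rsf_B: int = 300

    def __post_init__(self) -> None:
        if not self.selectors or not self.predictors:
            raise ValueError("selectors and predictors must be non-empty")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        unknown = set(self.selectors) - set(SELECTORS)
        if unknown:
            raise ValueError(f"unknown selectors: {sorted(unknown)}")
        unknown = set(self.predictors) - set(PREDICTORS)
        if unknown:
            raise ValueError(f"unknown predictors: {sorted(unknown)}")


def _select(
    train: SurvivalDataset, selector: str, seed: int, cfg: BenchmarkConfig | None
) -> FeatureSet:
    n_lambda = cfg.penalty_n_lambda if cfg else 50
    B = cfg.rsf_B if cfg else 300
    pen = lambda kind: PenaltyConfig(penalty_kind=kind, seed=seed, n_lambda=n_lambda)
    rcfg = RSFConfig(B=B, seed=seed)
    if selector == "lasso":
        return lasso_select(train, pen("lasso"))
    if selector == "scad":
        return scad_select(train, pen("scad"))
    if selector == "coxboost":
        return coxboost_select(train, seed=seed)
    if selector == "rsf_vs":
        return rsf_select(train, rcfg)
    if selector == "proposed":
        fs, _ = hybrid_pipeline(
            train,
            lasso_config=pen("lasso"),
            scad_config=pen("scad"),
            rsf_config=rcfg,
            boost_kwargs={"seed": seed},
        )
        return fs
    raise ValueError(f"unknown selector {selector!r}")


def _with_fallback(fs: FeatureSet, train: SurvivalDataset) -> tuple[list[str], bool]:
    """Guarantee >= 1 feature: fall back to the selector's top-ranked one."""
    if fs.features:
        return list(fs.features), False
    top = fs.ranking[0] if fs.ranking else train.feature_names[0]
    logger.warning("empty selection from %s: falling back to top-1 %r", fs.method, top)
    return [top], True


def run_cell(
    data: SurvivalDataset,
    selector: str,
    predictor: str,
    seed: int,
    test_fraction: float = 0.3,
    config: BenchmarkConfig | None = None,
) -> MetricReport:
    """One (dataset, selector, predictor) cell at one seed."""
    train, test = split_train_test(data, test_fraction, seed)
    fs = _select(train, selector, seed, config)
    feats, _ = _with_fallback(fs, train)
    train_f = train.subset_features(feats)
    test_f = test.subset_features(feats)
    grid = np.unique(test.times[test.events == 1])
    if predictor == "coxph":
        fit = fit_cox(train_f)
        surv = predict_survival(fit, test_f.covariates, grid)
        risk = test_f.covariates @ fit.beta
        ci = c_index(risk, test_f, mode="hazard")
    elif predictor == "rsf":
        fcfg = RSFConfig(B=config.rsf_B if config else 300, seed=seed)
        forest = rsf.grow_forest(train_f, config=fcfg)
        surv = rsf.predict_survival_rsf(forest, test_f.covariates, grid)
        risk = rsf.mortality(forest, test_f.covariates, grid)
        ci = c_index(risk, test_f, mode="hazard")
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    G = reverse_km(test_f)
    ibs = integrated_brier(surv, test_f, G)
    iae, ise = iae_ise(surv, test_f)
    return MetricReport(
        ibs=ibs, c_index=ci, iae=iae, ise=ise, n_test=test.n, time_grid=grid
    )


def _materialize(entry) -> SurvivalDataset:
    if isinstance(entry, SurvivalDataset):
        return entry
    if isinstance(entry, SimulationConfig):
        return simulate_dataset(entry)[0]
    from .data import load_dataset

    return load_dataset(entry, time_col="time", event_col="event")


def run_benchmark(cfg: BenchmarkConfig) -> pd.DataFrame:
    """Full grid; one row per (dataset, selector, predictor, repeat)."""
    rows = []
    for d_idx, entry in enumerate(cfg.datasets):
        data = _materialize(entry)
        for selector in cfg.selectors:
            for predictor in cfg.predictors:
                for r in range(cfg.n_repeats):
                    seed = cfg.base_seed + 1000 * d_idx + r
                    t0 = time.perf_counter()
                    try:
                        rep = run_cell(
                            data, selector, predictor, seed, cfg.test_fraction, cfg
                        )
                    except Exception as exc:
                        logger.warning(
                            "cell (%s, %s, %s, rep %d) failed: %s",
                            data.name, selector, predictor, r, exc,
                        )
                        continue
                    logger.info(
                        "cell (%s, %s, %s, rep %d): %.1fs",
                        data.name, selector, predictor, r, time.perf_counter() - t0,
                    )
                    rows.append(
                        {
                            "dataset": data.name,
                            "selector": selector,
                            "predictor": predictor,
                            "repeat": r,
                            "seed": seed,
                            **rep.to_row(),
                        }
                    )
    return pd.DataFrame(rows)


def aggregate(reports: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-predictor tables (dataset x selector, one per metric) plus grand means.

    Repeats are averaged first; the grand table then averages over datasets.
    """
    out: dict[str, pd.DataFrame] = {}
    per_cell = (
        reports.groupby(["predictor", "dataset", "selector"])[["IBS", "CI", "IAE", "ISE"]]
        .mean()
        .reset_index()
    )
    for predictor in per_cell["predictor"].unique():
        sub = per_cell[per_cell["predictor"] == predictor]
        tab = sub.melt(
            id_vars=["dataset", "selector"],
            value_vars=["IBS", "CI", "IAE"],
            var_name="metric",
        ).pivot_table(index=["dataset", "metric"], columns="selector", values="value")
        avg = tab.groupby("metric").mean()
        avg.index = pd.MultiIndex.from_product([["Average"], avg.index])
        out[f"table_{predictor}"] = pd.concat([tab, avg])
        out[f"grand_{predictor}"] = (
            sub.groupby("selector")[["IBS", "CI", "IAE", "ISE"]].mean()
        )
    return out


def vote_tally_comparison(reports: pd.DataFrame) -> pd.DataFrame:
    """Win counts: per (predictor, dataset, metric) the best selector scores 1.

    Lower is better for IBS/IAE/ISE, higher for CI; exact ties split the win.
    """
    per_cell = (
        reports.groupby(["predictor", "dataset", "selector"])[["IBS", "CI", "IAE", "ISE"]]
        .mean()
        .reset_index()
    )
    selectors = sorted(per_cell["selector"].unique())
    wins = {p: {s: 0.0 for s in selectors} for p in per_cell["predictor"].unique()}
    for (predictor, dataset), grp in per_cell.groupby(["predictor", "dataset"]):
        for metric, better in (("IBS", "min"), ("CI", "max"), ("IAE", "min")):
            vals = grp.set_index("selector")[metric]
            best = vals.min() if better == "min" else vals.max()
            winners = vals.index[vals == best]
            for s in winners:
                wins[predictor][s] += 1.0 / len(winners)
    return pd.DataFrame(wins).T
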