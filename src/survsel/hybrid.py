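"""Majority-vote hybrid feature selection.

Runs the four base selectors (lasso-Cox, RSF variable selection, SCAD-Cox,
component-wise Cox boosting) on the same data and keeps every feature chosen
by at least ``threshold`` of them (default 3 of 4). The intuition: selectors
with very different mechanisms — shrinkage, tree depth, boosting path —
should nonetheless agree on genuinely informative covariates, so agreement
filters mechanism-specific false positives.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .boosting import coxboost_select
from .data import SurvivalDataset
from .features import FeatureSet
from .forest import RSFConfig, rsf_select
from .penalized import PenaltyConfig, lasso_select, scad_select

logger = logging.getLogger(__name__)

__all__ = [
    "VoteTally",
    "SelectorError",
    "run_all_selectors",
    "count_votes",
    "hybrid_select",
    "hybrid_pipeline",
]


class SelectorError(RuntimeError):
    """A base selector failed; the hybrid cannot proceed on a partial panel."""


@dataclasses.dataclass
class VoteTally:
    counts: dict[str, int]
    source_sets: list[FeatureSet]
    threshold: int = 3

    def __post_init__(self) -> None:
        k = len(self.source_sets)
        if any(c > k for c in self.counts.values()):
            raise ValueError("a vote count exceeds the number of source sets")

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "counts": self.counts,
            "sources": [fs.to_dict() for fs in self.source_sets],
        }


def run_all_selectors(
    data: SurvivalDataset,
    lasso_config: PenaltyConfig | None = None,
    scad_config: PenaltyConfig | None = None,
    rsf_config: RSFConfig | None = None,
    boost_kwargs: dict | None = None,
) -> list[FeatureSet]:
    """Run the four base selectors; any failure aborts with its name."""
    jobs = [
        ("lasso", lambda: lasso_select(data, lasso_config)),
        ("rsf_vs", lambda: rsf_select(data, rsf_config)),
        ("scad", lambda: scad_select(data, scad_config)),
        ("coxboost", lambda: coxboost_select(data, **(boost_kwargs or {}))),
    ]
    results = []
    for name, job in jobs:
        try:
            results.append(job())
        except Exception as exc:
            raise SelectorError(f"base selector {name!r} failed: {exc}") from exc
    return results


def count_votes(sets: list[FeatureSet], threshold: int = 3) -> VoteTally:
    """Vote counts over the union of the given feature sets."""
    if not 2 <= len(sets) <= 4:
        raise ValueError("expected between 2 and 4 feature sets")
    counts: dict[str, int] = {}
    for fs in sets:
        for f in fs.features:
            counts[f] = counts.get(f, 0) + 1
    return VoteTally(counts=counts, source_sets=list(sets), threshold=threshold)


def hybrid_select(tally: VoteTally) -> FeatureSet:
    """Features with count >= threshold, by descending count then name."""
    if not 1 <= tally.threshold <= len(tally.source_sets):
        raise ValueError("threshold must lie in {1..number of sets}")
    chosen = sorted(
        (f for f, c in tally.counts.items() if c >= tally.threshold),
        key=lambda f: (-tally.counts[f], f),
    )
    if not chosen:
        logger.warning(
            "hybrid vote produced an EMPTY feature set (threshold=%d)", tally.threshold
        )
    ranking = sorted(tally.counts, key=lambda f: (-tally.counts[f], f))
    return FeatureSet(
        features=chosen,
        method="proposed",
        tuning={"threshold": tally.threshold},
        scores={f: float(tally.counts[f]) for f in chosen},
        ranking=ranking,
    )


def hybrid_pipeline(
    data: SurvivalDataset,
    threshold: int = 3,
    lasso_config: PenaltyConfig | None = None,
    scad_config: PenaltyConfig | None = None,
    rsf_config: RSFConfig | None = None,
    boost_kwargs: dict | None = None,
) -> tuple[FeatureSet, VoteTally]:
    """Run the four selectors, tally, and apply the majority rule."""
    sets = run_all_selectors(data, lasso_config, scad_config, rsf_config, boost_kwargs)
    tally = count_votes(sets, threshold=threshold)
    return hybrid_select(tally), tally
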