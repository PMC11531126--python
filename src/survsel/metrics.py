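"""Censoring-aware performance metrics.

Implements the inverse-probability-of-censoring-weighted (IPCW) Brier score
and its time-normalized integral (IBS), a comparable-pairs concordance index
with an explicit censoring-aware pairing rule, and Kaplan–Meier-referenced
integrated absolute / squared errors (IAE / ISE).

Pairing rule: a pair (i, j) with t_i < t_j is comparable iff subject i (the
earlier one) experienced the event; with t_i = t_j the pair is comparable iff
exactly one of the two is an event (the event subject ordered first). Under
this rule five uncensored ordered subjects yield C(5,2) = 10 pairs, and
censoring the 2nd and 4th leaves 6.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from lifelines import KaplanMeierFitter

from .coxph import SurvCurveSet
from .data import SurvivalDataset

logger = logging.getLogger(__name__)

__all__ = [
    "CensoringEstimate",
    "MetricReport",
    "reverse_km",
    "brier_score",
    "integrated_brier",
    "comparable_pairs",
    "c_index",
    "iae_ise",
]


@dataclasses.dataclass
class CensoringEstimate:
    """Kaplan–Meier estimate G(t) of the censoring survival distribution."""

    times: np.ndarray
    G_hat: np.ndarray  # non-increasing step values, G(0) = 1

    def at(self, t: np.ndarray) -> np.ndarray:
        """Right-continuous step lookup, G = 1 before the first drop."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.where(idx >= 0, self.G_hat[np.clip(idx, 0, None)], 1.0)


@dataclasses.dataclass
class MetricReport:
    """IBS, C-index, IAE, ISE for one (selector, predictor, dataset) cell."""

    ibs: float
    c_index: float
    iae: float
    ise: float
    n_test: int
    time_grid: np.ndarray

    def __post_init__(self) -> None:
        if not (0 <= self.ibs <= 1 and 0 <= self.c_index <= 1):
            raise ValueError("IBS and C-index must lie in [0, 1]")
        if self.iae < 0 or self.ise < 0:
            raise ValueError("IAE and ISE must be non-negative")

    def to_row(self) -> dict:
        return {
            "IBS": self.ibs,
            "CI": self.c_index,
            "IAE": self.iae,
            "ISE": self.ise,
            "n_test": self.n_test,
        }


def _km(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = t > 0
    return t[keep], s[keep]


def reverse_km(data: SurvivalDataset) -> CensoringEstimate:
    """Censoring survival function: product-limit with 1 - delta as the event."""
    t, g = _km(data.times, 1 - data.events)
    return CensoringEstimate(times=t, G_hat=g)


def km_survival(data: SurvivalDataset) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary Kaplan–Meier survival estimate (reference curve for IAE/ISE)."""
    return _km(data.times, data.events)


def brier_score(
    surv: SurvCurveSet, test: SurvivalDataset, t: float, G: CensoringEstimate
) -> float:
    """IPCW Brier score at time t.

    Event before t:      (0 - S(t|z_i))^2 / G(t_i)
    Still at risk at t:  (1 - S(t|z_i))^2 / G(t)
    Censored before t:   contributes 0 (excluded by the weighting).
    Subjects whose required G value is 0 are dropped with a warning.
    """
    s_t = surv.at_time(t)
    times, events = test.times, test.events
    G_ti = G.at(times)
    G_t = float(G.at(np.array([t]))[0])
    contrib = np.zeros(test.n)
    n_used = test.n
    event_before = (times <= t) & (events == 1)
    at_risk = times > t
    bad = np.zeros(test.n, dtype=bool)
    bad |= event_before & (G_ti <= 0)
    if at_risk.any() and G_t <= 0:
        bad |= at_risk
    if bad.any():
        logger.warning("Brier score: %d subject(s) dropped (G=0)", int(bad.sum()))
        n_used -= int(bad.sum())
        if n_used == 0:
            raise ValueError("no subjects usable for Brier score at t")
    ok = ~bad
    contrib[event_before & ok] = (0.0 - s_t[event_before & ok]) ** 2 / G_ti[
        event_before & ok
    ]
    if G_t > 0:
        contrib[at_risk & ok] = (1.0 - s_t[at_risk & ok]) ** 2 / G_t
    return float(contrib.sum() / n_used)


def _event_time_grid(test: SurvivalDataset) -> np.ndarray:
    return np.unique(test.times[test.events == 1])


def integrated_brier(
    surv: SurvCurveSet, test: SurvivalDataset, G: CensoringEstimate | None = None
) -> float:
    """Trapezoidal integral of BS(t) over the distinct test event times,
    normalized by the largest observed time."""
    if G is None:
        G = reverse_km(test)
    grid = _event_time_grid(test)
    bs = np.array([brier_score(surv, test, t, G) for t in grid])
    if len(grid) == 1:
        logger.warning("single event time: IBS degenerates to BS at that time")
        return float(bs[0])
    t_max = float(test.times.max())
    # constant extension of the BS step curve to the ends of (0, t_max]
    grid_full = np.concatenate([[0.0], grid])
    bs_full = np.concatenate([[bs[0]], bs])
    if grid[-1] < t_max:
        grid_full = np.concatenate([grid_full, [t_max]])
        bs_full = np.concatenate([bs_full, [bs[-1]]])
    return float(min(1.0, np.trapezoid(bs_full, grid_full) / t_max))


def comparable_pairs(test: SurvivalDataset) -> list[tuple[int, int]]:
    """Index pairs (i, j) usable for concordance, i the earlier/event subject."""
    t, e = test.times, test.events
    n = test.n
    pairs: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if t[i] < t[j] and e[i] == 1:
                pairs.append((i, j))
            elif t[i] == t[j] and i < j and e[i] + e[j] == 1:
                # same time, exactly one event: event subject ordered first
                pairs.append((i, j) if e[i] == 1 else (j, i))
    return pairs


def c_index(
    risk_or_surv: np.ndarray | SurvCurveSet,
    test: SurvivalDataset,
    mode: str = "hazard",
) -> float:
    """Concordance over comparable pairs; tied scores count 1/2.

    hazard mode: scores are per-subject risks (higher = shorter survival);
    concordant when the earlier-event subject has the higher risk.
    survival mode: scores come from predicted curves evaluated at the median
    observed event time; concordant when the longer-lived subject has the
    higher predicted survival there.
    """
    if mode == "hazard":
        risk = np.asarray(risk_or_surv, dtype=float)
    elif mode == "survival":
        if not isinstance(risk_or_surv, SurvCurveSet):
            raise TypeError("survival mode requires a SurvCurveSet")
        t_ref = float(np.median(test.times[test.events == 1]))
        risk = -risk_or_surv.at_time(t_ref)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pairs = comparable_pairs(test)
    if not pairs:
        raise ValueError("no comparable pairs")
    conc = 0.0
    for i, j in pairs:
        if risk[i] > risk[j]:
            conc += 1.0
        elif risk[i] == risk[j]:
            conc += 0.5
    return conc / len(pairs)


def iae_ise(surv: SurvCurveSet, test: SurvivalDataset) -> tuple[float, float]:
    """Integrated absolute/squared error between the Kaplan–Meier reference
    and the cohort-average (marginal) predicted curve, trapezoidal over the
    event-time grid from 0 to the last observed time."""
    grid = _event_time_grid(test)
    km_t, km_s = km_survival(test)
    idx = np.searchsorted(km_t, grid, side="right") - 1
    S_ref = np.where(idx >= 0, km_s[np.clip(idx, 0, None)], 1.0)
    S_hat = np.array([surv.at_time(t).mean() for t in grid])
    grid_full = np.concatenate([[0.0], grid])
    diff = np.concatenate([[0.0], np.abs(S_ref - S_hat)])
    iae = float(np.trapezoid(diff, grid_full))
    ise = float(np.trapezoid(diff**2, grid_full))
    return iae, ise
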