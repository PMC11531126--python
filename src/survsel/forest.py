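"""Random survival forest: bootstrap trees with log-rank splitting.

Each tree is grown on a bootstrap resample (with replacement). At every
node, ``mtry`` randomly chosen features are scanned; candidate cut points
are midpoints of observed in-node values (capped at ``nsplit`` quantile
midpoints for speed), scored by the two-sample log-rank statistic, and the
best admissible split (each daughter keeps at least one event) is taken.
Leaves store the Nelson–Aalen cumulative hazard of their in-node bootstrap
rows; the ensemble prediction averages leaf hazards across trees, and
out-of-bag (OOB) rows give an honest error estimate.

Variable selection comes in two modes, dispatched on the dimensionality
ratio: for p/n < 10, features are ranked by mean minimal depth (the depth of
the shallowest node split on the feature, per tree; unused features are
penalized at that tree's max depth + 1) and those below the forest-wide mean
are kept. For p/n >= 10, a variable-hunting mode repeatedly subsamples rows
and features, grows a model in minimal-depth order until its out-of-bag
importance stabilizes, and keeps features appearing in at least half the
repetitions.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .coxph import SurvCurveSet
from .data import SurvivalDataset
from .features import FeatureSet
from .metrics import c_index

logger = logging.getLogger(__name__)

__all__ = [
    "RSFConfig",
    "SurvTreeNode",
    "SurvForest",
    "grow_forest",
    "ensemble_chf",
    "oob_error",
    "minimal_depth",
    "rsf_select",
    "logrank_split_scores",
]


@dataclasses.dataclass
class RSFConfig:
    """Forest and selector parameters.

    nodesize is the minimum number of rows a node needs to attempt a split;
    a node additionally needs at least ``min_events_split`` distinct event
    times, and every daughter must retain at least one event.
    """

    B: int = 300
    mtry: int | None = None  # None -> ceil(sqrt(p))
    nodesize: int = 15
    min_events_split: int = 3
    nsplit: int = 32
    seed: int = 0
    vh_repetitions: int = 50
    vh_B: int = 50
    vh_row_fraction: float = 0.8
    vh_keep_fraction: float = 0.5


@dataclasses.dataclass
class SurvTreeNode:
    depth: int
    split_feature: int | None = None
    split_value: float = math.nan
    left: "SurvTreeNode | None" = None
    right: "SurvTreeNode | None" = None
    chf_times: np.ndarray | None = None  # leaf Nelson–Aalen step function
    chf_values: np.ndarray | None = None

    @property
    def is_leaf(self) -> bool:
        return self.split_feature is None


@dataclasses.dataclass
class SurvForest:
    trees: list[SurvTreeNode]
    bootstrap_indices: list[np.ndarray]
    mtry: int
    nodesize: int
    seed: int
    n_train: int
    feature_names: list[str]

    @property
    def B(self) -> int:
        return len(self.trees)

    def oob_indices(self, b: int) -> np.ndarray:
        inbag = np.zeros(self.n_train, dtype=bool)
        inbag[self.bootstrap_indices[b]] = True
        return np.flatnonzero(~inbag)


def _nelson_aalen(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ut = np.unique(times[events == 1])
    if len(ut) == 0:
        return np.array([]), np.array([])
    d = np.array([int(((times == t) & (events == 1)).sum()) for t in ut])
    at_risk = np.array([int((times >= t).sum()) for t in ut])
    return ut, np.cumsum(d / at_risk)


def logrank_split_scores(
    times: np.ndarray, events: np.ndarray, x: np.ndarray, cutpoints: np.ndarray
) -> np.ndarray:
    """Squared standardized log-rank statistic for each split x <= c.

    Inadmissible splits (a daughter without events, or zero variance) score
    -inf. Vectorized over cutpoints via cumulative at-risk / event counts.
    """
    ut = np.unique(times[events == 1])
    if len(ut) == 0:
        return np.full(len(cutpoints), -np.inf)
    d = ((times[None, :] == ut[:, None]) & (events == 1)).sum(axis=1).astype(float)
    R = times[None, :] >= ut[:, None]  # (K, m) at-risk indicator
    E = (times[None, :] == ut[:, None]) & (events[None, :] == 1)
    Y = R.sum(axis=1).astype(float)
    M = x[None, :] <= cutpoints[:, None]  # (L, m) membership of the left daughter
    Y1 = M.astype(float) @ R.T.astype(float)  # (L, K)
    D1 = M.astype(float) @ E.T.astype(float)
    num = (D1 - Y1 * (d / Y)[None, :]).sum(axis=1)
    frac = Y1 / Y[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = frac * (1.0 - frac) * ((Y - d) / np.maximum(Y - 1.0, 1.0))[None, :] * d[None, :]
    var_terms[:, Y <= 1] = 0.0
    var = var_terms.sum(axis=1)
    ev_left = M @ events.astype(float)
    ev_right = events.sum() - ev_left
    n_left = M.sum(axis=1)
    admissible = (ev_left >= 1) & (ev_right >= 1) & (n_left >= 1) & (n_left < len(x)) & (var > 1e-12)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = num**2 / var
    score[~admissible] = -np.inf
    return score


def _candidate_cutpoints(x: np.ndarray, nsplit: int) -> np.ndarray:
    xs = np.unique(x)
    if len(xs) < 2:
        return np.array([])
    mids = 0.5 * (xs[:-1] + xs[1:])
    if len(mids) > nsplit:
        take = np.unique(np.linspace(0, len(mids) - 1, nsplit).round().astype(int))
        mids = mids[take]
    return mids


def _grow_tree(
    times: np.ndarray,
    events: np.ndarray,
    X: np.ndarray,
    rng: np.random.Generator,
    cfg: RSFConfig,
    mtry: int,
    depth: int = 0,
) -> SurvTreeNode:
    node = SurvTreeNode(depth=depth)
    m = len(times)
    n_unique_event_times = len(np.unique(times[events == 1]))
    if m >= cfg.nodesize and n_unique_event_times >= cfg.min_events_split:
        p = X.shape[1]
        feats = rng.choice(p, size=min(mtry, p), replace=False)
        best_score = -np.inf
        best: list[tuple[int, float]] = []
        for j in feats:
            cuts = _candidate_cutpoints(X[:, j], cfg.nsplit)
            if len(cuts) == 0:
                continue
            scores = logrank_split_scores(times, events, X[:, j], cuts)
            k = int(np.argmax(scores))
            if scores[k] > best_score + 1e-12:
                best_score = scores[k]
                best = [(int(j), float(cuts[k]))]
            elif np.isfinite(scores[k]) and abs(scores[k] - best_score) <= 1e-12:
                best.append((int(j), float(cuts[k])))
        if best and np.isfinite(best_score):
            j, c = best[int(rng.integers(len(best)))] if len(best) > 1 else best[0]
            mask = X[:, j] <= c
            node.split_feature = j
            node.split_value = c
            node.left = _grow_tree(
                times[mask], events[mask], X[mask], rng, cfg, mtry, depth + 1
            )
            node.right = _grow_tree(
                times[~mask], events[~mask], X[~mask], rng, cfg, mtry, depth + 1
            )
            return node
    node.chf_times, node.chf_values = _nelson_aalen(times, events)
    return node


def grow_forest(
    data: SurvivalDataset,
    B: int = 300,
    mtry: int | None = None,
    nodesize: int = 15,
    seed: int = 0,
    config: RSFConfig | None = None,
) -> SurvForest:
    """Grow B bootstrap survival trees with log-rank splitting."""
    cfg = config or RSFConfig(B=B, mtry=mtry, nodesize=nodesize, seed=seed)
    if config is not None:
        B, mtry, nodesize, seed = cfg.B, cfg.mtry, cfg.nodesize, cfg.seed
    if B < 1:
        raise ValueError("B must be >= 1")
    p = data.p
    mtry_eff = mtry if mtry is not None else int(math.ceil(math.sqrt(p)))
    if not 1 <= mtry_eff <= p:
        raise ValueError(f"mtry must lie in [1, p={p}]")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(B)
    trees = []
    boot = []
    for b in range(B):
        rng = np.random.default_rng(children[b])
        idx = rng.integers(0, data.n, data.n)
        boot.append(np.sort(idx))
        trees.append(
            _grow_tree(
                data.times[idx], data.events[idx], data.covariates[idx], rng, cfg, mtry_eff
            )
        )
    return SurvForest(
        trees=trees,
        bootstrap_indices=boot,
        mtry=mtry_eff,
        nodesize=cfg.nodesize,
        seed=seed,
        n_train=data.n,
        feature_names=list(data.feature_names),
    )


def _leaf_of(node: SurvTreeNode, row: np.ndarray) -> SurvTreeNode:
    while not node.is_leaf:
        node = node.left if row[node.split_feature] <= node.split_value else node.right
    return node


def _chf_at(node: SurvTreeNode, eval_times: np.ndarray) -> np.ndarray:
    if node.chf_times is None or len(node.chf_times) == 0:
        return np.zeros(len(eval_times))
    idx = np.searchsorted(node.chf_times, eval_times, side="right") - 1
    return np.where(idx >= 0, node.chf_values[np.clip(idx, 0, None)], 0.0)


def ensemble_chf(
    forest: SurvForest, X_new: np.ndarray, eval_times: np.ndarray
) -> tuple[np.ndarray, SurvCurveSet]:
    """Mean cumulative hazard across trees; also returns S = exp(-CHF) curves."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    eval_times = np.asarray(eval_times, dtype=float)
    chf = np.zeros((X_new.shape[0], len(eval_times)))
    for tree in forest.trees:
        for i in range(X_new.shape[0]):
            chf[i] += _chf_at(_leaf_of(tree, X_new[i]), eval_times)
    chf /= forest.B
    surv = SurvCurveSet(eval_times=eval_times, surv=np.exp(-chf))
    return chf, surv


def predict_survival_rsf(
    forest: SurvForest, X_new: np.ndarray, eval_times: np.ndarray
) -> SurvCurveSet:
    return ensemble_chf(forest, X_new, eval_times)[1]


def mortality(forest: SurvForest, X_new: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Ensemble mortality: CHF summed over the event-time grid (risk score)."""
    chf, _ = ensemble_chf(forest, X_new, grid)
    return chf.sum(axis=1)


def oob_error(forest: SurvForest, data: SurvivalDataset) -> float:
    """1 - C-index of out-of-bag ensemble mortality."""
    grid = np.unique(data.times[data.events == 1])
    chf = np.zeros((data.n, len(grid)))
    counts = np.zeros(data.n)
    for b, tree in enumerate(forest.trees):
        oob = forest.oob_indices(b)
        for i in oob:
            chf[i] += _chf_at(_leaf_of(tree, data.covariates[i]), grid)
            counts[i] += 1
    used = counts > 0
    if not used.any():
        raise ValueError("no out-of-bag rows: increase B")
    if not used.all():
        logger.warning("%d row(s) never OOB; excluded", int((~used).sum()))
    risk = chf[used].sum(axis=1) / counts[used]
    sub = data.subset_rows(np.flatnonzero(used))
    return 1.0 - c_index(risk, sub, mode="hazard")


def _tree_min_depths(node: SurvTreeNode, p: int):
    """Per-feature minimal split depth in one tree, and the tree's max depth."""
    md = np.full(p, np.inf)
    max_depth = 0

    def walk(nd: SurvTreeNode):
        nonlocal max_depth
        max_depth = max(max_depth, nd.depth)
        if nd.is_leaf:
            return
        md[nd.split_feature] = min(md[nd.split_feature], nd.depth)
        walk(nd.left)
        walk(nd.right)

    walk(node)
    return md, max_depth


def minimal_depth(forest: SurvForest) -> np.ndarray:
    """Mean minimal depth per feature; unused features take max depth + 1."""
    p = len(forest.feature_names)
    total = np.zeros(p)
    for tree in forest.trees:
        md, max_depth = _tree_min_depths(tree, p)
        md[~np.isfinite(md)] = max_depth + 1
        total += md
    return total / forest.B


def _minimal_depth_select(data: SurvivalDataset, cfg: RSFConfig) -> FeatureSet:
    forest = grow_forest(data, config=cfg)
    md = minimal_depth(forest)
    threshold = float(md.mean())
    order = np.argsort(md, kind="stable")
    selected = [data.feature_names[j] for j in order if md[j] < threshold]
    if not selected:
        logger.warning("minimal-depth selection is empty (degenerate forest)")
    return FeatureSet(
        features=selected,
        method="rsf_vs",
        tuning={"mode": "minimal_depth", "B": cfg.B, "threshold": threshold},
        scores={data.feature_names[j]: float(md[j]) for j in order if md[j] < threshold},
        ranking=[data.feature_names[j] for j in order],
    )


def _variable_hunt_once(
    data: SurvivalDataset, cfg: RSFConfig, rng: np.random.Generator
) -> list[str]:
    n, p = data.n, data.p
    rows = rng.choice(n, size=max(4, int(round(cfg.vh_row_fraction * n))), replace=False)
    sub_rows = data.subset_rows(np.sort(rows))
    if sub_rows.events.sum() == 0:
        return []
    n_feats = min(p, max(10, n))
    feats = sorted(rng.choice(p, size=n_feats, replace=False).tolist())
    names = [data.feature_names[j] for j in feats]
    sub = sub_rows.subset_features(names)
    fcfg = dataclasses.replace(cfg, B=cfg.vh_B, seed=int(rng.integers(2**31 - 1)))
    forest = grow_forest(sub, config=fcfg)
    md = minimal_depth(forest)
    order = np.argsort(md, kind="stable")
    cap = min(len(names), max(2, sub.n // 2))
    model: list[str] = [names[order[0]]]
    imps: list[float] = []
    for k in range(1, cap):
        model.append(names[order[k]])
        mcfg = dataclasses.replace(cfg, B=cfg.vh_B, seed=int(rng.integers(2**31 - 1)))
        try:
            err = oob_error(grow_forest(sub.subset_features(model), config=mcfg), sub.subset_features(model))
        except ValueError:
            break
        imps.append(1.0 - err)  # joint OOB importance of the nested model
        if len(imps) >= 4:
            recent = np.abs(np.diff(imps[-4:]))
            if np.all(recent < 1e-3):
                break
    return model


def _variable_hunt_select(data: SurvivalDataset, cfg: RSFConfig) -> FeatureSet:
    rng = np.random.default_rng(cfg.seed)
    counts: dict[str, int] = {}
    for _ in range(cfg.vh_repetitions):
        for f in _variable_hunt_once(data, cfg, rng):
            counts[f] = counts.get(f, 0) + 1
    cutoff = cfg.vh_keep_fraction * cfg.vh_repetitions
    selected = sorted(
        (f for f, c in counts.items() if c >= cutoff), key=lambda f: -counts[f]
    )
    if not selected:
        logger.warning("variable hunting selected no stable features")
    ranking = sorted(counts, key=lambda f: -counts[f]) + [
        f for f in data.feature_names if f not in counts
    ]
    return FeatureSet(
        features=selected,
        method="rsf_vs",
        tuning={"mode": "variable_hunting", "repetitions": cfg.vh_repetitions},
        scores={f: float(counts[f]) for f in selected},
        ranking=ranking,
    )


def rsf_select(data: SurvivalDataset, config: RSFConfig | None = None) -> FeatureSet:
    """Forest-based selection: minimal depth if p/n < 10, else variable hunting."""
    cfg = config or RSFConfig()
    if data.p / data.n < 10:
        logger.info("p/n = %.2f < 10: minimal-depth mode", data.p / data.n)
        return _minimal_depth_select(data, cfg)
    logger.info("p/n = %.2f >= 10: variable-hunting mode", data.p / data.n)
    return _variable_hunt_select(data, cfg)
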