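"""Bivariate Granger causality over feature pairs and cluster centroids,
and assembly of the significant edges into a directed network.

A series x Granger-causes y at lag L if the past L values of x
significantly improve an autoregressive prediction of y. Both models are
fit by ordinary least squares on the T = N - L aligned observations:

    restricted:    y_t = a0 + sum_{i=1..L} a_i y_{t-i}
    unrestricted:  y_t = a0 + sum a_i y_{t-i} + sum b_i x_{t-i}

    F = ((SSR_r - SSR_u) / L) / (SSR_u / (T - 2L - 1))

with the p-value from the upper tail of F(L, T - 2L - 1). Stages are
treated as equally spaced integer time; lags are in stages. No multiple
testing correction is applied by default (raw p < alpha is recorded,
each lag independently); Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import false_discovery_control

from .multivariate import ClusterModel
from .quantify import StageSeries

logger = logging.getLogger(__name__)

DEFAULT_LAGS = (1, 2, 3)


@dataclass(frozen=True)
class GrangerResult:
    F: float
    p: float
    T: int  # observations used after lag alignment
    degenerate: bool = False


@dataclass(frozen=True)
class GrangerEdge:
    cause: str
    effect: str
    lag: int
    F: float
    p: float
    T: int
    degenerate: bool = False

    def __post_init__(self):
        if self.cause == self.effect:
            raise ValueError("self-edges are not allowed")


def _lag_matrix(z: np.ndarray, lag: int) -> np.ndarray:
    """Columns z_{t-1} .. z_{t-lag} for t = lag..N-1 (T = N - lag rows)."""
    n = len(z)
    return np.column_stack([z[lag - i : n - i] for i in range(1, lag + 1)])


def _ssr(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def restricted_ssr(y: np.ndarray, lag: int) -> float:
    """SSR of the autoregressive-only model (shared across causes of y)."""
    y = np.asarray(y, dtype=float)
    T = len(y) - lag
    target = y[lag:]
    X_r = np.column_stack([np.ones(T), _lag_matrix(y, lag)])
    return _ssr(X_r, target)


def granger_test(x, y, lag: int) -> GrangerResult:
    """Bivariate Granger F-test: does x's past improve prediction of y?

    Raises if the series are too short for the residual degrees of
    freedom (T - 2L - 1 >= 1), non-finite, or constant over the fitted
    window. A perfect unrestricted fit (SSR_u = 0) is reported as p = 0
    with the ``degenerate`` flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series contain non-finite values")
    if lag < 1:
        raise ValueError("lag must be >= 1")
    N = len(x)
    T = N - lag
    df_den = T - 2 * lag - 1
    if df_den < 1:
        raise ValueError(f"series too short for lag {lag}: need N >= {3 * lag + 2}, got {N}")
    target = y[lag:]
    if np.ptp(target) == 0 or np.ptp(_lag_matrix(x, lag), axis=0).max() == 0:
        raise ValueError("constant regressor block over the fitted window")
    ssr_r = restricted_ssr(y, lag)
    X_u = np.column_stack([np.ones(T), _lag_matrix(y, lag), _lag_matrix(x, lag)])
    ssr_u = _ssr(X_u, target)
    scale = float(np.sum((target - target.mean()) ** 2))
    if ssr_u <= 1e-12 * max(scale, 1e-300):
        return GrangerResult(F=math.inf, p=0.0, T=T, degenerate=True)
    F = max(ssr_r - ssr_u, 0.0) / lag / (ssr_u / df_den)
    p = float(f_dist.sf(F, lag, df_den))
    return GrangerResult(F=F, p=p, T=T, degenerate=False)


def _granger_given_restricted(x, y, lag, ssr_r) -> GrangerResult:
    """As granger_test but reusing the per-(y, lag) restricted SSR."""
    N = len(x)
    T = N - lag
    df_den = T - 2 * lag - 1
    target = y[lag:]
    X_u = np.column_stack([np.ones(T), _lag_matrix(y, lag), _lag_matrix(x, lag)])
    ssr_u = _ssr(X_u, target)
    scale = float(np.sum((target - target.mean()) ** 2))
    if ssr_u <= 1e-12 * max(scale, 1e-300):
        return GrangerResult(F=math.inf, p=0.0, T=T, degenerate=True)
    F = max(ssr_r - ssr_u, 0.0) / lag / (ssr_u / df_den)
    return GrangerResult(F=F, p=float(f_dist.sf(F, lag, df_den)), T=T, degenerate=False)


def granger_all_pairs(
    series: StageSeries,
    lags=DEFAULT_LAGS,
    alpha: float = 0.05,
    fdr: str = "off",
) -> list[GrangerEdge]:
    """Run granger_test for every ordered feature pair and every lag.

    Both directions are tested independently; records with p < alpha are
    retained, each (pair, lag) on its own. A (pair, lag) that fails the
    degrees-of-freedom or constancy precondition is skipped and logged.
    With ``fdr='bh'`` the p-values are Benjamini-Hochberg adjusted per
    lag before thresholding.
    """
    data = {fid: series.values.loc[fid].to_numpy(float) for fid in series.features}
    ids = series.features
    N = series.values.shape[1]
    edges: list[GrangerEdge] = []
    for lag in lags:
        if N - 3 * lag - 1 < 1:  # residual df of the unrestricted model
            logger.info("skipping lag %d entirely: %d stages too short", lag, N)
            continue
        # restricted model depends only on the effect series: fit once per effect
        ssr_cache: dict[str, float] = {}
        candidates: list[GrangerEdge] = []
        for cause, effect in permutations(ids, 2):
            x, y = data[cause], data[effect]
            if np.ptp(y[lag:]) == 0 or np.ptp(_lag_matrix(x, lag), axis=0).max() == 0:
                logger.info(
                    "skipping %s -> %s at lag %d: constant block over fitted window",
                    cause, effect, lag,
                )
                continue
            if effect not in ssr_cache:
                ssr_cache[effect] = restricted_ssr(y, lag)
            res = _granger_given_restricted(x, y, lag, ssr_cache[effect])
            candidates.append(
                GrangerEdge(cause, effect, lag, res.F, res.p, res.T, res.degenerate)
            )
        if fdr == "bh" and candidates:
            adj = false_discovery_control([e.p for e in candidates], method="bh")
            candidates = [
                GrangerEdge(e.cause, e.effect, e.lag, e.F, float(q), e.T, e.degenerate)
                for e, q in zip(candidates, adj)
            ]
        edges.extend(e for e in candidates if e.p < alpha)
    return edges


def granger_clusters(
    model: ClusterModel, lags=DEFAULT_LAGS, alpha: float = 0.05, fdr: str = "off"
) -> list[GrangerEdge]:
    """Granger causality between k-means cluster centroid series."""
    centroids = model.centroids.rename(index=lambda c: f"C{c}")
    return granger_all_pairs(StageSeries(centroids, zscored=False), lags, alpha, fdr)


# --- network assembly ------------------------------------------------------


@dataclass
class GrangerNetwork:
    """Directed causality network with neighbor-degree statistics.

    Parallel edges (same ordered pair at different lags) stay distinct
    attributed edges, but collapse to a single adjacency for neighbor
    counting: ``neighbor_count`` is the number of distinct adjacent nodes
    regardless of direction; in/out degree count distinct predecessors /
    successors.
    """

    nodes: list[str]
    edges: list[GrangerEdge]
    neighbor_count: dict[str, int]
    in_degree: dict[str, int]
    out_degree: dict[str, int]
    mean_neighbors: float
    empty: bool = False


def build_network(edges: list[GrangerEdge]) -> GrangerNetwork:
    """Assemble significant edges into a network with degree statistics.

    Nodes are the ids appearing in at least one edge. The mean neighbor
    count equals 2 x (number of distinct unordered adjacent pairs) /
    (number of nodes); an empty edge list yields an empty network with
    mean 0, flagged.
    """
    nodes = sorted({e.cause for e in edges} | {e.effect for e in edges})
    if not nodes:
        return GrangerNetwork([], [], {}, {}, {}, 0.0, empty=True)
    neighbors: dict[str, set[str]] = {n: set() for n in nodes}
    preds: dict[str, set[str]] = {n: set() for n in nodes}
    succs: dict[str, set[str]] = {n: set() for n in nodes}
    for e in edges:
        neighbors[e.cause].add(e.effect)
        neighbors[e.effect].add(e.cause)
        succs[e.cause].add(e.effect)
        preds[e.effect].add(e.cause)
    neighbor_count = {n: len(neighbors[n]) for n in nodes}
    mean_neighbors = sum(neighbor_count.values()) / len(nodes)
    return GrangerNetwork(
        nodes=nodes,
        edges=list(edges),
        neighbor_count=neighbor_count,
        in_degree={n: len(preds[n]) for n in nodes},
        out_degree={n: len(succs[n]) for n in nodes},
        mean_neighbors=mean_neighbors,
    )


def hub_ranking(network: GrangerNetwork, top_n: int | None = None) -> list[str]:
    """Nodes by descending neighbor count; ties broken lexicographically."""
    if not network.nodes:
        raise ValueError("empty network has no hubs")
    ranked = sorted(network.nodes, key=lambda n: (-network.neighbor_count[n], n))
    return ranked if top_n is None else ranked[:top_n]


def node_table(network: GrangerNetwork) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "neighbors": pd.Series(network.neighbor_count),
            "in_degree": pd.Series(network.in_degree),
            "out_degree": pd.Series(network.out_degree),
        }
    ).loc[network.nodes]
    df.index.name = "node"
    return df
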