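"""Per-city co-abundance networks from Pearson correlations of taxa.

For each city a level-by-level Pearson correlation matrix of the normalized
profiles is thresholded on absolute value (strict ``>``); taxa that keep at
least one edge become nodes.  Thresholds are calibrated per city so networks
have comparable node counts, and high-degree taxa (hubs) are compared across
cities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import PreconditionError
from .preprocess import NormalizedTable

logger = logging.getLogger(__name__)

__all__ = [
    "CoAbundanceNetwork",
    "correlation_matrix",
    "threshold_network",
    "calibrate_threshold",
    "network_summary",
]


@dataclass
class CoAbundanceNetwork:
    city: str
    rank: str
    graph: nx.Graph            # nodes = levels with >= 1 retained edge
    threshold: float

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"city": self.city, "rank": self.rank, "level_a": a, "level_b": b,
             "r": d["weight"]}
            for a, b, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows,
                            columns=["city", "rank", "level_a", "level_b", "r"])


def correlation_matrix(norm: NormalizedTable, city: str) -> pd.DataFrame:
    """Pearson correlations between levels over one city's samples.

    Constant levels have undefined correlations and are excluded with a
    warning.  Requires at least 3 samples in the city.
    """
    cols = list(norm.meta.index[norm.meta["city"] == city])
    if len(cols) < 3:
        raise PreconditionError(
            f"city {city!r} has {len(cols)} samples; need >= 3"
        )
    block = norm.values[cols]
    std = block.std(axis=1, ddof=1)
    constant = list(block.index[(std == 0) | std.isna()])
    if constant:
        logger.warning("city %s: dropping %d constant levels: %s",
                       city, len(constant), constant[:5])
        block = block.drop(index=constant)
    corr = np.corrcoef(block.to_numpy(dtype=float))
    corr = (corr + corr.T) / 2.0        # corrcoef can be off-symmetric by 1 ulp
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=block.index, columns=block.index)


def threshold_network(corr: pd.DataFrame, threshold: float,
                      city: str = "", rank: str = "") -> CoAbundanceNetwork:
    """Keep edges with ``|r| > threshold`` (strict); drop isolated levels."""
    if not 0 <= threshold < 1:
        raise PreconditionError("threshold must lie in [0, 1)")
    levels = list(corr.index)
    r = corr.to_numpy()
    graph = nx.Graph()
    n = len(levels)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(r[i, j]) > threshold:
                graph.add_edge(levels[i], levels[j], weight=float(r[i, j]))
    return CoAbundanceNetwork(city=city, rank=rank, graph=graph,
                              threshold=float(threshold))


def _node_count_at(abs_r: np.ndarray, threshold: float) -> int:
    keep = abs_r > threshold
    return int((keep.any(axis=1)).sum())


def calibrate_threshold(corr: pd.DataFrame, target_nodes: int,
                        tolerance: int | None = None) -> float:
    """Largest threshold whose network keeps ~``target_nodes`` nodes.

    Searches the sorted unique off-diagonal ``|r|`` values (node count is a
    step function of the threshold, non-increasing).  Returns the largest
    threshold whose node count is within ``tolerance`` of the target
    (default: 10% of target, rounded); when unattainable, returns the
    closest-achieving threshold with a warning.
    """
    if target_nodes < 2:
        raise PreconditionError("target_nodes must be >= 2")
    if target_nodes > corr.shape[0]:
        raise PreconditionError("target_nodes exceeds number of levels")
    if tolerance is None:
        tolerance = max(1, round(0.1 * target_nodes))
    abs_r = np.abs(corr.to_numpy()).copy()
    np.fill_diagonal(abs_r, 0.0)
    uniq = np.unique(abs_r[np.triu_indices_from(abs_r, k=1)])
    # candidate thresholds: just below 0 is impossible, so 0 plus each unique
    # |r| value (a threshold equal to a value excludes that value's edges)
    candidates = np.concatenate(([0.0], uniq[uniq < 1.0]))
    best, best_gap = None, None
    within = []
    for t in candidates:
        nodes = _node_count_at(abs_r, t)
        gap = abs(nodes - target_nodes)
        if gap <= tolerance:
            within.append(t)
        if best_gap is None or gap < best_gap or (gap == best_gap and t > best):
            best, best_gap = t, gap
    if within:
        return float(max(within))
    logger.warning(
        "no threshold reaches %d +/- %d nodes; closest misses by %d",
        target_nodes, tolerance, best_gap,
    )
    return float(best)


def network_summary(networks: dict, top_k: int = 3) -> dict:
    """Cross-city topology summary: sizes, degree counts, hubs, shared hubs.

    Hubs are the ``top_k`` highest-degree nodes per city, ties broken
    lexicographically; shared hubs are the intersection of the per-city hub
    sets.
    """
    if not networks:
        raise PreconditionError("need >= 1 network")
    per_city = {}
    hub_sets = []
    for city, net in networks.items():
        degrees = dict(net.graph.degree())
        ordered = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))
        hubs = [name for name, _ in ordered[:top_k]]
        per_city[city] = {
            "n_nodes": net.n_nodes,
            "n_edges": net.n_edges,
            "threshold": net.threshold,
            "degree": degrees,
            "hubs": hubs,
        }
        hub_sets.append(set(hubs))
    shared = set.intersection(*hub_sets) if hub_sets else set()
    return {"per_city": per_city, "shared_hubs": sorted(shared)}
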