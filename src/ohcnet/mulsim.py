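"""Cross-layer structural similarity.

Three complementary views: multiplexity counts (how many unordered pairs are
connected in exactly k layers), Spearman rank correlations of per-node in-
or out-degree between layers, and Jaccard overlap of the directed edge sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .netbuild import MultirelationalNetwork
from .synth import CHANNELS
from .topo import UndefinedMetricError


class InsufficientDataError(ValueError):
    pass


def connected_pairs(net: nx.DiGraph) -> set[frozenset]:
    """Unordered pairs with at least one directed edge either way."""
    return {frozenset((u, v)) for u, v in net.edges}


def multiplexity_counts(multinet: MultirelationalNetwork) -> dict[int, int]:
    """Number of unordered pairs connected in exactly k ∈ {1..4} layers."""
    membership: dict[frozenset, int] = {}
    for channel in CHANNELS:
        for pair in connected_pairs(multinet.layer(channel)):
            membership[pair] = membership.get(pair, 0) + 1
    counts = {k: 0 for k in range(1, len(CHANNELS) + 1)}
    for k in membership.values():
        counts[k] += 1
    return counts


def _degree_vectors(
    netA: nx.DiGraph, netB: nx.DiGraph, side: str, scope: str
) -> tuple[np.ndarray, np.ndarray]:
    if side not in ("in", "out"):
        raise ValueError(f"side must be 'in' or 'out', got {side!r}")
    if scope == "union":
        nodes = sorted(set(netA.nodes) | set(netB.nodes))
    elif scope == "intersection":
        nodes = sorted(set(netA.nodes) & set(netB.nodes))
    else:
        raise ValueError(f"unknown node scope {scope!r}")

    def deg(net, node):
        if node not in net:
            return 0
        return net.in_degree(node) if side == "in" else net.out_degree(node)

    a = np.array([deg(netA, n) for n in nodes], dtype=float)
    b = np.array([deg(netB, n) for n in nodes], dtype=float)
    return a, b


def degree_rank_correlation(
    netA: nx.DiGraph,
    netB: nx.DiGraph,
    side: str = "in",
    scope: str = "union",
) -> tuple[float, float]:
    """Spearman rho (average ranks on ties) and its t-approximation p-value
    between per-node degrees of two layers.

    Default scope is the union of both layers' active nodes, with a degree of
    zero filled in for the layer a node is absent from — the only scope
    defined for every layer pair.
    """
    a, b = _degree_vectors(netA, netB, side, scope)
    if len(a) < 3:
        raise InsufficientDataError(
            f"need at least 3 nodes in scope, got {len(a)}"
        )
    result = stats.spearmanr(a, b)
    return float(result.statistic), float(result.pvalue)


def edge_jaccard(netA: nx.DiGraph, netB: nx.DiGraph) -> float:
    """|E_A ∩ E_B| / |E_A ∪ E_B| over directed (ordered-pair) edge sets."""
    ea, eb = set(netA.edges), set(netB.edges)
    union = ea | eb
    if not union:
        raise UndefinedMetricError("Jaccard undefined when both edge sets are empty")
    return len(ea & eb) / len(union)


@dataclass
class SimilarityReport:
    multiplexity: dict[int, int]
    spearman_in: dict[str, dict[str, float | None]]
    spearman_in_p: dict[str, dict[str, float | None]]
    spearman_out: dict[str, dict[str, float | None]]
    spearman_out_p: dict[str, dict[str, float | None]]
    jaccard: dict[str, dict[str, float | None]]
    scope: str

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        payload = {"schema_version": 1, **self.to_dict()}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    def matrix_frame(self, which: str) -> pd.DataFrame:
        data = getattr(self, which)
        return pd.DataFrame(data).reindex(index=list(CHANNELS), columns=list(CHANNELS))


def similarity_report(
    multinet: MultirelationalNetwork, scope: str = "union"
) -> SimilarityReport:
    """All pairwise layer similarities; undefined cells (degenerate layers)
    are None."""
    def blank():
        return {a: {b: (1.0 if a == b else None) for b in CHANNELS} for a in CHANNELS}

    rho_in, p_in, rho_out, p_out, jac = blank(), blank(), blank(), blank(), blank()
    for a, b in combinations(CHANNELS, 2):
        na, nb = multinet.layer(a), multinet.layer(b)
        for side, rho_m, p_m in (("in", rho_in, p_in), ("out", rho_out, p_out)):
            try:
                rho, p = degree_rank_correlation(na, nb, side=side, scope=scope)
            except InsufficientDataError:
                rho, p = None, None
            rho_m[a][b] = rho_m[b][a] = rho
            p_m[a][b] = p_m[b][a] = p
        try:
            j = edge_jaccard(na, nb)
        except UndefinedMetricError:
            j = None
        jac[a][b] = jac[b][a] = j
    for c in CHANNELS:
        p_in[c][c] = p_out[c][c] = 0.0
        if multinet.layer(c).number_of_edges() == 0:
            jac[c][c] = None
    return SimilarityReport(
        multiplexity=multiplexity_counts(multinet),
        spearman_in=rho_in,
        spearman_in_p=p_in,
        spearman_out=rho_out,
        spearman_out_p=p_out,
        jaccard=jac,
        scope=scope,
    )
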