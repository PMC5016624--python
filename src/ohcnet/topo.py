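"""Topological characterization of one directed layer.

Conventions match the dyad-based bookkeeping of the analysis this package
implements: density divides the edge count by the ordered pairs among nodes
of degree > 0; reciprocity is the fraction of *connected dyads* (unordered
pairs with at least one tie) that are *mutual* (ties both ways), so that
mutual dyads = edges − connected dyads always holds; connectedness is
summarized by the largest strongly connected component (LSCC) and the mean
directed shortest-path length within it.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np

#: LSCCs above this size are path-sampled unless exact=True is forced.
SAMPLING_THRESHOLD = 20_000


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is empty (e.g. density on < 2 nodes)."""


def density_from_counts(n_nodes: int, n_edges: int) -> float:
    """E / (N·(N−1)) for a directed graph without self-loops."""
    if n_nodes < 2:
        raise UndefinedMetricError("density undefined for fewer than 2 nodes")
    return n_edges / (n_nodes * (n_nodes - 1))


def density(net: nx.DiGraph) -> float:
    return density_from_counts(net.number_of_nodes(), net.number_of_edges())


@dataclass(frozen=True)
class Reciprocity:
    mutual_dyads: int
    connected_dyads: int
    fraction: float


def reciprocity_from_counts(n_edges: int, connected_dyads: int) -> Reciprocity:
    """Dyad-based reciprocity from an edge count and a connected-dyad count.

    Every mutual dyad contributes two edges and every asymmetric dyad one,
    so mutual = edges − connected dyads.
    """
    if connected_dyads == 0:
        raise UndefinedMetricError("reciprocity undefined for an empty edge set")
    mutual = n_edges - connected_dyads
    return Reciprocity(mutual, connected_dyads, mutual / connected_dyads)


def reciprocity(net: nx.DiGraph) -> Reciprocity:
    if net.number_of_edges() == 0:
        raise UndefinedMetricError("reciprocity undefined for an empty edge set")
    connected = {frozenset((u, v)) for u, v in net.edges}
    mutual = sum(1 for u, v in net.edges if u < v and net.has_edge(v, u))
    return Reciprocity(mutual, len(connected), mutual / len(connected))


def largest_scc(net: nx.DiGraph) -> tuple[frozenset, float]:
    """Members of the largest strongly connected component and their share of
    the layer's nodes. Size ties break toward the component containing the
    lexicographically smallest member (degenerate but deterministic)."""
    if net.number_of_nodes() == 0:
        return frozenset(), 0.0
    sized: dict[int, list[set]] = {}
    for comp in nx.strongly_connected_components(net):
        sized.setdefault(len(comp), []).append(comp)
    best = min(sized[max(sized)], key=min)
    return frozenset(best), len(best) / net.number_of_nodes()


def mean_shortest_path_lscc(
    net: nx.DiGraph,
    sample_size: int | None = None,
    seed: int | None = None,
) -> float:
    """Mean directed shortest-path length over ordered pairs within the LSCC.

    Exact (breadth-first search from every member) unless ``sample_size`` is
    given and smaller than the LSCC, in which case BFS runs from a uniform
    sample of source nodes.
    """
    members, _ = largest_scc(net)
    if len(members) < 2:
        raise UndefinedMetricError("mean shortest path undefined for LSCC smaller than 2")
    sub = net.subgraph(members)
    nodes = sorted(members)
    if sample_size is not None and sample_size < len(nodes):
        rng = np.random.default_rng(seed)
        sources = [nodes[i] for i in rng.choice(len(nodes), size=sample_size, replace=False)]
    else:
        sources = nodes
    total = 0
    n_pairs = 0
    for src in sources:
        lengths = nx.single_source_shortest_path_length(sub, src)
        total += sum(lengths.values())  # src→src contributes 0
        n_pairs += len(nodes) - 1
    return total / n_pairs


@dataclass(frozen=True)
class DegreeHistograms:
    """Exact frequency tables keyed by degree value, over the layer's nodes.

    A node kept in the layer by incoming ties alone contributes out-degree 0,
    which is how read-only members surface in the out-degree table.
    """

    in_degree: dict[int, int]
    out_degree: dict[int, int]
    total_degree: dict[int, int]


def degree_histograms(net: nx.DiGraph) -> DegreeHistograms:
    return DegreeHistograms(
        in_degree=dict(Counter(d for _, d in net.in_degree())),
        out_degree=dict(Counter(d for _, d in net.out_degree())),
        total_degree=dict(Counter(d for _, d in net.degree())),
    )


@dataclass
class TopologyReport:
    channel: str
    n_nodes: int
    n_edges: int
    density: float | None
    connected_dyads: int
    mutual_dyads: int
    reciprocity: float | None
    lscc_size: int
    lscc_fraction: float
    mean_path_lscc: float | None
    mean_path_sampled: bool
    in_degree_hist: dict[int, int]
    out_degree_hist: dict[int, int]
    total_degree_hist: dict[int, int]

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        payload = {"schema_version": 1, **self.to_dict()}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def topology_report(
    net: nx.DiGraph,
    sample_size: int | None = None,
    seed: int | None = None,
    exact_paths: bool = False,
) -> TopologyReport:
    """Full per-layer summary. Undefined metrics on small/empty layers are
    reported as None rather than raising, so empty layers survive a run."""
    n, e = net.number_of_nodes(), net.number_of_edges()
    dens = density(net) if n >= 2 else None
    if e > 0:
        rec = reciprocity(net)
        connected, mutual, frac = rec.connected_dyads, rec.mutual_dyads, rec.fraction
    else:
        connected = mutual = 0
        frac = None
    members, lscc_frac = largest_scc(net)
    sampled = False
    mean_path = None
    if len(members) >= 2:
        if sample_size is None and not exact_paths and len(members) > SAMPLING_THRESHOLD:
            sample_size = 1000
        sampled = sample_size is not None and sample_size < len(members)
        mean_path = mean_shortest_path_lscc(net, sample_size=sample_size, seed=seed)
    hists = degree_histograms(net)
    return TopologyReport(
        channel=net.graph.get("channel", "NA"),
        n_nodes=n,
        n_edges=e,
        density=dens,
        connected_dyads=connected,
        mutual_dyads=mutual,
        reciprocity=frac,
        lscc_size=len(members),
        lscc_fraction=lscc_frac,
        mean_path_lscc=mean_path,
        mean_path_sampled=sampled,
        in_degree_hist=hists.in_degree,
        out_degree_hist=hists.out_degree,
        total_degree_hist=hists.total_degree,
    )
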