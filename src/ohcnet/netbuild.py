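"""Construct the four directed channel subnetworks and their aggregation.

Tie rule (information flow): a directed edge A→B means that B accessed
information contributed by A. For the public channels (blogs BL, message
boards MB, group discussions GD) an edge A→B exists iff B has at least one
access event on content authored by A in that channel; replies show up as
access events of their own, so a reply in the opposite direction creates the
reciprocating edge. For private messages (PM), an edge A→B exists iff B
*read* a message sent by A — delivery alone moves no information.

Each edge carries ``first_ts``, the earliest event establishing the tie.
Self-interactions (an author reading their own content) are discarded.
Construction is order-independent: the first-contact timestamp is a minimum
over qualifying events, so shuffling input rows changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .synth import CHANNELS, PUBLIC_CHANNELS, EventLog

FIRST_TS = "first_ts"


class UnknownChannelError(ValueError):
    pass


class DanglingContentError(ValueError):
    pass


def _add_tie(graph: nx.DiGraph, src: str, dst: str, ts: int) -> None:
    if src == dst:
        return
    if graph.has_edge(src, dst):
        if ts < graph[src][dst][FIRST_TS]:
            graph[src][dst][FIRST_TS] = ts
    else:
        graph.add_edge(src, dst, **{FIRST_TS: int(ts)})


def build_channel_network(log: EventLog, channel: str) -> nx.DiGraph:
    """Build one directed subnetwork. Nodes are exactly the users with at
    least one incident tie in the channel (degree > 0)."""
    if channel not in CHANNELS:
        raise UnknownChannelError(
            f"unknown channel token {channel!r}; expected one of {CHANNELS}"
        )
    graph = nx.DiGraph(channel=channel)
    if channel == "PM":
        read = log.pms[log.pms["read_ts"].notna()]
        for sender, recipient, ts in zip(
            read["sender_id"], read["recipient_id"], read["read_ts"]
        ):
            _add_tie(graph, sender, recipient, int(ts))
        return graph

    posts = log.creations[log.creations["channel"] == channel]
    author_of = dict(zip(posts["content_id"], posts["author_id"]))
    channel_of = dict(zip(log.creations["content_id"], log.creations["channel"]))
    for reader, cid, ts in zip(
        log.accesses["reader_id"], log.accesses["content_id"], log.accesses["ts"]
    ):
        if cid not in channel_of:
            raise DanglingContentError(f"access event references unknown content {cid!r}")
        if channel_of[cid] != channel:
            continue
        _add_tie(graph, author_of[cid], reader, int(ts))
    return graph


@dataclass
class MultirelationalNetwork:
    """The four channel layers plus their aggregated union view."""

    layers: dict[str, nx.DiGraph]
    aggregated: nx.DiGraph = field(init=False)

    def __post_init__(self) -> None:
        self.aggregated = aggregate_layers(self.layers)

    def layer(self, channel: str) -> nx.DiGraph:
        if channel not in self.layers:
            raise UnknownChannelError(f"unknown channel token {channel!r}")
        return self.layers[channel]


def aggregate_layers(layers: dict[str, nx.DiGraph]) -> nx.DiGraph:
    """Union of nodes and directed edges; edge timestamp is the minimum
    first-contact time across layers."""
    agg = nx.DiGraph(channel="AGG")
    for graph in layers.values():
        agg.add_nodes_from(graph.nodes)
        for src, dst, data in graph.edges(data=True):
            _add_tie(agg, src, dst, data[FIRST_TS])
    return agg


def build_multinet(log: EventLog) -> MultirelationalNetwork:
    """Build all four layers and the aggregated network from one log.

    An empty log yields an empty network; malformed logs (unknown channel
    tokens, accesses to content never created) raise.
    """
    bad = set(log.creations["channel"]) - set(PUBLIC_CHANNELS)
    if bad:
        raise UnknownChannelError(f"unknown channel tokens in creations: {sorted(bad)}")
    return MultirelationalNetwork(
        layers={c: build_channel_network(log, c) for c in CHANNELS}
    )


def write_edgelist(graph: nx.DiGraph, path: str | Path) -> None:
    """Timestamped edge list as TSV: src, dst, channel, first_ts."""
    channel = graph.graph.get("channel", "NA")
    rows = sorted(
        (src, dst, channel, data[FIRST_TS]) for src, dst, data in graph.edges(data=True)
    )
    frame = pd.DataFrame(rows, columns=["src", "dst", "channel", "first_ts"])
    frame.to_csv(path, sep="\t", index=False)


def read_edgelist(path: str | Path) -> nx.DiGraph:
    frame = pd.read_csv(path, sep="\t", dtype={"src": str, "dst": str})
    channels = set(frame["channel"])
    if len(channels) > 1:
        raise ValueError(f"edge list mixes channels: {sorted(channels)}")
    graph = nx.DiGraph(channel=channels.pop() if len(channels) == 1 else "NA")
    for src, dst, ts in zip(frame["src"], frame["dst"], frame["first_ts"]):
        graph.add_edge(src, dst, **{FIRST_TS: int(ts)})
    return graph
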