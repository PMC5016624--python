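"""Temporal coevolution of ties across layers.

For every unordered pair of users connected anywhere, the pair's history is
reduced to the sequence of distinct layers ordered by the pair-level
first-tie time (the earliest first-contact timestamp over both directions in
each layer). From those sequences come the share of first ties each layer
hosts, the conditional probabilities of a second and third tie given the
starting layer, and the most common 2- and 3-layer sequences.

Analysis is pair-level and direction-agnostic, which makes the first-tie
denominators sum exactly to the multiplexity pair total.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

from .netbuild import FIRST_TS, MultirelationalNetwork
from .synth import CHANNELS

logger = logging.getLogger(__name__)

#: ties on equal first-tie timestamps break by this fixed layer order
DEFAULT_LAYER_ORDER = tuple(CHANNELS)


@dataclass(frozen=True)
class PairTimeline:
    """One connected pair's layer-formation history, earliest first."""

    pair: tuple[str, str]
    events: tuple[tuple[int, str], ...]  # (first_ts, channel), sorted

    @property
    def sequence(self) -> tuple[str, ...]:
        return tuple(channel for _, channel in self.events)


def pair_timelines(
    multinet: MultirelationalNetwork,
    layer_order: tuple[str, ...] = DEFAULT_LAYER_ORDER,
) -> list[PairTimeline]:
    """One timeline per pair connected in at least one layer.

    Equal first-tie timestamps across layers (possible only in logs without
    globally unique timestamps) break by ``layer_order``; the number of
    affected pairs is logged.
    """
    rank = {channel: i for i, channel in enumerate(layer_order)}
    first: dict[tuple[str, str], dict[str, int]] = {}
    for channel in CHANNELS:
        for u, v, data in multinet.layer(channel).edges(data=True):
            if FIRST_TS not in data:
                raise ValueError(f"edge {u!r}->{v!r} in {channel} has no first_ts")
            pair = (u, v) if u < v else (v, u)
            times = first.setdefault(pair, {})
            ts = data[FIRST_TS]
            if channel not in times or ts < times[channel]:
                times[channel] = ts

    timelines = []
    n_tiebreaks = 0
    for pair in sorted(first):
        times = first[pair]
        stamps = list(times.values())
        if len(set(stamps)) != len(stamps):
            n_tiebreaks += 1
        events = tuple(sorted(
            ((ts, channel) for channel, ts in times.items()),
            key=lambda e: (e[0], rank[e[1]]),
        ))
        timelines.append(PairTimeline(pair=pair, events=events))
    if n_tiebreaks:
        logger.info("layer-order tie-break applied to %d pairs", n_tiebreaks)
    return timelines


@dataclass
class CoevolutionReport:
    n_pairs: int
    first_counts: dict[str, int]
    p_first: dict[str, float]
    second_counts: dict[str, int]          # timelines of length >= 2 per start
    p_second: dict[str, float]
    third_counts: dict[str, int]           # timelines of length >= 3 per start
    p_third: dict[str, float]
    top_2tie: dict[str, dict]              # per start: sequence, count, share
    top_3tie: dict[str, dict]
    sequence_counts_2: dict[str, dict[str, int]] = field(default_factory=dict)
    sequence_counts_3: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        payload = {"schema_version": 1, **self.to_dict()}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _seq_token(sequence: tuple[str, ...]) -> str:
    return "→".join(sequence)  # e.g. "BL→MB→GD"


def coevolution_report(timelines: list[PairTimeline]) -> CoevolutionReport:
    """Descriptive probabilities of first-tie hosting and subsequent ties.

    Top-sequence shares use all timelines starting in the layer as
    denominator; raw counts for every observed 2- and 3-prefix are retained
    so any alternative convention can be recomputed.
    """
    if not timelines:
        raise ValueError("coevolution report requires at least one pair timeline")
    n = len(timelines)
    first = {c: 0 for c in CHANNELS}
    second = {c: 0 for c in CHANNELS}
    third = {c: 0 for c in CHANNELS}
    seq2: dict[str, dict[str, int]] = {c: {} for c in CHANNELS}
    seq3: dict[str, dict[str, int]] = {c: {} for c in CHANNELS}
    for tl in timelines:
        seq = tl.sequence
        start = seq[0]
        first[start] += 1
        if len(seq) >= 2:
            second[start] += 1
            token = _seq_token(seq[:2])
            seq2[start][token] = seq2[start].get(token, 0) + 1
        if len(seq) >= 3:
            third[start] += 1
            token = _seq_token(seq[:3])
            seq3[start][token] = seq3[start].get(token, 0) + 1

    def top(table: dict[str, int], denom: int) -> dict | None:
        if not table or denom == 0:
            return None
        token = min(table, key=lambda t: (-table[t], t))
        return {"sequence": token, "count": table[token], "share": table[token] / denom}

    return CoevolutionReport(
        n_pairs=n,
        first_counts=first,
        p_first={c: first[c] / n for c in CHANNELS},
        second_counts=second,
        p_second={c: second[c] / first[c] if first[c] else 0.0 for c in CHANNELS},
        third_counts=third,
        p_third={c: third[c] / first[c] if first[c] else 0.0 for c in CHANNELS},
        top_2tie={c: top(seq2[c], first[c]) for c in CHANNELS},
        top_3tie={c: top(seq3[c], first[c]) for c in CHANNELS},
        sequence_counts_2=seq2,
        sequence_counts_3=seq3,
    )
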