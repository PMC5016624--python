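import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ohcnet import EventLog, FIRST_TS, SynthConfig, build_multinet, generate_event_log
from ohcnet.synth import _empty_pms


def make_log(creations=(), accesses=(), pms=()):
    """Build an EventLog from plain tuples.

    creations: (author, content_id, channel, ts)
    accesses:  (reader, content_id, ts)
    pms:       (sender, recipient, message_id, send_ts, read_ts_or_None)
    """
    cre = pd.DataFrame(list(creations), columns=["author_id", "content_id", "channel", "ts"])
    acc = pd.DataFrame(list(accesses), columns=["reader_id", "content_id", "ts"])
    if pms:
        pm = pd.DataFrame(list(pms), columns=["sender_id", "recipient_id", "message_id", "send_ts", "read_ts"])
        pm["read_ts"] = pm["read_ts"].astype("Int64")
    else:
        pm = _empty_pms()
    if cre.empty:
        cre = cre.astype({"ts": "int64"}) if "ts" in cre else cre
    return EventLog(creations=cre, accesses=acc, pms=pm)


def random_digraph(n, p, seed, with_ts=True):
    g = nx.gnp_random_graph(n, p, seed=seed, directed=True)
    if with_ts:
        for i, (u, v) in enumerate(sorted(g.edges())):
            g[u][v][FIRST_TS] = i + 1
    return g


@pytest.fixture(scope="session")
def tiny_log():
    """A hand-traceable log: blog post + comment + comment-read, one message
    board read, one read and one unread private message."""
    return make_log(
        creations=[
            ("A", "c1", "BL", 1),   # A's blog post
            ("B", "c2", "BL", 3),   # B's comment on it
            ("C", "c3", "MB", 5),   # C's message-board post
        ],
        accesses=[
            ("B", "c1", 2),         # B reads A's post  -> BL edge A->B @2
            ("A", "c2", 4),         # A reads B's comment -> BL edge B->A @4
            ("A", "c3", 6),         # A reads C's post  -> MB edge C->A @6
        ],
        pms=[
            ("A", "B", "m1", 7, 8),     # read -> PM edge A->B @8
            ("B", "A", "m2", 9, None),  # unread -> no edge
        ],
    )


@pytest.fixture(scope="session")
def default_config():
    return SynthConfig(n_users=500, n_trial_users=300, seed=11)


@pytest.fixture(scope="session")
def default_log(default_config):
    return generate_event_log(default_config)


@pytest.fixture(scope="session")
def default_multinet(default_log):
    return build_multinet(default_log)
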