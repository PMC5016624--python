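"""Synthetic online-community event logs and trial outcomes.

Emulates the statistical structure of a smoking-cessation online health
community: four communication channels (blogs BL, message boards MB, group
discussions GD, private messages PM), heavy-tailed degree distributions
driven by popularity-biased reading, a large read-only (lurker) cohort with
zero out-degree, one-way welcome messages that depress private-message
reciprocity, cross-channel coupling of dyads, and a trial outcome table in
which abstinence probability rises with a user's aggregated network degree
while a sizeable fraction of participants never answer the follow-up survey.

Timestamps are integer event counters: every downstream computation depends
only on event order, so wall-clock simulation would add nothing but
parsing. Counters are globally unique, which makes the temporal order total.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

PUBLIC_CHANNELS = ("BL", "MB", "GD")
CHANNELS = ("BL", "MB", "GD", "PM")

CREATION_COLUMNS = ["author_id", "content_id", "channel", "ts"]
ACCESS_COLUMNS = ["reader_id", "content_id", "ts"]
PM_COLUMNS = ["sender_id", "recipient_id", "message_id", "send_ts", "read_ts"]
OUTCOME_COLUMNS = ["user_id", "responded", "abstinent"]

# Probability a delivered private message is eventually opened. Unread
# messages are logged but create no tie downstream.
_PM_READ_PROB = 0.9
_N_GREETERS = 5


class ConfigError(ValueError):
    """A SynthConfig field is out of its admissible range."""


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults are the package's study conditions.

    Rates are means of Poisson counts. ``read_attachment`` is the exponent of
    the popularity bias: a read picks a post with probability proportional to
    ``(1 + author's readership in that channel) ** read_attachment``.
    """

    n_users: int = 500
    n_trial_users: int = 300
    activity_rate: float = 3.0      # mean posts per active user per public channel
    read_rate: float = 6.0          # mean reads per visiting user per public channel
    read_attachment: float = 1.0
    reader_only_frac: float = 0.40  # never posts or sends messages
    never_visit_frac: float = 0.15  # registered but no community activity at all
    welcome_prob: float = 0.9
    pm_rate: float = 0.3            # mean organic private messages per active user
    coupling: float = 0.25
    abstinence_intercept: float = -2.9
    abstinence_slope: float = 0.55
    nonresponse_rate: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users <= 0:
            raise ConfigError("n_users must be a positive count")
        if not 0 <= self.n_trial_users <= self.n_users:
            raise ConfigError("n_trial_users must satisfy 0 <= n_trial_users <= n_users")
        for name in ("activity_rate", "read_rate", "pm_rate", "read_attachment"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        for name in (
            "reader_only_frac",
            "never_visit_frac",
            "welcome_prob",
            "coupling",
            "nonresponse_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")


@dataclass
class EventLog:
    """Timestamped interaction records: content creations, content accesses,
    and private messages (with optional read time)."""

    creations: pd.DataFrame
    accesses: pd.DataFrame
    pms: pd.DataFrame

    def validate(self) -> None:
        """Check referential integrity and temporal sanity; raise on failure."""
        known = set(self.creations["content_id"])
        dangling = set(self.accesses["content_id"]) - known
        if dangling:
            raise ValueError(f"access events reference unknown content ids: {sorted(dangling)[:5]}")
        bad_channels = set(self.creations["channel"]) - set(PUBLIC_CHANNELS)
        if bad_channels:
            raise ValueError(f"unknown channel tokens: {sorted(bad_channels)}")
        read = self.pms["read_ts"].dropna()
        if (read < self.pms.loc[read.index, "send_ts"]).any():
            raise ValueError("private message read before it was sent")
        post_ts = self.creations.set_index("content_id")["ts"]
        if (self.accesses["ts"].to_numpy()
                < post_ts.reindex(self.accesses["content_id"]).to_numpy()).any():
            raise ValueError("content accessed before it was created")
        all_ts = np.concatenate([
            self.creations["ts"].to_numpy(dtype=np.int64),
            self.accesses["ts"].to_numpy(dtype=np.int64),
            self.pms["send_ts"].to_numpy(dtype=np.int64),
            read.to_numpy(dtype=np.int64),
        ])
        if len(np.unique(all_ts)) != len(all_ts):
            raise ValueError("timestamps are not unique; temporal order is ambiguous")

    def is_empty(self) -> bool:
        return self.creations.empty and self.accesses.empty and self.pms.empty

    def user_ids(self) -> set[str]:
        """Every user id appearing anywhere in the log."""
        return (
            set(self.creations["author_id"])
            | set(self.accesses["reader_id"])
            | set(self.pms["sender_id"])
            | set(self.pms["recipient_id"])
        )

    def to_csv_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.creations.to_csv(directory / "creations.csv", index=False)
        self.accesses.to_csv(directory / "accesses.csv", index=False)
        self.pms.to_csv(directory / "pm.csv", index=False)

    @classmethod
    def from_csv_dir(cls, directory: str | Path) -> "EventLog":
        directory = Path(directory)
        for name in ("creations.csv", "accesses.csv", "pm.csv"):
            if not (directory / name).exists():
                raise FileNotFoundError(f"missing event-log file: {directory / name}")
        creations = pd.read_csv(directory / "creations.csv", dtype={"ts": np.int64})
        accesses = pd.read_csv(directory / "accesses.csv", dtype={"ts": np.int64})
        pms = pd.read_csv(directory / "pm.csv", dtype={"send_ts": np.int64, "read_ts": "Int64"})
        if pms.empty:
            pms = _empty_pms()
        return cls(creations=creations, accesses=accesses, pms=pms)


def _empty_creations() -> pd.DataFrame:
    return pd.DataFrame({
        "author_id": pd.Series(dtype=str),
        "content_id": pd.Series(dtype=str),
        "channel": pd.Series(dtype=str),
        "ts": pd.Series(dtype=np.int64),
    })


def _empty_accesses() -> pd.DataFrame:
    return pd.DataFrame({
        "reader_id": pd.Series(dtype=str),
        "content_id": pd.Series(dtype=str),
        "ts": pd.Series(dtype=np.int64),
    })


def _empty_pms() -> pd.DataFrame:
    return pd.DataFrame({
        "sender_id": pd.Series(dtype=str),
        "recipient_id": pd.Series(dtype=str),
        "message_id": pd.Series(dtype=str),
        "send_ts": pd.Series(dtype=np.int64),
        "read_ts": pd.Series(dtype="Int64"),
    })


def _user_id(i: int) -> str:
    return f"u{i:05d}"


class _Community:
    """Mutable generation state shared across phases."""

    def __init__(self, config: SynthConfig):
        ss = np.random.SeedSequence(config.seed)
        # One independent stream per phase so that changing one parameter
        # (e.g. coupling) leaves every other phase's draws untouched; this is
        # what makes the cross-layer coupling monotone under a common seed.
        (self.rng_role, self.rng_welcome, self.rng_posts, self.rng_reads,
         self.rng_pm, self.rng_couple, _) = map(np.random.default_rng, ss.spawn(7))
        self.config = config
        self.ts = 0
        self.content_seq = 0
        self.message_seq = 0
        self.creations: list[tuple[str, str, str, int]] = []
        self.accesses: list[tuple[str, str, int]] = []
        self.pms: list[tuple[str, str, str, int, int | None]] = []
        # per channel: posts as parallel lists, author readership counters
        self.posts: dict[str, list[tuple[str, str]]] = {c: [] for c in PUBLIC_CHANNELS}
        self.readership: dict[str, dict[str, set[str]]] = {c: {} for c in PUBLIC_CHANNELS}

    def next_ts(self) -> int:
        self.ts += 1
        return self.ts

    def add_post(self, author: str, channel: str) -> str:
        self.content_seq += 1
        cid = f"c{self.content_seq:06d}"
        self.creations.append((author, cid, channel, self.next_ts()))
        self.posts[channel].append((cid, author))
        return cid

    def add_access(self, reader: str, content_id: str, author: str, channel: str) -> None:
        self.accesses.append((reader, content_id, self.next_ts()))
        self.readership[channel].setdefault(author, set()).add(reader)

    def add_pm(self, sender: str, recipient: str, read: bool) -> None:
        self.message_seq += 1
        mid = f"m{self.message_seq:06d}"
        send_ts = self.next_ts()
        read_ts = self.next_ts() if read else None
        self.pms.append((sender, recipient, mid, send_ts, read_ts))


def generate_event_log(config: SynthConfig) -> EventLog:
    """Simulate the community and return its full event log.

    Phases run in a fixed order on a shared integer clock: user arrival with
    welcome messages, content posting, popularity-biased reading, organic
    private messaging, and finally cross-channel duplication of existing
    dyads at rate ``coupling``.
    """
    state = _Community(config)
    users = [_user_id(i) for i in range(config.n_users)]

    u = state.rng_role.random(config.n_users)
    # roles are carved out of one uniform draw per user: visitors split into
    # active contributors and read-only members; the rest never visit
    never_visit = u < config.never_visit_frac
    reader_only = ~never_visit & (
        u < config.never_visit_frac + (1 - config.never_visit_frac) * config.reader_only_frac
    )
    active = [uid for uid, nv, ro in zip(users, never_visit, reader_only) if not nv and not ro]
    readers = [uid for uid, nv in zip(users, never_visit) if not nv]
    greeters = active[:_N_GREETERS]

    _phase_welcome(state, users, set(active), greeters, never_visit)
    _phase_posts(state, active)
    _phase_reads(state, readers)
    _phase_organic_pm(state, active, readers)
    _phase_coupling(state, set(active))

    creations = pd.DataFrame(state.creations, columns=CREATION_COLUMNS) \
        if state.creations else _empty_creations()
    accesses = pd.DataFrame(state.accesses, columns=ACCESS_COLUMNS) \
        if state.accesses else _empty_accesses()
    if state.pms:
        pms = pd.DataFrame(state.pms, columns=PM_COLUMNS)
        pms["read_ts"] = pms["read_ts"].astype("Int64")
    else:
        pms = _empty_pms()
    creations["ts"] = creations["ts"].astype(np.int64)
    accesses["ts"] = accesses["ts"].astype(np.int64)
    log = EventLog(creations=creations, accesses=accesses, pms=pms)
    log.validate()
    return log


def _phase_welcome(state, users, active, greeters, never_visit) -> None:
    """Each arriving visitor may receive a one-way welcome PM from a greeter;
    only active recipients ever reply, with probability ``coupling``."""
    cfg = state.config
    for uid, nv in zip(users, never_visit):
        # draw unconditionally so the stream is identical across parameter values
        u_welcome = state.rng_welcome.random()
        greeter_pick = state.rng_welcome.integers(0, max(len(greeters), 1))
        u_reply = state.rng_welcome.random()
        if nv or not greeters or uid in greeters:
            continue
        if u_welcome >= cfg.welcome_prob:
            continue
        greeter = greeters[greeter_pick]
        state.add_pm(greeter, uid, read=True)
        if uid in active and u_reply < cfg.coupling:
            state.add_pm(uid, greeter, read=True)


def _phase_posts(state, active) -> None:
    for channel in PUBLIC_CHANNELS:
        for uid in active:
            for _ in range(state.rng_posts.poisson(state.config.activity_rate)):
                state.add_post(uid, channel)


def _phase_reads(state, readers) -> None:
    """Visitors read posts; choice is popularity-biased: weight of a post is
    (1 + distinct readers its author already has in the channel) ** alpha."""
    cfg = state.config
    requests: list[tuple[str, str]] = []
    for channel in PUBLIC_CHANNELS:
        for uid in readers:
            requests.extend((uid, channel) for _ in range(state.rng_reads.poisson(cfg.read_rate)))
    order = state.rng_reads.permutation(len(requests))
    for idx in order:
        reader, channel = requests[idx]
        posts = state.posts[channel]
        if not posts:
            continue
        counts = state.readership[channel]
        weights = np.array(
            [(1.0 + len(counts.get(author, ()))) ** cfg.read_attachment
             for _, author in posts]
        )
        for j, (_, author) in enumerate(posts):
            if author == reader:
                weights[j] = 0.0
        total = weights.sum()
        if total <= 0:
            continue
        pick = np.searchsorted(np.cumsum(weights), state.rng_reads.random() * total, side="right")
        pick = min(pick, len(posts) - 1)
        cid, author = posts[pick]
        state.add_access(reader, cid, author, channel)


def _phase_organic_pm(state, active, readers) -> None:
    cfg = state.config
    pool = [uid for uid in readers]
    for uid in active:
        for _ in range(state.rng_pm.poisson(cfg.pm_rate)):
            target_pick = state.rng_pm.integers(0, len(pool))
            u_read = state.rng_pm.random()
            target = pool[target_pick]
            if target == uid:
                continue
            state.add_pm(uid, target, read=u_read < _PM_READ_PROB)


def _connected_pairs(state) -> list[tuple[str, str]]:
    pairs: set[tuple[str, str]] = set()
    post_author = {cid: (author, channel)
                   for channel in PUBLIC_CHANNELS
                   for cid, author in state.posts[channel]}
    for reader, cid, _ in state.accesses:
        author, _channel = post_author[cid]
        if author != reader:
            pairs.add(tuple(sorted((author, reader))))
    for sender, recipient, _, _, read_ts in state.pms:
        if read_ts is not None and sender != recipient:
            pairs.add(tuple(sorted((sender, recipient))))
    return sorted(pairs)


def _phase_coupling(state, active) -> None:
    """Each connected dyad interacts again in another (public) channel with
    probability ``coupling``: one member reads — creating it first if needed —
    a post by the dyad's active member there."""
    cfg = state.config
    for a, b in _connected_pairs(state):
        u = state.rng_couple.random()
        channel_pick = state.rng_couple.integers(0, len(PUBLIC_CHANNELS))
        side_pick = state.rng_couple.integers(0, 2)
        if u >= cfg.coupling:
            continue
        candidates = [x for x in (a, b) if x in active]
        if not candidates:
            continue
        author = candidates[side_pick % len(candidates)]
        reader = b if author == a else a
        channel = PUBLIC_CHANNELS[channel_pick]
        own = [(cid, au) for cid, au in state.posts[channel] if au == author]
        cid = own[0][0] if own else state.add_post(author, channel)
        state.add_access(reader, cid, author, channel)


@dataclass
class OutcomeTable:
    """Trial outcome rows (user_id, responded, abstinent) plus the ground
    truth used to generate them, kept for recovery tests."""

    table: pd.DataFrame
    true_intercept: float = 0.0
    true_slope: float = 0.0
    latent_abstinent: pd.Series | None = None

    def validate(self) -> None:
        bad = self.table["abstinent"] & ~self.table["responded"]
        if bad.any():
            raise ValueError("abstinent=True recorded for a survey nonresponder")

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "OutcomeTable":
        table = pd.read_csv(path, dtype={"user_id": str})
        table["responded"] = table["responded"].astype(bool)
        table["abstinent"] = table["abstinent"].astype(bool)
        out = cls(table=table)
        out.validate()
        return out


def generate_outcomes(log: EventLog, config: SynthConfig) -> OutcomeTable:
    """Draw trial outcomes for the first ``n_trial_users`` registered users.

    Latent abstinence follows a logistic model on log(1 + aggregated total
    degree); nonresponders are flagged at ``nonresponse_rate`` and, following
    the intent-to-treat convention downstream, carry no abstinence report.
    """
    if log.is_empty():
        raise ValueError("cannot assign outcomes for an empty event log")
    from . import netbuild  # local import: synth is importable without graphs

    multinet = netbuild.build_multinet(log)
    agg = multinet.aggregated
    cohort = [_user_id(i) for i in range(config.n_trial_users)]
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(7)[6])

    rows = []
    latent = {}
    for uid in cohort:
        degree = agg.degree(uid) if uid in agg else 0
        eta = config.abstinence_intercept + config.abstinence_slope * np.log1p(degree)
        p = 1.0 / (1.0 + np.exp(-eta))
        u_abst = rng.random()
        u_resp = rng.random()
        truly_abstinent = u_abst < p
        responded = u_resp >= config.nonresponse_rate
        rows.append((uid, responded, bool(truly_abstinent and responded)))
        latent[uid] = bool(truly_abstinent)
    table = pd.DataFrame(rows, columns=OUTCOME_COLUMNS)
    out = OutcomeTable(
        table=table,
        true_intercept=config.abstinence_intercept,
        true_slope=config.abstinence_slope,
        latent_abstinent=pd.Series(latent),
    )
    out.validate()
    return out
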