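"""Typed bipartite data model, I/O, filtering and pairwise sufficient statistics.

A bipartite network G = (U, V, E) connects agents (U) to events (V); each
link carries one of ``n`` qualitative link types a_1..a_n (e.g. support /
oppose / abstain, or buy / sell / day-trade).  Absence of a link is encoded
as absence from the incidence mapping.  Everything downstream — the null
models and the validated projection — consumes only the sufficient
statistics computed here:

* per-agent degree ``N_i`` and empirical link-type preferences ``p_i``,
* per-pair joint-event count ``N_ij``, same-type overlap ``Ñ_ij``,
  opposing-type overlap ``N^d_ij`` and per-type overlaps ``N_ij(a_k)``,
* chance probabilities ``p_ij`` (same type) and ``q_ij`` (opposing types).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LinkTypeSet",
    "TypedBipartiteNetwork",
    "AgentProfile",
    "PairStatistics",
    "TradeRecord",
    "TRADING_TYPES",
    "load_incidence",
    "read_incidence_tsv",
    "write_incidence_tsv",
    "agent_profile",
    "population_preferences",
    "pair_statistics",
    "herfindahl_hirschman",
    "discretize_trading_state",
    "read_trades_tsv",
    "filter_agents_by_degree",
    "filter_events_by_degree",
]


@dataclass(frozen=True)
class LinkTypeSet:
    """Declared link types, with optional neutral types and opposing pairs.

    ``opposing_pairs`` lists unordered pairs ``(a_+, a_-)`` of mutually
    opposing types (buy/sell, support/oppose); ``neutral`` types take part
    in neither direction of the opposition.
    """

    types: tuple[str, ...]
    neutral: tuple[str, ...] = ()
    opposing_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "types", tuple(str(t) for t in self.types))
        object.__setattr__(self, "neutral", tuple(str(t) for t in self.neutral))
        object.__setattr__(
            self,
            "opposing_pairs",
            tuple((str(a), str(b)) for a, b in self.opposing_pairs),
        )
        if not self.types:
            raise ValueError("link-type set must be non-empty")
        if len(set(self.types)) != len(self.types):
            raise ValueError(f"duplicate link types in {self.types!r}")
        known = set(self.types)
        for t in self.neutral:
            if t not in known:
                raise ValueError(f"neutral type {t!r} is not a declared link type")
        in_pairs: set[str] = set()
        for a, b in self.opposing_pairs:
            if a not in known or b not in known:
                raise ValueError(f"opposing pair ({a!r}, {b!r}) uses undeclared types")
            if a == b:
                raise ValueError(f"opposing pair ({a!r}, {b!r}) must join distinct types")
            in_pairs.update((a, b))
        clash = in_pairs & set(self.neutral)
        if clash:
            raise ValueError(f"types {sorted(clash)} are both neutral and opposing")

    @property
    def n_types(self) -> int:
        return len(self.types)

    def index(self, link_type: str) -> int:
        return self.types.index(link_type)

    def to_json(self) -> str:
        return json.dumps(
            {
                "types": list(self.types),
                "neutral": list(self.neutral),
                "opposing_pairs": [list(p) for p in self.opposing_pairs],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LinkTypeSet":
        obj = json.loads(text)
        return cls(
            types=tuple(obj["types"]),
            neutral=tuple(obj.get("neutral", ())),
            opposing_pairs=tuple(tuple(p) for p in obj.get("opposing_pairs", ())),
        )


#: Trading-state link types of the investor application: primarily buying,
#: primarily selling, day-trading (neutral); buy opposes sell.
TRADING_TYPES = LinkTypeSet(types=("b", "s", "bs"), neutral=("bs",), opposing_pairs=(("b", "s"),))


@dataclass(frozen=True)
class TradeRecord:
    """One agent-event trading record with bought and sold volumes."""

    agent: str
    event: str
    bought: float
    sold: float


class TypedBipartiteNetwork:
    """Agents U, events V and a typed incidence mapping B.

    ``incidence[(agent, event)]`` is the link type; pairs that are absent
    carry no link (``B_it = 0``).  Agent and event order is first-appearance
    order of the input, so all derived outputs are deterministic.
    """

    def __init__(
        self,
        agents: Sequence[str],
        events: Sequence[str],
        link_types: LinkTypeSet,
        incidence: Mapping[tuple[str, str], str],
    ) -> None:
        self.agents: tuple[str, ...] = tuple(agents)
        self.events: tuple[str, ...] = tuple(events)
        self.link_types = link_types
        if len(set(self.agents)) != len(self.agents):
            raise ValueError("duplicate agent identifiers")
        if len(set(self.events)) != len(self.events):
            raise ValueError("duplicate event identifiers")
        if not self.events:
            raise ValueError("a bipartite network needs at least one event (N > 0)")
        agent_set, event_set = set(self.agents), set(self.events)
        known_types = set(link_types.types)
        self.incidence: dict[tuple[str, str], str] = {}
        self._by_agent: dict[str, dict[str, str]] = {a: {} for a in self.agents}
        for (a, e), t in incidence.items():
            if a not in agent_set:
                raise ValueError(f"incidence references unregistered agent {a!r}")
            if e not in event_set:
                raise ValueError(f"incidence references unregistered event {e!r}")
            if t not in known_types:
                raise ValueError(f"unknown link type {t!r} for ({a!r}, {e!r})")
            self.incidence[(a, e)] = t
            self._by_agent[a][e] = t

    # -- basic accessors ---------------------------------------------------

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_agents(self) -> int:
        return len(self.agents)

    def degree(self, agent: str) -> int:
        return len(self._by_agent[agent])

    def event_degree(self, event: str) -> int:
        return sum(1 for (_, e) in self.incidence if e == event)

    def links_of(self, agent: str) -> Mapping[str, str]:
        """Event -> link type mapping for one agent."""
        return self._by_agent[agent]

    def type_counts(self, agent: str) -> np.ndarray:
        counts = np.zeros(self.link_types.n_types, dtype=np.int64)
        for t in self._by_agent[agent].values():
            counts[self.link_types.index(t)] += 1
        return counts

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"TypedBipartiteNetwork(|U|={self.n_agents}, |V|={self.n_events}, "
            f"links={len(self.incidence)}, types={self.link_types.types})"
        )


@dataclass(frozen=True)
class AgentProfile:
    """Degree N_i and empirical link-type preference vector p_i."""

    agent: str
    degree: int
    preferences: np.ndarray | None

    @property
    def defined(self) -> bool:
        return self.preferences is not None


@dataclass(frozen=True)
class PairStatistics:
    """All sufficient statistics for one unordered agent pair.

    ``p_same`` is p_ij = sum_k p_i(a_k) p_j(a_k); ``p_opposing`` is
    q_ij = sum over opposing pairs of p_i(a_+)p_j(a_-) + p_i(a_-)p_j(a_+).
    Both are NaN when either agent has degree zero (flagged undefined).
    """

    agent_i: str
    agent_j: str
    n_events: int
    degree_i: int
    degree_j: int
    co_events: int
    same_type: int
    opposing_type: int
    per_type_overlap: np.ndarray
    p_same: float
    p_opposing: float

    @property
    def defined(self) -> bool:
        return not np.isnan(self.p_same)


# -- construction ---------------------------------------------------------


def load_incidence(
    records: Iterable[tuple[str, str, str]],
    link_types: LinkTypeSet,
    *,
    agents: Sequence[str] | None = None,
    events: Sequence[str] | None = None,
) -> TypedBipartiteNetwork:
    """Build a network from (agent, event, link_type) triplets.

    Agent/event order is first-appearance order; identifiers declared via
    ``agents``/``events`` are registered first (allowing zero-degree agents
    and unattended events).  A repeated triplet with an identical type is
    kept once with a logged warning; a conflicting type is a hard error.
    """
    agent_order: dict[str, None] = dict.fromkeys(str(a) for a in (agents or ()))
    event_order: dict[str, None] = dict.fromkeys(str(e) for e in (events or ()))
    incidence: dict[tuple[str, str], str] = {}
    n_dupes = 0
    for agent, event, link_type in records:
        agent, event, link_type = str(agent), str(event), str(link_type)
        if link_type not in link_types.types:
            raise ValueError(
                f"unknown link type {link_type!r} for ({agent!r}, {event!r}); "
                f"declared types are {link_types.types}"
            )
        key = (agent, event)
        if key in incidence:
            if incidence[key] != link_type:
                raise ValueError(
                    f"conflicting link types for pair ({agent!r}, {event!r}): "
                    f"{incidence[key]!r} vs {link_type!r}"
                )
            n_dupes += 1
            continue
        agent_order.setdefault(agent)
        event_order.setdefault(event)
        incidence[key] = link_type
    if n_dupes:
        logger.warning("ignored %d duplicate incidence records", n_dupes)
    if not event_order:
        raise ValueError("no events: declare events explicitly or provide records")
    return TypedBipartiteNetwork(tuple(agent_order), tuple(event_order), link_types, incidence)


def read_incidence_tsv(
    path,
    link_types: LinkTypeSet,
    *,
    agents: Sequence[str] | None = None,
    events: Sequence[str] | None = None,
) -> TypedBipartiteNetwork:
    """Read a headered TSV with columns agent_id, event_id, link_type.

    The format carries one row per connection, so events no agent attends
    (and zero-degree agents) must be re-declared via ``events``/``agents``
    to survive a round trip.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["agent_id", "event_id", "link_type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"incidence TSV misses columns {missing}")
    return load_incidence(
        df[required].itertuples(index=False, name=None),
        link_types,
        agents=agents,
        events=events,
    )


def write_incidence_tsv(net: TypedBipartiteNetwork, path) -> None:
    """Write the incidence in first-appearance agent/event order."""
    rows = [
        (a, e, net._by_agent[a][e])
        for a in net.agents
        for e in net.events
        if e in net._by_agent[a]
    ]
    pd.DataFrame(rows, columns=["agent_id", "event_id", "link_type"]).to_csv(
        path, sep="\t", index=False
    )


# -- profiles and pair statistics -----------------------------------------


def agent_profile(net: TypedBipartiteNetwork, agent: str) -> AgentProfile:
    """Degree N_i and preferences p_i(a_k) = (# a_k links) / N_i."""
    if agent not in net._by_agent:
        raise KeyError(f"agent {agent!r} is not registered")
    counts = net.type_counts(agent)
    degree = int(counts.sum())
    if degree == 0:
        return AgentProfile(agent=agent, degree=0, preferences=None)
    return AgentProfile(agent=agent, degree=degree, preferences=counts / degree)


def population_preferences(net: TypedBipartiteNetwork) -> np.ndarray:
    """Link-type frequencies pooled over all agents: p(a_k) = sum counts / sum N_i."""
    counts = np.zeros(net.link_types.n_types, dtype=np.int64)
    for t in net.incidence.values():
        counts[net.link_types.index(t)] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("population preferences are undefined on an empty incidence")
    return counts / total


def _chance_probs(
    lts: LinkTypeSet, p_i: np.ndarray, p_j: np.ndarray
) -> tuple[float, float]:
    p_same = float(np.dot(p_i, p_j))
    q = 0.0
    for a, b in lts.opposing_pairs:
        ia, ib = lts.index(a), lts.index(b)
        q += p_i[ia] * p_j[ib] + p_i[ib] * p_j[ia]
    p_opposing = float(q) if lts.opposing_pairs else float("nan")
    return p_same, p_opposing


def pair_statistics(
    net: TypedBipartiteNetwork,
    i: str,
    j: str,
    preference_mode: str = "per_agent",
) -> PairStatistics:
    """Overlap counts and chance probabilities for the pair (i, j).

    Same-type overlap counts only events where *both* agents are connected
    and via equal types; events missing from both are never counted.
    ``preference_mode`` selects per-agent preferences (default) or the
    population-pooled vector for both agents.
    """
    if i == j:
        raise ValueError("pair statistics need two distinct agents")
    if preference_mode not in ("per_agent", "population"):
        raise ValueError(f"unknown preference_mode {preference_mode!r}")
    lts = net.link_types
    links_i, links_j = net.links_of(i), net.links_of(j)
    if len(links_j) < len(links_i):
        small, big = links_j, links_i
    else:
        small, big = links_i, links_j
    co = same = 0
    per_type = np.zeros(lts.n_types, dtype=np.int64)
    opposing = 0
    opp_idx = {(lts.index(a), lts.index(b)) for a, b in lts.opposing_pairs}
    opp_idx |= {(b, a) for a, b in opp_idx}
    for event, t_small in small.items():
        t_big = big.get(event)
        if t_big is None:
            continue
        co += 1
        if t_small == t_big:
            same += 1
            per_type[lts.index(t_small)] += 1
        elif (lts.index(t_small), lts.index(t_big)) in opp_idx:
            opposing += 1
    deg_i, deg_j = len(links_i), len(links_j)
    if deg_i == 0 or deg_j == 0:
        p_same = p_opp = float("nan")
    elif preference_mode == "population":
        pop = population_preferences(net)
        p_same, p_opp = _chance_probs(lts, pop, pop)
    else:
        p_i = net.type_counts(i) / deg_i
        p_j = net.type_counts(j) / deg_j
        p_same, p_opp = _chance_probs(lts, p_i, p_j)
    return PairStatistics(
        agent_i=i,
        agent_j=j,
        n_events=net.n_events,
        degree_i=deg_i,
        degree_j=deg_j,
        co_events=co,
        same_type=same,
        opposing_type=opposing,
        per_type_overlap=per_type,
        p_same=p_same,
        p_opposing=p_opp,
    )


def herfindahl_hirschman(stats: PairStatistics) -> float:
    """Concentration of same-type overlap across link types.

    HH = sum_k N_ij(a_k)^2 / Ñ_ij^2, in [1/n, 1].  NaN (flagged) when the
    pair shares no same-type events.
    """
    if stats.same_type == 0:
        logger.warning(
            "Herfindahl-Hirschman undefined for (%s, %s): zero same-type overlap",
            stats.agent_i,
            stats.agent_j,
        )
        return float("nan")
    overlap = stats.per_type_overlap.astype(float)
    return float(np.sum(overlap**2) / stats.same_type**2)


# -- trading-state discretization -----------------------------------------


def discretize_trading_state(rec: TradeRecord, theta: float = 0.1) -> str:
    """Map bought/sold volumes to a trading state via the net-scaled volume.

    v = (B - S) / (B + S); returns ``"b"`` when v > theta, ``"s"`` when
    v < -theta, ``"bs"`` otherwise (the neutral day-trading band is the
    closed interval [-theta, theta]).
    """
    if not 0 < theta < 1:
        raise ValueError(f"theta must lie in (0, 1), got {theta}")
    if rec.bought < 0 or rec.sold < 0:
        raise ValueError("volumes must be non-negative")
    total = rec.bought + rec.sold
    if total == 0:
        raise ValueError(f"no volume traded by {rec.agent!r} on {rec.event!r}: no link")
    v = (rec.bought - rec.sold) / total
    if v > theta:
        return "b"
    if v < -theta:
        return "s"
    return "bs"


def read_trades_tsv(path, theta: float = 0.1) -> TypedBipartiteNetwork:
    """Read agent_id, event_id, bought, sold records and discretize to b/s/bs."""
    df = pd.read_csv(path, sep="\t", dtype={"agent_id": str, "event_id": str})
    records = (
        (
            row.agent_id,
            row.event_id,
            discretize_trading_state(
                TradeRecord(row.agent_id, row.event_id, row.bought, row.sold), theta
            ),
        )
        for row in df.itertuples(index=False)
    )
    return load_incidence(records, TRADING_TYPES)


# -- degree filters --------------------------------------------------------


def filter_agents_by_degree(
    net: TypedBipartiteNetwork, min_degree: int
) -> TypedBipartiteNetwork:
    """Keep agents with degree >= min_degree (single pass; events untouched)."""
    if min_degree < 0:
        raise ValueError("min_degree must be >= 0")
    keep = tuple(a for a in net.agents if net.degree(a) >= min_degree)
    keep_set = set(keep)
    incidence = {(a, e): t for (a, e), t in net.incidence.items() if a in keep_set}
    return TypedBipartiteNetwork(keep, net.events, net.link_types, incidence)


def filter_events_by_degree(
    net: TypedBipartiteNetwork, min_degree: int
) -> TypedBipartiteNetwork:
    """Keep events attended by >= min_degree agents (single pass; agents untouched)."""
    if min_degree < 0:
        raise ValueError("min_degree must be >= 0")
    attendance: dict[str, int] = dict.fromkeys(net.events, 0)
    for (_, e) in net.incidence:
        attendance[e] += 1
    keep = tuple(e for e in net.events if attendance[e] >= min_degree)
    keep_set = set(keep)
    incidence = {(a, e): t for (a, e), t in net.incidence.items() if e in keep_set}
    return TypedBipartiteNetwork(net.agents, keep, net.link_types, incidence)
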