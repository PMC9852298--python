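"""Independent-cascade-style influence model on a ground-truth social graph.

Generates synthetic typed bipartite networks in which neighboring agents of
a known monopartite graph are more likely to attend the same events with
the same link types — the setting in which a validated projection should be
able to reconstruct the original graph.

Each agent ``i`` carries three fixed attributes per network realization:

* ``n_i`` — probability of connecting to an event when asked,
* ``c_i`` — probability of mimicking a neighbor's link type,
* ``p_i`` — link-type preference vector.

Every event starts a fresh cascade: a uniformly chosen seed agent connects
(always) with a type drawn from its preferences; then, breadth-first from
the seed, each not-yet-decided graph neighbor of a connected agent decides
once — it connects with probability ``n_i`` and, if it connects, copies the
type of a uniformly chosen already-connected neighbor with probability
``c_i``, otherwise draws from its own preferences.  The cascade stops when
the frontier empties; agents outside the seed's component never connect.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .bipartite import LinkTypeSet, TypedBipartiteNetwork

__all__ = [
    "InfluenceAttributes",
    "SimulationConfig",
    "sample_attributes",
    "simulate_event_cascade",
    "simulate_bipartite",
    "simulate_network",
]

#: Preference-concentration presets: log10 range of the symmetric Dirichlet
#: concentration parameter, spanning near one-hot (small) to near uniform
#: (large).  "one_hot" bypasses the Dirichlet and emits exact unit vectors.
_CONCENTRATION_PRESETS: dict[str, tuple[float, float]] = {
    "mixed": (-2.0, 2.0),
    "concentrated": (-2.0, -1.0),
    "diffuse": (1.0, 2.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation sizes and optional attribute restrictions.

    Defaults are the benchmark conditions: 100 events, 3 link types,
    ``n_i`` and ``c_i`` uniform on [0, 1], preference concentration mixed
    (log10 Dirichlet concentration uniform on [-2, 2] per agent).
    """

    n_events: int = 100
    n_link_types: int = 3
    seed: int | None = None
    connect_range: tuple[float, float] = (0.0, 1.0)
    mimic_range: tuple[float, float] = (0.0, 1.0)
    pref_concentration: str | tuple[float, float] = "mixed"

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1 (N > 0)")
        if self.n_link_types < 2:
            raise ValueError("n_link_types must be >= 2")
        for name, (lo, hi) in (("connect_range", self.connect_range), ("mimic_range", self.mimic_range)):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name}={lo, hi} must satisfy 0 <= lo <= hi <= 1")
        if isinstance(self.pref_concentration, str):
            if self.pref_concentration not in _CONCENTRATION_PRESETS and self.pref_concentration != "one_hot":
                raise ValueError(f"unknown preference concentration {self.pref_concentration!r}")

    @property
    def link_types(self) -> LinkTypeSet:
        return LinkTypeSet(types=tuple(f"a{k + 1}" for k in range(self.n_link_types)))


@dataclass(frozen=True)
class InfluenceAttributes:
    """Fixed per-agent cascade parameters for one network realization."""

    agents: tuple[str, ...]
    connect_prob: np.ndarray  # n_i, shape (n_agents,)
    mimic_prob: np.ndarray  # c_i, shape (n_agents,)
    preferences: np.ndarray  # p_i, shape (n_agents, n_link_types)

    def __post_init__(self) -> None:
        n = len(self.agents)
        if self.connect_prob.shape != (n,) or self.mimic_prob.shape != (n,):
            raise ValueError("attribute arrays must have one entry per agent")
        if self.preferences.shape[0] != n:
            raise ValueError("preference matrix must have one row per agent")
        for name, arr in (("connect_prob", self.connect_prob), ("mimic_prob", self.mimic_prob)):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} entries outside [0, 1]")
        if np.any(self.preferences < 0) or not np.allclose(self.preferences.sum(axis=1), 1.0):
            raise ValueError("preference rows must be probability vectors")


def _sorted_nodes(graph: nx.Graph) -> tuple[str, ...]:
    return tuple(sorted(str(n) for n in graph.nodes))


def sample_attributes(
    graph: nx.Graph,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> InfluenceAttributes:
    """Draw one attribute set: n_i, c_i uniform; preferences Dirichlet.

    Preference vectors use a two-stage scheme — a per-agent concentration
    level drawn uniformly in log10 space, then a symmetric Dirichlet — so
    realizations span complete concentration on one link type through equal
    preference for all types.  Consumes the generator in a fixed order
    (connect, mimic, concentration, preferences).
    """
    agents = _sorted_nodes(graph)
    n = len(agents)
    connect = rng.uniform(*config.connect_range, size=n)
    mimic = rng.uniform(*config.mimic_range, size=n)
    if config.pref_concentration == "one_hot":
        prefs = np.zeros((n, config.n_link_types))
        prefs[np.arange(n), rng.integers(0, config.n_link_types, size=n)] = 1.0
    else:
        if isinstance(config.pref_concentration, str):
            lo, hi = _CONCENTRATION_PRESETS[config.pref_concentration]
        else:
            lo, hi = config.pref_concentration
        conc = 10.0 ** rng.uniform(lo, hi, size=n)
        prefs = np.vstack(
            [rng.dirichlet(np.full(config.n_link_types, c)) for c in conc]
        )
    return InfluenceAttributes(
        agents=agents, connect_prob=connect, mimic_prob=mimic, preferences=prefs
    )


def simulate_event_cascade(
    graph: nx.Graph,
    attrs: InfluenceAttributes,
    rng: np.random.Generator,
    config: SimulationConfig | None = None,
) -> dict[str, int]:
    """One event's cascade: returns {agent: link-type index} for connectors.

    Each agent decides at most once per event.  Frontier expansion is
    breadth-first with neighbors visited in sorted order, so a fixed
    generator state yields a fixed cascade.
    """
    agents = attrs.agents
    index = {a: k for k, a in enumerate(agents)}
    neighbors = {
        str(n): sorted(str(m) for m in graph.neighbors(n)) for n in graph.nodes
    }
    n_types = attrs.preferences.shape[1]

    seed_agent = agents[rng.integers(0, len(agents))]
    connected: dict[str, int] = {
        seed_agent: int(rng.choice(n_types, p=attrs.preferences[index[seed_agent]]))
    }
    decided = {seed_agent}
    frontier = [nb for nb in neighbors[seed_agent] if nb not in decided]
    queued = set(frontier)
    while frontier:
        next_frontier: list[str] = []
        for agent in frontier:
            decided.add(agent)
            k = index[agent]
            if rng.random() >= attrs.connect_prob[k]:
                continue
            connected_neighbors = [nb for nb in neighbors[agent] if nb in connected]
            if connected_neighbors and rng.random() < attrs.mimic_prob[k]:
                donor = connected_neighbors[int(rng.integers(0, len(connected_neighbors)))]
                link = connected[donor]
            else:
                link = int(rng.choice(n_types, p=attrs.preferences[k]))
            connected[agent] = link
            for nb in neighbors[agent]:
                if nb not in decided and nb not in queued:
                    queued.add(nb)
                    next_frontier.append(nb)
        frontier = next_frontier
    return connected


def simulate_bipartite(
    graph: nx.Graph,
    attrs: InfluenceAttributes,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TypedBipartiteNetwork:
    """Run ``config.n_events`` independent cascades into one bipartite network.

    Event identifiers are event_000, event_001, ...; all graph nodes are
    registered as agents (a node may end with degree zero).  With ``rng``
    omitted, a fresh generator is built from ``config.seed``, making the
    realization a pure function of (graph, attrs, config).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lts = config.link_types
    incidence: dict[tuple[str, str], str] = {}
    events = tuple(f"event_{t:03d}" for t in range(config.n_events))
    for t, event in enumerate(events):
        for agent, link in simulate_event_cascade(graph, attrs, rng, config).items():
            incidence[(agent, event)] = lts.types[link]
    return TypedBipartiteNetwork(attrs.agents, events, lts, incidence)


def simulate_network(
    graph: nx.Graph,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[TypedBipartiteNetwork, InfluenceAttributes]:
    """Sample fresh attributes, then simulate one bipartite network."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    attrs = sample_attributes(graph, config, rng)
    return simulate_bipartite(graph, attrs, config, rng), attrs
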