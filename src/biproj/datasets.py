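"""Bundled fixtures: the two-agent worked example and the karate-club graph.

The worked example is a 2-agent, 100-event, 3-link-type network whose
contingency table (counts of events by the pair of types used) is::

               agent j
               a1  a2  a3   -
    agent i a1  2   1   0   1   (N_i(a1) = 4)
            a2  1   0  14   5   (N_i(a2) = 20)
            a3  0   3   0  13   (N_i(a3) = 16)
            -   0   3   6  51

giving degrees N_i = 40, N_j = 30, joint events N_ij = 21, same-type
overlap Ñ_ij = 2 and, with (a2, a3) opposing, N^d_ij = 17.  It is the
canonical check for every statistic and tail probability in the package.
"""

from __future__ import annotations

from importlib import resources

import networkx as nx
import pandas as pd

from .bipartite import LinkTypeSet, TypedBipartiteNetwork, load_incidence

__all__ = [
    "TABLE1_TYPES",
    "two_agent_example",
    "two_agent_contingency",
    "karate_club_fixture",
    "load_ground_truth_tsv",
]

#: Link types of the worked example: a1 neutral, a2/a3 mutually opposing.
TABLE1_TYPES = LinkTypeSet(
    types=("a1", "a2", "a3"), neutral=("a1",), opposing_pairs=(("a2", "a3"),)
)

# (type of agent i, type of agent j) -> number of events; None = no link.
_TABLE1_CELLS: dict[tuple[str | None, str | None], int] = {
    ("a1", "a1"): 2, ("a1", "a2"): 1, ("a1", "a3"): 0, ("a1", None): 1,
    ("a2", "a1"): 1, ("a2", "a2"): 0, ("a2", "a3"): 14, ("a2", None): 5,
    ("a3", "a1"): 0, ("a3", "a2"): 3, ("a3", "a3"): 0, ("a3", None): 13,
    (None, "a1"): 0, (None, "a2"): 3, (None, "a3"): 6, (None, None): 51,
}


def two_agent_contingency() -> pd.DataFrame:
    """The worked example's contingency table as a labelled DataFrame."""
    labels = ["a1", "a2", "a3", "-"]
    df = pd.DataFrame(0, index=labels, columns=labels)
    for (ti, tj), count in _TABLE1_CELLS.items():
        df.loc[ti or "-", tj or "-"] = count
    return df


def two_agent_example() -> TypedBipartiteNetwork:
    """The 2-agent, 100-event worked-example network (agents "i" and "j")."""
    records: list[tuple[str, str, str]] = []
    events: list[str] = []
    idx = 0
    for (ti, tj), count in _TABLE1_CELLS.items():
        for _ in range(count):
            event = f"event_{idx:03d}"
            events.append(event)
            idx += 1
            if ti is not None:
                records.append(("i", event, ti))
            if tj is not None:
                records.append(("j", event, tj))
    assert idx == 100
    return load_incidence(records, TABLE1_TYPES, agents=("i", "j"), events=events)


def karate_club_fixture() -> nx.Graph:
    """The Zachary karate-club social network (34 nodes, 78 edges).

    Read from the packaged static edge list; node identifiers are the
    conventional integers 0..33, returned as strings for consistency with
    agent identifiers elsewhere.
    """
    with resources.files("biproj.data").joinpath("karate_club_edges.tsv").open() as fh:
        return load_ground_truth_tsv(fh)


def load_ground_truth_tsv(path_or_buffer) -> nx.Graph:
    """Read a two-column edge-list TSV into a simple undirected graph."""
    df = pd.read_csv(path_or_buffer, sep="\t", dtype=str)
    graph = nx.Graph()
    for a, b in df.itertuples(index=False):
        if a == b:
            raise ValueError(f"self-loop on node {a!r} in ground-truth graph")
        graph.add_edge(str(a), str(b))
    return graph
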