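"""Pairwise validation, signed network construction, triads, windows, comparison.

A positive link between two agents means their same-type overlap ``Ñ_ij``
is significantly larger than the mixture null expects; a negative link
means the same for their opposing-type overlap ``N^d_ij``.  The classical
hypergeometric null, applied per link type and aggregated, is available as
the reference model.  Multiple testing is controlled with Bonferroni,
by default correcting the positive and negative test families independently.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .bipartite import PairStatistics, TypedBipartiteNetwork, pair_statistics
from .nullmodels import NullParams, hb_mixture_survival, hypergeometric_survival

logger = logging.getLogger(__name__)

__all__ = [
    "ValidatedEdge",
    "SignedNetwork",
    "TriadCensus",
    "JaccardResult",
    "validate_pair",
    "validate_pair_reference",
    "project",
    "triad_census",
    "rolling_window_projection",
    "jaccard_links",
    "write_edges_tsv",
    "read_edges_tsv",
    "to_networkx",
]


@dataclass(frozen=True)
class ValidatedEdge:
    """One validated signed link with its raw p-value and pair statistics."""

    agent_i: str
    agent_j: str
    sign: str  # "positive" | "negative"
    p_value: float
    stats: PairStatistics | None = None

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.agent_i, self.agent_j)))

    @property
    def key(self) -> tuple[str, str, str]:
        return (*self.pair, self.sign)


@dataclass(frozen=True)
class SignedNetwork:
    """Validated monopartite projection with per-edge sign and p-value."""

    nodes: tuple[str, ...]
    edges: tuple[ValidatedEdge, ...]
    alpha: float
    correction: str
    n_tests: dict[str, int] = field(default_factory=dict)

    def edge_keys(self) -> set[tuple[str, str, str]]:
        return {e.key for e in self.edges}

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        seen: set[tuple[str, str, str]] = set()
        for e in self.edges:
            if e.agent_i not in node_set or e.agent_j not in node_set:
                raise ValueError(f"edge endpoint outside node set: {e.key}")
            if e.key in seen:
                raise ValueError(f"duplicate signed edge {e.key}")
            seen.add(e.key)


@dataclass(frozen=True)
class TriadCensus:
    """Counts of closed signed triangles by sign multiset.

    A triangle is stable iff the product of its three signs is positive:
    stable classes are (+,+,+) and (+,-,-); unstable are (+,+,-) and (-,-,-).
    """

    ppp: int
    pmm: int
    ppm: int
    mmm: int

    @property
    def stable_total(self) -> int:
        return self.ppp + self.pmm

    @property
    def unstable_total(self) -> int:
        return self.ppm + self.mmm

    @property
    def total(self) -> int:
        return self.stable_total + self.unstable_total


def _mixture_params(n: int, deg_a: int, deg_b: int, p: float) -> NullParams:
    # order the degrees so (i, j) and (j, i) build bit-identical parameters
    lo, hi = sorted((deg_a, deg_b))
    return NullParams(n_events=n, degree_i=lo, degree_j=hi, success_prob=p)


def validate_pair(
    net: TypedBipartiteNetwork,
    i: str,
    j: str,
    mode: str = "positive",
    preference_mode: str = "per_agent",
) -> tuple[float, PairStatistics]:
    """Mixture-null p-value for a positive (same-type) or negative
    (opposing-type) link between agents ``i`` and ``j``.

    Returns the upper tail P(Y >= observed overlap) together with the pair's
    sufficient statistics.  Both agents must have degree > 0.
    """
    stats = pair_statistics(net, i, j, preference_mode=preference_mode)
    if stats.degree_i == 0 or stats.degree_j == 0:
        raise ValueError(f"pair ({i!r}, {j!r}) has a zero-degree agent")
    if mode == "positive":
        observed, p = stats.same_type, stats.p_same
    elif mode == "negative":
        if not net.link_types.opposing_pairs:
            raise ValueError("negative validation needs declared opposing pairs")
        observed, p = stats.opposing_type, stats.p_opposing
    else:
        raise ValueError(f"mode must be 'positive' or 'negative', got {mode!r}")
    params = _mixture_params(stats.n_events, stats.degree_i, stats.degree_j, p)
    return hb_mixture_survival(observed, params), stats


def validate_pair_reference(
    net: TypedBipartiteNetwork,
    i: str,
    j: str,
    aggregation: str = "min",
    return_stats: bool = False,
):
    """Reference hypergeometric p-value(s) for the pair, per link type.

    For each link type a_k the upper hypergeometric tail of the per-type
    overlap N_ij(a_k) is computed with the per-type degrees N_i(a_k),
    N_j(a_k) against the full event count N; a type unused by either agent
    has overlap 0 and tail 1.  ``aggregation`` is one of min / mean / max /
    none (none returns the per-type vector).
    """
    if aggregation not in ("min", "mean", "max", "none"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    stats = pair_statistics(net, i, j)
    counts_i = net.type_counts(i)
    counts_j = net.type_counts(j)
    pvals = np.ones(net.link_types.n_types)
    for k in range(net.link_types.n_types):
        lo, hi = sorted((int(counts_i[k]), int(counts_j[k])))
        params = NullParams(n_events=net.n_events, degree_i=lo, degree_j=hi)
        pvals[k] = hypergeometric_survival(int(stats.per_type_overlap[k]), params, "upper")
    if aggregation == "none":
        result = pvals
    else:
        result = float({"min": np.min, "mean": np.mean, "max": np.max}[aggregation](pvals))
    return (result, stats) if return_stats else result


def _eligible_pairs(net: TypedBipartiteNetwork) -> list[tuple[str, str]]:
    active = sorted(a for a in net.agents if net.degree(a) > 0)
    skipped = net.n_agents - len(active)
    if skipped:
        logger.info("excluding %d zero-degree agents from validation", skipped)
    return list(itertools.combinations(active, 2))


def project(
    net: TypedBipartiteNetwork,
    alpha: float = 0.01,
    correction: str = "bonferroni",
    modes: tuple[str, ...] = ("positive", "negative"),
    preference_mode: str = "per_agent",
    model: str = "mixture",
    bonferroni_family: str = "per_sign",
) -> SignedNetwork:
    """Validated signed one-mode projection of the bipartite network.

    Tests every unordered pair of agents with degree > 0.  ``model`` is
    ``"mixture"`` or ``"reference-min"`` / ``"reference-mean"`` /
    ``"reference-max"`` (the reference model only yields positive links).
    With Bonferroni correction each sign family is corrected with its own
    test count m by default; ``bonferroni_family="joint"`` uses the summed
    count for both families.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    if bonferroni_family not in ("per_sign", "joint"):
        raise ValueError(f"unknown bonferroni_family {bonferroni_family!r}")
    reference = model.startswith("reference")
    if not reference and model != "mixture":
        raise ValueError(f"unknown model {model!r}")
    if reference:
        modes = ("positive",)
    if "negative" in modes and not net.link_types.opposing_pairs:
        raise ValueError("negative validation needs declared opposing pairs")

    pairs = _eligible_pairs(net)
    if not pairs:
        logger.warning("no eligible pairs: empty signed network")
    m = len(pairs)
    n_tests = {mode: m for mode in modes}
    if correction == "none":
        thresholds = {mode: alpha for mode in modes}
    elif bonferroni_family == "joint":
        total = m * len(modes)
        thresholds = {mode: alpha / total if total else alpha for mode in modes}
    else:
        thresholds = {mode: alpha / m if m else alpha for mode in modes}

    edges: list[ValidatedEdge] = []
    agg = model.split("-", 1)[1] if reference else None
    for i, j in pairs:
        if reference:
            p, stats = validate_pair_reference(net, i, j, aggregation=agg, return_stats=True)
            candidates = [("positive", p, stats)]
        else:
            candidates = []
            for mode in modes:
                p, stats = validate_pair(net, i, j, mode, preference_mode)
                candidates.append((mode, p, stats))
        for sign, p, stats in candidates:
            if p <= thresholds[sign]:
                edges.append(ValidatedEdge(i, j, sign, p, stats))
    nodes = tuple(sorted({a for a in net.agents if net.degree(a) > 0}))
    return SignedNetwork(
        nodes=nodes,
        edges=tuple(edges),
        alpha=alpha,
        correction=correction,
        n_tests=n_tests,
    )


def triad_census(snet: SignedNetwork, pair_resolution: str = "min_p") -> TriadCensus:
    """Census of closed signed triangles in the projection.

    A pair validated in both directions is resolved before the census:
    ``"min_p"`` (default) keeps the sign with the smaller p-value,
    ``"positive"`` / ``"negative"`` force that sign for doubly validated
    pairs.  Stability follows the sign-product rule.
    """
    if pair_resolution not in ("min_p", "positive", "negative"):
        raise ValueError(f"unknown pair_resolution {pair_resolution!r}")
    best: dict[tuple[str, str], ValidatedEdge] = {}
    for edge in snet.edges:
        other = best.get(edge.pair)
        if other is None:
            best[edge.pair] = edge
        elif pair_resolution == "min_p":
            if edge.p_value < other.p_value:
                best[edge.pair] = edge
        elif edge.sign == pair_resolution:
            best[edge.pair] = edge
    adjacency: dict[str, set[str]] = {}
    sign_of: dict[tuple[str, str], str] = {}
    for (a, b), edge in best.items():
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
        sign_of[(a, b)] = edge.sign
    counts = {3: 0, 2: 0, 1: 0, 0: 0}  # keyed by number of positive signs
    for a in sorted(adjacency):
        for b in sorted(n for n in adjacency[a] if n > a):
            for c in sorted(n for n in (adjacency[a] & adjacency[b]) if n > b):
                n_pos = sum(
                    sign_of[pair] == "positive"
                    for pair in ((a, b), (a, c), (b, c))
                )
                counts[n_pos] += 1
    return TriadCensus(ppp=counts[3], ppm=counts[2], pmm=counts[1], mmm=counts[0])


def rolling_window_projection(
    net: TypedBipartiteNetwork,
    window_size: int,
    step: int,
    pair_list: list[tuple[str, str]] | None = None,
    preference_mode: str = "per_agent",
) -> pd.DataFrame:
    """Positive-link p-values recomputed inside a moving event window.

    Events are taken in their declared order; windows start at 0, step,
    2*step, ... while a full window fits.  Profiles and pair statistics are
    re-estimated within each window only.  Pairs with a zero-degree agent
    in a window get a NaN p-value there (flagged, not an error).

    Returns a tidy frame with columns window, start, agent_i, agent_j, p_value.
    """
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be >= 1")
    if window_size > net.n_events:
        raise ValueError(
            f"window_size={window_size} exceeds the number of events N={net.n_events}"
        )
    rows = []
    for w, start in enumerate(range(0, net.n_events - window_size + 1, step)):
        window_events = net.events[start : start + window_size]
        keep = set(window_events)
        sub = TypedBipartiteNetwork(
            net.agents,
            window_events,
            net.link_types,
            {k: t for k, t in net.incidence.items() if k[1] in keep},
        )
        pairs = pair_list if pair_list is not None else _eligible_pairs(sub)
        for i, j in pairs:
            if sub.degree(i) == 0 or sub.degree(j) == 0:
                p = float("nan")
            else:
                p, _ = validate_pair(sub, i, j, "positive", preference_mode)
            rows.append((w, start, *sorted((i, j)), p))
    return pd.DataFrame(rows, columns=["window", "start", "agent_i", "agent_j", "p_value"])


@dataclass(frozen=True)
class JaccardResult:
    """Signed-edge overlap between two validated networks."""

    jaccard: float
    n_common: int
    n_only_a: int
    n_only_b: int


def jaccard_links(net_a: SignedNetwork, net_b: SignedNetwork) -> JaccardResult:
    """Jaccard similarity of the signed edge sets, with unique-link counts.

    Edges are compared as unordered pairs with their sign.  Two empty
    networks compare as identical (similarity 1, with a warning).
    """
    keys_a, keys_b = net_a.edge_keys(), net_b.edge_keys()
    union = keys_a | keys_b
    common = keys_a & keys_b
    if not union:
        logger.warning("both networks are empty: Jaccard defined as 1")
        return JaccardResult(1.0, 0, 0, 0)
    return JaccardResult(
        jaccard=len(common) / len(union),
        n_common=len(common),
        n_only_a=len(keys_a - keys_b),
        n_only_b=len(keys_b - keys_a),
    )


# -- I/O -------------------------------------------------------------------


def write_edges_tsv(snet: SignedNetwork, path) -> None:
    rows = []
    for e in sorted(snet.edges, key=lambda e: e.key):
        s = e.stats
        rows.append(
            (
                *e.pair,
                e.sign,
                e.p_value,
                s.co_events if s else np.nan,
                s.same_type if s else np.nan,
                s.opposing_type if s else np.nan,
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "agent_i",
            "agent_j",
            "sign",
            "p_value",
            "n_co_events",
            "n_same_type",
            "n_opposing",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_edges_tsv(path, alpha: float = 0.01, correction: str = "bonferroni") -> SignedNetwork:
    df = pd.read_csv(path, sep="\t", dtype={"agent_i": str, "agent_j": str})
    edges = tuple(
        ValidatedEdge(r.agent_i, r.agent_j, r.sign, float(r.p_value))
        for r in df.itertuples(index=False)
    )
    nodes = tuple(sorted(set(df["agent_i"]) | set(df["agent_j"])))
    return SignedNetwork(nodes=nodes, edges=edges, alpha=alpha, correction=correction)


def to_networkx(snet: SignedNetwork, pair_resolution: str = "min_p") -> nx.Graph:
    """Signed projection as a networkx graph with sign/p_value edge attributes."""
    best: dict[tuple[str, str], ValidatedEdge] = {}
    for e in snet.edges:
        cur = best.get(e.pair)
        if cur is None or (pair_resolution == "min_p" and e.p_value < cur.p_value):
            best[e.pair] = e
    graph = nx.Graph()
    graph.add_nodes_from(snet.nodes)
    for (a, b), e in best.items():
        graph.add_edge(a, b, sign=e.sign, p_value=e.p_value)
    return graph
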