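"""Independent brute-force oracles used by the test suite.

Everything here is computed from first principles (explicit subset
enumeration, exact Fraction arithmetic, direct combinatorial formulas) and
never calls the implementation under test.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction
from functools import lru_cache


@lru_cache(maxsize=None)
def _joint_event_counts(n: int, ni: int, nj: int) -> tuple[int, ...]:
    """counts[x] = number of nj-subsets of n events meeting a fixed ni-set in x.

    Computed by explicit enumeration of all C(n, nj) subsets (the first ni
    events are agent i's, w.l.o.g. by exchangeability).
    """
    counts = [0] * (min(ni, nj) + 1)
    for subset in itertools.combinations(range(n), nj):
        counts[sum(1 for e in subset if e < ni)] += 1
    return tuple(counts)


@lru_cache(maxsize=None)
def _binom_tail(k: int, trials: int, p: Fraction) -> Fraction:
    return sum(
        Fraction(math.comb(trials, s)) * p**s * (1 - p) ** (trials - s)
        for s in range(k, trials + 1)
    )


def mixture_tail_exact(k: int, n: int, ni: int, nj: int, p) -> Fraction:
    """Exact mixture tail P(Y >= k) by enumeration over event choices.

    Averages, over every equally likely pair of event sets, the probability
    that at least k of the joint events produce a same-type success.
    """
    p = Fraction(p)
    counts = _joint_event_counts(n, ni, nj)
    total = sum(
        count * _binom_tail(k, x, p) for x, count in enumerate(counts) if k <= x
    )
    return total / math.comb(n, nj)


def two_agent_classes(n_events: int, n_types: int):
    """All realizable two-agent sufficient-statistic classes by brute force.

    Enumerates every labeled assignment of per-event states (one of
    (n_types+1)^2 joint states per event), keeps those where both agents
    have degree >= 1, and reduces to (x, y, s) classes: per-type degree
    vectors of both agents and per-type same-type overlaps.  Returns a dict
    class -> number of labeled assignments.
    """
    states = list(itertools.product(range(n_types + 1), repeat=2))
    classes: dict[tuple, int] = {}
    for assignment in itertools.product(states, repeat=n_events):
        x = [0] * n_types
        y = [0] * n_types
        s = [0] * n_types
        for ti, tj in assignment:
            if ti:
                x[ti - 1] += 1
            if tj:
                y[tj - 1] += 1
            if ti and ti == tj:
                s[ti - 1] += 1
        if sum(x) == 0 or sum(y) == 0:
            continue
        key = (tuple(x), tuple(y), tuple(s))
        classes[key] = classes.get(key, 0) + 1
    return classes


def signed_triangles(edges: dict[tuple[str, str], int]):
    """Classify every closed triangle of a signed graph by brute force.

    ``edges`` maps sorted node pairs to +1/-1.  Returns a dict keyed by
    number of positive edges (0..3) -> triangle count.
    """
    nodes = sorted({n for pair in edges for n in pair})
    counts = {0: 0, 1: 0, 2: 0, 3: 0}
    for a, b, c in itertools.combinations(nodes, 3):
        trio = [(a, b), (a, c), (b, c)]
        if all(pair in edges for pair in trio):
            counts[sum(edges[pair] > 0 for pair in trio)] += 1
    return counts


def paired_t_statistic(a, b) -> float:
    """Textbook paired t statistic: mean(d) / (sd(d)/sqrt(n)), ddof=1."""
    d = [float(x) - float(y) for x, y in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    var = sum((v - mean) ** 2 for v in d) / (n - 1)
    return mean / math.sqrt(var / n)
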