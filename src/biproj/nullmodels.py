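"""Tail probabilities for the hypergeometric and hypergeometric-binomial nulls.

Two null models for the overlap of two agents that connect to ``N_i`` and
``N_j`` of ``N`` events:

* the classical hypergeometric null (the reference model), which fixes both
  agents' degrees and asks how many *joint* events occur by chance, and
* the hypergeometric-binomial mixture null, which additionally models the
  link types: conditional on ``X`` joint events, the number of same-type
  matches is binomial with success probability ``p`` (the chance that the
  two agents pick the same — or, for negative links, opposing — type).

The mixture upper tail is

    P(Y >= k | N, N_i, N_j, p) =
        sum_{X=k}^{min(N_i, N_j)} H(X | N, N_i, N_j) * B(Y >= k | X, p),

with H the hypergeometric pmf and B the binomial survival function.  All
tails are computed from scipy's log-space implementations; the mixture sum
has only non-negative terms, so plain accumulation loses no precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "NullParams",
    "hypergeometric_pmf",
    "hypergeometric_survival",
    "binomial_survival",
    "hb_mixture_survival",
    "monte_carlo_null",
]


@dataclass(frozen=True)
class NullParams:
    """Parameter tuple (N, N_i, N_j, p) of the null models.

    ``success_prob`` is p_ij for positive (same-type) tests, q_ij for
    negative (opposing-type) tests, or a per-type probability for the
    reference null.
    """

    n_events: int
    degree_i: int
    degree_j: int
    success_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if not (0 <= self.degree_i <= self.n_events):
            raise ValueError(f"degree_i={self.degree_i} outside [0, N={self.n_events}]")
        if not (0 <= self.degree_j <= self.n_events):
            raise ValueError(f"degree_j={self.degree_j} outside [0, N={self.n_events}]")
        if not (0.0 <= self.success_prob <= 1.0) or np.isnan(self.success_prob):
            raise ValueError(f"success_prob={self.success_prob} outside [0, 1]")

    @property
    def support_max(self) -> int:
        return min(self.degree_i, self.degree_j)

    @property
    def support_min(self) -> int:
        return max(self.degree_i + self.degree_j - self.n_events, 0)

    def _frozen_hypergeom(self):
        # scipy's convention: M = population, n = successes, N = draws
        return stats.hypergeom(M=self.n_events, n=self.degree_i, N=self.degree_j)


def hypergeometric_pmf(x: int, params: NullParams) -> float:
    """H(X = x | N, N_i, N_j); zero outside the support."""
    return float(params._frozen_hypergeom().pmf(x))


def hypergeometric_survival(k: int, params: NullParams, tail: str = "upper") -> float:
    """Hypergeometric tail: P(X >= k) (``upper``) or P(X <= k) (``lower``)."""
    hg = params._frozen_hypergeom()
    if tail == "upper":
        if k <= params.support_min:
            return 1.0
        return float(hg.sf(k - 1))
    if tail == "lower":
        return float(hg.cdf(k))
    raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")


def binomial_survival(k: int, trials: int, p: float) -> float:
    """P(Y >= k | trials, p) via the regularized incomplete beta function."""
    if trials < 0 or k < 0:
        raise ValueError("k and trials must be >= 0")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    if k == 0:
        return 1.0
    if k > trials:
        return 0.0
    return float(stats.binom.sf(k - 1, trials, p))


def hb_mixture_survival(k: int, params: NullParams) -> float:
    """Upper tail of the hypergeometric-binomial mixture null.

    Probability that two agents with degrees (N_i, N_j) over N events share
    at least ``k`` events with matching outcomes, when each joint event
    matches independently with probability ``params.success_prob``.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return 1.0
    upper = params.support_max
    if k > upper:
        logger.warning(
            "overlap k=%d exceeds min(N_i, N_j)=%d: impossible under the null", k, upper
        )
        return 0.0
    xs = np.arange(k, upper + 1)
    hg = params._frozen_hypergeom()
    pmf = hg.pmf(xs)
    btail = stats.binom.sf(k - 1, xs, params.success_prob)
    # non-negative terms only; sum ascending in X (pmf mass concentrates
    # near the mode, small terms first when k sits in the upper tail)
    return float(min(np.sum(pmf * btail), 1.0))


def monte_carlo_null(
    k: int,
    params: NullParams,
    reps: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the mixture tail, with binomial standard error.

    Simulates the null directly: each rep draws the two agents' event sets
    uniformly without replacement, flips an independent success coin with
    probability ``p`` for every joint event, and counts reps with >= k
    successes.  Serves as an oracle for :func:`hb_mixture_survival`.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n, ni, nj, p = params.n_events, params.degree_i, params.degree_j, params.success_prob
    hits = 0
    for _ in range(reps):
        events_i = rng.choice(n, size=ni, replace=False)
        events_j = rng.choice(n, size=nj, replace=False)
        joint = np.intersect1d(events_i, events_j, assume_unique=True).size
        successes = rng.binomial(joint, p) if joint else 0
        if successes >= k:
            hits += 1
    est = hits / reps
    se = float(np.sqrt(est * (1.0 - est) / reps))
    return est, se
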