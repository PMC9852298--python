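"""Reconstruction scoring, AUC, ensemble benchmarks and the two-agent study.

Benchmarks the mixture-null projection against the per-type hypergeometric
reference on synthetic bipartite networks generated by the influence model,
scoring reconstructed edge sets against the ground-truth graph with
precision / recall / F1 / accuracy over all unordered agent pairs, and
ranking p-values with a Mann-Whitney AUC.  Also provides the exhaustive
study of every two-agent bipartite configuration at small event counts.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .bipartite import TypedBipartiteNetwork, pair_statistics
from .influence import SimulationConfig, simulate_network
from .nullmodels import NullParams, hb_mixture_survival
from .projection import _mixture_params

logger = logging.getLogger(__name__)

__all__ = [
    "ReconstructionScores",
    "EnsembleSummary",
    "TwoAgentStudy",
    "reconstruction_scores",
    "auc_from_pvalues",
    "pair_pvalue_table",
    "paired_ttest",
    "ensemble_experiment",
    "restricted_ensembles",
    "enumerate_two_agent_study",
]

MODELS = ("mixture", "reference-min", "reference-mean", "reference-max")


# -- confusion-matrix scoring ---------------------------------------------


@dataclass(frozen=True)
class ReconstructionScores:
    """Confusion counts and derived metrics over all unordered agent pairs.

    With an empty prediction, precision is reported as 0 and flagged via
    ``empty_prediction`` so ensemble averages stay defined.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    empty_prediction: bool

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            return 0.0
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            return 0.0
        return self.tp / (self.tp + self.fn)

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 0.0 if p + r == 0 else 2 * p * r / (p + r)

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.fn + self.tn
        return (self.tp + self.tn) / total if total else 0.0


def _canonical_pairs(edges: Iterable[tuple[str, str]]) -> set[tuple[str, str]]:
    return {tuple(sorted((str(a), str(b)))) for a, b in edges}


def reconstruction_scores(
    predicted: Iterable[tuple[str, str]], truth: nx.Graph
) -> ReconstructionScores:
    """Score a predicted edge set against the ground-truth graph."""
    nodes = {str(n) for n in truth.nodes}
    pred = _canonical_pairs(predicted)
    stray = {p for p in pred if not set(p) <= nodes}
    if stray:
        raise ValueError(f"predicted edges reference unknown nodes: {sorted(stray)[:3]}")
    true_edges = _canonical_pairs(truth.edges)
    n = len(nodes)
    all_pairs = n * (n - 1) // 2
    tp = len(pred & true_edges)
    fp = len(pred - true_edges)
    fn = len(true_edges - pred)
    tn = all_pairs - tp - fp - fn
    return ReconstructionScores(tp=tp, fp=fp, fn=fn, tn=tn, empty_prediction=not pred)


def auc_from_pvalues(
    pvalues: Mapping[tuple[str, str], float], truth: nx.Graph
) -> float:
    """Rank-based (Mann-Whitney) AUC of the score 1-p against edge labels.

    Every unordered pair of ground-truth nodes enters; pairs missing from
    ``pvalues`` are scored as p = 1.  Ties receive average ranks.  Returns
    NaN (with a warning) when the labels are degenerate.
    """
    nodes = sorted(str(n) for n in truth.nodes)
    true_edges = _canonical_pairs(truth.edges)
    scores, labels = [], []
    for pair in itertools.combinations(nodes, 2):
        scores.append(1.0 - float(pvalues.get(pair, 1.0)))
        labels.append(pair in true_edges)
    labels_arr = np.asarray(labels)
    n_pos = int(labels_arr.sum())
    n_neg = labels_arr.size - n_pos
    if n_pos == 0 or n_neg == 0:
        logger.warning("degenerate labels (all edges or none): AUC undefined")
        return float("nan")
    ranks = sps.rankdata(scores)
    return float((ranks[labels_arr].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# -- per-network p-value tables -------------------------------------------


def pair_pvalue_table(
    net: TypedBipartiteNetwork,
    nodes: Sequence[str] | None = None,
    preference_mode: str = "per_agent",
) -> pd.DataFrame:
    """Mixture and per-type-reference p-values for every unordered pair.

    One row per pair of ``nodes`` (default: all agents), with columns
    agent_i, agent_j, eligible (both degrees > 0) and one p-value column
    per model in :data:`MODELS`.  Ineligible pairs carry p = 1.
    """
    agents = sorted(str(n) for n in (nodes if nodes is not None else net.agents))
    counts = {a: net.type_counts(a) for a in agents}
    degrees = {a: int(counts[a].sum()) for a in agents}
    pairs = list(itertools.combinations(agents, 2))
    n_types = net.link_types.n_types
    n = net.n_events

    mix = np.ones(len(pairs))
    ref_xs = np.zeros((len(pairs), n_types), dtype=np.int64)
    ref_ys = np.zeros_like(ref_xs)
    ref_obs = np.zeros_like(ref_xs)
    eligible = np.zeros(len(pairs), dtype=bool)
    for idx, (i, j) in enumerate(pairs):
        if degrees[i] == 0 or degrees[j] == 0:
            continue
        eligible[idx] = True
        st = pair_statistics(net, i, j, preference_mode=preference_mode)
        mix[idx] = hb_mixture_survival(
            st.same_type, _mixture_params(n, st.degree_i, st.degree_j, st.p_same)
        )
        ref_xs[idx] = np.minimum(counts[i], counts[j])
        ref_ys[idx] = np.maximum(counts[i], counts[j])
        ref_obs[idx] = st.per_type_overlap
    # one vectorized survival call for all pairs x types
    ref = np.ones((len(pairs), n_types))
    if eligible.any():
        e = eligible
        ref[e] = sps.hypergeom.sf(ref_obs[e] - 1, n, ref_xs[e], ref_ys[e])
        ref = np.clip(ref, 0.0, 1.0)
    df = pd.DataFrame(pairs, columns=["agent_i", "agent_j"])
    df["eligible"] = eligible
    df["mixture"] = mix
    df["reference-min"] = np.where(eligible, ref.min(axis=1), 1.0)
    df["reference-mean"] = np.where(eligible, ref.mean(axis=1), 1.0)
    df["reference-max"] = np.where(eligible, ref.max(axis=1), 1.0)
    return df


# -- paired tests ----------------------------------------------------------


def paired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Paired two-sample t-test (t statistic, two-sided p-value).

    Zero-variance differences are handled explicitly: identical samples
    give p = 1; a constant non-zero difference gives p = 0.
    """
    diffs = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if diffs.size < 2 or np.ptp(diffs) == 0.0:
        if np.allclose(diffs, 0.0):
            return 0.0, 1.0
        return math.copysign(math.inf, float(diffs.mean())), 0.0
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


# -- ensemble experiment ---------------------------------------------------


@dataclass(frozen=True)
class EnsembleSummary:
    """Benchmark results over an ensemble of simulated bipartite networks.

    ``auc`` holds one row per simulation, one column per model;
    ``scores`` is tidy (one row per simulation x alpha x model);
    ``summary`` aggregates per alpha: mixture means, mean paired differences
    against the reference, paired t-test p-values, and the fraction of runs
    where the mixture matched or beat the reference.
    """

    n_sims: int
    alpha_grid: tuple[float, ...]
    reference_model: str
    auc: pd.DataFrame
    auc_mean: dict[str, float]
    auc_ttest: dict[str, float]
    scores: pd.DataFrame
    summary: pd.DataFrame


_METRICS = ("precision", "recall", "f1", "accuracy")


def ensemble_experiment(
    graph: nx.Graph,
    config: SimulationConfig,
    n_sims: int,
    alpha_grid: Sequence[float] = tuple(10.0 ** -k for k in range(10, 0, -1)),
    models: Sequence[str] = MODELS,
    seed: int | None = None,
    reference_model: str = "reference-min",
) -> EnsembleSummary:
    """Simulate ``n_sims`` bipartite networks and benchmark reconstruction.

    Each simulation draws fresh agent attributes, generates a network,
    computes per-pair p-values under every model, the AUC against the
    ground-truth adjacency, and Bonferroni-thresholded edge-set scores at
    each alpha (m = number of eligible pairs).  The whole experiment is a
    pure function of (graph, config, n_sims, seed).
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2 for paired comparisons")
    if reference_model not in models:
        raise ValueError(f"reference_model {reference_model!r} not among models")
    base = seed if seed is not None else config.seed
    children = np.random.SeedSequence(base).spawn(n_sims)
    nodes = sorted(str(n) for n in graph.nodes)
    truth_edges = _canonical_pairs(graph.edges)

    auc_rows, score_rows = [], []
    for s, child in enumerate(children):
        rng = np.random.default_rng(child)
        net, _ = simulate_network(graph, config, rng)
        table = pair_pvalue_table(net, nodes=nodes)
        pair_index = list(zip(table["agent_i"], table["agent_j"]))
        m = int(table["eligible"].sum())
        auc_rows.append(
            {
                "sim": s,
                **{
                    mod: auc_from_pvalues(dict(zip(pair_index, table[mod])), graph)
                    for mod in models
                },
            }
        )
        for alpha in alpha_grid:
            threshold = alpha / m if m else alpha
            for mod in models:
                keep = table[mod].to_numpy() <= threshold
                predicted = [pair_index[k] for k in np.flatnonzero(keep)]
                sc = reconstruction_scores(predicted, graph)
                score_rows.append(
                    {
                        "sim": s,
                        "alpha": alpha,
                        "model": mod,
                        "n_edges": len(predicted),
                        "precision": sc.precision,
                        "recall": sc.recall,
                        "f1": sc.f1,
                        "accuracy": sc.accuracy,
                        "empty_prediction": sc.empty_prediction,
                    }
                )
    auc = pd.DataFrame(auc_rows).set_index("sim")
    scores = pd.DataFrame(score_rows)
    auc_mean = {mod: float(auc[mod].mean()) for mod in models}
    t, p = paired_ttest(auc["mixture"].to_numpy(), auc[reference_model].to_numpy())
    auc_ttest = {
        "t": t,
        "p_value": p,
        "frac_ge": float((auc["mixture"] >= auc[reference_model]).mean()),
    }

    rows = []
    for alpha in alpha_grid:
        at = scores[scores["alpha"] == alpha]
        mix = at[at["model"] == "mixture"].set_index("sim")
        ref = at[at["model"] == reference_model].set_index("sim")
        row: dict[str, float] = {"alpha": alpha}
        for metric in _METRICS:
            a, b = mix[metric].to_numpy(), ref[metric].to_numpy()
            _, pval = paired_ttest(a, b)
            row[f"mean_{metric}"] = float(a.mean())
            row[f"dmean_{metric}"] = float((a - b).mean())
            row[f"ttest_p_{metric}"] = pval
            row[f"frac_ge_{metric}"] = float((a >= b).mean())
        rows.append(row)
    summary = pd.DataFrame(rows)
    return EnsembleSummary(
        n_sims=n_sims,
        alpha_grid=tuple(alpha_grid),
        reference_model=reference_model,
        auc=auc,
        auc_mean=auc_mean,
        auc_ttest=auc_ttest,
        scores=scores,
        summary=summary,
    )


def restricted_ensembles(
    graph: nx.Graph,
    base_config: SimulationConfig,
    restrictions: Mapping[str, dict],
    n_sims: int,
    seed: int | None = None,
    **kwargs,
) -> dict[str, EnsembleSummary]:
    """Run the ensemble experiment under named attribute restrictions.

    Each entry of ``restrictions`` maps a label to SimulationConfig field
    overrides (e.g. ``{"high_activity": {"connect_range": (0.8, 1.0)}}``).
    """
    from dataclasses import replace

    out = {}
    for k, (name, overrides) in enumerate(sorted(restrictions.items())):
        cfg = replace(base_config, **overrides)
        child_seed = None if seed is None else (seed * 1000 + k) % (2**31)
        out[name] = ensemble_experiment(
            graph, cfg, n_sims, seed=child_seed, **kwargs
        )
    return out


# -- exhaustive two-agent configuration study ------------------------------


@lru_cache(maxsize=None)
def _compositions(total: int, parts: int) -> np.ndarray:
    """All compositions of ``total`` into ``parts`` non-negative integers."""
    if parts == 1:
        return np.array([[total]], dtype=np.int64)
    blocks = []
    for first in range(total + 1):
        rest = _compositions(total - first, parts - 1)
        blocks.append(
            np.column_stack([np.full(len(rest), first, dtype=np.int64), rest])
        )
    return np.vstack(blocks)


def _count_classes(n_events: int, n_types: int) -> int:
    """Upper bound on sufficient-statistic rows (before feasibility filtering)."""
    total = 0
    for ni in range(1, n_events + 1):
        for nj in range(ni, n_events + 1):
            x = _compositions(ni, n_types)
            y = _compositions(nj, n_types)
            mins = np.minimum(x[:, None, :], y[None, :, :])
            total += int(np.prod(mins + 1, axis=2).sum())
    return total


def _reference_tail_table(n_events: int) -> np.ndarray:
    """T[x, y, s] = hypergeometric upper tail P(X >= s | N, x, y), flattened."""
    g = n_events + 1
    x, y, s = np.meshgrid(np.arange(g), np.arange(g), np.arange(g), indexing="ij")
    table = sps.hypergeom.sf(s - 1, n_events, x, y)
    return np.clip(np.nan_to_num(table, nan=0.0), 0.0, 1.0).ravel()


def _mixture_table(n_events: int, ni: int, nj: int, nums: np.ndarray) -> np.ndarray:
    """M[u, k] = mixture tail P(Y >= k | N, ni, nj, nums[u] / (ni * nj))."""
    mmax = min(ni, nj)
    xs = np.arange(mmax + 1)
    pmf = sps.hypergeom.pmf(xs, n_events, ni, nj)
    ps = nums.astype(float) / (ni * nj)
    table = np.empty((len(nums), mmax + 1))
    table[:, 0] = 1.0
    for k in range(1, mmax + 1):
        btail = sps.binom.sf(k - 1, xs[k:][None, :], ps[:, None])
        table[:, k] = np.minimum((pmf[k:][None, :] * btail).sum(axis=1), 1.0)
    return table


@dataclass(frozen=True)
class TwoAgentStudy:
    """Exhaustive study of all two-agent bipartite configurations.

    Configurations are the feasible sufficient-statistic classes: per-type
    degree vectors of both agents plus per-type same-type overlaps; all
    computed p-values depend only on these.  ``cells`` groups the mixture
    p-value by concentration (Herfindahl-Hirschman) and overlap fraction;
    ``validated`` gives the fraction of configurations below each alpha per
    method; ``minima`` the smallest p-value each method ever produced.
    """

    n_events: int
    n_types: int
    weighting: str
    n_configurations: float
    cells: pd.DataFrame
    validated: pd.DataFrame
    minima: dict[str, float]


def _iter_classes_weighted(n_events: int, n_types: int):
    """Brute-force (x, y, s, weight) over all labeled contingency tables.

    Weight is the multinomial count of labeled event assignments per table.
    Only tractable for small ``n_events``; used for multiplicity weighting.
    """
    g = n_types + 1  # type indices 1..n_types; 0 = absent
    cells = list(itertools.product(range(g), repeat=2))
    n_cells = len(cells)
    n_tables = math.comb(n_events + n_cells - 1, n_cells - 1)
    if n_tables > 2_000_000:
        raise ValueError(
            f"multiplicity weighting needs {n_tables} labeled tables at "
            f"n_events={n_events}; use a smaller n_events or weighting='none'"
        )
    factorial = [math.factorial(k) for k in range(n_events + 1)]
    for combo in itertools.combinations(range(n_events + n_cells - 1), n_cells - 1):
        counts = []
        prev = -1
        for c in combo:
            counts.append(c - prev - 1)
            prev = c
        counts.append(n_events + n_cells - 2 - prev)
        x = np.zeros(n_types, dtype=np.int64)
        y = np.zeros(n_types, dtype=np.int64)
        s = np.zeros(n_types, dtype=np.int64)
        weight = factorial[n_events]
        for (ti, tj), cnt in zip(cells, counts):
            weight //= factorial[cnt]
            if ti > 0:
                x[ti - 1] += cnt
            if tj > 0:
                y[tj - 1] += cnt
            if ti > 0 and ti == tj:
                s[ti - 1] += cnt
        if x.sum() == 0 or y.sum() == 0:
            continue
        yield x, y, s, weight


def enumerate_two_agent_study(
    n_events: int = 20,
    n_types: int = 3,
    alpha_grid: Sequence[float] | None = None,
    hh_bin_edges: Sequence[float] | None = None,
    overlap_bin_edges: Sequence[float] | None = None,
    weighting: str = "none",
    max_classes: int = 400_000_000,
    chunk_rows: int = 2_000_000,
) -> TwoAgentStudy:
    """Enumerate every two-agent bipartite configuration and compare methods.

    Iterates all feasible sufficient-statistic classes with degrees
    1 <= N_i, N_j <= n_events and computes, per class, the mixture p-value
    and the per-type reference p-values (min/mean/max aggregations).
    ``weighting="multiplicity"`` weights each class by its number of labeled
    event assignments (brute force; small ``n_events`` only).

    Classes with zero same-type overlap enter the validated fractions and
    minima (their p-values are 1) but not the concentration cells, where
    the Herfindahl-Hirschman index is undefined.
    """
    if n_types < 1 or n_events < 1:
        raise ValueError("n_events and n_types must be >= 1")
    if weighting not in ("none", "multiplicity"):
        raise ValueError(f"unknown weighting {weighting!r}")
    n_raw = _count_classes(n_events, n_types)
    if weighting == "none" and n_raw > max_classes:
        raise ValueError(
            f"enumeration would visit ~{n_raw} classes; reduce n_events "
            f"(currently {n_events}) or raise max_classes"
        )
    alphas = np.asarray(
        alpha_grid if alpha_grid is not None else np.logspace(-12, -1, 23), dtype=float
    )
    hh_edges = np.asarray(
        hh_bin_edges if hh_bin_edges is not None else np.linspace(1.0 / n_types, 1.0, 8)
    )
    ov_edges = np.asarray(
        overlap_bin_edges if overlap_bin_edges is not None else np.linspace(0.0, 1.0, 11)
    )
    n_hh, n_ov = len(hh_edges) - 1, len(ov_edges) - 1
    methods = list(MODELS)

    total_weight = 0.0
    validated_counts = {mod: np.zeros(len(alphas)) for mod in methods}
    minima = {mod: 1.0 for mod in methods}
    cell_count = np.zeros(n_hh * n_ov)
    cell_mix_sum = np.zeros(n_hh * n_ov)
    cell_better = np.zeros(n_hh * n_ov)
    t_flat = _reference_tail_table(n_events)
    g = n_events + 1

    def _accumulate(mixp, ref3, ntil, s2, weight):
        nonlocal total_weight
        refmin = ref3.min(axis=1)
        refmean = ref3.mean(axis=1)
        refmax = ref3.max(axis=1)
        per_method = {
            "mixture": mixp,
            "reference-min": refmin,
            "reference-mean": refmean,
            "reference-max": refmax,
        }
        w_sum = weight.sum() if isinstance(weight, np.ndarray) else weight * len(mixp)
        total_weight += w_sum
        for mod, vals in per_method.items():
            if len(vals):
                minima[mod] = min(minima[mod], float(vals.min()))
            le = vals[None, :] <= alphas[:, None]
            if isinstance(weight, np.ndarray):
                validated_counts[mod] += le @ weight
            else:
                validated_counts[mod] += weight * le.sum(axis=1)
        pos = ntil > 0
        if not pos.any():
            return
        hh = s2[pos] / ntil[pos].astype(float) ** 2
        ov = ntil[pos] / n_events
        hh_bin = np.clip(np.digitize(hh, hh_edges[1:-1]), 0, n_hh - 1)
        ov_bin = np.clip(np.digitize(ov, ov_edges[1:-1]), 0, n_ov - 1)
        cell = hh_bin * n_ov + ov_bin
        w_pos = weight[pos] if isinstance(weight, np.ndarray) else weight
        np.add.at(cell_count, cell, w_pos)
        np.add.at(cell_mix_sum, cell, mixp[pos] * w_pos)
        np.add.at(cell_better, cell, (mixp[pos] < refmin[pos]) * w_pos)

    if weighting == "multiplicity":
        for x, y, s, weight in _iter_classes_weighted(n_events, n_types):
            ni, nj = int(x.sum()), int(y.sum())
            ntil = int(s.sum())
            num = int(x @ y)
            p = num / (ni * nj)
            mixp = hb_mixture_survival(
                ntil, NullParams(n_events, min(ni, nj), max(ni, nj), p)
            )
            ref3 = t_flat[(x * g + y) * g + s]
            _accumulate(
                np.array([mixp]),
                ref3[None, :],
                np.array([ntil]),
                np.array([int((s**2).sum())]),
                np.array([float(weight)]),
            )
    else:
        for ni in range(1, n_events + 1):
            for nj in range(ni, n_events + 1):
                block_w = 1.0 if ni == nj else 2.0  # unordered agent symmetry
                x = _compositions(ni, n_types)
                y = _compositions(nj, n_types)
                cx, cy = len(x), len(y)
                num = (x @ y.T).ravel()
                nums_unique, num_inv = np.unique(num, return_inverse=True)
                mix_table = _mixture_table(n_events, ni, nj, nums_unique)
                xf = np.repeat(x, cy, axis=0)
                yf = np.tile(y, (cx, 1))
                ref_key = (xf * g + yf) * g
                mins = np.minimum(xf, yf)
                tri_unique, tri_inv = np.unique(mins, axis=0, return_inverse=True)
                order = np.argsort(tri_inv, kind="stable")
                bounds = np.searchsorted(tri_inv[order], np.arange(len(tri_unique) + 1))
                for t_idx in range(len(tri_unique)):
                    members = order[bounds[t_idx] : bounds[t_idx + 1]]
                    grid = tri_unique[t_idx] + 1
                    s_grid = (
                        np.indices(grid).reshape(n_types, -1).T.astype(np.int64)
                    )
                    ntil = s_grid.sum(axis=1)
                    s2 = (s_grid**2).sum(axis=1)
                    n_s = len(s_grid)
                    step = max(1, chunk_rows // n_s)
                    for lo in range(0, len(members), step):
                        ch = members[lo : lo + step]
                        u = xf[ch][:, None, :] - s_grid[None, :, :]
                        v = yf[ch][:, None, :] - s_grid[None, :, :]
                        spare_i = ni - ntil
                        spare_j = nj - ntil
                        forced = ni + nj - ntil - n_events
                        cross_cap = np.minimum(
                            np.minimum(spare_i, spare_j)[None, :],
                            (spare_i + spare_j)[None, :] - (u + v).max(axis=2),
                        )
                        feas = forced[None, :] <= cross_cap
                        mixp = mix_table[num_inv[ch][:, None], ntil[None, :]]
                        ref3 = t_flat[ref_key[ch][:, None, :] + s_grid[None, :, :]]
                        keep = feas.ravel()
                        _accumulate(
                            mixp.ravel()[keep],
                            ref3.reshape(-1, n_types)[keep],
                            np.broadcast_to(ntil, feas.shape).ravel()[keep],
                            np.broadcast_to(s2, feas.shape).ravel()[keep],
                            block_w,
                        )

    validated = pd.DataFrame(
        [
            {"alpha": a, "method": mod, "fraction": validated_counts[mod][k] / total_weight}
            for k, a in enumerate(alphas)
            for mod in methods
        ]
    )
    cell_rows = []
    for hb in range(n_hh):
        for ob in range(n_ov):
            c = hb * n_ov + ob
            if cell_count[c] == 0:
                continue
            cell_rows.append(
                {
                    "hh_low": hh_edges[hb],
                    "hh_high": hh_edges[hb + 1],
                    "overlap_low": ov_edges[ob],
                    "overlap_high": ov_edges[ob + 1],
                    "n": cell_count[c],
                    "mean_mixture_p": cell_mix_sum[c] / cell_count[c],
                    "frac_mixture_lt_refmin": cell_better[c] / cell_count[c],
                }
            )
    return TwoAgentStudy(
        n_events=n_events,
        n_types=n_types,
        weighting=weighting,
        n_configurations=total_weight,
        cells=pd.DataFrame(cell_rows),
        validated=validated,
        minima=minima,
    )
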