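# biproj

Statistically validated, optionally signed, one-mode projections of
bipartite networks whose links carry qualitative types.

Many systems are observed as agent-event bipartite data in which each
connection has a *type*: parliament members cast support / oppose / abstain
votes on motions; investors buy, sell, or day-trade a stock on given days;
species interact with sites in qualitatively different ways.  Direct
agent-agent relationships are unobserved and must be inferred from
co-behavior.  `biproj` links two agents only when their typed overlap is
statistically incompatible with a null model of random, independent
behavior, producing a monopartite projection free of spurious links.

## The model

For agents *i*, *j* over *N* events with degrees `N_i`, `N_j`, let `Ñ_ij`
be the number of events both attend **via the same link type**, and
`p_ij = Σ_k p_i(a_k) p_j(a_k)` the chance they pick the same type at a
joint event, with `p_i` the empirical type-preference vector of agent *i*.
Under the null — both agents pick events uniformly at random and types
independently from their preferences — the same-type overlap follows a
hypergeometric-binomial mixture, with upper tail

```
P(Y ≥ Ñ_ij | N, N_i, N_j, p_ij) = Σ_{X=Ñ_ij}^{min(N_i,N_j)} H(X | N, N_i, N_j) · B(Y ≥ Ñ_ij | X, p_ij)
```

where `H` is the hypergeometric pmf and `B` the binomial survival
function.  Small tails mean a *positive* link.  Replacing `Ñ_ij` with the
opposing-type overlap `N^d_ij` and `p_ij` with the opposing-chance
`q_ij = Σ_{(a+,a−)} p_i(a+)p_j(a−) + p_i(a−)p_j(a+)` tests for *negative*
links, yielding a signed network amenable to structural-balance analysis
(a triangle is stable iff the product of its edge signs is positive).

The classical per-type hypergeometric null (validate each link type
separately, aggregate the p-values by min / mean / max) is implemented as
the reference model, and an independent-cascade-style influence simulator
generates synthetic benchmarks from a known ground-truth graph (the
Zachary karate club, 34 nodes / 78 edges, is bundled).

## Worked example

The bundled two-agent network (2 agents, 100 events, 3 link types, type
`a1` neutral, `a2`/`a3` opposing) illustrates why typed validation matters:

```python
>>> import biproj as bp
>>> net = bp.two_agent_example()
>>> st = bp.pair_statistics(net, "i", "j")
>>> st.co_events, st.same_type, st.opposing_type
(21, 2, 17)
>>> bp.validate_pair_reference(net, "i", "j", aggregation="min")
0.0035868893011750153
>>> bp.validate_pair(net, "i", "j", mode="positive")[0]
0.9666852125776149
>>> bp.validate_pair(net, "i", "j", mode="negative")[0]
1.702082031341309e-07
```

The per-type reference null flags the pair as significantly similar
(p = 3.6e-3) because both rarely use type `a1` yet share two `a1` events —
overlap in a rare type dominates.  Taking all types together, the mixture
null finds no significant similarity (p = 0.967): two same-type events out
of 21 joint ones is unremarkable given these preferences.  It instead
finds a strongly significant *negative* link (p = 1.7e-7) from the 17
joint events with opposing types.  `bp.project(net, alpha=0.01)`
accordingly returns a single negative edge.

On the synthetic benchmark (influence model on the karate club, 100
events, 3 types, 200 simulations) the mixture model separates true from
false edges with mean AUC ≈ 0.79 versus ≈ 0.78 for the best (min-
aggregated) reference, and the model ordering
mixture > reference-min > reference-mean > reference-max holds throughout.

## Command line

```
biproj simulate --graph karate --events 100 --seed 7 --out net.tsv
biproj project  --input net.tsv --config types.json --alpha 0.01 --model mixture --out edges.tsv
biproj evaluate --graph karate --sims 200 --seed 1 --out summary.tsv
biproj enumerate --events 20 --types 3 --out study.tsv
```

Every command writes a resolved-config JSON next to its outputs and is
deterministic under a fixed seed.

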