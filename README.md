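# bcdbn — exact structure learning of dynamic Bayesian networks

`bcdbn` learns the structure of discrete-valued stochastic processes —
e.g. discretised gene-expression time courses, clinical trajectories, or
any multivariate categorical time series — as a **dynamic Bayesian network
(DBN)**: a prior over the first *m* slices plus transition networks giving
every variable `X_i[t+1]` a set of *inter-slice* parents (from slices
`t−m+1..t`) and *intra-slice* parents (within slice `t+1`).

Learning transition networks with unrestricted intra-slice structure is
NP-hard, so the package implements two exact polynomial-time learners over
restricted — but still expressive — search spaces, under decomposable
log-likelihood (LL) or minimum description length (MDL) scores:

* **tDBN** — the intra-slice graph is a spanning tree: each node gets
  exactly one intra parent (except the root) plus at most *p* past
  parents.  The tree is the maximum-weight spanning arborescence (Chu–Liu/
  Edmonds) of the gain graph.
* **bcDBN** — the intra-slice graph may have in-degree up to *k*, as long
  as every edge points forward in the breadth-first-search (BFS) order of
  the optimal branching.  This space is exponentially larger than the tree
  space, yet a total order over the slice makes per-node parent selection
  independent, so the optimum is found exactly in polynomial time.

The gain of the candidate intra edge `X_j[t+1] → X_i[t+1]` is

    e_ij = s_ij − s_i,
    s_i  = max_{|P| ≤ p} ϕ_i(P),      s_ij = max_{|P| ≤ p} ϕ_i(P ∪ {X_j[t+1]}),

with ϕ_i the local LL or MDL score; after Edmonds' algorithm and the BFS
ordering, each node's past set (≤ *p*) and intra set (≤ *k*, drawn from
its BFS predecessors) are maximised jointly by exhaustive subset search.
MDL scores each node as `LL_i − ½ ln(N)(r_i−1)q_i` with *N* the number of
transition rows.

The package also ships a simulator (random transition structures, Dirichlet
CPTs with an optional strong-dependence floor, forward sampling), recovery
metrics (precision/recall/F1 on exact directed edges), a benchmark runner
with confidence intervals, CSV/edge-list/DOT I/O and a small CLI.

## Worked example

`examples/01_simulate_and_learn.py` draws a 5-variable transition network
with a complete BFS-consistent intra graph (k=2) and 2 past parents per
node, samples 2000 transition rows, and learns it back with bcDBN+MDL:

```
# transition network n=5 m=1 attrs=X0,X1,X2,X3,X4
X0[t] -> X3[t+1]
X1[t] -> X0[t+1]
...
X2[t+1] -> X3[t+1]
X4[t+1] -> X0[t+1]

score of learned structure: -3302.47
recovery vs truth: TP=17 FP=0 FN=0 precision=1.00 recall=1.00 F1=1.00
```

All 17 true edges (inter- and intra-slice) are recovered with no false
positives: at this sample size the MDL-optimal BFS-consistent structure is
the generating one.  `examples/02_tdbn_vs_bcdbn.py` shows the score gap to
the tree-restricted baseline on the same data (bcDBN gains +260.85 in MDL
score, using 8 intra edges where the tree allows 5), and
`examples/03_recovery_benchmark.py` prints a benchmark table of mean
precision/recall/F1 ± 95% CI over sample sizes for all four
learner/criterion combinations.

Equivalently from the shell:

```
bcdbn simulate -n 5 -p 2 -k 2 -N 2000 --dominance 0.8 --seed 1 -o sim
bcdbn learn -i sim.csv -p 2 -k 2 -s mdl -o fit --dot
bcdbn evaluate --truth sim.truth.edges --learned fit.edges
```

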