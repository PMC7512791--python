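# Methods

## Model

A discrete dynamic Bayesian network over attributes `X_1..X_n`, each with
`r_i ≥ 2` states, factorises one transition window `{t−m+1..t} → t+1` as

    P(X[t+1] | X[t−m+1..t]) = ∏_i P(X_i[t+1] | Pa_i),

where `Pa_i` splits into inter-slice (past) parents and intra-slice
parents, and *m* is the Markov lag.  Inter-slice edges always point forward
in time; the intra-slice graph must be acyclic.  A stationary process
shares one transition network across windows; a non-stationary one keeps
one per window.  The prior over the initial *m* slices is represented
(intra-slice-only network, or independent uniform when absent) but never
learned: learning and evaluation target transition networks only, and the
simulator's trajectories start from the uniform prior by default since the
benchmark protocol never conditions on a particular initial distribution.

State codes are 0-based in label order.  Parent configurations are indexed
by mixed-radix encoding over the canonical parent order (sorted by
(slice, attr)), with the last parent as least significant digit.  The
encoding is arbitrary but fixed and documented; all counting, CPT and
sampling code shares it.

## Scores

Both criteria are decomposable, natural-log, and evaluated per node from
the counts `N_ijk` over transition rows:

* `LL_i = Σ_jk N_ijk ln(N_ijk / N_ij)` with `0·ln 0 := 0`;
* `MDL_i = LL_i − ½ ln(N) (r_i − 1) q_i`.

One log base must serve both terms for them to be commensurable; natural
log matches the penalty's `ln(N)`.  The penalty is structural: parent
configurations never observed in the data still count toward `q_i`.  *N*
is the number of transition rows actually scored — `N_subjects·(T−m+1)`
when stationary learning pools all windows, the single window's row count
otherwise.  CPT export uses the observed frequency estimate
`(N_ijk + α)/(N_ij + r_i α)` with pseudo-count α (default 0; unobserved
rows fall back to uniform).

Scores are memoised per (child, canonical parent set): the edge-weight
computation and the final parent selection revisit many overlapping sets,
and for singleton intra sets they coincide exactly.

## Learners

Both learners first compute, for every child *i*, the best past-parent
score `s_i` over all subsets of the `n·m` past candidates of size ≤ *p*,
and for every ordered pair the best score `s_ij` with `X_j[t+1]` forced
in.  Candidate subsets are enumerated size-ascending, then
lexicographically; a running maximum with strict `>` keeps the **first**
maximiser, which deterministically prefers smaller, earlier parent sets on
ties.  Score comparisons are exact floating-point — no epsilon — so
identical inputs give bit-identical structures.

The complete directed graph over slice `t+1` weighted with
`e_ij = s_ij − s_i` feeds the Chu–Liu/Edmonds algorithm (implemented
in-package; ties between equal-weight incoming edges keep the smaller
source index, cycle contraction is deterministic).  Two modes:

* **spanning** (default): best single-root spanning arborescence, matching
  the tree the tDBN baseline needs; negative gains are tolerated because
  the tree must span.
* **forest**: the literal maximum branching; non-positive edges are
  dropped, possibly leaving several roots.

The BFS of the branching — roots seeded ascending, children visited in
ascending index, FIFO frontier — yields a total order.  A node's
*ancestors* are its **full BFS prefix**, not merely the root-to-node path:
the prefix reading gives the larger search space, matches the claimed
`O(n^k)` per-node subset count, and is required for the exactness argument
(any BFS-consistent graph's parent sets are subsets of prefixes).

bcDBN then maximises each node's (past ≤ *p*) × (intra ≤ *k* within
ancestors) parent sets jointly by exhaustive enumeration (past outer loop,
intra inner).  Decomposability plus the shared total order make these
per-node optima globally optimal among all BFS-consistent structures, and
acyclicity is automatic.  tDBN instead keeps the arborescence's edges and,
for each non-root child with tree parent *j*, the cached argmax past set
of `s_ij` (the root uses the `s_i` argmax); its total score therefore
equals the branching weight plus `Σ_i s_i`, an identity the tests check
exactly.  The tDBN tree lies inside the bcDBN space for `k ≥ 1`, so
bcDBN's score dominates tDBN's on any dataset.

Worst-case cost is polynomial in *n* and *r* and exponential only in *p*
and *k*; a regression test pins this by counting distinct score
evaluations at doubled *n*.

## Simulator

The generator draws a uniformly random total order over the slice, then:

* `complete_intra` — the node at rank *i* takes its `min(k, i)` nearest
  predecessors as intra parents (the "complete" BFS-consistent k-graph);
* `tree` — each non-first node takes exactly one uniform predecessor
  (random spanning tree, the tDBN-structured truth);
* `random` — a uniform subset of predecessors of uniform size
  `0..min(k, i)`.

Past parents are a uniform subset of the `n·m` candidates: of size exactly
*p* in the complete and tree modes — "complete" truths saturate the
in-degree bound, so the learner's search-space boundary coincides with the
truth's in-degrees — and of uniform size `0..p` in random mode.

CPT rows are symmetric Dirichlet(concentration, default 1).  With the
`dominance` option (recovery experiments use 0.8), one uniformly chosen
state per row is **rescaled** into `[dominance, 1]` by a strictly monotone
map (`d + (1−d)·p`), the rest renormalised.  The monotone map — rather
than a hard floor at `dominance` — keeps distinct Dirichlet rows distinct:
with a hard floor and binary states most rows collapse to exactly
`(d, 1−d)`, so rows differing in one parent's value coincide with
probability ≈ ½ and the drawn graph is not faithful to its distribution —
such edges are unrecoverable by any method and recovery metrics against
the drawn graph become meaningless.  `dominance = 1` still yields
deterministic CPTs.

Forward sampling draws the initial *m* slices from the prior, then each
slice child-by-child in intra-topological order, conditioning on realised
parents; one `numpy` Generator seeds structure, CPTs and trajectories.

What the generator does **not** emulate: real discretised expression data
has measurement noise, non-stationarity, hidden confounders, unequal
cardinalities and missing values.  Passing recovery tests therefore shows
the learners are correct and statistically efficient under the model's own
assumptions, not that any particular biological network is recoverable.

## Recovery evaluation

Precision, recall and F1 are computed on exact directed-edge identity over
the union of inter- and intra-slice edges (prior network excluded;
direction reversals count as both a FP and a FN).  Degenerate 0/0 ratios
are reported as 0 — not NaN — so means over trials stay defined.  The
benchmark runner repeats generate → sample → learn → compare with trial
*t* seeded `seed + t`, samples `T = m` slices so that *N* counts
transition rows, and reports mean ± `1.96·sd/√trials` (a Student-t
interval is available via `ci="t"`).

In the two headline regimes (5 trials, dominance 0.8) the package obtains
≈ 90–95% average recall for bcDBN+MDL on the complete n=5, p=k=2 truth at
N=2000, and 100% average precision on the tree n=10, p=2, k=1 truth at
N=1000.  Residual recall losses trace to two effects: (i) a sampled parent
can still be weakly informative, so the MDL penalty correctly drops it at
finite N; (ii) when several of a node's ancestors explain it comparably,
the single-parent gain tree flattens, and BFS index tie-breaking can place
a true intra parent after its child, removing that edge from the search
space.  Both effects depend on the arbitrary CPT draw, which is why these
numbers are reported with confidence intervals.

## Numerical and degenerate-input choices

* CPT rows must sum to 1 within 1e−12 (generator rows are renormalised
  exactly); `log_joint` returns −∞ on any zero factor.
* Empty datasets, `T < m`, out-of-range state codes, self-parents and
  intra-slice cycles raise `ValueError` with specific messages; CSV
  dialect violations raise `DataFormatError` naming the offending
  row/column.
* A constant data column is padded with a synthetic second state label so
  every attribute remains a genuine variable (`r_i ≥ 2`).
* `n = 1` learns with no intra edges; `k = 0` reduces bcDBN to a pure
  inter-slice learner; `p = 0` leaves only intra structure.

## Problem sizes used in the shipped checks

Exhaustive-oracle comparisons run at n ≤ 4–5, N ≤ 60, where brute-force
enumeration is exact and fast; recovery benchmarks use the regimes above
(n ≤ 10, N ≤ 2000, 5 trials).  These sizes make every guarantee checkable
by enumeration or within-CI comparison while keeping the whole suite in
seconds on one CPU.

## Known limitations

* No hidden variables, missing data, or continuous attributes; no
  Bayesian (BDe/BDeu) or mutual-information scores.
* The prior network is never learned.
* tDBN's root past set is defined via the `s_i` argmax (the score identity
  above is taken as tDBN's definition).
* Forest-mode branchings are provided but the BFS order defaults to the
  spanning arborescence, which is what the tree baseline presupposes.
* Non-stationary sampling is not implemented (non-stationary *learning*
  is).
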