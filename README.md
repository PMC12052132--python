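# morancol

Colonization times of the Moran Birth-death process on directed graphs.

## The problem

Evolutionary graph theory models a spatially structured population as a
directed graph *G* on *n* nodes: each node holds one individual, and an
edge (u, v) means an offspring born at *u* can migrate to *v*.  In the
classic Moran Birth-death process an individual is selected for
reproduction with probability proportional to its fitness and its
offspring replaces a uniformly random out-neighbor.  This package studies
the **colonization limit**: invading mutants have relative fitness
r → ∞, so residents never reproduce — the biology of a species colonizing
an otherwise empty environment.  In that limit the process simplifies to
the *modified* Moran process: each step picks a uniformly random node; if
it is a mutant it reproduces onto a uniform out-neighbor, otherwise
nothing happens.  The **colonization time** T(G, v) is the expected
number of such steps from a single mutant at node *v* until every node is
mutant, and T(G) = max over v of T(G, v).

Key facts the package makes computable and reproducible:

* **General cubic bound.** For every graph, T(G) ≤ ½n³ − ½n², and the
  bound is attained *exactly* by the backward graph B_n (a one-way path
  plus all reverse edges): T(B_n, 0) = ½n³ − ½n².  So while fixation at
  fixed finite r can take exponentially many steps on some digraphs,
  colonization is always polynomial.
* **Undirected and regular graphs are faster.** T ≤ 4n²√n + o(n²√n) for
  undirected graphs, and T = O(n²) for regular (isothermal) graphs.
  Among undirected graphs the star, T(S_n) = n(n−1)H(n−1), is the slowest
  structure known — a constant factor slower than the double star.
* **Three clocks.** Counting classic Moran steps leads to paradoxes — on
  the lollipop graph (a ~√n path feeding a complete cluster), *adding*
  initial mutants *increases* the expected classic step count.  The
  package therefore tracks three measures per trajectory: modified steps,
  classic steps, and **real time**, where one classic step lasts 1/F
  units (F = total population fitness).  In the colonization limit the
  expected real time equals the colonization time divided by n, exactly.

## What's inside

* `morancol.graph_core` — graph container and constructors: complete,
  cycle, star, double star, total order, backward, lollipop, seeded
  random reachable digraphs; reachability/regularity predicates; TSV
  edge-list I/O.
* `morancol.moran_engine` — seeded simulation of both processes with the
  three-measure ledger; per-replicate counter-based substreams.
* `morancol.exact_times` — exact expected times: a monotone mutant-set
  dynamic program (exact rationals up to n = 12), an independent
  brute-force subset oracle, a finite-r absorbing-chain solver, validated
  closed forms, and O(k²)/O(n√n) symmetry-reduced programs for double
  stars and lollipops.
* `morancol.experiments` — scaling curves, exact bound audits, and the
  lollipop crossover scan.
* `morancol` CLI — `simulate`, `exact`, `scaling`, `crossover`, `audit`
  subcommands, all seeded, all emitting CSV.

## Worked example

`examples/lollipop_paradox.py` compares two initializations of the
classic process (r = 10) on the 100-node lollipop — A: one mutant at the
path start; B: the same plus the entire 90-node cluster:

```
lollipop n=100 (path 10, cluster 90), r=10.0, 4000 replicates
  A (1 mutant):           770.5 classic steps
  B (1 + full cluster):    876.1 classic steps
  B - A = +105.6  (20.3 SE)
  real time:  A     1.98   B     0.92 units
```

B starts with 91 of 100 nodes already mutant yet needs ~14% *more*
classic steps: its cluster mutants win almost every selection but cannot
advance the path frontier.  In real time the head start behaves as it
should — B finishes in half the time.  The other examples solve the
backward graph exactly against the cubic bound (`slowest_graph.py`),
check simulation against the exact solver (`simulate_vs_exact.py`),
compare star and double star (`star_vs_double_star.py`), and audit the
bounds on random digraphs (`bound_audit.py`).

A one-liner from the shell:

```sh
$ morancol exact --graph backward --n 10 --start 0
graph,n,start,modified_steps,classic_steps,real_time,states_visited,arithmetic
backward,10,0,450.0,285.0,45.0,10,rational
```

450 = ½·10³ − ½·10² modified steps, of which 285 are classic steps, and
45 = 450/10 units of real time.

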