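# Methods

## Model

A population structure is a directed graph *G* on *n* nodes with no
self-loops and no parallel edges; out-degree 0 is legal (the total-order
graph ends in a sink).  A state is the pair (G, M) with M the mutant set.
Two update rules are implemented:

* **Modified process (colonization limit, r → ∞).**  Each step draws a
  node uniformly from all *n*.  A drawn mutant with out-degree d places an
  offspring on a uniform out-neighbor (a no-op if the target is already a
  mutant); a drawn resident, or a drawn sink, does nothing.  M only
  grows, and if every node is reachable from the initial set the process
  fixes with probability 1 in finite expected time.  The colonization
  time T(G, v) is the expected number of these steps from M = {v}.
* **Classic process (finite r).**  A node is selected with probability
  proportional to fitness (mutants r, residents 1); its offspring
  replaces a uniform out-neighbor, so mutants can be lost and the chain
  has two absorbing states.  Same-type replacements and sink selections
  are counted steps: the process has no retry.

Three time measures are tracked simultaneously: modified steps, classic
steps (reproduction events only), and real time, in which one classic
step lasts 1/F units with F the total population fitness.  At r → ∞ we
take the fitness-1-mutant convention, F = |M|; since a modified step is a
classic step with probability |M|/n, the expected real-time increment per
modified step is exactly 1/n, giving the identity

    E[real time] = E[modified steps] / n        (every graph, every start).

The deterministic real-time mode accrues this expectation (1/n per
modified step), which makes the identity hold per replicate, not just in
expectation; the sampled mode draws exponential holding times with mean
1/F for the continuous-time interpretation, and matches in expectation.

## Exact solvers

**Monotone dynamic program.**  At r → ∞ the chain over mutant sets is
acyclic, so expectations satisfy a one-pass recursion over the reachable
sets: with per-step gain probabilities
p(M → M+w) = (1/n) Σ_{u∈M, w∈N(u)} 1/deg(u) and p_leave their sum,

    E_mod[M] = (1 + Σ_w p_w E_mod[M+w]) / p_leave(M),

and E_cls replaces the leading 1 by |M|/n.  States are canonical bitmask
integers discovered by BFS from the start set, processed in decreasing
popcount order.  Arithmetic is exact `fractions.Fraction` by default for
n ≤ 12 and IEEE float beyond; the state cap (default 2·10⁶) triggers an
explicit refusal naming the count reached, never a silent truncation.

**Brute-force oracle.**  An independent solver enumerates *every* mutant
superset of the start (n ≤ 14) and works from the full one-step kernel —
self-loop mass from idle draws, sink draws, and wasted reproductions is
eliminated explicitly.  The two solvers must agree bit-exactly in
rational mode; the test suite enforces this on all families and on
seeded random digraphs.

**Closed forms** (each re-derived by stage analysis and validated against
the oracle, since their original derivations are not available to us):
backward n²(n−1)/2 — the stage with m mutants has gain probability
1/(nm); complete 2(n−1)H(n−1) — stage gain m(n−m)/(n(n−1)); cycle
n(n−1) — every stage gains with probability exactly 1/n; star
n(n−1)H(n−1), identical from center and leaf starts.  Harmonic numbers
are computed by direct summation (small terms first in float mode).

**Symmetry-reduced programs.**  The double star is solved over states
(center₁, center₂, leaf counts ℓ₁, ℓ₂) — O(k²) states for 2k nodes — and
the lollipop over (path prefix length, cluster mutant count) — O(n√n)
states — exploiting leaf/cluster exchangeability and the strictly
left-to-right colonization of a one-way path.  Both are validated against
the full mutant-set DP at sizes where it is tractable.

**Finite-r absorbing chain.**  For n ≤ 12, the full 2ⁿ-state linear
system (sparse LU) yields fixation probability, unconditional expected
classic steps, and expected real time.  The cap is deliberate: the
finite-r chain is not monotone and the exponential state space is its
true cost; beyond n = 12 the classic simulation engine is the only route.

## Simulation

The colonization engine optionally collapses the run of idle resident
draws before each mutant draw into a single geometric sample
(`skip_idle`, default on); mutant draws are never skipped, so classic
steps and sampled real time remain exact samples, and the ledger is
distributionally identical to the step-by-step run (checked at 4·SE).
The classic engine selects the mutant/resident group by total fitness and
then uniformly within the group (resident selection by rejection over
nodes — cheap in the regimes used here).  `max_steps` (default 10⁹)
truncation is an explicit outcome, excluded from means and surfaced in
summaries.  Randomness: one root seed; replicate i draws its RNG from
`SeedSequence(seed, spawn_key=(i,))`, so any replicate is reproducible in
isolation and estimates are bit-for-bit reproducible.

## Graph families and defaults

Constructors follow the standard definitions (complete, undirected cycle,
star with center 0, double star D₂ₖ as two S_k joined center-to-center,
total order with edges i→j for i<j, backward graph as a forward path plus
all reverse edges).  The lollipop uses a path of p = round(√n) nodes; the
last path node sends a one-way edge to **every** cluster node (an
`attach="one"` variant is provided since the wiring at the junction is a
genuinely open choice), and no edges return from cluster to path — this
matches the "repeatedly invade the cluster until an attempt succeeds"
picture and keeps the path one-way.  Default starts: path-like families
start at node 0; the star at a leaf (its time is start-independent —
proved by the stage analysis and confirmed exactly by the solver).  The
random-digraph fixture samples edges independently and rejection-resamples
until all nodes are reachable from node 0.

## Experiments and problem sizes

Scaling runs prefer the exact solver whenever the reachable state space
fits a cap and fall back to simulation; log-log slopes are least-squares
fits over the top half of the size grid to suppress small-n transients.
The bound audit certifies nH(n−1) ≤ T(G, v) ≤ ½n³ − ½n² per (graph,
start) in rational arithmetic, plus 4n²√n for undirected instances.  The
lollipop crossover defines r* as the sign change of mean(A) − mean(B)
with linear interpolation and a replicate-bootstrap CI; the full-scale
configuration (n = 1600, r ∈ [2, 10], ≥10³ replicates per point) is
exposed unchanged but takes hours on one CPU, so the shipped tests and
examples run the scan at n = 100, where the same reversal appears within
seconds and the paradox margin at r = 10 exceeds twenty standard errors.

## What the tests do and do not show

All experimental inputs are generated by the package itself (named
families and seeded random digraphs); there are no external data.  The
random-digraph audits certify the proved bounds on a sample of
structures, not on all 2^(n(n-1)) digraphs; the asymptotic statements
(n²√n, n², n log n) are checked as finite-size slope/ratio windows on
modest grids, which demonstrates the predicted growth on those grids but
is not a proof of the limit.  Monte-Carlo checks are z-tests at 3·SE with
fixed seeds: they validate the engines against exact expectations, not
the full distribution (the distribution itself is exercised only through
the geometric/exponential equivalences noted above).

## Known limitations

* The finite-r exact solver stops at n = 12; the half-path family and
  weak-selection (r → 1) theory are out of scope, as is death-Birth
  updating.
* Conditional fixation times at finite r are not separated from
  unconditional ones (at r → ∞ the two coincide, which is the regime of
  the exact solvers here).
* `worst_start_time` excludes starts that cannot reach the whole graph
  rather than reporting them as infinite, consistent with the standing
  reachability assumption.
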