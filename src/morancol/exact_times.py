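"""Exact expected colonization times on directed graphs.

In the colonization limit (mutant relative fitness r -> infinity) the
mutant set M only grows, so the chain over mutant sets is acyclic and the
expected time to fixation satisfies a one-pass recursion over the reachable
mutant sets.  From state M the per-step probability of gaining node w is

    p(M -> M + w) = (1/n) * sum_{u in M, w in N(u)} 1 / deg(u),

and with p_leave(M) the sum over all such w,

    E_mod[M] = ( 1 + sum_w p_w * E_mod[M + w] ) / p_leave(M).

Classic Moran steps (only mutant draws count) replace the 1 in the
numerator by |M|/n, and real time (one classic step lasts 1/F = 1/|M|
units) replaces it by 1/n — hence expected real time is exactly the
expected modified-step count divided by n, for every graph and start.

This module provides:

* :func:`colonization_exact` — memoized dynamic program over reachable
  mutant sets, exact rationals by default up to n = 12;
* :func:`colonization_exact_bruteforce` — an independent oracle that
  enumerates *all* mutant supersets of the start and eliminates the
  explicit one-step self-loops, for cross-checking the DP;
* :func:`absorption_exact_classic` — the finite-r absorbing-chain linear
  system over all 2^n states (fixation probability, unconditional expected
  classic steps, expected real time);
* :func:`closed_form` — validated closed forms for the backward graph,
  complete graph, cycle, and star;
* :func:`double_star_exact`, :func:`lollipop_exact` — symmetry-reduced
  programs with O(k^2) and O(sqrt(n) * n) states respectively;
* :func:`worst_start_time` — T(G) = max over valid starts of T(G, v).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Optional, Union

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .graph_core import DirectedGraph, reachable_from

__all__ = [
    "ExactResult",
    "WorstStartResult",
    "ClassicAbsorption",
    "StartPairTimes",
    "colonization_exact",
    "colonization_exact_bruteforce",
    "absorption_exact_classic",
    "closed_form",
    "harmonic",
    "double_star_exact",
    "lollipop_exact",
    "worst_start_time",
]

Number = Union[Fraction, float]

DEFAULT_STATE_CAP = 2_000_000
RATIONAL_MAX_N = 12  # exact rationals by default up to here; float beyond


class StateCapExceeded(RuntimeError):
    """The reachable mutant-set space outgrew the caller's state cap."""


@dataclass
class ExactResult:
    """Exact expectations of the three time measures from one start set."""

    expected_modified_steps: Number
    expected_classic_steps: Number
    expected_real_time: Number
    states_visited: int
    arithmetic: str

    def __post_init__(self) -> None:
        assert self.arithmetic in ("rational", "float")


@dataclass
class WorstStartResult:
    """Per-start colonization times and their maximum T(G)."""

    per_start: dict[int, Number]
    excluded_starts: tuple[int, ...]
    argmax: int
    value: Number


@dataclass
class ClassicAbsorption:
    """Finite-r absorbing-chain solution from one start set."""

    fixation_probability: float
    expected_classic_steps: float
    expected_real_time: float
    states: int


@dataclass
class StartPairTimes:
    """Exact results for the two canonical starts of a reduced solver."""

    first: ExactResult
    second: ExactResult


def _resolve_arithmetic(n: int, arithmetic: str) -> str:
    if arithmetic == "auto":
        return "rational" if n <= RATIONAL_MAX_N else "float"
    if arithmetic not in ("rational", "float"):
        raise ValueError(f"unknown arithmetic {arithmetic!r}")
    return arithmetic


def _init_mask(g: DirectedGraph, init: Iterable[int]) -> int:
    mask = 0
    nodes = list(init)
    if not nodes:
        raise ValueError("initial mutant set must be non-empty")
    for v in nodes:
        if not (0 <= v < g.n):
            raise ValueError(f"initial node {v} outside [0, {g.n})")
        mask |= 1 << v
    if len(reachable_from(g, nodes)) != g.n:
        raise ValueError("initial mutant set cannot reach every node")
    return mask


def colonization_exact(
    g: DirectedGraph,
    init: Iterable[int],
    state_cap: int = DEFAULT_STATE_CAP,
    arithmetic: str = "auto",
) -> ExactResult:
    """Expected colonization times by dynamic programming over the monotone
    mutant-set chain reachable from ``init``.

    ``arithmetic="rational"`` gives bit-exact :class:`fractions.Fraction`
    results; ``"float"`` uses IEEE doubles; ``"auto"`` picks rational for
    n <= 12.  Refuses explicitly (``StateCapExceeded``) once more than
    ``state_cap`` mutant sets are reachable.
    """
    arith = _resolve_arithmetic(g.n, arithmetic)
    start = _init_mask(g, init)
    n = g.n
    adj = g.out_neighbors
    full = (1 << n) - 1

    # discover reachable mutant sets (BFS over gains)
    states: list[int] = [start]
    seen = {start}
    head = 0
    while head < len(states):
        mask = states[head]
        head += 1
        if mask == full:
            continue
        for u in range(n):
            if not (mask >> u) & 1:
                continue
            for w in adj[u]:
                nxt = mask | (1 << w)
                if nxt != mask and nxt not in seen:
                    seen.add(nxt)
                    states.append(nxt)
                    if len(states) > state_cap:
                        raise StateCapExceeded(
                            f"more than {state_cap} reachable mutant sets "
                            f"(reached {len(states)})"
                        )

    one = Fraction(1) if arith == "rational" else 1.0
    zero = one * 0
    e_mod: dict[int, Number] = {full: zero}
    e_cls: dict[int, Number] = {full: zero}

    # supersets first: larger popcount states are always gained from smaller
    for mask in sorted(states, key=lambda s: -s.bit_count()):
        if mask == full:
            continue
        gains: dict[int, Number] = {}
        for u in range(n):
            if not (mask >> u) & 1:
                continue
            deg = len(adj[u])
            if deg == 0:
                continue
            wgt = one / (n * deg)
            for w in adj[u]:
                if not (mask >> w) & 1:
                    gains[w] = gains.get(w, zero) + wgt
        p_leave = sum(gains.values(), zero)
        m = mask.bit_count()
        num_mod = one
        num_cls = one * m / n
        for w, p_w in gains.items():
            nxt = mask | (1 << w)
            num_mod += p_w * e_mod[nxt]
            num_cls += p_w * e_cls[nxt]
        e_mod[mask] = num_mod / p_leave
        e_cls[mask] = num_cls / p_leave

    t_mod = e_mod[start]
    return ExactResult(
        expected_modified_steps=t_mod,
        expected_classic_steps=e_cls[start],
        expected_real_time=t_mod / n,
        states_visited=len(states),
        arithmetic=arith,
    )


def colonization_exact_bruteforce(
    g: DirectedGraph,
    init: Iterable[int],
    arithmetic: str = "auto",
) -> ExactResult:
    """Oracle solver: enumerate every mutant superset of ``init`` and
    eliminate the explicit one-step self-loop of the full transition kernel.

    From state M a step picks node u with probability 1/n and, if u is a
    mutant with out-degree d, sends the offspring to each neighbor with
    probability 1/(n d); everything else is a self-transition.  Expected
    times then follow by sweeping supersets in inclusion order.  Limited to
    n <= 14 (full subset enumeration); must agree with
    :func:`colonization_exact` bit-exactly in rational mode.
    """
    if g.n > 14:
        raise ValueError("brute-force oracle is limited to n <= 14")
    arith = _resolve_arithmetic(g.n, arithmetic)
    start = _init_mask(g, init)
    n = g.n
    adj = g.out_neighbors
    full = (1 << n) - 1
    free = [v for v in range(n) if not (start >> v) & 1]

    one = Fraction(1) if arith == "rational" else 1.0
    zero = one * 0
    e_mod: dict[int, Number] = {full: zero}
    e_cls: dict[int, Number] = {full: zero}

    count = 1
    # inclusion order: largest supersets first
    for size in range(len(free) - 1, -1, -1):
        for extra in combinations(free, size):
            mask = start
            for v in extra:
                mask |= 1 << v
            # one-step kernel: self-loop weight + outgoing weights
            p_self = zero
            p_out: dict[int, Number] = {}
            cls_inc = zero  # probability this step is a classic (mutant-draw) step
            for u in range(n):
                pick = one / n
                if not (mask >> u) & 1:
                    p_self += pick  # idle resident draw
                    continue
                cls_inc += pick
                d = len(adj[u])
                if d == 0:
                    p_self += pick  # counted no-op at a sink
                    continue
                for w in adj[u]:
                    if (mask >> w) & 1:
                        p_self += pick / d  # wasted reproduction onto a mutant
                    else:
                        key = mask | (1 << w)
                        p_out[key] = p_out.get(key, zero) + pick / d
            num_mod = one
            num_cls = cls_inc
            for nxt, p in p_out.items():
                num_mod += p * e_mod[nxt]
                num_cls += p * e_cls[nxt]
            leave = one - p_self
            e_mod[mask] = num_mod / leave
            e_cls[mask] = num_cls / leave
            count += 1

    t_mod = e_mod[start]
    return ExactResult(
        expected_modified_steps=t_mod,
        expected_classic_steps=e_cls[start],
        expected_real_time=t_mod / n,
        states_visited=count,
        arithmetic=arith,
    )


def absorption_exact_classic(
    g: DirectedGraph,
    init: Iterable[int],
    r: float,
) -> ClassicAbsorption:
    """Solve the classic Moran Birth-death chain at finite r exactly.

    Builds the sparse absorbing-chain system over all 2^n mutant sets
    (the finite-r chain is not monotone, so the full state space is the
    true cost) and returns the fixation probability, the unconditional
    expected number of classic steps, and the expected real time (each
    step lasting 1/F units, F = r|M| + n - |M|).  Limited to n <= 12.
    """
    if g.n > 12:
        raise ValueError("finite-r absorbing-chain solver is limited to n <= 12")
    if not (r > 0) or math.isinf(r):
        raise ValueError("r must be a positive finite real")
    nodes = sorted(set(init))
    if not nodes:
        raise ValueError("initial mutant set must be non-empty")
    n = g.n
    adj = g.out_neighbors
    full = (1 << n) - 1
    start = 0
    for v in nodes:
        if not (0 <= v < n):
            raise ValueError(f"initial node {v} outside [0, {n})")
        start |= 1 << v
    if start == full:
        return ClassicAbsorption(1.0, 0.0, 0.0, states=1)

    transient = [m for m in range(1, full) ]
    index = {m: i for i, m in enumerate(transient)}
    nt = len(transient)

    rows, cols, vals = [], [], []
    to_full = np.zeros(nt)
    to_zero = np.zeros(nt)
    step_cost = np.ones(nt)
    real_cost = np.zeros(nt)
    for mask in transient:
        i = index[mask]
        m = mask.bit_count()
        F = r * m + (n - m)
        real_cost[i] = 1.0 / F
        for u in range(n):
            f_u = r if (mask >> u) & 1 else 1.0
            d = len(adj[u])
            if d == 0:
                continue  # counted no-op: stays in mask (self-loop, implicit)
            base = f_u / (F * d)
            u_mut = (mask >> u) & 1
            for w in adj[u]:
                if u_mut and not (mask >> w) & 1:
                    nxt = mask | (1 << w)
                elif not u_mut and (mask >> w) & 1:
                    nxt = mask & ~(1 << w)
                else:
                    continue  # same-type replacement: self-loop
                if nxt == full:
                    to_full[i] += base
                elif nxt == 0:
                    to_zero[i] += base  # extinction absorbs with value 0
                else:
                    rows.append(i)
                    cols.append(index[nxt])
                    vals.append(base)

    Q = scipy.sparse.csr_matrix((vals, (rows, cols)), shape=(nt, nt))
    # self-loop mass is 1 - (off-diagonal + absorbing) mass; eliminating the
    # self-loops turns (I - P) into diag(leaving mass) - Q
    out_mass = np.asarray(Q.sum(axis=1)).ravel() + to_full + to_zero
    A = (scipy.sparse.diags(out_mass) - Q).tocsc()
    lu = scipy.sparse.linalg.splu(A)
    phi = lu.solve(to_full)
    steps = lu.solve(step_cost)
    real = lu.solve(real_cost)
    i0 = index[start]
    return ClassicAbsorption(
        fixation_probability=float(phi[i0]),
        expected_classic_steps=float(steps[i0]),
        expected_real_time=float(real[i0]),
        states=nt + 2,
    )


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------

def harmonic(k: int, exact: bool = False) -> Number:
    """k-th harmonic number H(k) = 1 + 1/2 + ... + 1/k by direct summation."""
    if k < 0:
        raise ValueError("harmonic number needs k >= 0")
    if exact:
        return sum((Fraction(1, j) for j in range(1, k + 1)), Fraction(0))
    # summing small terms first keeps the float error negligible for k <= 1e7
    return float(sum(1.0 / j for j in range(k, 0, -1)))


def closed_form(family: str, n: int, exact: bool = False) -> Number:
    """Expected modified steps T for families with a known closed form.

    * backward: n^2 (n-1) / 2 — the general cubic upper bound, attained
      with equality (start at the path's first node);
    * complete: 2 (n-1) H(n-1) — stage m gains with probability
      m (n-m) / (n (n-1));
    * cycle: n (n-1) — every stage gains with probability exactly 1/n;
    * star: n (n-1) H(n-1) — identical for center and leaf starts.

    Each form is validated against the brute-force oracle in the test
    suite; H is the harmonic number.
    """
    if n < 2:
        raise ValueError("closed forms need n >= 2")
    fam = family.replace("-", "_")
    one = Fraction(1) if exact else 1.0
    if fam == "backward":
        return one * n * n * (n - 1) / 2
    if fam == "complete":
        return 2 * (n - 1) * harmonic(n - 1, exact=exact) * one
    if fam == "cycle":
        return one * n * (n - 1)
    if fam == "star":
        return n * (n - 1) * harmonic(n - 1, exact=exact) * one
    raise ValueError(f"no closed form for family {family!r}")


# ---------------------------------------------------------------------------
# Symmetry-reduced solvers
# ---------------------------------------------------------------------------

def _reduced_solve(
    states: list,
    gains: dict,
    mutant_count: dict,
    n: int,
    arith: str,
) -> dict:
    """Shared backward sweep for symmetry-reduced chains.

    ``states`` must be ordered so that every transition target precedes its
    source; ``gains[s]`` maps target state -> per-step gain probability.
    Returns per-state (E_mod, E_cls) pairs.
    """
    one = Fraction(1) if arith == "rational" else 1.0
    zero = one * 0
    table: dict = {}
    for s in states:
        gs = gains[s]
        if not gs:
            table[s] = (zero, zero)  # absorbing
            continue
        p_leave = sum(gs.values(), zero)
        num_mod = one
        num_cls = one * mutant_count[s] / n
        for t, p in gs.items():
            em, ec = table[t]
            num_mod += p * em
            num_cls += p * ec
        table[s] = (num_mod / p_leave, num_cls / p_leave)
    return table


def double_star_exact(k: int, arithmetic: str = "float") -> StartPairTimes:
    """Exact colonization times on the double star D_{2k} by a
    symmetry-reduced program over (center1, center2, leaves1, leaves2).

    Leaf identity within a star is exchangeable, so O(k^2) states replace
    the 2^(2k) mutant sets.  Returns the result for a center start
    (``first``) and a leaf start (``second``).
    """
    if k < 2:
        raise ValueError("double star needs k >= 2")
    arith = "rational" if arithmetic == "rational" else "float"
    one = Fraction(1) if arith == "rational" else 1.0
    zero = one * 0
    n = 2 * k

    def gains(state):
        s1, s2, l1, l2 = state
        g: dict = {}

        def add(target, p):
            if p != zero:
                g[target] = g.get(target, zero) + p

        # a resident center is gained from its own mutant leaves (degree-1,
        # they point only at it) or from the mutant center across the bridge
        if s1 == 0:
            p = one * l1 / n
            if s2 == 1:
                p += one / (n * k)
            add((1, s2, l1, l2), p)
        elif l1 < k - 1:
            # mutant center 1 reproduces onto one of its resident leaves
            add((s1, s2, l1 + 1, l2), one * (k - 1 - l1) / (n * k))
        if s2 == 0:
            p = one * l2 / n
            if s1 == 1:
                p += one / (n * k)
            add((s1, 1, l1, l2), p)
        elif l2 < k - 1:
            add((s1, s2, l1, l2 + 1), one * (k - 1 - l2) / (n * k))
        return g

    states = [
        (s1, s2, l1, l2)
        for s1 in (0, 1)
        for s2 in (0, 1)
        for l1 in range(k)
        for l2 in range(k)
    ]
    states.sort(key=lambda s: -(s[0] + s[1] + s[2] + s[3]))
    gain_map = {s: gains(s) for s in states}
    m_map = {s: s[0] + s[1] + s[2] + s[3] for s in states}
    table = _reduced_solve(states, gain_map, m_map, n, arith)
    n_states = len(states)

    def result(state) -> ExactResult:
        em, ec = table[state]
        return ExactResult(em, ec, em / n, n_states, arith)

    return StartPairTimes(first=result((1, 0, 0, 0)), second=result((0, 0, 1, 0)))


def lollipop_exact(n: int, arithmetic: str = "float") -> StartPairTimes:
    """Exact colonization times on the lollipop graph by a reduced program
    over (path prefix length, cluster mutant count).

    The one-way path colonizes strictly left to right and cluster nodes
    are exchangeable, so O(sqrt(n) * n) states suffice.  Returns the
    result for a single mutant at the path start (``first``) and for the
    path start plus the full cluster (``second``) — the two initializations
    of the step-counting paradox.
    """
    from .graph_core import lollipop_path_length

    if n < 4:
        raise ValueError("lollipop needs n >= 4")
    arith = "rational" if arithmetic == "rational" else "float"
    one = Fraction(1) if arith == "rational" else 1.0
    zero = one * 0
    p = lollipop_path_length(n)
    c = n - p  # cluster size

    def gains(state):
        j, m = state  # nodes 0..j-1 of the path mutant; m cluster mutants
        g: dict = {}
        if j < p:
            # frontier path node j-1 has the single out-edge j-1 -> j
            g[(j + 1, m)] = one / n
        elif m < c:
            # last path node feeds every cluster node
            g[(j, m + 1)] = one * (c - m) / (n * c)
        if 0 < m < c:
            # cluster-internal spread (complete graph on c nodes)
            g[(j, m + 1)] = g.get((j, m + 1), zero) + one * m * (c - m) / (n * (c - 1))
        return g

    states = [(j, m) for j in range(1, p + 1) for m in range(c + 1)]
    states.sort(key=lambda s: -(s[0] + s[1]))
    gain_map = {s: gains(s) for s in states}
    m_map = {s: s[0] + s[1] for s in states}
    table = _reduced_solve(states, gain_map, m_map, n, arith)
    n_states = len(states)

    def result(state) -> ExactResult:
        em, ec = table[state]
        return ExactResult(em, ec, em / n, n_states, arith)

    return StartPairTimes(first=result((1, 0)), second=result((1, c)))


def worst_start_time(
    g: DirectedGraph,
    state_cap: int = DEFAULT_STATE_CAP,
    arithmetic: str = "auto",
) -> WorstStartResult:
    """T(G) = max over starting nodes v of T(G, v).

    Starts that cannot reach every node are excluded (and reported) rather
    than assigned infinite time, matching the standing reachability
    assumption of the colonization limit.
    """
    per_start: dict[int, Number] = {}
    excluded: list[int] = []
    for v in range(g.n):
        if len(reachable_from(g, {v})) != g.n:
            excluded.append(v)
            continue
        res = colonization_exact(g, {v}, state_cap=state_cap, arithmetic=arithmetic)
        per_start[v] = res.expected_modified_steps
    if not per_start:
        raise ValueError("no start node reaches the whole graph")
    argmax = max(per_start, key=lambda v: per_start[v])
    return WorstStartResult(
        per_start=per_start,
        excluded_starts=tuple(excluded),
        argmax=argmax,
        value=per_start[argmax],
    )
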