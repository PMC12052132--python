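"""Seeded stochastic simulation of Moran Birth-death dynamics on graphs.

Two engines are provided.

``run_colonization`` simulates the modified Moran process in the
colonization limit (mutant relative fitness r -> infinity, residents never
reproduce): each step draws a uniformly random node; if it is a mutant it
places an offspring on a uniformly random out-neighbor, otherwise nothing
happens.  The mutant set only grows, so the run always ends with all nodes
mutant.

``run_classic`` simulates the classic Moran Birth-death process at finite
relative fitness r (or r = infinity): a node is selected proportional to
fitness (mutants r, residents 1) and its offspring replaces a uniform
out-neighbor, so mutants can also be lost and the run may end in
extinction.

Both engines keep a :class:`TimeLedger` with three simultaneous time
measures:

* ``modified_steps`` — steps of the modified process (every uniform node
  draw counts, including idle resident draws);
* ``classic_steps`` — steps of the classic process (only reproduction
  events, i.e. draws of a fitness-positive node);
* ``real_time`` — continuous time in which one classic step lasts 1/F
  units, F being the total population fitness.  In the colonization limit
  (mutant fitness 1, resident fitness 0) F = |M|, and the expected real
  time equals the expected modified-step count divided by n.

Reproducibility: every replicate derives its own counter-based substream
from the root seed (``numpy.random.SeedSequence`` spawn keys), so
replicate ``i`` can be reproduced in isolation.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .graph_core import DirectedGraph, reachable_from

__all__ = [
    "TimeLedger",
    "ReplicateOutcome",
    "EstimateSummary",
    "MeasureEstimate",
    "run_colonization",
    "run_classic",
    "estimate",
    "replicate_rng",
]

MEASURES = ("modified_steps", "classic_steps", "real_time")


@dataclass
class TimeLedger:
    """One trajectory's three time measures."""

    modified_steps: int = 0
    classic_steps: int = 0
    real_time: float = 0.0

    def as_tuple(self) -> tuple[int, int, float]:
        return (self.modified_steps, self.classic_steps, self.real_time)


@dataclass
class ReplicateOutcome:
    """Terminal state of one classic-engine replicate.

    ``outcome`` is ``"fixed"``, ``"extinct"``, or ``"truncated"`` when the
    step budget ran out before absorption.  Truncated replicates are never
    silently folded into means.
    """

    outcome: str
    ledger: TimeLedger


@dataclass
class MeasureEstimate:
    mean: float
    se: float


@dataclass
class EstimateSummary:
    """Monte-Carlo summary over independent replicates.

    ``measures`` maps each time-measure name to its sample mean and
    standard error (sample SD / sqrt(replicates)).  For the classic engine
    ``fixed``/``extinct``/``truncated`` count terminal outcomes; means are
    computed over non-truncated replicates only.
    """

    replicates: int
    seed: int
    engine: str
    measures: dict[str, MeasureEstimate]
    fixed: int = 0
    extinct: int = 0
    truncated: int = 0

    @property
    def mean_modified(self) -> float:
        return self.measures["modified_steps"].mean

    @property
    def mean_classic(self) -> float:
        return self.measures["classic_steps"].mean

    @property
    def mean_real(self) -> float:
        return self.measures["real_time"].mean


def replicate_rng(seed: int, replicate: int) -> random.Random:
    """Substream RNG for one replicate, reproducible in isolation."""
    ss = np.random.SeedSequence(seed, spawn_key=(replicate,))
    return random.Random(int(ss.generate_state(1, dtype=np.uint64)[0]))


def _check_init(g: DirectedGraph, init: Iterable[int]) -> list[int]:
    nodes = sorted(set(init))
    if not nodes:
        raise ValueError("initial mutant set must be non-empty")
    for v in nodes:
        if not (0 <= v < g.n):
            raise ValueError(f"initial node {v} outside [0, {g.n})")
    return nodes


def run_colonization(
    g: DirectedGraph,
    init: Iterable[int],
    seed: Optional[int] = None,
    rng: Optional[random.Random] = None,
    skip_idle: bool = True,
    real_time_mode: str = "deterministic",
) -> TimeLedger:
    """Simulate the modified Moran process (r -> infinity) to fixation.

    Requires every node to be reachable from ``init``, which guarantees
    fixation with probability 1 in finite expected time.

    ``skip_idle=True`` replaces the run of idle resident draws before each
    mutant draw by a single geometric sample — the ledger distribution is
    unchanged but runs are much faster on large graphs.

    ``real_time_mode="deterministic"`` accrues the expected real-time
    increment 1/n per modified step, which makes the per-replicate identity
    ``real_time * n == modified_steps`` exact.  ``"sampled"`` draws the
    continuous-time interpretation instead: an exponential holding time
    with mean 1/|M| per classic (mutant-draw) step.
    """
    if real_time_mode not in ("deterministic", "sampled"):
        raise ValueError(f"unknown real_time_mode {real_time_mode!r}")
    mutants = _check_init(g, init)
    if len(reachable_from(g, mutants)) != g.n:
        raise ValueError("initial mutant set cannot reach every node")
    if rng is None:
        rng = random.Random(seed)

    n = g.n
    is_mut = bytearray(n)
    for v in mutants:
        is_mut[v] = 1
    m = len(mutants)
    adj = g.out_neighbors

    modified = 0
    classic = 0
    real = 0.0
    u01 = rng.random
    randrange = rng.randrange

    while m < n:
        if skip_idle:
            # number of uniform draws until a mutant is hit ~ Geometric(m/n)
            u = 1.0 - u01()  # in (0, 1]: keeps log() finite
            k = int(math.log(u) / math.log1p(-m / n)) + 1 if m < n else 1
            modified += k
            classic += 1
            if real_time_mode == "sampled":
                real += rng.expovariate(m)
            u_node = mutants[randrange(m)]
        else:
            modified += 1
            u_node = randrange(n)
            if not is_mut[u_node]:
                continue
            classic += 1
            if real_time_mode == "sampled":
                real += rng.expovariate(m)
        nbrs = adj[u_node]
        if nbrs:
            w = nbrs[randrange(len(nbrs))] if len(nbrs) > 1 else nbrs[0]
            if not is_mut[w]:
                is_mut[w] = 1
                mutants.append(w)
                m += 1
    if real_time_mode == "deterministic":
        # each modified step advances the clock by its expected duration
        # 1/n, so the identity real_time * n == modified_steps is exact
        real = modified / n
    return TimeLedger(modified, classic, real)


def run_classic(
    g: DirectedGraph,
    init: Iterable[int],
    r: float,
    seed: Optional[int] = None,
    rng: Optional[random.Random] = None,
    max_steps: int = 10**9,
) -> ReplicateOutcome:
    """Simulate the classic Moran Birth-death process at relative fitness r.

    Mutants have fitness r, residents fitness 1; selection is proportional
    to fitness and the offspring replaces a uniform out-neighbor (wasted
    reproductions onto a same-type node consume a step and real time).  A
    selected sink (out-degree 0) is a counted no-op.  For ``r = math.inf``
    selection is uniform over mutants and real time uses total fitness
    F = |M| (mutant fitness 1, residents 0); every node must then be
    reachable from ``init`` and the run always fixes.

    Runs until fixation, extinction, or ``max_steps`` (reported as
    ``"truncated"``).
    """
    if r <= 0:
        raise ValueError(f"fitness r must be positive, got {r}")
    mutants = _check_init(g, init)
    infinite = math.isinf(r)
    if infinite and len(reachable_from(g, mutants)) != g.n:
        raise ValueError("initial mutant set cannot reach every node")
    if rng is None:
        rng = random.Random(seed)

    n = g.n
    adj = g.out_neighbors
    is_mut = bytearray(n)
    for v in mutants:
        is_mut[v] = 1
    # position of each mutant in the mutants list, for O(1) removal
    pos = {v: i for i, v in enumerate(mutants)}
    m = len(mutants)

    classic = 0
    real = 0.0
    u01 = rng.random
    randrange = rng.randrange

    while 0 < m < n and classic < max_steps:
        classic += 1
        if infinite:
            real += 1.0 / m
            u_node = mutants[randrange(m)]
        else:
            F = r * m + (n - m)
            real += 1.0 / F
            # select group (mutants vs residents), then uniform within group
            if u01() * F < r * m:
                u_node = mutants[randrange(m)]
            else:
                # uniform resident: rejection over nodes is O(n/(n-m));
                # fine for the regimes simulated here
                while True:
                    cand = randrange(n)
                    if not is_mut[cand]:
                        u_node = cand
                        break
        nbrs = adj[u_node]
        if not nbrs:
            continue
        w = nbrs[randrange(len(nbrs))] if len(nbrs) > 1 else nbrs[0]
        if is_mut[u_node] and not is_mut[w]:
            is_mut[w] = 1
            pos[w] = m
            mutants.append(w)
            m += 1
        elif not is_mut[u_node] and is_mut[w]:
            is_mut[w] = 0
            i = pos.pop(w)
            last = mutants.pop()
            m -= 1
            if last != w:
                mutants[i] = last
                pos[last] = i

    if m == n:
        outcome = "fixed"
    elif m == 0:
        outcome = "extinct"
    else:
        outcome = "truncated"
    # modified steps are a colonization-limit notion; the classic engine
    # records its step count in both integer slots
    return ReplicateOutcome(outcome, TimeLedger(classic, classic, real))


def estimate(
    g: DirectedGraph,
    init: Iterable[int],
    engine: str = "colonization",
    replicates: int = 1000,
    seed: int = 0,
    r: float = math.inf,
    max_steps: int = 10**9,
    skip_idle: bool = True,
    real_time_mode: str = "deterministic",
    return_samples: bool = False,
):
    """Monte-Carlo estimate of the time measures over independent replicates.

    Each replicate uses its own substream derived from ``seed``; the result
    is bit-for-bit reproducible given (seed, replicates, engine).  Returns
    an :class:`EstimateSummary`; with ``return_samples=True`` also the raw
    per-replicate arrays (dict of measure -> ndarray, truncated replicates
    excluded).
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates for a standard error")
    if engine not in ("colonization", "classic"):
        raise ValueError(f"unknown engine {engine!r}")
    init_list = list(init)
    samples = {meas: [] for meas in MEASURES}
    fixed = extinct = truncated = 0
    for rep in range(replicates):
        rng = replicate_rng(seed, rep)
        if engine == "colonization":
            ledger = run_colonization(
                g, init_list, rng=rng, skip_idle=skip_idle,
                real_time_mode=real_time_mode,
            )
            fixed += 1
        else:
            out = run_classic(g, init_list, r=r, rng=rng, max_steps=max_steps)
            if out.outcome == "truncated":
                truncated += 1
                continue
            if out.outcome == "fixed":
                fixed += 1
            else:
                extinct += 1
            ledger = out.ledger
        samples["modified_steps"].append(ledger.modified_steps)
        samples["classic_steps"].append(ledger.classic_steps)
        samples["real_time"].append(ledger.real_time)

    measures = {}
    arrays = {}
    for meas in MEASURES:
        arr = np.asarray(samples[meas], dtype=float)
        arrays[meas] = arr
        if arr.size >= 2:
            measures[meas] = MeasureEstimate(
                mean=float(arr.mean()),
                se=float(arr.std(ddof=1) / math.sqrt(arr.size)),
            )
        else:
            measures[meas] = MeasureEstimate(mean=float("nan"), se=float("nan"))
    summary = EstimateSummary(
        replicates=replicates, seed=seed, engine=engine, measures=measures,
        fixed=fixed, extinct=extinct, truncated=truncated,
    )
    if return_samples:
        return summary, arrays
    return summary
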