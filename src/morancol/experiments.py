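"""Scaling curves, bound audits, and the lollipop crossover experiment.

These runners tie the graph constructors, the exact solvers, and the
seeded simulation engines together and emit tidy :class:`pandas.DataFrame`
tables, one row per measured point.  Every row records the seed that
produced it, and every run is a deterministic function of (config, seed).

* :func:`run_scaling` — colonization time versus population size for the
  named graph families, exact where the state space permits and simulated
  otherwise, with a log-log slope fit over the top half of the size grid.
* :func:`run_bound_audit` — certifies, on random reachable digraphs plus
  the named families, the cubic upper bound T(G, v) <= n^3/2 - n^2/2 (with
  equality exactly for the backward graph started at node 0), the lower
  bound T(G, v) >= n H(n-1), and the n^2 sqrt(n) bound for undirected
  graphs.
* :func:`run_lollipop_crossover` — the step-counting paradox: classic
  Moran steps on the lollipop graph under two initializations (single
  mutant at the path start, versus additionally the whole cluster), with
  the crossover fitness r* located by the sign change of the difference
  of means and a bootstrap confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .graph_core import (
    DirectedGraph,
    GraphFamilySpec,
    build_family,
    backward_graph,
    default_start,
    lollipop_graph,
    lollipop_path_length,
    is_undirected,
    random_reachable_digraph,
)
from .moran_engine import estimate
from .exact_times import (
    StateCapExceeded,
    colonization_exact,
    harmonic,
    worst_start_time,
)

__all__ = [
    "ExperimentConfig",
    "CrossoverResult",
    "run_scaling",
    "run_bound_audit",
    "run_lollipop_crossover",
    "fit_loglog_slope",
]


@dataclass
class ExperimentConfig:
    """Configuration of a scaling run.

    ``families`` are family names from :mod:`morancol.graph_core`;
    ``n_grid`` must be strictly increasing.  A point is solved exactly when
    its reachable mutant-set space fits within ``exact_state_cap``,
    otherwise simulated with ``replicates`` replicates (at least 100).
    """

    families: Sequence[str]
    n_grid: Sequence[int]
    replicates: int = 1000
    seed: int = 0
    exact_state_cap: int = 200_000

    def __post_init__(self) -> None:
        grid = list(self.n_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("n grid must be strictly increasing")
        if self.replicates < 100:
            raise ValueError("simulated points need at least 100 replicates")


@dataclass
class CrossoverResult:
    """Outcome of the lollipop initialization comparison over an r grid.

    ``table`` holds per-r means and standard errors of classic Moran steps
    for initialization A (single mutant at the path start) and B (path
    start plus the full cluster).  ``r_star`` is the fitness at which the
    mean difference A - B changes sign (linear interpolation between
    adjacent grid points), with a bootstrap confidence interval; it is
    ``None`` when the difference does not change sign on the grid.
    """

    n: int
    table: pd.DataFrame
    r_star: Optional[float]
    r_star_ci: Optional[tuple[float, float]]
    replicates: int
    seed: int


def fit_loglog_slope(ns: Sequence[float], values: Sequence[float],
                     top_half: bool = True) -> float:
    """Least-squares slope of log(value) against log(n).

    With ``top_half`` only the upper half of the size grid enters the fit,
    which suppresses small-n transients.
    """
    ns = np.asarray(ns, dtype=float)
    vals = np.asarray(values, dtype=float)
    order = np.argsort(ns)
    ns, vals = ns[order], vals[order]
    if top_half and len(ns) >= 4:
        keep = len(ns) // 2
        ns, vals = ns[-keep - 1:], vals[-keep - 1:]
    slope, _ = np.polyfit(np.log(ns), np.log(vals), 1)
    return float(slope)


def _family_graph(family: str, n: int, seed: int) -> DirectedGraph:
    return build_family(GraphFamilySpec(family=family, n=n, seed=seed))


def run_scaling(config: ExperimentConfig) -> tuple[pd.DataFrame, dict[str, float]]:
    """Colonization time versus n for each configured family.

    Returns a table with columns (family, n, start, method, mean, se,
    states, seed, status) and a dict of per-family log-log slopes fitted
    over the top half of the grid.  Points whose exact state space exceeds
    the cap fall back to simulation; a point that fails outright is
    emitted with status ``"skipped"``, never silently dropped.
    """
    rows = []
    for family in config.families:
        for n in config.n_grid:
            start = default_start(family)
            row = {
                "family": family, "n": n, "start": start, "seed": config.seed,
                "method": "exact", "mean": np.nan, "se": 0.0,
                "states": 0, "status": "ok",
            }
            try:
                g = _family_graph(family, n, config.seed)
            except Exception as exc:  # family too small at this n
                row.update(method="none", status=f"skipped: {exc}")
                rows.append(row)
                continue
            try:
                res = colonization_exact(
                    g, {start}, state_cap=config.exact_state_cap,
                    arithmetic="float",
                )
                row.update(mean=float(res.expected_modified_steps),
                           states=res.states_visited)
            except StateCapExceeded:
                summ = estimate(
                    g, {start}, engine="colonization",
                    replicates=config.replicates, seed=config.seed,
                )
                row.update(
                    method="simulation",
                    mean=summ.mean_modified,
                    se=summ.measures["modified_steps"].se,
                )
            rows.append(row)
    table = pd.DataFrame(rows)
    slopes = {}
    for family, sub in table[table["status"] == "ok"].groupby("family"):
        if len(sub) >= 2:
            slopes[family] = fit_loglog_slope(sub["n"], sub["mean"])
    return table, slopes


AUDIT_FAMILIES = ("complete", "cycle", "star", "double_star",
                  "total_order", "backward", "lollipop")


def run_bound_audit(
    n_list: Sequence[int],
    graphs_per_n: int = 50,
    seed: int = 0,
    edge_prob: float = 0.5,
) -> pd.DataFrame:
    """Audit the colonization-time bounds on random digraphs and families.

    For every sampled random reachable digraph, every named family that
    exists at the given n, and every start that reaches all nodes, checks

        n H(n-1)  <=  T(G, v)  <=  n^3/2 - n^2/2,

    and for undirected instances additionally T <= 4 n^2 sqrt(n).  The
    upper bound must be attained with equality exactly by the backward
    graph started at node 0.  Exact (rational) arithmetic throughout, so
    the audit requires n <= 12.  One row per (graph, start).
    """
    from fractions import Fraction

    rows = []
    for n in n_list:
        if n > 12:
            raise ValueError("bound audit uses exact rationals; needs n <= 12")
        upper = Fraction(n**3 - n**2, 2)
        lower = n * harmonic(n - 1, exact=True)
        graphs: list[tuple[str, DirectedGraph]] = []
        for family in AUDIT_FAMILIES:
            try:
                graphs.append((family, _family_graph(family, n, seed)))
            except Exception:
                continue  # family undefined at this n (e.g. lollipop at n=2)
        for i in range(graphs_per_n):
            graphs.append(
                (f"random[{i}]",
                 random_reachable_digraph(n, edge_prob, seed=seed * 100003 + i))
            )
        for name, g in graphs:
            wsr = worst_start_time(g, arithmetic="rational")
            undirected = is_undirected(g)
            for v, t in wsr.per_start.items():
                rows.append({
                    "n": n,
                    "graph": name,
                    "start": v,
                    "T": float(t),
                    "lower": float(lower),
                    "upper": float(upper),
                    "lower_ok": t >= lower,
                    "upper_ok": t <= upper,
                    "upper_tight": t == upper,
                    "undirected": undirected,
                    "undirected_ok": (not undirected)
                    or t <= 4 * n**2 * math.sqrt(n),
                    "ratio_upper": float(t / upper),
                    "seed": seed,
                })
    return pd.DataFrame(rows)


def run_lollipop_crossover(
    n: int,
    r_grid: Sequence[float],
    replicates: int = 1000,
    seed: int = 0,
    max_steps: int = 10**9,
    bootstrap: int = 1000,
) -> CrossoverResult:
    """Classic Moran steps on the lollipop graph under two initializations.

    Initialization A places a single mutant at the path start; B
    additionally fills the whole cluster with mutants.  B is a strict
    superset of A, yet for large enough fitness r its expected classic
    step count is *larger* — cluster mutants soak up reproduction events
    without advancing the path frontier.  The crossover r* is estimated
    from the sign change of mean(A) - mean(B) along the grid.  Replicates
    truncated by ``max_steps`` invalidate their point (status column).
    """
    if n < 16:
        raise ValueError("crossover experiment needs n >= 16")
    r_grid = sorted(float(r) for r in r_grid)
    if any(r <= 1 for r in r_grid):
        raise ValueError("crossover grid must lie in (1, inf)")
    g = lollipop_graph(n)
    p = lollipop_path_length(n)
    init_a = [0]
    init_b = [0] + list(range(p, n))

    rows = []
    samples: dict[tuple[float, str], np.ndarray] = {}
    for gi, r in enumerate(r_grid):
        for label, init in (("A", init_a), ("B", init_b)):
            sub_seed = seed + 1_000_003 * gi + (0 if label == "A" else 500_009)
            summ, arrs = estimate(
                g, init, engine="classic", r=r, replicates=replicates,
                seed=sub_seed, max_steps=max_steps, return_samples=True,
            )
            samples[(r, label)] = arrs["classic_steps"]
            rows.append({
                "n": n, "r": r, "init": label,
                "mean_classic": summ.mean_classic,
                "se_classic": summ.measures["classic_steps"].se,
                "replicates": replicates,
                "truncated": summ.truncated,
                "status": "ok" if summ.truncated == 0 else "truncated",
                "seed": sub_seed,
            })
    table = pd.DataFrame(rows)

    r_star, ci = _crossover_from_samples(r_grid, samples, bootstrap, seed)
    return CrossoverResult(
        n=n, table=table, r_star=r_star, r_star_ci=ci,
        replicates=replicates, seed=seed,
    )


def _interp_sign_change(rs: Sequence[float], diffs: Sequence[float]) -> Optional[float]:
    for (r0, d0), (r1, d1) in zip(zip(rs, diffs), list(zip(rs, diffs))[1:]):
        if d0 == 0:
            return float(r0)
        if d0 * d1 < 0:
            return float(r0 + (r1 - r0) * abs(d0) / (abs(d0) + abs(d1)))
    return None


def _crossover_from_samples(r_grid, samples, bootstrap, seed):
    diffs = [samples[(r, "A")].mean() - samples[(r, "B")].mean() for r in r_grid]
    r_star = _interp_sign_change(r_grid, diffs)
    if r_star is None or bootstrap < 2:
        return r_star, None
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(999,)))
    boots = []
    for _ in range(bootstrap):
        bdiffs = []
        for r in r_grid:
            a = samples[(r, "A")]
            b = samples[(r, "B")]
            bdiffs.append(
                a[rng.integers(0, a.size, a.size)].mean()
                - b[rng.integers(0, b.size, b.size)].mean()
            )
        bs = _interp_sign_change(r_grid, bdiffs)
        if bs is not None:
            boots.append(bs)
    if len(boots) < max(2, bootstrap // 10):
        return r_star, None
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return r_star, (float(lo), float(hi))
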