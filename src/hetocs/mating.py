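"""Mate allocation: turning contributions into an integer mating plan.

Optimized contributions are first discretized into per-parent gamete counts
(largest-remainder rounding of ``2 * n_offspring * c``), then paired. The
optimizing allocator minimizes total pair cost — the off-diagonal entries of
the (beta-adjusted) relationship matrix, so expected progeny homozygosity —
subject to exact gamete-degree constraints, via the LP relaxation of the
degree-constrained b-matching problem. Vertex solutions of that relaxation
are half-integral with fractional support on disjoint odd cycles; a repair
pass rounds each pair of odd cycles to integers, preserving degrees exactly,
by the minimum-cost combination of near-perfect matchings plus one bridge
edge. A random allocator with the same degree guarantees serves as control.

Each unit of the pair-count matrix is one mating event producing exactly one
offspring from independent meioses of the two parents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

__all__ = [
    "GameteAllocation",
    "MatePlan",
    "contributions_to_gametes",
    "solve_mating",
    "random_mating",
    "expected_progeny_homozygosity",
]


@dataclass
class GameteAllocation:
    """Integer gamete counts per parent; sums to ``2 * n_offspring``."""

    g: np.ndarray
    n_offspring: int

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=np.int64)
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")
        if self.g.sum() != 2 * self.n_offspring:
            raise ValueError("gamete counts must sum to 2 * n_offspring")
        if np.any(self.g < 0):
            raise ValueError("gamete counts must be nonnegative")
        if np.any(self.g > self.n_offspring):
            raise ValueError(
                "no parent may hold more than half the gametes (no-selfing feasibility)"
            )


@dataclass
class MatePlan:
    """Symmetric integer pair-count matrix; entry (i, j) = matings of i x j."""

    pair_counts: np.ndarray
    n_offspring: int

    def __post_init__(self) -> None:
        self.pair_counts = np.asarray(self.pair_counts, dtype=np.int64)
        P = self.pair_counts
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("pair_counts must be square")
        if not np.array_equal(P, P.T):
            raise ValueError("pair_counts must be symmetric")
        if np.any(np.diag(P) != 0):
            raise ValueError("selfing entries must be zero")
        if np.any(P < 0):
            raise ValueError("pair counts must be nonnegative")
        if np.triu(P, 1).sum() != self.n_offspring:
            raise ValueError("pair counts must sum to n_offspring")

    @property
    def degrees(self) -> np.ndarray:
        """Gametes used per parent: row sums of the symmetric count matrix."""
        return self.pair_counts.sum(axis=1)

    def pairs(self) -> list[tuple[int, int, int]]:
        """(i, j, count) for i < j with count > 0, in index order."""
        out = []
        n = self.pair_counts.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                if self.pair_counts[i, j] > 0:
                    out.append((i, j, int(self.pair_counts[i, j])))
        return out


def contributions_to_gametes(c: np.ndarray, n_offspring: int) -> GameteAllocation:
    """Largest-remainder rounding of ``2 * n_offspring * c`` to integers.

    Ties go to the larger contribution, then the lower index; the per-parent
    cap ``g_i <= n_offspring`` is enforced by redistributing any excess to
    the next-largest remainders.
    """
    c = np.asarray(c, dtype=float)
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    if np.any(c < -1e-9) or abs(c.sum() - 1.0) > 1e-6:
        raise ValueError("contributions must be nonnegative and sum to 1")
    if np.any(c > 0.5 + 1e-9):
        raise ValueError("contributions must not exceed 0.5")
    target = 2 * n_offspring * np.clip(c, 0.0, 0.5)
    g = np.floor(target + 1e-9).astype(np.int64)
    remainder = target - g
    short = int(2 * n_offspring - g.sum())
    # order: remainder desc, contribution desc, index asc
    order = sorted(range(len(c)), key=lambda i: (-remainder[i], -c[i], i))
    pos = 0
    while short > 0:
        i = order[pos % len(order)]
        if g[i] < n_offspring:
            g[i] += 1
            short -= 1
        pos += 1
        if pos > 4 * len(order):  # all capped: infeasible rounding
            raise ValueError("cannot place all gametes under the per-parent cap")
    # cap enforcement (float fuzz can push a floor above the cap)
    while np.any(g > n_offspring):
        i = int(np.argmax(g))
        excess = int(g[i] - n_offspring)
        g[i] = n_offspring
        for j in order:
            if excess == 0:
                break
            if j != i and g[j] < n_offspring:
                g[j] += 1
                excess -= 1
    return GameteAllocation(g=g, n_offspring=n_offspring)


def _check_degrees_feasible(g: np.ndarray) -> None:
    total = g.sum()
    gmax = g.max(initial=0)
    if gmax > total - gmax:
        raise ValueError(
            "infeasible gamete degrees: one parent holds more gametes than "
            "all others combined"
        )


def _fractional_cycles(frac_edges: list[tuple[int, int]]) -> list[list[int]]:
    """Split the half-integral support into its disjoint cycles (vertex lists)."""
    adj: dict[int, list[int]] = {}
    for i, j in frac_edges:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    for v, nb in adj.items():
        if len(nb) != 2:
            raise RuntimeError("fractional support is not a disjoint union of cycles")
    cycles = []
    seen: set[int] = set()
    for start in sorted(adj):
        if start in seen:
            continue
        cycle = [start]
        seen.add(start)
        prev, cur = None, start
        while True:
            # 2-regular: exactly one way forward except at the start vertex
            step = [w for w in adj[cur] if w != prev][0]
            if step == start:
                break
            cycle.append(step)
            seen.add(step)
            prev, cur = cur, step
        cycles.append(cycle)
    return cycles


def _cycle_rounding(cycle: list[int], avoid: int, cost: np.ndarray):
    """Near-perfect matching of an odd cycle leaving ``avoid`` uncovered.

    Returns (edges_up, edges_down, delta_cost) where up-edges go 1/2 -> 1 and
    down-edges 1/2 -> 0; the matching is unique once the uncovered vertex is
    fixed (alternate along the remaining even path).
    """
    k = len(cycle)
    start = cycle.index(avoid)
    path = [cycle[(start + t) % k] for t in range(k)]  # path[0] == avoid
    up, down = [], []
    # edges along the cycle: (path[t], path[t+1]) for t in 0..k-1 (wrap)
    for t in range(k):
        e = (path[t], path[(t + 1) % k])
        if t == 0 or t == k - 1:
            down.append(e)  # edges touching the uncovered vertex go to 0
        elif t % 2 == 1:
            up.append(e)
        else:
            down.append(e)
    delta = 0.5 * (sum(cost[e] for e in up) - sum(cost[e] for e in down))
    return up, down, delta


def solve_mating(g: GameteAllocation, cost: np.ndarray) -> MatePlan:
    """Minimum-cost degree-constrained pairing of the gametes.

    Solves the LP relaxation ``min sum n_ij cost_ij`` subject to
    ``sum_j n_ij = g_i``, ``n >= 0`` over unordered pairs, then repairs any
    half-integral odd cycles in the vertex solution to integers without
    disturbing the degrees.
    """
    cost = np.asarray(cost, dtype=float)
    gv = g.g
    n = gv.shape[0]
    if cost.shape != (n, n):
        raise ValueError("cost matrix shape does not match gamete vector")
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix must be finite")
    _check_degrees_feasible(gv)
    active = np.flatnonzero(gv > 0)
    plan = np.zeros((n, n), dtype=np.int64)
    if active.size == 0:
        raise ValueError("no gametes to allocate")
    pairs = [(i, j) for ai, i in enumerate(active) for j in active[ai + 1 :]]
    if not pairs:
        raise ValueError("a single active parent cannot be mated (selfing forbidden)")
    m = len(pairs)
    c_vec = np.array([cost[i, j] for i, j in pairs])
    A_eq = np.zeros((active.size, m))
    for e, (i, j) in enumerate(pairs):
        A_eq[np.searchsorted(active, i), e] = 1.0
        A_eq[np.searchsorted(active, j), e] = 1.0
    res = scipy.optimize.linprog(
        c_vec, A_eq=A_eq, b_eq=gv[active].astype(float),
        bounds=[(0, None)] * m, method="highs",
    )
    if not res.success:
        raise ValueError(f"mate-allocation LP failed: {res.message}")
    x = res.x
    vals = {}
    frac_edges = []
    for e, (i, j) in enumerate(pairs):
        v = x[e]
        iv = int(np.floor(v + 1e-6))
        f = v - iv
        vals[(i, j)] = float(iv) + (0.5 if abs(f - 0.5) < 1e-4 else 0.0)
        if abs(f - 0.5) < 1e-4:
            frac_edges.append((i, j))
        elif min(f, 1 - f) > 1e-4:
            raise RuntimeError("LP vertex is not half-integral")
    if frac_edges:
        cost_sym = (cost + cost.T) / 2.0
        cycles = _fractional_cycles(frac_edges)
        if len(cycles) % 2 != 0:
            raise RuntimeError("odd number of fractional cycles (parity violation)")
        # pair cycles greedily by cheapest joint repair
        remaining = list(range(len(cycles)))
        while remaining:
            a = remaining.pop(0)
            best = None
            for b in remaining:
                for u in cycles[a]:
                    up_a, down_a, d_a = _cycle_rounding(cycles[a], u, cost_sym)
                    for v in cycles[b]:
                        up_b, down_b, d_b = _cycle_rounding(cycles[b], v, cost_sym)
                        delta = d_a + d_b + cost_sym[u, v]
                        if best is None or delta < best[0] - 1e-12:
                            best = (delta, b, up_a + up_b, down_a + down_b, (u, v))
            _, b, ups, downs, bridge = best
            remaining.remove(b)
            for i, j in ups:
                key = (min(i, j), max(i, j))
                vals[key] = vals.get(key, 0.0) + 0.5
            for i, j in downs:
                key = (min(i, j), max(i, j))
                vals[key] = vals.get(key, 0.0) - 0.5
            key = (min(bridge), max(bridge))
            vals[key] = vals.get(key, 0.0) + 1.0
    for (i, j), v in vals.items():
        iv = int(round(v))
        if abs(v - iv) > 1e-6 or iv < 0:
            raise RuntimeError("integer repair failed to produce a valid plan")
        plan[i, j] = iv
        plan[j, i] = iv
    mate_plan = MatePlan(pair_counts=plan, n_offspring=g.n_offspring)
    if not np.array_equal(mate_plan.degrees, gv):
        raise RuntimeError("mate plan does not conserve gamete degrees")
    return mate_plan


def random_mating(g: GameteAllocation, seed) -> MatePlan:
    """Pair gametes uniformly at random (no selfing), degrees exact.

    Parents are drawn with probability proportional to their remaining
    gametes; if the draw strands all remaining gametes on one parent, an
    existing mating not involving that parent is rewired to absorb them.
    """
    rng = np.random.default_rng(seed)
    gv = g.g.copy()
    _check_degrees_feasible(gv)
    n = gv.shape[0]
    plan = np.zeros((n, n), dtype=np.int64)
    remaining = gv.astype(np.int64).copy()
    while remaining.sum() > 0:
        holders = np.flatnonzero(remaining > 0)
        if holders.size == 1:
            i = int(holders[0])
            # rewire: replace a mating (j, k) with (i, j) and (i, k)
            jj, kk = np.nonzero(np.triu(plan, 1))
            eligible = [(j, k) for j, k in zip(jj, kk) if j != i and k != i]
            if not eligible:
                raise ValueError("random mating stuck: no rewirable mating exists")
            j, k = eligible[rng.integers(len(eligible))]
            plan[j, k] -= 1; plan[k, j] -= 1
            plan[i, j] += 1; plan[j, i] += 1
            plan[i, k] += 1; plan[k, i] += 1
            remaining[i] -= 2
            continue
        p = remaining / remaining.sum()
        i = int(rng.choice(n, p=p))
        p2 = remaining.astype(float).copy()
        p2[i] = 0.0
        p2 /= p2.sum()
        j = int(rng.choice(n, p=p2))
        plan[i, j] += 1
        plan[j, i] += 1
        remaining[i] -= 1
        remaining[j] -= 1
    mate_plan = MatePlan(pair_counts=plan, n_offspring=g.n_offspring)
    if not np.array_equal(mate_plan.degrees, g.g):
        raise RuntimeError("random mating failed to conserve degrees")
    return mate_plan


def expected_progeny_homozygosity(
    G: np.ndarray, plan: MatePlan, n_loci: int
) -> float:
    """Mean expected count of homozygous offspring loci under the plan.

    For a mating i x j the expected number of homozygous loci of the
    offspring is ``(L + G_ij) / 2`` under Mendelian segregation (shared
    homozygotes fix the locus, opposite homozygotes forbid homozygosity,
    pairs involving a heterozygote contribute 1/2); the plan average weights
    matings by their counts.
    """
    G = np.asarray(G, dtype=float)
    total = 0.0
    for i, j, cnt in plan.pairs():
        total += cnt * (n_loci + G[i, j]) / 2.0
    return total / plan.n_offspring
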