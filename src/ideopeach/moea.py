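"""From-scratch elitist NSGA-II for the three-objective fruit problem.

Supports two decision spaces behind one loop:

* continuous — the seven model parameters inside a box, varied by simulated
  binary crossover (SBX) and polynomial mutation;
* binary — 31 allele bits or 17 haplotype-block bits, varied by single-point
  crossover and per-bit flips.

Constraints enter through Deb's feasibility rule: feasible solutions dominate
infeasible ones, and among infeasible solutions the smaller total violation
wins.  The result carries both the final population and a deduplicated
archive of every rank-1 solution seen across generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "NsgaConfig",
    "Problem",
    "NsgaResult",
    "dominates",
    "domination_matrix",
    "fast_non_dominated_sort",
    "crowding_distance",
    "sbx_crossover",
    "polynomial_mutation",
    "variation_continuous",
    "variation_binary",
    "evolve",
    "pareto_filter",
    "pareto_mask",
    "hypervolume",
]

_FEAS_EPS = 1e-12


@dataclass(frozen=True)
class NsgaConfig:
    """Algorithm settings (defaults follow the published run configuration).

    ``mutation_prob=None`` resolves to 0.1 for continuous and 0.01 for binary
    decision spaces.
    """

    population_size: int = 100
    max_generations: int = 250
    crossover_prob: float = 0.9
    mutation_prob: float | None = None
    eta_crossover: float = 20.0
    eta_mutation: float = 10.0
    seed: int = 0
    constraint_mode: str = "block_encoding"      # or "constraint_domination"
    archive_mode: str = "all_nondominated"       # or "final_population"

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population_size must be an even integer >= 2")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        for name in ("crossover_prob",):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mutation_prob is not None and not 0 <= self.mutation_prob <= 1:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if self.constraint_mode not in ("block_encoding", "constraint_domination"):
            raise ValueError("unknown constraint_mode")
        if self.archive_mode not in ("all_nondominated", "final_population"):
            raise ValueError("unknown archive_mode")

    def resolved_mutation_prob(self, binary: bool) -> float:
        if self.mutation_prob is not None:
            return self.mutation_prob
        return 0.01 if binary else 0.1


@dataclass
class Problem:
    """An evaluable multi-objective problem.

    ``evaluate(X)`` maps an ``(n, n_var)`` decision matrix to an ``(n, m)``
    objective matrix (minimization) and an ``(n,)`` violation vector
    (zeros when unconstrained).  For binary problems set ``binary=True`` and
    leave the bounds at their defaults.
    """

    n_var: int
    evaluate: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]
    binary: bool = False
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.binary:
            if self.lower is None or self.upper is None:
                raise ValueError("continuous problems need box bounds")
            self.lower = np.asarray(self.lower, dtype=float)
            self.upper = np.asarray(self.upper, dtype=float)
            if self.lower.shape != (self.n_var,) or self.upper.shape != (self.n_var,):
                raise ValueError("bounds must have shape (n_var,)")
            if np.any(self.lower >= self.upper):
                raise ValueError("lower bounds must be strictly below upper bounds")


@dataclass
class NsgaResult:
    """Final population plus the distinct non-dominated archive."""

    X: np.ndarray                  # final decision matrix (N, n_var)
    F: np.ndarray                  # final objectives (N, m)
    violations: np.ndarray         # final violations (N,)
    archive_X: np.ndarray          # distinct non-dominated decisions
    archive_F: np.ndarray
    n_evaluations: int
    config: NsgaConfig


# ---------------------------------------------------------------------------
# Domination and sorting
# ---------------------------------------------------------------------------

def dominates(fa, fb, va: float = 0.0, vb: float = 0.0, eps: float = _FEAS_EPS) -> bool:
    """Constraint-aware Pareto domination (Deb's feasibility rule)."""
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    if fa.shape != fb.shape:
        raise ValueError("objective vectors must share a dimensionality")
    a_feas, b_feas = va <= eps, vb <= eps
    if a_feas and b_feas:
        return bool(np.all(fa <= fb) and np.any(fa < fb))
    if a_feas != b_feas:
        return a_feas
    return va < vb


def domination_matrix(F: np.ndarray, violations: np.ndarray | None = None,
                      eps: float = _FEAS_EPS) -> np.ndarray:
    """Boolean matrix ``D[i, j] = i dominates j`` for a whole population."""
    F = np.asarray(F, dtype=float)
    weak = (F[:, None, :] <= F[None, :, :]).all(axis=-1)
    strict = (F[:, None, :] < F[None, :, :]).any(axis=-1)
    pareto = weak & strict
    if violations is None:
        return pareto
    v = np.asarray(violations, dtype=float)
    feas = v <= eps
    both_feas = feas[:, None] & feas[None, :]
    i_only = feas[:, None] & ~feas[None, :]
    neither = ~feas[:, None] & ~feas[None, :]
    return (both_feas & pareto) | i_only | (neither & (v[:, None] < v[None, :]))


def fast_non_dominated_sort(F: np.ndarray, violations: np.ndarray | None = None,
                            ) -> list[np.ndarray]:
    """Partition a population into non-dominated fronts F1, F2, ...

    Returns a list of index arrays; every individual appears in exactly one
    front.  F1 is the set dominated by nobody; each later front is computed
    after discounting the earlier ones.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[0] == 0:
        raise ValueError("population must be a non-empty (n, m) objective matrix")
    dom = domination_matrix(F, violations)
    n_dominators = dom.sum(axis=0)
    fronts: list[np.ndarray] = []
    assigned = np.zeros(F.shape[0], dtype=bool)
    while not assigned.all():
        current = np.flatnonzero((n_dominators == 0) & ~assigned)
        fronts.append(current)
        assigned[current] = True
        n_dominators = n_dominators - dom[current].sum(axis=0)
    return fronts


def ranks_from_fronts(fronts: Sequence[np.ndarray], n: int) -> np.ndarray:
    ranks = np.empty(n, dtype=int)
    for r, front in enumerate(fronts, start=1):
        ranks[front] = r
    return ranks


def crowding_distance(F: np.ndarray) -> np.ndarray:
    """Crowding distance within one front (larger = more isolated).

    Individuals attaining an objective's minimum or maximum get +inf;
    interior ones accumulate normalized neighbor gaps.  Objectives with zero
    range contribute nothing, so a fully degenerate front gets all zeros
    (fronts of one or two individuals get +inf as boundaries).
    """
    F = np.asarray(F, dtype=float)
    n = F.shape[0]
    if n == 0:
        raise ValueError("front must be non-empty")
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for j in range(F.shape[1]):
        col = F[:, j]
        spread = col.max() - col.min()
        if spread == 0:
            continue
        order = np.argsort(col, kind="stable")
        # every extreme-attaining individual is a boundary, ties included
        dist[col == col.min()] = np.inf
        dist[col == col.max()] = np.inf
        gaps = (col[order[2:]] - col[order[:-2]]) / spread
        np.add.at(dist, order[1:-1], gaps)
    return dist


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------

def _sbx_beta(u: np.ndarray, eta: float) -> np.ndarray:
    """Inverse-CDF sample of the SBX spread factor for uniform ``u``."""
    u = np.asarray(u, dtype=float)
    beta = np.where(u < 0.5,
                    (2.0 * u) ** (1.0 / (eta + 1.0)),
                    (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0)))
    return beta


def sbx_crossover(p1: np.ndarray, p2: np.ndarray, lower, upper, eta: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Simulated binary crossover of two parents (per-variable, bounded)."""
    c1, c2 = p1.copy(), p2.copy()
    for k in range(p1.size):
        if rng.random() > 0.5 or abs(p1[k] - p2[k]) < 1e-14:
            continue
        beta = float(_sbx_beta(rng.random(), eta))
        x1 = 0.5 * ((1 + beta) * p1[k] + (1 - beta) * p2[k])
        x2 = 0.5 * ((1 - beta) * p1[k] + (1 + beta) * p2[k])
        c1[k] = np.clip(x1, lower[k], upper[k])
        c2[k] = np.clip(x2, lower[k], upper[k])
    return c1, c2


def polynomial_mutation(x: np.ndarray, lower, upper, eta: float, prob: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Bounded polynomial mutation, applied per variable with probability ``prob``."""
    y = x.copy()
    for k in range(x.size):
        if rng.random() >= prob:
            continue
        lo, hi = lower[k], upper[k]
        span = hi - lo
        u = rng.random()
        d1 = (y[k] - lo) / span
        d2 = (hi - y[k]) / span
        if u < 0.5:
            delta = (2 * u + (1 - 2 * u) * (1 - d1) ** (eta + 1)) ** (1 / (eta + 1)) - 1
        else:
            delta = 1 - (2 * (1 - u) + 2 * (u - 0.5) * (1 - d2) ** (eta + 1)) ** (1 / (eta + 1))
        y[k] = np.clip(y[k] + delta * span, lo, hi)
    return y


def variation_continuous(parents: np.ndarray, problem: Problem, cfg: NsgaConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """SBX crossover plus polynomial mutation over a mating pool."""
    lower, upper = problem.lower, problem.upper
    pm = cfg.resolved_mutation_prob(binary=False)
    children = np.empty_like(parents)
    for i in range(0, parents.shape[0], 2):
        p1, p2 = parents[i], parents[(i + 1) % parents.shape[0]]
        if rng.random() < cfg.crossover_prob:
            c1, c2 = sbx_crossover(p1, p2, lower, upper, cfg.eta_crossover, rng)
        else:
            c1, c2 = p1.copy(), p2.copy()
        children[i] = polynomial_mutation(c1, lower, upper, cfg.eta_mutation, pm, rng)
        if i + 1 < parents.shape[0]:
            children[i + 1] = polynomial_mutation(c2, lower, upper, cfg.eta_mutation, pm, rng)
    return children


def variation_binary(parents: np.ndarray, problem: Problem, cfg: NsgaConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Single-point crossover plus independent per-bit flips."""
    pm = cfg.resolved_mutation_prob(binary=True)
    children = parents.copy()
    n_bits = problem.n_var
    for i in range(0, parents.shape[0], 2):
        p1, p2 = parents[i], parents[(i + 1) % parents.shape[0]]
        c1, c2 = p1.copy(), p2.copy()
        if rng.random() < cfg.crossover_prob and n_bits > 1:
            cut = int(rng.integers(1, n_bits))
            c1 = np.concatenate([p1[:cut], p2[cut:]])
            c2 = np.concatenate([p2[:cut], p1[cut:]])
        children[i] = c1
        if i + 1 < parents.shape[0]:
            children[i + 1] = c2
    if pm > 0:
        flips = rng.random(children.shape) < pm
        children = np.where(flips, 1 - children, children)
    return children.astype(np.int8)


# ---------------------------------------------------------------------------
# Selection and the main loop
# ---------------------------------------------------------------------------

def _tournament(ranks, crowding, n_pick, rng):
    """Binary tournaments on (rank asc, crowding desc), random tie-break."""
    n = ranks.size
    winners = np.empty(n_pick, dtype=int)
    a = rng.integers(0, n, size=n_pick)
    b = rng.integers(0, n, size=n_pick)
    for i in range(n_pick):
        x, y = a[i], b[i]
        if ranks[x] != ranks[y]:
            winners[i] = x if ranks[x] < ranks[y] else y
        elif crowding[x] != crowding[y]:
            winners[i] = x if crowding[x] > crowding[y] else y
        else:
            winners[i] = x if rng.random() < 0.5 else y
    return winners


def _select_next(F, violations, N):
    """Environmental selection: fill fronts, trim the last by crowding."""
    fronts = fast_non_dominated_sort(F, violations)
    chosen: list[int] = []
    for front in fronts:
        if len(chosen) + front.size <= N:
            chosen.extend(front.tolist())
            if len(chosen) == N:
                break
        else:
            dist = crowding_distance(F[front])
            order = np.argsort(-dist, kind="stable")
            chosen.extend(front[order[: N - len(chosen)]].tolist())
            break
    return np.array(chosen, dtype=int)


def _dedup_rows(X: np.ndarray, binary: bool, rtol: float = 1e-12) -> np.ndarray:
    """Indices of first occurrences of distinct rows.

    Binary rows compare exactly; continuous rows are duplicates when equal
    componentwise within ``rtol`` relative tolerance (detected on lexsorted
    neighbors).
    """
    n = X.shape[0]
    if n == 0:
        return np.array([], dtype=int)
    if binary:
        _, first = np.unique(X, axis=0, return_index=True)
        return np.sort(first)
    order = np.lexsort(X.T[::-1])
    keep = [order[0]]
    for prev, cur in zip(order[:-1], order[1:]):
        if not np.allclose(X[cur], X[prev], rtol=rtol, atol=0.0):
            keep.append(cur)
    return np.sort(np.array(keep, dtype=int))


def evolve(problem: Problem, cfg: NsgaConfig) -> NsgaResult:
    """Run the (mu + lambda) elitist NSGA-II loop.

    Deterministic for a fixed seed.  The archive collects the distinct,
    feasible rank-1 solutions accumulated across all generations
    (``archive_mode="all_nondominated"``, default) or just the final
    population's first front (``"final_population"``).
    """
    rng = np.random.default_rng(cfg.seed)
    N = cfg.population_size
    if problem.binary:
        X = rng.integers(0, 2, size=(N, problem.n_var)).astype(np.int8)
    else:
        X = problem.lower + rng.random((N, problem.n_var)) * (problem.upper - problem.lower)
    F, V = _evaluate(problem, X)
    n_eval = N
    arch_X, arch_F = _update_archive(None, None, X, F, V, problem.binary)

    for _ in range(cfg.max_generations):
        fronts = fast_non_dominated_sort(F, V)
        ranks = ranks_from_fronts(fronts, N)
        crowd = np.empty(N)
        for front in fronts:
            crowd[front] = crowding_distance(F[front])
        parents_idx = _tournament(ranks, crowd, N, rng)
        if problem.binary:
            children = variation_binary(X[parents_idx], problem, cfg, rng)
        else:
            children = variation_continuous(X[parents_idx], problem, cfg, rng)
        Fc, Vc = _evaluate(problem, children)
        n_eval += children.shape[0]
        X_all = np.vstack([X, children])
        F_all = np.vstack([F, Fc])
        V_all = np.concatenate([V, Vc])
        sel = _select_next(F_all, V_all, N)
        X, F, V = X_all[sel], F_all[sel], V_all[sel]
        if cfg.archive_mode == "all_nondominated":
            arch_X, arch_F = _update_archive(arch_X, arch_F, X, F, V, problem.binary)

    if cfg.archive_mode == "final_population":
        arch_X, arch_F = _update_archive(None, None, X, F, V, problem.binary)
    return NsgaResult(X=X, F=F, violations=V, archive_X=arch_X, archive_F=arch_F,
                      n_evaluations=n_eval, config=cfg)


def _evaluate(problem: Problem, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    F, V = problem.evaluate(X)
    F = np.asarray(F, dtype=float)
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(F)):
        bad = np.flatnonzero(~np.isfinite(F).all(axis=1))[0]
        raise RuntimeError(f"non-finite objectives for decision vector {X[bad]!r}")
    return F, V


def _update_archive(arch_X, arch_F, X, F, V, binary):
    feas = V <= _FEAS_EPS
    cand_X = X[feas]
    cand_F = F[feas]
    if arch_X is not None:
        cand_X = np.vstack([arch_X, cand_X])
        cand_F = np.vstack([arch_F, cand_F])
    if cand_X.shape[0] == 0:
        return cand_X, cand_F
    keep = _dedup_rows(cand_X, binary)
    cand_X, cand_F = cand_X[keep], cand_F[keep]
    mask = pareto_mask(cand_F)
    return cand_X[mask], cand_F[mask]


# ---------------------------------------------------------------------------
# Reporting helpers
# ---------------------------------------------------------------------------

def pareto_mask(F: np.ndarray) -> np.ndarray:
    """Boolean mask of the non-dominated rows of ``F`` (duplicates all kept).

    Iterative shrinking sweep: pick the next surviving candidate, drop every
    row it strictly dominates, advance.  Each pass is a vectorized scan of
    the surviving rows, so the cost is O(front size x n) with rapidly
    shrinking n — exhaustive 2^17 enumerations stay tractable.
    """
    F = np.asarray(F, dtype=float)
    n = F.shape[0]
    if n == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(F.sum(axis=1), kind="stable")  # heuristic: strong rows first
    idx = order.copy()
    costs = F[order]
    next_i = 0
    while next_i < costs.shape[0]:
        f = costs[next_i]
        dominated = (costs >= f).all(axis=1) & (costs > f).any(axis=1)
        keep = ~dominated
        idx = idx[keep]
        costs = costs[keep]
        next_i = int(keep[:next_i].sum()) + 1
    mask = np.zeros(n, dtype=bool)
    mask[idx] = True
    return mask


def pareto_filter(F: np.ndarray, X: np.ndarray | None = None, binary: bool = True):
    """Distinct non-dominated subset of a solution set (idempotent).

    Returns filtered ``F`` (and ``X`` when given).  Duplicate decision
    vectors are removed when ``X`` is given, duplicate objective rows
    otherwise.
    """
    F = np.asarray(F, dtype=float)
    mask = pareto_mask(F)
    idx = np.flatnonzero(mask)
    if X is not None:
        X = np.asarray(X)
        keep = _dedup_rows(X[idx], binary)
        idx = idx[keep]
        return F[idx], X[idx]
    keep = _dedup_rows(F[idx], binary=False)
    return F[idx[keep]]


def hypervolume(F: np.ndarray, ref: np.ndarray) -> float:
    """Dominated hypervolume of a minimization front w.r.t. ``ref`` (2-d or 3-d).

    Points not strictly below ``ref`` in every objective contribute nothing.
    3-d volume is computed by sweeping the third objective and accumulating
    2-d staircase areas.
    """
    F = np.asarray(F, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if F.ndim != 2 or F.shape[1] not in (2, 3) or ref.shape != (F.shape[1],):
        raise ValueError("hypervolume supports (n, 2) or (n, 3) fronts")
    F = F[(F < ref).all(axis=1)]
    if F.shape[0] == 0:
        return 0.0
    F = F[pareto_mask(F)]
    if F.shape[1] == 2:
        return _hv2d(F, ref)
    order = np.argsort(F[:, 2], kind="stable")
    Fs = F[order]
    total = 0.0
    z_levels = np.append(Fs[:, 2], ref[2])
    for i in range(Fs.shape[0]):
        dz = z_levels[i + 1] - z_levels[i]
        if dz > 0:
            total += dz * _hv2d(Fs[: i + 1, :2], ref[:2])
    return float(total)


def _hv2d(F: np.ndarray, ref: np.ndarray) -> float:
    pts = F[pareto_mask(F)]
    pts = pts[np.argsort(pts[:, 0], kind="stable")]
    area = 0.0
    y_prev = ref[1]
    for x, y in pts:
        if y < y_prev:
            area += (ref[0] - x) * (y_prev - y)
            y_prev = y
    return float(area)
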