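"""Exact parent-selection solvers and Pareto-frontier utilities.

Two scalarizations of the multiobjective subset-selection problem
(choose S of n candidates to maximize all per-trait sums simultaneously):

* **Index selection** — maximize the weighted sum
  ``sum_k w_k sum_{i in x} v[i,k]``.  Separable per individual, so the
  exact optimum is the top-S by the per-individual score
  ``sum_k w_k v[i,k]``.  Any optimum with strictly positive weights is
  Pareto optimal, but only *supported* (convex-hull) Pareto optima are
  reachable, and the winner depends on the measurement units of the raw
  trait values.

* **L-shaped selection** — maximize the Chebyshev-like max-min objective
  ``min_k ( sum_{i in x} vn[i,k] / w_k )`` over normalized values
  ``vn in (0,1)``.  Its level sets are L-shaped in two dimensions.  Every
  Pareto-optimal subset is the optimum under its own constructive weights
  ``w_k = sum_{i in x} vn[i,k]`` (with objective value exactly 1), so the
  method can reach the entire Pareto frontier, including unsupported
  points, and is invariant under per-trait affine changes of units once
  normalization is recomputed.

Solvers are exact: full enumeration of all C(n, S) subsets up to a
configurable cap, and an exact mixed-integer linear program (HiGHS via
scipy) beyond it.  No heuristics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .core import GeneticValues
from .errors import CapacityError

__all__ = [
    "WeightVector",
    "SelectionResult",
    "FrontierSet",
    "index_select",
    "lshaped_objective",
    "lshaped_select",
    "weights_for_solution",
    "pareto_front",
    "supported_front",
    "lshaped_weight_regions_2traits",
]

#: default cap on the number of subsets enumerated exactly
MAX_ENUMERATE = 10**6

_REL_TOL = 1e-9  # relative tie tolerance on floating-point objectives


@dataclass(frozen=True)
class WeightVector:
    """Strictly positive per-trait weights."""

    values: np.ndarray

    def __post_init__(self):
        v = np.atleast_1d(np.asarray(self.values, dtype=float))
        if v.ndim != 1 or v.size == 0:
            raise ValueError("weights must be a nonempty 1-d vector")
        if not (np.isfinite(v).all() and (v > 0).all()):
            raise ValueError("all weights must be finite and strictly positive")
        object.__setattr__(self, "values", v)

    @classmethod
    def normalized(cls, values) -> "WeightVector":
        """Construct with weights rescaled to sum to 1."""
        v = np.atleast_1d(np.asarray(values, dtype=float))
        return cls(v / v.sum())

    def __len__(self) -> int:
        return self.values.size

    def __iter__(self):
        return iter(self.values)


def _as_weights(w) -> np.ndarray:
    if isinstance(w, WeightVector):
        return w.values
    return WeightVector(np.asarray(w, dtype=float)).values


@dataclass
class SelectionResult:
    """A selected parent set with its objective value and provenance."""

    selected: tuple[int, ...]
    objective: float
    weights: WeightVector
    method: str
    individual_ids: tuple[str, ...] = ()

    def __post_init__(self):
        self.selected = tuple(int(i) for i in self.selected)
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected indices must be unique")


@dataclass
class FrontierSet:
    """Indices into the original point list plus their trait vectors."""

    indices: list[int]
    vectors: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# index selection
# ---------------------------------------------------------------------------


def index_select(V: GeneticValues, w, S: int) -> SelectionResult:
    """Exact weighted-sum (index) selection of S individuals.

    The objective is separable, so the optimum is the S individuals with
    the largest score ``sum_k w_k v[i,k]``.  Score ties are broken
    lexicographically by individual identifier for determinism.
    """
    wv = _as_weights(w)
    n = V.n_individuals
    if not 0 < S <= n:
        raise ValueError(f"S={S} must be in 1..{n}")
    if wv.size != V.n_traits:
        raise ValueError("weight dimension does not match trait dimension")
    scores = V.values @ wv
    ids = np.array(V.individual_ids)
    order = np.lexsort((ids, -scores))  # primary: score desc; ties: id asc
    sel = tuple(sorted(int(i) for i in order[:S]))
    objective = float(scores[list(sel)].sum())
    return SelectionResult(
        sel,
        objective,
        WeightVector(wv),
        "index",
        tuple(V.individual_ids[i] for i in sel),
    )


# ---------------------------------------------------------------------------
# L-shaped selection
# ---------------------------------------------------------------------------


def lshaped_objective(selected, Vn: GeneticValues, w) -> float:
    """Max-min objective ``min_k (sum_{i in selected} vn[i,k] / w_k)``."""
    if not Vn.is_normalized:
        raise ValueError("L-shaped objective requires normalized values")
    wv = _as_weights(w)
    sums = Vn.values[list(selected)].sum(axis=0)
    return float((sums / wv).min())


def _enumerate_lshaped(values: np.ndarray, wv: np.ndarray, S: int):
    n = values.shape[0]
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), S)),
        dtype=np.int64,
    ).reshape(-1, S)
    sums = values[combos].sum(axis=1)  # (C, K)
    obj = (sums / wv).min(axis=1)
    best = obj.max()
    tol = _REL_TOL * max(1.0, abs(best))
    tied = np.flatnonzero(obj >= best - tol)
    totals = sums[tied].sum(axis=1)
    best_total = totals.max()
    tied = tied[totals >= best_total - _REL_TOL * max(1.0, abs(best_total))]
    pick = int(tied[0])  # combos are generated in lexicographic order
    return tuple(int(i) for i in combos[pick]), float(obj[pick])


def _milp_lshaped(values: np.ndarray, wv: np.ndarray, S: int):
    n, K = values.shape
    # variables: x_0..x_{n-1} binary, z continuous; maximize z
    c = np.zeros(n + 1)
    c[-1] = -1.0
    A_card = np.zeros((1, n + 1))
    A_card[0, :n] = 1.0
    A_z = np.hstack([-(values / wv).T, np.ones((K, 1))])  # z - sum x*v/w_k <= 0
    constraints = [
        LinearConstraint(A_card, S, S),
        LinearConstraint(A_z, -np.inf, 0.0),
    ]
    integrality = np.concatenate([np.ones(n), [0]])
    lb = np.concatenate([np.zeros(n), [-np.inf]])
    ub = np.concatenate([np.ones(n), [np.inf]])
    res = milp(
        c,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(lb, ub),
    )
    if not res.success:
        raise CapacityError(f"exact MILP backend failed: {res.message}")
    sel = tuple(int(i) for i in np.flatnonzero(np.round(res.x[:n]) > 0.5))
    return sel


def lshaped_select(
    Vn: GeneticValues,
    w,
    S: int,
    backend: str = "auto",
    max_enumerate: int = MAX_ENUMERATE,
) -> SelectionResult:
    """Exact L-shaped (max-min) selection of S individuals.

    ``backend`` is ``"enumerate"`` (all C(n,S) subsets, exact tie-breaks),
    ``"milp"`` (exact integer program, HiGHS), or ``"auto"`` which
    enumerates when C(n,S) <= ``max_enumerate`` and otherwise falls back
    to the MILP.  Forcing enumeration on an instance above the cap raises
    :class:`CapacityError` — there is no silent heuristic path.

    Among max-min-optimal subsets (which can be weakly dominated), ties
    are broken by the largest total normalized sum, then by the
    lexicographically smallest index set, so the returned optimum is
    itself Pareto optimal and runs are reproducible.
    """
    if not Vn.is_normalized:
        raise ValueError("L-shaped selection requires normalized values")
    wv = _as_weights(w)
    n = Vn.n_individuals
    if not 0 < S <= n:
        raise ValueError(f"S={S} must be in 1..{n}")
    if wv.size != Vn.n_traits:
        raise ValueError("weight dimension does not match trait dimension")
    n_subsets = comb(n, S)
    if backend not in ("auto", "enumerate", "milp"):
        raise ValueError(f"unknown backend {backend!r}")
    if backend == "enumerate" and n_subsets > max_enumerate:
        raise CapacityError(
            f"C({n},{S}) = {n_subsets} subsets exceeds the enumeration cap "
            f"({max_enumerate}); use the 'milp' backend"
        )
    if backend == "milp" or (backend == "auto" and n_subsets > max_enumerate):
        sel = _milp_lshaped(Vn.values, wv, S)
        objective = lshaped_objective(sel, Vn, wv)
    else:
        sel, objective = _enumerate_lshaped(Vn.values, wv, S)
    return SelectionResult(
        sel,
        objective,
        WeightVector(wv),
        "lshaped",
        tuple(Vn.individual_ids[i] for i in sel),
    )


def weights_for_solution(selected, Vn: GeneticValues) -> WeightVector:
    """Constructive weights under which a Pareto-optimal subset is optimal.

    ``w_k = sum_{i in selected} vn[i,k]`` — strictly positive because
    normalized values lie in (0, 1).  With these weights the subset's own
    max-min objective equals exactly 1, and no subset can exceed 1 unless
    it dominates the given one.
    """
    if not Vn.is_normalized:
        raise ValueError("constructive weights require normalized values")
    sel = list(selected)
    if not sel:
        raise ValueError("selected set must be nonempty")
    return WeightVector(Vn.values[sel].sum(axis=0))


# ---------------------------------------------------------------------------
# frontiers
# ---------------------------------------------------------------------------


def _points_array(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("points must be a nonempty 2-d array-like")
    return pts


def pareto_front(points) -> FrontierSet:
    """Non-dominated points (dominance: >= in every trait, > in at least one).

    Duplicate vectors never dominate each other, so all copies of a
    non-dominated vector are retained.
    """
    pts = _points_array(points)
    keep = []
    for i, p in enumerate(pts):
        dominated = ((pts >= p).all(axis=1) & (pts > p).any(axis=1)).any()
        if not dominated:
            keep.append(i)
    return FrontierSet(keep, pts[keep])


def _upper_hull_2d(pts: np.ndarray, include_weak: bool) -> list[int]:
    """Indices (into pts) of weighted-sum maximizers; pts are unique Pareto
    points sorted by trait 1 ascending (trait 2 strictly descending)."""
    tol = 1e-12 * max(1.0, float(np.abs(pts).max()))
    chain: list[int] = []
    for i in range(len(pts)):
        while len(chain) >= 2:
            o, a, b = pts[chain[-2]], pts[chain[-1]], pts[i]
            cross = (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])
            # cross > 0: chain[-1] strictly below segment o-b  -> always pop
            # cross ~ 0: collinear (weakly supported)          -> pop unless kept
            if cross > tol or (not include_weak and cross >= -tol):
                chain.pop()
            else:
                break
        chain.append(i)
    return chain


def _supported_lp(pts: np.ndarray, include_weak: bool) -> list[int]:
    """General-K exact test: point p is supported iff strictly positive
    weights exist making it a (strict) maximizer of the weighted sum."""
    uniq, inverse = np.unique(pts, axis=0, return_inverse=True)
    n_u, K = uniq.shape
    supported_u = np.zeros(n_u, dtype=bool)
    for u in range(n_u):
        p = uniq[u]
        others = np.delete(uniq, u, axis=0)
        if others.shape[0] == 0:
            supported_u[u] = True
            continue
        # max t  s.t.  w.(p - q) >= t  for all q,  1 <= w_k <= 1e6,  t <= 1
        diffs = p - others  # (m, K)
        A_ub = np.hstack([-diffs, np.ones((diffs.shape[0], 1))])
        c = np.zeros(K + 1)
        c[-1] = -1.0
        bounds = [(1.0, 1e6)] * K + [(None, 1.0)]
        res = linprog(c, A_ub=A_ub, b_ub=np.zeros(diffs.shape[0]), bounds=bounds,
                      method="highs")
        if not res.success:
            continue
        t = res.x[-1]
        supported_u[u] = t > 1e-9 or (include_weak and t > -1e-9)
    return [i for i in range(pts.shape[0]) if supported_u[inverse[i]]]


def supported_front(points, include_weak: bool = False, method: str = "auto") -> FrontierSet:
    """Points attainable as weighted-sum maximizers with strictly positive
    weights — the convex (supported) part of the Pareto frontier.

    By default only strict maximizers (hull vertices) are returned; points
    lying in the interior of a hull segment are reachable only as ties and
    are excluded unless ``include_weak`` is set.  For two traits the
    upper-right convex hull is computed directly; for more traits each
    candidate is tested exactly with a small linear program.
    """
    pts = _points_array(points)
    K = pts.shape[1]
    if method not in ("auto", "hull", "lp"):
        raise ValueError(f"unknown method {method!r}")
    if method == "hull" and K != 2:
        raise ValueError("hull method requires exactly 2 traits")
    pf = pareto_front(pts)
    if method == "lp" or (method == "auto" and K != 2):
        idx_local = _supported_lp(pf.vectors, include_weak)
        idx = [pf.indices[i] for i in idx_local]
        return FrontierSet(idx, pts[idx])
    # K == 2 hull path on unique Pareto vectors
    uniq = np.unique(pf.vectors, axis=0)  # sorted by v1 asc, then v2
    order = np.lexsort((-uniq[:, 1], uniq[:, 0]))
    uniq = uniq[order]
    chain = _upper_hull_2d(uniq, include_weak)
    chosen = {tuple(uniq[i]) for i in chain}
    idx = [i for i in range(pts.shape[0]) if tuple(pts[i]) in chosen]
    return FrontierSet(idx, pts[idx])


def lshaped_weight_regions_2traits(points):
    """Partition of w1 in (0, 1) (w2 = 1 - w1) into L-shaped optimality regions.

    For normalized two-trait points, the max-min optimum as a function of
    the weights walks along the Pareto front; two adjacent Pareto points
    ``p`` (smaller trait 1) and ``q`` tie exactly when the L-shaped level
    curve touches both, i.e. at ``w1 / w2 = p_1 / q_2``.  Every Pareto
    point therefore owns one nonempty open interval of w1 — including the
    unsupported points that weighted-sum selection can never return.

    Returns a list of ``((w1_lo, w1_hi), index, vector)`` triples ordered
    by increasing w1, with indices into the original point list (first
    occurrence for duplicated vectors).
    """
    pts = _points_array(points)
    if pts.shape[1] != 2:
        raise ValueError("weight regions are defined for exactly 2 traits")
    if not ((pts > 0).all() and (pts < 1).all()):
        raise ValueError("points must lie strictly inside the unit square")
    pf = pareto_front(pts)
    uniq, first = np.unique(pf.vectors, axis=0, return_index=True)
    order = np.lexsort((-uniq[:, 1], uniq[:, 0]))
    uniq = uniq[order]
    orig = [pf.indices[first[i]] for i in order]
    m = uniq.shape[0]
    ratios = [uniq[i, 0] / uniq[i + 1, 1] for i in range(m - 1)]
    cuts = [0.0] + [r / (1.0 + r) for r in ratios] + [1.0]
    return [
        ((cuts[i], cuts[i + 1]), orig[i], uniq[i].copy())
        for i in range(m)
    ]
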