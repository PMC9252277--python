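"""Recurrent breeding simulation under a recombination map.

Meiosis follows the standard no-interference model: within a chromosome
the gamete starts on a uniformly chosen parental haplotype and switches
haplotype between adjacent loci independently with the interval's
recombination frequency r; intervals spanning a chromosome boundary are
fixed at r = 0.5, which makes chromosomes assort independently.

The breeding loop mirrors a simple recurrent-selection program: from the
current population, select S parents with the configured method (index
selection on raw values, or L-shaped selection on normalized values),
produce N progeny from one biparental cross (S = 2; for larger parent
sets each progeny draws two distinct parents at random), and repeat for
T generations.  Selection uses true additive genetic values throughout —
no phenotyping noise, no dominance or epistasis.

Normalization bounds during a run follow a configurable policy:

* ``"incremental"`` (default) — running per-trait min/max over every
  individual seen so far in the run, re-padded each generation.  All
  individuals ever compared are inside the reference set, so progeny that
  transgress the founder range (genetic gain) remain normalizable.
* ``"founders"`` — bounds frozen from generation 0; raises if a later
  generation transgresses them.
* ``"attainable"`` — genotype-support bounds from the effect matrix,
  frozen and valid for any conceivable genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    EffectMatrix,
    GeneticValues,
    GenotypeMatrix,
    TraitBounds,
    TraitDirections,
    attainable_bounds,
    compute_bounds,
    compute_genetic_values,
    normalize_values,
    orient_effects,
)
from .errors import AlignmentError
from .metrics import (
    EvaluatedIndividual,
    EvaluationSet,
    diversity,
    pareto_optimality_gap,
    pareto_subset,
)
from .selection import SelectionResult, WeightVector, index_select, lshaped_select

__all__ = [
    "RecombinationMap",
    "BreedingConfig",
    "BreedingResult",
    "make_gamete",
    "cross",
    "run_breeding_program",
    "run_experiment_grid",
    "evaluate_experiment",
]

_BOUND_POLICIES = ("incremental", "founders", "attainable")


@dataclass
class RecombinationMap:
    """Recombination frequency per adjacent-locus interval.

    ``r`` has length ``n_loci - 1``; every entry lies in [0, 0.5] and
    intervals crossing a chromosome boundary must equal 0.5 exactly.
    """

    locus_ids: list[str]
    r: np.ndarray
    chromosome_of_locus: np.ndarray

    def __post_init__(self):
        self.locus_ids = [str(x) for x in self.locus_ids]
        self.r = np.asarray(self.r, dtype=float)
        self.chromosome_of_locus = np.asarray(self.chromosome_of_locus, dtype=np.int64)
        L = len(self.locus_ids)
        if self.r.shape != (max(L - 1, 0),):
            raise ValueError("r must have length n_loci - 1")
        if self.chromosome_of_locus.shape != (L,):
            raise ValueError("chromosome_of_locus must have length n_loci")
        if L > 1:
            if not ((self.r >= 0) & (self.r <= 0.5)).all():
                raise ValueError("recombination frequencies must lie in [0, 0.5]")
            boundary = self.chromosome_of_locus[1:] != self.chromosome_of_locus[:-1]
            if not (self.r[boundary] == 0.5).all():
                raise ValueError("chromosome-boundary intervals must have r = 0.5")

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)


@dataclass
class BreedingConfig:
    """Run parameters for one recurrent-selection breeding program."""

    weights: WeightVector
    method: str = "lshaped"
    S: int = 2
    N: int = 200
    T: int = 5
    seed: object = None
    epsilon_rel: float = 1e-6
    normalize_for_index: bool = False
    bounds_policy: str = "incremental"

    def __post_init__(self):
        if not isinstance(self.weights, WeightVector):
            self.weights = WeightVector(np.asarray(self.weights, dtype=float))
        if self.method not in ("index", "lshaped"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.S < 2 or self.N < 1 or self.T < 1:
            raise ValueError("require S >= 2, N >= 1, T >= 1")
        if self.bounds_policy not in _BOUND_POLICIES:
            raise ValueError(f"bounds_policy must be one of {_BOUND_POLICIES}")


@dataclass
class BreedingResult:
    """Final population plus the per-generation genetic-value trace."""

    final: GenotypeMatrix
    values_per_generation: list[GeneticValues]
    selections: list[SelectionResult]
    bounds: TraitBounds
    config: BreedingConfig


def make_gamete(parent_haplotypes: np.ndarray, rmap: RecombinationMap, rng) -> np.ndarray:
    """One meiotic gamete from a (2, n_loci) pair of parental haplotypes.

    The starting haplotype is uniform; a phase switch occurs between
    adjacent loci independently with probability r (no crossover
    interference).  Chromosome-boundary intervals carry r = 0.5, which is
    equivalent to drawing a fresh uniform starting phase per chromosome.
    """
    haps = np.asarray(parent_haplotypes)
    if haps.ndim != 2 or haps.shape[0] != 2 or haps.shape[1] != rmap.n_loci:
        raise ValueError("parent haplotypes must have shape (2, n_loci) matching the map")
    L = haps.shape[1]
    phase = np.empty(L, dtype=np.int64)
    phase[0] = rng.integers(0, 2)
    if L > 1:
        switches = rng.random(L - 1) < rmap.r
        phase[1:] = (phase[0] + np.cumsum(switches)) % 2
    return haps[phase, np.arange(L)]


def cross(
    parentA: np.ndarray,
    parentB: np.ndarray,
    n_progeny: int,
    rmap: RecombinationMap,
    rng,
    locus_ids=None,
    chromosome_of_locus=None,
    id_prefix: str = "p",
) -> GenotypeMatrix:
    """Biparental cross: each progeny receives one independent gamete from
    each parent.  Parents are (2, n_loci) haplotype pairs."""
    locus_ids = list(locus_ids) if locus_ids is not None else list(rmap.locus_ids)
    chrom = (
        np.asarray(chromosome_of_locus)
        if chromosome_of_locus is not None
        else rmap.chromosome_of_locus
    )
    haps = np.empty((n_progeny, 2, rmap.n_loci), dtype=np.int8)
    for i in range(n_progeny):
        haps[i, 0] = make_gamete(parentA, rmap, rng)
        haps[i, 1] = make_gamete(parentB, rmap, rng)
    ids = [f"{id_prefix}{i}" for i in range(n_progeny)]
    return GenotypeMatrix(ids, locus_ids, chrom, haps)


class _BoundsTracker:
    """Maintains normalization bounds for one run under the chosen policy."""

    def __init__(self, policy: str, epsilon_rel: float, effects: EffectMatrix):
        self.policy = policy
        self.epsilon_rel = epsilon_rel
        self._vmin: np.ndarray | None = None
        self._vmax: np.ndarray | None = None
        self._frozen: TraitBounds | None = (
            attainable_bounds(effects, epsilon_rel) if policy == "attainable" else None
        )

    def update(self, V: GeneticValues) -> TraitBounds:
        if self.policy == "attainable":
            return self._frozen
        vmin = V.values.min(axis=0)
        vmax = V.values.max(axis=0)
        if self._vmin is None:
            self._vmin, self._vmax = vmin, vmax
        elif self.policy == "incremental":
            self._vmin = np.minimum(self._vmin, vmin)
            self._vmax = np.maximum(self._vmax, vmax)
        # "founders": range stays frozen at generation 0
        rng = self._vmax - self._vmin
        if (rng == 0).any():
            raise ValueError(
                "degenerate trait range in the reference population; "
                "use the 'attainable' bounds policy or add variation"
            )
        eps = self.epsilon_rel * rng
        return TraitBounds(self._vmin - eps, self._vmax + eps, self.epsilon_rel)


def _select_parents(
    V: GeneticValues, bounds: TraitBounds, cfg: BreedingConfig
) -> SelectionResult:
    if cfg.method == "lshaped":
        Vn = normalize_values(V, bounds)
        return lshaped_select(Vn, cfg.weights, cfg.S)
    if cfg.normalize_for_index:
        V = normalize_values(V, bounds)
        # re-wrap: index_select accepts either form
    return index_select(V, cfg.weights, cfg.S)


def run_breeding_program(
    founders: GenotypeMatrix,
    effects: EffectMatrix,
    rmap: RecombinationMap,
    cfg: BreedingConfig,
    directions: TraitDirections | None = None,
) -> BreedingResult:
    """Run T generations of select-and-cross starting from the founders.

    Returns the generation-T population together with the genetic-value
    trace for generations 0..T and the selection made at each step.
    """
    if founders.locus_ids != effects.locus_ids or founders.locus_ids != rmap.locus_ids:
        raise AlignmentError("founders, effects and recombination map must share loci")
    if directions is not None:
        effects = orient_effects(effects, directions)
    rng = np.random.default_rng(cfg.seed)
    tracker = _BoundsTracker(cfg.bounds_policy, cfg.epsilon_rel, effects)

    pop = founders
    trace: list[GeneticValues] = []
    selections: list[SelectionResult] = []
    bounds: TraitBounds | None = None
    for t in range(cfg.T):
        if pop.n_individuals < cfg.S:
            raise ValueError("population smaller than the number of parents")
        V = compute_genetic_values(pop, effects)
        trace.append(V)
        bounds = tracker.update(V)
        sel = _select_parents(V, bounds, cfg)
        selections.append(sel)
        parent_haps = [pop.haplotypes[i] for i in sel.selected]
        if cfg.S == 2:
            pop = cross(
                parent_haps[0], parent_haps[1], cfg.N, rmap, rng,
                id_prefix=f"g{t + 1}_",
            )
        else:
            haps = np.empty((cfg.N, 2, rmap.n_loci), dtype=np.int8)
            for i in range(cfg.N):
                a, b = rng.choice(cfg.S, size=2, replace=False)
                haps[i, 0] = make_gamete(parent_haps[a], rmap, rng)
                haps[i, 1] = make_gamete(parent_haps[b], rmap, rng)
            pop = GenotypeMatrix(
                [f"g{t + 1}_{i}" for i in range(cfg.N)],
                founders.locus_ids,
                founders.chromosome_of_locus,
                haps,
            )
    V_final = compute_genetic_values(pop, effects)
    trace.append(V_final)
    bounds = tracker.update(V_final)
    return BreedingResult(pop, trace, selections, bounds, cfg)


def run_experiment_grid(
    founders: GenotypeMatrix,
    effects: EffectMatrix,
    rmap: RecombinationMap,
    methods: list[str],
    weight_grid: list,
    reps: int,
    master_seed: int,
    cfg_template: BreedingConfig | None = None,
    directions: TraitDirections | None = None,
) -> dict[str, EvaluationSet]:
    """The weight-grid experiment: every method x weight x repetition.

    Each run gets an independent deterministic seed derived from
    ``(master_seed, method_index, weight_index, repetition)``.  Final-
    generation individuals are pooled per method into an
    :class:`EvaluationSet`, each tagged with the weight vector of the run
    that produced it (the provenance used by the gap metric).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    grid = [w if isinstance(w, WeightVector) else WeightVector(np.asarray(w, float))
            for w in weight_grid]
    pools: dict[str, EvaluationSet] = {}
    for m_idx, method in enumerate(methods):
        individuals: list[EvaluatedIndividual] = []
        for w_idx, w in enumerate(grid):
            for rep in range(reps):
                base = cfg_template or BreedingConfig(weights=w)
                cfg = BreedingConfig(
                    weights=w,
                    method=method,
                    S=base.S,
                    N=base.N,
                    T=base.T,
                    seed=[int(master_seed), m_idx, w_idx, rep],
                    epsilon_rel=base.epsilon_rel,
                    normalize_for_index=base.normalize_for_index,
                    bounds_policy=base.bounds_policy,
                )
                res = run_breeding_program(founders, effects, rmap, cfg, directions)
                V = res.values_per_generation[-1]
                for i in range(V.n_individuals):
                    individuals.append(
                        EvaluatedIndividual(
                            V.values[i],
                            w.values,
                            id=f"{method}_w{w_idx}_r{rep}_{V.individual_ids[i]}",
                        )
                    )
        pools[method] = EvaluationSet(individuals, label=method)
    return pools


def evaluate_experiment(
    pools: dict[str, EvaluationSet],
    epsilon_rel: float = 1e-6,
    diversity_weights=None,
) -> dict[str, dict[str, float]]:
    """Score each method's pooled final generation against the union.

    Trait values of all pools are normalized jointly (bounds from the
    pooled union — the set of all individuals being compared), then each
    method's Pareto subset is scored: Pareto optimality gap against the
    Pareto subset of the union, and diversity under uniform weights by
    default.
    """
    labels = list(pools)
    all_values = np.vstack([pools[m].values for m in labels])
    K = all_values.shape[1]
    ref = GeneticValues(
        [f"u{i}" for i in range(all_values.shape[0])],
        [f"t{k}" for k in range(K)],
        all_values,
    )
    bounds = compute_bounds(ref, epsilon_rel=epsilon_rel)

    def _normalized(es: EvaluationSet, label: str) -> EvaluationSet:
        V = GeneticValues(
            [ind.id or str(i) for i, ind in enumerate(es.individuals)],
            ref.trait_ids,
            es.values,
        )
        Vn = normalize_values(V, bounds)
        inds = [
            EvaluatedIndividual(Vn.values[i], es.individuals[i].provenance_weights,
                                es.individuals[i].id)
            for i in range(len(es.individuals))
        ]
        return EvaluationSet(inds, label=label)

    union = EvaluationSet(
        [ind for m in labels for ind in pools[m].individuals], label="union"
    )
    P_union = pareto_subset(_normalized(union, "union"))
    w_div = (
        np.full(K, 1.0 / K) if diversity_weights is None
        else np.asarray(diversity_weights, dtype=float)
    )
    out: dict[str, dict[str, float]] = {}
    for m in labels:
        P0 = pareto_subset(_normalized(pools[m], m))
        out[m] = {
            "gap": pareto_optimality_gap(P0, P_union, reduction="sum"),
            "gap_mean": pareto_optimality_gap(P0, P_union, reduction="mean"),
            "diversity": diversity(P0, w_div),
            "n_pareto": float(len(P0.individuals)),
        }
    return out
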