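"""Genotypes, additive genetic values, trait orientation, and normalization.

The additive model used throughout the package: the genetic value of
individual ``i`` on trait ``k`` is

    v[i, k] = sum_j G[i, j] * beta[j, k]

where ``G[i, j]`` is the allele dosage at locus ``j`` (0, 1 or 2 copies of
the counted allele, the sum of the two phased haplotypes) and
``beta[j, k]`` is the additive effect of one allele copy on trait ``k``.
Dominance, epistasis and environment are assumed negligible, and the allele
effects are taken as known and constant.

Normalization maps each trait into the open unit interval using per-trait
bounds padded by a small epsilon, so that values from a chosen reference set
land strictly inside (0, 1).  The padding is *relative* — a fixed fraction
of the observed per-trait range — which makes the whole normalization
pipeline invariant under a change of measurement units (any per-trait
positive affine rescaling of the raw values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, DegenerateTraitError, NormalizationError

__all__ = [
    "GenotypeMatrix",
    "EffectMatrix",
    "GeneticValues",
    "TraitBounds",
    "TraitDirections",
    "compute_genetic_values",
    "orient_traits",
    "orient_effects",
    "compute_bounds",
    "normalize_values",
    "attainable_bounds",
]


def _as_str_list(xs) -> list[str]:
    return [str(x) for x in xs]


@dataclass
class GenotypeMatrix:
    """Phased diploid biallelic genotypes with chromosome assignment.

    ``haplotypes`` has shape (n_individuals, 2, n_loci) with allele values
    in {0, 1}.  Loci belonging to one chromosome must form a contiguous
    block, in the same order as the recombination map that will be used
    with them.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    chromosome_of_locus: np.ndarray
    haplotypes: np.ndarray

    def __post_init__(self):
        self.individual_ids = _as_str_list(self.individual_ids)
        self.locus_ids = _as_str_list(self.locus_ids)
        self.chromosome_of_locus = np.asarray(self.chromosome_of_locus, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        n, two, L = self.haplotypes.shape if self.haplotypes.ndim == 3 else (0, 0, 0)
        if self.haplotypes.ndim != 3 or two != 2:
            raise ValueError("haplotypes must have shape (n_individuals, 2, n_loci)")
        if n != len(self.individual_ids):
            raise ValueError("individual_ids length does not match haplotypes")
        if L != len(self.locus_ids) or L != self.chromosome_of_locus.size:
            raise ValueError("locus_ids / chromosome_of_locus length mismatch")
        if len(set(self.locus_ids)) != L:
            raise ValueError("duplicated locus id")
        alleles = np.unique(self.haplotypes)
        if alleles.size and not np.isin(alleles, [0, 1]).all():
            raise ValueError("allele values must be 0 or 1")
        # each chromosome label must occupy one contiguous block
        c = self.chromosome_of_locus
        if L and np.unique(c).size != 1 + int(np.count_nonzero(np.diff(c) != 0)):
            raise ValueError("loci of one chromosome must be contiguous")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def dosage(self) -> np.ndarray:
        """Allele dosage matrix, shape (n_individuals, n_loci), values 0/1/2."""
        return self.haplotypes.sum(axis=1, dtype=np.int64)

    def subset(self, indices) -> "GenotypeMatrix":
        """New matrix restricted to the given individual indices."""
        idx = list(indices)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in idx],
            self.locus_ids,
            self.chromosome_of_locus,
            self.haplotypes[idx],
        )


@dataclass
class EffectMatrix:
    """Per-locus, per-trait additive allele effects (effect units per copy)."""

    locus_ids: list[str]
    trait_ids: list[str]
    effects: np.ndarray

    def __post_init__(self):
        self.locus_ids = _as_str_list(self.locus_ids)
        self.trait_ids = _as_str_list(self.trait_ids)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.shape != (len(self.locus_ids), len(self.trait_ids)):
            raise ValueError("effects must have shape (n_loci, n_traits)")
        if not np.isfinite(self.effects).all():
            raise ValueError("effects must be finite")

    @property
    def n_traits(self) -> int:
        return len(self.trait_ids)


@dataclass
class GeneticValues:
    """Genetic values, raw or normalized, shape (n_individuals, n_traits)."""

    individual_ids: list[str]
    trait_ids: list[str]
    values: np.ndarray
    is_normalized: bool = False

    def __post_init__(self):
        self.individual_ids = _as_str_list(self.individual_ids)
        self.trait_ids = _as_str_list(self.trait_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.individual_ids), len(self.trait_ids)):
            raise ValueError("values must have shape (n_individuals, n_traits)")
        if not np.isfinite(self.values).all():
            raise ValueError("values must be finite")
        if self.is_normalized and self.values.size:
            if self.values.min() <= 0.0 or self.values.max() >= 1.0:
                raise ValueError("normalized values must lie strictly in (0, 1)")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_traits(self) -> int:
        return len(self.trait_ids)


@dataclass
class TraitBounds:
    """Per-trait lower/upper normalization bounds and the padding fraction."""

    lower: np.ndarray
    upper: np.ndarray
    epsilon_rel: float = 1e-6

    def __post_init__(self):
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape:
            raise ValueError("lower/upper shape mismatch")
        if not (self.lower < self.upper).all():
            raise ValueError("lower must be strictly below upper for every trait")
        if not self.epsilon_rel > 0:
            raise ValueError("epsilon_rel must be positive")


@dataclass
class TraitDirections:
    """Improvement direction per trait: 'maximize' or 'minimize'."""

    directions: list[str] = field(default_factory=list)

    def __post_init__(self):
        bad = [d for d in self.directions if d not in ("maximize", "minimize")]
        if bad:
            raise ValueError(f"unknown direction(s): {bad}")

    @property
    def signs(self) -> np.ndarray:
        return np.array([1.0 if d == "maximize" else -1.0 for d in self.directions])


def compute_genetic_values(G: GenotypeMatrix, B: EffectMatrix) -> GeneticValues:
    """Additive genetic values ``v = G_dosage @ beta`` for every individual/trait.

    Raises :class:`AlignmentError` if the locus sets of genotypes and
    effects differ (same ids, same order).
    """
    if G.locus_ids != B.locus_ids:
        raise AlignmentError(
            "locus sets of genotypes and effects do not align "
            f"({len(G.locus_ids)} vs {len(B.locus_ids)} loci)"
        )
    values = G.dosage.astype(float) @ B.effects
    return GeneticValues(G.individual_ids, B.trait_ids, values, is_normalized=False)


def orient_traits(V: GeneticValues, d: TraitDirections) -> GeneticValues:
    """Flip minimized traits so that every trait is to be maximized.

    A trait flagged ``minimize`` has its column negated; applying the same
    directions twice returns the original values.
    """
    if V.is_normalized:
        raise ValueError("orient_traits expects raw (non-normalized) values")
    if len(d.directions) != V.n_traits:
        raise ValueError("one direction flag per trait required")
    return GeneticValues(V.individual_ids, V.trait_ids, V.values * d.signs, False)


def orient_effects(B: EffectMatrix, d: TraitDirections) -> EffectMatrix:
    """Equivalent orientation applied at the effect level (columns negated)."""
    if len(d.directions) != B.n_traits:
        raise ValueError("one direction flag per trait required")
    return EffectMatrix(B.locus_ids, B.trait_ids, B.effects * d.signs)


def compute_bounds(
    V_ref: GeneticValues,
    epsilon_rel: float = 1e-6,
    fallback_range: float | None = None,
) -> TraitBounds:
    """Per-trait normalization bounds from a reference set of individuals.

    lower_k = min_i v[i,k] - eps_k, upper_k = max_i v[i,k] + eps_k, with
    eps_k = epsilon_rel * (max_i v[i,k] - min_i v[i,k]).  The relative
    padding keeps every reference value strictly inside the bounds and
    makes the bounds transform exactly under per-trait positive affine
    rescaling of the raw values.

    A trait whose reference values are all identical has no usable range;
    this raises :class:`DegenerateTraitError` unless ``fallback_range``
    supplies an absolute range to substitute.
    """
    if not epsilon_rel > 0:
        raise ValueError("epsilon_rel must be positive")
    vmin = V_ref.values.min(axis=0)
    vmax = V_ref.values.max(axis=0)
    rng = vmax - vmin
    degenerate = rng == 0
    if degenerate.any():
        if fallback_range is None:
            bad = [V_ref.trait_ids[k] for k in np.flatnonzero(degenerate)]
            raise DegenerateTraitError(
                f"trait(s) {bad} have zero range in the reference set"
            )
        rng = np.where(degenerate, float(fallback_range), rng)
    eps = epsilon_rel * rng
    return TraitBounds(vmin - eps, vmax + eps, epsilon_rel=epsilon_rel)


def normalize_values(V: GeneticValues, bounds: TraitBounds) -> GeneticValues:
    """Map values into (0, 1) per trait: ``(v - lower) / (upper - lower)``.

    Every value must lie strictly between its trait's bounds (guaranteed by
    construction for members of the reference set that produced the
    bounds).  A value outside raises :class:`NormalizationError` naming the
    individual and trait — silent clamping would corrupt the max-min
    objective downstream.
    """
    if V.is_normalized:
        raise ValueError("values are already normalized")
    if bounds.lower.size != V.n_traits:
        raise ValueError("bounds trait dimension mismatch")
    lo, hi = bounds.lower, bounds.upper
    outside = (V.values <= lo) | (V.values >= hi)
    if outside.any():
        i, k = map(int, np.argwhere(outside)[0])
        raise NormalizationError(
            f"value {V.values[i, k]:g} of individual {V.individual_ids[i]!r} "
            f"on trait {V.trait_ids[k]!r} lies outside the reference bounds "
            f"({lo[k]:g}, {hi[k]:g})"
        )
    out = (V.values - lo) / (hi - lo)
    return GeneticValues(V.individual_ids, V.trait_ids, out, is_normalized=True)


def attainable_bounds(B: EffectMatrix, epsilon_rel: float = 1e-6) -> TraitBounds:
    """Bounds covering every genotype representable under the effect matrix.

    The extreme additive values are reached by the genotypes carrying two
    copies of every beneficial (resp. deleterious) allele:
    lower_k = 2 * sum_j min(beta[j,k], 0), upper_k = 2 * sum_j max(beta[j,k], 0),
    padded relative to that span.  Useful as frozen normalization bounds
    that no progeny can ever transgress.
    """
    lo = 2.0 * np.minimum(B.effects, 0.0).sum(axis=0)
    hi = 2.0 * np.maximum(B.effects, 0.0).sum(axis=0)
    rng = hi - lo
    if (rng == 0).any():
        bad = [B.trait_ids[k] for k in np.flatnonzero(rng == 0)]
        raise DegenerateTraitError(f"trait(s) {bad} have all-zero effects")
    eps = epsilon_rel * rng
    return TraitBounds(lo - eps, hi + eps, epsilon_rel=epsilon_rel)
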