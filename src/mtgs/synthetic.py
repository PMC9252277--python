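"""Synthetic founders, pleiotropic effects and recombination maps.

The generators emulate the structure of a maize inbred-line panel: fully
homozygous diploid founders, a few hundred biallelic SNP loci spread
contiguously over ten linkage groups, and two quantitative traits with
pleiotropic additive effects whose genetic correlation can be targeted.
The default scale — 200 founders, 10 chromosomes x 100 loci, 2 traits
with a founder genetic-value correlation near 0.375 — matches the study
conditions the package is built to reproduce at desk scale.

Distributional choices (documented, minimal, configurable):

* allele frequency per locus ~ Beta(2, 2);
* within-chromosome recombination frequencies ~ Normal(mean, sd)
  truncated to [0, 0.5] (a zero sd gives a constant map);
* additive effects per locus ~ bivariate Gaussian with correlation rho
  (general K takes a full correlation matrix).

Because founders carry sampling LD, the correlation realized between the
founder genetic-value columns differs slightly from the effect-level
rho; the maize-like preset tunes rho by bisection until the *value*
correlation hits the target, and reports both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .breeding import RecombinationMap
from .core import EffectMatrix, GeneticValues, GenotypeMatrix, compute_genetic_values

__all__ = [
    "SyntheticSpec",
    "simulate_founders",
    "simulate_effects",
    "simulate_recomb_map",
    "realized_value_correlation",
    "maize_like",
    "example1_fixture",
    "Example1",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic genome, panel and genetic architecture."""

    n_founders: int = 200
    n_chromosomes: int = 10
    loci_per_chromosome: int = 100
    allele_freq_alpha: float = 2.0
    allele_freq_beta: float = 2.0
    recomb_mean: float = 0.015
    recomb_sd: float = 0.01
    n_traits: int = 2
    rho: float = 0.375
    effect_scale: float = 0.05
    effect_corr: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self):
        if min(self.n_founders, self.n_chromosomes, self.loci_per_chromosome,
               self.n_traits) < 1:
            raise ValueError("counts must be positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")

    @property
    def n_loci(self) -> int:
        return self.n_chromosomes * self.loci_per_chromosome

    def locus_ids(self) -> list[str]:
        return [f"L{j:04d}" for j in range(self.n_loci)]

    def chromosomes(self) -> np.ndarray:
        return np.repeat(np.arange(1, self.n_chromosomes + 1),
                         self.loci_per_chromosome)


def simulate_founders(spec: SyntheticSpec, rng) -> GenotypeMatrix:
    """Fully homozygous founders (inbred lines).

    Per locus, an allele frequency is drawn from Beta(alpha, beta); each
    founder then carries allele 1 at that locus (on both haplotypes) with
    that frequency.  Loci are assigned contiguously to chromosomes.
    """
    freqs = rng.beta(spec.allele_freq_alpha, spec.allele_freq_beta, size=spec.n_loci)
    hap = (rng.random((spec.n_founders, spec.n_loci)) < freqs).astype(np.int8)
    haps = np.stack([hap, hap], axis=1)  # homozygous: identical haplotypes
    ids = [f"f{i:03d}" for i in range(spec.n_founders)]
    return GenotypeMatrix(ids, spec.locus_ids(), spec.chromosomes(), haps)


def _corr_matrix(spec: SyntheticSpec) -> np.ndarray:
    if spec.effect_corr is not None:
        C = np.asarray(spec.effect_corr, dtype=float)
        if C.shape != (spec.n_traits, spec.n_traits):
            raise ValueError("effect_corr must be (n_traits, n_traits)")
        return C
    if spec.n_traits == 2:
        return np.array([[1.0, spec.rho], [spec.rho, 1.0]])
    if spec.n_traits == 1:
        return np.ones((1, 1))
    raise ValueError("for n_traits > 2 supply a full effect_corr matrix")


def simulate_effects(spec: SyntheticSpec, rng) -> EffectMatrix:
    """Zero-mean Gaussian pleiotropic effects with the requested
    between-trait correlation (Cholesky of the correlation matrix)."""
    C = _corr_matrix(spec)
    try:
        chol = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("requested correlation matrix is not positive definite") from exc
    Z = rng.standard_normal((spec.n_loci, spec.n_traits))
    eff = spec.effect_scale * (Z @ chol.T)
    traits = [f"trait{k + 1}" for k in range(spec.n_traits)]
    return EffectMatrix(spec.locus_ids(), traits, eff)


def simulate_recomb_map(spec: SyntheticSpec, rng) -> RecombinationMap:
    """Within-chromosome interval r ~ Normal(mean, sd) truncated to
    [0, 0.5]; chromosome-boundary intervals fixed at 0.5."""
    L = spec.n_loci
    chrom = spec.chromosomes()
    if spec.recomb_sd > 0:
        r = rng.normal(spec.recomb_mean, spec.recomb_sd, size=max(L - 1, 0))
    else:
        r = np.full(max(L - 1, 0), spec.recomb_mean)
    r = np.clip(r, 0.0, 0.5)
    boundary = chrom[1:] != chrom[:-1]
    r[boundary] = 0.5
    return RecombinationMap(spec.locus_ids(), r, chrom)


def realized_value_correlation(G: GenotypeMatrix, B: EffectMatrix) -> np.ndarray:
    """Correlation matrix of the founder genetic-value columns."""
    V = compute_genetic_values(G, B)
    return np.corrcoef(V.values, rowvar=False)


def maize_like(
    seed: int | None = None,
    target_value_corr: float = 0.375,
    spec: SyntheticSpec | None = None,
    tol: float = 0.005,
    max_iter: int = 40,
):
    """Maize-panel preset: founders + map + effects with the founder
    genetic-value correlation tuned to the target.

    A single pair of standard-normal effect columns is drawn once; the
    candidate correlation rho mixes them (``b2 = rho*z1 + sqrt(1-rho^2)*z2``)
    so the realized value correlation is continuous and monotone in rho,
    and a bisection on rho in (-0.95, 0.95) matches the target.  Returns
    ``(founders, effects, rmap, info)`` where ``info`` records the tuned
    rho and both realized correlations.
    """
    spec = spec or SyntheticSpec()
    if spec.n_traits != 2:
        raise ValueError("the maize-like preset targets exactly 2 traits")
    rng = np.random.default_rng(seed)
    founders = simulate_founders(spec, rng)
    rmap = simulate_recomb_map(spec, rng)
    z1 = rng.standard_normal(spec.n_loci)
    z2 = rng.standard_normal(spec.n_loci)
    dosage = founders.dosage.astype(float)
    traits = ["trait1", "trait2"]

    def value_corr(rho: float) -> float:
        b2 = rho * z1 + np.sqrt(1 - rho**2) * z2
        V = dosage @ (spec.effect_scale * np.column_stack([z1, b2]))
        return float(np.corrcoef(V, rowvar=False)[0, 1])

    lo, hi = -0.95, 0.95
    c_lo, c_hi = value_corr(lo), value_corr(hi)
    if not c_lo <= target_value_corr <= c_hi:
        raise ValueError("target correlation not bracketed by rho in (-0.95, 0.95)")
    rho = 0.0
    for _ in range(max_iter):
        rho = 0.5 * (lo + hi)
        c = value_corr(rho)
        if abs(c - target_value_corr) < tol:
            break
        if c < target_value_corr:
            lo = rho
        else:
            hi = rho
    b2 = rho * z1 + np.sqrt(1 - rho**2) * z2
    effects = EffectMatrix(
        spec.locus_ids(), traits,
        spec.effect_scale * np.column_stack([z1, b2]),
    )
    info = {
        "rho_effects_used": float(rho),
        "realized_effect_corr": float(np.corrcoef(effects.effects, rowvar=False)[0, 1]),
        "realized_value_corr": float(realized_value_correlation(founders, effects)[0, 1]),
        "target_value_corr": float(target_value_corr),
    }
    return founders, effects, rmap, info


# ---------------------------------------------------------------------------
# the printed worked example
# ---------------------------------------------------------------------------


@dataclass
class Example1:
    """The 4-individual, 2-trait worked example and its expected outputs."""

    values: GeneticValues
    cross_names: list[str]
    cross_pairs: list[tuple[str, str]]
    cross_sums: np.ndarray
    supported_names: list[str] = field(default_factory=lambda: ["c1", "c5", "c6"])
    pareto_names: list[str] = field(
        default_factory=lambda: ["c1", "c2", "c3", "c4", "c5", "c6"]
    )


def example1_fixture() -> Example1:
    """Four candidate individuals, six possible crosses.

    The individual trait values already lie inside (0, 1) and are used
    directly as normalized values.  The six pairwise trait sums are all
    Pareto optimal, but only c1, c5, c6 sit on the convex (supported)
    frontier that weighted-sum selection can reach.
    """
    vals = np.array([
        [0.05, 0.33],
        [0.22, 0.22],
        [0.30, 0.15],
        [0.44, 0.06],
    ])
    V = GeneticValues(["i1", "i2", "i3", "i4"], ["v1", "v2"], vals)
    pairs = [("i1", "i2"), ("i1", "i3"), ("i1", "i4"),
             ("i2", "i3"), ("i2", "i4"), ("i3", "i4")]
    names = [f"c{j}" for j in range(1, 7)]
    idx = {f"i{j + 1}": j for j in range(4)}
    sums = np.array([vals[idx[a]] + vals[idx[b]] for a, b in pairs])
    return Example1(V, names, pairs, sums)
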