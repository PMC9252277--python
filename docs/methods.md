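# Methods

## Model and assumptions

Genetic values are purely additive: `v_ik = Σ_j G_ij β_jk` with dosage
`G_ij ∈ {0,1,2}` summed over two phased haplotypes. Dominance, epistasis,
genotype-by-environment interaction and phenotyping noise are out of
scope; allele effects are treated as known and constant over the breeding
horizon. Traits to be minimized are handled by negating their values (or,
equivalently, their effect columns) so that every model below maximizes.

Parent selection of `S` from `n` candidates is treated as an exact
combinatorial problem throughout. Index selection maximizes
`Σ_k w_k Σ_i x_i v_ik`; because the objective is separable per individual
it reduces to truncation on the score `Σ_k w_k v_ik`. L-shaped selection
maximizes `min_k (Σ_i x_i ṽ_ik / w_k)` over normalized values. Weights are
strictly positive in both models; scaling all weights by a common constant
changes neither selection.

## Normalization

`ṽ_ik = (v_ik − lower_k) / (upper_k − lower_k)` with
`lower_k = min_i v_ik − ε_k` and `upper_k = max_i v_ik + ε_k` over a
reference population. The padding is *relative*:
`ε_k = epsilon_rel × (max_i v_ik − min_i v_ik)`, default
`epsilon_rel = 1e-6`. An absolute ε would break exact invariance under
per-trait affine unit changes; the relative form preserves it, which is
the point of normalizing in the first place, while keeping every reference
value strictly inside (0, 1). Values outside the bounds raise an error
naming the individual and trait — clamping would silently corrupt the
max-min objective. Constant (zero-range) traits are an error unless an
absolute fallback range is configured.

During a breeding run the reference set must contain every individual that
will be compared, but future progeny are unknown when selection happens.
Three policies are provided:

* **incremental** (default) — running per-trait min/max over all
  individuals seen so far in the run, re-padded each generation. Every
  individual ever normalized is inside the reference set, so transgressive
  progeny (the expected outcome of selection) never fault.
* **founders** — bounds frozen from generation 0; faithful to a fixed
  reference set but raises as soon as progeny transgress the founder range.
* **attainable** — genotype-support bounds
  `[2 Σ_j min(β_jk, 0), 2 Σ_j max(β_jk, 0)]`, frozen and valid for any
  conceivable genotype; the safest choice when runs must share one scale.

When pooled populations from several runs are scored jointly, bounds are
recomputed over the pooled union so all methods are normalized on the same
scale.

## Solvers, ties and degenerate inputs

Both L-shaped backends are exact. Enumeration covers all `C(n, S)`
subsets when that count is at most 10^6 (the standard two-parent case with
a few hundred candidates is ~2×10^4); larger instances go to an exact
mixed-integer formulation (maximize z subject to
`z ≤ Σ_i x_i ṽ_ik / w_k` for all k, `Σ x_i = S`, x binary) solved by
HiGHS branch-and-cut through scipy. Forcing enumeration above the cap is a
capacity error — there is no heuristic fallback. Objective comparisons use
a relative tolerance of 1e-9 to absorb floating-point summation noise.

A max-min optimum can be weakly dominated, so ties are broken by the
largest total normalized sum (guaranteeing the returned subset is itself
Pareto optimal) and then by the lexicographically smallest index set for
reproducibility. Index-selection score ties break lexicographically by
individual identifier.

The supported frontier is computed for two traits by the upper-right
convex hull with exact vertex tests (collinear points — weakly supported,
reachable only as ties — are excluded by default and available behind a
flag), and for more traits by a small linear program per candidate that
searches for strictly positive weights making the point a strict
maximizer. The two paths are cross-checked against each other and against
a dense weight sweep in the test suite.

For two traits the max-min optimality regions over `w1 ∈ (0,1)`,
`w2 = 1 − w1` follow from a monotonicity argument: walking along the
Pareto front (trait-1 sum increasing, trait-2 sum decreasing), the
objective `min(p_1/w_1, p_2/w_2)` is unimodal, so only adjacent Pareto
points can tie, and the tie sits where one L-corner touches both points:
`w1/w2 = p_1/q_2` for the adjacent pair (p, q). This yields one nonempty
interval per Pareto point, with each point's own trait-sum weights lying
strictly inside its interval.

## Performance metrics

The Pareto optimality gap of `P0` against `P1` is the literal triple-min
formula `Σ_{i∈P0} min_{i'∈P1} min_k w_ik (v_i'k − v_ik)+`. Two
consequences of reading it literally: an individual tied on even one trait
contributes 0 (an arbitrarily small improvement breaks the dominance), and
a term is positive only when *every* member of P1 strictly dominates the
individual — which is why both inputs are expected to be Pareto subsets
(the package reduces with `pareto_subset`, which also deduplicates
identical trait vectors). The gap is reported as the raw sum, with the
per-individual mean logged alongside. Gap weights are *provenance*
weights: each pooled individual carries the weight vector of the breeding
run that produced it, so a run emphasising one trait is judged by its own
priorities; external point sets without provenance fall back to uniform
weights with a warning.

Diversity defaults to the literal form
`Σ_k w_k/|P0| Σ_i Σ_i' (v_ik − v_i'k)²` (all ordered pairs, no square
root); `mean` (divisor |P0|²) and `rms` (root of the per-pair mean)
variants are available behind a flag since the plain-language reading
("average Euclidean distance") and the printed formula disagree.

## Breeding simulator

Meiosis is the standard no-interference model: per chromosome a uniform
starting haplotype, then independent Bernoulli(r) phase switches between
adjacent loci; chromosome boundaries are encoded as r = 0.5 intervals,
which makes chromosomes assort independently. Each generation computes
true genetic values, selects S parents exactly (L-shaped on normalized
values; index on raw values by default, normalized behind a flag), and
produces N progeny from one biparental cross. With S = 2 the two selected
parents make the single cross (the distinct-index constraint of the
selection model rules out selfing); for S > 2 each progeny draws two
distinct parents uniformly from the selected set. Candidates are always
the current generation only.

The weight-grid experiment runs every method × weight × repetition with
run seeds derived deterministically as
`(master_seed, method_index, weight_index, repetition)` fed to numpy's
seed-sequence machinery — independent streams, bit-reproducible whole
experiments. Final-generation individuals are pooled per method, tagged
with their run's weights.

## Synthetic data

The generators emulate an inbred maize panel: fully homozygous founders
with per-locus allele frequencies drawn from Beta(2, 2); within-chromosome
recombination frequencies from Normal(0.015, 0.01) truncated to [0, 0.5]
(about 1.5 cM between adjacent markers — a dense-map scale chosen so that
a 100-locus chromosome spans roughly 1.5 Morgans); and zero-mean Gaussian
pleiotropic effects with a requested between-column correlation. Default
scale: 200 founders, 10 chromosomes × 100 loci, 2 traits.

Sampling linkage disequilibrium among founders makes the realized
correlation of genetic-value columns differ from the effect-level one, so
the maize-like preset tunes the effect correlation by bisection until the
founder *value* correlation reaches the target (default 0.375), and
reports both (e.g. at seed 0 the preset uses an effect-level mix of 0.46
to realize a value correlation of 0.3735). What the generator does not
emulate: realistic LD blocks, allele-frequency spectra from real
demography, map heterogeneity, or non-additive architecture — so passing
simulation tests demonstrates correctness of the machinery under the
additive model, not performance on any real panel.

## Scaled experiment in the test suite

The full-scale comparison protocol (hundreds of founders, 9 weight sets ×
10 repetitions × 5 generations per method) is supported by the same code
paths, but the suite exercises a desk-scale version: 50 founders, 200 loci
on 4 chromosomes, 3 generations, 50 progeny, weight grid
{0.2, 0.5, 0.8} × 3 repetitions per method, replicated 10 times with
replication index as the seed. The directional expectation — L-shaped
pooled progeny score a gap no larger than, and diversity no smaller than,
index-selection progeny against their union — is asserted in at least 8 of
10 replications; at this scale both methods' literal gaps are usually
exactly 0 (unanimous strict dominance of a Pareto point is rare in small
pools), so the gap comparison typically holds with equality while the
diversity comparison does the discriminating.

## Known limitations

* The exact MILP path inherits HiGHS's default integrality tolerances;
  tie-breaking among multiple max-min optima is only guaranteed on the
  enumeration path.
* The incremental bounds policy makes normalized values comparable within
  a run but not across runs; cross-run comparisons should renormalize on
  the pooled union (as `evaluate_experiment` does) or use attainable
  bounds.
* Weight-region decomposition is implemented for two traits only; for
  more traits the constructive-weights route individually certifies any
  Pareto point.
* No estimation: allele effects and recombination frequencies are inputs,
  never inferred.
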