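"""Performance measures for multitrait selection experiments.

Two set-level measures over final-generation populations:

* **Pareto optimality gap** of a set ``P0`` against a reference set
  ``P1`` (normally the Pareto subset of the pooled progeny of all
  competing methods):

      sum_{i in P0}  min_{i' in P1}  min_k  w[i,k] * max(v[i',k] - v[i,k], 0)

  — the minimal weighted trait improvement needed in each member of P0 to
  break every dominance by P1, summed over P0.  Zero means nothing in P0
  is (strictly, in every trait) dominated.  The weight ``w[i,k]`` is the
  weight vector of the breeding run that *produced* individual ``i``
  (its provenance), so a run emphasising trait 1 is judged by its own
  priorities.

* **Diversity** of ``P0``:

      sum_k  w_k / |P0|  *  sum_{i in P0} sum_{i' in P0} (v[i,k] - v[i',k])^2

  — a weighted spread of the Pareto subset across trait space.  This is
  the literal formula (all ordered pairs, divisor |P0|, no square root);
  ``variant`` exposes a mean (divisor |P0|^2) and an RMS form.

Larger diversity and smaller gap are better: the method offers more
trade-off options without being dominated by its competitor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .selection import _as_weights, supported_front

__all__ = [
    "EvaluatedIndividual",
    "EvaluationSet",
    "pareto_subset",
    "pareto_optimality_gap",
    "gap_terms",
    "diversity",
]

log = logging.getLogger(__name__)


@dataclass
class EvaluatedIndividual:
    """A trait vector plus the weight vector of the run that produced it."""

    trait_values: np.ndarray
    provenance_weights: np.ndarray | None = None
    id: str | None = None

    def __post_init__(self):
        self.trait_values = np.atleast_1d(np.asarray(self.trait_values, dtype=float))
        if self.provenance_weights is not None:
            w = np.atleast_1d(np.asarray(self.provenance_weights, dtype=float))
            if w.shape != self.trait_values.shape:
                raise ValueError("provenance weights must match trait dimension")
            if not (w > 0).all():
                raise ValueError("provenance weights must be strictly positive")
            self.provenance_weights = w


@dataclass
class EvaluationSet:
    """A labelled collection of evaluated individuals (e.g. one method's pool)."""

    individuals: list[EvaluatedIndividual]
    label: str = ""

    def __post_init__(self):
        if not self.individuals:
            raise ValueError("evaluation set must be nonempty")
        K = self.individuals[0].trait_values.size
        if any(ind.trait_values.size != K for ind in self.individuals):
            raise ValueError("inconsistent trait dimension inside evaluation set")

    @property
    def n_traits(self) -> int:
        return self.individuals[0].trait_values.size

    @property
    def values(self) -> np.ndarray:
        return np.vstack([ind.trait_values for ind in self.individuals])

    def weights_matrix(self) -> np.ndarray:
        """Provenance weights row per individual; uniform rows substituted
        (with a warning) where provenance is missing."""
        K = self.n_traits
        rows = []
        missing = 0
        for ind in self.individuals:
            if ind.provenance_weights is None:
                rows.append(np.full(K, 1.0 / K))
                missing += 1
            else:
                rows.append(ind.provenance_weights)
        if missing:
            log.warning(
                "%d/%d individuals in %r lack provenance weights; "
                "substituting uniform weights",
                missing, len(self.individuals), self.label or "evaluation set",
            )
        return np.vstack(rows)

    @classmethod
    def from_arrays(cls, values, weights=None, label: str = "", ids=None) -> "EvaluationSet":
        values = np.atleast_2d(np.asarray(values, dtype=float))
        inds = []
        for i in range(values.shape[0]):
            w = None if weights is None else np.asarray(weights, dtype=float)[i]
            iid = None if ids is None else str(ids[i])
            inds.append(EvaluatedIndividual(values[i], w, iid))
        return cls(inds, label=label)


def pareto_subset(S: EvaluationSet, include_weak: bool = False) -> EvaluationSet:
    """Members attaining the maximum of some strictly-positive-weighted sum.

    Delegates to :func:`mtgs.selection.supported_front`; duplicate trait
    vectors are collapsed keeping the first occurrence, so metrics are not
    inflated by genetically identical progeny.
    """
    front = supported_front(S.values, include_weak=include_weak)
    seen: set[tuple] = set()
    chosen = []
    for i in front.indices:
        key = tuple(S.individuals[i].trait_values)
        if key not in seen:
            seen.add(key)
            chosen.append(S.individuals[i])
    return EvaluationSet(chosen, label=f"P({S.label})" if S.label else "P")


def gap_terms(P0: EvaluationSet, P1: EvaluationSet) -> np.ndarray:
    """Per-individual gap contributions of P0 against P1 (see module docs)."""
    if P0.n_traits != P1.n_traits:
        raise ValueError("trait dimension mismatch between the two sets")
    v0, v1 = P0.values, P1.values
    w0 = P0.weights_matrix()
    diff = np.clip(v1[None, :, :] - v0[:, None, :], 0.0, None)  # (n0, n1, K)
    weighted = w0[:, None, :] * diff
    per_pair = weighted.min(axis=2)  # smallest weighted trait gap per (i, i')
    return per_pair.min(axis=1)  # least-dominating i' per i


def pareto_optimality_gap(
    P0: EvaluationSet, P1: EvaluationSet, reduction: str = "sum"
) -> float:
    """Pareto optimality gap of P0 against P1.

    ``reduction="sum"`` is the defining formula; ``"mean"`` divides by
    |P0| (the per-individual average dominance depth).
    """
    terms = gap_terms(P0, P1)
    if reduction == "sum":
        return float(terms.sum())
    if reduction == "mean":
        return float(terms.mean())
    raise ValueError(f"unknown reduction {reduction!r}")


def diversity(P0: EvaluationSet, w, variant: str = "literal") -> float:
    """Weighted trait-space spread of a Pareto subset.

    variant:
      * ``"literal"`` — sum_k w_k/|P0| * sum_{i,i'} (v_ik - v_i'k)^2
      * ``"mean"``    — divisor |P0|^2 instead of |P0|
      * ``"rms"``     — sum_k w_k * sqrt(mean over unordered pairs of squared
        difference), a true average Euclidean-style distance
    """
    wv = _as_weights(w)
    v = P0.values
    n, K = v.shape
    if wv.size != K:
        raise ValueError("weight dimension does not match trait dimension")
    if n < 2:
        return 0.0
    # sum_{i,i'} (v_ik - v_i'k)^2 = 2n * sum v^2 - 2 (sum v)^2, per trait
    ss = (v**2).sum(axis=0)
    s = v.sum(axis=0)
    pair_sq = 2.0 * n * ss - 2.0 * s**2
    if variant == "literal":
        return float((wv * pair_sq / n).sum())
    if variant == "mean":
        return float((wv * pair_sq / n**2).sum())
    if variant == "rms":
        n_unordered = n * (n - 1)
        return float((wv * np.sqrt(pair_sq / n_unordered)).sum())
    raise ValueError(f"unknown variant {variant!r}")
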