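"""Collapsing functions: indicator, sum and weighted sum.

A collapsing function maps the genotypes of a *member set* of variants to one
per-individual burden score:

* indicator — 1 if the individual carries any minor allele among the members
  (CAST-style presence/absence),
* sum — total minor-allele count across the members (proportion coding),
* weighted sum — counts divided by per-variant weights
  ``w_j = sqrt(n q_j (1 - q_j))`` with the pseudocount frequency estimate
  ``q_j = (1 + sum_i r_ij) / (2 + 2n)`` taken over all subjects, so rarer
  alleles contribute more per copy.

Scores are pure functions of (genotypes, member set, method): composition in
the forward-selection algorithm always re-collapses from scratch over the
whole member set, never incrementally on a previous score vector.  Weights
depend only on genotypes, never on the phenotype — this keeps them fixed
under phenotype permutation.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Literal, Sequence

import numpy as np

from .data_io import GenotypeMatrix

__all__ = [
    "CollapseMethod",
    "METHODS",
    "WeightVector",
    "CollapsedScore",
    "collapse_indicator",
    "collapse_sum",
    "compute_weights",
    "collapse_weighted_sum",
    "collapse",
]

CollapseMethod = Literal["indicator", "sum", "weighted_sum"]
METHODS: tuple[CollapseMethod, ...] = ("indicator", "sum", "weighted_sum")


@dataclasses.dataclass
class WeightVector:
    """Per-variant weights and the frequency estimates behind them."""

    variant_indices: np.ndarray
    qhat: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.variant_indices = np.asarray(self.variant_indices, dtype=np.intp)
        self.qhat = np.asarray(self.qhat, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (self.weights > 0).all():
            raise ValueError("weights must be strictly positive")

    def for_members(self, members: np.ndarray) -> np.ndarray:
        """Weights aligned to ``members``; raises if any member lacks a weight."""
        pos = {int(v): i for i, v in enumerate(self.variant_indices)}
        try:
            idx = [pos[int(m)] for m in members]
        except KeyError as exc:
            raise KeyError(f"no weight for variant column {exc.args[0]}") from exc
        return self.weights[idx]


@dataclasses.dataclass
class CollapsedScore:
    method: CollapseMethod
    members: np.ndarray
    scores: np.ndarray


def _member_array(members: Iterable[int] | np.ndarray) -> np.ndarray:
    arr = np.asarray(list(members) if not isinstance(members, np.ndarray) else members,
                     dtype=np.intp)
    if arr.size == 0:
        raise ValueError("member set must be non-empty")
    return arr


def collapse_indicator(gm: GenotypeMatrix, members: Sequence[int]) -> CollapsedScore:
    """Presence/absence of any minor allele among the member variants."""
    m = _member_array(members)
    scores = (gm.counts[:, m].sum(axis=1) > 0).astype(float)
    return CollapsedScore(method="indicator", members=m, scores=scores)


def collapse_sum(gm: GenotypeMatrix, members: Sequence[int]) -> CollapsedScore:
    """Total minor-allele count across the member variants."""
    m = _member_array(members)
    scores = gm.counts[:, m].sum(axis=1).astype(float)
    return CollapsedScore(method="sum", members=m, scores=scores)


def compute_weights(gm: GenotypeMatrix, members: Sequence[int]) -> WeightVector:
    """Allele-frequency weights w_j = sqrt(n q_j (1-q_j)) over all subjects.

    The +1/+2 pseudocounts keep q strictly inside (0, 1) so even an unobserved
    allele gets a positive weight.  Frequencies use every individual: with a
    quantitative trait there is no "unaffected" subgroup to estimate from.
    """
    m = _member_array(members)
    n = gm.n_samples
    if n < 2:
        raise ValueError("need at least two individuals to estimate weights")
    totals = gm.counts[:, m].sum(axis=0)
    qhat = (1.0 + totals) / (2.0 + 2.0 * n)
    weights = np.sqrt(n * qhat * (1.0 - qhat))
    return WeightVector(variant_indices=m, qhat=qhat, weights=weights)


def collapse_weighted_sum(
    gm: GenotypeMatrix, members: Sequence[int], weights: WeightVector
) -> CollapsedScore:
    """Weighted minor-allele count: score_i = sum_j r_ij / w_j."""
    m = _member_array(members)
    w = weights.for_members(m)
    scores = (gm.counts[:, m] / w[None, :]).sum(axis=1)
    return CollapsedScore(method="weighted_sum", members=m, scores=scores)


def collapse(
    gm: GenotypeMatrix,
    members: Sequence[int],
    method: CollapseMethod,
    weights: WeightVector | None = None,
) -> CollapsedScore:
    """Dispatch to the named collapsing function."""
    if method == "indicator":
        return collapse_indicator(gm, members)
    if method == "sum":
        return collapse_sum(gm, members)
    if method == "weighted_sum":
        if weights is None:
            weights = compute_weights(gm, members)
        return collapse_weighted_sum(gm, members, weights)
    raise ValueError(f"unknown collapse method {method!r}")
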