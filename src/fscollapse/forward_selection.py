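"""Data-adaptive forward selection of rare variants around a common base SNP.

The algorithm, per gene:

1. Regress the adjusted trait on each common variant's raw minor-allele
   counts; the variant with the largest regression F statistic becomes the
   *base* of the collapsed set.
2. For each remaining rare variant g, collapse {base} ∪ selected ∪ {g} with
   the chosen collapsing function and refit; keep the candidate with the
   largest F_new.
3. Accept the candidate iff F_new > F (strictly); repeat until no candidate
   improves F or no rare variants remain.

The gene's statistic FS is the absolute t statistic of the final one-predictor
regression (so FS² equals the final F).  Because greedy selection inflates F,
FS is never referred to an analytic null — see :mod:`fscollapse.permutation`.

This module is the readable reference path, used for single analyses and as
the ground truth the batched engine (:mod:`fscollapse._engine`) is tested
against.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .collapsing import CollapseMethod, WeightVector, collapse, compute_weights
from .data_io import GeneRegion, GenotypeMatrix

__all__ = [
    "RegressionResult",
    "ForwardSelectionResult",
    "DegeneratePredictorError",
    "simple_linreg",
    "select_base",
    "extend_one",
    "run_forward_selection",
]

_VAR_TOL = 1e-12

# Relative margin for "F strictly improved".  An analytic tie (e.g. a rare
# variant whose column is collinear with the current score) must stop the
# loop; comparing at machine precision would let floating-point reassociation
# decide it.  Genuine improvements are many orders of magnitude larger.
F_IMPROVEMENT_RTOL = 1e-9


class DegeneratePredictorError(ValueError):
    """The predictor has (numerically) zero variance; the fit is undefined."""


@dataclasses.dataclass
class RegressionResult:
    """Simple linear regression y = b0 + b1 s + e with 1 and N-2 df."""

    slope: float
    intercept: float
    t_stat: float
    F_stat: float
    p_value: float
    df_resid: int
    perfect_fit: bool = False


@dataclasses.dataclass
class ForwardSelectionResult:
    gene_id: str
    method: CollapseMethod
    base_variant: int
    selected_rares: list[int]
    f_trace: list[float]
    fs_stat: float
    final_scores: np.ndarray

    @property
    def members(self) -> np.ndarray:
        return np.asarray([self.base_variant, *self.selected_rares], dtype=np.intp)


def simple_linreg(y: np.ndarray, s: np.ndarray) -> RegressionResult:
    """Closed-form OLS of y on a single score vector.

    F = MSR/MSE on (1, N-2) df; t = slope / se(slope); F = t² exactly.  A
    perfect fit (MSE = 0) is returned flagged with infinite F rather than
    raised, since downstream code only compares F values.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    n = y.size
    if s.size != n or n < 3:
        raise ValueError("need equal-length y and s with at least 3 observations")
    sbar = s.mean()
    ybar = y.mean()
    sxx = float(((s - sbar) ** 2).sum())
    if sxx <= _VAR_TOL * n:
        raise DegeneratePredictorError("degenerate predictor (zero variance score)")
    sxy = float(((s - sbar) * (y - ybar)).sum())
    syy = float(((y - ybar) ** 2).sum())
    slope = sxy / sxx
    intercept = ybar - slope * sbar
    ssr = slope * sxy
    sse = max(syy - ssr, 0.0)
    df = n - 2
    if sse <= max(syy, 1.0) * 1e-14:
        return RegressionResult(
            slope=slope, intercept=intercept, t_stat=np.inf * np.sign(slope or 1.0),
            F_stat=np.inf, p_value=0.0, df_resid=df, perfect_fit=True,
        )
    mse = sse / df
    F = ssr / mse
    t = slope / np.sqrt(mse / sxx)
    p = 2.0 * stats.t.sf(abs(t), df)
    return RegressionResult(
        slope=slope, intercept=intercept, t_stat=t, F_stat=F, p_value=p, df_resid=df
    )


def select_base(
    y: np.ndarray, gene: GeneRegion, gm: GenotypeMatrix
) -> tuple[int, float]:
    """Pick the common variant with the largest F on its raw counts.

    Ties break to the lowest variant index; variants with zero genotype
    variance are skipped.
    """
    best: tuple[int, float] | None = None
    for j in gene.common_variants:
        try:
            res = simple_linreg(y, gm.counts[:, j])
        except DegeneratePredictorError:
            continue
        if best is None or res.F_stat > best[1]:
            best = (int(j), res.F_stat)
    if best is None:
        raise DegeneratePredictorError(
            f"gene {gene.gene_id}: no common variant with nonzero genotype variance"
        )
    return best


def extend_one(
    y: np.ndarray,
    gm: GenotypeMatrix,
    method: CollapseMethod,
    current_members: np.ndarray,
    remaining_rares: np.ndarray,
    weights: WeightVector | None = None,
) -> tuple[int, float] | None:
    """Best single-rare extension of the current member set, or None.

    Evaluates F for every candidate's re-collapsed score; candidates whose
    score is (numerically) constant are skipped.  Returns (variant, F_new)
    with ties broken to the lowest variant index, or None when every
    candidate is degenerate.
    """
    if len(remaining_rares) == 0:
        raise ValueError("no remaining rare candidates")
    best: tuple[int, float] | None = None
    for g in remaining_rares:
        members = np.append(current_members, g)
        score = collapse(gm, members, method, weights)
        try:
            res = simple_linreg(y, score.scores)
        except DegeneratePredictorError:
            continue
        if best is None or res.F_stat > best[1]:
            best = (int(g), res.F_stat)
    return best


def run_forward_selection(
    y: np.ndarray,
    gm: GenotypeMatrix,
    gene: GeneRegion,
    method: CollapseMethod,
    weights: WeightVector | None = None,
) -> ForwardSelectionResult:
    """Full greedy selection for one gene; returns the FS statistic and trace.

    ``weights`` (weighted_sum only) default to frequency weights computed once
    over all of the gene's variants from the full sample; they stay frozen
    during selection so scores remain pure functions of the genotypes.
    """
    if method == "weighted_sum" and weights is None:
        weights = compute_weights(gm, gene.all_variants)

    base, F = select_base(y, gene, gm)
    f_trace = [F]
    selected: list[int] = []
    remaining = [int(g) for g in gene.rare_variants]

    while remaining:
        step = extend_one(
            y, gm, method, np.asarray([base, *selected], dtype=np.intp),
            np.asarray(remaining, dtype=np.intp), weights,
        )
        if step is None:
            break
        g, F_new = step
        if not F_new > F * (1.0 + F_IMPROVEMENT_RTOL):
            break
        selected.append(g)
        remaining.remove(g)
        F = F_new
        f_trace.append(F)

    members = np.asarray([base, *selected], dtype=np.intp)
    if selected:
        final = collapse(gm, members, method, weights).scores
    else:
        # member set of size 1: the statistic is that of the base regression
        # on raw counts (collapsing first applies once a rare is accreted)
        final = gm.counts[:, base].astype(float)
    res = simple_linreg(y, final)
    return ForwardSelectionResult(
        gene_id=gene.gene_id,
        method=method,
        base_variant=base,
        selected_rares=selected,
        f_trace=f_trace,
        fs_stat=abs(res.t_stat),
        final_scores=final,
    )
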