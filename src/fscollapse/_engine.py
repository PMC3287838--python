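"""Batched evaluation of the forward-selection statistic over many phenotypes.

The permutation null requires re-running the entire greedy selection for every
gene on every permuted phenotype.  This module exploits two facts to make that
cheap:

* For a single-predictor OLS fit with a centered, unit-norm response y, the F
  statistic is a monotone function of r² = (yᵀs_c)² / ‖s_c‖², so all model
  comparisons can be made on the r² scale.
* The sum and weighted-sum collapses are additive in their member columns, so
  yᵀs, Σs and ‖s‖² update in O(1) per accretion from a per-gene Gram matrix —
  no length-n vector is touched inside the greedy loop.  The indicator
  collapse is a carrier-set union, updated incrementally from per-variant
  carrier index lists (short for rare variants).

The per-gene cost is one (p_gene × n) · (n × q) matrix product for all q
phenotypes plus a tiny greedy loop per phenotype.  Results are tested to be
identical to the reference path in :mod:`fscollapse.forward_selection`.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .collapsing import CollapseMethod, WeightVector, compute_weights
from .data_io import GeneRegion, GenotypeMatrix
from .forward_selection import F_IMPROVEMENT_RTOL

_TOL = 1e-12


def _improved(r2_new: float, r2_cur: float) -> bool:
    """Accept iff F_new > F * (1 + rtol); F is a monotone map of the odds
    r²/(1-r²), so the comparison is done on cross-multiplied odds."""
    if r2_new >= 1.0:
        return r2_cur < 1.0
    if r2_cur >= 1.0:
        return False
    return r2_new * (1.0 - r2_cur) > r2_cur * (1.0 - r2_new) * (1.0 + F_IMPROVEMENT_RTOL)

__all__ = ["GenePlan", "plan_gene", "fs_batch", "center_unit_columns"]


def center_unit_columns(Y: np.ndarray) -> np.ndarray:
    """Center each column and scale to unit norm (constant columns -> zeros)."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Yc = Y - Y.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(Yc, axis=0)
    return Yc / np.where(norms > 0, norms, 1.0)


@dataclasses.dataclass
class GenePlan:
    """Precomputed per-gene, per-method quantities reused across phenotypes."""

    gene_id: str
    method: CollapseMethod
    n: int
    m: int  # number of common variants
    nr: int  # number of rare variants
    # additive methods (sum / weighted_sum)
    A: np.ndarray | None = None  # n x (m+nr) effective score columns
    colsum: np.ndarray | None = None
    diag: np.ndarray | None = None
    G_rare_all: np.ndarray | None = None  # G[m:, :]
    G_rare_rare: np.ndarray | None = None  # G[m:, m:]
    # indicator method
    C: np.ndarray | None = None  # n x m raw common counts
    base_masks: np.ndarray | None = None  # n x m bool carrier masks
    base_counts: np.ndarray | None = None
    carriers: list[np.ndarray] | None = None
    # base selection (all methods): centered SS of base-candidate columns
    cvar_base: np.ndarray | None = None
    weights: WeightVector | None = None


def plan_gene(
    gm: GenotypeMatrix,
    gene: GeneRegion,
    method: CollapseMethod,
    weights: WeightVector | None = None,
    weight_base: bool = True,
) -> GenePlan:
    """Build the reusable per-gene workspace for one collapsing method."""
    n = gm.n_samples
    common = gene.common_variants
    rare = gene.rare_variants
    m, nr = common.size, rare.size
    if m == 0:
        raise ValueError(f"gene {gene.gene_id} has no common variant")
    plan = GenePlan(gene_id=gene.gene_id, method=method, n=n, m=m, nr=nr)

    if method == "indicator":
        C = gm.counts[:, common].astype(float)
        plan.C = C
        plan.cvar_base = (C**2).sum(axis=0) - C.sum(axis=0) ** 2 / n
        plan.base_masks = gm.counts[:, common] > 0
        plan.base_counts = plan.base_masks.sum(axis=0)
        plan.carriers = [np.flatnonzero(gm.counts[:, g] > 0) for g in rare]
        return plan

    if method == "weighted_sum":
        if weights is None:
            weights = compute_weights(gm, gene.all_variants)
        plan.weights = weights
        w_common = weights.for_members(common)
        w_rare = weights.for_members(rare) if nr else np.empty(0)
        Ac = gm.counts[:, common] / (w_common[None, :] if weight_base else 1.0)
        Ar = gm.counts[:, rare] / w_rare[None, :] if nr else np.empty((n, 0))
        A = np.column_stack([Ac, Ar]).astype(float)
    elif method == "sum":
        A = gm.counts[:, np.concatenate([common, rare])].astype(float)
    else:
        raise ValueError(f"unknown collapse method {method!r}")

    G = A.T @ A
    plan.A = A
    plan.colsum = A.sum(axis=0)
    plan.diag = np.diag(G).copy()
    plan.G_rare_all = G[m:, :]
    plan.G_rare_rare = G[m:, m:]
    plan.cvar_base = plan.diag[:m] - plan.colsum[:m] ** 2 / n
    return plan


def _r2_to_fs(r2: float, n: int) -> float:
    denom = 1.0 - r2
    if denom <= 0:
        return np.inf
    return float(np.sqrt((n - 2) * r2 / denom))


def fs_batch(plan: GenePlan, Yc: np.ndarray) -> np.ndarray:
    """FS statistics (|t| of the final fit) for every column of ``Yc``.

    ``Yc`` must hold centered, unit-norm phenotype columns (see
    :func:`center_unit_columns`); permutations of a centered vector stay
    centered, so one normalization serves all permuted columns.
    """
    if plan.method == "indicator":
        return _fs_batch_indicator(plan, Yc)
    return _fs_batch_additive(plan, Yc)


def _select_base_r2(d_common: np.ndarray, cvar: np.ndarray) -> tuple[int, float]:
    # r² of each base candidate; zero-variance columns are invalid (-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(cvar > _TOL, d_common**2 / np.where(cvar > _TOL, cvar, 1.0), -1.0)
    b = int(np.argmax(r2))
    return b, float(r2[b])


def _fs_batch_additive(plan: GenePlan, Yc: np.ndarray) -> np.ndarray:
    n, m, nr = plan.n, plan.m, plan.nr
    D = plan.A.T @ Yc  # (m+nr) x q
    q = Yc.shape[1]
    out = np.empty(q)
    colsum, diag = plan.colsum, plan.diag
    Gr, Grr = plan.G_rare_all, plan.G_rare_rare
    cvar_base = plan.cvar_base
    rare_diag = diag[m:]
    rare_colsum = colsum[m:]
    for j in range(q):
        d = D[:, j]
        b, r2 = _select_base_r2(d[:m], cvar_base)
        if r2 < 0:
            out[j] = np.nan
            continue
        if nr:
            u = Gr[:, b].copy()  # current-score dot each rare column
            ssum = colsum[b]
            ss = diag[b]
            sy = d[b]
            d_rare = d[m:]
            alive = np.ones(nr, dtype=bool)
            while True:
                idx = np.flatnonzero(alive)
                if idx.size == 0:
                    break
                nss = ss + 2.0 * u[idx] + rare_diag[idx]
                nsum = ssum + rare_colsum[idx]
                nsy = sy + d_rare[idx]
                var = nss - nsum * nsum / n
                ok = var > _TOL
                if not ok.any():
                    break
                cand = np.where(ok, nsy * nsy / np.where(ok, var, 1.0), -1.0)
                k = int(np.argmax(cand))
                if not _improved(float(cand[k]), r2):
                    break
                r2 = float(cand[k])
                c = int(idx[k])
                u += Grr[:, c]
                ss = float(nss[k])
                ssum = float(nsum[k])
                sy = float(nsy[k])
                alive[c] = False
        out[j] = _r2_to_fs(r2, n)
    return out


def _fs_batch_indicator(plan: GenePlan, Yc: np.ndarray) -> np.ndarray:
    n, m, nr = plan.n, plan.m, plan.nr
    DC = plan.C.T @ Yc  # m x q
    BS = plan.base_masks.T.astype(float) @ Yc  # m x q: sum of y over base carriers
    q = Yc.shape[1]
    out = np.empty(q)
    carriers = plan.carriers
    base_counts = plan.base_counts
    cvar_base = plan.cvar_base
    for j in range(q):
        b, r2 = _select_base_r2(DC[:, j], cvar_base)
        if r2 < 0:
            out[j] = np.nan
            continue
        if nr:
            y = Yc[:, j]
            cur = plan.base_masks[:, b].copy()
            cnt = int(base_counts[b])
            sy = float(BS[b, j])
            alive = [True] * nr
            while True:
                best_r2 = -1.0
                best: tuple[int, np.ndarray, int, float] | None = None
                for c in range(nr):
                    if not alive[c]:
                        continue
                    carr = carriers[c]
                    novel = carr[~cur[carr]]
                    ncnt = cnt + novel.size
                    if ncnt == 0 or ncnt == n:
                        continue  # constant score: degenerate candidate
                    nsy = sy + float(y[novel].sum()) if novel.size else sy
                    var = ncnt * (1.0 - ncnt / n)
                    cand_r2 = nsy * nsy / var
                    if cand_r2 > best_r2:
                        best_r2 = cand_r2
                        best = (c, novel, ncnt, nsy)
                if best is None or not _improved(best_r2, r2):
                    break
                c, novel, cnt, sy = best
                cur[novel] = True
                alive[c] = False
                r2 = best_r2
        out[j] = _r2_to_fs(r2, n)
    return out
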