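"""Shared fixtures and independent oracles for the test suite.

The naive forward-selection oracle here deliberately re-derives everything
from first principles (scipy's linregress, explicit score materialization at
every step) so it shares no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from fscollapse.data_io import GeneRegion, GenotypeMatrix


def make_gm(counts, samples=None, variants=None) -> GenotypeMatrix:
    counts = np.asarray(counts)
    n, p = counts.shape
    return GenotypeMatrix(
        samples=samples or [f"s{i}" for i in range(n)],
        variants=variants or [f"v{j}" for j in range(p)],
        counts=counts,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def random_gene_dataset(
    rng: np.random.Generator,
    n: int = 50,
    n_common: int = 2,
    n_rare: int = 6,
    common_maf=(0.05, 0.4),
    rare_maf=(0.01, 0.08),
):
    """A single random polymorphic gene (relaxed MAFs keep tiny n informative)."""
    while True:
        common = rng.binomial(2, rng.uniform(*common_maf, size=(1, n_common)), size=(n, n_common))
        rare = rng.binomial(2, rng.uniform(*rare_maf, size=(1, n_rare)), size=(n, n_rare))
        counts = np.column_stack([common, rare])
        if (counts.std(axis=0)[:n_common] > 0).all():
            break
    gm = make_gm(counts)
    gene = GeneRegion(
        gene_id="G",
        common_variants=np.arange(n_common),
        rare_variants=np.arange(n_common, n_common + n_rare),
    )
    return gm, gene


# ---------------------------------------------------------------------------
# independent oracles


def oracle_collapse(counts: np.ndarray, members: list[int], method: str) -> np.ndarray:
    sub = counts[:, members]
    if method == "indicator":
        return (sub.sum(axis=1) > 0).astype(float)
    if method == "sum":
        return sub.sum(axis=1).astype(float)
    if method == "weighted_sum":
        n = counts.shape[0]
        q = (1.0 + counts.sum(axis=0)) / (2.0 + 2.0 * n)  # all-variant weights
        w = np.sqrt(n * q * (1.0 - q))
        return (sub / w[members]).sum(axis=1)
    raise ValueError(method)


def oracle_f(y: np.ndarray, s: np.ndarray) -> float | None:
    """F statistic via scipy.stats.linregress; None for a constant score."""
    if np.ptp(s) == 0:
        return None
    res = stats.linregress(s, y)
    if not np.isfinite(res.stderr) or res.stderr == 0:
        return np.inf
    return float((res.slope / res.stderr) ** 2)


def naive_forward_selection(y, counts, common_idx, rare_idx, method):
    """Per-step exhaustive greedy, materializing every candidate score.

    Returns (base, selected list, f_trace, fs_stat).
    """
    best_base, best_f = None, -np.inf
    for j in common_idx:
        f = oracle_f(y, counts[:, j].astype(float))
        if f is not None and f > best_f:
            best_base, best_f = int(j), f
    assert best_base is not None
    f_trace = [best_f]
    selected: list[int] = []
    remaining = [int(j) for j in rare_idx]
    while remaining:
        cand_best, cand_f = None, -np.inf
        for g in remaining:
            s = oracle_collapse(counts, [best_base, *selected, g], method)
            f = oracle_f(y, s)
            if f is not None and f > cand_f:
                cand_best, cand_f = g, f
        if cand_best is None or not cand_f > f_trace[-1] * (1 + 1e-9):
            break
        selected.append(cand_best)
        remaining.remove(cand_best)
        f_trace.append(cand_f)
    if selected:
        final = oracle_collapse(counts, [best_base, *selected], method)
    else:
        final = counts[:, best_base].astype(float)
    res = stats.linregress(final, y)
    fs = abs(res.slope / res.stderr) if res.stderr > 0 else np.inf
    return best_base, selected, f_trace, float(fs)
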