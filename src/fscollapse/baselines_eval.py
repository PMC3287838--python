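"""Non-selective baseline tests and the type-I-error / power evaluation harness.

Baselines (all 1-df simple regressions of the adjusted trait on a fixed
region score, with analytic t-distribution p-values):

* ``T_ind`` — indicator collapse over ALL of the gene's rare variants,
* ``T_sum`` — sum collapse over all rare variants,
* ``T_ws``  — weighted-sum collapse over all variants (common + rare),
* ``T_com`` — the single most significant common variant (max |t|).

The evaluation harness mirrors a fixed-genotype, replicated-phenotype
simulation design: the type-I error of a test is its pooled rejection
proportion over null genes x replicates, power is the per-causal-gene
rejection proportion over replicates, and per-test significance levels can be
calibrated (empirical quantile of pooled null p-values) so that every test is
compared at the same realized false-positive rate.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .collapsing import WeightVector, collapse_indicator, collapse_sum, collapse_weighted_sum, compute_weights
from .data_io import GeneRegion, GenotypeMatrix
from .forward_selection import RegressionResult, select_base, simple_linreg

__all__ = [
    "EvaluationSummary",
    "t_ind",
    "t_sum",
    "t_ws",
    "t_com",
    "bonferroni",
    "evaluate",
    "calibrate_alpha",
]


@dataclasses.dataclass
class EvaluationSummary:
    """Per-test significance levels, type-I error rates and per-gene power."""

    alphas: dict[str, float]
    type_i_error: dict[str, float]
    power: pd.DataFrame  # causal genes x tests, rejection proportion
    n_replicates: int
    n_null_genes: int

    def type_i_table(self) -> pd.DataFrame:
        tests = list(self.alphas)
        return pd.DataFrame(
            {
                "test": tests,
                "alpha": [self.alphas[t] for t in tests],
                "type_i_error": [self.type_i_error[t] for t in tests],
            }
        )


def t_ind(y_adj: np.ndarray, gm: GenotypeMatrix, gene: GeneRegion) -> RegressionResult:
    """Indicator burden test over the gene's full rare-variant set."""
    if gene.rare_variants.size == 0:
        raise ValueError(f"gene {gene.gene_id} has no rare variants")
    score = collapse_indicator(gm, gene.rare_variants)
    return simple_linreg(y_adj, score.scores)


def t_sum(y_adj: np.ndarray, gm: GenotypeMatrix, gene: GeneRegion) -> RegressionResult:
    """Sum (proportion-coding) burden test over the full rare-variant set."""
    if gene.rare_variants.size == 0:
        raise ValueError(f"gene {gene.gene_id} has no rare variants")
    score = collapse_sum(gm, gene.rare_variants)
    return simple_linreg(y_adj, score.scores)


def t_ws(
    y_adj: np.ndarray,
    gm: GenotypeMatrix,
    gene: GeneRegion,
    weights: WeightVector | None = None,
) -> RegressionResult:
    """Weighted-sum test over all of the gene's variants (common + rare)."""
    members = gene.all_variants
    if members.size == 0:
        raise ValueError(f"gene {gene.gene_id} is empty")
    if weights is None:
        weights = compute_weights(gm, members)
    score = collapse_weighted_sum(gm, members, weights)
    return simple_linreg(y_adj, score.scores)


def t_com(y_adj: np.ndarray, gm: GenotypeMatrix, gene: GeneRegion) -> RegressionResult:
    """Single-marker test on the most significant common variant (max F = max t²)."""
    base, _ = select_base(y_adj, gene, gm)
    return simple_linreg(y_adj, gm.counts[:, base])


def bonferroni(p: float | np.ndarray, k: int) -> float | np.ndarray:
    """Bonferroni-adjusted p-value min(1, k p) for k tested genes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.minimum(1.0, k * p)
    return out if out.ndim else float(out)


def evaluate(
    reports: pd.DataFrame,
    causal_genes: set[str],
    alphas: dict[str, float],
) -> EvaluationSummary:
    """Pooled type-I error and per-gene power from a long p-value table.

    ``reports`` needs columns ``replicate``, ``gene_id``, ``test``, ``p``.
    A gene-test is rejected when p <= alpha for that test.  Type-I error
    pools rejections over null genes x replicates; power is computed per
    causal gene over replicates.
    """
    required = {"replicate", "gene_id", "test", "p"}
    if missing := required - set(reports.columns):
        raise ValueError(f"reports table lacks columns {sorted(missing)}")
    genes = set(reports["gene_id"].astype(str))
    df = reports.copy()
    df["gene_id"] = df["gene_id"].astype(str)
    df["causal"] = df["gene_id"].isin(causal_genes)
    df["alpha"] = df["test"].map(alphas)
    if df["alpha"].isna().any():
        bad = sorted(set(df.loc[df["alpha"].isna(), "test"]))
        raise ValueError(f"no significance level supplied for tests {bad}")
    df["reject"] = df["p"] <= df["alpha"]

    n_reps = df["replicate"].nunique()
    null_genes = genes - causal_genes
    type_i = {}
    for test, sub in df[~df["causal"]].groupby("test"):
        type_i[str(test)] = float(sub["reject"].sum() / (n_reps * len(null_genes)))

    power = (
        df[df["causal"]]
        .groupby(["gene_id", "test"])["reject"]
        .mean()
        .unstack(fill_value=0.0)
        if causal_genes
        else pd.DataFrame()
    )
    return EvaluationSummary(
        alphas=dict(alphas),
        type_i_error=type_i,
        power=power,
        n_replicates=n_reps,
        n_null_genes=len(null_genes),
    )


def run_simulation_study(
    config,
    methods: tuple[str, ...] = ("indicator", "sum", "weighted_sum"),
    baseline_tests: tuple[str, ...] = ("T_ind", "T_sum", "T_ws", "T_com"),
    M: int = 200,
    target_rate: float = 0.05,
    seed: int = 0,
    fs_pvalue: str = "gene_p",
) -> tuple[pd.DataFrame, EvaluationSummary]:
    """Replicated simulation: run all tests, calibrate alphas, summarize.

    Simulates one fixed genotype set from ``config`` and
    ``config.n_replicates`` phenotype replicates; on each replicate runs the
    forward-selection tests (with an M-permutation null per replicate) and the
    requested baselines; then calibrates each test's significance level on
    the pooled null-gene p-values to ``target_rate`` and evaluates type-I
    error and per-causal-gene power at those levels.

    ``fs_pvalue`` picks which permutation p enters the table for FS tests:
    the per-gene permutation p (default — the scale on which a per-gene
    false-positive rate can be calibrated) or the family-wise ``global_p``.
    Baselines contribute their analytic t-distribution p-values; calibration
    is invariant to any monotone adjustment of them.

    Returns the long p-value table (replicate, gene_id, test, p) and the
    :class:`EvaluationSummary`.
    """
    from .forward_selection import DegeneratePredictorError
    from .permutation import fs_permutation_test
    from .phenotype_adjust import adjust_phenotype, select_covariates
    from .synthetic_data import simulate_genotypes, simulate_phenotype

    data = simulate_genotypes(config)
    gm = data.genotypes
    genes = [r for r in data.regions if r.common_variants.size >= 1]
    fs_name = {"indicator": "FS_ind", "sum": "FS_sum", "weighted_sum": "FS_ws"}
    base_fn = {"T_ind": t_ind, "T_sum": t_sum, "T_ws": t_ws, "T_com": t_com}
    rows: list[dict] = []
    causal: set[str] = set()
    for rep in range(config.n_replicates):
        y, cov, causal = simulate_phenotype(data, config, rep)
        if config.covariate_effects:
            chosen = select_covariates(y, cov, 0.05)
            y_adj = adjust_phenotype(y, cov[chosen] if chosen else None)
        else:
            y_adj = adjust_phenotype(y, None)
        perm_seed = int(
            np.random.SeedSequence([seed, 11, rep]).generate_state(1)[0] % (2**31)
        )
        for method in methods:
            df, _ = fs_permutation_test(y_adj, gm, genes, method, M=M, seed=perm_seed)
            pcol = df[fs_pvalue].to_numpy()
            rows.extend(
                dict(replicate=rep, gene_id=g, test=fs_name[method], p=p)
                for g, p in zip(df["gene_id"], pcol)
            )
        for name in baseline_tests:
            for gene in genes:
                try:
                    res = base_fn[name](y_adj, gm, gene)
                except (ValueError, DegeneratePredictorError):
                    continue
                rows.append(
                    dict(replicate=rep, gene_id=gene.gene_id, test=name, p=res.p_value)
                )
    table = pd.DataFrame(rows)
    alphas = {
        str(test): calibrate_alpha(
            sub.loc[~sub["gene_id"].isin(causal), "p"].to_numpy(), target_rate
        )
        for test, sub in table.groupby("test")
    }
    summary = evaluate(table, causal, alphas)
    return table, summary


def calibrate_alpha(null_pvals: np.ndarray, target_rate: float) -> float:
    """Largest significance level whose empirical null rejection rate <= target.

    Scans the unique values of the pooled null p-values (the only points where
    the empirical rejection rate changes) and returns the largest one at which
    the rate stays within the target; when even the smallest observed p-value
    is too heavily tied to qualify, a level just below it (rejection rate 0)
    is returned.  Raises when the p-values are all identical, since no level
    can separate anything then.
    """
    p = np.asarray(null_pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty null p-value set")
    if not 0 < target_rate < 1:
        raise ValueError("target_rate must be in (0, 1)")
    uniq, counts = np.unique(p, return_counts=True)
    if uniq.size == 1:
        raise ValueError("target unreachable: all null p-values identical")
    rates = np.cumsum(counts) / p.size
    ok = rates <= target_rate
    if not ok.any():
        return float(np.nextafter(uniq[0], -np.inf))
    return float(uniq[np.flatnonzero(ok)[-1]])
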