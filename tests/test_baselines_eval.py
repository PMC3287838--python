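"""Non-selective baseline tests, Bonferroni, and the evaluation machinery."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_gm, oracle_f, random_gene_dataset
from fscollapse.baselines_eval import (
    bonferroni,
    calibrate_alpha,
    evaluate,
    t_com,
    t_ind,
    t_sum,
    t_ws,
)
from fscollapse.collapsing import WeightVector, compute_weights
from fscollapse.data_io import GeneRegion
from fscollapse.forward_selection import DegeneratePredictorError, select_base


class TestBurdenBaselines:
    def test_shifted_carriers_detected(self, rng):
        n = 120
        rare = rng.binomial(2, 0.02, size=(n, 6))
        common = rng.binomial(2, 0.3, size=(n, 1))
        carriers = rare.sum(axis=1) > 0
        y = rng.normal(size=n) + 1.5 * carriers
        gm = make_gm(np.column_stack([common, rare]))
        gene = GeneRegion("G", np.array([0]), np.arange(1, 7))
        res = t_ind(y, gm, gene)
        assert abs(res.t_stat) > 3 and res.p_value < 1e-3

    def test_no_rare_carriers_degenerate(self, rng):
        counts = np.column_stack([rng.integers(0, 3, 20), np.zeros(20, dtype=int)])
        gm = make_gm(counts)
        gene = GeneRegion("G", np.array([0]), np.array([1]))
        with pytest.raises(DegeneratePredictorError):
            t_ind(np.arange(20.0), gm, gene)

    def test_sum_equals_indicator_on_singleton_carriers(self, rng):
        # each carrier holds exactly one rare allele across the region
        n = 60
        rare = np.zeros((n, 4), dtype=int)
        for i, j in enumerate(rng.integers(0, 4, size=12)):
            rare[i * 5, j] = 1
        gm = make_gm(np.column_stack([rng.integers(0, 3, n), rare]))
        gene = GeneRegion("G", np.array([0]), np.arange(1, 5))
        y = rng.normal(size=n)
        assert t_sum(y, gm, gene).t_stat == pytest.approx(
            t_ind(y, gm, gene).t_stat, rel=1e-10
        )

    def test_doubling_a_count_moves_sum_not_indicator(self, rng):
        gm, gene = random_gene_dataset(rng, n=80, n_rare=5)
        y = rng.normal(size=80)
        counts2 = gm.counts.copy()
        carrier_rows = np.flatnonzero(counts2[:, gene.rare_variants[0]] == 1)
        counts2[carrier_rows[0], gene.rare_variants[0]] = 2
        gm2 = make_gm(counts2)
        assert t_ind(y, gm2, gene).t_stat == pytest.approx(
            t_ind(y, gm, gene).t_stat, rel=1e-12
        )
        assert t_sum(y, gm2, gene).t_stat != pytest.approx(
            t_sum(y, gm, gene).t_stat, rel=1e-12
        )

    def test_matches_regression_oracle(self, rng):
        gm, gene = random_gene_dataset(rng, n=70, n_rare=6)
        y = rng.normal(size=70)
        s = gm.counts[:, gene.rare_variants].sum(axis=1).astype(float)
        assert t_sum(y, gm, gene).F_stat == pytest.approx(oracle_f(y, s), rel=1e-10)


class TestWeightedSumBaseline:
    def test_single_variant_equals_raw_regression(self, rng):
        # t is invariant to rescaling the predictor by a positive weight
        n = 50
        col = rng.binomial(2, 0.3, size=(n, 1))
        gm = make_gm(col)
        gene = GeneRegion("G", np.array([0]), np.array([], dtype=int))
        y = rng.normal(size=n)
        from fscollapse.forward_selection import simple_linreg

        assert t_ws(y, gm, gene).t_stat == pytest.approx(
            simple_linreg(y, col[:, 0].astype(float)).t_stat, rel=1e-10
        )

    def test_unit_weights_reduce_to_region_sum(self, rng):
        gm, gene = random_gene_dataset(rng, n=60)
        y = rng.normal(size=60)
        members = gene.all_variants
        wv = WeightVector(members, np.full(members.size, 0.2), np.ones(members.size))
        s = gm.counts[:, members].sum(axis=1).astype(float)
        assert abs(t_ws(y, gm, gene, weights=wv).t_stat) == pytest.approx(
            np.sqrt(oracle_f(y, s)), rel=1e-8
        )

    def test_weight_scale_invariance(self, rng):
        gm, gene = random_gene_dataset(rng, n=60)
        y = rng.normal(size=60)
        wv = compute_weights(gm, gene.all_variants)
        scaled = WeightVector(wv.variant_indices, wv.qhat, 3.7 * wv.weights)
        assert t_ws(y, gm, gene, weights=wv).t_stat == pytest.approx(
            t_ws(y, gm, gene, weights=scaled).t_stat, rel=1e-10
        )


class TestTCom:
    def test_causal_common_snp_chosen(self, rng):
        n = 150
        x1 = rng.binomial(2, 0.3, n)
        x2 = rng.binomial(2, 0.3, n)
        y = 1.0 * x1 + rng.normal(size=n)
        gm = make_gm(np.column_stack([x2, x1]))
        gene = GeneRegion("G", np.array([0, 1]), np.array([], dtype=int))
        res = t_com(y, gm, gene)
        base, F = select_base(y, gene, gm)
        assert base == 1
        assert res.t_stat**2 == pytest.approx(F, rel=1e-8)

    def test_equals_select_base_f(self, rng):
        gm, gene = random_gene_dataset(rng, n=90, n_common=3)
        y = rng.normal(size=90)
        _, F = select_base(y, gene, gm)
        assert t_com(y, gm, gene).F_stat == pytest.approx(F, rel=1e-12)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,k,expected", [(1e-4, 553, 0.0553), (0.01, 553, 1.0), (0.2, 1, 0.2)]
    )
    def test_adjustment(self, p, k, expected):
        assert bonferroni(p, k) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni(1.5, 10)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


def _long_table(p_by_gene_test, n_reps):
    rows = []
    for rep in range(n_reps):
        for (gene, test), p in p_by_gene_test.items():
            rows.append(dict(replicate=rep, gene_id=gene, test=test, p=p))
    return pd.DataFrame(rows)


class TestEvaluate:
    def test_pooled_type_i_error(self):
        # 10 null genes x 100 replicates, exactly 5 rejections in one test
        rows = []
        k = 0
        for rep in range(100):
            for g in range(10):
                p = 0.01 if k < 5 else 0.5
                k += 1
                rows.append(dict(replicate=rep, gene_id=f"g{g}", test="T", p=p))
        summary = evaluate(pd.DataFrame(rows), set(), {"T": 0.05})
        assert summary.type_i_error["T"] == pytest.approx(0.005)

    def test_power_per_causal_gene(self):
        rows = [
            dict(replicate=r, gene_id="causal", test="T", p=0.01 if r < 190 else 0.9)
            for r in range(200)
        ]
        rows += [dict(replicate=r, gene_id="null", test="T", p=0.5) for r in range(200)]
        summary = evaluate(pd.DataFrame(rows), {"causal"}, {"T": 0.05})
        assert summary.power.loc["causal", "T"] == pytest.approx(0.95)

    def test_zero_alpha_rejects_nothing(self):
        df = _long_table({("g", "T"): 0.2, ("c", "T"): 1e-9}, 5)
        # alpha = 0 still "rejects" p = 0 only; no finite p qualifies except 0
        summary = evaluate(df, {"c"}, {"T": 0.0})
        assert summary.type_i_error["T"] == 0.0
        assert summary.power.loc["c", "T"] == 0.0

    def test_rates_are_exact_rationals(self):
        df = _long_table({("g1", "T"): 0.01, ("g2", "T"): 0.9}, 4)
        summary = evaluate(df, set(), {"T": 0.05})
        assert summary.type_i_error["T"] == 4 / 8

    def test_missing_alpha_rejected(self):
        df = _long_table({("g", "T"): 0.5}, 1)
        with pytest.raises(ValueError, match="significance level"):
            evaluate(df, set(), {})


class TestCalibrateAlpha:
    def test_uniform_grid(self):
        p = np.arange(1, 1001) / 1000.0
        assert calibrate_alpha(p, 0.05) == pytest.approx(0.05)

    def test_all_identical_unreachable(self):
        with pytest.raises(ValueError, match="unreachable"):
            calibrate_alpha(np.ones(100), 0.05)

    def test_uniform_draws_near_target(self, rng):
        p = rng.uniform(size=10_000)
        alpha = calibrate_alpha(p, 0.06)
        se = np.sqrt(0.06 * 0.94 / 10_000)
        assert abs(alpha - 0.06) < 4 * se
        assert (p <= alpha).mean() <= 0.06

    def test_monotone_in_target(self, rng):
        p = rng.uniform(size=500)
        alphas = [calibrate_alpha(p, t) for t in (0.01, 0.05, 0.1, 0.2)]
        assert alphas == sorted(alphas)

    def test_heavy_tie_falls_below_smallest_value(self):
        p = np.array([0.3] * 99 + [0.9])
        alpha = calibrate_alpha(p, 0.05)
        assert alpha < 0.3
        assert (p <= alpha).mean() == 0.0
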