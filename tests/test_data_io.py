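"""Genotype/phenotype I/O, MAF computation, variant classes and gene filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_gm
from fscollapse import data_io
from fscollapse.data_io import (
    DataFormatError,
    GeneRegion,
    GenotypeMatrix,
    build_gene_regions,
    classify_variants,
    compute_maf,
    filter_genes,
    read_genotypes,
    recode_minor,
    write_genotypes_tsv,
)


class TestReadGenotypes:
    def test_tsv_identity_read(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("sample_id\tv1\ns1\t0\ns2\t1\ns3\t2\n")
        gm = read_genotypes(p, format="tsv")
        assert gm.samples == ["s1", "s2", "s3"]
        assert gm.variants == ["v1"]
        np.testing.assert_array_equal(gm.counts[:, 0], [0, 1, 2])

    def test_major_allele_coding_is_flipped(self, tmp_path):
        # coded-allele frequency 5/6 > 0.5 -> counts flipped to the minor allele
        p = tmp_path / "g.tsv"
        p.write_text("sample_id\tv1\ns1\t2\ns2\t2\ns3\t1\n")
        gm = read_genotypes(p)
        np.testing.assert_array_equal(gm.counts[:, 0], [0, 0, 1])

    def test_missing_rejected_by_default(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("sample_id\tv1\ns1\t0\ns2\tNA\n")
        with pytest.raises(DataFormatError, match="missing"):
            read_genotypes(p)

    def test_missing_mean_imputation(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("sample_id\tv1\ns1\t0\ns2\t2\ns3\tNA\n")
        gm = read_genotypes(p, missing_policy="mean")
        assert gm.counts[2, 0] == pytest.approx(1.0)

    def test_invalid_genotype_value(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("sample_id\tv1\ns1\t3\n")
        with pytest.raises(DataFormatError, match="invalid genotype"):
            read_genotypes(p)

    def test_tsv_round_trip(self, tmp_path, rng):
        gm = make_gm(rng.integers(0, 2, size=(5, 4)))
        write_genotypes_tsv(gm, tmp_path / "rt.tsv")
        back = read_genotypes(tmp_path / "rt.tsv")
        assert back.samples == gm.samples and back.variants == gm.variants
        np.testing.assert_array_equal(back.counts, gm.counts)


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1,length=1000>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
)


class TestReadVcf:
    def _write(self, tmp_path, body):
        p = tmp_path / "t.vcf"
        p.write_text(VCF_HEADER + body)
        return p

    def test_diploid_alt_counts(self, tmp_path):
        p = self._write(tmp_path, "1\t10\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n")
        gm = read_genotypes(p, format="vcf")
        assert gm.variants == ["rs1"]
        np.testing.assert_array_equal(gm.counts[:, 0], [0, 1, 2])

    def test_missing_genotype_errors(self, tmp_path):
        p = self._write(tmp_path, "1\t10\trs1\tA\tG\t.\t.\t.\tGT\t./.\t0/1\t0/0\n")
        with pytest.raises(DataFormatError, match="missing"):
            read_genotypes(p, format="vcf")

    def test_multiallelic_rejected(self, tmp_path):
        p = self._write(tmp_path, "1\t10\trs1\tA\tG,T\t.\t.\t.\tGT\t0/0\t0/1\t1/2\n")
        with pytest.raises(DataFormatError, match="multi-allelic"):
            read_genotypes(p, format="vcf")


class TestMafAndClasses:
    def test_direct_count(self):
        gm = make_gm(np.array([[0], [1], [2], [1]]))
        assert compute_maf(gm)[0] == pytest.approx(0.5)

    def test_all_zero_column(self):
        gm = make_gm(np.zeros((4, 1), dtype=int))
        assert compute_maf(gm)[0] == 0.0

    def test_single_heterozygote_is_rare(self):
        counts = np.zeros((100, 1), dtype=int)
        counts[0, 0] = 1
        maf = compute_maf(make_gm(counts))
        assert maf[0] == pytest.approx(0.005)
        assert classify_variants(maf)[0] == "rare"

    @pytest.mark.parametrize(
        "maf,expected",
        [(0.009, "rare"), (0.010, "common"), (0.0, "monomorphic"), (0.5, "common")],
    )
    def test_classification_boundaries(self, maf, expected):
        assert classify_variants(np.array([maf]), rare_threshold=0.01)[0] == expected

    @given(st.lists(st.floats(0, 0.5), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=50)
    def test_classes_partition_variants(self, mafs):
        classes = classify_variants(np.array(mafs))
        assert set(classes) <= {"rare", "common", "monomorphic"}
        for m, c in zip(mafs, classes):
            assert c == ("monomorphic" if m == 0 else "rare" if m < 0.01 else "common")

    @given(
        st.lists(st.integers(0, 2), min_size=4, max_size=40).map(
            lambda xs: np.array(xs).reshape(-1, 1)
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_minor_recode_idempotent(self, col):
        once = recode_minor(col)
        np.testing.assert_array_equal(recode_minor(once), once)
        assert once.mean() / 2 <= 0.5


def _region(gid, n_common, n_rare):
    return GeneRegion(
        gene_id=gid,
        common_variants=np.arange(n_common),
        rare_variants=np.arange(100, 100 + n_rare),
    )


class TestFilterGenes:
    def test_region_filter_rule(self):
        kept = filter_genes(
            [_region("ten_one", 1, 9), _region("no_common", 0, 12), _region("small", 3, 6)],
            min_region_size=10,
        )
        assert [g.gene_id for g in kept] == ["ten_one"]

    def test_subset_and_order_invariance(self, rng):
        regions = [
            _region(f"g{i}", int(rng.integers(0, 3)), int(rng.integers(5, 15)))
            for i in range(20)
        ]
        kept = filter_genes(regions)
        assert set(g.gene_id for g in kept) <= set(g.gene_id for g in regions)
        shuffled = list(regions)
        rng.shuffle(shuffled)
        assert set(g.gene_id for g in filter_genes(shuffled)) == set(
            g.gene_id for g in kept
        )


class TestRegions:
    def test_monomorphic_excluded_from_regions(self):
        counts = np.array([[1, 0, 0], [2, 0, 1], [1, 0, 0], [0, 0, 0]])
        gm = make_gm(counts)
        gmap = pd.DataFrame({"variant_id": ["v0", "v1", "v2"], "gene_id": ["G"] * 3})
        (region,) = build_gene_regions(gm, gmap)
        assert list(region.common_variants) == [0, 2]  # v2 maf 0.125 -> common
        assert list(region.rare_variants) == []
        # v1 (monomorphic) is in neither set
        assert 1 not in set(region.all_variants)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GeneRegion("G", np.array([1, 2]), np.array([2, 3]))


class TestReportsAndAlignment:
    def test_empty_report_is_header_only(self, tmp_path):
        data_io.write_report([], tmp_path / "r.tsv")
        assert (tmp_path / "r.tsv").read_text().strip() == "\t".join(
            data_io.REPORT_COLUMNS
        )

    def test_report_round_trip(self, tmp_path):
        rec = dict(
            gene_id="G1", test="FS_sum", statistic=2.5, adj_statistic=1.1,
            p_value=0.01, selected_variants="v1,v2", f_trace_len=3,
        )
        data_io.write_report([rec], tmp_path / "r.tsv")
        df = data_io.read_report(tmp_path / "r.tsv")
        assert len(df) == 1
        assert df.loc[0, "gene_id"] == "G1"
        assert df.loc[0, "statistic"] == pytest.approx(2.5)
        assert df.loc[0, "selected_variants"] == "v1,v2"

    def test_align_samples_by_id_not_position(self):
        gm = make_gm(np.array([[0], [1], [2]]), samples=["a", "b", "c"])
        pheno = pd.DataFrame({"Q": [30.0, 10.0, 20.0]}, index=["c", "a", "b"])
        sub, aligned = data_io.align_samples(gm, pheno)
        assert sub.samples == ["a", "b", "c"]
        np.testing.assert_array_equal(aligned["Q"].to_numpy(), [10.0, 20.0, 30.0])

    def test_align_drops_unshared_samples(self):
        gm = make_gm(np.array([[0], [1], [2]]), samples=["a", "b", "c"])
        pheno = pd.DataFrame({"Q": [1.0, 2.0]}, index=["a", "c"])
        sub, aligned = data_io.align_samples(gm, pheno)
        assert sub.samples == ["a", "c"]
        np.testing.assert_array_equal(sub.counts[:, 0], [0, 2])


class TestGenotypeMatrixInvariants:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GenotypeMatrix(["s", "s"], ["v"], np.zeros((2, 1), dtype=int))

    def test_bad_entries_rejected(self):
        gm = make_gm(np.array([[3]]))
        with pytest.raises(ValueError, match=r"\{0, 1, 2\}"):
            gm.validate_counts()
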