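"""Genotype, phenotype and gene-map I/O, allele-frequency computation and gene filtering.

Genotypes are stored as minor-allele counts (0/1/2) in an individuals x variants
matrix.  A gene region partitions its variants into *common* and *rare* members
by minor-allele frequency (MAF); monomorphic variants belong to neither.  Only
genes with at least ``min_region_size`` polymorphic variants and at least one
common variant are analyzable: collapsing tests behave poorly on tiny regions,
and the forward-selection statistic needs a common base SNP.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "VariantAnnotation",
    "GeneRegion",
    "read_genotypes",
    "write_genotypes_tsv",
    "compute_maf",
    "classify_variants",
    "annotate_variants",
    "build_gene_regions",
    "filter_genes",
    "read_gene_map",
    "read_phenotypes",
    "read_covariates",
    "align_samples",
    "write_report",
    "read_report",
]

RARE_THRESHOLD_DEFAULT = 0.01
MIN_REGION_SIZE_DEFAULT = 10


class DataFormatError(ValueError):
    """Raised when an input file violates the declared format contract."""


@dataclasses.dataclass
class GenotypeMatrix:
    """Minor-allele count matrix with sample/variant identifiers.

    ``counts[i, j]`` is the number of minor alleles individual ``i`` carries at
    variant ``j``.  Entries are in {0, 1, 2} unless missing genotypes were
    mean-imputed, in which case imputed cells hold the per-variant mean.
    """

    samples: list[str]
    variants: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        n, p = self.counts.shape
        if len(self.samples) != n or len(self.variants) != p:
            raise ValueError(
                f"identifier lengths ({len(self.samples)}, {len(self.variants)}) "
                f"do not match matrix shape {self.counts.shape}"
            )
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample identifiers")
        if len(set(self.variants)) != p:
            raise ValueError("duplicate variant identifiers")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_variants(self) -> int:
        return self.counts.shape[1]

    def validate_counts(self) -> None:
        """Assert every entry is a valid diploid minor-allele count."""
        if not np.isin(self.counts, (0, 1, 2)).all():
            raise ValueError("genotype entries must be in {0, 1, 2}")


@dataclasses.dataclass
class VariantAnnotation:
    """Per-variant gene assignment, MAF and frequency class."""

    variant_id: str
    gene_id: str
    maf: float
    variant_class: Literal["rare", "common", "monomorphic"]


@dataclasses.dataclass
class GeneRegion:
    """A gene's variant columns split into common and rare index sets.

    Indices point into the columns of the :class:`GenotypeMatrix` the region
    was built from and are kept in ascending order so that tie-breaking in the
    selection algorithm ("lowest variant index wins") is deterministic.
    """

    gene_id: str
    common_variants: np.ndarray
    rare_variants: np.ndarray

    def __post_init__(self) -> None:
        self.common_variants = np.asarray(self.common_variants, dtype=np.intp)
        self.rare_variants = np.asarray(self.rare_variants, dtype=np.intp)
        if np.intersect1d(self.common_variants, self.rare_variants).size:
            raise ValueError("common and rare index sets overlap")

    @property
    def size(self) -> int:
        return self.common_variants.size + self.rare_variants.size

    @property
    def all_variants(self) -> np.ndarray:
        return np.concatenate([self.common_variants, self.rare_variants])


# ---------------------------------------------------------------------------
# genotype reading


def read_genotypes(
    path: str | Path,
    format: Literal["tsv", "vcf"] = "tsv",
    missing_policy: Literal["error", "mean"] = "error",
) -> GenotypeMatrix:
    """Read a genotype matrix and recode to minor-allele counts.

    TSV dialect: samples as rows, variants as columns, a header row of variant
    ids, first column sample ids, tab-separated.  VCF records must be diploid
    and biallelic.  Per variant, if the coded (ALT) allele frequency exceeds
    0.5 the counts are flipped (g -> 2 - g) so that counts always refer to the
    minor allele.

    ``missing_policy='error'`` (default) rejects missing genotypes;
    ``'mean'`` fills them with the per-variant mean of observed counts.
    """
    path = Path(path)
    if format == "tsv":
        raw, samples, variants = _read_tsv_genotypes(path)
    elif format == "vcf":
        raw, samples, variants = _read_vcf_genotypes(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")

    missing = raw < 0
    if missing.any():
        if missing_policy == "error":
            i, j = np.argwhere(missing)[0]
            raise DataFormatError(
                f"missing genotype for sample {samples[i]!r} at variant "
                f"{variants[j]!r} (missing_policy='error')"
            )
        raw = raw.astype(float)
        col_means = np.where(
            (~missing).sum(axis=0) > 0,
            np.nansum(np.where(missing, np.nan, raw), axis=0)
            / np.maximum((~missing).sum(axis=0), 1),
            0.0,
        )
        raw = np.where(missing, col_means[None, :], raw)

    counts = recode_minor(raw)
    return GenotypeMatrix(samples=samples, variants=variants, counts=counts)


def recode_minor(raw: np.ndarray) -> np.ndarray:
    """Flip columns whose coded-allele frequency exceeds 0.5 (g -> 2 - g)."""
    raw = np.asarray(raw)
    freq = raw.mean(axis=0) / 2.0
    flipped = np.where(freq > 0.5, 2 - raw, raw)
    if np.issubdtype(raw.dtype, np.integer):
        flipped = flipped.astype(raw.dtype)
    return flipped


def _read_tsv_genotypes(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, dtype=str, keep_default_na=False, na_values=[]
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataFormatError(f"cannot parse genotype TSV {path}: {exc}") from exc
    variants = [str(c) for c in df.columns]
    samples = [str(s) for s in df.index]
    arr = df.to_numpy()
    out = np.empty(arr.shape, dtype=np.int16)
    valid = {"0": 0, "1": 1, "2": 2, "NA": -1, ".": -1, "": -1}
    for (i, j), v in np.ndenumerate(arr):
        key = str(v).strip()
        if key not in valid:
            raise DataFormatError(
                f"invalid genotype value {v!r} at row {samples[i]}, column {variants[j]}"
            )
        out[i, j] = valid[key]
    return out, samples, variants


def _read_vcf_genotypes(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    variants: list[str] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise DataFormatError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS}; split or "
                "filter the VCF first (the tests are defined on biallelic SNPs)"
            )
        gts = rec.genotype.array()  # (n, ploidy+1); last col is phasing
        alleles = gts[:, :-1]
        if alleles.shape[1] != 2:
            raise DataFormatError(f"non-diploid genotype at {rec.CHROM}:{rec.POS}")
        col = np.where((alleles < 0).any(axis=1), -1, (alleles > 0).sum(axis=1))
        rows.append(col.astype(np.int16))
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variants.append(vid)
    if not rows:
        raise DataFormatError(f"no variant records in {path}")
    return np.stack(rows, axis=1), samples, variants


def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype matrix in the TSV dialect :func:`read_genotypes` reads."""
    df = pd.DataFrame(gm.counts, index=gm.samples, columns=gm.variants)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# frequencies, classes, regions


def compute_maf(gm: GenotypeMatrix) -> np.ndarray:
    """Per-variant minor-allele frequency, folded into [0, 0.5].

    maf_j = sum_i counts_ij / (2 n), then min(maf, 1 - maf).  With counts
    already minor-allele coded the fold is a no-op; it is kept so the function
    is correct on arbitrarily coded input.
    """
    if gm.n_samples == 0 or gm.n_variants == 0:
        raise ValueError("empty genotype matrix")
    freq = gm.counts.sum(axis=0) / (2.0 * gm.n_samples)
    return np.minimum(freq, 1.0 - freq)


def classify_variants(
    maf: np.ndarray, rare_threshold: float = RARE_THRESHOLD_DEFAULT
) -> np.ndarray:
    """Classify variants as monomorphic (maf=0), rare (0<maf<threshold) or common."""
    maf = np.asarray(maf, dtype=float)
    if not (0 < rare_threshold < 0.5):
        raise ValueError("rare_threshold must be in (0, 0.5)")
    if (maf < 0).any() or (maf > 0.5).any():
        raise ValueError("maf values must lie in [0, 0.5]")
    out = np.where(maf == 0, "monomorphic", np.where(maf < rare_threshold, "rare", "common"))
    return out.astype(object)


def annotate_variants(
    gm: GenotypeMatrix,
    gene_map: pd.DataFrame,
    rare_threshold: float = RARE_THRESHOLD_DEFAULT,
) -> list[VariantAnnotation]:
    """Combine MAFs, classes and the variant->gene map into per-variant annotations."""
    maf = compute_maf(gm)
    classes = classify_variants(maf, rare_threshold)
    gene_of = dict(zip(gene_map["variant_id"].astype(str), gene_map["gene_id"].astype(str)))
    return [
        VariantAnnotation(variant_id=v, gene_id=gene_of.get(v, ""), maf=float(m), variant_class=c)
        for v, m, c in zip(gm.variants, maf, classes)
    ]


def build_gene_regions(
    gm: GenotypeMatrix,
    gene_map: pd.DataFrame,
    rare_threshold: float = RARE_THRESHOLD_DEFAULT,
) -> list[GeneRegion]:
    """Group genotype columns by gene, excluding monomorphic variants.

    Genes appear in first-occurrence order of the gene map; indices within a
    gene are in ascending genotype-column order.
    """
    maf = compute_maf(gm)
    classes = classify_variants(maf, rare_threshold)
    col_of = {v: j for j, v in enumerate(gm.variants)}
    by_gene: dict[str, list[int]] = {}
    for vid, gid in zip(gene_map["variant_id"].astype(str), gene_map["gene_id"].astype(str)):
        if vid in col_of:
            by_gene.setdefault(gid, []).append(col_of[vid])
    regions = []
    for gid, cols in by_gene.items():
        cols = np.array(sorted(cols), dtype=np.intp)
        cls = classes[cols]
        regions.append(
            GeneRegion(
                gene_id=gid,
                common_variants=cols[cls == "common"],
                rare_variants=cols[cls == "rare"],
            )
        )
    return regions


def filter_genes(
    regions: Iterable[GeneRegion], min_region_size: int = MIN_REGION_SIZE_DEFAULT
) -> list[GeneRegion]:
    """Keep genes with >= min_region_size polymorphic variants and >= 1 common SNP."""
    return [
        r for r in regions if r.size >= min_region_size and r.common_variants.size >= 1
    ]


# ---------------------------------------------------------------------------
# tabular inputs


def read_gene_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"variant_id", "gene_id"} - set(df.columns)
    if missing:
        raise DataFormatError(f"gene map {path} lacks columns {sorted(missing)}")
    return df


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype TSV: sample_id column plus one column per trait."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise DataFormatError(f"phenotype file {path} lacks a sample_id column")
    return df.set_index(df["sample_id"].astype(str)).drop(columns="sample_id")


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise DataFormatError(f"covariate file {path} lacks a sample_id column")
    return df.set_index(df["sample_id"].astype(str)).drop(columns="sample_id")


def align_samples(
    gm: GenotypeMatrix, *tables: pd.DataFrame
) -> tuple[GenotypeMatrix, ...]:
    """Reconcile sample order between the genotype matrix and id-indexed tables.

    Returns the genotype matrix restricted to samples present in every table,
    followed by each table reindexed to that order.  Matching is by id, never
    by position.
    """
    keep = [s for s in gm.samples if all(s in t.index for t in tables)]
    if not keep:
        raise ValueError("no samples shared between genotypes and tables")
    idx = [gm.samples.index(s) for s in keep]
    sub = GenotypeMatrix(samples=keep, variants=gm.variants, counts=gm.counts[idx])
    return (sub, *[t.loc[keep] for t in tables])


# ---------------------------------------------------------------------------
# reports

REPORT_COLUMNS = [
    "gene_id",
    "test",
    "statistic",
    "adj_statistic",
    "p_value",
    "selected_variants",
    "f_trace_len",
]


def write_report(records: Sequence[dict] | pd.DataFrame, path: str | Path) -> None:
    """Write per-gene per-test results as a TSV (one row per gene per test)."""
    df = pd.DataFrame(list(records) if not isinstance(records, pd.DataFrame) else records)
    if df.empty:
        df = pd.DataFrame(columns=REPORT_COLUMNS)
    for col in REPORT_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df[REPORT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
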