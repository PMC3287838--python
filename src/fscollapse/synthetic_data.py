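"""Synthetic genotype/phenotype generator for the evaluation harness.

Emulates the structure the collapsing tests assume: genes of >= 10 variants
dominated by rare alleles (MAF < 0.01) with at least one common SNP, fixed
genotypes, and replicated quantitative phenotypes that are linear in a subset
of causal variants plus covariates and Gaussian noise.  Genotypes are drawn
per variant as Binomial(2, MAF) independently across variants (no linkage
disequilibrium); every variant is conditioned on being polymorphic, and
common-class variants on realizing MAF at or above the rare/common threshold,
so every generated gene passes the analyzability filter by construction.

The whole dataset is a pure function of the :class:`SimulationConfig`
(including its seed); phenotype replicates redraw only the noise and
covariates while the genotypes and the causal architecture stay fixed.
An optional two-population mode adds allele-frequency divergence and a mean
trait shift to exercise the ancestry-PC adjustment path.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import GeneRegion, GenotypeMatrix, build_gene_regions

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate_genotypes", "simulate_phenotype"]


@dataclasses.dataclass
class SimulationConfig:
    """Generator settings; defaults give a desk-scale null study.

    Effect sizes are in trait units per minor allele (the trait noise is
    ``noise_sd``-unit Gaussian, so a ``beta_rare`` of 1 means one rare allele
    shifts the trait by one noise SD).  ``causal_rare_fraction`` is the share
    of a causal gene's rare variants that carry an effect — the rest are the
    "misclassified" noise variants whose dilution the forward selection is
    designed to resist.  ``effect_sign_mix`` is the fraction of causal rare
    effects flipped negative.
    """

    n_individuals: int = 300
    n_genes: int = 200
    variants_per_gene: int = 12
    n_common_per_gene: int | tuple[int, int] = (1, 2)
    common_maf_range: tuple[float, float] = (0.05, 0.3)
    rare_maf_range: tuple[float, float] = (0.001, 0.009)
    rare_threshold: float = 0.01
    causal_genes: tuple[str, ...] = ()
    causal_rare_fraction: float = 0.5
    beta_common: float = 0.0
    beta_rare: float = 0.0
    effect_sign_mix: float = 0.0
    noise_sd: float = 1.0
    covariate_effects: Mapping[str, float] = dataclasses.field(default_factory=dict)
    n_replicates: int = 1
    seed: int = 0
    stratified: bool = False
    strat_maf_shift: float = 0.2
    strat_trait_shift: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.common_maf_range
        if not (self.rare_threshold <= lo <= hi <= 0.5):
            raise ValueError("common_maf_range must lie in [rare_threshold, 0.5]")
        rlo, rhi = self.rare_maf_range
        if not (0 < rlo <= rhi < self.rare_threshold):
            raise ValueError("rare_maf_range must lie in (0, rare_threshold)")
        n_common = self.n_common_per_gene
        hi_common = n_common[1] if isinstance(n_common, tuple) else n_common
        if hi_common > self.variants_per_gene:
            raise ValueError("n_common_per_gene exceeds variants_per_gene")
        if not 0 <= self.causal_rare_fraction <= 1:
            raise ValueError("causal_rare_fraction must be in [0, 1]")
        if not 0 <= self.effect_sign_mix <= 1:
            raise ValueError("effect_sign_mix must be in [0, 1]")


@dataclasses.dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    gene_map: pd.DataFrame
    regions: list[GeneRegion]
    causal_variants: dict[str, float]  # variant_id -> effect size
    populations: np.ndarray | None = None


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *stream]))


def _draw_polymorphic(
    rng: np.random.Generator, maf: float, n: int, require_common: bool, threshold: float
) -> np.ndarray:
    """Binomial(2, maf) column conditioned on being usable for its class."""
    for _ in range(1000):
        g = rng.binomial(2, maf, size=n)
        total = g.sum()
        if total == 0 or total == 2 * n:
            continue
        if require_common and total / (2 * n) < threshold:
            continue
        return g
    raise RuntimeError("could not draw a usable genotype column (MAF too extreme?)")


def simulate_genotypes(config: SimulationConfig) -> SimulatedDataset:
    """Draw the fixed genotype matrix, gene map and causal architecture."""
    rng = _rng(config, 1)
    n = config.n_individuals
    pops = None
    if config.stratified:
        pops = (np.arange(n) >= n // 2).astype(int)

    cols: list[np.ndarray] = []
    variant_ids: list[str] = []
    map_rows: list[tuple[str, str]] = []
    common_ids: dict[str, list[str]] = {}
    rare_ids: dict[str, list[str]] = {}

    for g in range(config.n_genes):
        gid = f"GENE{g:04d}"
        common_ids[gid] = []
        rare_ids[gid] = []
        nc = config.n_common_per_gene
        if isinstance(nc, tuple):
            nc = int(rng.integers(nc[0], nc[1] + 1))
        for v in range(config.variants_per_gene):
            vid = f"{gid}:V{v:03d}"
            is_common = v < nc
            lo, hi = config.common_maf_range if is_common else config.rare_maf_range
            maf = rng.uniform(lo, hi)
            if config.stratified and is_common:
                shift = config.strat_maf_shift / 2.0
                f = np.where(
                    pops == 0,
                    np.clip(maf - shift, 0.001, 0.499),
                    np.clip(maf + shift, 0.001, 0.499),
                )
                col = rng.binomial(2, f)
                if col.sum() in (0, 2 * n) or col.sum() / (2 * n) < config.rare_threshold:
                    col = _draw_polymorphic(rng, maf, n, True, config.rare_threshold)
            else:
                col = _draw_polymorphic(rng, maf, n, is_common, config.rare_threshold)
            cols.append(col)
            variant_ids.append(vid)
            map_rows.append((vid, gid))
            (common_ids if is_common else rare_ids)[gid].append(vid)

    counts = np.stack(cols, axis=1).astype(np.int16)
    # fold any column the binomial draw pushed past 0.5
    freq = counts.sum(axis=0) / (2 * n)
    counts = np.where(freq > 0.5, 2 - counts, counts).astype(np.int16)
    gm = GenotypeMatrix(
        samples=[f"S{i:04d}" for i in range(n)], variants=variant_ids, counts=counts
    )
    gene_map = pd.DataFrame(map_rows, columns=["variant_id", "gene_id"])
    regions = build_gene_regions(gm, gene_map, config.rare_threshold)

    # causal architecture: fixed across replicates
    erng = _rng(config, 2)
    causal: dict[str, float] = {}
    for gid in config.causal_genes:
        if gid not in common_ids:
            raise ValueError(f"unknown causal gene {gid}")
        if config.beta_common != 0 and common_ids[gid]:
            causal[common_ids[gid][0]] = config.beta_common
        rares = rare_ids[gid]
        k = int(round(config.causal_rare_fraction * len(rares)))
        chosen = list(erng.choice(len(rares), size=k, replace=False)) if k else []
        n_neg = int(round(config.effect_sign_mix * len(chosen)))
        for rank, ci in enumerate(sorted(chosen)):
            sign = -1.0 if rank < n_neg else 1.0
            causal[rares[ci]] = sign * config.beta_rare
    return SimulatedDataset(
        genotypes=gm, gene_map=gene_map, regions=regions, causal_variants=causal,
        populations=pops,
    )


def simulate_phenotype(
    data: SimulatedDataset, config: SimulationConfig, replicate_index: int
) -> tuple[np.ndarray, pd.DataFrame, set[str]]:
    """One phenotype replicate: trait vector, covariate table, causal gene set.

    y_i = sum_v beta_v g_iv + sum_c gamma_c C_ic + eps_i with
    eps ~ Normal(0, noise_sd²).  Covariates (one binary ``Sex``, one
    continuous ``Age``, one binary ``Smoke``) are redrawn per replicate, as is
    the noise; genotypes and effect assignments are fixed.
    """
    rng = _rng(config, 3, replicate_index)
    gm = data.genotypes
    n = gm.n_samples
    y = rng.normal(0.0, config.noise_sd, size=n)

    col_of = {v: j for j, v in enumerate(gm.variants)}
    for vid, beta in data.causal_variants.items():
        y = y + beta * gm.counts[:, col_of[vid]]

    cov = pd.DataFrame(
        {
            "Sex": rng.integers(0, 2, size=n).astype(float),
            "Age": rng.normal(50.0, 10.0, size=n),
            "Smoke": rng.integers(0, 2, size=n).astype(float),
        },
        index=pd.Index(gm.samples, name="sample_id"),
    )
    for name, gamma in config.covariate_effects.items():
        if name not in cov.columns:
            raise ValueError(f"unknown covariate {name!r}")
        y = y + gamma * cov[name].to_numpy()
    if config.stratified and config.strat_trait_shift:
        y = y + config.strat_trait_shift * data.populations

    causal_gene_set = {vid.split(":")[0] for vid in data.causal_variants}
    return y, cov, causal_gene_set
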