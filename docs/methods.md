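# Methods

## Problem and model

`fscollapse` tests whether a gene-sized genomic region is associated with a
quantitative trait when the region holds a mixture of common and rare
variants.  Classical burden (collapsing) tests compress a region's rare
variants into one per-individual score and run a single 1-df test; they gain
power when every collapsed variant pushes the trait in the same direction and
lose it badly when neutral ("misclassified") variants are swept into the
score.  The package implements a data-adaptive alternative: a greedy forward
selection that only accretes rare variants which improve the association
signal.

For a region with genotype columns $r_{ij}$ (minor-allele counts, individuals
$i$, variants $j$):

1. **Base.** Fit $y = \beta_0 + \beta_1 x_j + \varepsilon$ on each common
   variant's raw counts; the variant with the largest model F statistic
   (1, N−2 df) is the base SNP $S$.
2. **Accretion.** For each remaining rare variant $g$, recompute the
   collapsed score of the member set $\{S\} \cup \text{selected} \cup \{g\}$
   and refit.  The best candidate is accepted iff $F_\text{new} > F$
   (strictly); accepted variants leave the candidate pool.
3. **Stop** when no candidate improves F or no rare variants remain.  The
   region's statistic is $\mathrm{FS} = |t|$ of the final fit (so
   $\mathrm{FS}^2$ equals the final F).

Three collapsing functions are supported, applied to the whole member set
from scratch at every evaluation:

* indicator: $s_i = \mathbf{1}\{\sum_{j \in S} r_{ij} > 0\}$ (CAST-style);
* sum: $s_i = \sum_{j \in S} r_{ij}$ (proportion coding);
* weighted sum: $s_i = \sum_{j \in S} r_{ij} / w_j$ with Madsen–Browning
  weights $w_j = \sqrt{n\,\hat q_j (1-\hat q_j)}$,
  $\hat q_j = (1 + \sum_i r_{ij}) / (2n + 2)$ estimated from **all**
  individuals — a quantitative trait offers no "unaffected" subgroup, and a
  phenotype-free weight is required for the permutation null to be
  exchangeable.  The base SNP is weighted like any other member (a flag can
  exempt it).

The non-selective baselines are `T_ind`/`T_sum` (indicator/sum over the full
rare set), `T_ws` (weighted sum over all variants) and `T_com` (best single
common variant), with analytic t-distribution p-values and optional
Bonferroni adjustment over the analyzed genes.

## Permutation calibration

Greedy maximization inflates FS and the inflation varies with region size
and allele-frequency spectrum, so FS has no analytic null and is not
comparable across genes.  Both issues are handled by one genome-wide
permutation pass: M phenotype permutations are drawn once, shared by every
gene, and the **entire selection path** is recomputed per gene per
permutation.  Per gene, $\hat\mu_i$ and $\hat\sigma_i$ (sd with M−1
denominator) of the permuted statistics standardize the observed value,
$\mathrm{FS}^{adj}_i = (\mathrm{FS}_i - \hat\mu_i)/\hat\sigma_i$; permuted
statistics are standardized with the same $\hat\mu_i, \hat\sigma_i$.

Two p-values are reported, and they answer different questions:

* **Global (family-wise) p** — the proportion of per-permutation maxima
  $m_j = \max_i \mathrm{FS}^{adj*}_{ij}$ exceeding $\mathrm{FS}^{adj}_i$.
  Because the permutation stream is shared, this controls the family-wise
  error rate across the gene set and is the right scale for genome-wide
  discovery claims.
* **Per-gene p** — the proportion of the gene's own permuted statistics
  exceeding its observed FS.  This is the pointwise test of a single gene,
  uniform (up to the 1/M grid) under its null.

The evaluation harness calibrates significance levels on the per-gene p.
This is deliberate: for k genes and M permutations, the per-gene rejection
rate of the max-statistic p at any threshold below 1 is bounded near
$H_M / k$ (≈3% at k = M = 200), so a per-gene false-positive target of ~5%
is simply not reachable on the family-wise scale — the two scales must not
be conflated when reconstructing per-test type-I error tables.

Degenerate genes ($\hat\sigma_i = 0$) are flagged and reported with p = 1
rather than dropped.  The strict ">" in the p-value counts is the default;
add-one smoothing $(1+\#)/(1+M)$ is available because exact zeros break
−log₁₀ displays.  M defaults to 1,000 for analyses; the simulation studies
below use M = 200.

## Numerical choices

* All per-candidate model comparisons are made on the scale of
  $r^2 = (y^\top s_c)^2 / (\lVert s_c\rVert^2)$ for centered unit-norm $y$;
  $F = (N-2)\, r^2/(1-r^2)$ is a monotone map, so argmax and improvement
  decisions are identical to comparing F.
* "F strictly improved" is assessed with a relative margin of 1e−9
  (`F_IMPROVEMENT_RTOL`).  Analytic ties occur structurally — e.g. a rare
  column collinear with the current score — and at machine precision the
  accept/stop decision would be made by floating-point reassociation.
  Genuine improvements are many orders of magnitude above the margin.
* Candidate ties break to the lowest variant index; zero-variance
  (degenerate) candidate scores are skipped, not fatal — indicator scores
  saturate easily.  A perfect fit (MSE = 0) is returned flagged with
  infinite F.
* Zero-variance predictors are detected at centered-SS ≤ 1e−12·n.
* The batched engine (`_engine`) evaluates all permutations of a gene from
  one Gram matrix (additive collapses update $y^\top s$, $\sum s$,
  $\lVert s\rVert^2$ in O(1) per accretion; the indicator collapse updates a
  carrier-set union from per-variant carrier lists).  It is tested to agree
  with the readable reference path to 1e−8 relative on the statistic and
  exactly on the selection path.
* Genotype PCA standardizes columns by $\sqrt{p(1-p)}$ with the posterior
  frequency estimate $p = (1+\sum_i g_{ij})/(2+2n)$ and centers by the
  column mean; eigenvector signs are fixed so the largest-magnitude entry is
  positive.

## Covariate adjustment

Confounders are screened with one multivariate OLS fit of the trait on all
candidates; those with coefficient p < `alpha_cov` (default 0.05) are kept,
the top `n_pcs` (default 5) ancestry PCs are always appended, and the
adjusted phenotype is the OLS residual of the trait on the selected design.
An `invert` flag selects p > `alpha_cov` instead, for strict reproduction of
pipelines that state that rule; screening for *associated* covariates is the
scientifically meaningful default.  When a study uses replicated phenotypes,
selection is meant to be done once (on the first replicate) and reused.

## Synthetic data and what it does (not) show

The generator mirrors the structure of a resequencing benchmark with
unrelated individuals: fixed genotypes, Binomial(2, MAF) per variant with no
LD, genes of ≥10 variants with a rare-dominated MAF spectrum
(rare MAF ∈ [0.001, 0.009], 1–2 common variants with MAF ∈ [0.05, 0.3]), and
replicated phenotypes $y = \sum_v \beta_v g_v + \sum_c \gamma_c C_c +
\varepsilon$ with fresh noise per replicate.  Every variant is conditioned on
being polymorphic and common slots on realizing MAF ≥ 0.01, so generated
genes pass the analyzability filter by construction (the conditioning is the
usual ascertainment of segregating sites).  An optional two-population mode
adds allele-frequency divergence and a trait shift to exercise the PC
adjustment.

Because variants are LD-free and effects are linear and homoscedastic,
passing tests demonstrate calibration and the selection mechanism — not
robustness to LD between the base SNP and causal rares, to non-normal trait
noise, or to relatedness, none of which the generator emulates.

## Study designs used by the shipped simulations

* **Null calibration study** (acceptance script and the type-I test):
  200 genes × 12 variants, n = 300, 25 phenotype replicates of pure N(0,1)
  noise, M = 200 permutations, all three FS tests; per-test levels calibrated
  to a 5% per-gene false-positive target on the pooled 5,000 null p-values
  per test.  These sizes keep a full run in a few minutes on one core while
  leaving the binomial standard error of the rate near 0.3%.
* **Misclassification power study**: 40 genes, 8 causal, 100 replicates,
  M = 150, n = 300; causal genes carry a weak common effect (β = 0.15) and
  50% causal rares with concordant sign (β = 0.8, i.e. 0.8 noise-SD per
  allele — the moderate-to-high effect regime the rare-variant hypothesis
  posits).  FS and baseline tests are compared at matched empirical per-gene
  false-positive rates via a paired one-sided exact binomial on discordant
  causal-gene × replicate rejections.

## Known limitations

* Genes without a usable common variant are skipped (the analyzability
  filter requires one); there is no rare-only fallback mode.
* The selective advantage is collapse-function dependent.  In the shipped
  misclassification study the sum variant's gain over its non-selective
  baseline is large and decisive, while the indicator variant's gain is
  small and within Monte-Carlo noise: the indicator score saturates (one
  carrier suffices), and in LD-free synthetic data the mandatory common base
  carries no information about which rares are causal, so selection gains
  roughly what selection noise costs.  In real data, where a base SNP can
  tag causal rares through LD, the indicator variant is expected to fare
  better; the LD-free generator cannot show that.
* No backward elimination: an accreted rare variant is never removed.
* Baseline burden tests' analytic p-values are conservative for very sparse
  scores (few carriers); the calibration step absorbs this in comparisons,
  but raw `T_*` p-values should not be read as exact for singleton-dominated
  regions.
* Multi-allelic VCF records are rejected rather than split; missing
  genotypes are either an error or per-variant mean-imputed.
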