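# Methods

This note documents the statistical models implemented in `bloodeqtl`,
the design of the synthetic cohort the test suite runs on, and the
numerical choices that affect results.

## The association model

For each (variant, transcript) pair the scan fits a simple linear
regression of covariate-residualized expression `y` on alt-allele
dosage `g`:

    beta = cov(g, y) / var(g)
    se   = sqrt(RSS / df / SS_g),   df = n - 2
    t    = beta / se
    r2   = t^2 / (t^2 + df)

`r2` is the partial variance in residual expression explained by the
variant. The scan is blockwise-vectorized (`X'Y` over variant blocks)
but algebraically identical to the per-pair fit; the test suite checks
agreement with a naive per-pair OLS oracle to 1e-10.

Degrees of freedom are fixed at `n - 2`, ignoring the degrees consumed
by the residualization stage. This matches the two-stage design
(covariates are regressed out once, then each variant is tested against
the residuals) and is internally consistent: recomputing `r2` from `t`
at df = n - 2 reproduces the reported `r2` column exactly. A
`df_policy = "n-2-k"` escape hatch subtracts a user-stated number of
residualization degrees for sensitivity analyses, since the correct
convention cannot be decided from association output alone.

**Thresholds.** Variants are retained at minor allele count MAC >= 10
(MAC = min(alt count, 2n - alt count)). A pair is *cis* when variant and
gene share a chromosome and |pos - TSS| <= 1 Mb (boundary inclusive;
TSS = start on the + strand, end on the - strand); otherwise *trans*.
Significance is declared at p < 5e-8 (cis) and p < 1e-12 (trans);
records at p < 1e-4 are stored with full statistics, and the total test
count is kept separately so the inflation factor and any FDR need no
re-scan.

**Extreme tails.** p-values are carried as log10(p) alongside p. Where
scipy's `t.logsf` underflows (|t| beyond roughly 60 at df ~ 2600), the
tail is evaluated through the leading terms of the incomplete-beta
series, `sf(t) ~ x^a / (2 a B(a, 1/2))` with `a = df/2`,
`x = df/(df + t^2)`. The relative error of this branch on the log scale
is below 1e-3 at the switch point and shrinks as |t| grows; it only
engages far beyond any decision threshold.

**Genomic inflation.** lambda_GC is the median of the 1-df chi-square
quantiles `Q(1 - p)` over the full (unthresholded) p distribution,
divided by the null median 0.454936. The pipeline evaluates it on the
chromosome of median variant count, mirroring the convention of
computing it on one median-length chromosome to bound storage. p = 0
underflow is handled by mapping t-statistics directly on the log scale.

## Preprocessing

**Blood-cell imputation.** Blood-cell components (WBC and platelet
counts, five differential percentages) are predicted from expression by
PLS regression, trained on the samples with measured counts using
3-fold cross-validation. The number of latent components (1..10 by
default) is chosen to maximize mean held-out R^2 across targets — the
component count is a free parameter here, and CV is the natural
selector given the cross-validated framing of the imputation. Measured
samples keep their observed values; only unmeasured samples receive
predictions, and provenance flags are updated. Zero-variance targets
are excluded and reported with undefined R^2.

**Principal components.** Genotype PCs (default 5, standardized dosage
matrix) absorb population structure; expression PCs (default 15) absorb
unknown expression confounders. Scores come from the SVD of the
centered matrix with a deterministic sign convention (the
largest-magnitude loading of each component is positive), so results
are invariant to sample ordering up to nothing at all.

**Residualization.** One joint OLS design: intercept, age, sex, batch
(one-hot, first level dropped), log-scale-free cell counts, four of the
five differential percentages (basophil dropped — the five sum to 100,
so including all five with an intercept is exactly collinear), genotype
PCs, expression PCs. Expression PCs are computed on the raw expression
and entered in the same single-pass design rather than sequentially;
this makes the result independent of adjustment order. Collinear
columns are removed by pivoted QR with a warning; a design that
collapses to the intercept is an error. Residualization is idempotent
and the residuals are orthogonal to every design column by
construction. Kinship adjustment is not implemented; cohorts with
related individuals can supply an externally adjusted expression matrix
through the `precomputed_residuals` hook.

## Post-scan summaries

- **Lead selection**: the minimal-p record per eGene; exact ties on the
  stored log10 p (within 1e-12 — variants in perfect LD tie exactly)
  are broken by a seeded uniform draw, with the tie count recorded. The
  per-gene seed is derived from the root seed and the gene ID, so leads
  do not depend on record order.
- **MAF bins**: |beta| quartiles over [0.1, 0.5), [0.05, 0.1),
  [0.01, 0.05), (0.003, 0.01), plus a Jonckheere–Terpstra rank trend
  test (normal approximation, ties counted half, no tie correction in
  the variance) across the ordered bins. Leads with MAF outside
  (0.003, 0.5) are excluded with a warning: the bin partition starts at
  0.003 although MAC >= 10 can admit slightly rarer variants at large n,
  and those leads belong to no bin.
- **Mood's median test** is the classical 2x2 chi-square on the pooled
  median (counts above vs <= the median, no continuity correction).
  Rank-score variants of the test implemented elsewhere can differ in
  the third decimal of p; the classical form is fully reproducible from
  the definition. Degenerate (all-equal) samples return p = 1.
- **TSS distance bins** for cis leads: <=100 kb, 101–200 kb, 201–500 kb,
  501 kb–1 Mb on |signed distance| (variant pos - TSS), upper edges
  inclusive. A cis lead beyond 1 Mb is an internal error by definition.
- **Cross-study concordance**: among pairs significant in both result
  sets at a shared threshold, the proportion with the same effect sign.
- **lncRNA–neighbor correlation**: Pearson correlation of the two
  genes' OLS residuals on the covariate design, with an empirical p
  from resampling: 500 iterations of 1000 randomly sampled genes paired
  at random form the null; p = (k + 1)/(N + 1) with k the number of
  null |r| at or above the observed |r| (add-one smoothing avoids p = 0;
  "more extreme" is two-sided on |r|).

## Enrichment

Variant-level: per trait, a 2x2 table of query membership x trait
membership over a universe of all MAC-passing tested variants with
rsIDs (the test is only meaningful against the tested background), with
the two-sided Fisher exact p (sum of all tables with point probability
<= observed). Gene-level: one-sided hypergeometric upper tail of the
overlap between the top eGenes (default top 1000 by lead p) and each
user-supplied GMT set, intersected with the tested-gene universe.
Benjamini–Hochberg step-up q-values across traits or terms; FDR < 0.05
is the reporting threshold. LD among query variants is ignored, which
can overstate the effective number of independent query signals.

## Mendelian randomization

Two-sample MR of a gene's expression (exposure) on an outcome GWAS.

- **Instruments**: significant cis-eQTL variants (p < 5e-8) of the gene
  that also appear in the outcome GWAS, greedily LD-pruned (sorted by
  exposure p; kept iff dosage r^2 < 0.1 with every kept variant). LD is
  computed from the study genotypes themselves, not an external panel.
- **Harmonization**: outcome effects are aligned to the exposure effect
  allele (beta negated when alleles are swapped); palindromic variants
  (A/T, C/G) with allele frequency in [0.42, 0.58] are dropped as
  unresolvable, as are mismatched allele pairs. All drops are logged.
- **Wald ratios** b_j = Gamma_j / gamma_j with first-order standard
  error se_Gamma_j / |gamma_j|. Ignoring the exposure-side error is
  standard with genome-wide-significant instruments; it slightly
  understates uncertainty for weak instruments.
- **IVW** (primary): fixed-effect inverse-variance-weighted mean of the
  ratios; heterogeneity by Cochran's Q against chi-square(J - 1).
  Heterogeneity is reported rather than absorbed into a multiplicative
  random-effects variance, because the workflow switches to robust
  estimators when Q is significant.
- **MR-Egger**: weighted regression of Gamma on gamma with an
  intercept (weights 1/se_Gamma^2), instruments reoriented so every
  gamma >= 0. The intercept estimates directional pleiotropy. Inference
  uses t with J - 2 df, with the residual dispersion floored at 1 (no
  underdispersion credit). Requires J >= 3.
- **Weighted median**: the ratio at cumulative normalized IVW weight
  0.5, interpolating linearly between order statistics (midpoint
  convention); consistent when valid instruments carry > 50% of the
  weight. SE by parametric bootstrap (default 1000 draws of
  (gamma_j, Gamma_j) from their stated normals, weights recomputed per
  draw).
- **Weighted mode**: argmax of the IVW-weighted Gaussian-kernel density
  of the ratios, bandwidth = factor x 0.9 min(sd, IQR/1.349) J^(-1/5)
  (a modified Silverman rule on the ratio dispersion; factor
  configurable, default 1). All-equal ratios return that value exactly.
  SE by the same bootstrap.
- **Study-wise reporting**: IVW per gene; Egger whenever J >= 3; median
  and mode additionally when Q_p < 0.05. Genes with no usable
  instruments are excluded from the Bonferroni denominator; a gene is
  flagged causal when its IVW p < 0.05 / n_genes_tested.

## The synthetic cohort

The generator emulates a whole-blood eQTL cohort of unrelated
individuals; every output is a pure function of one config + seed, via
named substreams, so any piece can be regenerated independently.

- **Genotypes**: per haplotype, a latent standard-normal AR(1) process
  along each chromosome (parameter `ld_decay`, default 0.6) is
  thresholded at `Phi^-1(MAF_j)`; dosage = sum of two haplotypes. This
  Gaussian-copula construction keeps every variant's marginal exactly
  Bernoulli(MAF_j) — so empirical MAFs sit inside exact binomial
  intervals around their targets regardless of LD strength — while
  giving tunable local correlation. (A simpler neighbor-copying scheme
  was considered and rejected: copying a neighbor's genotype drags each
  variant's frequency toward the neighbor's target whenever the two
  differ.) MAFs are a Beta(0.8, 2) draw mapped to (0.01, 0.5) with a
  10% rare mass uniform on (0.003, 0.01), populating rare bins.
  A configurable fraction of variants (default 15%) get palindromic
  (A/T or C/G) alleles to exercise harmonization.
- **Covariates**: age ~ N(55, 10) clipped to [20, 90], sex ~
  Bernoulli(0.5), batch uniform over levels, WBC and platelet counts
  log-normal around typical clinical values, differential percentages a
  Dirichlet draw around (neut 60, lymph 30, mono 7, eos 2.5, baso 0.5)%
  scaled to sum exactly to 100. The first round(0.8 n) samples are
  flagged measured (matching an 80/20 measured/imputed split).
- **Expression**: continuous, log-TPM-like scale. Each gene =
  random linear loadings on (standardized) age, sex, log counts, scaled
  differentials, a batch shift, plus an optional planted genetic effect
  and N(0, noise_sd^2) noise. Counts are not modeled — the scan
  consumes residualized continuous values, so count noise would add
  nothing the tests exercise. 25% of genes (default) receive one cis
  causal variant within 1 Mb of their TSS, 5% one trans causal variant
  on another chromosome; planted betas are sized so the variant
  explains a drawn fraction (uniform 0.05–0.3) of non-covariate
  variance. 13% of genes carry the lncRNA biotype. The truth table
  records every planted quantity.
- **Outcome GWAS**: for each instrument, Gamma_j = theta gamma_j +
  alpha_j + e_j with e_j ~ N(0, se_j^2), se_j uniform on (0.02, 0.05);
  alpha_j = 0 for valid instruments and a configured offset for the
  invalid fraction. theta and each alpha are recorded in the truth
  table.
- **Trait–SNP table**: each variant joins each trait with a base odds
  (rate 0.02); configured traits have their odds multiplied for
  designated variants, planting genuine over-representation.

What the generator does *not* emulate: relatedness/family structure,
population stratification and admixture, count-level expression noise,
read-level artifacts, and realistic genome-scale LD blocks. Passing
tests therefore demonstrate the correctness and calibration of the
statistical machinery under the stated model, not robustness to those
real-data features; in particular the absence of kinship means the
mixed-model adjustments a family cohort would need are out of scope.

## Problem sizes and determinism

The default test suite runs on desk-scale cohorts (hundreds of samples,
hundreds to thousands of variants); the end-to-end smoke test uses
n = 500 samples, 20,000 variants and 2,000 genes, which exercises the
blockwise scan path (36M tests) and completes in about a minute. These
sizes were chosen so the full statistical battery — calibration at 1e5
null tests, 200-replicate coverage, bootstrap MR — runs comfortably on
a single CPU. All randomness descends from one root seed through named
per-stage substreams (CRC32 of the stage name), no stage touches global
RNG state, and re-running any stage with the same config reproduces its
outputs byte-for-byte.

## Known limitations

- First-order Wald-ratio SEs understate uncertainty for weak
  instruments; instruments here are genome-wide significant by
  construction.
- The Fisher enrichment ignores LD between query variants.
- The Jonckheere trend test uses the no-tie variance; heavy ties would
  make it slightly anticonservative.
- df = n - 2 ignores residualization degrees of freedom; at cohort
  sizes in the thousands the difference is negligible, at small n it is
  not, and `df_policy` exists for that reason.
- Gene-set enrichment takes user-supplied GMT files; it does not query
  live annotation services, whose versioned term databases are not
  reproducible.
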