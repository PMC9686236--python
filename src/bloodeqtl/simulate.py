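"""Synthetic whole-blood cohort generator.

Produces, from one :class:`~bloodeqtl.config.SimulationConfig` and its
seed, every input the analysis consumes: biallelic genotype dosages with
a rare-inclusive MAF spectrum and local LD, blood-cell-composition
covariates that confound expression, a continuous (log-TPM-like)
expression matrix with planted cis and trans genetic effects, outcome
GWAS summary statistics generated under a known causal effect of gene
expression, and a GWAS-catalog-style trait-SNP table — plus the ground
truth needed to test parameter recovery.

Genotypes use a Gaussian-copula AR(1): each haplotype is a latent
standard-normal AR(1) process along the chromosome, thresholded at
Phi^-1(MAF_j) per variant. Marginals are therefore exactly
Bernoulli(MAF_j) regardless of the LD strength, while adjacent variants
share a tunable correlation (``ld_decay``).

All randomness flows from named substreams of the config seed, so each
output is reproducible independently of whether the others are drawn.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigurationError, DataError, SimulationConfig
from .datatypes import (
    ExpressionMatrix,
    GenotypeMatrix,
    TruthTable,
    is_palindromic,
    tss,
)

CELL_PCT_COLUMNS = [
    "neutrophil_pct",
    "lymphocyte_pct",
    "monocyte_pct",
    "eosinophil_pct",
    "basophil_pct",
]
CELL_COUNT_COLUMNS = ["wbc_count", "platelet_count"]
CELL_COLUMNS = CELL_COUNT_COLUMNS + CELL_PCT_COLUMNS

# typical adult whole-blood differential means (percent) and Dirichlet
# concentration; chosen to put neutrophils ~60%, lymphocytes ~30%
_DIFFERENTIAL_MEANS = np.array([0.60, 0.30, 0.07, 0.025, 0.005])
_DIRICHLET_PRECISION = 120.0

_NONPALINDROMIC = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"), ("A", "C"), ("G", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Named substream of the config seed (stable across processes)."""
    key = zlib.crc32(stream.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(key,)))


def _sample_ids(n: int) -> pd.Index:
    return pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id")


def draw_mafs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Mixture MAF law: truncated Beta for common + uniform rare mass."""
    n = config.n_variants
    rare = rng.random(n) < config.frac_rare
    a, b = config.maf_common_beta
    common = rng.beta(a, b, size=n) * 0.49 + 0.01  # map into (0.01, 0.5)
    rare_maf = rng.uniform(0.003, 0.01, size=n)
    return np.where(rare, rare_maf, common)


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw dosages in {0,1,2} with per-variant target MAF and local LD.

    Two latent AR(1) haplotypes per sample are thresholded at the normal
    quantile of each variant's target MAF; the dosage is their sum. The
    AR parameter (``ld_decay``) resets at chromosome boundaries.
    """
    if not isinstance(config, SimulationConfig):
        raise ConfigurationError("config must be a SimulationConfig")
    rng = _rng(config, "genotypes")
    n, m = config.n_samples, config.n_variants

    mafs = draw_mafs(config, rng)
    thresholds = stats.norm.ppf(mafs)

    # variant metadata
    chroms = np.sort(rng.integers(1, config.n_chromosomes + 1, size=m))
    gaps = rng.exponential(config.mean_variant_spacing, size=m).astype(np.int64) + 1
    pos = np.empty(m, dtype=np.int64)
    for c in np.unique(chroms):
        mask = chroms == c
        pos[mask] = 10_000 + np.cumsum(gaps[mask])
    palindromic = rng.random(m) < config.frac_palindromic
    allele_idx_np = rng.integers(0, len(_NONPALINDROMIC), size=m)
    allele_idx_p = rng.integers(0, len(_PALINDROMIC), size=m)
    ref = np.where(
        palindromic,
        [_PALINDROMIC[i][0] for i in allele_idx_p],
        [_NONPALINDROMIC[i][0] for i in allele_idx_np],
    )
    alt = np.where(
        palindromic,
        [_PALINDROMIC[i][1] for i in allele_idx_p],
        [_NONPALINDROMIC[i][1] for i in allele_idx_np],
    )

    rho = config.ld_decay
    new_chrom = np.empty(m, dtype=bool)
    new_chrom[0] = True
    new_chrom[1:] = chroms[1:] != chroms[:-1]

    dosage = np.zeros((n, m), dtype=np.int8)
    for _ in range(2):  # two haplotypes
        eps = rng.standard_normal((n, m))
        z = np.empty((n, m))
        z[:, 0] = eps[:, 0]
        scale = np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            if new_chrom[j]:
                z[:, j] = eps[:, j]
            else:
                z[:, j] = rho * z[:, j - 1] + scale * eps[:, j]
        dosage += (z < thresholds[None, :]).astype(np.int8)

    variant_ids = pd.Index(
        [f"var{c}_{p}" for c, p in zip(chroms, pos)], name="variant_id"
    )
    variants = pd.DataFrame(
        {
            "chrom": chroms.astype(str),
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "rsid": [f"rs{100000 + i}" for i in range(m)],
            "target_maf": mafs,
        },
        index=variant_ids,
    )
    dosages = pd.DataFrame(dosage, index=_sample_ids(n), columns=variant_ids, dtype=np.float64)
    return GenotypeMatrix(dosages=dosages, variants=variants)


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Age, sex, batch, blood-cell counts and differential percentages.

    Differential percentages per sample are Dirichlet draws scaled to
    sum exactly to 100. The first ``round(frac_measured_cells * n)``
    samples are flagged ``cell_measured``; the rest are to be imputed.
    """
    rng = _rng(config, "covariates")
    n = config.n_samples
    ids = _sample_ids(n)

    age = rng.normal(55.0, 10.0, size=n).clip(20.0, 90.0)
    sex = rng.integers(0, 2, size=n)
    batch = rng.integers(0, config.batch_levels, size=n)
    wbc = np.exp(rng.normal(np.log(6.5), 0.25, size=n))  # 10^3 cells/uL
    platelet = np.exp(rng.normal(np.log(250.0), 0.2, size=n))  # 10^3/uL
    diff = rng.dirichlet(_DIFFERENTIAL_MEANS * _DIRICHLET_PRECISION, size=n)
    diff = diff / diff.sum(axis=1, keepdims=True) * 100.0

    n_measured = int(round(config.frac_measured_cells * n))
    measured = np.zeros(n, dtype=bool)
    measured[:n_measured] = True

    table = pd.DataFrame(
        {
            "age": age,
            "sex": np.where(sex == 1, "F", "M"),
            "batch": [f"batch{b}" for b in batch],
            "wbc_count": wbc,
            "platelet_count": platelet,
            "neutrophil_pct": diff[:, 0],
            "lymphocyte_pct": diff[:, 1],
            "monocyte_pct": diff[:, 2],
            "eosinophil_pct": diff[:, 3],
            "basophil_pct": diff[:, 4],
            "cell_measured": measured,
        },
        index=ids,
    )
    return table


def _covariate_signal(
    covariates: pd.DataFrame, rng: np.random.Generator, n_genes: int, sd: float
) -> np.ndarray:
    """Linear confounding of expression by cohort covariates."""
    cols = np.column_stack(
        [
            (covariates["age"] - covariates["age"].mean()) / covariates["age"].std(),
            (covariates["sex"] == "F").astype(float) - 0.5,
            np.log(covariates["wbc_count"]) - np.log(covariates["wbc_count"]).mean(),
            np.log(covariates["platelet_count"]) - np.log(covariates["platelet_count"]).mean(),
            (covariates["neutrophil_pct"] - covariates["neutrophil_pct"].mean()) / 10.0,
            (covariates["lymphocyte_pct"] - covariates["lymphocyte_pct"].mean()) / 10.0,
            (covariates["monocyte_pct"] - covariates["monocyte_pct"].mean()) / 5.0,
            (covariates["eosinophil_pct"] - covariates["eosinophil_pct"].mean()) / 2.0,
        ]
    )
    loadings = rng.normal(0.0, sd, size=(cols.shape[1], n_genes))
    signal = cols @ loadings
    # batch shifts
    batches = pd.Categorical(covariates["batch"])
    shifts = rng.normal(0.0, sd, size=(len(batches.categories), n_genes))
    signal += shifts[batches.codes]
    return signal


def simulate_expression(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, TruthTable]:
    """Expression = covariate confounding + planted genetic effect + noise.

    A fraction of genes receive one cis causal variant (within 1 Mb of
    the TSS, same chromosome) and a disjoint fraction one trans causal
    variant (another chromosome). The planted per-dosage beta is sized
    so the variant explains a drawn fraction ``target_r2`` of the
    non-covariate expression variance.
    """
    if not genotypes.sample_ids.equals(covariates.index):
        raise DataError("genotype and covariate sample sets differ")
    rng = _rng(config, "expression")
    n, g = config.n_samples, config.n_genes
    variants = genotypes.variants

    # gene placement: chromosome, TSS near the simulated variant span
    chrom_choices = variants["chrom"].to_numpy()
    gene_rows = []
    vpos = variants["pos"].to_numpy()
    vchrom = chrom_choices
    for i in range(g):
        j = rng.integers(0, len(vpos))  # anchor near a variant so cis windows are populated
        chrom = vchrom[j]
        tss_pos = int(vpos[j] + rng.integers(-200_000, 200_000))
        tss_pos = max(tss_pos, 1_000)
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(np.exp(rng.normal(np.log(30_000), 0.8)))
        if strand == "+":
            start, end = tss_pos, tss_pos + length
        else:
            start, end = max(tss_pos - length, 1), tss_pos
        gene_rows.append((f"GENE{i:05d}", f"SYM{i:05d}", chrom, strand, start, end))
    annotation = pd.DataFrame(
        gene_rows, columns=["gene_id", "symbol", "chrom", "strand", "start", "end"]
    )
    biotype = np.where(
        np.arange(g) < int(round(config.frac_lncrna * g)), "lncRNA", "protein_coding"
    )
    rng.shuffle(biotype)
    annotation["biotype"] = biotype
    annotation = annotation.set_index("gene_id", drop=False)

    # eGene assignment
    n_cis = int(round(config.frac_cis_egenes * g))
    n_trans = int(round(config.frac_trans_egenes * g))
    order = rng.permutation(g)
    cis_genes = set(order[:n_cis])
    trans_genes = set(order[n_cis : n_cis + n_trans])

    gene_tss = tss(annotation).to_numpy()
    dos = genotypes.dosages.to_numpy()
    dos_sd = dos.std(axis=0, ddof=1)
    common_enough = dos_sd > 1e-6

    lo, hi = config.effect_r2_range
    signal = _covariate_signal(covariates, rng, g, config.covariate_effect_sd)
    noise = rng.normal(0.0, config.noise_sd, size=(n, g))
    expr = signal + noise

    truth_rows = []
    variant_ids = genotypes.dosages.columns.to_numpy()
    for i in range(g):
        causal, beta, target_r2, kind = None, 0.0, 0.0, "none"
        if i in cis_genes or i in trans_genes:
            if i in cis_genes:
                mask = (
                    (vchrom == annotation["chrom"].iloc[i])
                    & (np.abs(vpos - gene_tss[i]) <= 1_000_000)
                    & common_enough
                )
                kind = "cis"
            else:
                mask = (vchrom != annotation["chrom"].iloc[i]) & common_enough
                kind = "trans"
            idx = np.flatnonzero(mask)
            if idx.size:
                j = int(rng.choice(idx))
                causal = variant_ids[j]
                target_r2 = rng.uniform(lo, hi)
                beta = config.noise_sd * np.sqrt(target_r2 / (1.0 - target_r2)) / dos_sd[j]
                expr[:, i] += beta * dos[:, j]
            else:
                kind = "none"
        truth_rows.append(
            (
                annotation["gene_id"].iloc[i],
                annotation["biotype"].iloc[i],
                kind == "cis",
                kind == "trans",
                causal,
                beta,
                target_r2,
            )
        )

    truth_genes = pd.DataFrame(
        truth_rows,
        columns=[
            "gene_id",
            "biotype",
            "is_cis_egene",
            "is_trans_egene",
            "causal_variant",
            "beta",
            "target_r2",
        ],
    ).set_index("gene_id", drop=False)

    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=genotypes.sample_ids, columns=annotation.index.rename("gene_id"))
    )
    return expression, annotation, TruthTable(genes=truth_genes)


def simulate_outcome_gwas(
    truth: TruthTable,
    exposure_stats: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Two-sample outcome GWAS under a known causal effect of expression.

    For each instrument j with exposure effect gamma_j, the outcome
    effect is ``Gamma_j = theta * gamma_j + alpha_j + e_j`` with
    ``e_j ~ N(0, se_j^2)``; ``alpha_j`` is zero for valid instruments
    and ``mr_pleiotropy_alpha`` for the configured invalid fraction.

    ``exposure_stats`` needs columns variant, chrom, pos, effect_allele,
    other_allele, eaf, beta, se (one row per candidate IV). Returns a
    GWAS summary table in the same allele orientation, and records the
    per-IV truth (theta, alpha) on ``truth.instruments``.
    """
    required = {"variant", "beta"}
    missing = required - set(exposure_stats.columns)
    if missing:
        raise DataError(f"exposure stats missing columns {sorted(missing)}")
    if exposure_stats["beta"].isna().any():
        bad = exposure_stats.loc[exposure_stats["beta"].isna(), "variant"].tolist()
        raise DataError(f"missing exposure stat for variants {bad}")
    rng = _rng(config, "outcome_gwas")
    m = len(exposure_stats)
    theta = config.mr_theta
    invalid = rng.random(m) < config.mr_frac_invalid
    alpha = np.where(invalid, config.mr_pleiotropy_alpha, 0.0)
    lo, hi = config.outcome_se_range
    se = rng.uniform(lo, hi, size=m)
    gamma = exposure_stats["beta"].to_numpy(dtype=float)
    big_gamma = theta * gamma + alpha + rng.normal(0.0, se)
    z = np.divide(big_gamma, se, out=np.zeros_like(big_gamma), where=se > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    out = pd.DataFrame(
        {
            "variant": exposure_stats["variant"].to_numpy(),
            "chrom": exposure_stats.get("chrom", pd.Series([""] * m)).to_numpy(),
            "pos": exposure_stats.get("pos", pd.Series([0] * m)).to_numpy(),
            "effect_allele": exposure_stats.get("effect_allele", pd.Series(["A"] * m)).to_numpy(),
            "other_allele": exposure_stats.get("other_allele", pd.Series(["G"] * m)).to_numpy(),
            "eaf": exposure_stats.get("eaf", pd.Series([np.nan] * m)).to_numpy(),
            "beta": big_gamma,
            "se": se,
            "p": p,
        }
    )
    inst = pd.DataFrame(
        {
            "variant_id": out["variant"],
            "gene_id": exposure_stats.get("gene_id", pd.Series([""] * m)).to_numpy(),
            "theta": theta,
            "alpha": alpha,
        }
    )
    truth.instruments = inst
    return out


def simulate_gwas_catalog(
    variants: pd.DataFrame,
    n_traits: int,
    enrichment_spec: dict[str, float] | None = None,
    seed: int = 0,
    eqtl_variants: set[str] | None = None,
    base_rate: float = 0.02,
) -> pd.DataFrame:
    """GWAS-catalog-style (rsid, trait) table with planted enrichment.

    Each variant joins each trait independently with probability
    ``base_rate``; for traits named in ``enrichment_spec`` the odds of
    inclusion are multiplied by the given factor for variants in
    ``eqtl_variants``, so those traits are genuinely over-represented in
    the designated set.
    """
    if len(variants) == 0:
        raise DataError("variant table is empty")
    rng = np.random.default_rng(seed)
    enrichment_spec = enrichment_spec or {}
    rsids = variants["rsid"].to_numpy()
    if eqtl_variants is None:
        eqtl_mask = np.zeros(len(rsids), dtype=bool)
    else:
        eqtl_mask = np.isin(rsids, list(eqtl_variants))
    base_odds = base_rate / (1.0 - base_rate)

    rows: list[tuple[str, str]] = []
    for t in range(n_traits):
        trait = f"trait_{t:04d}"
        odds_mult = enrichment_spec.get(trait, 1.0)
        odds = np.where(eqtl_mask, base_odds * odds_mult, base_odds)
        prob = odds / (1.0 + odds)
        hit = rng.random(len(rsids)) < prob
        rows.extend((r, trait) for r in rsids[hit])
    return pd.DataFrame(rows, columns=["rsid", "trait"])


def simulate_cohort(config: SimulationConfig):
    """Convenience: genotypes, covariates, expression, annotation, truth."""
    genotypes = simulate_genotypes(config)
    covariates = simulate_covariates(config)
    expression, annotation, truth = simulate_expression(genotypes, covariates, config)
    return genotypes, covariates, expression, annotation, truth
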