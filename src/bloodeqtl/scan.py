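"""Genome-wide marginal eQTL scan.

Every retained variant is regressed against every residualized
transcript in a simple (one-predictor) linear model. The scan is
blockwise-vectorized over variants but algebraically identical to the
per-pair ordinary least squares fit:

    beta = cov(g, y) / var(g)
    se   = sqrt(RSS / df / sum((g - mean(g))^2)),  df = n - 2
    t    = beta / se
    r2   = t^2 / (t^2 + df)       (partial variance explained)

Pairs are classified cis (same chromosome, |pos - TSS| <= 1 Mb,
inclusive) or trans; records below the storage threshold (p < 1e-4) are
kept with full statistics, and the total number of tests performed is
returned for inflation and FDR bookkeeping. Extreme p-values are carried
on the log10 scale to avoid underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .config import DataError, ScanConfig
from .datatypes import EQTL_COLUMNS, ExpressionMatrix, GenotypeMatrix, tss

#: null median of a 1-df chi-square, the lambda_GC denominator
CHI2_1DF_NULL_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.454936...

_LOG10 = np.log(10.0)


def filter_variants_by_mac(genotypes: GenotypeMatrix, min_mac: int = 10) -> GenotypeMatrix:
    """Drop variants with minor allele count below ``min_mac``.

    MAC is min(alt count, 2n - alt count), computed from dosages rounded
    to the nearest integer. Dosages outside [0, 2] are rejected.
    """
    d = genotypes.dosages.to_numpy()
    if np.isnan(d).any():
        raise DataError("dosage matrix contains NaN; impute missing genotypes first")
    if d.min() < 0 or d.max() > 2:
        raise DataError("dosages must lie in [0, 2]")
    mac = genotypes.mac()
    keep = mac.index[mac >= min_mac]
    if len(keep) == 0:
        raise DataError("no variants pass MAC filter")
    return genotypes.subset_variants(keep)


def mean_impute(dosages: pd.DataFrame) -> pd.DataFrame:
    """Replace missing dosage calls with the per-variant mean of observed calls."""
    return dosages.fillna(dosages.mean(axis=0))


def classify_pair(variant: pd.Series, gene: pd.Series, cis_window: int = 1_000_000) -> str:
    """cis if same chromosome and |pos - TSS| <= window (inclusive), else trans."""
    strand = str(gene.get("strand", "+"))
    gene_tss = gene["end"] if strand in ("-", "-1") else gene["start"]
    if str(variant["chrom"]) != str(gene["chrom"]):
        return "trans"
    return "cis" if abs(int(variant["pos"]) - int(gene_tss)) <= cis_window else "trans"


@dataclass
class ScanResult:
    """Stored records plus the bookkeeping the scan-wide statistics need."""

    records: pd.DataFrame  # EQTL_COLUMNS
    n_tests: int
    n_cis_tests: int
    n_trans_tests: int
    df: int


def _log10_sf_t(abs_t: np.ndarray, df: int) -> np.ndarray:
    """log10 of the two-sided t-tail, computed on the log scale.

    Where scipy's logsf underflows to -inf at extreme |t|, the tail is
    evaluated through the incomplete-beta series: with a = df/2, b = 1/2
    and x = df/(df + t^2), sf(t) = I_x(a, b)/2 ~ x^a / (2 a B(a, b))
    (first-order series term included), which stays finite for any
    finite t.
    """
    with np.errstate(divide="ignore"):
        logsf = stats.t.logsf(abs_t, df)
    bad = ~np.isfinite(logsf) & np.isfinite(abs_t)
    if np.any(bad):
        t_bad = np.asarray(abs_t, dtype=float)[bad]
        a, b = df / 2.0, 0.5
        logx = np.log(df) - np.log(df + t_bad**2)
        series = np.log1p(a * (1.0 - b) * np.exp(logx) / (a + 1.0))
        logsf[bad] = (
            np.log(0.5) + a * logx - np.log(a) - special.betaln(a, b) + series
        )
    return (logsf + np.log(2.0)) / _LOG10


def scan(
    genotypes: GenotypeMatrix,
    residuals: ExpressionMatrix,
    annotation: pd.DataFrame,
    config: ScanConfig | None = None,
) -> ScanResult:
    """Marginal scan of every variant against every transcript.

    ``residuals`` should be covariate-residualized expression (the scan
    centers both sides, so raw expression is also accepted for
    single-pair uses). ``annotation`` must cover every gene in
    ``residuals`` and provide chrom/strand/start/end for cis/trans
    classification.
    """
    config = config or ScanConfig()
    if not genotypes.sample_ids.equals(residuals.sample_ids):
        raise DataError("genotype and expression sample sets differ")
    missing = residuals.gene_ids.difference(annotation.index)
    if len(missing):
        raise DataError(f"genes missing from annotation: {list(missing[:5])}")

    n = genotypes.n_samples
    df = config.dof(n)

    Y = residuals.values.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise DataError("expression residuals contain NaN")
    Y = Y - Y.mean(axis=0)
    ss_y = (Y**2).sum(axis=0)

    ann = annotation.loc[residuals.gene_ids]
    gene_tss = tss(ann).to_numpy()
    gene_chrom = ann["chrom"].astype(str).to_numpy()
    gene_ids = residuals.gene_ids.to_numpy()

    var_meta = genotypes.variants
    v_pos = var_meta["pos"].to_numpy(dtype=np.int64)
    v_chrom = var_meta["chrom"].astype(str).to_numpy()
    variant_ids = genotypes.dosages.columns.to_numpy()
    eaf_all = genotypes.alt_frequency().to_numpy()

    G_all = genotypes.dosages.to_numpy(dtype=float)
    if np.isnan(G_all).any():
        raise DataError("dosage matrix contains NaN; impute missing genotypes first")

    chunks = []
    n_tests = 0
    n_cis = 0
    m = G_all.shape[1]
    for start in range(0, m, config.block_size):
        stop = min(start + config.block_size, m)
        G = G_all[:, start:stop]
        Gc = G - G.mean(axis=0)
        ss_g = (Gc**2).sum(axis=0)  # MAC filter guarantees > 0
        if np.any(ss_g <= 0):
            raise DataError("zero-variance genotype encountered; apply the MAC filter first")

        xty = Gc.T @ Y  # (v, g)
        beta = xty / ss_g[:, None]
        rss = np.maximum(ss_y[None, :] - beta * xty, 0.0)
        se = np.sqrt(rss / df / ss_g[:, None])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        log10_p = _log10_sf_t(np.abs(t), df)

        n_tests += beta.size
        same_chrom = v_chrom[start:stop, None] == gene_chrom[None, :]
        dist = v_pos[start:stop, None] - gene_tss[None, :]
        cis_mask = same_chrom & (np.abs(dist) <= config.cis_window)
        n_cis += int(cis_mask.sum())

        keep = log10_p < np.log10(config.store_threshold)
        if not keep.any():
            continue
        vi, gi = np.nonzero(keep)
        t_k = t[vi, gi]
        with np.errstate(invalid="ignore"):
            r2_k = np.where(np.isinf(t_k), 1.0, t_k**2 / (t_k**2 + df))
        chunks.append(
            pd.DataFrame(
                {
                    "variant_id": variant_ids[start + vi],
                    "gene_id": gene_ids[gi],
                    "beta": beta[vi, gi],
                    "se": se[vi, gi],
                    "t": t_k,
                    "p": np.power(10.0, np.maximum(log10_p[vi, gi], -300.0)),
                    "log10_p": log10_p[vi, gi],
                    "r2": r2_k,
                    "category": np.where(cis_mask[vi, gi], "cis", "trans"),
                    "tss_distance": np.where(
                        same_chrom[vi, gi], dist[vi, gi].astype(float), np.nan
                    ),
                    "eaf": eaf_all[start + vi],
                }
            )
        )

    if chunks:
        records = pd.concat(chunks, ignore_index=True)[EQTL_COLUMNS]
    else:
        records = pd.DataFrame(columns=EQTL_COLUMNS)
    return ScanResult(
        records=records,
        n_tests=n_tests,
        n_cis_tests=n_cis,
        n_trans_tests=n_tests - n_cis,
        df=df,
    )


def scan_pvalues(
    genotypes: GenotypeMatrix,
    residuals: ExpressionMatrix,
    config: ScanConfig | None = None,
) -> np.ndarray:
    """All p-values of the full (unthresholded) scan, for diagnostics.

    Returns a flat array of length n_variants * n_genes; used for the
    genomic-inflation factor, which needs the complete p distribution.
    """
    config = config or ScanConfig()
    if not genotypes.sample_ids.equals(residuals.sample_ids):
        raise DataError("genotype and expression sample sets differ")
    n = genotypes.n_samples
    df = config.dof(n)
    Y = residuals.values.to_numpy(dtype=float)
    Y = Y - Y.mean(axis=0)
    ss_y = (Y**2).sum(axis=0)
    G_all = genotypes.dosages.to_numpy(dtype=float)
    out = []
    for start in range(0, G_all.shape[1], config.block_size):
        G = G_all[:, start : start + config.block_size]
        Gc = G - G.mean(axis=0)
        ss_g = (Gc**2).sum(axis=0)
        xty = Gc.T @ Y
        beta = xty / ss_g[:, None]
        rss = np.maximum(ss_y[None, :] - beta * xty, 0.0)
        se = np.sqrt(rss / df / ss_g[:, None])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, np.inf)
        out.append((2.0 * stats.t.sf(np.abs(t), df)).ravel())
    return np.concatenate(out)


def genomic_inflation(pvalues=None, t_values=None, df: int | None = None) -> float:
    """Genomic inflation factor lambda_GC.

    Each p-value is mapped to its 1-df chi-square quantile
    ``Q_chi2(1 - p)``; lambda is the median of those over the null
    median 0.45494. p-values of exactly 0 (t-statistic underflow) are
    handled by passing the t-statistics and df instead, in which case
    the chi-square quantiles are computed from the t-tail on the log
    scale.
    """
    if pvalues is not None:
        p = np.asarray(pvalues, dtype=float)
        if p.size == 0:
            raise DataError("empty p-value collection")
        if np.any((p <= 0) | (p > 1)):
            if t_values is None or df is None:
                raise DataError(
                    "p-values of 0 present; supply t_values and df for log-scale handling"
                )
            p = None
    if pvalues is None or p is None:
        if t_values is None or df is None:
            raise DataError("provide pvalues or (t_values, df)")
        logp = stats.t.logsf(np.abs(np.asarray(t_values, dtype=float)), df) + np.log(2.0)
        # chi2.isf on the log scale via the exact p where representable,
        # else the asymptotic identity chi2_1 quantile ~ t^2 at large |t|
        p_safe = np.exp(np.clip(logp, np.log(np.finfo(float).tiny) + 5, 0.0))
        chi2 = stats.chi2.isf(p_safe, 1)
        big = logp < np.log(np.finfo(float).tiny) + 5
        if np.any(big):
            chi2[big] = np.asarray(t_values, dtype=float)[big] ** 2
        return float(np.median(chi2) / CHI2_1DF_NULL_MEDIAN)
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1DF_NULL_MEDIAN)
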