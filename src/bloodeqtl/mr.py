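"""Two-sample Mendelian randomization of gene expression on an outcome.

Instruments are LD-pruned significant cis-eQTL variants of one gene
(exposure side) intersected with outcome GWAS summary statistics. Four
estimators are provided: inverse-variance-weighted (primary), MR-Egger
(directional pleiotropy), weighted median and weighted mode (both with
parametric-bootstrap standard errors). Per-instrument Wald ratios use
the first-order standard error se_Gamma / |gamma| — standard two-sample
practice with genome-wide-significant instruments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigurationError, DataError
from .datatypes import GenotypeMatrix, is_palindromic

logger = logging.getLogger(__name__)

MR_COLUMNS = [
    "gene_id", "method", "n_snps", "beta", "se", "p",
    "Q", "Q_p", "egger_intercept", "egger_intercept_p",
]


@dataclass
class InstrumentSet:
    """Harmonized exposure/outcome effects of one gene's pruned IVs.

    ``table`` columns: variant_id, gamma (exposure beta), se_gamma,
    Gamma (outcome beta), se_Gamma, effect_allele, other_allele, eaf.
    """

    gene_id: str
    table: pd.DataFrame
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.table) and (self.table["se_Gamma"] <= 0).any():
            raise DataError("non-positive outcome standard error in instrument set")

    @property
    def n(self) -> int:
        return len(self.table)


@dataclass
class MrEstimate:
    gene_id: str
    method: str
    n_snps: int
    beta: float
    se: float
    p: float
    Q: float = np.nan
    Q_p: float = np.nan
    egger_intercept: float = np.nan
    egger_intercept_p: float = np.nan

    def as_row(self) -> dict:
        return {k: getattr(self, k if k != "n_snps" else "n_snps") for k in
                ["gene_id", "method", "n_snps", "beta", "se", "p", "Q", "Q_p",
                 "egger_intercept", "egger_intercept_p"]}


def ld_r2(genotypes: GenotypeMatrix, v1: str, v2: str) -> float:
    """Squared Pearson correlation of two variants' dosage columns."""
    a = genotypes.dosages[v1].to_numpy(dtype=float)
    b = genotypes.dosages[v2].to_numpy(dtype=float)
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def select_instruments(
    cis_records: pd.DataFrame,
    genotypes: GenotypeMatrix,
    outcome_gwas: pd.DataFrame,
    r2_threshold: float = 0.1,
) -> pd.DataFrame:
    """Greedy LD pruning of one gene's significant cis-eQTL variants.

    Candidates are intersected with the outcome GWAS variants, sorted by
    exposure p ascending, and kept iff their dosage r^2 with every
    already-kept variant is below ``r2_threshold``. Returns the retained
    exposure records (empty frame if no overlap).
    """
    available = set(outcome_gwas["variant"])
    cand = cis_records[cis_records["variant_id"].isin(available)]
    if cand.empty:
        logger.info("no overlap between cis-eQTLs and outcome GWAS; gene skipped")
        return cand
    cand = cand.sort_values(["log10_p", "variant_id"], kind="stable")
    kept_ids: list[str] = []
    dos = genotypes.dosages
    kept_matrix: list[np.ndarray] = []
    for _, row in cand.iterrows():
        vid = row["variant_id"]
        if vid not in dos.columns:
            continue
        g = dos[vid].to_numpy(dtype=float)
        gc = g - g.mean()
        norm = np.sqrt((gc**2).sum())
        if norm == 0:
            continue
        gc = gc / norm
        if all((gc @ k) ** 2 < r2_threshold for k in kept_matrix):
            kept_ids.append(vid)
            kept_matrix.append(gc)
    return cand[cand["variant_id"].isin(kept_ids)]


def harmonize(
    gene_id: str,
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_eaf_window: tuple[float, float] = (0.42, 0.58),
) -> InstrumentSet:
    """Align outcome effects to the exposure effect allele.

    ``exposure`` columns: variant_id, beta, se, effect_allele,
    other_allele, eaf. ``outcome`` is a GWAS summary table (variant,
    effect_allele, other_allele, beta, se, ...). When the outcome effect
    allele equals the exposure other allele, the outcome beta is negated
    and its alleles swapped. Palindromic (A/T, C/G) variants with eaf in
    the ambiguity window are dropped, as are variants whose allele pairs
    do not match; all drops are logged and returned on ``dropped``.
    """
    out = outcome.set_index("variant")
    rows, dropped = [], []
    lo, hi = palindromic_eaf_window
    for _, e in exposure.iterrows():
        vid = e["variant_id"]
        if vid not in out.index:
            dropped.append({"variant_id": vid, "reason": "absent from outcome"})
            continue
        o = out.loc[vid]
        ea, oa = str(e["effect_allele"]).upper(), str(e["other_allele"]).upper()
        oea, ooa = str(o["effect_allele"]).upper(), str(o["other_allele"]).upper()
        if is_palindromic(ea, oa):
            eaf = float(e.get("eaf", np.nan))
            if np.isnan(eaf) or lo <= eaf <= hi:
                dropped.append({"variant_id": vid, "reason": "palindromic, ambiguous eaf"})
                continue
        if (oea, ooa) == (ea, oa):
            gamma_out = float(o["beta"])
        elif (oea, ooa) == (oa, ea):
            gamma_out = -float(o["beta"])
        else:
            dropped.append({"variant_id": vid, "reason": f"allele mismatch {ea}/{oa} vs {oea}/{ooa}"})
            continue
        rows.append({
            "variant_id": vid,
            "gamma": float(e["beta"]),
            "se_gamma": float(e["se"]),
            "Gamma": gamma_out,
            "se_Gamma": float(o["se"]),
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": float(e.get("eaf", np.nan)),
        })
    for d in dropped:
        logger.info("harmonize(%s): dropped %s (%s)", gene_id, d["variant_id"], d["reason"])
    return InstrumentSet(
        gene_id=gene_id,
        table=pd.DataFrame(rows, columns=["variant_id", "gamma", "se_gamma", "Gamma",
                                          "se_Gamma", "effect_allele", "other_allele", "eaf"]),
        dropped=pd.DataFrame(dropped),
    )


def _ratios_weights(iv_set: InstrumentSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Wald ratios, their first-order ses, and IVW weights; zero-gamma IVs dropped."""
    t = iv_set.table
    gamma = t["gamma"].to_numpy(dtype=float)
    keep = gamma != 0
    if not keep.all():
        logger.warning("dropping %d IVs with zero exposure effect", (~keep).sum())
    gamma = gamma[keep]
    big = t["Gamma"].to_numpy(dtype=float)[keep]
    se_big = t["se_Gamma"].to_numpy(dtype=float)[keep]
    ratios = big / gamma
    ses = se_big / np.abs(gamma)
    weights = 1.0 / ses**2
    return ratios, ses, weights


def mr_ivw(iv_set: InstrumentSet) -> MrEstimate:
    """Fixed-effect inverse-variance-weighted estimate over Wald ratios.

    beta = sum(w_j b_j) / sum(w_j), se = sum(w_j)^-1/2, two-sided normal
    p; Cochran Q = sum w_j (b_j - beta)^2 with chi-square_{J-1} p.
    """
    ratios, _, w = _ratios_weights(iv_set)
    if len(ratios) < 1:
        raise DataError("IVW needs at least one instrument")
    beta = float((w * ratios).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    q = float((w * (ratios - beta) ** 2).sum())
    q_p = float(stats.chi2.sf(q, len(ratios) - 1)) if len(ratios) > 1 else np.nan
    return MrEstimate(iv_set.gene_id, "IVW", len(ratios), beta, se, p, Q=q, Q_p=q_p)


def mr_egger(iv_set: InstrumentSet, min_instruments: int = 3) -> MrEstimate:
    """MR-Egger: weighted regression of Gamma on gamma with an intercept.

    Instruments are reoriented so every gamma is non-negative (flipping
    gamma and Gamma jointly); weights are 1/se_Gamma^2. The slope is the
    causal estimate; a nonzero intercept signals directional pleiotropy.
    p-values from the t distribution with J - 2 df.
    """
    t = iv_set.table
    gamma = t["gamma"].to_numpy(dtype=float)
    keep = gamma != 0
    gamma = gamma[keep]
    big = t["Gamma"].to_numpy(dtype=float)[keep]
    se_big = t["se_Gamma"].to_numpy(dtype=float)[keep]
    j = len(gamma)
    if j < min_instruments:
        raise DataError(f"MR-Egger needs >= {min_instruments} instruments, got {j}")
    flip = np.sign(gamma)
    flip[flip == 0] = 1.0
    x = gamma * flip
    y = big * flip
    w = 1.0 / se_big**2
    X = np.column_stack([np.ones(j), x])
    WX = X * w[:, None]
    xtx = X.T @ WX
    coef = np.linalg.solve(xtx, WX.T @ y)
    resid = y - X @ coef
    df = j - 2
    if df > 0:
        sigma2 = float((w * resid**2).sum() / df)
        # Egger convention: residual dispersion floored at 1 (no underdispersion)
        sigma2 = max(sigma2, 1.0)
        cov = np.linalg.inv(xtx) * sigma2
        se_int, se_slope = np.sqrt(np.diag(cov))
        p_slope = float(2.0 * stats.t.sf(abs(coef[1]) / se_slope, df))
        p_int = float(2.0 * stats.t.sf(abs(coef[0]) / se_int, df))
    else:  # exactly-identified two-point fit (test mode)
        cov = np.linalg.inv(xtx)
        se_int, se_slope = np.sqrt(np.diag(cov))
        p_slope = p_int = np.nan
    q = float((w * resid**2).sum())
    q_p = float(stats.chi2.sf(q, df)) if df > 0 else np.nan
    return MrEstimate(iv_set.gene_id, "Egger", j, float(coef[1]), float(se_slope),
                      p_slope, Q=q, Q_p=q_p,
                      egger_intercept=float(coef[0]), egger_intercept_p=p_int)


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation between order statistics."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w  # midpoint convention
    if cum[0] >= 0.5:
        return float(v[0])
    if cum[-1] <= 0.5:
        return float(v[-1])
    return float(np.interp(0.5, cum, v))


def mr_weighted_median(
    iv_set: InstrumentSet, n_boot: int = 1000, seed: int = 0
) -> MrEstimate:
    """Weighted median of Wald ratios; robust to <50% invalid weight.

    The standard error is a parametric bootstrap: gamma_j and Gamma_j
    are resampled from normals at their estimates, ratios and weights
    recomputed, and the SD of the bootstrap medians reported.
    """
    if n_boot < 100:
        logger.warning("n_boot=%d is small; bootstrap se will be noisy", n_boot)
    ratios, _, w = _ratios_weights(iv_set)
    if len(ratios) < 3:
        raise DataError("weighted median needs >= 3 instruments")
    est = weighted_median(ratios, w)

    t = iv_set.table[iv_set.table["gamma"] != 0]
    gamma = t["gamma"].to_numpy(dtype=float)
    se_gamma = t["se_gamma"].to_numpy(dtype=float)
    big = t["Gamma"].to_numpy(dtype=float)
    se_big = t["se_Gamma"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        g = rng.normal(gamma, se_gamma)
        G = rng.normal(big, se_big)
        g[g == 0] = np.finfo(float).tiny
        r = G / g
        wb = (np.abs(g) / se_big) ** 2
        boots[i] = weighted_median(r, wb)
    se = float(boots.std(ddof=1))
    p = float(2.0 * stats.norm.sf(abs(est) / se)) if se > 0 else (0.0 if est else 1.0)
    return MrEstimate(iv_set.gene_id, "weighted-median", len(ratios), est, se, p)


def _weighted_mode(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float) -> float:
    if np.ptp(ratios) == 0:
        return float(ratios[0])
    w = weights / weights.sum()
    # modified Silverman bandwidth on the ratio dispersion
    sd = ratios.std(ddof=1)
    iqr = np.subtract(*np.percentile(ratios, [75, 25]))
    s = min(sd, iqr / 1.349) if iqr > 0 else sd
    h = bandwidth_factor * 0.9 * s * len(ratios) ** (-0.2)
    if h <= 0:
        return float(ratios[np.argmax(w)])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 2048)
    dens = (w[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2)).sum(axis=0)
    return float(grid[np.argmax(dens)])


def mr_mode(
    iv_set: InstrumentSet,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MrEstimate:
    """Weighted mode: maximum of the IVW-weighted smoothed ratio density.

    Gaussian kernel with a modified-Silverman bandwidth scaled by
    ``bandwidth_factor``; bootstrap standard error as for the weighted
    median. Degenerate (all-equal) ratios return that value exactly.
    """
    ratios, _, w = _ratios_weights(iv_set)
    if len(ratios) < 3:
        raise DataError("mode-based estimator needs >= 3 instruments")
    est = _weighted_mode(ratios, w, bandwidth_factor)

    t = iv_set.table[iv_set.table["gamma"] != 0]
    gamma = t["gamma"].to_numpy(dtype=float)
    se_gamma = t["se_gamma"].to_numpy(dtype=float)
    big = t["Gamma"].to_numpy(dtype=float)
    se_big = t["se_Gamma"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        g = rng.normal(gamma, se_gamma)
        G = rng.normal(big, se_big)
        g[g == 0] = np.finfo(float).tiny
        r = G / g
        wb = (np.abs(g) / se_big) ** 2
        boots[i] = _weighted_mode(r, wb, bandwidth_factor)
    se = float(boots.std(ddof=1))
    p = float(2.0 * stats.norm.sf(abs(est) / se)) if se > 0 else (0.0 if est else 1.0)
    return MrEstimate(iv_set.gene_id, "mode", len(ratios), est, se, p)


def mr_for_genes(
    gene_ids: list[str],
    cis_records: pd.DataFrame,
    exposure_meta: pd.DataFrame,
    genotypes: GenotypeMatrix,
    outcome_gwas: pd.DataFrame,
    r2_threshold: float = 0.1,
    cis_alpha: float = 5e-8,
    heterogeneity_alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Study-wise MR: IVW primary per gene, Bonferroni across tested genes.

    ``cis_records`` is the scan output (all genes); ``exposure_meta``
    maps variant_id -> effect_allele, other_allele, eaf. Per gene: the
    significant cis records are pruned, harmonized, and fed to IVW;
    Egger is attempted whenever J >= 3; if Cochran Q_p < 0.05 the
    weighted-median and mode sensitivity estimators run too (flagged on
    ``heterogeneity``). Genes with no usable instruments are excluded
    from the Bonferroni denominator. The significance flag is
    IVW p < 0.05 / n_genes_tested.
    """
    meta = exposure_meta.set_index("variant_id") if "variant_id" in exposure_meta else exposure_meta
    all_rows: list[dict] = []
    tested_genes: list[str] = []
    for gene in gene_ids:
        recs = cis_records[
            (cis_records["gene_id"] == gene)
            & (cis_records["category"] == "cis")
            & (cis_records["p"] < cis_alpha)
        ]
        if recs.empty:
            continue
        pruned = select_instruments(recs, genotypes, outcome_gwas, r2_threshold)
        if pruned.empty:
            continue
        exposure = pruned.merge(
            meta[["effect_allele", "other_allele", "eaf"]].rename_axis("variant_id"),
            left_on="variant_id", right_index=True, how="left", suffixes=("", "_meta"),
        )
        if "eaf_meta" in exposure:
            exposure["eaf"] = exposure["eaf"].fillna(exposure.pop("eaf_meta"))
        iv_set = harmonize(gene, exposure, outcome_gwas)
        if iv_set.n < 1:
            continue
        tested_genes.append(gene)
        ivw = mr_ivw(iv_set)
        hetero = (not np.isnan(ivw.Q_p)) and ivw.Q_p < heterogeneity_alpha
        rows = [ivw.as_row() | {"heterogeneity": hetero}]
        if iv_set.n >= 3:
            rows.append(mr_egger(iv_set).as_row() | {"heterogeneity": hetero})
            if hetero:
                gene_seed = (seed + zlib_crc(gene)) % (2**31)
                rows.append(
                    mr_weighted_median(iv_set, n_boot=n_boot, seed=gene_seed).as_row()
                    | {"heterogeneity": hetero}
                )
                rows.append(
                    mr_mode(iv_set, n_boot=n_boot, seed=gene_seed + 1).as_row()
                    | {"heterogeneity": hetero}
                )
        all_rows.extend(rows)
    if not all_rows:
        return pd.DataFrame(columns=MR_COLUMNS + ["heterogeneity", "n_genes_tested", "significant"])
    out = pd.DataFrame(all_rows)
    n_tested = len(tested_genes)
    out["n_genes_tested"] = n_tested
    ivw_p = out["method"] == "IVW"
    out["significant"] = ivw_p & (out["p"] < 0.05 / n_tested)
    return out.reset_index(drop=True)


def zlib_crc(s: str) -> int:
    import zlib

    return zlib.crc32(s.encode("utf-8"))
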