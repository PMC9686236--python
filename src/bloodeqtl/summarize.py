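"""Post-scan summaries.

Lead-variant selection per eGene, MAF-binned effect-size quartiles with
a rank trend test, TSS-distance binning, median-R^2 group comparisons
via Mood's median test, cross-study directional concordance, and
partial-correlation analysis of lncRNA/neighbor gene pairs with a
resampling empirical null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigurationError, DataError
from .datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)

#: MAF partition used for effect-size comparisons, ordered common -> rare
MAF_BINS = [
    ("[0.1, 0.5)", 0.1, 0.5),
    ("[0.05, 0.1)", 0.05, 0.1),
    ("[0.01, 0.05)", 0.01, 0.05),
    ("(0.003, 0.01)", 0.003, 0.01),
]

#: |TSS distance| partition for cis leads (upper edges inclusive)
DISTANCE_BINS = [
    ("<=100kb", 0, 100_000),
    ("101-200kb", 100_000, 200_000),
    ("201-500kb", 200_000, 500_000),
    ("501kb-1Mb", 500_000, 1_000_000),
]


@dataclass
class LeadEqtl:
    gene_id: str
    record: pd.Series
    n_tied: int
    selection_seed: int


def select_lead(records: pd.DataFrame, scope: str = "cis", alpha: float | None = None,
                seed: int = 0) -> LeadEqtl | None:
    """Minimal-p record of one gene, ties broken by a seeded uniform draw.

    ``records`` holds one gene's scan records; only rows matching
    ``scope`` (cis/trans) and, if given, passing ``alpha`` are eligible.
    Ties are defined on stored log10 p equal to within 1e-12 (records in
    perfect LD share p exactly). Returns None when nothing is eligible.
    """
    sub = records[records["category"] == scope]
    if alpha is not None:
        sub = sub[sub["p"] < alpha]
    if sub.empty:
        return None
    log10p = sub["log10_p"].to_numpy()
    best = log10p.min()
    tied = np.flatnonzero(np.abs(log10p - best) <= 1e-12)
    rng = np.random.default_rng(seed)
    pick = tied[rng.integers(0, len(tied))] if len(tied) > 1 else tied[0]
    gene_id = str(sub["gene_id"].iloc[0]) if "gene_id" in sub else ""
    return LeadEqtl(gene_id=gene_id, record=sub.iloc[pick], n_tied=len(tied), selection_seed=seed)


def select_leads(records: pd.DataFrame, scope: str, alpha: float, seed: int = 0) -> pd.DataFrame:
    """Lead table over all genes: one row per eGene with >=1 passing record."""
    rows = []
    for gene_id, sub in records.groupby("gene_id", sort=True):
        # per-gene seed derived from the root so leads are order-independent
        gene_seed = (seed + abs(hash_stable(str(gene_id)))) % (2**31)
        lead = select_lead(sub, scope=scope, alpha=alpha, seed=gene_seed)
        if lead is None:
            continue
        row = lead.record.copy()
        row["n_tied"] = lead.n_tied
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=list(records.columns) + ["n_tied"])
    return pd.DataFrame(rows).reset_index(drop=True)


def hash_stable(s: str) -> int:
    """Process-independent string hash (CRC32)."""
    import zlib

    return zlib.crc32(s.encode("utf-8"))


def jonckheere_trend_test(groups: list[np.ndarray]) -> tuple[float, float]:
    """Jonckheere–Terpstra rank trend test across ordered groups.

    Two-sided p from the normal approximation (no tie correction in the
    variance). Sums Mann–Whitney counts over all ordered group pairs.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise DataError("trend test needs at least two non-empty groups")
    j_stat = 0.0
    for i in range(len(groups)):
        for k in range(i + 1, len(groups)):
            a, b = groups[i], groups[k]
            # count of pairs with b > a, ties counted half
            diff = b[None, :] - a[:, None]
            j_stat += (diff > 0).sum() + 0.5 * (diff == 0).sum()
    sizes = np.array([len(g) for g in groups])
    n = sizes.sum()
    mean = (n * n - (sizes**2).sum()) / 4.0
    var = (n * n * (2 * n + 3) - (sizes**2 * (2 * sizes + 3)).sum()) / 72.0
    if var <= 0:
        return j_stat, 1.0
    z = (j_stat - mean) / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def maf_bin_effect_table(leads: pd.DataFrame, bins=None) -> tuple[pd.DataFrame, float]:
    """|beta| quartiles per MAF bin + rank trend test across ordered bins.

    MAF is min(eaf, 1 - eaf); leads with MAF outside (0.003, 0.5) are
    excluded with a warning. Returns (table, trend p). The trend is
    tested common -> rare, so a positive trend means rarer variants have
    larger absolute effects.
    """
    bins = bins or MAF_BINS
    maf = np.minimum(leads["eaf"].to_numpy(dtype=float), 1.0 - leads["eaf"].to_numpy(dtype=float))
    abs_beta = np.abs(leads["beta"].to_numpy(dtype=float))
    out_of_range = (maf <= 0.003) | (maf >= 0.5)
    if out_of_range.any():
        logger.warning("excluding %d leads with MAF outside (0.003, 0.5)", out_of_range.sum())
    rows, groups = [], []
    for label, lo, hi in bins:
        mask = (maf >= lo) & (maf < hi) & ~out_of_range
        vals = abs_beta[mask]
        if len(vals):
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
        else:
            q1 = med = q3 = np.nan
        rows.append({"bin": label, "n": int(mask.sum()), "median_abs_beta": med,
                     "q1_abs_beta": q1, "q3_abs_beta": q3})
        groups.append(vals)
    nonempty = [g for g in groups if len(g)]
    trend_p = np.nan
    if len(nonempty) >= 2:
        _, trend_p = jonckheere_trend_test(groups)
    return pd.DataFrame(rows), trend_p


def mood_median_test(x, y) -> tuple[float, float]:
    """Classical Mood's median test: 2x2 chi-square on the pooled median.

    Counts above vs <= the pooled median per sample; the statistic is
    the 1-df chi-square n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) without
    continuity correction. If all values are identical (degenerate
    table) p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    m = np.median(pooled)
    a, b = int((x > m).sum()), int((x <= m).sum())
    c, d = int((y > m).sum()), int((y <= m).sum())
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    statistic = n * (a * d - b * c) ** 2 / denom
    p = float(stats.chi2.sf(statistic, 1))
    return float(statistic), p


def tss_distance_bins(leads: pd.DataFrame) -> pd.DataFrame:
    """Proportions of cis leads by |TSS distance| bin (edges inclusive above)."""
    dist = np.abs(leads["tss_distance"].to_numpy(dtype=float))
    if np.any(np.isnan(dist)) or np.any(dist > 1_000_000):
        raise DataError("cis lead with missing or >1Mb TSS distance: classification bug")
    rows = []
    total = len(dist)
    for label, lo, hi in DISTANCE_BINS:
        mask = (dist > lo) & (dist <= hi) if lo > 0 else dist <= hi
        rows.append({"bin": label, "n": int(mask.sum()),
                     "proportion": mask.sum() / total if total else np.nan})
    return pd.DataFrame(rows)


def compare_r2_groups(
    leads: pd.DataFrame, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median lead R^2 by (category x biotype) group + Mood contrasts.

    Contrasts: cis vs trans overall; protein_coding vs lncRNA within cis
    and within trans. Groups with fewer than two members skip their
    contrast with a warning.
    """
    df = leads.merge(
        annotation[["biotype"]], left_on="gene_id", right_index=True, how="left"
    )
    medians = (
        df.groupby(["category", "biotype"])["r2"].agg(["median", "count"]).reset_index()
    )
    contrasts = []

    def add_contrast(name, x, y):
        if len(x) < 2 or len(y) < 2:
            logger.warning("skipping contrast %s: group with <2 members", name)
            return
        stat, p = mood_median_test(x, y)
        contrasts.append(
            {"contrast": name, "median_a": float(np.median(x)), "median_b": float(np.median(y)),
             "statistic": stat, "p": p}
        )

    cis = df[df["category"] == "cis"]["r2"].to_numpy()
    trans = df[df["category"] == "trans"]["r2"].to_numpy()
    add_contrast("cis_vs_trans", cis, trans)
    for cat in ("cis", "trans"):
        sub = df[df["category"] == cat]
        add_contrast(
            f"{cat}_protein_coding_vs_lncRNA",
            sub[sub["biotype"] == "protein_coding"]["r2"].to_numpy(),
            sub[sub["biotype"] == "lncRNA"]["r2"].to_numpy(),
        )
    return medians, pd.DataFrame(contrasts)


def directional_concordance(
    results_a: pd.DataFrame, results_b: pd.DataFrame, p_threshold: float
) -> tuple[int, int, float]:
    """Same-sign proportion among pairs significant in both result sets.

    Returns (n_common, n_same_sign, proportion); proportion is NaN when
    there is no overlap.
    """
    key = ["variant_id", "gene_id"]
    a = results_a[results_a["p"] < p_threshold][key + ["beta"]]
    b = results_b[results_b["p"] < p_threshold][key + ["beta"]]
    merged = a.merge(b, on=key, suffixes=("_a", "_b"))
    n_common = len(merged)
    if n_common == 0:
        return 0, 0, float("nan")
    same = int((np.sign(merged["beta_a"]) == np.sign(merged["beta_b"])).sum())
    return n_common, same, same / n_common


def partial_pearson(
    x: np.ndarray, y: np.ndarray, design: pd.DataFrame | np.ndarray | None = None
) -> float:
    """Pearson correlation of OLS residuals of x and y on a covariate design.

    With an empty design this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if design is not None and np.size(design):
        X = np.asarray(design, dtype=float)
        coef_x, *_ = np.linalg.lstsq(X, x, rcond=None)
        coef_y, *_ = np.linalg.lstsq(X, y, rcond=None)
        x = x - X @ coef_x
        y = y - X @ coef_y
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    if denom == 0:
        raise DataError("zero residual variance; partial correlation undefined")
    return float((x * y).sum() / denom)


def lncrna_adjacent_correlation(
    expression: ExpressionMatrix,
    gene_pair: tuple[str, str],
    design: pd.DataFrame | None = None,
) -> float:
    """Partial Pearson correlation of a lncRNA and its neighboring gene."""
    a, b = gene_pair
    for g in (a, b):
        if g not in expression.gene_ids:
            raise DataError(f"gene {g} not in expression matrix")
    return partial_pearson(
        expression.values[a].to_numpy(), expression.values[b].to_numpy(), design
    )


def empirical_pvalue(
    observed_r: float,
    expression: ExpressionMatrix,
    design: pd.DataFrame | None = None,
    n_genes_per_draw: int = 1000,
    n_iterations: int = 500,
    seed: int = 0,
) -> float:
    """Resampling empirical p for a partial correlation.

    Each iteration samples ``n_genes_per_draw`` genes (capped at the
    number available), pairs them at random, and records the partial
    Pearson correlation of each pair. p = (k + 1) / (N + 1) where k is
    the number of null |r| >= |observed_r| — the add-one rule, so finite
    resampling never returns 0.
    """
    if n_iterations < 1:
        raise ConfigurationError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    gene_ids = expression.gene_ids.to_numpy()
    if len(gene_ids) < 2:
        raise DataError("need at least two genes for the resampling null")
    n_draw = min(n_genes_per_draw, len(gene_ids))
    if n_draw % 2:
        n_draw -= 1

    values = expression.values.to_numpy(dtype=float)
    if design is not None and np.size(design):
        X = np.asarray(design, dtype=float)
        coef, *_ = np.linalg.lstsq(X, values, rcond=None)
        values = values - X @ coef
    values = values - values.mean(axis=0)
    norms = np.sqrt((values**2).sum(axis=0))
    norms[norms == 0] = np.nan

    k = 0
    total = 0
    for _ in range(n_iterations):
        idx = rng.choice(len(gene_ids), size=n_draw, replace=False)
        left, right = idx[: n_draw // 2], idx[n_draw // 2 :]
        num = (values[:, left] * values[:, right]).sum(axis=0)
        r = num / (norms[left] * norms[right])
        r = r[~np.isnan(r)]
        k += int((np.abs(r) >= abs(observed_r)).sum())
        total += len(r)
    return (k + 1) / (total + 1)
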