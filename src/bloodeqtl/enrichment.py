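"""Over-representation tests with Benjamini–Hochberg FDR.

Variant-level enrichment of a query set (e.g. significant cis-eQTL
variants) against a trait–SNP table via the two-sided Fisher exact
test, and gene-level over-representation of a top-eGene list against
user-supplied GMT gene sets via the hypergeometric upper tail.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import DataError

ENRICHMENT_COLUMNS = [
    "term", "a", "b", "c", "d", "odds_ratio", "fold_enrichment", "p", "q",
]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order preserved.

    q_(i) = min over j >= i of p_(j) * m / j, clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise DataError("NaN p-value passed to BH correction")
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def _fisher_row(a: int, b: int, c: int, d: int) -> dict:
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    n = a + b + c + d
    query_rate = a / (a + b) if (a + b) else np.nan
    bg_rate = (a + c) / n if n else np.nan
    fold = query_rate / bg_rate if bg_rate else np.nan
    return {"a": a, "b": b, "c": c, "d": d, "odds_ratio": odds,
            "fold_enrichment": fold, "p": float(p)}


def fisher_enrichment(
    query_variants: set[str],
    trait_table: pd.DataFrame,
    universe: set[str],
    rsid_col: str = "rsid",
    trait_col: str = "trait",
) -> pd.DataFrame:
    """Per-trait 2x2 Fisher enrichment of query variants over a universe.

    For each trait: a = |query ∩ trait|, b = |query \\ trait|,
    c = |trait \\ query| (within universe), d = the rest. Two-sided p by
    hypergeometric enumeration (all tables with probability <= the
    observed one). Traits with no universe SNP are skipped. q is BH
    across traits.
    """
    query = set(query_variants)
    universe = set(universe)
    offenders = query - universe
    if offenders:
        raise DataError(f"query variants outside the universe: {sorted(offenders)[:5]}")
    n_univ = len(universe)
    n_query = len(query)
    rows = []
    for trait, sub in trait_table.groupby(trait_col, sort=True):
        members = set(sub[rsid_col]) & universe
        if not members:
            continue
        a = len(members & query)
        b = n_query - a
        c = len(members) - a
        d = n_univ - a - b - c
        row = _fisher_row(a, b, c, d)
        row["term"] = trait
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values("p", kind="stable").reset_index(drop=True)[ENRICHMENT_COLUMNS]


def read_gmt(path: str) -> dict[str, set[str]]:
    """Parse a GMT file: one set per line (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def go_overrepresentation(
    top_genes: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of top genes per term.

    Gene sets are intersected with the universe of tested genes; terms
    with empty intersection are skipped. p is the hypergeometric upper
    tail P(X >= overlap); q is BH across terms.
    """
    universe = set(universe)
    top = set(top_genes) & universe
    n_univ, n_top = len(universe), len(top)
    rows = []
    for term, members in gene_sets.items():
        in_univ = members & universe
        if not in_univ:
            continue
        k_set = len(in_univ)
        a = len(in_univ & top)
        b = n_top - a
        c = k_set - a
        d = n_univ - a - b - c
        p = float(stats.hypergeom.sf(a - 1, n_univ, k_set, n_top))
        query_rate = a / n_top if n_top else np.nan
        bg_rate = k_set / n_univ
        rows.append({"term": term, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": (a * d) / (b * c) if b * c else np.inf,
                     "fold_enrichment": query_rate / bg_rate if bg_rate else np.nan,
                     "p": p})
    if not rows:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values("p", kind="stable").reset_index(drop=True)[ENRICHMENT_COLUMNS]
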