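"""In-memory containers shared across the pipeline.

Thin dataclasses around pandas objects: the DataFrame is the canonical
representation, the wrapper enforces alignment between the value matrix
and its metadata and provides a few derived quantities (MAF, MAC, TSS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DataError

#: columns of the variant metadata table
VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "rsid"]

#: columns of the gene annotation table
ANNOTATION_COLUMNS = ["gene_id", "symbol", "chrom", "strand", "start", "end", "biotype"]

#: columns of an eQTL record table, in output order
EQTL_COLUMNS = [
    "variant_id",
    "gene_id",
    "beta",
    "se",
    "t",
    "p",
    "log10_p",
    "r2",
    "category",
    "tss_distance",
    "eaf",
]

#: columns of a GWAS summary-statistics table
GWAS_COLUMNS = ["variant", "chrom", "pos", "effect_allele", "other_allele", "eaf", "beta", "se", "p"]


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix plus per-variant metadata.

    ``dosages`` rows are sample IDs, columns variant IDs; values are alt
    allele dosages in [0, 2]. ``variants`` is indexed by variant ID with
    columns chrom, pos (1-based), ref, alt, rsid.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.columns.equals(self.variants.index):
            raise DataError("dosage columns and variant metadata index differ")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise DataError(f"variant metadata missing columns {missing}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def alt_frequency(self) -> pd.Series:
        """Alt-allele (effect-allele) frequency per variant."""
        return self.dosages.sum(axis=0) / (2.0 * self.n_samples)

    def maf(self) -> pd.Series:
        f = self.alt_frequency()
        return np.minimum(f, 1.0 - f)

    def mac(self) -> pd.Series:
        """Minor allele count: min(alt count, 2n - alt count), integer."""
        alt = self.dosages.sum(axis=0).round().astype(np.int64)
        return np.minimum(alt, 2 * self.n_samples - alt)

    def subset_variants(self, variant_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages.loc[:, variant_ids],
            variants=self.variants.loc[variant_ids],
        )


@dataclass
class ExpressionMatrix:
    """Samples x transcripts real-valued expression (raw or residualized)."""

    values: pd.DataFrame

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


def tss(annotation: pd.DataFrame) -> pd.Series:
    """Transcription start site: ``start`` on the + strand, ``end`` on -.

    Unknown strand values are treated as '+'.
    """
    strand = annotation["strand"].astype(str)
    minus = strand.isin(["-", "-1"])
    return annotation["end"].where(minus, annotation["start"]).astype(np.int64)


@dataclass
class TruthTable:
    """Ground truth of a simulated cohort, for parameter-recovery tests.

    ``genes``: one row per gene — gene_id, biotype, is_cis_egene,
    is_trans_egene, causal_variant (or NA), beta (planted per-dosage
    effect), target_r2.
    ``instruments``: one row per outcome-GWAS instrument — variant_id,
    gene_id, theta (true causal effect of the gene on the outcome),
    alpha (pleiotropy offset; 0 for valid IVs).
    """

    genes: pd.DataFrame
    instruments: pd.DataFrame = field(default_factory=pd.DataFrame)


PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def is_palindromic(a1: str, a2: str) -> bool:
    return (str(a1).upper(), str(a2).upper()) in PALINDROMIC_PAIRS
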