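import numpy as np
import pandas as pd
import pytest

from bloodeqtl.config import SimulationConfig
from bloodeqtl.datatypes import ExpressionMatrix, GenotypeMatrix
from bloodeqtl.simulate import simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_samples=200, n_variants=600, n_genes=60, seed=42)


@pytest.fixture(scope="session")
def cohort(small_config):
    """One small synthetic cohort shared across read-only tests."""
    genotypes, covariates, expression, annotation, truth = simulate_cohort(small_config)
    return {
        "genotypes": genotypes,
        "covariates": covariates,
        "expression": expression,
        "annotation": annotation,
        "truth": truth,
        "config": small_config,
    }


def make_genotypes(dosages: np.ndarray, chrom="1", pos0=1000, spacing=1000) -> GenotypeMatrix:
    """Hand-built genotype matrix for targeted tests."""
    n, m = dosages.shape
    ids = pd.Index([f"v{j}" for j in range(m)], name="variant_id")
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": [pos0 + j * spacing for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "rsid": [f"rs{j}" for j in range(m)],
        },
        index=ids,
    )
    samples = pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")
    return GenotypeMatrix(pd.DataFrame(dosages, index=samples, columns=ids, dtype=float), variants)


def make_expression(values: np.ndarray, sample_index=None) -> ExpressionMatrix:
    n, g = values.shape
    idx = sample_index if sample_index is not None else pd.Index(
        [f"S{i:04d}" for i in range(n)], name="sample_id"
    )
    cols = pd.Index([f"G{j}" for j in range(g)], name="gene_id")
    return ExpressionMatrix(pd.DataFrame(values, index=idx, columns=cols))


def make_annotation(gene_ids, chrom="1", tss=5000, strand="+") -> pd.DataFrame:
    rows = []
    for g in gene_ids:
        rows.append((g, g, chrom, strand, tss, tss + 10_000))
    ann = pd.DataFrame(rows, columns=["gene_id", "symbol", "chrom", "strand", "start", "end"])
    ann["biotype"] = "protein_coding"
    return ann.set_index("gene_id", drop=False)
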