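"""Reading and writing the pipeline's file formats.

Genotypes travel as minimal VCF 4.2 (GT fields) or as a dosage TSV;
expression, covariates, annotation, GWAS summary statistics, trait-SNP
tables and eQTL records are plain TSV with a one-line header. A JSON
run manifest records the config, per-stage seeds, input digests and
counts, enough to re-run a pipeline bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DataError
from .datatypes import ExpressionMatrix, GenotypeMatrix, VARIANT_COLUMNS

logger = logging.getLogger(__name__)


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as a minimal VCF 4.2 with GT fields.

    Dosages are rounded to {0,1,2} genotypes (0/0, 0/1, 1/1); missing
    dosages become './.'.
    """
    path = Path(path)
    samples = list(genotypes.sample_ids)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        dosages = genotypes.dosages.to_numpy()
        meta = genotypes.variants
        for j, vid in enumerate(genotypes.dosages.columns):
            row = meta.loc[vid]
            calls = []
            for d in dosages[:, j]:
                if np.isnan(d):
                    calls.append("./.")
                else:
                    calls.append(gt_map[int(round(d))])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['rsid']}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def _normalize_contig(c: str) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


def read_genotypes(path: str | Path, multiallelic: str = "skip") -> tuple[GenotypeMatrix, dict]:
    """Read a VCF (GT or DS) or dosage TSV into a GenotypeMatrix.

    Multi-allelic VCF records are skipped (and counted in the returned
    stats dict) under the default policy. Contig names are normalized
    ('chr1' == '1'). Returns (matrix, stats).
    """
    path = Path(path)
    if path.suffix in (".tsv", ".txt"):
        return _read_dosage_tsv(path)
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    dosage_rows, meta_rows, ids = [], [], []
    n_multi = 0
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            if multiallelic == "skip":
                n_multi += 1
                continue
            raise DataError(f"multi-allelic record at line {i + 1} and policy is {multiallelic!r}")
        try:
            try:
                ds = rec.format("DS")
            except KeyError:
                ds = None
            if ds is not None:
                dose = np.asarray(ds, dtype=float).ravel()
            else:
                gts = np.asarray(rec.genotypes)[:, :2]
                dose = np.where((gts < 0).any(axis=1), np.nan, (gts > 0).sum(axis=1)).astype(float)
        except Exception as exc:  # malformed record
            raise DataError(f"malformed VCF record at line {i + 1}: {exc}") from exc
        chrom = _normalize_contig(rec.CHROM)
        vid = f"var{chrom}_{rec.POS}"
        ids.append(vid)
        meta_rows.append((chrom, rec.POS, rec.REF, rec.ALT[0], rec.ID or vid))
        dosage_rows.append(dose)
    if not ids:
        raise DataError(f"no usable biallelic records in {path}")
    idx = pd.Index(ids, name="variant_id")
    variants = pd.DataFrame(meta_rows, columns=VARIANT_COLUMNS, index=idx)
    dosages = pd.DataFrame(
        np.column_stack(dosage_rows), index=pd.Index(samples, name="sample_id"), columns=idx
    )
    return GenotypeMatrix(dosages=dosages, variants=variants), {"n_multiallelic_skipped": n_multi}


def _read_dosage_tsv(path: Path) -> tuple[GenotypeMatrix, dict]:
    """Dosage TSV: metadata columns chrom,pos,ref,alt,rsid then one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_cols = [c for c in VARIANT_COLUMNS if c in df.columns]
    if len(meta_cols) != len(VARIANT_COLUMNS):
        raise DataError(f"dosage TSV must carry columns {VARIANT_COLUMNS}")
    variants = df[meta_cols].copy()
    variants["chrom"] = variants["chrom"].map(_normalize_contig)
    dosages = df.drop(columns=meta_cols).T.astype(float)
    dosages.index.name = "sample_id"
    dosages.columns = variants.index
    return GenotypeMatrix(dosages=dosages, variants=variants), {"n_multiallelic_skipped": 0}


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = pd.concat([genotypes.variants[VARIANT_COLUMNS], genotypes.dosages.T], axis=1)
    df.to_csv(path, sep="\t")


def write_expression_tsv(expression: ExpressionMatrix, path: str | Path) -> None:
    """Expression as genes x samples TSV, header row of sample IDs."""
    expression.values.T.to_csv(path, sep="\t")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.T
    values.index.name = "sample_id"
    values.columns.name = "gene_id"
    return ExpressionMatrix(values)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (Path,)):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
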