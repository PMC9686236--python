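"""End-to-end orchestration of the eQTL + MR analysis.

Stage order: (optional) simulate -> impute blood cells -> genotype and
expression PCs -> residualize -> MAC filter -> genome-wide scan ->
genomic inflation -> lead selection and summaries -> enrichment -> MR.
Each stochastic stage draws its seed from the root seed through a named
substream; the manifest records everything needed to re-run
bit-identically.
"""

from __future__ import annotations

import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .datatypes import GenotypeMatrix
from .enrichment import fisher_enrichment, go_overrepresentation
from .io import (
    write_expression_tsv,
    write_manifest,
    write_table,
    write_vcf,
)
from .mr import mr_for_genes
from .preprocess import prepare_residuals
from .scan import filter_variants_by_mac, genomic_inflation, scan, scan_pvalues
from .simulate import (
    simulate_cohort,
    simulate_gwas_catalog,
    simulate_outcome_gwas,
)
from .summarize import (
    compare_r2_groups,
    maf_bin_effect_table,
    select_leads,
    tss_distance_bins,
)

logger = logging.getLogger(__name__)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    return (root_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on the synthetic cohort and write all outputs.

    Returns the manifest dict (also written to ``manifest.json``).
    Partial outputs are preserved on failure: each stage writes its
    tables as soon as they exist.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    seeds = {s: stage_seed(sim.seed, s) for s in
             ("leads", "mr", "catalog", "empirical")}
    manifest: dict = {
        "software_version": __version__,
        "config": config.to_dict(),
        "seeds": {"root": sim.seed, **seeds},
        "counts": {},
    }

    stage = "simulate"
    try:
        genotypes, covariates, expression, annotation, truth = simulate_cohort(sim)
        write_vcf(genotypes, outdir / "genotypes.vcf")
        write_expression_tsv(expression, outdir / "expression.tsv")
        write_table(covariates, outdir / "covariates.tsv", index=True)
        write_table(annotation.drop(columns=["gene_id"]), outdir / "annotation.tsv", index=True)
        write_table(truth.genes.drop(columns=["gene_id"]), outdir / "truth_genes.tsv", index=True)
        manifest["counts"]["n_samples"] = genotypes.n_samples
        manifest["counts"]["n_variants_simulated"] = genotypes.n_variants
        manifest["counts"]["n_genes"] = expression.n_genes

        stage = "preprocess"
        residuals, covariates, cv_r2, _, _ = prepare_residuals(
            expression,
            covariates,
            genotypes=genotypes,
            n_genotype_pcs=config.n_genotype_pcs,
            n_expression_pcs=config.n_expression_pcs,
            pls_folds=config.pls_folds,
            pls_max_components=config.pls_max_components,
        )
        write_expression_tsv(residuals, outdir / "residuals.tsv")
        if cv_r2 is not None:
            write_table(cv_r2.rename("cv_r2").to_frame(), outdir / "pls_cv_r2.tsv", index=True)

        stage = "mac_filter"
        filtered = filter_variants_by_mac(genotypes, config.scan.min_mac)
        manifest["counts"]["n_variants_mac_pass"] = filtered.n_variants

        stage = "scan"
        result = scan(filtered, residuals, annotation, config.scan)
        write_table(result.records, outdir / "eqtl_records.tsv")
        manifest["counts"]["n_tests"] = result.n_tests
        manifest["counts"]["n_records_stored"] = len(result.records)

        stage = "inflation"
        # full-scan p distribution on the chromosome of median length
        chroms = filtered.variants["chrom"]
        sizes = chroms.value_counts()
        median_chrom = sizes.index[len(sizes) // 2]
        sub = filtered.subset_variants(chroms.index[chroms == median_chrom])
        lam = genomic_inflation(scan_pvalues(sub, residuals, config.scan))
        manifest["lambda_gc"] = lam
        manifest["lambda_gc_chrom"] = str(median_chrom)

        stage = "summarize"
        cis_leads = select_leads(result.records, "cis", config.scan.cis_alpha, seeds["leads"])
        trans_leads = select_leads(result.records, "trans", config.scan.trans_alpha, seeds["leads"])
        write_table(cis_leads, outdir / "cis_leads.tsv")
        write_table(trans_leads, outdir / "trans_leads.tsv")
        manifest["counts"]["n_cis_egenes"] = len(cis_leads)
        manifest["counts"]["n_trans_egenes"] = len(trans_leads)
        if len(cis_leads):
            maf_table, trend_p = maf_bin_effect_table(cis_leads)
            maf_table["trend_p"] = trend_p
            write_table(maf_table, outdir / "cis_maf_bins.tsv")
            write_table(tss_distance_bins(cis_leads), outdir / "cis_distance_bins.tsv")
        all_leads = pd.concat([cis_leads, trans_leads], ignore_index=True)
        if len(all_leads):
            medians, contrasts = compare_r2_groups(all_leads, annotation)
            write_table(medians, outdir / "r2_group_medians.tsv")
            write_table(contrasts, outdir / "r2_group_contrasts.tsv")

        stage = "enrichment"
        if len(cis_leads):
            universe = set(filtered.variants["rsid"])
            sig_cis = result.records[
                (result.records["category"] == "cis")
                & (result.records["p"] < config.scan.cis_alpha)
            ]["variant_id"].unique()
            query = set(filtered.variants.loc[
                filtered.variants.index.isin(sig_cis), "rsid"
            ])
            catalog = simulate_gwas_catalog(
                filtered.variants, n_traits=20, seed=seeds["catalog"],
                eqtl_variants=query,
                enrichment_spec={"trait_0000": 8.0},
            )
            write_table(catalog, outdir / "gwas_catalog.tsv")
            enr = fisher_enrichment(query, catalog, universe)
            write_table(enr, outdir / "trait_enrichment.tsv")
            manifest["counts"]["n_traits_tested"] = len(enr)
            # gene-set over-representation against synthetic sets
            top = cis_leads.sort_values("log10_p").head(config.top_n_egenes)["gene_id"]
            universe_genes = set(annotation.index)
            rng = np.random.default_rng(seeds["catalog"])
            gene_arr = np.array(sorted(universe_genes))
            sets = {
                f"set_{i:03d}": set(rng.choice(gene_arr, size=min(50, len(gene_arr)), replace=False))
                for i in range(10)
            }
            go = go_overrepresentation(set(top), sets, universe_genes)
            write_table(go, outdir / "gene_set_enrichment.tsv")

        stage = "mr"
        sig_cis_records = result.records[
            (result.records["category"] == "cis")
            & (result.records["p"] < config.scan.cis_alpha)
        ]
        mr_genes = sorted(sig_cis_records["gene_id"].unique())
        exposure_meta = filtered.variants.rename(
            columns={"alt": "effect_allele", "ref": "other_allele"}
        )
        exposure_meta["eaf"] = filtered.alt_frequency()
        exposure_meta = exposure_meta.rename_axis("variant_id").reset_index()
        # one exposure row per candidate IV: the lead record per (gene, variant)
        candidates = sig_cis_records.merge(
            exposure_meta[["variant_id", "chrom", "pos", "effect_allele", "other_allele"]],
            on="variant_id",
        )
        outcome = simulate_outcome_gwas(
            truth,
            candidates.rename(columns={"variant_id": "variant"})[
                ["variant", "chrom", "pos", "effect_allele", "other_allele", "eaf", "beta", "gene_id"]
            ].drop_duplicates("variant"),
            sim,
        )
        write_table(outcome, outdir / "outcome_gwas.tsv")
        mr_table = mr_for_genes(
            mr_genes,
            sig_cis_records,
            exposure_meta,
            filtered,
            outcome,
            r2_threshold=config.mr_r2_threshold,
            cis_alpha=config.scan.cis_alpha,
            n_boot=config.mr_n_boot,
            seed=seeds["mr"],
        )
        write_table(mr_table, outdir / "mr_results.tsv")
        manifest["counts"]["n_mr_genes_tested"] = (
            int(mr_table["n_genes_tested"].iloc[0]) if len(mr_table) else 0
        )
    except Exception:
        logger.exception("pipeline failed at stage %r; partial outputs kept in %s", stage, outdir)
        raise

    write_manifest(manifest, outdir / "manifest.json")
    return manifest
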