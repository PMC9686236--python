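"""Configuration objects for simulation, scanning and pipeline runs.

All knobs that downstream stages consume live here, as plain dataclasses
with eager validation, so that a run is fully described by one config plus
one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml


class ConfigurationError(ValueError):
    """A config field is missing, out of range, or inconsistent."""


class DataError(ValueError):
    """Input data violate a precondition (mismatched samples, NaNs, ...)."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic whole-blood cohort.

    The defaults describe a desk-scale cohort with the statistical
    structure the analysis assumes: a MAF spectrum with a rare-variant
    mass, local LD, blood-cell-composition confounding of expression,
    planted cis and trans genetic effects, and batch structure.

    Attributes
    ----------
    n_samples : int
        Number of unrelated individuals (>= 30).
    n_variants : int
        Number of biallelic SNPs spread over ``n_chromosomes``.
    n_genes : int
        Number of expressed transcripts.
    maf_common_beta : (float, float)
        Beta(a, b) law for common minor allele frequencies, truncated to
        (0.01, 0.5).
    frac_rare : float
        Mass of the rare component: MAF drawn uniformly in (0.003, 0.01).
    ld_decay : float
        Latent AR(1) correlation between adjacent variants on a
        chromosome, in [0, 1). 0 means independent variants.
    frac_cis_egenes, frac_trans_egenes : float
        Fractions of genes given one planted cis (resp. trans) causal
        variant.
    effect_r2_range : (float, float)
        Planted effects are parameterized by the partial variance in
        residual expression they explain; drawn uniformly in this range.
    frac_lncrna : float
        Fraction of genes labeled with the lncRNA biotype; the rest are
        protein_coding.
    frac_palindromic : float
        Fraction of variants with strand-ambiguous (A/T or C/G) alleles.
    frac_measured_cells : float
        Fraction of samples with directly measured blood-cell counts; the
        rest are flagged for imputation.
    batch_levels : int
        Number of technical batch levels.
    noise_sd : float
        SD of the residual Gaussian noise on expression.
    covariate_effect_sd : float
        SD of the random loadings of expression on the confounding
        covariates (cell fractions, age, sex, batch).
    n_chromosomes : int
        Chromosomes the variants and genes are spread over.
    mean_variant_spacing : float
        Mean base-pair gap between adjacent variants.
    mr_theta : float
        True causal effect of an exposure gene on the simulated outcome.
    mr_frac_invalid : float
        Fraction of instruments given a pleiotropic offset.
    mr_pleiotropy_alpha : float
        Direct (pleiotropic) effect of each invalid instrument on the
        outcome.
    outcome_se_range : (float, float)
        Uniform law for outcome GWAS standard errors.
    seed : int
        Root seed; fully determines every simulated output.
    """

    n_samples: int = 500
    n_variants: int = 2000
    n_genes: int = 300
    maf_common_beta: tuple[float, float] = (0.8, 2.0)
    frac_rare: float = 0.1
    ld_decay: float = 0.6
    frac_cis_egenes: float = 0.25
    frac_trans_egenes: float = 0.05
    effect_r2_range: tuple[float, float] = (0.05, 0.3)
    frac_lncrna: float = 0.13
    frac_palindromic: float = 0.15
    frac_measured_cells: float = 0.8
    batch_levels: int = 3
    noise_sd: float = 1.0
    covariate_effect_sd: float = 0.3
    n_chromosomes: int = 4
    mean_variant_spacing: float = 1500.0
    mr_theta: float = 0.3
    mr_frac_invalid: float = 0.0
    mr_pleiotropy_alpha: float = 0.05
    outcome_se_range: tuple[float, float] = (0.02, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_rare",
            "frac_cis_egenes",
            "frac_trans_egenes",
            "frac_lncrna",
            "frac_palindromic",
            "frac_measured_cells",
            "mr_frac_invalid",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_samples < 30:
            raise ConfigurationError(f"n_samples must be >= 30, got {self.n_samples}")
        if self.n_variants < 1 or self.n_genes < 1:
            raise ConfigurationError("n_variants and n_genes must be positive")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ConfigurationError(f"ld_decay must be in [0, 1), got {self.ld_decay}")
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be positive, got {self.noise_sd}")
        if self.batch_levels < 1:
            raise ConfigurationError("batch_levels must be >= 1")
        lo, hi = self.effect_r2_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError(f"effect_r2_range must be within (0,1), got {self.effect_r2_range}")
        if self.frac_cis_egenes + self.frac_trans_egenes > 1.0:
            raise ConfigurationError("frac_cis_egenes + frac_trans_egenes must be <= 1")
        if self.n_chromosomes < 1:
            raise ConfigurationError("n_chromosomes must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class ScanConfig:
    """Thresholds and policies of the genome-wide marginal scan.

    ``min_mac`` drops variants with minor allele count below 10;
    cis/trans significance and storage thresholds follow the standard
    whole-blood eQTL conventions (5e-8 cis, 1e-12 trans, records kept at
    p < 1e-4). Degrees of freedom are fixed at n - 2 (simple regression
    of residualized expression on one dosage).
    """

    min_mac: int = 10
    cis_window: int = 1_000_000
    cis_alpha: float = 5e-8
    trans_alpha: float = 1e-12
    store_threshold: float = 1e-4
    df_policy: str = "n-2"
    extra_df_lost: int = 0  # used when df_policy == "n-2-k"
    block_size: int = 2048

    def __post_init__(self) -> None:
        for name in ("cis_alpha", "trans_alpha", "store_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1), got {v}")
        if self.cis_window <= 0:
            raise ConfigurationError("cis_window must be positive")
        if self.min_mac < 0:
            raise ConfigurationError("min_mac must be non-negative")
        if self.df_policy not in ("n-2", "n-2-k"):
            raise ConfigurationError(f"unknown df_policy {self.df_policy!r}")

    def dof(self, n_samples: int) -> int:
        df = n_samples - 2
        if self.df_policy == "n-2-k":
            df -= self.extra_df_lost
        if df < 1:
            raise ConfigurationError(f"non-positive degrees of freedom for n={n_samples}")
        return df

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class PipelineConfig:
    """Top-level configuration: simulation + preprocessing + scan + MR."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    n_genotype_pcs: int = 5
    n_expression_pcs: int = 15
    pls_folds: int = 3
    pls_max_components: int = 10
    mr_r2_threshold: float = 0.1
    mr_n_boot: int = 1000
    top_n_egenes: int = 1000
    fdr_alpha: float = 0.05

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        scan = d.pop("scan", {})
        known = {f for f in cls.__dataclass_fields__ if f not in ("simulation", "scan")}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            simulation=SimulationConfig(**{k: _tuplify(v) for k, v in sim.items()}),
            scan=ScanConfig(**scan),
            **d,
        )

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


def _tuplify(v: Any) -> Any:
    return tuple(v) if isinstance(v, list) else v
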