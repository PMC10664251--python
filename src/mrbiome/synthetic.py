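"""Synthetic GWAS summary statistics with known causal ground truth.

The generator emulates the structure of the real inputs — per-SNP effect
estimates whose standard errors follow from allele frequency and sample
size, a block-structured LD reference, and a hierarchical panel of 211
bacterial taxa over five taxonomic levels — while planting a known causal
effect, pleiotropy regime and outliers, so every pipeline stage can be
validated against truth without downloading consortium data.

Data-generating model (standardized traits):

    gamma_j  ~ per-SNP true effect on the exposure
    alpha_j  ~ pleiotropic direct effect on the outcome
               (0 | Normal(0, sd²) balanced | Normal(mean, sd²) directional)
    beta_out_true,j = theta · gamma_j + alpha_j
    se_j = 1 / sqrt(2·maf_j·(1−maf_j)·N)   per trait
    observed betas = true betas + Normal(0, se_j) noise

which makes the generated records consistent with the
R² = beta²/(beta² + N·SE²) algebra used for instrument strength.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DomainError
from .gwas_io import HarmonizedTable, LDReference, SummaryStatSet

__all__ = [
    "GeneratorConfig",
    "TruthRecord",
    "generate_pair",
    "generate_taxa_panel",
    "plant_outliers",
    "simulate_harmonized_table",
    "taxon_seed",
]

LEVELS = ("phylum", "class", "order", "family", "genus")
DEFAULT_TAXA_COUNTS = {"phylum": 9, "class": 16, "order": 20, "family": 35, "genus": 131}

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]  # non-palindromic


@dataclass
class TruthRecord:
    """Ground truth stored alongside every generated dataset."""

    true_theta: float = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    outlier_snps: list[str] = field(default_factory=list)
    reverse_theta: float = 0.0
    seeds: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigurationError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")


@dataclass
class GeneratorConfig:
    """Shapes and scales of the emulated study.

    Defaults mirror the real data structure: exposure GWAS of 38,602
    individuals, microbiome GWAS of 18,340, and a 211-taxon panel
    (9 phyla, 16 classes, 20 orders, 35 families, 131 genera).  Strong
    instrument effects are planted with |z| drawn from ``strong_z_range``,
    chosen so selected instruments land in the F = z² tens band and the
    F > 10 filter is non-trivial.
    """

    n_snps: int = 200
    n_exposure_sample: int = 38_602
    n_outcome_sample: int = 18_340
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_effect_sd: float = 0.004
    n_strong: int = 12
    strong_z_range: tuple[float, float] = (6.0, 9.0)
    ld_block_size: int = 5
    within_block_r2: float = 0.8
    taxa_counts: dict = field(default_factory=lambda: dict(DEFAULT_TAXA_COUNTS))
    instrument_range: tuple[int, int] = (3, 13)
    binary_outcome: bool = False

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError("maf_range must satisfy 0 < low <= high < 1")
        if self.n_exposure_sample < 1000 or self.n_outcome_sample < 1000:
            raise ConfigurationError("sample sizes must be >= 1000 for SE realism")
        if set(self.taxa_counts) - set(LEVELS):
            raise ConfigurationError(f"taxa_counts keys must be within {LEVELS}")
        if self.n_strong > self.n_snps // self.ld_block_size:
            raise ConfigurationError(
                "n_strong must not exceed the number of LD blocks "
                f"({self.n_snps // self.ld_block_size})"
            )


def taxon_seed(base_seed: int, name: str) -> int:
    """Stable per-taxon seed below 2**31, derived from a base seed."""
    return (int(base_seed) * 1_000_003 + zlib.crc32(name.encode())) % (2**31)


def _se_from_maf(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _snp_map(config: GeneratorConfig, rng: np.random.Generator):
    """SNP ids, alleles, mafs, positions and block ids for the panel.

    SNPs are laid out in LD blocks of ``ld_block_size`` adjacent variants
    1 kb apart; blocks sit 50,000 kb apart (outside any clumping window)
    and cycle through chromosomes 1..22.
    """
    n = config.n_snps
    snp_ids = np.array([f"rs{100000 + i}" for i in range(n)])
    mafs = rng.uniform(*config.maf_range, size=n)
    block = np.arange(n) // config.ld_block_size
    chrom = (block % 22 + 1).astype(str)
    within = np.arange(n) % config.ld_block_size
    pos = (block // 22 + 1) * 50_000_000 + within * 1000
    alleles = np.array([_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(n)])
    return snp_ids, alleles, mafs, chrom, pos, block


def _ld_reference(snp_ids, chrom, pos, block, within_block_r2) -> LDReference:
    pairs = []
    for b in np.unique(block):
        members = snp_ids[block == b]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.append((members[i], members[j], within_block_r2))
    positions = pd.DataFrame({"snp_id": snp_ids, "chrom": chrom, "pos": pos})
    pairs_df = pd.DataFrame(pairs, columns=["snp_id_a", "snp_id_b", "r2"])
    return LDReference(pairs_df, positions)


def _summary_set(name, role, level, snp_ids, alleles, mafs, chrom, pos, beta, se, n):
    z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    records = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": alleles[:, 0],
            "other_allele": alleles[:, 1],
            "eaf": mafs,
            "beta": beta,
            "se": se,
            "pvalue": pval,
            "n": np.full(len(snp_ids), int(n)),
        }
    )
    return SummaryStatSet(trait_name=name, records=records, trait_role=role, taxon_level=level)


def generate_pair(
    config: GeneratorConfig,
    truth: TruthRecord,
    seed: int,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    outcome_level: str = "none",
    n_strong: int | None = None,
) -> tuple[SummaryStatSet, SummaryStatSet, LDReference]:
    """One exposure/outcome pair of summary-stat sets plus an LD reference.

    ``n_strong`` planted instruments (one per LD block, so they survive
    clumping) get |z| ~ Uniform(strong_z_range) effects on the causal trait;
    remaining SNPs carry small Normal(0, exposure_effect_sd²) effects.  With
    ``truth.reverse_theta`` set (and ``true_theta`` 0) the direct effects act
    on the outcome and propagate back to the exposure, flipping the per-SNP
    variance-explained ordering that Steiger filtering tests.
    """
    rng = np.random.default_rng(seed)
    snp_ids, alleles, mafs, chrom, pos, block = _snp_map(config, rng)
    n = config.n_snps
    if n_strong is None:
        n_strong = config.n_strong

    se_exp = _se_from_maf(mafs, config.n_exposure_sample)
    se_out = _se_from_maf(mafs, config.n_outcome_sample)

    reverse = truth.reverse_theta != 0.0 and truth.true_theta == 0.0
    # direct genetic effects act on the exposure (forward) or outcome (reverse)
    driver_se = se_out if reverse else se_exp
    direct = rng.normal(0.0, config.exposure_effect_sd, size=n)
    if n_strong:
        blocks = np.unique(block)
        strong_blocks = rng.choice(blocks, size=n_strong, replace=False)
        idx = np.array([np.flatnonzero(block == b)[0] for b in strong_blocks])
        z = rng.uniform(*config.strong_z_range, size=n_strong)
        sign = rng.choice([-1.0, 1.0], size=n_strong)
        direct[idx] = sign * z * driver_se[idx]

    alpha = np.zeros(n)
    if truth.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, truth.pleiotropy_sd, size=n)
    elif truth.pleiotropy_mode == "directional":
        alpha = rng.normal(truth.pleiotropy_mean, truth.pleiotropy_sd, size=n)

    if reverse:
        beta_out_true = direct
        beta_exp_true = truth.reverse_theta * direct + alpha
    else:
        beta_exp_true = direct
        beta_out_true = truth.true_theta * direct + alpha

    beta_exp = beta_exp_true + rng.normal(0.0, se_exp)
    beta_out = beta_out_true + rng.normal(0.0, se_out)

    exposure = _summary_set(
        exposure_name, "exposure", "none",
        snp_ids, alleles, mafs, chrom, pos, beta_exp, se_exp, config.n_exposure_sample,
    )
    outcome = _summary_set(
        outcome_name, "outcome", outcome_level,
        snp_ids, alleles, mafs, chrom, pos, beta_out, se_out, config.n_outcome_sample,
    )
    ld = _ld_reference(snp_ids, chrom, pos, block, config.within_block_r2)
    truth.seeds.append(int(seed))
    return exposure, outcome, ld


def generate_taxa_panel(
    config: GeneratorConfig,
    seed: int,
    n_causal: int = 2,
    causal_theta: float = 0.3,
    trait_name: str = "nicotine_dependence",
) -> tuple[pd.DataFrame, dict[str, SummaryStatSet], SummaryStatSet, LDReference, dict[str, TruthRecord]]:
    """A hierarchical taxa panel paired with a single (host trait) outcome.

    Returns ``(manifest, taxa_sets, trait_set, ld, truths)``.  The manifest
    has one row per taxon (name, level); per-taxon instrument counts are
    drawn uniformly from ``config.instrument_range`` (default 3–13, the
    observed per-taxon range).  ``n_causal`` randomly chosen taxa have a
    true causal effect ``causal_theta`` on the trait; the rest are null.
    Taxon sets are generated as exposures (taxa → trait direction); each
    taxon's summary set shares the panel-wide SNP map and LD reference.
    """
    rng = np.random.default_rng(seed)
    snp_ids, alleles, mafs, chrom, pos, block = _snp_map(config, rng)
    n = config.n_snps
    n_blocks = n // config.ld_block_size
    if config.instrument_range[1] > n_blocks:
        raise ConfigurationError(
            f"instrument_range upper bound {config.instrument_range[1]} exceeds "
            f"the {n_blocks} available LD blocks; increase n_snps"
        )
    se_taxa = _se_from_maf(mafs, config.n_outcome_sample)
    se_trait = _se_from_maf(mafs, config.n_exposure_sample)

    names, levels = [], []
    for level in LEVELS:
        for i in range(config.taxa_counts.get(level, 0)):
            names.append(f"{level}.Taxon{i + 1:03d}")
            levels.append(level)
    manifest = pd.DataFrame({"taxon_name": names, "level": levels})

    causal = set(rng.choice(len(names), size=min(n_causal, len(names)), replace=False).tolist())
    blocks = np.unique(block)

    taxa_sets: dict[str, SummaryStatSet] = {}
    truths: dict[str, TruthRecord] = {}
    trait_direct = np.zeros(n)  # causal contributions accumulate on the trait

    lo, hi = config.instrument_range
    for t_idx, (name, level) in enumerate(zip(names, levels)):
        t_rng = np.random.default_rng(taxon_seed(seed, name))
        k_inst = int(t_rng.integers(lo, hi + 1))
        gamma = t_rng.normal(0.0, config.exposure_effect_sd, size=n)
        strong_blocks = t_rng.choice(blocks, size=k_inst, replace=False)
        idx = np.array([np.flatnonzero(block == b)[0] for b in strong_blocks])
        z = t_rng.uniform(*config.strong_z_range, size=k_inst)
        sign = t_rng.choice([-1.0, 1.0], size=k_inst)
        gamma[idx] = sign * z * se_taxa[idx]

        beta_obs = gamma + t_rng.normal(0.0, se_taxa)
        taxa_sets[name] = _summary_set(
            name, "exposure", level,
            snp_ids, alleles, mafs, chrom, pos, beta_obs, se_taxa,
            config.n_outcome_sample,
        )
        theta = causal_theta if t_idx in causal else 0.0
        truths[name] = TruthRecord(true_theta=theta, seeds=[int(taxon_seed(seed, name))])
        if theta:
            trait_direct += theta * gamma

    beta_trait = trait_direct + rng.normal(0.0, se_trait)
    trait_set = _summary_set(
        trait_name, "outcome", "none",
        snp_ids, alleles, mafs, chrom, pos, beta_trait, se_trait,
        config.n_exposure_sample,
    )
    ld = _ld_reference(snp_ids, chrom, pos, block, config.within_block_r2)
    return manifest, taxa_sets, trait_set, ld, truths


def plant_outliers(
    table: HarmonizedTable,
    truth: TruthRecord,
    k_outliers: int,
    offset_scale: float = 10.0,
    seed: int = 0,
) -> tuple[HarmonizedTable, TruthRecord]:
    """Add ``offset_scale × se_out`` to ``k_outliers`` random rows' outcome
    effects, recording the affected SNPs in a new TruthRecord."""
    k = len(table)
    if k_outliers >= k / 2:
        raise DomainError(f"k_outliers must be < n_instruments/2 = {k / 2}")
    if k_outliers == 0:
        return table, truth
    rng = np.random.default_rng(seed)
    idx = rng.choice(k, size=k_outliers, replace=False)
    t = table.table.copy()
    t.loc[t.index[idx], "beta_out"] += offset_scale * t.loc[t.index[idx], "se_out"]
    planted = [t.loc[t.index[i], "snp_id"] for i in idx]
    new_truth = replace(
        truth,
        outlier_snps=sorted(set(truth.outlier_snps) | set(planted)),
        seeds=truth.seeds + [int(seed)],
    )
    return HarmonizedTable(table=t, dropped=table.dropped), new_truth


def simulate_harmonized_table(
    n_snp: int,
    theta: float,
    seed: int,
    z_range: tuple[float, float] = (6.0, 9.0),
    n_exposure: int = 38_602,
    n_outcome: int = 18_340,
    maf_range: tuple[float, float] = (0.05, 0.5),
    pleiotropy_mode: str = "none",
    pleiotropy_sd: float = 0.0,
    pleiotropy_mean: float = 0.0,
) -> tuple[HarmonizedTable, TruthRecord]:
    """Directly emulate a post-selection instrument panel.

    Produces a :class:`HarmonizedTable` of ``n_snp`` independent strong
    instruments (|z| ~ Uniform(z_range) on the exposure) without running the
    file-level selection machinery — the fast path for estimator calibration
    studies where thousands of replicates are needed.
    """
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(*maf_range, size=n_snp)
    se_exp = _se_from_maf(mafs, n_exposure)
    se_out = _se_from_maf(mafs, n_outcome)
    z = rng.uniform(*z_range, size=n_snp)
    sign = rng.choice([-1.0, 1.0], size=n_snp)
    gamma = sign * z * se_exp

    alpha = np.zeros(n_snp)
    if pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, pleiotropy_sd, size=n_snp)
    elif pleiotropy_mode == "directional":
        alpha = rng.normal(pleiotropy_mean, pleiotropy_sd, size=n_snp)
    elif pleiotropy_mode != "none":
        raise ConfigurationError(f"unknown pleiotropy_mode {pleiotropy_mode!r}")

    beta_exp = gamma + rng.normal(0.0, se_exp)
    beta_out = theta * gamma + alpha + rng.normal(0.0, se_out)
    table = HarmonizedTable.from_arrays(
        snp_id=[f"rs{100000 + i}" for i in range(n_snp)],
        beta_exp=beta_exp,
        se_exp=se_exp,
        beta_out=beta_out,
        se_out=se_out,
        eaf_exp=mafs,
        n_exp=n_exposure,
        eaf_out=mafs,
        n_out=n_outcome,
    )
    truth = TruthRecord(
        true_theta=theta,
        pleiotropy_mode=pleiotropy_mode,
        pleiotropy_sd=pleiotropy_sd,
        pleiotropy_mean=pleiotropy_mean,
        seeds=[int(seed)],
    )
    return table, truth
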