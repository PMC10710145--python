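"""Synthetic radiogenomic-style study generator.

Emulates the statistical structure the pipeline assumes so every stage is
testable without real data: biallelic SNP genotypes at chosen minor-allele
frequencies under Hardy-Weinberg equilibrium (optionally with a simple
two-subpopulation allele-frequency split for stratification tests), a
continuous phenotype linear in a sparse causal-SNP set plus covariates plus
Gaussian noise, and two or more continuous feature views generated from a
shared low-dimensional latent factor with view-specific loadings and noise —
the factor structure a multi-view autoencoder assumes.

Everything is driven by a single seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gwas import GenotypeMatrix

__all__ = [
    "SimStudyConfig",
    "SimStudy",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_phenotype",
    "simulate_multiview",
    "views_from_latent",
    "make_study",
]

_N_CHROMS = 22


@dataclass
class SimStudyConfig:
    """Study-generator settings.

    Defaults mirror a male osteoporosis-cohort setting: 931 subjects, age /
    weight / height covariates on adult-male scales, a fracture-load-like
    phenotype in Newtons (intercept ~2300 N, residual SD 300 N), and two
    feature views of widths 196 (imaging-like) and 256 (genotype-like).
    """

    n_subjects: int = 931
    n_snps: int = 2000
    maf_range: tuple = (0.05, 0.5)
    n_causal: int = 5
    causal_effect_sd: float = 100.0
    intercept: float = 2320.0
    covariate_effects: tuple = (-10.0, 5.0, 8.0)  # age, weight, height
    noise_sd: float = 300.0
    n_views: int = 2
    latent_dim_true: int = 4
    loadings_sd: float = 1.0
    view_noise_sd: float = 0.3
    view_dims: tuple = (196, 256)
    latent_effects: tuple = (150.0, 150.0, 150.0, 150.0)  # phenotype on latent
    subpop_fraction: float = 0.0
    maf_divergence: float = 0.2
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if len(self.view_dims) != self.n_views:
            raise ValueError("view_dims must have n_views entries")
        if not 0.0 <= self.subpop_fraction <= 1.0:
            raise ValueError("subpop_fraction must lie in [0, 1]")
        if len(self.latent_effects) != self.latent_dim_true:
            raise ValueError("latent_effects must have latent_dim_true entries")


@dataclass
class SimStudy:
    """A generated study: genotypes, covariates, phenotype, views, and the
    ground truth (causal SNPs, effects, latent factors, loadings) needed for
    recovery tests."""

    genotypes: GenotypeMatrix
    covariates: np.ndarray
    covariate_names: list
    phenotype: np.ndarray
    causal_index: np.ndarray
    causal_effects: np.ndarray
    views: list
    latent_true: np.ndarray
    loadings: list
    config: SimStudyConfig = field(repr=False, default=None)


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


def simulate_genotypes(
    n_subjects: int,
    n_snps: int,
    maf_range: tuple = (0.05, 0.5),
    subpop_fraction: float = 0.0,
    maf_divergence: float = 0.0,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Biallelic genotypes as two Bernoulli allele draws per subject/SNP.

    Per-SNP minor-allele frequencies are uniform on ``maf_range``.  If
    ``subpop_fraction`` > 0, that fraction of subjects belongs to a second
    subpopulation whose allele frequencies are shifted by +-
    ``maf_divergence``/2 (clipped to (0.01, 0.99)) — a minimal, controllable
    stand-in for ancestry structure.  Synthetic chromosome/position metadata
    is assigned in ascending order across 22 chromosomes.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie within (0, 0.5]; got ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=n_snps)

    freqs = np.tile(maf, (n_subjects, 1))
    if subpop_fraction > 0.0:
        n_b = int(round(subpop_fraction * n_subjects))
        pop_b = np.zeros(n_subjects, dtype=bool)
        pop_b[n_subjects - n_b:] = True
        shift = maf_divergence / 2.0
        freqs[~pop_b] = np.clip(maf - shift, 0.01, 0.99)
        freqs[pop_b] = np.clip(maf + shift, 0.01, 0.99)

    counts = rng.binomial(2, freqs).astype(float)
    if missing_rate > 0.0:
        counts[rng.random(counts.shape) < missing_rate] = np.nan

    per_chrom = -(-n_snps // _N_CHROMS)
    chrom = 1 + np.arange(n_snps) // per_chrom
    position = 1 + 1000 * (np.arange(n_snps) % per_chrom)
    return GenotypeMatrix(
        counts=counts,
        subject_ids=[f"S{i:05d}" for i in range(n_subjects)],
        variant_ids=[f"snp{j:06d}" for j in range(n_snps)],
        chromosome=chrom,
        position=position,
    )


def simulate_covariates(n_subjects: int, seed: int = 0) -> tuple:
    """Age (years), weight (kg), height (cm) on adult-male cohort scales."""
    rng = np.random.default_rng(seed)
    age = np.clip(rng.normal(36.5, 8.4, n_subjects), 20.0, 51.0)
    weight = np.clip(rng.normal(83.0, 16.7, n_subjects), 50.0, 136.0)
    height = np.clip(rng.normal(175.1, 6.9, n_subjects), 154.0, 198.0)
    return np.column_stack([age, weight, height]), ["age", "weight", "height"]


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    causal_index,
    causal_effects,
    covariates: np.ndarray,
    covariate_effects,
    noise_sd: float,
    seed: int = 0,
    intercept: float = 0.0,
    latent: np.ndarray | None = None,
    latent_effects=None,
) -> np.ndarray:
    """Continuous phenotype linear in causal-SNP counts, covariates and
    (optionally) the shared latent factors, plus Gaussian noise:

        y_i = a0 + sum_c a_c v_c(i) + sum_{j in causal} b_j g_ij
              [+ sum_d c_d z_id] + eps_i,   eps_i ~ N(0, noise_sd^2)
    """
    causal_index = np.asarray(causal_index, dtype=int)
    causal_effects = np.asarray(causal_effects, dtype=float)
    if causal_index.size and (causal_index.min() < 0 or causal_index.max() >= genotypes.n_variants):
        raise ValueError("causal index out of range")
    if causal_index.size != causal_effects.size:
        raise ValueError("causal_index and causal_effects must match in length")
    n = genotypes.n_subjects
    cov = np.asarray(covariates, dtype=float)
    cov_eff = np.asarray(covariate_effects, dtype=float)
    if cov.shape[0] != n or (cov_eff.size and cov.shape[1] != cov_eff.size):
        raise ValueError("covariate dimensions not conformable")

    y = np.full(n, float(intercept))
    if cov_eff.size:
        y += cov @ cov_eff
    if causal_index.size:
        g = np.nan_to_num(genotypes.counts[:, causal_index], nan=0.0)
        y += g @ causal_effects
    if latent is not None and latent_effects is not None:
        y += np.asarray(latent, dtype=float) @ np.asarray(latent_effects, dtype=float)
    rng = np.random.default_rng(seed)
    return y + rng.normal(0.0, noise_sd, n)


def views_from_latent(
    latent: np.ndarray,
    loadings: list,
    view_noise_sd: float,
    seed: int = 0,
) -> list:
    """Feature views ``latent @ L_m + E_m`` for given loading matrices."""
    rng = np.random.default_rng(seed)
    z = np.asarray(latent, dtype=float)
    views = []
    for L in loadings:
        L = np.asarray(L, dtype=float)
        noise = rng.normal(0.0, view_noise_sd, (z.shape[0], L.shape[1])) if view_noise_sd > 0 else 0.0
        views.append(z @ L + noise)
    return views


def simulate_multiview(
    n_subjects: int,
    latent_dim_true: int,
    view_dims,
    loadings_sd: float = 1.0,
    view_noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple:
    """Shared-latent linear-Gaussian views.

    latent_true ~ N(0, I); view_m = latent_true @ L_m + E_m with loadings
    L_m ~ N(0, loadings_sd^2) and noise E_m ~ N(0, view_noise_sd^2).
    Returns (views, latent_true, loadings) so recovery tests can compare
    against ground truth.
    """
    if latent_dim_true < 1 or any(d < 1 for d in view_dims):
        raise ValueError("all dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    latent = rng.normal(size=(n_subjects, latent_dim_true))
    loadings = [rng.normal(0.0, loadings_sd, (latent_dim_true, d)) for d in view_dims]
    noise_seed = int(rng.integers(2**31 - 1))
    views = views_from_latent(latent, loadings, view_noise_sd, seed=noise_seed)
    return views, latent, loadings


def make_study(config: SimStudyConfig) -> SimStudy:
    """Bundle genotypes, covariates, phenotype and views under one seed.

    The phenotype loads on the causal SNPs, the covariates and (by default)
    the shared latent factors, so both the genotype view and the
    latent-generated views carry predictive signal.
    """
    gm = simulate_genotypes(
        config.n_subjects,
        config.n_snps,
        config.maf_range,
        config.subpop_fraction,
        config.maf_divergence,
        seed=int(_stage_rng(config.seed, 0).integers(2**31 - 1)),
        missing_rate=config.missing_rate,
    )
    cov, cov_names = simulate_covariates(
        config.n_subjects, seed=int(_stage_rng(config.seed, 1).integers(2**31 - 1))
    )
    views, latent, loadings = simulate_multiview(
        config.n_subjects,
        config.latent_dim_true,
        config.view_dims,
        config.loadings_sd,
        config.view_noise_sd,
        seed=int(_stage_rng(config.seed, 2).integers(2**31 - 1)),
    )
    rng_c = _stage_rng(config.seed, 3)
    causal_index = np.sort(rng_c.choice(config.n_snps, size=config.n_causal, replace=False))
    causal_effects = rng_c.normal(0.0, config.causal_effect_sd, config.n_causal)
    phenotype = simulate_phenotype(
        gm,
        causal_index,
        causal_effects,
        cov,
        config.covariate_effects,
        config.noise_sd,
        seed=int(_stage_rng(config.seed, 4).integers(2**31 - 1)),
        intercept=config.intercept,
        latent=latent,
        latent_effects=config.latent_effects,
    )
    return SimStudy(
        genotypes=gm,
        covariates=cov,
        covariate_names=cov_names,
        phenotype=phenotype,
        causal_index=causal_index,
        causal_effects=causal_effects,
        views=views,
        latent_true=latent,
        loadings=loadings,
        config=config,
    )
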