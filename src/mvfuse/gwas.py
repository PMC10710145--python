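"""Variant QC, population-structure covariates, and score-test association.

Implements the feature-selection stage of the pipeline: genotype quality
control (variant missingness, Hardy-Weinberg exact test, minor allele
frequency, subject missingness), genotype PCA for population stratification,
covariate residualization of phenotype and genotype, the score test

    T = U^2 / V,   U = sum_i y~_i g~_i,   V = (1/N) sum_i y~_i^2 sum_i g~_i^2,

with y~ and g~ the residuals of phenotype and genotype after linear
adjustment for covariates, and selection of the top-K variants by p-value.

P-values are taken from the upper tail of a chi-square(1) distribution at T,
the standard score-test convention (equivalent to a two-sided normal test on
U/sqrt(V)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

__all__ = [
    "GenotypeMatrix",
    "QCThresholds",
    "QCReport",
    "CovariateSet",
    "AssociationRecord",
    "compute_missing_rates",
    "hwe_exact_p",
    "compute_maf",
    "qc_filter",
    "genotype_pca",
    "residualize",
    "score_test",
    "run_gwas",
    "select_top_k",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """N x S matrix of minor-allele counts with variant metadata.

    ``counts`` is a float array; missing genotypes are ``NaN``.  Entries must
    otherwise lie in {0, 1, 2}.  ``chromosome`` is an integer label per
    variant and ``position`` a 1-based coordinate, nondecreasing within each
    chromosome.
    """

    counts: np.ndarray
    subject_ids: list
    variant_ids: list
    chromosome: np.ndarray
    position: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.chromosome = np.asarray(self.chromosome)
        self.position = np.asarray(self.position)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D subjects x variants matrix")
        n, s = self.counts.shape
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match counts rows")
        if len(self.variant_ids) != s:
            raise ValueError("variant_ids length does not match counts columns")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject ids")
        if len(set(self.variant_ids)) != s:
            raise ValueError("duplicate variant ids")
        obs = self.counts[~np.isnan(self.counts)]
        if obs.size and not np.isin(obs, [0.0, 1.0, 2.0]).all():
            raise ValueError("genotype counts must be in {0, 1, 2} or missing")
        for c in np.unique(self.chromosome):
            pos = self.position[self.chromosome == c]
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions decrease within chromosome {c}")

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[0]

    @property
    def n_variants(self) -> int:
        return self.counts.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.counts)

    def take_subjects(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.counts[idx],
            [self.subject_ids[i] for i in idx],
            self.variant_ids,
            self.chromosome,
            self.position,
        )

    def take_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.counts[:, idx],
            self.subject_ids,
            [self.variant_ids[i] for i in idx],
            self.chromosome[idx],
            self.position[idx],
        )


@dataclass
class QCThresholds:
    """QC cut-offs: variant missing rate > 5%, HWE exact p < 1e-4,
    MAF < 5%, subject missing rate > 20% are removed by default."""

    variant_missing_max: float = 0.05
    hwe_p_min: float = 1e-4
    maf_min: float = 0.05
    subject_missing_max: float = 0.20

    def __post_init__(self):
        for name in ("variant_missing_max", "hwe_p_min", "maf_min", "subject_missing_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class QCReport:
    removed_subjects: list = field(default_factory=list)  # (id, reasons, stats)
    removed_variants: list = field(default_factory=list)

    @property
    def n_removed_subjects(self) -> int:
        return len(self.removed_subjects)

    @property
    def n_removed_variants(self) -> int:
        return len(self.removed_variants)


@dataclass
class CovariateSet:
    """Covariates used for adjustment (age, weight, height, PCs...).

    ``matrix`` is N x C without an intercept column; an intercept is always
    prepended during residualization.
    """

    matrix: np.ndarray
    names: list

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] < 1:
            raise ValueError("covariate matrix must be N x C with C >= 1")
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("names length does not match covariate columns")
        if np.isnan(self.matrix).any():
            raise ValueError("covariates must not contain missing entries")


@dataclass
class AssociationRecord:
    variant_id: str
    U: float
    V: float
    T: float
    p: float
    flagged: bool = False


# ---------------------------------------------------------------------------
# QC statistics
# ---------------------------------------------------------------------------

def compute_missing_rates(genotypes: GenotypeMatrix):
    """Per-variant and per-subject proportions of missing genotype calls."""
    mask = genotypes.missing_mask
    if mask.size == 0:
        raise ValueError("empty genotype matrix")
    variant_rates = mask.mean(axis=0)
    subject_rates = mask.mean(axis=1)
    return variant_rates, subject_rates


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg equilibrium test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count (same subject and minor-allele totals) whose
    conditional probability does not exceed that of the observed count.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one subject required for the HWE exact test")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    # attainable heterozygote counts share the parity of the minor-allele count
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    homs_minor = (n_minor - hs) // 2
    homs_major = n - hs - homs_minor
    # log P(het = h | n, n_minor) up to a common constant:
    #   n! 2^h / (hom_minor! h! hom_major!)  over  (2n)! / (n_minor! n_major!)
    logp = hs * math.log(2.0) - (
        gammaln(homs_minor + 1) + gammaln(hs + 1) + gammaln(homs_major + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hs == n_Aa][0]
    # tiny relative slack guards against ties lost to rounding
    p = probs[probs <= obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def compute_maf(genotype_column: np.ndarray) -> float:
    """Minor allele frequency of one variant, ignoring missing calls."""
    col = np.asarray(genotype_column, dtype=float)
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        raise ValueError("cannot compute MAF: all genotypes missing")
    freq = obs.sum() / (2.0 * obs.size)
    return float(min(freq, 1.0 - freq))


def _hwe_p_column(col: np.ndarray) -> float:
    obs = col[~np.isnan(col)]
    n_AA = int((obs == 0).sum())
    n_Aa = int((obs == 1).sum())
    n_aa = int((obs == 2).sum())
    return hwe_exact_p(n_AA, n_Aa, n_aa)


def qc_filter(genotypes: GenotypeMatrix, thresholds: QCThresholds | None = None):
    """Apply subject- then variant-level QC; returns (filtered, QCReport).

    Subjects with missing rate above ``subject_missing_max`` are dropped
    first; variant statistics (missing rate, HWE, MAF) are then recomputed on
    the retained subjects.  A variant failing several rules is listed once
    with every reason.
    """
    thresholds = thresholds or QCThresholds()
    report = QCReport()

    _, subj_rates = compute_missing_rates(genotypes)
    keep_subj = subj_rates <= thresholds.subject_missing_max
    for i in np.flatnonzero(~keep_subj):
        report.removed_subjects.append(
            (genotypes.subject_ids[i], ["missing"], {"missing_rate": float(subj_rates[i])})
        )
    gm = genotypes.take_subjects(np.flatnonzero(keep_subj))
    if gm.n_subjects == 0:
        raise ValueError("QC removed every subject")

    var_rates, _ = compute_missing_rates(gm)
    keep_var = np.ones(gm.n_variants, dtype=bool)
    for j in range(gm.n_variants):
        reasons, stats = [], {"missing_rate": float(var_rates[j])}
        if var_rates[j] > thresholds.variant_missing_max:
            reasons.append("missing")
        col = gm.counts[:, j]
        if var_rates[j] < 1.0:
            maf = compute_maf(col)
            hwe_p = _hwe_p_column(col)
            stats.update(maf=maf, hwe_p=hwe_p)
            if hwe_p < thresholds.hwe_p_min:
                reasons.append("hwe")
            if maf < thresholds.maf_min:
                reasons.append("maf")
        if reasons:
            keep_var[j] = False
            report.removed_variants.append((gm.variant_ids[j], reasons, stats))
    if not keep_var.any():
        raise ValueError("QC removed every variant")
    return gm.take_variants(np.flatnonzero(keep_var)), report


# ---------------------------------------------------------------------------
# Population structure
# ---------------------------------------------------------------------------

def mean_impute(counts: np.ndarray) -> np.ndarray:
    """Replace missing genotype calls by the per-variant mean count."""
    out = np.array(counts, dtype=float)
    mask = np.isnan(out)
    if mask.any():
        col_means = np.nanmean(out, axis=0)
        out[mask] = np.take(col_means, np.nonzero(mask)[1])
    return out


def genotype_pca(genotypes: GenotypeMatrix, k: int) -> np.ndarray:
    """Top-k principal-component scores of the standardized genotype matrix.

    Missing calls are mean-imputed; each variant is centered at 2*p_hat and
    scaled by sqrt(2*p_hat*(1 - p_hat)) (the usual allele-frequency scaling).
    The sign of each PC is fixed so its largest-magnitude variant loading is
    positive.
    """
    if k > min(genotypes.n_subjects, genotypes.n_variants):
        raise ValueError("k exceeds matrix rank bound")
    x = mean_impute(genotypes.counts)
    p_hat = x.mean(axis=0) / 2.0
    scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    informative = scale > 0
    if not informative.any():
        raise ValueError("zero-variance genotype matrix: PCA undefined")
    z = (x[:, informative] - 2.0 * p_hat[informative]) / scale[informative]
    if not np.any(np.abs(z - z[0]) > 0):
        raise ValueError("all subjects identical: PCA undefined")
    u, s, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    scores = u[:, :k] * s[:k]
    for d in range(min(k, vt.shape[0])):
        lead = vt[d, np.argmax(np.abs(vt[d]))]
        if lead < 0:
            scores[:, d] = -scores[:, d]
    return scores


# ---------------------------------------------------------------------------
# Association testing
# ---------------------------------------------------------------------------

def _design(covariates: CovariateSet) -> np.ndarray:
    X = np.column_stack([np.ones(covariates.matrix.shape[0]), covariates.matrix])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the first column linearly dependent on its predecessors
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                name = covariates.names[j - 1]
                raise ValueError(f"rank-deficient covariates: column '{name}' is redundant")
    return X


def residualize(values: np.ndarray, covariates: CovariateSet | None) -> np.ndarray:
    """Residuals of ``values`` after least-squares adjustment for covariates
    (intercept included); ``covariates=None`` means intercept-only, i.e.
    mean removal."""
    y = np.asarray(values, dtype=float)
    if covariates is None:
        return y - y.mean()
    X = _design(covariates)
    if y.shape[0] <= X.shape[1]:
        raise ValueError("need more subjects than covariates (plus intercept)")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def score_test(y_res: np.ndarray, g_res: np.ndarray) -> AssociationRecord:
    """Score test on covariate-adjusted residuals.

    U = sum y~ g~, V = (1/N) * sum(y~^2) * sum(g~^2), T = U^2 / V; the
    p-value is the chi-square(1) upper tail at T.
    """
    y = np.asarray(y_res, dtype=float)
    g = np.asarray(g_res, dtype=float)
    n = y.shape[0]
    if n < 3 or g.shape[0] != n:
        raise ValueError("residual vectors must share length N >= 3")
    syy = float(y @ y)
    sgg = float(g @ g)
    if syy == 0.0 or sgg == 0.0:
        return AssociationRecord("", U=0.0, V=0.0, T=0.0, p=1.0, flagged=True)
    U = float(y @ g)
    V = syy * sgg / n
    T = U * U / V
    p = float(chi2.sf(T, df=1))
    return AssociationRecord("", U=U, V=V, T=T, p=max(p, np.finfo(float).tiny))


def run_gwas(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    covariates: CovariateSet,
) -> pd.DataFrame:
    """Score-test association of every variant with the phenotype.

    The phenotype is residualized once; each mean-imputed genotype column is
    residualized against the same covariates.  Returns a table with columns
    variant_id, chrom, pos, U, V, T, p, sorted by p (ties by chrom, pos).
    """
    y = np.asarray(phenotype, dtype=float)
    if y.shape[0] != genotypes.n_subjects:
        raise ValueError("phenotype length does not match genotype subjects")
    X = _design(covariates)
    if X.shape[0] != y.shape[0]:
        raise ValueError("covariate rows do not match genotype subjects")
    q, _ = np.linalg.qr(X)
    y_res = y - q @ (q.T @ y)
    G = mean_impute(genotypes.counts)
    G_res = G - q @ (q.T @ G)

    n = y.shape[0]
    syy = float(y_res @ y_res)
    sgg = np.einsum("ij,ij->j", G_res, G_res)
    U = G_res.T @ y_res
    V = syy * sgg / n
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(V > 0, U * U / np.where(V > 0, V, 1.0), 0.0)
    p = chi2.sf(T, df=1)
    p = np.where((V > 0) & (syy > 0), np.maximum(p, np.finfo(float).tiny), 1.0)

    table = pd.DataFrame(
        {
            "variant_id": genotypes.variant_ids,
            "chrom": genotypes.chromosome,
            "pos": genotypes.position,
            "U": U,
            "V": V,
            "T": T,
            "p": p,
        }
    )
    return table.sort_values(["p", "chrom", "pos"], kind="mergesort").reset_index(drop=True)


def select_top_k(table: pd.DataFrame, genotypes: GenotypeMatrix, k: int = 256):
    """The k variants with smallest p (ties by chromosome then position) and
    their mean-imputed genotype columns in selection order."""
    if table.empty:
        raise ValueError("empty association table")
    if k > len(table):
        raise ValueError(f"k={k} exceeds table size {len(table)}")
    ordered = table.sort_values(["p", "chrom", "pos"], kind="mergesort")
    ids = ordered["variant_id"].head(k).tolist()
    col_of = {v: j for j, v in enumerate(genotypes.variant_ids)}
    cols = [col_of[v] for v in ids]
    features = mean_impute(genotypes.counts)[:, cols]
    return ids, features
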