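"""QC statistics, HWE exact test, PCA, residualization and the score test."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import pearsonr

from mvfuse.gwas import (
    CovariateSet,
    GenotypeMatrix,
    QCThresholds,
    compute_maf,
    compute_missing_rates,
    genotype_pca,
    hwe_exact_p,
    qc_filter,
    residualize,
    run_gwas,
    score_test,
    select_top_k,
)
from mvfuse.synthetic import simulate_genotypes


# ---------------------------------------------------------------------------
# Missing rates and MAF
# ---------------------------------------------------------------------------

def test_missing_rates_zero_when_complete():
    gm = simulate_genotypes(10, 5, seed=0)
    var_r, subj_r = compute_missing_rates(gm)
    assert (var_r == 0).all() and (subj_r == 0).all()


def test_missing_rates_hand_count():
    gm = GenotypeMatrix(
        np.array([[0.0, np.nan], [1.0, 2.0]]),
        ["s1", "s2"], ["v1", "v2"], np.array([1, 1]), np.array([1, 2]),
    )
    var_r, subj_r = compute_missing_rates(gm)
    assert var_r.tolist() == [0.0, 0.5]
    assert subj_r.tolist() == [0.5, 0.0]


def test_missing_rates_fully_missing_subject():
    gm = GenotypeMatrix(
        np.array([[np.nan, np.nan], [1.0, 2.0]]),
        ["s1", "s2"], ["v1", "v2"], np.array([1, 1]), np.array([1, 2]),
    )
    _, subj_r = compute_missing_rates(gm)
    assert subj_r[0] == 1.0


@pytest.mark.parametrize(
    "col, expected",
    [
        ([0, 0, 0, 0], 0.0),
        ([0, 1, 2, 2], 0.375),  # 5/8 folds to 3/8
        ([1, 1], 0.5),
    ],
)
def test_maf_examples(col, expected):
    assert compute_maf(np.asarray(col, dtype=float)) == pytest.approx(expected)


def test_maf_ignores_missing_and_rejects_all_missing():
    assert compute_maf(np.array([0.0, np.nan, 2.0])) == 0.5
    with pytest.raises(ValueError):
        compute_maf(np.array([np.nan, np.nan]))


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Exact-rational enumeration of every heterozygote count consistent
    with the observed allele totals; independent of the gammaln route."""
    n = n_AA + n_Aa + n_aa
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    weights = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        weights[h] = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(hom_minor) * math.factorial(h) * math.factorial(hom_major),
        )
    total = sum(weights.values())
    obs = weights[n_Aa]
    return float(sum(w for w in weights.values() if w <= obs) / total)


def test_hwe_monomorphic_is_one():
    assert hwe_exact_p(7, 0, 0) == 1.0
    assert hwe_exact_p(0, 0, 7) == 1.0


def test_hwe_two_subjects_two_minor_alleles():
    # attainable het counts {0, 2} with probabilities 2/6 and 4/6;
    # the observed (2 hets) is the more probable outcome
    assert hwe_exact_p(0, 2, 0) == pytest.approx(1.0)
    assert hwe_exact_p(1, 0, 1) == pytest.approx(2.0 / 6.0)


@pytest.mark.parametrize("seed", range(5))
def test_hwe_matches_enumeration_oracle_random_tables(seed, rng=None):
    r = np.random.default_rng(seed)
    for _ in range(50):
        n = int(r.integers(1, 31))
        n_AA = int(r.integers(0, n + 1))
        n_Aa = int(r.integers(0, n - n_AA + 1))
        n_aa = n - n_AA - n_Aa
        assert hwe_exact_p(n_AA, n_Aa, n_aa) == pytest.approx(
            hwe_enumeration_oracle(n_AA, n_Aa, n_aa), rel=1e-10
        )


def test_hwe_rejects_empty():
    with pytest.raises(ValueError):
        hwe_exact_p(0, 0, 0)


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

def test_qc_clean_data_untouched():
    gm = simulate_genotypes(200, 20, maf_range=(0.3, 0.3), seed=1)
    filtered, report = qc_filter(gm, QCThresholds())
    assert filtered.n_variants == 20 and filtered.n_subjects == 200
    assert report.n_removed_subjects == 0 and report.n_removed_variants == 0


def test_qc_monomorphic_removed_for_maf():
    gm = simulate_genotypes(100, 5, maf_range=(0.3, 0.3), seed=2)
    counts = gm.counts.copy()
    counts[:, 2] = 0.0
    gm = GenotypeMatrix(counts, gm.subject_ids, gm.variant_ids,
                        gm.chromosome, gm.position)
    filtered, report = qc_filter(gm)
    removed = {v: reasons for v, reasons, _ in report.removed_variants}
    assert removed == {gm.variant_ids[2]: ["maf"]}
    assert filtered.n_variants == 4


def test_qc_variant_failing_two_rules_listed_once_with_both():
    gm = simulate_genotypes(100, 30, maf_range=(0.3, 0.3), seed=3)
    counts = gm.counts.copy()
    # rare variant that is also wildly out of HWE: two hom-alt carriers only
    counts[:, 1] = 0.0
    counts[:2, 1] = 2.0
    counts[10:17, 1] = np.nan  # and 7% missing
    gm = GenotypeMatrix(counts, gm.subject_ids, gm.variant_ids,
                        gm.chromosome, gm.position)
    _, report = qc_filter(gm)
    entries = [e for e in report.removed_variants if e[0] == gm.variant_ids[1]]
    assert len(entries) == 1
    assert set(entries[0][1]) == {"missing", "hwe", "maf"}


def test_qc_subject_filter_runs_first():
    gm = simulate_genotypes(50, 10, maf_range=(0.4, 0.4), seed=4)
    counts = gm.counts.copy()
    counts[0, :] = np.nan  # fully missing subject
    gm = GenotypeMatrix(counts, gm.subject_ids, gm.variant_ids,
                        gm.chromosome, gm.position)
    filtered, report = qc_filter(gm)
    assert report.n_removed_subjects == 1
    # after dropping the subject, the variants carry no missingness
    assert report.n_removed_variants == 0
    assert filtered.n_subjects == 49


def test_qc_idempotent():
    gm = simulate_genotypes(150, 30, maf_range=(0.05, 0.5), seed=5,
                            missing_rate=0.03)
    once, _ = qc_filter(gm)
    twice, report = qc_filter(once)
    assert report.n_removed_subjects == 0 and report.n_removed_variants == 0
    assert np.array_equal(once.counts, twice.counts, equal_nan=True)


def test_qc_all_removed_is_error():
    gm = GenotypeMatrix(
        np.zeros((20, 2)), [f"s{i}" for i in range(20)], ["v1", "v2"],
        np.array([1, 1]), np.array([1, 2]),
    )
    with pytest.raises(ValueError, match="every variant"):
        qc_filter(gm)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_separates_subpopulations():
    gm = simulate_genotypes(300, 500, maf_range=(0.1, 0.5),
                            subpop_fraction=0.5, maf_divergence=0.2, seed=6)
    scores = genotype_pca(gm, 2)
    labels = np.zeros(300)
    labels[150:] = 1.0
    r, _ = pearsonr(scores[:, 0], labels)
    assert abs(r) > 0.9


def test_pca_rejects_constant_matrix():
    gm = GenotypeMatrix(
        np.ones((10, 4)), [f"s{i}" for i in range(10)],
        [f"v{j}" for j in range(4)], np.ones(4, dtype=int), np.arange(1, 5),
    )
    with pytest.raises(ValueError):
        genotype_pca(gm, 2)


def test_pca_scores_orthogonal():
    gm = simulate_genotypes(120, 200, seed=7)
    scores = genotype_pca(gm, 5)
    gram = scores.T @ scores
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8


def test_pca_invariant_to_variant_reordering():
    gm = simulate_genotypes(80, 100, seed=8)
    perm = np.random.default_rng(0).permutation(100)
    # rebuild with permuted columns but fresh ascending metadata: PCA must
    # not depend on variant order
    gm_perm = GenotypeMatrix(
        gm.counts[:, perm], gm.subject_ids,
        [gm.variant_ids[j] for j in perm],
        np.ones(100, dtype=int), np.arange(1, 101),
    )
    scores_a = genotype_pca(gm, 3)
    scores_b = genotype_pca(gm_perm, 3)
    assert np.allclose(scores_a, scores_b, atol=1e-8)


# ---------------------------------------------------------------------------
# Residualization and score test
# ---------------------------------------------------------------------------

def test_residualize_intercept_only_is_mean_removal():
    res = residualize(np.array([1.0, 2.0, 3.0]), None)
    assert np.allclose(res, [-1.0, 0.0, 1.0])


def test_residualize_perfect_fit():
    x = np.linspace(0, 1, 10)
    cov = CovariateSet(x.reshape(-1, 1), ["x"])
    assert np.allclose(residualize(x, cov), 0.0, atol=1e-12)


def test_residualize_matches_normal_equations(rng):
    n, c = 50, 4
    C = rng.normal(size=(n, c))
    y = rng.normal(size=n)
    cov = CovariateSet(C, [f"c{i}" for i in range(c)])
    X = np.column_stack([np.ones(n), C])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert np.allclose(residualize(y, cov), y - X @ beta, atol=1e-10)
    # residuals orthogonal to every covariate column and the intercept
    res = residualize(y, cov)
    assert abs(res.sum()) < 1e-8
    assert np.abs(C.T @ res).max() < 1e-8


def test_residualize_rank_deficient_names_column(rng):
    C = rng.normal(size=(20, 2))
    C = np.column_stack([C, C[:, 0] * 2.0])
    cov = CovariateSet(C, ["a", "b", "dup"])
    with pytest.raises(ValueError, match="dup"):
        residualize(np.zeros(20), cov)


def test_score_test_hand_example():
    rec = score_test(np.array([1.0, -1.0, 0.0]), np.array([1.0, 0.0, -1.0]))
    assert rec.U == pytest.approx(1.0)
    assert rec.V == pytest.approx(4.0 / 3.0)
    assert rec.T == pytest.approx(0.75)


def test_score_test_orthogonal_residuals():
    rec = score_test(np.array([1.0, -1.0, 0.0]), np.array([1.0, 1.0, -2.0]))
    assert rec.U == pytest.approx(0.0)
    assert rec.T == pytest.approx(0.0)
    assert rec.p == pytest.approx(1.0)


def test_score_test_equals_n_r_squared(rng):
    for _ in range(100):
        n = int(rng.integers(10, 200))
        y = rng.normal(size=n)
        g = rng.normal(size=n)
        y -= y.mean()
        g -= g.mean()
        rec = score_test(y, g)
        r, _ = pearsonr(y, g)
        assert rec.T == pytest.approx(n * r * r, abs=1e-10)


def test_score_test_zero_variance_flagged():
    rec = score_test(np.zeros(5), np.array([1.0, -1.0, 0.0, 0.5, -0.5]))
    assert rec.flagged and rec.p == 1.0


# ---------------------------------------------------------------------------
# run_gwas and selection
# ---------------------------------------------------------------------------

def _study(n=300, s=50, seed=0):
    gm = simulate_genotypes(n, s, seed=seed)
    r = np.random.default_rng(seed + 1)
    cov = CovariateSet(r.normal(size=(n, 2)), ["c1", "c2"])
    y = r.normal(size=n)
    return gm, y, cov


def test_run_gwas_planted_causal_has_smallest_p():
    gm, y, cov = _study(seed=10)
    y = y + 1.5 * np.nan_to_num(gm.counts[:, 7])
    table = run_gwas(gm, y, cov)
    assert table.iloc[0]["variant_id"] == gm.variant_ids[7]


def test_run_gwas_permutation_invariance():
    gm, y, cov = _study(n=100, s=20, seed=11)
    table = run_gwas(gm, y, cov)
    perm = np.random.default_rng(3).permutation(100)
    table_p = run_gwas(gm.take_subjects(perm), y[perm],
                       CovariateSet(cov.matrix[perm], cov.names))
    a = table.set_index("variant_id")["p"]
    b = table_p.set_index("variant_id")["p"]
    assert np.allclose(a.loc[gm.variant_ids], b.loc[gm.variant_ids], rtol=1e-9)


def test_run_gwas_dimension_mismatch():
    gm, y, cov = _study(n=50, s=10, seed=12)
    with pytest.raises(ValueError):
        run_gwas(gm, y[:-1], cov)


def test_select_top_k_full_table_and_bounds():
    gm, y, cov = _study(n=200, s=30, seed=13)
    table = run_gwas(gm, y, cov)
    ids, feats = select_top_k(table, gm, k=30)
    assert len(ids) == 30 and feats.shape == (200, 30)
    with pytest.raises(ValueError):
        select_top_k(table, gm, k=31)


def test_select_top_k_p_ordering():
    gm, y, cov = _study(n=200, s=40, seed=14)
    table = run_gwas(gm, y, cov)
    ids, _ = select_top_k(table, gm, k=10)
    sel_p = table.set_index("variant_id").loc[ids, "p"]
    excluded = table[~table["variant_id"].isin(ids)]["p"]
    assert sel_p.max() <= excluded.min()


def test_select_top_k_tie_broken_by_position():
    import pandas as pd

    gm = simulate_genotypes(50, 3, seed=15)
    table = pd.DataFrame(
        {
            "variant_id": gm.variant_ids,
            "chrom": [1, 1, 1],
            "pos": [300, 100, 200],
            "U": 0.0, "V": 1.0, "T": 0.0,
            "p": [0.5, 0.5, 0.1],
        }
    )
    ids, _ = select_top_k(table, gm, k=2)
    # smallest p first; the tie at 0.5 resolves to the smaller position
    assert ids == [gm.variant_ids[2], gm.variant_ids[1]]
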