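"""Random-set enrichment core: moments, scores, permutation p/FDR/FWER."""
import numpy as np
import pytest
from scipy.stats import hypergeom

from rsnpset import (
    PermutationScores,
    combine_blocks,
    compute_fdr,
    compute_fwer,
    count_in_set,
    count_significant,
    enrichment_pvalue,
    hypergeom_moments,
    observed_scores,
    permutation_scores,
    report_from_scores,
    run_rs_snp,
    standardized_score,
)
from rsnpset.snp_sets import SnpSet


def _set(name, idx):
    return SnpSet(name, np.asarray(idx), genes_matched=0, genes_unmatched=0)


# ---------------------------------------------------------------------------
# counting and moments
# ---------------------------------------------------------------------------

def test_count_significant_inclusive_threshold():
    p = [0.001, 0.5, 0.009, 0.2]
    assert count_significant(p, 0.01) == 2
    assert count_significant([0.01, 0.5], 0.01) == 1  # P == alpha counts
    assert count_significant(p, 1.0) == 4


def test_count_in_set():
    p = np.array([0.001, 0.5, 0.009, 0.2])
    assert count_in_set(p, _set("s", [0, 2]), 0.01) == 2
    assert count_in_set(p, _set("s", [1, 3]), 0.01) == 0
    assert count_in_set(p, _set("s", [0, 1, 2, 3]), 0.01) == count_significant(p, 0.01)


def test_hypergeom_moments_match_pmf_summation():
    m, d, n = 10, 20, 100
    mu, sigma2 = hypergeom_moments(m, d, n)
    ys = np.arange(0, m + 1)
    pmf = hypergeom.pmf(ys, n, d, m)
    assert mu == pytest.approx((ys * pmf).sum(), rel=1e-12)
    assert sigma2 == pytest.approx(((ys - mu) ** 2 * pmf).sum(), rel=1e-10)
    assert (mu, sigma2) == (2.0, pytest.approx(10 * 0.2 * 0.8 * 90 / 99))


@pytest.mark.parametrize(
    "m,d,n,expected",
    [(5, 0, 50, (0.0, 0.0)), (50, 13, 50, (13.0, 0.0)), (0, 10, 50, (0.0, 0.0))],
)
def test_hypergeom_moments_degenerate(m, d, n, expected):
    mu, sigma2 = hypergeom_moments(m, d, n)
    assert (mu, sigma2) == (pytest.approx(expected[0]), pytest.approx(expected[1]))


def test_hypergeom_moments_range_check():
    with pytest.raises(ValueError):
        hypergeom_moments(11, 5, 10)


def test_standardized_score():
    assert standardized_score(2, 10, 20, 100) == 0.0  # y equals mu
    z = standardized_score(6, 10, 20, 100)
    assert z == pytest.approx(4 / np.sqrt(10 * 0.2 * 0.8 * 90 / 99))
    assert standardized_score(0, 10, 0, 100) == 0.0  # sigma = 0 convention


# ---------------------------------------------------------------------------
# p-value, FDR, FWER on hand-built score matrices
# ---------------------------------------------------------------------------

def test_enrichment_pvalue_conventions():
    zp = np.array([0.0, 1.0, 2.0, 3.0])
    assert enrichment_pvalue(4.0, zp) == 0.0
    assert enrichment_pvalue(4.0, zp, smooth=True) == pytest.approx(1 / 5)
    assert enrichment_pvalue(2.0, zp) == pytest.approx(2 / 4)  # >= convention
    assert enrichment_pvalue(1.0, np.ones(10)) == 1.0  # all ties count


def test_fdr_top_set_with_clean_null_is_zero():
    z_obs = np.array([5.0, 1.0, 0.5])
    z_perm = np.full((20, 3), 0.2)
    fdr = compute_fdr(z_obs, z_perm)
    assert fdr[0] == 0.0
    assert (fdr >= 0).all() and (fdr <= 1).all()


def test_fdr_saturated_null_is_one():
    z_obs = np.array([2.0, 1.0, 0.0])
    z_perm = np.tile(z_obs, (7, 1))
    assert compute_fdr(z_obs, z_perm) == pytest.approx(np.ones(3))


def test_fwer_definition_and_dominance():
    z_obs = np.array([2.5, 0.5])
    z_perm = np.array([[1.0, 3.0], [0.2, 0.1], [2.6, 0.0]])
    fwer = compute_fwer(z_obs, z_perm)
    # max per permutation: 3.0, 0.2, 2.6 -> counts >= 2.5: 2; >= 0.5: 2
    assert fwer == pytest.approx([2 / 3, 2 / 3])
    for t, z in enumerate(z_obs):
        assert fwer[t] >= enrichment_pvalue(z, z_perm[:, t]) - 1e-12


def test_fwer_equals_pvalue_for_single_set():
    z_obs = np.array([1.5])
    z_perm = np.array([[0.4], [2.0], [1.5], [0.1]])
    assert compute_fwer(z_obs, z_perm)[0] == pytest.approx(
        enrichment_pvalue(1.5, z_perm[:, 0])
    )


# ---------------------------------------------------------------------------
# permutation machinery on synthetic data
# ---------------------------------------------------------------------------

def test_identity_permutation_reproduces_observed(null_dataset_small, null_sets_small):
    data = null_dataset_small
    obs = observed_scores(data.genotypes, data.labels, null_sets_small, alpha=0.05)
    identity = np.arange(data.genotypes.n_samples)[None, :]
    scores = permutation_scores(
        data.genotypes, data.labels, null_sets_small, alpha=0.05,
        permutation_indices=identity,
    )
    np.testing.assert_allclose(scores.z[0], obs["z"].to_numpy(), atol=1e-12)
    assert scores.d[0] == obs["d"].iloc[0]


def test_same_seed_reproduces_scores(null_dataset_small, null_sets_small):
    data = null_dataset_small
    kw = dict(alpha=0.05, n_permutations=20, seed=42)
    a = permutation_scores(data.genotypes, data.labels, null_sets_small, **kw)
    b = permutation_scores(data.genotypes, data.labels, null_sets_small, **kw)
    np.testing.assert_array_equal(a.z, b.z)
    np.testing.assert_array_equal(a.d, b.d)


def test_batching_does_not_change_scores(null_dataset_small, null_sets_small):
    data = null_dataset_small
    kw = dict(alpha=0.05, n_permutations=17, seed=3)
    a = permutation_scores(data.genotypes, data.labels, null_sets_small,
                           batch_size=4, **kw)
    b = permutation_scores(data.genotypes, data.labels, null_sets_small,
                           batch_size=256, **kw)
    np.testing.assert_allclose(a.z, b.z, atol=1e-12)


def test_mean_significant_fraction_tracks_alpha(null_dataset_small, null_sets_small):
    """Under uniform null p-values, E[d_pi / n] is about alpha."""
    data = null_dataset_small
    alpha = 0.2
    scores = permutation_scores(
        data.genotypes, data.labels, null_sets_small, alpha=alpha,
        n_permutations=100, seed=5,
    )
    frac = scores.d.mean() / scores.n
    se = np.sqrt(alpha * (1 - alpha) / (scores.n * 100))
    assert abs(frac - alpha) < max(5 * se, 0.02)


def test_alpha_one_saturates_everything(null_dataset_small, null_sets_small):
    data = null_dataset_small
    report = run_rs_snp(
        data.genotypes, data.labels, null_sets_small, alpha=1.0,
        n_permutations=10, seed=0,
    )
    assert report.d == data.genotypes.n_snps
    assert (report.table["y"] == report.table["m_snps"]).all()
    assert (report.table["z"] == 0.0).all()
    assert (report.table["p_value"] == 1.0).all()


def test_indicator_score_insensitive_to_pvalue_magnitude(null_sets_small, null_dataset_small):
    """Any member p-value below alpha contributes identically (1e-10 vs 1e-3)."""
    from rsnpset.enrichment import _membership, _scores_from_pvalues

    n = null_dataset_small.genotypes.n_snps
    member, m = _membership(null_sets_small, n)
    rng = np.random.default_rng(0)
    p = rng.uniform(0.02, 1.0, size=n)
    idx = null_sets_small[0].snp_indices[:3]
    p[idx] = 1e-10
    y1, z1, d1 = _scores_from_pvalues(p, member, m, alpha=0.01)
    p2 = p.copy()
    p2[idx] = 1e-3
    y2, z2, d2 = _scores_from_pvalues(p2, member, m, alpha=0.01)
    np.testing.assert_array_equal(y1, y2)
    np.testing.assert_array_equal(z1, z2)
    assert d1 == d2


def test_combine_blocks_equals_pooled_run(null_dataset_small, null_sets_small):
    """k blocks over split permutation streams pool to the concatenated run."""
    data = null_dataset_small
    rng = np.random.default_rng(99)
    l = data.genotypes.n_samples
    perms = np.stack([rng.permutation(l) for _ in range(12)])
    pooled = permutation_scores(
        data.genotypes, data.labels, null_sets_small, alpha=0.05,
        permutation_indices=perms,
    )
    blocks = [
        permutation_scores(
            data.genotypes, data.labels, null_sets_small, alpha=0.05,
            permutation_indices=perms[i: i + 4], block_id=i,
        )
        for i in range(0, 12, 4)
    ]
    combined = combine_blocks(blocks)
    np.testing.assert_allclose(combined.z, pooled.z, atol=1e-12)
    np.testing.assert_array_equal(combined.d, pooled.d)
    obs = observed_scores(data.genotypes, data.labels, null_sets_small, alpha=0.05)
    rep_pooled = report_from_scores(obs, pooled)
    rep_combined = report_from_scores(obs, combined)
    for col in ("p_value", "FDR", "FWER"):
        np.testing.assert_allclose(rep_pooled.table[col], rep_combined.table[col])
    # block order is irrelevant
    rep_rev = report_from_scores(obs, combine_blocks(blocks[::-1]))
    np.testing.assert_allclose(
        np.sort(rep_rev.table["p_value"]), np.sort(rep_pooled.table["p_value"])
    )


def test_combine_blocks_rejects_mismatched_runs(null_dataset_small, null_sets_small):
    data = null_dataset_small
    a = permutation_scores(data.genotypes, data.labels, null_sets_small,
                           alpha=0.05, n_permutations=3, seed=0)
    b = permutation_scores(data.genotypes, data.labels, null_sets_small,
                           alpha=0.01, n_permutations=3, seed=1)
    with pytest.raises(ValueError, match="alpha|model|n"):
        combine_blocks([a, b])
    assert combine_blocks([a]) is a


def test_scores_round_trip_npz(tmp_path, null_dataset_small, null_sets_small):
    data = null_dataset_small
    scores = permutation_scores(data.genotypes, data.labels, null_sets_small,
                                alpha=0.05, n_permutations=5, seed=8)
    path = tmp_path / "block.npz"
    scores.save(path)
    again = PermutationScores.load(path)
    assert again.set_names == scores.set_names
    np.testing.assert_array_equal(again.z, scores.z)
    np.testing.assert_array_equal(again.d, scores.d)
    assert (again.n, again.alpha, again.model, again.seed) == (
        scores.n, scores.alpha, scores.model, scores.seed,
    )


def test_report_invariants(null_dataset_small, null_sets_small):
    data = null_dataset_small
    report = run_rs_snp(data.genotypes, data.labels, null_sets_small,
                        alpha=0.05, n_permutations=50, seed=2)
    t = report.table
    for col in ("p_value", "FDR", "FWER"):
        assert ((t[col] >= 0) & (t[col] <= 1)).all()
    assert (t["FWER"] >= t["p_value"] - 1e-12).all()
    assert (t["y"] <= np.minimum(t["m_snps"], t["d"])).all()
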