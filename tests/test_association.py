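"""Single-SNP association statistics under the five genetic models."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.stats import chi2_contingency

from rsnpset import (
    GenotypeMatrix,
    PhenotypeLabels,
    associate_all,
    cochran_armitage_trend,
    genotype_table,
    test_dominant,
    test_general,
    test_multiplicative,
    test_recessive,
)
from rsnpset.association import AssociationKernel


def trend_oracle(table) -> float:
    """Subject-level trend chi-square: N * rho^2 with population variances,
    computed by expanding the table to per-subject vectors."""
    table = np.asarray(table)
    dosage, case = [], []
    for cls in (0, 1):
        for k in (0, 1, 2):
            dosage.extend([k] * table[cls, k])
            case.extend([cls] * table[cls, k])
    dosage = np.array(dosage, dtype=float)
    case = np.array(case, dtype=float)
    vd = dosage.var()
    vc = case.var()
    if vd == 0 or vc == 0:
        return 0.0
    cov = ((dosage - dosage.mean()) * (case - case.mean())).mean()
    return len(dosage) * cov**2 / (vd * vc)


def test_genotype_table_counts_and_missing():
    row = np.array([0, 1, 2, 1])
    labels = np.array([False, False, True, True])
    assert genotype_table(row, labels).tolist() == [[1, 1, 0], [0, 1, 1]]
    row_miss = np.array([-1, 1, 2, 1])
    table = genotype_table(row_miss, labels)
    assert table.sum() == 3  # missing excluded from its class
    assert table[0].sum() == 1 and table[1].sum() == 2


def test_genotype_table_empty_class_errors():
    with pytest.raises(ValueError, match="class"):
        genotype_table(np.array([-1, -1, 1, 2]), np.array([False, False, True, True]))


def test_identical_distributions_give_null_results():
    table = [[10, 20, 30], [10, 20, 30]]
    for fn in (test_general, test_dominant, test_recessive, test_multiplicative,
               cochran_armitage_trend):
        res = fn(table)
        assert res.D == pytest.approx(0.0)
        assert res.P == pytest.approx(1.0)


def test_general_matches_chi2_oracle():
    table = [[10, 20, 30], [30, 20, 10]]
    want = chi2_contingency(table, correction=False)
    res = test_general(table)
    assert res.D == pytest.approx(want.statistic)
    assert res.P == pytest.approx(want.pvalue)


def test_dominant_collapse_matches_2x2_oracle():
    # ((10,20,30),(30,20,10)) collapses to ((10,50),(30,30))
    want = chi2_contingency([[10, 50], [30, 30]], correction=False)
    res = test_dominant([[10, 20, 30], [30, 20, 10]])
    assert res.D == pytest.approx(want.statistic)
    assert res.P == pytest.approx(want.pvalue)


def test_multiplicative_allelic_table():
    # genotype ((10,20,30),(30,20,10)) -> allelic ((40,80),(80,40))
    want = chi2_contingency([[40, 80], [80, 40]], correction=False)
    res = test_multiplicative([[10, 20, 30], [30, 20, 10]])
    assert res.D == pytest.approx(want.statistic)
    assert res.P == pytest.approx(want.pvalue)
    # allele totals are twice the genotype totals
    table = np.array([[10, 20, 30], [30, 20, 10]])
    assert 2 * table.sum() == (40 + 80) * 2


def test_trend_matches_subject_level_oracle():
    table = [[10, 20, 30], [30, 20, 10]]
    res = cochran_armitage_trend(table)
    assert res.D == pytest.approx(trend_oracle(table), rel=1e-10)
    assert res.P == pytest.approx(stats.chi2.sf(trend_oracle(table), 1))


def test_trend_affine_weight_invariance():
    table = [[12, 5, 9], [3, 14, 7]]
    base = cochran_armitage_trend(table, weights=(0, 1, 2)).D
    for a, b in ((5, 2), (-1, 3), (0.5, 0.25)):
        shifted = cochran_armitage_trend(table, weights=(a, a + b, a + 2 * b)).D
        assert shifted == pytest.approx(base, rel=1e-10)


def test_trend_monomorphic_is_null():
    res = cochran_armitage_trend([[10, 0, 0], [12, 0, 0]])
    assert (res.D, res.P) == (0.0, 1.0)


def test_small_counts_switch_to_fisher():
    table = [[1, 1, 1], [3, 0, 0]]  # tiny expected counts
    res = test_dominant(table)
    want = stats.fisher_exact([[1, 2], [3, 0]])[1]
    assert res.P == pytest.approx(want)


def test_degenerate_single_column_table():
    res = test_general([[5, 0, 0], [7, 0, 0]])
    assert (res.D, res.P) == (0.0, 1.0)


@given(
    st.lists(st.integers(min_value=0, max_value=15), min_size=6, max_size=6)
)
@settings(deadline=None, derandomize=True, max_examples=300)
def test_general_chi2_property_vs_scipy(cells):
    table = np.array(cells).reshape(2, 3)
    res = test_general(table)
    assert 0.0 <= res.P <= 1.0 and res.D >= 0.0
    # compare against scipy on tables it accepts, after dropping empty columns
    sub = table[:, table.sum(axis=0) > 0]
    if sub.shape[1] >= 2 and (sub.sum(axis=1) > 0).all():
        want = chi2_contingency(sub, correction=False)
        assert res.D == pytest.approx(want.statistic, abs=1e-10)
        assert res.P == pytest.approx(want.pvalue, abs=1e-10)


def test_associate_all_order_and_exchangeability(tiny_genotypes, tiny_labels):
    out = associate_all(tiny_genotypes, tiny_labels, "additive")
    assert list(out["snp_id"]) == tiny_genotypes.snp_ids
    # permuting sample columns together with labels changes nothing
    perm = np.array([3, 0, 5, 2, 1, 4])
    geno_p = tiny_genotypes.select_samples(perm)
    lab_p = tiny_labels.reorder(geno_p.sample_ids)
    out_p = associate_all(geno_p, lab_p, "additive")
    np.testing.assert_allclose(out["D"], out_p["D"])
    np.testing.assert_allclose(out["P"], out_p["P"])


def test_associate_all_handles_all_missing_class_without_abort():
    dosages = np.array([[0, 1, 2, 1], [-1, -1, 1, 2]], dtype=np.int8)
    geno = GenotypeMatrix(["a", "b"], ["s1", "s2", "s3", "s4"], dosages)
    labels = PhenotypeLabels(["s1", "s2", "s3", "s4"], [False, False, True, True])
    out = associate_all(geno, labels, "additive")
    assert out.loc[1, "P"] == 1.0


@pytest.mark.parametrize("model", ["general", "dominant", "recessive",
                                   "multiplicative", "additive"])
def test_kernel_batch_equals_scalar_path(model, null_dataset_small, rng):
    """The batched (permutation) kernel reproduces the per-label scan."""
    geno = null_dataset_small.genotypes.select_snps(np.arange(40))
    status = null_dataset_small.labels.status.astype(float)
    kernel = AssociationKernel(geno.dosages)
    cases = np.stack([rng.permutation(status) for _ in range(5)], axis=1)
    batch = kernel.pvalues_batch(cases, model)
    for j in range(5):
        single = kernel.pvalues(cases[:, j], model)[1]
        np.testing.assert_allclose(batch[:, j], single, atol=1e-12)


def test_null_pvalues_near_nominal_level(null_dataset_small):
    """Under label-genotype independence, the trend test rejects at about
    its nominal level (binomial 99% band, 200 SNPs is checked loosely here;
    the 2000-SNP check runs in the acceptance suite)."""
    data = null_dataset_small
    out = associate_all(data.genotypes, data.labels, "additive")
    frac = (out["P"] <= 0.05).mean()
    half = 2.576 * np.sqrt(0.05 * 0.95 / len(out))
    assert abs(frac - 0.05) <= half + 0.01  # grid slack for a discrete statistic
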