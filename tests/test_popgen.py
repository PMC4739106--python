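import numpy as np
import pytest
from scipy import stats as sps

from codhoming.genotypes import GenotypeDataset, Locus, SampleCollection
from codhoming.popgen import (
    PairwiseFstMatrix,
    allele_frequencies,
    classical_mds,
    diversity_stats,
    fst_permutation_test,
    pairwise_fst_matrix,
    per_allele_hwe,
    temporal_stability,
    wc_theta,
)
from codhoming.simulate import SyntheticConfig, simulate_allele_freqs, simulate_genotypes

from conftest import make_dataset, make_sample


# ---------------------------------------------------------------------------
# allele frequencies & diversity


def test_allele_frequencies_basic():
    ds = make_dataset({"S": ["AA", "AB", "BB"]})
    codes, freqs, genes = allele_frequencies(ds.samples[0], 0)
    assert genes == 6
    assert dict(zip(codes.tolist(), freqs)) == {101: 0.5, 102: 0.5}
    one = make_dataset({"S": ["AB"]})
    _, freqs, _ = allele_frequencies(one.samples[0], 0)
    np.testing.assert_allclose(freqs, [0.5, 0.5])
    mono = make_dataset({"S": ["AA"] * 10})
    codes, freqs, genes = allele_frequencies(mono.samples[0], 0)
    assert len(codes) == 1 and freqs[0] == 1.0 and genes == 20


def test_allele_frequencies_all_missing_is_error():
    ds = make_dataset({"S": ["00AA", "00AB"]})
    with pytest.raises(ValueError):
        allele_frequencies(ds.samples[0], 0)


def test_diversity_monomorphic_locus():
    ds = make_dataset({"S": ["AA"] * 10})
    d = diversity_stats(ds, "S")
    assert d.He == 0.0 and d.Ho == 0.0 and d.Na == 1.0


def test_diversity_unbiased_he(one_locus_hw_sample):
    # AA=25, AB=50, BB=25 (n=100): Ho = 0.5, He = (2n/(2n-1))*(1-Σp²) = (200/199)*0.5
    d = diversity_stats(one_locus_hw_sample, "hw")
    assert d.Ho == pytest.approx(0.5)
    assert d.He == pytest.approx(200 / 199 * 0.5, abs=1e-12)


def test_diversity_skips_empty_locus_with_warning(caplog):
    ds = make_dataset({"S": ["AA00", "AB00"]})
    with caplog.at_level("WARNING"):
        d = diversity_stats(ds, "S")
    assert "dropped" in caplog.text
    assert d.Na == 2.0  # only the informative locus contributes


# ---------------------------------------------------------------------------
# per-allele HWE screen


def test_hwe_exact_proportions_give_null_result(one_locus_hw_sample):
    tests = per_allele_hwe(one_locus_hw_sample, "hw", "L1")
    for t in tests:
        assert t.f_is == pytest.approx(0.0, abs=1e-12)
        assert t.p == pytest.approx(1.0)


def test_hwe_complete_heterozygote_deficit():
    ds = make_dataset({"S": ["AA"] * 50 + ["BB"] * 50})
    tests = per_allele_hwe(ds, "S", "L1")
    for t in tests:
        assert t.f_is == pytest.approx(1.0)
        assert t.chi2 == pytest.approx(100.0)
        assert t.p < 1e-20


def test_hwe_derived_example_and_literal_statistic():
    # AA=30, AB=40, BB=30: p=0.5, Ho=0.4, He=0.5 -> F_IS=0.2, chi2=n*F^2=4
    ds = make_dataset({"S": ["AA"] * 30 + ["AB"] * 40 + ["BB"] * 30})
    t = per_allele_hwe(ds, "S", "L1")[0]
    assert t.f_is == pytest.approx(0.2)
    assert t.chi2 == pytest.approx(4.0)
    assert t.p == pytest.approx(sps.chi2.sf(4.0, 1), abs=1e-12)  # ≈ 0.0455
    # the literal n*F_IS form offered as a configuration switch
    t2 = per_allele_hwe(ds, "S", "L1", hwe_stat="n_fis")[0]
    assert t2.chi2 == pytest.approx(20.0)


# ---------------------------------------------------------------------------
# Weir–Cockerham θ


def _wc_oracle_biallelic(ga, gb):
    """Independent scalar transcription of the 1984 variance components for
    a one-locus, two-sample, biallelic table; genotypes as strings."""
    total_a = total_all = 0.0
    for allele in ("A", "B"):
        n1, n2 = len(ga), len(gb)
        p1 = sum(g.count(allele) for g in ga) / (2 * n1)
        p2 = sum(g.count(allele) for g in gb) / (2 * n2)
        h1 = sum(1 for g in ga if g.count(allele) == 1) / n1
        h2 = sum(1 for g in gb if g.count(allele) == 1) / n2
        r = 2
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        total_a += a
        total_all += a + b + c
    return total_a / total_all


def test_wc_theta_matches_hand_oracle(wc_toy_dataset):
    expected = _wc_oracle_biallelic(
        ["AA", "AA", "AB", "AB", "BB"], ["AB", "BB", "BB", "BB", "AB"]
    )
    res = wc_theta(wc_toy_dataset)
    assert res.theta == pytest.approx(expected, abs=1e-12)
    assert res.per_locus_theta[0] == pytest.approx(expected, abs=1e-12)


def test_wc_theta_identical_samples_near_zero():
    rng = np.random.default_rng(7)
    genos = ["".join(rng.choice(list("AB"), size=2)) for _ in range(60)]
    ds = make_dataset({"X": genos, "Y": genos})
    assert abs(wc_theta(ds).theta) < 0.02


def test_wc_theta_fixation_is_one(fixation_dataset):
    assert wc_theta(fixation_dataset).theta == pytest.approx(1.0)


def test_wc_theta_monomorphic_everywhere_is_error():
    ds = make_dataset({"X": ["AA"] * 4, "Y": ["AA"] * 4})
    with pytest.raises(ValueError):
        wc_theta(ds)


def test_wc_theta_needs_two_samples():
    ds = make_dataset({"X": ["AA", "AB"]})
    with pytest.raises(ValueError):
        wc_theta(ds)


# ---------------------------------------------------------------------------
# permutation significance


def test_permutation_p_extreme_under_fixation(fixation_dataset):
    res = fst_permutation_test(fixation_dataset, reps=999, seed=1)
    # only degenerate permutations tie θ = 1
    assert res.p < 0.05


def test_permutation_p_null_median_near_half():
    cfg = SyntheticConfig(fst_target=0.001, sample_sizes=(40, 40), n_loci=6, seed=5)
    freqs = simulate_allele_freqs(cfg)
    rng = np.random.default_rng(5)
    ps = []
    for rep in range(20):
        # one population split in two: the null
        sample = simulate_genotypes(freqs[0], 80, 0.0, rng, label="all")
        half1 = SampleCollection("h1", sample.individuals[:40])
        half2 = SampleCollection("h2", sample.individuals[40:])
        ds = GenotypeDataset([Locus(f"L{j}") for j in range(6)], [half1, half2]).registered()
        ps.append(fst_permutation_test(ds, reps=99, seed=rng).p)
    assert 0.25 < np.median(ps) < 0.75


def test_permutation_rejects_true_differentiation():
    cfg = SyntheticConfig(fst_target=0.05, sample_sizes=(50, 50), n_loci=8, seed=11)
    freqs = simulate_allele_freqs(cfg)
    rng = np.random.default_rng(11)
    hits = 0
    for rep in range(10):
        samples = [
            simulate_genotypes(freqs[i], 50, 0.0, rng, label=f"p{i}") for i in range(2)
        ]
        ds = GenotypeDataset([Locus(f"L{j}") for j in range(8)], samples).registered()
        if fst_permutation_test(ds, reps=199, seed=rng).p < 0.01:
            hits += 1
    assert hits >= 8


# ---------------------------------------------------------------------------
# pairwise matrix, temporal stability, MDS


def test_pairwise_matrix_structure():
    cfg = SyntheticConfig(fst_target=0.02, sample_sizes=(30, 30), n_loci=6, seed=3)
    freqs = simulate_allele_freqs(cfg)
    rng = np.random.default_rng(3)
    samples = [simulate_genotypes(freqs[i % 2], 30, 0.0, rng, label=f"s{i}") for i in range(3)]
    ds = GenotypeDataset([Locus(f"L{j}") for j in range(6)], samples).registered()
    m = pairwise_fst_matrix(ds)
    np.testing.assert_array_equal(np.diag(m.values), 0.0)
    np.testing.assert_allclose(m.values, m.values.T)


def test_pairwise_matrix_identical_samples_near_zero():
    genos = ["AB", "AA", "BB", "AB"] * 10
    ds = make_dataset({"X": genos, "Y": genos, "Z": genos})
    m = pairwise_fst_matrix(ds)
    off = m.values[np.triu_indices(3, k=1)]
    assert np.all(np.abs(off) < 0.05)


def test_temporal_stability_null_and_small_cohort_guard(caplog):
    cfg = SyntheticConfig(fst_target=0.001, sample_sizes=(80, 80), n_loci=6, seed=9)
    freqs = simulate_allele_freqs(cfg)
    rng = np.random.default_rng(9)
    sample = simulate_genotypes(freqs[0], 80, 0.0, rng, label="R")
    sample.cohorts = ["2000"] * 38 + ["2001"] * 39 + ["2002"] * 3  # tiny third cohort
    ds = GenotypeDataset([Locus(f"L{j}") for j in range(6)], [sample]).registered()
    with caplog.at_level("WARNING"):
        table = temporal_stability(ds, {"R": "regionA"}, reps=99, seed=2)
    assert "excluded" in caplog.text
    assert len(table) == 1  # only the 2000-vs-2001 comparison
    assert table.p.iloc[0] > 0.01


def test_mds_equilateral_triangle():
    m = PairwiseFstMatrix(["a", "b", "c"], np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]]))
    mds = classical_mds(m, k=2)
    d01 = np.linalg.norm(mds.coords[0] - mds.coords[1])
    d02 = np.linalg.norm(mds.coords[0] - mds.coords[2])
    d12 = np.linalg.norm(mds.coords[1] - mds.coords[2])
    np.testing.assert_allclose([d01, d02, d12], 1.0, atol=1e-9)
    np.testing.assert_allclose(mds.coords.mean(axis=0), 0.0, atol=1e-9)


def test_mds_collinear_three_points_reduces_to_one_dimension():
    m = PairwiseFstMatrix(["a", "b", "c"], np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0.0]]))
    mds = classical_mds(m, k=1)
    x = np.sort(mds.coords[:, 0])
    np.testing.assert_allclose(x - x.mean(), [-1, 0, 1], atol=1e-9)


def test_mds_negative_cells_clamped_and_label_order_invariant():
    vals = np.array([[0, -0.001, 0.02], [-0.001, 0, 0.03], [0.02, 0.03, 0.0]])
    mds = classical_mds(PairwiseFstMatrix(["a", "b", "c"], vals), k=2)
    perm = [2, 0, 1]
    mds2 = classical_mds(PairwiseFstMatrix(["c", "a", "b"], vals[np.ix_(perm, perm)]), k=2)

    def dists(c):
        return sorted(
            np.linalg.norm(c[i] - c[j]) for i in range(3) for j in range(i + 1, 3)
        )

    np.testing.assert_allclose(dists(mds.coords), dists(mds2.coords), atol=1e-12)


def test_mds_reduces_k_with_warning(caplog):
    m = PairwiseFstMatrix(["a", "b"], np.array([[0, 1], [1, 0.0]]))
    with caplog.at_level("WARNING"):
        mds = classical_mds(m, k=5)
    assert mds.k == 1
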