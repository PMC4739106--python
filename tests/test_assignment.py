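import math

import numpy as np
import pytest
from scipy import stats as sps

from codhoming.assignment import (
    AssignmentScorer,
    assign_individuals,
    build_pool,
    exclusion_test,
    self_assign_loo,
    subsample_robustness,
)
from codhoming.behaviour import TaggedFish
from codhoming.genotypes import GenotypeDataset, IndividualGenotype, Locus, SampleCollection
from codhoming.simulate import SyntheticConfig, simulate_allele_freqs, simulate_genotypes

from conftest import make_dataset, make_sample

import datetime


def _fishify(sample, region="Kattegat"):
    """Wrap a SampleCollection's individuals as TaggedFish (genotype only)."""
    return [
        TaggedFish(
            ind.individual_id,
            datetime.date(2003, 10, 1),
            datetime.date(2004, 3, 1),
            (56.8, 11.9),
            region,
            genotype=ind,
        )
        for ind in sample.individuals
    ]


def _sim_pools(F, n, seed, n_loci=12, K=15, missing=0.0):
    cfg = SyntheticConfig(
        fst_target=F, sample_sizes=(n, n), n_loci=n_loci, alleles_per_locus=K,
        missing_rate=missing, seed=seed,
    )
    freqs = simulate_allele_freqs(cfg)
    rng = np.random.default_rng(seed + 1)
    names = ["Kattegat", "NorthSea_WSkagerrak"]
    samples = [simulate_genotypes(freqs[i], n, missing, rng, label=names[i]) for i in range(2)]
    locus_names = [f"L{j}" for j in range(n_loci)]
    pools = [build_pool([s], s.label, locus_names) for s in samples]
    return freqs, pools, locus_names


# ---------------------------------------------------------------------------
# pool building


def test_build_pool_table2_sizes():
    sizes = {"SK00": 31, "SK01": 70, "NS02": 100}
    samples = [make_sample(lb, ["AB"] * n) for lb, n in sizes.items()]
    pool = build_pool(samples, "NorthSea_WSkagerrak", ["L1"])
    assert pool.n == 201
    sizes_k = {"KA00": 77, "OR00": 99, "KA01": 58, "KA04a": 41, "KA04b": 60, "KA04c": 100}
    pool_k = build_pool([make_sample(lb, ["AB"] * n) for lb, n in sizes_k.items()], "Kattegat", ["L1"])
    assert pool_k.n == 435


def test_build_pool_counts_and_associativity():
    s1 = make_sample("a", ["AA", "AB"])
    s2 = make_sample("b", ["BB"])
    single = build_pool([s1], "p", ["L1"])
    assert single.allele_counts[0] == {101: 3, 102: 1}
    both = build_pool([s1, s2], "p", ["L1"])
    # pool of pools equals pool of the union
    merged = SampleCollection("m", s1.individuals + s2.individuals)
    union = build_pool([merged], "p", ["L1"])
    assert both.allele_counts == union.allele_counts
    assert np.array_equal(both.gene_counts, union.gene_counts)


def test_build_pool_missing_contributes_no_genes():
    s = make_sample("a", ["AA", "00"])
    pool = build_pool([s], "p", ["L1"])
    assert pool.gene_counts[0] == 2


# ---------------------------------------------------------------------------
# genotype likelihood (Dirichlet posterior-predictive)


def test_loglik_dirichlet_homozygote_closed_form():
    # one locus, pool counts A=4 (gene count 4), k=2:
    # P(AA) = (4+1/2)(5+1/2) / (5*6) = 0.825
    pool = build_pool([make_sample("p", ["AA", "AA"])], "p", ["L1"])
    other = build_pool([make_sample("q", ["AA", "AB"])], "q", ["L1"])  # brings allele B: k=2
    scorer = AssignmentScorer([pool, other])
    calls = np.array([[101, 101]], dtype=np.int32)
    assert math.exp(scorer.loglik(calls, pool)) == pytest.approx(0.825, abs=1e-12)


def test_loglik_unseen_allele_stays_finite():
    pool = build_pool([make_sample("p", ["AA", "AA"])], "p", ["L1"])
    other = build_pool([make_sample("q", ["BB", "BB"])], "q", ["L1"])
    scorer = AssignmentScorer([pool, other])
    ll = scorer.loglik(np.array([[102, 102]], dtype=np.int32), pool)  # B absent from p
    assert np.isfinite(ll)
    # closed form with pseudo-count 1/k = 0.5: (0.5*1.5)/(5*6)
    assert math.exp(ll) == pytest.approx(0.5 * 1.5 / 30, abs=1e-12)


def test_loglik_identical_pools_symmetric():
    pool1 = build_pool([make_sample("p", ["AA", "AB", "BB"])], "p", ["L1"])
    pool2 = build_pool([make_sample("q", ["AA", "AB", "BB"])], "q", ["L1"])
    scorer = AssignmentScorer([pool1, pool2])
    g = np.array([[101, 102]], dtype=np.int32)
    assert scorer.loglik(g, pool1) == pytest.approx(scorer.loglik(g, pool2), abs=1e-14)


def test_loglik_requires_shared_locus():
    pool = build_pool([make_sample("p", ["AA"])], "p", ["L1"])
    scorer = AssignmentScorer([pool])
    with pytest.raises(ValueError):
        scorer.loglik(np.array([[0, 0]], dtype=np.int32), pool)


def test_leave_one_out_lowers_own_pool_likelihood():
    _, pools, _ = _sim_pools(0.02, 50, seed=21)
    scorer = AssignmentScorer(pools)
    pool = pools[0]
    for i in range(20):
        plain = scorer.loglik(pool.members[i], pool, holdout=False)
        loo = scorer.loglik(pool.members[i], pool, holdout=True)
        assert loo < plain


# ---------------------------------------------------------------------------
# self-assignment and tagged-fish assignment


def test_self_assignment_accuracy_high_at_strong_divergence():
    _, pools, _ = _sim_pools(0.1, 100, seed=31)
    _, summaries = self_assign_loo(pools)
    for s in summaries:
        assert s.proportions[s.group] > 0.9
        assert sum(s.counts.values()) == 100
        assert sum(s.proportions.values()) == pytest.approx(1.0)


def test_self_assignment_accuracy_monotone_in_divergence():
    acc = []
    for F in (0.004, 0.02, 0.1):
        vals = []
        for rep in range(6):
            _, pools, _ = _sim_pools(F, 80, seed=1000 * rep + int(F * 1e4))
            _, summaries = self_assign_loo(pools)
            vals.append(np.mean([s.proportions[s.group] for s in summaries]))
        acc.append(np.mean(vals))
    assert acc[0] < acc[1] < acc[2]


def test_self_assignment_identical_pools_splits_half():
    genos = ["AA", "AB", "BB", "AB"] * 10
    pools = [
        build_pool([make_sample("X", genos)], "X", ["L1"]),
        build_pool([make_sample("Y", genos)], "Y", ["L1"]),
    ]
    records, _ = self_assign_loo(pools)
    frac_x = np.mean([r.assigned == "X" for r in records])
    assert frac_x == pytest.approx(0.5, abs=0.1)


def test_assign_individuals_majority_correct_and_missing_handled():
    freqs, pools, locus_names = _sim_pools(0.02, 200, seed=41)
    rng = np.random.default_rng(43)
    sample = simulate_genotypes(freqs[0], 200, 0.0, rng, label="t")
    fish = _fishify(sample)
    # one fish with no data at all
    blank = IndividualGenotype("blank", np.zeros((12, 2), dtype=np.int32))
    fish.append(
        TaggedFish("blank", datetime.date(2003, 10, 1), datetime.date(2004, 3, 1),
                   (56.8, 11.9), "Kattegat", genotype=blank)
    )
    records = assign_individuals(fish, pools)
    ok = [r for r in records if r.error is None]
    assert np.mean([r.assigned == "Kattegat" for r in ok]) > 0.6
    assert records[-1].error is not None and records[-1].assigned is None


def test_assignment_coin_flip_for_identical_pools():
    genos = ["AA", "AB", "BB", "AB"] * 25
    pools = [
        build_pool([make_sample("X", genos)], "X", ["L1"]),
        build_pool([make_sample("Y", genos)], "Y", ["L1"]),
    ]
    fish = _fishify(make_sample("t", ["AB"] * 10))
    records = assign_individuals(fish, pools)
    # exact ties: broken toward the first configured pool, deterministically
    assert all(r.assigned == "X" for r in records)


# ---------------------------------------------------------------------------
# Monte-Carlo exclusion


def test_exclusion_common_homozygote_ranks_high():
    genos = ["AA"] * 45 + ["AB"] * 10 + ["BB"] * 5
    pools = [
        build_pool([make_sample("P", genos)], "P", ["L1"]),
        build_pool([make_sample("Q", genos)], "Q", ["L1"]),
    ]
    fish = _fishify(make_sample("t", ["AA"]))[0]
    rec = exclusion_test(fish, pools, n_sim=500, seed=3)
    assert rec.exclusion_p["P"] > 0.5


def test_exclusion_p_uniform_for_own_pool_members():
    freqs, pools, _ = _sim_pools(0.02, 200, seed=51)
    rng = np.random.default_rng(53)
    sample = simulate_genotypes(freqs[0], 200, 0.0, rng, label="f")
    ps = []
    for fish in _fishify(sample):
        rec = exclusion_test(fish, [pools[0]], n_sim=200, seed=7)
        ps.append(rec.exclusion_p["Kattegat"])
    stat = sps.kstest(ps, "uniform")
    assert stat.pvalue > 0.01


def test_exclusion_results_independent_of_processing_order():
    freqs, pools, _ = _sim_pools(0.02, 50, seed=61)
    rng = np.random.default_rng(67)
    fish = _fishify(simulate_genotypes(freqs[0], 5, 0.0, rng, label="f"))
    fwd = {f.fish_id: exclusion_test(f, pools, n_sim=100, seed=9).exclusion_p for f in fish}
    rev = {f.fish_id: exclusion_test(f, pools, n_sim=100, seed=9).exclusion_p for f in reversed(fish)}
    assert fwd == rev


def test_exclusion_low_coverage_warning(caplog):
    # a genotype alien to both pools should trigger the coverage warning
    pools = [
        build_pool([make_sample("P", ["AAAAAA"] * 60)], "P", ["L1", "L2", "L3"]),
        build_pool([make_sample("Q", ["AAAAAA"] * 60)], "Q", ["L1", "L2", "L3"]),
    ]
    fish = _fishify(make_sample("t", ["BBBBBB"]))[0]
    with caplog.at_level("WARNING"):
        rec = exclusion_test(fish, pools, n_sim=200, seed=5, threshold=0.05)
    assert max(rec.exclusion_p.values()) < 0.05
    assert "origin may lie outside" in caplog.text


# ---------------------------------------------------------------------------
# subsampling robustness


def test_subsample_full_size_reproduces_original_assignment():
    freqs, pools, _ = _sim_pools(0.05, 60, seed=71)
    rng = np.random.default_rng(73)
    fish = _fishify(simulate_genotypes(freqs[0], 30, 0.0, rng, label="t"))
    groups = {f.fish_id: "G" for f in fish}
    base = assign_individuals(fish, pools)
    df = subsample_robustness(fish, pools, groups, n_target=pools[0].n, reps=3, seed=1)
    expected = np.mean([r.assigned == "Kattegat" for r in base])
    assert df.loc[0, "Kattegat"] == pytest.approx(expected, abs=1e-12)


def test_subsample_reproducible_and_bounded():
    freqs, pools, _ = _sim_pools(0.05, 60, seed=81)
    rng = np.random.default_rng(83)
    fish = _fishify(simulate_genotypes(freqs[0], 20, 0.0, rng, label="t"))
    groups = {f.fish_id: "G" for f in fish}
    df1 = subsample_robustness(fish, pools, groups, n_target=40, reps=5, seed=11)
    df2 = subsample_robustness(fish, pools, groups, n_target=40, reps=5, seed=11)
    assert df1.equals(df2)
    with pytest.raises(ValueError):
        subsample_robustness(fish, pools, groups, n_target=1000, reps=2, seed=1)
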