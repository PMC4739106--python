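import numpy as np
import pytest

from codhoming.genotypes import (
    GenotypeDataset,
    IndividualGenotype,
    Locus,
    SampleCollection,
)

# allele letters -> integer codes used throughout the toy fixtures
CODE = {"A": 101, "B": 102, "C": 103, "D": 104, "0": 0}


def make_sample(label, genotype_strings, n_loci=None):
    """Build a SampleCollection from per-individual strings like ["AB", "A0B0"].

    Each string holds two letters per locus ('0' pairs = missing).
    """
    inds = []
    for i, s in enumerate(genotype_strings):
        pairs = [s[j : j + 2] for j in range(0, len(s), 2)]
        calls = np.array([[CODE[p[0]], CODE[p[1]]] for p in pairs], dtype=np.int32)
        inds.append(IndividualGenotype(f"{label}_{i + 1}", calls))
    return SampleCollection(label, inds)


def make_dataset(samples_dict):
    """GenotypeDataset from {label: [genotype strings]}; loci named L1..Lk."""
    samples = [make_sample(label, strings) for label, strings in samples_dict.items()]
    n_loci = samples[0].individuals[0].calls.shape[0]
    loci = [Locus(f"L{j + 1}") for j in range(n_loci)]
    return GenotypeDataset(loci, samples).registered()


@pytest.fixture
def one_locus_hw_sample():
    """One locus in exact HWE proportions: AA=25, AB=50, BB=25."""
    return make_dataset({"hw": ["AA"] * 25 + ["AB"] * 50 + ["BB"] * 25})


@pytest.fixture
def fixation_dataset():
    """Two samples fixed for different alleles at one locus (θ = 1)."""
    return make_dataset({"A": ["AA"] * 5, "B": ["BB"] * 5})


@pytest.fixture
def wc_toy_dataset():
    """The ≤6-individual toy used against the hand variance-component oracle."""
    return make_dataset(
        {"A": ["AA", "AA", "AB", "AB", "BB"], "B": ["AB", "BB", "BB", "BB", "AB"]}
    )
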