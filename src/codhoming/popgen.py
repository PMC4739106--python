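"""Population-genetic statistics for microsatellite samples.

Implements gene-diversity summaries (He, Ho, Na), a per-allele
Hardy–Weinberg screen based on F_IS, the Weir–Cockerham (1984) F_ST
estimator θ with individual-permutation significance, pairwise θ matrices,
within-region year-class (temporal) stability tests, and classical metric
multidimensional scaling of a pairwise-θ matrix.

Conventions
-----------
* He is Nei's unbiased gene diversity, (2n/(2n−1))·(1−Σp²), averaged over
  loci with at least one non-missing genotype.
* Multilocus θ is the ratio of summed variance components Σa / Σ(a+b+c)
  over loci *and* alleles — never the mean of per-locus ratios.  Negative
  estimates are reported as-is.
* Permutation p-values use the +1 correction: (1 + #{θ* ≥ θ})/(reps + 1),
  permuting whole multilocus individuals among samples.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeDataset, Locus, SampleCollection

logger = logging.getLogger(__name__)


@dataclass
class DiversityStats:
    sample_label: str
    panel_size: int
    He: float
    Ho: float
    Na: float
    n: int


@dataclass
class HweAlleleTest:
    sample_label: str
    locus: str
    allele: int
    f_is: float
    chi2: float
    p: float
    df: int = 1


@dataclass
class FstResult:
    labels: tuple[str, ...]
    loci: tuple[str, ...]
    per_locus_theta: np.ndarray
    theta: float
    p: float | None = None


@dataclass
class PairwiseFstMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal; NaN where a pair failed


@dataclass
class MdsCoordinates:
    labels: list[str]
    k: int
    coords: np.ndarray  # (n_labels, k)
    eigenvalues: np.ndarray  # descending, all retained eigenvalues


# ---------------------------------------------------------------------------
# Allele frequencies and diversity


def allele_frequencies(sample: SampleCollection, locus_index: int):
    """Allele codes, frequencies and gene count for one sample at one locus.

    Returns (codes, freqs, gene_count); gene count = 2 × non-missing
    individuals.  Raises if every genotype is missing.
    """
    calls = sample.calls_array()[:, locus_index, :]
    genes = calls[calls != MISSING]
    if genes.size == 0:
        raise ValueError(f"sample {sample.label}: no data at locus index {locus_index}")
    codes, counts = np.unique(genes, return_counts=True)
    return codes, counts / genes.size, int(genes.size)


def diversity_stats(
    dataset: GenotypeDataset, sample_label: str, panel: list[str] | None = None
) -> DiversityStats:
    """Mean He (unbiased), Ho and allele count over a locus panel."""
    panel = panel or dataset.locus_names
    if not panel:
        raise ValueError("empty locus panel")
    s = dataset.sample(sample_label)
    arr = s.calls_array()
    he, ho, na = [], [], []
    for name in panel:
        j = dataset.locus_index(name)
        calls = arr[:, j, :]
        present = calls[:, 0] != MISSING
        n = int(present.sum())
        if n == 0:
            logger.warning("sample %s: locus %s has no data; dropped from averages", sample_label, name)
            continue
        genes = calls[present].ravel()
        _, counts = np.unique(genes, return_counts=True)
        p = counts / (2 * n)
        gene_div = 1.0 - np.sum(p**2)
        he.append((2 * n) / (2 * n - 1) * gene_div if n > 1 else gene_div)
        ho.append(float(np.mean(calls[present, 0] != calls[present, 1])))
        na.append(len(counts))
    if not he:
        raise ValueError(f"sample {sample_label}: no locus in the panel has data")
    return DiversityStats(sample_label, len(panel), float(np.mean(he)), float(np.mean(ho)), float(np.mean(na)), s.n)


# ---------------------------------------------------------------------------
# Per-allele HWE screen


def per_allele_hwe(
    dataset: GenotypeDataset,
    sample_label: str,
    locus_name: str,
    hwe_stat: str = "n_fis2",
) -> list[HweAlleleTest]:
    """Allele-specific Hardy–Weinberg screen (dropout / null-allele check).

    Each allele in turn is tested against the pool of all other alleles:
    F_IS = 1 − Ho/He on the recoded biallelic data with He = 2p(1−p).  The
    default statistic is the classical one-degree-of-freedom form n·F_IS²;
    ``hwe_stat="n_fis"`` uses n·F_IS literally instead.  Monomorphic
    recodings are skipped.
    """
    if hwe_stat not in ("n_fis2", "n_fis"):
        raise ValueError("hwe_stat must be 'n_fis2' or 'n_fis'")
    s = dataset.sample(sample_label)
    j = dataset.locus_index(locus_name)
    calls = s.calls_array()[:, j, :]
    present = calls[:, 0] != MISSING
    calls = calls[present]
    n = calls.shape[0]
    if n == 0:
        raise ValueError(f"sample {sample_label}: no data at locus {locus_name}")
    codes = np.unique(calls)
    if len(codes) < 2:
        raise ValueError(f"locus {locus_name} monomorphic in sample {sample_label}")
    out = []
    for a in codes:
        copies = (calls == a).sum(axis=1)
        p = copies.sum() / (2 * n)
        if p >= 1.0 or p <= 0.0:
            continue
        ho = float(np.mean(copies == 1))
        he = 2 * p * (1 - p)
        f_is = 1.0 - ho / he
        chi2 = n * f_is**2 if hwe_stat == "n_fis2" else n * f_is
        pval = float(stats.chi2.sf(chi2, df=1)) if chi2 >= 0 else 1.0
        out.append(HweAlleleTest(sample_label, locus_name, int(a), float(f_is), float(chi2), pval))
    return out


# ---------------------------------------------------------------------------
# Weir–Cockerham θ


def _locus_components(per_sample_calls: list[np.ndarray]):
    """Weir–Cockerham (1984) variance components for one locus.

    ``per_sample_calls``: list of (n_i, 2) call arrays (0 = missing).
    Returns (a, b, c) summed over alleles, or None when fewer than two
    samples have data (or n̄ ≤ 1).
    """
    ns, ps, hs, all_codes = [], [], [], []
    for calls in per_sample_calls:
        present = calls[:, 0] != MISSING
        if present.sum() == 0:
            continue
        sub = calls[present]
        ns.append(sub.shape[0])
        all_codes.append(np.unique(sub))
        ps.append(sub)
    if len(ns) < 2:
        return None
    codes = np.unique(np.concatenate(all_codes))
    r = len(ns)
    n = np.asarray(ns, dtype=float)
    nbar = n.mean()
    if nbar <= 1.0:
        return None
    nc = (r * nbar - np.sum(n**2) / (r * nbar)) / (r - 1)
    # p[i, a]: allele frequency; h[i, a]: heterozygote (single-copy) frequency
    p = np.empty((r, len(codes)))
    h = np.empty((r, len(codes)))
    for i, sub in enumerate(ps):
        copies = (sub[:, :, None] == codes[None, None, :]).sum(axis=1)  # (n_i, A)
        p[i] = copies.sum(axis=0) / (2 * n[i])
        h[i] = (copies == 1).sum(axis=0) / n[i]
    pbar = (n[:, None] * p).sum(axis=0) / (r * nbar)
    s2 = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n[:, None] * h).sum(axis=0) / (r * nbar)
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def _theta_from_calls(calls_by_sample: list[np.ndarray], n_loci: int):
    """(per-locus θ, multilocus θ) from per-sample (n_i, L, 2) call arrays."""
    per_locus = np.full(n_loci, np.nan)
    tot_a = tot_abc = 0.0
    for j in range(n_loci):
        comp = _locus_components([c[:, j, :] for c in calls_by_sample])
        if comp is None:
            continue
        a, b, cc = comp
        denom = a + b + cc
        if denom != 0.0:
            per_locus[j] = a / denom
        tot_a += a
        tot_abc += denom
    if tot_abc == 0.0:
        raise ValueError("θ undefined: zero total variance (all loci monomorphic?)")
    return per_locus, tot_a / tot_abc


def wc_theta(
    dataset: GenotypeDataset, labels: list[str] | None = None, panel: list[str] | None = None
) -> FstResult:
    """Multilocus Weir–Cockerham θ among the given samples over a locus panel."""
    labels = labels or [s.label for s in dataset.samples]
    if len(labels) < 2:
        raise ValueError("θ needs at least two samples")
    panel = panel or dataset.locus_names
    idx = [dataset.locus_index(name) for name in panel]
    calls = [dataset.sample(lb).calls_array()[:, idx, :] for lb in labels]
    per_locus, theta = _theta_from_calls(calls, len(idx))
    return FstResult(tuple(labels), tuple(panel), per_locus, float(theta))


def fst_permutation_test(
    dataset: GenotypeDataset,
    labels: list[str] | None = None,
    panel: list[str] | None = None,
    reps: int = 999,
    seed: int | np.random.Generator = 0,
) -> FstResult:
    """Permutation p-value for θ: whole individuals shuffled among samples,
    sample sizes preserved; p = (1 + #{θ* ≥ θ}) / (reps + 1)."""
    if reps < 99:
        raise ValueError("reps must be ≥ 99")
    res = wc_theta(dataset, labels, panel)
    labels = list(res.labels)
    idx = [dataset.locus_index(name) for name in res.loci]
    calls = [dataset.sample(lb).calls_array()[:, idx, :] for lb in labels]
    sizes = [c.shape[0] for c in calls]
    pool = np.concatenate(calls, axis=0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bounds = np.cumsum(sizes)[:-1]
    hits = 0
    for _ in range(reps):
        perm = rng.permutation(pool.shape[0])
        parts = np.split(pool[perm], bounds)
        try:
            _, theta_star = _theta_from_calls(parts, len(idx))
        except ValueError:
            continue
        if theta_star >= res.theta:
            hits += 1
    res.p = (1 + hits) / (reps + 1)
    return res


def pairwise_fst_matrix(dataset: GenotypeDataset, panel: list[str] | None = None) -> PairwiseFstMatrix:
    """Symmetric matrix of pairwise multilocus θ (NaN where a pair fails)."""
    labels = [s.label for s in dataset.samples]
    if len(labels) < 2:
        raise ValueError("need at least two samples")
    m = np.zeros((len(labels), len(labels)))
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            try:
                th = wc_theta(dataset, [labels[i], labels[j]], panel).theta
            except ValueError as exc:
                logger.warning("pairwise θ failed for (%s, %s): %s", labels[i], labels[j], exc)
                th = np.nan
            m[i, j] = m[j, i] = th
    return PairwiseFstMatrix(labels, m)


def temporal_stability(
    dataset: GenotypeDataset,
    region_of: dict[str, str],
    panel: list[str] | None = None,
    min_n: int = 10,
    reps: int = 199,
    seed: int = 0,
) -> pd.DataFrame:
    """Year-class heterogeneity within regions: pairwise θ + permutation p
    between cohorts pooled inside each region (cohorts with n < ``min_n``
    excluded with a warning).  Single-cohort regions yield no rows."""
    rng = np.random.default_rng(seed)
    rows = []
    regions: dict[str, dict[str, list]] = {}
    for s in dataset.samples:
        region = region_of.get(s.label)
        if region is None or s.cohorts is None:
            continue
        by_cohort = regions.setdefault(region, {})
        for ind, cohort in zip(s.individuals, s.cohorts):
            by_cohort.setdefault(cohort, []).append(ind)
    for region, by_cohort in regions.items():
        kept = {}
        for cohort, inds in sorted(by_cohort.items()):
            if len(inds) < min_n:
                logger.warning("region %s cohort %s: n=%d < %d, excluded", region, cohort, len(inds), min_n)
                continue
            kept[cohort] = inds
        cohorts = sorted(kept)
        for i in range(len(cohorts)):
            for j in range(i + 1, len(cohorts)):
                sub = GenotypeDataset(
                    list(dataset.loci),
                    [
                        SampleCollection(f"{region}:{cohorts[i]}", kept[cohorts[i]]),
                        SampleCollection(f"{region}:{cohorts[j]}", kept[cohorts[j]]),
                    ],
                )
                res = fst_permutation_test(sub, panel=panel, reps=reps, seed=rng)
                rows.append(
                    {
                        "region": region,
                        "cohort_a": cohorts[i],
                        "cohort_b": cohorts[j],
                        "n_a": len(kept[cohorts[i]]),
                        "n_b": len(kept[cohorts[j]]),
                        "theta": res.theta,
                        "p": res.p,
                    }
                )
    return pd.DataFrame(rows, columns=["region", "cohort_a", "cohort_b", "n_a", "n_b", "theta", "p"])


# ---------------------------------------------------------------------------
# Classical MDS (cmdscale)


def classical_mds(matrix: PairwiseFstMatrix, k: int = 2) -> MdsCoordinates:
    """Classical (Torgerson) metric MDS of a pairwise-θ matrix.

    Negative input cells (valid for θ, invalid as distances) are clamped to 0
    before squaring.  Coordinates are the top-k eigenvectors of the
    double-centred matrix scaled by √eigenvalue; negative eigenvalues are
    truncated, and k is reduced (with a warning) if fewer positive
    eigenvalues exist.
    """
    if k < 1:
        raise ValueError("k must be ≥ 1")
    d = np.asarray(matrix.values, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, equal_nan=True):
        raise ValueError("input must be a square symmetric matrix")
    d = np.clip(d, 0.0, None)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-12, 1e-9 * abs(eigval[0])) if eigval.size else 0.0
    npos = int((eigval > tol).sum())
    if k > npos:
        logger.warning("requested k=%d but only %d positive eigenvalues; reducing", k, npos)
        k = max(npos, 1)
    coords = eigvec[:, :k] * np.sqrt(np.clip(eigval[:k], 0.0, None))
    return MdsCoordinates(list(matrix.labels), k, coords, eigval)


# ---------------------------------------------------------------------------
# Table writers (4-decimal TSV + full-precision JSON sidecar)


def _write_tsv_with_sidecar(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(json.loads(df.to_json(orient="records")), fh, indent=1)


def write_diversity_table(stats_list: list[DiversityStats], path):
    df = pd.DataFrame(
        [
            {"sample": s.sample_label, "n": s.n, "panel_size": s.panel_size, "He": s.He, "Ho": s.Ho, "Na": s.Na}
            for s in stats_list
        ]
    )
    _write_tsv_with_sidecar(df, path)


def write_fst_matrix(matrix: PairwiseFstMatrix, path):
    df = pd.DataFrame(matrix.values, columns=matrix.labels)
    df.insert(0, "sample", matrix.labels)
    _write_tsv_with_sidecar(df, path)


def write_mds_coordinates(mds: MdsCoordinates, path):
    df = pd.DataFrame(mds.coords, columns=[f"dim{i + 1}" for i in range(mds.k)])
    df.insert(0, "sample", mds.labels)
    _write_tsv_with_sidecar(df, path)
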