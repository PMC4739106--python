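"""Genetic assignment of individuals to pooled reference populations.

The default scoring rule is the Bayesian (Rannala–Mountain-style) Dirichlet
posterior-predictive genotype likelihood.  With per-locus allele counts n_i,
gene count n and k distinct alleles at the locus across all pools (a common
Dirichlet(1/k, …, 1/k) prior), and α = n + 1:

    P(homozygote ii)   = (n_i + 1/k)(n_i + 1 + 1/k) / (α(α + 1))
    P(heterozygote ij) = 2 (n_i + 1/k)(n_j + 1/k)   / (α(α + 1))

Loci missing in the scored genotype are skipped.  Leave-one-out (LOO)
self-assignment removes the focal individual's two genes from its own pool
before scoring.  The exclusion test ranks an individual's likelihood within
the likelihoods of genotypes simulated from the pool (Monte-Carlo rank
p-value with the +1 correction).

A frequency-based criterion (observed frequencies, pseudo-frequency
1/(2N+1) for unobserved alleles) is available for sensitivity analysis.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeDataset, IndividualGenotype, SampleCollection

logger = logging.getLogger(__name__)


@dataclass
class ReferencePool:
    """Pooled reference sample: per-locus allele counts plus member calls."""

    name: str
    locus_names: list[str]
    allele_counts: list[dict[int, int]]  # per locus: code -> gene count
    gene_counts: np.ndarray  # per locus
    members: np.ndarray  # (n, L, 2) calls
    member_ids: list[str]

    @property
    def n(self) -> int:
        return self.members.shape[0]

    def frequencies(self, locus: int) -> dict[int, float]:
        g = self.gene_counts[locus]
        return {a: c / g for a, c in self.allele_counts[locus].items()} if g else {}


def build_pool(samples: list[SampleCollection], name: str, locus_names: list[str]) -> ReferencePool:
    """Aggregate samples into a reference pool (missing calls add 0 genes)."""
    if not samples:
        raise ValueError("cannot build a pool from zero samples")
    members = np.concatenate([s.calls_array() for s in samples], axis=0)
    if members.shape[1] != len(locus_names):
        raise ValueError("samples and locus_names disagree on panel size")
    n_loci = members.shape[1]
    counts: list[dict[int, int]] = []
    genes = np.zeros(n_loci, dtype=int)
    for j in range(n_loci):
        calls = members[:, j, :]
        observed = calls[calls != MISSING]
        codes, cnt = np.unique(observed, return_counts=True)
        counts.append({int(a): int(c) for a, c in zip(codes, cnt)})
        genes[j] = observed.size
    ids = [ind.individual_id for s in samples for ind in s.individuals]
    return ReferencePool(name, list(locus_names), counts, genes, members, ids)


@dataclass
class AssignmentRecord:
    individual_id: str
    loglik: dict[str, float]
    assigned: str | None
    loo: bool = False
    exclusion_p: dict[str, float] | None = None
    error: str | None = None


@dataclass
class AssignmentSummary:
    group: str
    counts: dict[str, int]
    proportions: dict[str, float]


def summarize(group: str, records: list[AssignmentRecord], pool_names: list[str]) -> AssignmentSummary:
    counts = {p: 0 for p in pool_names}
    for r in records:
        if r.assigned is not None:
            counts[r.assigned] += 1
    total = sum(counts.values())
    props = {p: (c / total if total else float("nan")) for p, c in counts.items()}
    return AssignmentSummary(group, counts, props)


class AssignmentScorer:
    """Scores genotypes against a fixed set of reference pools.

    ``k`` per locus (the Dirichlet prior dimension) is counted once over the
    union of all pools plus any extra individuals to be assigned, so the
    prior is common across pools for the whole run.
    """

    def __init__(
        self,
        pools: list[ReferencePool],
        extra_calls: np.ndarray | None = None,
        criterion: str = "bayesian",
    ):
        if len(pools) < 1:
            raise ValueError("need at least one pool")
        if criterion not in ("bayesian", "frequency"):
            raise ValueError("criterion must be 'bayesian' or 'frequency'")
        panel = pools[0].locus_names
        for p in pools[1:]:
            if p.locus_names != panel:
                raise ValueError("pools must share one locus panel")
        self.pools = pools
        self.locus_names = panel
        self.criterion = criterion
        self.k = np.zeros(len(panel), dtype=int)
        for j in range(len(panel)):
            codes: set[int] = set()
            for p in pools:
                codes.update(p.allele_counts[j])
            if extra_calls is not None:
                obs = extra_calls[:, j, :]
                codes.update(int(a) for a in np.unique(obs[obs != MISSING]))
            self.k[j] = max(len(codes), 1)

    def _pair_prob(self, pool: ReferencePool, j: int, a: int, b: int, drop: tuple[int, int] | None) -> float:
        counts = pool.allele_counts[j]
        gene = int(pool.gene_counts[j])
        na = counts.get(a, 0)
        nb = counts.get(b, 0)
        if drop is not None:  # remove the focal individual's own two genes
            da, db = drop
            gene -= 2
            na -= (da == a) + (db == a)
            nb -= (da == b) + (db == b)
        if gene < 0 or na < 0 or nb < 0:
            raise ValueError("holdout removed more genes than the pool holds")
        if self.criterion == "bayesian":
            inv_k = 1.0 / self.k[j]
            alpha = gene + 1.0
            if a == b:
                return (na + inv_k) * (na + 1 + inv_k) / (alpha * (alpha + 1))
            return 2.0 * (na + inv_k) * (nb + inv_k) / (alpha * (alpha + 1))
        # frequency criterion
        pseudo = 1.0 / (2 * pool.n + 1)
        fa = na / gene if gene and na else pseudo
        fb = nb / gene if gene and nb else pseudo
        return fa * fa if a == b else 2.0 * fa * fb

    def loglik(
        self,
        calls: np.ndarray,
        pool: ReferencePool,
        holdout: bool = False,
    ) -> float:
        """Log-likelihood of one genotype (calls (L, 2)) under ``pool``.

        ``holdout=True`` applies the leave-one-out rule: the genotype's own
        genes are removed from the pool counts locus by locus.
        """
        total = 0.0
        used = 0
        for j in range(len(self.locus_names)):
            a, b = int(calls[j, 0]), int(calls[j, 1])
            if a == MISSING:
                continue
            if pool.gene_counts[j] == 0:
                continue  # pool has an all-missing locus: skip everywhere
            drop = (a, b) if holdout else None
            total += np.log(self._pair_prob(pool, j, a, b, drop))
            used += 1
        if used == 0:
            raise ValueError("genotype shares no scored locus with the pool")
        return total

    # -- batch operations ---------------------------------------------------

    def assign(self, individual_id: str, calls: np.ndarray, own_pool: str | None = None) -> AssignmentRecord:
        logliks: dict[str, float] = {}
        try:
            for pool in self.pools:
                logliks[pool.name] = self.loglik(calls, pool, holdout=(pool.name == own_pool))
        except ValueError as exc:
            return AssignmentRecord(individual_id, {}, None, loo=own_pool is not None, error=str(exc))
        best = max(logliks.values())
        winners = [name for name, v in logliks.items() if v == best]
        if len(winners) > 1:
            if own_pool in winners:
                winners = [own_pool]
            logger.info("assignment tie for %s: %s -> %s", individual_id, sorted(logliks), winners[0])
        return AssignmentRecord(individual_id, logliks, winners[0], loo=own_pool is not None)


def self_assign_loo(
    pools: list[ReferencePool], criterion: str = "bayesian"
) -> tuple[list[AssignmentRecord], list[AssignmentSummary]]:
    """Leave-one-out self-assignment of every reference individual."""
    if len(pools) < 2:
        raise ValueError("self-assignment needs at least two pools")
    scorer = AssignmentScorer(pools, criterion=criterion)
    records, summaries = [], []
    for pool in pools:
        pool_records = [
            scorer.assign(ind_id, pool.members[i], own_pool=pool.name)
            for i, ind_id in enumerate(pool.member_ids)
        ]
        records.extend(pool_records)
        summaries.append(summarize(pool.name, pool_records, [p.name for p in pools]))
    return records, summaries


def assign_individuals(
    fish: list, pools: list[ReferencePool], criterion: str = "bayesian"
) -> list[AssignmentRecord]:
    """Assign tagged fish (no leave-one-out: fish are not pool members)."""
    genotyped = [f.genotype.calls for f in fish if f.genotype is not None]
    extra = np.stack(genotyped) if genotyped else None
    scorer = AssignmentScorer(pools, extra_calls=extra, criterion=criterion)
    records = []
    for f in fish:
        if f.genotype is None or f.genotype.missing_mask().all():
            records.append(AssignmentRecord(f.fish_id, {}, None, error="no genotype data"))
            continue
        records.append(scorer.assign(f.fish_id, f.genotype.calls))
    return records


# ---------------------------------------------------------------------------
# Monte-Carlo exclusion


def _fish_rng(seed: int, fish_id: str) -> np.random.Generator:
    # per-fish stream keyed by a stable hash so results are order-independent
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(fish_id.encode())]))


def exclusion_test(
    fish,
    pools: list[ReferencePool],
    n_sim: int = 1000,
    seed: int = 0,
    threshold: float = 0.01,
    criterion: str = "bayesian",
) -> AssignmentRecord:
    """Monte-Carlo exclusion probabilities for one tagged fish.

    For each pool, ``n_sim`` multilocus genotypes are simulated in HWE from
    the pool's posterior allele frequencies (counts + 1/k prior mass,
    consistent with the scoring model) at the fish's non-missing loci;
    exclusion_p = (1 + #{simulated loglik ≤ fish loglik}) / (n_sim + 1).
    A fish is flagged (warning only) when max-over-pools p < ``threshold``.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be ≥ 100")
    scorer = AssignmentScorer(
        pools,
        extra_calls=fish.genotype.calls[None, :, :] if fish.genotype is not None else None,
        criterion=criterion,
    )
    rng = _fish_rng(seed, fish.fish_id)
    calls = fish.genotype.calls
    record = scorer.assign(fish.fish_id, calls)
    if record.error:
        return record
    excl: dict[str, float] = {}
    loci = [
        j
        for j in range(len(scorer.locus_names))
        if calls[j, 0] != MISSING and all(p.gene_counts[j] > 0 for p in pools)
    ]
    for pool in pools:
        sim_ll = np.zeros(n_sim)
        for j in loci:
            codes = np.array(sorted(pool.allele_counts[j]))
            adj = np.array([pool.allele_counts[j][int(a)] for a in codes], dtype=float) + 1.0 / scorer.k[j]
            freqs = adj / adj.sum()
            i1 = rng.choice(len(codes), size=n_sim, p=freqs)
            i2 = rng.choice(len(codes), size=n_sim, p=freqs)
            alpha = pool.gene_counts[j] + 1.0
            c1, c2 = adj[i1], adj[i2]
            hom = i1 == i2
            prob = np.where(hom, c1 * (c1 + 1.0), 2.0 * c1 * c2) / (alpha * (alpha + 1.0))
            sim_ll += np.log(prob)
        fish_ll = sum(
            np.log(scorer._pair_prob(pool, j, int(calls[j, 0]), int(calls[j, 1]), None)) for j in loci
        )
        excl[pool.name] = (1 + int((sim_ll <= fish_ll).sum())) / (n_sim + 1)
    record.exclusion_p = excl
    if max(excl.values()) < threshold:
        logger.warning(
            "fish %s: max exclusion p %.4f < %.3f — origin may lie outside the references",
            fish.fish_id,
            max(excl.values()),
            threshold,
        )
    return record


# ---------------------------------------------------------------------------
# Reference-subsampling robustness


def subsample_robustness(
    fish: list,
    pools: list[ReferencePool],
    groups: dict[str, str],
    n_target: int = 201,
    reps: int = 10,
    seed: int = 0,
    criterion: str = "bayesian",
) -> pd.DataFrame:
    """Re-assign tagged fish after repeatedly subsampling the largest pool to
    ``n_target`` individuals; returns mean assignment proportions per
    behavioural group over the replicates."""
    largest = max(pools, key=lambda p: p.n)
    if n_target > largest.n:
        raise ValueError(f"n_target={n_target} exceeds pool {largest.name} (n={largest.n})")
    rng = np.random.default_rng(seed)
    pool_names = [p.name for p in pools]
    acc: dict[str, list[dict[str, float]]] = {}
    for _ in range(reps):
        chosen = rng.choice(largest.n, size=n_target, replace=False)
        sub_sample = SampleCollection(
            largest.name,
            [IndividualGenotype(largest.member_ids[i], largest.members[i]) for i in sorted(chosen)],
        )
        sub_pool = build_pool([sub_sample], largest.name, largest.locus_names)
        rep_pools = [sub_pool if p is largest else p for p in pools]
        records = assign_individuals(fish, rep_pools, criterion=criterion)
        by_group: dict[str, list[AssignmentRecord]] = {}
        for f, r in zip(fish, records):
            g = groups.get(f.fish_id)
            if g is not None and r.assigned is not None:
                by_group.setdefault(g, []).append(r)
        for g, recs in by_group.items():
            acc.setdefault(g, []).append(summarize(g, recs, pool_names).proportions)
    rows = []
    for g in sorted(acc):
        mean_props = {p: float(np.mean([d[p] for d in acc[g]])) for p in pool_names}
        rows.append({"group": g, "reps": len(acc[g]), **mean_props})
    return pd.DataFrame(rows)
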