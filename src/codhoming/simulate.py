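"""Synthetic study generator: reference populations, tagged cohort, tracks.

Emulates the study design the analysis assumes: two reference regions
(Kattegat and North Sea/W Skagerrak) diverged at F_ST ≈ 0.004, a 12-locus
microsatellite panel with ~15 alleles per locus, reference sample sizes of
201 and 435, and a cohort of 100 archival-tagged fish of mixed origin with
five behavioural patterns, daily-longitude geolocation tracks with
Gaussian noise and isolated single-day outliers, and a philopatry
probability φ governing whether a directional migrant heads toward its
region of genetic origin.

Population divergence uses the Balding–Nichols model: each population's
allele frequencies at a locus are Dirichlet-distributed around the
ancestral frequencies p⁰ with concentration p⁰·(1−F)/F, so the expected
Weir–Cockerham θ between populations is ≈ F.  Genotypes are drawn in HWE.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import date as Date, timedelta

import numpy as np
import pandas as pd

from .behaviour import DIRECTION_OF, BehaviourCategory, TaggedFish
from .genotypes import (
    MISSING,
    GenotypeDataset,
    IndividualGenotype,
    Locus,
    SampleCollection,
    write_genepop,
    write_track_table,
)

logger = logging.getLogger(__name__)

POOL_NAMES = ("Kattegat", "NorthSea_WSkagerrak")
REGION_OF_POOL = {"Kattegat": "Kattegat", "NorthSea_WSkagerrak": "NorthSea"}

# reference geography (lat, lon): release/recapture anchors per region
POS = {
    "ESkagerrak": (58.30, 11.00),
    "Kattegat": (56.80, 11.90),
    "NorthSea": (56.00, 7.00),
    "KattegatDest": (56.70, 11.80),
}


@dataclass
class SyntheticConfig:
    """All generative parameters; defaults mirror the study conditions."""

    n_pops: int = 2
    fst_target: float = 0.004
    n_loci: int = 12
    alleles_per_locus: int | list[int] = 15
    ancestral_freq_model: str = "broken_stick"  # or "uniform"
    sample_sizes: tuple[int, ...] = (435, 201)  # aligned to pool_names
    missing_rate: float = 0.02
    n_tagged: int = 100
    origin_mix: tuple[float, ...] = (0.5, 0.5)
    philopatry_prob: float = 0.9
    p_migratory: float = 0.35
    release_mix: tuple[float, float] = (0.6, 0.4)  # (ESkagerrak, Kattegat)
    track_noise_sd: float = 0.2
    outlier_rate: float = 0.05
    group_sizes: tuple[int, int, int, int, int] | None = None  # exact behaviour counts
    seed: int = 0
    pool_names: tuple[str, ...] = POOL_NAMES

    def __post_init__(self):
        if not 0.0 < self.fst_target < 1.0:
            raise ValueError("fst_target must lie in (0, 1)")
        if not 0.0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5]")
        if not 0.0 <= self.outlier_rate <= 0.2:
            raise ValueError("outlier_rate must lie in [0, 0.2]")
        if abs(sum(self.origin_mix) - 1.0) > 1e-9:
            raise ValueError("origin_mix must sum to 1")
        if len(self.origin_mix) != self.n_pops or len(self.sample_sizes) != self.n_pops:
            raise ValueError("origin_mix and sample_sizes must have n_pops entries")
        if min(self.sample_sizes) < 1 or self.n_tagged < 1 or self.n_loci < 1:
            raise ValueError("all counts must be ≥ 1")
        k_min = (
            self.alleles_per_locus
            if isinstance(self.alleles_per_locus, int)
            else min(self.alleles_per_locus)
        )
        if k_min < 2:
            raise ValueError("each locus needs at least 2 alleles")


# ---------------------------------------------------------------------------
# Allele frequencies and genotypes


def simulate_allele_freqs(config: SyntheticConfig, seed: int | None = None) -> list[list[np.ndarray]]:
    """Per-population, per-locus allele frequency vectors (Balding–Nichols)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    counts = (
        [config.alleles_per_locus] * config.n_loci
        if isinstance(config.alleles_per_locus, int)
        else list(config.alleles_per_locus)
    )
    if min(counts) < 2:
        raise ValueError("each locus needs at least 2 alleles")
    f = config.fst_target
    ancestral = []
    for k in counts:
        if config.ancestral_freq_model == "uniform":
            p0 = np.full(k, 1.0 / k)
        elif config.ancestral_freq_model == "broken_stick":
            # classical broken-stick abundance sequence: uneven but with no
            # unobservable ultra-rare alleles (rarest ≈ 1/k² of the mass)
            p0 = np.array([sum(1.0 / j for j in range(i, k + 1)) for i in range(1, k + 1)]) / k
        else:
            raise ValueError(f"unknown ancestral model {config.ancestral_freq_model!r}")
        ancestral.append(p0)
    freqs: list[list[np.ndarray]] = []
    for _ in range(config.n_pops):
        pop = [rng.dirichlet(p0 * (1.0 - f) / f) for p0 in ancestral]
        freqs.append(pop)
    return freqs


def simulate_genotypes(
    freqs: list[np.ndarray],
    n: int,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    label: str = "sim",
) -> SampleCollection:
    """Draw ``n`` HWE individuals from per-locus frequency vectors.

    Allele codes are 1-based indices into each frequency vector; each
    locus-call is erased (both slots zero) with ``missing_rate``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_loci = len(freqs)
    calls = np.zeros((n, n_loci, 2), dtype=np.int32)
    for j, p in enumerate(freqs):
        codes = np.arange(1, len(p) + 1)
        calls[:, j, 0] = rng.choice(codes, size=n, p=p)
        calls[:, j, 1] = rng.choice(codes, size=n, p=p)
    if missing_rate > 0:
        erase = rng.random((n, n_loci)) < missing_rate
        calls[erase] = MISSING
    inds = [IndividualGenotype(f"{label}_{i + 1}", calls[i]) for i in range(n)]
    return SampleCollection(label, inds)


def simulate_reference_dataset(config: SyntheticConfig, freqs=None) -> GenotypeDataset:
    """Reference samples for every population, as a GenotypeDataset."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 1]))
    freqs = freqs if freqs is not None else simulate_allele_freqs(config)
    samples = [
        simulate_genotypes(freqs[i], config.sample_sizes[i], config.missing_rate, rng, label=config.pool_names[i])
        for i in range(config.n_pops)
    ]
    loci = [Locus(f"L{j + 1:02d}") for j in range(config.n_loci)]
    return GenotypeDataset(loci, samples).registered()


# ---------------------------------------------------------------------------
# Tagged cohort


def _behaviour_for(release_region: str, origin_pool: str, migratory: bool, philopatric: bool):
    """True behaviour label given release region, genetic origin and the
    philopatry coin.  A 'migrant' whose destination equals its release
    region ends up nonmigratory there."""
    if not migratory:
        return (
            BehaviourCategory.NONMIGRATORY_SKAGERRAK
            if release_region == "ESkagerrak"
            else BehaviourCategory.NONMIGRATORY_KATTEGAT
        )
    dest_pool = origin_pool if philopatric else [p for p in POOL_NAMES if p != origin_pool][0]
    dest_region = REGION_OF_POOL[dest_pool]
    if dest_region == "NorthSea":
        return (
            BehaviourCategory.SKAGERRAK_TO_NORTH_SEA
            if release_region == "ESkagerrak"
            else BehaviourCategory.KATTEGAT_TO_NORTH_SEA
        )
    # destination Kattegat
    if release_region == "ESkagerrak":
        return BehaviourCategory.SKAGERRAK_TO_KATTEGAT
    return BehaviourCategory.NONMIGRATORY_KATTEGAT


_GROUP_ORDER = (
    BehaviourCategory.SKAGERRAK_TO_NORTH_SEA,
    BehaviourCategory.KATTEGAT_TO_NORTH_SEA,
    BehaviourCategory.SKAGERRAK_TO_KATTEGAT,
    BehaviourCategory.NONMIGRATORY_SKAGERRAK,
    BehaviourCategory.NONMIGRATORY_KATTEGAT,
)

_RELEASE_OF_GROUP = {
    BehaviourCategory.SKAGERRAK_TO_NORTH_SEA: "ESkagerrak",
    BehaviourCategory.KATTEGAT_TO_NORTH_SEA: "Kattegat",
    BehaviourCategory.SKAGERRAK_TO_KATTEGAT: "ESkagerrak",
    BehaviourCategory.NONMIGRATORY_SKAGERRAK: "ESkagerrak",
    BehaviourCategory.NONMIGRATORY_KATTEGAT: "Kattegat",
}

#: the genetically "expected" pool per behaviour group: destination for
#: migrants, residence for nonmigratory fish (eastern Skagerrak residents
#: are of North Sea larval origin in this system).
_HOME_POOL_OF_GROUP = {
    BehaviourCategory.SKAGERRAK_TO_NORTH_SEA: "NorthSea_WSkagerrak",
    BehaviourCategory.KATTEGAT_TO_NORTH_SEA: "NorthSea_WSkagerrak",
    BehaviourCategory.SKAGERRAK_TO_KATTEGAT: "Kattegat",
    BehaviourCategory.NONMIGRATORY_SKAGERRAK: "NorthSea_WSkagerrak",
    BehaviourCategory.NONMIGRATORY_KATTEGAT: "Kattegat",
}


def simulate_tagged_cohort(
    config: SyntheticConfig, freqs=None, seed: int | None = None
) -> tuple[list[TaggedFish], pd.DataFrame]:
    """Simulate the tagged cohort with known truth.

    Each fish draws a genetic origin pool (``origin_mix``), a genotype from
    that pool's frequencies, a release region (``release_mix``) and a
    behaviour: directional with probability ``p_migratory``, heading toward
    its origin region with probability φ (``philopatry_prob``).  When
    ``group_sizes`` is set, the five behaviour-group counts are fixed
    exactly and origins are drawn conditionally (home pool with
    probability φ).  Returns the fish plus a truth table.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([(config.seed if seed is None else seed) & 0x7FFFFFFF, 2])
    )
    freqs = freqs if freqs is not None else simulate_allele_freqs(config)
    pool_idx = {name: i for i, name in enumerate(config.pool_names)}

    plan: list[tuple[str, str, BehaviourCategory]] = []  # (origin, release, behaviour)
    if config.group_sizes is not None:
        for group, size in zip(_GROUP_ORDER, config.group_sizes):
            for _ in range(size):
                home = _HOME_POOL_OF_GROUP[group]
                other = [p for p in POOL_NAMES if p != home][0]
                origin = home if rng.random() < config.philopatry_prob else other
                plan.append((origin, _RELEASE_OF_GROUP[group], group))
    else:
        for _ in range(config.n_tagged):
            origin = config.pool_names[rng.choice(config.n_pops, p=np.asarray(config.origin_mix))]
            release = "ESkagerrak" if rng.random() < config.release_mix[0] else "Kattegat"
            migratory = rng.random() < config.p_migratory
            philopatric = rng.random() < config.philopatry_prob
            plan.append((origin, release, _behaviour_for(release, origin, migratory, philopatric)))

    fish_list, truth_rows = [], []
    for i, (origin, release_region, behaviour) in enumerate(plan):
        fid = f"tag{i + 1:03d}"
        geno_sample = simulate_genotypes(
            freqs[pool_idx[origin]], 1, config.missing_rate, rng, label=fid
        )
        genotype = IndividualGenotype(fid, geno_sample.individuals[0].calls)
        release_date = Date(2003, 10, 1) + timedelta(days=int(rng.integers(0, 30)))
        liberty = int(rng.integers(60, 300))
        recapture_date = release_date + timedelta(days=liberty)
        fish = TaggedFish(
            fish_id=fid,
            release_date=release_date,
            recapture_date=recapture_date,
            release_pos=POS[release_region],
            release_region=release_region,
            genotype=genotype,
        )
        simulate_track(fish, behaviour, config, rng)
        fish_list.append(fish)
        truth_rows.append(
            {
                "fish_id": fid,
                "origin_pool": origin,
                "release_region": release_region,
                "behaviour": behaviour.value,
                "direction": DIRECTION_OF.get(behaviour, ""),
                "days_at_liberty": liberty,
            }
        )
    return fish_list, pd.DataFrame(truth_rows)


def simulate_track(
    fish: TaggedFish,
    behaviour: BehaviourCategory,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> None:
    """Attach a daily longitude series and recapture position to ``fish``.

    Directional fish drift linearly from the release longitude to a
    destination beyond the relevant boundary, reaching it at ~60% of the
    liberty period; nonmigratory fish hold station.  Gaussian noise
    (``track_noise_sd``) plus isolated single-day outliers (>1.5° jumps at
    ``outlier_rate``, never three in a row) are superimposed.
    """
    days = (fish.recapture_date - fish.release_date).days
    release_lat, release_lon = fish.release_pos
    if behaviour in (BehaviourCategory.SKAGERRAK_TO_NORTH_SEA, BehaviourCategory.KATTEGAT_TO_NORTH_SEA):
        dest = POS["NorthSea"]
    elif behaviour is BehaviourCategory.SKAGERRAK_TO_KATTEGAT:
        dest = POS["KattegatDest"]
    else:
        dest = fish.release_pos
    t = np.arange(1, days)
    if days > 1:
        frac = np.clip(t / max(0.6 * days, 1.0), 0.0, 1.0)
        lons = release_lon + frac * (dest[1] - release_lon)
        lons = lons + rng.normal(0.0, config.track_noise_sd, size=lons.size)
        outlier = rng.random(lons.size) < config.outlier_rate
        for i in range(2, lons.size):  # never ≥3 consecutive outliers
            if outlier[i - 2] and outlier[i - 1]:
                outlier[i] = False
        jumps = rng.uniform(1.5, 3.0, size=lons.size) * rng.choice([-1.0, 1.0], size=lons.size)
        lons = np.where(outlier, lons + jumps, lons)
        fish.track = [
            (fish.release_date + timedelta(days=int(d)), float(lon)) for d, lon in zip(t, lons)
        ]
    else:
        fish.track = []
    fish.recapture_pos = (
        float(dest[0] + rng.normal(0.0, 0.05)),
        float(dest[1] + rng.normal(0.0, 0.05)),
    )


# ---------------------------------------------------------------------------
# Whole-study bundle


def simulate_study(config: SyntheticConfig):
    """References + tagged cohort + truth, from one root seed."""
    freqs = simulate_allele_freqs(config)
    refs = simulate_reference_dataset(config, freqs)
    fish, truth = simulate_tagged_cohort(config, freqs)
    return refs, fish, truth


def write_study(config: SyntheticConfig, outdir) -> dict:
    """Write Genepop references, tagged-fish Genepop, track CSV and truth JSON."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    refs, fish, truth = simulate_study(config)
    write_genepop(refs, out / "references.gen")
    # label "tag" matches the fish-id prefix so ids survive the Genepop
    # round trip unchanged and re-join the track table by fish_id
    tagged = GenotypeDataset(
        list(refs.loci),
        [SampleCollection("tag", [f.genotype for f in fish])],
    ).registered()
    write_genepop(tagged, out / "tagged.gen")
    write_track_table(fish, out / "tracks.csv")
    truth.to_csv(out / "truth.csv", index=False)
    payload = {"config": asdict(config), "n_reference": int(sum(config.sample_sizes)), "n_tagged": len(fish)}
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
    return payload
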