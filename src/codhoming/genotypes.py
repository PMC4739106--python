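"""Multilocus genotype containers and plain-text I/O.

The central object is :class:`GenotypeDataset`: an ordered locus panel plus a
sequence of population samples, each holding diploid allele calls as small
integer codes (microsatellite fragment sizes or arbitrary labels).  Allele
code 0 is reserved for missing data; a call is either fully present (both
allele slots > 0) or fully missing (both 0) — half-calls are rejected at
parse time because none of the downstream estimators defines them.

I/O covers the Genepop exchange format (title line, locus names, ``pop``
blocks, fixed-width 2- or 3-digit allele codes), a sidecar CSV for sample
metadata that Genepop cannot carry, and a CSV dialect for archival-tag
release/recapture metadata plus daily longitude series.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from datetime import date as Date

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = 0

REGIONS = ("NorthSea", "WSkagerrak", "ESkagerrak", "Kattegat", "Oresund")
STAGES = ("adult", "juvenile", "tagged")


class GenepopFormatError(ValueError):
    """Malformed Genepop input (names the offending line)."""


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus: a name and the allele codes observed for it."""

    name: str
    allele_codes: tuple[int, ...] = ()

    def __post_init__(self):
        if any(a <= 0 for a in self.allele_codes):
            raise ValueError(f"locus {self.name}: allele codes must be positive (0 is missing)")


@dataclass
class IndividualGenotype:
    """One individual's diploid calls, aligned to the dataset locus order.

    ``calls`` has shape (n_loci, 2); a missing call is (0, 0).
    """

    individual_id: str
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int32)
        if self.calls.ndim != 2 or self.calls.shape[1] != 2:
            raise ValueError("calls must have shape (n_loci, 2)")
        half = (self.calls == MISSING).sum(axis=1) == 1
        if half.any():
            raise ValueError(
                f"individual {self.individual_id}: half-missing call at locus index "
                f"{int(np.nonzero(half)[0][0])}"
            )

    def missing_mask(self) -> np.ndarray:
        return self.calls[:, 0] == MISSING


@dataclass
class SampleCollection:
    """A population sample (e.g. a spawning aggregation) with metadata."""

    label: str
    individuals: list[IndividualGenotype]
    region: str | None = None
    stage: str | None = None
    date: str | None = None
    lat: float | None = None
    lon: float | None = None
    cohorts: list[str] | None = None  # optional per-individual year-class labels

    def __post_init__(self):
        if len(self.individuals) < 1:
            raise ValueError(f"sample {self.label}: needs at least one individual")
        if self.cohorts is not None and len(self.cohorts) != len(self.individuals):
            raise ValueError(f"sample {self.label}: cohort labels must match individuals")

    @property
    def n(self) -> int:
        return len(self.individuals)

    def calls_array(self) -> np.ndarray:
        """All calls stacked, shape (n, n_loci, 2)."""
        return np.stack([ind.calls for ind in self.individuals])


@dataclass
class GenotypeDataset:
    loci: list[Locus]
    samples: list[SampleCollection]

    def __post_init__(self):
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names")
        labels = [s.label for s in self.samples]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate sample labels")
        for s in self.samples:
            for ind in s.individuals:
                if ind.calls.shape[0] != len(self.loci):
                    raise ValueError(
                        f"individual {ind.individual_id} in {s.label}: "
                        f"{ind.calls.shape[0]} loci, dataset has {len(self.loci)}"
                    )

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def locus_index(self, name: str) -> int:
        try:
            return self.locus_names.index(name)
        except ValueError:
            raise KeyError(f"unknown locus {name!r}") from None

    def sample(self, label: str) -> SampleCollection:
        for s in self.samples:
            if s.label == label:
                return s
        raise KeyError(f"unknown sample {label!r}")

    def registered(self) -> "GenotypeDataset":
        """Return a copy with every observed allele code registered in its Locus."""
        observed: list[set[int]] = [set(l.allele_codes) for l in self.loci]
        for s in self.samples:
            arr = s.calls_array()
            for j in range(len(self.loci)):
                codes = arr[:, j, :].ravel()
                observed[j].update(int(c) for c in codes[codes != MISSING])
        loci = [Locus(l.name, tuple(sorted(obs))) for l, obs in zip(self.loci, observed)]
        return GenotypeDataset(loci, self.samples)


# ---------------------------------------------------------------------------
# Genepop I/O


def _infer_pop_label(ids: list[str], k: int, taken: set[str]) -> str:
    # Real Genepop files conventionally repeat the population name in every
    # individual id (or prefix ids with it); use the common prefix, falling
    # back to the last id, then to an auto-generated label.
    prefix = os.path.commonprefix(ids).rstrip("_-. ")
    label = prefix or (ids[-1].strip() if ids and ids[-1].strip() else f"pop{k}")
    base, i = label, 1
    while label in taken:
        i += 1
        label = f"{base}.{i}"
    return label


def _decode_allele_token(token: str, lineno: int) -> tuple[int, int, int]:
    if len(token) == 4:
        digits = 2
    elif len(token) == 6:
        digits = 3
    else:
        raise GenepopFormatError(
            f"line {lineno}: allele string {token!r} has odd length (expected 4 or 6 digits)"
        )
    if not token.isdigit():
        raise GenepopFormatError(f"line {lineno}: non-numeric allele string {token!r}")
    a, b = int(token[:digits]), int(token[digits:])
    if (a == MISSING) != (b == MISSING):
        raise GenepopFormatError(f"line {lineno}: half-missing call {token!r}")
    return a, b, digits


def read_genepop(path) -> GenotypeDataset:
    """Parse a Genepop file into a :class:`GenotypeDataset`.

    Accepts locus names one per line or comma-separated, ``pop`` delimiters in
    any case, and 2- or 3-digit allele encodings (0-codes = missing).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenepopFormatError("empty file")

    def is_pop(line: str) -> bool:
        return line.strip().lower() == "pop"

    locus_names: list[str] = []
    i = 1
    while i < len(lines) and not is_pop(lines[i]):
        locus_names.extend(t.strip() for t in lines[i].split(",") if t.strip())
        i += 1
    if i == len(lines):
        raise GenepopFormatError("no 'pop' delimiter found")

    pops: list[tuple[list[str], list[list[tuple[int, int]]]]] = []
    digits_seen: set[int] = set()
    while i < len(lines):
        assert is_pop(lines[i])
        ids: list[str] = []
        rows: list[list[tuple[int, int]]] = []
        i += 1
        while i < len(lines) and not is_pop(lines[i]):
            line = lines[i]
            if line.strip():
                if "," in line:
                    ind_id, rest = line.split(",", 1)
                else:  # tolerate comma-less dialects: first token is the id
                    ind_id, _, rest = line.strip().partition(" ")
                tokens = rest.split()
                if len(tokens) != len(locus_names):
                    raise GenepopFormatError(
                        f"line {i + 1}: {len(tokens)} genotypes for {len(locus_names)} loci"
                    )
                calls = []
                for tok in tokens:
                    a, b, d = _decode_allele_token(tok, i + 1)
                    digits_seen.add(d)
                    calls.append((a, b))
                ids.append(ind_id.strip())
                rows.append(calls)
            i += 1
        if not rows:
            raise GenepopFormatError("empty pop block")
        pops.append((ids, rows))
    if len(digits_seen) > 1:
        logger.warning("mixed 2- and 3-digit allele encodings in %s", path)

    taken: set[str] = set()
    samples = []
    for k, (ids, rows) in enumerate(pops, start=1):
        label = _infer_pop_label(ids, k, taken)
        taken.add(label)
        inds = [
            IndividualGenotype(ind_id, np.array(calls, dtype=np.int32))
            for ind_id, calls in zip(ids, rows)
        ]
        samples.append(SampleCollection(label, inds))
    loci = [Locus(name) for name in locus_names]
    return GenotypeDataset(loci, samples).registered()


def write_genepop(dataset: GenotypeDataset, path, digits: int = 3, title: str | None = None):
    """Write ``dataset`` in Genepop format (input order preserved, re-readable).

    Individual ids are emitted prefixed with their sample label when they do
    not already carry it, so that labels survive a read-back.
    """
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    if not dataset.samples:
        raise ValueError("refusing to write a Genepop file with no samples")
    limit = 10**digits
    for locus in dataset.loci:
        for a in locus.allele_codes:
            if a >= limit:
                raise ValueError(
                    f"allele code {a} at locus {locus.name} does not fit in {digits} digits"
                )
    out = [title or "codhoming genotype export"]
    out.extend(dataset.locus_names)
    for s in dataset.samples:
        out.append("pop")
        for ind in s.individuals:
            if int(ind.calls.max(initial=0)) >= limit:
                raise ValueError(
                    f"allele code {int(ind.calls.max())} ({ind.individual_id}) "
                    f"does not fit in {digits} digits"
                )
            ind_id = ind.individual_id
            if not ind_id.startswith(s.label):
                ind_id = f"{s.label}_{ind_id}"
            tokens = [
                f"{int(a):0{digits}d}{int(b):0{digits}d}" for a, b in ind.calls
            ]
            out.append(f"{ind_id} ,  " + " ".join(tokens))
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Panel subsetting and sample pooling


def subset_loci(dataset: GenotypeDataset, panel: list[str]) -> GenotypeDataset:
    """Restrict the dataset to a locus panel (individuals are retained even if
    fully missing on the panel)."""
    if not panel:
        raise ValueError("empty locus panel")
    idx = [dataset.locus_index(name) for name in panel]
    loci = [dataset.loci[j] for j in idx]
    samples = []
    for s in dataset.samples:
        inds = [
            IndividualGenotype(ind.individual_id, ind.calls[idx])
            for ind in s.individuals
        ]
        samples.append(replace(s, individuals=inds))
    return GenotypeDataset(loci, samples)


def pool_samples(dataset: GenotypeDataset, pooling: dict[str, str]) -> GenotypeDataset:
    """Merge samples into pools per a label→pool-name map.

    Samples whose label is not in the map are dropped.  Pool n equals the sum
    of member n; member order follows the dataset.
    """
    for label in pooling:
        dataset.sample(label)  # raises on unknown label
    pool_order: list[str] = []
    members: dict[str, list[SampleCollection]] = {}
    for s in dataset.samples:
        pool = pooling.get(s.label)
        if pool is None:
            continue
        if pool not in members:
            members[pool] = []
            pool_order.append(pool)
        members[pool].append(s)
    if not pool_order:
        raise ValueError("pooling produced no pools")
    pooled = []
    for pool in pool_order:
        inds = [ind for s in members[pool] for ind in s.individuals]
        cohorts = None
        if all(s.cohorts is not None for s in members[pool]):
            cohorts = [c for s in members[pool] for c in s.cohorts]
        regions = {s.region for s in members[pool]}
        pooled.append(
            SampleCollection(
                pool,
                inds,
                region=regions.pop() if len(regions) == 1 else None,
                cohorts=cohorts,
            )
        )
    return GenotypeDataset(list(dataset.loci), pooled)


# ---------------------------------------------------------------------------
# Sample-metadata sidecar and archival-tag track tables


def attach_metadata(dataset: GenotypeDataset, path) -> GenotypeDataset:
    """Attach region/stage/date/coordinates from a CSV keyed by sample label."""
    meta = pd.read_csv(path).set_index("label")
    for s in dataset.samples:
        if s.label in meta.index:
            row = meta.loc[s.label]
            s.region = row.get("region", s.region)
            s.stage = row.get("stage", s.stage)
            s.date = row.get("date", s.date)
            s.lat = float(row["lat"]) if "lat" in row and pd.notna(row["lat"]) else s.lat
            s.lon = float(row["lon"]) if "lon" in row and pd.notna(row["lon"]) else s.lon
    return dataset


def read_track_table(path, genotypes: dict[str, IndividualGenotype] | None = None):
    """Read the archival-tag CSV: ``record=meta`` rows carry release/recapture
    metadata, ``record=daily`` rows carry (fish_id, date, longitude).

    Returns a list of :class:`codhoming.behaviour.TaggedFish`, daily series
    date-ordered.  A fish with no daily rows gets a length-0 track.
    """
    from .behaviour import TaggedFish  # deferred: behaviour imports this module

    df = pd.read_csv(path)
    meta = df[df["record"] == "meta"]
    daily = df[df["record"] == "daily"]
    known = set(meta["fish_id"])
    orphans = set(daily["fish_id"]) - known
    if orphans:
        raise ValueError(f"daily rows for unknown fish_id(s): {sorted(orphans)}")
    fish = []
    for _, row in meta.iterrows():
        fid = row["fish_id"]
        rel = pd.Timestamp(row["release_date"]).date()
        rec = pd.Timestamp(row["recapture_date"]).date()
        if rec < rel:
            raise ValueError(f"fish {fid}: recapture {rec} before release {rel}")
        sub = daily[daily["fish_id"] == fid].copy()
        sub["date"] = pd.to_datetime(sub["date"]).dt.date
        sub = sub.sort_values("date")
        track = list(zip(sub["date"], sub["longitude"].astype(float)))
        fish.append(
            TaggedFish(
                fish_id=str(fid),
                release_date=rel,
                recapture_date=rec,
                release_pos=(float(row["release_lat"]), float(row["release_lon"])),
                recapture_pos=(float(row["recapture_lat"]), float(row["recapture_lon"]))
                if pd.notna(row.get("recapture_lat"))
                else None,
                release_region=str(row["release_region"]),
                track=track,
                genotype=(genotypes or {}).get(str(fid)),
            )
        )
    return fish


def write_track_table(fish_list, path):
    """Inverse of :func:`read_track_table` (genotypes travel separately)."""
    rows = []
    for f in fish_list:
        rows.append(
            {
                "record": "meta",
                "fish_id": f.fish_id,
                "release_date": f.release_date,
                "release_lat": f.release_pos[0],
                "release_lon": f.release_pos[1],
                "release_region": f.release_region,
                "recapture_date": f.recapture_date,
                "recapture_lat": f.recapture_pos[0] if f.recapture_pos else "",
                "recapture_lon": f.recapture_pos[1] if f.recapture_pos else "",
                "date": "",
                "longitude": "",
            }
        )
        for d, lon in f.track:
            rows.append(
                {
                    "record": "daily",
                    "fish_id": f.fish_id,
                    "release_date": "",
                    "release_lat": "",
                    "release_lon": "",
                    "release_region": "",
                    "recapture_date": "",
                    "recapture_lat": "",
                    "recapture_lon": "",
                    "date": d,
                    "longitude": lon,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
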