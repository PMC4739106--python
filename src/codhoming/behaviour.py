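"""Geolocation validation and migratory-behaviour classification.

Archival tags yield noisy daily longitude estimates.  A new longitude is
accepted as a genuine relocation only when three or more consecutive daily
estimates each depart more than one degree from the currently valid
longitude and cohere mutually (each within one degree of their window
mean); the committed location is that window mean, dated at the window's
first day.  Isolated excursions are discarded as noise.

Classification into the five behavioural categories:

* time at liberty must exceed 30 days (strict), else the fish is excluded;
* any validated longitude — or the recapture longitude — west of 10°E means
  the fish migrated towards the North Sea;
* otherwise a fish released in the eastern Skagerrak but recaptured inside
  the Kattegat box migrated Skagerrak → Kattegat;
* otherwise it is nonmigratory within its release region.

The Skagerrak/Kattegat boundary is not a standard definition; the default
puts the Kattegat at latitude < 57.75°N (Skagen's parallel) and longitude
≥ 10°E, and both numbers are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from enum import Enum

from .genotypes import IndividualGenotype

NORTH_SEA_LON = 10.0  # "west of 10°E" rule


class BehaviourCategory(str, Enum):
    SKAGERRAK_TO_NORTH_SEA = "SkagerrakToNorthSea"
    KATTEGAT_TO_NORTH_SEA = "KattegatToNorthSea"
    SKAGERRAK_TO_KATTEGAT = "SkagerrakToKattegat"
    NONMIGRATORY_SKAGERRAK = "NonmigratorySkagerrak"
    NONMIGRATORY_KATTEGAT = "NonmigratoryKattegat"
    EXCLUDED = "Excluded"


#: categories that count as directional migration, with their direction
DIRECTION_OF = {
    BehaviourCategory.SKAGERRAK_TO_NORTH_SEA: "towardsNorthSea",
    BehaviourCategory.KATTEGAT_TO_NORTH_SEA: "towardsNorthSea",
    BehaviourCategory.SKAGERRAK_TO_KATTEGAT: "towardsKattegat",
}


@dataclass
class Boundary:
    """Skagerrak/Kattegat partition: Kattegat = lat < ``lat_cut`` and lon ≥ ``lon_cut``."""

    lat_cut: float = 57.75
    lon_cut: float = 10.0

    def in_kattegat(self, lat: float, lon: float) -> bool:
        return lat < self.lat_cut and lon >= self.lon_cut


@dataclass
class TaggedFish:
    fish_id: str
    release_date: Date
    recapture_date: Date
    release_pos: tuple[float, float]  # (lat, lon), WGS84, east-positive
    release_region: str  # "ESkagerrak" | "Kattegat"
    recapture_pos: tuple[float, float] | None = None
    track: list[tuple[Date, float]] = field(default_factory=list)  # (date, longitude)
    genotype: IndividualGenotype | None = None
    spans_spawning: bool = True  # spring-tagged fish may not span a spawning season

    def __post_init__(self):
        if self.recapture_date < self.release_date:
            raise ValueError(f"fish {self.fish_id}: recapture before release")


@dataclass
class Classification:
    fish_id: str
    category: BehaviourCategory
    days_at_liberty: int
    min_validated_longitude: float
    reason: str | None = None


def days_at_liberty(fish: TaggedFish) -> int:
    """Calendar days between release and recapture."""
    return (fish.recapture_date - fish.release_date).days


def validate_geolocations(
    track: list[tuple[Date, float]], release_lon: float, window: int = 3, degree: float = 1.0
) -> list[tuple[Date | None, float]]:
    """Reduce a noisy daily longitude series to validated relocations.

    Returns the validated series, starting with (None, release longitude).
    A run of ``window`` consecutive estimates, each departing more than
    ``degree`` from the current valid longitude and each within ``degree``
    of the run mean, commits the run mean at the run's first date.
    """
    validated: list[tuple[Date | None, float]] = [(None, release_lon)]
    current = release_lon
    buf: list[tuple[Date, float]] = []
    for day, lon in track:
        if abs(lon - current) > degree:
            buf.append((day, lon))
            if len(buf) >= window:
                recent = buf[-window:]
                mean = sum(l for _, l in recent) / window
                if all(abs(l - mean) <= degree for _, l in recent):
                    current = mean
                    validated.append((recent[0][0], mean))
                    buf = []
        else:
            buf = []
    return validated


def classify_behaviour(
    fish: TaggedFish,
    validated: list[tuple[Date | None, float]] | None = None,
    boundary: Boundary | None = None,
) -> Classification:
    """Map one tagged fish to exactly one behavioural category.

    Deterministic and total: every fish gets a category, or Excluded with a
    reason code (``short_liberty`` or ``unreconstructable``).
    """
    boundary = boundary or Boundary()
    liberty = days_at_liberty(fish)
    if validated is None:
        validated = validate_geolocations(fish.track, fish.release_pos[1])
    lons = [lon for _, lon in validated]
    min_lon = min(lons)
    if liberty <= 30:
        return Classification(fish.fish_id, BehaviourCategory.EXCLUDED, liberty, min_lon, "short_liberty")
    if fish.recapture_pos is None and not fish.track:
        return Classification(fish.fish_id, BehaviourCategory.EXCLUDED, liberty, min_lon, "unreconstructable")
    rec_lon = fish.recapture_pos[1] if fish.recapture_pos else None
    west = min_lon < NORTH_SEA_LON or (rec_lon is not None and rec_lon < NORTH_SEA_LON)
    release_sk = fish.release_region != "Kattegat"
    if west:
        cat = (
            BehaviourCategory.SKAGERRAK_TO_NORTH_SEA
            if release_sk
            else BehaviourCategory.KATTEGAT_TO_NORTH_SEA
        )
        return Classification(fish.fish_id, cat, liberty, min_lon)
    if release_sk and fish.recapture_pos is not None and boundary.in_kattegat(*fish.recapture_pos):
        return Classification(fish.fish_id, BehaviourCategory.SKAGERRAK_TO_KATTEGAT, liberty, min_lon)
    cat = (
        BehaviourCategory.NONMIGRATORY_SKAGERRAK if release_sk else BehaviourCategory.NONMIGRATORY_KATTEGAT
    )
    return Classification(fish.fish_id, cat, liberty, min_lon)


def classify_cohort(
    fish_list: list[TaggedFish], boundary: Boundary | None = None
) -> list[Classification]:
    return [classify_behaviour(f, boundary=boundary) for f in fish_list]
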