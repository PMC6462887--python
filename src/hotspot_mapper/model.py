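"""Core domain model for venue-based programmatic mapping.

Programmatic mapping enumerates the venues ("hotspots") where a key
population congregates to meet sex partners, validates each venue on
site, and aggregates per-venue head counts into subcounty- and
county-level population size estimates.  This module defines the typed
records exchanged between pipeline stages and the strict three-tier
geography (county > subcounty > zone) that scopes both deduplication
and the mobility adjustment.

All counts are integers at ingestion; estimates become reals only after
the min/max midpoint operation in :mod:`hotspot_mapper.estimation`.
Geographic coordinates are deliberately not modeled: the method works
on named venues within administrative units.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date
from typing import Dict, Iterable, Iterator, List, Optional, Tuple


class MappingError(Exception):
    """Base class for all domain errors raised by this package."""


class SchemaError(MappingError):
    """A tabular input is missing a required column or has a bad header."""


class RecordValidationError(MappingError):
    """A record violates a domain invariant (e.g. min_count > max_count)."""


class UnknownReferenceError(MappingError):
    """A record references a geography unit, hotspot or code that does not exist."""


class InfeasibleConfigError(MappingError):
    """A generator configuration cannot be realised (e.g. mobility degree
    exceeding the number of venues in a subcounty)."""


class GeoLevel(str, enum.Enum):
    COUNTY = "county"
    SUBCOUNTY = "subcounty"
    ZONE = "zone"


class Typology(str, enum.Enum):
    """The eight venue typologies used to profile sex work hotspots."""

    PUBLIC_PLACE = "public_place"
    STREET = "street"
    BAR_NIGHTCLUB = "bar_nightclub_casino_hotel"
    BAR_RESTAURANT = "bar_restaurant_cafe"
    GUESTHOUSE = "guesthouse_lodge"
    SEX_DEN = "sex_den_brothel"
    BREW_DEN = "local_brew_den"
    OTHER = "other"

    @property
    def label(self) -> str:
        return _TYPOLOGY_LABELS[self]


_TYPOLOGY_LABELS = {
    Typology.PUBLIC_PLACE: "Public place",
    Typology.STREET: "Street",
    Typology.BAR_NIGHTCLUB: "Bar/nightclub/casino/hotel (with rooms)",
    Typology.BAR_RESTAURANT: "Bar/restaurant/café (without rooms)",
    Typology.GUESTHOUSE: "Guesthouse/lodge (without bars)",
    Typology.SEX_DEN: "Sex den/brothel",
    Typology.BREW_DEN: "Local brew den",
    Typology.OTHER: "Other",
}


class Group(str, enum.Enum):
    """Population groups counted at each venue during on-site validation."""

    FSW_ALL = "fsw_all"
    FSW_14_24 = "fsw_14_24"
    TRANSACTIONAL_14_24 = "transactional_14_24"
    CASUAL_14_24 = "casual_14_24"


class Day(str, enum.Enum):
    NORMAL = "normal"
    PEAK = "peak"


class HotspotStatus(str, enum.Enum):
    NAMED = "named"
    VALIDATED_ACTIVE = "validated_active"
    INACTIVE = "inactive"


class HotspotSource(str, enum.Enum):
    LEVEL_ONE = "level_one"
    LEVEL_TWO_SNOWBALL = "level_two_snowball"
    PROGRAM_LISTING = "program_listing"


@dataclass(frozen=True)
class GeoUnit:
    """One node of the administrative hierarchy, with female population
    denominators (persons) used for proportion-of-population reporting."""

    id: str
    name: str
    level: GeoLevel
    parent_id: Optional[str] = None
    female_pop_14_24: int = 0
    female_pop_14_44: int = 0

    def __post_init__(self) -> None:
        if not self.id:
            raise RecordValidationError("geography unit id must be nonempty")
        if self.level == GeoLevel.COUNTY and self.parent_id:
            raise RecordValidationError(f"county {self.id!r} must not have a parent")
        if self.level != GeoLevel.COUNTY and not self.parent_id:
            raise RecordValidationError(f"{self.level.value} {self.id!r} requires a parent")
        if self.female_pop_14_24 < 0 or self.female_pop_14_44 < 0:
            raise RecordValidationError(f"negative denominator for {self.id!r}")


class Geography:
    """A validated county > subcounty > zone tree with denominator lookups."""

    def __init__(self, units: Iterable[GeoUnit]):
        self._units: Dict[str, GeoUnit] = {}
        for u in units:
            if u.id in self._units:
                raise RecordValidationError(f"duplicate geography id {u.id!r}")
            self._units[u.id] = u
        self._validate_tree()

    def _validate_tree(self) -> None:
        expected_parent = {GeoLevel.ZONE: GeoLevel.SUBCOUNTY, GeoLevel.SUBCOUNTY: GeoLevel.COUNTY}
        for u in self._units.values():
            if u.level == GeoLevel.COUNTY:
                continue
            parent = self._units.get(u.parent_id or "")
            if parent is None:
                raise UnknownReferenceError(
                    f"{u.level.value} {u.id!r} references unknown parent {u.parent_id!r}"
                )
            if parent.level != expected_parent[u.level]:
                raise RecordValidationError(
                    f"{u.level.value} {u.id!r} must have a {expected_parent[u.level].value} "
                    f"parent, got {parent.level.value} {parent.id!r}"
                )

    def __iter__(self) -> Iterator[GeoUnit]:
        return iter(sorted(self._units.values(), key=lambda u: (u.level.value, u.id)))

    def __contains__(self, geo_id: str) -> bool:
        return geo_id in self._units

    def unit(self, geo_id: str) -> GeoUnit:
        try:
            return self._units[geo_id]
        except KeyError:
            raise UnknownReferenceError(f"unknown geography unit {geo_id!r}") from None

    def units(self, level: Optional[GeoLevel] = None) -> List[GeoUnit]:
        out = [u for u in self._units.values() if level is None or u.level == level]
        return sorted(out, key=lambda u: u.id)

    def parent(self, geo_id: str) -> Optional[GeoUnit]:
        u = self.unit(geo_id)
        return self._units[u.parent_id] if u.parent_id else None

    def children(self, geo_id: str) -> List[GeoUnit]:
        return sorted(
            (u for u in self._units.values() if u.parent_id == geo_id), key=lambda u: u.id
        )

    def subcounty_of(self, geo_id: str) -> GeoUnit:
        """Resolve a zone (or subcounty) id to its subcounty."""
        u = self.unit(geo_id)
        if u.level == GeoLevel.SUBCOUNTY:
            return u
        if u.level == GeoLevel.ZONE:
            return self._units[u.parent_id]  # type: ignore[index]
        raise RecordValidationError(f"{geo_id!r} is a county, not within a subcounty")

    def county_of(self, geo_id: str) -> GeoUnit:
        u = self.unit(geo_id)
        while u.parent_id:
            u = self._units[u.parent_id]
        return u

    def contains(self, ancestor_id: str, geo_id: str) -> bool:
        """True if ``geo_id`` equals or lies below ``ancestor_id`` in the tree."""
        u: Optional[GeoUnit] = self.unit(geo_id)
        self.unit(ancestor_id)
        while u is not None:
            if u.id == ancestor_id:
                return True
            u = self._units.get(u.parent_id) if u.parent_id else None
        return False

    def zones_in(self, geo_id: str) -> List[GeoUnit]:
        return sorted(
            (u for u in self._units.values()
             if u.level == GeoLevel.ZONE and self.contains(geo_id, u.id)),
            key=lambda u: u.id,
        )


@dataclass(frozen=True)
class HotspotMention:
    """One raw level-one report of a venue by one key informant."""

    raw_name: str
    zone_id: str
    informant_type: str
    typology_guess: Optional[Typology] = None
    mention_date: Optional[date] = None

    def __post_init__(self) -> None:
        if not self.raw_name or not self.raw_name.strip():
            raise RecordValidationError("mention raw_name must be nonempty")
        if not self.zone_id:
            raise RecordValidationError("mention zone_id must be nonempty")


@dataclass
class Hotspot:
    """A canonical, deduplicated venue in the hotspot register.

    ``typology`` may be unset while status is ``named``; it must be
    assigned (normally from the level-two validation record) before the
    hotspot enters any estimation.
    """

    id: str
    canonical_name: str
    zone_id: str
    typology: Optional[Typology] = None
    status: HotspotStatus = HotspotStatus.NAMED
    known_to_program: bool = False
    source: HotspotSource = HotspotSource.LEVEL_ONE

    def __post_init__(self) -> None:
        if not self.id or not self.canonical_name or not self.zone_id:
            raise RecordValidationError("hotspot id, name and zone are required")


@dataclass(frozen=True)
class CountPair:
    """A reported minimum/maximum head count (persons) for one venue."""

    min_count: int
    max_count: int

    def __post_init__(self) -> None:
        if self.min_count < 0 or self.max_count < 0:
            raise RecordValidationError(
                f"counts must be nonnegative, got ({self.min_count}, {self.max_count})"
            )
        if self.min_count > self.max_count:
            raise RecordValidationError(
                f"min_count {self.min_count} exceeds max_count {self.max_count}"
            )


@dataclass(frozen=True)
class MobilityResponse:
    """One respondent's answer on venue mobility.

    ``total_hotspots_visited`` counts distinct venues *including* the
    index venue, so 1 means the respondent visits no other venue.
    """

    total_hotspots_visited: int

    def __post_init__(self) -> None:
        if self.total_hotspots_visited < 1:
            raise RecordValidationError("total_hotspots_visited must be >= 1")

    @property
    def visits_other_hotspots(self) -> bool:
        return self.total_hotspots_visited >= 2


CountKey = Tuple[Group, Day]


@dataclass
class LevelTwoRecord:
    """On-site validation record for one venue: typology, active status,
    min/max head counts per population group on a normal and a peak day,
    mobility responses, and snowball venue mentions."""

    hotspot_id: str
    hotspot_name: str
    zone_id: str
    typology: Optional[Typology]
    active: bool
    counts: Dict[CountKey, CountPair]
    peak_day_of_week: str = ""
    peak_time: str = ""
    mobility_responses: List[MobilityResponse] = field(default_factory=list)
    men_count: Optional[CountPair] = None  # collected, stored, never analysed
    snowball_mentions: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for day in Day:
            all_cp = self.counts.get((Group.FSW_ALL, day))
            young_cp = self.counts.get((Group.FSW_14_24, day))
            if all_cp is not None and young_cp is not None:
                if young_cp.min_count > all_cp.min_count or young_cp.max_count > all_cp.max_count:
                    raise RecordValidationError(
                        f"hotspot {self.hotspot_id!r}: fsw_14_24 {day.value}-day counts "
                        f"({young_cp.min_count}, {young_cp.max_count}) exceed fsw_all "
                        f"({all_cp.min_count}, {all_cp.max_count})"
                    )

    def count(self, group: Group, day: Day) -> CountPair:
        cp = self.counts.get((group, day))
        return cp if cp is not None else CountPair(0, 0)


@dataclass(frozen=True)
class MobilityParams:
    """Subcounty-level mobility summary feeding the deduplication heuristic.

    ``p`` is the proportion of respondents who visit other venues and
    ``m`` the mean number of venues visited (index venue included) among
    those who do; ``m`` is defined as 1 when ``p`` is 0.
    """

    geo_id: str
    p: float
    m: float
    n_respondents: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise RecordValidationError(f"p must be in [0, 1], got {self.p}")
        if self.m < 1.0:
            raise RecordValidationError(f"m must be >= 1, got {self.m}")
        if self.p > 0 and self.m < 2.0:
            raise RecordValidationError(
                f"m counts the index venue, so p > 0 requires m >= 2 (got m={self.m})"
            )


@dataclass(frozen=True)
class SizeEstimate:
    """A point/low/high population size estimate for a group in a geography."""

    geo_id: str
    group: Group
    point: float
    low: float
    high: float
    adjusted_for_mobility: bool = False
    n_hotspots: int = 0

    def __post_init__(self) -> None:
        eps = 1e-9
        if self.low < -eps or self.point < -eps or self.high < -eps:
            raise RecordValidationError("estimates must be nonnegative")
        if self.low > self.point + eps or self.point > self.high + eps:
            raise RecordValidationError(
                f"estimate ordering violated: low={self.low} point={self.point} high={self.high}"
            )
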