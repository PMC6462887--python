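"""Shared fixtures: a small geography, record builders, and the published
typology-by-subcounty counts from the 2014 Mombasa mapping round, used as
input data for the contingency-table tests."""

import pytest

from hotspot_mapper.model import (
    CountPair,
    Day,
    GeoLevel,
    GeoUnit,
    Geography,
    Group,
    Hotspot,
    HotspotStatus,
    LevelTwoRecord,
    Typology,
)

# Typology x subcounty hotspot counts (columns A-D), published totals
# 280 / 164 / 466 / 115 and grand total 1025.
TABLE2_COUNTS = {
    Typology.PUBLIC_PLACE: (12, 6, 13, 2),
    Typology.STREET: (21, 29, 31, 2),
    Typology.BAR_NIGHTCLUB: (63, 40, 81, 26),
    Typology.BAR_RESTAURANT: (82, 49, 118, 22),
    Typology.GUESTHOUSE: (19, 10, 38, 6),
    Typology.SEX_DEN: (8, 6, 2, 0),
    Typology.BREW_DEN: (68, 19, 173, 57),
    Typology.OTHER: (7, 5, 10, 0),
}


@pytest.fixture
def geography() -> Geography:
    """One county, four subcounties, one zone each."""
    units = [
        GeoUnit(id="county-1", name="County", level=GeoLevel.COUNTY,
                female_pop_14_24=134_885, female_pop_14_44=319_032),
    ]
    for i in range(1, 5):
        units.append(GeoUnit(id=f"sc-{i}", name=f"Subcounty {i}",
                             level=GeoLevel.SUBCOUNTY, parent_id="county-1",
                             female_pop_14_24=134_885 // 4, female_pop_14_44=319_032 // 4))
        units.append(GeoUnit(id=f"zone-{i}", name=f"Zone {i}",
                             level=GeoLevel.ZONE, parent_id=f"sc-{i}"))
    return Geography(units)


def make_record(
    hotspot_id: str,
    zone_id: str = "zone-1",
    fsw_peak=(0, 0),
    fsw_normal=None,
    young_peak=(0, 0),
    tc_peak=(0, 0),
    casual_peak=(0, 0),
    active: bool = True,
    typology: Typology = Typology.BAR_RESTAURANT,
    mobility=(),
    snowball=(),
    name: str = "",
) -> LevelTwoRecord:
    from hotspot_mapper.model import MobilityResponse

    counts = {(g, d): CountPair(0, 0) for g in Group for d in Day}
    counts[(Group.FSW_ALL, Day.PEAK)] = CountPair(*fsw_peak)
    counts[(Group.FSW_ALL, Day.NORMAL)] = CountPair(*(fsw_normal or fsw_peak))
    counts[(Group.FSW_14_24, Day.PEAK)] = CountPair(*young_peak)
    counts[(Group.TRANSACTIONAL_14_24, Day.PEAK)] = CountPair(*tc_peak)
    counts[(Group.CASUAL_14_24, Day.PEAK)] = CountPair(*casual_peak)
    return LevelTwoRecord(
        hotspot_id=hotspot_id,
        hotspot_name=name or hotspot_id,
        zone_id=zone_id,
        typology=typology,
        active=active,
        counts=counts,
        mobility_responses=[MobilityResponse(k) for k in mobility],
        snowball_mentions=list(snowball),
    )


def make_hotspot(
    hotspot_id: str,
    name: str = "",
    zone_id: str = "zone-1",
    typology: Typology = Typology.BAR_RESTAURANT,
    status: HotspotStatus = HotspotStatus.VALIDATED_ACTIVE,
    known: bool = False,
) -> Hotspot:
    return Hotspot(
        id=hotspot_id,
        canonical_name=name or hotspot_id,
        zone_id=zone_id,
        typology=typology,
        status=status,
        known_to_program=known,
    )


@pytest.fixture
def table2_register(geography):
    """A validated register reproducing the published typology-by-subcounty
    counts, with known/new flags set so that 419 of 1025 hotspots are known
    and 226 of the 317 local brew dens are newly identified."""
    register = []
    idx = 0
    for typology, per_sc in TABLE2_COUNTS.items():
        for sc, count in enumerate(per_sc, start=1):
            for _ in range(count):
                idx += 1
                register.append(make_hotspot(f"hs-{idx:05d}", zone_id=f"zone-{sc}",
                                             typology=typology))
    # brew dens: 91 known / 226 new; everything else: 328 known / 380 new
    brew = [h for h in register if h.typology == Typology.BREW_DEN]
    other = [h for h in register if h.typology != Typology.BREW_DEN]
    for h in brew[:91]:
        h.known_to_program = True
    for h in other[:328]:
        h.known_to_program = True
    return register
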