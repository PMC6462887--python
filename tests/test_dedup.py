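"""Name normalization, mention clustering, program-listing flags and
snowball closure."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from hotspot_mapper import dedup
from hotspot_mapper.model import (
    HotspotMention,
    HotspotSource,
    HotspotStatus,
    RecordValidationError,
)
from hotspot_mapper.synthetic import GeneratorConfig, generate_county

from conftest import make_hotspot, make_record


def mention(name, zone="zone-1"):
    return HotspotMention(raw_name=name, zone_id=zone, informant_type="fsw")


class TestNormalizeLabel:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("  Mama Njeri's  BAR ", "mama njeris bar"),
            ("CLUB-X", "club x"),
            ("club x", "club x"),
            ("Blue   Bay—Den", "blue bay den"),
        ],
    )
    def test_examples(self, raw, expected):
        assert dedup.normalize_label(raw) == expected

    def test_empty_rejected(self):
        with pytest.raises(RecordValidationError):
            dedup.normalize_label("   ")

    @given(st.text(min_size=1).filter(lambda s: s.strip()))
    @settings(max_examples=200, deadline=None)
    def test_idempotent(self, s):
        once = dedup.normalize_label(s)
        if once:
            assert dedup.normalize_label(once) == once


class TestDedupeMentions:
    def test_identical_names_collapse_within_zone(self):
        register = dedup.dedupe_mentions([mention("Club X")] * 3)
        assert len(register) == 1
        assert register[0].status == HotspotStatus.NAMED

    def test_same_name_in_two_zones_stays_distinct(self):
        register = dedup.dedupe_mentions(
            [mention("Club X", "zone-1"), mention("Club X", "zone-2")]
        )
        assert len(register) == 2

    def test_canonical_name_is_most_frequent_spelling(self):
        ms = [mention("CLUB X"), mention("Club X"), mention("Club X"), mention("club-x")]
        register = dedup.dedupe_mentions(ms)
        assert len(register) == 1
        assert register[0].canonical_name == "Club X"

    def test_canonical_tie_broken_lexicographically(self):
        register = dedup.dedupe_mentions([mention("club x"), mention("CLUB X")])
        assert register[0].canonical_name == "CLUB X"

    def test_fuzzy_merge_catches_single_edit(self):
        register = dedup.dedupe_mentions(
            [mention("Mama Njeris Bar"), mention("Mama Njeris Baar")], 0.9
        )
        assert len(register) == 1
        # exact-only threshold keeps them apart
        register = dedup.dedupe_mentions(
            [mention("Mama Njeris Bar"), mention("Mama Njeris Baar")], 1.0
        )
        assert len(register) == 2

    def test_order_independence(self):
        county = generate_county(GeneratorConfig(seed=5, n_venues=60, n_fsw_true=500))
        base = dedup.dedupe_mentions(county.mentions)
        rng = random.Random(0)
        for _ in range(3):
            shuffled = list(county.mentions)
            rng.shuffle(shuffled)
            assert dedup.dedupe_mentions(shuffled) == base

    def test_register_size_monotone_in_threshold(self):
        county = generate_county(GeneratorConfig(seed=5, n_venues=60, n_fsw_true=500))
        sizes = [len(dedup.dedupe_mentions(county.mentions, thr))
                 for thr in (1.0, 0.9, 0.7)]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_register_size_tracks_reachable_venues(self):
        county = generate_county(GeneratorConfig(seed=5))
        register = dedup.dedupe_mentions(county.mentions)
        register = dedup.snowball_update(register, county.level_two_records)
        n_reachable = len(county.ground_truth.reachable_venue_ids)
        assert n_reachable <= len(register) <= round(1.1 * n_reachable)


class TestProgramListing:
    def test_empty_listing_flags_nothing(self):
        register = dedup.dedupe_mentions([mention("Club X")])
        assert all(not h.known_to_program
                   for h in dedup.merge_with_listing(register, []))

    def test_identical_listing_flags_everything(self):
        register = dedup.dedupe_mentions([mention("Club X"), mention("Bar Y")])
        listing = [make_hotspot(f"prog-{i}", name=h.canonical_name, zone_id=h.zone_id)
                   for i, h in enumerate(register)]
        assert all(h.known_to_program
                   for h in dedup.merge_with_listing(register, listing))

    def test_match_is_zone_scoped(self):
        register = dedup.dedupe_mentions([mention("Club X", "zone-1")])
        listing = [make_hotspot("prog-1", name="Club X", zone_id="zone-2")]
        assert not dedup.merge_with_listing(register, listing)[0].known_to_program

    def test_flags_match_ground_truth_without_noise(self):
        county = generate_county(GeneratorConfig.noise_free(seed=9))
        register = dedup.dedupe_mentions(county.mentions)
        register = dedup.merge_with_listing(register, county.program_listing)
        truth = {v.name: v.known_to_program for v in county.venues}
        for h in register:
            assert h.known_to_program == truth[h.canonical_name]
        share = sum(h.known_to_program for h in register) / len(register)
        truth_share = sum(truth.values()) / len(truth)
        assert share == pytest.approx(truth_share)


class TestSnowball:
    def test_chained_referrals_reach_closure(self):
        register = dedup.dedupe_mentions([mention("Venue A")])
        records = [
            make_record("r1", name="Venue A", snowball=["Venue B"]),
            make_record("r2", name="Venue B", snowball=["Venue C"]),
            make_record("r3", name="Venue C"),
        ]
        updated = dedup.snowball_update(register, records)
        names = sorted(h.canonical_name for h in updated)
        assert names == ["Venue A", "Venue B", "Venue C"]
        added = [h for h in updated if h.source == HotspotSource.LEVEL_TWO_SNOWBALL]
        assert len(added) == 2
        assert all(h.status == HotspotStatus.NAMED for h in added)

    def test_known_venue_not_duplicated(self):
        register = dedup.dedupe_mentions([mention("Venue A"), mention("Venue B")])
        records = [make_record("r1", name="Venue A", snowball=["Venue B", "venue-b"])]
        assert len(dedup.snowball_update(register, records)) == 2


class TestValidationLinkage:
    def test_statuses_and_typology_follow_records(self, geography):
        register = dedup.dedupe_mentions(
            [mention("Venue A"), mention("Venue B"), mention("Venue C")]
        )
        records = [
            make_record("rA", name="Venue A", active=True),
            make_record("rB", name="Venue B", active=False),
        ]
        linked = dedup.link_records(register, records)
        updated = dedup.apply_validation(register, linked)
        by_name = {h.canonical_name: h for h in updated}
        assert by_name["Venue A"].status == HotspotStatus.VALIDATED_ACTIVE
        assert by_name["Venue A"].typology == records[0].typology
        assert by_name["Venue B"].status == HotspotStatus.INACTIVE
        assert by_name["Venue C"].status == HotspotStatus.NAMED

    def test_duplicate_exact_claims_rejected(self):
        register = dedup.dedupe_mentions([mention("Venue A")])
        records = [make_record("r1", name="Venue A"), make_record("r2", name="venue a")]
        with pytest.raises(RecordValidationError, match="more than"):
            dedup.link_records(register, records)
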