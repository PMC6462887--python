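"""Consolidation of raw venue mentions into a unique hotspot register.

Level-one key informant interviews produce many overlapping, noisily
spelled reports of the same venues.  This module collapses them into a
canonical register, checks the register against the HIV prevention
program's listing of venues it already serves ("known" vs "newly
identified"), and folds in venues discovered through level-two snowball
referrals until closure.

Matching is *zone-scoped*: identical names in different data collection
zones are treated as distinct venues, and venues are never merged across
zone boundaries.  Within a zone, names are compared on a normalized key
(case-folded, punctuation-stripped, whitespace-collapsed), with optional
fuzzy merging of keys whose edit similarity reaches a threshold.  The
default threshold of 0.9 tolerates single-character misspellings of
typical venue names while keeping distinct venues apart; a threshold of
1.0 disables fuzzy merging entirely.

The whole procedure is deterministic and order-independent: permuting
the input mentions yields an identical register.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from difflib import SequenceMatcher
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .model import (
    Hotspot,
    HotspotMention,
    HotspotSource,
    HotspotStatus,
    LevelTwoRecord,
    RecordValidationError,
    Typology,
)

logger = logging.getLogger(__name__)

_APOSTROPHES = "'’ʼ"
_NON_WORD = re.compile(r"[^\w]+", flags=re.UNICODE)

DEFAULT_SIMILARITY_THRESHOLD = 0.9


def normalize_label(raw_name: str) -> str:
    """Normalize a venue name to its matching key.

    Apostrophes are deleted (``Njeri's`` -> ``njeris``), every other
    non-word character becomes a space, case is folded and whitespace
    collapsed.  Idempotent by construction.
    """
    if not raw_name or not raw_name.strip():
        raise RecordValidationError("cannot normalize an empty venue name")
    s = raw_name.casefold()
    for ch in _APOSTROPHES:
        s = s.replace(ch, "")
    s = _NON_WORD.sub(" ", s).replace("_", " ")
    return " ".join(s.split())


def label_similarity(a: str, b: str) -> float:
    """Edit similarity in [0, 1] between two normalized keys."""
    if a == b:
        return 1.0
    # cheap upper bound prefilter before the quadratic matcher
    if min(len(a), len(b)) * 2 < max(len(a), len(b)):
        return 0.0
    return SequenceMatcher(None, a, b).ratio()


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self._parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self._parent[x] != x:
            self._parent[x] = self._parent[self._parent[x]]
            x = self._parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller key becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self._parent[rb] = ra


def _cluster_keys(keys: Sequence[str], threshold: float) -> Dict[str, str]:
    """Partition normalized keys by transitive fuzzy similarity.

    Returns a map key -> cluster root.  Built from the sorted unique key
    list with all-pairs comparison, so independent of input order, and
    monotone: lowering the threshold only adds merges.
    """
    keys = sorted(set(keys))
    uf = _UnionFind(keys)
    if threshold < 1.0:
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                if label_similarity(a, b) >= threshold:
                    uf.union(a, b)
    return {k: uf.find(k) for k in keys}


def dedupe_mentions(
    mentions: Sequence[HotspotMention],
    similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
) -> List[Hotspot]:
    """Collapse level-one mentions into a register of ``named`` hotspots.

    One hotspot is created per match cluster within a zone.  The
    canonical name is the most frequent raw spelling in the cluster
    (ties broken lexicographically); the typology is the most frequent
    informant guess, if any.  Ids are assigned deterministically from
    the sorted (zone, cluster key) order.
    """
    if not 0.0 <= similarity_threshold <= 1.0:
        raise RecordValidationError("similarity_threshold must be in [0, 1]")
    by_zone: Dict[str, List[HotspotMention]] = defaultdict(list)
    for m in mentions:
        by_zone[m.zone_id].append(m)

    clusters: List[Tuple[str, str, List[HotspotMention]]] = []  # (zone, root, members)
    for zone_id in sorted(by_zone):
        zone_mentions = by_zone[zone_id]
        key_of = {id(m): normalize_label(m.raw_name) for m in zone_mentions}
        root_of = _cluster_keys(list(key_of.values()), similarity_threshold)
        members: Dict[str, List[HotspotMention]] = defaultdict(list)
        for m in zone_mentions:
            members[root_of[key_of[id(m)]]].append(m)
        for root in sorted(members):
            clusters.append((zone_id, root, members[root]))
            logger.debug(
                "zone %s: cluster %r <- %d mention(s)", zone_id, root, len(members[root])
            )

    register = []
    for idx, (zone_id, _root, cluster) in enumerate(clusters, start=1):
        name_counts = Counter(m.raw_name for m in cluster)
        top = max(name_counts.values())
        canonical = min(n for n, c in name_counts.items() if c == top)
        guess_counts = Counter(
            m.typology_guess for m in cluster if m.typology_guess is not None
        )
        typology: Optional[Typology] = None
        if guess_counts:
            top = max(guess_counts.values())
            typology = min((t for t, c in guess_counts.items() if c == top), key=lambda t: t.value)
        register.append(
            Hotspot(
                id=f"hs-{idx:05d}",
                canonical_name=canonical,
                zone_id=zone_id,
                typology=typology,
                status=HotspotStatus.NAMED,
                source=HotspotSource.LEVEL_ONE,
            )
        )
    return register


def _zone_keys(hotspots: Iterable[Hotspot]) -> Dict[str, List[Tuple[str, Hotspot]]]:
    out: Dict[str, List[Tuple[str, Hotspot]]] = defaultdict(list)
    for h in hotspots:
        out[h.zone_id].append((normalize_label(h.canonical_name), h))
    return out


def _match_in_zone(
    key: str,
    zone_entries: Sequence[Tuple[str, Hotspot]],
    threshold: float,
) -> Optional[Hotspot]:
    exact = [h for entry_key, h in zone_entries if entry_key == key]
    if exact:
        return min(exact, key=lambda h: h.id)
    if threshold >= 1.0:
        return None
    best: Optional[Tuple[float, str, Hotspot]] = None
    for entry_key, hotspot in zone_entries:
        sim = label_similarity(key, entry_key)
        if sim >= threshold and (best is None or (sim, entry_key) > (best[0], best[1])):
            best = (sim, entry_key, hotspot)
    return best[2] if best else None


def merge_with_listing(
    register: Sequence[Hotspot],
    program_listing: Sequence[Hotspot],
    similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
) -> List[Hotspot]:
    """Flag register venues already known to the program.

    A hotspot is flagged ``known_to_program`` iff a zone-scoped key match
    (exact or fuzzy at the dedup threshold) exists in the program listing.
    Returns a new register; the input is not mutated.
    """
    listing_keys: Dict[str, List[Tuple[str, Hotspot]]] = _zone_keys(program_listing)
    out = []
    for h in register:
        key = normalize_label(h.canonical_name)
        match = _match_in_zone(key, listing_keys.get(h.zone_id, []), similarity_threshold)
        out.append(
            Hotspot(
                id=h.id,
                canonical_name=h.canonical_name,
                zone_id=h.zone_id,
                typology=h.typology,
                status=h.status,
                known_to_program=match is not None,
                source=h.source,
            )
        )
    return out


def link_records(
    register: Sequence[Hotspot],
    records: Sequence[LevelTwoRecord],
    similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
) -> Dict[str, LevelTwoRecord]:
    """Attach level-two records to register hotspots.

    A record matches by exact register id first, then by zone-scoped
    exact name key; records still unmatched are fuzzy-matched, but only
    to register entries that no other record has claimed (an ambiguous
    fuzzy hit on an already-linked hotspot is dropped, not an error).
    Two records claiming the same hotspot exactly violate the
    one-validation-visit-per-venue invariant and raise.
    """
    by_id = {h.id: h for h in register}
    zone_entries = _zone_keys(register)
    linked: Dict[str, LevelTwoRecord] = {}
    deferred: List[LevelTwoRecord] = []
    for rec in records:
        target: Optional[Hotspot] = by_id.get(rec.hotspot_id)
        if target is None and rec.hotspot_name:
            key = normalize_label(rec.hotspot_name)
            target = _match_in_zone(key, zone_entries.get(rec.zone_id, []), 1.0)
            if target is None:
                deferred.append(rec)
                continue
        if target is None:
            logger.debug("level-two record %r matches no register entry", rec.hotspot_id)
            continue
        if target.id in linked:
            raise RecordValidationError(
                f"hotspot {target.id!r} ({target.canonical_name!r}) matched by more than "
                "one level-two record"
            )
        linked[target.id] = rec
    for rec in deferred:
        key = normalize_label(rec.hotspot_name)
        target = _match_in_zone(key, zone_entries.get(rec.zone_id, []), similarity_threshold)
        if target is None or target.id in linked:
            logger.debug("level-two record %r left unlinked", rec.hotspot_id)
            continue
        linked[target.id] = rec
    return linked


def apply_validation(
    register: Sequence[Hotspot],
    linked: Mapping[str, LevelTwoRecord],
) -> List[Hotspot]:
    """Set validation outcome (active/inactive) and on-site typology from
    the linked level-two records.  Unvisited hotspots stay ``named``."""
    out = []
    for h in register:
        rec = linked.get(h.id)
        if rec is None:
            status, typology = h.status, h.typology
        else:
            status = HotspotStatus.VALIDATED_ACTIVE if rec.active else HotspotStatus.INACTIVE
            typology = rec.typology if rec.typology is not None else h.typology
        out.append(
            Hotspot(
                id=h.id,
                canonical_name=h.canonical_name,
                zone_id=h.zone_id,
                typology=typology,
                status=status,
                known_to_program=h.known_to_program,
                source=h.source,
            )
        )
    return out


def snowball_update(
    register: Sequence[Hotspot],
    level_two_records: Sequence[LevelTwoRecord],
    similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
) -> List[Hotspot]:
    """Add venues named during level-two snowball referrals, to closure.

    Each snowball mention is scoped to the referring record's zone.  A
    mention that matches no existing register key (exact or fuzzy) enters
    the register as a new ``named`` hotspot with
    ``source=level_two_snowball``.  Only records linked to the current
    register contribute referrals, and the pass is iterated until no new
    venue appears.
    """
    register = list(register)
    while True:
        linked = link_records(register, level_two_records, similarity_threshold)
        zone_entries = _zone_keys(register)
        # (zone, key) -> raw spellings proposed for the new venue
        candidates: Dict[Tuple[str, str], Counter] = defaultdict(Counter)
        for rec_id, rec in sorted(linked.items()):
            for raw in rec.snowball_mentions:
                key = normalize_label(raw)
                if _match_in_zone(key, zone_entries.get(rec.zone_id, []),
                                  similarity_threshold) is None:
                    candidates[(rec.zone_id, key)][raw] += 1
        if not candidates:
            return register
        # collapse fuzzy-close candidate keys within each zone before adding
        added_keys: Dict[str, List[str]] = defaultdict(list)
        next_idx = len(register) + 1
        for (zone_id, key), spellings in sorted(candidates.items()):
            if any(label_similarity(key, k) >= similarity_threshold
                   for k in added_keys[zone_id]):
                continue
            added_keys[zone_id].append(key)
            top = max(spellings.values())
            canonical = min(n for n, c in spellings.items() if c == top)
            register.append(
                Hotspot(
                    id=f"hs-{next_idx:05d}",
                    canonical_name=canonical,
                    zone_id=zone_id,
                    status=HotspotStatus.NAMED,
                    source=HotspotSource.LEVEL_TWO_SNOWBALL,
                )
            )
            next_idx += 1
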