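"""Readers and writers for the pipeline's tabular interchange files.

All tabular files are UTF-8 comma-delimited text with a header row;
reports and ground truth are JSON.  The exact column contracts are
documented in ``docs/schemas.md`` and mirrored by the ``*_COLUMNS``
constants below.  Every reader enforces the domain invariants of
:mod:`hotspot_mapper.model` and raises:

* :class:`~hotspot_mapper.model.SchemaError` — a required column is missing,
* :class:`~hotspot_mapper.model.RecordValidationError` — a row violates an
  invariant (the message names the offending row),
* :class:`~hotspot_mapper.model.UnknownReferenceError` — a row references an
  unknown zone, hotspot or typology code.

Writer/reader pairs round-trip: ``read_x(write_x(records)) == records``.
"""

from __future__ import annotations

import json
from datetime import date
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .model import (
    CountPair,
    Day,
    GeoLevel,
    GeoUnit,
    Geography,
    Group,
    Hotspot,
    HotspotMention,
    HotspotSource,
    HotspotStatus,
    LevelTwoRecord,
    MobilityResponse,
    RecordValidationError,
    SchemaError,
    Typology,
    UnknownReferenceError,
)

PathLike = Union[str, Path]

GEOGRAPHY_COLUMNS = ["id", "name", "level", "parent_id", "female_pop_14_24", "female_pop_14_44"]
MENTION_COLUMNS = ["raw_name", "zone_id", "informant_type", "typology_guess", "mention_date"]
REGISTER_COLUMNS = [
    "id", "canonical_name", "zone_id", "typology", "status", "known_to_program", "source",
]

_COUNT_COLUMNS = [
    f"{group.value}_{day.value}_{bound}"
    for group in Group
    for day in Day
    for bound in ("min", "max")
]
LEVEL_TWO_COLUMNS = (
    ["hotspot_id", "hotspot_name", "zone_id", "typology", "active",
     "peak_day_of_week", "peak_time"]
    + _COUNT_COLUMNS
    + ["men_min", "men_max", "mobility_responses", "snowball_mentions"]
)

# list-valued cells are flattened into delimited strings inside one CSV cell
_RESPONSE_SEP = ";"
_SNOWBALL_SEP = "|"


def _read_csv(path: PathLike, required: Sequence[str], kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{kind} file {path}: missing required column {col!r}")
    return df


def _to_int(value: str, row: int, col: str, path: PathLike) -> int:
    value = value.strip()
    if value == "":
        return 0
    try:
        return int(value)
    except ValueError:
        raise RecordValidationError(
            f"{path} row {row}: column {col!r} is not an integer: {value!r}"
        ) from None


def _parse_typology(value: str, row: int, path: PathLike) -> Optional[Typology]:
    value = value.strip()
    if value == "":
        return None
    try:
        return Typology(value)
    except ValueError:
        raise UnknownReferenceError(
            f"{path} row {row}: unknown typology code {value!r}"
        ) from None


def read_geography(path: PathLike) -> Geography:
    df = _read_csv(path, GEOGRAPHY_COLUMNS, "geography")
    units = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            level = GeoLevel(row.level.strip())
        except ValueError:
            raise UnknownReferenceError(
                f"{path} row {i}: unknown geography level {row.level!r}"
            ) from None
        units.append(
            GeoUnit(
                id=row.id.strip(),
                name=row.name.strip(),
                level=level,
                parent_id=row.parent_id.strip() or None,
                female_pop_14_24=_to_int(row.female_pop_14_24, i, "female_pop_14_24", path),
                female_pop_14_44=_to_int(row.female_pop_14_44, i, "female_pop_14_44", path),
            )
        )
    geo = Geography(units)
    for county in geo.units(GeoLevel.COUNTY):
        if county.female_pop_14_24 <= 0 or county.female_pop_14_44 <= 0:
            raise RecordValidationError(
                f"county {county.id!r} must carry positive female population denominators"
            )
    return geo


def write_geography(path: PathLike, geography: Geography) -> None:
    rows = [
        {
            "id": u.id, "name": u.name, "level": u.level.value,
            "parent_id": u.parent_id or "",
            "female_pop_14_24": u.female_pop_14_24,
            "female_pop_14_44": u.female_pop_14_44,
        }
        for u in geography
    ]
    pd.DataFrame(rows, columns=GEOGRAPHY_COLUMNS).to_csv(path, index=False)


def read_mentions(path: PathLike, geography: Optional[Geography] = None) -> List[HotspotMention]:
    df = _read_csv(path, MENTION_COLUMNS, "mentions")
    mentions = []
    for i, row in enumerate(df.itertuples(index=False)):
        zone_id = row.zone_id.strip()
        if geography is not None and zone_id not in geography:
            raise UnknownReferenceError(f"{path} row {i}: unknown zone {zone_id!r}")
        raw_date = row.mention_date.strip()
        try:
            mentions.append(
                HotspotMention(
                    raw_name=row.raw_name,
                    zone_id=zone_id,
                    informant_type=row.informant_type.strip(),
                    typology_guess=_parse_typology(row.typology_guess, i, path),
                    mention_date=date.fromisoformat(raw_date) if raw_date else None,
                )
            )
        except RecordValidationError as exc:
            raise RecordValidationError(f"{path} row {i}: {exc}") from None
    return mentions


def write_mentions(path: PathLike, mentions: Sequence[HotspotMention]) -> None:
    rows = [
        {
            "raw_name": m.raw_name,
            "zone_id": m.zone_id,
            "informant_type": m.informant_type,
            "typology_guess": m.typology_guess.value if m.typology_guess else "",
            "mention_date": m.mention_date.isoformat() if m.mention_date else "",
        }
        for m in mentions
    ]
    pd.DataFrame(rows, columns=MENTION_COLUMNS).to_csv(path, index=False)


def read_level_two(path: PathLike, geography: Optional[Geography] = None) -> List[LevelTwoRecord]:
    df = _read_csv(path, LEVEL_TWO_COLUMNS, "level-two")
    records = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False)):
        d = row._asdict()
        hotspot_id = d["hotspot_id"].strip()
        if hotspot_id in seen:
            raise RecordValidationError(
                f"{path} row {i}: duplicate level-two record for hotspot {hotspot_id!r}"
            )
        seen.add(hotspot_id)
        zone_id = d["zone_id"].strip()
        if geography is not None and zone_id not in geography:
            raise UnknownReferenceError(f"{path} row {i}: unknown zone {zone_id!r}")
        counts: Dict = {}
        try:
            for group in Group:
                for day in Day:
                    lo = _to_int(d[f"{group.value}_{day.value}_min"], i,
                                 f"{group.value}_{day.value}_min", path)
                    hi = _to_int(d[f"{group.value}_{day.value}_max"], i,
                                 f"{group.value}_{day.value}_max", path)
                    counts[(group, day)] = CountPair(lo, hi)
            men: Optional[CountPair] = None
            if d["men_min"].strip() or d["men_max"].strip():
                men = CountPair(_to_int(d["men_min"], i, "men_min", path),
                                _to_int(d["men_max"], i, "men_max", path))
            responses = [
                MobilityResponse(int(tok))
                for tok in d["mobility_responses"].split(_RESPONSE_SEP)
                if tok.strip()
            ]
            records.append(
                LevelTwoRecord(
                    hotspot_id=hotspot_id,
                    hotspot_name=d["hotspot_name"],
                    zone_id=zone_id,
                    typology=_parse_typology(d["typology"], i, path),
                    active=d["active"].strip().lower() in ("true", "1", "yes"),
                    counts=counts,
                    peak_day_of_week=d["peak_day_of_week"].strip(),
                    peak_time=d["peak_time"].strip(),
                    mobility_responses=responses,
                    men_count=men,
                    snowball_mentions=[
                        tok for tok in d["snowball_mentions"].split(_SNOWBALL_SEP) if tok.strip()
                    ],
                )
            )
        except RecordValidationError as exc:
            raise RecordValidationError(f"{path} row {i}: {exc}") from None
    return records


def write_level_two(path: PathLike, records: Sequence[LevelTwoRecord]) -> None:
    rows = []
    for r in records:
        d = {
            "hotspot_id": r.hotspot_id,
            "hotspot_name": r.hotspot_name,
            "zone_id": r.zone_id,
            "typology": r.typology.value if r.typology else "",
            "active": str(r.active).lower(),
            "peak_day_of_week": r.peak_day_of_week,
            "peak_time": r.peak_time,
        }
        for group in Group:
            for day in Day:
                cp = r.count(group, day)
                d[f"{group.value}_{day.value}_min"] = cp.min_count
                d[f"{group.value}_{day.value}_max"] = cp.max_count
        d["men_min"] = r.men_count.min_count if r.men_count else ""
        d["men_max"] = r.men_count.max_count if r.men_count else ""
        d["mobility_responses"] = _RESPONSE_SEP.join(
            str(resp.total_hotspots_visited) for resp in r.mobility_responses
        )
        d["snowball_mentions"] = _SNOWBALL_SEP.join(r.snowball_mentions)
        rows.append(d)
    pd.DataFrame(rows, columns=LEVEL_TWO_COLUMNS).to_csv(path, index=False)


def _read_hotspot_rows(path: PathLike, geography: Optional[Geography]) -> List[Hotspot]:
    df = _read_csv(path, REGISTER_COLUMNS, "hotspot register")
    hotspots = []
    for i, row in enumerate(df.itertuples(index=False)):
        zone_id = row.zone_id.strip()
        if geography is not None and zone_id not in geography:
            raise UnknownReferenceError(f"{path} row {i}: unknown zone {zone_id!r}")
        try:
            status = HotspotStatus(row.status.strip())
            source = HotspotSource(row.source.strip())
        except ValueError as exc:
            raise UnknownReferenceError(f"{path} row {i}: {exc}") from None
        hotspots.append(
            Hotspot(
                id=row.id.strip(),
                canonical_name=row.canonical_name,
                zone_id=zone_id,
                typology=_parse_typology(row.typology, i, path),
                status=status,
                known_to_program=row.known_to_program.strip().lower() in ("true", "1", "yes"),
                source=source,
            )
        )
    return hotspots


def read_register(path: PathLike, geography: Optional[Geography] = None) -> List[Hotspot]:
    return _read_hotspot_rows(path, geography)


def read_program_listing(path: PathLike, geography: Optional[Geography] = None) -> List[Hotspot]:
    """A program listing uses the same columns as a register; its entries
    carry ``source=program_listing``."""
    return _read_hotspot_rows(path, geography)


def write_register(path: PathLike, hotspots: Sequence[Hotspot]) -> None:
    rows = [
        {
            "id": h.id,
            "canonical_name": h.canonical_name,
            "zone_id": h.zone_id,
            "typology": h.typology.value if h.typology else "",
            "status": h.status.value,
            "known_to_program": str(h.known_to_program).lower(),
            "source": h.source.value,
        }
        for h in hotspots
    ]
    pd.DataFrame(rows, columns=REGISTER_COLUMNS).to_csv(path, index=False)


def write_report(path: PathLike, report: dict) -> None:
    """Serialise a report bundle deterministically (sorted keys, stable floats)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_report(path: PathLike) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
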