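"""Population size estimation from validated hotspot counts.

The estimator follows the venue-based ("programmatic mapping") method:

* **Crude estimate** ``Cr``: per venue, the point estimate is the
  midpoint of the reported minimum/maximum head count; the geographic
  estimate sums venue minima (low), midpoints (point) and maxima (high)
  over all validated-active venues, so ``point = (low + high) / 2``.

* **Mobility adjustment**: women who solicit at several venues are
  counted once per venue by the crude sum.  With ``p`` the proportion of
  respondents who visit other venues and ``m`` the mean number of venues
  visited (index venue included) among them, the deduplicated estimate is

      ``Ni = Cr * (1 - p) + Cr * p / m``

  applied per subcounty; subcounty estimates are then summed to the
  county.  Since ``(1 - p) + p / m <= 1`` for ``m >= 1``, the adjusted
  estimate never exceeds the crude one.

* **Transactional / casual sex estimates** for women aged 14-24 use the
  peak-day midpoint per venue, summed directly — their mobility across
  venues is assumed limited, so no adjustment is applied.

Which day's counts feed the female-sex-worker crude estimate is a
convention the data leave open; the default here is the **peak day**
(matching the transactional/casual convention), configurable to normal.

Final reported point estimates truncate the half-integer midpoint toward
zero (e.g. 11777.5 -> 11777); intermediate arithmetic is never rounded.
Percentages use round-half-up at the requested number of decimals.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, List, Mapping, Optional, Sequence

from .model import (
    CountPair,
    Day,
    Geography,
    Group,
    Hotspot,
    HotspotStatus,
    LevelTwoRecord,
    MappingError,
    MobilityParams,
    RecordValidationError,
    SizeEstimate,
)

logger = logging.getLogger(__name__)


class NoMobilityDataError(MappingError):
    """No mobility responses available in the requested geography; callers
    should fall back to county-pooled parameters."""


def hotspot_point(count_pair: CountPair) -> float:
    """Midpoint of a reported min/max head count, unrounded."""
    return (count_pair.min_count + count_pair.max_count) / 2.0


def _validated_records_in(
    linked_records: Mapping[str, LevelTwoRecord],
    register_by_id: Mapping[str, Hotspot],
    geography: Geography,
    geo_id: str,
) -> List[LevelTwoRecord]:
    out = []
    for hotspot_id in sorted(linked_records):
        hotspot = register_by_id.get(hotspot_id)
        if hotspot is None or hotspot.status != HotspotStatus.VALIDATED_ACTIVE:
            continue
        if geography.contains(geo_id, hotspot.zone_id):
            out.append(linked_records[hotspot_id])
    return out


def crude_estimate(
    linked_records: Mapping[str, LevelTwoRecord],
    register_by_id: Mapping[str, Hotspot],
    geography: Geography,
    geo_id: str,
    group: Group,
    day: Day = Day.PEAK,
) -> SizeEstimate:
    """Sum venue min/max/midpoint counts over validated-active hotspots
    in ``geo_id`` (a zone, subcounty or county)."""
    records = _validated_records_in(linked_records, register_by_id, geography, geo_id)
    if not records:
        logger.warning("no validated hotspots in %s for %s; estimate is zero", geo_id, group.value)
    low = sum(r.count(group, day).min_count for r in records)
    high = sum(r.count(group, day).max_count for r in records)
    point = sum(hotspot_point(r.count(group, day)) for r in records)
    return SizeEstimate(
        geo_id=geo_id, group=group, point=point, low=float(low), high=float(high),
        adjusted_for_mobility=False, n_hotspots=len(records),
    )


def estimate_mobility(
    linked_records: Mapping[str, LevelTwoRecord],
    register_by_id: Mapping[str, Hotspot],
    geography: Geography,
    geo_id: str,
) -> MobilityParams:
    """Pool mobility responses over validated hotspots in a geography.

    ``p`` is the share of respondents visiting other venues; ``m`` the
    mean of ``total_hotspots_visited`` among those respondents (so ``m``
    includes the index venue and is 1 by definition when ``p`` is 0).
    """
    records = _validated_records_in(linked_records, register_by_id, geography, geo_id)
    responses = [resp for r in records for resp in r.mobility_responses]
    if not responses:
        raise NoMobilityDataError(
            f"no mobility responses in {geo_id!r}; fall back to county-pooled parameters"
        )
    mobile = [resp.total_hotspots_visited for resp in responses if resp.visits_other_hotspots]
    p = len(mobile) / len(responses)
    m = (sum(mobile) / len(mobile)) if mobile else 1.0
    return MobilityParams(geo_id=geo_id, p=p, m=m, n_respondents=len(responses))


def mobility_adjust(crude: SizeEstimate, params: MobilityParams) -> SizeEstimate:
    """Apply the deduplication heuristic ``Ni = Cr(1-p) + Cr*p/m``.

    The formula is applied independently to low, point and high, which
    preserves the midpoint identity point = (low + high) / 2.
    """
    if crude.adjusted_for_mobility:
        raise RecordValidationError("estimate is already mobility-adjusted")
    factor = (1.0 - params.p) + params.p / params.m
    return SizeEstimate(
        geo_id=crude.geo_id,
        group=crude.group,
        point=crude.point * factor,
        low=crude.low * factor,
        high=crude.high * factor,
        adjusted_for_mobility=True,
        n_hotspots=crude.n_hotspots,
    )


def county_estimate(
    subcounty_estimates: Sequence[SizeEstimate],
    geo_id: Optional[str] = None,
) -> SizeEstimate:
    """Component-wise sum of one estimate per subcounty (same group)."""
    if not subcounty_estimates:
        raise RecordValidationError("county_estimate requires at least one subcounty estimate")
    groups = {e.group for e in subcounty_estimates}
    if len(groups) > 1:
        raise RecordValidationError(f"cannot sum estimates for mixed groups: {sorted(g.value for g in groups)}")
    adjusted = {e.adjusted_for_mobility for e in subcounty_estimates}
    if len(adjusted) > 1:
        raise RecordValidationError("cannot sum adjusted with unadjusted estimates")
    return SizeEstimate(
        geo_id=geo_id or "+".join(e.geo_id for e in subcounty_estimates),
        group=subcounty_estimates[0].group,
        point=sum(e.point for e in subcounty_estimates),
        low=sum(e.low for e in subcounty_estimates),
        high=sum(e.high for e in subcounty_estimates),
        adjusted_for_mobility=adjusted.pop(),
        n_hotspots=sum(e.n_hotspots for e in subcounty_estimates),
    )


def tc_estimate(
    linked_records: Mapping[str, LevelTwoRecord],
    register_by_id: Mapping[str, Hotspot],
    geography: Geography,
    geo_id: str,
    group: Group,
) -> SizeEstimate:
    """Peak-day estimate for transactional or casual sex (ages 14-24),
    never mobility-adjusted."""
    if group not in (Group.TRANSACTIONAL_14_24, Group.CASUAL_14_24):
        raise RecordValidationError(
            f"tc_estimate is for transactional/casual groups, got {group.value}"
        )
    return crude_estimate(linked_records, register_by_id, geography, geo_id, group, Day.PEAK)


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal round-half-up (0.125 -> 0.13 at 2 decimals), unlike
    banker's rounding of the builtin ``round``."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def proportion_of_population(estimate_point: float, denominator: float, decimals: int = 2) -> float:
    """Percentage of a denominator population, round-half-up."""
    if denominator <= 0:
        raise RecordValidationError("denominator population must be positive")
    if estimate_point < 0:
        raise RecordValidationError("estimate must be nonnegative")
    return round_half_up(100.0 * estimate_point / denominator, decimals)


def report_point(point_real: float) -> int:
    """Final reported integer point estimate: truncation toward zero
    (half-integer midpoints report their floor, e.g. 11777.5 -> 11777)."""
    if point_real < 0:
        raise RecordValidationError("point estimate must be nonnegative")
    return int(point_real)
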