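"""Synthetic county generator with exported ground truth.

Field data from a venue-based mapping exercise are sensitive and are
not deposited publicly, so every pipeline stage here is exercised on a
fully synthetic county instead.  The generator emulates, with known
ground truth:

* a three-tier geography (county > subcounties > data collection zones),
* venues with a typology mix and an active/closed ("turnover") flag,
* a female-sex-worker population in which each woman has a home venue
  and, if mobile, visits additional venues within her subcounty — the
  source of the double counting the mobility adjustment corrects,
* per-venue attendance of women aged 14-24 engaging in transactional or
  casual sex (venue-local, no mobility),
* noisy level-one mentions (duplicated reports, spelling perturbations,
  silently missed venues),
* level-two validation records (min/max counts bracketing the true
  attendance, mobility responses, snowball referrals of missed venues),
* a partial program listing of venues already known to the program.

Everything is deterministic under a fixed seed; separate RNG streams
per stage keep the landscape invariant when only observation noise
settings change.  Mobility respondents at a venue are drawn from the
women *based* at that venue (each woman interviewable once), so the
recovered (p, m) estimate the population parameters without the
venue-visit oversampling of mobile women.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

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
    InfeasibleConfigError,
    LevelTwoRecord,
    MobilityResponse,
    RecordValidationError,
    Typology,
)

# venue-name vocabulary: three-word combinations keep distinct venues well
# below the fuzzy-merge similarity threshold even after one-character noise
_NAME_FIRST = ["Blue", "Coral", "Sunset", "Ocean", "Safari", "Golden",
               "Mango", "Baobab", "Jambo", "Tausi", "Kivuli", "Pwani"]
_NAME_MIDDLE = ["Bay", "Star", "Garden", "Breeze", "Pearl", "Dune",
                "Crown", "Haven", "Lagoon", "Summit"]
_NAME_LAST = ["Bar", "Club", "Tavern", "Lounge", "Den", "Kiosk",
              "Grill", "Palace", "Corner", "Spot", "Hall", "Shack"]

_INFORMANT_TYPES = [
    "fsw", "taxi_driver", "bar_staff", "security_guard", "local_brew_seller",
    "boda_rider", "shop_keeper", "community_health_worker", "police", "beach_operator",
]

_CATEGORIES = ("both", "transactional_only", "casual_only", "exclusive")

# default typology mix follows the county-wide distribution observed in a
# coastal Kenyan mapping round (brew dens and bars dominate)
_DEFAULT_TYPOLOGY_MIX = (0.032, 0.081, 0.205, 0.264, 0.071, 0.016, 0.309, 0.022)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic county.

    Defaults describe a county scaled to ~100 venues and 1200 female sex
    workers with the mobility, typology, discovery-noise and program-
    coverage characteristics of a realistic coastal urban mapping round;
    :meth:`mombasa_scale` produces the ~1025-venue analogue.
    """

    seed: int = 0
    n_subcounties: int = 4
    n_zones_per_subcounty: Union[int, Tuple[int, ...]] = 2
    n_venues: int = 100
    typology_mix: Tuple[float, ...] = _DEFAULT_TYPOLOGY_MIX
    n_fsw_true: int = 1200
    age_14_24_share: float = 0.52
    p_mobile: float = 0.6
    m_distribution: Tuple[str, float] = ("shifted_poisson", 0.5)  # m = 2 + Poisson(mu)
    tc_rates: Tuple[float, float] = (5.2, 4.1)  # mean transactional / casual per venue
    exclusive_share: float = 0.046
    transactional_only_share: float = 0.10
    casual_only_share: float = 0.006
    inactive_rate: float = 0.08
    mention_rate: float = 1.2  # expected mentions per reported venue, >= 1
    name_noise: float = 0.10
    venue_miss_rate: float = 0.05
    snowball_rate: float = 0.7
    program_known_share: float = 0.41
    count_noise: float = 0.2
    normal_presence: float = 0.65
    mobility_respondents_per_venue: Optional[int] = 5  # None = every home-based woman
    typology_guess_rate: float = 0.7
    female_pop_14_24: int = 134_885
    female_pop_14_44: int = 319_032

    def __post_init__(self) -> None:
        props = {
            "age_14_24_share": self.age_14_24_share, "p_mobile": self.p_mobile,
            "exclusive_share": self.exclusive_share,
            "transactional_only_share": self.transactional_only_share,
            "casual_only_share": self.casual_only_share,
            "inactive_rate": self.inactive_rate, "name_noise": self.name_noise,
            "venue_miss_rate": self.venue_miss_rate, "snowball_rate": self.snowball_rate,
            "program_known_share": self.program_known_share,
            "normal_presence": self.normal_presence,
            "typology_guess_rate": self.typology_guess_rate,
        }
        for name, value in props.items():
            if not 0.0 <= value <= 1.0:
                raise InfeasibleConfigError(f"{name} must be in [0, 1], got {value}")
        if len(self.typology_mix) != len(Typology):
            raise InfeasibleConfigError(
                f"typology_mix needs {len(Typology)} entries, got {len(self.typology_mix)}"
            )
        if abs(sum(self.typology_mix) - 1.0) > 1e-6:
            raise InfeasibleConfigError("typology_mix must sum to 1")
        if self.mention_rate < 1.0:
            raise InfeasibleConfigError("mention_rate is per reported venue and must be >= 1")
        if self.exclusive_share + self.transactional_only_share + self.casual_only_share > 1.0:
            raise InfeasibleConfigError("venue category shares exceed 1")
        if self.m_distribution[0] != "shifted_poisson":
            raise InfeasibleConfigError(
                f"unknown m_distribution family {self.m_distribution[0]!r}"
            )
        if self.count_noise < 0:
            raise InfeasibleConfigError("count_noise must be nonnegative")

    @property
    def zones_per_subcounty(self) -> Tuple[int, ...]:
        z = self.n_zones_per_subcounty
        if isinstance(z, int):
            return (z,) * self.n_subcounties
        if len(z) != self.n_subcounties:
            raise InfeasibleConfigError("n_zones_per_subcounty tuple length mismatch")
        return tuple(z)

    @classmethod
    def noise_free(cls, seed: int = 0, **overrides) -> "GeneratorConfig":
        """Every venue mentioned exactly once by its true name, counts
        exact, no venue turnover, every home-based woman interviewed."""
        params = dict(
            seed=seed, mention_rate=1.0, name_noise=0.0, venue_miss_rate=0.0,
            count_noise=0.0, inactive_rate=0.0, mobility_respondents_per_venue=None,
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def mombasa_scale(cls, seed: int = 0, **overrides) -> "GeneratorConfig":
        """A county of ~1025 venues across 4 subcounties and 9 zones."""
        params = dict(
            seed=seed, n_venues=1025, n_fsw_true=12_000,
            n_zones_per_subcounty=(3, 2, 2, 2),
        )
        params.update(overrides)
        return cls(**params)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_zones_per_subcounty"] = (
            list(z) if isinstance((z := self.n_zones_per_subcounty), tuple) else z
        )
        d["typology_mix"] = list(self.typology_mix)
        d["m_distribution"] = list(self.m_distribution)
        d["tc_rates"] = list(self.tc_rates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("typology_mix", "m_distribution", "tc_rates", "n_zones_per_subcounty"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class VenueTruth:
    """Ground-truth state of one synthetic venue."""

    id: str
    name: str
    zone_id: str
    subcounty_id: str
    typology: Typology
    active: bool
    known_to_program: bool
    category: str  # one of both / transactional_only / casual_only / exclusive
    attendance: Dict[str, int] = field(default_factory=dict)  # "<group>_<day>" -> persons
    men_peak: int = 0

    def true_count(self, group: Group, day: Day) -> int:
        return self.attendance.get(f"{group.value}_{day.value}", 0)


@dataclass
class GroundTruth:
    """Everything the generator knows that the observation files hide."""

    config: GeneratorConfig
    venues: List[VenueTruth]
    true_population: Dict[str, Dict[str, int]]  # geo_id -> group code -> distinct persons
    mobility: Dict[str, Dict[str, float]]  # subcounty -> {p, m, n_women, n_mobile}
    home_visit_sizes: Dict[str, List[int]] = field(default_factory=dict)
    # ^ venue id -> visit-set sizes of the women based there (the respondent pool)
    mentioned_venue_ids: List[str] = field(default_factory=list)
    reachable_venue_ids: List[str] = field(default_factory=list)

    def venue(self, venue_id: str) -> VenueTruth:
        for v in self.venues:
            if v.id == venue_id:
                return v
        raise KeyError(venue_id)

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "venues": [dataclasses.asdict(v) | {"typology": v.typology.value}
                       for v in self.venues],
            "true_population": self.true_population,
            "mobility": self.mobility,
            "home_visit_sizes": self.home_visit_sizes,
            "mentioned_venue_ids": self.mentioned_venue_ids,
            "reachable_venue_ids": self.reachable_venue_ids,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        venues = [
            VenueTruth(**{**v, "typology": Typology(v["typology"])}) for v in d["venues"]
        ]
        return cls(
            config=GeneratorConfig.from_dict(d["config"]),
            venues=venues,
            true_population=d["true_population"],
            mobility=d["mobility"],
            home_visit_sizes={k: list(v) for k, v in d.get("home_visit_sizes", {}).items()},
            mentioned_venue_ids=list(d["mentioned_venue_ids"]),
            reachable_venue_ids=list(d["reachable_venue_ids"]),
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n",
                              encoding="utf-8")

    @classmethod
    def read(cls, path) -> "GroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def generate_geography(config: GeneratorConfig) -> Geography:
    """County > subcounty > zone tree with female population denominators
    at county level, split evenly across subcounties."""
    units = [
        GeoUnit(
            id="county-1", name="Synthetic County", level=GeoLevel.COUNTY,
            female_pop_14_24=config.female_pop_14_24,
            female_pop_14_44=config.female_pop_14_44,
        )
    ]
    n_sc = config.n_subcounties
    per_sc_young = config.female_pop_14_24 // n_sc
    per_sc_all = config.female_pop_14_44 // n_sc
    for s, n_zones in enumerate(config.zones_per_subcounty, start=1):
        units.append(
            GeoUnit(
                id=f"sc-{s}", name=f"Subcounty {s}", level=GeoLevel.SUBCOUNTY,
                parent_id="county-1",
                female_pop_14_24=per_sc_young, female_pop_14_44=per_sc_all,
            )
        )
        for z in range(1, n_zones + 1):
            units.append(
                GeoUnit(id=f"zone-{s}-{z}", name=f"Zone {s}.{z}", level=GeoLevel.ZONE,
                        parent_id=f"sc-{s}")
            )
    return Geography(units)


def _venue_names(n: int, rng: np.random.Generator) -> List[str]:
    combos = [f"{a} {b} {c}" for a, b, c in
              itertools.product(_NAME_FIRST, _NAME_MIDDLE, _NAME_LAST)]
    if n > len(combos):
        combos += [f"{name} {i}" for i, name in
                   enumerate(itertools.cycle(combos), start=2)][: n - len(combos)]
    order = rng.permutation(len(combos))[:n]
    return [combos[i] for i in order]


def generate_landscape(config: GeneratorConfig) -> Tuple[List[VenueTruth], GroundTruth]:
    """Lay out venues and populations; deterministic under ``config.seed``."""
    rng = np.random.default_rng([config.seed, 0])
    geography = generate_geography(config)
    zones = [u.id for u in geography.units(GeoLevel.ZONE)]
    subcounty_of_zone = {u.id: geography.subcounty_of(u.id).id for u in geography.units(GeoLevel.ZONE)}

    names = _venue_names(config.n_venues, rng)
    typ_list = list(Typology)
    venues: List[VenueTruth] = []
    cat_probs = [
        1.0 - config.exclusive_share - config.transactional_only_share - config.casual_only_share,
        config.transactional_only_share,
        config.casual_only_share,
        config.exclusive_share,
    ]
    for i in range(config.n_venues):
        zone = zones[int(rng.integers(len(zones)))]
        venues.append(
            VenueTruth(
                id=f"v-{i + 1:04d}",
                name=names[i],
                zone_id=zone,
                subcounty_id=subcounty_of_zone[zone],
                typology=typ_list[int(rng.choice(len(typ_list), p=list(config.typology_mix)))],
                active=bool(rng.random() >= config.inactive_rate),
                known_to_program=bool(rng.random() < config.program_known_share),
                category=_CATEGORIES[int(rng.choice(len(_CATEGORIES), p=cat_probs))],
            )
        )

    active_idx = [i for i, v in enumerate(venues) if v.active]
    if not active_idx:
        raise InfeasibleConfigError("no active venues in the generated landscape")
    active_by_sc: Dict[str, List[int]] = {}
    for i in active_idx:
        active_by_sc.setdefault(venues[i].subcounty_id, []).append(i)

    # female sex workers: home venue + optional extra venues within subcounty
    mu = config.m_distribution[1]
    home = rng.integers(0, len(active_idx), size=config.n_fsw_true)
    young = rng.random(config.n_fsw_true) < config.age_14_24_share
    mobile = rng.random(config.n_fsw_true) < config.p_mobile
    m_draws = np.where(mobile, 2 + rng.poisson(mu, size=config.n_fsw_true), 1)

    peak_all = np.zeros(len(venues), dtype=int)
    peak_young = np.zeros(len(venues), dtype=int)
    normal_all = np.zeros(len(venues), dtype=int)
    normal_young = np.zeros(len(venues), dtype=int)
    women_by_home: Dict[str, List[int]] = {}  # venue id -> visit-set sizes of women based there
    sc_women: Dict[str, List[int]] = {}  # subcounty -> visit-set sizes of resident women

    for w in range(config.n_fsw_true):
        home_venue = active_idx[home[w]]
        sc = venues[home_venue].subcounty_id
        m = int(m_draws[w])
        pool = active_by_sc[sc]
        if m > len(pool):
            raise InfeasibleConfigError(
                f"mobility degree m={m} exceeds the {len(pool)} active venues in {sc}"
            )
        visit_set = [home_venue]
        if m > 1:
            others = [i for i in pool if i != home_venue]
            extra = rng.choice(len(others), size=m - 1, replace=False)
            visit_set += [others[j] for j in extra]
        women_by_home.setdefault(venues[home_venue].id, []).append(len(visit_set))
        sc_women.setdefault(sc, []).append(len(visit_set))
        for vi in visit_set:
            peak_all[vi] += 1
            if young[w]:
                peak_young[vi] += 1
            if rng.random() < config.normal_presence:
                normal_all[vi] += 1
                if young[w]:
                    normal_young[vi] += 1

    # transactional / casual attendance is venue-local
    t_rate, c_rate = config.tc_rates
    for i, v in enumerate(venues):
        att = {f"{g.value}_{d.value}": 0 for g in Group for d in Day}
        if v.active:
            att[f"{Group.FSW_ALL.value}_peak"] = int(peak_all[i])
            att[f"{Group.FSW_ALL.value}_normal"] = int(normal_all[i])
            att[f"{Group.FSW_14_24.value}_peak"] = int(peak_young[i])
            att[f"{Group.FSW_14_24.value}_normal"] = int(normal_young[i])
            if v.category in ("both", "transactional_only"):
                tp = 1 + int(rng.poisson(max(t_rate - 1.0, 0.0)))
                att[f"{Group.TRANSACTIONAL_14_24.value}_peak"] = tp
                att[f"{Group.TRANSACTIONAL_14_24.value}_normal"] = int(
                    rng.binomial(tp, config.normal_presence)
                )
            if v.category in ("both", "casual_only"):
                cp = 1 + int(rng.poisson(max(c_rate - 1.0, 0.0)))
                att[f"{Group.CASUAL_14_24.value}_peak"] = cp
                att[f"{Group.CASUAL_14_24.value}_normal"] = int(
                    rng.binomial(cp, config.normal_presence)
                )
            v.men_peak = int(rng.poisson(10))
        v.attendance = att

    # distinct-individual truths (each woman counted once, in her home subcounty)
    true_pop: Dict[str, Dict[str, int]] = {}
    sc_ids = sorted({v.subcounty_id for v in venues})
    home_sc = np.array([venues[active_idx[h]].subcounty_id for h in home])
    for geo in sc_ids + ["county-1"]:
        in_geo = np.ones(config.n_fsw_true, dtype=bool) if geo == "county-1" else home_sc == geo
        venue_in_geo = [v for v in venues if geo == "county-1" or v.subcounty_id == geo]
        true_pop[geo] = {
            Group.FSW_ALL.value: int(in_geo.sum()),
            Group.FSW_14_24.value: int((in_geo & young).sum()),
            Group.TRANSACTIONAL_14_24.value: sum(
                v.true_count(Group.TRANSACTIONAL_14_24, Day.PEAK) for v in venue_in_geo
            ),
            Group.CASUAL_14_24.value: sum(
                v.true_count(Group.CASUAL_14_24, Day.PEAK) for v in venue_in_geo
            ),
        }

    mobility: Dict[str, Dict[str, float]] = {}
    for sc in sc_ids:
        sizes = sc_women.get(sc, [])
        mobile_sizes = [s for s in sizes if s >= 2]
        mobility[sc] = {
            "p": len(mobile_sizes) / len(sizes) if sizes else 0.0,
            "m": sum(mobile_sizes) / len(mobile_sizes) if mobile_sizes else 1.0,
            "n_women": float(len(sizes)),
            "n_mobile": float(len(mobile_sizes)),
        }

    truth = GroundTruth(
        config=config, venues=venues, true_population=true_pop, mobility=mobility,
        home_visit_sizes=women_by_home,
    )
    return venues, truth


def _perturb_name(name: str, rng: np.random.Generator) -> str:
    op = int(rng.integers(4))
    if op == 0 and len(name) > 4:
        return name[:-1]
    if op == 1 and len(name) > 3:
        i = int(rng.integers(len(name) - 1))
        return name[:i] + name[i + 1] + name[i] + name[i + 2:]
    if op == 2:
        i = int(rng.integers(len(name)))
        return name[:i + 1] + name[i] + name[i + 1:]
    return name.upper()


def generate_mentions(
    venues: Sequence[VenueTruth],
    config: GeneratorConfig,
    ground_truth: Optional[GroundTruth] = None,
) -> List[HotspotMention]:
    """Emulate the level-one listing: duplicated, noisily spelled venue
    reports, with some venues silently missed."""
    rng = np.random.default_rng([config.seed, 1])
    start = date(2014, 5, 15)
    mentions: List[HotspotMention] = []
    mentioned: List[str] = []
    for v in venues:
        if rng.random() < config.venue_miss_rate:
            continue
        k = 1 + int(rng.poisson(config.mention_rate - 1.0))
        mentioned.append(v.id)
        for _ in range(k):
            raw = v.name
            if rng.random() < config.name_noise:
                raw = _perturb_name(raw, rng)
            guess = v.typology if rng.random() < config.typology_guess_rate else None
            mentions.append(
                HotspotMention(
                    raw_name=raw,
                    zone_id=v.zone_id,
                    informant_type=_INFORMANT_TYPES[int(rng.integers(len(_INFORMANT_TYPES)))],
                    typology_guess=guess,
                    mention_date=start + timedelta(days=int(rng.integers(36))),
                )
            )
    order = rng.permutation(len(mentions))
    if ground_truth is not None:
        ground_truth.mentioned_venue_ids = mentioned
    return [mentions[i] for i in order]


def generate_level_two(
    venues: Sequence[VenueTruth],
    ground_truth: GroundTruth,
    config: GeneratorConfig,
) -> List[LevelTwoRecord]:
    """Emulate the level-two validation visits for every discovered venue.

    Discovered = mentioned at level one, plus missed active venues that a
    same-zone discovered venue reveals through snowball referral.
    Reported min/max bracket the true attendance with relative dispersion
    ``count_noise`` (shared factors across groups preserve the nesting of
    the 14-24 subgroup within all ages).  Sets
    ``ground_truth.reachable_venue_ids``.
    """
    if not ground_truth.mentioned_venue_ids:
        raise RecordValidationError("generate_mentions must run first (no mentioned venues)")
    rng = np.random.default_rng([config.seed, 2])
    by_id = {v.id: v for v in venues}
    discovered = set(ground_truth.mentioned_venue_ids)
    snowballs: Dict[str, List[str]] = {}

    for v in venues:
        if v.id in discovered or not v.active:
            continue
        if rng.random() >= config.snowball_rate:
            continue
        hosts = sorted(i for i in discovered if by_id[i].zone_id == v.zone_id)
        if not hosts:
            continue
        host = hosts[int(rng.integers(len(hosts)))]
        referred = v.name
        if rng.random() < config.name_noise:
            referred = _perturb_name(referred, rng)
        snowballs.setdefault(host, []).append(referred)
        discovered.add(v.id)

    records: List[LevelTwoRecord] = []
    for vid in sorted(discovered):
        v = by_id[vid]
        counts: Dict[Tuple[Group, Day], CountPair] = {}
        for day in Day:
            lo_f = rng.uniform(0.0, config.count_noise)
            hi_f = rng.uniform(0.0, config.count_noise)
            for group in Group:
                true = v.true_count(group, day)
                counts[(group, day)] = CountPair(
                    int(math.floor(true * (1.0 - lo_f))),
                    int(math.ceil(true * (1.0 + hi_f))),
                )
        men = None
        if v.active:
            lo_f = rng.uniform(0.0, config.count_noise)
            hi_f = rng.uniform(0.0, config.count_noise)
            men = CountPair(int(math.floor(v.men_peak * (1.0 - lo_f))),
                            int(math.ceil(v.men_peak * (1.0 + hi_f))))
        responses: List[MobilityResponse] = []
        if v.active:
            sizes = ground_truth.home_visit_sizes.get(vid, [])
            k = len(sizes) if config.mobility_respondents_per_venue is None else min(
                len(sizes), config.mobility_respondents_per_venue
            )
            if k:
                chosen = rng.choice(len(sizes), size=k, replace=False)
                responses = [MobilityResponse(sizes[int(j)]) for j in chosen]
        records.append(
            LevelTwoRecord(
                hotspot_id=v.id,
                hotspot_name=v.name,
                zone_id=v.zone_id,
                typology=v.typology,
                active=v.active,
                counts=counts,
                peak_day_of_week=["friday", "saturday"][int(rng.integers(2))],
                peak_time=["20:00", "22:00", "23:00"][int(rng.integers(3))],
                mobility_responses=responses,
                men_count=men,
                snowball_mentions=snowballs.get(vid, []),
            )
        )
    ground_truth.reachable_venue_ids = sorted(discovered)
    return records


def make_program_listing(venues: Sequence[VenueTruth]) -> List[Hotspot]:
    """The venues the HIV prevention program already had on file."""
    return [
        Hotspot(
            id=f"prog-{i + 1:04d}",
            canonical_name=v.name,
            zone_id=v.zone_id,
            typology=v.typology,
            status=HotspotStatus.NAMED,
            known_to_program=True,
            source=HotspotSource.PROGRAM_LISTING,
        )
        for i, v in enumerate(v for v in venues if v.known_to_program)
    ]


def exact_dedup_estimate(ground_truth: GroundTruth, geo_id: str, group: Group) -> int:
    """True population size by exact deduplication: each individual
    counted once regardless of the number of venues she visits."""
    try:
        return ground_truth.true_population[geo_id][group.value]
    except KeyError:
        raise RecordValidationError(
            f"no ground-truth population for {geo_id!r} / {group.value}"
        ) from None


@dataclass
class SyntheticCounty:
    """One complete synthetic data bundle, ready for the pipeline."""

    config: GeneratorConfig
    geography: Geography
    venues: List[VenueTruth]
    ground_truth: GroundTruth
    mentions: List[HotspotMention]
    level_two_records: List[LevelTwoRecord]
    program_listing: List[Hotspot]


def generate_county(config: GeneratorConfig) -> SyntheticCounty:
    """Run all generator stages in order under one seed."""
    venues, truth = generate_landscape(config)
    mentions = generate_mentions(venues, config, ground_truth=truth)
    records = generate_level_two(venues, truth, config)
    listing = make_program_listing(venues)
    return SyntheticCounty(
        config=config,
        geography=generate_geography(config),
        venues=venues,
        ground_truth=truth,
        mentions=mentions,
        level_two_records=records,
        program_listing=listing,
    )
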