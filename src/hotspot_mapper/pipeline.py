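"""End-to-end pipeline: simulate/ingest -> dedupe -> estimate -> analyse.

``run_pipeline`` chains the stages in the order the field method runs
them — level-one listing consolidation, program-listing comparison,
level-two snowball closure and validation, population size estimation
(crude, then mobility-adjusted per subcounty, summed to the county),
overlap classification, typology and program-coverage tables — and
returns a deterministic, JSON-serialisable report bundle.  The bundle
is a pure function of (inputs, configuration, seed): rerunning with the
same configuration produces a byte-identical report file.

Every convention the method leaves open (which day's counts feed the
estimate, the fuzzy-match threshold, rounding rules) is recorded in the
report's ``conventions`` block.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import dedup, estimation, io, overlap
from .model import (
    Day,
    GeoLevel,
    Geography,
    Group,
    Hotspot,
    HotspotStatus,
    MappingError,
    MobilityParams,
    SizeEstimate,
)
from .synthetic import GeneratorConfig, SyntheticCounty, generate_county


class StageError(MappingError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run.

    Either ``simulate`` holds a :class:`GeneratorConfig` or the four
    input paths point at existing observation files.
    """

    simulate: Optional[GeneratorConfig] = None
    mentions_path: Optional[str] = None
    level_two_path: Optional[str] = None
    geography_path: Optional[str] = None
    listing_path: Optional[str] = None
    similarity_threshold: float = dedup.DEFAULT_SIMILARITY_THRESHOLD
    estimation_day: Day = Day.PEAK
    adjust_mobility: bool = True
    monte_carlo_p: bool = False
    mc_simulations: int = 2000

    def to_dict(self) -> dict:
        return {
            "simulate": self.simulate.to_dict() if self.simulate else None,
            "mentions_path": self.mentions_path,
            "level_two_path": self.level_two_path,
            "geography_path": self.geography_path,
            "listing_path": self.listing_path,
            "similarity_threshold": self.similarity_threshold,
            "estimation_day": self.estimation_day.value,
            "adjust_mobility": self.adjust_mobility,
            "monte_carlo_p": self.monte_carlo_p,
            "mc_simulations": self.mc_simulations,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulate"):
            d["simulate"] = GeneratorConfig.from_dict(d["simulate"])
        if "estimation_day" in d and not isinstance(d["estimation_day"], Day):
            d["estimation_day"] = Day(d["estimation_day"])
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {})


def _estimate_to_dict(e: SizeEstimate) -> dict:
    return {
        "geo_id": e.geo_id,
        "group": e.group.value,
        "point": e.point,
        "low": e.low,
        "high": e.high,
        "point_reported": estimation.report_point(e.point),
        "low_reported": estimation.report_point(e.low),
        "high_reported": estimation.report_point(e.high),
        "adjusted_for_mobility": e.adjusted_for_mobility,
        "n_hotspots": e.n_hotspots,
    }


def _denominator(geography: Geography, geo_id: str, group: Group) -> int:
    unit = geography.unit(geo_id)
    if group == Group.FSW_ALL:
        return unit.female_pop_14_44
    return unit.female_pop_14_24


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the report bundle."""
    synthetic: Optional[SyntheticCounty] = None

    try:
        if config.simulate is not None:
            synthetic = generate_county(config.simulate)
            geography = synthetic.geography
            mentions = synthetic.mentions
            records = synthetic.level_two_records
            listing = synthetic.program_listing
        else:
            if not (config.mentions_path and config.level_two_path and config.geography_path):
                raise MappingError(
                    "either a simulate block or mentions/level_two/geography paths are required"
                )
            geography = io.read_geography(config.geography_path)
            mentions = io.read_mentions(config.mentions_path, geography)
            records = io.read_level_two(config.level_two_path, geography)
            listing = (
                io.read_program_listing(config.listing_path, geography)
                if config.listing_path else []
            )
    except MappingError as exc:
        raise StageError("ingest", exc) from exc

    thr = config.similarity_threshold
    try:
        register = dedup.dedupe_mentions(mentions, thr)
        n_level_one_clusters = len(register)
        register = dedup.snowball_update(register, records, thr)
        register = dedup.merge_with_listing(register, listing, thr)
        linked = dedup.link_records(register, records, thr)
        register = dedup.apply_validation(register, linked)
    except MappingError as exc:
        raise StageError("dedup", exc) from exc

    by_id = {h.id: h for h in register}
    validated = [h for h in register if h.status == HotspotStatus.VALIDATED_ACTIVE]
    county = geography.units(GeoLevel.COUNTY)[0]
    subcounties = geography.units(GeoLevel.SUBCOUNTY)

    try:
        estimates: Dict[str, Dict[str, dict]] = {}
        mobility_block: Dict[str, dict] = {}
        pooled: Optional[MobilityParams] = None
        if config.adjust_mobility:
            try:
                pooled = estimation.estimate_mobility(linked, by_id, geography, county.id)
            except estimation.NoMobilityDataError as exc:
                raise MappingError(f"mobility adjustment requested but {exc}") from exc

        for group in (Group.FSW_ALL, Group.FSW_14_24):
            per_geo: Dict[str, dict] = {}
            adjusted_subcounties: List[SizeEstimate] = []
            crude_subcounties: List[SizeEstimate] = []
            for sc in subcounties:
                crude = estimation.crude_estimate(
                    linked, by_id, geography, sc.id, group, config.estimation_day
                )
                crude_subcounties.append(crude)
                entry = {"crude": _estimate_to_dict(crude)}
                if config.adjust_mobility:
                    try:
                        params = estimation.estimate_mobility(linked, by_id, geography, sc.id)
                        fallback = False
                    except estimation.NoMobilityDataError:
                        params = MobilityParams(
                            geo_id=sc.id, p=pooled.p, m=pooled.m,
                            n_respondents=pooled.n_respondents,
                        )
                        fallback = True
                    adjusted = estimation.mobility_adjust(crude, params)
                    adjusted_subcounties.append(adjusted)
                    entry["adjusted"] = _estimate_to_dict(adjusted)
                    mobility_block[sc.id] = {
                        "p": params.p, "m": params.m,
                        "n_respondents": params.n_respondents,
                        "county_pooled_fallback": fallback,
                    }
                per_geo[sc.id] = entry
            county_crude = estimation.county_estimate(crude_subcounties, county.id)
            county_entry = {"crude": _estimate_to_dict(county_crude)}
            best = county_crude
            if config.adjust_mobility:
                county_adjusted = estimation.county_estimate(adjusted_subcounties, county.id)
                county_entry["adjusted"] = _estimate_to_dict(county_adjusted)
                best = county_adjusted
            county_entry["proportion_pct"] = estimation.proportion_of_population(
                best.point, _denominator(geography, county.id, group)
            )
            per_geo[county.id] = county_entry
            estimates[group.value] = per_geo

        for group in (Group.TRANSACTIONAL_14_24, Group.CASUAL_14_24):
            per_geo = {}
            sc_estimates = []
            for sc in subcounties:
                est = estimation.tc_estimate(linked, by_id, geography, sc.id, group)
                sc_estimates.append(est)
                per_geo[sc.id] = {"crude": _estimate_to_dict(est)}
            county_est = estimation.county_estimate(sc_estimates, county.id)
            per_geo[county.id] = {
                "crude": _estimate_to_dict(county_est),
                "proportion_pct": estimation.proportion_of_population(
                    county_est.point, _denominator(geography, county.id, group)
                ),
            }
            estimates[group.value] = per_geo
    except MappingError as exc:
        raise StageError("estimation", exc) from exc

    try:
        active_records = [linked[h.id] for h in validated if h.id in linked]
        overlap_summary = overlap.classify_overlap(active_records)
        typology = overlap.typology_table(register, geography)
        chi = _chi_square_or_none(typology, config)
        split = overlap.known_new_split(register)
    except MappingError as exc:
        raise StageError("analysis", exc) from exc

    n_named = len(mentions)
    report = {
        "config": config.to_dict(),
        "conventions": {
            "estimation_day": config.estimation_day.value,
            "similarity_threshold": thr,
            "point_reporting": "midpoint of summed min/max bounds, truncated toward zero",
            "percent_rounding": "round-half-up (2 decimals; 1 decimal in typology tables)",
            "overlap_presence_rule": "peak-day maximum count >= 1",
            "mobility_adjustment": "Ni = Cr(1-p) + Cr*p/m per subcounty, summed to county",
        },
        "register": {
            "n_mentions": n_named,
            "n_level_one_hotspots": n_level_one_clusters,
            "n_register_total": len(register),
            "n_validated_active": len(validated),
            "n_inactive": sum(1 for h in register if h.status == HotspotStatus.INACTIVE),
            "n_unvisited": sum(1 for h in register if h.status == HotspotStatus.NAMED),
            "pct_validated_of_mentions": estimation.round_half_up(
                100.0 * len(validated) / n_named, 2
            ) if n_named else None,
        },
        "mobility": mobility_block,
        "estimates": estimates,
        "overlap": {
            "n_total": overlap_summary.n_total,
            "n_both": overlap_summary.n_both,
            "n_transactional_only": overlap_summary.n_transactional_only,
            "n_casual_only": overlap_summary.n_casual_only,
            "n_exclusive_sex_work": overlap_summary.n_exclusive_sex_work,
            "percentages": overlap_summary.percentages,
        },
        "typology_table": {
            "counts": {
                r: {c: int(x) for c, x in typology.table.loc[r].to_dict().items()}
                for r in typology.table.index
            },
            "column_pct": {
                r: {c: (None if pd.isna(x) else x)
                    for c, x in typology.column_percentages().loc[r].to_dict().items()}
                for r in typology.table.index
            },
            "chi_square": chi,
        },
        "known_new": {
            "n_total": split.n_total,
            "n_known": split.n_known,
            "n_new": split.n_new,
            "pct_known": split.pct_known,
            "pct_new": split.pct_new,
            "by_typology": {
                t: {k: (None if pd.isna(v) else (int(v) if k != "pct_new" else v))
                    for k, v in row.items()}
                for t, row in split.by_typology.iterrows()
            },
            "chi_square": _chi_result_to_dict(split.chi_square),
        },
    }
    if synthetic is not None:
        truth = synthetic.ground_truth
        report["ground_truth_comparison"] = {
            "true_n_venues": len(synthetic.venues),
            "n_reachable_venues": len(truth.reachable_venue_ids),
            "true_population_county": truth.true_population[county.id],
            "true_mobility": truth.mobility,
        }
    return report


def _chi_result_to_dict(res: Optional[overlap.ChiSquareResult]) -> Optional[dict]:
    if res is None:
        return None
    return {
        "statistic": res.statistic,
        "degrees_of_freedom": res.degrees_of_freedom,
        "p_value": res.p_value,
        "min_expected_count": res.min_expected_count,
        "low_expected_warning": res.low_expected_warning,
        "monte_carlo_p": res.monte_carlo_p,
    }


def _chi_square_or_none(table: overlap.ContingencyTable, config: PipelineConfig) -> Optional[dict]:
    res = overlap.chi_square_on_nonempty(
        table,
        monte_carlo=config.monte_carlo_p,
        n_simulations=config.mc_simulations,
        seed=config.simulate.seed if config.simulate else 0,
    )
    return _chi_result_to_dict(res)


_GROUP_TITLES = {
    Group.FSW_ALL: "Sex work, all ages",
    Group.FSW_14_24: "Sex work, 14-24 years",
    Group.TRANSACTIONAL_14_24: "Transactional sex, 14-24 years",
    Group.CASUAL_14_24: "Casual sex, 14-24 years",
}


def render_table1(
    estimates: Mapping[Group, SizeEstimate],
    denominators: Mapping[Group, int],
) -> pd.DataFrame:
    """Render county estimates in the standard published layout: reported
    point estimate, min-max range, and percent of the female population
    denominator of the matching age band."""
    rows = []
    for group, est in estimates.items():
        rows.append({
            "group": _GROUP_TITLES[group],
            "point_estimate": estimation.report_point(est.point),
            "range_low": estimation.report_point(est.low),
            "range_high": estimation.report_point(est.high),
            "pct_of_female_population": estimation.proportion_of_population(
                est.point, denominators[group]
            ),
        })
    return pd.DataFrame(rows).set_index("group")


def write_report_bundle(report: dict, outdir) -> List[Path]:
    """Write report.json plus CSV renderings of its tables; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    path = outdir / "report.json"
    io.write_report(path, report)
    written.append(path)

    est_rows = []
    for group, per_geo in report["estimates"].items():
        for geo_id, entry in per_geo.items():
            for kind in ("crude", "adjusted"):
                if kind in entry:
                    e = entry[kind]
                    est_rows.append({
                        "group": group, "geo_id": geo_id, "kind": kind,
                        "point": e["point"], "low": e["low"], "high": e["high"],
                        "point_reported": e["point_reported"],
                        "n_hotspots": e["n_hotspots"],
                    })
    path = outdir / "estimates.csv"
    pd.DataFrame(est_rows).to_csv(path, index=False)
    written.append(path)

    counts = pd.DataFrame(report["typology_table"]["counts"]).T
    path = outdir / "typology_table.csv"
    counts.to_csv(path, index_label="typology")
    written.append(path)

    kn = pd.DataFrame(report["known_new"]["by_typology"]).T
    path = outdir / "known_new.csv"
    kn.to_csv(path, index_label="typology")
    written.append(path)

    path = outdir / "overlap.csv"
    pd.DataFrame([report["overlap"]]).drop(columns=["percentages"]).to_csv(path, index=False)
    written.append(path)
    return written
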