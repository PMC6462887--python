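"""Crude and mobility-adjusted size estimation: arithmetic, formula
limits, the heuristic's overestimation bias, and parameter recovery."""

import pytest
from hypothesis import given, settings, strategies as st

from hotspot_mapper import dedup, estimation
from hotspot_mapper.model import (
    CountPair,
    Group,
    HotspotStatus,
    MobilityParams,
    RecordValidationError,
    SizeEstimate,
)
from hotspot_mapper.synthetic import GeneratorConfig, generate_county

from conftest import make_hotspot, make_record


def _setup(geography, entries):
    """entries: list of (hotspot_id, zone, fsw_peak_pair, mobility tuple)."""
    register, records = [], []
    for hid, zone, pair, mob in entries:
        register.append(make_hotspot(hid, zone_id=zone))
        records.append(make_record(hid, zone_id=zone, fsw_peak=pair, mobility=mob))
    by_id = {h.id: h for h in register}
    linked = dedup.link_records(register, records)
    return linked, by_id


class TestHotspotPoint:
    @pytest.mark.parametrize(
        "pair, expected",
        [((0, 0), 0.0), ((4, 10), 7.0), ((9265, 14290), 11777.5)],
    )
    def test_midpoint(self, pair, expected):
        assert estimation.hotspot_point(CountPair(*pair)) == expected


class TestCrudeEstimate:
    def test_single_hotspot(self, geography):
        linked, by_id = _setup(geography, [("h1", "zone-1", (4, 10), ())])
        est = estimation.crude_estimate(linked, by_id, geography, "county-1", Group.FSW_ALL)
        assert (est.low, est.point, est.high) == (4.0, 7.0, 10.0)
        assert est.n_hotspots == 1 and not est.adjusted_for_mobility

    def test_additivity_over_partition(self, geography):
        entries = [("h1", "zone-1", (4, 10), ()), ("h2", "zone-2", (6, 10), ())]
        linked, by_id = _setup(geography, entries)
        county = estimation.crude_estimate(linked, by_id, geography, "county-1", Group.FSW_ALL)
        parts = [
            estimation.crude_estimate(linked, by_id, geography, f"sc-{i}", Group.FSW_ALL)
            for i in range(1, 5)
        ]
        assert (county.low, county.point, county.high) == (10.0, 15.0, 20.0)
        assert sum(p.point for p in parts) == county.point
        assert sum(p.low for p in parts) == county.low
        assert sum(p.high for p in parts) == county.high

    def test_zero_hotspots_yields_zero_estimate(self, geography):
        est = estimation.crude_estimate({}, {}, geography, "county-1", Group.FSW_ALL)
        assert (est.low, est.point, est.high) == (0.0, 0.0, 0.0)

    def test_inactive_hotspots_excluded(self, geography):
        register = [make_hotspot("h1"),
                    make_hotspot("h2", status=HotspotStatus.INACTIVE)]
        records = [make_record("h1", fsw_peak=(2, 4)), make_record("h2", fsw_peak=(100, 100))]
        linked = dedup.link_records(register, records)
        by_id = {h.id: h for h in register}
        est = estimation.crude_estimate(linked, by_id, geography, "county-1", Group.FSW_ALL)
        assert est.point == 3.0 and est.n_hotspots == 1


class TestMobilityEstimation:
    def test_no_travellers_means_p_zero_m_one(self, geography):
        linked, by_id = _setup(geography, [("h1", "zone-1", (4, 10), (1, 1, 1))])
        params = estimation.estimate_mobility(linked, by_id, geography, "sc-1")
        assert params.p == 0.0 and params.m == 1.0 and params.n_respondents == 3

    def test_direct_arithmetic(self, geography):
        linked, by_id = _setup(geography, [("h1", "zone-1", (4, 10), (1, 2, 4))])
        params = estimation.estimate_mobility(linked, by_id, geography, "sc-1")
        assert params.p == pytest.approx(2 / 3)
        assert params.m == pytest.approx(3.0)

    def test_no_responses_instructs_fallback(self, geography):
        linked, by_id = _setup(geography, [("h1", "zone-1", (4, 10), ())])
        with pytest.raises(estimation.NoMobilityDataError, match="county-pooled"):
            estimation.estimate_mobility(linked, by_id, geography, "sc-1")

    def test_recovers_generator_parameters_at_500_respondents(self):
        # default config: 100 venues x 5 respondents -> ~500 county-wide
        county = generate_county(GeneratorConfig(seed=123))
        register = dedup.dedupe_mentions(county.mentions)
        register = dedup.snowball_update(register, county.level_two_records)
        linked = dedup.link_records(register, county.level_two_records)
        register = dedup.apply_validation(register, linked)
        by_id = {h.id: h for h in register}
        params = estimation.estimate_mobility(linked, by_id, county.geography, "county-1")
        assert params.n_respondents >= 400
        cfg = county.config
        assert params.p == pytest.approx(cfg.p_mobile, abs=0.08)
        assert params.m == pytest.approx(2 + cfg.m_distribution[1], abs=0.15)


class TestMobilityAdjust:
    def _crude(self, value=100.0):
        return SizeEstimate(geo_id="sc-1", group=Group.FSW_ALL,
                            point=value, low=value, high=value)

    @pytest.mark.parametrize(
        "p, m, expected",
        [(0.0, 1.0, 100.0), (1.0, 2.0, 50.0), (0.5, 2.0, 75.0)],
    )
    def test_formula_limits_and_arithmetic(self, p, m, expected):
        params = MobilityParams(geo_id="sc-1", p=p, m=m, n_respondents=10)
        adjusted = estimation.mobility_adjust(self._crude(), params)
        assert adjusted.point == pytest.approx(expected, abs=1e-12)
        assert adjusted.adjusted_for_mobility

    def test_m_below_one_rejected(self):
        with pytest.raises(RecordValidationError):
            MobilityParams(geo_id="sc-1", p=0.0, m=0.5, n_respondents=1)

    @given(
        p=st.floats(0.0, 1.0),
        m_extra=st.floats(0.0, 48.0),
        cr=st.floats(0.0, 1e6),
    )
    @settings(max_examples=300, deadline=None)
    def test_adjusted_never_exceeds_crude(self, p, m_extra, cr):
        m = 1.0 if p == 0 else 2.0 + m_extra
        params = MobilityParams(geo_id="g", p=p, m=m, n_respondents=1)
        crude = SizeEstimate(geo_id="g", group=Group.FSW_ALL, point=cr, low=cr, high=cr)
        adjusted = estimation.mobility_adjust(crude, params)
        assert adjusted.point <= crude.point + 1e-9
        if p == 0.0:
            assert adjusted.point == crude.point
        if p == 1.0:
            assert adjusted.point == pytest.approx(cr / m)

    @pytest.mark.parametrize("p", [0.0, 0.25, 0.5, 0.75, 1.0])
    @pytest.mark.parametrize("m", [1, 2, 3, 5])
    def test_overestimation_bias_on_homogeneous_population(self, p, m):
        """In a population of N women where a fraction p attend exactly m
        venues and the rest one venue, the venue-sum is Cr = N[(1-p)+pm],
        exact deduplication recovers N = Cr/[(1-p)+pm], and the adjusted
        estimate satisfies Ni/N = [(1-p)+pm][(1-p)+p/m] >= 1 with equality
        exactly when p is 0 or 1 or m = 1."""
        n_women = 1200
        n_mobile = round(p * n_women)
        crude_value = float((n_women - n_mobile) + n_mobile * m)
        m_hat = 1.0 if n_mobile == 0 else float(m)
        p_hat = n_mobile / n_women
        if p_hat > 0 and m_hat < 2:
            # a woman counted as mobile visits >= 2 venues by definition
            with pytest.raises(RecordValidationError, match="m >= 2"):
                MobilityParams(geo_id="g", p=p_hat, m=m_hat, n_respondents=n_women)
            return
        params = MobilityParams(geo_id="g", p=p_hat, m=m_hat, n_respondents=n_women)
        crude = SizeEstimate(geo_id="g", group=Group.FSW_ALL,
                             point=crude_value, low=crude_value, high=crude_value)
        adjusted = estimation.mobility_adjust(crude, params)
        ratio = adjusted.point / n_women
        expected_ratio = ((1 - p_hat) + p_hat * m_hat) * ((1 - p_hat) + p_hat / m_hat)
        assert ratio == pytest.approx(expected_ratio, rel=1e-12)
        assert ratio >= 1.0 - 1e-12
        if p_hat in (0.0, 1.0) or m_hat == 1.0:
            assert ratio == pytest.approx(1.0)
        else:
            assert ratio > 1.0
        assert n_women - 1e-9 <= adjusted.point <= crude.point + 1e-9


class TestAggregation:
    def test_county_sum(self):
        parts = [
            SizeEstimate(geo_id=f"sc-{i}", group=Group.FSW_ALL,
                         point=15.0, low=10.0, high=20.0, adjusted_for_mobility=True)
            for i in range(1, 5)
        ]
        total = estimation.county_estimate(parts, "county-1")
        assert (total.low, total.point, total.high) == (40.0, 60.0, 80.0)
        assert total.adjusted_for_mobility

    def test_single_subcounty_is_identity(self):
        e = SizeEstimate(geo_id="sc-1", group=Group.FSW_14_24, point=15.0, low=10.0, high=20.0)
        total = estimation.county_estimate([e], "county-1")
        assert (total.low, total.point, total.high) == (e.low, e.point, e.high)

    def test_mixed_groups_rejected(self):
        parts = [
            SizeEstimate(geo_id="sc-1", group=Group.FSW_ALL, point=1, low=1, high=1),
            SizeEstimate(geo_id="sc-2", group=Group.FSW_14_24, point=1, low=1, high=1),
        ]
        with pytest.raises(RecordValidationError, match="mixed groups"):
            estimation.county_estimate(parts)


class TestTransactionalCasual:
    def test_peak_day_midpoint(self, geography):
        register = [make_hotspot("h1")]
        records = [make_record("h1", tc_peak=(2, 4))]
        linked = dedup.link_records(register, records)
        est = estimation.tc_estimate(linked, {"h1": register[0]}, geography,
                                     "county-1", Group.TRANSACTIONAL_14_24)
        assert est.point == 3.0
        assert not est.adjusted_for_mobility

    def test_fsw_group_rejected(self, geography):
        with pytest.raises(RecordValidationError):
            estimation.tc_estimate({}, {}, geography, "county-1", Group.FSW_ALL)


class TestReporting:
    @pytest.mark.parametrize(
        "numerator, denominator, expected",
        [(6127, 134_885, 4.54), (9508, 134_885, 7.05), (0, 134_885, 0.0),
         (11_777, 319_032, 3.69)],
    )
    def test_population_proportions(self, numerator, denominator, expected):
        assert estimation.proportion_of_population(numerator, denominator) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(RecordValidationError):
            estimation.proportion_of_population(10, 0)

    @pytest.mark.parametrize(
        "value, expected", [(11_777.5, 11_777), (6127.5, 6127), (42.0, 42)]
    )
    def test_point_reporting_truncates(self, value, expected):
        assert estimation.report_point(value) == expected

    def test_round_half_up_differs_from_bankers(self):
        assert estimation.round_half_up(0.125, 2) == 0.13
        assert estimation.round_half_up(71.25, 1) == 71.3
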