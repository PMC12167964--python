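"""Decay-curve fitting and reef flux scenario construction."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from helpers import grid_scan_decay_fit
from reefcarb import scenarios as sc


@pytest.fixture(params=sc.RCP_IDS)
def rcp_id(request):
    return request.param


class TestDecayCurveFit:
    def test_interpolates_all_anchors(self, rcp_id):
        curve = sc.fit_decay_curve(sc.NECAnchors.for_rcp(rcp_id))
        for year, value in sc.NEC_ANCHORS[rcp_id]:
            assert abs(curve.nec(year) - value) < 1e-6
        assert curve.b > 0 and curve.k > 0
        assert abs((curve.a + curve.b) - sc.NEC_ANCHORS[rcp_id][0][1]) < 1e-9
        # asymptote lies below the last (lowest) anchor
        assert curve.a < sc.NEC_ANCHORS[rcp_id][2][1]

    def test_rcp85_asymptote_and_plateau(self):
        curve = sc.fit_decay_curve(sc.NECAnchors.for_rcp("RCP8.5"))
        assert -1.58 < curve.a <= -1.57
        assert abs(curve.nec(2200) - curve.a) < 1e-2

    def test_fit_matches_brute_force_grid_scan(self):
        """Dense (a, k) scan minimizing anchor misfit recovers the same curve."""
        anchors = sc.NECAnchors.for_rcp("RCP8.5")
        curve = sc.fit_decay_curve(anchors)
        a, b, k = grid_scan_decay_fit(anchors, a_range=(-2.0, 0.0), k_range=(0.01, 0.2))
        assert abs(a - curve.a) <= 2.0 / 2000
        assert abs(k - curve.k) <= 0.19 / 2000
        assert abs(b - curve.b) <= 2.0 / 2000

    def test_flat_anchors_rejected(self):
        with pytest.raises(sc.UnfittableAnchorsError, match="unfittable"):
            sc.NECAnchors(rcp_id="RCP2.6", points=((2005, 2.8), (2050, 2.8), (2100, 2.8)))

    def test_non_monotone_anchors_rejected(self):
        with pytest.raises(sc.UnfittableAnchorsError):
            sc.NECAnchors(rcp_id="RCP2.6", points=((2005, 2.8), (2050, 0.5), (2100, 0.9)))

    def test_unbracketable_ratio_raises_no_fit(self):
        # decline between the last two anchors faster than between the first
        # two: no positive decay rate can fit
        anchors = sc.NECAnchors(rcp_id="RCP2.6", points=((2005, 2.8), (2050, 2.7), (2100, 0.1)))
        with pytest.raises(sc.NoExponentialFitError, match="no exponential fit"):
            sc.fit_decay_curve(anchors)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        a=st.floats(-3.0, 1.0),
        b=st.floats(0.5, 5.0),
        k=st.floats(0.005, 0.2),
    )
    def test_roundtrip_recovery(self, a, b, k):
        """Anchors sampled from a known curve are fitted back exactly."""
        assume(a + b > 0.05)  # present-day NEC must be positive
        truth = sc.DecayCurve(a=a, b=b, k=k)
        points = tuple((y, float(truth.nec(y))) for y in (2005, 2050, 2100))
        anchors = sc.NECAnchors(rcp_id="RCP4.5", points=points)
        curve = sc.fit_decay_curve(anchors)
        assert curve.a == pytest.approx(a, abs=1e-7)
        assert curve.b == pytest.approx(b, abs=1e-7)
        assert curve.k == pytest.approx(k, abs=1e-9)


class TestRelativeAnomaly:
    def test_zero_at_and_before_reference_year(self, rcp_id):
        curve = sc.fit_decay_curve(sc.NECAnchors.for_rcp(rcp_id))
        assert sc.relative_anomaly(curve, 2005) == 0.0
        assert sc.relative_anomaly(curve, 1900) == 0.0

    @pytest.mark.parametrize(
        "rcp_id,expected",
        [("RCP2.6", (2.8 - 0.73) / 2.8), ("RCP8.5", (2.8 + 1.57) / 2.8)],
    )
    def test_anomaly_2100_from_printed_anchors(self, rcp_id, expected):
        curve = sc.fit_decay_curve(sc.NECAnchors.for_rcp(rcp_id))
        assert sc.relative_anomaly(curve, 2100) == pytest.approx(expected, abs=1e-9)

    def test_non_decreasing_and_pre1850_rejected(self, rcp_id):
        curve = sc.fit_decay_curve(sc.NECAnchors.for_rcp(rcp_id))
        years = np.arange(1850, 2301)
        rel = sc.relative_anomaly(curve, years)
        assert np.all(np.diff(rel) >= 0)
        with pytest.raises(ValueError):
            sc.relative_anomaly(curve, 1700)


class TestFluxConversion:
    @pytest.mark.parametrize(
        "rel,g0,alk_rounded,dic_rounded",
        [((2.8 - 0.73) / 2.8, 30.0, 0.004, 0.002), ((2.8 + 1.57) / 2.8, 300.0, 0.08, 0.04)],
    )
    def test_printed_global_fluxes(self, rel, g0, alk_rounded, dic_rounded):
        alk, dic = sc.anomaly_to_global_fluxes(rel, g0)
        assert alk == 2.0 * dic
        assert round(alk, 3 if alk < 0.01 else 2) == alk_rounded
        assert round(dic, 3 if dic < 0.01 else 2) == dic_rounded

    def test_zero_anomaly_zero_flux(self):
        assert sc.anomaly_to_global_fluxes(0.0, 150.0) == (0.0, 0.0)

    def test_negative_anomaly_rejected(self):
        with pytest.raises(ValueError):
            sc.anomaly_to_global_fluxes(-0.1, 150.0)

    @pytest.mark.parametrize("g,expected", [(150.0, 1.25), (30.0, 0.25), (300.0, 2.50), (0.0, 0.0)])
    def test_tgc_to_pgcaco3(self, g, expected):
        assert round(sc.tgc_to_pgcaco3(g), 2) == expected


class TestBuildScenario:
    def test_two_to_one_ratio_exact_and_zero_before_2005(self, rcp_id):
        series = sc.build_scenario(sc.ScenarioSpec(rcp_id, 150.0))
        assert np.array_equal(series.alk_flux, 2.0 * series.dic_flux)
        assert np.all(series.alk_flux[series.years < 2005] == 0.0)
        assert np.all(np.diff(series.alk_flux) >= 0)

    def test_linear_scaling_in_g0(self, rcp_id):
        s30 = sc.build_scenario(sc.ScenarioSpec(rcp_id, 30.0))
        s300 = sc.build_scenario(sc.ScenarioSpec(rcp_id, 300.0))
        np.testing.assert_allclose(s300.alk_flux, 10.0 * s30.alk_flux, rtol=1e-12)

    def test_rcp_ordering_of_fluxes(self):
        runs = {r: sc.build_scenario(sc.ScenarioSpec(r, 150.0)) for r in sc.RCP_IDS}
        late = runs["RCP2.6"].years >= 2010
        assert np.all(runs["RCP8.5"].alk_flux[late] >= runs["RCP4.5"].alk_flux[late])
        assert np.all(runs["RCP4.5"].alk_flux[late] >= runs["RCP2.6"].alk_flux[late])

    def test_most_decline_before_2050(self, rcp_id):
        curve = sc.fit_decay_curve(sc.NECAnchors.for_rcp(rcp_id))
        ratio = sc.relative_anomaly(curve, 2050) / sc.relative_anomaly(curve, 2300)
        assert ratio > 0.75

    def test_plateau_after_2150(self, rcp_id):
        series = sc.build_scenario(sc.ScenarioSpec(rcp_id, 300.0))
        f2150 = series.flux_at(2150)[0]
        f2300 = series.flux_at(2300)[0]
        assert (f2300 - f2150) < 0.01 * f2300

    def test_production_rate_independent_ratio(self):
        """dic(2050)/dic(2100) equals the relative-anomaly ratio for any G0."""
        series = sc.build_scenario(sc.ScenarioSpec("RCP4.5", 150.0))
        ratio = series.flux_at(2050)[1] / series.flux_at(2100)[1]
        expected = ((2.8 + 0.63) / 2.8) / ((2.8 + 1.39) / 2.8)
        assert ratio == pytest.approx(expected, rel=1e-12)
        assert ratio == pytest.approx(1.225 / 1.496, rel=1e-3)

    def test_pre_2005_zero(self):
        series = sc.build_scenario(sc.ScenarioSpec("RCP8.5", 300.0))
        assert series.flux_at(1900) == (0.0, 0.0)
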