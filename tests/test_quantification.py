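import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from gelquant.densitometry import Peak
from gelquant.quantification import (
    CalibrationModel,
    MarkerBand,
    MarkerLane,
    beer_lambert_concentration,
    calibrate_from_marker,
    culture_concentration,
    estimate_mw,
    estimate_mw_global_fit,
    fit_marker_multipoint,
    fit_zero_intercept,
    intensity_ratio_report,
    load_marker_table,
    mixture_concentrations,
    protein_load,
    quantify_band,
)


def peak(area, centroid=0.0, max_intensity=None):
    return Peak(
        left_pos=int(centroid) - 5,
        right_pos=int(centroid) + 5,
        baseline_left_value=0.0,
        baseline_right_value=0.0,
        area=area,
        max_intensity=area / 5 if max_intensity is None else max_intensity,
        centroid_pos=centroid,
    )


class TestBeerLambert:
    def test_zero_absorbance(self):
        assert beer_lambert_concentration(0.0, 6.6, 1.0) == 0.0

    def test_one_percent_solution(self):
        # A280 = eps * l corresponds to 1% w/v = 10 mg/ml by definition
        assert beer_lambert_concentration(6.6, 6.6, 1.0) == pytest.approx(10.0)

    def test_short_path(self):
        assert beer_lambert_concentration(0.66, 6.6, 0.1) == pytest.approx(10.0)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            beer_lambert_concentration(1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            beer_lambert_concentration(-0.1, 6.6, 1.0)


class TestMixture:
    def test_single_stock_identity(self):
        assert mixture_concentrations([("BSA", 8.9, 100.0)]) == [("BSA", 8.9)]

    def test_three_standard_mixture(self):
        # equal 100 ul volumes of the three stock standards
        out = dict(
            mixture_concentrations(
                [("BSA", 8.9, 100.0), ("CA", 9.1, 100.0), ("OV", 5.9, 100.0)]
            )
        )
        assert out["BSA"] == pytest.approx(8.9 / 3)
        assert out["CA"] == pytest.approx(9.1 / 3)
        assert out["OV"] == pytest.approx(5.9 / 3)
        # rounded to the nearest mg/ml: 3, 3 and 2
        assert round(out["BSA"]) == 3 and round(out["CA"]) == 3 and round(out["OV"]) == 2

    def test_dilution(self):
        out = mixture_concentrations([("x", 6.0, 100.0), ("buffer", 0.0, 200.0)])
        assert out[0][1] == pytest.approx(2.0)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            mixture_concentrations([])


class TestProteinLoad:
    @pytest.mark.parametrize(
        "conc,vol,factor,expected",
        [(0.0, 10.0, 0.5, 0.0), (0.3, 10.0, 0.5, 1500.0), (0.06, 10.0, 0.5, 300.0)],
    )
    def test_values(self, conc, vol, factor, expected):
        assert protein_load(conc, vol, factor) == pytest.approx(expected)

    def test_homogeneous_in_concentration(self):
        base = protein_load(0.1, 10.0)
        assert protein_load(0.7, 10.0) == pytest.approx(7 * base)


class TestFitZeroIntercept:
    def test_exact_line(self):
        m = fit_zero_intercept([(1, 2), (2, 4), (3, 6)])
        assert m.slope == pytest.approx(2.0)
        assert m.r2 == pytest.approx(1.0)
        assert m.slope_se == pytest.approx(0.0)

    def test_closed_form_two_points(self):
        m = fit_zero_intercept([(1, 2), (2, 3)])
        assert m.slope == pytest.approx(1.6)

    def test_matches_numeric_minimizer(self, rng):
        for _ in range(20):
            n = rng.integers(2, 10)
            P = rng.uniform(0.1, 100, n)
            A = rng.uniform(0.0, 300, n)
            m = fit_zero_intercept(list(zip(P, A)))
            sse = lambda s: float(((A - s * P) ** 2).sum())
            best = minimize_scalar(
                sse, bracket=(m.slope - 1.0, m.slope + 1.0), method="brent"
            ).x
            assert m.slope == pytest.approx(best, rel=1e-7)

    def test_matches_statsmodels_inference(self, rng):
        import statsmodels.api as sm

        P = rng.uniform(1, 50, 6)
        A = 3.2 * P + rng.normal(0, 5, 6)
        m = fit_zero_intercept(list(zip(P, A)))
        res = sm.OLS(A, P).fit()  # no-intercept OLS
        assert m.slope == pytest.approx(res.params[0], rel=1e-12)
        assert m.slope_se == pytest.approx(res.bse[0], rel=1e-10)
        assert m.r2 == pytest.approx(res.rsquared, rel=1e-10)
        assert m.p_value == pytest.approx(res.pvalues[0], rel=1e-8)

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            fit_zero_intercept([(0, 1), (0, 2)])
        with pytest.raises(ValueError):
            fit_zero_intercept([(1, 1)])


def ladder_lane(volume_ul=10.0, slope=3.193):
    """Marker lane whose characterized bands follow area = slope*load."""
    table = load_marker_table()
    bands = []
    for i, b in enumerate(table):
        load = b.load_ng(volume_ul)
        area = slope * load if load is not None else 1.0
        bands.append((b, peak(area, centroid=40.0 * i + 30.0)))
    return MarkerLane(volume_ul=volume_ul, bands=tuple(bands))


class TestMarkerCalibration:
    def test_printed_reference_slope(self):
        """A 750 ng reference band of area 2394.75 pixel*AU gives the
        reported 3.193 (pixel*AU)/ng slope."""
        lane = MarkerLane(
            volume_ul=10.0,
            bands=((MarkerBand(50.0, 750.0, True), peak(2394.75, 10.0)),
                   (MarkerBand(25.0, None, True), peak(100.0, 20.0))),
        )
        m = calibrate_from_marker(lane, 50.0)
        assert m.slope == pytest.approx(3.193)
        assert m.source == "single-point-marker"
        assert m.slope_se is None and m.r2 is None and m.p_value is None

    def test_unit_slope(self):
        lane = MarkerLane(
            volume_ul=10.0, bands=((MarkerBand(50.0, 750.0, True), peak(750.0)),)
        )
        assert calibrate_from_marker(lane, 50.0).slope == pytest.approx(1.0)

    def test_volume_scaling(self):
        lane = MarkerLane(
            volume_ul=5.0, bands=((MarkerBand(50.0, 750.0, True), peak(1000.0)),)
        )
        assert calibrate_from_marker(lane, 50.0).slope == pytest.approx(1000.0 / 375.0)

    def test_missing_reference_band(self):
        lane = MarkerLane(
            volume_ul=10.0, bands=((MarkerBand(50.0, 750.0, True), peak(1.0)),)
        )
        with pytest.raises(ValueError):
            calibrate_from_marker(lane, 37.0)

    def test_placeholder_band_cannot_calibrate(self):
        lane = MarkerLane(
            volume_ul=10.0, bands=((MarkerBand(75.0, None, True), peak(100.0)),)
        )
        with pytest.raises(ValueError, match="stated load"):
            calibrate_from_marker(lane, 75.0)

    def test_multipoint_recovers_common_slope(self):
        m = fit_marker_multipoint(ladder_lane(slope=3.193))
        assert m.slope == pytest.approx(3.193)
        assert m.n_points == 3  # 100, 50, 20 kDa are characterized


class TestQuantifyBand:
    def test_zero_area(self):
        model = CalibrationModel(3.193, None, None, None, 1, "single-point-marker")
        assert quantify_band(peak(0.0), model) == 0.0

    def test_reference_self_consistency(self):
        lane = ladder_lane()
        model = calibrate_from_marker(lane, 50.0)
        _, ref_peak = lane.band(50.0)
        assert quantify_band(ref_peak, model) == pytest.approx(750.0)

    def test_hand_arithmetic(self):
        model = CalibrationModel(3.193, None, None, None, 1, "single-point-marker")
        assert quantify_band(peak(958.0), model) == pytest.approx(958.0 / 3.193)
        assert quantify_band(peak(3.193 * 300.0), model) == pytest.approx(300.0)


class TestEstimateMW:
    def test_node_exact(self):
        lane = ladder_lane()
        for band, pk in lane.bands:
            assert estimate_mw(pk.centroid_pos, lane) == pytest.approx(band.mw_kda)

    def test_log_midpoint(self):
        lane = MarkerLane(
            volume_ul=10.0,
            bands=((MarkerBand(50.0, 750.0, True), peak(10, 100.0)),
                   (MarkerBand(37.0), peak(10, 140.0))),
        )
        got = estimate_mw(120.0, lane)
        assert got == pytest.approx(10 ** ((np.log10(50) + np.log10(37)) / 2), rel=1e-9)
        assert got == pytest.approx(43.0, abs=0.05)

    def test_monotone_decreasing(self):
        lane = ladder_lane()
        positions = np.linspace(30.0, 390.0, 40)
        mws = [estimate_mw(p, lane) for p in positions]
        assert np.all(np.diff(mws) < 0)

    def test_extrapolation_warns(self):
        lane = ladder_lane()
        with pytest.warns(UserWarning, match="extrapolating"):
            estimate_mw(5.0, lane)

    def test_global_fit_agrees_on_log_linear_ladder(self):
        lane = ladder_lane()  # centroids exactly linear in band index, not log MW
        # build an exactly log-linear lane instead
        table = load_marker_table()
        bands = tuple(
            (b, peak(10.0, centroid=500.0 - 150.0 * np.log10(b.mw_kda)))
            for b in table
        )
        lane = MarkerLane(volume_ul=10.0, bands=bands)
        for pos in (160.0, 250.0, 300.0):
            assert estimate_mw_global_fit(pos, lane) == pytest.approx(
                estimate_mw(pos, lane), rel=1e-9
            )

    def test_needs_two_bands(self):
        lane = MarkerLane(volume_ul=10.0, bands=((MarkerBand(50.0), peak(1.0)),))
        with pytest.raises(ValueError):
            estimate_mw(10.0, lane)


class TestCultureConcentration:
    def test_single_eluate(self):
        # 1 mg/L in 1 ml eluate out of a 25 ml culture sample
        assert culture_concentration([(1.0, 1.0)], 25.0) == pytest.approx(0.04)

    def test_two_eluates_one_empty(self):
        assert culture_concentration([(1.0, 1.0), (0.0, 1.0)], 25.0) == pytest.approx(0.04)

    def test_zero_mass(self):
        assert culture_concentration([(0.0, 1.0)], 25.0) == 0.0

    def test_homogeneous_in_concentration(self):
        el = [(2.0, 1.5), (0.5, 1.0)]
        scaled = [(6.0, 1.5), (1.5, 1.0)]
        assert culture_concentration(scaled, 25.0) == pytest.approx(
            3 * culture_concentration(el, 25.0)
        )

    def test_rejects_bad_volume(self):
        with pytest.raises(ValueError):
            culture_concentration([(1.0, 1.0)], 0.0)


class TestMarkerLaneInvariants:
    def test_rejects_non_monotone_centroids(self):
        with pytest.raises(ValueError, match="centroids"):
            MarkerLane(
                volume_ul=10.0,
                bands=((MarkerBand(50.0), peak(1.0, 100.0)),
                       (MarkerBand(37.0), peak(1.0, 90.0))),
            )

    def test_intensity_ratio_report(self):
        lane = ladder_lane()
        rows = intensity_ratio_report(lane)
        assert {r["reference_mw_kda"] for r in rows} == {75.0, 50.0, 25.0}
        for r in rows:
            assert r["ratio_by_area"] > 0 and r["ratio_by_max_intensity"] > 0
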