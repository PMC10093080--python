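"""Bearing composition, calibration, endpoint projection and the sampling
diagnostics, checked against closed-form and brute-force oracles."""

import math
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dancemap import (
    CalibrationError,
    CalibrationModel,
    HiveSite,
    ValidationError,
    WagglePhase,
    bearing_from_dance,
    calibrate,
    distance_from_duration,
    inverse_point,
    nyquist_margin,
    phase_endpoints,
    project_endpoint,
    read_endpoints_geojson,
    ring_spacing,
    sector_width,
    waggle_accuracy,
    write_endpoints_geojson,
)

from _oracles import sweep_sector_width, vector_destination

EQUATOR = HiveSite(lat_deg=0.0, lon_deg=0.0, fps=60.0)


class TestBearing:
    @pytest.mark.parametrize(
        "angle, azimuth, expected",
        [(0.0, 137.0, 137.0), (90.0, 180.0, 270.0), (350.0, 20.0, 10.0)],
    )
    def test_sum_mod_360(self, angle, azimuth, expected):
        assert bearing_from_dance(angle, azimuth) == pytest.approx(expected)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            bearing_from_dance(float("nan"), 10.0)


class TestDistance:
    def test_feeder_distance_from_median_duration(self):
        assert distance_from_duration(0.60, CalibrationModel(v=383.33)) == pytest.approx(
            230.0, abs=0.01
        )

    def test_zero_duration_maps_to_hive(self):
        assert distance_from_duration(0.0, 400.0) == 0.0

    def test_negative_duration_rejected(self):
        with pytest.raises(ValidationError):
            distance_from_duration(-0.1, 380.0)

    @given(tau=st.floats(0.0, 10.0), k=st.floats(0.0, 5.0))
    def test_linearity(self, tau, k):
        v = CalibrationModel(v=383.33)
        assert distance_from_duration(k * tau, v) == pytest.approx(
            k * distance_from_duration(tau, v), rel=1e-12, abs=1e-9
        )


class TestProjection:
    def test_one_degree_east_at_equator(self):
        # 2*pi*R/360 = 111,194.93 m per degree along the equator
        e = project_endpoint(EQUATOR, 90.0, 2 * math.pi * 6_371_000.0 / 360.0)
        assert e.lat_deg == pytest.approx(0.0, abs=1e-6)
        assert e.lon_deg == pytest.approx(1.0, abs=1e-6)

    def test_zero_distance_returns_hive(self):
        e = project_endpoint(EQUATOR, 123.0, 0.0)
        assert (e.lat_deg, e.lon_deg) == (0.0, 0.0)

    def test_north_south_symmetry_at_equator(self):
        n = project_endpoint(EQUATOR, 0.0, 5000.0)
        s = project_endpoint(EQUATOR, 180.0, 5000.0)
        assert n.lat_deg == pytest.approx(-s.lat_deg, abs=1e-12)
        assert n.lon_deg == pytest.approx(s.lon_deg, abs=1e-12)

    @given(
        lat=st.floats(-80.0, 80.0),
        lon=st.floats(-179.0, 179.0),
        bearing=st.floats(0.0, 360.0),
        distance=st.floats(0.0, 10_000.0),
    )
    def test_agrees_with_vector_algebra_oracle(self, lat, lon, bearing, distance):
        site = HiveSite(lat_deg=lat, lon_deg=lon)
        e = project_endpoint(site, bearing, distance)
        ref_lat, ref_lon = vector_destination(lat, lon, bearing, distance)
        # chord distance between the two results, in meters
        def xyz(la, lo):
            la, lo = math.radians(la), math.radians(lo)
            return np.array(
                [math.cos(la) * math.cos(lo), math.cos(la) * math.sin(lo), math.sin(la)]
            )
        err = np.linalg.norm(xyz(e.lat_deg, e.lon_deg) - xyz(ref_lat, ref_lon)) * 6_371_000.0
        assert err < 0.1

    def test_inverse_recovers_bearing_and_distance(self):
        e = project_endpoint(EQUATOR, 37.0, 4321.0)
        d, b = inverse_point(0.0, 0.0, e.lat_deg, e.lon_deg)
        assert d == pytest.approx(4321.0, abs=1e-6)
        assert b == pytest.approx(37.0, abs=1e-9)


class TestCalibrate:
    def test_feeder_calibration_factor(self):
        cal = calibrate([0.55, 0.60, 0.72], 230.0, estimator="median")
        assert cal.v == pytest.approx(230.0 / 0.60, abs=1e-9)
        assert cal.v_rounded == 380

    def test_equal_durations_exact(self):
        cal = calibrate([0.5, 0.5, 0.5], 200.0)
        assert cal.v == pytest.approx(400.0)

    def test_hand_example(self):
        assert calibrate([0.5, 0.6, 0.7], 300.0).v == pytest.approx(500.0)

    def test_empty_durations_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate([], 230.0)

    def test_zero_estimator_value_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate([0.0, 0.0, 0.0], 230.0)

    @given(
        durations=st.lists(st.floats(0.1, 3.0), min_size=1, max_size=30),
        distance=st.floats(10.0, 5000.0),
    )
    def test_round_trip_through_distance(self, durations, distance):
        cal = calibrate(durations, distance)
        eta = float(np.median(durations))
        assert distance_from_duration(eta, cal) == pytest.approx(distance, rel=1e-12)


class TestDiagnostics:
    def test_waggle_accuracy_study_configuration(self):
        q = waggle_accuracy(380.0, 13.0)
        assert q.value == pytest.approx(29.23, abs=0.005)
        assert q.rounded == 29

    @pytest.mark.parametrize("v, f, expected", [(380.0, 380.0, 1.0), (500.0, 12.5, 40.0)])
    def test_waggle_accuracy_scaling(self, v, f, expected):
        assert waggle_accuracy(v, f).value == pytest.approx(expected)

    def test_ring_spacing_study_configuration(self):
        q = ring_spacing(380.0, 60.0)
        assert q.value == pytest.approx(6.333, abs=0.001)
        assert q.rounded == 6

    @pytest.mark.parametrize("v, fps, expected", [(380.0, 120.0, 3.1667), (60.0, 60.0, 1.0)])
    def test_ring_spacing_scaling(self, v, fps, expected):
        assert ring_spacing(v, fps).value == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize(
        "fps, fmax, ratio, adequate",
        [(60.0, 18.0, 60 / 36, True), (60.0, 30.0, 1.0, True), (25.0, 13.0, 25 / 26, False)],
    )
    def test_nyquist_margin(self, fps, fmax, ratio, adequate):
        m = nyquist_margin(fps, fmax)
        assert m.ratio == pytest.approx(ratio)
        assert m.adequate is adequate

    @pytest.mark.parametrize("fn", [waggle_accuracy, ring_spacing])
    def test_non_positive_rate_rejected(self, fn):
        with pytest.raises(ValidationError):
            fn(380.0, 0.0)


class TestSectorWidth:
    def test_identical_bearings(self):
        assert sector_width([42.0] * 5, 0.5) == 0.0
        assert sector_width([42.0] * 5, 1.0) == 0.0

    def test_wraparound_cluster(self):
        # smallest covering arc runs 350 -> 20 (oracle: brute-force sweep)
        assert sector_width([0.0, 10.0, 20.0, 350.0], 1.0) == pytest.approx(30.0)

    def test_uniform_bearings_approach_full_circle(self):
        bearings = np.arange(0.0, 360.0, 1.0)
        assert sector_width(bearings, 1.0) == pytest.approx(359.0)

    def test_partial_coverage_drops_outlier(self):
        assert sector_width([0.0, 1.0, 2.0, 3.0, 180.0], 0.8) == pytest.approx(3.0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            sector_width([], 1.0)

    @given(
        bearings=st.lists(st.floats(0.0, 359.999), min_size=1, max_size=25),
        coverage=st.sampled_from([0.5, 0.75, 0.9, 1.0]),
    )
    def test_agrees_with_sweep_oracle(self, bearings, coverage):
        got = sector_width(bearings, coverage)
        ref = sweep_sector_width(bearings, coverage)
        # the sweep includes exact bearings as anchors, so the optima coincide
        assert got == pytest.approx(ref, abs=1e-9)


class TestRotationEquivariance:
    def test_solar_azimuth_shift_rotates_endpoints_about_hive(self, site):
        """Adding a shift to the solar azimuth rotates every endpoint bearing
        by that shift and leaves hive distances unchanged."""
        t0 = datetime(2022, 6, 21, 10, 50, tzinfo=timezone.utc)
        phases = [
            WagglePhase("d1", j, j * 100, j * 100 + 30 + j, angle_deg=30.0 * j,
                        timestamp_utc=t0 + timedelta(seconds=3 * j))
            for j in range(6)
        ]
        cal = CalibrationModel(v=383.33)
        base = phase_endpoints(phases, site, cal)
        delta = 25.0
        shifted = [
            project_endpoint(site, (e.bearing_deg + delta) % 360.0, e.distance_m)
            for e in base
        ]
        for e, s in zip(base, shifted):
            d_e, b_e = inverse_point(site.lat_deg, site.lon_deg, e.lat_deg, e.lon_deg)
            d_s, b_s = inverse_point(site.lat_deg, site.lon_deg, s.lat_deg, s.lon_deg)
            assert d_s == pytest.approx(d_e, abs=1e-6)
            assert (b_s - b_e) % 360.0 == pytest.approx(delta, abs=1e-6)

    def test_quantized_durations_give_ring_distances(self, site):
        """Frame-quantized durations land on distances k * v / fps."""
        t0 = datetime(2022, 6, 21, 10, 50, tzinfo=timezone.utc)
        rng = np.random.default_rng(5)
        phases = [
            WagglePhase("d1", j, 0, int(rng.integers(1, 90)), angle_deg=float(rng.uniform(0, 360)),
                        timestamp_utc=t0)
            for j in range(40)
        ]
        cal = CalibrationModel(v=380.0)
        quantum = ring_spacing(cal, site.fps).value
        for e in phase_endpoints(phases, site, cal):
            k = e.distance_m / quantum
            assert k == pytest.approx(round(k), abs=1e-9)


class TestEndpointIO:
    def test_geojson_round_trip(self, tmp_path, site):
        t0 = datetime(2022, 6, 21, 10, 50, tzinfo=timezone.utc)
        phases = [
            WagglePhase("d1", j, j * 60, j * 60 + 36, angle_deg=40.0 + j,
                        timestamp_utc=t0 + timedelta(seconds=2 * j))
            for j in range(4)
        ]
        endpoints = phase_endpoints(phases, site, CalibrationModel(v=383.33))
        path = tmp_path / "endpoints.geojson"
        write_endpoints_geojson(endpoints, path)
        back = read_endpoints_geojson(path)
        assert back == endpoints
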