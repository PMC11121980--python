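import math
from datetime import date, datetime, timedelta

import numpy as np
import pytest

from windtrace.atmosphere import Domain, make_uniform_field
from windtrace.solar import Site
from windtrace.trajectory import (M_PER_DEG_LAT, M_PER_DEG_LON_EQ,
                                  ReleaseSpec, TrajectoryParams,
                                  batch_simulate, endpoints, simulate)

from conftest import make_window

ORIGIN = (24.0, 97.83)


def _release(direction="forward", hours=1.0,
             start=datetime(2019, 4, 26, 20, 0)):
    return ReleaseSpec(*ORIGIN, date(2019, 4, 26), direction,
                       make_window(start, hours))


class TestUniformFieldKinematics:
    def test_eastward_closed_form_displacement(self, uniform_east_grid):
        """1 h at u = 10 m/s -> 36.00 km east = 0.3540 deg lon at 24 N."""
        trajs = simulate(_release(hours=1.0), uniform_east_grid,
                         TrajectoryParams(altitudes_agl=(500.0,)))
        (t,) = trajs
        dlon = t.endpoint.lon - ORIGIN[1]
        expected = 36_000.0 / (M_PER_DEG_LON_EQ * math.cos(math.radians(24.0)))
        assert dlon == pytest.approx(expected, rel=1e-6)
        assert dlon == pytest.approx(0.3540, abs=5e-5)
        assert t.endpoint.lat == pytest.approx(ORIGIN[0], abs=1e-12)

    def test_zero_wind_is_stationary(self, study_domain):
        calm = make_uniform_field(0.0, 0.0, 20.0, study_domain)
        trajs = simulate(_release(hours=2.0), calm, TrajectoryParams())
        for t in trajs:
            assert t.termination == "window_end"
            assert all(p.lat == ORIGIN[0] and p.lon == ORIGIN[1]
                       for p in t.points)

    def test_point_count_12h_window(self, uniform_east_grid):
        """12 h at 10-min steps -> 1 + 72 = 73 recorded points."""
        trajs = simulate(
            _release(hours=12.0, start=datetime(2019, 4, 26, 18, 0)),
            uniform_east_grid, TrajectoryParams(altitudes_agl=(300.0,)))
        assert len(trajs[0].points) == 73
        assert trajs[0].termination == "window_end"

    def test_backward_retraces_forward(self, uniform_east_grid):
        params = TrajectoryParams(altitudes_agl=(400.0,))
        fwd = simulate(_release("forward", 3.0), uniform_east_grid, params)[0]
        # release the backward run where the forward run landed
        win = fwd.release.window
        back_spec = ReleaseSpec(fwd.endpoint.lat, fwd.endpoint.lon,
                                fwd.release.date, "backward", win)
        bwd = simulate(back_spec, uniform_east_grid, params)[0]
        assert bwd.endpoint.lat == pytest.approx(ORIGIN[0], abs=1e-9)
        assert bwd.endpoint.lon == pytest.approx(ORIGIN[1], abs=1e-6)

    def test_displacement_accumulates_per_step_wind(self, uniform_east_grid):
        """Euler: each displacement = wind at step start x step duration."""
        trajs = simulate(_release(hours=2.0), uniform_east_grid,
                         TrajectoryParams(altitudes_agl=(200.0,)))
        pts = trajs[0].points
        for a, b in zip(pts, pts[1:]):
            dt_s = (b.time - a.time).total_seconds()
            assert dt_s == 600.0
            dlon_expected = a.u * dt_s / (
                M_PER_DEG_LON_EQ * math.cos(math.radians(a.lat)))
            dlat_expected = a.v * dt_s / M_PER_DEG_LAT
            assert b.lon - a.lon == pytest.approx(dlon_expected, rel=1e-9)
            assert b.lat - a.lat == pytest.approx(dlat_expected, abs=1e-15)


class TestTemperatureGate:
    @pytest.mark.parametrize("temp,expect_flight", [(13.0, False), (13.2, True)])
    def test_strict_threshold_at_takeoff(self, study_domain, temp, expect_flight):
        grid = make_uniform_field(5.0, 5.0, temp, study_domain)
        trajs = simulate(_release(hours=1.0), grid, TrajectoryParams())
        for t in trajs:
            if expect_flight:
                assert t.termination == "window_end"
                assert len(t.points) > 1
            else:
                assert t.termination == "temperature_stop"
                assert len(t.points) == 1
                assert t.endpoint.lat == ORIGIN[0]

    def test_infinite_thresholds_are_degenerate(self, uniform_east_grid):
        never = simulate(_release(hours=1.0), uniform_east_grid,
                         TrajectoryParams(temp_threshold=-math.inf))
        assert all(t.termination != "temperature_stop" for t in never)
        always = simulate(_release(hours=1.0), uniform_east_grid,
                          TrajectoryParams(temp_threshold=math.inf))
        assert all(t.termination == "temperature_stop" for t in always)

    def test_continuous_gate_stops_mid_flight(self, study_domain):
        # temperature drops below threshold away from the release point
        grid = make_uniform_field(10.0, 0.0, 20.0, study_domain)
        temp = grid.temperature.copy()
        cold = grid.lons > ORIGIN[1] + 0.5
        temp[:, :, :, cold] = 5.0
        from windtrace.atmosphere import WindGrid
        grid = WindGrid(grid.times, grid.heights_agl, grid.lats, grid.lons,
                        grid.u, grid.v, temp)
        cont = simulate(_release(hours=12.0,
                                 start=datetime(2019, 4, 26, 18, 0)),
                        grid, TrajectoryParams(altitudes_agl=(500.0,),
                                               temp_gate_mode="continuous"))
        assert cont[0].termination == "temperature_stop"
        take_off_only = simulate(
            _release(hours=12.0, start=datetime(2019, 4, 26, 18, 0)), grid,
            TrajectoryParams(altitudes_agl=(500.0,)))
        assert take_off_only[0].termination == "window_end"


class TestBoundary:
    def test_exit_keeps_last_inside_point(self):
        dom = Domain(23.0, 25.0, 97.0, 99.0, 0, 2000,
                     "2019-04-26T00:00:00", "2019-04-28T00:00:00")
        grid = make_uniform_field(30.0, 0.0, 20.0, dom)  # fast eastward
        trajs = simulate(_release(hours=12.0,
                                  start=datetime(2019, 4, 26, 18, 0)),
                         grid, TrajectoryParams(altitudes_agl=(500.0,)))
        t = trajs[0]
        assert t.termination == "boundary_exit"
        for p in t.points:
            assert grid.contains(p.time, p.lat, p.lon, p.altitude_agl)
        # the very next step would have left the domain
        last = t.endpoint
        assert last.lon + 30.0 * 600 / (
            M_PER_DEG_LON_EQ * math.cos(math.radians(last.lat))) > 99.0

    def test_origin_outside_domain_rejected(self):
        dom = Domain(30.0, 32.0, 97.0, 99.0, 0, 2000,
                     "2019-04-26T00:00:00", "2019-04-28T00:00:00")
        grid = make_uniform_field(1.0, 0.0, 20.0, dom)
        with pytest.raises(ValueError, match="outside grid domain"):
            simulate(_release(hours=1.0), grid, TrajectoryParams())

    def test_window_outside_grid_time_range_rejected(self, uniform_east_grid):
        with pytest.raises(ValueError, match="time range"):
            simulate(_release(hours=2.0, start=datetime(2019, 5, 10, 20, 0)),
                     uniform_east_grid, TrajectoryParams())


class TestEndpointsAndBatch:
    def test_endpoint_is_last_point(self, uniform_east_grid):
        trajs = simulate(_release(hours=1.0), uniform_east_grid,
                         TrajectoryParams())
        eps = endpoints(trajs)
        assert len(eps) == len(trajs) == 10
        for t, e in zip(trajs, eps):
            assert e is t.points[-1]

    def test_empty_endpoint_input_rejected(self):
        with pytest.raises(ValueError):
            endpoints([])

    def test_batch_cardinality_and_determinism(self, uniform_east_grid):
        site = Site(lat=24.0, lon=97.83, utc_offset=8.0, name="trap")
        dates = [date(2019, 4, 26), date(2019, 4, 27)]
        run1, fail1 = batch_simulate([site], dates, uniform_east_grid)
        run2, _ = batch_simulate([site], dates, uniform_east_grid)
        assert not fail1
        assert len(run1) == 2 * 2 * 10  # dates x directions x altitudes
        assert [(t.release.date, t.release.direction, t.altitude_agl,
                 t.endpoint.lat, t.endpoint.lon) for t in run1] == \
               [(t.release.date, t.release.direction, t.altitude_agl,
                 t.endpoint.lat, t.endpoint.lon) for t in run2]

    def test_batch_matches_direct_simulate(self, uniform_east_grid):
        site = Site(lat=24.0, lon=97.83, utc_offset=8.0, name="trap")
        d = date(2019, 4, 26)
        batch, _ = batch_simulate([site], [d], uniform_east_grid,
                                  directions=("forward",))
        from windtrace.solar import flight_window
        direct = simulate(ReleaseSpec(site.lat, site.lon, d, "forward",
                                      flight_window(site, d)),
                          uniform_east_grid)
        assert [t.endpoint.lon for t in batch] == \
               [t.endpoint.lon for t in direct]

    def test_batch_logs_failures_without_aborting(self, uniform_east_grid):
        inside = Site(lat=24.0, lon=97.83, utc_offset=8.0, name="ok")
        outside = Site(lat=60.0, lon=97.83, utc_offset=8.0, name="far")
        trajs, failures = batch_simulate([inside, outside],
                                         [date(2019, 4, 26)],
                                         uniform_east_grid)
        assert len(trajs) == 20  # the inside site still ran fully
        assert len(failures) == 2  # one per direction of the outside site
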