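"""Mapping contracts: peaks, interpolation, half-width areas, overlap."""

import math

import numpy as np
import pytest

import sepmap.synthetic as syn
import sepmap.topography as topo
from sepmap.containers import AveragedResponse
from sepmap.geometry import GridGeometry


def flat_response(grid, value=0.0, fs=2000.0):
    data = np.full((grid.n_channels, 3000), value)
    return AveragedResponse(data=data, fs=fs, pre=0.5, post=1.0,
                            n_trials_averaged=1, geometry=grid)


class TestPeakDetection:
    def test_p8_latencies_recovered_within_1ms(self, bc_analysis):
        peaks = bc_analysis["peaks"]
        assert peaks["P"] and peaks["N"]
        assert peaks["P"].latency == pytest.approx(42.0, abs=1.0)
        assert peaks["N"].latency == pytest.approx(62.0, abs=1.0)
        assert peaks["P"].amplitude > 0
        assert peaks["N"].amplitude < 0
        assert peaks["N"].latency > peaks["P"].latency

    def test_p_channel_is_footprint_nearest_electrode(self, bc_analysis,
                                                      grid):
        comp = bc_analysis["recording"].ground_truth["components"][0]
        d = np.hypot(grid.positions[:, 0] - comp["center"][0],
                     grid.positions[:, 1] - comp["center"][1])
        nearest = d.min()
        peak_d = d[bc_analysis["peaks"]["P"].channel_index]
        assert peak_d <= nearest + grid.pitch  # among the nearest electrodes

    def test_pure_noise_gives_no_response(self, grid, rng):
        data = rng.normal(scale=5.0, size=(grid.n_channels, 3000))
        avg = AveragedResponse(data=data, fs=2000.0, pre=0.5, post=1.0,
                               n_trials_averaged=8, geometry=grid)
        peaks = topo.find_component_peaks(avg)
        assert not peaks["P"]
        assert not peaks["N"]


class TestWindowMap:
    def test_constant_trace_maps_to_constant(self, grid):
        avg = flat_response(grid, 3.0)
        pk = topo.ComponentPeak("P", "A1", 0, 50.0, 3.0)
        vals = topo.window_amplitude_map(avg, pk, half_window=1.0)
        assert np.allclose(vals, 3.0)

    def test_symmetric_pulse_window_mean_matches_closed_form(self, grid):
        """The ±1 ms window mean under-reads the peak by exactly the
        analytic window-mean factor of the Gaussian pulse."""
        fs, width, latency = 2000.0, 4.0, 50.0
        t_ms = (np.arange(3000) / fs - 0.5) * 1000.0
        trace = syn.gaussian_pulse(t_ms - latency, width)
        data = np.tile(trace, (grid.n_channels, 1))
        avg = AveragedResponse(data=data, fs=fs, pre=0.5, post=1.0,
                               n_trials_averaged=1, geometry=grid)
        pk = topo.ComponentPeak("P", "A1", 0, latency, 1.0)
        vals = topo.window_amplitude_map(avg, pk, half_window=1.0)
        expected = syn.pulse_window_mean(width, 1.0)
        # 0.5 ms sampling of the window adds a small discrete bias
        assert vals[0] == pytest.approx(expected, rel=0.01)
        assert vals[0] < 1.0  # averaging bias

    def test_zero_window_degenerates_to_peak_sample(self, grid):
        avg = flat_response(grid, 0.0)
        avg.data[0, :] = np.arange(3000)
        pk = topo.ComponentPeak("P", "A1", 0, 100.0, 0.0)
        vals = topo.window_amplitude_map(avg, pk, half_window=0.0)
        assert vals[0] == pytest.approx(avg.time_to_index(100.0))


class TestInterpolation:
    def test_constant_values_give_flat_map(self, grid):
        tmap = topo.interpolate_map(np.full(grid.n_channels, 2.5), grid,
                                    step=50.0)
        assert np.allclose(tmap.field, 2.5, atol=1e-9)

    def test_bilinear_field_reproduced_everywhere(self, grid):
        pos = grid.positions
        vals = 1.0 + 2e-3 * pos[:, 0] + 3e-3 * pos[:, 1]
        tmap = topo.interpolate_map(vals, grid, step=50.0)
        nx, ny = tmap.field.shape
        xs = tmap.origin[0] + np.arange(nx) * tmap.step
        ys = tmap.origin[1] + np.arange(ny) * tmap.step
        expected = 1.0 + 2e-3 * xs[:, None] + 3e-3 * ys[None, :]
        assert np.abs(tmap.field - expected).max() < 1e-9

    def test_exact_at_electrode_positions(self, grid, rng):
        vals = rng.normal(size=grid.n_channels)
        tmap = topo.interpolate_map(vals, grid, step=100.0)
        for ch in range(grid.n_channels):
            x, y = grid.positions[ch]
            i = int(round((x - tmap.origin[0]) / tmap.step))
            j = int(round((y - tmap.origin[1]) / tmap.step))
            assert tmap.field[i, j] == pytest.approx(vals[ch], rel=1e-6,
                                                     abs=1e-9)

    def test_step_convergence_of_peak_location(self, grid):
        comp = syn.ComponentSpec("P", +1, 42.0, 4.0, 1.0, (900.0, 1700.0),
                                 footprint_sigma=500.0)
        vals = syn.spatial_gain(comp, grid.positions)
        fine = topo.locate_peak(topo.interpolate_map(vals, grid, step=2.0))
        coarse = topo.locate_peak(topo.interpolate_map(vals, grid, step=10.0))
        assert math.hypot(fine.x - coarse.x, fine.y - coarse.y) <= 10.0

    def test_step_above_pitch_warns(self, grid, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="sepmap.topography"):
            topo.interpolate_map(np.zeros(grid.n_channels), grid, step=500.0)
        assert any("exceeds electrode pitch" in r.message
                   for r in caplog.records)


class TestPeakLocation:
    def test_off_center_gaussian_recovered_within_a_pixel(self, grid):
        center = (870.0, 1930.0)
        comp = syn.ComponentSpec("P", +1, 42.0, 4.0, 1.0, center,
                                 footprint_sigma=500.0)
        vals = syn.spatial_gain(comp, grid.positions)
        tmap = topo.interpolate_map(vals, grid, step=10.0)
        loc = topo.locate_peak(tmap)
        assert math.hypot(loc.x - center[0], loc.y - center[1]) <= 10.0

    def test_flat_map_tie_breaks_to_first_pixel(self, grid, caplog):
        import logging

        tmap = topo.TopoMap(field=np.ones((21, 37)), step=100.0,
                            origin=(0.0, 0.0), component="P")
        with caplog.at_level(logging.WARNING, logger="sepmap.topography"):
            loc = topo.locate_peak(tmap, refine=False)
        assert (loc.x, loc.y) == tmap.origin
        assert any("degenerate" in r.message for r in caplog.records)

    def test_negative_lobe_uses_argmin(self, grid):
        comp = syn.ComponentSpec("N", -1, 62.0, 8.0, 1.0, (1200.0, 1600.0),
                                 footprint_sigma=500.0)
        vals = -syn.spatial_gain(comp, grid.positions)
        tmap = topo.interpolate_map(vals, grid, step=20.0, component="N")
        loc = topo.locate_peak(tmap)
        assert loc.amplitude < 0
        assert math.hypot(loc.x - 1200.0, loc.y - 1600.0) <= 20.0


class TestHalfWidthRegion:
    def test_gaussian_area_matches_closed_form(self, grid):
        """σ = 505 μm on a raw (un-referenced) map: A = 2π ln2 σ² ≈ 1.11 mm²
        within 2%."""
        sigma = 505.0
        comp = syn.ComponentSpec("N", -1, 62.0, 8.0, 60.0,
                                 (1277.7, 1605.6), footprint_sigma=sigma)
        tmap = syn.footprint_field_map(comp, grid, step=10.0)
        loc = topo.locate_peak(tmap)
        region = topo.half_width_region(tmap, loc)
        expected = 2 * math.pi * math.log(2) * sigma**2 / 1e6
        assert region.area == pytest.approx(expected, rel=0.02)
        assert not region.truncated

    def test_disk_area_is_pi_r_squared(self, grid):
        comp = syn.ComponentSpec("P", +1, 42.0, 4.0, 40.0, (1000.0, 1800.0),
                                 footprint_radius=450.0)
        tmap = syn.footprint_field_map(comp, grid, step=10.0)
        region = topo.half_width_region(tmap, topo.locate_peak(tmap))
        assert region.area == pytest.approx(math.pi * 0.45**2, rel=0.02)

    def test_disjoint_satellite_lobe_excluded(self):
        field = np.zeros((40, 40))
        field[5:10, 5:10] = 1.0  # satellite
        field[25:32, 25:32] = 2.0  # main lobe containing the peak
        tmap = topo.TopoMap(field=field, step=10.0, origin=(0.0, 0.0),
                            component="P")
        loc = topo.locate_peak(tmap)
        region = topo.half_width_region(tmap, loc)
        assert region.mask[27, 27]
        assert not region.mask[7, 7]

    def test_border_touching_region_flagged_truncated(self, grid):
        comp = syn.ComponentSpec("P", +1, 42.0, 4.0, 40.0, (0.0, 0.0),
                                 footprint_sigma=600.0)
        tmap = syn.footprint_field_map(comp, grid, step=20.0)
        region = topo.half_width_region(tmap, topo.locate_peak(tmap))
        assert region.truncated

    def test_area_grows_with_footprint_sigma(self, grid):
        areas = []
        for sigma in (300.0, 400.0, 500.0):
            comp = syn.ComponentSpec("P", +1, 42.0, 4.0, 1.0,
                                     (1000.0, 1800.0),
                                     footprint_sigma=sigma)
            tmap = syn.footprint_field_map(comp, grid, step=10.0)
            areas.append(
                topo.half_width_region(tmap, topo.locate_peak(tmap)).area
            )
        assert areas[0] < areas[1] < areas[2]


class TestOverlap:
    @staticmethod
    def disk_region(grid, center, radius, step=20.0, label="P"):
        polarity = +1 if label == "P" else -1
        comp = syn.ComponentSpec(label, polarity, 42.0, 4.0, 40.0, center,
                                 footprint_radius=radius)
        tmap = syn.footprint_field_map(comp, grid, step=step)
        return topo.half_width_region(tmap, topo.locate_peak(tmap))

    def test_identical_regions_fully_overlap(self, grid):
        a = self.disk_region(grid, (1000.0, 1800.0), 400.0)
        res = topo.overlap(a, a)
        assert res.frac_of_a == pytest.approx(1.0)
        assert res.frac_of_b == pytest.approx(1.0)

    def test_disjoint_regions_do_not_overlap(self, grid):
        a = self.disk_region(grid, (600.0, 1000.0), 300.0)
        b = self.disk_region(grid, (1400.0, 2600.0), 300.0)
        res = topo.overlap(a, b)
        assert res.intersection_area == 0.0
        assert res.frac_of_a == 0.0

    @pytest.mark.parametrize("r1,r2,d", [
        (400.0, 500.0, 300.0),
        (350.0, 600.0, 450.0),
        (500.0, 500.0, 200.0),
    ])
    def test_lens_closed_form_within_one_percent(self, grid, r1, r2, d):
        a = self.disk_region(grid, (900.0, 1600.0), r1)
        b = self.disk_region(grid, (900.0 + d, 1600.0), r2)
        res = topo.overlap(a, b)
        expected = topo.circle_lens_area(r1, r2, d) / 1e6
        assert res.intersection_area == pytest.approx(expected, rel=0.01)

    def test_intersection_is_symmetric(self, grid):
        a = self.disk_region(grid, (900.0, 1600.0), 400.0)
        b = self.disk_region(grid, (1200.0, 1900.0), 500.0)
        assert (topo.overlap(a, b).intersection_area
                == topo.overlap(b, a).intersection_area)

    def test_mismatched_grids_rejected(self, grid):
        a = self.disk_region(grid, (900.0, 1600.0), 400.0, step=20.0)
        b = self.disk_region(grid, (900.0, 1600.0), 400.0, step=10.0)
        with pytest.raises(ValueError, match="different pixel grids"):
            topo.overlap(a, b)


class TestDisplacement:
    def test_pure_caudal_is_zero_degrees(self):
        a = topo.PeakLocation(0.0, 0.0, 1.0)
        b = topo.PeakLocation(300.0, 0.0, 1.0)
        d = topo.displacement(a, b)
        assert d.theta == pytest.approx(0.0)

    def test_pure_lateral_is_minus_ninety(self):
        a = topo.PeakLocation(0.0, 0.0, 1.0)
        b = topo.PeakLocation(0.0, -250.0, 1.0)
        assert topo.displacement(a, b).theta == pytest.approx(-90.0)

    def test_three_four_five_triangle(self):
        a = topo.PeakLocation(0.0, 0.0, 1.0)
        b = topo.PeakLocation(300.0, -400.0, 1.0)
        assert topo.displacement(a, b).r == pytest.approx(500.0)

    def test_coincident_points_have_undefined_angle(self):
        a = topo.PeakLocation(100.0, 100.0, 1.0)
        d = topo.displacement(a, a)
        assert d.r == 0.0
        assert d.theta is None


class TestMapInvariance:
    def test_constant_offset_before_referencing_moves_no_peaks(self, grid):
        """Adding a constant to all channels is removed by the common
        average reference and cannot move peak locations."""
        import sepmap.preprocessing as pp

        comp = syn.ComponentSpec("P", +1, 42.0, 4.0, 40.0, (900.0, 1700.0),
                                 footprint_sigma=450.0)
        cfg = syn.ScenarioConfig(components=(comp,), n_trials=2,
                                 noise_sd=0.0, latency_jitter_sd=0.0,
                                 rng_seed=0)
        rec = syn.simulate_grid_session(cfg, grid, 4000.0)
        shifted = rec.with_data(rec.data + 17.0)
        locs = []
        for r in (rec, shifted):
            avg = pp.preprocess(r)
            pk = topo.find_component_peaks(avg)["P"]
            _, loc, _ = topo.analyze_component(avg, pk, step=20.0)
            locs.append(loc)
        assert locs[0].x == pytest.approx(locs[1].x, abs=1e-3)
        assert locs[0].y == pytest.approx(locs[1].y, abs=1e-3)
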