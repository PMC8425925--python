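"""Fluence reconstruction: segment extraction, rasterization, conservation."""

import numpy as np
import pytest

from logqa import (
    ErrorSpec,
    FluenceError,
    FluenceGrid,
    FluenceMap,
    SimConfig,
    auto_grid,
    delivered_fluence,
    extract_segments,
    make_fixture_plan,
    plan_fluence,
    rasterize_aperture,
    read_fluence,
    simulate_delivery,
    write_fluence,
)
from logqa.fluence import extract_segments_detailed, segment_open_area_mm2


class TestSegmentExtraction:
    def test_zero_noise_recovers_plan_segments_exactly(self, prostate_plan, prostate_log):
        segs = extract_segments(prostate_log)
        assert len(segs) == len(prostate_plan.segments)
        for d, p in zip(segs, prostate_plan.segments):
            assert d.mu == pytest.approx(p.mu, abs=1e-9)
            np.testing.assert_array_equal(d.leaf_a_mm, p.leaf_a_mm)
            np.testing.assert_array_equal(d.leaf_b_mm, p.leaf_b_mm)
            assert d.gantry_deg == pytest.approx(p.gantry_deg, abs=1e-9)

    def test_noisy_log_keeps_segment_count_and_total_mu(self, prostate_plan):
        log = simulate_delivery(
            prostate_plan, SimConfig(leaf_noise_sd_mm=0.1, seed=11))
        segs = extract_segments(log)
        assert len(segs) == len(prostate_plan.segments)
        assert sum(s.mu for s in segs) == pytest.approx(prostate_plan.total_mu)
        for d, p in zip(segs, prostate_plan.segments):
            assert np.abs(d.leaf_a_mm - p.leaf_a_mm).max() < 0.3

    def test_discarded_subthreshold_intervals_are_counted(self, rect_plan, zero_noise):
        log = simulate_delivery(rect_plan, zero_noise)
        # forge a one-sample beam-on blip carrying ~0 MU after the tail
        log.beam_on[-1] = True
        segs, n_discarded = extract_segments_detailed(log)
        assert len(segs) == 1
        assert n_discarded == 1

    def test_empty_delivery_rejected(self, rect_plan, zero_noise):
        log = simulate_delivery(rect_plan, zero_noise)
        log.beam_on[:] = False
        with pytest.raises(FluenceError, match="no beam-on"):
            extract_segments(log)


class TestRasterization:
    def test_auto_grid_snaps_to_lattice(self, rect_plan):
        grid = auto_grid(rect_plan, spacing_mm=1.0, margin_mm=10.0)
        # 100 x 100 mm aperture + 10 mm margin on a 1 mm lattice
        assert (grid.nx, grid.ny) == (120, 120)
        assert grid.origin_x_mm == -59.5  # pixel centers on the half-integer lattice
        assert grid.origin_y_mm == -59.5

    def test_rect_field_pixel_count(self, rect_plan):
        grid = auto_grid(rect_plan)
        fm = plan_fluence(rect_plan, grid)
        # pixel centers at x in [-49.5, 49.5]: 100 columns x 100 rows open
        assert int((fm.values > 0).sum()) == 100 * 100
        assert np.all(fm.values[fm.values > 0] == 100.0)
        assert fm.integral_mu_mm2 == pytest.approx(100.0 * 100 * 100)

    def test_half_open_leaf_rows(self, geometry40):
        """A pixel center on a leaf-pair boundary belongs to the upper pair."""
        grid = FluenceGrid(origin_x_mm=-7.0, origin_y_mm=-7.0, spacing_mm=7.0, nx=3, ny=3)
        a = np.full(40, 110.0)
        b = np.full(40, 110.0)
        pair = geometry40.pair_index_at(0.0)
        a[pair], b[pair] = -10.0, 10.0  # only the pair owning y=0 is open
        fm = rasterize_aperture(a, b, (-20, 20, -20, 20), 5.0, geometry40, grid)
        assert np.all(fm.values[1] == 5.0)  # y = 0 row belongs to the open pair
        assert np.all(fm.values[0] == 0.0)  # y = -7 row: pair below, closed
        assert np.all(fm.values[2] == 0.0)  # y = +7 row: pair above, closed

    def test_jaw_clipping(self, geometry40, rect_plan):
        seg = rect_plan.segments[0]
        grid = auto_grid(rect_plan)
        narrow = rasterize_aperture(
            seg.leaf_a_mm, seg.leaf_b_mm, (-20.0, 20.0, -50.0, 50.0),
            seg.mu, geometry40, grid)
        # leaves open [-50, 50] but jaws clip x to [-20, 20]: 40 columns remain
        assert int((narrow.values[50] > 0).sum()) == 40

    def test_aperture_outside_grid_raises(self, geometry40, rect_plan):
        seg = rect_plan.segments[0]
        small = FluenceGrid(-9.5, -9.5, 1.0, 20, 20)
        with pytest.raises(FluenceError, match="does not cover"):
            rasterize_aperture(
                seg.leaf_a_mm, seg.leaf_b_mm, (-50, 50, -50, 50),
                seg.mu, geometry40, small)

    def test_parked_pairs_need_no_grid_coverage(self, geometry40):
        """Closed pairs parked far outside the jaws contribute nothing and
        must not trigger the coverage check."""
        a = np.full(40, 130.0)
        b = np.full(40, 134.0)
        pair = geometry40.pair_index_at(0.0)
        a[pair], b[pair] = -10.0, 10.0
        grid = FluenceGrid(-14.5, -14.5, 1.0, 30, 30)
        fm = rasterize_aperture(a, b, (-20, 20, -20, 20), 2.0, geometry40, grid)
        assert fm.integral_mu_mm2 > 0


class TestConservation:
    def test_integral_equals_mu_weighted_area(self, prostate_plan):
        """Sum over segments of MU x pixel-counted open area equals the
        fluence integral -- brute-force pixel count as the oracle."""
        grid = auto_grid(prostate_plan)
        fm = plan_fluence(prostate_plan, grid)
        expected = 0.0
        for seg in prostate_plan.segments:
            dia = (seg.diaphragm_x1_mm, seg.diaphragm_x2_mm,
                   seg.diaphragm_y1_mm, seg.diaphragm_y2_mm)
            expected += seg.mu * segment_open_area_mm2(
                seg.leaf_a_mm, seg.leaf_b_mm, dia, prostate_plan.geometry, grid)
        assert fm.integral_mu_mm2 == pytest.approx(expected, rel=1e-12)

    def test_zero_noise_delivery_reproduces_plan_fluence(self, prostate_plan, prostate_log):
        grid = auto_grid(prostate_plan)
        planned = plan_fluence(prostate_plan, grid)
        delivered = delivered_fluence(prostate_log, grid)
        np.testing.assert_array_equal(planned.values, delivered.values)

    def test_park_override_leaves_fluence_bit_identical(self, prostate_plan, zero_noise):
        grid = auto_grid(prostate_plan)
        clean = simulate_delivery(prostate_plan, zero_noise)
        parked = simulate_delivery(prostate_plan, zero_noise, [ErrorSpec("park_override")])
        np.testing.assert_array_equal(
            delivered_fluence(clean, grid).values,
            delivered_fluence(parked, grid).values)


class TestFluenceIO:
    def test_text_roundtrip_is_exact(self, tmp_path, prostate_plan):
        fm = plan_fluence(prostate_plan)
        path = tmp_path / "f.txt"
        write_fluence(fm, path)
        back = read_fluence(path)
        assert back.grid == fm.grid
        np.testing.assert_array_equal(back.values, fm.values)

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "f.txt"
        path.write_text("not a fluence file\n")
        with pytest.raises(FluenceError, match="header"):
            read_fluence(path)

    def test_adding_maps_on_different_grids_rejected(self):
        a = FluenceMap(FluenceGrid(0, 0, 1.0, 4, 4), np.zeros((4, 4)))
        b = FluenceMap(FluenceGrid(0, 0, 2.0, 4, 4), np.zeros((4, 4)))
        with pytest.raises(FluenceError, match="different grids"):
            a + b
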