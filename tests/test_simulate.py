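"""Delivery simulator: timing, seeding contract, error injection, fixtures."""

import numpy as np
import pytest

from logqa import (
    DEFAULT_CLOSED_GAP_MM,
    ErrorSpec,
    SimConfig,
    SimulationError,
    default_geometry,
    make_fixture_plan,
    simulate_delivery,
)
from logqa.logfile import log_to_string
from logqa.simulate import PLAN_CLOSED_POSITION_MM


class TestTiming:
    def test_100mu_at_400mu_per_min_gives_60_beam_on_samples(self, rect_plan, zero_noise):
        """100 MU at 400 MU/min is 15 s of beam-on: 60 samples at 4 Hz."""
        log = simulate_delivery(rect_plan, zero_noise)
        assert int(log.beam_on.sum()) == 60
        on = log.beam_on
        assert log.t_s[on][-1] - log.t_s[on][0] == pytest.approx(14.75)  # 60 samples span
        assert log.mu_cum[-1] == 100.0  # exact clamp

    def test_zero_noise_positions_equal_plan(self, rect_plan, zero_noise):
        log = simulate_delivery(rect_plan, zero_noise)
        on = log.beam_on
        seg = rect_plan.segments[0]
        assert np.array_equal(log.leaf_a_mm[on], np.tile(seg.leaf_a_mm, (on.sum(), 1)))
        assert np.array_equal(log.leaf_b_mm[on], np.tile(seg.leaf_b_mm, (on.sum(), 1)))
        assert np.all(log.gantry_deg == seg.gantry_deg)

    def test_slow_leaves_extend_beam_off(self, geometry40):
        plan = make_fixture_plan("sliding_window_steps", geometry40)
        fast = simulate_delivery(plan, SimConfig(leaf_noise_sd_mm=0, gantry_noise_sd_deg=0,
                                                 leaf_move_speed_mm_per_s=50.0))
        slow = simulate_delivery(plan, SimConfig(leaf_noise_sd_mm=0, gantry_noise_sd_deg=0,
                                                 leaf_move_speed_mm_per_s=5.0))
        assert slow.t_s[-1] > fast.t_s[-1]
        assert slow.mu_cum[-1] == fast.mu_cum[-1] == plan.total_mu


class TestSeeding:
    def test_same_seed_byte_identical(self, prostate_plan):
        cfg = SimConfig(seed=1)
        a = log_to_string(simulate_delivery(prostate_plan, cfg))
        b = log_to_string(simulate_delivery(prostate_plan, cfg))
        assert a == b

    def test_different_seeds_differ_with_noise(self, prostate_plan):
        a = simulate_delivery(prostate_plan, SimConfig(seed=1, leaf_noise_sd_mm=0.1))
        b = simulate_delivery(prostate_plan, SimConfig(seed=2, leaf_noise_sd_mm=0.1))
        assert not np.array_equal(a.leaf_a_mm, b.leaf_a_mm)

    def test_noise_truncated_at_three_sd(self, rect_plan):
        log = simulate_delivery(
            rect_plan, SimConfig(seed=5, leaf_noise_sd_mm=0.2, gantry_noise_sd_deg=0.0))
        dev = np.abs(log.leaf_a_mm - rect_plan.segments[0].leaf_a_mm)
        assert dev.max() <= 0.6 + 1e-12


class TestErrors:
    def test_park_override_moves_only_shielded_closed_pairs(self, prostate_plan, zero_noise):
        log = simulate_delivery(prostate_plan, zero_noise, [ErrorSpec("park_override")])
        g = prostate_plan.geometry
        seg = prostate_plan.segments[0]
        on = np.nonzero(log.beam_on)[0]
        first_on = on[0]
        for i in range(g.n_leaf_pairs):
            low, high = g.pair_y_interval(i)
            shielded = high <= seg.diaphragm_y1_mm or low >= seg.diaphragm_y2_mm
            closed = seg.leaf_b_mm[i] - seg.leaf_a_mm[i] <= DEFAULT_CLOSED_GAP_MM
            if shielded and closed:
                assert log.leaf_a_mm[first_on, i] == g.park_positions_mm[0]
                assert log.leaf_b_mm[first_on, i] == g.park_positions_mm[1]
            else:
                assert log.leaf_a_mm[first_on, i] == seg.leaf_a_mm[i]

    def test_systematic_offset_shifts_in_field_pairs_only(self, prostate_plan, zero_noise):
        err = ErrorSpec("systematic_leaf_offset", magnitude_mm=2.0)
        log = simulate_delivery(prostate_plan, zero_noise, [err])
        seg = prostate_plan.segments[0]
        first_on = np.nonzero(log.beam_on)[0][0]
        pairs = err.resolve_pairs(seg, prostate_plan.geometry)
        assert pairs.size >= 5
        np.testing.assert_array_equal(
            log.leaf_a_mm[first_on, pairs], seg.leaf_a_mm[pairs] + 2.0)
        others = np.setdiff1d(np.arange(prostate_plan.geometry.n_leaf_pairs), pairs)
        np.testing.assert_array_equal(
            log.leaf_a_mm[first_on, others], seg.leaf_a_mm[others])

    def test_gantry_offset(self, rect_plan, zero_noise):
        log = simulate_delivery(rect_plan, zero_noise,
                                [ErrorSpec("gantry_offset", magnitude_deg=1.5)])
        assert np.all(log.gantry_deg == 1.5)

    def test_unknown_kind_rejected(self):
        with pytest.raises(SimulationError, match="unknown error kind"):
            ErrorSpec("leaf_teleport")

    def test_zero_mu_plan_rejected(self, rect_plan, zero_noise):
        plan = rect_plan.copy()
        for s in plan.segments:
            s.mu = 0.0
        plan.total_mu = 0.0
        with pytest.raises(SimulationError, match="zero-MU"):
            simulate_delivery(plan, zero_noise)


class TestFixtures:
    def test_rect_field_40_pairs(self, geometry40):
        plan = make_fixture_plan("rect_field", geometry40)
        assert len(plan.segments) == 1
        assert plan.total_mu == 100.0
        seg = plan.segments[0]
        open_pairs = seg.leaf_b_mm - seg.leaf_a_mm > 0
        assert np.all(seg.leaf_a_mm[open_pairs] == -50.0)
        assert np.all(seg.leaf_b_mm[open_pairs] == 50.0)
        assert (seg.diaphragm_y1_mm, seg.diaphragm_y2_mm) == (-50.0, 50.0)

    def test_random_segments_deterministic(self):
        a = make_fixture_plan("random_segments", seed=3)
        b = make_fixture_plan("random_segments", seed=3)
        for s1, s2 in zip(a.segments, b.segments):
            np.testing.assert_array_equal(s1.leaf_a_mm, s2.leaf_a_mm)
            assert s1.mu == s2.mu
        c = make_fixture_plan("random_segments", seed=4)
        assert not np.array_equal(a.segments[0].leaf_a_mm, c.segments[0].leaf_a_mm)

    def test_prostate_like_structure(self, prostate_plan):
        assert len(prostate_plan.segments) >= 5
        seg = prostate_plan.segments[0]
        g = prostate_plan.geometry
        n_closed_shielded = 0
        for i in range(g.n_leaf_pairs):
            low, high = g.pair_y_interval(i)
            shielded = high <= seg.diaphragm_y1_mm or low >= seg.diaphragm_y2_mm
            if shielded and seg.leaf_b_mm[i] - seg.leaf_a_mm[i] <= DEFAULT_CLOSED_GAP_MM:
                n_closed_shielded += 1
                assert seg.leaf_a_mm[i] == PLAN_CLOSED_POSITION_MM
        assert n_closed_shielded >= 2

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown fixture kind"):
            make_fixture_plan("vmat_arc")
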