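"""Stimulus generator tests: geometry, schedules, transients, rasterization."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stprf.stimulus import (
    ALL_CONDITIONS,
    GridSpec,
    Rect,
    RetinotopyDesign,
    RunDesign,
    StimulusSequence,
    build_square_layout,
    count_transients,
    generate_retinotopy_run,
    generate_seqsim_pair,
    generate_seqsim_run,
    on_time_per_square,
    rasterize,
)


# ---------------------------------------------------------------------------
# layout geometry
# ---------------------------------------------------------------------------

class TestSquareLayout:
    def test_small_extent(self):
        lay = build_square_layout(2, 0.82, (5, 5))
        bb = lay.bounding_box
        assert bb.x_min == pytest.approx(2.59)
        assert bb.x_max == pytest.approx(7.41)
        assert bb.y_min == pytest.approx(2.59)
        assert bb.y_max == pytest.approx(7.41)

    def test_big_extent(self):
        bb = build_square_layout(4, 0.82, (5, 5)).bounding_box
        assert bb.x_min == pytest.approx(0.59)
        assert bb.x_max == pytest.approx(9.41)

    def test_zero_gap_tiles_single_square(self):
        lay = build_square_layout(2, 0, (5, 5))
        bb = lay.bounding_box
        assert bb.width == pytest.approx(4.0)
        assert bb.height == pytest.approx(4.0)
        total_area = sum(s.area for s in lay.squares)
        assert total_area == pytest.approx(bb.area)

    def test_eccentricity(self):
        lay = build_square_layout(2, 0.82, (5, 5))
        assert lay.eccentricity_deg == pytest.approx(math.sqrt(50))
        assert round(lay.eccentricity_deg, 1) == 7.1

    def test_lower_left_is_point_reflection(self):
        ur = build_square_layout(2, 0.82, (5, 5))
        ll = build_square_layout(2, 0.82, (-5, -5))
        reflected = sorted(
            (-s.x_max, -s.x_min, -s.y_max, -s.y_min) for s in ur.squares
        )
        actual = sorted((s.x_min, s.x_max, s.y_min, s.y_max) for s in ll.squares)
        assert np.allclose(reflected, actual)

    def test_squares_congruent_and_separated(self):
        lay = build_square_layout(4, 0.82, (5, 5))
        widths = {round(s.width, 9) for s in lay.squares}
        heights = {round(s.height, 9) for s in lay.squares}
        assert widths == {4.0} and heights == {4.0}
        s0, s1 = lay.squares[0], lay.squares[1]
        assert s1.x_min - s0.x_max == pytest.approx(0.82)

    @pytest.mark.parametrize("bad_center", [(0, 5), (5, 0), (0, 0)])
    def test_center_on_axis_rejected(self, bad_center):
        with pytest.raises(ValueError):
            build_square_layout(2, 0.82, bad_center)

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            build_square_layout(0, 0.82, (5, 5))
        with pytest.raises(ValueError):
            build_square_layout(-1, 0.82, (5, 5))

    @settings(max_examples=50, deadline=None)
    @given(
        size=st.floats(0.5, 6),
        gap=st.floats(0, 2),
        cx=st.floats(4, 9),
        cy=st.floats(4, 9),
    )
    def test_geometry_invariants(self, size, gap, cx, cy):
        lay = build_square_layout(size, gap, (cx, cy))
        bb = lay.bounding_box
        assert bb.width == pytest.approx(2 * size + gap)
        assert bb.height == pytest.approx(2 * size + gap)
        # non-overlap: pairwise disjoint interiors
        for i in range(4):
            for j in range(i + 1, 4):
                a, b = lay.squares[i], lay.squares[j]
                sep_x = a.x_max <= b.x_min + 1e-12 or b.x_max <= a.x_min + 1e-12
                sep_y = a.y_max <= b.y_min + 1e-12 or b.y_max <= a.y_min + 1e-12
                assert sep_x or sep_y or gap == 0


# ---------------------------------------------------------------------------
# run schedules
# ---------------------------------------------------------------------------

class TestSeqSimRun:
    def test_block_count_and_condition_balance(self, run0):
        _, schedule = run0
        assert len(schedule) == 16
        labels = [b.condition.label for b in schedule.blocks]
        for c in ALL_CONDITIONS:
            assert labels.count(c.label) == 2

    def test_determinism(self, design):
        a = generate_seqsim_run(design, 0)
        b = generate_seqsim_run(design, 0)
        assert a[1] == b[1]
        assert a[0] == b[0]

    def test_unique_runs_differ(self, design):
        (_, s0), (_, s1) = generate_seqsim_pair(design)
        assert [b.condition.label for b in s0.blocks] != [
            b.condition.label for b in s1.blocks
        ]

    def test_distinct_seeds_change_order_not_counts(self, design):
        other = dataclasses.replace(design, seed=design.seed + 1)
        _, s0 = generate_seqsim_run(design, 0)
        _, s1 = generate_seqsim_run(other, 0)
        assert [b.condition.label for b in s0.blocks] != [
            b.condition.label for b in s1.blocks
        ]
        for a, b in zip(s0.blocks, s1.blocks):
            assert len(a.events) == sum(
                1 for _ in b.events
            ) or a.condition.label != b.condition.label

    def test_seq_long_block_structure(self, run0, design):
        _, schedule = run0
        block = next(b for b in schedule.blocks if b.condition.label == "SEQ-long-small")
        ur = [e for e in block.events if e.quadrant == "upper_right"]
        assert len(ur) == 8  # 2 trials x 4 squares
        ur.sort(key=lambda e: e.on_ms)
        for e in ur:
            assert e.duration_ms == 1000
        gaps = [b.on_ms - a.off_ms for a, b in zip(ur, ur[1:])]
        assert all(g == design.isi_ms for g in gaps)

    def test_short_block_has_eight_trials(self, run0):
        _, schedule = run0
        block = next(b for b in schedule.blocks if b.condition.label == "SIM-short-big")
        ur_onsets = sorted({e.on_ms for e in block.events if e.quadrant == "upper_right"})
        assert len(ur_onsets) == 8

    def test_sim_long_second_trial_at_4s(self, run0):
        _, schedule = run0
        for block in schedule.blocks:
            if block.condition.label.startswith("SIM-long"):
                onsets = sorted(
                    {e.on_ms for e in block.events if e.quadrant == "upper_right"}
                )
                assert onsets == [block.onset_ms, block.onset_ms + 4000]

    def test_sim_short_first_trial_locked_rest_in_slots(self, run0):
        _, schedule = run0
        for block in schedule.blocks:
            if not block.condition.label.startswith("SIM-short"):
                continue
            onsets = sorted({e.on_ms for e in block.events if e.quadrant == "upper_right"})
            assert onsets[0] == block.onset_ms
            for j, on in enumerate(onsets):
                slot = block.onset_ms + j * 1000
                assert slot <= on and on + 200 <= slot + 1000

    def test_on_time_matched_between_seq_and_sim(self, run0):
        _, schedule = run0
        totals: dict[str, dict] = {}
        for b in schedule.blocks:
            acc = totals.setdefault(b.condition.label, {})
            for k, v in on_time_per_square(b).items():
                acc[k] = acc.get(k, 0) + v
        for c in ALL_CONDITIONS:
            if c.seq_type == "SEQ":
                sim = c.label.replace("SEQ", "SIM")
                assert totals[c.label] == totals[sim]

    def test_events_stay_within_block_window(self, run0, design):
        _, schedule = run0
        period = design.block_period_s * 1000
        for b in schedule.blocks:
            for e in b.events:
                assert b.onset_ms <= e.on_ms < e.off_ms <= b.onset_ms + period

    def test_onset_matched_mode_first_square_identical(self):
        design = RunDesign(seed=3, onset_matched=True)
        _, schedule = generate_seqsim_run(design, 0)
        by_label: dict[str, list] = {}
        for b in schedule.blocks:
            intervals = sorted(
                (e.on_ms - b.onset_ms, e.off_ms - b.onset_ms)
                for e in b.events
                if e.quadrant == "upper_right" and e.square_index == 0
            )
            by_label.setdefault(b.condition.label, []).append(intervals)
        for c in ALL_CONDITIONS:
            if c.seq_type == "SEQ":
                sim = c.label.replace("SEQ", "SIM")
                assert sorted(by_label[c.label]) == sorted(by_label[sim])


@pytest.fixture(scope="module")
def small_ur_squares(design):
    return design.layouts()[("small", "upper_right")].squares


class TestTransients:
    def _block(self, schedule, label):
        return next(b for b in schedule.blocks if b.condition.label == label)

    def test_seq_long_16(self, run0, small_ur_squares):
        _, schedule = run0
        assert count_transients(self._block(schedule, "SEQ-long-small"), small_ur_squares) == 16

    def test_seq_short_64(self, run0, small_ur_squares):
        _, schedule = run0
        assert count_transients(self._block(schedule, "SEQ-short-small"), small_ur_squares) == 64

    def test_quadrupling_holds_for_sim_too(self, run0, small_ur_squares):
        _, schedule = run0
        sim_long = count_transients(self._block(schedule, "SIM-long-small"), small_ur_squares)
        sim_short = count_transients(self._block(schedule, "SIM-short-small"), small_ur_squares)
        assert sim_short == 4 * sim_long

    def test_single_square_equal_for_pairs(self, run0, small_ur_squares):
        _, schedule = run0
        fp = small_ur_squares[:1]
        for timing in ("short", "long"):
            seq = count_transients(self._block(schedule, f"SEQ-{timing}-small"), fp)
            sim = count_transients(self._block(schedule, f"SIM-{timing}-small"), fp)
            assert seq == sim

    def test_empty_footprint_rejected(self, run0):
        _, schedule = run0
        with pytest.raises(ValueError):
            count_transients(schedule.blocks[0], [])


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

class TestRasterize:
    def test_blank_period_all_zero(self, run0):
        seq, schedule = run0
        grid = GridSpec(0, 10, 0, 10, 0.5)
        frames = rasterize(seq, grid, [0, 5000, 11000])
        assert frames.sum() == 0

    def test_sim_big_active_area(self, run0):
        seq, schedule = run0
        block = next(b for b in schedule.blocks if b.condition.label == "SIM-long-big")
        t = block.onset_ms + 100
        grid = GridSpec(0, 12, 0, 12, 0.05)
        frame = rasterize(seq, grid, [t])[:, :, 0]
        area = frame.sum() * 0.05**2
        assert area == pytest.approx(4 * 16, rel=0.02)

    def test_out_of_range_slice_rejected(self, run0):
        seq, _ = run0
        with pytest.raises(ValueError):
            rasterize(seq, GridSpec(0, 10, 0, 10, 1.0), [seq.duration_ms + 1])

    def test_rasterization_matches_event_list(self):
        rect = Rect(1, 2, 1, 2)
        seq = StimulusSequence(((rect, 100, 200),), 300)
        grid = GridSpec(0, 3, 0, 3, 0.1)
        frames = rasterize(seq, grid, list(range(0, 300, 50)))
        active = frames.sum(axis=(0, 1)) > 0
        assert list(active) == [t in (100, 150) for t in range(0, 300, 50)]

    def test_event_clipping(self):
        rect = Rect(0, 1, 0, 1)
        seq = StimulusSequence(((rect, 100, 200),), 300)
        clip = seq.clipped(150, 300)
        assert clip.events == ((rect, 0, 50),)
        with pytest.raises(ValueError):
            StimulusSequence(((rect, -5, 10),), 300)


# ---------------------------------------------------------------------------
# retinotopy bars
# ---------------------------------------------------------------------------

class TestRetinotopy:
    def test_sweep_structure(self):
        stim = generate_retinotopy_run()
        assert stim.n_frames == 8 * 12
        assert stim.duration_s == pytest.approx(192)

    def test_horizontal_sweep_partitions_aperture(self):
        stim = generate_retinotopy_run()
        # first 12 frames: orientation 0, forward; offsets are step centers
        thetas = {th for th, _ in stim.frames[:12]}
        assert thetas == {0.0}
        offsets = [off for _, off in stim.frames[:12]]
        assert np.allclose(offsets, np.arange(-11, 12, 2))
        # masks move rightward accordingly
        grid = GridSpec(-12, 12, -12, 12, 0.25)
        X, _ = np.meshgrid(grid.xs, grid.ys)
        centers = [
            X[stim.frame_mask(i, grid).astype(bool)].mean() for i in (3, 4, 5, 6, 7, 8)
        ]
        assert np.allclose(np.diff(centers), 2.0, atol=0.05)

    def test_outside_aperture_zero(self):
        stim = generate_retinotopy_run()
        grid = GridSpec(-12, 12, -12, 12, 0.25)
        X, Y = np.meshgrid(grid.xs, grid.ys)
        outside = X**2 + Y**2 > stim.design.radius_deg**2
        movie = stim.rasterize(grid)
        assert movie[outside].sum() == 0

    def test_reverse_sweep_time_reversed(self):
        stim = generate_retinotopy_run()
        fwd = stim.frames[:12]
        rev = stim.frames[12:24]
        assert list(rev) == list(reversed(fwd))

    def test_bar_wider_than_aperture_rejected(self):
        with pytest.raises(ValueError):
            RetinotopyDesign(bar_width_deg=30)
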