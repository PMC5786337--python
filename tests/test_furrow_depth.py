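import numpy as np
import pytest

from furrowdyn.furrow_depth import (
    build_ringmap,
    deepest_extent,
    detect_rings,
    extract_trace,
    find_apical_reference,
    intact_depth,
)
from furrowdyn.simulate import simulate_depth_trace


class TestRingDetection:
    def test_complete_rings_detected_with_full_completeness(self, wt13_movie_clean, wt13_small_clean):
        stack, gt = wt13_movie_clean
        plane = stack.membrane()[0, gt.apical_z_index]
        rings = detect_rings(plane, wt13_small_clean.pixel_size)
        assert len(rings) == len(gt.nuclear_positions)
        assert all(r.completeness >= 0.98 for r in rings)

    def test_partial_rings_score_rendered_completeness(self, fragmented_movie_clean):
        cfg, (stack, gt) = fragmented_movie_clean
        # frame in the fragmented zone: complete to 4 um, partial below
        trace, _ = simulate_depth_trace(cfg, seed=gt.rng_seed)
        fr = int(np.argmax(trace.deepest_extent))
        z_broken = gt.apical_z_index + int(cfg.fragmentation_depth / cfg.z_step) + 2
        rings = detect_rings(stack.membrane()[fr, z_broken], cfg.pixel_size)
        assert len(rings) > 0
        mean_c = np.mean([r.completeness for r in rings])
        assert mean_c == pytest.approx(cfg.ring_completeness_broken, abs=0.05)

    def test_blank_plane_gives_empty_list(self):
        assert detect_rings(np.zeros((64, 64)), 0.25) == []

    def test_intensity_rescaling_invariance(self, wt13_movie_clean, wt13_small_clean):
        stack, gt = wt13_movie_clean
        plane = stack.membrane()[10, gt.apical_z_index + 2].astype(float)
        a = detect_rings(plane, wt13_small_clean.pixel_size)
        b = detect_rings(plane * 2.7, wt13_small_clean.pixel_size)
        assert len(a) == len(b)
        assert [r.completeness for r in a] == pytest.approx(
            [r.completeness for r in b], abs=1e-9
        )


class TestApicalReference:
    def test_recovers_rendered_apical_slice(self, wt13_movie_clean, wt13_small_clean):
        stack, gt = wt13_movie_clean
        za = find_apical_reference(stack.membrane()[0], wt13_small_clean.pixel_size)
        assert za == gt.apical_z_index

    def test_all_zero_frame_errors(self):
        with pytest.raises(ValueError, match="no apical surface"):
            find_apical_reference(np.zeros((10, 64, 64)), 0.25)

    def test_scale_invariance(self, wt13_movie_clean, wt13_small_clean):
        stack, gt = wt13_movie_clean
        frame = stack.membrane()[0].astype(float)
        za0 = find_apical_reference(frame, wt13_small_clean.pixel_size)
        za1 = find_apical_reference(frame * 3.0, wt13_small_clean.pixel_size)
        assert za0 == za1

    def test_too_few_slices_rejected(self):
        with pytest.raises(ValueError, match="5 slices"):
            find_apical_reference(np.zeros((3, 64, 64)), 0.25)


class TestDepthRules:
    def test_intact_depth_matches_ground_truth(self, wt13_movie_clean, wt13_small_clean):
        stack, gt = wt13_movie_clean
        cfg = wt13_small_clean
        trace, _ = simulate_depth_trace(cfg, seed=gt.rng_seed)
        fr = int(np.argmax(trace.intact_depth))
        rm = build_ringmap(stack.membrane()[fr], cfg.pixel_size)
        za = find_apical_reference(stack.membrane()[fr], cfg.pixel_size, ringmap=rm)
        measured = intact_depth(rm, za, cfg.z_step)
        true = trace.intact_depth[fr]
        assert abs(measured - true) <= cfg.z_step

    def test_fragmentation_caps_intact_but_not_deepest(self, fragmented_movie_clean):
        cfg, (stack, gt) = fragmented_movie_clean
        trace, _ = simulate_depth_trace(cfg, seed=gt.rng_seed)
        fr = int(np.argmax(trace.deepest_extent))
        rm = build_ringmap(stack.membrane()[fr], cfg.pixel_size)
        za = find_apical_reference(stack.membrane()[fr], cfg.pixel_size, ringmap=rm)
        d_in = intact_depth(rm, za, cfg.z_step)
        d_ex = deepest_extent(rm, za, cfg.z_step)
        assert d_in == pytest.approx(cfg.fragmentation_depth, abs=cfg.z_step)
        assert d_ex == pytest.approx(trace.deepest_extent[fr], abs=cfg.z_step)
        assert d_ex >= d_in

    def test_apical_only_frame_is_zero_depth(self, wt13_movie_clean, wt13_small_clean):
        stack, gt = wt13_movie_clean
        # last extra frame: cycle complete, furrows fully retracted
        rm = build_ringmap(stack.membrane()[-1], wt13_small_clean.pixel_size)
        za = find_apical_reference(
            stack.membrane()[-1], wt13_small_clean.pixel_size, ringmap=rm
        )
        assert intact_depth(rm, za, wt13_small_clean.z_step) == 0.0

    def test_deepest_extent_never_below_intact(self, fragmented_movie_clean):
        cfg, (stack, gt) = fragmented_movie_clean
        for fr in (5, 20, 35):
            rm = build_ringmap(stack.membrane()[fr], cfg.pixel_size)
            za = find_apical_reference(stack.membrane()[fr], cfg.pixel_size, ringmap=rm)
            assert deepest_extent(rm, za, cfg.z_step) >= intact_depth(rm, za, cfg.z_step)


class TestExtractTrace:
    def test_noiseless_roundtrip_within_one_zstep(self, wt13_movie_clean, wt13_small_clean):
        stack, gt = wt13_movie_clean
        cfg = wt13_small_clean
        truth, _ = simulate_depth_trace(cfg, seed=gt.rng_seed)
        trace = extract_trace(stack, embryo_id="rt", cycle_index=13)
        n = len(truth)
        err = np.abs(trace.intact_depth[:n] - truth.intact_depth[:n])
        assert np.all(err <= cfg.z_step + 1e-9)

    def test_noisy_roundtrip_mostly_within_one_zstep(self, wt13_movie_noisy, wt13_small):
        stack, gt = wt13_movie_noisy
        cfg = wt13_small
        from dataclasses import replace

        truth, _ = simulate_depth_trace(replace(cfg, depth_noise_sd=0.0), seed=gt.rng_seed)
        trace = extract_trace(stack, embryo_id="rt", cycle_index=13)
        n = len(truth)
        err = np.abs(trace.intact_depth[:n] - truth.intact_depth[:n])
        assert np.mean(err <= cfg.z_step + 1e-9) >= 0.95

    def test_single_frame_movie(self, wt13_movie_clean):
        stack, _ = wt13_movie_clean
        sub = stack.membrane()[:1]
        trace = extract_trace(
            sub,
            calibration={"pixel_size_um": stack.pixel_size, "z_step_um": stack.z_step,
                         "frame_interval_s": stack.frame_interval},
        )
        assert len(trace) == 1

    def test_missing_calibration_names_field(self, wt13_movie_clean):
        stack, _ = wt13_movie_clean
        with pytest.raises(ValueError, match="z_step_um"):
            extract_trace(
                stack.membrane()[:1],
                calibration={"pixel_size_um": 0.25, "frame_interval_s": 20.0},
            )


class TestMovieIO:
    def test_ome_tiff_roundtrip(self, wt13_movie_clean, tmp_path):
        from furrowdyn.io import read_movie, write_movie

        stack, _ = wt13_movie_clean
        path = tmp_path / "movie.ome.tif"
        write_movie(path, stack)
        back = read_movie(path)
        assert back.data.shape == stack.data.shape
        assert np.array_equal(back.data, stack.data)
        assert back.pixel_size == pytest.approx(stack.pixel_size)
        assert back.z_step == pytest.approx(stack.z_step)
        assert back.frame_interval == pytest.approx(stack.frame_interval)
        assert back.channel_names == ("membrane", "histone")
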