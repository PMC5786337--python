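from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from furrowdyn import (
    KineticConfig,
    average_phase_rate,
    default_configs,
    has_discrete_ingressionII,
    max_depth_and_time,
    max_ingression_rate,
    segment_trace,
    simulate_depth_trace,
)
from furrowdyn.simulate import DepthTrace


def _trace(times, depths, cycle=13):
    return DepthTrace("t", cycle, np.asarray(times), np.asarray(depths), np.asarray(depths))


class TestSegmentationNoiseless:
    def test_wt13_four_phase_recovery_exact(self, wt13_small_clean):
        trace, _ = simulate_depth_trace(wt13_small_clean, seed=1)
        seg = segment_trace(trace)
        assert seg.labels() == ["IngressionI", "Stabilization", "IngressionII", "Retraction"]
        cfg = wt13_small_clean
        ing1, stab, ing2, _ = seg.segments
        assert ing1.duration == pytest.approx(cfg.ingI_duration, abs=1e-3)
        assert ing1.slope == pytest.approx(cfg.ingI_rate, abs=1e-3)
        assert stab.duration == pytest.approx(cfg.stab_duration, abs=1e-3)
        assert ing2.duration == pytest.approx(cfg.ingII_duration, abs=1e-3)
        assert ing2.slope == pytest.approx(cfg.ingII_rate, abs=1e-3)
        assert ing2.depth_change == pytest.approx(4.3, abs=1e-2)

    def test_rise_then_fall_has_no_ingressionII(self):
        t = np.arange(0, 10, 1 / 3)
        d = np.where(t < 4, t * 1.0, 4.0 - (t - 4) * 0.8)
        seg = segment_trace(_trace(t, d))
        assert seg.labels() == ["IngressionI", "Retraction"]

    def test_cellularization_slow_fast_split(self, wt_configs):
        cfg = replace(wt_configs[14], depth_noise_sd=0.0)
        trace, _ = simulate_depth_trace(cfg, seed=1)
        seg = segment_trace(trace)
        assert seg.labels() == ["IngressionI", "IngressionII"]
        assert seg.get("IngressionII").slope / seg.get("IngressionI").slope == pytest.approx(
            2.4, abs=1e-3
        )

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="short"):
            segment_trace(_trace(np.arange(5), np.arange(5.0)))

    def test_segment_depth_change_consistency(self, wt13_small_clean):
        trace, _ = simulate_depth_trace(wt13_small_clean, seed=1)
        seg = segment_trace(trace)
        for s in seg.segments:
            assert s.depth_change == pytest.approx(s.slope * s.duration, abs=1e-9)


@st.composite
def pwl_configs(draw):
    """Random one-cycle kinetic configs whose retraction ends exactly at cycle end."""
    d1 = draw(st.floats(1.5, 4.0))
    r1 = draw(st.floats(0.6, 1.6))
    d2 = draw(st.floats(2.0, 5.0))
    with_ing2 = draw(st.booleans())
    d3 = draw(st.floats(2.0, 6.0)) if with_ing2 else 0.0
    r3 = draw(st.floats(0.45, 1.2)) if with_ing2 else 0.0
    w = draw(st.floats(2.5, 6.0))
    peak = d1 * r1 + d3 * r3
    total = d1 + d2 + d3 + w
    return KineticConfig(
        cycle_index=13,
        ingI_duration=d1, ingI_rate=r1,
        stab_duration=d2,
        ingII_probability=1.0 if with_ing2 else 0.0,
        ingII_duration=d3, ingII_rate=r3,
        retraction_rate=peak / w,
        cc_interphase=total - 3.0, cc_prophase=1.0, cc_metaphase=1.0, cc_anatelo=1.0,
        depth_noise_sd=0.0,
    )


class TestSegmentationProperties:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(cfg=pwl_configs())
    def test_noiseless_breakpoint_exactness(self, cfg):
        trace, gt = simulate_depth_trace(cfg, seed=1)
        seg = segment_trace(trace)
        expected = ["IngressionI", "Stabilization"]
        if gt.has_ingressionII:
            expected.append("IngressionII")
        expected.append("Retraction")
        assert seg.labels() == expected
        assert seg.get("IngressionI").duration == pytest.approx(cfg.ingI_duration, abs=0.02)
        assert seg.get("Stabilization").duration == pytest.approx(cfg.stab_duration, abs=0.03)
        if gt.has_ingressionII:
            assert seg.get("IngressionII").duration == pytest.approx(cfg.ingII_duration, abs=0.03)
            assert seg.get("IngressionII").slope == pytest.approx(cfg.ingII_rate, abs=0.02)

    def test_shift_and_offset_invariance(self, wt13_small_clean):
        trace, _ = simulate_depth_trace(wt13_small_clean, seed=3)
        seg0 = segment_trace((trace.times, trace.intact_depth))
        seg1 = segment_trace((trace.times + 7.0, trace.intact_depth + 2.5))
        for a, b in zip(seg0.segments, seg1.segments):
            assert a.label == b.label
            assert b.start - a.start == pytest.approx(7.0, abs=1e-6)
            assert b.slope == pytest.approx(a.slope, abs=1e-6)

    def test_ingII_duration_monotonic_in_max_depth(self, wt13_small_clean):
        depths = []
        for d3 in (3.0, 5.0, 7.0):
            cfg = replace(
                wt13_small_clean,
                ingII_duration=d3,
                retraction_rate=(3.7 + d3 * wt13_small_clean.ingII_rate)
                / (18.8 - 2.4 - 5.1 - d3),
            )
            trace, _ = simulate_depth_trace(cfg, seed=1)
            depths.append(max_depth_and_time(trace)[0])
        assert depths[0] < depths[1] < depths[2]


class TestRollingRates:
    def test_constant_slope(self):
        t = np.arange(0, 8, 1 / 3)
        assert max_ingression_rate(_trace(t, t * 1.0)) == pytest.approx(1.0)

    def test_flat_trace_zero(self):
        t = np.arange(0, 8, 1 / 3)
        assert max_ingression_rate(_trace(t, np.full_like(t, 3.0))) == pytest.approx(0.0)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 15, 1 / 3)
        d = np.cumsum(rng.normal(0.1, 0.3, len(t)))
        trace = _trace(t, d)
        w = 2.0
        best = -np.inf  # independent exhaustive scan over admissible windows
        for i in range(len(t)):
            for j in range(i + 1, len(t)):
                if abs((t[j] - t[i]) - w) < 1e-9:
                    best = max(best, (d[j] - d[i]) / (t[j] - t[i]))
        assert max_ingression_rate(trace, w) == pytest.approx(best, abs=1e-9)

    def test_window_longer_than_trace_rejected(self):
        t = np.arange(0, 1.0, 1 / 3)
        with pytest.raises(ValueError, match="window"):
            max_ingression_rate(_trace(t, t), window=2.0)

    def test_phase_restricted_rate_equals_segment_slope_noiseless(self, wt13_small_clean):
        trace, _ = simulate_depth_trace(wt13_small_clean, seed=1)
        seg = segment_trace(trace)
        r = max_ingression_rate(trace, 2.0, seg, "IngressionII")
        assert r == pytest.approx(wt13_small_clean.ingII_rate, abs=0.02)

    def test_max_rate_bounds_average_rate(self, wt13_small_clean):
        trace, _ = simulate_depth_trace(wt13_small_clean, seed=1)
        seg = segment_trace(trace)
        r_max = max_ingression_rate(trace, 2.0, seg, "IngressionII")
        r_avg = average_phase_rate(seg, "IngressionII")
        assert r_max >= r_avg - 1e-6


class TestPhaseQueries:
    def test_average_rate_arithmetic(self, wt13_small_clean):
        trace, _ = simulate_depth_trace(wt13_small_clean, seed=1)
        seg = segment_trace(trace)
        # 4.3 um over 6.2 min
        assert average_phase_rate(seg, "IngressionII") == pytest.approx(0.694, abs=0.01)
        assert average_phase_rate(seg, "Stabilization") == pytest.approx(0.0, abs=0.01)

    def test_absent_phase_is_none_not_zero(self, wt_configs):
        cfg = replace(wt_configs[14], depth_noise_sd=0.0)
        trace, _ = simulate_depth_trace(cfg, seed=1)
        seg = segment_trace(trace)
        assert average_phase_rate(seg, "Retraction") is None

    def test_discrete_ingressionII_calls(self, wt13_small_clean):
        trace, _ = simulate_depth_trace(wt13_small_clean, seed=1)
        assert has_discrete_ingressionII(segment_trace(trace))
        amanitin = replace(
            default_configs("alpha_amanitin")[13], depth_noise_sd=0.0
        )
        trace_a, _ = simulate_depth_trace(amanitin, seed=1)
        assert not has_discrete_ingressionII(segment_trace(trace_a))

    def test_plateau_only_trace_not_discrete(self):
        t = np.arange(0, 10, 1 / 3)
        d = np.where(t < 3, t, 3.0)
        assert not has_discrete_ingressionII(segment_trace(_trace(t, d)))


class TestMaxDepth:
    def test_wt13_noiseless_depth_and_time(self, wt13_small_clean):
        trace, _ = simulate_depth_trace(wt13_small_clean, seed=1)
        depth, t_max = max_depth_and_time(trace)
        assert depth == pytest.approx(8.0, abs=0.1)
        assert t_max == pytest.approx(13.7, abs=1 / 3)

    def test_monotone_rise_peaks_at_end(self):
        t = np.arange(0, 8, 1 / 3)
        depth, t_max = max_depth_and_time(_trace(t, t * 0.5))
        assert t_max == pytest.approx(t[-1])

    def test_tie_breaks_to_earliest(self):
        t = np.arange(0, 8, 1 / 3)
        d = np.minimum(t, 3.0)  # plateau of equal maxima
        _, t_max = max_depth_and_time(_trace(t, d), window=0.0)
        assert t_max == pytest.approx(3.0, abs=1e-9)
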