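from dataclasses import replace

import numpy as np
import pytest

from furrowdyn import default_configs, segment_trace, simulate_depth_trace
from furrowdyn.cell_cycle import (
    CellCycleAnnotation,
    align_traces,
    annotate,
    phase_correspondence,
)
from furrowdyn.render import render_movie
from furrowdyn.simulate import DepthTrace


def _annotation(ana=13.7, total=18.8, cycle=13):
    return CellCycleAnnotation(
        cycle_index=cycle,
        intervals=[
            ("interphase", 0.0, 7.5),
            ("prophase", 7.5, 10.7),
            ("metaphase", 10.7, ana),
            ("anaphase_telophase", ana, total),
        ],
        anaphase_onset=ana,
        total_cycle_time=total,
    )


class TestAnnotate:
    def test_scripted_boundaries_recovered_within_one_frame(self, wt_configs):
        # scripted chromatin schedule: condensation 8.0, disassembly 11.5,
        # segregation 15.3 min
        cfg = replace(
            wt_configs[13], field_area=900.0,
            cc_interphase=8.0, cc_prophase=3.5, cc_metaphase=3.8, cc_anatelo=3.5,
        )
        stack, gt = render_movie(cfg, seed=21)
        ann = annotate(stack.histone(), cfg.frame_interval, cfg.pixel_size, 13)
        dt = cfg.frame_interval / 60.0
        starts = {lab: s for lab, s, _ in ann.intervals}
        assert starts["prophase"] == pytest.approx(8.0, abs=dt + 1e-9)
        assert starts["metaphase"] == pytest.approx(11.5, abs=dt + 1e-9)
        assert ann.anaphase_onset == pytest.approx(15.3, abs=dt + 1e-9)

    def test_total_cycle_time_recovered(self, wt13_movie_noisy, wt13_small):
        stack, gt = wt13_movie_noisy
        ann = annotate(stack.histone(), wt13_small.frame_interval, wt13_small.pixel_size, 13)
        assert ann.total_cycle_time == pytest.approx(gt.total_cycle_time, abs=0.5)

    def test_truncated_movie_errors(self, wt13_movie_noisy, wt13_small):
        stack, gt = wt13_movie_noisy
        dt = wt13_small.frame_interval / 60.0
        n_before_ana = int(gt.anaphase_onset / dt) - 2
        with pytest.raises(ValueError, match="no anaphase onset"):
            annotate(stack.histone()[:n_before_ana], wt13_small.frame_interval,
                     wt13_small.pixel_size, 13)

    def test_interval_invariants(self, wt13_movie_noisy, wt13_small):
        stack, _ = wt13_movie_noisy
        ann = annotate(stack.histone(), wt13_small.frame_interval, wt13_small.pixel_size, 13)
        labels = [lab for lab, _, _ in ann.intervals]
        assert labels == ["interphase", "prophase", "metaphase", "anaphase_telophase"]
        assert ann.anaphase_onset == ann.interval("anaphase_telophase")[0]
        durs = sum(e - s for _, s, e in ann.intervals)
        assert durs == pytest.approx(ann.total_cycle_time)

    def test_canonical_order_enforced(self):
        with pytest.raises(ValueError, match="order"):
            CellCycleAnnotation(
                cycle_index=13,
                intervals=[("prophase", 0, 1), ("interphase", 1, 2)],
                anaphase_onset=1.0,
            )


class TestAlignTraces:
    def _trace(self, times, depths, eid="e", cycle=13):
        d = np.asarray(depths, float)
        return DepthTrace(eid, cycle, np.asarray(times, float), d, d)

    def test_shift_invariance(self):
        t = np.arange(0, 18, 1 / 3)
        d = np.minimum(t, 8.0)
        tr_a = self._trace(t, d, "a")
        tr_b = self._trace(t + 5.0, d, "b")  # same embryo, clock offset +5
        ann_a = _annotation(ana=13.7)
        ann_b = _annotation(ana=18.7)
        ens = align_traces([tr_a, tr_b], [ann_a, ann_b])
        ok = ~np.isnan(ens.traces).any(axis=0)
        assert np.allclose(ens.traces[0][ok], ens.traces[1][ok])

    def test_single_trace_ensemble_is_identity(self):
        t = np.arange(0, 10, 1 / 3)
        tr = self._trace(t, np.sqrt(t))
        ens = align_traces([tr], [_annotation()])
        assert np.allclose(ens.mean, tr.intact_depth)

    def test_mismatched_cycles_rejected(self):
        t = np.arange(0, 10, 1 / 3)
        tr12 = self._trace(t, t, cycle=12)
        tr13 = self._trace(t, t, cycle=13)
        with pytest.raises(ValueError, match="cycle"):
            align_traces([tr12, tr13], [_annotation(cycle=12), _annotation(cycle=13)])

    def test_noisy_ensemble_mean_near_truth(self, wt13_small, wt13_small_clean):
        truth, _ = simulate_depth_trace(wt13_small_clean, seed=0)
        traces = [simulate_depth_trace(wt13_small, seed=s)[0] for s in range(1, 9)]
        anns = [_annotation() for _ in traces]
        ens = align_traces(traces, anns)
        sem = ens.sd / np.sqrt(len(traces))
        ok = ~np.isnan(ens.mean)
        resid = np.abs(ens.mean[ok] - truth.intact_depth[ok])
        # mean within 2 SEM at (nearly) every grid point; allow Monte Carlo slack
        assert np.mean(resid <= 2 * np.maximum(sem[ok], 1e-6)) >= 0.9


class TestPhaseCorrespondence:
    def test_retraction_lies_in_anaphase(self, wt13_small_clean):
        trace, _ = simulate_depth_trace(wt13_small_clean, seed=1)
        seg = segment_trace(trace)
        tab = phase_correspondence(seg, _annotation())
        row = tab.loc["Retraction"]
        assert row["anaphase_telophase"] == pytest.approx(1.0, abs=1e-6)
        assert row[["interphase", "prophase", "metaphase"]].sum() == pytest.approx(0.0, abs=1e-6)

    def test_rows_sum_to_one_when_clocks_overlap(self, wt13_small_clean):
        trace, _ = simulate_depth_trace(wt13_small_clean, seed=1)
        seg = segment_trace(trace)
        tab = phase_correspondence(seg, _annotation())
        sums = tab[["interphase", "prophase", "metaphase", "anaphase_telophase"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-6)

    def test_disjoint_intervals_flagged_zero_row(self, wt13_small_clean):
        trace, _ = simulate_depth_trace(wt13_small_clean, seed=1)
        seg = segment_trace(trace)
        ann = CellCycleAnnotation(
            cycle_index=13,
            intervals=[("interphase", 100.0, 110.0), ("anaphase_telophase", 110.0, 112.0)],
            anaphase_onset=110.0,
        )
        tab = phase_correspondence(seg, ann)
        assert (tab["flag"] == "disjoint").all()
        assert np.allclose(
            tab[["interphase", "prophase", "metaphase", "anaphase_telophase"]].to_numpy(), 0.0
        )
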