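"""Cell-cycle phase annotation from the histone channel, and anaphase alignment.

Phase calls follow chromatin morphology: interphase runs from the appearance of
new nuclei to the first chromosomal condensation (bright puncta); prophase to
nuclear disassembly; metaphase to the onset of chromosome segregation; and
anaphase/telophase to the formation of the next cycle's daughter nuclei.

The field of nuclei is summarized per frame by simple features (blob count,
median blob area, foreground intensity coefficient of variation); threshold
crossings of these features against the interphase baseline give the phase
boundaries. Asynchrony across the field is collapsed by using field-level
(median/count) features. Feature thresholds are calibrated against the
renderer's contrast settings and are recorded in the annotation metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops

from .simulate import DepthTrace

CC_ORDER = ("interphase", "prophase", "metaphase", "anaphase_telophase")

# feature-threshold calibration (relative to the interphase baseline)
PUNCTA_RATIO_FACTOR = 1.25  # p99/median brightness rise marking condensation puncta
AREA_DISASSEMBLY_FACTOR = 0.55  # blob-area drop marking the compact metaphase plate
COUNT_SEGREGATION_FACTOR = 1.5  # blob-count rise marking two-mass separation
INTENSITY_REFORM_FACTOR = 1.25  # mean-intensity return to baseline at decondensation


@dataclass
class CellCycleAnnotation:
    """Contiguous phase intervals for one nuclear cycle (minutes)."""

    cycle_index: int
    intervals: list[tuple[str, float, float]]
    anaphase_onset: float
    cycle_start: float = 0.0
    total_cycle_time: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [lab for lab, _, _ in self.intervals]
        if labels != [p for p in CC_ORDER if p in labels]:
            raise ValueError(f"intervals out of canonical order: {labels}")
        for (_, _, e0), (_, s1, _) in zip(self.intervals, self.intervals[1:]):
            if abs(e0 - s1) > 1e-9:
                raise ValueError("intervals must be contiguous")
        if not self.total_cycle_time:
            self.total_cycle_time = self.intervals[-1][2] - self.intervals[0][1]

    def interval(self, phase: str) -> tuple[float, float] | None:
        for lab, s, e in self.intervals:
            if lab == phase:
                return (s, e)
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals, columns=["phase", "start_min", "end_min"])


def frame_features(
    hist: np.ndarray,
    pixel_size: float,
    min_blob_area: float = 0.8,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Per-frame field-level chromatin features from a (T,Z,Y,X) or (T,Y,X) movie.

    Columns: ``n_blobs``, ``median_area`` (um^2), ``cv`` and
    ``mean_intensity`` of foreground pixels, and ``puncta_ratio`` (99th
    percentile / median of foreground intensity; bright condensation puncta
    raise it).

    By default the foreground threshold is fixed from the first frame
    (interphase baseline), so blob footprints are comparable across the cycle
    even as condensed figures brighten; pass ``threshold`` to override.
    """
    hist = np.asarray(hist)
    if hist.ndim == 4:
        hist = hist.max(axis=1)
    if threshold is None:
        img0 = hist[0].astype(float)
        threshold = threshold_otsu(img0) if img0.max() > img0.min() else np.inf
    rows = []
    for ti in range(hist.shape[0]):
        img = hist[ti].astype(float)
        binary = img > threshold
        n, med_area, cv, ratio, mean_i = 0, 0.0, 0.0, 1.0, 0.0
        if binary.any():
            labels = sk_label(binary)
            areas = np.array([p.area for p in regionprops(labels)]) * pixel_size**2
            areas = areas[areas >= min_blob_area]
            n = len(areas)
            med_area = float(np.median(areas)) if n else 0.0
            fg = img[binary]
            mean_i = float(np.mean(fg))
            cv = float(np.std(fg) / max(mean_i, 1e-9))
            ratio = float(np.percentile(fg, 99) / max(np.median(fg), 1e-9))
        rows.append({"n_blobs": n, "median_area": med_area, "cv": cv,
                     "puncta_ratio": ratio, "mean_intensity": mean_i})
    return pd.DataFrame(rows)


def _first_crossing(values, start, predicate):
    for i in range(start, len(values)):
        if predicate(values[i]):
            return i
    return None


def annotate(
    movie_or_features,
    frame_interval: float,
    pixel_size: float | None = None,
    cycle_index: int = 0,
) -> CellCycleAnnotation:
    """Annotate one nuclear cycle from the histone channel.

    Parameters
    ----------
    movie_or_features:
        Histone movie as (T,Z,Y,X)/(T,Y,X) array (requires ``pixel_size``), or
        a precomputed feature table from :func:`frame_features`.
    frame_interval:
        Seconds between frames.

    Raises ``ValueError`` ("no anaphase onset") if no segregation event is
    found, e.g. for a movie truncated before mitosis.
    """
    if isinstance(movie_or_features, pd.DataFrame):
        feats = movie_or_features
    else:
        if pixel_size is None:
            raise ValueError("pixel_size required when passing a raw movie")
        feats = frame_features(movie_or_features, pixel_size)
    dt_min = frame_interval / 60.0
    base = feats.iloc[: max(2, min(3, len(feats)))]
    ratio0 = float(base["puncta_ratio"].median())
    area0 = float(base["median_area"].median())
    count0 = float(base["n_blobs"].median())
    mean0 = float(base["mean_intensity"].median())

    i_cond = _first_crossing(
        feats["puncta_ratio"].values, 1, lambda v: v >= PUNCTA_RATIO_FACTOR * ratio0
    )
    if i_cond is None:
        raise ValueError("no anaphase onset (no condensation found)")
    i_meta = _first_crossing(
        feats["median_area"].values, i_cond, lambda v: v <= AREA_DISASSEMBLY_FACTOR * area0
    )
    if i_meta is None:
        raise ValueError("no anaphase onset (no nuclear disassembly found)")
    i_ana = _first_crossing(
        feats["n_blobs"].values, i_meta, lambda v: v >= COUNT_SEGREGATION_FACTOR * count0
    )
    if i_ana is None:
        raise ValueError("no anaphase onset")
    i_end = _first_crossing(
        feats["mean_intensity"].values, i_ana + 1,
        lambda v: v <= INTENSITY_REFORM_FACTOR * mean0,
    )
    complete = i_end is not None
    if not complete:
        i_end = len(feats) - 1

    t = lambda i: i * dt_min  # noqa: E731
    intervals = [
        ("interphase", 0.0, t(i_cond)),
        ("prophase", t(i_cond), t(i_meta)),
        ("metaphase", t(i_meta), t(i_ana)),
        ("anaphase_telophase", t(i_ana), t(i_end)),
    ]
    return CellCycleAnnotation(
        cycle_index=cycle_index,
        intervals=intervals,
        anaphase_onset=t(i_ana),
        total_cycle_time=t(i_end),
        metadata={
            "complete": complete,
            "asynchrony_reduction": "field-median",
            "puncta_ratio_baseline": ratio0,
            "area_baseline_um2": area0,
            "count_baseline": count0,
        },
    )


@dataclass
class AlignedEnsemble:
    """Anaphase-aligned trace ensemble on the reference embryo's clock."""

    grid: np.ndarray  # minutes, reference embryo's cycle-start clock
    traces: np.ndarray  # (n_embryos, n_grid), NaN outside a trace's support
    embryo_ids: list[str]
    anaphase_onset: float

    @property
    def mean(self) -> np.ndarray:
        return np.nanmean(self.traces, axis=0)

    @property
    def sd(self) -> np.ndarray:
        return np.nanstd(self.traces, axis=0, ddof=1) if len(self.traces) > 1 else np.zeros_like(self.grid)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.traces.T, index=self.grid, columns=self.embryo_ids)
        df.index.name = "time_min"
        df["mean"] = self.mean
        df["sd"] = self.sd
        return df


def align_traces(
    traces: list[DepthTrace],
    annotations: list[CellCycleAnnotation],
    use: str = "intact",
) -> AlignedEnsemble:
    """Align depth traces on the onset of chromosome segregation.

    Each trace's clock is shifted so its anaphase onset coincides with the
    first (reference) embryo's; the ensemble is interpolated onto the reference
    time grid. Cycle indices must match across traces and annotations.
    """
    if len(traces) != len(annotations):
        raise ValueError("need one annotation per trace")
    if len(traces) == 0:
        raise ValueError("empty ensemble")
    cycles = {tr.cycle_index for tr in traces} | {an.cycle_index for an in annotations}
    if len(cycles) > 1:
        raise ValueError(f"mismatched cycle indices: {sorted(cycles)}")
    ref_ana = annotations[0].anaphase_onset
    grid = traces[0].times
    rows = []
    for tr, an in zip(traces, annotations):
        shift = ref_ana - an.anaphase_onset
        t = tr.times + shift
        y = tr.intact_depth if use == "intact" else tr.deepest_extent
        vals = np.interp(grid, t, y, left=np.nan, right=np.nan)
        rows.append(vals)
    return AlignedEnsemble(
        grid=grid,
        traces=np.array(rows),
        embryo_ids=[tr.embryo_id for tr in traces],
        anaphase_onset=ref_ana,
    )


def phase_correspondence(segmentation, annotation: CellCycleAnnotation) -> pd.DataFrame:
    """Fraction of each furrow phase's duration spent in each cell-cycle phase.

    Rows (furrow phases) sum to 1 when the clocks overlap; a furrow phase
    disjoint from the annotated cycle yields a zero row flagged in the
    ``flag`` column.
    """
    rows = {}
    flags = {}
    for seg in segmentation.segments:
        overlaps = {}
        for lab, s, e in annotation.intervals:
            lo, hi = max(seg.start, s), min(seg.end, e)
            overlaps[lab] = max(0.0, hi - lo) / max(seg.duration, 1e-12)
        rows[seg.label] = overlaps
        flags[seg.label] = "disjoint" if sum(overlaps.values()) < 1e-9 else ""
    df = pd.DataFrame(rows).T.reindex(columns=list(CC_ORDER), fill_value=0.0)
    df["flag"] = pd.Series(flags)
    return df
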