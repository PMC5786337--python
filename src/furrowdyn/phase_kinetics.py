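"""Biphasic phase segmentation and ingression-rate statistics for depth traces.

Each trace is fit with a continuous piecewise-linear (free-knot hinge) model;
breakpoints are searched exhaustively on the sampling grid (with a
coarse-to-fine pass for large grids), the breakpoint count (1-4) is selected by
BIC, and the fitted segments are mapped to the canonical phase vocabulary:
Ingression I -> Stabilization -> Ingression II -> Retraction.

The hinge-basis normal equations are assembled from suffix sums, so evaluating
one candidate breakpoint set costs O(k^2) independent of trace length, and all
candidate sets for a given k are solved in one batched call.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .simulate import DepthTrace

PHASE_ORDER = ("IngressionI", "Stabilization", "IngressionII", "Retraction")


@dataclass
class Segment:
    label: str
    start: float  # min
    end: float  # min
    slope: float  # um/min (depth_change / duration)
    depth_change: float  # um

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class PhaseSegmentation:
    """Ordered labeled phases with the underlying piecewise-linear fit."""

    segments: list[Segment]
    breakpoints: np.ndarray  # interior knot times of the selected fit (min)
    knot_values: np.ndarray  # fitted depth at [t0, knots..., tN] (um)
    fit_score: float  # BIC of the selected model
    n_breakpoints: int

    def get(self, label: str) -> Segment | None:
        for s in self.segments:
            if s.label == label:
                return s
        return None

    def labels(self) -> list[str]:
        return [s.label for s in self.segments]


# ---------------------------------------------------------------------------
# free-knot continuous piecewise-linear least squares
# ---------------------------------------------------------------------------

def _suffix_sums(t: np.ndarray, y: np.ndarray):
    rev = slice(None, None, -1)
    cnt = np.arange(len(t), 0, -1, dtype=float)
    St = np.cumsum(t[rev])[rev]
    St2 = np.cumsum((t * t)[rev])[rev]
    Sy = np.cumsum(y[rev])[rev]
    Sty = np.cumsum((t * y)[rev])[rev]
    return cnt, St, St2, Sy, Sty


def _batched_fit(t, y, knots_idx):
    """Least-squares continuous PWL fit for many knot sets at once.

    Parameters
    ----------
    knots_idx : (M, k) int array of interior knot grid indices, sorted per row.

    Returns
    -------
    coefs : (M, k+2) [intercept, base slope, slope changes...]
    rss : (M,)
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = len(t)
    M, k = knots_idx.shape
    p = k + 2
    cnt, St, St2, Sy, Sty = _suffix_sums(t, y)
    sum_t, sum_t2, sum_y, sum_ty = St[0], St2[0], Sy[0], Sty[0]
    sum_yy = float(np.dot(y, y))

    tk = t[knots_idx]  # (M, k)
    A = np.empty((M, p, p))
    b = np.empty((M, p))
    A[:, 0, 0] = n
    A[:, 0, 1] = A[:, 1, 0] = sum_t
    A[:, 1, 1] = sum_t2
    b[:, 0] = sum_y
    b[:, 1] = sum_ty
    # hinge columns
    h1 = St[knots_idx] - tk * cnt[knots_idx]  # <1, h_a>
    ht = St2[knots_idx] - tk * St[knots_idx]  # <t, h_a>
    hy = Sty[knots_idx] - tk * Sy[knots_idx]  # <y, h_a>
    A[:, 0, 2:] = h1
    A[:, 2:, 0] = h1
    A[:, 1, 2:] = ht
    A[:, 2:, 1] = ht
    b[:, 2:] = hy
    for a in range(k):
        for c in range(a, k):
            # knots sorted: index c is the later knot
            jb = knots_idx[:, c]
            ta, tb = tk[:, a], tk[:, c]
            v = St2[jb] - (ta + tb) * St[jb] + ta * tb * cnt[jb]
            A[:, 2 + a, 2 + c] = v
            A[:, 2 + c, 2 + a] = v
    try:
        coefs = np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        coefs = np.array([np.linalg.lstsq(A[i], b[i], rcond=None)[0] for i in range(M)])
    rss = sum_yy - np.einsum("ij,ij->i", coefs, b)
    return coefs, np.maximum(rss, 0.0)


def _combo_array(cands: np.ndarray, k: int, min_sep: int) -> np.ndarray:
    combos = np.array(list(itertools.combinations(cands, k)), dtype=int)
    if combos.size == 0:
        return combos.reshape(0, k)
    if k > 1:
        ok = np.all(np.diff(combos, axis=1) >= min_sep, axis=1)
        combos = combos[ok]
    return combos


def _search_knots(t, y, k, min_seg, combo_limit=80_000):
    """Best k-knot fit; exhaustive on the grid, coarse-to-fine when too large."""
    n = len(t)
    lo, hi = min_seg, n - 1 - min_seg
    if hi < lo:
        return None
    cands = np.arange(lo, hi + 1)

    def n_combos(m):
        from math import comb
        return comb(m, k)

    if n_combos(len(cands)) <= combo_limit:
        combos = _combo_array(cands, k, min_seg)
        if len(combos) == 0:
            return None
        coefs, rss = _batched_fit(t, y, combos)
        i = int(np.argmin(rss))
        return combos[i], coefs[i], float(rss[i])

    # coarse pass on a strided grid, then refine each knot locally
    stride = 2
    while n_combos(len(cands[::stride])) > combo_limit:
        stride += 1
    coarse = _combo_array(cands[::stride], k, min_seg)
    coefs, rss = _batched_fit(t, y, coarse)
    best = coarse[int(np.argmin(rss))]
    windows = [
        np.unique(np.clip(np.arange(b - stride, b + stride + 1), lo, hi)) for b in best
    ]
    fine = np.array(
        [c for c in itertools.product(*windows)
         if all(c[i + 1] - c[i] >= min_seg for i in range(k - 1))],
        dtype=int,
    )
    coefs, rss = _batched_fit(t, y, fine)
    i = int(np.argmin(rss))
    return fine[i], coefs[i], float(rss[i])


def _hinge_design(t, knots):
    return np.column_stack([np.ones_like(t), t] + [np.maximum(t - k, 0.0) for k in knots])


def _rss_at_knots(t, y, knots):
    X = _hinge_design(t, knots)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r), coef


def _refine_knots(t, y, knot_times, min_seg):
    """Polish grid knots by continuous optimization (true breakpoints need not
    lie on the sampling grid)."""
    from scipy.optimize import minimize

    lo, hi = t[min_seg], t[-1 - min_seg]

    def objective(x):
        k = np.clip(np.sort(x), lo, hi)
        return _rss_at_knots(t, y, k)[0]

    x = np.asarray(knot_times, float)
    for _ in range(2):  # restart once: NM stalls on nearly-flat simplices
        res = minimize(objective, x, method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-14,
                                "maxiter": 400 * len(knot_times)})
        x = res.x
    refined = np.clip(np.sort(x), lo, hi)
    rss_r, coef_r = _rss_at_knots(t, y, refined)
    rss_g, coef_g = _rss_at_knots(t, y, knot_times)
    if rss_r < rss_g:
        return refined, coef_r, rss_r
    return np.asarray(knot_times, float), coef_g, rss_g


def _fit_model(times, depths, max_breakpoints, min_seg):
    """Select breakpoint count 1..max by BIC; return (knot_times, coefs, rss, bic)."""
    n = len(times)
    best = None
    rss_floor = n * 1e-16
    for k in range(1, max_breakpoints + 1):
        res = _search_knots(times, depths, k, min_seg)
        if res is None:
            continue
        knots_idx, _, _ = res
        knot_times, coefs, rss = _refine_knots(times, depths, times[knots_idx], min_seg)
        p_eff = 2 + 2 * k  # slopes/intercept plus free knot locations
        bic = n * np.log(max(rss, rss_floor) / n) + p_eff * np.log(n)
        if best is None or bic < best[3]:
            best = (knot_times, coefs, rss, bic)
    if best is None:
        raise ValueError("trace too short for any breakpoint configuration")
    return best


def _eval_pwl(coefs, knot_times, t):
    t = np.asarray(t, float)
    out = coefs[0] + coefs[1] * t
    for c, tk in zip(coefs[2:], knot_times):
        out = out + c * np.maximum(t - tk, 0.0)
    return out


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

def _classify_slope(s, stab_bound, rise_floor):
    """Classify a fitted slope: ingression requires >= rise_floor; slopes in
    the ambiguous band (stab_bound, rise_floor) count as plateau."""
    if s >= rise_floor:
        return "rise"
    if s < -stab_bound:
        return "fall"
    return "flat"


def _label_runs(bounds, slopes, stab_bound, rise_floor, rise_split_ratio=1.8):
    """Merge raw fitted pieces into constant-class runs.

    ``bounds`` has len(slopes)+1 entries. Consecutive pieces of the same slope
    class merge, except two 'rise' pieces whose slopes differ by at least
    ``rise_split_ratio`` (the cellularization slow->fast transition). A flat
    piece following a fall (retraction completed, depth clamped at zero) merges
    into the fall. Returns list of [cls, t0, t1, duration-weighted slope].
    """
    classes = [_classify_slope(s, stab_bound, rise_floor) for s in slopes]
    runs: list[list] = []
    for cls, s, t0, t1 in zip(classes, slopes, bounds[:-1], bounds[1:]):
        if runs:
            pcls, pt0, pt1, ps = runs[-1]
            same = cls == pcls
            if same and cls == "rise":
                ratio = max(s, ps) / max(min(s, ps), 1e-12)
                if ratio >= rise_split_ratio:
                    same = False
            if not same and pcls == "fall" and cls == "flat":
                same = True  # clamp tail joins retraction
            if same:
                dur = (pt1 - pt0) + (t1 - t0)
                runs[-1] = [pcls, pt0, t1, (ps * (pt1 - pt0) + s * (t1 - t0)) / dur]
                continue
        runs.append([cls, t0, t1, s])
    return runs


def _extend(entry, t1, s):
    dur0 = entry[2] - entry[1]
    dur1 = t1 - entry[2]
    entry[3] = (entry[3] * dur0 + s * dur1) / max(dur0 + dur1, 1e-12)
    entry[2] = t1


def _runs_to_phases(runs, rise_split_ratio=1.8, min_slow_phase=3.0):
    """Map merged slope runs to the canonical phase labels (each at most once,
    in order IngressionI, Stabilization, IngressionII, Retraction).

    Retraction is terminal within a cycle, so a fall run occurring before a
    substantial (>= 1 min) rise run is reinterpreted as plateau; without this,
    a noise-tilted stabilization fit would truncate the segmentation early.
    """
    last_rise = max(
        (i for i, r in enumerate(runs) if r[0] == "rise" and r[2] - r[1] >= 1.0),
        default=-1,
    )
    runs = [
        (("flat" if cls == "fall" and i < last_rise else cls), t0, t1, s)
        for i, (cls, t0, t1, s) in enumerate(runs)
    ]
    labels: list[list] = []  # [label, t0, t1, weighted slope]
    state = 1
    for cls, t0, t1, s in runs:
        if not labels:
            labels.append(["IngressionI", t0, t1, s])
            state = 1
            continue
        prev = labels[-1]
        if cls == "fall":
            if prev[0] == "Retraction":
                _extend(prev, t1, s)
            else:
                labels.append(["Retraction", t0, t1, s])
                state = 4
        elif cls == "flat":
            if state <= 1 and prev[0] == "IngressionI":
                labels.append(["Stabilization", t0, t1, s])
                state = 2
            else:  # plateau after IngII or Retraction: absorb
                _extend(prev, t1, s)
        else:  # rise
            if prev[0] == "IngressionII":
                _extend(prev, t1, s)
            elif state == 2:  # rise after stabilization
                labels.append(["IngressionII", t0, t1, s])
                state = 3
            elif state <= 1 and prev[0] == "IngressionI":
                # direct slow->fast transition (no plateau, cellularization):
                # requires an established slow phase and a markedly faster rise
                if (prev[2] - prev[1] >= min_slow_phase and prev[3] > 0
                        and s / max(prev[3], 1e-12) >= rise_split_ratio):
                    labels.append(["IngressionII", t0, t1, s])
                    state = 3
                else:
                    _extend(prev, t1, s)
            else:  # rise after retraction: end-of-cycle noise, absorb
                _extend(prev, t1, s)
    return labels


def segment_trace(
    trace: DepthTrace | tuple[np.ndarray, np.ndarray],
    max_breakpoints: int = 4,
    stab_slope_bound: float = 0.15,
    ingression_slope_floor: float = 0.3,
    min_segment_frames: int = 2,
) -> PhaseSegmentation:
    """Segment a depth trace into furrow phases.

    Fits continuous piecewise-linear models with 1..``max_breakpoints``
    breakpoints, selects the count by BIC, then labels the merged constant-slope
    runs in canonical order. Segment ``slope`` is depth_change/duration computed
    from the fitted curve, so ``depth_change == slope * duration`` holds exactly.

    Raises ``ValueError`` for traces with fewer than 8 points or non-monotone
    times.
    """
    if isinstance(trace, DepthTrace):
        times, depths = trace.times, trace.intact_depth
    else:
        times, depths = np.asarray(trace[0], float), np.asarray(trace[1], float)
    if len(times) < 8:
        raise ValueError(f"trace too short to segment ({len(times)} < 8 points)")
    if not np.all(np.diff(times) > 0):
        raise ValueError("trace times must be strictly increasing")

    knot_times, coefs, rss, bic = _fit_model(times, depths, max_breakpoints, min_segment_frames)
    bounds = np.concatenate([[times[0]], knot_times, [times[-1]]])
    slopes = np.cumsum(np.concatenate([[coefs[1]], coefs[2:]]))

    runs = _label_runs(bounds, slopes, stab_slope_bound, ingression_slope_floor)
    phases = _runs_to_phases(runs)
    vals = _eval_pwl(coefs, knot_times, np.array([p[1] for p in phases] + [phases[-1][2]]))
    segments = []
    for (label, t0, t1, _s), v0, v1 in zip(phases, vals[:-1], vals[1:]):
        dur = t1 - t0
        dch = float(v1 - v0)
        segments.append(Segment(label=label, start=float(t0), end=float(t1),
                                slope=dch / dur if dur > 0 else 0.0, depth_change=dch))
    return PhaseSegmentation(
        segments=segments,
        breakpoints=knot_times,
        knot_values=_eval_pwl(coefs, knot_times, bounds),
        fit_score=float(bic),
        n_breakpoints=len(knot_times),
    )


# ---------------------------------------------------------------------------
# rate and depth statistics
# ---------------------------------------------------------------------------

def max_ingression_rate(
    trace: DepthTrace,
    window: float = 2.0,
    segmentation: PhaseSegmentation | None = None,
    phase: str | None = None,
) -> float:
    """Maximal furrow ingression rate from a rolling window (um/min).

    Maximum over window start positions of ``(depth(t+w) - depth(t)) / w`` on
    the intact-depth trace; depth at ``t+w`` is linearly interpolated when the
    window end falls between samples. With ``phase`` given (and a segmentation),
    windows must lie entirely within that phase segment.
    """
    t, d = trace.times, trace.intact_depth
    if phase is not None:
        if segmentation is None:
            raise ValueError("phase restriction requires a segmentation")
        seg = segmentation.get(phase)
        if seg is None:
            raise ValueError(f"phase {phase!r} absent from segmentation")
        sel = (t >= seg.start - 1e-9) & (t <= seg.end + 1e-9)
        t, d = t[sel], d[sel]
    if len(t) < 2 or t[-1] - t[0] < window - 1e-9:
        raise ValueError("window longer than trace (or than the restricted phase)")
    starts = t[t <= t[-1] - window + 1e-9]
    d_end = np.interp(starts + window, t, d)
    d_start = np.interp(starts, t, d)
    return float(np.max((d_end - d_start) / window))


def average_phase_rate(segmentation: PhaseSegmentation, phase: str) -> float | None:
    """Average rate (depth change / duration) of one phase; ``None`` if absent."""
    seg = segmentation.get(phase)
    if seg is None or seg.duration <= 0:
        return None
    return seg.depth_change / seg.duration


def has_discrete_ingressionII(
    segmentation: PhaseSegmentation,
    min_duration: float = 1.0,
    min_slope: float = 0.3,
) -> bool:
    """True iff a discrete Ingression II segment exists (duration and slope floors)."""
    seg = segmentation.get("IngressionII")
    return seg is not None and seg.duration >= min_duration and seg.slope >= min_slope


def max_depth_and_time(trace: DepthTrace, window: float = 1.0) -> tuple[float, float]:
    """Maximum intact furrow depth and the time it is reached.

    The peak is located on a centered rolling mean (suppressing observation
    noise), then the reported depth/time are the raw maximum within half a
    window of that location, so noiseless tent-shaped peaks are not eroded.
    Ties break to the earliest time.
    """
    t, d = trace.times, trace.intact_depth
    if len(t) == 0:
        raise ValueError("empty trace")
    if len(t) == 1:
        return float(d[0]), float(t[0])
    dt = float(np.median(np.diff(t)))
    half = max(0, int(round(window / (2 * dt))))
    if half > 0:
        kernel = np.ones(2 * half + 1)
        smooth = np.convolve(d, kernel, mode="same") / np.convolve(
            np.ones_like(d), kernel, mode="same"
        )
    else:
        smooth = d
    i0 = int(np.argmax(smooth))
    lo, hi = max(0, i0 - half), min(len(d), i0 + half + 1)
    i = lo + int(np.argmax(d[lo:hi]))
    return float(d[i]), float(t[i])
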