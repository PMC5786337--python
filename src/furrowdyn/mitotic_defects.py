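"""Mitotic-figure tracking, outcome classification, defect rates and density.

Each metaphase figure is tracked through anaphase into the next interphase by
nearest-neighbor linking of segmented chromatin masses. Outcomes follow the
terminal configuration of a figure's two daughter masses:

* ``normal`` — the daughters end in two distinct new nuclei;
* ``adjacent_fusion`` — a daughter ends in a nucleus shared with a *different*
  figure's daughter (failure to separate adjacent mitoses);
* ``mitotic_collapse`` — the figure's own daughters re-merge into one nucleus.

Figures whose daughters cannot be followed to the end of the movie are
``indeterminate`` and excluded from rate denominators (logged in the summary).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops

from .cell_cycle import CellCycleAnnotation

OUTCOMES = ("normal", "adjacent_fusion", "mitotic_collapse")


@dataclass
class MitoticFigureTrack:
    """One mitotic figure's trajectory and terminal assignment."""

    figure_id: int
    origin: tuple[float, float]  # metaphase centroid, um
    daughter_paths: list[list[tuple[float, float]]]  # two centroid paths, um
    terminal_nuclei: tuple[int | None, int | None]  # final-frame mass labels
    frames: tuple[int, int]  # first and last tracked frame index
    outcome: str | None = None
    partner_id: int | None = None
    edge: bool = False


def _segment_masses(img: np.ndarray, pixel_size: float, min_area: float = 0.5):
    """Centroids (um) and labels of chromatin masses in one 2D frame."""
    img = np.asarray(img, float)
    if img.max() <= img.min():
        return np.empty((0, 2)), []
    binary = img > threshold_otsu(img)
    labels = sk_label(binary)
    cents, labs = [], []
    for p in regionprops(labels):
        if p.area * pixel_size**2 < min_area:
            continue
        cents.append((p.centroid[1] * pixel_size, p.centroid[0] * pixel_size))
        labs.append(p.label)
    return np.asarray(cents).reshape(-1, 2), labs


def track_figures(
    hist_movie: np.ndarray,
    annotation: CellCycleAnnotation,
    pixel_size: float,
    frame_interval: float,
    gate: float = 3.0,
    edge_margin: float = 1.0,
) -> list[MitoticFigureTrack]:
    """Track every metaphase figure through mitosis.

    ``hist_movie`` is the histone channel as (T,Z,Y,X) or (T,Y,X). The
    annotation supplies the mitosis window; tracking runs from the last
    metaphase frame to the end of the movie. Daughter masses are linked by
    proximity (``gate`` um per frame step). Figures whose metaphase centroid
    lies within ``edge_margin`` um of the field border are flagged ``edge``.
    """
    meta = annotation.interval("metaphase")
    if meta is None or annotation.interval("anaphase_telophase") is None:
        raise ValueError("annotation has no mitosis window")
    hist = np.asarray(hist_movie)
    if hist.ndim == 4:
        hist = hist.max(axis=1)
    dt_min = frame_interval / 60.0
    i_ana = int(round(annotation.anaphase_onset / dt_min))
    i_meta_last = max(0, i_ana - 1)
    n_frames = hist.shape[0]
    side = hist.shape[-1] * pixel_size

    figure_pos, _ = _segment_masses(hist[i_meta_last], pixel_size)
    if len(figure_pos) == 0:
        raise ValueError("no metaphase figures found")
    if len(figure_pos) > 1:
        diffs = figure_pos[:, None, :] - figure_pos[None, :, :]
        dmat = np.hypot(diffs[..., 0], diffs[..., 1])
        np.fill_diagonal(dmat, np.inf)
        # linking gate must stay below half the figure spacing
        gate = min(gate, 0.45 * float(dmat.min(axis=1).mean()))

    # two daughter cursors per figure, both starting at the figure centroid
    daughters = np.repeat(figure_pos, 2, axis=0).astype(float)  # (2N, 2)
    paths = [[tuple(p)] for p in daughters]
    lost = np.zeros(len(daughters), bool)
    terminal = [None] * len(daughters)
    for fi in range(i_ana, n_frames):
        cents, labs = _segment_masses(hist[fi], pixel_size)
        if len(cents) == 0:
            lost[:] = True
            break
        for nf in range(len(figure_pos)):
            ia, ib = 2 * nf, 2 * nf + 1
            if lost[ia] and lost[ib]:
                continue
            da = np.hypot(*(cents - daughters[ia]).T)
            db = np.hypot(*(cents - daughters[ib]).T)
            near = np.flatnonzero(np.minimum(da, db) <= gate)
            picks: dict[int, int] = {}
            if len(near) >= 2:
                # joint assignment to distinct masses (anaphase separation)
                pairs = [(da[i] + db[j], i, j) for i in near for j in near if i != j
                         if da[i] <= gate and db[j] <= gate]
                if pairs:
                    _, i, j = min(pairs)
                    picks = {ia: i, ib: j}
            if not picks and len(near) >= 1:
                # single reachable mass: both daughters merge onto it
                i = near[int(np.argmin(np.minimum(da, db)[near]))]
                picks = {k: i for k in (ia, ib)
                         if min(da[i] if k == ia else db[i], np.inf) <= gate}
            for di in (ia, ib):
                if lost[di]:
                    continue
                if di not in picks:
                    lost[di] = True
                    continue
                j = picks[di]
                daughters[di] = cents[j]
                paths[di].append(tuple(cents[j]))
                if fi == n_frames - 1:
                    terminal[di] = labs[j]

    tracks = []
    for i, (x, y) in enumerate(figure_pos):
        t0, t1 = terminal[2 * i], terminal[2 * i + 1]
        edge = min(x, y, side - x, side - y) < edge_margin
        tracks.append(
            MitoticFigureTrack(
                figure_id=i,
                origin=(float(x), float(y)),
                daughter_paths=[paths[2 * i], paths[2 * i + 1]],
                terminal_nuclei=(t0, t1),
                frames=(i_meta_last, n_frames - 1),
                edge=edge,
            )
        )
    classify_outcomes(tracks)
    return tracks


def classify_outcomes(tracks: list[MitoticFigureTrack]) -> list[str]:
    """Assign an outcome to every track (in place); returns the labels.

    A terminal nucleus shared between figures means adjacent fusion for each
    of them; a figure whose own daughters share an unshared terminal nucleus
    collapsed; unresolvable tracks are ``indeterminate``.
    """
    owners: dict[int, set[int]] = {}
    for tr in tracks:
        for term in tr.terminal_nuclei:
            if term is not None:
                owners.setdefault(term, set()).add(tr.figure_id)
    for tr in tracks:
        t0, t1 = tr.terminal_nuclei
        if t0 is None or t1 is None:
            tr.outcome = "indeterminate"
            continue
        shared = [term for term in (t0, t1) if len(owners[term]) > 1]
        if shared:
            tr.outcome = "adjacent_fusion"
            others = owners[shared[0]] - {tr.figure_id}
            tr.partner_id = min(others) if others else None
        elif t0 == t1:
            tr.outcome = "mitotic_collapse"
        else:
            tr.outcome = "normal"
    return [tr.outcome for tr in tracks]


def classify_outcome(track: MitoticFigureTrack, tracks: list[MitoticFigureTrack]) -> str:
    """Outcome of one track given the full track set (terminal-sharing rules)."""
    classify_outcomes(tracks)
    return track.outcome


def _classifiable(tracks, include_edge=False):
    return [
        t for t in tracks
        if t.outcome in OUTCOMES and (include_edge or not t.edge)
    ]


def defect_rate(tracks: list[MitoticFigureTrack], include_edge: bool = False) -> float:
    """Percent of classifiable mitoses that are defective.

    Defective = adjacent fusion + mitotic collapse, divided by classifiable
    division events (indeterminate and edge figures excluded).
    """
    ok = _classifiable(tracks, include_edge)
    if not ok:
        raise ValueError("no classifiable tracks")
    n_def = sum(t.outcome != "normal" for t in ok)
    return 100.0 * n_def / len(ok)


def defect_summary(tracks: list[MitoticFigureTrack], include_edge: bool = False) -> dict:
    """Outcome breakdown: counts, defect percent, and the fusion/collapse split."""
    ok = _classifiable(tracks, include_edge)
    n_fus = sum(t.outcome == "adjacent_fusion" for t in ok)
    n_col = sum(t.outcome == "mitotic_collapse" for t in ok)
    n_def = n_fus + n_col
    return {
        "n_total": len(tracks),
        "n_classifiable": len(ok),
        "n_indeterminate": sum(t.outcome == "indeterminate" for t in tracks),
        "n_edge_excluded": sum(t.edge for t in tracks) if not include_edge else 0,
        "n_normal": sum(t.outcome == "normal" for t in ok),
        "n_adjacent_fusion": n_fus,
        "n_mitotic_collapse": n_col,
        "percent_defective": 100.0 * n_def / len(ok) if ok else float("nan"),
        "percent_fusion_of_defects": 100.0 * n_fus / n_def if n_def else float("nan"),
    }


def tracks_to_frame(tracks: list[MitoticFigureTrack]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "figure_id": [t.figure_id for t in tracks],
            "outcome": [t.outcome for t in tracks],
            "partner_id": [t.partner_id for t in tracks],
            "edge": [t.edge for t in tracks],
            "x_um": [t.origin[0] for t in tracks],
            "y_um": [t.origin[1] for t in tracks],
        }
    )


def nuclear_density(positions: np.ndarray, field_area: float) -> float:
    """Interphase nuclei per 1000 um^2 of cortical field."""
    if field_area <= 0:
        raise ValueError("field_area must be positive")
    return 1000.0 * len(np.atleast_2d(np.asarray(positions))) / field_area if np.size(positions) else 0.0
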