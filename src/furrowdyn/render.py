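"""Two-channel 4D movie rendering of syncytial furrow and chromatin dynamics.

Emulates spinning-disk acquisition of the early embryo cortex: ~30 z-slices at
0.5 um spacing, 20-30 s frame intervals, a membrane channel and a histone
channel.

Membrane channel: each nucleus is surrounded by a closed polygonal (circular)
furrow ring. Rings are drawn at every z from the apical reference down to the
current ground-truth furrow depth; below ``fragmentation_depth`` only a partial
arc (``ring_completeness_broken`` of the perimeter) is drawn, reproducing the
"broken furrow" phenotype.

Histone channel: per-nucleus chromatin blobs follow the cell-cycle schedule —
diffuse interphase disc, condensation puncta in prophase, a compact metaphase
plate, two separating anaphase masses, then daughter nuclei. Scheduled
adjacent-fusion and mitotic-collapse events are rendered accordingly.

Camera noise is Poisson-Gaussian (normal approximation of shot noise plus read
noise) on its own RNG sub-stream, so disabling it leaves the kinetic and
defect realizations unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import KineticConfig, hex_spacing
from .simulate import (
    GroundTruth,
    _phase_schedule,
    _rng,
    _STREAM_CAMERA,
    depth_profile,
    nuclear_layout,
    realize_ingressionII,
    schedule_mitoses,
)

_STREAM_RENDER = 61

MEMBRANE_AMP = 180.0
HISTONE_AMP = 110.0
BACKGROUND = 10.0
READ_NOISE = 2.0


@dataclass
class ImageStack:
    """Calibrated (T, C, Z, Y, X) image stack; channel 0 membrane, 1 histone."""

    data: np.ndarray
    pixel_size: float  # um
    z_step: float  # um
    frame_interval: float  # s
    channel_names: tuple[str, ...] = ("membrane", "histone")
    axes: str = "TCZYX"

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def membrane(self) -> np.ndarray:
        return self.data[:, self.channel_names.index("membrane")]

    def histone(self) -> np.ndarray:
        return self.data[:, self.channel_names.index("histone")]

    def calibration(self) -> dict:
        return {
            "pixel_size_um": self.pixel_size,
            "z_step_um": self.z_step,
            "frame_interval_s": self.frame_interval,
        }


def _ring_pixels(cx, cy, r_px, shape, completeness=1.0, phase0=0.0, width=2):
    """Flat pixel indices of a (possibly partial) circular ring."""
    n_pts = max(16, int(np.ceil(2 * np.pi * r_px * 2)))
    span = 2 * np.pi * completeness
    theta = phase0 + np.linspace(0.0, span, max(2, int(n_pts * completeness)), endpoint=False)
    idx = []
    for dr in np.linspace(-(width - 1) / 2.0, (width - 1) / 2.0, width):
        xs = np.round(cx + (r_px + dr) * np.cos(theta)).astype(int)
        ys = np.round(cy + (r_px + dr) * np.sin(theta)).astype(int)
        ok = (xs >= 0) & (xs < shape[1]) & (ys >= 0) & (ys < shape[0])
        idx.append(ys[ok] * shape[1] + xs[ok])
    return np.unique(np.concatenate(idx))


def _add_gaussian(plane, cx, cy, sx, sy, amp, angle=0.0):
    """Accumulate an (optionally rotated, anisotropic) Gaussian blob (px units)."""
    half = int(np.ceil(3.0 * max(sx, sy)))
    x0, x1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
    y0, y1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
    H, W = plane.shape
    xa0, xa1 = max(x0, 0), min(x1, W)
    ya0, ya1 = max(y0, 0), min(y1, H)
    if xa0 >= xa1 or ya0 >= ya1:
        return
    yy, xx = np.mgrid[ya0:ya1, xa0:xa1]
    dx, dy = xx - cx, yy - cy
    if angle:
        c, s = np.cos(angle), np.sin(angle)
        dx, dy = c * dx + s * dy, -s * dx + c * dy
    plane[ya0:ya1, xa0:xa1] += amp * np.exp(-0.5 * ((dx / sx) ** 2 + (dy / sy) ** 2))


def _figure_geometry(events, positions, rng):
    """Per-figure division axis, daughter signs and fusion targets."""
    n = len(positions)
    base = np.pi / 2.0
    angles = base + rng.uniform(-np.pi / 12, np.pi / 12, n)
    fusion_target = {}
    for ev in events:
        if ev.outcome == "adjacent_fusion" and ev.partner_id is not None:
            mid = 0.5 * (positions[ev.figure_id] + positions[ev.partner_id])
            fusion_target[ev.figure_id] = mid
    return angles, fusion_target


def render_movie(
    config: KineticConfig,
    seed: int,
    camera_noise: bool = True,
    extra_frames: int = 3,
) -> tuple[ImageStack, GroundTruth]:
    """Render one embryo cycle as a calibrated two-channel (T,C,Z,Y,X) stack.

    Deterministic for fixed (config, seed). ``extra_frames`` frames past the
    scheduled cycle end show the daughter nuclei of the next interphase (needed
    to call cycle completion and mitosis outcomes).
    """
    config.validate()
    side = float(np.sqrt(config.field_area))
    px = config.pixel_size
    npx = int(round(side / px))
    spacing = hex_spacing(config.nuclear_density)
    r_ring_um = 0.46 * spacing
    if npx < 16 or side < 2.2 * spacing:
        raise ValueError(
            f"field too small for requested density (side {side:.1f} um, "
            f"nucleus spacing {spacing:.1f} um)"
        )

    positions = nuclear_layout(config, seed)
    events = schedule_mitoses(config, seed, positions)
    with_ingII = realize_ingressionII(config, seed)
    rng_r = _rng(seed, _STREAM_RENDER)
    angles, fusion_mid = _figure_geometry(events, positions, rng_r)
    puncta_offsets = rng_r.normal(0.0, 0.55, (len(positions), 6, 2))

    dt_min = config.frame_interval / 60.0
    total = config.total_cycle_time
    n_cycle = int(np.floor(total / dt_min + 1e-9)) + 1
    n_frames = n_cycle + extra_frames
    times = np.arange(n_frames) * dt_min
    depth_t = depth_profile(config, np.minimum(times, total), with_ingII)

    Z = config.n_z
    za = config.apical_z_index
    z_nuc = min(Z - 2, za + int(round(3.0 / config.z_step)))

    # static membrane ring planes; per-nucleus radii capped by the nearest
    # neighbor so rings in one plane never touch (>= ~0.7 um contour gap)
    pos_px = positions / px
    shape = (npx, npx)
    plane_complete = np.zeros(shape, np.float32)
    plane_broken = np.zeros(shape, np.float32)
    if len(positions) > 1:
        diffs = positions[:, None, :] - positions[None, :, :]
        dmat = np.hypot(diffs[..., 0], diffs[..., 1])
        np.fill_diagonal(dmat, np.inf)
        dmin = dmat.min(axis=1)
    else:
        dmin = np.full(len(positions), np.inf)
    radii_um = np.minimum(r_ring_um, 0.5 * dmin - 0.5)
    radii_um = np.maximum(radii_um, 3 * px)
    phase0 = rng_r.uniform(0, 2 * np.pi, len(positions))
    for i, (x, y) in enumerate(pos_px):
        r_px = radii_um[i] / px
        plane_complete.ravel()[_ring_pixels(x, y, r_px, shape)] = MEMBRANE_AMP
        plane_broken.ravel()[
            _ring_pixels(x, y, r_px, shape, config.ring_completeness_broken, phase0[i])
        ] = MEMBRANE_AMP

    t_cond = config.cc_interphase
    t_meta = t_cond + config.cc_prophase
    t_ana = config.anaphase_onset
    ana_dur = max(config.cc_anatelo, 1e-6)
    # daughter separation scaled to the realized neighbor distance so masses
    # from adjacent figures stay resolvable
    min_nn = float(dmin.min()) if np.isfinite(dmin).any() else 10.0
    sep_max = min(2.2, 0.25 * min_nn)
    sep_start = min(1.4, 0.75 * sep_max)
    collapse_off = min(1.2, 0.6 * sep_max)

    data = np.zeros((n_frames, 2, Z, npx, npx), np.float32)
    for ti, t in enumerate(times):
        # ---- membrane ----
        d = depth_t[ti]
        frag = config.fragmentation_depth
        d_complete = d if frag is None else min(d, frag)
        n_complete = int(np.floor(d_complete / config.z_step + 1e-9))
        n_total = int(np.floor(d / config.z_step + 1e-9))
        mem = data[ti, 0]
        for dz in range(0, n_total + 1):
            z = za + dz
            if z >= Z:
                break
            mem[z] = plane_complete if dz <= n_complete else plane_broken
        # ---- histone ----
        hist = np.zeros(shape, np.float32)
        for ev in events:
            i = ev.figure_id
            cx, cy = pos_px[i]
            ax = np.array([np.cos(angles[i]), np.sin(angles[i])])
            if t < t_cond:  # interphase: diffuse disc
                _add_gaussian(hist, cx, cy, 0.9 / px, 0.9 / px, HISTONE_AMP)
            elif t < t_meta:  # prophase: disc + bright condensation puncta
                _add_gaussian(hist, cx, cy, 0.9 / px, 0.9 / px, 0.9 * HISTONE_AMP)
                for ox, oy in puncta_offsets[i]:
                    _add_gaussian(hist, cx + ox / px, cy + oy / px,
                                  0.30 / px, 0.30 / px, 1.5 * HISTONE_AMP)
            elif t < t_ana:  # metaphase: compact plate
                _add_gaussian(hist, cx, cy, 0.7 / px, 0.3 / px,
                              2.2 * HISTONE_AMP, angle=angles[i])
            else:
                prog = min(1.0, (t - t_ana) / ana_dur)
                new_cycle = t >= total
                if ev.outcome == "mitotic_collapse":
                    # separate briefly, then re-merge into one polyploid nucleus
                    off = collapse_off * np.sin(np.pi * min(1.0, prog / 0.8)) * (prog < 0.8)
                    if new_cycle or off < 0.05:
                        sig = (0.8 if new_cycle else 1.0) / px
                        _add_gaussian(hist, cx, cy, sig, sig,
                                      (1.0 if new_cycle else 1.8) * HISTONE_AMP)
                    else:
                        for sgn in (+1, -1):
                            mx, my = (np.array([cx, cy]) + sgn * off * ax / px)
                            _add_gaussian(hist, mx, my, 0.5 / px, 0.5 / px,
                                          2.0 * HISTONE_AMP)
                    continue
                sep = sep_start + (sep_max - sep_start) * min(1.0, prog / 0.6)
                d_pos = [np.array([cx, cy]) + s * sep * ax / px for s in (+1, -1)]
                if ev.outcome == "adjacent_fusion" and i in fusion_mid:
                    # the partner-facing daughter migrates to the pair midpoint
                    mid_px = fusion_mid[i] / px
                    to_partner = mid_px - np.array([cx, cy])
                    j = int(np.argmax([float(np.dot(p - (cx, cy), to_partner)) for p in d_pos]))
                    pull = max(0.0, (prog - 0.6) / 0.4)
                    d_pos[j] = d_pos[j] + pull * (mid_px - d_pos[j])
                for p in d_pos:
                    if new_cycle:
                        # compact daughter nuclei at interphase brightness
                        _add_gaussian(hist, p[0], p[1], 0.7 / px, 0.7 / px, HISTONE_AMP)
                    else:
                        _add_gaussian(hist, p[0], p[1], 0.5 / px, 0.5 / px,
                                      2.0 * HISTONE_AMP)
        for z, w in ((z_nuc - 1, 0.6), (z_nuc, 1.0), (z_nuc + 1, 0.6)):
            data[ti, 1, z] += w * hist

    # Poisson-Gaussian camera noise and quantization, frame by frame to keep
    # peak memory at one (C,Z,Y,X) chunk
    rng_c = _rng(seed, _STREAM_CAMERA)
    out = np.empty(data.shape, np.uint16)
    for ti in range(n_frames):
        fr = data[ti]
        fr += BACKGROUND
        if camera_noise:
            noise = rng_c.standard_normal(fr.shape, dtype=np.float32)
            fr += noise * np.sqrt(fr + READ_NOISE**2, dtype=np.float32)
        np.clip(fr, 0, 65535, out=fr)
        out[ti] = fr
    stack = ImageStack(
        data=out,
        pixel_size=px,
        z_step=config.z_step,
        frame_interval=config.frame_interval,
    )

    bps, labels = _phase_schedule(config, with_ingII)
    gt = GroundTruth(
        rng_seed=int(seed),
        true_breakpoints=[float(b) for b in bps],
        true_phase_labels=labels,
        true_max_depth=float(np.max(depth_t)),
        true_max_depth_time=float(times[int(np.argmax(depth_t))]),
        has_ingressionII=with_ingII,
        cycle_index=config.cycle_index,
        total_cycle_time=total,
        anaphase_onset=t_ana,
        condensation_onset=t_cond,
        metaphase_onset=t_meta,
        mitosis_events=events,
        nuclear_positions=positions,
        fragmentation_depth=config.fragmentation_depth,
        apical_z_index=za,
    )
    return stack, gt
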