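"""Ground-truth kinetic simulation: depth traces, nuclear layouts, mitosis schedules.

The furrow-depth model is piecewise linear within one nuclear cycle: depth rises
at ``ingI_rate`` for ``ingI_duration``, plateaus for ``stab_duration``, optionally
rises again at ``ingII_rate`` for ``ingII_duration`` (present with probability
``ingII_probability``), then falls at ``retraction_rate`` and is clamped at zero.
When Ingression II is absent the plateau is extended by the period that would
normally comprise it, so retraction initiates at the same clock time.

Randomness is split into independent sub-streams (kinetics, defects, camera) so
that e.g. toggling camera noise does not change the kinetic realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import KineticConfig, hex_spacing

# sub-stream ids appended to the user seed
_STREAM_KINETICS = 11
_STREAM_DEFECTS = 23
_STREAM_CAMERA = 37
_STREAM_LAYOUT = 53


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


@dataclass
class DepthTrace:
    """Furrow depth versus time for one embryo and one nuclear cycle.

    ``intact_depth`` is the depth of the deepest z-layer carrying a local patch
    of complete furrow rings; ``deepest_extent`` is the deepest layer with any
    partial furrow signal. Both are in um, positive downward from the apical
    reference; times are minutes from cycle start.
    """

    embryo_id: str
    cycle_index: int
    times: np.ndarray
    intact_depth: np.ndarray
    deepest_extent: np.ndarray
    apical_z: np.ndarray | None = None
    anaphase_onset: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intact_depth = np.asarray(self.intact_depth, dtype=float)
        self.deepest_extent = np.asarray(self.deepest_extent, dtype=float)
        if not (len(self.times) == len(self.intact_depth) == len(self.deepest_extent)):
            raise ValueError("times, intact_depth and deepest_extent must share length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class MitosisEvent:
    figure_id: int
    outcome: str  # normal | adjacent_fusion | mitotic_collapse
    event_time: float  # minutes; anaphase onset of this figure
    partner_id: int | None = None


@dataclass
class GroundTruth:
    """Oracle record for one simulated embryo/cycle (used by recovery tests)."""

    rng_seed: int
    true_breakpoints: list[float]
    true_phase_labels: list[str]
    true_max_depth: float
    true_max_depth_time: float
    has_ingressionII: bool
    cycle_index: int
    total_cycle_time: float
    anaphase_onset: float
    condensation_onset: float
    metaphase_onset: float
    mitosis_events: list[MitosisEvent] = field(default_factory=list)
    nuclear_positions: np.ndarray | None = None  # (N, 2) um
    fragmentation_depth: float | None = None
    apical_z_index: int | None = None


def depth_profile(config: KineticConfig, times: np.ndarray, with_ingII: bool) -> np.ndarray:
    """Noise-free piecewise-linear depth at the given times (minutes)."""
    t = np.asarray(times, dtype=float)
    d1, r1 = config.ingI_duration, config.ingI_rate
    d2 = config.stab_duration
    d3 = config.ingII_duration if with_ingII else 0.0
    r3 = config.ingII_rate if with_ingII else 0.0
    # plateau extended when IngII is skipped so retraction starts on time
    d2_eff = d2 if with_ingII else d2 + config.ingII_duration
    t_peak = d1 + d2_eff + d3
    peak = config.carry_over_depth + d1 * r1 + d3 * r3

    depth = np.empty_like(t)
    depth = config.carry_over_depth + np.minimum(t, d1) * r1
    in_ingII = t > d1 + d2_eff
    depth = np.where(in_ingII, config.carry_over_depth + d1 * r1
                     + np.minimum(t - d1 - d2_eff, d3) * r3, depth)
    if config.retraction_rate is not None:
        falling = t > t_peak
        depth = np.where(falling, peak - (t - t_peak) * config.retraction_rate, depth)
    return np.maximum(depth, 0.0)


def realize_ingressionII(config: KineticConfig, seed: int) -> bool:
    """Bernoulli draw for Ingression II presence (kinetics sub-stream).

    Shared by the trace simulator and the movie renderer so that, for a given
    seed, both realize the same kinetic schedule.
    """
    if config.ingII_duration <= 0 or config.ingII_probability <= 0.0:
        return False
    if config.ingII_probability >= 1.0:
        return True
    rng_k = _rng(seed, _STREAM_KINETICS)
    return bool(rng_k.random() < config.ingII_probability)


def _phase_schedule(config: KineticConfig, with_ingII: bool) -> tuple[list[float], list[str]]:
    d1 = config.ingI_duration
    d2_eff = config.stab_duration + (0.0 if with_ingII else config.ingII_duration)
    labels = ["IngressionI", "Stabilization"]
    bps = [d1, d1 + d2_eff]
    if with_ingII and config.ingII_duration > 0:
        labels.append("IngressionII")
        bps.append(bps[-1] + config.ingII_duration)
    if config.retraction_rate is not None and config.total_cycle_time > bps[-1]:
        labels.append("Retraction")
    else:
        bps.pop()  # trace ends at the last ingression/stabilization boundary
    return bps, labels


def simulate_depth_trace(
    config: KineticConfig, seed: int, embryo_id: str | None = None
) -> tuple[DepthTrace, GroundTruth]:
    """Simulate one noisy depth trace and its ground truth.

    The trace is sampled at ``config.frame_interval`` starting at cycle time 0.
    Additive Gaussian observation noise of sd ``config.depth_noise_sd`` is
    applied; with sd 0 the trace equals the closed-form piecewise model exactly.
    Deterministic for fixed (config, seed).
    """
    config.validate()
    dt_min = config.frame_interval / 60.0
    n = int(np.floor(config.total_cycle_time / dt_min + 1e-9)) + 1
    times = np.arange(n) * dt_min
    with_ingII = realize_ingressionII(config, seed)

    full = depth_profile(config, times, with_ingII)
    if config.fragmentation_depth is not None:
        intact_clean = np.minimum(full, config.fragmentation_depth)
    else:
        intact_clean = full
    deepest_clean = full

    rng_n = _rng(seed, _STREAM_CAMERA)
    if config.depth_noise_sd > 0:
        noise_i = rng_n.normal(0.0, config.depth_noise_sd, n)
        noise_d = rng_n.normal(0.0, config.depth_noise_sd, n)
        intact = intact_clean + noise_i
        deepest = np.maximum(deepest_clean + noise_d, intact)
    else:
        intact = intact_clean
        deepest = deepest_clean

    bps, labels = _phase_schedule(config, with_ingII)
    gt = GroundTruth(
        rng_seed=int(seed),
        true_breakpoints=[float(b) for b in bps],
        true_phase_labels=labels,
        true_max_depth=float(np.max(deepest_clean)),
        true_max_depth_time=float(times[int(np.argmax(deepest_clean))]),
        has_ingressionII=with_ingII,
        cycle_index=config.cycle_index,
        total_cycle_time=config.total_cycle_time,
        anaphase_onset=config.anaphase_onset,
        condensation_onset=config.cc_interphase,
        metaphase_onset=config.cc_interphase + config.cc_prophase,
        fragmentation_depth=config.fragmentation_depth,
    )
    trace = DepthTrace(
        embryo_id=embryo_id or f"sim-{config.genotype}-c{config.cycle_index}-s{seed}",
        cycle_index=config.cycle_index,
        times=times,
        intact_depth=intact,
        deepest_extent=deepest,
        anaphase_onset=config.anaphase_onset,
    )
    return trace, gt


# ---------------------------------------------------------------------------
# nuclear layouts and mitosis schedules
# ---------------------------------------------------------------------------

def nuclear_layout(config: KineticConfig, seed: int, margin: float | None = None) -> np.ndarray:
    """Jittered hexagonal nuclear positions (um) inside the square field.

    Spacing follows ``config.nuclear_density``; positions are inset from the
    field border by ``margin`` (default: 55% of the spacing) so that rendered
    furrow rings stay inside the field.
    """
    rng = _rng(seed, _STREAM_LAYOUT)
    side = float(np.sqrt(config.field_area))
    s0 = hex_spacing(config.nuclear_density)
    n_target = config.nuclear_density * config.field_area / 1000.0

    def lattice(s: float, m: float) -> list[tuple[float, float]]:
        pts = []
        row_h = s * np.sqrt(3.0) / 2.0
        j = 0
        y = m
        while y <= side - m + 1e-9:
            x = m + (s / 2.0 if j % 2 else 0.0)
            while x <= side - m + 1e-9:
                pts.append((x, y))
                x += s
            y += row_h
            j += 1
        return pts

    # shrink the spacing until the count over the inset region realizes the
    # requested whole-field density (rendered rings must not clip the border)
    s = s0
    pts = []
    for _ in range(8):
        m = margin if margin is not None else 0.55 * s
        if side - 2 * m <= 0:
            break
        pts = lattice(s, m)
        if not pts:
            break
        if abs(len(pts) - n_target) <= max(1.0, 0.06 * n_target):
            break
        s = float(np.clip(s * np.sqrt(len(pts) / n_target), 0.25 * s0, s0))
        if s <= 0.25 * s0 + 1e-9 and len(pts) < n_target:
            break
    pos = np.asarray(pts, dtype=float).reshape(-1, 2)
    if len(pos) == 0:
        raise ValueError(
            f"field too small for requested density (side {side:.1f} um, spacing {s0:.1f} um)"
        )
    # bounded jitter keeps neighboring furrow rings from touching when rendered
    pos += rng.uniform(-0.03 * s, 0.03 * s, pos.shape)
    return pos


def schedule_mitoses(
    config: KineticConfig,
    seed: int,
    positions: np.ndarray | None = None,
) -> list[MitosisEvent]:
    """Assign a mitosis outcome to every nucleus in the field.

    Adjacent-fusion events are drawn as spatial neighbor *pairs* (both partners
    labeled ``adjacent_fusion``) so the fraction of nuclei with a fusion outcome
    is ``p_adjacent_fusion``; ``mitotic_collapse`` is drawn on the remaining
    nuclei at a rate that makes the overall defective fraction equal
    ``p_adjacent_fusion + p_collapse``.
    """
    config.validate()
    if positions is None:
        positions = nuclear_layout(config, seed)
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n < 2 and config.p_adjacent_fusion > 0:
        raise ValueError("adjacent fusion requires at least 2 nuclei in the field")

    rng = _rng(seed, _STREAM_DEFECTS)
    t_ana = config.anaphase_onset
    outcomes = np.array(["normal"] * n, dtype=object)
    partners: dict[int, int] = {}

    p_f, p_c = config.p_adjacent_fusion, config.p_collapse
    if p_f > 0:
        n_pairs = rng.binomial(n // 2, p_f)
        free = set(range(n))
        order = rng.permutation(n)
        made = 0
        for i in order:
            if made >= n_pairs:
                break
            if i not in free:
                continue
            others = [k for k in free if k != i]
            if not others:
                break
            d = np.linalg.norm(positions[others] - positions[i], axis=1)
            j = others[int(np.argmin(d))]
            outcomes[i] = outcomes[j] = "adjacent_fusion"
            partners[i], partners[j] = j, i
            free.discard(i)
            free.discard(j)
            made += 1
    if p_c > 0:
        p_c_eff = min(1.0, p_c / max(1e-12, 1.0 - p_f))
        for i in range(n):
            if outcomes[i] == "normal" and rng.random() < p_c_eff:
                outcomes[i] = "mitotic_collapse"

    return [
        MitosisEvent(figure_id=i, outcome=str(outcomes[i]), event_time=t_ana,
                     partner_id=partners.get(i))
        for i in range(n)
    ]
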