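"""Per-cycle kinetic parameter sets driving simulation and serving as recovery targets.

A :class:`KineticConfig` holds everything needed to simulate one nuclear cycle of
syncytial furrow dynamics in the early *Drosophila* embryo: the piecewise-linear
furrow kinetics (Ingression I -> Stabilization -> optional Ingression II ->
Retraction), the cell-cycle phase schedule used by the histone-channel renderer,
the nuclear layout density, and the mitotic-defect probabilities.

Presets for the genotypes characterized in the source study are transcribed from
the published numbers where printed; values the study does not print are filled
with documented defaults and flagged in ``inferred``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

PHASES = ("IngressionI", "Stabilization", "IngressionII", "Retraction")
CC_PHASES = ("interphase", "prophase", "metaphase", "anaphase_telophase")

GENOTYPES = (
    "WT",
    "alpha_amanitin",
    "zelda",
    "mei41",
    "aneuploid_X",
    "nullo_Df",
    "aneuploid_2L",
    "aneuploid_2R",
    "aneuploid_3L",
    "aneuploid_3R",
    "smg",
)


@dataclass
class KineticConfig:
    """Ground-truth parameters for one genotype x nuclear cycle.

    Durations are in minutes, rates in um/min, depths in um, areas in um^2.
    ``retraction_rate`` is stored as a positive magnitude; depth decreases at
    that rate during retraction and is clamped at zero. For cycle-14
    (cellularization) presets retraction is absent and ``retraction_rate`` is
    ``None``.
    """

    cycle_index: int
    genotype: str = "WT"
    # furrow kinetics
    ingI_duration: float = 2.5
    ingI_rate: float = 0.6
    stab_duration: float = 3.5
    ingII_probability: float = 0.0
    ingII_duration: float = 0.0
    ingII_rate: float = 0.0
    retraction_rate: float | None = 0.8
    carry_over_depth: float = 0.0
    # cell-cycle phase schedule (sums to the total cycle time)
    cc_interphase: float = 3.0
    cc_prophase: float = 1.5
    cc_metaphase: float = 1.5
    cc_anatelo: float = 1.8
    # noise / sampling
    depth_noise_sd: float = 0.3
    frame_interval: float = 20.0  # seconds
    z_step: float = 0.5  # um
    # field geometry and nuclei
    field_area: float = 3600.0  # um^2 (60 x 60 field)
    nuclear_density: float = 2.3  # nuclei per 1000 um^2
    # mitotic defects
    p_adjacent_fusion: float = 0.0
    p_collapse: float = 0.0
    # broken-furrow rendering
    fragmentation_depth: float | None = None
    ring_completeness_broken: float = 0.5
    # rendering geometry
    pixel_size: float = 0.25  # um
    n_z: int = 32
    apical_z_index: int = 4
    # bookkeeping: which fields were not printed in the study and are defaults
    inferred: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def total_cycle_time(self) -> float:
        """Total cycle time in minutes (sum of the cell-cycle phase durations)."""
        return self.cc_interphase + self.cc_prophase + self.cc_metaphase + self.cc_anatelo

    @property
    def anaphase_onset(self) -> float:
        return self.cc_interphase + self.cc_prophase + self.cc_metaphase

    def peak_depth(self, with_ingII: bool = True) -> float:
        d = self.carry_over_depth + self.ingI_duration * self.ingI_rate
        if with_ingII:
            d += self.ingII_duration * self.ingII_rate
        return d

    def peak_time(self, with_ingII: bool = True) -> float:
        t = self.ingI_duration + self.stab_duration
        if with_ingII:
            t += self.ingII_duration
        else:
            # without Ingression II the stabilization plateau is extended by the
            # period that would normally comprise it; retraction starts on time
            t += self.ingII_duration
        return t

    def n_nuclei(self) -> int:
        return max(1, round(self.nuclear_density * self.field_area / 1000.0))

    def validate(self) -> None:
        durations = {
            "ingI_duration": self.ingI_duration,
            "stab_duration": self.stab_duration,
            "ingII_duration": self.ingII_duration,
            "cc_interphase": self.cc_interphase,
            "cc_prophase": self.cc_prophase,
            "cc_metaphase": self.cc_metaphase,
            "cc_anatelo": self.cc_anatelo,
        }
        for name, v in durations.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        rates = {"ingI_rate": self.ingI_rate, "ingII_rate": self.ingII_rate}
        if self.retraction_rate is not None:
            rates["retraction_rate"] = self.retraction_rate
        for name, v in rates.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name in ("ingII_probability", "p_adjacent_fusion", "p_collapse"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.ring_completeness_broken < 1.0:
            raise ValueError("ring_completeness_broken must be in [0, 1)")
        if self.depth_noise_sd < 0:
            raise ValueError("depth_noise_sd must be >= 0")
        if self.frame_interval <= 0 or self.z_step <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval, z_step and pixel_size must be > 0")
        if self.field_area <= 0 or self.nuclear_density < 0:
            raise ValueError("field_area must be > 0 and nuclear_density >= 0")
        if self.cycle_index not in range(10, 15):
            raise ValueError(f"cycle_index must be in 10..14, got {self.cycle_index}")


def _wt_configs() -> dict[int, KineticConfig]:
    """Wild-type presets, cycles 10-14.

    Printed anchors: IngI 2.5 min (c10) / 3.6 min (c11); IngII 2.0 min (c12,
    58% of embryos) / 6.2 min (c13, contributing 4.3 um); Stabilization ~3.5 min
    (c10-12) / 5.1 min (c13); maximal depths ~1.5 / ~3.5 / ~5.5 / 8 um for
    c10-13 and ~28 um at c14; depth peak at 13.7 min in c13; total c13 time
    18.8 min; fast/slow phase maximal-rate ratio 2.4 at c14; interphase nuclear
    densities 2.3 (c10), 15.4 (c13), 29.8 (c14) per 1000 um^2.
    """
    cfgs = {}
    cfgs[10] = KineticConfig(
        cycle_index=10,
        ingI_duration=2.5, ingI_rate=0.6,  # -> 1.5 um
        stab_duration=3.5,
        ingII_probability=0.0, ingII_duration=0.0, ingII_rate=0.0,
        retraction_rate=1.5 / 1.8,
        cc_interphase=3.0, cc_prophase=1.5, cc_metaphase=1.5, cc_anatelo=1.8,
        nuclear_density=2.3,
        inferred=frozenset({"cc_interphase", "cc_prophase", "cc_metaphase", "cc_anatelo"}),
    )
    cfgs[11] = KineticConfig(
        cycle_index=11,
        ingI_duration=3.6, ingI_rate=3.5 / 3.6,  # -> 3.5 um
        stab_duration=3.5,
        ingII_probability=0.0, ingII_duration=0.0, ingII_rate=0.0,
        retraction_rate=3.5 / 2.4,
        cc_interphase=3.6, cc_prophase=1.5, cc_metaphase=2.0, cc_anatelo=2.4,
        nuclear_density=4.4,
        inferred=frozenset(
            {"cc_interphase", "cc_prophase", "cc_metaphase", "cc_anatelo", "nuclear_density"}
        ),
    )
    cfgs[12] = KineticConfig(
        cycle_index=12,
        ingI_duration=3.6, ingI_rate=1.0,  # -> 3.6 um
        stab_duration=3.5,
        ingII_probability=0.58, ingII_duration=2.0, ingII_rate=0.95,  # -> +1.9 um
        retraction_rate=5.5 / 3.4,
        cc_interphase=4.6, cc_prophase=2.0, cc_metaphase=2.5, cc_anatelo=3.4,
        nuclear_density=8.2,
        inferred=frozenset(
            {"cc_interphase", "cc_prophase", "cc_metaphase", "cc_anatelo", "nuclear_density"}
        ),
    )
    cfgs[13] = KineticConfig(
        cycle_index=13,
        # peak at 13.7 min fixes IngI duration: 13.7 - 5.1 - 6.2 = 2.4 min
        ingI_duration=2.4, ingI_rate=3.7 / 2.4,  # -> 3.7 um
        stab_duration=5.1,
        ingII_probability=1.0, ingII_duration=6.2, ingII_rate=4.3 / 6.2,  # -> +4.3 um
        retraction_rate=8.0 / 5.1,
        cc_interphase=7.5, cc_prophase=3.2, cc_metaphase=3.0, cc_anatelo=5.1,
        nuclear_density=15.4,
        inferred=frozenset({"ingI_duration", "cc_interphase", "cc_prophase", "cc_metaphase"}),
    )
    cfgs[14] = KineticConfig(
        cycle_index=14,
        # cellularization: slow phase then fast phase, 2.4x maximal-rate ratio,
        # ~28 um total; no stabilization plateau and no retraction
        ingI_duration=33.0, ingI_rate=0.3,  # slow phase, -> 9.9 um
        stab_duration=0.0,
        ingII_probability=1.0, ingII_duration=25.0, ingII_rate=0.72,  # fast, -> +18 um
        retraction_rate=None,
        cc_interphase=58.0, cc_prophase=0.0, cc_metaphase=0.0, cc_anatelo=0.0,
        frame_interval=30.0,
        nuclear_density=29.8,
        inferred=frozenset({"ingI_duration", "ingII_duration", "cc_interphase"}),
    )
    return cfgs


def _cycle13_variant(**kw) -> KineticConfig:
    base = _wt_configs()[13]
    inferred = kw.pop("inferred", frozenset())
    return replace(base, inferred=frozenset(inferred), **kw)


def default_configs(genotype_name: str) -> dict[int, KineticConfig]:
    """Return the per-cycle presets for one genotype.

    Parameters
    ----------
    genotype_name:
        One of ``WT, alpha_amanitin, zelda, mei41, aneuploid_X, nullo_Df,
        aneuploid_2L, aneuploid_2R, aneuploid_3L, aneuploid_3R, smg``.

    Returns
    -------
    dict mapping cycle index to :class:`KineticConfig`. WT covers cycles
    10-14; perturbed genotypes carry at least the cycle-13 preset (the cycle
    on which the study quantifies them).
    """
    if genotype_name not in GENOTYPES:
        raise ValueError(
            f"unknown genotype {genotype_name!r}; valid names: {', '.join(GENOTYPES)}"
        )
    wt = _wt_configs()
    for c in wt.values():
        c.genotype = "WT"
    if genotype_name == "WT":
        # WT mitotic defects are near zero (not printed; inferred small)
        wt[13] = replace(
            wt[13], p_adjacent_fusion=0.003, p_collapse=0.001,
            inferred=wt[13].inferred | {"p_adjacent_fusion", "p_collapse"},
        )
        return wt

    if genotype_name == "alpha_amanitin":
        # IngII ablated; furrows reach only 3 um; stabilization extended by the
        # period that would comprise IngII; total cycle time 22.2 min with the
        # extra time in metaphase; defects 47.1% (fusion share inferred 90%)
        c13 = _cycle13_variant(
            genotype="alpha_amanitin",
            ingI_duration=2.4, ingI_rate=3.0 / 2.4,
            stab_duration=5.1 + 6.2,
            ingII_probability=0.0, ingII_duration=0.0, ingII_rate=0.0,
            retraction_rate=3.0 / 8.5,
            cc_interphase=7.5, cc_prophase=3.2, cc_metaphase=6.4, cc_anatelo=5.1,
            p_adjacent_fusion=0.471 * 0.9, p_collapse=0.471 * 0.1,
            inferred={"ingI_duration", "cc_interphase", "cc_prophase",
                      "cc_metaphase", "p_adjacent_fusion", "p_collapse"},
        )
        return {13: c13}

    if genotype_name == "zelda":
        # IngII almost entirely lost; furrows ~4 um; total cycle 19.0 min with
        # shortened interphase; 16.2% defective, ~95% adjacent fusions
        c13 = _cycle13_variant(
            genotype="zelda",
            ingI_duration=2.4, ingI_rate=4.0 / 2.4,
            stab_duration=5.1 + 6.2,
            ingII_probability=0.0, ingII_duration=0.0, ingII_rate=0.0,
            retraction_rate=4.0 / 5.3,
            cc_interphase=6.5, cc_prophase=3.2, cc_metaphase=4.0, cc_anatelo=5.3,
            p_adjacent_fusion=0.15, p_collapse=0.012,
            inferred={"ingI_duration", "cc_interphase", "cc_prophase", "cc_metaphase"},
        )
        return {13: c13}

    if genotype_name == "mei41":
        # checkpoint mutant: depth peaks at 8.9 min, reaches only 5 um, short
        # unstable stabilization, shortened total cycle
        c13 = _cycle13_variant(
            genotype="mei41",
            ingI_duration=2.4, ingI_rate=3.0 / 2.4,
            stab_duration=1.5,
            ingII_probability=1.0, ingII_duration=5.0, ingII_rate=0.4,
            retraction_rate=5.0 / 4.1,
            cc_interphase=5.0, cc_prophase=2.2, cc_metaphase=1.7, cc_anatelo=4.1,
            inferred={"ingI_duration", "stab_duration", "ingII_duration", "ingII_rate",
                      "cc_interphase", "cc_prophase", "cc_metaphase", "cc_anatelo"},
        )
        return {13: c13}

    if genotype_name in ("aneuploid_X", "nullo_Df"):
        # broken-furrow genotypes: intact rings plateau at ~4 um while
        # fragmented furrows extend to ~7 um; defects 7.6% / 4.5%
        p_def = 0.076 if genotype_name == "aneuploid_X" else 0.045
        c13 = _cycle13_variant(
            genotype=genotype_name,
            ingI_duration=4.0, ingI_rate=1.0,
            stab_duration=5.1,
            ingII_probability=1.0, ingII_duration=3.0, ingII_rate=1.0,  # deepest -> 7 um
            retraction_rate=7.0 / 6.7,
            fragmentation_depth=4.0, ring_completeness_broken=0.5,
            p_adjacent_fusion=p_def * 0.92, p_collapse=p_def * 0.08,
            inferred={"ingI_duration", "ingI_rate", "ingII_duration", "ingII_rate",
                      "p_adjacent_fusion", "p_collapse"},
        )
        return {13: c13}

    if genotype_name == "aneuploid_2L":
        c13 = _cycle13_variant(
            genotype="aneuploid_2L",
            ingI_duration=3.6, ingI_rate=1.0,
            stab_duration=5.1,
            ingII_probability=1.0, ingII_duration=2.0, ingII_rate=0.3,  # deeply reduced
            retraction_rate=4.2 / 8.1,
            p_adjacent_fusion=0.11, p_collapse=0.01,
            inferred={"ingI_duration", "ingII_duration", "ingII_rate",
                      "p_adjacent_fusion", "p_collapse"},
        )
        return {13: c13}

    if genotype_name == "aneuploid_2R":
        c13 = _cycle13_variant(
            genotype="aneuploid_2R",
            p_adjacent_fusion=0.009, p_collapse=0.001,
            inferred={"p_adjacent_fusion", "p_collapse"},
        )
        return {13: c13}

    if genotype_name in ("aneuploid_3L", "aneuploid_3R"):
        # slight deepening through increased IngII rates
        c13 = _cycle13_variant(
            genotype=genotype_name,
            ingII_rate=(4.3 / 6.2) * 1.15,
            retraction_rate=(3.7 + 4.3 * 1.15) / 5.1,
            inferred={"ingII_rate"},
        )
        return {13: c13}

    if genotype_name == "smg":
        # maternal-clearance mutant: WT-like dynamics, furrows ~1 um deeper
        c13 = _cycle13_variant(
            genotype="smg",
            ingI_rate=4.7 / 2.4,
            retraction_rate=9.0 / 5.1,
            inferred={"ingI_rate"},
        )
        return {13: c13}

    raise AssertionError("unreachable")


def hex_spacing(density_per_1000um2: float) -> float:
    """Center-to-center spacing (um) of a hexagonal layout at the given density."""
    per_um2 = density_per_1000um2 / 1000.0
    return math.sqrt(2.0 / (math.sqrt(3.0) * per_um2))
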