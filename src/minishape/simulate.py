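"""Seeded synthetic data with the statistical structure the pipeline assumes.

Real inputs to this pipeline come from capillary-electrophoresis SHAPE
experiments and LC-MS runs that cannot be redistributed here.  This module
generates stand-ins with the same shape: paired-low / loop-high reactivity
over a dot-bracket structure, replicate noise and additive background,
predicted profiles correlated with experimental ones at a chosen level,
planted differential outliers and footprint protections, and Gaussian
chromatographic peaks at stated m/z values.  Every generator takes a seed
and routes all randomness through one ``numpy.random.Generator``, so equal
seeds give byte-identical outputs.  Each generator also returns the ground
truth recorded *before* noise, for parameter-recovery tests.

The module additionally provides a synthetic numbered source sequence that
emulates the 23S rRNA domain-V region: the catalytically important motifs
(P-loop ``UGGGGCG`` at 2249-2255, A-loop ``UGUUC`` at 2552-2556, the
junction pentamers, GC-rich termini) and the wild-type base of every
catalogued design mutation are planted at their native positions, with
random bases elsewhere.  It is a synthetic stand-in, not the biological
sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .compare import DifferentialProfile
from .construct import (
    Construct,
    NumberedSequence,
    PTC_JUNCTIONS,
    PTC_SEGMENTS,
    add_reference_flanks,
    assemble_construct,
)
from .errors import SpecificationError, StructureError
from .mutations import design_catalog
from .footprint import PeakRecord
from .reactivity import MISSING, RawMeasurement, ReactivityProfile, parse_dotbracket


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a synthetic SHAPE experiment.

    Defaults mirror the experimental design the pipeline targets: three
    modification replicates against two no-modification controls, paired
    positions drawn from a half-normal law (scale 0.15 reactivity units),
    unpaired positions from a gamma law with mean 1.2, modest replicate
    noise and additive background.
    """

    seed: int
    structure: str
    paired_law: tuple[str, dict] = ("halfnorm", {"scale": 0.15})
    unpaired_law: tuple[str, dict] = ("gamma", {"shape": 4.0, "scale": 0.3})
    replicate_noise_sd: float = 0.1
    background_level: float = 0.2
    n_mod: int = 3
    n_control: int = 2


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth recorded before noise; consumed only by tests."""

    true_reactivities: np.ndarray | None = None
    true_rho: float | None = None
    true_outliers: tuple[object, ...] = ()
    true_protected: tuple[object, ...] = ()
    true_enhanced: tuple[object, ...] = ()
    true_peak_areas: tuple[tuple[float, float], ...] = ()  # (mz, area)


def _draw_law(rng: np.random.Generator, law: tuple[str, dict], size: int) -> np.ndarray:
    name, params = law
    if name == "halfnorm":
        return np.abs(rng.normal(0.0, params["scale"], size))
    if name == "gamma":
        return rng.gamma(params["shape"], params["scale"], size)
    if name == "uniform":
        return rng.uniform(params.get("low", 0.0), params.get("high", 1.0), size)
    raise SpecificationError(f"unknown reactivity law {name!r}")


def simulate_reactivity_profiles(
    spec: SimulationSpec,
) -> tuple[list[RawMeasurement], list[RawMeasurement], SimulationTruth]:
    """Draw true reactivities from the structure and emit noisy replicates.

    Paired positions (those with a dot-bracket partner) draw from the paired
    law, unpaired from the unpaired law.  Each modification replicate is
    ``truth + background + N(0, noise_sd)`` and each control replicate is
    ``background + N(0, noise_sd)``, both clipped at zero (band intensities
    are non-negative).  In the noiseless, zero-background limit the
    background-subtraction stage recovers the truth exactly.
    """
    partner = parse_dotbracket(spec.structure)  # validates the structure
    n = len(spec.structure)
    rng = np.random.default_rng(spec.seed)
    paired_mask = np.array([p is not None for p in partner])

    truth = np.empty(n)
    truth[paired_mask] = _draw_law(rng, spec.paired_law, int(paired_mask.sum()))
    truth[~paired_mask] = _draw_law(rng, spec.unpaired_law, int((~paired_mask).sum()))

    def _replicate(base: np.ndarray, rid: str, condition: str) -> RawMeasurement:
        noisy = base + spec.background_level + rng.normal(
            0.0, spec.replicate_noise_sd, n
        ) if spec.replicate_noise_sd > 0 else base + spec.background_level
        return RawMeasurement(np.clip(noisy, 0.0, None), condition, rid)

    mods = [_replicate(truth, f"mod{i+1}", "modified") for i in range(spec.n_mod)]
    controls = [
        _replicate(np.zeros(n), f"ctl{i+1}", "control") for i in range(spec.n_control)
    ]
    return mods, controls, SimulationTruth(true_reactivities=truth.copy())


def simulate_profile_pair(
    n: int, target_rho: float, seed: int
) -> tuple[ReactivityProfile, ReactivityProfile, SimulationTruth]:
    """A unit-scaled experimental/predicted profile pair at a set correlation.

    The pair is drawn from a bivariate normal with population correlation
    ``target_rho`` and each margin is min-max rescaled to [0, 1]; the rescale
    is affine and monotone, so the Pearson correlation is preserved exactly.
    """
    if n < 10:
        raise SpecificationError(f"need n >= 10, got {n}")
    if not -1.0 <= target_rho <= 1.0:
        raise SpecificationError("target_rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    z1 = rng.normal(size=n)
    z2 = rng.normal(size=n)
    x = z1
    y = target_rho * z1 + np.sqrt(max(0.0, 1.0 - target_rho**2)) * z2

    def _unit(v: np.ndarray) -> np.ndarray:
        lo, hi = v.min(), v.max()
        return (v - lo) / (hi - lo)

    exp = ReactivityProfile(_unit(x), state="unit_scaled", name="experimental")
    pred = ReactivityProfile(_unit(y), state="unit_scaled", name="predicted")
    return exp, pred, SimulationTruth(true_rho=target_rho)


def plant_outliers(
    deltas: DifferentialProfile,
    plan: Sequence[tuple[int, float, str]],
) -> tuple[DifferentialProfile, SimulationTruth]:
    """Overwrite chosen delta positions with extreme values.

    ``plan`` entries are ``(position, magnitude, sign)`` with 1-based
    positions and sign in {'high', 'low'}; the planted delta is
    ``+magnitude`` or ``-magnitude``.  A magnitude that does not clear the
    current 3x-IQR fences is planted anyway but triggers a warning, since it
    is unrecoverable by definition.
    """
    from .compare import iqr_outliers  # local import avoids a cycle

    values = deltas.deltas.copy()
    if not plan:
        return deltas, SimulationTruth()
    fences = iqr_outliers(deltas, multiplier=3.0)
    planted: list[object] = []
    for pos, magnitude, sign in plan:
        if not 1 <= pos <= len(values):
            raise SpecificationError(f"planted position {pos} outside profile")
        if sign not in ("high", "low"):
            raise SpecificationError(f"sign must be high|low, got {sign!r}")
        value = magnitude if sign == "high" else -magnitude
        if fences.lower_fence <= value <= fences.upper_fence:
            warnings.warn(
                f"planted delta {value:+.3f} at position {pos} lies inside the "
                f"3xIQR fences [{fences.lower_fence:.3f}, {fences.upper_fence:.3f}] "
                "and will not be recoverable",
                stacklevel=2,
            )
        values[pos - 1] = value
        planted.append(deltas.label_at(pos))
    return (
        DifferentialProfile(values, labels=deltas.labels),
        SimulationTruth(true_outliers=tuple(planted)),
    )


def simulate_footprint(
    profile: ReactivityProfile,
    protections: Sequence[tuple[int, float]],
    seed: int,
    noise_sd: float = 0.0,
) -> tuple[ReactivityProfile, SimulationTruth]:
    """Synthesize a ligand-bound profile from a free one.

    ``protections`` lists ``(position, effect)`` with 1-based positions;
    negative effects are protections, positive ones enhancements (flagged in
    the truth accordingly).  Gaussian noise of the given SD is added at every
    position; with no protections and no noise the bound profile equals the
    free one.
    """
    rng = np.random.default_rng(seed)
    values = profile.values.copy()
    mask = profile.mask
    protected: list[object] = []
    enhanced: list[object] = []
    for pos, effect in protections:
        if not 1 <= pos <= len(values):
            raise SpecificationError(f"protection position {pos} outside profile")
        if values[pos - 1] == MISSING:
            raise SpecificationError(f"protection planted at missing position {pos}")
        values[pos - 1] += effect
        (protected if effect < 0 else enhanced).append(pos)
    if noise_sd > 0:
        values[mask] += rng.normal(0.0, noise_sd, int(mask.sum()))
    bound = ReactivityProfile(
        values, profile.errors.copy(), state=profile.state, name=profile.name + "+ligand"
    )
    return bound, SimulationTruth(
        true_protected=tuple(protected), true_enhanced=tuple(enhanced)
    )


def simulate_chromatogram(
    peak_specs: Sequence[tuple[float, float, float, float]],
    rt_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[PeakRecord], SimulationTruth]:
    """Gaussian chromatographic peaks sampled on a retention-time grid.

    ``peak_specs`` entries are ``(mz, rt_center, area, width)``; each peak
    contributes records at its m/z with intensity
    ``area * N(rt; center, width)`` plus non-negative baseline noise.  True
    areas are recorded in the truth.
    """
    rng = np.random.default_rng(seed)
    rt = np.asarray(rt_grid, dtype=float)
    records: list[PeakRecord] = []
    areas = []
    for mz, center, area, width in peak_specs:
        if width <= 0:
            raise SpecificationError(f"peak width must be > 0, got {width}")
        intensity = area * np.exp(-0.5 * ((rt - center) / width) ** 2) / (
            width * np.sqrt(2 * np.pi)
        )
        if noise_sd > 0:
            intensity = np.clip(intensity + rng.normal(0.0, noise_sd, rt.size), 0, None)
        records.extend(
            PeakRecord(mz=mz, rt=float(t), intensity=float(v))
            for t, v in zip(rt, intensity)
        )
        areas.append((mz, area))
    return records, SimulationTruth(true_peak_areas=tuple(areas))


# ---------------------------------------------------------------------------
# synthetic source sequence and flanks for the minimized-PTC worked example

#: motifs planted at their native 23S positions (synthetic source)
_PLANTED_MOTIFS: tuple[tuple[int, str], ...] = (
    (2249, "UGGGGCG"),  # P-loop
    (2552, "UGUUC"),  # A-loop
    (2254, "CGGUC"),  # 3' end of H80 joined to the central-loop arm
    (2426, "ACGGA"),  # loop receiving the direct join
    (2043, "CGGG"),  # GC-rich 5' terminus (first base fixed by the catalog)
    (2622, "CCCG"),  # GC-rich 3' terminus (last base fixed by the catalog)
)

SOURCE_FIRST_LABEL = 2043
SOURCE_LAST_LABEL = 2625

#: synthetic reference-hairpin flanks (73 nt total) with GAGUA loops;
#: designed stand-ins, not the experimental flank sequences
FLANK_5 = "GGAACAAACAAC" + "GCAGCC" + "GAGUA" + "GGCUGC" + "AACAAC"  # 35 nt
FLANK_3 = "AACAAC" + "GCUGCC" + "GAGUA" + "GGCAGC" + "AAACAACAACAAACG"  # 38 nt
FLANK_5_LOOP = tuple(range(19, 24))  # GAGUA positions within FLANK_5
FLANK_3_LOOP = tuple(range(13, 18))  # GAGUA positions within FLANK_3


def synthetic_ptc_source(seed: int = 0) -> NumberedSequence:
    """A synthetic numbered source emulating 23S rRNA residues 2043-2625.

    The planted motifs and the wild-type base of every mutation in the
    shipped design catalog sit at their native positions; all other bases
    are drawn uniformly at random from the seeded generator.  This is a
    synthetic stand-in for the biological sequence: its lengths, numbering
    and motif content are faithful, its remaining bases are not.
    """
    rng = np.random.default_rng(seed)
    n = SOURCE_LAST_LABEL - SOURCE_FIRST_LABEL + 1
    bases = list(rng.choice(list("ACGU"), size=n))
    fixed: dict[int, str] = {}
    for start, motif in _PLANTED_MOTIFS:
        for k, b in enumerate(motif):
            prev = fixed.get(start + k)
            if prev is not None and prev != b:
                raise SpecificationError(
                    f"conflicting planted bases at {start + k}: {prev} vs {b}"
                )
            fixed[start + k] = b
    for ms in design_catalog().values():
        for mut in ms:
            prev = fixed.get(mut.native_pos)
            if prev is not None and prev != mut.wt_base:
                raise SpecificationError(
                    f"catalog wild-type base {mut.wt_base} at {mut.native_pos} "
                    f"conflicts with planted base {prev}"
                )
            fixed[mut.native_pos] = mut.wt_base
    for pos, b in fixed.items():
        bases[pos - SOURCE_FIRST_LABEL] = b
    return NumberedSequence("".join(bases), first_label=SOURCE_FIRST_LABEL)


def wt_mini_ptc(seed: int = 0, *, with_flanks: bool = False) -> Construct:
    """Assemble the 284-nt minimized-PTC core from the synthetic source.

    With ``with_flanks=True`` the synthetic GAGUA reference-hairpin flanks
    are attached, giving the 357-nt probing construct.
    """
    core = assemble_construct(
        synthetic_ptc_source(seed),
        PTC_SEGMENTS,
        PTC_JUNCTIONS,
        name="WT mini-PTC",
    )
    if not with_flanks:
        return core
    return add_reference_flanks(
        core,
        FLANK_5,
        FLANK_3,
        reference_loop_5=FLANK_5_LOOP,
        reference_loop_3=FLANK_3_LOOP,
    )
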