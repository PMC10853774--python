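"""Ligand footprinting from paired SHAPE profiles, and LC-MS yield
quantification of the fragment reaction.

Footprinting compares a construct's reactivity profile measured free in
solution against the profile measured in the presence of substrate mimics
(e.g. 100 uM CCA-pcb, a P-site peptidyl-tRNA analog, plus 100 uM C-pmn, an
A-site aminoacyl-tRNA analog).  Positions whose reactivity drops by more
than a threshold are called protected; positions whose reactivity rises are
enhanced.  Calls are compared against a reference set of residues known to
be protected by tRNA substrates in the intact ribosome.

Yield quantification integrates extracted-ion chromatograms (EICs): peak
records within a ppm window of a target m/z are kept and their intensity is
integrated over retention time by the trapezoid rule.  The reaction yield is
the product area over the internal-standard area, times 10^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import AlignmentError, SpecificationError
from .reactivity import MISSING, ReactivityProfile


@dataclass(frozen=True)
class FootprintExperiment:
    """Paired free/bound reactivity profiles plus ligand metadata."""

    profile_free: ReactivityProfile
    profile_bound: ReactivityProfile
    ligands: tuple[tuple[str, float], ...] = ()  # (name, concentration in uM)
    labels: tuple[object, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.profile_free) != len(self.profile_bound):
            raise AlignmentError("free and bound profiles differ in length")
        if self.profile_free.state != self.profile_bound.state:
            raise AlignmentError(
                "free and bound profiles must be in the same processing state"
            )
        if self.labels is not None and len(self.labels) != len(self.profile_free):
            raise AlignmentError("labels length must match the profiles")


@dataclass(frozen=True)
class ProtectionCall:
    """Per-position change in reactivity upon ligand binding."""

    position: object  # native label or 1-based index
    delta: float  # bound - free
    protected: bool
    enhanced: bool

    def __post_init__(self) -> None:
        if self.protected and self.enhanced:
            raise SpecificationError(
                "a position cannot be both protected and enhanced"
            )


def footprint_delta(
    exp: FootprintExperiment,
    protection_threshold: float = 0.3,
    significance_z: float | None = None,
) -> list[ProtectionCall]:
    """Call protections and enhancements from bound-minus-free deltas.

    delta(i) = bound(i) - free(i).  A position is protected when
    ``delta <= -threshold`` and enhanced when ``delta >= +threshold``; when
    ``significance_z`` is given and both profiles carry errors, the call
    additionally requires ``|delta| / pooled_error >= z``.  Positions missing
    in either profile are skipped.
    """
    free, bound = exp.profile_free, exp.profile_bound
    calls = []
    for i in range(len(free)):
        vf, vb = float(free.values[i]), float(bound.values[i])
        if vf == MISSING or vb == MISSING:
            continue
        delta = vb - vf
        significant = True
        if significance_z is not None:
            pooled = float(np.hypot(free.errors[i], bound.errors[i]))
            significant = pooled > 0 and abs(delta) / pooled >= significance_z
        protected = delta <= -protection_threshold and significant
        enhanced = delta >= protection_threshold and significant
        label = exp.labels[i] if exp.labels is not None else i + 1
        calls.append(
            ProtectionCall(
                position=label, delta=delta, protected=protected, enhanced=enhanced
            )
        )
    return calls


def overlap_with_reference(
    calls: Sequence[ProtectionCall], reference: Iterable[object]
) -> tuple[int, int, float]:
    """Overlap of protected calls with a reference protected-residue set.

    Returns ``(n_overlap, n_reference, fraction)``.
    """
    ref = set(reference)
    if not ref:
        raise SpecificationError("reference protected-residue set is empty")
    protected = {c.position for c in calls if c.protected}
    n_overlap = len(ref & protected)
    return n_overlap, len(ref), n_overlap / len(ref)


# ---------------------------------------------------------------------------
# LC-MS: extracted-ion chromatograms and yields

#: exact masses used by the fragment-reaction assay
MZ_PRODUCT_PMN_PCB = 958.4604  # puromycin-phenylalanine-caproic acid-biotin
MZ_STANDARD_LEU_ENK = 556.2771  # leucine enkephalin internal standard


@dataclass(frozen=True)
class PeakRecord:
    """One (m/z, retention time, intensity) observation."""

    mz: float
    rt: float  # minutes
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise SpecificationError(f"m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise SpecificationError("intensity must be non-negative")


@dataclass(frozen=True)
class EICSpec:
    """Mass window for chromatogram extraction: target m/z +- ppm."""

    target_mz: float
    tolerance_ppm: float = 100.0

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0:
            raise SpecificationError("tolerance_ppm must be > 0")
        if self.target_mz <= 0:
            raise SpecificationError("target_mz must be > 0")

    def matches(self, mz: float) -> bool:
        # inclusive boundary, matching the "+-ppm" phrasing; the 1e-9 ppm
        # slack absorbs float round-off at the exact boundary
        ppm = abs(mz - self.target_mz) / self.target_mz * 1e6
        return ppm - self.tolerance_ppm <= 1e-9


@dataclass(frozen=True)
class EICResult:
    """Filtered records and their trapezoid-integrated area."""

    records: tuple[PeakRecord, ...]
    area: float
    empty: bool


def extract_eic(records: Sequence[PeakRecord], spec: EICSpec) -> EICResult:
    """Extract and integrate the ion chromatogram for one target mass.

    Records within the ppm window are kept, sorted by retention time, and
    their intensity is integrated over retention time by the trapezoid
    rule.  No surviving records yields an empty EIC with area 0 (flagged,
    not raised).
    """
    kept = sorted((r for r in records if spec.matches(r.mz)), key=lambda r: r.rt)
    if not kept:
        return EICResult(records=(), area=0.0, empty=True)
    if len(kept) == 1:
        return EICResult(records=tuple(kept), area=0.0, empty=False)
    rts = np.array([r.rt for r in kept])
    ints = np.array([r.intensity for r in kept])
    area = float(np.trapezoid(ints, rts))
    return EICResult(records=tuple(kept), area=area, empty=False)


@dataclass(frozen=True)
class YieldResult:
    """Fragment-reaction yield: product area over standard area, x 10^3."""

    area_product: float
    area_standard: float
    value: float


def compute_yield(area_product: float, area_standard: float) -> YieldResult:
    """yield = (area_product / area_standard) * 1000."""
    if area_standard <= 0:
        raise SpecificationError(
            f"internal-standard area must be > 0, got {area_standard}"
        )
    if area_product < 0:
        raise SpecificationError("product area must be >= 0")
    return YieldResult(
        area_product=float(area_product),
        area_standard=float(area_standard),
        value=float(area_product) / float(area_standard) * 1e3,
    )
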