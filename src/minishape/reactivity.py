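"""SHAPE reactivity processing.

Turns replicate per-nucleotide band intensities (modified vs no-modification
control) into normalized reactivity profiles:

1. background subtraction — mean over modification replicates minus mean
   over control replicates, clamped at zero, errors propagated in quadrature
   from the replicate standard errors;
2. reference-hairpin normalization — division by the mean reactivity over
   the designated GAGUA loop positions of the 5'/3' flank hairpins;
3. unit scaling — min-max scaling to [0, 1] for cross-profile comparison.

Missing values use the community ``.shape`` sentinel -999 and are excluded
from every statistic.  Profile state advances only forward through
``raw -> background_subtracted -> hairpin_normalized -> unit_scaled``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import (
    AlignmentError,
    DegeneracyError,
    NormalizationError,
    SpecificationError,
    StateError,
    StructureError,
)

logger = logging.getLogger(__name__)

MISSING = -999.0

STATES = ("raw", "background_subtracted", "hairpin_normalized", "unit_scaled")


@dataclass(frozen=True)
class RawMeasurement:
    """One replicate of per-position band intensities."""

    values: np.ndarray
    condition: str  # "modified" | "control"
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.condition not in ("modified", "control"):
            raise SpecificationError(
                f"condition must be 'modified' or 'control', got {self.condition!r}"
            )
        vals = np.asarray(self.values, dtype=float)
        finite = vals[vals != MISSING]
        if np.any(finite < 0):
            raise SpecificationError("intensities must be non-negative")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class ReactivityProfile:
    """Per-position reactivities with standard errors and a processing state.

    ``values`` and ``errors`` share a length; positions equal to
    :data:`MISSING` in ``values`` are treated as absent everywhere.
    """

    values: np.ndarray
    errors: np.ndarray | None = None
    state: str = "raw"
    name: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        errs = (
            np.zeros_like(vals)
            if self.errors is None
            else np.asarray(self.errors, dtype=float)
        )
        if errs.shape != vals.shape:
            raise AlignmentError("values and errors differ in length")
        if self.state not in STATES:
            raise SpecificationError(f"unknown profile state {self.state!r}")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "errors", errs)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of non-missing positions."""
        return self.values != MISSING

    def finite_values(self) -> np.ndarray:
        return self.values[self.mask]

    def _advance(self, new_state: str, **changes) -> "ReactivityProfile":
        if STATES.index(new_state) <= STATES.index(self.state):
            raise StateError(
                f"cannot move profile state backwards or in place "
                f"({self.state} -> {new_state})"
            )
        return replace(self, state=new_state, **changes)


def subtract_background(
    mod: Sequence[RawMeasurement], control: Sequence[RawMeasurement]
) -> ReactivityProfile:
    """Background-subtract replicate measurements.

    value(i) = max(0, mean over modified replicates - mean over control
    replicates); the error is the quadrature sum of the two replicate
    standard errors of the mean.  Positions missing in any replicate are
    missing in the output.  Negative differences are clamped to zero and the
    clamp count logged.
    """
    if not mod or not control:
        raise SpecificationError("need at least one replicate of each condition")
    for m in mod:
        if m.condition != "modified":
            raise SpecificationError("mod replicates must have condition='modified'")
    for c in control:
        if c.condition != "control":
            raise SpecificationError("control replicates must have condition='control'")
    lengths = {len(m.values) for m in (*mod, *control)}
    if len(lengths) != 1:
        raise AlignmentError(f"replicate length mismatch: {sorted(lengths)}")

    mod_stack = np.stack([m.values for m in mod])
    ctl_stack = np.stack([c.values for c in control])
    missing = np.any(mod_stack == MISSING, axis=0) | np.any(
        ctl_stack == MISSING, axis=0
    )

    mean_mod = mod_stack.mean(axis=0)
    mean_ctl = ctl_stack.mean(axis=0)
    diff = mean_mod - mean_ctl
    clamped = int(np.sum((diff < 0) & ~missing))
    if clamped:
        logger.info("clamped %d negative background-subtracted values to 0", clamped)
    values = np.where(diff < 0, 0.0, diff)

    def _sem(stack: np.ndarray) -> np.ndarray:
        n = stack.shape[0]
        if n == 1:
            return np.zeros(stack.shape[1])
        return stack.std(axis=0, ddof=1) / np.sqrt(n)

    errors = np.sqrt(_sem(mod_stack) ** 2 + _sem(ctl_stack) ** 2)
    values[missing] = MISSING
    errors[missing] = 0.0
    return ReactivityProfile(values, errors, state="background_subtracted")


def normalize_to_hairpins(
    profile: ReactivityProfile, reference_positions: Iterable[int]
) -> ReactivityProfile:
    """Divide the profile by its mean over the GAGUA reference-loop positions.

    ``reference_positions`` are 1-based construct indices of the flank
    hairpin loop residues.  After normalization the mean over those positions
    is exactly 1.  Raises :class:`NormalizationError` when the reference mean
    is non-positive or any reference position is missing.
    """
    if profile.state != "background_subtracted":
        raise StateError(
            f"hairpin normalization expects a background_subtracted profile, "
            f"got {profile.state}"
        )
    refs = sorted(set(int(p) for p in reference_positions))
    if not refs:
        raise SpecificationError("no reference positions supplied")
    idx = np.array(refs) - 1
    if idx.min() < 0 or idx.max() >= len(profile):
        raise SpecificationError("reference positions outside the profile")
    ref_vals = profile.values[idx]
    if np.any(ref_vals == MISSING):
        raise NormalizationError("reference-hairpin positions contain missing values")
    ref_mean = float(ref_vals.mean())
    if ref_mean <= 0:
        raise NormalizationError(
            f"reference-hairpin mean reactivity is {ref_mean:.4g} (must be > 0)"
        )
    mask = profile.mask
    values = profile.values.copy()
    errors = profile.errors.copy()
    values[mask] = values[mask] / ref_mean
    errors[mask] = errors[mask] / ref_mean
    return profile._advance("hairpin_normalized", values=values, errors=errors)


def scale_unit(
    profile: ReactivityProfile, *, winsorize: float | None = None
) -> ReactivityProfile:
    """Min-max scale non-missing values to [0, 1].

    With ``winsorize=q`` (e.g. 0.05), values are first clipped to the
    [q, 1-q] quantile range before scaling; off by default.  A constant
    profile raises :class:`DegeneracyError`.
    """
    mask = profile.mask
    if not mask.any():
        raise DegeneracyError("profile has no non-missing values")
    vals = profile.values.copy()
    errs = profile.errors.copy()
    work = vals[mask]
    if winsorize is not None:
        lo_q, hi_q = np.quantile(work, [winsorize, 1 - winsorize])
        work = np.clip(work, lo_q, hi_q)
    lo, hi = float(work.min()), float(work.max())
    if hi == lo:
        raise DegeneracyError("cannot unit-scale a constant profile")
    span = hi - lo
    vals[mask] = (work - lo) / span
    errs[mask] = errs[mask] / span
    if profile.state == "unit_scaled":
        # idempotent re-scale of an already scaled profile is a no-op range-wise
        return replace(profile, values=vals, errors=errs)
    return profile._advance("unit_scaled", values=vals, errors=errs)


@dataclass(frozen=True)
class HeatmapThresholds:
    """Reactivity cutoffs for the high/intermediate/low heatmap classes.

    Experimental and predicted profiles live on different scales, so each
    carries its own pair: experimental reactivity counts as high above 1.5
    and low below 0.5; predicted reactivity as high above 0.5 and low below
    0.25.  Comparisons are strict, so a value exactly at a cutoff is
    intermediate.
    """

    high_exp: float = 1.5
    low_exp: float = 0.5
    high_pred: float = 0.5
    low_pred: float = 0.25

    def __post_init__(self) -> None:
        if not (self.low_exp < self.high_exp and self.low_pred < self.high_pred):
            raise SpecificationError("low threshold must be below high threshold")

    def pair(self, kind: str) -> tuple[float, float]:
        if kind == "experimental":
            return self.high_exp, self.low_exp
        if kind == "predicted":
            return self.high_pred, self.low_pred
        raise SpecificationError(f"kind must be experimental|predicted, got {kind!r}")


def classify_reactivity(
    profile: ReactivityProfile,
    thresholds: HeatmapThresholds | None = None,
    kind: str = "experimental",
) -> list[str]:
    """Per-position category in {'high', 'intermediate', 'low', 'missing'}."""
    thresholds = thresholds or HeatmapThresholds()
    high, low = thresholds.pair(kind)
    out = []
    for v in profile.values:
        if v == MISSING:
            out.append("missing")
        elif v > high:
            out.append("high")
        elif v < low:
            out.append("low")
        else:
            out.append("intermediate")
    return out


def parse_dotbracket(structure: str) -> list[int | None]:
    """Pair table for a dot-bracket string: 1-based partner or None.

    Only ``.()`` are accepted; an unbalanced string raises
    :class:`StructureError`.
    """
    partner: list[int | None] = [None] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {i + 1}")
            j = stack.pop()
            partner[i] = j + 1
            partner[j] = i + 1
        elif ch != ".":
            raise StructureError(f"unexpected character {ch!r} in dot-bracket")
    if stack:
        raise StructureError(f"{len(stack)} unclosed '(' in dot-bracket")
    return partner


def count_reactive_paired(
    profile: ReactivityProfile,
    structure: str,
    rule: Callable[[float], bool] | None = None,
) -> tuple[int, int, float]:
    """Count base-paired positions that react significantly over background.

    Returns ``(reactive_count, paired_count, fraction)`` where the fraction
    is reactive/paired as a percentage rounded to one decimal.  The default
    significance predicate is reactivity above the low-experimental heatmap
    cutoff (0.5).
    """
    if len(structure) != len(profile):
        raise AlignmentError(
            f"structure length {len(structure)} != profile length {len(profile)}"
        )
    rule = rule or (lambda v: v > HeatmapThresholds().low_exp)
    partner = parse_dotbracket(structure)
    paired = 0
    reactive = 0
    for v, p in zip(profile.values, partner):
        if p is None:
            continue
        paired += 1
        if v != MISSING and rule(float(v)):
            reactive += 1
    fraction = round(100.0 * reactive / paired, 1) if paired else 0.0
    return reactive, paired, fraction
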