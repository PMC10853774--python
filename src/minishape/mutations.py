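"""Mutation notation, application, diffing and design-constraint validation.

Mutations are written in native-numbering notation, e.g. ``C2043U``:
wild-type base, native position, substituted base.  Designs are
substitution-only; indels are out of scope.  Constraint validation encodes
the crowdsourced-design rules: mutations only at allowed positions
(positions variable in >1% of gammaproteobacterial 23S sequences, or shown
to retain >=40% of wild-type ribosome activity), and at most a fixed number
of substitutions per design (default 40).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .construct import Construct, NativeLabel, apply_substitution
from .errors import (
    AlignmentError,
    ConsistencyError,
    MappingError,
    ParseError,
    SpecificationError,
)

_MUTATION_RE = re.compile(r"^\s*([ACGUT])(\d+)([ACGUT])\s*$")


@dataclass(frozen=True, order=True)
class Mutation:
    """A single base substitution in native numbering."""

    native_pos: int
    wt_base: str
    alt_base: str

    def __post_init__(self) -> None:
        for b, which in ((self.wt_base, "wild-type"), (self.alt_base, "substituted")):
            if b not in "ACGU":
                raise ParseError(f"{which} base {b!r} is not one of ACGU")
        if self.wt_base == self.alt_base:
            raise ParseError(
                f"no-op substitution {self.wt_base}{self.native_pos}{self.alt_base}"
            )

    def __str__(self) -> str:
        return f"{self.wt_base}{self.native_pos}{self.alt_base}"


@dataclass(frozen=True)
class MutationSet:
    """An ordered, duplicate-free list of mutations for one design."""

    mutations: tuple[Mutation, ...]
    design_name: str = ""

    def __post_init__(self) -> None:
        positions = [m.native_pos for m in self.mutations]
        dupes = {p for p in positions if positions.count(p) > 1}
        if dupes:
            raise SpecificationError(
                f"duplicate mutated positions in {self.design_name or 'set'}: "
                f"{sorted(dupes)}"
            )

    def __len__(self) -> int:
        return len(self.mutations)

    def __iter__(self):
        return iter(self.mutations)

    def sorted(self) -> "MutationSet":
        return MutationSet(
            tuple(sorted(self.mutations)), design_name=self.design_name
        )

    def __str__(self) -> str:
        return ", ".join(str(m) for m in self.mutations)


def parse_mutation(notation: str) -> Mutation:
    """Parse one ``C2043U``-style token (T tolerated, read as U)."""
    m = _MUTATION_RE.match(notation)
    if not m:
        raise ParseError(f"malformed mutation notation {notation!r}")
    wt, pos, alt = m.groups()
    return Mutation(int(pos), wt.replace("T", "U"), alt.replace("T", "U"))


def parse_mutation_list(text: str, design_name: str = "") -> MutationSet:
    """Parse a comma-separated list of mutations, tolerating whitespace."""
    tokens = [t for t in (tok.strip() for tok in text.split(",")) if t]
    return MutationSet(tuple(parse_mutation(t) for t in tokens), design_name)


def apply_mutations(construct: Construct, ms: MutationSet) -> Construct:
    """Apply a mutation set, checking each declared wild-type base.

    Raises :class:`MappingError` for excised positions and
    :class:`ConsistencyError` when the construct base disagrees with the
    declared wild-type base.
    """
    out = construct
    for mut in ms:
        idx = construct.native_to_construct(mut.native_pos)
        if idx is None:
            raise MappingError(
                f"mutation {mut}: native position {mut.native_pos} not in construct"
            )
        observed = construct.sequence[idx - 1]
        if observed != mut.wt_base:
            raise ConsistencyError(
                f"mutation {mut}: construct carries {observed} at native "
                f"{mut.native_pos}, not {mut.wt_base}"
            )
        out = apply_substitution(out, idx, mut.alt_base)
    return out


def diff_sequences(a: Construct, b: Construct) -> MutationSet:
    """Substitutions turning ``a`` into ``b``, ascending by native position.

    Both constructs must share a coordinate map; the count equals the
    Hamming distance between the sequences.
    """
    if len(a) != len(b):
        raise AlignmentError(
            f"constructs differ in length ({len(a)} vs {len(b)})"
        )
    if tuple(e.label for e in a.coords) != tuple(e.label for e in b.coords):
        raise AlignmentError("constructs do not share a coordinate map")
    muts = []
    for entry, base_a, base_b in zip(a.coords, a.sequence, b.sequence):
        if base_a != base_b:
            if not isinstance(entry.label, int):
                raise AlignmentError(
                    f"difference at flank position {entry.label}: flanks are "
                    "not mutable in native notation"
                )
            muts.append(Mutation(entry.label, base_a, base_b))
    return MutationSet(tuple(sorted(muts)), design_name=f"{b.name}-vs-{a.name}")


@dataclass(frozen=True)
class DesignConstraints:
    """Allowed mutation positions and the per-design substitution budget."""

    allowed_positions: frozenset[int]
    max_mutations: int = 40

    def __post_init__(self) -> None:
        if self.max_mutations < 0:
            raise SpecificationError("max_mutations must be >= 0")
        object.__setattr__(
            self, "allowed_positions", frozenset(self.allowed_positions)
        )


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of checking a design against its constraints."""

    violations: tuple[tuple[str, str], ...]  # (mutation or set label, rule)

    @property
    def passed(self) -> bool:
        return not self.violations


def derive_allowed_positions(
    variation: Mapping[int, float],
    activity: Mapping[int, float] | None = None,
    *,
    freq_threshold: float = 0.01,
    activity_threshold: float = 0.40,
    mode: str = "union",
) -> frozenset[int]:
    """Positions mutable under the variation and/or activity rules.

    ``variation`` maps native position -> fraction of homologous sequences
    carrying a variant base; ``activity`` maps native position -> fraction of
    wild-type ribosome activity retained when the position is mutated.  A
    position is allowed when its variant frequency exceeds ``freq_threshold``
    (strict) or its retained activity is at least ``activity_threshold``
    (inclusive).  ``mode`` selects ``"union"`` (either rule), ``"frequency"``
    or ``"activity"`` (a single rule alone).
    """
    if mode not in ("union", "frequency", "activity"):
        raise SpecificationError(f"unknown mode {mode!r}")
    if not variation and not (activity or {}):
        raise SpecificationError("variation and activity tables are both empty")
    by_freq = {p for p, f in variation.items() if f > freq_threshold}
    by_act = {
        p for p, a in (activity or {}).items() if a >= activity_threshold
    }
    if mode == "frequency":
        return frozenset(by_freq)
    if mode == "activity":
        return frozenset(by_act)
    return frozenset(by_freq | by_act)


def validate_design(
    ms: MutationSet, constraints: DesignConstraints
) -> ValidationReport:
    """Check a design against position and count constraints.

    Violations are reported, never raised: a design with 41 substitutions
    under a budget of 40 yields one count-rule violation; each mutation at a
    disallowed position yields one position-rule violation.
    """
    violations: list[tuple[str, str]] = []
    if len(ms) > constraints.max_mutations:
        violations.append(
            (
                ms.design_name or "design",
                f"count rule: {len(ms)} mutations exceed the maximum of "
                f"{constraints.max_mutations}",
            )
        )
    for mut in ms:
        if mut.native_pos not in constraints.allowed_positions:
            violations.append(
                (str(mut), f"position rule: {mut.native_pos} is not mutable")
            )
    return ValidationReport(tuple(violations))


# ---------------------------------------------------------------------------
# shipped design catalog: the seven top-ranked crowdsourced variants of the
# minimized PTC, as comma-separated native-notation lists.

ETERNA_DESIGNS: dict[str, str] = {
    "mini-PTC 1.1": (
        "C2043U, A2070C, G2083A, G2237A, G2253A, C2254U, U2441G, G2458A, "
        "G2505U, A2516G, U2568C, G2625A"
    ),
    "mini-PTC 1.2": "C2043U, G2083A, C2089U, G2237A, G2458A, G2543A, G2625A",
    "mini-PTC 1.3": "A2503U, G2505U, G2608A, C2611U",
    "mini-PTC 1.4": (
        "C2050U, A2051U, G2057C, C2073G, U2075A, C2232U, U2245A, U2249A, "
        "G2253A, G2255A, G2428A, G2436C, G2447A, G2454A, U2460A, U2493A, "
        "G2505A, U2506C, G2509U, U2511A, C2512A, A2513G, G2543A, U2548A, "
        "U2552A, C2556A, A2560U, U2571C, A2572G, G2576A, C2579A, U2580C, "
        "G2581U, U2584C, U2586A, G2608A, C2611G, A2614U, G2618A"
    ),
    "mini-PTC 1.5": (
        "A2070C, G2083A, C2089U, G2237A, U2441G, G2458A, G2505U, A2516G, U2568C"
    ),
    "mini-PTC 1.6": "C2456U, U2584A, C2610G",
    "mini-PTC 1.7": (
        "C2043U, G2087A, C2091U, C2232U, G2253A, G2447A, G2543A, U2552A, "
        "U2555A, G2583A, C2606U, G2607C, G2608A, U2609A, G2625A"
    ),
}


def design_catalog() -> dict[str, MutationSet]:
    """The shipped variant catalog as parsed :class:`MutationSet` objects."""
    return {
        name: parse_mutation_list(text, design_name=name)
        for name, text in ETERNA_DESIGNS.items()
    }
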