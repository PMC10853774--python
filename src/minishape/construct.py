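"""Assembly of minimized RNA constructs from noncontiguous segments.

A minimized construct is built by excising segments of a natively numbered
source RNA (e.g. *E. coli* 23S rRNA domain V, residues numbered 2043..2625),
joining them 5'->3' with synthetic junction elements (a stable tetraloop cap
closing a truncated helix, or a direct loop-to-loop join), and optionally
wrapping the core in reference-hairpin flanks whose GAGUA loops anchor SHAPE
normalization.

Every construct carries a bidirectional coordinate map between construct
indices (1-based) and native labels, so that downstream analyses can speak
the source numbering even though most of the source is gone.  Inserted
junction residues receive native-style integer labels continuing the
preceding segment's numbering (the tetraloop closing a helix that ends at
2091 is labelled 2092-2095); flank residues, which have no native number,
are labelled ``F5.k`` / ``F3.k``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

from .errors import (
    AlphabetError,
    MappingError,
    RangeError,
    SpecificationError,
    StateError,
)

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: native label of a construct position: an int for segment and insert
#: residues (native numbering, possibly synthetic continuation), a string
#: like "F5.3" for flank residues.
NativeLabel = int | str

JUNCTION_KINDS = ("tetraloop_cap", "direct_join", "terminal_pairs")


def clean_rna(sequence: str, *, context: str = "sequence") -> str:
    """Uppercase and validate an RNA string, converting T->U with a warning.

    DNA input is tolerated because transcription templates are DNA; any
    other non-ACGU character raises :class:`AlphabetError`.
    """
    seq = sequence.upper().replace(" ", "").replace("\n", "")
    if "T" in seq:
        logger.warning("%s contains T; converting to U (DNA input assumed)", context)
        seq = seq.replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"{context} contains non-RNA characters: {sorted(bad)}"
        )
    return seq


@dataclass(frozen=True)
class NumberedSequence:
    """A source RNA with a contiguous 1-based native numbering.

    Positions run ``first_label .. first_label + len(sequence) - 1``.
    """

    sequence: str
    first_label: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", clean_rna(self.sequence, context="source sequence")
        )

    @property
    def last_label(self) -> int:
        return self.first_label + len(self.sequence) - 1

    def __len__(self) -> int:
        return len(self.sequence)

    def base_at(self, native_pos: int) -> str:
        if not self.first_label <= native_pos <= self.last_label:
            raise RangeError(
                f"native position {native_pos} outside source numbering "
                f"[{self.first_label}, {self.last_label}]"
            )
        return self.sequence[native_pos - self.first_label]

    def slice(self, start: int, end: int) -> str:
        """Subsequence for the inclusive native span ``start..end``."""
        if start > end:
            raise SpecificationError(f"span start {start} > end {end}")
        if start < self.first_label or end > self.last_label:
            raise RangeError(
                f"span {start}-{end} outside source numbering "
                f"[{self.first_label}, {self.last_label}]"
            )
        i = start - self.first_label
        return self.sequence[i : i + (end - start + 1)]


@dataclass(frozen=True)
class SegmentSpec:
    """An inclusive native span ``start..end`` excised from the source."""

    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SpecificationError(
                f"segment start {self.start} > end {self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class JunctionSpec:
    """A synthetic element placed between two segments (or at a terminus).

    ``tetraloop_cap`` inserts a loop sequence (e.g. AAAA) closing a
    truncated helix; ``direct_join`` concatenates the flanking segments
    with no insert; ``terminal_pairs`` marks termini closed by base pairs
    already present in the segments and likewise inserts nothing unless a
    sequence is given.
    """

    kind: str
    insert_sequence: str = ""
    synthetic_labels: tuple[NativeLabel, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in JUNCTION_KINDS:
            raise SpecificationError(
                f"unknown junction kind {self.kind!r}; expected one of {JUNCTION_KINDS}"
            )
        if self.insert_sequence:
            object.__setattr__(
                self,
                "insert_sequence",
                clean_rna(self.insert_sequence, context="junction insert"),
            )
        if self.kind == "direct_join" and self.insert_sequence:
            raise SpecificationError("direct_join junction must have an empty insert")
        if self.synthetic_labels and len(self.synthetic_labels) != len(
            self.insert_sequence
        ):
            raise SpecificationError(
                "synthetic_labels length must equal insert_sequence length"
            )


@dataclass(frozen=True)
class RegionAnnotation:
    """A named set of native labels (a loop, a junction, a motif)."""

    name: str
    positions: frozenset[NativeLabel]

    def __post_init__(self) -> None:
        if not self.positions:
            raise SpecificationError(f"region {self.name!r} has no positions")
        object.__setattr__(self, "positions", frozenset(self.positions))

    @classmethod
    def from_span(cls, name: str, start: int, end: int) -> "RegionAnnotation":
        return cls(name, frozenset(range(start, end + 1)))

    def sorted_positions(self) -> list[NativeLabel]:
        return sorted(self.positions, key=_label_sort_key)


def _label_sort_key(label: NativeLabel) -> tuple[int, float | str]:
    # integers sort before flank labels; flank labels sort lexically
    if isinstance(label, int):
        return (0, label)
    return (1, label)


@dataclass(frozen=True)
class CoordEntry:
    """One row of the coordinate map."""

    index: int  # 1-based construct index
    label: NativeLabel
    origin: str  # "segment" | "insert" | "flank"


@dataclass(frozen=True)
class Construct:
    """A single-strand construct plus its construct<->native coordinate map.

    ``coords[i]`` describes construct position ``i + 1``.  The map restricted
    to segment/insert positions is a bijection onto its labels; flank labels
    are likewise unique.  ``reference_positions`` holds the construct indices
    of the flank GAGUA loop residues used for normalization (empty until
    flanks are attached).
    """

    sequence: str
    coords: tuple[CoordEntry, ...]
    name: str = "construct"
    has_flanks: bool = False
    reference_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.coords):
            raise SpecificationError("coordinate map does not cover the sequence")
        labels = [e.label for e in self.coords]
        if len(set(labels)) != len(labels):
            raise SpecificationError("coordinate map labels are not unique")

    def __len__(self) -> int:
        return len(self.sequence)

    # -- coordinate mapping ------------------------------------------------

    def _native_index(self) -> dict[NativeLabel, int]:
        return {e.label: e.index for e in self.coords}

    def native_to_construct(self, label: NativeLabel) -> int | None:
        """Construct index carrying ``label``, or None if excised."""
        return self._native_index().get(label)

    def construct_to_native(self, index: int) -> NativeLabel:
        if not 1 <= index <= len(self):
            raise RangeError(
                f"construct index {index} out of bounds [1, {len(self)}]"
            )
        return self.coords[index - 1].label

    def base_at_native(self, label: NativeLabel) -> str:
        idx = self.native_to_construct(label)
        if idx is None:
            raise MappingError(f"native label {label!r} is not in the construct")
        return self.sequence[idx - 1]

    def core_entries(self) -> Iterator[CoordEntry]:
        """Coordinate entries of non-flank (segment + insert) positions."""
        return (e for e in self.coords if e.origin != "flank")

    # -- motif extraction --------------------------------------------------

    def motif(self, region: RegionAnnotation) -> str:
        """Construct subsequence at the region's native labels, 5'->3'.

        Raises :class:`MappingError` naming any excised label.
        """
        index = self._native_index()
        missing = [p for p in region.sorted_positions() if p not in index]
        if missing:
            raise MappingError(
                f"region {region.name!r} positions not in construct: {missing}"
            )
        idxs = sorted(index[p] for p in region.positions)
        return "".join(self.sequence[i - 1] for i in idxs)


# ---------------------------------------------------------------------------
# assembly


def assemble_construct(
    source: NumberedSequence,
    segments: Sequence[SegmentSpec],
    junctions: Sequence[JunctionSpec],
    *,
    name: str = "construct",
) -> Construct:
    """Concatenate native segments and junction inserts into one strand.

    ``junctions`` must contain exactly one entry per inter-segment gap, plus
    optionally one trailing terminal entry.  The returned coordinate map
    assigns source numbering to segment residues and synthetic labels
    (continuing the preceding segment's numbering unless given explicitly)
    to insert residues.
    """
    if not segments:
        raise SpecificationError("at least one segment is required")
    n_gaps = len(segments) - 1
    if len(junctions) not in (n_gaps, n_gaps + 1):
        raise SpecificationError(
            f"{len(segments)} segments need {n_gaps} inter-segment junctions "
            f"(plus an optional terminal entry); got {len(junctions)}"
        )
    for prev, cur in zip(segments, segments[1:]):
        if cur.start <= prev.end:
            raise SpecificationError(
                f"segments must be non-overlapping and ascending 5'->3': "
                f"{prev.start}-{prev.end} then {cur.start}-{cur.end}"
            )

    parts: list[str] = []
    entries: list[CoordEntry] = []
    idx = 0
    segment_labels = {
        pos for seg in segments for pos in range(seg.start, seg.end + 1)
    }

    def _push_segment(seg: SegmentSpec) -> None:
        nonlocal idx
        parts.append(source.slice(seg.start, seg.end))
        for pos in range(seg.start, seg.end + 1):
            idx += 1
            entries.append(CoordEntry(idx, pos, "segment"))

    def _push_insert(junc: JunctionSpec, after_label: int) -> None:
        nonlocal idx
        if not junc.insert_sequence:
            return
        labels = junc.synthetic_labels or tuple(
            after_label + k + 1 for k in range(len(junc.insert_sequence))
        )
        taken = segment_labels | {e.label for e in entries}
        clash = [l for l in labels if l in taken]
        if clash:
            raise SpecificationError(
                f"junction insert labels {clash} collide with segment labels; "
                "supply explicit synthetic_labels"
            )
        parts.append(junc.insert_sequence)
        for base_label in labels:
            idx += 1
            entries.append(CoordEntry(idx, base_label, "insert"))

    for i, seg in enumerate(segments):
        _push_segment(seg)
        if i < n_gaps:
            _push_insert(junctions[i], after_label=seg.end)
    if len(junctions) == n_gaps + 1:
        _push_insert(junctions[-1], after_label=segments[-1].end)

    return Construct(sequence="".join(parts), coords=tuple(entries), name=name)


def add_reference_flanks(
    construct: Construct,
    flank_5: str,
    flank_3: str,
    *,
    reference_loop_5: Iterable[int] = (),
    reference_loop_3: Iterable[int] = (),
) -> Construct:
    """Wrap the core in 5'/3' reference-hairpin flanks.

    ``reference_loop_5`` / ``reference_loop_3`` are 1-based positions within
    each flank marking the GAGUA loop residues whose reactivity anchors
    normalization.  Flank residues are labelled ``F5.k`` / ``F3.k``.
    Empty flanks leave the construct unchanged.
    """
    if construct.has_flanks:
        raise StateError("construct already has reference flanks attached")
    f5 = clean_rna(flank_5, context="5' flank") if flank_5 else ""
    f3 = clean_rna(flank_3, context="3' flank") if flank_3 else ""
    loop5 = tuple(reference_loop_5)
    loop3 = tuple(reference_loop_3)
    if not f5 and not f3 and not loop5 and not loop3:
        return construct
    for pos in loop5:
        if not 1 <= pos <= len(f5):
            raise SpecificationError(
                f"5' reference-loop position {pos} outside flank of length {len(f5)}"
            )
    for pos in loop3:
        if not 1 <= pos <= len(f3):
            raise SpecificationError(
                f"3' reference-loop position {pos} outside flank of length {len(f3)}"
            )

    entries: list[CoordEntry] = []
    idx = 0
    for k in range(1, len(f5) + 1):
        idx += 1
        entries.append(CoordEntry(idx, f"F5.{k}", "flank"))
    core_offset = idx
    for e in construct.coords:
        idx += 1
        entries.append(CoordEntry(idx, e.label, e.origin))
    tail_offset = idx
    for k in range(1, len(f3) + 1):
        idx += 1
        entries.append(CoordEntry(idx, f"F3.{k}", "flank"))

    refs = tuple(core_offset - len(f5) + p for p in loop5) + tuple(
        tail_offset + p for p in loop3
    )
    return Construct(
        sequence=f5 + construct.sequence + f3,
        coords=tuple(entries),
        name=construct.name,
        has_flanks=True,
        reference_positions=refs,
    )


def map_coordinates(
    construct: Construct,
    query: NativeLabel,
    direction: str = "native_to_construct",
) -> NativeLabel | None:
    """Map a position across the construct<->native coordinate map.

    For ``native_to_construct``, excised native positions return ``None``
    (absence, not an error).  For ``construct_to_native``, an out-of-bounds
    index raises :class:`RangeError`.
    """
    if direction == "native_to_construct":
        return construct.native_to_construct(query)
    if direction == "construct_to_native":
        return construct.construct_to_native(int(query))
    raise SpecificationError(f"unknown direction {direction!r}")


def motif_lookup(construct: Construct, region: RegionAnnotation) -> str:
    """See :meth:`Construct.motif`."""
    return construct.motif(region)


def apply_substitution(construct: Construct, index: int, base: str) -> Construct:
    """Return a construct with the base at 1-based ``index`` replaced."""
    if not 1 <= index <= len(construct):
        raise RangeError(f"construct index {index} out of bounds")
    if base not in RNA_ALPHABET:
        raise AlphabetError(f"substituted base {base!r} is not one of ACGU")
    seq = construct.sequence[: index - 1] + base + construct.sequence[index:]
    return replace(construct, sequence=seq)


# ---------------------------------------------------------------------------
# shipped default region annotations (native 23S numbering)

DEFAULT_REGIONS: tuple[RegionAnnotation, ...] = (
    RegionAnnotation.from_span("P-loop", 2249, 2255),
    RegionAnnotation.from_span("A-loop", 2552, 2556),
    RegionAnnotation.from_span("L75-L80", 2426, 2434),
    RegionAnnotation.from_span("tetraloop", 2092, 2095),
    RegionAnnotation.from_span("L89", 2472, 2478),
    RegionAnnotation.from_span("L91", 2529, 2534),
    RegionAnnotation.from_span("L90-L93", 2584, 2587),
    RegionAnnotation.from_span("central loop", 2447, 2454),
)

#: segment spans of the minimized PTC core in native 23S numbering
PTC_SEGMENTS: tuple[SegmentSpec, ...] = (
    SegmentSpec(2043, 2091, "H73/H74 arm"),
    SegmentSpec(2228, 2258, "H80/P-loop arm"),
    SegmentSpec(2426, 2625, "central-loop arm"),
)

#: junctions of the minimized PTC core: an A4 tetraloop capping the first
#: gap (labelled 2092-2095) and a direct loop-to-loop join at the second
PTC_JUNCTIONS: tuple[JunctionSpec, ...] = (
    JunctionSpec("tetraloop_cap", "AAAA", (2092, 2093, 2094, 2095)),
    JunctionSpec("direct_join"),
)
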