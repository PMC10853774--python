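import numpy as np
import pytest

from minishape import (
    NumberedSequence,
    SegmentSpec,
    JunctionSpec,
    assemble_construct,
    design_catalog,
    synthetic_ptc_source,
    wt_mini_ptc,
)


@pytest.fixture(scope="session")
def source():
    """Synthetic numbered source emulating 23S residues 2043-2625."""
    return synthetic_ptc_source(seed=0)


@pytest.fixture(scope="session")
def wt_core(source):
    """284-nt minimized-PTC core (no flanks)."""
    return wt_mini_ptc(seed=0)


@pytest.fixture(scope="session")
def wt_flanked():
    """357-nt probing construct with GAGUA reference-hairpin flanks."""
    return wt_mini_ptc(seed=0, with_flanks=True)


@pytest.fixture(scope="session")
def catalog():
    return design_catalog()


@pytest.fixture
def toy_source():
    """20-nt toy source with default 1-based numbering."""
    return NumberedSequence("AUGCUAGCUAAGGCUAGCUA", first_label=1)


@pytest.fixture
def toy_construct(toy_source):
    """Segments 1-5 and 11-15 joined by an AAAA tetraloop (14 nt)."""
    return assemble_construct(
        toy_source,
        [SegmentSpec(1, 5), SegmentSpec(11, 15)],
        [JunctionSpec("tetraloop_cap", "AAAA")],
    )


def brute_force_coord_map(source, segments, junctions):
    """Independent enumeration oracle: walk segments and inserts by hand."""
    entries = []
    for i, seg in enumerate(segments):
        for pos in range(seg.start, seg.end + 1):
            base = source.sequence[pos - source.first_label]
            entries.append((base, pos, "segment"))
        if i < len(segments) - 1 and i < len(junctions):
            junc = junctions[i]
            labels = junc.synthetic_labels or tuple(
                seg.end + k + 1 for k in range(len(junc.insert_sequence))
            )
            for base, label in zip(junc.insert_sequence, labels):
                entries.append((base, label, "insert"))
    return entries
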