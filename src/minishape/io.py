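"""Readers and writers for the pipeline's on-disk formats.

FASTA (via Biopython, wrapped at 60 columns) for sequences; the two-column
community ``.shape`` format (position, reactivity; -999 missing) and a
richer TSV for reactivity profiles; TSV for coordinate maps and
variation/activity tables; JSON for assembly specifications, outlier and
footprint reports; CSV for design tables and LC-MS peak records.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .compare import OutlierReport
from .construct import (
    Construct,
    JunctionSpec,
    NumberedSequence,
    SegmentSpec,
)
from .errors import ParseError, SpecificationError
from .footprint import PeakRecord, ProtectionCall
from .mutations import MutationSet, ValidationReport, parse_mutation_list
from .reactivity import MISSING, ReactivityProfile


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, *, first_label: int = 1) -> NumberedSequence:
    """Read the first record of a FASTA file as a numbered sequence.

    A ``start=<n>`` token in the record description overrides
    ``first_label``, so sources carrying native numbering are
    self-describing.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    rec = records[0]
    for token in rec.description.split():
        if token.startswith("start="):
            first_label = int(token.split("=", 1)[1])
    return NumberedSequence(str(rec.seq), first_label=first_label)


def write_fasta(
    sequence: str, path: str | Path, *, name: str = "construct", description: str = ""
) -> None:
    rec = SeqRecord(Seq(sequence), id=name.replace(" ", "_"), description=description)
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")  # Biopython wraps at 60 columns


# ---------------------------------------------------------------------------
# assembly specification JSON and coordinate-map TSV


def read_assembly_spec(
    path: str | Path,
) -> tuple[list[SegmentSpec], list[JunctionSpec], dict]:
    """Read segments/junctions/flanks from a JSON specification file.

    Layout::

        {"segments": [{"start": 2043, "end": 2091, "label": "..."}, ...],
         "junctions": [{"kind": "tetraloop_cap", "insert_sequence": "AAAA",
                        "synthetic_labels": [2092, 2093, 2094, 2095]}, ...],
         "flanks": {"flank_5": "...", "flank_3": "...",
                    "reference_loop_5": [...], "reference_loop_3": [...]}}
    """
    spec = json.loads(Path(path).read_text())
    segments = [
        SegmentSpec(s["start"], s["end"], s.get("label", ""))
        for s in spec.get("segments", [])
    ]
    junctions = [
        JunctionSpec(
            j["kind"],
            j.get("insert_sequence", ""),
            tuple(j.get("synthetic_labels", ())),
        )
        for j in spec.get("junctions", [])
    ]
    return segments, junctions, spec.get("flanks", {})


def write_coord_map(construct: Construct, path: str | Path) -> None:
    """TSV coordinate map: construct_index, native_label, origin."""
    pd.DataFrame(
        {
            "construct_index": [e.index for e in construct.coords],
            "native_label": [e.label for e in construct.coords],
            "origin": [e.origin for e in construct.coords],
        }
    ).to_csv(path, sep="\t", index=False)


def read_coord_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    # native labels are ints for core positions, strings for flanks
    df["native_label"] = [
        int(x) if str(x).lstrip("-").isdigit() else str(x)
        for x in df["native_label"]
    ]
    return df


# ---------------------------------------------------------------------------
# reactivity profiles


def read_shape(path: str | Path) -> ReactivityProfile:
    """Read a two-column .shape file (position, reactivity; -999 missing)."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["position", "reactivity"], comment="#"
    )
    order = df.sort_values("position")
    return ReactivityProfile(order["reactivity"].to_numpy(dtype=float))


def write_shape(profile: ReactivityProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(profile.values, start=1):
            fh.write(f"{i}\t{v:.6f}\n" if v != MISSING else f"{i}\t-999\n")


def write_profile_tsv(
    profile: ReactivityProfile, path: str | Path, construct: Construct | None = None
) -> None:
    """Richer TSV: construct_index, native_label, reactivity, error, state."""
    n = len(profile)
    labels = (
        [e.label for e in construct.coords] if construct is not None else list(
            range(1, n + 1)
        )
    )
    pd.DataFrame(
        {
            "construct_index": np.arange(1, n + 1),
            "native_label": labels,
            "reactivity": profile.values,
            "error": profile.errors,
            "state": profile.state,
        }
    ).to_csv(path, sep="\t", index=False)


def read_profile_tsv(path: str | Path) -> ReactivityProfile:
    df = pd.read_csv(path, sep="\t")
    state = str(df["state"].iloc[0]) if "state" in df and len(df) else "raw"
    return ReactivityProfile(
        df["reactivity"].to_numpy(dtype=float),
        df["error"].to_numpy(dtype=float) if "error" in df else None,
        state=state,
    )


# ---------------------------------------------------------------------------
# mutation designs, variation/activity tables


def read_design_table(path: str | Path) -> dict[str, MutationSet]:
    """Read a design-catalog CSV (columns: design_name, mutation_list)."""
    df = pd.read_csv(path)
    required = {"design_name", "mutation_list"}
    if not required <= set(df.columns):
        raise ParseError(f"design table needs columns {sorted(required)}")
    return {
        str(row.design_name): parse_mutation_list(
            str(row.mutation_list), design_name=str(row.design_name)
        )
        for row in df.itertuples()
    }


def read_position_table(path: str | Path) -> dict[int, float]:
    """Read a TSV of (native_label, value) pairs, e.g. variation or activity."""
    df = pd.read_csv(path, sep="\t", header=None, names=["native_label", "value"])
    return {int(r.native_label): float(r.value) for r in df.itertuples()}


def write_validation_report(report: ValidationReport, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "pass": report.passed,
                "violations": [
                    {"item": item, "rule": rule} for item, rule in report.violations
                ],
            },
            indent=2,
        )
    )


# ---------------------------------------------------------------------------
# outlier and footprint reports


def write_outlier_report(report: OutlierReport, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "q1": report.q1,
                "q3": report.q3,
                "iqr": report.iqr,
                "multiplier": report.multiplier,
                "upper_fence": report.upper_fence,
                "lower_fence": report.lower_fence,
                "n_positions": report.n_positions,
                "regions_hit": list(report.regions_hit),
                "outliers": [
                    {
                        "position": o.position,
                        "delta": o.delta,
                        "sign": o.sign,
                        "region": o.region,
                    }
                    for o in report.outliers
                ],
            },
            indent=2,
        )
    )


def write_footprint_report(
    calls: Sequence[ProtectionCall],
    path: str | Path,
    *,
    overlap: tuple[int, int, float] | None = None,
) -> None:
    payload: dict = {
        "calls": [
            {
                "position": c.position,
                "delta": c.delta,
                "protected": c.protected,
                "enhanced": c.enhanced,
            }
            for c in calls
        ]
    }
    if overlap is not None:
        payload["reference_overlap"] = {
            "n_overlap": overlap[0],
            "n_reference": overlap[1],
            "fraction": overlap[2],
        }
    Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# LC-MS peak records


def read_peaks_csv(path: str | Path) -> list[PeakRecord]:
    """Read PeakRecords from a CSV with columns mz, rt, intensity."""
    df = pd.read_csv(path)
    required = {"mz", "rt", "intensity"}
    if not required <= set(df.columns):
        raise ParseError(f"peaks CSV needs columns {sorted(required)}")
    return [
        PeakRecord(float(r.mz), float(r.rt), float(r.intensity))
        for r in df.itertuples()
    ]


def write_peaks_csv(records: Sequence[PeakRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "mz": [r.mz for r in records],
            "rt": [r.rt for r in records],
            "intensity": [r.intensity for r in records],
        }
    ).to_csv(path, index=False)
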