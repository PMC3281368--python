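"""Readers and writers for the pipeline's on-disk formats.

FASTA via Bio.SeqIO (wrapped at 60 columns on output), repeat annotations as
GFF3 (1-based inclusive coordinates per the standard, converted from the
package's internal 0-based half-open spans), distance matrices in square
PHYLIP, trees in newick, tabular outputs as TSV, configuration as YAML.
Every writer here has a matching reader so outputs round-trip.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .distances import DistanceMatrix
from .records import RepeatArray, RepeatUnit, SpacerRecord, validate_nucleotides
from .simulate import RecordTruth, SimulationConfig, TruthAnnotation, UnitTruth

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_alignment_fasta",
    "write_units_fasta",
    "write_gff3",
    "read_gff3",
    "write_matches_tsv",
    "write_groups_tsv",
    "read_groups_tsv",
    "write_phylip",
    "read_phylip",
    "write_truth",
    "read_truth",
    "write_config",
    "read_config",
]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[SpacerRecord]:
    """Read spacer records, preserving order; uppercases and validates.

    Duplicate ids and non-IUPAC characters raise ValueError (the latter with
    the offending position).  An empty file yields an empty list.
    """
    records: list[SpacerRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        validate_nucleotides(seq, f"record {rec.id!r}")
        records.append(SpacerRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records, path, wrap: int = 60) -> None:
    seq_records = []
    for r in records:
        rid = r.id if hasattr(r, "id") else r.name
        seq_records.append(SeqRecord(Seq(r.sequence), id=rid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seq_records)


def write_alignment_fasta(alignment, path, wrap: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(row), id=label, description="")
        for label, row in zip(alignment.labels, alignment.rows)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seq_records)


def write_units_fasta(units: list[RepeatUnit], path, wrap: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(u.sequence), id=u.name, description=f"{u.parent_id}:{u.start}-{u.end}")
        for u in units
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# GFF3 repeat annotations


def write_gff3(arrays: list[RepeatArray], path) -> None:
    """One ``repeat_region`` feature per array, child ``repeat_unit`` per unit."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for array in arrays:
            aid = f"{array.parent_id}.array"
            fh.write(
                "\t".join(
                    [
                        array.parent_id,
                        "its2repeats",
                        "repeat_region",
                        str(array.start + 1),
                        str(array.end),
                        ".",
                        "+",
                        ".",
                        f"ID={aid};period={array.period:g}",
                    ]
                )
                + "\n"
            )
            for u in array.units:
                fh.write(
                    "\t".join(
                        [
                            array.parent_id,
                            "its2repeats",
                            "repeat_unit",
                            str(u.start + 1),
                            str(u.end),
                            ".",
                            "+",
                            ".",
                            f"ID={u.name};Parent={aid};boundary={u.boundary}",
                        ]
                    )
                    + "\n"
                )


def read_gff3(path, records: list[SpacerRecord] | None = None) -> list[RepeatArray]:
    """Read back arrays written by :func:`write_gff3`.

    When ``records`` is given, unit sequences are filled in from them;
    otherwise sequences are left as placeholders of the right length.
    """
    by_id = {r.id: r for r in (records or [])}
    arrays: dict[str, RepeatArray] = {}
    units: dict[str, list[RepeatUnit]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            seqid, _, ftype, start, end, _, _, _, attrs = line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            s, e = int(start) - 1, int(end)
            if ftype == "repeat_region":
                arrays[fields["ID"]] = RepeatArray(
                    parent_id=seqid, start=s, end=e, period=float(fields.get("period", 0))
                )
            elif ftype == "repeat_unit":
                rec = by_id.get(seqid)
                seq = rec.sequence[s:e] if rec else "N" * (e - s)
                idx = len(units.setdefault(fields["Parent"], [])) + 1
                units[fields["Parent"]].append(
                    RepeatUnit(
                        parent_id=seqid,
                        index=idx,
                        start=s,
                        end=e,
                        name=fields["ID"],
                        sequence=seq,
                        boundary=fields.get("boundary", "motif"),
                    )
                )
    out = []
    for aid, array in arrays.items():
        array.units = sorted(units.get(aid, []), key=lambda u: u.start)
        for i, u in enumerate(array.units, start=1):
            u.index = i
        out.append(array)
    return out


# ---------------------------------------------------------------------------
# TSV tables


def write_matches_tsv(matches, path) -> None:
    df = pd.DataFrame(
        [(m.offset, m.start, m.length, m.identity) for m in matches],
        columns=["offset", "start", "length", "identity"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_groups_tsv(assignment, path) -> None:
    rows = [(u, assignment.label(u)) for u in assignment.assignment]
    df = pd.DataFrame(rows, columns=["unit", "group"])
    df.to_csv(path, sep="\t", index=False)
    over = pd.DataFrame(
        [(e.kind, ",".join(e.units), e.group, e.support) for e in assignment.overrides],
        columns=["kind", "units", "group", "support"],
    )
    over.to_csv(str(path) + ".overrides", sep="\t", index=False)


def read_groups_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["unit"], df["group"]))


# ---------------------------------------------------------------------------
# PHYLIP square distance matrices


def write_phylip(dm: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(dm)}\n")
        for label, row in zip(dm.labels, dm.values):
            cells = " ".join(f"{v:.6f}" for v in row)
            fh.write(f"{label:<12s} {cells}\n")


def read_phylip(path) -> DistanceMatrix:
    import numpy as np

    with open(path) as fh:
        n = int(fh.readline().strip())
        labels, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    values = np.asarray(rows)
    # symmetrise away the round-off introduced by fixed-precision printing
    values = (values + values.T) / 2.0
    return DistanceMatrix(labels=labels, values=values)


# ---------------------------------------------------------------------------
# truth sidecar and configuration


def write_truth(truth: TruthAnnotation, path) -> None:
    rows = []
    for rec in truth.records.values():
        for u in rec.units:
            rows.append(
                (
                    rec.record_id,
                    rec.species_code,
                    rec.array_start,
                    rec.array_end,
                    u.name,
                    u.start,
                    u.end,
                    u.group,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "record_id",
            "species_code",
            "array_start",
            "array_end",
            "unit",
            "start",
            "end",
            "group",
        ],
    )
    with open(path, "w") as fh:
        fh.write(f"#seed={truth.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_truth(path) -> TruthAnnotation:
    with open(path) as fh:
        header = fh.readline()
        seed = int(header.strip().split("=", 1)[1]) if header.startswith("#seed=") else 0
        df = pd.read_csv(fh, sep="\t")
    records: dict[str, RecordTruth] = {}
    for rid, sub in df.groupby("record_id", sort=False):
        sub = sub.sort_values("start")
        records[rid] = RecordTruth(
            record_id=rid,
            species_code=str(sub["species_code"].iloc[0]),
            array_start=int(sub["array_start"].iloc[0]),
            array_end=int(sub["array_end"].iloc[0]),
            units=[
                UnitTruth(
                    name=row["unit"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    group=int(row["group"]),
                )
                for _, row in sub.iterrows()
            ],
        )
    return TruthAnnotation(seed=seed, records=records)


def write_config(config: SimulationConfig, path) -> None:
    data = dataclasses.asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_config(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    for key in (
        "unit_length_range",
        "flank_lengths",
        "background_lengths",
        "species_codes",
        "units_per_species",
    ):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    if "short_units" in data and data["short_units"]:
        data["short_units"] = {
            sp: {int(k): int(v) for k, v in d.items()} for sp, d in data["short_units"].items()
        }
    return SimulationConfig(**data)
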