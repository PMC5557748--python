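"""Readers and writers for the pipeline's standard inputs.

Four plain-text formats are consumed: a tab-delimited OTU count table
(OTUs in rows, samples in columns), an aligned FASTA of representative
OTU sequences, a pedigree CSV and a sample-metadata CSV.  Everything is
validated on read so downstream stages can assume well-formed data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "ValidationError",
    "AlignmentError",
    "OtuCountTable",
    "OtuSequenceSet",
    "SampleMetadata",
    "read_count_table",
    "write_count_table",
    "read_aligned_fasta",
    "write_aligned_fasta",
    "read_metadata",
    "write_metadata",
]

VALID_BASES = frozenset("ACGTN-")
LIFE_STAGES = frozenset({"adult", "juvenile", "egg"})


class FormatError(ValueError):
    """The file does not conform to the documented dialect."""


class ValidationError(ValueError):
    """The file parses but violates a data-model invariant."""


class AlignmentError(ValidationError):
    """Sequences that must form an alignment have unequal lengths."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} {i!r}")
        seen.add(i)


@dataclass
class OtuCountTable:
    """Integer read counts, OTUs in rows and samples in columns."""

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_otus, n_samples) int64

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        _check_unique(self.otu_ids, "otu_id")
        _check_unique(self.sample_ids, "sample_id")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise FormatError("counts must be non-negative")
        empty = np.flatnonzero(self.counts.sum(axis=0) == 0)
        if empty.size:
            names = ", ".join(self.sample_ids[j] for j in empty)
            raise ValidationError(f"sample(s) with zero total counts: {names}")

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def select_otus(self, otu_ids: Sequence[str]) -> "OtuCountTable":
        idx = {o: i for i, o in enumerate(self.otu_ids)}
        rows = [idx[o] for o in otu_ids]
        return OtuCountTable(list(otu_ids), list(self.sample_ids), self.counts[rows])


@dataclass
class OtuSequenceSet:
    """Aligned representative sequences, one per OTU, equal length."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            by_len: dict[int, list[str]] = {}
            for k, s in self.sequences.items():
                by_len.setdefault(len(s), []).append(k)
            raise AlignmentError(f"unequal sequence lengths: { {k: v for k, v in by_len.items()} }")
        for otu, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(f"invalid character(s) {sorted(bad)} in sequence {otu!r}")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.sequences)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def matches(self, table: OtuCountTable) -> bool:
        return set(self.sequences) == set(table.otu_ids)

    def subset(self, otu_ids: Sequence[str]) -> "OtuSequenceSet":
        return OtuSequenceSet({o: self.sequences[o] for o in otu_ids})


@dataclass
class SampleMetadata:
    """Per-sample study annotations linking communities to the pedigree."""

    records: dict[str, tuple[str, str, str, str]] = field(default_factory=dict)
    # sample_id -> (individual_id, life_stage, group_id, cohort)

    def __post_init__(self) -> None:
        for sid, (_, stage, _, _) in self.records.items():
            if stage not in LIFE_STAGES:
                raise ValidationError(f"sample {sid!r}: unknown life stage {stage!r}")

    def individual(self, sample_id: str) -> str:
        return self.records[sample_id][0]

    def group(self, sample_id: str) -> str:
        return self.records[sample_id][2]

    def validate_against(self, table: OtuCountTable, pedigree_ids: set[str]) -> None:
        for sid in self.records:
            if sid not in table.sample_ids:
                raise ValidationError(f"metadata sample {sid!r} absent from count table")
        for sid, (ind, _, _, _) in self.records.items():
            if ind not in pedigree_ids:
                raise ValidationError(
                    f"sample {sid!r}: individual {ind!r} not in pedigree"
                )


def read_count_table(path: str | Path) -> OtuCountTable:
    """Parse a tab-delimited count table with an ``otu_id`` header column."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if not header or header[0] != "otu_id":
            raise FormatError(f"{path}: first header cell must be 'otu_id'")
        sample_ids = header[1:]
        otu_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} cells, got {len(row)}")
            otu_ids.append(row[0])
            try:
                values = [int(c) for c in row[1:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer count ({exc})") from None
            if any(v < 0 for v in values):
                raise FormatError(f"{path}:{lineno}: negative count")
            rows.append(values)
    _check_unique(otu_ids, "otu_id")
    _check_unique(sample_ids, "sample_id")
    counts = np.asarray(rows, dtype=np.int64).reshape(len(otu_ids), len(sample_ids))
    return OtuCountTable(otu_ids, sample_ids, counts)


def write_count_table(table: OtuCountTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["otu_id", *table.sample_ids])
        for otu, row in zip(table.otu_ids, table.counts):
            writer.writerow([otu, *row.tolist()])


def read_aligned_fasta(path: str | Path) -> OtuSequenceSet:
    """Read an aligned FASTA; sequences are uppercased, '-' is the only gap."""
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"{path}: duplicate record id {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise FormatError(f"{path}: no FASTA records")
    return OtuSequenceSet(sequences)


def write_aligned_fasta(seqs: OtuSequenceSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=otu, description="") for otu, s in seqs.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta-2line")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read the sample-metadata CSV (sample_id,individual_id,life_stage,group_id,cohort)."""
    path = Path(path)
    expected = ["sample_id", "individual_id", "life_stage", "group_id", "cohort"]
    records: dict[str, tuple[str, str, str, str]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != expected:
            raise FormatError(f"{path}: header must be {','.join(expected)}")
        for row in reader:
            sid = row["sample_id"]
            if sid in records:
                raise FormatError(f"{path}: duplicate sample_id {sid!r}")
            records[sid] = (
                row["individual_id"],
                row["life_stage"],
                row["group_id"],
                row["cohort"],
            )
    return SampleMetadata(records)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["sample_id", "individual_id", "life_stage", "group_id", "cohort"])
        for sid, (ind, stage, grp, cohort) in meta.records.items():
            writer.writerow([sid, ind, stage, grp, cohort])
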