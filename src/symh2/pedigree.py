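"""Pedigrees and the additive (numerator) relationship matrix.

Two breeding designs are supported, mirroring the two coral study systems:
a half-diallel cross (a set of parents crossed pairwise, self-crosses
excluded, as for broadcast-spawning *Acropora tenuis*) and a maternal-only
design (eggs of known dam and unknown sire, as for *Montipora digitata*).

The A matrix is built with the tabular method: processing individuals in
pedigree order,

    A_ii = 1 + 0.5 * A(sire, dam)        (0 if either parent unknown)
    A_ij = 0.5 * (A(j, sire_i) + A(j, dam_i))   for earlier j,

with an unknown parent contributing nothing.  Founders are assumed
non-inbred and mutually unrelated.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PedigreeError",
    "PedigreeRecord",
    "Pedigree",
    "AMatrix",
    "build_diallel_pedigree",
    "build_maternal_pedigree",
    "additive_relationship_matrix",
    "read_pedigree",
    "write_pedigree",
]

UNKNOWN = None


class PedigreeError(ValueError):
    pass


@dataclass(frozen=True)
class PedigreeRecord:
    individual_id: str
    sire_id: Optional[str]
    dam_id: Optional[str]


@dataclass
class Pedigree:
    """Topologically ordered pedigree: every parent precedes its offspring."""

    records: list[PedigreeRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.individual_id in seen:
                raise PedigreeError(f"duplicate individual {rec.individual_id!r}")
            for parent in (rec.sire_id, rec.dam_id):
                if parent is not None and parent not in seen:
                    raise PedigreeError(
                        f"parent {parent!r} of {rec.individual_id!r} not defined earlier"
                    )
            if rec.individual_id in (rec.sire_id, rec.dam_id):
                raise PedigreeError(f"{rec.individual_id!r} is its own parent")
            seen.add(rec.individual_id)

    @property
    def ids(self) -> list[str]:
        return [r.individual_id for r in self.records]

    @property
    def founders(self) -> list[str]:
        return [
            r.individual_id
            for r in self.records
            if r.sire_id is None and r.dam_id is None
        ]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class AMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("A matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("A matrix must be symmetric")
        if np.any(np.diag(self.values) < 1 - 1e-12):
            raise ValueError("A matrix diagonal must be >= 1")
        eigmin = float(np.linalg.eigvalsh(self.values).min())
        if eigmin < -1e-8:
            raise ValueError(f"A matrix not PSD (min eigenvalue {eigmin:.3g})")

    def index(self, individual_id: str) -> int:
        return self.ids.index(individual_id)

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        pos = {x: i for i, x in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids])
        return self.values[np.ix_(idx, idx)]


def build_diallel_pedigree(
    parents: Sequence[str],
    crosses: Sequence[tuple[str, str]],
    offspring_counts: Sequence[int],
) -> Pedigree:
    """Pedigree for a (half-)diallel design: founders first, then offspring.

    Offspring are named ``F{k}_{i}`` for the i-th offspring of the k-th cross
    (1-based).  Self-crosses are a design error.
    """
    if len(crosses) != len(offspring_counts):
        raise PedigreeError("one offspring count per cross required")
    parent_set = set(parents)
    if len(parent_set) != len(parents):
        raise PedigreeError("duplicate parent ids")
    records = [PedigreeRecord(p, UNKNOWN, UNKNOWN) for p in parents]
    for k, ((sire, dam), n_off) in enumerate(zip(crosses, offspring_counts), start=1):
        if sire == dam:
            raise PedigreeError(f"self-cross ({sire!r}, {dam!r}) not allowed")
        for parent in (sire, dam):
            if parent not in parent_set:
                raise PedigreeError(f"cross references unknown parent {parent!r}")
        if n_off < 0:
            raise PedigreeError("offspring count must be non-negative")
        for i in range(1, n_off + 1):
            records.append(PedigreeRecord(f"F{k}_{i}", sire, dam))
    return Pedigree(records)


def build_maternal_pedigree(
    dams: Sequence[str], eggs_per_dam: Sequence[int]
) -> Pedigree:
    """Pedigree of eggs with known dam and unknown sire.

    Eggs of one dam are maternal half-sibs (A = 0.25) under the tabular
    rules; each egg-dam pair has A = 0.5.
    """
    if len(dams) != len(eggs_per_dam):
        raise PedigreeError("one egg count per dam required")
    records = [PedigreeRecord(d, UNKNOWN, UNKNOWN) for d in dams]
    for dam, n_eggs in zip(dams, eggs_per_dam):
        if n_eggs < 1:
            raise PedigreeError("each dam needs at least one egg")
        for i in range(1, n_eggs + 1):
            records.append(PedigreeRecord(f"{dam}_egg{i}", UNKNOWN, dam))
    return Pedigree(records)


def additive_relationship_matrix(ped: Pedigree) -> AMatrix:
    """Tabular-method A matrix over the pedigree's individuals, in order."""
    n = len(ped)
    index = {r.individual_id: i for i, r in enumerate(ped.records)}
    A = np.zeros((n, n))
    for i, rec in enumerate(ped.records):
        s = index[rec.sire_id] if rec.sire_id is not None else None
        d = index[rec.dam_id] if rec.dam_id is not None else None
        if s is not None and d is not None:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        for j in range(i):
            a = 0.0
            if s is not None:
                a += 0.5 * A[j, s]
            if d is not None:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
    return AMatrix(ped.ids, A)


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree CSV (individual_id,sire_id,dam_id; blank or NA = unknown)."""
    path = Path(path)
    records: list[PedigreeRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != ["individual_id", "sire_id", "dam_id"]:
            raise PedigreeError(f"{path}: header must be individual_id,sire_id,dam_id")
        for row in reader:
            def _parse(v: str) -> Optional[str]:
                return None if v in ("", "NA") else v
            records.append(
                PedigreeRecord(row["individual_id"], _parse(row["sire_id"]), _parse(row["dam_id"]))
            )
    return Pedigree(records)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["individual_id", "sire_id", "dam_id"])
        for rec in ped.records:
            writer.writerow(
                [rec.individual_id, rec.sire_id or "NA", rec.dam_id or "NA"]
            )
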