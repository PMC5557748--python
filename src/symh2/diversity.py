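"""Similarity-sensitive diversity of OTU communities.

The phenotype handed to the quantitative-genetic stages is the
Leinster–Cobbold effective number of species ^qD^Z(p): a Hill number of
order q generalized by a similarity matrix Z so that near-identical OTUs
(e.g. intragenomic rDNA variants) contribute less independent diversity
than genetically distant ones.

Z is built from "raw" pairwise distances between aligned OTU sequences —
the plain proportion of differing nucleotides, with no substitution model.
Alignment columns where both sequences have a gap, or where either has an
N, are excluded from the comparison; a gap aligned to a base counts as a
difference.

For q ∉ {1, ∞}:   D = ( Σ_i p_i ((Zp)_i)^(q-1) )^(1/(1-q)),
for q = 1:        D = exp( − Σ_i p_i ln (Zp)_i ),
for q = ∞:        D = 1 / max_i (Zp)_i,
with all sums and the max restricted to OTUs with p_i > 0.  q tunes the
weight of rare OTUs: q=0 counts every present OTU equally (richness-like),
large q is dominated by the most ordinary OTU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance import NormalizedAbundanceTable
from .io import OtuSequenceSet

__all__ = [
    "DistanceMatrix",
    "SimilarityMatrix",
    "DiversityTrait",
    "raw_distances",
    "similarity_from_distances",
    "leinster_cobbold",
    "diversity_phenotypes",
]

_NORMALIZATION_TOL = 1e-8


@dataclass
class DistanceMatrix:
    otu_ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.otu_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("distances must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.otu_ids, columns=self.otu_ids)


@dataclass
class SimilarityMatrix:
    otu_ids: list[str]
    values: np.ndarray  # Z = 1 - distance; unit diagonal

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.otu_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape mismatch")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("similarity matrix must have unit diagonal")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("similarities must lie in [0, 1]")

    @classmethod
    def identity(cls, otu_ids: list[str]) -> "SimilarityMatrix":
        return cls(list(otu_ids), np.eye(len(otu_ids)))

    def subset(self, otu_ids: list[str]) -> "SimilarityMatrix":
        idx = {o: i for i, o in enumerate(self.otu_ids)}
        rows = np.array([idx[o] for o in otu_ids])
        return SimilarityMatrix(list(otu_ids), self.values[np.ix_(rows, rows)])


@dataclass
class DiversityTrait:
    sample_id: str
    D: float
    q: float
    p: np.ndarray  # per-sample relative abundances, sums to 1


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 5}


def raw_distances(seqs: OtuSequenceSet) -> DistanceMatrix:
    """Proportion of differing nucleotides for every pair of aligned OTUs."""
    otu_ids = seqs.otu_ids
    n = len(otu_ids)
    length = seqs.length
    enc = np.empty((n, length), dtype=np.uint8)
    for i, otu in enumerate(otu_ids):
        enc[i] = np.frombuffer(seqs.sequences[otu].encode(), dtype=np.uint8)
    is_n = enc == ord("N")
    is_gap = enc == ord("-")
    d = np.zeros((n, n))
    for i in range(n):
        # columns dropped: either sequence N, or both gapped
        comparable = ~(is_n[i] | is_n[i + 1:]) & ~(is_gap[i] & is_gap[i + 1:])
        diff = (enc[i] != enc[i + 1:]) & comparable
        denom = comparable.sum(axis=1)
        zero = np.flatnonzero(denom == 0)
        if zero.size:
            j = int(zero[0]) + i + 1
            raise ValueError(
                f"no comparable alignment positions between {otu_ids[i]!r} and {otu_ids[j]!r}"
            )
        d[i, i + 1:] = diff.sum(axis=1) / denom
    d = d + d.T
    return DistanceMatrix(list(otu_ids), d)


def similarity_from_distances(d: DistanceMatrix) -> SimilarityMatrix:
    """Z = 1 − distance, elementwise."""
    return SimilarityMatrix(list(d.otu_ids), 1.0 - d.values)


def leinster_cobbold(p: np.ndarray, Z: SimilarityMatrix, q: float) -> float:
    """Effective number of species of order q under similarity matrix Z."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.shape[0] != len(Z.otu_ids):
        raise ValueError("p must be a vector matching Z's OTU axis")
    if np.any(p < 0):
        raise ValueError("relative abundances must be non-negative")
    if abs(p.sum() - 1.0) > _NORMALIZATION_TOL:
        raise ValueError(f"p must sum to 1 (got {p.sum()!r})")
    if q < 0:
        raise ValueError("q must be non-negative")
    support = p > 0
    zp = (Z.values @ p)[support]
    if np.any(zp <= 0):
        raise ValueError("(Zp)_i vanished on the support of p")
    ps = p[support]
    if math.isinf(q):
        return float(1.0 / zp.max())
    if q == 1:
        return float(np.exp(-np.sum(ps * np.log(zp))))
    return float(np.sum(ps * zp ** (q - 1.0)) ** (1.0 / (1.0 - q)))


def diversity_phenotypes(
    norm: NormalizedAbundanceTable, Z: SimilarityMatrix, q: float = 1.0
) -> list[DiversityTrait]:
    """Per-sample ^qD^Z over a normalized abundance table.

    Each sample's column is rescaled to sum to one before the metric is
    applied, so the phenotype reflects composition, not sequencing depth.
    """
    if list(norm.otu_ids) != list(Z.otu_ids):
        raise ValueError("normalized table and similarity matrix OTU axes disagree")
    traits = []
    totals = norm.values.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("sample with zero total normalized abundance")
    for j, sample in enumerate(norm.sample_ids):
        p = norm.values[:, j] / totals[j]
        traits.append(DiversityTrait(sample, leinster_cobbold(p, Z, q), q, p))
    return traits


def traits_to_frame(traits: list[DiversityTrait]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [t.sample_id for t in traits],
            "q": [t.q for t in traits],
            "D": [t.D for t in traits],
        }
    )
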