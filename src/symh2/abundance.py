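"""Variance normalization and OTU classification.

Counts are placed on a common scale by per-sample size factors estimated with
the median-of-ratios method used for negative-binomial count models (each
sample's factor is the median, over reference OTUs, of the ratio of its count
to that OTU's geometric mean across samples).  Amplicon tables are often too
sparse to contain an OTU observed in every sample, so a positive-counts
fallback computes the geometric mean of each OTU over its nonzero entries
only.

Normalized abundances feed two one-per-OTU classifications:

* abundance — ``principal`` vs ``background`` at 0.01% of total normalized
  reads (dataset-wide share);
* ubiquity — ``core`` (>75% of samples), ``common`` (25–75%) or ``rare``
  (<25%), from presence/absence of raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import OtuCountTable

__all__ = [
    "NormalizedAbundanceTable",
    "OtuClassification",
    "SizeFactorError",
    "size_factors",
    "size_factors_matrix",
    "normalize",
    "classify_abundance",
    "classify_ubiquity",
    "classify",
    "write_classification",
]

BACKGROUND_THRESHOLD = 1e-4  # 0.01% of total normalized reads
CORE_FRACTION = 0.75
RARE_FRACTION = 0.25


class SizeFactorError(ValueError):
    pass


@dataclass
class NormalizedAbundanceTable:
    otu_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # counts / per-sample size factor
    size_factors: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if np.any(self.size_factors <= 0):
            raise SizeFactorError("size factors must be positive")
        if self.values.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match axes")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.otu_ids, columns=self.sample_ids)


@dataclass
class OtuClassification:
    """Per-OTU abundance and ubiquity classes plus the raw statistics."""

    abundance_class: dict[str, str]   # principal | background
    ubiquity_class: dict[str, str]    # core | common | rare
    total_relative_abundance: dict[str, float]
    presence_fraction: dict[str, float]


def size_factors(table: OtuCountTable, allow_sparse_fallback: bool = True) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Reference OTUs are those with nonzero counts in every sample.  When no
    such OTU exists the positive-counts fallback takes, per OTU, the
    geometric mean over nonzero entries only, and per sample the median ratio
    over the OTUs observed in that sample.
    """
    return size_factors_matrix(table.counts, allow_sparse_fallback)


def size_factors_matrix(
    values: np.ndarray, allow_sparse_fallback: bool = True
) -> np.ndarray:
    """Median-of-ratios on a raw (OTU x sample) non-negative matrix."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise SizeFactorError("need at least two samples to estimate size factors")
    counts = values
    all_positive = np.all(counts > 0, axis=1)
    if np.any(all_positive):
        ref = counts[all_positive]
        log_geo = np.mean(np.log(ref), axis=1, keepdims=True)
        ratios = ref / np.exp(log_geo)
        factors = np.median(ratios, axis=0)
    else:
        if not allow_sparse_fallback:
            raise SizeFactorError(
                "no OTU observed in all samples; enable the positive-counts fallback"
            )
        logs = np.full(counts.shape, np.nan)
        np.log(counts, out=logs, where=counts > 0)
        log_geo = np.nanmean(logs, axis=1, keepdims=True)
        ratios = np.where(counts > 0, counts / np.exp(log_geo), np.nan)
        factors = np.nanmedian(ratios, axis=0)
        if np.any(~np.isfinite(factors)):
            raise SizeFactorError("a sample shares no OTU with the rest of the table")
    # fix the overall scale: geometric mean of the factors is 1
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def normalize(table: OtuCountTable, factors: np.ndarray) -> NormalizedAbundanceTable:
    """Divide each sample's counts by its size factor."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (table.n_samples,):
        raise ValueError("one size factor per sample required")
    if np.any(factors <= 0):
        raise SizeFactorError("size factors must be positive")
    values = table.counts / factors[np.newaxis, :]
    return NormalizedAbundanceTable(
        list(table.otu_ids), list(table.sample_ids), values, factors
    )


def classify_abundance(
    norm: NormalizedAbundanceTable, threshold: float = BACKGROUND_THRESHOLD,
    per_sample: bool = False,
) -> dict[str, str]:
    """Label each OTU ``principal`` or ``background``.

    An OTU is background iff its share of the total normalized reads is
    strictly below ``threshold`` (default 0.01%); an OTU exactly at the
    threshold is principal.  With ``per_sample=True`` the share is the OTU's
    maximum per-sample relative abundance instead of the dataset-wide share.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if norm.values.size == 0:
        raise ValueError("empty table")
    if per_sample:
        shares = (norm.values / norm.values.sum(axis=0, keepdims=True)).max(axis=1)
    else:
        shares = norm.values.sum(axis=1) / norm.values.sum()
    return {
        otu: ("background" if share < threshold else "principal")
        for otu, share in zip(norm.otu_ids, shares)
    }


def classify_ubiquity(table: OtuCountTable) -> dict[str, str]:
    """Label each OTU core (>75% of samples), rare (<25%) or common."""
    if table.counts.size == 0:
        raise ValueError("empty table")
    presence = (table.counts > 0).mean(axis=1)
    out = {}
    for otu, f in zip(table.otu_ids, presence):
        if f > CORE_FRACTION:
            out[otu] = "core"
        elif f < RARE_FRACTION:
            out[otu] = "rare"
        else:
            out[otu] = "common"
    return out


def classify(
    table: OtuCountTable, norm: NormalizedAbundanceTable,
    threshold: float = BACKGROUND_THRESHOLD,
) -> OtuClassification:
    shares = norm.values.sum(axis=1) / norm.values.sum()
    presence = (table.counts > 0).mean(axis=1)
    return OtuClassification(
        abundance_class=classify_abundance(norm, threshold),
        ubiquity_class=classify_ubiquity(table),
        total_relative_abundance=dict(zip(norm.otu_ids, shares.tolist())),
        presence_fraction=dict(zip(table.otu_ids, presence.tolist())),
    )


def write_classification(cls: OtuClassification, path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "otu_id": list(cls.abundance_class),
            "abundance_class": list(cls.abundance_class.values()),
            "ubiquity_class": [cls.ubiquity_class[o] for o in cls.abundance_class],
            "total_relative_abundance": [
                cls.total_relative_abundance[o] for o in cls.abundance_class
            ],
            "presence_fraction": [cls.presence_fraction[o] for o in cls.abundance_class],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
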