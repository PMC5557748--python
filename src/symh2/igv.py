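"""Intragenomic-variant (IGV) detection and collapsing.

ITS-2 is a multicopy rDNA marker: one *Symbiodinium* genome can carry
several distinct sequence copies that OTU clustering then reports as
separate taxa.  Because such pseudo-variants ride along in the same
genome, their abundances co-vary almost perfectly across samples.  The
three-step procedure here exploits both signals:

1. candidate grouping — average-linkage hierarchical clustering of the
   raw-distance matrix, cut at a small height (default 0.03, the
   complement of the conventional 97% OTU identity), keeps clusters of
   two or more OTUs;
2. correlation filter — within each candidate group, members whose
   pairwise Pearson correlation of normalized abundance satisfies
   |r| in [0.8, 1] are retained (the largest mutually-correlated subset);
3. collapse — member counts are summed into the group's most abundant
   member and the other rows (and sequences) are dropped.

Re-estimating heritability on the collapsed table quantifies how much
pseudo-variants biased the original estimate; for truly co-inherited
variants the shift is expected to be tiny.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats

from .abundance import NormalizedAbundanceTable
from .io import OtuCountTable, OtuSequenceSet
from .diversity import DistanceMatrix

__all__ = [
    "IgvGroup",
    "IgvGroupSet",
    "candidate_groups",
    "correlation_filter",
    "collapse",
]

DEFAULT_CUT_HEIGHT = 0.03  # complement of the 97% OTU-identity convention
DEFAULT_R_BAND = (0.8, 1.0)


@dataclass
class IgvGroup:
    members: list[str]
    representative: str
    correlations: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class IgvGroupSet:
    groups: list[IgvGroup]
    excluded_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    # (otu_a, otu_b, reason) for pairs whose correlation was undefined

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            if len(g.members) < 2:
                raise ValueError("IGV groups must have at least 2 members")
            overlap = seen & set(g.members)
            if overlap:
                raise ValueError(f"IGV groups overlap on {sorted(overlap)}")
            seen.update(g.members)

    @property
    def n_members(self) -> int:
        return sum(len(g.members) for g in self.groups)


def candidate_groups(
    d: DistanceMatrix, cut_height: float = DEFAULT_CUT_HEIGHT
) -> list[list[str]]:
    """Clusters of >= 2 OTUs below ``cut_height`` under average linkage."""
    if not 0 < cut_height < 1:
        raise ValueError("cut_height must lie in (0, 1)")
    n = len(d.otu_ids)
    if n < 2:
        return []
    condensed = squareform(d.values, checks=False)
    tree = linkage(condensed, method="average")
    labels = fcluster(tree, t=cut_height, criterion="distance")
    by_label: dict[int, list[str]] = {}
    for otu, lab in zip(d.otu_ids, labels):
        by_label.setdefault(int(lab), []).append(otu)
    return [members for _, members in sorted(by_label.items()) if len(members) >= 2]


def _largest_clique(members: list[str], ok: set[frozenset[str]]) -> list[str]:
    """Largest subset of ``members`` whose pairs are all in ``ok``.

    Bron-Kerbosch with pivoting; candidate groups from real tables are
    small and their correlation graphs sparse, so this is effectively
    instant.  Ties resolve to the first maximum clique found, which is
    deterministic given the input order.
    """
    adj = {m: set() for m in members}
    for a, b in combinations(members, 2):
        if frozenset((a, b)) in ok:
            adj[a].add(b)
            adj[b].add(a)
    best: list[str] = []

    def expand(r: list[str], p: set[str], x: set[str]) -> None:
        nonlocal best
        if not p and not x:
            if len(r) > len(best):
                best = list(r)
            return
        if len(r) + len(p) <= len(best):
            return  # cannot beat the incumbent
        pivot = max(p | x, key=lambda v: len(adj[v] & p))
        for v in [m for m in members if m in p - adj[pivot]]:
            expand(r + [v], p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    expand([], set(members), set())
    return best


def correlation_filter(
    groups: list[list[str]],
    norm: NormalizedAbundanceTable,
    r_band: tuple[float, float] = DEFAULT_R_BAND,
    method: str = "pearson",
) -> IgvGroupSet:
    """Keep, per candidate group, the largest mutually-correlated subset.

    A pair passes when |r| of its normalized-abundance profiles lies in
    ``r_band`` (both strong positive and strong negative correlations count
    as intragenomic-variant signal).  Zero-variance profiles make r
    undefined; such pairs are excluded with a logged reason.
    """
    lo, hi = r_band
    if not 0 <= lo <= hi <= 1:
        raise ValueError("r_band must satisfy 0 <= lo <= hi <= 1")
    idx = {o: i for i, o in enumerate(norm.otu_ids)}
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    out_groups: list[IgvGroup] = []
    excluded: list[tuple[str, str, str]] = []
    totals = norm.values.sum(axis=1)
    for members in groups:
        for m in members:
            if m not in idx:
                raise ValueError(f"group member {m!r} absent from abundance table")
        ok: set[frozenset[str]] = set()
        correlations: dict[tuple[str, str], float] = {}
        for a, b in combinations(members, 2):
            xa, xb = norm.values[idx[a]], norm.values[idx[b]]
            if np.var(xa) == 0 or np.var(xb) == 0:
                excluded.append((a, b, "zero-variance abundance profile"))
                continue
            r = float(corr(xa, xb)[0])
            correlations[(a, b)] = r
            if lo <= abs(r) <= hi:
                ok.add(frozenset((a, b)))
        kept = _largest_clique(members, ok)
        if len(kept) >= 2:
            # representative: highest total abundance, ties lexicographic
            best = max(totals[idx[o]] for o in kept)
            tied = sorted(o for o in kept if totals[idx[o]] == best)
            rep = tied[0]
            out_groups.append(
                IgvGroup(
                    members=sorted(kept),
                    representative=rep,
                    correlations={
                        k: v for k, v in correlations.items()
                        if k[0] in kept and k[1] in kept
                    },
                )
            )
    return IgvGroupSet(out_groups, excluded)


def collapse(
    table: OtuCountTable,
    seqs: Optional[OtuSequenceSet],
    igv: IgvGroupSet,
) -> tuple[OtuCountTable, Optional[OtuSequenceSet]]:
    """Sum each group's counts into its representative row.

    Non-representative members are removed from the table (and the
    sequence set, if given); per-sample column totals are conserved
    exactly.  OTU order follows the input table with members deleted in
    place of their representative.
    """
    idx = {o: i for i, o in enumerate(table.otu_ids)}
    for g in igv.groups:
        for m in g.members:
            if m not in idx:
                raise ValueError(f"IGV member {m!r} absent from count table")
    counts = table.counts.copy()
    drop: set[str] = set()
    for g in igv.groups:
        rep_row = idx[g.representative]
        for m in g.members:
            if m == g.representative:
                continue
            counts[rep_row] += counts[idx[m]]
            drop.add(m)
    keep = [o for o in table.otu_ids if o not in drop]
    rows = [idx[o] for o in keep]
    new_table = OtuCountTable(keep, list(table.sample_ids), counts[rows])
    new_seqs = seqs.subset(keep) if seqs is not None else None
    return new_table, new_seqs
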