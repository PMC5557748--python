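"""Synthetic coral-symbiont heritability studies with known ground truth.

The generator emulates the two study systems end to end:

* a breeding design — either a half-diallel cross (parents crossed
  pairwise, no self-crosses; template: 4 parents / 9 families and
  8 parents / 25 families) or a maternal-only design (~9 dams each
  contributing 5–12 eggs, sire unknown);
* a heritable latent host trait simulated under the infinitesimal model
  on the pedigree (founder breeding values N(0, sigma2_A), offspring the
  parental mean plus a Mendelian-sampling deviation, optional
  maternal-environment effect shared by a dam's offspring);
* clade-structured OTU sequences (a few divergent clades, members nearly
  identical within a clade) giving the similarity matrix Z its block
  structure;
* sparse OTU count tables: a handful of principal OTUs whose geometric
  rank-abundance evenness is a logistic function of the latent trait
  (higher trait -> more even community -> higher diversity), a long tail
  of background OTUs each far below 0.01% of reads and present in a
  minority of samples, and negative-binomial read-count noise.

Because the diversity metric has no closed-form inverse under a
non-trivial Z, the latent trait is transmitted to the phenotype through
community evenness; fidelity is checked by a rank-correlation contract
between latent trait and computed diversity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import (
    OtuCountTable,
    OtuSequenceSet,
    SampleMetadata,
    write_aligned_fasta,
    write_count_table,
    write_metadata,
)
from .pedigree import Pedigree, PedigreeError, PedigreeRecord, write_pedigree

__all__ = [
    "SimulationTruth",
    "StudyConfig",
    "StudyBundle",
    "simulate_pedigree_design",
    "simulate_trait",
    "simulate_sequences",
    "simulate_community_counts",
    "split_pseudo_variants",
    "simulate_study",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationTruth:
    """Everything a recovery test needs to score an estimate."""

    h2: float
    sigma2_a: float
    sigma2_e: float
    m2: float
    design: str
    breeding_values: dict[str, float]
    trait_values: dict[str, float]
    n_principal: int
    n_background: int
    n_clades: int
    library_size_mean: float
    nb_dispersion: float
    seed: int

    def __post_init__(self) -> None:
        expected = self.sigma2_a / (self.sigma2_a + self.sigma2_e)
        if abs(self.h2 - expected) > 1e-12:
            raise ValueError("truth h2 inconsistent with variance components")

    def to_json(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            json.dump(asdict(self), fh, indent=2)


def simulate_pedigree_design(
    design: str,
    n_parents: int,
    n_families: int,
    offspring_per_family: int | tuple[int, int],
    seed: int,
) -> Pedigree:
    """Reproducible pedigree for a half-diallel or maternal-only design.

    ``offspring_per_family`` is either a fixed count or an inclusive
    (low, high) range sampled per family — the study template had 1-29
    juveniles per cross and 5-12 eggs per dam.
    """
    rng = np.random.default_rng(seed)

    def _count() -> int:
        if isinstance(offspring_per_family, tuple):
            lo, hi = offspring_per_family
            return int(rng.integers(lo, hi + 1))
        return int(offspring_per_family)

    if design == "half_diallel":
        max_crosses = n_parents * (n_parents - 1) // 2
        if n_families > max_crosses:
            raise PedigreeError(
                f"{n_families} families infeasible: {n_parents} parents allow at "
                f"most {max_crosses} non-self undirected crosses"
            )
        parents = [f"P{i+1}" for i in range(n_parents)]
        all_pairs = [
            (parents[i], parents[j])
            for i in range(n_parents)
            for j in range(i + 1, n_parents)
        ]
        chosen = rng.choice(len(all_pairs), size=n_families, replace=False)
        records = [PedigreeRecord(p, None, None) for p in parents]
        for k, pair_idx in enumerate(sorted(chosen.tolist()), start=1):
            sire, dam = all_pairs[pair_idx]
            for i in range(1, _count() + 1):
                records.append(PedigreeRecord(f"F{k}_{i}", sire, dam))
        return Pedigree(records)
    if design == "maternal_only":
        dams = [f"D{i+1}" for i in range(n_parents)]
        records = [PedigreeRecord(d, None, None) for d in dams]
        for dam in dams:
            for i in range(1, _count() + 1):
                records.append(PedigreeRecord(f"{dam}_egg{i}", None, dam))
        return Pedigree(records)
    raise ValueError(f"unknown design {design!r}")


def simulate_trait(
    ped: Pedigree,
    sigma2_a: float,
    sigma2_e: float,
    m2: float,
    seed: int,
    mu: float = 0.0,
) -> tuple[dict[str, float], SimulationTruth]:
    """Infinitesimal-model latent trait on a pedigree.

    Breeding values: founders ~ N(0, sigma2_A); offspring with two known
    parents get the parental mean plus N(0, 0.5 sigma2_A) Mendelian
    sampling; a single known parent contributes half its value with
    N(0, 0.75 sigma2_A) deviation.  A maternal-environment effect
    N(0, m2 * sigma2_P) is shared by all offspring of one dam.  The trait
    is mu + a + m + N(0, sigma2_E).
    """
    if sigma2_a < 0 or sigma2_e < 0 or m2 < 0:
        raise ValueError("variances must be non-negative")
    rng = np.random.default_rng(seed)
    sigma2_p = sigma2_a + sigma2_e
    a: dict[str, float] = {}
    maternal: dict[str, float] = {}
    traits: dict[str, float] = {}
    sd_m = np.sqrt(m2 * sigma2_p)
    for rec in ped.records:
        s, d = rec.sire_id, rec.dam_id
        if s is None and d is None:
            a[rec.individual_id] = rng.normal(0.0, np.sqrt(sigma2_a))
        elif s is not None and d is not None:
            mend = rng.normal(0.0, np.sqrt(0.5 * sigma2_a))
            a[rec.individual_id] = 0.5 * (a[s] + a[d]) + mend
        else:
            parent = s if s is not None else d
            mend = rng.normal(0.0, np.sqrt(0.75 * sigma2_a))
            a[rec.individual_id] = 0.5 * a[parent] + mend
        m_eff = 0.0
        if d is not None and m2 > 0:
            if d not in maternal:
                maternal[d] = rng.normal(0.0, sd_m)
            m_eff = maternal[d]
        traits[rec.individual_id] = (
            mu + a[rec.individual_id] + m_eff + rng.normal(0.0, np.sqrt(sigma2_e))
        )
    truth = SimulationTruth(
        h2=sigma2_a / (sigma2_a + sigma2_e),
        sigma2_a=sigma2_a,
        sigma2_e=sigma2_e,
        m2=m2,
        design="custom",
        breeding_values=a,
        trait_values=traits,
        n_principal=0,
        n_background=0,
        n_clades=0,
        library_size_mean=0.0,
        nb_dispersion=0.0,
        seed=seed,
    )
    return traits, truth


def simulate_sequences(
    n_otus: int,
    length: int,
    n_clades: int,
    within_clade_divergence: float,
    between_clade_divergence: float,
    seed: int,
) -> OtuSequenceSet:
    """Clade-structured aligned sequences.

    Each clade's ancestor is the root mutated at ~between/2 of its
    positions (so ancestors sit ~``between`` apart pairwise); each member
    is its ancestor mutated at ~``within`` of positions.  OTU ids are
    ``OTU1..OTUn`` assigned to clades round-robin.
    """
    if not (0 <= within_clade_divergence < between_clade_divergence < 1):
        raise ValueError("need 0 <= within < between < 1")
    n_between = int(round(length * between_clade_divergence / 2.0))
    n_within = int(round(length * within_clade_divergence))
    if n_between > length or n_within > length:
        raise ValueError("divergence infeasible for sequence length")
    rng = np.random.default_rng(seed)
    root = rng.choice(BASES, size=length)

    def _mutate(seq: np.ndarray, n_sites: int) -> np.ndarray:
        out = seq.copy()
        if n_sites == 0:
            return out
        sites = rng.choice(length, size=n_sites, replace=False)
        for s in sites:
            choices = BASES[BASES != out[s]]
            out[s] = rng.choice(choices)
        return out

    ancestors = [_mutate(root, n_between) for _ in range(n_clades)]
    sequences: dict[str, str] = {}
    for i in range(n_otus):
        clade = i % n_clades
        seq = _mutate(ancestors[clade], n_within)
        sequences[f"OTU{i+1}"] = seq.tobytes().decode()
    return OtuSequenceSet(sequences)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mean + mean^2 * dispersion."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    positive = mean > 0
    out[positive] = rng.negative_binomial(r, p[positive])
    return out


def simulate_community_counts(
    latent: dict[str, float],
    seqs: OtuSequenceSet,
    n_principal: int,
    n_background: int,
    library_size_mean: float,
    nb_dispersion: float,
    seed: int,
) -> OtuCountTable:
    """OTU counts whose community evenness tracks the latent host trait.

    The first ``n_principal`` OTUs receive geometric rank-abundance shares
    w_j proportional to r^j, with the ratio r the logistic transform of the
    individual's standardized latent trait — a monotone map from trait to
    evenness, hence to diversity.  The remaining OTUs are background: each
    is present in a random minority of samples (per-OTU inclusion rate
    drawn from U(0.05, 0.25)) at an expected share below 0.01%.  Counts
    are negative binomial around library-size-scaled expectations.
    """
    if n_principal + n_background != len(seqs.otu_ids):
        raise ValueError("n_principal + n_background must equal the sequence count")
    if n_principal < 2:
        raise ValueError("need at least two principal OTUs to vary evenness")
    values = np.array([latent[k] for k in latent])
    if not np.all(np.isfinite(values)):
        raise ValueError("latent trait values must be finite")
    if library_size_mean < 1e4:
        # background OTUs sit below 1e-4 relative abundance; small libraries
        # cannot resolve them
        import warnings

        warnings.warn(
            "library_size_mean is small; background OTUs may be unobservable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    individuals = list(latent)
    n_samples = len(individuals)
    scale = values.std() if values.std() > 0 else 1.0
    z = (values - values.mean()) / scale
    evenness = 1.0 / (1.0 + np.exp(-z))  # in (0,1); higher -> more even

    otu_ids = seqs.otu_ids
    principal_ids = otu_ids[:n_principal]
    background_ids = otu_ids[n_principal:]
    incl_rate = rng.uniform(0.05, 0.25, size=n_background)
    bg_share = rng.uniform(2e-6, 5e-5, size=n_background)

    counts = np.zeros((len(otu_ids), n_samples), dtype=np.int64)
    lib_sigma = 0.3
    lib_sizes = rng.lognormal(
        np.log(library_size_mean) - 0.5 * lib_sigma**2, lib_sigma, size=n_samples
    )
    ranks = np.arange(n_principal)
    for j in range(n_samples):
        r = evenness[j]
        w = r**ranks
        w = w / w.sum()
        present = rng.random(n_background) < incl_rate
        bg = np.where(present, bg_share, 0.0)
        shares = np.concatenate([w * (1.0 - bg.sum()), bg])
        mean = shares * lib_sizes[j]
        counts[:, j] = _nb_draw(rng, mean, nb_dispersion)
        if counts[:, j].sum() == 0:  # guard against an empty library
            counts[np.argmax(shares), j] = 1
    sample_ids = [f"S_{ind}" for ind in individuals]
    return OtuCountTable(list(otu_ids), sample_ids, counts)


def split_pseudo_variants(
    table: OtuCountTable,
    seqs: OtuSequenceSet,
    group_sizes: Sequence[int],
    seed: int,
    target_otus: Optional[Sequence[str]] = None,
) -> tuple[OtuCountTable, OtuSequenceSet, list[list[str]]]:
    """Split OTUs into perfectly co-inherited pseudo-variants.

    Used to emulate intragenomic rDNA variants: for each requested group
    size g, one source OTU's counts are apportioned deterministically
    across g variant rows (fixed proportions, remainders to the first
    variant, column sums conserved), and each variant's sequence is the
    source sequence with a single substitution at a distinct site.  The
    true variant groups are returned for recovery checks.
    """
    rng = np.random.default_rng(seed)
    if target_otus is None:
        totals = table.counts.sum(axis=1)
        order = np.argsort(-totals, kind="stable")
        target_otus = [table.otu_ids[i] for i in order[: len(group_sizes)]]
    if len(target_otus) != len(group_sizes):
        raise ValueError("one target OTU per group size required")
    idx = {o: i for i, o in enumerate(table.otu_ids)}
    new_otu_ids: list[str] = []
    new_rows: list[np.ndarray] = []
    new_seqs: dict[str, str] = {}
    groups: list[list[str]] = []
    split_map = dict(zip(target_otus, group_sizes))
    length = seqs.length
    for otu in table.otu_ids:
        row = table.counts[idx[otu]]
        if otu not in split_map:
            new_otu_ids.append(otu)
            new_rows.append(row)
            new_seqs[otu] = seqs.sequences[otu]
            continue
        g = split_map[otu]
        if g < 2:
            raise ValueError("group sizes must be >= 2")
        props = rng.dirichlet(np.full(g, 5.0))
        parts = np.floor(row[np.newaxis, :] * props[:, np.newaxis]).astype(np.int64)
        parts[0] += row - parts.sum(axis=0)  # conserve column sums exactly
        base = np.frombuffer(seqs.sequences[otu].encode(), dtype=np.uint8)
        sites = rng.choice(length, size=g - 1, replace=False)
        members = []
        for v in range(g):
            name = otu if v == 0 else f"{otu}_igv{v}"
            seq = base.copy()
            if v > 0:
                s = sites[v - 1]
                seq[s] = rng.choice(BASES[BASES != seq[s]])
            new_otu_ids.append(name)
            new_rows.append(parts[v])
            new_seqs[name] = seq.tobytes().decode()
            members.append(name)
        groups.append(members)
    new_table = OtuCountTable(new_otu_ids, list(table.sample_ids), np.vstack(new_rows))
    return new_table, OtuSequenceSet(new_seqs), groups


@dataclass
class StudyConfig:
    """Parameters of one synthetic study; defaults mirror the maternal design."""

    design: str = "maternal_only"            # or "half_diallel"
    n_parents: int = 9
    n_families: int = 9
    offspring_per_family: int | tuple[int, int] = (5, 12)
    sigma2_a: float = 0.6
    sigma2_e: float = 0.4
    m2: float = 0.0
    trait_mean: float = 0.0
    n_principal: int = 8
    n_background: int = 60
    n_clades: int = 3
    seq_length: int = 300
    within_clade_divergence: float = 0.01
    between_clade_divergence: float = 0.25
    library_size_mean: float = 20_000.0
    nb_dispersion: float = 0.2
    seed: int = 0

    @property
    def true_h2(self) -> float:
        return self.sigma2_a / (self.sigma2_a + self.sigma2_e)


@dataclass
class StudyBundle:
    """In-memory synthetic study: inputs plus ground truth."""

    table: OtuCountTable
    seqs: OtuSequenceSet
    pedigree: Pedigree
    metadata: SampleMetadata
    truth: SimulationTruth
    latent: dict[str, float]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


def simulate_study(config: StudyConfig, out_dir: Optional[str | Path] = None) -> StudyBundle:
    """Generate a complete study; optionally write the pipeline input files.

    Written files: ``counts.tsv``, ``otus.fasta``, ``pedigree.csv``,
    ``metadata.csv`` and ``truth.json``.
    """
    seeds = _spawn_seeds(config.seed, 4)
    ped = simulate_pedigree_design(
        config.design,
        config.n_parents,
        config.n_families,
        config.offspring_per_family,
        seeds[0],
    )
    latent, truth = simulate_trait(
        ped, config.sigma2_a, config.sigma2_e, config.m2, seeds[1], mu=config.trait_mean
    )
    seqs = simulate_sequences(
        config.n_principal + config.n_background,
        config.seq_length,
        config.n_clades,
        config.within_clade_divergence,
        config.between_clade_divergence,
        seeds[2],
    )
    table = simulate_community_counts(
        latent,
        seqs,
        config.n_principal,
        config.n_background,
        config.library_size_mean,
        config.nb_dispersion,
        seeds[3],
    )
    truth.design = config.design
    truth.n_principal = config.n_principal
    truth.n_background = config.n_background
    truth.n_clades = config.n_clades
    truth.library_size_mean = config.library_size_mean
    truth.nb_dispersion = config.nb_dispersion
    truth.seed = config.seed

    founders = set(ped.founders)
    records: dict[str, tuple[str, str, str, str]] = {}
    for rec in ped.records:
        ind = rec.individual_id
        if ind in founders:
            stage = "adult"
            group = ind
        elif config.design == "maternal_only":
            stage = "egg"
            group = rec.dam_id or ind
        else:
            stage = "juvenile"
            group = ind.rsplit("_", 1)[0]  # family tag F{k}
        records[f"S_{ind}"] = (ind, stage, group, "sim")
    metadata = SampleMetadata(records)

    bundle = StudyBundle(table, seqs, ped, metadata, truth, latent)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_count_table(table, out_dir / "counts.tsv")
        write_aligned_fasta(seqs, out_dir / "otus.fasta")
        write_pedigree(ped, out_dir / "pedigree.csv")
        write_metadata(metadata, out_dir / "metadata.csv")
        truth.to_json(out_dir / "truth.json")
    return bundle
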