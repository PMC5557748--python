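"""End-to-end pipeline: normalize -> classify -> diversity -> heritability.

The pipeline reads the four standard inputs, computes per-sample
similarity-sensitive diversity as the host phenotype, estimates
narrow-sense heritability with the Bayesian animal model and with
parent-offspring regression, optionally re-runs the estimate after
intragenomic-variant collapsing, and writes every intermediate artifact
plus a machine-validated JSON report.

A single top-level seed governs all stochastic stages: each stage derives
its own seed from (seed, stage-name), so stages are independently
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import abundance as ab
from . import diversity as dv
from . import igv as igv_mod
from .animal_model import (
    H2Posterior,
    InverseGammaPrior,
    MCMCSettings,
    ModelSpec,
    compare_maternal_models,
    gibbs_animal_model,
    write_chains_tsv,
)
from .io import (
    read_aligned_fasta,
    read_count_table,
    read_metadata,
)
from .pedigree import additive_relationship_matrix, read_pedigree
from .regression import (
    RegressionError,
    midparent_regression,
    single_parent_regression,
)

__all__ = ["PipelineConfig", "StudyReport", "validate_config", "run_pipeline", "derive_seed"]

logger = logging.getLogger("symh2")


def derive_seed(seed: int, stage: str) -> int:
    """Stage-keyed seed derivation: stable, documented, below 2^31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class MCMCConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_iterations: int = Field(60_000, ge=1)
    burn_in: float = Field(0.10, ge=0.0, lt=1.0)
    thinning: int = Field(25, ge=1)
    prior_shape: float = Field(0.001, gt=0)
    prior_scale: float = Field(0.001, gt=0)


class IgvConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = False
    cut_height: float = Field(igv_mod.DEFAULT_CUT_HEIGHT, gt=0.0, lt=1.0)
    r_low: float = Field(0.8, ge=0.0, le=1.0)
    r_high: float = Field(1.0, ge=0.0, le=1.0)
    correlation: Literal["pearson", "spearman"] = "pearson"


class PipelineConfig(BaseModel):
    """Validated configuration for one pipeline run."""

    model_config = ConfigDict(extra="forbid")

    counts: str
    fasta: str
    pedigree: str
    metadata: str
    output_dir: str = "pipeline_out"
    q: float = Field(1.0, ge=0.0)
    abundance_threshold: float = Field(ab.BACKGROUND_THRESHOLD, gt=0.0, lt=1.0)
    seed: int = 0
    mcmc: MCMCConfig = Field(default_factory=MCMCConfig)
    regression_mode: Literal["auto", "midparent", "single_parent", "none"] = "auto"
    maternal_comparison: bool = True
    igv: IgvConfig = Field(default_factory=IgvConfig)


class RegressionBlock(BaseModel):
    mode: str
    slope: float
    se_slope: float
    intercept: float
    n: int
    h2: float
    warnings: list[str]


class BayesBlock(BaseModel):
    h2_mode: float
    h2_mean: float
    h2_sd: float
    ci95: list[float]
    dic: float
    n_retained: int
    seed: int
    diagnostics: dict[str, float]
    warnings: list[str]


class MaternalBlock(BaseModel):
    dic_no_maternal: float
    dic_maternal: float
    delta_dic: float
    selected: str


class IgvBlock(BaseModel):
    n_groups: int
    n_members: int
    n_otus_before: int
    n_otus_after: int
    groups: list[list[str]]
    h2_mode_raw: float
    h2_mode_collapsed: float
    h2_shift: float


class StudyReport(BaseModel):
    """Machine-readable pipeline result; the schema ships next to it."""

    model_config = ConfigDict(extra="forbid")

    n_samples: int
    n_otus: int
    q: float
    seed: int
    config_hash: str
    diversity: dict[str, float]
    classification_counts: dict[str, dict[str, int]]
    bayes: Optional[BayesBlock] = None
    maternal: Optional[MaternalBlock] = None
    regression: list[RegressionBlock] = Field(default_factory=list)
    igv: Optional[IgvBlock] = None


def validate_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config; defaults filled, unknown keys rejected."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def _round6(x: float) -> float:
    return float(f"{x:.6g}")


def _fit_to_block(fit: H2Posterior) -> BayesBlock:
    return BayesBlock(
        h2_mode=_round6(fit.summary.mode),
        h2_mean=_round6(fit.summary.mean),
        h2_sd=_round6(fit.summary.sd),
        ci95=[_round6(fit.summary.ci95[0]), _round6(fit.summary.ci95[1])],
        dic=_round6(fit.dic),
        n_retained=fit.n_retained,
        seed=fit.settings.seed,
        diagnostics={k: _round6(v) for k, v in fit.diagnostics.items()},
        warnings=fit.warnings,
    )


def run_pipeline(config: PipelineConfig) -> StudyReport:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = config.model_dump_json()
    config_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]
    logger.info("pipeline start (seed=%d, q=%g, hash=%s)", config.seed, config.q, config_hash)

    table = read_count_table(config.counts)
    seqs = read_aligned_fasta(config.fasta)
    ped = read_pedigree(config.pedigree)
    meta = read_metadata(config.metadata)
    if not seqs.matches(table):
        raise ValueError("FASTA OTU ids do not match the count table")
    meta.validate_against(table, set(ped.ids))

    # --- normalization and classification -------------------------------
    factors = ab.size_factors(table)
    norm = ab.normalize(table, factors)
    cls = ab.classify(table, norm, config.abundance_threshold)
    ab.write_classification(cls, out / "classification.tsv")
    norm.to_frame().to_csv(out / "normalized.tsv", sep="\t")
    logger.info("size factors and classification done (%d OTUs)", table.n_otus)

    # --- diversity phenotype ---------------------------------------------
    dist = dv.raw_distances(seqs)
    Z = dv.similarity_from_distances(dist)
    # align Z to count-table OTU order
    Z = Z.subset(list(table.otu_ids))
    dist.to_frame().to_csv(out / "distances.tsv", sep="\t")
    traits = dv.diversity_phenotypes(norm, Z, config.q)
    dv.traits_to_frame(traits).to_csv(out / "traits.tsv", sep="\t", index=False)
    trait_by_sample = {t.sample_id: t.D for t in traits}
    logger.info("diversity computed at q=%g for %d samples", config.q, len(traits))

    # --- genetics ---------------------------------------------------------
    A = additive_relationship_matrix(ped)
    np.savetxt(out / "amatrix.tsv", A.values, delimiter="\t")
    parent_of = {r.individual_id: (r.sire_id, r.dam_id) for r in ped.records}

    offspring_samples = [
        sid for sid, (ind, stage, _, _) in meta.records.items() if stage != "adult"
    ]
    adult_trait = {
        meta.individual(sid): trait_by_sample[sid]
        for sid, (_, stage, _, _) in meta.records.items()
        if stage == "adult" and sid in trait_by_sample
    }

    bayes_block = None
    maternal_block = None
    bayes_fit = None
    spec = None
    if offspring_samples:
        y = np.array([trait_by_sample[s] for s in offspring_samples])
        individuals = [meta.individual(s) for s in offspring_samples]
        dams = [parent_of[i][1] for i in individuals]
        dam_ids = [d if d is not None else f"unknown_{i}" for d, i in zip(dams, individuals)]
        prior = InverseGammaPrior(config.mcmc.prior_shape, config.mcmc.prior_scale)
        spec = ModelSpec(
            y=y,
            individual_ids=individuals,
            dam_ids=dam_ids,
            prior_additive=prior,
            prior_residual=prior,
            prior_maternal=prior,
        )
        settings = MCMCSettings(
            config.mcmc.n_iterations,
            config.mcmc.burn_in,
            config.mcmc.thinning,
            derive_seed(config.seed, "animal_model"),
        )
        bayes_fit = gibbs_animal_model(spec, A, settings, include_maternal=False)
        write_chains_tsv(bayes_fit, out / "chains.tsv")
        bayes_block = _fit_to_block(bayes_fit)
        logger.info(
            "animal model: h2 mode %.3f, mean %.3f, CI [%.3f, %.3f]",
            bayes_fit.summary.mode, bayes_fit.summary.mean, *bayes_fit.summary.ci95,
        )
        if config.maternal_comparison and len(set(dam_ids)) >= 2:
            cmp_settings = MCMCSettings(
                config.mcmc.n_iterations,
                config.mcmc.burn_in,
                config.mcmc.thinning,
                derive_seed(config.seed, "maternal_comparison"),
            )
            comparison = compare_maternal_models(spec, A, cmp_settings)
            maternal_block = MaternalBlock(
                dic_no_maternal=_round6(comparison.no_maternal.dic),
                dic_maternal=_round6(comparison.maternal.dic),
                delta_dic=_round6(comparison.delta_dic),
                selected=comparison.selected,
            )

    # --- regression -------------------------------------------------------
    regression_blocks: list[RegressionBlock] = []
    if config.regression_mode != "none" and offspring_samples and adult_trait:
        offspring_records = []
        for sid in offspring_samples:
            ind = meta.individual(sid)
            offspring_records.append((ind, trait_by_sample[sid]))
        modes = (
            ["midparent", "single_parent"]
            if config.regression_mode == "auto"
            else [config.regression_mode]
        )
        for mode in modes:
            try:
                if mode == "midparent":
                    fam_records = []
                    fam_parents = {}
                    for ind, t in offspring_records:
                        sire, dam = parent_of[ind]
                        if sire is None or dam is None:
                            continue
                        if sire not in adult_trait or dam not in adult_trait:
                            continue
                        fam = f"{sire}x{dam}"
                        fam_records.append((fam, t))
                        fam_parents[fam] = (adult_trait[dam], adult_trait[sire])
                    result = midparent_regression(fam_records, fam_parents)
                else:
                    dam_records = []
                    for ind, t in offspring_records:
                        dam = parent_of[ind][1]
                        if dam is not None and dam in adult_trait:
                            dam_records.append((dam, t))
                    result = single_parent_regression(dam_records, adult_trait)
            except RegressionError as exc:
                if config.regression_mode == "auto":
                    logger.info("regression mode %s skipped: %s", mode, exc)
                    continue
                raise
            regression_blocks.append(
                RegressionBlock(
                    mode=result.mode,
                    slope=_round6(result.slope),
                    se_slope=_round6(result.se_slope),
                    intercept=_round6(result.intercept),
                    n=result.n,
                    h2=_round6(result.h2),
                    warnings=result.warnings,
                )
            )

    # --- intragenomic-variant comparison ---------------------------------
    igv_block = None
    if config.igv.enabled and bayes_fit is not None and spec is not None:
        candidates = igv_mod.candidate_groups(dist, config.igv.cut_height)
        groups = igv_mod.correlation_filter(
            candidates, norm, (config.igv.r_low, config.igv.r_high),
            method=config.igv.correlation,
        )
        collapsed_table, collapsed_seqs = igv_mod.collapse(table, seqs, groups)
        factors_c = ab.size_factors(collapsed_table)
        norm_c = ab.normalize(collapsed_table, factors_c)
        Z_c = dv.similarity_from_distances(dv.raw_distances(collapsed_seqs)).subset(
            list(collapsed_table.otu_ids)
        )
        traits_c = dv.diversity_phenotypes(norm_c, Z_c, config.q)
        trait_c = {t.sample_id: t.D for t in traits_c}
        spec_c = ModelSpec(
            y=np.array([trait_c[s] for s in offspring_samples]),
            individual_ids=[meta.individual(s) for s in offspring_samples],
            dam_ids=spec.dam_ids,
            prior_additive=spec.prior_additive,
            prior_residual=spec.prior_residual,
            prior_maternal=spec.prior_maternal,
        )
        fit_c = gibbs_animal_model(spec_c, A, bayes_fit.settings, include_maternal=False)
        igv_block = IgvBlock(
            n_groups=len(groups.groups),
            n_members=groups.n_members,
            n_otus_before=table.n_otus,
            n_otus_after=collapsed_table.n_otus,
            groups=[g.members for g in groups.groups],
            h2_mode_raw=_round6(bayes_fit.summary.mode),
            h2_mode_collapsed=_round6(fit_c.summary.mode),
            h2_shift=_round6(fit_c.summary.mode - bayes_fit.summary.mode),
        )

    # --- report -----------------------------------------------------------
    cls_counts = {
        "abundance": {
            k: sum(1 for v in cls.abundance_class.values() if v == k)
            for k in ("principal", "background")
        },
        "ubiquity": {
            k: sum(1 for v in cls.ubiquity_class.values() if v == k)
            for k in ("core", "common", "rare")
        },
    }
    report = StudyReport(
        n_samples=table.n_samples,
        n_otus=table.n_otus,
        q=config.q,
        seed=config.seed,
        config_hash=config_hash,
        diversity={s: _round6(d) for s, d in trait_by_sample.items()},
        classification_counts=cls_counts,
        bayes=bayes_block,
        maternal=maternal_block,
        regression=regression_blocks,
        igv=igv_block,
    )
    with (out / "report.json").open("w") as fh:
        fh.write(report.model_dump_json(indent=2))
    with (out / "report.schema.json").open("w") as fh:
        json.dump(StudyReport.model_json_schema(), fh, indent=2)
    logger.info("report written to %s", out / "report.json")
    return report
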