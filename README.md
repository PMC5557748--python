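# symh2 — heritability of coral-associated *Symbiodinium* communities

Reef-building corals host communities of dinoflagellate symbionts
(*Symbiodinium*) whose composition shapes the holobiont's thermal
tolerance. Whether that composition is under host genetic control is a
quantitative-genetics question: treat each coral's symbiont community as
a *host phenotype* and ask what fraction of its variation is explained by
host relatedness. `symh2` implements that analysis end to end for
ITS-2 OTU community data from breeding designs — either a half-diallel
cross (juveniles of known sire and dam, symbionts acquired from the
environment) or a maternal design (eggs of known dam, symbionts
transmitted vertically).

The pipeline:

1. **Community phenotype.** Counts are variance-normalized with
   median-of-ratios size factors; OTUs are classified by abundance
   (principal vs background at 0.01% of normalized reads) and ubiquity
   (core >75%, common 25–75%, rare <25% of samples). Each sample's
   composition `p` is collapsed into the similarity-sensitive diversity

   ```
   qD^Z(p) = ( Σ_i p_i ((Zp)_i)^(q-1) )^(1/(1-q)),    Z_ij = 1 − d_ij,
   ```

   the effective number of species of order `q` under the OTU similarity
   matrix `Z` built from raw pairwise sequence distances (proportion of
   differing aligned nucleotides). `q = 1` (the exponential-entropy limit)
   is the default order.
2. **Heritability.** The per-sample diversity `D` is the trait `y` in the
   Bayesian animal model `y = Xβ + a + e`, `a ~ N(0, A·σ²_A)`, with `A`
   the additive relationship matrix computed from the pedigree by the
   tabular method. Gibbs sampling with inverse-gamma priors yields the
   posterior of `h² = σ²_A/(σ²_A + σ²_e)`, reported as mode (headline),
   mean ± SD and 95% credibility interval; maternal-environment effects
   are screened by DIC. Parent–offspring regression gives the classical
   counterpart: `h² = slope` on midparent values, `h² = 2·slope` on a
   single parent.
3. **Intragenomic variants.** Multicopy rDNA can split one symbiont
   genotype into several OTUs. Candidate variants are OTUs that cluster
   below 0.03 on the average-linkage dendrogram *and* have abundance
   correlation |r| ∈ [0.8, 1]; they are collapsed into their most
   abundant member and h² is re-estimated.

A first-class synthetic-study generator (`symh2.simulate`) produces
pedigrees, heritable latent traits, clade-structured sequences and sparse
OTU tables with known ground truth, so the whole pipeline is testable
without any sequencing data.

## Worked example

```
python analysis/01_simulate_studies.py
python analysis/02_community_classification.py
python analysis/03_diversity_phenotypes.py
python analysis/04_estimate_heritability.py
python analysis/05_igv_collapse.py
```

The drivers simulate two studies — a half-diallel (8 parents, 20
families × ~10 juveniles, true h² = 0.3) and a maternal design (9 dams ×
11 eggs, true h² = 0.6) — and printed, on the run recorded here:

```
diallel: 68 OTUs -> 8 principal / 60 background; 60 rare, 8 core
diallel: q=1 diversity in [1.02, 1.19], Spearman(latent trait, D) = 0.811
diallel:  h2 mode 0.385, mean 0.449 +/- 0.167, 95% CI [0.171, 0.810];
          midparent regression h2 = 0.635 (slope 0.635); DIC favours no_maternal
maternal: h2 mode 0.432, mean 0.477 +/- 0.179, 95% CI [0.171, 0.822];
          single_parent regression h2 = 0.353 (slope 0.176); DIC favours no_maternal
101 OTUs with planted variants -> 6 groups of 16 OTUs detected -> 91 OTUs after collapse
h2 mode 0.2239 +/- 0.215 (raw) vs 0.2199 +/- 0.216 (collapsed); shift -0.0040
```

Reading the output: each study's wide credibility interval covers its
true h²; the posterior mode is the headline estimate. Single-replicate
regression estimates are far noisier than the animal model (their
sampling spread at these family counts is large), which is why the animal
model is the primary estimator. Collapsing perfectly co-inherited
pseudo-variants moves h² by less than half a percentage point — variant
splitting biases diversity within every family alike, so between-family
variance is almost untouched.

The same stages are available as a CLI (`symh2 simulate | run |
diversity | h2-bayes | h2-regression | igv`); `symh2 run --config
config.yaml` executes the whole pipeline and writes a validated JSON
report plus all intermediate tables.

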