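# Methods

## The phenotype: similarity-sensitive diversity

Community composition is reduced to one scalar per sample so that a
univariate heritability model applies. For relative abundances `p`
(each sample's normalized column rescaled to sum to 1) and OTU
similarity matrix `Z`,

```
q ∉ {1, ∞}:  D = ( Σ_{i: p_i>0} p_i ((Zp)_i)^(q-1) )^(1/(1-q))
q = 1:       D = exp( − Σ_{i: p_i>0} p_i ln (Zp)_i )
q = ∞:       D = 1 / max_{i: p_i>0} (Zp)_i
```

with all sums restricted to the support of `p`. `(Zp)_i` is the
"ordinariness" of OTU i — how much abundance sits at or near it — so
near-identical OTUs (e.g. intragenomic rDNA variants) are automatically
discounted. `Z = I` recovers classical Hill numbers; `Z = 1` (all OTUs
identical) gives `D = 1`; `D` is non-increasing in `q` and bounded by the
support size. These limits, continuity at `q = 1`, and a brute-force
evaluation of the defining sum are all enforced by tests.

`Z = 1 − d` with `d` the raw pairwise distance between aligned
sequences: the proportion of differing positions, no substitution model.
Columns where both sequences are gapped, or where either has an `N`, are
excluded from the denominator; a gap aligned to a base counts as a
difference. A pair with no comparable columns is an error, not a zero.

**Order q.** The weighting of rare OTUs is a free choice; the default is
`q = 1`, the balanced (exponential-entropy) order, and every report
records the `q` used. The full profile `q ∈ {0, 0.5, 1, 2, ∞}` is
computable. Because `q` is a convention, phenotype values — and hence h²
estimates — are comparable only at matched `q`.

## Normalization and classification

Size factors are median-of-ratios: each sample's factor is the median
over reference OTUs of `count / geometric-mean-of-that-OTU's-row`,
rescaled so the factors' geometric mean is 1. Reference OTUs are those
observed in every sample; sparse amplicon tables often have none, so a
positive-counts fallback takes each OTU's geometric mean over its nonzero
entries only. Scaling one sample's counts by `c` scales its factor by `c`
and leaves the normalized table unchanged up to the (global) geometric-
mean convention. No pseudo-counts are added.

Classification is per OTU, dataset-wide: *background* iff its share of
total normalized reads is strictly below 0.01% (boundary values fall in
the less extreme class, i.e. *principal*); ubiquity from presence
fractions with *core* > 75%, *rare* < 25%, boundaries closed toward
*common*. A per-sample abundance mode exists behind a flag.

## Pedigrees and the relationship matrix

Two designs: half-diallel (parents crossed pairwise, no selfs) and
maternal-only (eggs with known dam, unknown sire — the standard encoding
for unfertilized eggs, which makes one dam's eggs maternal half-sibs,
A = 0.25). Founders are assumed non-inbred and mutually unrelated;
unknown parents contribute nothing to the tabular recursion
`A_ii = 1 + 0.5·A(sire,dam)`, `A_ij = 0.5·(A(j,sire) + A(j,dam))`.
Tests pin the textbook coefficients (0.5 full sibs, 0.25 half sibs,
0.5 parent–offspring, 1.25 diagonal for a full-sib-mating offspring) and
positive semi-definiteness on random pedigrees.

## The animal model and its sampler

`y = Xβ + Za (+ Wm) + e`, `a ~ N(0, σ²_A A)` over *all* pedigree
individuals, `m ~ N(0, σ²_M I)` over dam levels, `e ~ N(0, σ²_E I)`.
Priors: inverse-gamma(0.001, 0.001) on each variance (configurable), an
improper flat prior on β (intercept only by default; extra columns, e.g.
cohort year, can be appended). The heritability draw is
`h² = σ²_A/(σ²_A + σ²_E)`; maternal variance is excluded from the
denominator by default (flag to include it).

Sampling: write `a = Lu`, `L = chol(A)`, so `u` is a priori white. A
single eigendecomposition of `(ZL)'(ZL)` makes the full conditional of
`u` diagonal in its eigenbasis for every variance configuration, so each
Gibbs sweep is a handful of dense matrix–vector products — no
per-iteration factorization. Updates cycle `u | β, m`, `β | u, m`,
`m | ...`, then the three inverse-gamma variance conditionals. A fixed
seed reproduces chains exactly.

Summaries: posterior mean, SD, central 2.5–97.5% credibility interval,
and the headline **mode** located by a Gaussian KDE (Scott's bandwidth)
on a 2001-point grid over the sample range. Diagnostics record lag-1
autocorrelation and an initial-positive-sequence effective sample size.

Correctness is established two independent ways: (i) on a 12-individual
pedigree the Gibbs posterior mean of h² matches brute-force 200×200 grid
integration of the marginal posterior (β integrated analytically) to
well within 0.02; (ii) across replicate synthetic studies the 95%
credibility interval covers the true h² at both operating points
(0.3 half-diallel, 0.6 maternal) in ≥ 80% of replicates.

**DIC.** Model comparison (maternal term in or out) uses
`DIC = D̄ + pD`, `pD = D̄ − D̂`, with the deviance evaluated at the
variance-component level: breeding values, maternal effects and the
flat-prior fixed effects are integrated out analytically, so each draw's
deviance is the marginal Gaussian log-likelihood under
`V = σ²_A ZAZ' + σ²_M WW' + σ²_E I` and depends only on the sampled
variances. The conditional (random-effects-in-focus) deviance was
rejected after testing: the weak variance priors let the sampler visit
near-interpolating states (σ²_E → 0) where that deviance diverges,
making ΔDIC Monte-Carlo noise orders of magnitude larger than the signal.

**Identifiability caveat.** In an egg-only (maternal) design, σ²_M and
σ²_A are structurally confounded: same-dam covariance is
`0.25σ²_A + σ²_M` and all other covariances vanish, so no criterion can
separate them. Maternal-effect screening is therefore meaningful only in
designs where parents appear in several crosses (the half-diallel),
which is where the DIC comparison is exercised.

**Estimator behaviour under weak identification.** Even with ~200
offspring, a design drawing on 8 founders carries limited between-family
information; the per-replicate spread of the maximum-likelihood h² is
around 0.2 SD. In that regime the posterior mean under the
inverse-gamma(0.001, 0.001) priors sits visibly above the (unbiased)
maximum-likelihood and regression estimates — roughly +0.1 to +0.2 at
h² = 0.5 in simulation — while the credibility interval remains
calibrated (coverage tests above). Users comparing the Bayesian and
regression numbers should expect offsets of this size on small designs;
they reflect the prior and the skew of the h² posterior, not an error in
either estimator.

## Regression estimators

Unweighted OLS of individual offspring trait on the family midparent
value (`h² = slope`), or on the dam's value (`h² = 2·slope`). A
family-means variant is available by flag. Estimates outside [0, 1] are
reported raw with a warning. Slope standard errors come from the OLS
fit; no further h²-SE theory is attempted.

## Intragenomic-variant procedure

(1) average-linkage clustering of the raw-distance matrix, cut at 0.03 —
the complement of the conventional 97% OTU identity; clusters of ≥ 2 are
candidates. (2) Within each candidate, the largest subset whose pairwise
Pearson `|r|` of normalized abundance lies in [0.8, 1] is kept
(Bron–Kerbosch maximum clique on the passing-pair graph; Spearman by
flag; pairs with a zero-variance profile are excluded with a logged
reason — their correlation is undefined). Both strong positive *and*
strong negative correlations count, since variant calling balance can
anti-correlate copies. (3) Members are summed into the most abundant
member (ties lexicographic); column totals are conserved exactly.
Cut height and the correlation band are conventions, not fitted values.

## The synthetic-study generator

The generator defines the study conditions; every stage is tested
against it.

* **Designs.** Half-diallel: 4–8 parents, up to `n(n−1)/2` undirected
  crosses, 1–29 offspring per family. Maternal: ~9 dams × 5–12 eggs.
* **Trait.** Infinitesimal model: founder breeding values
  `N(0, σ²_A)`; offspring receive the parental mean plus Mendelian
  sampling `N(0, 0.5σ²_A)` (`0.75σ²_A` when only the dam is known);
  optional maternal effect `N(0, m²σ²_P)` shared within a dam;
  residual `N(0, σ²_E)`. Truth `h² = σ²_A/(σ²_A+σ²_E)` is recorded.
* **Sequences.** A root sequence, clade ancestors mutated at
  ~`between/2` of positions (pairwise ancestor distance ≈ `between`),
  members mutated at `within`. Defaults: length 300, 3 clades,
  within 0.01, between 0.25.
* **Counts.** The first `n_principal` (default 8) OTUs get geometric
  rank-abundance shares `w_j ∝ r^j`; the ratio `r` is the logistic
  transform of the sample's standardized latent trait, so a higher trait
  gives a more even, hence more diverse, community. There is no closed-
  form inverse of the diversity metric under a non-trivial `Z`, so
  fidelity is a contract, not a construction: Spearman(latent, D) ≥ 0.8
  at default settings (enforced by test). `n_background` (default 60)
  OTUs are present per sample with per-OTU Bernoulli rates drawn from
  U(0.05, 0.25) at expected shares of 2×10⁻⁶–5×10⁻⁵ — below the 0.01%
  principal threshold. Counts are negative binomial
  (variance = μ + μ²·dispersion, default dispersion 0.2) around
  library-size-scaled expectations; library sizes are lognormal around
  20,000 reads.

What the generator does *not* emulate: sequencing error and chimeras,
taxonomic structure beyond clade blocks, OTU-clustering artifacts,
compositional coupling between host condition and library size, and any
environmental covariance between families. Passing recovery tests
therefore demonstrate the estimators are correct for communities whose
diversity genuinely tracks a heritable latent trait — not that real
coral data meet that description.

Because the latent trait reaches the analysis only through the monotone
evenness map plus counting noise, the *realized* heritability of the
diversity phenotype is attenuated relative to the latent truth; recovery
is accordingly asserted through credibility-interval coverage (wide by
design at study-realistic sample sizes) and through replicate-averaged
regression on the latent trait itself.

## Problem sizes, numerics, reproducibility

Desk-scale MCMC defaults are 60,000 iterations, 10% burn-in, thinning 25
(2,160 retained draws); study-fidelity settings (1.5×10⁶ iterations,
thinning 800/250) are a config change away. Replicated checks
(coverage, DIC selection) use 8,000–10,000 iterations with 25% burn-in —
at the 100–250-observation sizes involved the sampler's effective sample
size stays in the hundreds, which those pass/fail proportions need,
while keeping a full run of the suite in minutes. A jitter of 1e-10 is
added to `A` before Cholesky; `(Zp)_i = 0` on the support of `p` is
impossible with a unit-diagonal `Z` but guarded anyway. Sample-sum
normalization of `p` is checked to 1e-8.

One top-level seed drives everything; each stage derives its own seed as
`sha256(seed:stage-name) mod 2³¹`, so stages can be re-run independently
yet reproducibly, and a re-run with the same config writes a
byte-identical report.

## Known limitations

* `q` for the phenotype is a convention; there is no data-driven choice.
* The maternal-design confounding of σ²_M with σ²_A (above) is a
  property of the design, not the implementation.
* DIC is reported without its constant `n log 2π` term's dependence
  removed across datasets — only comparisons on the same data are
  meaningful.
* Founder inbreeding and relatedness are assumed zero; marker-based
  relationship matrices are out of scope.
* Out-of-range regression h² values are flagged, not truncated;
  consumers must honor the warning field.
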