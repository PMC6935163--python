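# Methods

`pinegs` implements the genetic-evaluation workflow used to appraise genomic
selection for categorical ("non-key") traits in clonally replicated conifer
breeding trials: SNP-based pedigree correction, pedigree (ABLUP) and genomic
(GBLUP) mixed-model evaluation, and the translation of cross-validated
predictive abilities into per-year selection efficiency. This note records the
models, the defaults and why they were chosen, the numerical strategy, and the
limits of what the synthetic-data validation can show.

## Population and data model

The package targets trial populations of the kind used in radiata pine
breeding: a few dozen founders crossed under a single-pair or factorial
design, several hundred progeny propagated as clones, with 2–6 ramets of each
clone planted across 2–3 sites in a replicate / set-within-replicate /
incomplete-block layout. Scores on 9-point or 0–3 scales are treated as
Gaussian (their observed distributions are near-normal at these scales); no
threshold model is fitted.

Genotypes are biallelic SNP dosages in {0, 1, 2} with missing values. Allele
frequencies are estimated on a designated set of unrelated reference trees
(falling back to all genotyped individuals, logged); markers with minor allele
frequency strictly below 0.03 are excluded; missing genotypes are imputed by
the marker mean, using the reference-set means `2p` by default so that
imputation and centring are mutually consistent (column means are available
via an argument).

## Relationship matrices

**A** is built by the tabular method on a generation-ordered pedigree:
`a_ii = 1 + 0.5 a_{s,d}` and `a_ij = 0.5 (a_{j,s} + a_{j,d})`, with unknown
parents contributing zero. Individuals appearing only as parents are auto-added
as founders (logged). Inbreeding is `F_i = a_ii − 1`, and the status-number
effective population size of a group is `Ns = 0.5 / Θ`, where `Θ` is the mean
of `a_ij / 2` over all ordered pairs including self-pairs.

**G** is the VanRaden construction: `G = W Wᵀ / (2 Σ p_j (1 − p_j))` with `W`
the dosage matrix centred by `2 p_j`. The normalization makes G directly
comparable to A (diagonal ≈ 1 + F). When G must be inverted and is
near-singular it is blended as `0.99 G + 0.01 I` (logged).

## Parentage assignment and pedigree correction

The parentage panel keeps SNPs with call rate > 0.75, MAF in [0.35, 0.5], a
Hardy–Weinberg exact-test p ≥ 0.05 (the standard conditional-on-allele-counts
exact test, implemented here), and no pairwise LD above r² = 0.2 (greedy
prune, higher call rate wins), capped at the 704 best-call-rate markers.

A trio (progeny, parent1, parent2) is excluded at a SNP when the progeny
genotype is not among the four combinations of one transmitted allele per
parent; SNPs with any missing member are uninformative. All unordered
candidate pairs (including selfing pairs) are scored and the
minimum-exclusion pair is assigned. Ties prefer the documented pair, then the
pair with more informative markers, then lexicographic order — deterministic
and logged. A progeny is left unassigned when even the best pair's exclusion
rate exceeds `max_exclusion_rate`, default **0.15**: three genotypes enter
every trio, so with a per-genotype error rate near 5% the *trio-level*
incompatibility rate of a true trio is roughly three times that (≈ 6%
empirically on gene-drop data); a 5% trio threshold would reject most true
assignments, while 0.15 ≈ 3× the per-genotype error estimate accepts true
trios and still flags progeny whose parents are absent from the candidate
set. Corrected pedigrees substitute assigned pairs; unassigned progeny keep
their documented parents with a logged flag.

## Mixed models

Both evaluations use the individual-tree model for observations `y`:

    ABLUP:  y = Xβ + Z_a a + Z_d d + Z_r r + Z_w w + Z_b b + e
    GBLUP:  y = Xβ + Z_m m + Z_a a* + Z_d d + Z_r r + Z_w w + Z_b b + e

with fixed intercept and site; `a ~ N(0, σ²_a A)`; `m ~ N(0, σ²_m G)`;
`a* ~ N(0, σ²_a* A)` the residual polygenic effect; `d ~ N(0, σ²_d I)` the
clone-level non-additive effect (identifiable because ramets replicate each
clone); and replicate, set and block effects plus residuals with *per-site
diagonal* variances (no cross-site covariances; genetic variances homogeneous
across sites). Strata absent from the data are dropped with a warning. Traits
are fitted univariately. Factor-analytic or unstructured G×E covariances are
out of scope.

### REML

Variance components maximize the restricted likelihood. The default algorithm
is **average-information REML** with two EM warm-up iterations and an EM
fallback whenever an AI step would decrease the likelihood (step-halving
first); pure EM is selectable. AI typically converges in ~10 iterations,
which is what makes many-dataset validation studies and cross-validation
loops practical; EM alone needs hundreds of iterations for these models.
Convergence is declared when the maximum relative component change drops
below 1e-6; non-convergence raises an error carrying the last iterate.
Components are floored at 1e-8 × the phenotypic variance; a component pinned
at the floor with a negative score is held there (logged). Starting values
split the phenotypic variance evenly between the residual and the remaining
terms unless supplied.

The likelihood is evaluated on the observation-level covariance
`V = Σ_j θ_j V_j` with precomputed structure matrices; traces and the AI
matrix come from the projection matrix P. This is O(n³) per iteration and is
intended for desk-scale trials (n up to a few thousand observations).

### BLUP and PEV

At the REML estimates, Henderson's mixed-model equations give GLS fixed
effects, BLUPs for every random term, and prediction error variances from the
corresponding diagonal of the inverse coefficient matrix, so
`PEV_i ≤ (1 + F_i) σ²` holds by construction and accuracies are real-valued.

## Reported statistics

Per site *i* (cross-site summaries are unweighted means over sites):

- pedigree heritability `h²_a(i) = σ²_a / (σ²_a + σ²_d + σ²_e_i)`,
- marker heritability `h²_m(i) = σ²_m / (σ²_m + σ²_a* + σ²_d + σ²_e_i)`,
- combined `h²_am(i) = (σ²_m + σ²_a*) / (σ²_m + σ²_a* + σ²_d + σ²_e_i)`,
- accuracy `r_i = sqrt(1 − PEV_i / ((1 + F_i) σ²))` with `σ² = σ²_a` (ABLUP)
  or `σ²_m` (GBLUP) and `1 + F_i` taken from the diagonal of the matching
  covariance (A or G); the reported accuracy is the mean over phenotyped
  genotypes,
- `%VA = σ²_m / (σ²_m + σ²_a*) × 100`.

## Cross-validated predictive ability and efficiency

Genotypes are randomly partitioned into k folds (default k = 10) with 10
replications; all ramets of a clone travel together, folds differ by at most
one genotype, and the plan is reproducible from its seed (default 20191227,
always logged). Within a replication each fold's phenotypes are set missing
in turn, the model is refitted on the remainder, and every genotype receives
one out-of-fold prediction; one Pearson correlation per replication is taken
against reference EBVs from the full-data ABLUP fit, and the mean over
replications is the predictive ability. (An optional mode correlates with
clone-mean phenotypes instead.)

Two defaults matter here:

- **Components in CV folds.** By default the variance components are held at
  the full-data estimates and only the BLUP solutions are recomputed per fold
  (`reestimate=True` re-runs REML in every fold). Re-estimation changes the
  result negligibly at these sizes and costs an order of magnitude more.
- **CV predictor.** GBLUP folds predict withheld genotypes with the *total*
  additive merit `m̂ + â*` (`predict="marker"` uses `m̂` alone). The reason is
  the identifiability property discussed below: the split of additive
  variance between `m` and `a*` can be poorly determined, and `m̂` alone then
  carries an arbitrary share of the family signal, whereas the sum is stable.
  The accuracy formula, by contrast, is defined on the marker term and keeps
  `σ²_m`.

Relative efficiency of genomic over traditional forward selection:

    E = (r_g σ_Ag) / (r_a σ_Aa) · (L_a / L_g) · 100%

with `σ_Ag = sqrt(σ²_m)` from the full-data GBLUP, `σ_Aa = sqrt(σ²_a)` from
the full-data ABLUP, generation intervals `L_g = 9` years (genomic forward
selection) and `L_a = 17` or `14` years (traditional forward selection
without / with a clonal archive). Selection intensity cancels. E is linear in
`L_a`, so E₁₇ / E₁₄ = 17/14 identically.

## Synthetic data

The generator mirrors the models above so every stage can be validated
against known truth. Defaults describe the study conditions: two series (60
founders / 200 progeny, single-pair, two sites; 24 founders / 200 progeny,
factorial, three sites), 2 ramets per clone per site, 2000 unlinked markers
with founder MAF uniform on [0.03, 0.5], a 117-tree unrelated reference
analogue (40 by default at desk scale), total additive variance 0.3 of which
70% is marker-borne, clone variance 0.1, per-site residual 0.8 (h² = 0.25,
inside the 0.09–0.35 range typical of these traits), replicate/set/block
variances 0.05 each, 50% pedigree-error rate, 5% genotyping error, 8% missing
calls.

Founders are Binomial(2, p) draws (Hardy–Weinberg, unlinked); progeny
genotypes come from a per-marker gene drop (each parent transmits one
uniformly chosen allele). Marker breeding values are Gaussian-effect sums
over the markers, rescaled so their variance across progeny equals the
marker share of the additive variance; **by default effects sit at every
marker** (the infinitesimal mirror of GBLUP), with a sparse QTL subset
configurable. The residual-polygenic share is sampled down the pedigree
(founders `N(0, σ²)`, offspring midparent plus Mendelian deviation), so
`%VA` truth is `percent_va` by construction. Site / replicate / set / block
effects and residuals are drawn with the configured per-site variances; an
optional quantile mapping produces 1–9 or 0–3 scores. Pedigree errors replace
one or both parents of a random progeny subset with different candidates;
genotype noise replaces entries with a different genotype at the error rate,
then masks entries at the missing rate. Everything is bit-reproducible from
(config, seed).

What the generator does **not** emulate: linkage and LD between markers,
selection history, genotype-by-environment interaction, spatial field trends,
and non-Gaussian score processes. Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to those
real-data features.

## The marker/polygenic identifiability limit

With *unlinked* markers the realized relationship matrix converges to the
pedigree expectation as markers accumulate: at 2000 markers the realized
full-sib relationship deviates from 0.5 by only ~0.02 SD. G then differs from
A mostly by estimation noise, and the restricted likelihood for the GBLUP
split (σ²_m, σ²_a*, σ²_d) has a long, nearly flat ridge; single-dataset REML
lawfully lands on a boundary (%VA of 0 or 100). This was verified not to be
an optimizer artifact: multi-start AI-REML reaches identical log-likelihoods
from marker-heavy, polygenic-heavy and neutral starts, and data drawn exactly
from the model show the same behaviour at ~100 clones from 10 families. Real
exome panels do not have this degeneracy to the same degree: linkage makes
realized kinship deviate much more from expectation.

Consequences adopted here: (i) cross-validation predicts with `m̂ + â*`
(ridge-stable) as described above; (ii) recovery studies of %VA use designs
where the split is identified — factorial crossings with many distinct
families (40 founders × 300 progeny), several hundred clones, and a few
hundred markers rather than thousands (fewer unlinked markers *increase* the
realized-vs-expected contrast); (iii) reported %VA values from small
single-pair designs should be read as ridge endpoints, not point estimates.

## Validation studies and problem sizes

The test suite validates, among others: A against an independent recursive
coancestry oracle (≤ 30 individuals, |Δ| < 1e-10); MME solutions against
direct GLS (≤ 50 observations, |Δ| < 1e-8); REML against the closed-form
balanced one-way ANOVA estimator (tolerance 1e-6); exclusion counts against
exhaustive enumeration; heritability recovery (100 datasets of ~1000
observations at h² = 0.30, mean within 0.05); %VA recovery (12 all-additive
factorial datasets, mean ≥ 90%); pedigree-correction recovery (≥ 90% true
pairs at 50% errors, 300 SNPs, 5% genotyping error); and the qualitative
benefit of pedigree correction for predictive ability (20 datasets, one-sided
sign test). `scripts/acceptance.py` re-runs the full pipeline on the
two-series default conditions at 500 markers — the desk-scale marker count at
which the marker/polygenic split stays identified (see above) — with 10-fold
CV and 2 replications; sizes chosen so a complete analysis finishes in
minutes.

## Known limitations

- Dense linear algebra throughout: practical to a few thousand observations
  and a few thousand pedigree members; no sparse inverse-A (Henderson rules)
  or preconditioned solvers.
- No standard errors on heritabilities or %VA (delta-method SEs are future
  work), no threshold models for the categorical scales, no multi-trait or
  G×E covariance structures, no single-step blending of A and G.
- The status number is computed from the pedigree as documented/corrected; it
  inherits any residual pedigree errors.
- `%VA` and `σ²_m`-based quantities inherit the identifiability limit above
  whenever G carries little information beyond A.
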