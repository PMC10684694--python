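# Methods

`cohortnet` implements a two-layer weighted correlation network analysis for a
multimodal biomarker cohort contrasted by a binary gene variant (APOE4 carrier
status), together with the univariate statistics that surround it: nested
covariate-adjusted regressions with permutation correction, partial
correlations, balanced-resampling edge comparisons, and subgroup
stratification. Because the motivating cohort data are restricted, a synthetic
generator reproduces the statistical structure every stage assumes, at the
study's sizes.

## Data model

A cohort table holds one row per participant: the carrier label, covariates
(age, sex, education, intracranial volume), the hypertension/diabetes flags,
and the analysis variables of the packaged registry. The registry maps 60
variables to domains; 50 of them form the network node set — 2 diet scores,
2 B vitamins, 26 blood fatty acids, 3 cytokines, 4 lipids, 5 other blood
markers, the cardiovascular-risk count CVR (hypertension flag + diabetes flag,
0–2), BMI, and 6 medial-temporal white-matter neurite-density tracts. MMSE,
the 6 orientation-dispersion tracts and 3 grey-matter volumes are carried but
are not network nodes. Twenty-one of the fatty acids are documented
placeholders (`fa_06`…`fa_26`); the five named ones are behenic acid,
lignoceric acid, nervonic acid, DHA and total n-3. Completeness filtering is
listwise on the group label and the 50 network variables only — the network
needs a complete 50-column matrix, while MMSE/OD/volume missingness is
tolerated — and errors out rather than returning an empty table.

## Synthetic cohort generator

Defaults are the study conditions: 113 non-carriers, 43 carriers, plus 44
appended rows with a missing genotype or one missing blood marker (equal
chance), for a raw n of 200. Variables are Gaussian latents drawn per group
from a 50×50 correlation matrix assembled from three ingredients:

* within-domain correlation 0.3 for every non-fatty-acid domain;
* planted fatty-acid blocks of sizes 21/3/2 (within-block 0.7, between-block
  0.1), assigned contiguously over a fixed sampling order — the 21
  placeholders, then the behenic/lignoceric/nervonic trio, then DHA/total-n3 —
  so the planted partition matches the named clusters;
* group-specific cross-domain couplings; the default plants cytokine–WM
  correlation 0.10 in non-carriers and 0.45 in carriers.

The matrix is repaired to the nearest positive-definite correlation by
eigenvalue clipping when needed (with a warning). Age (mean 68, SD 6.7) and
sex (77% female) act linearly on every continuous variable (defaults
0.03/year and 0.5), so covariate adjustment is non-trivial and the configured
coefficients are recoverable by regression. CVR is generated by thresholding
the clinical latent into hypertension (60%) and diabetes (40%) flags, keeping
CVR = flag sum by construction. Retained-cohort ages are drawn antithetically
around the mean, so the sample mean equals the configured mean exactly and an
even cohort splits 78/78 at it — a deliberate calibration that makes the
age-stratified analysis deterministic in size. A null-pair generator
equalises the group couplings for type-I-error studies.

The generator makes no attempt at marginal realism: assay values are not
skewed, bounded or unit-scaled, and there are no longitudinal dynamics.
Passing tests therefore demonstrate that the pipeline recovers known
covariance structure and controls error under Gaussianity — not that it
would behave identically on heavy-tailed or artifact-laden assay data.

## Group statistics

Model 1 adjusts for age and sex; model 2 adds the age × carrier interaction;
model 3 adds education and CVR. Education is appended automatically for MMSE
outcomes and intracranial volume for hippocampal volumes. `B` is the
unstandardized carrier coefficient with a raw 95% t interval (intervals are
not permutation-adjusted).

Multiplicity is handled by Freedman–Lane permutation: the reduced model (all
covariates, no carrier terms) is fit per outcome; its residuals are permuted
jointly across the family, the full model refit, and the family max |t|
recorded; `p_adj = (1 + #{max|t*| ≥ |t|})/(1 + n_perm)`. This controls the
family-wise error in the weak sense by construction; a per-outcome
permutation + Benjamini–Hochberg variant sits behind `method="fdr"`, since
the exact correction used in comparable analyses is usually unstated.
Adjusted p-values are floored at the parametric raw p — a monotonicity guard,
so `p_adj ≥ p_raw` holds even when Monte-Carlo noise would say otherwise.
Default `n_perm` is 10,000 and the seed is mandatory. Partial correlations
are Pearson correlations of the two covariate-residualized vectors with a
t reference on `n − 2 − k` degrees of freedom, computed in a commutative form
so the result is exactly symmetric in its arguments; a family version applies
a shared-permutation max-|R| correction.

## Lower-level network

Each of the 50 variables is residualized on age and sex (matching the
univariate adjustment; Spearman on residual ranks is available for ordinal
nodes such as CVR), then correlated. Soft thresholding raises absolute
correlations to a power β (unsigned network); β is supplied or chosen as the
smallest integer in 1–20 whose degree distribution fits log–log linearity
with signed R² ≥ 0.8, falling back to the conventional 6 with a warning.
Edge weights are the unsigned topological overlap

    W_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),  W_ii = 1,

bounded in [0, 1]; a flag keeps the raw power adjacency as weights instead.

## Modules and upper-level network

Non-fatty-acid nodes map to predefined domain modules (Diet, BVitamins,
Cytokines, Lipids, OtherBlood, Clinical, WM). The 26 fatty acids are
clustered by average-linkage agglomeration on 1 − |r| of the residualized
values, cut at the candidate count k ∈ 2..6 maximising the mean silhouette
with all clusters of size ≥ 2; if no cut qualifies the acids form a single
cluster with a warning. Clusters are labelled FA1..FAk, largest first.
Clustering uses absolute correlation rather than TOM because the acids are
grouped before network weighting; a TOM-similarity input is accepted too.

The upper-level edge weight W^ave between two modules is the mean lower-level
weight over all cross-module node pairs; within-module density is computed
and exported but excluded from edge comparisons. Edges are banded by
percentile rank among all module pairs at the 50th/75th/90th percentiles
(bands 0–3). With the default 10-module partition the WM module has exactly
nine incident edges, reported ranked by W^ave with stable label-order
tie-breaks (warned).

## Resampling edge comparison

Each iteration draws, independently per group and without replacement,
`floor(0.8 × n_small)` participants (34 at the default 113/43 sizes), rebuilds
the lower- and upper-level networks, and records all module-pair W^ave values;
the default is 1,000 iterations. β and the module partition are fixed from
the full sample across iterations so edges match between groups — recomputing
either per subsample would break edge identity. Matching edge distributions
are compared with Mood's median test (2×2 chi-square of counts above vs
not-above the pooled grand median, ties counted not-above, df = 1, no
continuity correction) as the primary test and the Mann–Whitney U test
(exact enumeration for combined n ≤ 20; tie- and continuity-corrected normal
approximation otherwise) as the secondary; Benjamini–Hochberg FDR is applied
within the compared family (default: the nine WM edges; BH rather than BY).

**Caveat.** The resampled W^ave values of a group are i.i.d. across
iterations, but they measure subsampling variability around that group's
*observed* network. Two independent cohorts drawn from the same population
differ by O(1/√n) sampling noise, and with enough iterations the tests
resolve that difference — so under a two-cohorts null the procedure flags far
more than the nominal 5% of edges. The suite quantifies this
anti-conservativeness explicitly; the calibrated null (both labels given the
identical participant set) keeps its 5% level. Flagged edges should be read
as differences between the observed group networks, not population claims.

## Stratified subgroup comparisons

Strata combine genotype group with criteria on key variables: exact ordinal
values (e.g. CVR = 2) or dichotomization above/below a threshold, defaulting
to the within-group median because clinical cutoffs for "abnormally high"
markers are configuration, not assumption. Overlapping strata within one
analysis are an error. The outcome (default: right-ILF neurite density) is
residualized on age and sex; all pairwise mean differences are tested by
permutation of stratum labels (pooled-variance t statistic, 10,000
permutations) with max-statistic correction over the pairwise family.
All-pairs comparison is the default; strata below 3 members are rejected.

## Numerical choices and problem sizes

All randomness flows from `numpy.random.default_rng` with explicit seeds;
identical seeds give bit-identical tables and sample matrices. Cohort CSVs
are written with `%.17g` and read with round-trip float parsing so I/O is
lossless for finite doubles. The resampling inner loop is a vectorized
single-pass implementation verified in the test suite to match the explicit
network-building route to ~1e-14. Simulation sizes in the statistical
property suites are the package's own choices: the family-wise-error study
uses 200 null replicates of 40+40 participants at 200 permutations; the
planted-coupling power study uses 50 seeds at 200 resampling iterations; the
cluster-recovery study uses 100 seeds at the full default cohort size.

## Limitations

Gaussian-copula synthetic data cannot certify behaviour on skewed assay
distributions; the β selection criterion is a convention, not an inference;
the resampling comparison inherits the dependence caveat above; and the
stratified analysis offers no automated search over stratification criteria —
specs are user-supplied by design.
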