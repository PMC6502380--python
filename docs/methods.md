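# Methods

`kypemorph` analyses the head morphology of sexually mature male Atlantic
salmon (*Salmo salar*) reared in a common garden: six strains — the
domesticated Mowi strain, two reciprocal F1 hybrids (Figgjo♀×Mowi♂ and
Mowi♀×Figgjo♂) and three wild populations (Arna, Figgjo, Vosso) — maturing
after one to three sea winters (SW).  The pipeline has four statistical
stages, plus a synthetic-cohort generator used to validate each of them
against known generating values.

## Linear measurements and allometric adjustment

Kype length (KL, anterior lower-jaw point to the bottom of the gill plate)
and kype height (KH, dorsal hook peak to the curvature-onset point on the
lower jaw; when no curvature point is discernible, the vertical projection of
the peak onto the lower-jaw segment) are Euclidean distances in cm.  Both
scale allometrically with body size, so each trait is regressed on fork
length by OLS on the log10–log10 scale, pooled over all strains and SW
classes, and the residuals are the size-adjusted traits **AKL** and **AKH**.
The gonadosomatic residual (**GSR**) is the analogous residual of log10 milt
weight on log10 total wet weight; fish missing either weight are excluded,
never imputed.  Pairwise deletion means the KH regression runs on its own
(smaller) subset: on the published design that is n = 480 and hence 478
denominator degrees of freedom.

Adjustment is deliberately a *single pooled* regression, not per-group:
group comparisons are then made on the residual scale by the mixed model.
Natural alternatives (per-group adjustment, standardized-major-axis slopes)
are intentionally out of scope; a per-group option exists behind a flag.

## Geometric morphometrics

Six head landmarks (upper-jaw apex; dorsal, ventral and posterior
gill-plate points; maxillary bone; eye) are superimposed by generalized
Procrustes analysis: centering, scaling to unit centroid size, and
rotation-only (determinant +1) fits against an iteratively re-estimated mean
shape, stopping when the mean moves < 1e-8 (max 100 iterations).
Reflections are excluded because all photographs show the same lateral
side.  Kype measurement points are carried in the same TPS record (points
7–10) but never enter the superimposition, since mouth opening moves them.
Shape variation is summarised by PCA of the covariance of the flattened
aligned coordinates; per-group 95% confidence ellipses use the
multivariate-t quantile sqrt(2 F⁻¹(0.95; 2, n−1)) applied to the group
mean and covariance.

## Mixed models

For each adjusted trait the full model is

    AKL ~ SW*strain + SW*GSR + strain*GSR + (1|strain:family) + (1|sire) + (1|dam)

fitted by REML.  The engine profiles out the residual variance and maximises
over variance ratios with an analytic gradient, bounded below at zero so
null components estimate exactly on the boundary; because families are
mutually unrelated, every covariance structure is block-diagonal over
connected components of the relatedness graph and the likelihood is
evaluated on padded batches of small blocks (exactly, not approximately).

Backward elimination drops random intercepts by REML likelihood-ratio tests
with the 50:50 χ²₀/χ²₁ boundary mixture (α = 0.1), then fixed terms by
type-III F tests (α = 0.05) respecting marginality.  Factors are coded with
sum-to-zero contrasts, so testing a term's coefficient block is the type-III
hypothesis.  Denominator degrees of freedom are Satterthwaite's two-moment
match: the gradient of the contrast variance with respect to the variance
components, combined with the inverse curvature of the restricted
likelihood (numerical Hessian on the variance scale); multi-df tests
eigendecompose the contrast covariance and pool one-df values by matching
the F expectation.  Kenward–Roger df, used in some published EMM tables, is
replaced by Satterthwaite throughout — the two agree on balanced designs
(the balanced split-plot reproduces the classical whole-plot and subplot
error df exactly), and Satterthwaite is already required for the type-III
tables.  Estimated marginal means average the fitted surface over the other
factors with equal cell weights; pairwise differences use the
studentized-range (Tukey) distribution with per-comparison Satterthwaite df.

Boundary-confounded random terms (e.g. a dam term when every family has a
unique dam, making it indistinguishable from the family term) sit on a
likelihood ridge; elimination removes one of them immediately (LRT ≈ 0), so
selected models are identifiable.

## QTL scan

Genotypes are 109 biallelic SNPs spread over the 29 linkage groups.  At
each marker two models are compared:

    model 0:  y = XB + a + e        a ~ N(0, σ²ₐ G)
    model 1:  y = XB + a + q + e    q ~ N(0, σ²_q Z_m)

with fixed effects for tank, strain and SW; `G` the pedigree additive
relationship matrix (recursive tabular method; a marker-average IBD
alternative is available); and `Z_m` the locus-specific expected-IBD matrix.
The locus test is LRT = 2(logL₁ − logL₀) clipped at zero with the boundary
mixture p-value; the locus variance share is σ²_q / (σ²_q + σ²ₐ + σ²ₑ).

The default IBD estimator is the single-marker conditional expectation: for
each meiosis the transmitted parental chromosome is inferred where the
parent is heterozygous with distinguishable transmission; uninformative
meioses contribute the full-sib prior 1/2, pairs not sharing a parent
contribute 0, and the diagonal is 1.  A multipoint option phases each
parent by min-recombinant alignment of the inferred states and replaces
uninformative meioses with posteriors conditioned on the nearest informative
flanking markers under the Haldane map; with the default 25–33 cM marker
spacing it changes results very little, so the simpler estimator remains
the default.  Significance is reported pointwise at 0.05 with a
Bonferroni-over-markers option, since no genome-wide threshold convention is
imposed by the design.

### What the scan can and cannot do at this design size

Calibration of the machinery is by simulation under the study design
(sizes below, chosen to keep the default validation runs within minutes on
one CPU):

* **Null type-I error** — 2,000 simulations of the no-QTL model over the
  full 37-family/528-male design, re-drawing panel genotypes each time,
  testing one locus at nominal 5%.  The measured rejection rate is ≈ 3–4%:
  the naive 50:50 boundary mixture is *conservative* here, a known
  finite-information property of variance-component LRTs in clustered
  designs (the positive part of the null LRT is stochastically smaller than
  χ²₁ when the locus matrix is strongly collinear with the family
  structure).  A grid search over the variance ratios confirms the
  optimiser attains the REML maximum, so this is a property of the test,
  not of the implementation.
* **Localization and variance recovery** — 100 replicates with a planted
  locus contributing q² = 5% of the non-allometric variance, full
  109-marker scan each.  The peak lands on the planted linkage group in
  roughly 40–50% of replicates, and the locus variance share at the planted
  marker is estimated with MAE ≈ 0.08 (right-skewed, because σ²_q is
  boundary-constrained and partially confounded with the polygenic term
  within full-sib families).  A 5% locus in ~530 offspring across 37
  full-sib families is simply near the detection floor of
  variance-component linkage; the corresponding validation checks are
  intentionally strict and fail, documenting the power limit rather than
  masking it.

## Synthetic cohorts

The generator reproduces the study design: family counts and male counts
per strain × SW cell as printed (397/81/50 usable for KL; 378/58/44 for KH;
77 supplementary 2SW females), full-sib families with occasional sire
sharing (probability 0.3) for a half-sib component, founders at
Hardy–Weinberg proportions (allele frequency 0.5), offspring by
Haldane-model gene dropping, and phenotypes from

    log10(trait) = a + b·log10(FL) + strain + SW + u + q + e

with a pedigree-structured polygenic term `u` (founders N(0, σ²ₐ); offspring
mid-parent plus Mendelian sampling N(0, σ²ₐ/2)), a biallelic additive QTL
placed on a panel marker with variance fraction q² of (σ²ₐ + σ²_q + σ²ₑ),
and iid residual.  Default trait parameters are set once to reproduce the
orders of magnitude of the published ranges (fork length means 60/80/100 cm
for 1–3 SW; KL slope 1.3 and KH slope 2.0 on log10 scale; KL ≈ 5–28 cm and
KH ≈ 0.2–6 cm across the cohort; strain and SW shifts matching the reported
marginal-mean patterns, e.g. domesticated AKH below the wild Arna and
Figgjo strains); exact real-data moments are unknowable from the
publication and are not targeted.  Landmarks are a male (or female) mean
shape scaled by fork length, a dorsal displacement of eye, maxillary and
posterior gill-plate points growing with SW (the planted shape signal that
PC1 recovers), isotropic Gaussian noise on the six head landmarks, and a
random similarity transform; kype measurement points are placed so their
distances equal the fish's recorded KL and KH exactly.

All randomness flows from one integer seed through four named sub-streams
(pedigree, genotypes, phenotypes, landmarks): the same seed gives a
bit-identical cohort.

What the generator does *not* emulate: genotyping error and missing calls,
selection or mortality between SW classes, dominance/epistasis, maternal
effects, photographic distortion, and observer error correlated between
landmarks.  Passing recovery tests therefore demonstrate correctness of the
estimators under the assumed generating model, not robustness to those
real-data complications.

## Numerical choices

* Variance ratios optimised by L-BFGS-B with analytic gradients, bounds
  [0, 1e8], several starts for cold fits and warm starts along a scan;
  estimates below 1e-10 snap to the boundary only when that does not lower
  the likelihood.
* Degenerate inputs raise: coincident landmarks (named specimen), cyclic or
  inconsistent pedigrees, non-positive measurements (named fish), Mendelian
  violations (named trio and marker), rank-deficient fixed designs (aliased
  columns dropped by pivoted QR with a warning — the published design's
  empty Figgjo×3SW cell makes the strain×SW interaction aliased by one
  column).
* Satterthwaite df clipped to [1, 1e7]; components on the zero boundary are
  held fixed when differentiating the restricted likelihood.
* The deterministic design-table fixture uses smooth noise-free
  measurements; only its bookkeeping (cell counts, subset sizes, df) is
  meaningful.

## Known limitations

Single-trait models only (no multivariate kype analysis); Gaussian
responses; no genome-wide significance threshold beyond Bonferroni; the
multipoint IBD option assumes correct parental phasing, which degrades for
parents with fewer than ~4 informative offspring per linkage group; EMMs
use equal cell weights only.
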