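# Methods

This note documents the statistical procedures implemented in
`gutcompass`, the synthetic-data model used to validate them, and the
numerical and design choices a user should know about.

## 1. Transforms

Relative abundances are compositional; two transforms map them to spaces
where Euclidean operations are meaningful.

**clr.** Per sample, proportions receive a pseudocount, are re-closed, and
become `ln(x_i / geometric mean(x))`.  The pseudocount policy is *half the
smallest nonzero proportion in the whole table* — scale-aware and
conventional when zeros represent detection limits; it is overridable.
Rows of a clr matrix sum to 0 within 1e-9 and the transform is invariant
to per-sample rescaling of the raw counts.  Note that zeros become large
negative spikes (`ln` of the pseudocount); with 10% structural zeros these
spikes dominate per-taxon clr variance, which matters for power and
calibration (see §6, §7).

**Square-root + autoscale.** Element-wise square root of proportions, then
per-feature centering and division by the sample (n−1) standard deviation.
Constant features become all-zero columns and are flagged rather than
producing NaNs.  Every transformed matrix carries a provenance tag, and
downstream stages refuse the wrong transform (angles require
`sqrt_autoscaled`, associations and RDA require `clr`): the analyses use
different transforms and silently mixing them is the main foot-gun.

## 2. Diversity

Shannon `H = −Σ p ln p` in nats (the convention of the standard ecology
implementations), per sample at species level.  Pairwise cohort
comparisons use the Wilcoxon rank-sum test: for combined sizes ≤ 12 an
exact enumeration of all C(m+n, m) group assignments (valid under ties,
two-sided by distance from the null mean), otherwise the normal
approximation with tie and continuity corrections.  All pairwise p-values
are BH-adjusted jointly.

## 3. Enterotyping

Distances are √(Jensen–Shannon divergence) with natural-log entropies —
a true metric bounded by √(ln 2) — computed on genus-level profiles.
PAM is implemented directly (no installed Python library offers k-medoids
on a precomputed distance matrix): BUILD seeds greedily, SWAP applies the
best strictly-improving medoid/non-medoid exchange until a local optimum.
Determinism rules: equal-cost swaps are rejected; equidistant points join
the lowest-index medoid; restart 0 is the deterministic BUILD start and
further restarts draw random seeds (default 10 restarts, seeded).  On 100
random instances with n ≤ 8 the returned cost equals the exhaustively
enumerated optimum.

The Calinski–Harabasz index needs centroids, which a distance matrix does
not provide, so CH is evaluated on the full set of positive-eigenvalue
principal coordinates (classical scaling of −½D², double-centered;
negative eigenvalues are reported unaltered, never corrected).  The
pipeline records the CH curve over k = 2…6 and picks its maximum (ties to
the smaller k) but accepts a forced k, because model-selection indices are
a guide: a study may prefer k matching its design (e.g. five clusters when
CH slightly favors two).

## 4. Cohort-centroid angles

The bespoke statistic: after the square-root/autoscale transform, a full
SVD PCA (deterministic sign convention: each loading column's
largest-magnitude entry is positive) is fitted once.  Each component is
screened with a univariate logistic regression against a binary
reference-cohort-vs-rest indicator; components with two-sided P < 0.05
are retained, unadjusted — screening is meant to be permissive.  When a
fit separates or fails to converge, the Wald p collapses (Hauck–Donner:
the coefficient saturates and its standard error explodes, driving p
toward 1 exactly when the component is *most* informative), so the
implementation falls back to the likelihood-ratio test whenever the
standardized coefficient saturates, and flags the component.

Cohort centroids are the arithmetic means of sample scores on the retained
components (cohorts need ≥ 3 samples; a centroid indistinguishable from
the origin is an error).  Angles are `arccos` of the clipped cosine
similarity, in degrees on [0°, 180°].  Uncertainty comes from a stratified
nonparametric bootstrap: each of `n_iter = 500` iterations resamples
samples with replacement within each cohort and recomputes all pairwise
angles *in the fixed screened subspace*.  Holding PCA and screening fixed
keeps axes and signs commensurable across iterations; a
`refit_pca_per_iteration` switch (with sign alignment to the reference
loadings) is provided for sensitivity analysis, as is a
`variance_weighted` option that scales retained components by the square
root of their explained variance (default: unweighted, since the centroid
is defined as a plain mean of significant components).  Mean and SD per
pair are linear statistics on the bounded range — appropriate for a
quantity reported as, say, 141° ± 23°.  Interpretation bands (configurable)
map the mean angle to similar composition [0°, 60°), dissimilar
composition [60°, 120°), inversely correlated [120°, 180°].

Two properties of the estimator matter for interpreting results:

- Centroids are measured from the grand mean of the data, so the angles
  estimate the geometry of cohort offsets *relative to the pooled
  average*, not relative to any external baseline.
- Autoscaling normalizes each feature's total variance, which includes its
  between-cohort share; strongly anisotropic between-cohort structure is
  therefore partially whitened, biasing angles toward the whitened
  geometry.  The effect is small when per-feature between-cohort variance
  is well below the within-cohort variance.

## 5. Variance partitioning

RDA is the least-squares projection of the column-centered response matrix
onto the design's column space (intercept included):
`R² = tr(ŶᵀŶ)/tr(Y_cᵀY_c)`, Ezekiel-adjusted with m = design rank minus
intercept.  Categorical variables are treatment-coded; constant and
aliased columns are dropped with a warning.  Marginal partitioning fits one
single-variable RDA per covariate plus the joint model — per-variable
percentages from correlated predictors deliberately need not sum to the
joint total.  The default response is clr species abundances; a functional
module table can be column-bound after autoscaling both blocks so neither
dominates by scale.

Forward stepwise selection mirrors vegan's `ordiR2step` (verified against
it on identical data): at each step the candidate with the largest
adjusted-R² gain is tested by Freedman–Lane permutation of the current
model's residuals (computed efficiently through the residual inner-product
matrix, so each permutation costs O(n²) regardless of the number of
response columns), and admitted only if its conditional p < α and the
grown model's adjR² does not exceed the all-candidate global adjR²
ceiling.  Two consequences of this rule are worth knowing.  First, when
the last genuinely informative candidate enters, the model's adjR² and the
global adjR² estimate the same population quantity, so the ceiling blocks
that final step in roughly half of realizations — an intrinsic property of
the ceiling rule, reproduced exactly by vegan.  Second, with all-null
candidates the best-of-m candidate is tested with an unadjusted
per-candidate permutation p, so the probability of selecting at least one
null variable is well above α (≈ 20% with ten candidates at α = 0.05,
again matching vegan); the ceiling mitigates but does not remove the
selection effect.  Users should treat the selection order, not the
stopping point, as the robust output.

PERMANOVA uses Anderson's formulation: G = Gower-centered(−½D²),
pseudo-F = [tr(HG)/m] / [tr((I−H)G)/(n−m−1)] with H the hat matrix of the
(dummy-coded or continuous) design — this generalizes beyond one-way
groupings.  p-values use free row/column permutation of G with the add-one
rule (never exactly zero; identical seeds give identical p).  On Euclidean
distances the pseudo-F equals the classical RDA F exactly.  The default
distance is Bray–Curtis on relative abundances with Euclidean-on-clr
selectable; the choice is recorded in the output.

## 6. Two-step associations

Step one: per (feature, medication) pair, a Gaussian linear model of the
clr feature on the 0/1 exposure flag, computed in closed form and verified
against statsmodels.  One BH correction is applied jointly across *all*
feature × covariate tests (pooling scope is configurable; the joint pool is
the stricter default).  Step two: per feature with at least one surviving
medication, a single multivariate Gaussian model containing every screened
medication plus age and sex; aliased (perfectly collinear) medications are
dropped and flagged; no further multiplicity correction is applied, since
screening already paid the multiplicity price.  A gating invariant is
asserted on every run: no (feature, medication) pair reaches the
multivariate stage without a univariate BH q below threshold.  Age and sex
enter only the multivariate stage (the screening step isolates the
individual medication effect; confounder adjustment happens in the joint
model).  The heatmap export keeps features with ≥ 2 significant
multivariate associations.  Point-biserial correlation (≡ Pearson against
the 0/1 outcome) is bootstrapped with 1,000 resamples; one-class resamples
are redrawn and counted.

## 7. The synthetic-data generator

Per sample s and taxon i, log abundance is

    z_si = b_i + boost_{e(s),i} + shift_{c(s),i} + Σ_v x_sv β_vi + ε_si

with baseline profile `b ~ N(0, base_sd²)` (default 1.0), enterotype
boosts (`enterotype_dominance`, default 4.0 log-units, on all species of a
randomly chosen disjoint driver genus per enterotype — e^4 ≈ 55×, making
the driver genus dominate its samples as real enterotypes do), cohort
shift vectors, covariate effects (0/1 flags, disease, sex; age enters
z-scored), and `ε ~ N(0, dispersion²)` (default 1.0).  Abundances are
`exp(z)`, hit by structural zeros with probability `zero_rate`
(default 0.1) — never a sample's top-3 taxa, so no sample degenerates —
and closed to 100%.  Metadata carries cohort, per-cohort normal age,
Bernoulli sex and per-cohort Bernoulli medication flags;
`any_medication` is derived as the flag union.  The default study scenario
(5 cohorts × 60 samples, 200 species in 40 genera) mirrors the scale of a
multi-cohort clinical metagenomics study, with medication rates patterned
on the gradient from heavily medicated hematology cohorts to
medication-free healthy controls.  Everything planted is returned as a
`GroundTruth` object.

**Variance-fraction calibration.** `calibrate_variance_fraction` scales an
effect vector so its covariate explains a target share of total clr-space
variance *as measured by the downstream marginal RDA itself*: an analytic
first guess from the residual variance of an effect-free simulation,
followed by up to four multiplicative corrections from the realized
adjusted R² (three simulation replicates each, at the spec's own sample
sizes).  The simulation loop absorbs closure, pseudocount and
structural-zero attenuation that no analytic scale captures.  Dense effect
vectors are preferred for calibrated covariates: concentrating a given
variance share on few taxa requires per-taxon shifts so large that they
saturate against the zero/pseudocount floor and the calibration cannot
reach its target.

**Planting recoverable angle geometry.** The angle benchmark (four cohorts
of 60, 200 taxa) must plant pairwise angles that the estimator of §4 can
actually recover.  Four constructions make that possible, each neutralizing
one estimator property:

1. *Sum-zero shifts.* Centroids are measured from the grand mean, so the
   planted shift vectors are chosen to sum to zero across the equal-sized
   cohorts; the planted frame then coincides with the estimator's frame.
   Directions 0°/45°/225°/90° with magnitudes in the sum-zero family
   (m_ref = m_ortho = (m_anti − m_near)/√2) give the pairwise angle set
   exactly {45°, 90°, 135°, 180°}.
2. *Closure-orthogonality.* Compositional closure maps a log-space shift δ
   to δ − (p₀ᵀδ)·1 to first order, and the all-taxon direction has norm
   ~√(n_taxa) after autoscaling, so even a small p₀ᵀδ contaminates at the
   order of the signal.  Shift vectors are therefore built orthogonal to
   the expected composition p₀ (and to 1).
3. *Equal-row-norm embedding.* The 2-plane is embedded on taxa via
   equally-spaced directions on the circle (random rotation and
   permutation per seed) instead of Gaussian rows, so no taxon carries a
   disproportionate share of the signal and the autoscaling warp of §4
   stays uniform.
4. *Oblique, balanced magnitudes.* The reference direction must not be an
   eigenvector of the between-cohort covariance — otherwise the
   reference-vs-rest screen is structurally blind to the orthogonal plane
   axis and drops it.  The chosen magnitudes keep the reference oblique to
   both principal axes and the between-cohort covariance as isotropic as
   the angle set permits (a planar configuration containing a 180° pair
   cannot be exactly isotropic).

Signal scale is calibrated at 5× the noise SD (dispersion 0.35,
base_sd 0.5, no structural zeros in this benchmark: zero-inflation noise
in square-root space would swamp the planted plane at this dispersion).
Under these conditions the bootstrap mean angles land within ±10° of the
planted values in 20/20 seeds; the residual few-degree biases are the
quantified estimator properties (grand-mean centering correlation,
arccos curvature, autoscale whitening), not implementation error.

**What the generator does not emulate:** phylogenetic correlation between
taxa, read-count (sequencing-depth) noise, longitudinal structure,
realistic co-prescription correlation between medication classes, and
taxon-specific zero-inflation tied to abundance.  Passing recovery tests
on this generator therefore demonstrates correctness of the estimators
under the stated model, not robustness to every property of real
metagenomic data.

## 8. Determinism and numerics

Every stochastic stage takes an explicit seed and uses an independent
`numpy` generator; the CLI records the seed in each run's JSON manifest,
and identical seeds yield byte-identical TSVs (12-significant-digit
formatting, chosen so float64-scale results round-trip).  Tolerances:
symmetric-matrix and clr identities at 1e-9…1e-12; cosine clipping before
`arccos` (which loses ~√ε precision at ±1); permutation p-values use the
add-one rule; PAM asserts its cost is non-increasing across swaps.
Degenerate inputs fail loudly with the offending sample, cohort, or column
named: all-zero abundance vectors, one-class outcomes, sub-minimum
cohorts, rank-deficient designs (dropped with warnings), near-origin
centroids.

## 9. Problem sizes used by tests and the acceptance script

Angle recovery: 20 seeds × (240 samples × 200 taxa, 500 bootstrap
iterations).  Enterotypes: 10 seeds × (180 × 200, k = 2…6, 10 restarts).
PAM optimality: 100 instances, n ≤ 8.  √JSD axioms: 1,000 random triples.
RDA calibration: 50 replicates of 120 × 200.  Stepwise: 50 planted +
100 all-null runs of 120 samples × 200 taxa × 10 candidates at 199
permutations.  PERMANOVA: 200 null data sets of 40 × 20 at 199
permutations plus one exhaustively enumerated 6-sample instance.
Associations: 3 replicates of 150 × 500 × 10 (5,000 tests).  These sizes
make the whole validation suite run in a few minutes on one CPU while
keeping Monte-Carlo error within each check's stated tolerance.
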