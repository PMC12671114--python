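# gutcompass

Cross-cohort comparison of gut microbiome profiles: alpha diversity,
enterotype clustering, a cohort-centroid *angular similarity* statistic,
redundancy-analysis variance partitioning, PERMANOVA, and two-step
medication–taxon association regression — packaged with a synthetic
multi-cohort data generator that plants known ground truth, so every stage
of the pipeline can be validated end to end.

## Who this is for

Microbiome studies that span several patient cohorts (e.g. a disease of
interest, sicker and healthier comparator cohorts, and healthy controls)
face a recurring question: how much of the between-cohort difference in gut
composition is disease, and how much is medication, age, or sex?  Patient-level
metagenomic data in such studies is typically access-restricted, so
`gutcompass` pairs each analysis with a generator that emulates the study
design — cohorts of tens of samples, hundreds of species collapsed into
genera, dominant-genus enterotypes, cohort centroid shifts with controllable
pairwise geometry, covariate effects with controllable variance fractions,
and zero inflation — and records exactly what it planted.

## The analyses

Let `x_s` be a sample's relative-abundance vector (closed to 100%).

- **Diversity** — Shannon index `H = −Σ p_i ln p_i` (nats) at species level;
  all pairwise cohort comparisons by Wilcoxon rank-sum (exact enumeration for
  small groups, normal approximation with tie/continuity correction
  otherwise) with Benjamini–Hochberg correction.
- **Enterotypes** — square-root Jensen–Shannon divergence
  `d(P,Q) = √(H(M) − (H(P)+H(Q))/2)`, `M = (P+Q)/2`, between genus-level
  profiles; Partitioning Around Medoids (BUILD + SWAP, implemented here)
  for k = 2…6; Calinski–Harabasz index `[B/(k−1)]/[W/(n−k)]` on principal
  coordinates to guide the choice of k (a forced k is supported); top driver
  genera per cluster by median abundance.
- **Angular similarity** — PCA of square-root-transformed, autoscaled
  species abundances; univariate logistic screening of each component
  against a reference-cohort indicator (keep components with P < 0.05);
  cohort centroids = mean score vectors on the retained components; the
  angle `θ(A,B) = arccos(v_A·v_B / ‖v_A‖‖v_B‖)` between centroid vectors,
  bootstrapped (stratified within cohort, 500 iterations) for a mean ± SD
  per cohort pair, with interpretation bands: < 60° similar composition,
  60–120° dissimilar, > 120° inversely correlated.
- **Variance partitioning** — redundancy analysis of the clr-transformed
  abundance matrix on metadata designs; `R² = tr(Ŷᵀ Ŷ)/tr(Y_cᵀ Y_c)` with
  the Ezekiel adjustment `1 − (1−R²)(n−1)/(n−m−1)`; marginal single-variable
  fits, forward stepwise selection with Freedman–Lane permutation tests and
  a global-adjusted-R² ceiling (the `ordiR2step` logic, verified against
  vegan), and PERMANOVA via the Gower-centered matrix.
- **Associations** — per (taxon, medication) univariate Gaussian regression
  on clr abundances with one joint BH correction; survivors go into one
  multivariate model per taxon (screened medications + age + sex, no further
  correction); point-biserial feature–outcome correlation with a 1,000-draw
  bootstrap interval.

## Worked example

Simulate a five-cohort study (60 samples each, 200 species in 40 genera,
three planted enterotypes, disease/medication/age/sex effects calibrated to
few-percent variance fractions) and run every stage:

```bash
gutcompass simulate --seed 1 --outdir sim
gutcompass all --abundance sim/abundance.tsv --metadata sim/metadata.tsv \
    --seed 1 --outdir results
```

`results/variance_marginal.tsv` then reads:

```
variable        r2              adj_r2
disease         0.0313160013163 0.028065383871
any_medication  0.0218823515063 0.0186000775181
age             0.0082990049636 0.00497114927555
sex             0.00693178050829 0.00359933681872
__joint__       0.050500664801  0.0376260975441
```

i.e. disease explains ~2.8% of clr-space variance (it was planted at 3%),
any-medication ~1.9%, age and sex under 1%, and everything jointly ~3.8% —
the characteristic result that most gut microbiome variance stays
unexplained by clinical covariates.  `results/variance_stepwise.tsv` shows
the forward selection trace (disease entered first at adjusted R² 0.028,
then a corticosteroid-class flag, sex, and age), and
`results/permanova.tsv` reports a Bray–Curtis PERMANOVA across cohorts
(pseudo-F = 18.8, p = 0.001 at 999 permutations).  The angle stage writes
per-pair means, SDs and interpretations; on the angle benchmark (four
cohorts planted at pairwise angles {45°, 90°, 135°, 180°}) the bootstrap
means land within ±10° of the planted values in 20 of 20 seeds.

Each stage also writes a JSON manifest (inputs, seed, package versions,
parameters), and two runs with the same `--seed` produce byte-identical
TSVs.

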