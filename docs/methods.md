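# Methods

This note documents the models, rules and numerical choices behind
`sedadiv`, and what the synthetic-data generator does and does not
emulate.

## Quality scores and gating

Both scores summarize replication of a sample's 10 most read-abundant
sequences across its `n_replicates` (default 8) PCR replicates, as a
proportion of the 10 × n_replicates possible detections. MTQ uses every
sequence surviving the per-replicate low-count filter (identified or
not); MAQ restricts to identified, non-blacklisted sequences, so
co-amplification of contaminant or unidentifiable sequences depresses MTQ
relative to MAQ (the converse can also occur; a regression test keeps a
constructed counterexample). Choices that needed pinning:

* When a sample has fewer than 10 sequences, the denominator stays
  10 × n_replicates. This deliberately reproduces the known artifact that
  the scores correlate with richness when richness is low: sparse samples
  are penalized.
* Ties at the rank-10 boundary break by lexicographic sequence id, making
  the scores independent of row order.
* MTQ is computed on post-per-replicate-filter counts (pre-filter counts
  would reward unreplicated noise).
* Gating is inclusive: a sample passes at exactly MTQ = 0.75 and
  MAQ = 0.2. Among multiple DNA extracts of one sample, the extract with
  the greatest MAQ is kept; exact ties go to extract 1.

## Filtering and harmonization

Stages run in a fixed order — per-replicate filter, exact-match taxonomy,
blacklists, dataset-wide filter, same-taxon merging, non-target
exclusion — because the dataset-wide filter counts only what earlier
stages left behind; tests pin the order. Boundary semantics: a replicate
cell needs ≥3 reads; a sequence needs ≥10 reads *and* ≥3 positive
replicate cells over the entire dataset (removal when either condition
fails). The dataset-wide scope is the whole multi-lake dataset; a
per-lake scope flag exists for sensitivity analysis and is strictly more
aggressive.

Same-taxon barcodes are merged per connected component of the
co-occurrence graph (an edge wherever two barcodes share a sample):
within a sample, reads are summed per replicate, so the detection set is
the union of the inputs (≥ the max of either). Components that never
co-occur stay separate taxa with numeric suffixes. Merging conserves
every sample's total read count.

The two *Vaccinium* congeners share a barcode stem and differ in the 3′
poly-A run: ≤5 A's → *V. myrtillus*, >8 A's → *V. vitis-idaea*. The
unspecified gap (6–8 A's) is assigned to genus level — the conservative
completion of the rule. A sequence with no terminal A counts as run
length 0.

## Detectability and diversity

wtRep weights each PCR replicate by its share of the sample's retained
reads: a taxon's detectability is the summed weight of the replicates
where it was detected. Replicates with zero retained reads drop out of
both numerator and denominator. Because wtRep overstates detectability in
sparse samples, it is only used when the sample has ≥10 taxa and a mean
detection proportion ≥0.33 (the mean is taken over taxa); otherwise the
plain proportion of positive replicates is used. Hill numbers are
computed on the normalized detectability profile; N1 is rounded to whole
numbers only when fed to Poisson trend models, never in stored outputs.
Rarefaction is analytic (hypergeometric expected richness, computed in
log space), standardized within each lake to its smallest per-sample read
total; a seeded Monte-Carlo mode exists for cross-checking.

## Regional species pool

The pool is the cumulative count of distinct taxa over all retained
samples ordered oldest → youngest (age ties break by lake and sample id).
Growth rates over an age window are reported two ways: the OLS slope of
log cumulative count on log years-since-first-sample (the accumulation
scaling exponent), and the linear-scale rate in taxa per millennium.

For the binned estimate, samples join the nearest 500-year bin (exact
midpoints round to the older bin). Within a bin, Beals smoothing gives
each taxon an occurrence probability per sample; the focal taxon is
excluded from its own conditioning set (the standard form — the formula
is pinned explicitly in the code because published implementations vary
in detail). The completion threshold is per taxon within the bin: the
minimum probability among the samples where the taxon was observed, so
every observed occurrence is retained and thresholding can only add
occurrences. Taxa unobserved in a bin are never added. Completed bins are
standardized by 1000 subsamples of 5 samples (the smallest usable bin)
without replacement; each bin draws from an independent RNG substream of
one global seed. Bin-level trends are fitted by OLS: standardized pool on
bin age with and without a quadratic term, and mean richness on the
standardized pool.

## Drivers

The nutrient index is NI = (P + K + ln Ca) / H_min with P, K, Ca in ppm
and H_min the extended Mohs hardness of the most easily weathered
principal mineral. The division is a deliberate reading of an ambiguous
formula: nutrient release should decrease as the weakest mineral gets
harder; a multiplication mode is available behind a flag. ln Ca is used
because Ca tracks pH, which controls nutrient availability.

The temperature proxy joins by nearest age on its 50-year grid, ties to
the older point; values below −39 (cold outliers) are excluded from the
driver model by default. Holocene periods split at 8.3 and 4.25 ka with
boundary ages assigned to the older period; pre-Holocene samples
(>11.7 ka) are rejected.

Per-lake trends are penalized B-spline Poisson regressions fitted by
penalized IRLS. The basis (default dimension 10, capped at half the
sample count) is built on age rescaled to [0, 1] so the difference
penalty has order-one scale; the penalty weight minimizes AIC
(deviance + 2·edf) on a log-spaced grid. Fitted values are reported at
300 evenly spaced ages with a pointwise 95% band from the t distribution
on the Bayesian covariance of the penalized fit; reported edf excludes
the intercept. On flat Poisson data the band's pointwise coverage is
≈95% and edf ≈ 1–2.

The CAR1 option is a two-stage scheme: a continuous-time AR1 coefficient
φ (per millennium) is estimated on age-ordered Pearson residuals of the
plain fit by least squares, then the working model is refitted once with
AR1-whitened equations at the same penalty. φ is kept only when the
implied one-step residual correlation exceeds 2/√n; below that the
whitening is indistinguishable from noise. Because the spline absorbs
slow residual structure, detectable φ requires correlation faster than
the basis resolution — which is also why plain and CAR1 fits are near
identical on AR-free data (a property the tests assert).

The regional trend adds ridge-penalized lake indicator columns to the
shared smooth (the random-effects-as-smooths construction), keeping the
Poisson family; the reported curve sets lake effects to zero
(population level) and the random-intercept variance is the empirical
variance of the fitted lake coefficients. A single lake reduces exactly
to the per-lake fit.

The driver model is `statsmodels` MixedLM: log richness on per-period
δ¹⁸O and NI slopes plus period intercepts, with random intercept and
random age slope (age in ka) per lake, REML. A singular random-effects
covariance triggers a flagged refit without the random slope.
Period-by-driver interactions are tested by Wald F on slope-equality
contrasts. Variance explained uses the marginal/conditional
decomposition: fixed-effect variance over fixed + random + residual.

## The synthetic generator

The generator emulates the study design the pipeline targets: ~10 lakes
(two short, Late-Holocene-only records), 12–55 samples per lake, 8 PCR
replicates, a 288-taxon regional pool that accumulates at piecewise rates
(42.37, 9.35, 21.82 taxa per millennium, then ~4.85 so the last 3.3 ka
add ~16 taxa), expected log richness responding to the warming proxy
(β = 0.24, Early Holocene only) and to the catchment nutrient index
(β = 0.12), centered at reference values δ¹⁸O = −35.5 and NI = 5.
Realized richness is Poisson, truncated to the taxa colonized by the
sample's age; community membership uses persistent per-lake taxon
affinities; relative abundances are log-normal renormalized to the
simplex (a few dominant, many rare).

Read simulation: per-replicate retained-read depths are log-normal
(μ = 9, σ = 1 on the log scale, i.e. a median of ~8000 reads);
a taxon's per-replicate detection probability is
λ/(λ + h) with λ = abundance × depth and h the half-saturation constant
(default 8 reads), the simplest mechanism that yields abundance- and
depth-dependent replicate dropout. About 15% of samples are "inhibited"
(depths scaled down by a factor of 50–1000), which makes their top
sequences replicate sporadically and lets the MTQ/MAQ gate fail roughly
the fraction of samples seen in real multi-lake datasets. Contaminants
are novel random sequences absent from the reference database, so they
depress MTQ but not MAQ. Negative controls carry only sporadic low-count
detections and fail the gate by construction. A synthetic Greenland-style
δ¹⁸O series provides the proxy (Early warming at 0.92 per ka, flat
middle, slight late decline, AR(1) noise, and a brief cold oscillation
below −39 at the start so the outlier-exclusion rule is exercised).

What the generator does **not** emulate: sequencing error and chimera
formation, tag jumping, DNA damage patterns, age-model uncertainty
(ages are inputs), multiple DNA extracts per sample, and real taxonomic
structure in the reference database. Passing tests therefore demonstrate
that the pipeline's rules and estimators behave correctly under the
assumed generative structure, not that the structure captures every
failure mode of real sedaDNA.

## Validation designs and problem sizes

Parameter-recovery studies run at the community level (ground-truth
richness per sample) under a validation configuration in which the whole
pool is colonized from the start and the extra smooth term is off, so the
mixed model's assumptions hold exactly; 100 replicate simulations then
give ~92–95% CI coverage for the temperature and nutrient effects and a
~5–7% type-I rate for the interaction F-test. Under the default
colonization curve the Early-Holocene pool truncation biases the fitted
temperature slope upward (≈0.28 vs the generating 0.24) — an ecological
feature of pool-limited richness, visible in the acceptance output, not
an estimator defect. Unit and end-to-end tests use a scaled-down study
(5 lakes, 120-taxon pool) so the default suite stays fast; the
acceptance script runs the full default design.

## Known limitations

* Exact-match taxonomy only; no fuzzy or lowest-common-ancestor
  assignment.
* The AR1 correction is two-stage, not a joint likelihood; φ is
  conservative by design.
* Beals completion follows the pinned formula; external packages may
  differ in indicator conventions.
* The fixed-effect variance share depends on the decomposition
  convention; alternative estimators can differ by several points.
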