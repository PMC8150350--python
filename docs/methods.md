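# Methods

## Scope and data model

The package analyzes three patient-level tables: per-core immune-marker
densities (positive cells/mm² for CD3, CD8, FOXP3, CD56, CD68, CTLA-4,
LAG3, PD-1, GZMB, on up to four 1-mm TMA cores per patient — two at the
invasion front, two in the tumor center), per-assay PD-L1 readouts (IC%,
TC%, CPS for SP142, SP263, 22C3, 28-8), and per-patient annotations (sTILs
%, DSS/DFS times in months with event flags, clinical covariates). Image
analysis and pathologist scoring are upstream of this package: densities,
readouts and core-level QC flags are inputs. QC filtering removes failed
cores; a patient is retained with any surviving core and dropped (with a
logged warning) only when every core fails, since densities are then
unavailable for phenotyping.

## PD-L1 scoring and consensus

CPS = 100·(PD-L1⁺ tumor cells + PD-L1⁺ immune cells)/viable tumor cells,
capped at 100 and undefined for zero viable tumor cells. Dichotomization
uses inclusive cut-offs — CPS ≥ 10, Ventana IC ≥ 5%, TCarea ≥ 25% OR
ICarea ≥ 25% — matching the clinical convention that the cut-off value is
attained. Consensus scores are per-patient medians across assays, built to
damp inter-assay and section effects: CPS and TCarea consensus over
SP263/22C3/28-8 (SP142 is excluded from TC-dependent scores because of its
reduced TC detection sensitivity), IC-based consensus over all four assays.
The Ventana IC and ICarea consensus are computed by the same median rule
over `ic_percent` — both are the percentage of tumor area covered by
PD-L1⁺ immune cells, and nothing in the source material distinguishes them
operationally, so they are carried as two fields with one estimator. An
even number of assays yields the mean of the two middle values; missing
assays degrade gracefully to the median of the available eligible readouts,
and a score with no eligible assay is carried as missing and only raises
when a classification actually needs it. The durvalumab rule is implemented
as the pure 25% TC-or-IC disjunction; the low-infiltration immune-cells-
present sub-rule of the full label algorithm is out of scope.

## Features, ICIS and clustering

Per patient, marker and region, core densities are collapsed by the median
over QC-passing cores. Density features are transformed x → log2(x+1) — the
pseudocount is needed because zero densities are common, and maps 0 → 0 —
then Z-scored per feature with the population SD (divisor n; deterministic
and exact on two-point examples; switching to n−1 is a one-line change).
PD-L1 consensus features enter the same matrix Z-scored on their native
percent scale, without the log transform. Zero-variance features become
all-zero columns; missing cells are imputed with the feature's cohort
median before Z-scoring, which preserves the Z-centering with minimal
influence. sTILs is not a clustering feature.

ICIS is the mean (not the sum — scale-free in the number of features) of a
patient's 18 Z-scored density features; by construction the cohort mean is
0 (|mean| < 10⁻⁹) when nothing was imputed.

Patients are clustered by WPGMA (weighted pair-group average) linkage on
Euclidean distances over the 22 features, delegating the linkage to
`scipy.cluster.hierarchy.linkage(method="weighted")`, and the dendrogram is
cut into exactly k clusters (k = 4 by default). WPGMA is reducible, so the
scipy result is merge-order invariant whenever pairwise distances are
distinct; the test suite additionally verifies it against an independently
re-implemented exhaustive agglomerative oracle with smallest-index
tie-breaking. Cluster ids are relabeled 1..k in first-appearance order so
output is deterministic given the input row order.

Cluster-to-phenotype labeling is a fixed rule applied in order: highest
cluster-mean Z of TCarea consensus → *Evasion*; of the rest, highest
cluster-mean Z of ICarea consensus → *Inflamed: High*; of the remaining
two, higher mean ICIS → *Inflamed: Low*, lower → *Uninflamed*. Exact ties
fall to the lower cluster id with a logged warning.

## Concordance, coverage and rescue

OPA between two dichotomized algorithms is the fraction of patients on
which they agree (both positive or both negative); it is symmetric and
invariant to consistently flipping both vectors. The three statuses induce
an exact 8-region Venn partition whose region counts sum to the cohort and
reproduce the per-algorithm totals two ways. Coverage is, per (phenotype,
algorithm), the fraction of the cluster scored positive. The rescue rule
targets *Inflamed: Low* patients negative by at least one algorithm
(matching the published 48-case denominator) and flags those with CD8
density ≥ 201 cells/mm² (patient-level aggregate: median over QC-passing
cores, regions pooled) OR sTILs ≥ 10%, both inclusive. The default
cut-offs are the source cohort's medians and are parameters, since other
cohorts will have other medians.

A documented divergence: the published inter-algorithm OPA range
(63.1–87.7%) cannot be reproduced from the published Venn partition, which
under consensus-level statuses yields pairwise OPAs of 149/193 = 77.2%,
155/193 = 80.3% and 170/193 = 88.1%; the published range was plausibly
computed per assay rather than per consensus. The package reports
consensus-level OPA.

A second documented inconsistency: within the 48 PD-L1-negative
*Inflamed: Low* cases, the published per-algorithm negative counts
(Ventana 46, TC/IC 44, CPS 48) are incompatible with the published
triple-negative count of 33, because 46 + 44 − 48 forces at least 42
patients negative by both Ventana and TC/IC (and all 48 are CPS-negative).
The cross-tabulation fixture therefore encodes 48/46/33 and the rescue
count 39 exactly, and sets TC/IC-negative to 35, the largest consistent
value.

## Survival

The Kaplan–Meier product-limit estimator is implemented directly (events
at tied times are processed with censored subjects still in the risk set at
that time); 5-year rates are the curve value at 60 months, read
right-continuously. Median potential follow-up is the median of the
reverse-KM curve (event indicator inverted), with infinity as the
not-reached sentinel. Log-rank tests and Cox proportional-hazards fits
delegate to lifelines; Cox models adjust the indicator of interest for pT
stage, pN stage, lymphovascular invasion, age, gender, margin status,
adjuvant platinum chemotherapy and grade, with categorical covariates
dummy-encoded against a reference level, Efron tie handling (the lifelines
default), and complete-case exclusion of rows with missing covariates
(logged). Covariate encodings are data-driven rather than fixed, as the
original level collapsing is not published.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, not any real
patient data. Defaults, chosen once as the study conditions:

- **Cohort**: 193 patients; phenotype prevalences (Evasion, Inflamed: High,
  Inflamed: Low, Uninflamed) = (0.14, 0.14, 0.35, 0.37) — the two 27-patient
  clusters fix the first two at ≈ 27/193, the remaining split is an
  assumption — allocated exactly by largest-remainder rounding; 2 cores per
  region.
- **Densities**: per core, 2^N(μ, σ) − 1 truncated at 0, with μ = phenotype
  base (Evasion 7.0, Inflamed: High 9.0, Inflamed: Low 6.5, Uninflamed 4.0,
  in log2 cells/mm²) plus shared marker offsets (CD3 +1.5, CD8 +1.0, CD68
  +0.5, GZMB 0, FOXP3/PD-1 −0.5, CTLA-4/LAG3 −1.5, CD56 −2.5) and region
  offsets (±0.3, invasion front higher); σ = 1.0. These bases put
  phenotype-level CD8 medians around 30–1000 cells/mm², straddling the
  201/mm² rescue cut-off, and give the wide between-phenotype separation
  seen in real immune-profiling heat maps.
- **PD-L1**: patient-level latent (IC, TC) ~ N of the phenotype means —
  (3, 60) Evasion, (30, 4) Inflamed: High, (2, 1) Inflamed: Low,
  (0.5, 0.5) Uninflamed, with latent SD 8/8/2/1 — a CPS latent of
  min(100, TC + IC), then per-assay readouts with additive N(0, 5) assay
  noise, all clipped to [0, 100]; SP142's TC signal is multiplied by
  (1 − attenuation), default attenuation 0.8.
- **Survival**: per endpoint, exponential times with rate
  λ = −ln(S₅)/60 solving S(60) = the phenotype's 5-year rate; the DSS
  defaults (0.298, 0.747, 0.431, 0.277) and DFS defaults (0.258, 0.751,
  0.437, 0.237) are the published per-phenotype rates used as generator
  parameters. Censoring is administrative, C ~ U(0, H), with H solved
  numerically so the expected censored fraction under the phenotype mixture
  equals `censoring_rate` (default 0.4, typical of cystectomy cohorts with
  ~7-year follow-up). DSS and DFS are drawn independently, which real data
  violates (DFS events precede DSS events); nothing downstream uses their
  joint law.
- **sTILs** and clinical covariates are drawn from plausible marginal
  distributions (sTILs phenotype-linked; covariates independent of outcome,
  so adjusted and unadjusted effects coincide in expectation).

What passing recovery tests therefore shows: the pipeline recovers
phenotypes, 5-year rates and hazard ratios when the data actually contain
four separable phenotypes with these signal-to-noise levels. It does not
show that four clusters is the right k for an arbitrary real cohort, nor
that real assay noise is additive Gaussian, nor anything about spatial
autocorrelation within cores, inter-pathologist variance, or PD-L1/ICIS
relationships subtler than the phenotype means encode.

The two fixture builders are synthetic stand-ins reconstructed from
published marginal counts; patient identities within a Venn region are
arbitrary and only the region counts are contractual.

## Verification sizes and numerical choices

The test suite and the acceptance script size their checks as follows:
KM vs brute-force oracle on 100 random instances (n ≤ 60, tied times,
~40% censoring); WPGMA vs exhaustive oracle on 50 instances with n ≤ 12;
5-year-rate recovery on 20 cohorts of 5000 survival draws, asserting the
seed-averaged per-phenotype rate within ±3 percentage points (the single-
draw SD at these group sizes is 1.2–2.0 points, so only the seed-averaged
rate carries a calibration claim; the worst single draw is reported
alongside); Cox recovery of HR 0.5 on 20 cohorts of n = 2000, requiring
the estimate in [0.4, 0.6] for ≥ 90% of seeds; phenotype-label recovery
pooled over 20 default 193-patient cohorts, requiring ≥ 90%. Medians of
even counts are the mean of the middle pair throughout; all stochastic
tests run from fixed or CLI-provided seeds.

## Known limitations

- k = 4 is assumed, not selected; no gap statistic or silhouette support.
- The Cox layer exposes no proportionality diagnostics beyond lifelines
  warnings; no competing risks, no time-varying covariates.
- Consensus building treats assay readouts as already patient-level;
  consolidation of discordant duplicate cores happens upstream.
- The generator does not simulate images, per-cell point patterns, QC
  failure mechanisms, or correlated DSS/DFS.
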