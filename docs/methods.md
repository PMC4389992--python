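# Methods

This note records the statistical model behind `pathsurv`, the
conventions the implementation commits to where several were
defensible, and what the synthetic cohorts do and do not emulate.

## 1. Paired differential expression

For gene *g* and subject *i* with tumor/normal counts
(t<sub>gi</sub>, n<sub>gi</sub>):

* **Depth equalization.** Every library is binomially thinned to a
  common target depth *m* (default: the minimum library size): each
  count *c* in a library of depth *d* is replaced by Binomial(*c*,
  *m*/*d*). Thinning is repeated R times (default R = 20). Counts are
  integers and the thinned library total has expectation *m*, so depth
  is removed as a confounder without leaving the count scale.
* **Statistic.** Per resample, the Wilcoxon signed-rank statistic of
  the differences t − n: zero differences are dropped, tied absolute
  differences receive mid-ranks, and W = Σ sign·rank is standardized
  by its exact null SD √(Σ rank²). The reported statistic is the mean
  over resamples.
* **Permutation null.** Tumor/normal labels are flipped independently
  within pairs. Flips are shared across genes and across resamples,
  and null statistics are computed on the *same* resample stream as
  the observed statistic (common random numbers), so resampling noise
  cancels rather than inflating the null variance. Two-sided p-value
  by the add-one rule p = (1 + #{|null| ≥ |obs|}) / (B + 1) with
  B = 1,000 by default; for ≤ 10 pairs all 2ⁿ flips are enumerated and
  p = #{|null| ≥ |obs|} / 2ⁿ (the identity flip keeps p > 0).
  Benjamini–Hochberg q-values are reported per batch.
* **Fold change** is the ratio of the mean tumor to mean normal
  expression in counts per million with pseudocount 0.5 added to both
  means (the normalization and pseudocount are conventions; raw-mean
  ratios would be biased by depth).
* **Selection.** A gene is called de-regulated when p < 0.05 *and* the
  fold change is > 2 (or < 1/2) with the same direction in both
  discovery groups. Sidedness is two-sided (absolute-value
  comparison).

Measured operating characteristics (recomputed by the test suite and
`scripts/acceptance.py`): type-I error on a fully null cohort of 2,000
features × 30 pairs at 200 permutations sits inside 0.05 ± 0.01, null
p-values pass a Kolmogorov–Smirnov uniformity check, and power is
non-decreasing in the true fold change.

## 2. Discovery split

CRC deaths are randomly divided into groups A and B (counts differing
by ≤ 1); each deceased subject is matched without replacement to a
living subject of identical age category (5-year bins from 30 to 80+,
configurable) and sex, who inherits the group. Matching within exact
strata makes greedy matching optimal per stratum; strata short of
living partners log the shortfall. Other-cause deaths count as
non-deceased for the split. Unmatched living subjects stay out of the
discovery groups but remain in all cohort-level analyses.

## 3. DGES / DPES

The per-subject differential expression of gene *g* is
δ<sub>gi</sub> = log2((CPM<sup>t</sup> + c) / (CPM<sup>n</sup> + c)),
c = 0.5. Before scoring, δ is multiplied by the gene's cohort-level
direction (+1 up, −1 down) so that *larger always means more
de-regulated* — for a down-regulated gene the subjects closest to
normal have the least-negative δ and must land in the bottom bin. This
orientation is the single most consequential convention in the
package; without it the score inverts for down-regulated genes.

Scores: 1 if the oriented δ is strictly below the cohort's 25th
percentile, 3 if strictly above the 75th, 2 otherwise (boundary values
go to the middle bin; quantiles are linear-interpolation sample
quantiles over the full analysis cohort, not within discovery groups).
DPES is the sum of DGES over a pathway's scored genes, so a pathway
with G genes spans [G, 3G]. Per pathway, DPES is cut at the cohort's
33.3rd/66.7th percentiles into tertiles T1–T3; ties at a cut point go
to the *lower* tertile, keeping T3 conservative. A pathway whose
scores are all identical yields a degenerate single tertile and is
excluded from hazard estimation with a note.

## 4. Survival models

Event = CRC death; alive, other-cause death and unknown vital status
are censored at last contact. Records with non-positive follow-up or
unknown AJCC stage are dropped with a logged count. The Cox model uses
tertile indicators (T1 referent) plus age (continuous), sex, stage
indicators (2, 3, 4 vs 1) and binary TP53/KRAS/MSI/CIMP; ties are
handled by Efron's approximation (lifelines' default — real registry
follow-up is monthly and tied). Hazard ratios are exponentiated
partial-likelihood estimates with Wald 95% intervals. Kaplan–Meier
curves are fit per tertile; the stage analysis reports per-stage DPES
means/SDs and a Welch two-sample t-test between stages 1 and 4 (the
stage comparison test is not pinned down by convention; Welch is the
package's choice and is exercised against the closed-form statistic).

## 5. Synthetic cohorts

The generator emulates a population-based paired-sample study:

* **Counts.** Gene-level relative expression is log-normal; library
  depths are uniform on (0.5, 2) million reads; counts are negative
  binomial with variance μ + αμ² (α = 0.3 by default, the standard
  overdispersed RNA-seq model). A fraction `frac_de` (default 0.1) of
  genes carries a fold change drawn from (2, 6), 62% up-regulated.
* **Subject-level signal.** Each subject has a true de-regulation
  tertile (balanced 1/2/3). For DE genes inside *survival-linked*
  pathways, the subject's fold change is FC^s with exponent s =
  (0.6, 1.0, 1.4) by tertile, rescaled so the cohort-mean fold factor
  equals the drawn FC. This is what makes the true tertile recoverable
  from expression. Genes outside linked pathways are homogeneous, so
  background pathways are survival-null; an optional class of
  DE-enriched-but-unlinked pathways (`n_null_de_pathways`) provides
  matched null comparators for end-to-end checks.
* **Pathways.** Survival-linked pathways draw ~90% of members from the
  DE pool; background pathways draw uniformly. Pathways are disjoint
  by default; an overlap flag allows shared genes, as real canonical
  pathways overlap heavily.
* **Outcomes.** Survival is exponential with hazard
  h = h₀·exp(logHR[tertile]), h₀ = 0.004/month and logHR =
  (0, −0.9, −1.1) by default; administrative censoring at 120 months.
  Deaths are labelled other-cause with probability 0.30; 8.6% of
  subjects have unknown vital status and are censored at a uniform
  last-contact month. Covariates (age 65.2 ± 10.2 y truncated to
  30–99, 53.7% male, 47.9% proximal site, stage probabilities
  (0.23, 0.32, 0.33, 0.12), TP53 44% / KRAS 27.4% / MSI 18.3% / CIMP
  25.7%) match the descriptive composition of the cohort the package
  emulates, but are drawn independently of the hazard, so adjusted and
  unadjusted fits estimate the same tertile effect. Survival times are
  kept continuous (no rounding to whole months): parameter-recovery
  checks stay unbiased, while Efron tie-handling remains in place for
  real, discretized data.
* **Defaults as conditions.** 175 subjects is the default cohort; the
  default transcriptome is 2,000 genes in 20 pathways of 15 — a
  desk-scale problem size that keeps simulation studies (50 Cox
  replicates, 12 end-to-end replicates) in the seconds-to-minutes
  range. Everything is reproducible from a single integer seed via
  independent named substreams.

What the generator does **not** emulate: compositional normalization
artifacts beyond DE-driven depth inflation, FFPE degradation, isoform
structure, correlated gene–gene expression within pathways, batch
effects, covariate-dependent hazards, or non-proportional hazards.
Passing tests therefore demonstrate correctness of the statistical
machinery and recoverability of a planted signal under the stated
model — not robustness to every failure mode of real FFPE RNA-seq.

## 6. Numerical and design notes

* Exponential baseline hazard (constant) was chosen for closed-form
  checkability; the Cox fit is baseline-agnostic, so no generality is
  lost.
* The null-coverage simulation pools the T2 and T3 confidence
  intervals (100 CIs over 50 replicates) when checking the ≥ 90%
  coverage bound: per-coefficient counts of 50 have non-trivial
  probability of dipping below 90% even at exact 95% coverage.
* Degenerate inputs: all-zero differences give statistic 0 with a
  degenerate flag; constant delta profiles score 2 everywhere; Cox
  models with no events, missing tertile levels or non-convergence
  (separation) raise with diagnostics, and the pathway-level driver
  reports such pathways as not estimable rather than failing the run.
* Checks on `|null| ≥ |obs|` use a 1e-12 slack so mid-rank ties are
  counted as ties rather than lost to floating-point noise.
* Library-facing conventions: the hypergeometric tail is
  `scipy.stats.hypergeom.sf(k−1, N, K, n)`; BH adjustment wraps
  `statsmodels.stats.multitest.multipletests`; survival estimation
  uses `lifelines`. The resampled/permuted paired test and the
  DGES/DPES construction are implemented in this package and verified
  against enumeration and hand-computed oracles in the test suite.

## 7. Known limitations

* The enrichment step is generic GMT-based overrepresentation; it does
  not reproduce proprietary knowledge-base curation, network scoring
  or upstream-regulator analysis, so pathway *identities* from any
  specific commercial tool are out of scope.
* Whether per-subject differential expression should be a ratio or a
  difference, computed on which normalization and with which
  pseudocount, admits several defensible choices; the log2-CPM-ratio
  convention used here is symmetric, scale-free and standard, but
  alternatives would shift individual scores.
* With few events (small cohorts or rare tertiles) Wald intervals
  become unstable and tertile HRs may be reported as not estimable;
  no Firth-type correction is applied.
* Competing risks are handled by cause-specific censoring only; no
  Fine–Gray subdistribution model is provided.
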