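# Methods

This note documents the statistical models implemented in `metaprs-kit`,
the defaults chosen where the design was genuinely open, and what the
synthetic cohort does and does not establish about behavior on real data.

## Cohort simulator

### Population structure

Group-specific allele frequencies follow the Balding–Nichols model: for a
variant with ancestral frequency `p` and a group with divergence
parameter `F` (an FST-like quantity), the group frequency is drawn from
`Beta(p(1−F)/F, (1−p)(1−F)/F)`, which has mean `p` and variance
`F·p·(1−p)`, truncated to (0.001, 0.999).  This is the standard
single-parameter device for allele-frequency differentiation; it is
moment-checkable, which the test suite exploits.  Genotype dosages are
`Binomial(2, p_group)` per variant and individual — variants are
independent; linkage disequilibrium is deliberately not modeled, since
no pipeline stage here estimates or consumes LD (LD matters for PRS
*training*, which is out of scope).

Defaults: six groups labeled AFR, AMR, EAS, EUR, SAS and ADM, with
divergence parameters 0.15/0.08/0.12/0.02/0.10/0.06 relative to a
common ancestral pool and 20 000 individuals total.  The divergence
values are stylized (EUR is closest to the uniform ancestral base only
because the base frequencies are arbitrary); their purpose is to induce
raw-score shifts between groups large enough that ancestry adjustment is
demonstrably necessary, which is achieved for any values in this range.

### Traits

Eight weight panels mirror a cardiovascular panel set: LDL-C, HDL-C,
triglycerides, Lp(a), hypertension (HT), type 2 diabetes (T2DM), atrial
fibrillation (AF) and CAD.  Each panel selects a causal fraction
(default 0.2) of the variants and draws independent centered Gaussian
weights.  The standardized genetic score of panel `p` is `z_p`.

Quantitative lipids are affine maps of standardized liabilities
`sqrt(h²)·z_p + sqrt(1−h²)·ε` onto mg/dL scales (LDL 120 ± 30,
HDL 55 ± 14, TG 140 ± 60, Lp(a) 30 ± 25; h² = 0.3).  Binary lipid risk
states apply the guideline thresholds to these true values (LDL ≥ 160
and ≥ 190, TG ≥ 175, HDL < 40 mg/dL), so the EHR round trip has a
well-defined ground truth.  HT, T2DM and AF are liability-threshold
traits: case iff liability exceeds the empirical per-ancestry quantile
matching the target prevalence (defaults 0.25, 0.12, 0.04).  Using the
empirical quantile rather than the Gaussian-theory threshold makes the
realized prevalence match the target by construction, which is the
property downstream stages rely on.

The CAD liability is the device for the pipeline's central question —
whether a direct genetic CAD component exists beyond the genetics of the
risk factors:

    L_CAD = sqrt(s_med)·M + sqrt(s_dir)·z_CAD + sqrt(1−s_med−s_dir)·ε,

where `M` is the standardized weighted sum of the risk-factor
liabilities (weights 0.35 LDL, −0.20 HDL, 0.15 TG, 0.15 Lp(a), 0.30 HT,
0.25 T2DM, 0.10 AF) and the variance shares default to `s_med = 0.25`,
`s_dir = 0.10`.  Setting `s_dir = 0` produces the null world in which a
CAD panel adds nothing — the test suite verifies the pipeline detects
the component when present (10/10 seeds at the default share) and
reports no improvement when absent.

Age is uniform on 35–75 and sex is Bernoulli(0.6 female); both are
covariate fodder only and carry no effect on any outcome.

### EHR streams

The event generator emits diagnoses, labs, medication starts and
enrollment dates on a calendar axis (integer days from 2010-01-01 —
calendar realism is irrelevant to the rules being tested, only event
ordering matters).  True cases accumulate ≥ 2 pre-enrollment diagnosis
codes drawn from mixed ICD9/ICD10 code sets, except for a false-negative
fraction (default 0.05) who receive exactly one; controls receive a
single stray code at rate 0.05.  Each person gets 1–5 lab draws per
analyte, jittered with SD equal to 4% of the analyte scale and kept
inside the analyte's plausible range; implausible outliers (e.g. 600 or
5 mg/dL) are injected at rate 0.01.  A configurable fraction (default
0.3) of high-LDL and T2DM individuals starts the matching medication
class before enrollment, censoring their later lab draws.  With all
noise knobs at zero and exactly two lab repeats, phenotyping recovers
the simulated truth exactly — the round-trip oracle in the test suite.

What the simulator does **not** emulate: linkage disequilibrium,
admixture and relatedness, genotyping or imputation error, informative
missingness of labs, code-vocabulary drift, and correlated measurement
error between analytes.  Passing tests therefore demonstrate the
correctness of the pipeline's logic and estimators under the stated
generative model, not robustness to these real-data features.

## Pipeline stages

**Scoring.**  Variants match on (chromosome, 1-based position); rsID is
carried as an identifier only, since simulated and real exports always
carry coordinates.  If the panel's effect allele equals the genotype
reference allele the dosage enters as `2 − d` (allele flip); the default
policy allows flips, and a `drop_ambiguous` policy additionally discards
strand-ambiguous A/T and C/G entries.  Missing dosages are mean-imputed
at twice the cohort allele frequency, the common choice that keeps
scores comparable across missingness patterns.  Indels and non-ACGT
alleles are dropped with a report.  Zero matched variants is a hard
error, as it almost always means a coordinate-convention mismatch.

**Ancestry adjustment.**  Principal components are computed once on the
full cohort (column-standardized dosages, constant columns dropped,
components scaled to unit variance with signs fixed by the largest
loading); the regression on PC1–PC4 and the subsequent standardization
are per ancestry group.  Standardization uses the sample SD (ddof = 1);
normalization parameters come from the same subset used for fitting.
Groups with fewer than 10 members cannot support a stable fit and fall
back to the pooled model with a warning.  The pooled mode (one
regression, one global standardization) exists to quantify what
non-ancestry-aware processing leaves behind.

**Phenotyping.**  The censoring window for labs is *before the earliest*
of enrollment, first excluded-medication start and first CAD diagnosis —
the strictest reading of "before enrollment and/or before medication",
chosen because it is monotone and unambiguous.  Outlier bounds are open
intervals: boundary values (20, 500, 10, 100 mg/dL) are excluded.
Persons with fewer than the required number of surviving measurements
for a binary lipid state are *missing*, not controls, to avoid diluting
the control set with unmeasured individuals.

**metaPRS.**  Panels enter the fold-level logistic regression jointly
(a multivariable fit), since the composite is a weighted sum with
jointly estimated weights; age, sex and PC1–PC4 are covariates but do
not enter the composite.  Fold betas are combined by arithmetic mean;
fold-level values are retained.  The evaluation default is the held-out
("cv") composition, in which each individual's metaPRS uses betas from
folds that never saw them; a `mean` mode applies the averaged betas for
deployment-style scoring.  Ancestry groups are modeled independently
end-to-end with no partial pooling.

**Evaluation.**  The OR per SD comes from a logistic fit with Wald CI on
the log-odds scale.  AUC is computed on the score alone by default (a
covariate-adjusted linear-predictor mode exists).  The analytic
high-risk fraction `1 − Φ(ln r / ln OR)` references the odds of an
individual *at the score mean* (z = 0): an individual at score z carries
odds `OR^z` relative to that reference, so `OR^z ≥ r` iff
`z ≥ ln r / ln OR`.  The alternative reference — the population-average
*risk* rather than the mean individual — involves the lognormal mean
shift and does not reproduce published percentage values computed from
per-SD odds ratios; the mean-individual convention does, and the
empirical twin (`fraction of samples with exp(β·z) ≥ r`) agrees with it
to within 0.2 percentage points on standard-normal scores.

**Calibration.**  Bins are quantile-based (quintiles by default) rather
than equal-width: equal-count bins give stable Wilson intervals at every
risk level, and quintiles is the more specific published description of
the binning.  The binomial interval is Wilson's score interval, chosen
over Wald for its behavior at rates near 0 and 1.  The smoothing spline
is a monotone-preserving cubic (PCHIP) clamped to [0, 1]; an
unconstrained cubic through five bin points can leave the unit interval.
With fewer than three bins the curve degrades to linear interpolation.
The summary statistic is the count-weighted mean signed miscalibration
(observed − predicted); negative values mean risk overestimation.

**Workflow.**  The orchestrated run derives stage seeds as fixed offsets
from the config seed, writes all tables as TSV, and records a manifest
with a SHA-256 checksum per output; reruns with the same config
reproduce every numeric output bit-for-bit (only the manifest timestamp
differs).  The percent improvement between the two metaPRS evaluations
uses the OR-ratio convention `100·(OR₂/OR₁ − 1)`, with the
log-OR-ratio alternative reported alongside.

## Problem sizes and numerical choices

The default configuration (six groups, 20 000 individuals, 5 000
variants, eight panels, both metaPRS definitions, calibration report)
completes in well under two minutes on one CPU.  The test suite uses
scaled-down instances chosen to keep each check sharp: 240–400 variants
and 800–6 000 individuals for pipeline-level properties, 50 000
observations for estimator-recovery checks where the tolerance demands
it, and ten simulation seeds for the paired metaPRS contrast.  The AUC
bootstrap defaults to 2 000 resamples in the API and is reduced in
orchestrated runs and tests where the CI is not the quantity under test.

Degenerate inputs are handled explicitly: zero-variance residuals are an
error (a degenerate panel), all-missing variants are dropped with a
warning, fewer distinct predictions than bins merges bins with a
warning, and complete separation or non-convergence in any logistic fit
raises with the context named.

## Known limitations

* The liability-threshold thresholds are empirical group quantiles, so
  simulated prevalence is exact in-sample but the threshold itself is an
  estimate; at group sizes below a few hundred the case indicator
  becomes noticeably discrete.
* The analytic high-risk fraction assumes a standard-normal adjusted
  score and a correctly specified single-score logistic model; for
  heavy-tailed or skewed score distributions use the empirical variant.
* Per-ancestry independence means small groups get noisy panel betas;
  there is deliberately no partial pooling, matching the validation
  design being emulated, but a hierarchical extension would be natural.
* The simulator's EHR noise model is memoryless; it cannot represent
  care-seeking intensity differences between cases and controls, which
  in real data bias code-count phenotypes.
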