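# Methods

`neuro1c` reimplements, as a tested and fully synthetic-data-driven pipeline,
the statistical analysis of a post-mortem brain B-vitamin / one-carbon-
metabolism case-control design: five diagnostic groups (healthy controls
HC-CN; Parkinson's disease cognitively normal PD-CN, with mild cognitive
impairment PD-MCI, with dementia PD-D; Alzheimer's dementia AD-D), targeted
LC-MS/MS metabolite panels measured on multi-well plates, and a panel of
one-carbon-pathway SNPs.  This note records the models, the defaults and
their rationale, the numerical choices, and what the synthetic experiments
do and do not demonstrate.

## Synthetic cohort generator

The generator produces the three inputs the analysis consumes — subject
table, raw assay plates, genotype matrix — with the statistical structure
the downstream stages assume.

**Subjects.** Group sizes default to 36/14/19/32/35 (cortex cohort scale,
n=136).  Covariates are drawn per group from truncated normals and
Bernoullis parameterised by the published cohort characteristics (age ~82 y,
education ~15 y, BMI 22–27 kg/m², post-mortem interval ~3.3 h, freezer
storage 8–12 y, comorbidity prevalences 6–57%).  A fraction of PD subjects
carries acute levodopa exposure at death; the default fraction is 0.25.
This value is not published; it was chosen once as the largest plausible
fraction consistent with the collinearity bounds the analysis convention
imposes (max pairwise |r| < 0.6 and adjusted GVIF < 1.5 among regressors):
at 0.4 the PD-D x levodopa indicator correlates with the PD-D group
indicator at |r| ≈ 0.66 and the design would fail its own gate.

**Assay plates.** Metabolite concentrations are log-normal: a subject's
log-concentration is `base + noise_sd * (planted deviation) + plate offset +
N(0, noise_sd)` with `noise_sd = 0.25` (a 25% biological coefficient of
variation, typical for tissue metabolomics).  Planted group effects are
specified in control-SD units so the recovered regression coefficients are
directly comparable to the planted values.  Metabolite–metabolite couplings
(used to emulate the Hcy/betaine–vitamin association layer) mix the
predictor's unit-variance biological noise into the response at the planted
slope while renormalising the response's own noise to keep unit variance;
the group-adjusted regression of response on predictor, both
control-standardised, then centres on the planted slope itself.  The
instrument maps concentration to signal through a known quadratic response
(`signal = 50 + 100 c + 0.5 c²`); each plate carries ≥3 blank wells (signal
noise around the background), ≥3 QC replicates, and 7 calibrator wells
placed exactly on the response curve.  Acutely levodopa-exposed subjects
have log-DOPA elevated by 4 biological SDs — far beyond the control 95th
percentile threshold used to flag them.  Plate assignment is stratified by
group by default; plate offsets are N(0, 0.3) in log space.

**Genotypes.** Independent SNPs are sampled under Hardy-Weinberg equilibrium
at the declared minor-allele frequency, optionally rescaled per group on the
odds scale (to plant subgroup enrichment).  An LD pair is sampled from an
explicit four-haplotype pool whose frequencies are solved from the two MAFs
and the target D′ — exact by construction, no rejection sampling; at
D′ = 1 in repulsion phase the double-mutant haplotype has frequency zero
(the mutual-exclusivity pattern).  SNP effects on metabolites are routed
through the declared inheritance model (carrier indicator, homozygote
indicator, or allele count).

## Preprocessing

Per metabolite and plate: peak areas are calibrated by a least-squares
quadratic through the calibrator wells and inverted on the calibrated range
(fewer than three distinct calibrator levels falls back to uncalibrated
relative values, mirroring panels without external standards); the limit of
detection is the estimated 99.9th normal percentile of the blank signal,
mean + 3.09 SD (sample SD, ddof = 1).  A metabolite is excluded when a
strict majority (> 50%) of its sample signals sit below their plate's LOD.
Undetected peaks are interpolated at half the minimum detected
concentration.

**Plate normalisation** removes batch location/scale differences while
respecting group assignments: (1) subtract pooled per-group means,
(2) align each plate's residual mean and rescale its residual SD to the
location-aligned pooled SD, (3) restore the group means; the sweep is
iterated to a fixed point (ddof-0 moments make the pooled scale an exact
fixed point), which makes the operation idempotent.  Moment-based alignment
was chosen over median/MAD alignment after measurement: at plate sizes of
~70 the MAD ratio is noisy enough to couple with the downstream Box-Cox
exponent selection and systematically amplify planted group effects by
~8%, whereas mean/SD alignment leaves the end-to-end recovery unbiased;
remote outliers are in any case clamped later by the fencing stage.

**Box-Cox** exponents maximise the Gaussian profile log-likelihood over
λ ∈ [−3, 3] (bounded Brent on the negated likelihood); values are shifted
by 1 − min when non-positive, and the shift is recorded.  **Tukey fencing**
with k = 3 clamps values outside [Q1 − 3·IQR, Q3 + 3·IQR] to the nearer
fence (quartiles by linear interpolation of order statistics); winsorising
rather than removing keeps n constant and protects means without deflating
variance.  Values are finally **standardised against controls** (ddof = 1),
so every downstream coefficient reads in control-SD units.

Covariate imputation is the conditional (group × sex) cell mean with group-
then grand-mean fallback.  Rare SNPs with the alternate allele present in
fewer than 5 subjects are dropped (carrier counting by default; allele
counting available).  The acute-levodopa indicators threshold log-DOPA at
the control mean + 1.6449 SD (parametric 95th percentile) and route the
flag into separate PD-D and PD-ND covariates.

## Regression with group-specific variance

The differential model per metabolite is `z ~ group indicators + age + sex +
education + BMI + comorbidity flags + levodopa indicators + log PMI + log
storage` (logs capture exponential time decay), with residual variance
allowed to differ by group.  Estimation is maximum likelihood by iterated
weighted least squares: given per-group variances, WLS for β; given β, the
closed-form update σ²_g = RSS_g / n_g; convergence when the relative
log-likelihood change is below 1e-8 (max 200 iterations).  Wald t-tests use
df = n − p, and the covariance is rescaled by n/(n − p) so that with one
variance group the fit reproduces ordinary least squares exactly —
coefficients, standard errors and p-values; without the rescaling the pure-
ML standard errors are anti-conservative (~7% null rejection at α = 0.05 in
this design; ~5.4% with it).  The heteroscedastic log-likelihood never falls
below the homoscedastic one (nested models), and this is enforced as a test
invariant.

Multiplicity: Benjamini-Hochberg within each contrast family (one family
per group term across metabolites; FDR ≤ 0.05 convention), and Storey
q-values for larger families (the SNP scans; q ≤ 0.10 convention).  π₀ is
the cubic-trend smoother of #{p > λ}/(m(1−λ)) over λ = 0.05…0.95 evaluated
at the grid maximum, clamped to (0, 1]; with π₀ = 1 the q-values reduce
exactly to BH.  Families under 20 p-values fall back to BH.

Collinearity diagnostics are the max absolute pairwise Pearson correlation
and the adjusted generalized variance-inflation factor,
GVIF^(1/(2·df)), computed from determinant ratios of the regressor
correlation matrix.

## SNP analysis

Group scans compare allele counts (ordinal 0/1/2) between named group sets
with Wilcoxon-Mann-Whitney tests: exact two-sided permutation enumeration
when the pooled size is ≤ 16, the tie-corrected normal approximation
otherwise.  The exact path exists precisely because the normal approximation
does not track the coarse lattice null of heavily tied small samples; on
continuous data the two agree to within 0.011 at n = 8 + 8.

Inheritance-model selection fits dominant (g ≥ 1), recessive (g = 2) and
additive (g) codings by OLS with the objective covariates only (sex, age,
log PMI, log storage), excluding acutely levodopa-exposed subjects, and
keeps the minimum-BIC model.  All three codings have equal parameter
counts, so the BIC ranking reduces to likelihood ranking; ties prefer
additive, then dominant; the recessive coding is dropped when no
homozygote-mutant subject exists; a constant response short-circuits to the
additive convention with p = 1.

Two-locus LD uses EM over the double-heterozygote phase ambiguity
(convergence at 1e-10 on haplotype frequencies; exact counting when no
double heterozygote exists).  D = f_AB − p·q; D′ = |D|/D_max with the
sign-appropriate bound and the phase (coupling/repulsion) reported
separately; r from haplotype frequencies; significance by χ² = 2N·r² on
1 df (the standard composite-genotype test — the choice of test is a free
design point and is exposed as such).

## Composite scores

Score A counts polymorphisms significantly associated (q ≤ 0.10) with
elevated Hcy or decreased betaine, each under its chosen inheritance model;
score B counts the protective direction; score C counts vitamins
significantly (FDR ≤ 0.05) negatively associated with Hcy or positively
with betaine whose control-standardised level falls below the 5th
percentile threshold z < −1.6449 (displayed −1.64).  Additive-model SNPs
count in carrier mode by default (allele-count mode available).  A SNP with
a missing genotype contributes via rescaling the observed-member score to
the full set size.  Groups are compared with controls by percent mean
difference and two-sided WMW tests; a zero control mean switches to an
absolute difference with a flag.

## Expression-tree classifier

Operands are Boolean threshold tests — metabolite z ≥ t for
t ∈ {−2, −1, 0, 1, 2} (the symmetric threshold set) and allele count ≥ t
for t ∈ {0, 1, 2} — plus numeric allele-count leaves.  Operators are NOT,
AND, OR (arguments coerced Boolean via "> 0") and ADD, SUB, MUL, NEG
(Booleans coerced to 0/1); the root prediction is "value > 0".  Fitness is
the mean of the two per-class accuracies minus 0.05 per operand, plus
uniform [0, amp) selection noise whose amplitude decays linearly from 0.10
to 0 over the first half of a run (an annealing schedule); reported fitness
is always noise-free.  Evolution is tournament selection (size 4) with
crossover 0.6 / subtree mutation 0.3 / fresh random individuals 0.1, tree
depth capped at 6, and the best noise-free individual across independent
runs is returned.  The study-scale budget is population 100,000, 100
generations, best of 10 runs; the scaled-down preset (population 2,000, 20
generations, 3 runs) is the default in the orchestrated pipeline and
recovers planted two-operand rules reliably at n ≈ 100.  Stratified k-fold
cross-validation re-evolves per fold and scores held-out subjects.

## Problem sizes used by the experiments

The benchmark experiments (`neuro1c.experiments`, driven by
`scripts/acceptance.py` and the acceptance tests) run at the cohort scale
of the design: effect recovery uses 50 full pipeline replicates at n = 136;
type-I calibration uses 100 null cohort seeds (~16 metabolites × 4 group
terms each); variance-ratio recovery uses 50 replicates at n = 2,000;
Box-Cox coverage 100 samples of n = 500; inheritance-model selection 100
replicates at n = 150; LD at n = 500; rule recovery 10 seeds at population
5,000 / 30 generations / 5 runs on n = 100.

## What the synthetic experiments show — and what they do not

Passing recovery and calibration experiments demonstrate that the
implementation is internally consistent: effects planted under the
generator's assumptions (log-normal signals, additive plate offsets in log
space, Hardy-Weinberg genotypes, MCAR missingness) are recovered without
material bias, and null data produce null results at the nominal rate.
Real tissue data can violate these assumptions in ways the generator does
not emulate: non-log-normal concentration distributions, plate effects that
are not location/scale shifts, LOD censoring correlated with biology,
population structure in genotypes, informative missingness, and
measurement error correlated across metabolites within an assay.  Results
on real data therefore inherit the usual caveats of the underlying methods,
not a guarantee from these tests.

## Known limitations

- The group-variance ML fit uses a fixed df = n − p for Wald inference; no
  Satterthwaite-style per-term adjustment is attempted.
- Storey's π₀ smoother uses a cubic polynomial trend rather than a natural
  cubic spline; the two agree closely on the λ grid used but are not
  identical.
- The exact WMW path enumerates all C(n, n_a) assignments and is used only
  up to a pooled n of 16.
- The expression-tree engine's selection scheme and rates are free design
  choices (exposed in `GPConfig`); published results fix only the
  population size, step count, run count, penalty and noise schedule.
- Two-locus haplotype EM only; no multi-locus phasing.
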