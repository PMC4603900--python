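# Methods

This note documents the statistical procedures, the synthetic-data
model, the numerical choices and the known limitations of `snpindex`.

## Survival inference

**Kaplan-Meier.** The product-limit estimator with Greenwood variance,
evaluated at the distinct event times. `survival_at` treats the curve
as a right-continuous step function: 1 before the first event, last
value carried forward past the end of follow-up. "5-year" rates are
the curve evaluated at 60 months (all times are months).

**Log-rank.** The k-sample observed-minus-expected statistic with
hypergeometric variance summed over distinct event times, referred to
a chi-square on k−1 degrees of freedom. On untied two-group data it
coincides with the Cox score test, which the test suite checks
numerically.

**Cox proportional hazards.** Maximum partial likelihood with the
Efron approximation for tied event times — the default because
month-resolution follow-up produces heavy tying, and Efron is markedly
more accurate than Breslow under ties. The default path is backed by
`lifelines.CoxPHFitter` (convergence tightened to coefficient
precision 1e-9 so that small-sample fits agree with a brute-force
grid maximizer of the exact partial likelihood to 1e-4). A
Breslow-ties fit (`ties="breslow"`) is provided for cross-checks as an
in-house damped Newton-Raphson: analytic gradient and Hessian,
step-halving on likelihood decrease, gradient max-norm < 1e-8, at
most 50 iterations. Inference is Wald throughout: log-scale 95%
confidence intervals and two-sided p-values, matching the "HR (95%
CI)" presentation convention; no likelihood-ratio intervals and no
multiple-testing correction (a deliberate scope choice — panels of
eight SNPs analysed this way inherit the usual multiplicity caveat).

Degenerate designs are handled explicitly: a constant covariate
raises a non-identifiability error; monotone-likelihood/separation is
flagged through `converged=False`; a binary SNP coding with zero
events on one side is reported "not estimable" rather than fit.

**Categorical covariates** are reference-coded indicators with fixed
reference levels: age ≤64, female, never-smoker, SCC histology,
stage I, no adjuvant chemotherapy. Age enters dichotomized at 64
years (the cohort convention this package mirrors reports only that
split). Two adjustment presets exist: `table2` (age, sex, smoking,
histology, stage — the default) and `methods` (adds adjuvant
chemotherapy).

## Per-SNP association

For each SNP: genotype counts with column percentages over genotyped
subjects, minor allele frequency (folded to ≤0.5), a 1-df chi-square
Hardy-Weinberg test (adequate for common variants; no exact test),
Kaplan-Meier 5-year rates per genotype, genotype-level adjusted
hazard ratios (heterozygote and variant-homozygote each against the
wild-type homozygote), and the three collapsed-model fits. Genotype
coding follows the SNP's configured risk orientation — MAF folding is
reporting only and never flips the coding. Missing genotypes are
handled per SNP as complete-case: each SNP keeps its own denominator,
so per-SNP totals differ when missingness differs.

Genotype-by-factor contingency tables use the Pearson chi-square
without continuity correction.

## The prognostic index

**Model selection.** When a panel does not fix a SNP's genetic model,
the collapsed model (dominant/recessive/additive) with the smallest
OS Wald p among converged fits is selected; exact ties break by the
preference order additive > recessive > dominant. OS drives selection
because the scoring is anchored to relative risk of death. The
packaged eight-SNP panel carries its models explicitly (three
additive, one dominant, four recessive; variant allele is the risk
allele for all), so selection only engages for user panels.

**Scoring.** Additive genotypes score 1/2/3 by risk-allele count;
dominant/recessive genotypes score 1 for the low-risk grouping and 3
for the high-risk grouping. The index is the sum over the panel —
integers in [8, 24] for the packaged panel (the test suite verifies
the bounds by exhaustive enumeration of all 3⁸ combinations). A
subject missing any panel genotype has an undefined index and is
excluded from the combined analysis; an optional "score missing as 1"
mode was considered and rejected as a default because it biases the
index downward — complete-case exclusion keeps the denominator
honest.

**Cutoff.** The "approximate tertile" rule is made precise as: the
integer c minimizing |fraction(index ≥ c) − 1/3|, ties toward the
smaller c (scanning one past the maximum, so a degenerate
distribution yields an empty high group rather than everyone-high). A
fixed cutoff (e.g. 15) can be supplied instead to reproduce a
published split; both modes are CLI options. Whether such a cutoff
should be treated as a priori or data-derived is left to the user —
the package provides both without asserting intent.

**Combined analysis.** Group counts/percentages, events, KM 5-year
rates, log-rank p, and the adjusted Cox hazard ratio for the
high-risk indicator, plus exported KM curve points per group. The
index defines exactly two groups; the continuous index is exported
per subject for users who want finer analyses.

## The synthetic cohort generator

The generator emulates the statistical structure of an 814-patient
resected early-stage NSCLC cohort:

- **Genotypes**: Hardy-Weinberg draws per SNP at variant-allele
  frequencies back-calculated from the published genotype counts
  (0.14–0.56 across the panel); SNPs are independent (the panel's loci
  sit in different genes/regions, so no linkage disequilibrium is
  modelled). A configurable per-SNP missing-call rate (default 1%)
  exercises the complete-case bookkeeping downstream.
- **Covariates**: independent Bernoulli/multinomial draws at the
  published prevalences (47% age >64, 73% male, 69% ever-smoker,
  histology SCC/AC/LCC 45/51/4%, 40% stage II–IIIA). Adjuvant
  chemotherapy is not tabulated in the source cohort; 30% is used as
  a realistic rate for a cohort that is 40% stage II–IIIA, with zero
  generating effect. Pack-years are gamma draws (median ≈40) for
  ever-smokers only.
- **Event times**: death and recurrence are independent exponential
  latent times given the linear predictor; the death hazard uses the
  OS effect set, the recurrence hazard the DFS effect set. SNP
  effects enter on each SNP's assigned model coding (so the analysis
  model is correctly specified by default); per-genotype effect
  overrides exist for misspecification experiments. Default SNP
  effects are the published adjusted hazard ratios on the log scale;
  covariate effects mirror the direction and rough magnitude of the
  published univariate contrasts (stage ~1.9–2.2, age ~1.5/1.15,
  smaller sex/smoking/histology terms).
- **Censoring**: administrative only — cutoff − U(0, accrual) months,
  defaults 85 and 72, i.e. follow-up uniform on [13, 85] months. No
  dropout hazard: the simplest mechanism consistent with a surgical
  cohort truncated at analysis time. Times are rounded up to whole
  months by default (realistic ties; ceiling preserves the ordering
  invariants DFS ≤ OS and death ⇒ DFS event).
- **Calibration**: baseline rates 0.001055/month (death) and
  0.002469/month (recurrence) were chosen by bisection at large n so
  the default cohort reproduces ≈30.1% deaths, ≈49.4% DFS events and
  ≈64% KM 5-year OS. With exponential recurrence under this censoring
  window the DFS event fraction and the 5-year DFS rate cannot both
  be matched; the event fraction was prioritized, and the default
  5-year DFS comes out ≈42% (vs 46% in the source cohort). This is a
  known shape limitation of the constant-hazard recurrence model.

**Seed policy**: a master seed spawns fixed substreams (covariates,
survival, missingness, one per SNP by panel position) via
`numpy.random.SeedSequence`, so adding a SNP never perturbs covariate
or survival draws and a fixed seed reproduces a cohort bit-for-bit.

**What passing tests do and do not show.** The generator draws
covariates independently, makes death and recurrence conditionally
independent, and uses constant baseline hazards. Real cohorts have
correlated covariates (smoking–sex–histology), dependent death and
recurrence processes, non-constant hazards and non-administrative
dropout. Recovery tests therefore demonstrate that the estimation
pipeline is correct under its assumed model — not that the model
captures every feature of real data.

## Experiment sizes

Recovery experiments use 200 replicates of n=2000 (Monte-Carlo SE of
the mean hazard ratio ≈0.01–0.04, tight enough to resolve biases well
below practical relevance); generator calibration averages 50 seeds
of the default n=814 cohort; null calibration uses 500 two-group
simulations. Unit-level recovery checks run smaller (30–50
replicates) with correspondingly wider Monte-Carlo bands.

## Known limitations

- No VCF/PLINK import; cohorts are bespoke delimited tables.
- No haplotype, SNP–SNP interaction, or weighted (effect-size) scores
  — the index deliberately uses rank scores 1/2/3.
- No proportionality diagnostics, stratified or time-varying Cox.
- No competing-risks treatment of recurrence vs death.
- The HWE test is asymptotic; rare variants would need an exact test.
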