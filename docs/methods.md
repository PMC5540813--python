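# Methods

This note documents the statistical models, the synthetic study conditions,
and the numerical and design choices behind `subasym`.

## The two-level protocol

The package analyses volumetric asymmetry of seven paired subcortical
structures under a federation constraint: subject-level data stay at their
site, and only per-site summary statistics are pooled. The asymmetry index
AI = (L − R)/(L + R) is dimensionless in [−1, 1]; it removes overall size
differences, so covariate adjustment concerns residual age/ICV/sex effects
rather than head size per se.

### Within-site stage

Per structure, subjects missing either volume (or with L + R ≤ 0) are
dropped for that structure only, never listwise. Outlier exclusion uses an
adaptive fence of 2.5/3.0/3.5 sample SDs for site sizes N < 150,
150 ≤ N ≤ 1000, N > 1000 respectively; wider fences at larger N keep the
expected number of false exclusions roughly constant. The mean and SD are
computed once over all finite values (a single, non-iterative pass), and
the fence is applied independently to the left volume, the right volume and
the AI; a subject flagged by any of the three is dropped for that
structure. The pipeline order is fixed: compute AIs → exclude → residualise
→ test.

Group contrasts (sex: male − female; handedness: left − right handers) are
Welch two-sample t-tests with Satterthwaite degrees of freedom on AIs
residualised by OLS against age and ICV (plus sex for handedness). The age
effect is the OLS coefficient of AI on age with sex and ICV as covariates.
Population-level lateralization is a per-sex one-sample t-test of the raw
(non-residualised) AIs against zero; raw AIs are used because the question
is whether the population mean asymmetry differs from symmetry, not whether
it does so after covariate adjustment — this choice is a documented
convention, since the two-step protocol leaves it open.

What crosses the site boundary is the effect, its 95% CI and degrees of
freedom, group counts, the median age and the age IQR width, and the
segmentation-software version label. The pooling stage reconstructs the
standard error as (CI width)/(2·t₀.₉₇₅,df) for the Welch contrasts — an
exact round trip — and uses the reported SE for the ANCOVA coefficient.

### Meta-analysis stage

Pooling is DerSimonian–Laird random effects (the classical moment
estimator); when the between-study variance estimate τ² truncates at 0 the
result coincides exactly with the fixed-effect analysis, which is what
makes the printed I² zeros reproducible from Q and k alone. The pooled test
uses the normal reference on z = pooled/SE rather than a t on k − 1 df; at
k ≈ 36–43 the difference is small and the convention is documented here
because printed p-values cannot disambiguate the two. I² is computed from Q
and its df, not from τ² against a typical within-study variance, again to
stay consistent with I² = 0 whenever Q ≤ k − 1.

Rosenberg's weighted fail-safe N is defined operationally: the smallest
number m of hypothetical studies with effect 0 and weight equal to the mean
observed fixed-effect weight whose addition lifts the fixed-effect pooled
two-sided p to at least α (default 0.007, the Bonferroni level 0.05/7). The
implementation solves the closed form z(m)² ≤ z_α² and then verifies by
stepping, so it is guaranteed to match the incremental definition, which is
treated as normative.

Inclusion filters: ≥ 15 observations per contrast group (both sex groups
for the age ANCOVA, since the model adjusts for sex), and for the age
analyses an age IQR (Q3 − Q1) of at least 5 years, both bounds inclusive.
The post-hoc meta-regression of per-site age coefficients on site median
ages is weighted least squares with weights √n.

### Variance partitioning

η² = SS_between/SS_total is computed per factor as a one-way decomposition
of the pooled, post-exclusion, *non-residualised* AI vector. Because each
site runs exactly one software version, `dataset` and `version` are
confounded; a joint or nested decomposition is not identified, so the two
main effects are reported separately and no interaction is attempted. The
reported σ²_within is the one-way ANOVA within-group mean square for the
`dataset` factor (SS_within/(n − k)); the plausible alternative reading
(total variance minus between-dataset SS, normalised by n − 1) differs only
in df normalisation at these sample sizes.

### Heritability stage

The expected additive relationship matrix K = 2Φ comes from the recursive
tabular method; rows may arrive in any order (a topological sort is applied,
and cycles or half-specified parents are rejected). The univariate model

y = Xb + g + e, g ~ N(0, σ²_g K), e ~ N(0, σ²_e I)

is fitted by maximum likelihood: one eigendecomposition K = UΛU′ rotates
the problem so the covariance is diagonal in h² = σ²_g/(σ²_g + σ²_e); at
each candidate h² the fixed effects are solved by GLS and the total
variance analytically, leaving a 1-d bounded profile search. ML is used
rather than REML; with n ≈ 1200 and four fixed effects the REML correction
to h² is well below the Monte-Carlo noise of the recovery experiments, and
an unconstrained comparison of nested models is simpler under ML. The SE of
h² is the curvature of the profile log-likelihood at the optimum (reported
as NaN on the boundary, where it is meaningless); the test of h² = 0 is an
LRT against the boundary null with the ½χ²₀ + ½χ²₁ mixture, so a fit that
lands exactly on the boundary reports p = 0.5.

The bivariate model cov = G⊗K + E⊗I is parameterised by log-variances and
atanh-correlations (|ρ| bounded below 1 − 2·10⁻⁷, which is
indistinguishable from complete pleiotropy at these sample sizes), rotated
by the same eigendecomposition so the 2n-dimensional likelihood factorises
into n independent 2×2 blocks, and maximised by L-BFGS-B from two starts
(univariate fits + empirical correlation, and an equal-split start). Tests:
ρ_g = 0 by a 1-df LRT; ρ_g = 1 against the boundary with the ½χ² mixture.
The SE of ρ_g is a delta-method transform of the observed information
(finite-difference Hessian). The model-implied phenotypic correlation is
read off G + E and is verified in tests against the empirical residual
correlation. Non-PSD intermediate iterates are avoided by construction of
the parameterisation.

Fits on the whole sample use the full K; because K is block-diagonal by
family its eigendecomposition is cheap at the ~1200-individual scale used
throughout (a per-family implementation would scale better but is not
needed at these sizes).

## Synthetic study conditions

The multi-site generator emulates a 52-site consortium (≈ 25–600 subjects
per site, male fraction 0.475). Per subject and structure, the AI is

AI = μ + site offset + version offset + γ·(male − sex ratio)
     + κ·(age − site mean age) + ε, ε ~ N(0, σ_w²),

and the bilateral total T (linear in ICV, correlation 0.5, CV 0.12 around
field-typical structure means) is split as L = T(1 + AI)/2,
R = T(1 − AI)/2, so (L − R)/(L + R) returns the drawn AI to machine
precision. The sex and age terms are centred, making the per-site expected
mean AI exactly μ + offsets, and making γ and κ exactly the estimands of
the residualised contrast and the ANCOVA slope. Defaults: per-structure
mean AIs (e.g. putamen +0.0194, amygdala −0.0205), within-subject AI
variances (0.0006–0.0061), sex effects (pallidum +0.004, putamen −0.002,
others smaller), and age slopes (≈ ±1–2·10⁻⁴ per year) at the magnitudes
the analysis is designed to detect. Site-offset SDs are calibrated from the
targeted between-dataset variance shares via
σ²_between = σ²_w·η²/(1 − η²), with the version component (five version
labels, one per site, 75% of sites on the majority version, fixed offsets
standardised under the assignment probabilities) carved out of that total.
The AI noise is Gaussian — only means and variances are specified, so this
is the minimal assumption. ICV is log-normal (median 1.5·10⁶ mm³, log-SD
0.08) and by default independent of sex, so that the configured sex effect
on the AI coincides with the ICV-adjusted estimand; a `male_icv_factor`
knob reintroduces sex–ICV confounding for robustness studies. Handedness
is Bernoulli (10% left) and independent of AI, so handedness contrasts are
null under the defaults.

The pedigree generator uses a fixed three-generation template — two
founders, three adult children married into founder spouses, three
grandchildren per couple (17 individuals) — replicated 71 times
(1207 individuals), chosen for reproducibility and hand-verifiable kinship
rather than random mating graphs. Genetic values are drawn per family as
σ_g·L z with L the Cholesky factor of 2Φ (for two traits, with a matrix
square root of G applied across traits, giving cov = G⊗2Φ); environmental
deviations are iid with covariance E. Covariates (age by generation, sex,
ICV) enter the phenotype linearly. For the left/right volume recovery
experiment, the per-side volume heritability 0.627 is derived from the
configured correlation triple by ρ_phen = h²ρ_g + (1 − h²)ρ_e, making the
three configured correlations mutually consistent.

What the generator does **not** emulate: non-Gaussian AI tails and
segmentation failures (so the outlier stage removes only honest sampling
extremes), scanner/protocol differences beyond a mean site offset,
age-dependent variance or nonlinear age trends, assortative mating,
inbreeding, shared-household environmental components, and selection or
ascertainment of families. Passing recovery tests therefore demonstrates
the estimators are correct and calibrated under the stated model, not that
real consortium data meet these assumptions.

## Problem sizes in tests and reproduction runs

Recovery experiments run at the study-condition scale per replicate
(36–41 sites of 150–400 subjects for the meta-analytic contrasts, 71
pedigrees / ~1200 individuals for the variance components) with 10–20
replicates, sizes at which the Monte-Carlo SE of the averaged estimate is
well below the effects being recovered. Calibration suites (type-I error,
p-value uniformity) use 1000 replicates of reduced per-replicate size,
which is what those statistics need. All randomness is seeded; generators
are bit-reproducible given (config, seed).

## Known limitations

- The pooled p-value uses the normal reference; no Knapp–Hartung
  adjustment is offered.
- DL is the only τ² estimator implemented; REML pooling is not.
- The bivariate fit reports, but does not constrain, near-boundary G or E
  matrices beyond the correlation bound; SEs near boundaries are
  unreliable and NaN where meaningless.
- η² partitioning inherits the dataset/version confounding of the design;
  it quantifies, but cannot causally separate, the two sources.
- No household/dominance components, SNP-based relatedness, or
  ascertainment correction in the heritability stage.
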