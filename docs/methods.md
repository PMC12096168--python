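# Methods

`healtheq` implements an equity analysis of health-education utilization
among China's internal migrant ("mobile") population, organized as a
five-stage pipeline over respondent-level categorical survey microdata:
univariate χ² screening → bagged-tree out-of-bag permutation importance →
L1-penalized logistic selection → binary logistic modelling → income-rank
concentration-index decomposition.  The real microdata (the 2018 China
Migrants Dynamic Survey, N = 103,910 after cleaning) are access-restricted,
so the package ships a synthetic-data generator whose defaults encode the
published study conditions, and validates every stage against that known
generative truth plus the published aggregate tables.

## Data model

Respondents carry fourteen categorical covariates (gender, age band,
education, marital status, employment, hukou, mobility range and reason,
within-province income quintile, insurance location, illness, self-rated
health, health record, family-doctor contract), raw household income, a
province label, and the binary outcome: receipt of any health education in
the past year.

**Cleaning.** The source survey reports only pre/post cleaning sizes, not
rules.  The package's rules are configurable and default to: drop rows with
any missing required field, drop non-positive incomes, and trim incomes
above the 99.9th percentile.  Reproducing the source's exact N is not
attempted.

**Income quintiles.** Raw household income is converted to within-province
quintile bands (<20th, 20–39th, 40–59th, 60–79th, ≥80th percentile).  Each
respondent's percentile is the max-rank of their income within the province
divided by province size, so tied incomes share a band (a province with a
single distinct income falls entirely in one band); a percentile exactly on
a 20/40/60/80 edge belongs to the upper band, since the lowest band is
strictly below the 20th percentile and the top band is "≥ 80th".  Being
rank-based, the assignment is invariant to monotone transforms of income.

**Design matrix.** One indicator column per non-reference level, factors in
the published table order, levels ascending, the lowest code as reference;
the seven model factors yield 17 slope columns.  Levels absent from the
data are skipped; a factor with a single observed level contributes no
columns and warns.

## Synthetic generator

Covariates are drawn independently from the published marginal frequencies
(renormalized; a few printed panels are internally off by a respondent or a
rounding step).  Household income is log-normal (location 8.8, scale 0.6 on
the log scale — roughly a 6,600-CNY-median monthly household income) with
province-level location offsets spread over ±0.3 across 31 provinces.  The
outcome is Bernoulli with

    logit P(y=1) = β₀ + Σⱼ βⱼ xᵢⱼ + γ·rᵢ ,

where the βⱼ default to the published log-odds column, rᵢ is the
within-province fractional income rank with optional direct gradient γ
(default 0), and the latent logistic error is realized implicitly by the
Bernoulli draw.  β₀ is not published; it is solved at configuration time by
exact convolution of the linear-predictor distribution over the independent
factor marginals (quintiles at 1/5 each) so the expected outcome rate
equals the published 81.89%.  Under the defaults this gives β₀ ≈ 0.304.

Because quintile dummies carry positive coefficients and quintiles are a
deterministic function of income rank, the generated outcome is pro-rich
(CI > 0) by construction.  Non-income determinants have nonzero factor
concentration indices only when covariates associate with income, so the
*study configuration* (`study_config`) enables a dependence hook shifting
log-income location by 0.25 per education level away from the middle — the
one association needed for an interesting decomposition.  The generator
does **not** emulate the survey's multistage PPS sampling, survey weights,
spatial clustering, or real-world correlation among covariates beyond the
hook; passing tests therefore establish correctness of the methods under a
clean independence-plus-one-association design, not robustness to the full
dependence structure of real survey data.

## Univariate screening

Pearson χ² on each factor × outcome table, expected counts from margin
products, no continuity correction (this reproduces the published 2×2
statistics, e.g. 55.496 for marital status), p-values from the χ²
distribution with (L−1) df.  The pipeline's screen keeps factors with
p < 0.05 (the source reports all fourteen as significant).  Six published
panels are internally inconsistent with the descriptive margins (their
printed cells cannot reproduce their printed statistics); they are shipped
flagged and excluded from exact assertions.  For small-cell tables the
asymptotic p differs from an exact permutation p by up to ~0.05 — an
inherent property of the large-sample approximation that the oracle tests
account for.

## Forest importance

A bagged decision-tree ensemble (bootstrap resampling, per-tree OOB
bookkeeping) scores feature X by

    OOB_store(X) = Σᵢ (err_oob2ᵢ − err_oob1ᵢ) / N ,

the mean per-tree increase in OOB error after permuting X's values on that
tree's OOB rows only, one permutation per tree per feature.  The default
mode regresses on the 0/1 outcome with squared-error OOB loss (the %IncMSE
convention); a classification mode using misclassification rate is
selectable.  Trees with empty OOB sets are skipped with N decremented.
Factors enter integer-coded by default (one-hot selectable).  `mtry`
(features per split, default ⌈√p⌉) is deliberately a separate knob from
`min_samples_split`.  Hyperparameters are tuned by randomized search over
the ranges n_estimators 1–500, max_depth 1–20, min_samples_split 2–20,
min_samples_leaf 1–10, scored by stratified 5-fold CV accuracy; the search
machinery, not any particular argmax (which is data- and seed-dependent),
is the tested artifact.

## Penalized selection

L1-penalized binomial regression, intercept unpenalized, dummies
standardized before penalization (coefficients reported on the original
scale), solved per λ by warm-started saga descent down a log-spaced grid
from λ_max = max|⟨xⱼ, y−ȳ⟩|/n (the all-zero point) over three decades.
The solver iteration cap defaults to 100 per λ (tests that compare against
unpenalized fits raise it).  Ten-fold stratified CV scores each λ by
binomial deviance (squared error selectable): λ_min minimizes the curve;
λ_1se is the largest λ within one standard error of that minimum.  A factor
is *selected* iff any of its dummies is nonzero at the chosen λ.

Two λ rules serve two purposes.  Downstream modelling uses λ_min (the
published pick), which reliably retains every true factor but — as is
well known for CV-minimizing lasso — rarely zeroes all null factors.
Support *recovery* (truth in, nulls out) is therefore assessed at λ_1se,
the standard parsimonious rule.  The published λ_min = 0.000677 requires
the restricted microdata and is not a reproduction target.

## Logistic model

Unpenalized maximum likelihood via Newton/IRLS to a 1e-10 parameter
tolerance, Wald standard errors from the observed information, 95%
intervals exp(β ± 1.96·se).  Rank-deficient designs raise naming the
offending columns; diverging coefficients (|β| > 30) raise a separation
error.  All regressors are dummies, so average marginal effects use the
discrete change — mean over respondents of p̂(xⱼ=1) − p̂(xⱼ=0) holding
other columns at observed values — with the derivative approximation
mean[p̂(1−p̂)]·βⱼ only as a fallback for non-binary columns.

## Equity analysis

Fractional income ranks are weighted midpoint ranks: rᵢ = (cumulative
weight of strictly poorer respondents + half the tied block's weight)/total
weight; tied incomes share their block midpoint, making the weighted mean
rank exactly 0.5.  The concentration index is CI = 2·cov(y, r)/μ with
*population* (divide-by-n) covariance — the convention of the CI
literature; the n/(n−1) difference is O(1/n).  CI > 0 is pro-rich.  The
concentration curve steps through respondents poorest-to-richest; twice the
signed area between diagonal and curve approximates CI to O(1/n).

The Wagstaff decomposition writes C = Σⱼ ηⱼCⱼ + GC_ε/μ with elasticity
ηⱼ = AMEⱼ·X̄ⱼ/μ (the marginal effect standing in for the regression
coefficient, as the source prescribes), Cⱼ the concentration index of
dummy Xⱼ over the *same* income ranks (required for the identity), the
contribution ηⱼCⱼ, the contribution rate ηⱼCⱼ/C·100, and the residual
defined as C minus the summed contributions so the identity closes to
machine precision on every run (and is asserted).  Zero-mean columns are
flagged and contribute zero.  The published elasticity column cannot be
reverse-engineered from the published coefficients and means under any
standard formula, so only the printed arithmetic (elasticity × CI =
contribution) is asserted; note also that the published "contribution
rate" column is contribution/C *without* the ×100 its label suggests.  No
Erreygers/Wagstaff normalization is applied to the headline index (the
source reports the plain index); `erreygers_correct` (4μ·CI for a 0/1
outcome) is available but off by default.

Both the equity ranks and the quintile covariate use raw household income
by default; the ranking variable is exposed in configuration because the
source does not state which income concept feeds which role.

## Pipeline and problem sizes

The pipeline seeds every stochastic stage from one integer and produces
byte-identical report JSONs on repeat runs.  The χ² screen gates both the
forest and the penalized selection (in the source all fourteen factors
passed the screen, so the flows coincide there); the forest ranks but does
not gate.  Analyses and the acceptance script run the synthetic cohort at
n = 20,000 with a 100-tree ensemble and a 40–50-point λ grid; validation
suites use n = 4,000–20,000 with 20 seeds per property.  These sizes give
stable Monte-Carlo margins for every asserted property (e.g. recovery
within 3 Wald SEs, |CI| < 4/√n under independence) at interactive runtimes.

## Known limitations

- Independence of generated covariates (beyond the education-income hook)
  understates the multicollinearity real survey data would show.
- No survey weights, design effects, or CI standard errors (none are
  published for the quantities mirrored here).
- The published fitted values (CI = 0.0121, the β/SE table, elasticities,
  the importance ordering, λ_min, tuned hyperparameters) depend on the
  restricted microdata and are regeneration targets in shape only; under
  the default synthetic conditions the pipeline produces a positive CI of
  similar magnitude, but the match is qualitative, not a reproduction.
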